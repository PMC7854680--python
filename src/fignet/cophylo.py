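"""Event-based cophylogenetic reconciliation.

An associate tree (pollinator, or organelle genome) is mapped onto a host
tree (nuclear species tree) as a minimum-cost history of five event types:
cospeciation, duplication, host switch, loss (sorting / missing the boat),
and failure to diverge (one associate spanning several host tips).  At the
scale this package targets (tens of tips) the optimum is found by exact
dynamic programming over associate nodes x host edges, with switches
allowed between host edges whose time intervals overlap; all co-optimal
histories can be enumerated up to a cap.  Significance comes from random
tip-mapping and random associate-topology permutation tests, and the cost
scheme itself is chosen by scanning a grid for schemes that are significant
under both nulls and then minimizing the observed cost.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .treecore import Node, RootedTree, random_binary_tree

__all__ = [
    "CostScheme",
    "EventRecord",
    "Reconciliation",
    "PermutationResult",
    "reconcile",
    "event_tally",
    "permutation_test",
    "scan_cost_schemes",
    "default_cost_grid",
]

INF = math.inf
EVENT_TYPES = ("cospeciation", "duplication", "switch", "loss",
               "failure_to_diverge")


@dataclass(frozen=True)
class CostScheme:
    """Per-event costs; cospeciation/duplication/loss/failure-to-diverge in
    [0,1], switch in [0,2]."""

    cospeciation: float = 0.0
    duplication: float = 0.5
    switch: float = 1.0
    loss: float = 0.5
    failure_to_diverge: float = 0.5

    def __post_init__(self):
        for name in ("cospeciation", "duplication", "loss", "failure_to_diverge"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} cost must be in [0, 1]")
        if not (0.0 <= self.switch <= 2.0):
            raise ValueError("switch cost must be in [0, 2]")

    def of(self, etype: str) -> float:
        return getattr(self, etype)

    def astuple(self):
        return (self.cospeciation, self.duplication, self.switch, self.loss,
                self.failure_to_diverge)


@dataclass(frozen=True)
class EventRecord:
    type: str
    host: str                    # host edge (clade string) where it happens
    assoc: Optional[int] = None  # associate node id (postorder index)
    donor: Optional[str] = None
    recipient: Optional[str] = None


@dataclass
class Reconciliation:
    placement: dict              # assoc node id -> host edge label
    events: tuple                # EventRecords
    total_cost: float

    def count(self, etype: str) -> int:
        return sum(1 for e in self.events if e.type == etype)

    def switch_pairs(self):
        return [(e.donor, e.recipient) for e in self.events if e.type == "switch"]

    def to_json_dict(self):
        return {
            "total_cost": self.total_cost,
            "placement": {str(k): v for k, v in self.placement.items()},
            "events": [
                {k: v for k, v in e.__dict__.items() if v is not None}
                for e in self.events
            ],
        }


@dataclass
class OptimalSet:
    cost: float
    solutions: list
    truncated: bool
    n_enumerated: int


@dataclass
class PermutationResult:
    observed_cost: float
    null_costs: list
    mode: str

    @property
    def p_value(self) -> float:
        n_le = sum(1 for c in self.null_costs if c <= self.observed_cost)
        return (1 + n_le) / (len(self.null_costs) + 1)


# ---------------------------------------------------------------------------
# Host indexing
# ---------------------------------------------------------------------------

class _Host:
    """Edge table of the host tree; edge i is identified with its child node
    (the root contributes a virtual edge above itself)."""

    def __init__(self, tree: RootedTree):
        if not tree.is_binary():
            raise ValueError("host tree must be binary")
        self.tree = tree
        depth = tree.node_depths()
        if all(d == 0 for d in depth.values()):
            # no branch lengths: fall back to a topological rank order
            rank = {}
            for node in tree.postorder():
                rank[node] = 1 + max((rank[c] for c in node.children), default=0)
            top = rank[tree.root]
            depth = {n: float(top - rank[n]) for n in tree.postorder()}
        self.nodes = list(tree.postorder())
        self.idx = {n: i for i, n in enumerate(self.nodes)}
        self.depth = [depth[n] for n in self.nodes]
        self.parent = [self.idx[n.parent] if n.parent else -1 for n in self.nodes]
        self.children = [
            [self.idx[c] for c in n.children] for n in self.nodes
        ]
        self.is_tip = [n.is_leaf for n in self.nodes]
        self.tip_of = {n.name: self.idx[n] for n in self.nodes if n.is_leaf}
        root = self.idx[tree.root]
        self.root = root
        # edge i spans (top_i, bottom_i); the virtual root edge gets a short
        # stem so nothing overlaps it except itself
        span = max(self.depth) - min(self.depth) or 1.0
        self.top = [
            self.depth[self.parent[i]] if self.parent[i] >= 0
            else self.depth[i] - 0.01 * span
            for i in range(len(self.nodes))
        ]
        self.bottom = list(self.depth)
        self.leafset = [None] * len(self.nodes)
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                self.leafset[i] = frozenset([n.name])
            else:
                s = frozenset()
                for c in self.children[i]:
                    s |= self.leafset[c]
                self.leafset[i] = s
        self.label = [",".join(sorted(s)) for s in self.leafset]

    def overlap(self, e: int, f: int) -> bool:
        return max(self.top[e], self.top[f]) < min(self.bottom[e], self.bottom[f])


# ---------------------------------------------------------------------------
# Dynamic program
# ---------------------------------------------------------------------------

def _assoc_postorder(assoc: RootedTree):
    nodes = list(assoc.postorder())
    return nodes, {n: i for i, n in enumerate(nodes)}


def reconcile(host: RootedTree, assoc: RootedTree, tipmap: dict,
              costs: CostScheme, cap: int = 1000,
              max_tips: int = 24) -> OptimalSet:
    """Minimum-cost reconciliation and up to ``cap`` co-optimal histories.

    ``tipmap`` maps each associate tip name to a host tip name or a set of
    host tip names (multi-host tips engage failure-to-diverge).  Host node
    times come from branch lengths when present, else from topological rank.
    """
    if not assoc.is_binary():
        raise ValueError("associate tree must be binary")
    H = _Host(host)
    if len(H.tip_of) > max_tips or len(assoc.leaf_names()) > max_tips:
        raise ValueError(f"exact search supports at most {max_tips} tips")
    anodes, aidx = _assoc_postorder(assoc)
    n_edges = len(H.nodes)

    # normalize tip map to frozensets of host tip names
    tmap = {}
    for tip in assoc.leaves():
        if tip.name not in tipmap:
            raise ValueError(f"associate tip {tip.name!r} unmapped")
        hosts = tipmap[tip.name]
        hosts = frozenset([hosts] if isinstance(hosts, str) else hosts)
        for h in hosts:
            if h not in H.tip_of:
                raise ValueError(f"host tip {h!r} not in host tree")
        tmap[tip.name] = hosts

    best = {}     # (ai, e) -> cost of the event of ai happening on edge e
    best_ch = {}  # (ai, e) -> list of choice tuples
    into = {}     # (ai, e) -> cost of entering edge e at its top
    into_ch = {}
    covd = {}     # (ai, e) -> coverage cost for multi-host tips
    covd_ch = {}

    def compute_into(ai):
        for e in sorted(range(n_edges), key=lambda e: -H.depth[e]):
            c = best[(ai, e)]
            ch = [("event",)] if c < INF else []
            for ce in H.children[e]:
                alt = costs.loss + into[(ai, ce)]
                if alt < c - 1e-12:
                    c = alt
                    ch = [("loss", ce)]
                elif abs(alt - c) <= 1e-12 and c < INF:
                    ch.append(("loss", ce))
            into[(ai, e)] = c
            into_ch[(ai, e)] = ch

    def cover_tip(ai, hosts):
        """Failure-to-diverge coverage of a multi-host tip: the lineage must
        span exactly the hosts in the set, persisting across host splits
        (failure to diverge) or missing one side (loss).

        ``cov[e]`` covers hosts ∩ leafset(e); the tip may only be *placed*
        on an edge whose subtree contains the whole host set.
        """
        cov = {}
        cov_ch = {}
        for e in sorted(range(n_edges), key=lambda e: -H.depth[e]):
            if H.is_tip[e]:
                hit = H.leafset[e] <= hosts
                cov[e] = 0.0 if hit else INF
                cov_ch[e] = [("tip",)] if hit else []
                continue
            l, r = H.children[e]
            lhit = bool(H.leafset[l] & hosts)
            rhit = bool(H.leafset[r] & hosts)
            if lhit and rhit:
                c = costs.failure_to_diverge + cov[l] + cov[r]
                ch = [("ftd", l, r)]
            elif lhit:
                c = costs.loss + cov[l]
                ch = [("cover_loss", l, r)]
            elif rhit:
                c = costs.loss + cov[r]
                ch = [("cover_loss", r, l)]
            else:
                c, ch = INF, []
            cov[e] = c
            cov_ch[e] = ch if c < INF else []
        for e in range(n_edges):
            covd[(ai, e)] = cov[e]
            covd_ch[(ai, e)] = cov_ch[e]
            feasible = hosts <= H.leafset[e] and cov[e] < INF
            best[(ai, e)] = cov[e] if feasible else INF
            best_ch[(ai, e)] = [("cover",)] if feasible else []

    for ai, a in enumerate(anodes):
        if a.is_leaf:
            hosts = tmap[a.name]
            if len(hosts) == 1:
                tip_edge = H.tip_of[next(iter(hosts))]
                for e in range(n_edges):
                    hit = e == tip_edge
                    best[(ai, e)] = 0.0 if hit else INF
                    best_ch[(ai, e)] = [("tip",)] if hit else []
            else:
                cover_tip(ai, hosts)
        else:
            x, y = (aidx[c] for c in a.children)
            for e in range(n_edges):
                options = []
                # cospeciation at the head node of e
                if not H.is_tip[e]:
                    l, r = H.children[e]
                    for (cx, cy) in ((l, r), (r, l)):
                        c = costs.cospeciation + into[(x, cx)] + into[(y, cy)]
                        options.append((c, ("cosp", cx, cy)))
                # duplication on e
                c = costs.duplication + into[(x, e)] + into[(y, e)]
                options.append((c, ("dup",)))
                # switch: one child stays on e, the other jumps to f
                for stay, move in ((x, y), (y, x)):
                    base = into[(stay, e)]
                    if base == INF:
                        continue
                    for f in range(n_edges):
                        if f == e or not H.overlap(e, f):
                            continue
                        c = costs.switch + base + into[(move, f)]
                        options.append((c, ("switch", stay, move, f)))
                mn = min((c for c, _ in options), default=INF)
                best[(ai, e)] = mn
                best_ch[(ai, e)] = [ch for c, ch in options
                                    if c < INF and abs(c - mn) <= 1e-12]
        compute_into(ai)

    root_ai = len(anodes) - 1
    total = min(best[(root_ai, e)] for e in range(n_edges))
    if total == INF:
        raise ValueError("no feasible reconciliation")
    root_edges = [e for e in range(n_edges)
                  if abs(best[(root_ai, e)] - total) <= 1e-12]

    # ---- enumerate co-optimal histories ---------------------------------
    solutions = []
    truncated = False

    def expand_best(ai, e):
        """Yield (placement-dict, events-list) for the event of ai on e."""
        a = anodes[ai]
        for ch in best_ch[(ai, e)]:
            kind = ch[0]
            if kind == "tip":
                yield {ai: H.label[e]}, []
            elif kind == "cover":
                for evs in expand_cover(ai, e):
                    yield {ai: H.label[e]}, evs
            elif kind == "cosp":
                _, cx, cy = ch
                x, y = (aidx[c] for c in a.children)
                for pl_x, ev_x in expand_into(x, cx):
                    for pl_y, ev_y in expand_into(y, cy):
                        ev = [EventRecord("cospeciation", H.label[e], ai)]
                        yield {ai: H.label[e], **pl_x, **pl_y}, ev + ev_x + ev_y
            elif kind == "dup":
                x, y = (aidx[c] for c in a.children)
                for pl_x, ev_x in expand_into(x, e):
                    for pl_y, ev_y in expand_into(y, e):
                        ev = [EventRecord("duplication", H.label[e], ai)]
                        yield {ai: H.label[e], **pl_x, **pl_y}, ev + ev_x + ev_y
            else:  # switch
                _, stay, move, f = ch
                for pl_s, ev_s in expand_into(stay, e):
                    for pl_m, ev_m in expand_into(move, f):
                        ev = [EventRecord("switch", H.label[e], ai,
                                          donor=H.label[e], recipient=H.label[f])]
                        yield {ai: H.label[e], **pl_s, **pl_m}, ev + ev_s + ev_m

    def expand_cover(ai, e):
        for ch in covd_ch[(ai, e)]:
            kind = ch[0]
            if kind == "tip":
                yield []
            elif kind == "ftd":
                _, l, r = ch
                for ev_l in expand_cover(ai, l):
                    for ev_r in expand_cover(ai, r):
                        ev = [EventRecord("failure_to_diverge", H.label[e], ai)]
                        yield ev + ev_l + ev_r
            else:  # cover_loss
                _, keep, lost = ch
                for evs in expand_cover(ai, keep):
                    yield [EventRecord("loss", H.label[lost], ai)] + evs

    def expand_into(ai, e):
        for ch in into_ch[(ai, e)]:
            if ch[0] == "event":
                yield from expand_best(ai, e)
            else:
                _, ce = ch
                sibs = [c for c in H.children[e] if c != ce]
                lost_label = H.label[sibs[0]] if sibs else H.label[e]
                for pl, evs in expand_into(ai, ce):
                    yield pl, [EventRecord("loss", lost_label, None)] + evs

    gen = itertools.chain.from_iterable(
        expand_best(root_ai, e) for e in root_edges
    )
    for pl, evs in gen:
        if len(solutions) >= cap:
            truncated = True
            break
        solutions.append(Reconciliation(pl, tuple(evs), total))
    return OptimalSet(cost=total, solutions=solutions, truncated=truncated,
                      n_enumerated=len(solutions))


def event_tally(solutions: Sequence[Reconciliation]):
    """Mean and standard error of per-event counts across co-optimal
    solutions (the summary behind equally-parsimonious solution tallies)."""
    if not solutions:
        raise ValueError("empty solution set")
    out = {}
    n = len(solutions)
    for etype in EVENT_TYPES:
        counts = np.array([s.count(etype) for s in solutions], dtype=float)
        mean = counts.mean()
        se = counts.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
        out[etype] = (float(mean), float(se))
    return out


# ---------------------------------------------------------------------------
# Permutation tests and cost-scheme scan
# ---------------------------------------------------------------------------

def permutation_test(host: RootedTree, assoc: RootedTree, tipmap: dict,
                     costs: CostScheme, mode: str = "tip_shuffle",
                     N: int = 1000, seed: int = 0,
                     cap: int = 1) -> PermutationResult:
    """Null distribution of the optimal cost under label/topology
    randomization.

    ``tip_shuffle`` permutes the associate-to-host tip mapping uniformly;
    ``random_tree`` replaces the associate topology by a uniformly random
    binary labelled topology (tip map kept).  p = (1 + #{null <= observed})
    / (N + 1).
    """
    if mode not in ("tip_shuffle", "random_tree"):
        raise ValueError(f"unknown mode {mode!r}")
    if N < 100:
        import warnings

        warnings.warn(f"N={N} permutations is small; p-values are coarse")
    observed = reconcile(host, assoc, tipmap, costs, cap=cap).cost
    rng = np.random.default_rng(seed)
    tips = sorted(tipmap)
    values = [tipmap[t] for t in tips]
    null_costs = []
    for _ in range(N):
        if mode == "tip_shuffle":
            perm = rng.permutation(len(tips))
            tm = {tips[i]: values[perm[i]] for i in range(len(tips))}
            null_costs.append(reconcile(host, assoc, tm, costs, cap=cap).cost)
        else:
            rand = random_binary_tree(tips, rng)
            null_costs.append(reconcile(host, rand, tipmap, costs, cap=cap).cost)
    return PermutationResult(observed, null_costs, mode)


def default_cost_grid():
    """A small grid over the admissible cost ranges (cospeciation 0,
    duplication/loss/failure-to-diverge in {0.5, 1}, switch in {0.5, 1, 2})."""
    grid = []
    for dup in (0.5, 1.0):
        for loss in (0.5, 1.0):
            for switch in (0.5, 1.0, 2.0):
                grid.append(CostScheme(0.0, dup, switch, loss, min(loss, 1.0)))
    return grid


def scan_cost_schemes(host: RootedTree, assoc: RootedTree, tipmap: dict,
                      grid: Optional[Sequence[CostScheme]] = None,
                      alpha: float = 0.05, N: int = 200, seed: int = 0):
    """Choose the cost scheme: significant under both permutation modes,
    then lowest observed cost; ties broken by fewest switches, then by the
    lexicographic cost tuple.

    Returns ``(best_scheme_or_None, report_rows)``.
    """
    if grid is None:
        grid = default_cost_grid()
    if not grid:
        raise ValueError("empty cost grid")
    rows = []
    for si, scheme in enumerate(grid):
        res_tip = permutation_test(host, assoc, tipmap, scheme,
                                   mode="tip_shuffle", N=N, seed=seed + 2 * si)
        res_tree = permutation_test(host, assoc, tipmap, scheme,
                                    mode="random_tree", N=N, seed=seed + 2 * si + 1)
        opt = reconcile(host, assoc, tipmap, scheme, cap=50)
        n_switch = min(s.count("switch") for s in opt.solutions)
        rows.append({
            "scheme": scheme,
            "cost": opt.cost,
            "p_tip_shuffle": res_tip.p_value,
            "p_random_tree": res_tree.p_value,
            "eligible": res_tip.p_value < alpha and res_tree.p_value < alpha,
            "min_switches": n_switch,
        })
    eligible = [r for r in rows if r["eligible"]]
    if not eligible:
        return None, rows
    best = min(eligible, key=lambda r: (r["cost"], r["min_switches"],
                                        r["scheme"].astuple()))
    return best["scheme"], rows


def write_solutions_jsonl(solutions: Sequence[Reconciliation], path):
    import json

    with open(path, "w") as fh:
        for s in solutions:
            fh.write(json.dumps(s.to_json_dict()) + "\n")
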