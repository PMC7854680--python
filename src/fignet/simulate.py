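"""Synthetic-data generator.

Three simulators share this module:

* a multispecies-coalescent engine on a species *network* (a species tree
  plus zero or more instantaneous hybridization pulses, each transferring a
  fraction ``gamma`` of lineages from a donor branch to a recipient branch),
  producing per-locus gene trees in coalescent units;
* an infinite-sites mutation layer turning gene trees into biallelic SNP
  matrices with genomic coordinates, so each locus occupies one genomic
  window;
* a forward-time host/associate cophylogeny simulator with the five classic
  reconciliation events (cospeciation, duplication, host switch, loss,
  failure to diverge) and a ground-truth event log.

All randomness flows from one master seed through counter-based Philox
streams, so locus ``i`` is reproducible independently of ``n_loci``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .treecore import GeneTreeSet, Node, RootedTree

__all__ = [
    "HybridEdge",
    "SpeciesNetwork",
    "SimConfig",
    "CophyloRates",
    "CophyloSimLog",
    "simulate_gene_trees",
    "simulate_snp_matrix",
    "simulate_organelle_locus",
    "simulate_cophylogeny",
]


@dataclass(frozen=True)
class HybridEdge:
    """An instantaneous hybridization pulse.

    ``donor`` and ``recipient`` name branches of the base tree by the leaf
    set of the clade below them.  Backwards in time, each lineage found on
    the recipient branch at ``time`` traces into the donor branch with
    probability ``gamma`` (the inheritance probability: the fraction of the
    recipient's genome contributed by the donor).
    """

    donor: frozenset
    recipient: frozenset
    time: float
    gamma: float

    def __post_init__(self):
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must be in (0, 1)")
        if self.time < 0:
            raise ValueError("time must be >= 0")
        object.__setattr__(self, "donor", frozenset(self.donor))
        object.__setattr__(self, "recipient", frozenset(self.recipient))


class SpeciesNetwork:
    """An ultrametric species tree (coalescent units) with hybrid pulses.

    Branch lengths are in coalescent units (1 unit = 2N generations).  The
    network must be level-1 in the weak sense used here: pulses are
    independent instantaneous events, each referencing two branches of the
    base tree that are both alive at the pulse time.
    """

    def __init__(self, base_tree: RootedTree, hybrid_edges: Sequence[HybridEdge] = ()):
        if not base_tree.is_binary():
            raise ValueError("base tree must be binary")
        self.base_tree = base_tree
        self.hybrid_edges = list(hybrid_edges)
        self._prepare()

    @classmethod
    def from_newick(cls, text: str, hybrid_edges: Sequence[HybridEdge] = ()):
        from .treecore import parse_newick

        return cls(parse_newick(text, length_units="coalescent"), hybrid_edges)

    def _prepare(self):
        tree = self.base_tree
        # heights: time before present; tips at 0 (ultrametric required)
        depth = tree.node_depths()
        max_depth = max(depth[lf] for lf in tree.leaves())
        for lf in tree.leaves():
            if abs(depth[lf] - max_depth) > 1e-9 * max(1.0, max_depth):
                raise ValueError("base tree must be ultrametric (contemporaneous tips)")
        self.height = {n: max_depth - d for n, d in depth.items()}
        self.tree_height = max_depth
        self._clades = {}
        index = tree.compute_masks()
        rev = {i: name for name, i in index.items()}
        for node in tree.postorder():
            clade = frozenset(rev[i] for i in range(len(rev)) if node._mask >> i & 1)
            self._clades[clade] = node
        self.taxa = sorted(index)
        for he in self.hybrid_edges:
            d = self._resolve(he.donor)
            r = self._resolve(he.recipient)
            for node, tag in ((d, "donor"), (r, "recipient")):
                lo = self.height[node]
                hi = self.height[node.parent] if node.parent else math.inf
                if not (lo <= he.time <= hi):
                    raise ValueError(
                        f"hybrid pulse time {he.time} outside {tag} branch span "
                        f"[{lo}, {hi}]"
                    )

    def _resolve(self, clade: frozenset) -> Node:
        try:
            return self._clades[frozenset(clade)]
        except KeyError:
            raise KeyError(f"no branch subtends clade {sorted(clade)}") from None

    def edge_node(self, clade) -> Node:
        """The base-tree node under the branch subtending ``clade``."""
        return self._resolve(frozenset(clade))

    def write_truth_tsv(self, path):
        import pandas as pd

        rows = [
            {
                "donor": ",".join(sorted(h.donor)),
                "recipient": ",".join(sorted(h.recipient)),
                "time": h.time,
                "gamma": h.gamma,
            }
            for h in self.hybrid_edges
        ]
        pd.DataFrame(rows, columns=["donor", "recipient", "time", "gamma"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class SimConfig:
    """Knobs of the SNP/gene-tree simulator.

    ``theta`` is the expected number of mutations per coalescent unit of
    branch length per lineage (mutations drop at rate theta/2 per unit).
    ``window_layout = (n_chrom, window_len_bp)``: locus *i* is laid out in
    its own ``window_len_bp`` window, loci split evenly across chromosomes.
    """

    n_loci: int
    theta: float = 1.0
    samples_per_species: int = 1
    seed: int = 0
    window_layout: tuple = (1, 10_000)
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci >= 1")
        if self.theta < 0:
            raise ValueError("theta >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate in [0, 1)")
        if self.samples_per_species < 1:
            raise ValueError("samples_per_species >= 1")


def _philox(seed: int, stream: int, counter: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(key=[seed & 0xFFFFFFFFFFFFFFFF, stream], counter=[counter, 0, 0, 0])
    )


# ---------------------------------------------------------------------------
# Coalescent on a species network
# ---------------------------------------------------------------------------

class _NetSchedule:
    """Pre-sorted event timeline shared by all loci of one network."""

    def __init__(self, net: SpeciesNetwork):
        self.net = net
        tree = net.base_tree
        events = []
        for node in tree.postorder():
            if not node.is_leaf:
                # speciation (backwards: merge child populations) at height h
                events.append((net.height[node], 0, ("spec", node)))
        for he in net.hybrid_edges:
            d = net.edge_node(he.donor)
            r = net.edge_node(he.recipient)
            events.append((he.time, 1, ("hyb", r, d, he.gamma)))
        events.sort(key=lambda e: (e[0], e[1]))
        self.events = events
        self.tips = tree.leaves()


def _coalesce_in_pop(pop, t, t_end, rng, times, parents, lchild, rchild):
    """Coalesce lineages in ``pop`` between t and t_end (in place)."""
    k = len(pop)
    while k >= 2:
        rate = k * (k - 1) / 2.0
        t = t + rng.exponential(1.0 / rate)
        if t > t_end:
            return
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = pop[i], pop[j]
        new = len(times)
        times.append(t)
        parents.append(-1)
        lchild.append(a)
        rchild.append(b)
        parents[a] = new
        parents[b] = new
        # replace the two with the new lineage
        if i > j:
            i, j = j, i
        pop[i] = new
        pop[j] = pop[-1]
        pop.pop()
        k -= 1


def _one_gene_tree(schedule: _NetSchedule, rng, samples_per_species: int,
                   organelle: Optional[float] = None):
    """One coalescent genealogy; returns (times, parents, lchild, rchild, labels).

    ``organelle``: if not None, hybrid pulses route *all* lineages jointly to
    the donor with this probability (organelle capture), instead of each
    lineage independently with the pulse's gamma.
    """
    net = schedule.net
    times: list[float] = []
    parents: list[int] = []
    lchild: list[int] = []
    rchild: list[int] = []
    labels: list[str] = []
    pops: dict[Node, list[int]] = {}
    for tip in schedule.tips:
        ids = []
        for s in range(samples_per_species):
            ids.append(len(times))
            times.append(0.0)
            parents.append(-1)
            lchild.append(-1)
            rchild.append(-1)
            labels.append(tip.name if samples_per_species == 1 else f"{tip.name}_{s}")
        pops[tip] = ids
    t = 0.0
    for ev_time, _prio, ev in schedule.events:
        for pop in pops.values():
            if len(pop) >= 2:
                _coalesce_in_pop(pop, t, ev_time, rng, times, parents, lchild, rchild)
        t = ev_time
        if ev[0] == "spec":
            node = ev[1]
            merged = []
            for c in node.children:
                merged.extend(pops.pop(c, ()))
            pops[node] = merged
        else:
            _, recipient, donor, gamma = ev
            src = pops.get(recipient)
            if not src:
                continue
            dst = pops.setdefault(donor, [])
            if organelle is not None:
                if rng.random() < organelle:
                    dst.extend(src)
                    src.clear()
            else:
                keep = []
                for lin in src:
                    if rng.random() < gamma:
                        dst.append(lin)
                    else:
                        keep.append(lin)
                pops[recipient] = keep
    # ancestral population above the root: coalesce to one lineage
    root_pop = pops[net.base_tree.root]
    while len(root_pop) >= 2:
        k = len(root_pop)
        t = t + rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = root_pop[i], root_pop[j]
        new = len(times)
        times.append(t)
        parents.append(-1)
        lchild.append(a)
        rchild.append(b)
        parents[a] = new
        parents[b] = new
        if i > j:
            i, j = j, i
        root_pop[i] = new
        root_pop[j] = root_pop[-1]
        root_pop.pop()
    return times, parents, lchild, rchild, labels


def _arrays_to_tree(times, parents, lchild, rchild, labels) -> RootedTree:
    n = len(times)
    nodes = [None] * n
    for i in range(n):
        nodes[i] = Node(name=labels[i] if i < len(labels) else None)
    root_idx = n - 1
    for i in range(n):
        p = parents[i]
        if p >= 0:
            nodes[p].add_child(nodes[i])
            nodes[i].length = times[p] - times[i]
        else:
            root_idx = i
    return RootedTree(nodes[root_idx], length_units="coalescent")


def simulate_gene_trees(net: SpeciesNetwork, cfg: SimConfig) -> GeneTreeSet:
    """Per-locus coalescent gene trees on the species network.

    Within each branch, ``k`` lineages coalesce at rate k(k-1)/2 per
    coalescent unit; at a hybrid pulse each recipient-branch lineage
    independently follows the donor parent with probability gamma.
    """
    schedule = _NetSchedule(net)
    trees = []
    taxa = None
    for i in range(cfg.n_loci):
        rng = _philox(cfg.seed, 0, i)
        arrays = _one_gene_tree(schedule, rng, cfg.samples_per_species)
        tree = _arrays_to_tree(*arrays)
        trees.append(tree)
        if taxa is None:
            taxa = sorted(arrays[4])
    return GeneTreeSet(trees, taxa)


def simulate_organelle_locus(net: SpeciesNetwork, capture_prob: float,
                             seed: int = 0) -> RootedTree:
    """One non-recombining organelle genealogy.

    At each hybrid pulse the *whole* organelle lineage pool of the recipient
    follows the donor parent with probability ``capture_prob`` (organelle
    capture), else stays; a capture makes the organelle tree discordant with
    the base tree.
    """
    if not (0.0 <= capture_prob <= 1.0):
        raise ValueError("capture_prob in [0, 1]")
    schedule = _NetSchedule(net)
    rng = _philox(seed, 3, 0)
    arrays = _one_gene_tree(schedule, rng, 1, organelle=capture_prob)
    return _arrays_to_tree(*arrays)


# ---------------------------------------------------------------------------
# Infinite-sites SNP matrices
# ---------------------------------------------------------------------------

def simulate_snp_matrix(gts: GeneTreeSet, cfg: SimConfig,
                        outgroup: Optional[str] = None):
    """Drop infinite-sites mutations on each gene tree and emit a genotype
    matrix with genomic coordinates (one locus per window).

    Mutations arrive as a Poisson process at rate ``theta/2`` per unit
    branch length; each mutation creates one biallelic site whose derived
    allele is carried by the leaves under the mutated edge.  When
    ``outgroup`` is given, edges whose clade contains the outgroup carry no
    mutations, so the outgroup is fixed ancestral and the matrix is
    outgroup-polarized.
    """
    from .windows import GenotypeMatrix

    taxa = list(gts.taxa)
    index = {name: i for i, name in enumerate(taxa)}
    n_taxa = len(taxa)
    out_bit = 1 << index[outgroup] if outgroup is not None else 0
    n_chrom, win_len = cfg.window_layout
    wpc = -(-len(gts) // n_chrom)  # ceil

    chroms: list[int] = []
    positions: list[int] = []
    masks: list[int] = []
    any_sites = False
    for li, tree in enumerate(gts):
        rng = _philox(cfg.seed, 1, li)
        nodes = [n for n in tree.postorder() if n is not tree.root]
        tree.compute_masks(index)
        lens = np.array([n.length for n in nodes])
        nmut = rng.poisson(cfg.theta / 2.0 * lens)
        site_masks = []
        for node, k in zip(nodes, nmut):
            if k == 0:
                continue
            if out_bit and (node._mask & out_bit):
                continue
            site_masks.extend([node._mask] * int(k))
        if site_masks:
            any_sites = True
        chrom_id = li // wpc
        start = (li % wpc) * win_len
        npos = len(site_masks)
        if npos > 0:
            if npos > win_len:
                raise ValueError("more sites than window positions; raise window_len")
            pos = np.sort(rng.choice(win_len, size=npos, replace=False)) + start + 1
            for p, m in zip(pos, site_masks):
                chroms.append(chrom_id)
                positions.append(int(p))
                masks.append(m)
    if not any_sites:
        import warnings

        warnings.warn("zero segregating sites on every locus")
    n_sites = len(masks)
    counts = np.zeros((n_taxa, n_sites), dtype=np.int8)
    if n_sites:
        if n_taxa > 63:
            raise ValueError("more than 63 taxa not supported by the mask layout")
        mask_arr = np.array(masks, dtype=np.uint64)
        shifts = np.arange(n_taxa, dtype=np.uint64)[:, None]
        counts = ((mask_arr[None, :] >> shifts) & np.uint64(1)).astype(np.int8)
    if cfg.missing_rate > 0 and n_sites:
        rng = _philox(cfg.seed, 2, 0)
        miss = rng.random((n_taxa, n_sites)) < cfg.missing_rate
        counts[miss] = -1
    ploidy = np.ones(n_taxa, dtype=int)
    return GenotypeMatrix(
        taxa=taxa,
        chrom=np.array([f"chr{c + 1}" for c in chroms]),
        pos=np.array(positions, dtype=np.int64),
        counts=counts,
        ploidy=ploidy,
        polarized=outgroup is not None,
        outgroup=outgroup,
    )


# ---------------------------------------------------------------------------
# Cophylogeny
# ---------------------------------------------------------------------------

@dataclass
class CophyloRates:
    """Per-host-split outcome probabilities and per-lineage branch rates.

    At each host speciation an associate lineage on that branch either
    cospeciates, misses one daughter (a sorting loss), or fails to diverge
    (persists on both daughters without speciating); the three probabilities
    must sum to 1.  Duplications and host switches occur along branches as
    Poisson processes per associate lineage per coalescent-unit time.
    """

    p_cospeciation: float = 0.85
    p_loss: float = 0.10
    p_failure_to_diverge: float = 0.05
    duplication_rate: float = 0.02
    switch_rate: float = 0.10
    # host clades the associate never colonizes (forces a loss there)
    forbidden_clades: tuple = ()

    def __post_init__(self):
        s = self.p_cospeciation + self.p_loss + self.p_failure_to_diverge
        if abs(s - 1.0) > 1e-9:
            raise ValueError("split-outcome probabilities must sum to 1")
        if self.duplication_rate < 0 or self.switch_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class CophyloSimLog:
    """Ground-truth event list from the forward simulation."""

    events: list = field(default_factory=list)

    def count(self, etype: str) -> int:
        return sum(1 for e in self.events if e["type"] == etype)

    def switches(self) -> list:
        return [e for e in self.events if e["type"] == "switch"]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.events)

    def write_tsv(self, path):
        self.to_dataframe().to_csv(path, sep="\t", index=False)


class _Lineage:
    __slots__ = ("id", "hosts", "birth", "children", "death")

    def __init__(self, id, hosts, birth):
        self.id = id
        self.hosts = set(hosts)
        self.birth = birth
        self.children = []
        self.death = None


def _host_clade(node: Node) -> frozenset:
    out = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.add(n.name)
        else:
            stack.extend(n.children)
    return frozenset(out)


def simulate_cophylogeny(host: RootedTree, rates: CophyloRates = None,
                         seed: int = 0, max_retries: int = 20):
    """Forward simulation of an associate tree tracking a binary host tree.

    Returns ``(associate_tree, tip_map, log)`` where ``tip_map`` maps each
    associate tip name to the *set* of host tip names it occupies (sets of
    size > 1 arise from failure-to-diverge).  Raises if the simulation
    repeatedly ends with fewer than two associate lineages.
    """
    if rates is None:
        rates = CophyloRates()
    if not host.is_binary():
        raise ValueError("host tree must be binary")
    depth = host.node_depths()
    present = max(depth[lf] for lf in host.leaves())
    internal = sorted((n for n in host.postorder() if not n.is_leaf),
                      key=lambda n: depth[n])
    forbidden = {frozenset(c) for c in rates.forbidden_clades}

    for attempt in range(max_retries):
        rng = _philox(seed, 4, attempt)
        result = _run_cophylo(host, rates, rng, depth, present, internal, forbidden)
        if result is not None:
            return result
    raise RuntimeError("extinct associate tree: fewer than 2 lineages survived "
                       f"after {max_retries} attempts")


def _alive_edges(internal_and_tips, depth, t, host):
    alive = []
    for n in host.postorder():
        if n.parent is None:
            continue
        if depth[n.parent] <= t < depth[n]:
            alive.append(n)
    return alive


def _run_cophylo(host, rates, rng, depth, present, internal, forbidden):
    log = CophyloSimLog()
    lineages: list[_Lineage] = []
    next_id = [0]

    def new_lineage(hosts, birth):
        lin = _Lineage(next_id[0], hosts, birth)
        next_id[0] += 1
        lineages.append(lin)
        return lin

    # the associate enters on the host root's edge (virtual edge above root)
    root_lin = new_lineage({host.root}, 0.0)
    active = [root_lin]
    breakpoints = [(depth[v], v) for v in internal] + [(present, None)]
    t_prev = 0.0
    for t_ev, v in breakpoints:
        # branch-wise Poisson events (duplication, switch) in (t_prev, t_ev)
        t = t_prev
        total_rate = rates.duplication_rate + rates.switch_rate
        while total_rate > 0 and active:
            t = t + rng.exponential(1.0 / (total_rate * len(active)))
            if t >= t_ev:
                break
            lin = active[int(rng.integers(len(active)))]
            if rng.random() < rates.duplication_rate / total_rate:
                lin.death = t
                c1 = new_lineage(lin.hosts, t)
                c2 = new_lineage(lin.hosts, t)
                lin.children = [c1, c2]
                active.remove(lin)
                active.extend([c1, c2])
                log.events.append({
                    "type": "duplication", "time": t,
                    "host": ",".join(sorted(_host_clade(next(iter(lin.hosts))))),
                })
            else:
                src = list(lin.hosts)[int(rng.integers(len(lin.hosts)))]
                targets = [e for e in _alive_edges(None, depth, t, host)
                           if e not in lin.hosts and _host_clade(e) not in forbidden]
                if targets:
                    dst = targets[int(rng.integers(len(targets)))]
                    lin.hosts.discard(src)
                    lin.hosts.add(dst)
                    log.events.append({
                        "type": "switch", "time": t,
                        "donor": ",".join(sorted(_host_clade(src))),
                        "recipient": ",".join(sorted(_host_clade(dst))),
                    })
        t_prev = t_ev
        if v is None:
            break
        # host split at node v: edge v ends, edges to v's children begin
        c1, c2 = v.children
        for lin in list(active):
            if v not in lin.hosts:
                continue
            lost = None
            if _host_clade(c1) in forbidden:
                lost = (c1, c2)
            elif _host_clade(c2) in forbidden:
                lost = (c2, c1)
            if lost is not None:
                lin.hosts.discard(v)
                lin.hosts.add(lost[1])
                log.events.append({
                    "type": "loss", "time": t_ev,
                    "host": ",".join(sorted(_host_clade(lost[0]))),
                })
                continue
            u = rng.random()
            if u < rates.p_cospeciation:
                lin.death = t_ev
                k1 = new_lineage((lin.hosts - {v}) | {c1}, t_ev)
                k2 = new_lineage({c2}, t_ev)
                lin.children = [k1, k2]
                active.remove(lin)
                active.extend([k1, k2])
                log.events.append({
                    "type": "cospeciation", "time": t_ev,
                    "host": ",".join(sorted(_host_clade(v))),
                })
            elif u < rates.p_cospeciation + rates.p_loss:
                stay = c1 if rng.random() < 0.5 else c2
                other = c2 if stay is c1 else c1
                lin.hosts.discard(v)
                lin.hosts.add(stay)
                log.events.append({
                    "type": "loss", "time": t_ev,
                    "host": ",".join(sorted(_host_clade(other))),
                })
            else:
                lin.hosts.discard(v)
                lin.hosts.update((c1, c2))
                log.events.append({
                    "type": "failure_to_diverge", "time": t_ev,
                    "host": ",".join(sorted(_host_clade(v))),
                })
    if len(active) < 2:
        return None
    # build the associate tree from the lineage genealogy
    tip_map = {}
    used = set()

    def build(lin: _Lineage) -> Node:
        if lin.children:
            node = Node()
            node.length = (lin.death - lin.birth)
            for c in lin.children:
                node.add_child(build(c))
            return node
        hosts = sorted(h.name for h in lin.hosts)
        base = "w_" + hosts[0]
        name = base
        i = 1
        while name in used:
            i += 1
            name = f"{base}.{i}"
        used.add(name)
        node = Node(name=name, length=present - lin.birth)
        tip_map[name] = set(hosts)
        return node

    root_lin = lineages[0]
    root_node = build(root_lin)
    root_node.length = 0.0
    assoc = RootedTree(root_node, length_units="coalescent")
    return assoc, tip_map, log


def write_tip_map(tip_map: dict, path):
    with open(path, "w") as fh:
        for assoc_tip in sorted(tip_map):
            hosts = "\t".join(sorted(tip_map[assoc_tip]))
            fh.write(f"{assoc_tip}\t{hosts}\n")


def read_tip_map(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts and parts[0]:
                out[parts[0]] = set(parts[1:])
    return out
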