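"""Self-contained validation studies on synthetic data.

Each function runs one calibration/recovery experiment end to end through
the package — simulate, analyze, score against the known truth — and
returns a small dict of summary numbers.  They are used by the test suite
and by ``scripts/acceptance.py``; problem sizes are arguments so callers
can trade precision for runtime.

The reconciliation brute-force oracle here enumerates complete event
histories by explicit placement of every associate node on every host edge
(with all loss paths, cospeciation pairings and switch landing edges), a
deliberately different formulation from the dynamic program it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np

from . import cfhyb, cophylo, dstats, integrate, simulate, speciestree, windows
from .treecore import (GeneTreeSet, Node, RootedTree, induced_quartet,
                       parse_newick, random_binary_tree, rf_distance)

# Four ingroup taxa plus outgroup; {t} is the internal branch under test.
_QUAD_NWK = "(((P1:1,P2:1):{t},P3:{d}):8,O:{h});"


def quad_network(t: float, gamma: float = 0.0, hyb_time: float = 0.25):
    """Four-taxon(+outgroup) species network with internal branch ``t`` and,
    optionally, a P3 -> P2 hybridization pulse of strength gamma."""
    nwk = _QUAD_NWK.format(t=t, d=1 + t, h=9 + t)
    edges = []
    if gamma > 0:
        edges = [simulate.HybridEdge(frozenset(["P3"]), frozenset(["P2"]),
                                     hyb_time, gamma)]
    return simulate.SpeciesNetwork.from_newick(nwk, edges)


def _quad_dstat(net, n_loci, theta, seed, z_crit=3.0):
    cfg = simulate.SimConfig(n_loci=n_loci, theta=theta, seed=seed)
    gts = simulate.simulate_gene_trees(net, cfg)
    m = simulate.simulate_snp_matrix(gts, cfg, outgroup="O")
    ws = windows.partition_windows(m, "bp", cfg.window_layout[1])
    test = dstats.FourTaxonTest(frozenset(["P1"]), frozenset(["P2"]),
                                frozenset(["P3"]), "O")
    sums, n_used, _ = dstats.pattern_sums(m, test, ws)
    return dstats.d_with_jackknife(sums, test, z_crit=z_crit,
                                   n_sites_used=n_used), m.n_sites


def d_null_study(n_reps: int = 100, n_loci: int = 1600, theta: float = 4.0,
                 internal: float = 0.5, seed: int = 0, z_crit: float = 3.0):
    """Null calibration of D on ILS-only four-taxon simulations."""
    net = quad_network(internal)
    ds, zs, sites = [], [], []
    for rep in range(n_reps):
        r, n_sites = _quad_dstat(net, n_loci, theta, seed * 100003 + rep,
                                 z_crit=z_crit)
        ds.append(r.D)
        zs.append(r.Z if r.Z is not None else 0.0)
        sites.append(n_sites)
    ds = np.array(ds, dtype=float)
    zs = np.array(zs, dtype=float)
    return {
        "mean_D": float(ds.mean()),
        "se_mean_D": float(ds.std(ddof=1) / math.sqrt(n_reps)),
        "fpr": float((np.abs(zs) >= z_crit).mean()),
        "mean_sites": float(np.mean(sites)),
        "n_reps": n_reps,
    }


def d_power_study(n_reps: int = 60, gamma: float = 0.3, n_loci: int = 1600,
                  theta: float = 4.0, internal: float = 0.5, seed: int = 0,
                  z_crit: float = 3.0):
    """Power and sign of D with a planted P3 -> P2 pulse (expect D > 0)."""
    net = quad_network(internal, gamma=gamma)
    hits = 0
    for rep in range(n_reps):
        r, _ = _quad_dstat(net, n_loci, theta, seed * 100003 + rep,
                           z_crit=z_crit)
        if r.D is not None and r.D > 0 and r.Z is not None and abs(r.Z) >= z_crit:
            hits += 1
    return {"power": hits / n_reps, "n_reps": n_reps}


def quartet_cf_study(ts: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
                     n_loci: int = 30000, seed: int = 0):
    """Observed vs closed-form quartet CFs; deviations in binomial SEs."""
    out = []
    for t in ts:
        net = quad_network(t)
        cfg = simulate.SimConfig(n_loci=n_loci, theta=1.0, seed=seed + int(t * 7919))
        gts = simulate.simulate_gene_trees(net, cfg)
        counts = [0, 0, 0]
        # sorted quartet (O,P1,P2,P3): P1P2 sister = pairing q1q2 = index 2
        for tree in gts:
            q = induced_quartet(tree, ("P1", "P2", "P3", "O"))
            counts[q.topology] += 1
        n = sum(counts)
        major_obs = counts[2] / n
        major_exp = cfhyb.expected_quartet_cf(t)[0]
        se = math.sqrt(major_exp * (1 - major_exp) / n)
        minor_diff = abs(counts[0] - counts[1]) / n
        mexp = (1 - major_exp) / 2
        minor_se = math.sqrt(2 * mexp * (1 - mexp) / n)
        out.append({
            "t": t,
            "major_obs": major_obs,
            "major_exp": major_exp,
            "major_dev_se": abs(major_obs - major_exp) / se,
            "minor_diff": minor_diff,
            "minor_diff_se": minor_diff / minor_se if minor_se > 0 else 0.0,
            "n": n,
        })
    return out


def minor_test_study(n_null: int = 100, n_alt: int = 50, gamma: float = 0.3,
                     n_loci: int = 2000, internal: float = 0.5, seed: int = 0,
                     alpha: float = 0.05):
    """Type-I error and power of the minor-topology equality test."""

    def one(net, s):
        cfg = simulate.SimConfig(n_loci=n_loci, theta=1.0, seed=s)
        gts = simulate.simulate_gene_trees(net, cfg)
        obs = cfhyb.observed_quartet_cfs(gts, [("P1", "P2", "P3", "O")])[0]
        res = cfhyb.minor_equality_test(obs, alpha=alpha, major_index=2)
        return res["verdict"] == "ILS-incompatible"

    net0 = quad_network(internal)
    net1 = quad_network(internal, gamma=gamma)
    rej0 = sum(one(net0, seed * 9176 + i) for i in range(n_null))
    rej1 = sum(one(net1, seed * 9176 + 50000 + i) for i in range(n_alt))
    return {"type1": rej0 / n_null, "power": rej1 / n_alt,
            "n_null": n_null, "n_alt": n_alt}


_FIVE_NWK = "(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);"


def gamma_recovery_study(gammas: Sequence[float] = (0.1, 0.25, 0.4),
                         n_reps: int = 30, n_loci: int = 5000, seed: int = 0,
                         n_starts: int = 6):
    """Parameter recovery of the inheritance probability on a five-taxon
    system with one D -> B reticulation."""
    tree = parse_newick(_FIVE_NWK, length_units="coalescent")
    out = {}
    for gamma in gammas:
        net = simulate.SpeciesNetwork.from_newick(
            _FIVE_NWK,
            [simulate.HybridEdge(frozenset(["D"]), frozenset(["B"]), 0.5, gamma)],
        )
        hats = []
        for rep in range(n_reps):
            s = seed * 7919 + int(gamma * 1000) * 101 + rep
            cfg = simulate.SimConfig(n_loci=n_loci, theta=1.0, seed=s)
            gts = simulate.simulate_gene_trees(net, cfg)
            obs = cfhyb.observed_quartet_cfs(gts)
            fit = cfhyb.fit_gamma(obs, tree, donor=["D"], recipient=["B"],
                                  n_starts=n_starts, seed=rep)
            hats.append(fit.gamma)
        hats = np.array(hats)
        out[gamma] = {
            "mean_gamma_hat": float(hats.mean()),
            "bias": float(hats.mean() - gamma),
            "frac_within_0.1": float((np.abs(hats - gamma) <= 0.1).mean()),
            "n_reps": n_reps,
        }
    return out


def random_ultrametric_tree(names: Sequence[str], rng,
                            internal_min: float = 0.5,
                            internal_max: float = 1.0) -> RootedTree:
    """Random topology, ultrametric heights, every internal branch at least
    ``internal_min`` coalescent units."""
    shape = random_binary_tree(names, rng)
    height = {}
    for node in shape.postorder():
        if node.is_leaf:
            height[node] = 0.0
        else:
            height[node] = max(height[c] for c in node.children) + float(
                rng.uniform(internal_min, internal_max))
    for node in shape.postorder():
        if node.parent is not None:
            node.length = height[node.parent] - height[node]
    return RootedTree(shape.root, length_units="coalescent")


def species_tree_study(n_reps: int = 100, n_taxa: int = 15, n_loci: int = 1000,
                       internal_min: float = 0.5, seed: int = 0):
    """Greedy-consensus recovery of a random species tree from coalescent
    gene trees."""
    rng = np.random.default_rng(seed)
    names = [f"S{i:02d}" for i in range(n_taxa)]
    hits = 0
    for rep in range(n_reps):
        true = random_ultrametric_tree(names, rng, internal_min=internal_min)
        net = simulate.SpeciesNetwork(true)
        cfg = simulate.SimConfig(n_loci=n_loci, theta=1.0,
                                 seed=seed * 4409 + rep)
        gts = simulate.simulate_gene_trees(net, cfg)
        table = speciestree.clade_frequencies(gts)
        est = speciestree.greedy_consensus(table)
        if rf_distance(est.tree, true) == 0:
            hits += 1
    return {"recovery": hits / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# Reconciliation brute force
# ---------------------------------------------------------------------------

def brute_force_reconcile(host: RootedTree, assoc: RootedTree, tipmap: dict,
                          costs: cophylo.CostScheme):
    """Exhaustive minimum reconciliation cost and optimum count.

    Enumerates every full event history: a host edge per associate node,
    the event type with all its details (cospeciation pairing, switch
    landing edge), and the implied loss path, which is unique once the
    endpoints are fixed.  Only practical for a handful of tips.
    """
    H = cophylo._Host(host)
    n_edges = len(H.nodes)
    anodes = list(assoc.postorder())
    aidx = {n: i for i, n in enumerate(anodes)}
    tip_edge = {}
    for lf in assoc.leaves():
        hosts = tipmap[lf.name]
        if not isinstance(hosts, str):
            hosts = next(iter(hosts))
            if len(tipmap[lf.name]) != 1:
                raise ValueError("brute force handles one-to-one maps only")
        tip_edge[aidx[lf]] = H.tip_of[hosts]

    desc = [[] for _ in range(n_edges)]
    for e in range(n_edges):
        stack = [e]
        while stack:
            g = stack.pop()
            desc[e].append(g)
            stack.extend(H.children[g])

    def steps(e, f):
        """Edge-path length descending from e to f (f within subtree of e)."""
        k = 0
        while f != e:
            f = H.parent[f]
            k += 1
        return k

    def histories(ai, e):
        """Yield the cost of every event history with ai's event on edge e."""
        a = anodes[ai]
        if a.is_leaf:
            if tip_edge[ai] == e:
                yield 0.0
            return
        x, y = (aidx[c] for c in a.children)

        def down(child_ai, g):
            for f in desc[g]:
                for c in histories(child_ai, f):
                    yield steps(g, f) * costs.loss + c

        if not H.is_tip[e]:
            l, r = H.children[e]
            for cx, cy in ((l, r), (r, l)):
                for c1 in down(x, cx):
                    for c2 in down(y, cy):
                        yield costs.cospeciation + c1 + c2
        for c1 in down(x, e):
            for c2 in down(y, e):
                yield costs.duplication + c1 + c2
        for stay, move in ((x, y), (y, x)):
            for g in range(n_edges):
                if g == e or not H.overlap(e, g):
                    continue
                for c1 in down(stay, e):
                    for c2 in down(move, g):
                        yield costs.switch + c1 + c2

    best = math.inf
    count = 0
    for e in range(n_edges):
        for c in histories(len(anodes) - 1, e):
            if c < best - 1e-9:
                best, count = c, 1
            elif abs(c - best) <= 1e-9:
                count += 1
    return best, count


def reconcile_oracle_study(n_cases: int = 25, seed: int = 0,
                           schemes: Optional[Sequence] = None,
                           check_counts: bool = False):
    """DP vs brute-force agreement on random small host/associate pairs."""
    rng = np.random.default_rng(seed)
    if schemes is None:
        schemes = cophylo.default_cost_grid()
    agree = 0
    total = 0
    for case in range(n_cases):
        n = int(rng.integers(3, 6))
        names = [chr(65 + i) for i in range(n)]
        host = random_binary_tree(names, rng)
        assoc = random_binary_tree(["w" + x for x in names], rng)
        tipmap = {"w" + x: x for x in names}
        scheme = schemes[case % len(schemes)]
        opt = cophylo.reconcile(host, assoc, tipmap, scheme, cap=100000)
        bf_cost, bf_count = brute_force_reconcile(host, assoc, tipmap, scheme)
        total += 1
        ok = abs(opt.cost - bf_cost) <= 1e-9
        if check_counts:
            ok = ok and (opt.truncated or len(opt.solutions) == bf_count)
        if ok:
            agree += 1
    return {"agreement": agree / total, "n_cases": total}


def planted_switch_study(n_reps: int = 40, seed: int = 0):
    """Recovery of a planted host switch by the reconciliation DP.

    The associate tree is the host tree with one tip regrafted next to a
    non-sister tip (the planted switch); recovery means some co-optimal
    solution contains a switch whose donor and recipient clades bracket the
    planted donor/recipient tips.
    """
    rng = np.random.default_rng(seed)
    scheme = cophylo.CostScheme(0.0, 0.6, 1.0, 0.4, 0.6)
    hits = 0
    for rep in range(n_reps):
        n = 8
        names = [chr(65 + i) for i in range(n)]
        host = random_ultrametric_tree(names, rng)
        assoc = host.copy()
        for lf in assoc.leaves():
            lf.name = "w" + lf.name
        # pick a tip to move and a non-sister destination tip
        moved, dest = _pick_switch_pair(host, rng)
        assoc = cfhyb.spr_move(assoc, frozenset(["w" + moved]),
                               frozenset(["w" + dest]))
        tipmap = {"w" + x: x for x in names}
        opt = cophylo.reconcile(host, assoc, tipmap, scheme, cap=500)
        for sol in opt.solutions:
            found = False
            for donor, recip in sol.switch_pairs():
                dset = set(donor.split(","))
                rset = set(recip.split(","))
                if (dest in dset and moved in rset) or (moved in dset and dest in rset):
                    found = True
                    break
            if found:
                hits += 1
                break
    return {"recovery": hits / n_reps, "n_reps": n_reps}


def _pick_switch_pair(host: RootedTree, rng):
    leaves = host.leaf_names()
    while True:
        moved, dest = rng.choice(leaves, size=2, replace=False)
        m = host.find_leaf(str(moved))
        d = host.find_leaf(str(dest))
        if m.parent is not d.parent:  # not already sisters
            return str(moved), str(dest)


def congruence_p_study(n_random: int = 40, n_perm: int = 199, seed: int = 0):
    """Permutation p for a perfectly congruent pair, and the p distribution
    for random associate trees (should be roughly uniform)."""
    rng = np.random.default_rng(seed)
    names = [chr(65 + i) for i in range(8)]
    host = random_ultrametric_tree(names, rng)
    assoc = host.copy()
    for lf in assoc.leaves():
        lf.name = "w" + lf.name
    tipmap = {"w" + x: x for x in names}
    scheme = cophylo.CostScheme(0.0, 0.6, 1.0, 0.4, 0.6)
    res = cophylo.permutation_test(host, assoc, tipmap, scheme,
                                   mode="tip_shuffle", N=n_perm, seed=seed)
    p_congruent = res.p_value
    null_ps = []
    for rep in range(n_random):
        rnd = random_binary_tree(["w" + x for x in names], rng)
        r = cophylo.permutation_test(host, rnd, tipmap, scheme,
                                     mode="tip_shuffle", N=n_perm,
                                     seed=seed + 1 + rep)
        null_ps.append(r.p_value)
    return {"p_congruent": p_congruent, "null_ps": null_ps}


# ---------------------------------------------------------------------------
# Event-matching study
# ---------------------------------------------------------------------------

_SIX_NWK = "(((((A:1,B:1):1,C:2):1,(D:2,E:2):1):1,F:4):6,OUT:10);"


def match_study(n_reps: int = 30, coupled: bool = True, n_loci: int = 600,
                theta: float = 4.0, seed: int = 0):
    """Hybridization/switch cross-matching on joint simulations.

    A D -> C hybridization pulse (gamma 0.35) generates nuclear D-statistic
    events; the pollinator tree carries one planted switch — between the
    same clades when ``coupled``, between clades disjoint from the pulse
    (A and F) otherwise.  Reports the fraction of replicates where the
    top-|Z| hybridization event is matched by a switch.
    """
    net = simulate.SpeciesNetwork.from_newick(
        _SIX_NWK,
        [simulate.HybridEdge(frozenset(["D"]), frozenset(["C"]), 1.5, 0.35)],
    )
    from .treecore import Taxon

    host = net.base_tree
    taxa_meta = [Taxon(t, role="outgroup" if t == "OUT" else "ingroup")
                 for t in sorted(net.taxa)]
    matched = 0
    for rep in range(n_reps):
        s = seed * 6007 + rep
        cfg = simulate.SimConfig(n_loci=n_loci, theta=theta, seed=s)
        gts = simulate.simulate_gene_trees(net, cfg)
        m = simulate.simulate_snp_matrix(gts, cfg, outgroup="OUT")
        ws = windows.partition_windows(m, "bp", cfg.window_layout[1])
        tests, _ = dstats.enumerate_tests(host, "species", taxa_meta, "OUT")
        _, results = dstats.dstat_scan(m, tests, ws)
        hyb = integrate.collect_hyb_events(dstat_results=results)
        if not hyb:
            continue
        top = hyb[0]
        # pollinator tree with one planted switch
        assoc = host.copy()
        assoc = _drop_out(assoc, "OUT")
        for lf in assoc.leaves():
            lf.name = "w" + lf.name
        if coupled:
            moved, dest = "C", "D"
        else:
            moved, dest = "A", "F"
        assoc = cfhyb.spr_move(assoc, frozenset(["w" + moved]),
                               frozenset(["w" + dest]))
        tipmap = {name: name[1:] for name in assoc.leaf_names()}
        opt = cophylo.reconcile(_drop_out(host.copy(), "OUT"), assoc, tipmap,
                                cophylo.CostScheme(0.0, 0.6, 1.0, 0.4, 0.6),
                                cap=200)
        switches = []
        for rid, sol in enumerate(opt.solutions):
            for donor, recip in sol.switch_pairs():
                switches.append(integrate.SwitchEvent(
                    frozenset(donor.split(",")), frozenset(recip.split(",")),
                    source_id=rid))
        report = integrate.match_events([top], switches)
        if report.n_matched == 1:
            matched += 1
    return {"matched_fraction": matched / n_reps, "n_reps": n_reps}


def _drop_out(tree: RootedTree, name: str) -> RootedTree:
    from .dstats import _drop_leaf

    return _drop_leaf(tree, name)


def window_bookkeeping_check():
    """Exact window arithmetic on a printed toy: a 250-kb chromosome with
    2,500 SNPs at fixed positions, plus constructed filter violators."""
    rng = np.random.default_rng(12345)
    pos = np.sort(rng.choice(250000 - 2, size=2499, replace=False) + 1)
    pos = np.concatenate([pos, [250000]])  # pin the chromosome end
    n = 2500
    taxa = [f"T{i}" for i in range(17)]
    counts = np.zeros((17, n), dtype=np.int8)
    counts[0, :] = 1
    # site 0: 7 of 17 missing (41.2% > 40%); site 1: 6 of 17 (35.3%)
    counts[1:8, 0] = -1
    counts[1:7, 1] = -1
    m = windows.GenotypeMatrix(
        taxa=taxa, chrom=np.array(["chr1"] * n), pos=pos, counts=counts,
        ploidy=np.ones(17, dtype=int), polarized=True, outgroup=None,
    )
    bp = windows.partition_windows(m, "bp", 100000)
    bp_bounds = [(w.chrom, w.start, w.end) for w in bp]
    snp = windows.partition_windows(m, "snp", 1000, step=1100)
    snp_bounds = [(w.start, w.end, w.n_snps) for w in snp]
    filtered = windows.filter_sites(m, 0.4)
    # min-SNP filter on constructed windows of 49 vs 50 sites
    w49 = windows.GenomicWindow("chr1", 1, 49, np.arange(49))
    w50 = windows.GenomicWindow("chr1", 50, 99, np.arange(49, 99))
    ws = windows.WindowSet([w49, w50], "snp", 50)
    kept = windows.filter_windows(ws, 50)
    return {
        "bp_bounds": bp_bounds,
        "snp_bounds": snp_bounds,
        "n_sites_before": m.n_sites,
        "n_sites_after_missing_filter": filtered.n_sites,
        "windows_kept_after_min_snp": [(w.start, w.end) for w in kept],
    }
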