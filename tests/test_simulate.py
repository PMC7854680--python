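import math

import numpy as np
import pytest
from scipy import stats

from fignet.simulate import (CophyloRates, HybridEdge, SimConfig,
                             SpeciesNetwork, simulate_cophylogeny,
                             simulate_gene_trees, simulate_organelle_locus,
                             simulate_snp_matrix)
from fignet.treecore import induced_quartet, parse_newick, rf_distance, write_newick

QUAD = "(((P1:1,P2:1):{t},P3:{d}):8,O:{h});"


def quad_net(t, gamma=0.0):
    edges = []
    if gamma:
        edges = [HybridEdge(["P3"], ["P2"], 0.25, gamma)]
    return SpeciesNetwork.from_newick(QUAD.format(t=t, d=1 + t, h=9 + t), edges)


class TestNetworkValidation:
    def test_requires_ultrametric(self):
        with pytest.raises(ValueError, match="ultrametric"):
            SpeciesNetwork.from_newick("((A:1,B:2):1,C:2);")

    def test_pulse_time_must_be_on_both_branches(self):
        with pytest.raises(ValueError, match="outside"):
            SpeciesNetwork.from_newick(
                QUAD.format(t=1, d=2, h=10),
                [HybridEdge(["P3"], ["P2"], 5.0, 0.3)],
            )

    def test_gamma_bounds(self):
        with pytest.raises(ValueError):
            HybridEdge(["A"], ["B"], 1.0, 1.5)


class TestGeneTrees:
    def test_determinism(self):
        net = quad_net(1.0)
        cfg = SimConfig(n_loci=50, theta=1.0, seed=99)
        a = [write_newick(t) for t in simulate_gene_trees(net, cfg)]
        b = [write_newick(t) for t in simulate_gene_trees(net, cfg)]
        assert a == b

    def test_locus_streams_independent_of_n_loci(self):
        net = quad_net(1.0)
        a = simulate_gene_trees(net, SimConfig(n_loci=5, seed=7))
        b = simulate_gene_trees(net, SimConfig(n_loci=30, seed=7))
        assert [write_newick(t) for t in a] == [write_newick(t) for t in b[:5]]

    def test_deep_branches_suppress_discordance(self):
        net = SpeciesNetwork.from_newick(
            "(((P1:20,P2:20):20,P3:40):20,O:60);")
        gts = simulate_gene_trees(net, SimConfig(n_loci=500, seed=5))
        matches = sum(
            ("P1", "P2") in induced_quartet(t, ("P1", "P2", "P3", "O")).pairs()
            for t in gts
        )
        assert matches == 500

    def test_star_tree_symmetry(self):
        gts = simulate_gene_trees(quad_net(0.0), SimConfig(n_loci=3000, seed=3))
        counts = [0, 0, 0]
        for t in gts:
            counts[induced_quartet(t, ("P1", "P2", "P3", "O")).topology] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_quartet_cf_matches_closed_form_and_msprime(self):
        """Major-topology frequency at t=1 against theory and an independent
        coalescent simulator."""
        n = 20000
        gts = simulate_gene_trees(quad_net(1.0), SimConfig(n_loci=n, seed=11))
        major = sum(
            ("P1", "P2") in induced_quartet(t, ("P1", "P2", "P3", "O")).pairs()
            for t in gts
        ) / n
        expected = 1 - (2 / 3) * math.exp(-1)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(major - expected) < 3 * se

        import msprime

        dem = msprime.Demography()
        for p in ("P1", "P2", "P3", "O", "A12", "A123", "ROOT"):
            dem.add_population(name=p, initial_size=1)
        dem.add_population_split(time=1.0, derived=["P1", "P2"], ancestral="A12")
        dem.add_population_split(time=2.0, derived=["A12", "P3"], ancestral="A123")
        dem.add_population_split(time=10.0, derived=["A123", "O"], ancestral="ROOT")
        n_ms = 8000
        major_ms = 0
        reps = msprime.sim_ancestry(
            samples={"P1": 1, "P2": 1, "P3": 1, "O": 1}, demography=dem,
            ploidy=1, num_replicates=n_ms, random_seed=17)
        for ts in reps:
            tree = ts.first()
            if tree.mrca(0, 1) != tree.root and len(
                    list(tree.samples(tree.mrca(0, 1)))) == 2:
                major_ms += 1
        major_ms /= n_ms
        se_pair = math.sqrt(expected * (1 - expected) * (1 / n + 1 / n_ms))
        assert abs(major - major_ms) < 3 * se_pair

    def test_gamma_mixture_expectation(self):
        """One-hybrid network CFs match the gamma mixture of parental trees."""
        gamma, t = 0.4, 1.0
        n = 20000
        gts = simulate_gene_trees(quad_net(t, gamma=gamma),
                                  SimConfig(n_loci=n, seed=13))
        counts = [0, 0, 0]
        for tr in gts:
            counts[induced_quartet(tr, ("P1", "P2", "P3", "O")).topology] += 1
        # topology index on sorted (O,P1,P2,P3):
        # 0: P2-P3 sister, 1: P1-P3 sister, 2: P1-P2 sister
        # parental tree 1 (prob 1-gamma): major P1P2 (idx 2), internal t
        # parental tree 2 (prob gamma): P2 rides the P3 branch from the pulse
        # (0.25) to the join with the P1 lineage at height 1+t
        e_minor1 = math.exp(-t) / 3
        e_minor2 = math.exp(-(1 + t - 0.25)) / 3
        exp = np.array([
            (1 - gamma) * e_minor1 + gamma * (1 - 2 * e_minor2),
            (1 - gamma) * e_minor1 + gamma * e_minor2,
            (1 - gamma) * (1 - 2 * e_minor1) + gamma * e_minor2,
        ])
        obs = np.array(counts) / n
        se = np.sqrt(exp * (1 - exp) / n)
        assert np.all(np.abs(obs - exp) < 3.5 * se)


class TestSNPMatrix:
    def test_zero_theta_zero_sites(self):
        net = quad_net(1.0)
        cfg = SimConfig(n_loci=10, theta=0.0, seed=1)
        gts = simulate_gene_trees(net, cfg)
        with pytest.warns(UserWarning, match="zero segregating"):
            m = simulate_snp_matrix(gts, cfg)
        assert m.n_sites == 0

    def test_sites_compatible_with_gene_trees(self):
        """Infinite sites: every site's derived set is a clade of its locus'
        gene tree (and never contains the outgroup when polarized)."""
        net = quad_net(1.0)
        cfg = SimConfig(n_loci=30, theta=3.0, seed=21)
        gts = simulate_gene_trees(net, cfg)
        m = simulate_snp_matrix(gts, cfg, outgroup="O")
        win_len = cfg.window_layout[1]
        index = {t: i for i, t in enumerate(m.taxa)}
        oi = index["O"]
        for s in range(m.n_sites):
            locus = (m.pos[s] - 1) // win_len
            tree = gts[locus]
            tree.compute_masks(index)
            clades = {n._mask for n in tree.postorder() if n is not tree.root}
            site_mask = 0
            for ti in range(m.n_taxa):
                if m.counts[ti, s] == 1:
                    site_mask |= 1 << ti
            assert m.counts[oi, s] == 0
            assert site_mask in clades

    def test_poisson_site_count(self):
        """Mean segregating sites per locus ~ theta * total length / 2."""
        net = quad_net(1.0)
        cfg = SimConfig(n_loci=2000, theta=2.0, seed=8)
        gts = simulate_gene_trees(net, cfg)
        m = simulate_snp_matrix(gts, cfg)  # no outgroup masking
        total_len = np.array([
            sum(n.length for n in t.postorder() if n is not t.root)
            for t in gts
        ])
        expected = cfg.theta / 2 * total_len.mean()
        per_locus = m.n_sites / len(gts)
        se = math.sqrt(expected / len(gts))  # Poisson variance
        assert abs(per_locus - expected) < 4 * se

    def test_missingness_rate(self):
        net = quad_net(1.0)
        cfg = SimConfig(n_loci=300, theta=2.0, seed=8, missing_rate=0.2)
        gts = simulate_gene_trees(net, cfg)
        m = simulate_snp_matrix(gts, cfg)
        frac = (m.counts == -1).mean()
        assert abs(frac - 0.2) < 0.02


class TestOrganelle:
    NWK = "(((A:2,B:2):2,C:4):8,O:12);"

    def test_no_capture_matches_base(self):
        net = SpeciesNetwork.from_newick(
            "(((A:20,B:20):20,C:40):20,O:60);",
            [HybridEdge(["C"], ["B"], 5.0, 0.5)])
        org = simulate_organelle_locus(net, capture_prob=0.0, seed=4)
        assert rf_distance(org, net.base_tree) == 0

    def test_full_capture_reroutes_recipient(self):
        net = SpeciesNetwork.from_newick(
            "(((A:20,B:20):20,C:40):20,O:60);",
            [HybridEdge(["C"], ["B"], 5.0, 0.5)])
        org = simulate_organelle_locus(net, capture_prob=1.0, seed=4)
        # B's organelle captured from C: B groups with C, not A
        q = induced_quartet(org, ("A", "B", "C", "O"))
        assert ("B", "C") in q.pairs()

    def test_capture_frequency(self):
        net = SpeciesNetwork.from_newick(
            "(((A:20,B:20):20,C:40):20,O:60);",
            [HybridEdge(["C"], ["B"], 5.0, 0.5)])
        captures = 0
        n = 400
        for seed in range(n):
            org = simulate_organelle_locus(net, capture_prob=0.5, seed=seed)
            q = induced_quartet(org, ("A", "B", "C", "O"))
            if ("B", "C") in q.pairs():
                captures += 1
        se = math.sqrt(0.25 / n)
        assert abs(captures / n - 0.5) < 3 * se


class TestCophylogeny:
    def test_pure_cospeciation_isomorphic(self, host8):
        rates = CophyloRates(1.0, 0.0, 0.0, 0.0, 0.0)
        assoc, tipmap, log = simulate_cophylogeny(host8, rates, seed=1)
        assert log.count("cospeciation") == 7
        assert all(tm == {name[2:]} for name, tm in tipmap.items())
        renamed = assoc.copy()
        for lf in renamed.leaves():
            lf.name = lf.name[2:]
        assert rf_distance(renamed, host8) == 0

    def test_forbidden_clade_absent(self, host8):
        rates = CophyloRates(1.0, 0.0, 0.0, 0.0, 0.0,
                             forbidden_clades=(frozenset("FGH"),))
        assoc, tipmap, log = simulate_cophylogeny(host8, rates, seed=2)
        hosts = set().union(*tipmap.values())
        assert hosts == set("ABCDE")
        assert log.count("loss") == 1

    def test_switch_count_poisson(self):
        """On a perfectly balanced host with synchronous splits the total
        lineage-time is deterministic, so logged switches are Poisson."""
        host = parse_newick(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);")
        rate = 0.15
        rates = CophyloRates(1.0, 0.0, 0.0, 0.0, rate)
        n = 300
        total = 0
        for seed in range(n):
            _, _, log = simulate_cophylogeny(host, rates, seed=seed)
            total += log.count("switch")
        lineage_time = 2 * 1 + 4 * 1 + 8 * 1
        expected = rate * lineage_time
        se = math.sqrt(expected / n)
        assert abs(total / n - expected) < 3 * se

    def test_log_types_are_valid(self, host8):
        _, _, log = simulate_cophylogeny(host8, CophyloRates(), seed=0)
        valid = {"cospeciation", "duplication", "switch", "loss",
                 "failure_to_diverge"}
        assert all(e["type"] in valid for e in log.events)
        for sw in log.switches():
            assert sw["donor"] != sw["recipient"]
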