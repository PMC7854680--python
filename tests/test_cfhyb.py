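import math

import numpy as np
import pytest

from fignet.cfhyb import (DELTA_DEFAULT, QuartetCFObservation,
                          expected_quartet_cf, fit_gamma, fit_tree_model,
                          minor_equality_test, observed_quartet_cfs,
                          select_hmax, spr_move, _model_matrices, _neg_logplik)
from fignet.simulate import HybridEdge, SimConfig, SpeciesNetwork, \
    simulate_gene_trees
from fignet.treecore import parse_newick, rf_distance

FIVE = "(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);"


def five_net(gamma=0.0):
    edges = []
    if gamma:
        edges = [HybridEdge(["D"], ["B"], 0.5, gamma)]
    return SpeciesNetwork.from_newick(FIVE, edges)


class TestExpectedCF:
    @pytest.mark.parametrize("t", [0.0, 0.3, 1.0, 5.0, 50.0])
    def test_simplex(self, t):
        cf = expected_quartet_cf(t)
        assert sum(cf) == pytest.approx(1.0)
        assert all(c >= 0 for c in cf)
        assert cf[1] == cf[2]

    def test_star_and_limit(self):
        assert expected_quartet_cf(0.0) == pytest.approx((1 / 3,) * 3)
        assert expected_quartet_cf(40.0)[0] == pytest.approx(1.0)

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            expected_quartet_cf(-0.1)

    def test_matches_simulation(self):
        net = SpeciesNetwork.from_newick("(((P1:1,P2:1):1,P3:2):8,O:10);")
        gts = simulate_gene_trees(net, SimConfig(n_loci=10000, seed=31))
        obs = observed_quartet_cfs(gts, [("P1", "P2", "P3", "O")])[0]
        exp = expected_quartet_cf(1.0)
        n = obs.n_resolved
        # major topology (P1,P2 sister) is index 2 on sorted taxa
        se = math.sqrt(exp[0] * (1 - exp[0]) / n)
        assert abs(obs.counts[2] / n - exp[0]) < 3 * se


class TestMinorEquality:
    def test_balanced_minors(self):
        obs = QuartetCFObservation(("a", "b", "c", "d"), (100, 30, 30))
        res = minor_equality_test(obs)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["verdict"] == "ILS-compatible"
        assert res["ci_overlap"]

    def test_extreme_asymmetry(self):
        obs = QuartetCFObservation(("a", "b", "c", "d"), (100, 60, 0))
        res = minor_equality_test(obs)
        assert res["p_value"] == pytest.approx(2 * 0.5 ** 60, rel=1e-9)
        assert res["verdict"] == "ILS-incompatible"
        assert not res["ci_overlap"]

    def test_insufficient_data(self):
        obs = QuartetCFObservation(("a", "b", "c", "d"), (10, 2, 1))
        assert minor_equality_test(obs)["verdict"] == "insufficient data"
        obs = QuartetCFObservation(("a", "b", "c", "d"), (100, 1, 0))
        assert minor_equality_test(obs)["verdict"] == "insufficient minor signal"

    def test_type_one_error_rate(self):
        """ILS-only data rejected at ~alpha."""
        net = SpeciesNetwork.from_newick("(((P1:1,P2:1):0.5,P3:1.5):8.5,O:10);")
        rejections = 0
        n = 40
        for rep in range(n):
            gts = simulate_gene_trees(net, SimConfig(n_loci=1500, seed=1300 + rep))
            obs = observed_quartet_cfs(gts, [("P1", "P2", "P3", "O")])[0]
            res = minor_equality_test(obs, major_index=2)
            rejections += res["verdict"] == "ILS-incompatible"
        assert rejections <= 5  # ~5% of 40, with slack


class TestSprMove:
    def test_regrafts_recipient_next_to_donor(self):
        tree = parse_newick(FIVE)
        moved = spr_move(tree, frozenset(["B"]), frozenset(["D"]))
        expected = parse_newick("(((A:1,C:1):1):1,((B:1,D:1):1,E:1.5):1.5);",
                                )
        assert set(moved.leaf_names()) == set("ABCDE")
        # B now sisters D
        from fignet.treecore import induced_quartet

        q = induced_quartet(moved, ("A", "B", "D", "E"))
        assert ("B", "D") in q.pairs()


class TestFitGamma:
    def test_mixture_reduces_to_tree_at_gamma_zero(self):
        tree = parse_newick(FIVE)
        gts = simulate_gene_trees(five_net(), SimConfig(n_loci=300, seed=2))
        obs = observed_quartet_cfs(gts)
        counts = np.array([o.counts for o in obs], dtype=float)
        tree2 = spr_move(tree, frozenset(["B"]), frozenset(["D"]))
        params, reps = _model_matrices(tree, obs, tree2)
        lens = np.linspace(0.4, 1.8, len(params))
        params0, reps0 = _model_matrices(tree, obs)
        lens0 = lens[:len(params0)]
        with_g = _neg_logplik(np.concatenate([[0.0], lens]), reps, counts, True)
        tree_only = _neg_logplik(lens, [reps[0]], counts, False)
        assert with_g == pytest.approx(tree_only)

    def test_null_gamma_near_zero(self):
        tree = parse_newick(FIVE)
        gts = simulate_gene_trees(five_net(), SimConfig(n_loci=5000, seed=41))
        obs = observed_quartet_cfs(gts)
        fit0 = fit_tree_model(obs, tree, n_starts=4, seed=1)
        fit1 = fit_gamma(obs, tree, donor=["D"], recipient=["B"], n_starts=4,
                         seed=1)
        assert fit1.gamma <= 0.02
        assert fit0.neg_logplik - fit1.neg_logplik <= 1.0
        assert select_hmax(fit0, fit1).gamma is None

    def test_recovers_planted_gamma(self):
        tree = parse_newick(FIVE)
        gts = simulate_gene_trees(five_net(0.3), SimConfig(n_loci=5000, seed=43))
        obs = observed_quartet_cfs(gts)
        fit0 = fit_tree_model(obs, tree, n_starts=4, seed=2)
        fit1 = fit_gamma(obs, tree, donor=["D"], recipient=["B"], n_starts=4,
                         seed=2)
        assert 0.2 <= fit1.gamma <= 0.4
        assert select_hmax(fit0, fit1) is fit1

    def test_true_params_near_local_max(self):
        """The pseudolikelihood at the truth beats random perturbations."""
        tree = parse_newick(FIVE)
        gts = simulate_gene_trees(five_net(0.3), SimConfig(n_loci=5000, seed=47))
        obs = observed_quartet_cfs(gts)
        counts = np.array([o.counts for o in obs], dtype=float)
        tree2 = spr_move(tree, frozenset(["B"]), frozenset(["D"]))
        params, reps = _model_matrices(tree, obs, tree2)
        # true internal lengths from the base tree / SPR construction
        fit = fit_gamma(obs, tree, donor=["D"], recipient=["B"], n_starts=6,
                        seed=3)
        x_hat = np.concatenate([[fit.gamma],
                                [fit.edge_lengths[c] for c in params]])
        nll_hat = _neg_logplik(x_hat, reps, counts, True)
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = x_hat.copy()
            x[0] = min(max(x[0] + rng.normal(0, 0.1), 0.0), 1.0)
            x[1:] = np.maximum(x[1:] + rng.normal(0, 0.3, len(x) - 1), 1e-6)
            assert _neg_logplik(x, reps, counts, True) >= nll_hat - 1e-6

    def test_unidentifiable_candidate_rejected(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gts = simulate_gene_trees(
            SpeciesNetwork.from_newick("((A:1,B:1):1,(C:1,D:1):1);"),
            SimConfig(n_loci=100, seed=3))
        obs = observed_quartet_cfs(gts)
        # moving A next to B changes nothing
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_gamma(obs, tree, donor=["B"], recipient=["A"])

    def test_select_hmax_prefers_simpler_on_tie(self):
        tree = parse_newick(FIVE)
        gts = simulate_gene_trees(five_net(), SimConfig(n_loci=500, seed=4))
        obs = observed_quartet_cfs(gts)
        fit0 = fit_tree_model(obs, tree, n_starts=2, seed=1)
        assert select_hmax(fit0, fit0) is fit0

    def test_select_hmax_different_data_rejected(self):
        tree = parse_newick(FIVE)
        g1 = simulate_gene_trees(five_net(), SimConfig(n_loci=200, seed=5))
        g2 = simulate_gene_trees(five_net(), SimConfig(n_loci=200, seed=6))
        f1 = fit_tree_model(observed_quartet_cfs(g1), tree, n_starts=2, seed=1)
        f2 = fit_tree_model(observed_quartet_cfs(g2), tree, n_starts=2, seed=1)
        with pytest.raises(ValueError, match="same data"):
            select_hmax(f1, f2)
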