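import itertools
import math

import numpy as np
import pytest

from fignet.dstats import (DStatResult, FourTaxonTest, d_with_jackknife,
                           dstat_scan, enumerate_tests, pattern_sums)
from fignet.simulate import SimConfig, SpeciesNetwork, simulate_gene_trees, \
    simulate_snp_matrix
from fignet.treecore import Taxon, induced_quartet, parse_newick
from fignet.windows import GenomicWindow, GenotypeMatrix, WindowSet, \
    partition_windows


def _matrix(counts, polarized=True):
    counts = np.asarray(counts, dtype=np.int8)
    n_taxa, n_sites = counts.shape
    return GenotypeMatrix(
        taxa=[f"T{i}" for i in range(n_taxa - 1)] + ["O"],
        chrom=np.array(["chr1"] * n_sites),
        pos=np.arange(1, n_sites + 1),
        counts=counts,
        ploidy=np.ones(n_taxa, dtype=int),
        polarized=polarized,
    )


def _one_block(n_sites):
    return WindowSet([GenomicWindow("chr1", 1, n_sites, np.arange(n_sites))],
                     "bp", n_sites)


TEST = FourTaxonTest(frozenset(["T0"]), frozenset(["T1"]), frozenset(["T2"]), "O")


class TestPatternSums:
    @pytest.mark.parametrize("p,expected", [
        ((0, 1, 1), (1.0, 0.0)),   # ABBA
        ((1, 0, 1), (0.0, 1.0)),   # BABA
        ((0, 0, 0), (0.0, 0.0)),   # invariant
        ((1, 1, 1), (0.0, 0.0)),   # no contrast against P3-anchored patterns
        ((1, 1, 0), (0.0, 0.0)),   # derived absent from P3
    ])
    def test_single_site_patterns(self, p, expected):
        m = _matrix(np.array([[p[0]], [p[1]], [p[2]], [0]]))
        sums, _, _ = pattern_sums(m, TEST, _one_block(1))
        assert tuple(sums[0]) == expected

    def test_unpolarized_rejected(self):
        m = _matrix(np.zeros((4, 3)), polarized=False)
        with pytest.raises(ValueError, match="polarized"):
            pattern_sums(m, TEST, _one_block(3))

    def test_group_frequencies_average(self):
        # P2 = {T1, T2} with one derived of two members: p2 = 0.5
        counts = np.array([[0], [1], [0], [0], [0]])
        m = _matrix(counts)
        test = FourTaxonTest(["T0"], ["T1", "T2"], ["T3"], "O")
        sums, _, _ = pattern_sums(m, test, _one_block(1))
        assert tuple(sums[0]) == (0.0, 0.0)  # p3=0: uninformative
        counts = np.array([[0], [1], [0], [1], [0]])
        m = _matrix(counts)
        sums, _, _ = pattern_sums(m, test, _one_block(1))
        assert sums[0, 0] == pytest.approx(0.5)  # (1-0)*0.5*1

    def test_fully_missing_group_site_skipped(self):
        counts = np.array([[0, 0], [-1, 1], [1, 1], [0, 0]])
        m = _matrix(counts)
        sums, n_used, n_skipped = pattern_sums(m, TEST, _one_block(2))
        assert n_skipped == 1
        assert tuple(sums[0]) == (1.0, 0.0)


class TestJackknife:
    def test_symmetric_blocks_flagged(self):
        sums = np.tile([5.0, 5.0], (30, 1))
        r = d_with_jackknife(sums)
        assert r.D == 0 and r.Z is None
        assert any("se = 0" in f for f in r.flags)

    def test_all_abba_gives_one(self):
        sums = np.tile([10.0, 0.0], (30, 1))
        r = d_with_jackknife(sums)
        assert r.D == 1.0

    def test_no_informative_sites(self):
        r = d_with_jackknife(np.zeros((30, 2)))
        assert r.D is None and "no informative sites" in r.flags

    def test_min_block_flag(self):
        sums = np.tile([3.0, 1.0], (5, 1))
        r = d_with_jackknife(sums, min_blocks=20)
        assert any("non-empty blocks" in f for f in r.flags)

    def test_antisymmetry_and_duplicate_invariance(self):
        """Swapping P1 and P2 negates D; duplicating a group member leaves
        D unchanged."""
        net = SpeciesNetwork.from_newick("(((P1:1,P2:1):0.5,P3:1.5):8.5,O:10);")
        cfg = SimConfig(n_loci=400, theta=3.0, seed=17)
        gts = simulate_gene_trees(net, cfg)
        m = simulate_snp_matrix(gts, cfg, outgroup="O")
        ws = partition_windows(m, "bp", cfg.window_layout[1])

        def d_of(p1, p2, p3):
            t = FourTaxonTest(p1, p2, p3, "O")
            sums, _, _ = pattern_sums(m, t, ws)
            return d_with_jackknife(sums, t).D

        d12 = d_of(["P1"], ["P2"], ["P3"])
        d21 = d_of(["P2"], ["P1"], ["P3"])
        assert d12 == pytest.approx(-d21)

        m2 = GenotypeMatrix(
            taxa=m.taxa + ["P2b"],
            chrom=m.chrom, pos=m.pos,
            counts=np.vstack([m.counts, m.counts[m.taxa.index("P2")]]),
            ploidy=np.ones(m.n_taxa + 1, dtype=int),
            polarized=True,
        )
        t_dup = FourTaxonTest(["P1"], ["P2", "P2b"], ["P3"], "O")
        sums, _, _ = pattern_sums(m2, t_dup, ws)
        assert d_with_jackknife(sums, t_dup).D == pytest.approx(d12)

    def test_null_z_calibration(self):
        """Under ILS alone, mean D ~ 0 and Z rarely exceeds 3."""
        net = SpeciesNetwork.from_newick("(((P1:1,P2:1):0.5,P3:1.5):8.5,O:10);")
        ds, zs = [], []
        for rep in range(25):
            cfg = SimConfig(n_loci=800, theta=3.0, seed=900 + rep)
            gts = simulate_gene_trees(net, cfg)
            m = simulate_snp_matrix(gts, cfg, outgroup="O")
            ws = partition_windows(m, "bp", cfg.window_layout[1])
            sums, _, _ = pattern_sums(m, FourTaxonTest(["P1"], ["P2"], ["P3"], "O"), ws)
            r = d_with_jackknife(sums)
            ds.append(r.D)
            zs.append(r.Z)
        mean = np.mean(ds)
        se = np.std(ds, ddof=1) / math.sqrt(len(ds))
        assert abs(mean) < 3 * se + 1e-9
        assert sum(abs(z) >= 3 for z in zs) <= 2


META5 = [Taxon(x) for x in "abcd"] + [Taxon("OUT", role="outgroup")]


class TestEnumerateTests:
    def test_balanced_four_ingroup(self):
        stree = parse_newick("(((a:1,b:1):1,(c:1,d:1):1):1,OUT:3);")
        tests, excluded = enumerate_tests(stree, "species", META5, "OUT")
        got = {(tuple(sorted(("".join(t.p1), "".join(t.p2)))), "".join(t.p3))
               for t in tests}
        assert got == {(("a", "b"), "c"), (("a", "b"), "d"),
                       (("c", "d"), "a"), (("c", "d"), "b")}
        assert excluded == []

    def test_caterpillar_matches_quartet_oracle(self):
        meta = [Taxon(x) for x in "abcde"] + [Taxon("OUT", role="outgroup")]
        stree = parse_newick(
            "(((((a:1,b:1):1,c:2):1,d:3):1,e:4):1,OUT:5);")
        tests, _ = enumerate_tests(stree, "species", meta, "OUT")
        got = {(tuple(sorted(("".join(t.p1), "".join(t.p2)))), "".join(t.p3))
               for t in tests}
        # oracle: a triple is valid iff the species tree restricted to
        # (A, B, C, OUT) puts A and B sister
        expected = set()
        for a, b in itertools.combinations("abcde", 2):
            for c in "abcde":
                if c in (a, b):
                    continue
                q = induced_quartet(stree, (a, b, c, "OUT"))
                if (a, b) in (tuple(sorted(p)) for p in q.pairs()):
                    expected.add(((a, b), c))
        assert got == expected
        assert len(got) == 10

    def test_non_monophyletic_group_excluded(self):
        meta = [
            Taxon("a", group_labels={"section": "S1"}),
            Taxon("b", group_labels={"section": "S2"}),
            Taxon("c", group_labels={"section": "S1"}),
            Taxon("d", group_labels={"section": "S3"}),
            Taxon("OUT", role="outgroup"),
        ]
        stree = parse_newick("(((a:1,b:1):1,(c:1,d:1):1):1,OUT:3);")
        tests, excluded = enumerate_tests(stree, "section", meta, "OUT")
        assert excluded == ["S1"]  # a+c not monophyletic
        assert tests == []  # only two usable units remain, no outward C

    def test_missing_level_label_error(self):
        meta = [Taxon("a"), Taxon("b"), Taxon("OUT", role="outgroup")]
        stree = parse_newick("((a:1,b:1):1,OUT:2);")
        with pytest.raises(ValueError, match="lacks"):
            enumerate_tests(stree, "subgenus", meta, "OUT")


class TestScan:
    def test_empty_test_list(self):
        m = _matrix(np.zeros((4, 5)))
        df, results = dstat_scan(m, [], _one_block(5))
        assert len(df) == 0 and results == []

    def test_planted_hybrid_tops_scan(self):
        """With one planted pulse, the implicated pair gives the top |Z|
        and the correct direction."""
        from fignet.simulate import HybridEdge

        nwk = "((((a:1,b:1):1,c:2):1,d:3):7,OUT:10);"
        net = SpeciesNetwork.from_newick(
            nwk, [HybridEdge(frozenset(["d"]), frozenset(["c"]), 1.0, 0.3)])
        cfg = SimConfig(n_loci=1500, theta=3.0, seed=23)
        gts = simulate_gene_trees(net, cfg)
        m = simulate_snp_matrix(gts, cfg, outgroup="OUT")
        ws = partition_windows(m, "bp", cfg.window_layout[1])
        stree = parse_newick(nwk)
        tests, _ = enumerate_tests(stree, "species", META5, "OUT")
        df, _ = dstat_scan(m, tests, ws)
        top = df.iloc[0]
        assert top["significant"]
        assert set(top["direction"].split("<->")) == {"c", "d"}

    def test_fdr_mode_adds_q(self):
        m = _matrix(np.array([[0, 1], [1, 0], [1, 1], [0, 0]]))
        df, _ = dstat_scan(m, [TEST], _one_block(2), fdr_mode=True,
                           min_blocks=1)
        assert "q_value" in df.columns
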