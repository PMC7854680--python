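import numpy as np
import pytest

from fignet.simulate import SimConfig, SpeciesNetwork, simulate_gene_trees, \
    simulate_snp_matrix
from fignet.treecore import Taxon, rf_distance
from fignet.windows import (GenomicWindow, GenotypeMatrix, WindowSet,
                            filter_sites, filter_windows, partition_windows,
                            read_vcf, window_distances, window_tree, write_vcf)

TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\tI2\tI3\tOG
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\t0/1\t0/0
chr1\t200\t.\tA\tAT\t.\tPASS\t.\tGT\t0/0\t1/1\t0/0\t0/0
chr1\t300\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t1/1\t2/2\t0/0
chr1\t400\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/0\t1/1\t0/1
chr1\t500\t.\tG\tC\t.\tPASS\t.\tGT\t0/0\t1/1\t1/1\t1/1
"""

META = [Taxon("I1"), Taxon("I2"), Taxon("I3"), Taxon("OG", role="outgroup")]


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


class TestReadVCF:
    def test_indel_and_multiallelic_dropped(self, toy_vcf):
        m, report = read_vcf(toy_vcf, META)
        assert m.n_sites == 3
        assert report["n_indel"] == 1 and report["n_multiallelic"] == 1
        assert list(m.pos) == [100, 400, 500]

    def test_polarization_drops_het_outgroup_and_flips(self, toy_vcf):
        m, report = read_vcf(toy_vcf, META, polarize_on_outgroup=True)
        # site 400 dropped (outgroup 0/1); site 500 flipped (outgroup 1/1)
        assert list(m.pos) == [100, 500]
        assert report["n_outgroup_unusable"] == 1
        og = m.taxa.index("OG")
        assert np.all(m.counts[og] == 0)
        i1 = m.taxa.index("I1")
        assert m.counts[i1, 1] == 2  # 0/0 against an ALT-bearing outgroup

    def test_missing_sample_error(self, toy_vcf):
        with pytest.raises(ValueError, match="absent"):
            read_vcf(toy_vcf, META + [Taxon("ghost")])

    def test_simulator_roundtrip(self, tmp_path):
        net = SpeciesNetwork.from_newick("(((P1:1,P2:1):1,P3:2):8,O:10);")
        cfg = SimConfig(n_loci=50, theta=2.0, seed=6, missing_rate=0.1)
        gts = simulate_gene_trees(net, cfg)
        m = simulate_snp_matrix(gts, cfg, outgroup="O")
        path = tmp_path / "sim.vcf"
        write_vcf(m, path)
        meta = [Taxon(t, role="outgroup" if t == "O" else "ingroup")
                for t in m.taxa]
        back, _ = read_vcf(path, meta)
        assert back.taxa == m.taxa
        assert np.array_equal(back.counts, m.counts)
        assert np.array_equal(back.pos, m.pos)


def _matrix(n_taxa, n_sites, missing=(), pos=None, chrom=None):
    counts = np.zeros((n_taxa, n_sites), dtype=np.int8)
    for (t, s) in missing:
        counts[t, s] = -1
    return GenotypeMatrix(
        taxa=[f"T{i}" for i in range(n_taxa)],
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_sites),
        pos=np.array(pos if pos is not None else np.arange(1, n_sites + 1)),
        counts=counts,
        ploidy=np.ones(n_taxa, dtype=int),
        polarized=True,
    )


class TestFilterSites:
    def test_forty_percent_rule(self):
        # 17 taxa: 7 missing = 41.2% (dropped), 6 missing = 35.3% (kept)
        m = _matrix(17, 2, missing=[(i, 0) for i in range(7)]
                    + [(i, 1) for i in range(6)])
        out = filter_sites(m, 0.4)
        assert list(out.pos) == [2]

    def test_max_missing_one_is_identity(self):
        m = _matrix(5, 10, missing=[(0, i) for i in range(10)])
        assert filter_sites(m, 1.0).n_sites == 10

    def test_idempotent_and_matches_bruteforce(self, rng):
        counts = (rng.random((10, 1000)) < 0.3).astype(np.int8)
        counts[rng.random((10, 1000)) < 0.35] = -1
        m = _matrix(10, 1000)
        m.counts = counts
        once = filter_sites(m, 0.4)
        twice = filter_sites(once, 0.4)
        assert np.array_equal(once.counts, twice.counts)
        expected = [s for s in range(1000)
                    if (counts[:, s] == -1).sum() / 10 <= 0.4]
        assert list(once.pos) == [s + 1 for s in expected]


class TestPartitionWindows:
    def test_bp_mode_example(self):
        pos = np.concatenate([np.arange(1, 2500) * 100, [250000]])
        m = _matrix(4, len(pos), pos=pos)
        ws = partition_windows(m, "bp", 100000)
        assert [(w.start, w.end) for w in ws] == [
            (1, 100000), (100001, 200000), (200001, 250000)]

    def test_snp_mode_example(self):
        m = _matrix(4, 2500)
        ws = partition_windows(m, "snp", 1000, step=1100)
        assert [(w.start, w.end, w.n_snps) for w in ws] == [
            (1, 1000, 1000), (1101, 2100, 1000), (2201, 2500, 300)]

    def test_bp_partition_property(self, rng):
        pos = np.sort(rng.choice(50000, size=800, replace=False) + 1)
        m = _matrix(4, 800, pos=pos)
        ws = partition_windows(m, "bp", 7000)
        all_sites = np.concatenate([w.sites for w in ws])
        assert sorted(all_sites) == list(range(800))
        assert len(set(all_sites)) == 800

    def test_snp_gap_is_step_minus_size(self):
        m = _matrix(4, 5000)
        ws = partition_windows(m, "snp", 1000, step=1100)
        for a, b in zip(ws.windows, ws.windows[1:]):
            assert b.start - a.end - 1 == 100

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            partition_windows(_matrix(4, 10), "furlongs", 10)


class TestFilterWindows:
    def test_min_snp_boundary(self):
        w49 = GenomicWindow("chr1", 1, 49, np.arange(49))
        w50 = GenomicWindow("chr1", 50, 100, np.arange(49, 99))
        ws = WindowSet([w49, w50], "snp", 50)
        kept = filter_windows(ws, 50)
        assert [(w.start, w.end) for w in kept] == [(50, 100)]

    def test_zero_is_identity_and_idempotent(self):
        ws = WindowSet([GenomicWindow("c", 1, 10, np.arange(3))], "bp", 10)
        assert len(filter_windows(ws, 0)) == 1
        assert len(filter_windows(filter_windows(ws, 2), 2)) == 1


class TestWindowTree:
    def test_identical_taxa_zero_distance(self):
        m = _matrix(5, 40)
        m.counts[0] = m.counts[1] = (np.arange(40) % 2).astype(np.int8)
        w = GenomicWindow("chr1", 1, 40, np.arange(40))
        dist, kept = window_distances(m, w)
        i, j = kept.index("T0"), kept.index("T1")
        assert dist[i, j] == 0.0

    def test_recovers_generating_topology(self):
        """Windows whose generating gene tree left >= 3 site patterns on
        every internal clade (theta x branch well above 5) are resolved to
        the generating topology by JC+NJ nearly always."""
        net = SpeciesNetwork.from_newick(
            "((((A:2,B:2):2,C:4):2,D:6):6,O:12);")
        cfg = SimConfig(n_loci=60, theta=8.0, seed=10)
        gts = simulate_gene_trees(net, cfg)
        m = simulate_snp_matrix(gts, cfg, outgroup="O")
        ws = partition_windows(m, "bp", cfg.window_layout[1])
        index = {t: i for i, t in enumerate(m.taxa)}
        hits = usable = 0
        for w, gt in zip(ws, gts):
            gt.compute_masks(index)
            site_masks = [
                sum(1 << ti for ti in range(m.n_taxa) if m.counts[ti, s] == 1)
                for s in w.sites
            ]
            informative = True
            for node in gt.postorder():
                if node is gt.root or node.is_leaf:
                    continue
                if 1 << index["O"] & node._mask:
                    continue  # outgroup-side edges carry no polarized signal
                if site_masks.count(node._mask) < 3:
                    informative = False
            if not informative:
                continue
            usable += 1
            t = window_tree(m, w, outgroup="O")
            if t is not None and rf_distance(t, gt) == 0:
                hits += 1
        assert usable >= 30
        assert hits >= 0.95 * usable

    def test_all_missing_taxon_dropped(self):
        m = _matrix(6, 30)
        m.counts[np.arange(1, 6)[:, None], np.arange(30)[None, :] % 30] = \
            (np.arange(30) % 2).astype(np.int8)
        m.counts[2, :] = -1
        w = GenomicWindow("chr1", 1, 30, np.arange(30))
        dist, kept = window_distances(m, w)
        assert "T2" not in kept
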