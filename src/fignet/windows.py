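"""Genotype ingestion, site filtering, genomic windows, and window trees.

The window machinery mirrors a standard resequencing workflow: biallelic
SNPs are read from VCF, sites with too much missingness are dropped
(default: at most 40% missing per site), the genome is cut into
non-overlapping base-pair windows or fixed-SNP-count windows, windows with
fewer than 50 SNPs are discarded, and a tree is estimated per window from
Jukes-Cantor-corrected allele-sharing distances with neighbor joining.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .treecore import RootedTree, Taxon, parse_newick, root_on_outgroup

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Taxa x biallelic-site derived-allele counts.

    ``counts[t, s]`` is the derived (or ALT, if unpolarized) allele count of
    taxon ``t`` at site ``s`` in {0..ploidy[t]}, or -1 for missing.
    Positions are 1-based and strictly increasing within each chromosome.
    """

    taxa: list
    chrom: np.ndarray
    pos: np.ndarray
    counts: np.ndarray
    ploidy: np.ndarray
    polarized: bool = False
    outgroup: Optional[str] = None

    def __post_init__(self):
        self.taxa = [t.id if isinstance(t, Taxon) else t for t in self.taxa]
        if self.counts.shape != (len(self.taxa), len(self.pos)):
            raise ValueError("counts shape mismatch")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        over = (self.counts > self.ploidy[:, None]) & (self.counts != MISSING)
        if np.any(over):
            raise ValueError("derived count exceeds ploidy")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxon_index(self, name: str) -> int:
        return self.taxa.index(name)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return (self.counts == MISSING).mean(axis=0)

    def freqs(self) -> np.ndarray:
        """Per-taxon derived-allele frequency per site; NaN when missing."""
        f = self.counts.astype(float)
        f[self.counts == MISSING] = np.nan
        return f / self.ploidy[:, None]

    def take_sites(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            taxa=list(self.taxa),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            counts=self.counts[:, idx],
            ploidy=self.ploidy.copy(),
            polarized=self.polarized,
            outgroup=self.outgroup,
        )


@dataclass
class GenomicWindow:
    chrom: str
    start: int  # 1-based inclusive (bp mode) or first SNP ordinal (snp mode)
    end: int    # 1-based inclusive
    sites: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_snps(self) -> int:
        return len(self.sites)


@dataclass
class WindowSet:
    windows: list
    mode: str  # "bp" | "snp"
    size: int
    step: Optional[int] = None

    def __len__(self):
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i):
        return self.windows[i]

    def site_to_window(self, n_sites: int) -> np.ndarray:
        """Array mapping site index -> window index (-1 if unassigned)."""
        out = np.full(n_sites, -1, dtype=int)
        for wi, w in enumerate(self.windows):
            out[w.sites] = wi
        return out

    def write_bed(self, path):
        """BED-like TSV: chrom, start0 (0-based half-open), end, n_snps."""
        with open(path, "w") as fh:
            fh.write("chrom\tstart0\tend\tn_snps\n")
            for w in self.windows:
                fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\t{w.n_snps}\n")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def write_vcf(m: GenotypeMatrix, path, ref: str = "A", alt: str = "T") -> None:
    """Write a minimal VCF 4.2 (CHROM/POS/REF/ALT/GT).

    Haploid taxa get single-allele GT fields; synthetic REF/ALT bases are
    constant since the matrix only tracks biallelic 0/1 states.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(np.asarray(m.chrom).tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.taxa) + "\n")
        for s in range(m.n_sites):
            gts = []
            for t in range(m.n_taxa):
                cnt = m.counts[t, s]
                pl = m.ploidy[t]
                if cnt == MISSING:
                    gts.append("/".join(["."] * pl))
                else:
                    alleles = ["1"] * int(cnt) + ["0"] * int(pl - cnt)
                    gts.append("/".join(alleles))
            fh.write(
                f"{m.chrom[s]}\t{m.pos[s]}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf(path, metadata: Sequence[Taxon], polarize_on_outgroup: bool = False):
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and indel records are dropped (counted in the returned
    report).  With ``polarize_on_outgroup``, sites where the outgroup
    genotype is missing or heterozygous are dropped, and alleles are recoded
    so the outgroup carries the ancestral (count 0) state.

    Returns ``(matrix, report_dict)``.
    """
    import pysam

    taxa = [t.id for t in metadata]
    outgroups = [t.id for t in metadata if t.role == "outgroup"]
    if polarize_on_outgroup and not outgroups:
        raise ValueError("polarization requested but no outgroup in metadata")
    outgroup = outgroups[0] if outgroups else None

    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    missing_samples = [t for t in taxa if t not in vcf_samples]
    if missing_samples:
        raise ValueError(f"samples absent from VCF: {missing_samples}")

    report = {"n_multiallelic": 0, "n_indel": 0, "n_outgroup_unusable": 0,
              "n_kept": 0}
    chroms, positions, cols = [], [], []
    ploidy = None
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            report["n_multiallelic"] += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            report["n_indel"] += 1
            continue
        col = np.full(len(taxa), MISSING, dtype=np.int8)
        pl = np.ones(len(taxa), dtype=int)
        for i, t in enumerate(taxa):
            alleles = rec.samples[t]["GT"]
            if alleles is None:
                alleles = (None,)
            alleles = tuple(a for a in alleles)
            pl[i] = max(1, len(alleles))
            if any(a is None for a in alleles):
                col[i] = MISSING
            else:
                col[i] = sum(alleles)
        if polarize_on_outgroup:
            oi = taxa.index(outgroup)
            oc = col[oi]
            if oc == MISSING or (0 < oc < pl[oi]):
                report["n_outgroup_unusable"] += 1
                continue
            if oc == pl[oi]:  # outgroup carries ALT: flip so outgroup is ancestral
                ok = col != MISSING
                col[ok] = pl[ok] - col[ok]
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        cols.append(col)
        if ploidy is None:
            ploidy = pl
        report["n_kept"] += 1
    vf.close()
    if not cols:
        raise ValueError("zero sites survived VCF filters")
    m = GenotypeMatrix(
        taxa=taxa,
        chrom=np.array(chroms),
        pos=np.array(positions, dtype=np.int64),
        counts=np.column_stack(cols),
        ploidy=ploidy,
        polarized=polarize_on_outgroup,
        outgroup=outgroup,
    )
    return m, report


# ---------------------------------------------------------------------------
# Filters and windows
# ---------------------------------------------------------------------------

def filter_sites(m: GenotypeMatrix, max_missing: float = 0.4) -> GenotypeMatrix:
    """Drop sites whose missing fraction across all samples exceeds
    ``max_missing`` (default 40%); order preserved."""
    keep = m.missing_fraction() <= max_missing
    return m.take_sites(np.flatnonzero(keep))


def partition_windows(m: GenotypeMatrix, mode: str, size: int,
                      step: Optional[int] = None) -> WindowSet:
    """Cut sites into genomic windows.

    bp mode: per chromosome, non-overlapping windows [1, size],
    [size+1, 2*size], ... with the last window truncated at the final SNP
    position.  snp mode: window k covers SNP ordinals
    [k*step+1, k*step+size] within each chromosome (step >= size leaves a
    gap of step-size ordinals); the trailing partial window is retained and
    left to the downstream minimum-SNP filter.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    windows = []
    chrom_order = list(dict.fromkeys(np.asarray(m.chrom).tolist()))
    if mode == "bp":
        for c in chrom_order:
            idx = np.flatnonzero(m.chrom == c)
            pos = m.pos[idx]
            chrom_end = int(pos.max())
            n_win = -(-chrom_end // size)
            for k in range(n_win):
                lo, hi = k * size + 1, (k + 1) * size
                hi_eff = min(hi, chrom_end)
                sel = idx[(pos >= lo) & (pos <= hi)]
                windows.append(GenomicWindow(c, lo, hi_eff, sel))
    elif mode == "snp":
        if step is None:
            step = size
        if step < size:
            raise ValueError("snp mode requires step >= size")
        for c in chrom_order:
            idx = np.flatnonzero(m.chrom == c)
            n = len(idx)
            k = 0
            while k * step < n:
                lo = k * step        # 0-based start ordinal
                hi = min(lo + size, n)
                windows.append(GenomicWindow(c, lo + 1, hi, idx[lo:hi]))
                k += 1
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    return WindowSet(windows, mode, size, step)


def filter_windows(ws: WindowSet, min_snps: int = 50) -> WindowSet:
    """Keep only windows with at least ``min_snps`` SNPs (default 50)."""
    kept = [w for w in ws.windows if w.n_snps >= min_snps]
    return WindowSet(kept, ws.mode, ws.size, ws.step)


# ---------------------------------------------------------------------------
# Per-window distance trees
# ---------------------------------------------------------------------------

def _jc_correct(p: np.ndarray) -> np.ndarray:
    """Jukes-Cantor distance from raw mismatch fraction, capped near the
    p=3/4 saturation point."""
    p = np.minimum(p, 0.74999)
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def window_distances(m: GenotypeMatrix, w: GenomicWindow,
                     min_shared_sites: int = 10):
    """Pairwise JC-corrected allele-sharing distances in one window.

    Returns ``(dist, kept_taxa)``: taxa with no usable data, or with too few
    pairwise-complete sites against the rest, are dropped.
    """
    f = m.freqs()[:, w.sites]
    obs = ~np.isnan(f)
    # pairwise-complete counts and raw mean absolute frequency differences
    shared = obs.astype(float) @ obs.T.astype(float)
    fz = np.nan_to_num(f)
    # sum over shared sites of |f_i - f_j| computed via masked expansion
    n_t = f.shape[0]
    raw = np.zeros((n_t, n_t))
    for i in range(n_t):
        diff = np.abs(fz[i] - fz)          # uses zeros at missing, fixed below
        valid = obs[i] & obs
        diff[~valid] = 0.0
        raw[i] = diff.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(shared > 0, raw / np.maximum(shared, 1), np.nan)
    p[shared < min_shared_sites] = np.nan
    np.fill_diagonal(p, 0.0)
    # iteratively drop the taxon with the most undefined pairs
    keep = list(range(n_t))
    while True:
        sub = p[np.ix_(keep, keep)]
        bad = np.isnan(sub).sum(axis=1)
        if bad.max(initial=0) == 0:
            break
        keep.pop(int(bad.argmax()))
        if len(keep) < 4:
            break
    sub = p[np.ix_(keep, keep)]
    dist = _jc_correct(sub)
    np.fill_diagonal(dist, 0.0)
    return dist, [m.taxa[i] for i in keep]


def window_tree(m: GenotypeMatrix, w: GenomicWindow, outgroup: str,
                min_shared_sites: int = 10) -> Optional[RootedTree]:
    """Neighbor-joining tree of one window, rooted on the outgroup.

    Negative NJ branch lengths are clamped to zero.  Returns None when fewer
    than four taxa have usable data in the window.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dist, kept = window_distances(m, w, min_shared_sites=min_shared_sites)
    if len(kept) < 4 or outgroup not in kept:
        return None
    dm = DistanceMatrix(dist, ids=kept)
    sk_tree = nj(dm)
    buf = io.StringIO()
    sk_tree.write(buf, format="newick")
    tree = parse_newick(buf.getvalue(), length_units="subst")
    for node in tree.postorder():
        if node.length < 0:
            node.length = 0.0
    return root_on_outgroup(tree, outgroup)


def window_trees(m: GenotypeMatrix, ws: WindowSet, outgroup: str):
    """Window trees for a whole WindowSet; skipped windows reported.

    Returns ``(GeneTreeSet, skipped_indices)``.
    """
    from .treecore import GeneTreeSet

    trees, skipped = [], []
    for i, w in enumerate(ws):
        t = window_tree(m, w, outgroup)
        if t is None:
            skipped.append(i)
        else:
            trees.append(t)
    return GeneTreeSet(trees, taxa=list(m.taxa)), skipped
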