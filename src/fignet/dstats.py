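"""ABBA-BABA D-statistics with weighted block-jackknife significance.

For four taxa (((P1,P2),P3),O) with the outgroup fixed ancestral, ABBA
sites (P2 and P3 share the derived allele) and BABA sites (P1 and P3 share
it) are equally frequent under incomplete lineage sorting alone, so
D = (ABBA - BABA)/(ABBA + BABA) has expectation zero; significantly
positive D indicates gene flow between P2 and P3, negative between P1 and
P3.  Groups of several taxa enter through their derived-allele frequencies
(each member species acting as a sample replication), and the standard
error comes from a weighted delete-one jackknife over genomic windows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .treecore import RootedTree
from .windows import GenotypeMatrix, WindowSet

__all__ = [
    "FourTaxonTest",
    "DStatResult",
    "pattern_sums",
    "d_with_jackknife",
    "enumerate_tests",
    "dstat_scan",
]


@dataclass(frozen=True)
class FourTaxonTest:
    """A topology-concordant test ((P1,P2),P3) with outgroup O.

    Each of P1..P3 is a *group* of taxa (a frozenset) at some grouping level;
    the species-tree topology must place P1 and P2 closer to each other than
    either is to P3.
    """

    p1: frozenset
    p2: frozenset
    p3: frozenset
    outgroup: str
    level: str = "species"
    labels: tuple = ("P1", "P2", "P3")

    def __post_init__(self):
        sets = [frozenset(self.p1), frozenset(self.p2), frozenset(self.p3)]
        object.__setattr__(self, "p1", sets[0])
        object.__setattr__(self, "p2", sets[1])
        object.__setattr__(self, "p3", sets[2])
        for a, b in itertools.combinations(sets, 2):
            if a & b:
                raise ValueError("test groups must be disjoint")


@dataclass
class DStatResult:
    test: FourTaxonTest
    sum_abba: float
    sum_baba: float
    D: Optional[float]
    se: Optional[float]
    Z: Optional[float]
    n_blocks: int
    n_sites_used: int
    significant: bool
    direction: Optional[tuple]  # (donor-side pair of group labels)
    flags: list = field(default_factory=list)


def pattern_sums(m: GenotypeMatrix, test: FourTaxonTest, blocks: WindowSet):
    """Per-block (ABBA, BABA) frequency sums.

    Per site, group derived frequencies p1, p2, p3 are means over
    non-missing members; with the outgroup fixed ancestral,
    abba = (1-p1) p2 p3 and baba = p1 (1-p2) p3.  Sites with any group
    fully missing are skipped.

    Returns ``(block_sums, n_sites_used, n_skipped)`` with ``block_sums`` of
    shape (n_blocks, 2).
    """
    if not m.polarized:
        raise ValueError("matrix must be outgroup-polarized for D-statistics")
    if len(blocks) == 0:
        raise ValueError("empty block set")
    freqs = m.freqs()

    def group_freq(group):
        rows = [m.taxon_index(t) for t in sorted(group)]
        sub = freqs[rows]
        obs = ~np.isnan(sub)
        n = obs.sum(axis=0)
        total = np.where(obs, sub, 0.0).sum(axis=0)
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)

    p1 = group_freq(test.p1)
    p2 = group_freq(test.p2)
    p3 = group_freq(test.p3)
    usable = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3))
    abba = np.where(usable, (1 - p1) * p2 * p3, 0.0)
    baba = np.where(usable, p1 * (1 - p2) * p3, 0.0)
    site_block = blocks.site_to_window(m.n_sites)
    n_blocks = len(blocks)
    in_block = site_block >= 0
    sums = np.zeros((n_blocks, 2))
    sel = usable & in_block
    np.add.at(sums[:, 0], site_block[sel], abba[sel])
    np.add.at(sums[:, 1], site_block[sel], baba[sel])
    n_used = int(np.count_nonzero(sel & ((abba > 0) | (baba > 0))))
    n_skipped = int(np.count_nonzero(~usable))
    return sums, n_used, n_skipped


def d_from_sums(sum_abba: float, sum_baba: float) -> Optional[float]:
    denom = sum_abba + sum_baba
    if denom <= 0:
        return None
    return (sum_abba - sum_baba) / denom


def d_with_jackknife(block_sums: np.ndarray, test: Optional[FourTaxonTest] = None,
                     z_crit: float = 3.0, min_blocks: int = 20,
                     n_sites_used: int = 0) -> DStatResult:
    """D, weighted delete-one block-jackknife SE, and Z = D/SE.

    Block weights are proportional to informative mass (abba+baba per
    block); the weighted jackknife follows Busing et al.'s formulation so
    unequal windows are handled correctly.
    """
    block_sums = np.asarray(block_sums, dtype=float)
    mass = block_sums.sum(axis=1)
    nonempty = mass > 0
    g = int(nonempty.sum())
    flags = []
    if g < min_blocks:
        flags.append(f"only {g} non-empty blocks (< {min_blocks})")
    tot_abba, tot_baba = block_sums.sum(axis=0)
    D = d_from_sums(tot_abba, tot_baba)
    if D is None:
        return DStatResult(test, tot_abba, tot_baba, None, None, None, g,
                           n_sites_used, False, None, flags + ["no informative sites"])
    bs = block_sums[nonempty]
    mj = mass[nonempty]
    m_tot = mj.sum()
    theta_del = np.array([
        d_from_sums(tot_abba - a, tot_baba - b) for a, b in bs
    ], dtype=float)
    hj = m_tot / mj
    theta_jack = g * D - ((1 - mj / m_tot) * theta_del).sum()
    tau = hj * D - (hj - 1) * theta_del
    var = np.sum((tau - theta_jack) ** 2 / (hj - 1)) / g
    se = float(np.sqrt(var))
    if se == 0:
        flags.append("se = 0 (all blocks identical); Z undefined")
        Z = None
        significant = False
    else:
        Z = float(D / se)
        significant = abs(Z) >= z_crit
    if test is not None:
        direction = ("P2", "P3") if D > 0 else ("P1", "P3")
    else:
        direction = None
    return DStatResult(test, float(tot_abba), float(tot_baba), float(D), se, Z,
                       g, n_sites_used, significant, direction, flags)


# ---------------------------------------------------------------------------
# Test enumeration on the species tree
# ---------------------------------------------------------------------------

def _group_map(metadata, level: str) -> dict:
    """group label -> frozenset of ingroup taxon ids at the given level."""
    groups: dict[str, set] = {}
    for t in metadata:
        if t.role != "ingroup":
            continue
        if level == "species":
            label = t.group_labels.get("species", t.id)
        else:
            label = t.group_labels.get(level)
            if label is None:
                raise ValueError(f"taxon {t.id} lacks a {level!r} label")
        groups.setdefault(label, set()).add(t.id)
    return {k: frozenset(v) for k, v in groups.items()}


def monophyletic_groups(stree: RootedTree, groups: dict) -> tuple:
    """Split groups into (monophyletic, excluded) under the species tree."""
    leaf_set = set(stree.leaf_names())
    index = stree.leaf_index()
    stree.compute_masks(index)
    clade_masks = {n._mask for n in stree.postorder()}
    mono, excluded = {}, []
    for label, members in groups.items():
        if not members <= leaf_set:
            excluded.append(label)
            continue
        m = 0
        for t in members:
            m |= 1 << index[t]
        if m in clade_masks:
            mono[label] = members
        else:
            excluded.append(label)
    return mono, excluded


def enumerate_tests(stree: RootedTree, level: str, metadata,
                    outgroup: str) -> tuple:
    """All four-taxon tests concordant with the species-tree topology.

    At the chosen level, each monophyletic group becomes a unit; a test
    ((A,B),C) is emitted for every unordered unit pair {A,B} and outward
    unit C such that the species tree places A and B closer to each other
    than to C (MRCA(A,B) strictly below MRCA(A,B,C)).  Non-monophyletic
    groups are excluded and reported.

    Returns ``(tests, excluded_group_labels)``.
    """
    groups = _group_map(metadata, level)
    ingroup_tree = stree
    if outgroup in set(stree.leaf_names()):
        ingroup_tree = _drop_leaf(stree, outgroup)
    mono, excluded = monophyletic_groups(ingroup_tree, groups)
    index = ingroup_tree.leaf_index()
    ingroup_tree.compute_masks(index)
    unit_mask = {}
    for label, members in mono.items():
        m = 0
        for t in members:
            m |= 1 << index[t]
        unit_mask[label] = m
    # mrca masks via smallest clade containing a mask
    clades = sorted((n._mask for n in ingroup_tree.postorder() if not n.is_leaf),
                    key=lambda m: bin(m).count("1"))
    node_masks = [n._mask for n in ingroup_tree.postorder()]

    def mrca_mask(m):
        for c in clades:
            if (c & m) == m:
                return c
        return node_masks[-1]

    labels = sorted(mono)
    tests = []
    for a, b in itertools.combinations(labels, 2):
        mab = mrca_mask(unit_mask[a] | unit_mask[b])
        for c in labels:
            if c in (a, b):
                continue
            if unit_mask[c] & mab:
                continue  # C nested inside/overlapping MRCA(A,B): not outward
            tests.append(FourTaxonTest(mono[a], mono[b], mono[c], outgroup,
                                       level=level, labels=(a, b, c)))
    return tests, excluded


def _drop_leaf(tree: RootedTree, name: str) -> RootedTree:
    t = tree.copy()
    leaf = t.find_leaf(name)
    parent = leaf.parent
    parent.children.remove(leaf)
    node = parent
    while node is not None and node.parent is not None and len(node.children) == 1:
        only = node.children[0]
        only.length += node.length
        idx = node.parent.children.index(node)
        node.parent.children[idx] = only
        only.parent = node.parent
        node = node.parent
    root = t.root
    while len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
    return RootedTree(root, t.length_units)


# ---------------------------------------------------------------------------

def dstat_scan(m: GenotypeMatrix, tests: Sequence[FourTaxonTest],
               blocks: WindowSet, z_crit: float = 3.0,
               fdr_mode: bool = False, min_blocks: int = 20):
    """One DStatResult per test, as a table sorted by |Z|.

    With ``fdr_mode`` a Benjamini-Hochberg adjustment across the scan is
    applied to two-sided normal p-values of the Z scores (off by default:
    per-test reporting).
    """
    import pandas as pd
    from scipy import stats

    results = []
    for test in tests:
        sums, n_used, _ = pattern_sums(m, test, blocks)
        results.append(d_with_jackknife(sums, test, z_crit=z_crit,
                                        min_blocks=min_blocks,
                                        n_sites_used=n_used))
    rows = []
    for r in results:
        lbl = r.test.labels if r.test else ("P1", "P2", "P3")
        direction = None
        if r.direction is not None:
            pair = {"P1": lbl[0], "P2": lbl[1], "P3": lbl[2]}
            direction = f"{pair[r.direction[0]]}<->{pair[r.direction[1]]}"
        rows.append({
            "level": r.test.level if r.test else "",
            "P1": lbl[0], "P2": lbl[1], "P3": lbl[2],
            "O": r.test.outgroup if r.test else "",
            "nABBA": r.sum_abba, "nBABA": r.sum_baba,
            "D": r.D, "se": r.se, "Z": r.Z,
            "n_blocks": r.n_blocks,
            "significant": r.significant,
            "direction": direction,
        })
    df = pd.DataFrame(rows, columns=["level", "P1", "P2", "P3", "O", "nABBA",
                                     "nBABA", "D", "se", "Z", "n_blocks",
                                     "significant", "direction"])
    if fdr_mode and len(df):
        z = df["Z"].to_numpy(dtype=float)
        p = 2 * stats.norm.sf(np.abs(np.nan_to_num(z)))
        p[np.isnan(z)] = 1.0
        order = np.argsort(p)
        q = np.empty_like(p)
        prev = 1.0
        n = len(p)
        for rank_from_end, i in enumerate(order[::-1]):
            rank = n - rank_from_end
            prev = min(prev, p[i] * n / rank)
            q[i] = prev
        df["q_value"] = q
        df["significant"] = (q < 0.05) & df["Z"].notna()
    df = df.sort_values("Z", key=lambda s: s.abs(), ascending=False,
                        na_position="last").reset_index(drop=True)
    return df, results
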