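"""Greedy-consensus species tree with clade concordance factors.

A clade's concordance factor (CF) is the fraction of window/gene trees
supporting it.  The species tree is assembled greedily: clades are sorted
by CF and added whenever compatible with everything already accepted — the
primary-concordance-tree logic.  Uncertainty on each CF comes from a
nonparametric bootstrap over gene trees (a stand-in for Bayesian
concordance credibility intervals that keeps the same non-overlap logic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .treecore import GeneTreeSet, Node, RootedTree

__all__ = [
    "ConcordanceRow",
    "ConcordanceTable",
    "SpeciesTreeEstimate",
    "clade_frequencies",
    "greedy_consensus",
    "bootstrap_cf",
]


@dataclass
class ConcordanceRow:
    clade: frozenset          # the side of the split away from the reference
    cf: float
    n_support: int
    n_total: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass
class ConcordanceTable:
    rows: list
    taxa: list
    reference: str

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def lookup(self, clade) -> Optional[ConcordanceRow]:
        key = self._canon(frozenset(clade))
        for r in self.rows:
            if r.clade == key:
                return r
        return None

    def _canon(self, clade: frozenset) -> frozenset:
        if self.reference in clade:
            return frozenset(self.taxa) - clade
        return clade

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "clade_smaller_side": ",".join(sorted(r.clade)),
                    "cf": r.cf,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "n_support": r.n_support,
                    "n_total": r.n_total,
                }
                for r in self.rows
            ]
        )

    def write_tsv(self, path):
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class SpeciesTreeEstimate:
    tree: RootedTree
    table: ConcordanceTable
    method: str = "greedy_consensus"
    n_input_trees: int = 0
    rejected: list = field(default_factory=list)  # incompatible clades, by cf


# ---------------------------------------------------------------------------

def _tree_sides(gts: GeneTreeSet, index: dict):
    """Per tree: (present-taxa mask, set of observed split sides as masks,
    both orientations)."""
    out = []
    for tree in gts:
        present = 0
        for name in tree.leaf_names():
            present |= 1 << index[name]
        sides = set()
        tree.compute_masks(index)
        for node in tree.postorder():
            if node is tree.root or node.is_leaf:
                continue
            m = node._mask
            sides.add(m)
            sides.add(present & ~m)
        out.append((present, sides))
    return out


def _supports(key: int, full: int, present: int, sides: set) -> tuple:
    """(counts_toward_total, supports) of a full-set bipartition ``key`` by
    one gene tree.

    The tree counts toward the denominator when the bipartition's *smaller*
    side is fully present and the restriction to the tree's taxa is still
    informative; it supports the clade when that restriction appears among
    the tree's splits.
    """
    comp = full & ~key
    smaller = key if bin(key).count("1") <= bin(comp).count("1") else comp
    if (present & smaller) != smaller:
        return False, False
    r = key & present
    r_comp = present & ~r
    if bin(r).count("1") < 2 or bin(r_comp).count("1") < 2:
        return False, False
    return True, (r in sides)


def clade_frequencies(gts: GeneTreeSet, reference: Optional[str] = None) -> ConcordanceTable:
    """Support fraction of every clade observed in at least one gene tree.

    Clades are canonicalized to the split side not containing the reference
    taxon (default: lexicographically smallest; use the outgroup for rooted
    downstream work).  Gene trees with missing taxa count toward a clade
    only when the bipartition's smaller side is fully present (and the
    restricted split is informative); ``n_total`` is therefore per-clade.
    """
    if len(gts) == 0:
        raise ValueError("empty gene-tree set")
    taxa = sorted(gts.taxa)
    if reference is None:
        reference = min(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    full_mask = (1 << n) - 1
    ref_bit = 1 << index[reference]
    tree_sides = _tree_sides(gts, index)
    complete = all(present == full_mask for present, _ in tree_sides)

    # candidate keys: observed sides, canonicalized away from the reference
    keys = set()
    for present, sides in tree_sides:
        for s in sides:
            key = (present & ~s) if (s & ref_bit) else s
            if bin(key).count("1") >= 2 and bin(full_mask & ~key).count("1") >= 2:
                keys.add(key)

    rows = []
    names = {i: t for t, i in index.items()}
    for key in keys:
        if complete:
            n_total = len(tree_sides)
            n_sup = sum(1 for _, sides in tree_sides if key in sides)
        else:
            n_total = n_sup = 0
            for present, sides in tree_sides:
                tot, sup = _supports(key, full_mask, present, sides)
                n_total += tot
                n_sup += sup
        if n_total == 0 or n_sup == 0:
            continue
        clade = frozenset(names[i] for i in range(n) if key >> i & 1)
        rows.append(ConcordanceRow(clade, n_sup / n_total, n_sup, n_total))
    rows.sort(key=lambda r: (-r.cf, tuple(sorted(r.clade))))
    return ConcordanceTable(rows, taxa, reference)


def _compatible(a: frozenset, b: frozenset) -> bool:
    """Rooted-clade compatibility: disjoint or nested."""
    return a.isdisjoint(b) or a <= b or b <= a


def greedy_consensus(table: ConcordanceTable) -> SpeciesTreeEstimate:
    """Primary concordance tree: accept clades by decreasing CF when
    compatible with all previously accepted ones.

    Ties are broken deterministically on the lexicographic canonical form of
    the clade.  The output may be non-binary when accepted clades do not
    fully resolve the tree.
    """
    if not table.rows:
        raise ValueError("empty concordance table")
    accepted: list[ConcordanceRow] = []
    rejected: list[ConcordanceRow] = []
    for row in sorted(table.rows, key=lambda r: (-r.cf, tuple(sorted(r.clade)))):
        if all(_compatible(row.clade, a.clade) for a in accepted):
            accepted.append(row)
        else:
            rejected.append(row)
    tree = _tree_from_clades([r.clade for r in accepted], table.taxa,
                             cfs={frozenset(r.clade): r.cf for r in accepted})
    return SpeciesTreeEstimate(tree=tree, table=table,
                               n_input_trees=max((r.n_total for r in table.rows),
                                                 default=0),
                               rejected=rejected)


def _tree_from_clades(clades: Sequence[frozenset], taxa: Sequence[str],
                      cfs: Optional[dict] = None) -> RootedTree:
    """Build the tree whose internal nodes are the given nested clade set."""
    taxa = sorted(taxa)
    items = sorted(set(map(frozenset, clades)), key=len)
    full = frozenset(taxa)
    nodes: dict[frozenset, Node] = {frozenset([t]): Node(name=t) for t in taxa}
    # assign every clade (and each leaf) to its smallest strict superset
    all_clades = [frozenset([t]) for t in taxa] + items
    if full not in items:
        all_clades.append(full)
        items = items + [full]
    for clade in sorted(set(items), key=len):
        if clade not in nodes:
            node = Node()
            if cfs and clade in cfs:
                node.support = cfs[clade]
            nodes[clade] = node
    for clade in sorted(nodes, key=len):
        if clade == full:
            continue
        supersets = [c for c in nodes if len(c) > len(clade) and clade < c]
        parent = min(supersets, key=len)
        nodes[parent].add_child(nodes[clade])
        nodes[clade].length = 1.0
    return RootedTree(nodes[full], length_units="unitless")


def bootstrap_cf(gts: GeneTreeSet, n_boot: int = 1000, seed: int = 0,
                 reference: Optional[str] = None) -> ConcordanceTable:
    """Concordance table with percentile 95% bootstrap intervals.

    Gene trees are resampled with replacement ``n_boot`` times; each clade's
    CF is recomputed per replicate (denominator = trees containing all the
    clade's taxa within the replicate).
    """
    if len(gts) < 20:
        raise ValueError("need at least 20 gene trees for a bootstrap")
    table = clade_frequencies(gts, reference=reference)
    taxa = table.taxa
    index = {t: i for i, t in enumerate(taxa)}
    ref_bit = 1 << index[table.reference]
    clade_masks = []
    for r in table.rows:
        m = 0
        for t in r.clade:
            m |= 1 << index[t]
        clade_masks.append(m)
    n_trees = len(gts)
    full_mask = (1 << len(taxa)) - 1
    tree_sides = _tree_sides(gts, index)
    sup = np.zeros((len(clade_masks), n_trees), dtype=bool)
    tot = np.zeros((len(clade_masks), n_trees), dtype=bool)
    for ti, (present, sides) in enumerate(tree_sides):
        for ci, cm in enumerate(clade_masks):
            t, s = _supports(cm, full_mask, present, sides)
            tot[ci, ti] = t
            sup[ci, ti] = s
    rng = np.random.default_rng(seed)
    boot_cf = np.empty((n_boot, len(clade_masks)))
    for b in range(n_boot):
        pick = rng.integers(n_trees, size=n_trees)
        s = sup[:, pick].sum(axis=1)
        t = tot[:, pick].sum(axis=1)
        with np.errstate(invalid="ignore"):
            boot_cf[b] = np.where(t > 0, s / np.maximum(t, 1), np.nan)
    lo = np.nanpercentile(boot_cf, 2.5, axis=0)
    hi = np.nanpercentile(boot_cf, 97.5, axis=0)
    for r, l, h in zip(table.rows, lo, hi):
        r.ci_low = float(l)
        r.ci_high = float(h)
    return table
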