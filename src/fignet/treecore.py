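"""Rooted-tree data model and Newick I/O shared by every pipeline stage.

The tree class here is intentionally small: parent/child links, branch
lengths, an optional support value per internal node, and helpers for the
set-based operations the downstream statistics need (bipartitions, induced
quartet topologies, Robinson-Foulds distances).  Newick parsing is delegated
to dendropy; writing is a short recursion so round-trips are exact up to
numeric formatting.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

REGIONS = ("Eurasia", "Afrotropics", "Australasia", "Neotropics")
GROUP_LEVELS = ("species", "section", "subgenus", "main_clade")


@dataclass
class Taxon:
    """A study taxon with hierarchical group labels and an optional region."""

    id: str
    display_name: str = ""
    group_labels: dict = field(default_factory=dict)
    region: Optional[str] = None
    role: str = "ingroup"  # ingroup | outgroup

    def __post_init__(self):
        if not self.display_name:
            self.display_name = self.id
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.role not in ("ingroup", "outgroup"):
            raise ValueError(f"role must be ingroup/outgroup, got {self.role!r}")


def read_taxon_metadata(path_or_buf) -> list[Taxon]:
    """Read the taxon metadata TSV.

    Columns: taxon_id, display_name, species, section, subgenus, main_clade,
    region, role.  Empty region cells are allowed.
    """
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep="\t", dtype=str).fillna("")
    required = {"taxon_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    taxa = []
    for _, row in df.iterrows():
        labels = {
            lvl: row[lvl]
            for lvl in GROUP_LEVELS
            if lvl in df.columns and row[lvl] != ""
        }
        taxa.append(
            Taxon(
                id=row["taxon_id"],
                display_name=row.get("display_name", "") or row["taxon_id"],
                group_labels=labels,
                region=(row["region"] or None) if "region" in df.columns else None,
                role=row["role"],
            )
        )
    ids = [t.id for t in taxa]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids in metadata")
    return taxa


def write_taxon_metadata(taxa: Sequence[Taxon], path) -> None:
    import pandas as pd

    rows = []
    for t in taxa:
        row = {"taxon_id": t.id, "display_name": t.display_name}
        for lvl in GROUP_LEVELS:
            row[lvl] = t.group_labels.get(lvl, "")
        row["region"] = t.region or ""
        row["role"] = t.role
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class Node:
    __slots__ = ("parent", "children", "length", "name", "support", "_mask")

    def __init__(self, name=None, length=0.0, support=None):
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.length: float = length
        self.name: Optional[str] = name
        self.support: Optional[float] = support
        self._mask: int = 0

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name or ''} {kind}>"


class RootedTree:
    """A rooted tree over uniquely labelled leaves.

    ``length_units`` records the declared units of branch lengths
    (``coalescent`` | ``subst`` | ``unitless``).  ``support_scale`` records
    whether supports arrived on a [0,1] or [0,100] scale; stored values are
    always normalized to [0,1].
    """

    def __init__(self, root: Node, length_units: str = "unitless",
                 polytomies_allowed: bool = True, support_scale: Optional[str] = None):
        self.root = root
        self.length_units = length_units
        self.support_scale = support_scale
        self._validate(polytomies_allowed)

    # -- construction / validation -------------------------------------

    def _validate(self, polytomies_allowed: bool):
        names = [lf.name for lf in self.leaves()]
        if any(n is None for n in names):
            raise ValueError("every leaf must be named")
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dups}")
        for node in self.postorder():
            if node.length < 0:
                raise ValueError("negative branch length")
            if not polytomies_allowed and node.children and len(node.children) != 2:
                raise ValueError(
                    f"polytomy of degree {len(node.children)} but polytomies_allowed=False"
                )

    # -- traversal ------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                yield node
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find_leaf(self, name: str) -> Node:
        for n in self.postorder():
            if n.is_leaf and n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def node_depths(self) -> dict[Node, float]:
        """Depth (sum of branch lengths) of each node from the root."""
        depth = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + node.length
        return depth

    # -- bitmask machinery ----------------------------------------------

    def leaf_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(sorted(self.leaf_names()))}

    def compute_masks(self, index: Optional[dict[str, int]] = None) -> dict[str, int]:
        """Assign each node a bitmask of the leaves below it (stored on
        ``node._mask``); returns the leaf-name → bit index map used."""
        if index is None:
            index = self.leaf_index()
        for node in self.postorder():
            if node.is_leaf:
                node._mask = 1 << index[node.name]
            else:
                m = 0
                for c in node.children:
                    m |= c._mask
                node._mask = m
        return index

    # -- copy / edit ----------------------------------------------------

    def copy(self) -> "RootedTree":
        def rec(node):
            nn = Node(node.name, node.length, node.support)
            for c in node.children:
                nn.add_child(rec(c))
            return nn

        return RootedTree(rec(self.root), self.length_units,
                          polytomies_allowed=True, support_scale=self.support_scale)

    def __repr__(self):
        return f"<RootedTree {len(self.leaf_names())} leaves>"


class GeneTreeSet:
    """A collection of per-locus/per-window rooted trees over one taxon set.

    Individual trees may miss taxa (windows where a sample was entirely
    missing); ``taxa`` is the full study set.
    """

    def __init__(self, trees: Sequence[RootedTree], taxa: Optional[Sequence[str]] = None):
        self.trees = list(trees)
        if taxa is None:
            taxa = sorted(set().union(*(set(t.leaf_names()) for t in self.trees))) \
                if self.trees else []
        self.taxa = list(taxa)

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    def write(self, path):
        write_newick_multifile(self.trees, path)

    @classmethod
    def read(cls, path, length_units="unitless"):
        return cls(read_newick_multifile(path, length_units=length_units))


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split A|B induced by an internal edge.

    Canonical form: ``side_a`` is the side *not* containing the reference
    taxon (the lexicographically smallest leaf unless specified otherwise).
    """

    side_a: frozenset
    side_b: frozenset

    @staticmethod
    def make(side: Iterable[str], all_taxa: Iterable[str],
             reference: Optional[str] = None) -> "Bipartition":
        all_set = frozenset(all_taxa)
        s = frozenset(side)
        if not s or s == all_set:
            raise ValueError("bipartition side must be a proper nonempty subset")
        if reference is None:
            reference = min(all_set)
        if reference in s:
            s = all_set - s
        return Bipartition(s, all_set - s)

    @property
    def informative(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) >= 2

    def __eq__(self, other):
        return isinstance(other, Bipartition) and (
            {self.side_a, self.side_b} == {other.side_a, other.side_b}
        )

    def __hash__(self):
        return hash(frozenset((self.side_a, self.side_b)))

    def __repr__(self):
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        return f"{a} | {b}"


@dataclass(frozen=True)
class QuartetTopology:
    """Resolved quartet: which pairing of the four (sorted) taxa is sister.

    topology index 0: q0q1|q2q3, 1: q0q2|q1q3, 2: q0q3|q1q2;
    None means the quartet is unresolved (polytomy).
    """

    taxa: tuple
    topology: Optional[int]

    def pairs(self):
        q = self.taxa
        if self.topology is None:
            return None
        if self.topology == 0:
            return ((q[0], q[1]), (q[2], q[3]))
        if self.topology == 1:
            return ((q[0], q[2]), (q[1], q[3]))
        return ((q[0], q[3]), (q[1], q[2]))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _support_from_label(label: Optional[str]):
    if label is None or label == "":
        return None, None
    try:
        v = float(label)
    except ValueError:
        return None, None
    if 0.0 <= v <= 1.0:
        return v, "unit"
    if 0.0 <= v <= 100.0:
        return v / 100.0, "percent"
    return None, None


def parse_newick(text: str, length_units: str = "unitless",
                 polytomies_allowed: bool = True) -> RootedTree:
    """Parse one Newick string into a :class:`RootedTree`.

    Internal-node labels that look numeric are interpreted as support
    values; [0,100]-scale values are normalized to [0,1] with the original
    scale recorded on the tree.  Absent branch lengths default to 0.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {exc}") from exc

    scale_seen = set()

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name, length=dnode.edge.length or 0.0)
        else:
            support, scale = _support_from_label(dnode.label)
            if scale:
                scale_seen.add(scale)
            node = Node(name=None, length=dnode.edge.length or 0.0,
                        support=support)
            if support is None and dnode.label:
                node.name = dnode.label
            for c in dnode.child_nodes():
                node.add_child(convert(c))
        return node

    root = convert(dt.seed_node)
    scale = None
    if scale_seen:
        scale = "percent" if "percent" in scale_seen else "unit"
    return RootedTree(root, length_units=length_units,
                      polytomies_allowed=polytomies_allowed,
                      support_scale=scale)


def write_newick(tree: RootedTree, include_support: bool = True,
                 fmt: str = "%.10g") -> str:
    def rec(node: Node) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(rec(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = fmt % node.support
            elif node.name:
                label = node.name
            body = f"({inner}){label}"
        if node is tree.root:
            return body
        return body + ":" + (fmt % node.length)

    return rec(tree.root) + ";"


def read_newick_multifile(path, length_units: str = "unitless") -> list[RootedTree]:
    """One Newick tree per line; blank lines ignored."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line, length_units=length_units))
    return trees


def write_newick_multifile(trees: Sequence[RootedTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# Set-based tree operations
# ---------------------------------------------------------------------------

def bipartitions(tree: RootedTree, reference: Optional[str] = None) -> set:
    """All informative bipartitions of the (unrooted sense) tree.

    Trees with fewer than four leaves have none.  For a binary n-leaf tree
    there are exactly n-3.
    """
    names = tree.leaf_names()
    if len(names) < 4:
        return set()
    all_taxa = frozenset(names)
    index = tree.leaf_index()
    tree.compute_masks(index)
    bits = {index[n]: n for n in names}
    out = set()
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(bits[i] for i in range(len(names)) if node._mask >> i & 1)
        bp = Bipartition.make(side, all_taxa, reference=reference)
        if bp.informative:
            out.add(bp)
    return out


def induced_quartet(tree: RootedTree, q: Sequence[str]) -> QuartetTopology:
    """Restriction of the unrooted tree to four leaves.

    Returns topology None when no edge separates the quartet 2|2 (a
    polytomy spans it); such quartets are excluded from CF counts.
    """
    if len(set(q)) != 4:
        raise ValueError("need four distinct taxa")
    names = set(tree.leaf_names())
    for t in q:
        if t not in names:
            raise KeyError(f"taxon {t!r} not in tree")
    qs = tuple(sorted(q))
    index = tree.leaf_index()
    tree.compute_masks(index)
    qbits = [1 << index[t] for t in qs]
    qmask = qbits[0] | qbits[1] | qbits[2] | qbits[3]
    for node in tree.postorder():
        if node is tree.root:
            continue
        m = node._mask & qmask
        cnt = bin(m).count("1")
        if cnt == 2:
            if m == qbits[0] | qbits[1] or m == qbits[2] | qbits[3]:
                return QuartetTopology(qs, 0)
            if m == qbits[0] | qbits[2] or m == qbits[1] | qbits[3]:
                return QuartetTopology(qs, 1)
            return QuartetTopology(qs, 2)
    return QuartetTopology(qs, None)


def rf_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Robinson-Foulds distance: symmetric difference of bipartition sets."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("leaf sets differ")
    b1 = bipartitions(t1)
    b2 = bipartitions(t2)
    return len(b1 ^ b2)


def root_on_outgroup(tree: RootedTree, outgroup: str) -> RootedTree:
    """Re-root so the outgroup is one of the root's two children.

    The outgroup's pendant edge is split at its midpoint.  Existing rooting
    is discarded.
    """
    t = tree.copy()
    leaf = t.find_leaf(outgroup)
    if leaf.parent is t.root and len(t.root.children) == 2:
        return t
    # reverse the edges on the path from the outgroup's parent to the old
    # root, hanging everything under a new root that bisects the pendant edge
    path = []
    n = leaf.parent
    while n is not None:
        path.append(n)
        n = n.parent
    new_root = Node()
    half = leaf.length / 2.0
    leaf.length = half
    new_root.children = [leaf]
    leaf.parent = new_root
    prev = new_root
    prev_len = half
    for i, node in enumerate(path):
        child_to_remove = leaf if i == 0 else path[i - 1]
        node.children = [c for c in node.children if c is not child_to_remove]
        this_len = node.length
        node.length = prev_len
        prev.children.append(node)
        node.parent = prev
        prev = node
        prev_len = this_len

    # the old root is now a degree-2 pass-through node; splice such nodes out
    def splice(node):
        for c in list(node.children):
            splice(c)
        if node.children is not None and len(node.children) == 1 and node.parent is not None:
            only = node.children[0]
            only.length += node.length
            idx = node.parent.children.index(node)
            node.parent.children[idx] = only
            only.parent = node.parent

    splice(new_root)
    return RootedTree(new_root, t.length_units, polytomies_allowed=True,
                      support_scale=t.support_scale)


def random_binary_tree(names: Sequence[str], rng, min_len: float = 0.1,
                       max_len: float = 2.0) -> RootedTree:
    """Uniform rooted binary labelled topology with U(min,max) branch lengths.

    Built by inserting each leaf on a uniformly chosen existing edge, which
    yields the uniform distribution over the (2n-3)!! rooted topologies.
    """
    names = list(names)
    if len(names) < 2:
        raise ValueError("need >= 2 leaves")

    def L(name):
        return Node(name, float(rng.uniform(min_len, max_len)))

    root = Node()
    root.add_child(L(names[0]))
    root.add_child(L(names[1]))
    for name in names[2:]:
        # collect edges (all non-root nodes), pick one, bisect it
        edges = [n for n in _preorder(root) if n is not root]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = Node(length=float(rng.uniform(min_len, max_len)))
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(L(name))
    return RootedTree(root, "unitless")


def _preorder(node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def ascii_tree(tree: RootedTree) -> str:
    """Small ASCII rendering for debugging."""
    lines = []

    def rec(node, prefix, is_last):
        tag = node.name or ("*" if not node.is_leaf else "?")
        sup = f" [{node.support:.2f}]" if node.support is not None else ""
        connector = "`-" if is_last else "|-"
        lines.append(f"{prefix}{connector}{tag}:{node.length:.3g}{sup}")
        child_prefix = prefix + ("  " if is_last else "| ")
        for i, c in enumerate(node.children):
            rec(c, child_prefix, i == len(node.children) - 1)

    lines.append("root")
    for i, c in enumerate(tree.root.children):
        rec(c, "", i == len(tree.root.children) - 1)
    return "\n".join(lines)
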