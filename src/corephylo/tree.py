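"""Phylogenetic tree container used across the pipeline.

A tree is held as a rooted node structure; unrooted semantics come from the
bipartition view (edges as leaf-label splits). Splits are kept in canonical
form: the side that does NOT contain the lexicographically smallest taxon of
the full leaf set, so that a split is a clade once the tree is (conceptually)
rooted at that taxon. Branch lengths are substitutions/site; supports live on
internal edges on a [0, 1] scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import TreeError

__all__ = [
    "Node",
    "PhyloTree",
    "EdgeInfo",
    "canonical_split",
    "splits_compatible",
]


class Node:
    """One node of a rooted tree representation.

    ``label`` is set for leaves only. ``length`` is the length of the edge to
    the parent (``None`` at the root or when absent); ``support`` likewise
    annotates the edge to the parent.
    """

    __slots__ = ("children", "label", "length", "support")

    def __init__(self, label=None, length=None, support=None, children=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(
            self.label,
            self.length,
            self.support,
            [c.copy() for c in self.children],
        )

    def walk(self):
        """Pre-order traversal."""
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))


@dataclass
class EdgeInfo:
    length: float | None
    support: float | None
    trivial: bool  # pendant edge (one side is a single leaf)


def canonical_split(side: frozenset, taxa: frozenset) -> frozenset:
    """Canonical form of a bipartition: the side not containing min(taxa)."""
    smallest = min(taxa)
    return frozenset(taxa - side) if smallest in side else frozenset(side)


def splits_compatible(a: frozenset, b: frozenset, taxa: frozenset) -> bool:
    """Four-intersection compatibility test for two bipartitions of ``taxa``."""
    a2, b2 = taxa - a, taxa - b
    return not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2)


class PhyloTree:
    """Newick-representable tree with optional lengths and supports."""

    def __init__(self, root: Node):
        self.root = root
        labels = [n.label for n in root.walk() if n.is_leaf]
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")
        if any(lbl is None for lbl in labels):
            raise TreeError("unlabeled leaf")
        self._leaf_labels = frozenset(labels)

    # ------------------------------------------------------------------ basics
    @property
    def leaf_labels(self) -> frozenset:
        return self._leaf_labels

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def has_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.root.walk() if n is not self.root
        )

    def deroot(self) -> "PhyloTree":
        """Collapse a degree-2 root so the same unrooted tree has one edge fewer.

        The two root edges describe the same bipartition; their lengths are
        summed onto the surviving child edge and a defined support is kept.
        """
        r = self.root
        while len(r.children) == 2:
            a, b = r.children
            keep, fold = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:  # two-leaf tree: nothing sensible to collapse
                break
            if fold.length is not None or keep.length is not None:
                fold.length = (fold.length or 0.0) + (keep.length or 0.0)
            if fold.support is None:
                fold.support = keep.support
            r.children = keep.children + [fold]
        return self

    # ------------------------------------------------------------- bipartitions
    def bipartitions(self, include_trivial: bool = False) -> dict[frozenset, EdgeInfo]:
        """Map canonical split -> EdgeInfo for every edge of the unrooted tree.

        A degree-2 root contributes a single (deduplicated) edge whose length
        is the sum of the two root edges.
        """
        taxa = self._leaf_labels
        out: dict[frozenset, EdgeInfo] = {}

        # one recursive pass collecting per-node leaf sets
        def visit(node: Node) -> frozenset:
            if node.is_leaf:
                ls = frozenset([node.label])
            else:
                ls = frozenset().union(*(visit(c) for c in node.children))
            if node is self.root:
                return ls
            trivial = len(ls) == 1 or len(taxa - ls) == 1
            if not trivial or include_trivial:
                key = canonical_split(ls, taxa)
                if key in out:  # degree-2 root: same split seen from both sides
                    prev = out[key]
                    length = None
                    if prev.length is not None or node.length is not None:
                        length = (prev.length or 0.0) + (node.length or 0.0)
                    support = prev.support if prev.support is not None else node.support
                    out[key] = EdgeInfo(length, support, prev.trivial)
                else:
                    out[key] = EdgeInfo(node.length, node.support, trivial)
            return ls

        visit(self.root)
        return out

    def nontrivial_splits(self) -> dict[frozenset, EdgeInfo]:
        return {s: e for s, e in self.bipartitions().items() if not e.trivial}

    # ------------------------------------------------------------------ newick
    def newick(self, lengths: bool = True, supports: bool = True) -> str:
        def fmt(x: float) -> str:
            return f"{x:.12g}"

        def render(node: Node) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")"
                if supports and node.support is not None:
                    s += fmt(node.support)
            if lengths and node.length is not None:
                s += ":" + fmt(node.length)
            return s

        return render(self.root) + ";"

    def canonical_newick(self) -> str:
        """Topology-only canonical Newick: rooted at the smallest leaf's edge,
        children sorted by smallest contained label. Equal unrooted topologies
        map to equal strings."""
        t = self.copy().deroot()
        smallest = min(t.leaf_labels)

        # reroot: represent as (rest, smallest);
        def strip(node: Node, drop: str) -> Node | None:
            if node.is_leaf:
                return None if node.label == drop else Node(node.label)
            kids = [strip(c, drop) for c in node.children]
            kids = [k for k in kids if k is not None]
            if len(kids) == 1:
                return kids[0]
            return Node(children=kids)

        # find path: simply remove the smallest leaf and suppress the unary node
        rest = strip(t.root, smallest)

        def key(node: Node) -> str:
            return node.label if node.is_leaf else min(key(c) for c in node.children)

        def render(node: Node) -> str:
            if node.is_leaf:
                return node.label
            parts = sorted((render(c) for c in node.children))
            return "(" + ",".join(parts) + ")"

        return f"({render(rest)},{smallest});"

    # -------------------------------------------------------------- cophenetic
    def cophenetic(self, unit_if_missing: bool = True):
        """(sorted labels, symmetric matrix of leaf-to-leaf path lengths).

        Edges without a length count as 1 when ``unit_if_missing`` (needed for
        consensus/supertree outputs, which carry supports but no lengths).
        """
        labels = sorted(self._leaf_labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        mat = np.zeros((n, n))

        def visit(node: Node) -> dict[str, float]:
            if node.is_leaf:
                below = {node.label: 0.0}
            else:
                child_maps = []
                for c in node.children:
                    m = visit(c)
                    el = c.length
                    if el is None:
                        if not unit_if_missing:
                            raise TreeError("missing branch length in cophenetic computation")
                        el = 1.0
                    child_maps.append({k: v + el for k, v in m.items()})
                for m1, m2 in itertools.combinations(child_maps, 2):
                    for la, da in m1.items():
                        for lb, db in m2.items():
                            d = da + db
                            mat[idx[la], idx[lb]] = d
                            mat[idx[lb], idx[la]] = d
                below = {}
                for m in child_maps:
                    below.update(m)
            return below

        visit(self.root)
        return labels, mat

    # ------------------------------------------------------------ quartet view
    def leaf_edge_paths(self):
        """(edges, paths): ``edges`` maps an edge id to (support, is_internal);
        ``paths`` maps each leaf label to the set of edge ids on its path to
        the root. The path between two leaves is the symmetric difference."""
        edges: dict[int, tuple[float | None, bool]] = {}
        paths: dict[str, frozenset] = {}
        counter = itertools.count()

        def visit(node: Node, acc: tuple):
            for c in node.children:
                eid = next(counter)
                edges[eid] = (c.support, not c.is_leaf)
                if c.is_leaf:
                    paths[c.label] = frozenset(acc + (eid,))
                else:
                    visit(c, acc + (eid,))

        visit(self.root, ())
        return edges, paths

    # ------------------------------------------------------------ construction
    @classmethod
    def from_splits(
        cls,
        taxa,
        splits: dict[frozenset, float | None],
    ) -> "PhyloTree":
        """Build the (possibly multifurcating) unrooted tree containing exactly
        the given canonical non-trivial splits; values become edge supports.

        Splits must be pairwise compatible and canonical w.r.t. ``taxa``.
        """
        taxa = frozenset(taxa)
        if len(taxa) < 2:
            raise TreeError("need at least 2 taxa")
        smallest = min(taxa)
        for s in splits:
            if smallest in s or not s or not (taxa - s):
                raise TreeError(f"split not canonical for taxon set: {sorted(s)}")
            if not s <= taxa:
                raise TreeError(f"split contains unknown taxa: {sorted(s - taxa)}")
        ordered = sorted(splits, key=lambda s: (-len(s), tuple(sorted(s))))
        for a, b in itertools.combinations(ordered, 2):
            if not (a <= b or b <= a or not (a & b)):
                raise TreeError("splits are not pairwise compatible")

        root = Node()
        clade_nodes: list[tuple[frozenset, Node]] = []
        for s in ordered:
            parent = root
            for cs, cn in clade_nodes:  # ordered large->small; last container wins
                if s < cs:
                    parent = cn
            node = Node(support=splits[s])
            parent.children.append(node)
            clade_nodes.append((s, node))
        for leaf in sorted(taxa):
            parent = root
            for cs, cn in clade_nodes:
                if leaf in cs:
                    parent = cn
            parent.children.append(Node(leaf))
        return cls(root)

    # --------------------------------------------------------------------- NNI
    def nni_neighbors(self):
        """Yield copies of the tree, one per nearest-neighbor-interchange move.

        Moves swap a grandchild across an internal edge with one of its
        parent-edge siblings; duplicates (symmetric swaps) may occur, which is
        harmless for hill climbing.
        """
        base = self.copy().deroot()

        def locate(root: Node):
            # (parent, child) pairs where child is internal
            out = []
            for node in root.walk():
                for c in node.children:
                    if not c.is_leaf:
                        out.append((node, c))
            return out

        n_moves = []
        for pi, (parent, child) in enumerate(locate(base.root)):
            for gi in range(len(child.children)):
                for si in range(len(parent.children)):
                    if parent.children[si] is child:
                        continue
                    n_moves.append((pi, gi, si))
        for pi, gi, si in n_moves:
            t = base.copy()
            parent, child = locate(t.root)[pi]
            parent.children[si], child.children[gi] = (
                child.children[gi],
                parent.children[si],
            )
            yield PhyloTree(t.root)

    def __repr__(self):
        return f"<PhyloTree n_leaves={self.n_leaves}>"
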