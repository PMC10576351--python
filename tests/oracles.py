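"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's own tree machinery: Newick is parsed
with dendropy, bipartitions are enumerated as frozensets of labels, and all
scores are computed by literal enumeration. They exist to cross-check the
package, so they must stay independent of the code paths they verify.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import dendropy
import numpy as np


def _dendropy_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def splits_of(newick: str, include_trivial: bool = False):
    """Canonical bipartitions (frozenset of the side without the smallest
    label) -> summed branch length, via dendropy leaf-set enumeration."""
    t = _dendropy_tree(newick)
    taxa = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    smallest = min(taxa)
    out: dict[frozenset, float] = {}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) == len(taxa):
            continue
        trivial = len(side) == 1 or len(taxa - side) == 1
        if trivial and not include_trivial:
            continue
        key = frozenset(taxa - side) if smallest in side else side
        out[key] = out.get(key, 0.0) + (node.edge.length or 0.0)
    return taxa, out


def rf_brute(nw1: str, nw2: str) -> int:
    _, b1 = splits_of(nw1)
    _, b2 = splits_of(nw2)
    return len(set(b1) ^ set(b2))


def branch_score_brute(nw1: str, nw2: str) -> float:
    _, b1 = splits_of(nw1, include_trivial=True)
    _, b2 = splits_of(nw2, include_trivial=True)
    total = 0.0
    for s in set(b1) | set(b2):
        total += (b1.get(s, 0.0) - b2.get(s, 0.0)) ** 2
    return math.sqrt(total)


def path_lengths_brute(newick: str, unit: bool = False) -> dict[frozenset, float]:
    """Leaf-pair path sums by explicit edge-path enumeration."""
    t = _dendropy_tree(newick)
    leaves = list(t.leaf_node_iter())
    out = {}
    for a, b in itertools.combinations(leaves, 2):
        pa = set(id(e) for e in _edge_path_to_root(a))
        pb = set(id(e) for e in _edge_path_to_root(b))
        edges = {id(e): e for e in _edge_path_to_root(a) + _edge_path_to_root(b)}
        path = (pa | pb) - (pa & pb)
        d = sum(
            1.0 if unit or edges[e].length is None else edges[e].length for e in path
        )
        out[frozenset({a.taxon.label, b.taxon.label})] = d
    return out


def _edge_path_to_root(node):
    path = []
    while node.parent_node is not None:
        path.append(node.edge)
        node = node.parent_node
    return path


def ccc_brute(nw1: str, nw2: str) -> float:
    d1 = path_lengths_brute(nw1, unit=":" not in nw1)
    d2 = path_lengths_brute(nw2, unit=":" not in nw2)
    keys = sorted(d1, key=lambda s: tuple(sorted(s)))
    x = np.array([d1[k] for k in keys])
    y = np.array([d2[k] for k in keys])
    x = x - x.mean()
    y = y - y.mean()
    return float((x * y).sum() / math.sqrt((x * x).sum() * (y * y).sum()))


# ------------------------------------------------------------------- consensus
def compatible_brute(a: frozenset, b: frozenset, taxa: frozenset) -> bool:
    a2, b2 = taxa - a, taxa - b
    return not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2)


def consensus_brute(newicks: list[str]):
    """Literal majority-rule-extended rules: include every split in >50% of
    the trees, then add the remaining splits in frequency order (lexicographic
    tie-break) when compatible with all accepted, until fully resolved.
    Returns {split: support}."""
    n = len(newicks)
    taxa = None
    counts: Counter = Counter()
    for nw in newicks:
        tx, splits = splits_of(nw)
        taxa = tx if taxa is None else taxa
        assert tx == taxa
        counts.update(splits.keys())
    accepted: dict[frozenset, float] = {}
    order = sorted(counts, key=lambda s: (-counts[s], tuple(sorted(s))))
    for s in order:
        if counts[s] / n > 0.5:
            accepted[s] = counts[s] / n
    for s in order:
        if counts[s] / n > 0.5:
            continue
        if len(accepted) >= len(taxa) - 3:
            continue
        if all(compatible_brute(s, a, taxa) for a in accepted):
            accepted[s] = counts[s] / n
    return accepted


# --------------------------------------------------------------- quartet score
def quartet_topology_brute(newick: str, four: tuple):
    """Induced quartet split of a tree on 4 leaves, via the four-point
    condition on unit-length path sums; None when unresolved."""
    d = path_lengths_brute(newick, unit=True)
    a, b, c, dd = four
    s = (
        d[frozenset({a, b})] + d[frozenset({c, dd})],
        d[frozenset({a, c})] + d[frozenset({b, dd})],
        d[frozenset({a, dd})] + d[frozenset({b, c})],
    )
    pairs = (
        frozenset({frozenset({a, b}), frozenset({c, dd})}),
        frozenset({frozenset({a, c}), frozenset({b, dd})}),
        frozenset({frozenset({a, dd}), frozenset({b, c})}),
    )
    m = min(s)
    winners = [i for i, v in enumerate(s) if v == m]
    if len(winners) != 1:
        return None
    return pairs[winners[0]]


def quartet_score_brute(candidate_nw: str, gene_tables: list[dict]) -> float:
    """Score = sum over genes and 4-subsets of the gene's leaves of the
    quartet weight where candidate and gene tree induce the same split."""
    score = 0.0
    for table in gene_tables:
        for four, (pair, w) in table.items():
            cand = quartet_topology_brute(candidate_nw, tuple(sorted(four)))
            if cand == pair:
                score += w
    return score


def all_unrooted_topologies(labels: list[str]):
    """Newick strings of every unrooted binary topology (independent
    enumerator: grows trees as nested tuples, inserting leaves on edges)."""

    def edges(tree):
        # tree is a tuple-tree over 3 children at the root
        out = []

        def walk(node, path):
            out.append(path)
            if isinstance(node, tuple):
                for i, c in enumerate(node):
                    walk(c, path + (i,))

        for i, c in enumerate(tree):
            walk(c, (i,))
        return out

    def insert(tree, path, leaf):
        if len(path) == 1:
            return tuple(
                (c if i != path[0] else (c, leaf)) for i, c in enumerate(tree)
            )
        i = path[0]
        return tuple(
            (c if j != i else insert(c, path[1:], leaf)) for j, c in enumerate(tree)
        )

    labels = sorted(labels)
    trees = [tuple(labels[:3])]
    for leaf in labels[3:]:
        trees = [insert(t, p, leaf) for t in trees for p in edges(t)]

    def to_newick(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(to_newick(c) for c in node) + ")"

    return [to_newick(t) + ";" for t in trees]
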