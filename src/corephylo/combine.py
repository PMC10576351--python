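"""Combine gene trees into a single phylogeny.

Two strategies:

* majority-rule *extended* consensus — every bipartition in more than half of
  the gene trees is included; the remaining bipartitions are considered in
  order of decreasing frequency and added when compatible with everything
  accepted so far, until the tree is fully resolved. Edge supports are the
  bipartition frequencies; no branch lengths.

* weighted quartet supertree — chooses the topology maximizing a quartet
  agreement score over the gene trees. A quartet's weight in a gene tree is
  the minimum support on the internal path defining it (1 where supports are
  absent), so poorly supported gene-tree edges contribute less. Small taxon
  sets are solved exactly by exhaustive enumeration of unrooted topologies;
  larger ones by consensus-seeded nearest-neighbor-interchange hill climbing.
  Gene trees may miss taxa.

Both are deterministic: frequency ties break on the lexicographically
smallest canonical split, score ties on the smallest canonical Newick form.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

from .errors import TreeError
from .tree import Node, PhyloTree, canonical_split, splits_compatible

__all__ = [
    "majority_rule_extended",
    "quartet_supertree",
    "consensus_with_report",
    "gene_tree_quartets",
    "quartet_score",
    "EXACT_LIMIT",
]

EXACT_LIMIT = 8


@dataclass
class ConsensusRow:
    split: frozenset
    frequency: float
    rule: str  # "majority" | "extension" | "rejected"


def _split_sort_key(split: frozenset):
    return tuple(sorted(split))


def consensus_with_report(trees: list[PhyloTree]) -> tuple[PhyloTree, list[ConsensusRow]]:
    """Majority-rule-extended consensus plus the per-bipartition audit trail."""
    if len(trees) < 2:
        raise TreeError("consensus needs at least 2 trees")
    taxa = trees[0].leaf_labels
    for i, t in enumerate(trees[1:], start=2):
        if t.leaf_labels != taxa:
            raise TreeError(
                f"tree #{i} has a different taxon set "
                f"(only there: {sorted(t.leaf_labels - taxa)}; "
                f"missing: {sorted(taxa - t.leaf_labels)})"
            )
    n = len(trees)
    counts: Counter = Counter()
    for t in trees:
        counts.update(t.nontrivial_splits().keys())

    accepted: dict[frozenset, float] = {}
    rows: list[ConsensusRow] = []
    majority = [s for s, c in counts.items() if c / n > 0.5]
    for s in sorted(majority, key=lambda s: (-counts[s], _split_sort_key(s))):
        accepted[s] = counts[s] / n
        rows.append(ConsensusRow(s, counts[s] / n, "majority"))
    rest = [s for s in counts if counts[s] / n <= 0.5]
    max_splits = len(taxa) - 3  # fully resolved unrooted binary tree
    for s in sorted(rest, key=lambda s: (-counts[s], _split_sort_key(s))):
        if len(accepted) >= max_splits:
            rows.append(ConsensusRow(s, counts[s] / n, "rejected"))
            continue
        if all(splits_compatible(s, a, taxa) for a in accepted):
            accepted[s] = counts[s] / n
            rows.append(ConsensusRow(s, counts[s] / n, "extension"))
        else:
            rows.append(ConsensusRow(s, counts[s] / n, "rejected"))
    return PhyloTree.from_splits(taxa, accepted), rows


def majority_rule_extended(trees: list[PhyloTree]) -> PhyloTree:
    return consensus_with_report(trees)[0]


# ------------------------------------------------------------------- quartets
def _pairings(q: tuple):
    a, b, c, d = q
    yield frozenset({frozenset({a, b}), frozenset({c, d})})
    yield frozenset({frozenset({a, c}), frozenset({b, d})})
    yield frozenset({frozenset({a, d}), frozenset({b, c})})


def _tree_pairing(paths: dict, q: tuple):
    """Induced quartet topology of a tree (via edge-path disjointness), or
    (None, None) when the quartet is unresolved. Second element is the set of
    edge ids on the internal path defining the quartet."""
    a, b, c, d = q
    pa, pb, pc, pd = paths[a], paths[b], paths[c], paths[d]
    options = (
        (pa, pb, pc, pd, frozenset({frozenset({a, b}), frozenset({c, d})})),
        (pa, pc, pb, pd, frozenset({frozenset({a, c}), frozenset({b, d})})),
        (pa, pd, pb, pc, frozenset({frozenset({a, d}), frozenset({b, c})})),
    )
    for x1, x2, y1, y2, pair in options:
        if not ((x1 ^ x2) & (y1 ^ y2)):
            middle = (x1 ^ y1) & (x2 ^ y2)
            if middle:  # empty middle path = the four leaves meet at one node
                return pair, middle
            return None, None
    return None, None


def gene_tree_quartets(tree: PhyloTree):
    """Map 4-subset (frozenset) -> (pairing, weight) over the tree's leaves.

    Weight = min edge weight on the internal path defining the quartet, where
    an edge's weight is its support when present, else 1. Unresolved quartets
    are omitted.
    """
    edges, paths = tree.leaf_edge_paths()
    out = {}
    for q in itertools.combinations(sorted(tree.leaf_labels), 4):
        pair, middle = _tree_pairing(paths, q)
        if pair is None:
            continue
        supports = [edges[e][0] for e in middle]  # middle edges are always internal
        w = min((s if s is not None else 1.0) for s in supports)
        out[frozenset(q)] = (pair, w)
    return out


def _leaf_topo_dists(tree: PhyloTree) -> dict[str, dict[str, int]]:
    """All-pairs leaf distances in edge counts (unit branch lengths)."""
    adj: dict[int, list[tuple[int, str | None]]] = {}
    leaf_of: dict[str, int] = {}
    ids = itertools.count()

    def build(node: Node) -> int:
        nid = next(ids)
        adj.setdefault(nid, [])
        if node.is_leaf:
            leaf_of[node.label] = nid
        for c in node.children:
            cid = build(c)
            adj[nid].append((cid, None))
            adj[cid].append((nid, None))
        return nid

    build(tree.root)
    out: dict[str, dict[str, int]] = {}
    for lab, start in leaf_of.items():
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v, _ in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        out[lab] = {l2: dist[n2] for l2, n2 in leaf_of.items()}
    return out


def _merge_tables(tables: list[dict]) -> dict[tuple, list[float]]:
    """Collapse per-gene quartet tables into qtuple -> [w_ab|cd, w_ac|bd, w_ad|bc]."""
    merged: dict[tuple, list[float]] = {}
    for table in tables:
        for q, (pair, w) in table.items():
            qt = tuple(sorted(q))
            a, b, c, d = qt
            if frozenset({a, b}) in pair:
                idx = 0
            elif frozenset({a, c}) in pair:
                idx = 1
            else:
                idx = 2
            merged.setdefault(qt, [0.0, 0.0, 0.0])[idx] += w
    return merged


def _candidate_pairing_index(dists, qt) -> int | None:
    """0: ab|cd, 1: ac|bd, 2: ad|bc, None: unresolved (four-point on unit lengths)."""
    a, b, c, d = qt
    da = dists[a]
    db = dists[b]
    s = (da[b] + dists[c][d], da[c] + db[d], da[d] + db[c])
    m = min(s)
    idx = None
    for i, v in enumerate(s):
        if v == m:
            if idx is not None:
                return None  # tie: star quartet
            idx = i
    return idx


def _score_merged(candidate: PhyloTree, merged: dict[tuple, list[float]]) -> float:
    dists = _leaf_topo_dists(candidate)
    score = 0.0
    for qt, ws in merged.items():
        idx = _candidate_pairing_index(dists, qt)
        if idx is not None:
            score += ws[idx]
    return score


def quartet_score(candidate: PhyloTree, tables: list[dict]) -> float:
    """Summed weight of gene-tree quartets whose topology the candidate matches."""
    return _score_merged(candidate, _merge_tables(tables))


def _enumerate_topologies(taxa: list[str]):
    """Every unrooted binary topology on ``taxa`` (each exactly once), by
    sequential leaf insertion."""

    def insertions(root: Node, leaf: str):
        # attach at every edge (parent, child-index)
        nodes = [n for n in root.walk() if n.children]
        for node in nodes:
            for i in range(len(node.children)):
                t = root.copy()
                tn = [n for n in t.walk() if n.children][nodes.index(node)]
                child = tn.children[i]
                tn.children[i] = Node(children=[child, Node(leaf)])
                yield t

    first = sorted(taxa)
    base = Node(children=[Node(x) for x in first[:3]])
    trees = [base]
    for leaf in first[3:]:
        trees = [t2 for t in trees for t2 in insertions(t, leaf)]
    for t in trees:
        yield PhyloTree(t)


def _resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Deterministically resolve multifurcations by pairing the two children
    with the smallest minimum leaf labels (root keeps degree 3)."""
    t = tree.copy().deroot()

    def min_label(node: Node) -> str:
        return node.label if node.is_leaf else min(min_label(c) for c in node.children)

    def fix(node: Node, is_root: bool):
        for c in node.children:
            fix(c, False)
        limit = 3 if is_root else 2
        while len(node.children) > limit:
            node.children.sort(key=min_label)
            a = node.children.pop(0)
            b = node.children.pop(0)
            node.children.insert(0, Node(children=[a, b]))

    fix(t.root, True)
    return PhyloTree(t.root)


def quartet_supertree(
    trees: list[PhyloTree],
    taxa,
    exact_limit: int = EXACT_LIMIT,
) -> PhyloTree:
    """Species tree maximizing the weighted quartet agreement score."""
    taxa = frozenset(taxa)
    if len(trees) < 2:
        raise TreeError("supertree needs at least 2 gene trees")
    covered = frozenset().union(*(t.leaf_labels for t in trees))
    missing = taxa - covered
    if missing:
        raise TreeError(f"taxa present in no gene tree: {sorted(missing)}")
    extra = covered - taxa
    if extra:
        raise TreeError(f"gene trees contain taxa outside the target set: {sorted(extra)}")
    if len(taxa) < 4:
        return PhyloTree(Node(children=[Node(x) for x in sorted(taxa)]))

    tables = [gene_tree_quartets(t) for t in trees]
    merged = _merge_tables(tables)

    if len(taxa) <= exact_limit:
        best = None
        for cand in _enumerate_topologies(sorted(taxa)):
            s = _score_merged(cand, merged)
            if best is None or s > best[0] + 1e-9:
                best = (s, cand.canonical_newick(), cand)
            elif abs(s - best[0]) <= 1e-9:
                key = cand.canonical_newick()
                if key < best[1]:
                    best = (s, key, cand)
        result = best[2]
    else:
        result = _hill_climb(trees, taxa, merged)

    _attach_quartet_supports(result, tables)
    return result


def _insert_leaf_everywhere(tree: PhyloTree, leaf: str):
    root = tree.copy().root
    nodes = [n for n in root.walk() if n.children]
    for ni, node in enumerate(nodes):
        for i in range(len(node.children) + (1 if node is root else 0)):
            t = root.copy()
            tn = [n for n in t.walk() if n.children][ni]
            if i < len(node.children):
                child = tn.children[i]
                tn.children[i] = Node(children=[child, Node(leaf)])
            else:
                tn.children.append(Node(leaf))
            yield PhyloTree(t)


def _hill_climb(trees, taxa, merged) -> PhyloTree:
    full = [t for t in trees if t.leaf_labels == taxa]
    if len(full) >= 2:
        seed = majority_rule_extended(full)
    elif len(full) == 1:
        seed = PhyloTree.from_splits(taxa, dict.fromkeys(full[0].nontrivial_splits(), None))
    else:
        widest = max(trees, key=lambda t: (len(t.leaf_labels), -trees.index(t)))
        seed = PhyloTree.from_splits(
            widest.leaf_labels, dict.fromkeys(widest.nontrivial_splits(), None)
        )
        for leaf in sorted(taxa - widest.leaf_labels):
            best = None
            for cand in _insert_leaf_everywhere(seed, leaf):
                s = _score_merged(cand, merged)
                key = cand.canonical_newick()
                if best is None or s > best[0] + 1e-9 or (abs(s - best[0]) <= 1e-9 and key < best[1]):
                    best = (s, key, cand)
            seed = best[2]
    seed = _resolve_polytomies(seed)
    current, cur_score = seed, _score_merged(seed, merged)
    for _ in range(200):  # NNI hill climb to a local optimum
        best = None
        for cand in current.nni_neighbors():
            s = _score_merged(cand, merged)
            if best is None or s > best[0]:
                best = (s, cand)
        if best is None or best[0] <= cur_score + 1e-9:
            break
        cur_score, current = best[0], best[1]
    return current


def _attach_quartet_supports(tree: PhyloTree, tables: list[dict]) -> None:
    """Per internal edge: weighted fraction of its defining quartets on which
    the gene trees agree with this tree (0 when no gene covers any)."""
    edges, paths = tree.leaf_edge_paths()
    agree: dict[int, float] = {}
    total: dict[int, float] = {}
    all_q = set()
    for table in tables:
        all_q.update(table)
    for q in all_q:
        qt = tuple(sorted(q))
        if not all(x in paths for x in qt):
            continue
        cpair, middle = _tree_pairing(paths, qt)
        if cpair is None:
            continue
        internal_edges = [e for e in middle if edges[e][1]]
        if not internal_edges:
            continue
        for table in tables:
            if q not in table:
                continue
            pair, w = table[q]
            for e in internal_edges:
                total[e] = total.get(e, 0.0) + w
                if pair == cpair:
                    agree[e] = agree.get(e, 0.0) + w

    def visit(node: Node, eid_iter):
        for c in node.children:
            eid = next(eid_iter)
            c.length = None  # supertree carries supports, not lengths
            if not c.is_leaf:
                tot = total.get(eid, 0.0)
                c.support = (agree.get(eid, 0.0) / tot) if tot > 0 else 0.0
                visit(c, eid_iter)

    visit(tree.root, itertools.count())
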