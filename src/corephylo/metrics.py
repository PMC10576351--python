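"""Tree-comparison metrics: Robinson-Foulds, branch score, cophenetic correlation.

All metrics treat trees as unrooted and compare them over identical leaf sets.
The branch score follows the Kuhner-Felsenstein convention (pendant edges
included, absent bipartitions count with length 0). The cophenetic correlation
coefficient (CCC) is the Pearson correlation of the two trees' leaf-pair path
lengths; trees without branch lengths are given unit lengths for this purpose
only, so consensus/supertree topologies remain comparable.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .errors import TreeError
from .tree import PhyloTree

log = logging.getLogger(__name__)

__all__ = ["rf_distance", "branch_score", "ccc", "cophenetic_matrix", "compare_trees"]


def _check_leafsets(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.leaf_labels != t2.leaf_labels:
        only1 = sorted(t1.leaf_labels - t2.leaf_labels)
        only2 = sorted(t2.leaf_labels - t1.leaf_labels)
        raise TreeError(
            f"leaf sets differ: only in first {only1}; only in second {only2}"
        )


def rf_distance(t1: PhyloTree, t2: PhyloTree, normalized: bool = False) -> float:
    """Symmetric-difference count of non-trivial bipartitions.

    For binary trees this equals the classical "twice the number of differing
    internal branches". The normalized form divides by |B1| + |B2| and is 0
    when both trees are stars.
    """
    _check_leafsets(t1, t2)
    b1 = set(t1.nontrivial_splits())
    b2 = set(t2.nontrivial_splits())
    plain = len(b1 ^ b2)
    if not normalized:
        return float(plain)
    denom = len(b1) + len(b2)
    return plain / denom if denom else 0.0


def branch_score(t1: PhyloTree, t2: PhyloTree) -> float:
    """sqrt of the summed squared branch-length differences over the union of
    bipartitions, pendant edges matched by leaf; absent bipartitions get 0."""
    _check_leafsets(t1, t2)
    if not (t1.has_lengths() and t2.has_lengths()):
        raise TreeError("branch_score requires branch lengths on both trees")
    e1 = t1.bipartitions(include_trivial=True)
    e2 = t2.bipartitions(include_trivial=True)
    total = 0.0
    for split in set(e1) | set(e2):
        l1 = e1[split].length if split in e1 else 0.0
        l2 = e2[split].length if split in e2 else 0.0
        total += (l1 - l2) ** 2
    return math.sqrt(total)


def cophenetic_matrix(t: PhyloTree):
    """(sorted labels, dense symmetric matrix of leaf-pair path lengths)."""
    if not t.has_lengths():
        log.info("tree has no branch lengths; using unit lengths for cophenetic matrix")
    return t.cophenetic(unit_if_missing=True)


def ccc(t1: PhyloTree, t2: PhyloTree) -> float:
    """Cophenetic correlation coefficient in [-1, 1]; NaN when either
    cophenetic matrix has zero variance (e.g. an equal-length star)."""
    _check_leafsets(t1, t2)
    if t1.n_leaves < 4:
        raise TreeError("ccc needs at least 4 leaves")
    labels1, m1 = cophenetic_matrix(t1)
    labels2, m2 = cophenetic_matrix(t2)
    assert labels1 == labels2
    iu = np.triu_indices(len(labels1), k=1)
    x, y = m1[iu], m2[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero variance in a cophenetic matrix; CCC undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def compare_trees(trees: dict[str, PhyloTree], metrics: list[str]):
    """Pairwise metric table for any number of named trees.

    Returns a list of dict rows (tree_a, tree_b, metric, value); 'bs' rows are
    NaN for trees lacking branch lengths.
    """
    known = {"rf", "nrf", "bs", "ccc"}
    bad = set(metrics) - known
    if bad:
        raise ValueError(f"unknown metrics: {sorted(bad)} (choose from {sorted(known)})")
    names = list(trees)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for m in metrics:
                if m == "rf":
                    v = rf_distance(trees[a], trees[b])
                elif m == "nrf":
                    v = rf_distance(trees[a], trees[b], normalized=True)
                elif m == "bs":
                    try:
                        v = branch_score(trees[a], trees[b])
                    except TreeError:
                        v = float("nan")
                else:
                    v = ccc(trees[a], trees[b])
                rows.append({"tree_a": a, "tree_b": b, "metric": m, "value": v})
    return rows
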