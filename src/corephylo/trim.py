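"""Automatic alignment trimming: gappyout, strict, strictplus.

Column statistics:

* gap fraction g(c) — fraction of rows with '-' in column c;
* similarity s(c) — fraction of residue-residue pairs in the column with a
  BLOSUM62 score >= 1 (0 when fewer than 2 residues).

Thresholds are picked automatically from the data as the elbow of the sorted
statistic curve: the point with maximum perpendicular distance to the chord
joining the curve's endpoints. The three methods are nested by construction —
``strict`` starts from ``gappyout``'s retained columns, ``strictplus`` from
``strict``'s — so they are ordered in aggressiveness as the names imply:

* gappyout: drop columns with g(c) > g* (and always drop all-gap columns);
* strict: additionally drop columns with s(c) < s*, then drop retained
  columns not in a run of >= 3 consecutive retained columns;
* strictplus: from strict's set, keep only runs of >= 5, then drop any column
  with >= 3 of its 4 nearest original neighbors (c-2..c+2) outside the set
  (one simultaneous pass);
* none: identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .align import Alignment, _SCORE, _sym_index
from .errors import TrimError

__all__ = ["TrimReport", "trim_alignment", "gap_fractions", "similarity_scores", "elbow_threshold"]

TRIM_METHODS = ("gappyout", "strict", "strictplus", "none")


@dataclass
class TrimReport:
    method: str
    retained: list[int]  # ascending 0-based original column indices
    gap_threshold: float | None
    similarity_threshold: float | None

    def __post_init__(self):
        if any(b <= a for a, b in itertools.pairwise(self.retained)):
            raise TrimError("retained indices must be strictly increasing")


def gap_fractions(aln: Alignment) -> np.ndarray:
    rows = list(aln.rows.values())
    n = len(rows)
    return np.array(
        [sum(1 for r in rows if r[c] == "-") / n for c in range(aln.length)]
    )


def similarity_scores(aln: Alignment) -> np.ndarray:
    rows = list(aln.rows.values())
    out = np.zeros(aln.length)
    for c in range(aln.length):
        residues = [r[c] for r in rows if r[c] != "-"]
        if len(residues) < 2:
            out[c] = 0.0
            continue
        pos = tot = 0
        for a, b in itertools.combinations(residues, 2):
            tot += 1
            if _SCORE[_sym_index(a), _sym_index(b)] >= 1:
                pos += 1
        out[c] = pos / tot
    return out


def elbow_threshold(values: np.ndarray) -> float:
    """Value at the elbow of the ascending sorted curve: the point of maximum
    perpendicular distance *below* the chord joining the curve's endpoints.

    The below-chord (convex) knee marks the end of the low cluster — the
    gappy columns for g, the dissimilar columns for s. Curves that never dip
    below the chord (flat, or concave because most columns already sit on the
    high plateau) have no low cluster and yield the first value, so nothing
    is cut. Ties resolve to the first index."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 1:
        return float(v[0])
    x = np.arange(n, dtype=float)
    dx, dy = n - 1.0, v[-1] - v[0]
    norm = np.hypot(dx, dy)
    if norm == 0 or dy == 0:
        return float(v[0])
    below = (dy * x - dx * (v - v[0])) / norm  # positive where curve < chord
    best = int(np.argmax(below))
    if below[best] <= 0:
        return float(v[0])
    return float(v[best])


def _runs_filter(retained: list[int], min_run: int) -> list[int]:
    """Keep only columns inside a run of >= min_run consecutive original indices."""
    out: list[int] = []
    run: list[int] = []
    for c in retained + [-10]:  # sentinel flushes the last run
        if run and c != run[-1] + 1:
            if len(run) >= min_run:
                out.extend(run)
            run = []
        run.append(c)
    return out


def trim_alignment(aln: Alignment, method: str = "strict") -> tuple[Alignment, TrimReport]:
    if method not in TRIM_METHODS:
        raise ValueError(f"unknown trim method '{method}' (choose from {TRIM_METHODS})")
    all_cols = list(range(aln.length))
    if method == "none":
        return aln, TrimReport("none", all_cols, None, None)
    if aln.n_rows < 2:
        raise TrimError(f"method '{method}' needs >= 2 rows (similarity needs pairs)")

    g = gap_fractions(aln)
    g_star = elbow_threshold(g)
    retained = [c for c in all_cols if g[c] <= g_star and g[c] < 1.0]
    s_star = None

    if method in ("strict", "strictplus"):
        s = similarity_scores(aln)
        s_star = elbow_threshold(s)
        retained = [c for c in retained if s[c] >= s_star]
        retained = _runs_filter(retained, 3)

    if method == "strictplus":
        retained = _runs_filter(retained, 5)
        kept = set(retained)
        retained = [
            c
            for c in retained
            if sum(
                1
                for nb in (c - 2, c - 1, c + 1, c + 2)
                if 0 <= nb < aln.length and nb not in kept
            )
            < 3
        ]

    if not retained:
        raise TrimError(
            f"trimming '{method}' removed every column of gene '{aln.gene_id}'; "
            "consider method 'none'"
        )
    report = TrimReport(method, retained, float(g_star), None if s_star is None else float(s_star))
    return aln.take_columns(retained), report
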