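"""Distance-based tree inference: the internal engine and external adapters.

The internal engine is Saitou-Nei neighbor joining on p or Poisson-corrected
protein distances, with column-bootstrap supports. It is fully deterministic
(tie-breaks by label, seeded resampling), which is what the pipeline's
reproducibility contract relies on. Adapters can invoke any external tree
program (FastTree, IQ-TREE, ...) through a command template.
"""

from __future__ import annotations

import logging
import math
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ExternalToolError, TreeError
from .tree import Node, PhyloTree

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "nj_tree",
    "bootstrap_tree",
    "external_tree",
    "DISTANCE_CAP",
]

DISTANCE_CAP = 3.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, entries in [0, DISTANCE_CAP]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise TreeError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise TreeError("distance matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise TreeError("distance matrix diagonal must be zero")
        self.matrix = m


def _pairwise_p(a: str, b: str) -> tuple[int, int]:
    """(mismatches, compared sites) over columns where both rows have residues."""
    mism = comp = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comp += 1
        if x != y:
            mism += 1
    return mism, comp


def distance_matrix(aln, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from an alignment ('p' or 'poisson').

    poisson = -ln(1 - p), capped at DISTANCE_CAP for saturated pairs; pairs
    with zero comparable sites also get the cap (and a logged warning).
    """
    if model not in {"p", "poisson"}:
        raise ValueError(f"unknown distance model '{model}'")
    labels = list(aln.rows)
    if len(labels) < 2:
        raise TreeError("distance matrix needs >= 2 rows")
    n = len(labels)
    sat_p = 1.0 - math.exp(-DISTANCE_CAP)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism, comp = _pairwise_p(aln.rows[labels[i]], aln.rows[labels[j]])
            if comp == 0:
                log.warning(
                    "rows %s and %s share no comparable sites; distance capped at %.1f",
                    labels[i], labels[j], DISTANCE_CAP,
                )
                d = DISTANCE_CAP
            else:
                p = mism / comp
                if model == "p":
                    d = p
                elif p >= sat_p:
                    d = DISTANCE_CAP
                else:
                    d = -math.log(1.0 - p)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Q-criterion ties break on the lexicographically smallest (representative
    label_i, label_j) pair; negative branch lengths are clamped to 0; output
    is unrooted (root of degree 3, or a 3-taxon star).
    """
    if not np.all(np.isfinite(dm.matrix)):
        raise TreeError("non-finite entries in distance matrix")
    n = len(dm.labels)
    if n < 3:
        if n == 2:
            d = dm.matrix[0, 1]
            return PhyloTree(
                Node(children=[Node(dm.labels[0], d / 2), Node(dm.labels[1], d / 2)])
            )
        raise TreeError("neighbor joining needs >= 2 labels")

    nodes: dict[str, Node] = {lab: Node(lab) for lab in dm.labels}
    reps = {lab: lab for lab in dm.labels}  # cluster -> smallest member label
    d = {
        (a, b): dm.matrix[i, j]
        for i, a in enumerate(dm.labels)
        for j, b in enumerate(dm.labels)
        if i < j
    }

    def dist(a, b):
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    active = sorted(dm.labels)
    fresh = iter(range(10**9))
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = tuple(sorted((reps[a], reps[b])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"\x00{next(fresh)}"
        nodes[a].length, nodes[b].length = la, lb
        nodes[new] = Node(children=[nodes[a], nodes[b]])
        reps[new] = min(reps[a], reps[b])
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = max(0.5 * (dist(a, c) + dist(b, c) - dab), 0.0)
        active = sorted((c for c in active if c not in (a, b)), key=lambda x: reps[x])
        active.append(new)
        active.sort(key=lambda x: reps[x])

    # final three clusters join at the unrooted center
    a, b, c = sorted(active, key=lambda x: reps[x])
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lab].length = max(ln, 0.0)
    return PhyloTree(Node(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_tree(aln, n_reps: int, seed: int, model: str = "poisson") -> PhyloTree:
    """Point NJ tree with column-bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement (seeded NumPy
    generator), re-estimates distances and a NJ tree; an edge's support is the
    fraction of replicates whose tree contains the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = nj_tree(distance_matrix(aln, model))
    if point.n_leaves < 4:
        return point
    counts = {s: 0 for s in point.nontrivial_splits()}
    rng = np.random.default_rng(seed)
    labels = list(aln.rows)
    cols = np.array([[aln.rows[lab][c] for c in range(aln.length)] for lab in labels])
    for _ in range(n_reps):
        idx = rng.integers(0, aln.length, size=aln.length)
        rows = {lab: "".join(cols[i, idx]) for i, lab in enumerate(labels)}
        rep_aln = aln.__class__(gene_id=aln.gene_id, rows=rows)
        rep_tree = nj_tree(distance_matrix(rep_aln, model))
        for s in rep_tree.nontrivial_splits():
            if s in counts:
                counts[s] += 1

    def annotate(node, taxa):
        if node.is_leaf:
            return frozenset([node.label])
        ls = frozenset().union(*(annotate(c, taxa) for c in node.children))
        from .tree import canonical_split

        key = canonical_split(ls, taxa)
        if key in counts and len(ls) > 1 and len(taxa - ls) > 1:
            node.support = counts[key] / n_reps
        return ls

    for child in point.root.children:
        annotate(child, point.leaf_labels)
    return point


def external_tree(input_path, command_template: str, extra_options: str = "") -> PhyloTree:
    """Run an external tree program through a shell command template.

    The template must contain ``{input}``/``{output}`` (or ``{in}``/``{out}``)
    placeholders; ``extra_options`` (e.g. the contents of a passthrough options
    file) is substituted for ``{options}`` or appended to the command.
    Supports in the resulting Newick are normalized to [0, 1] on read.
    """
    from .io import read_newick

    if not any(k in command_template for k in ("{output}", "{out}")):
        raise ValueError("command template lacks an output placeholder")
    with tempfile.TemporaryDirectory(prefix="corephylo_ext_") as tmp:
        out_path = Path(tmp) / "tree.nwk"
        mapping = {
            "input": str(input_path),
            "in": str(input_path),
            "output": str(out_path),
            "out": str(out_path),
            "options": extra_options,
        }
        cmd = command_template
        if extra_options and "{options}" not in cmd:
            cmd = cmd + " " + extra_options
        try:
            cmd = cmd.format(**mapping)
        except KeyError as exc:
            raise ValueError(f"unknown placeholder {exc} in command template") from None
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        diag = (proc.stdout or "") + (proc.stderr or "")
        if proc.returncode != 0:
            raise ExternalToolError(
                f"external tree command exited with status {proc.returncode}: {cmd}",
                diagnostics=diag,
            )
        if not out_path.exists():
            raise ExternalToolError(
                f"external tree command produced no output file: {cmd}", diagnostics=diag
            )
        text = out_path.read_text().strip()
        try:
            return read_newick(text)
        except Exception as exc:
            raise ExternalToolError(
                f"could not parse Newick from external tree command: {exc}",
                diagnostics=diag,
            ) from None
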