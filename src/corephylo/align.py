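"""Multiple sequence alignment of gene clusters.

The internal engine is a deterministic progressive aligner: a neighbor-joining
guide tree on 3-mer fractional-common-count distances, then profile-profile
global dynamic programming with BLOSUM62 and affine gaps (open -10, extend -1;
a run of g gap characters costs -(10 + (g - 1))). It is not meant to rival
MUSCLE or Clustal Omega column-for-column — an external aligner can be plugged
in through a command template — but it is exact in the pairwise case and
dependency-free.
"""

from __future__ import annotations

import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .errors import CorePhyloError, ExternalToolError

__all__ = ["Alignment", "align_cluster", "pairwise_align", "GAP_OPEN", "GAP_EXTEND"]

GAP_OPEN = -10.0
GAP_EXTEND = -1.0

_AA = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")
# dense 21x21 lookup (20 aa + everything-else bucket scored 0)
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_SCORE = np.zeros((21, 21))
for _a in _AA:
    for _b in _AA:
        _SCORE[_AA_INDEX[_a], _AA_INDEX[_b]] = _B62[_a, _b]


def _sym_index(ch: str) -> int:
    return _AA_INDEX.get(ch, 20)  # gaps and ambiguity codes score 0


@dataclass
class Alignment:
    """Aligned gene cluster: equal-length rows over residues + '-'."""

    gene_id: str
    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        lens = {len(r) for r in self.rows.values()}
        if len(lens) > 1:
            raise CorePhyloError(f"ragged alignment for gene '{self.gene_id}': row lengths {sorted(lens)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, c: int) -> list[str]:
        return [r[c] for r in self.rows.values()]

    def ungapped(self, label: str) -> str:
        return self.rows[label].replace("-", "")

    def take_columns(self, indices: list[int]) -> "Alignment":
        return Alignment(
            self.gene_id,
            {lab: "".join(row[i] for i in indices) for lab, row in self.rows.items()},
        )


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if min(len(a), len(b)) < k:
        return 1.0
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    common = sum(min(ca[x], cb[x]) for x in ca.keys() & cb.keys())
    frac = common / (min(len(a), len(b)) - k + 1)
    return max(1.0 - frac, 0.0)


def _profile_columns(rows: dict[str, str]) -> np.ndarray:
    """(length, 21) residue-count matrix of a profile."""
    length = len(next(iter(rows.values())))
    counts = np.zeros((length, 21))
    for row in rows.values():
        for i, ch in enumerate(row):
            counts[i, _sym_index(ch)] += 1
    return counts


def _profile_align(pa: dict[str, str], pb: dict[str, str]) -> dict[str, str]:
    """Global affine-gap DP between two profiles; gap columns are inserted
    into every row of the receiving profile. Column score = mean BLOSUM62 over
    all member pairs (pairs involving a gap contribute 0)."""
    ca, cb = _profile_columns(pa), _profile_columns(pb)
    na, nb = len(pa), len(pb)
    la, lb = ca.shape[0], cb.shape[0]
    S = (ca @ _SCORE @ cb.T) / (na * nb)

    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consumes A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consumes B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    jj = np.arange(lb + 1, dtype=float)
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        # X consumes A only, so the whole row is independent of j-1 entries
        Xi[:] = np.maximum(np.maximum(Mi1, Yi1) + GAP_OPEN, Xi1 + GAP_EXTEND)
        Mi[1:] = np.maximum(np.maximum(Mi1[:-1], Xi1[:-1]), Yi1[:-1]) + S[i - 1]
        # Y[i,j] = max(open(j), Y[i,j-1]+e) with open(j) = max(M,X)[i,j-1]+GAP_OPEN
        # = e*j + running-max of (open(j) - e*j): a max-plus prefix scan
        open_in = np.full(lb + 1, NEG)
        open_in[1:] = np.maximum(Mi[:-1], Xi[:-1]) + GAP_OPEN
        Yi[:] = GAP_EXTEND * jj + np.maximum.accumulate(open_in - GAP_EXTEND * jj)
        Yi[0] = NEG
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops = []  # 0: align columns, 1: gap in B, 2: gap in A
    while i > 0 or j > 0:
        if state == 0:
            ops.append(0)
            prev = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            i, j, state = i - 1, j - 1, prev
        elif state == 1:
            ops.append(1)
            open_sc = max(M[i - 1, j], Y[i - 1, j]) + GAP_OPEN
            ext_sc = X[i - 1, j] + GAP_EXTEND
            if ext_sc >= open_sc:
                state = 1
            else:
                state = 0 if M[i - 1, j] >= Y[i - 1, j] else 2
            i -= 1
        else:
            ops.append(2)
            open_sc = max(M[i, j - 1], X[i, j - 1]) + GAP_OPEN
            ext_sc = Y[i, j - 1] + GAP_EXTEND
            if ext_sc >= open_sc:
                state = 2
            else:
                state = 0 if M[i, j - 1] >= X[i, j - 1] else 1
            j -= 1
    ops.reverse()
    out: dict[str, list[str]] = {lab: [] for lab in list(pa) + list(pb)}
    i = j = 0
    for op in ops:
        if op == 0:
            for lab in pa:
                out[lab].append(pa[lab][i])
            for lab in pb:
                out[lab].append(pb[lab][j])
            i += 1
            j += 1
        elif op == 1:
            for lab in pa:
                out[lab].append(pa[lab][i])
            for lab in pb:
                out[lab].append("-")
            i += 1
        else:
            for lab in pa:
                out[lab].append("-")
            for lab in pb:
                out[lab].append(pb[lab][j])
            j += 1
    return {lab: "".join(chars) for lab, chars in out.items()}


def pairwise_align(a: str, b: str) -> tuple[str, str]:
    """Optimal global alignment of two sequences under the engine's scores."""
    merged = _profile_align({"\x00a": a}, {"\x00b": b})
    return merged["\x00a"], merged["\x00b"]


def align_cluster(cluster, engine: str = "internal", command_template: str | None = None) -> Alignment:
    """Align one gene cluster.

    ``engine='internal'`` runs the progressive aligner; ``'external'`` runs
    ``command_template`` (with {input}/{output} placeholders) on a FASTA of
    the cluster and reads the aligned FASTA back.
    """
    members = dict(cluster.members)
    gene_id = cluster.gene_id
    if not members:
        raise CorePhyloError(f"gene '{gene_id}': empty cluster")
    if len(members) == 1:
        return Alignment(gene_id, dict(members))
    if engine == "external":
        return _align_external(gene_id, members, command_template)
    if engine != "internal":
        raise ValueError(f"unknown alignment engine '{engine}'")

    labels = sorted(members)
    if len(labels) == 2:
        a, b = pairwise_align(members[labels[0]], members[labels[1]])
        return Alignment(gene_id, {labels[0]: a, labels[1]: b})

    from .treebuild import DistanceMatrix, nj_tree

    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _kmer_distance(members[labels[i]], members[labels[j]])
    guide = nj_tree(DistanceMatrix(labels, m))

    def merge(node) -> dict[str, str]:
        if node.is_leaf:
            return {node.label: members[node.label]}
        profiles = [merge(c) for c in node.children]
        acc = profiles[0]
        for p in profiles[1:]:
            acc = _profile_align(acc, p)
        return acc

    rows = merge(guide.root)
    return Alignment(gene_id, {lab: rows[lab] for lab in labels})


def _align_external(gene_id: str, members: dict[str, str], command_template: str | None) -> Alignment:
    from .io import read_fasta, write_fasta

    if not command_template:
        raise ValueError("external alignment engine needs a command template")
    with tempfile.TemporaryDirectory(prefix="corephylo_aln_") as tmp:
        inp = Path(tmp) / f"{gene_id}.faa"
        outp = Path(tmp) / f"{gene_id}.aln.faa"
        write_fasta(members, inp)
        cmd = command_template.format(
            **{"input": str(inp), "in": str(inp), "output": str(outp), "out": str(outp)}
        )
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        diag = (proc.stdout or "") + (proc.stderr or "")
        if proc.returncode != 0:
            raise ExternalToolError(f"external aligner failed for gene '{gene_id}': {cmd}", diag)
        if not outp.exists():
            raise ExternalToolError(f"external aligner wrote no output for gene '{gene_id}'", diag)
        return Alignment(gene_id, read_fasta(outp))
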