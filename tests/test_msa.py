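"""Internal aligner optimality and trimming mode behavior."""

import numpy as np
import pytest

from corephylo.align import (
    GAP_EXTEND,
    GAP_OPEN,
    _SCORE,
    _sym_index,
    Alignment,
    align_cluster,
    pairwise_align,
)
from corephylo.errors import TrimError
from corephylo.homolog import GeneCluster
from corephylo.trim import elbow_threshold, trim_alignment

AA = "ACDEFGHIKLMNPQRSTVWY"


def alignment_score(ra, rb):
    """Score of a given pairwise alignment under the engine's conventions."""
    sc, state = 0.0, None
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            st = "x" if y == "-" else "y"
            sc += GAP_EXTEND if state == st else GAP_OPEN
            state = st
        else:
            sc += _SCORE[_sym_index(x), _sym_index(y)]
            state = None
    return sc


def reference_dp_score(a, b):
    """Scalar-loop affine DP (independent of the vectorized implementation)."""
    NEG = -1e30
    la, lb = len(a), len(b)
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _SCORE[_sym_index(a[i - 1]), _sym_index(b[j - 1])]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND, Y[i - 1, j] + GAP_OPEN)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND, X[i, j - 1] + GAP_OPEN)
    return max(M[la, lb], X[la, lb], Y[la, lb])


class TestAligner:
    def test_identical_members_align_without_gaps(self):
        seq = "MKVLAEGHTRWQDNSPYCFI"
        aln = align_cluster(GeneCluster("g", {"a": seq, "b": seq, "c": seq}))
        assert all(row == seq for row in aln.rows.values())

    def test_single_member_passthrough(self):
        aln = align_cluster(GeneCluster("g", {"a": "MKVL"}))
        assert aln.rows == {"a": "MKVL"}

    def test_known_single_gap_case(self):
        a, b = pairwise_align("ACDE", "ACKDE")
        assert (a, b) == ("AC-DE", "ACKDE")

    @pytest.mark.parametrize("trial", range(10))
    def test_pairwise_is_dp_optimal(self, trial):
        rng = np.random.default_rng(trial)
        a = "".join(rng.choice(list(AA), rng.integers(3, 30)))
        b = "".join(rng.choice(list(AA), rng.integers(3, 30)))
        ra, rb = pairwise_align(a, b)
        assert ra.replace("-", "") == a and rb.replace("-", "") == b
        assert alignment_score(ra, rb) == pytest.approx(reference_dp_score(a, b), abs=1e-9)

    def test_rows_ungap_to_input_sequences(self, rng):
        members = {
            f"m{i}": "".join(rng.choice(list(AA), rng.integers(20, 30))) for i in range(5)
        }
        aln = align_cluster(GeneCluster("g", members))
        for lab, seq in members.items():
            assert aln.ungapped(lab) == seq

    def test_external_engine_stub(self, tmp_path):
        template = "cp {input} {output}"  # identical sequences: copy is a valid MSA
        cluster = GeneCluster("g", {"a": "MKVL", "b": "MKVL"})
        aln = align_cluster(cluster, engine="external", command_template=template)
        assert aln.rows == {"a": "MKVL", "b": "MKVL"}


def random_gapped_alignment(rng, n_rows=6, n_cols=40):
    rows = {}
    for r in range(n_rows):
        rows[f"s{r}"] = "".join(
            "-" if rng.random() < 0.25 else AA[rng.integers(0, 20)] for _ in range(n_cols)
        )
    return Alignment("g", rows)


class TestTrim:
    def test_conserved_ungapped_alignment_unchanged_by_all_methods(self):
        seq = "MKVLAEGHTRWQDNSPYCFI"
        aln = Alignment("g", {"a": seq, "b": seq, "c": seq})
        for method in ("gappyout", "strict", "strictplus", "none"):
            out, rep = trim_alignment(aln, method)
            assert out.rows == aln.rows
            assert rep.retained == list(range(len(seq)))

    def test_all_gap_column_removed_by_every_method(self):
        rows = {"a": "MKVL-AEGHT", "b": "MKVL-AEGHT", "c": "MKVL-AEGHT"}
        for method in ("gappyout", "strict", "strictplus"):
            out, rep = trim_alignment(Alignment("g", rows), method)
            assert 4 not in rep.retained
            assert "-" not in "".join(out.rows.values())

    def test_none_is_identity(self, rng):
        aln = random_gapped_alignment(rng)
        out, rep = trim_alignment(aln, "none")
        assert out.rows == aln.rows
        assert rep.retained == list(range(aln.length))

    @pytest.mark.parametrize("trial", range(20))
    def test_methods_nest_by_aggressiveness(self, trial):
        rng = np.random.default_rng(trial)
        aln = random_gapped_alignment(rng)
        retained = {}
        for method in ("gappyout", "strict", "strictplus"):
            try:
                _, rep = trim_alignment(aln, method)
                retained[method] = set(rep.retained)
            except TrimError:
                retained[method] = set()
        assert retained["strictplus"] <= retained["strict"] <= retained["gappyout"]

    def test_retained_columns_are_verbatim_subsets(self, rng):
        # semi-conserved alignment: a shared backbone with scattered noise
        base = "".join(rng.choice(list(AA), 40))
        rows = {}
        for r in range(6):
            rows[f"s{r}"] = "".join(
                "-" if rng.random() < 0.1
                else (AA[rng.integers(0, 20)] if rng.random() < 0.2 else ch)
                for ch in base
            )
        aln = Alignment("g", rows)
        out, rep = trim_alignment(aln, "strict")
        for lab in aln.rows:
            assert out.rows[lab] == "".join(aln.rows[lab][i] for i in rep.retained)

    def test_single_row_rejected_for_similarity_methods(self):
        aln = Alignment("g", {"a": "MKVL"})
        with pytest.raises(TrimError):
            trim_alignment(aln, "strict")

    def test_empty_result_recommends_none(self):
        aln = Alignment("g", {"a": "----", "b": "----"})
        with pytest.raises(TrimError, match="none"):
            trim_alignment(aln, "gappyout")

    def test_elbow_flat_curve_returns_minimum(self):
        assert elbow_threshold(np.zeros(10)) == 0.0
        assert elbow_threshold(np.full(5, 0.7)) == pytest.approx(0.7)

    def test_elbow_finds_low_cluster_boundary(self):
        v = np.array([0.0] * 5 + [0.9] * 15)
        assert elbow_threshold(v) == 0.0
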