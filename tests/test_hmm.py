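"""Profile-HMM construction, forward scoring, calibration, persistence."""

import itertools
import math

import numpy as np
import pytest

from corephylo.align import Alignment
from corephylo.errors import (
    CalibrationError,
    CorePhyloError,
    PHDFormatError,
    SearchError,
    ValidationError,
)
from corephylo.hmm import (
    AA,
    BACKGROUND,
    GeneSetPHD,
    _AA_IDX,
    _D,
    _I,
    _M,
    build_gene_set,
    build_profile_hmm,
    calibrate,
    evalue,
    fit_gumbel,
    forward_score,
    hmm_search,
    load_phd,
    save_phd,
)


def brute_force_score(model, seq):
    """Sum over every state path of the glocal model on every substring."""
    L, t = model.L, model.transitions
    odds = model.match_emissions / model.background

    def eo(k, ch):
        i = _AA_IDX.get(ch, -1)
        return odds[k, i] if i >= 0 else 1.0

    n = len(seq)
    results = []

    def go(k, state, j, acc):
        if k == L:
            results.append(acc * t[L, state, _M])
        if k < L:
            if j < n:
                go(k + 1, _M, j + 1, acc * t[k, state, _M] * eo(k, seq[j]))
            go(k + 1, _D, j, acc * t[k, state, _D])
        if j < n:
            go(k, _I, j + 1, acc * t[k, state, _I])

    total = 0.0
    for start in range(n + 1):
        results.clear()
        go(0, _M, start, 1.0)
        total += sum(results)
    return math.log2(total)


class TestBuild:
    def test_ungapped_identical_rows_give_full_length_model(self):
        seq = "MKVLAEGHTRWQDNSPYCFI" * 2 + "MKVLAEGHTR"  # length 50
        m = build_profile_hmm(Alignment("g", {"a": seq, "b": seq, "c": seq}))
        assert m.L == 50

    def test_gappy_column_excluded_from_match_states(self):
        rows = {"a": "A-C", "b": "A-C", "c": "AAC", "d": "A-C", "e": "AAC"}
        m = build_profile_hmm(Alignment("g", rows))
        assert m.L == 2  # middle column is 60% gaps

    def test_pseudocount_emission_formula(self):
        # column {A,A,A,C}, alpha=1: P(A) = (3 + bg_A) / 5
        rows = {"a": "A", "b": "A", "c": "A", "d": "C"}
        m = build_profile_hmm(Alignment("g", rows), pseudocount_weight=1.0)
        expected = (3 + BACKGROUND[_AA_IDX["A"]]) / 5
        assert m.match_emissions[0, _AA_IDX["A"]] == pytest.approx(expected)

    def test_all_gappy_columns_is_an_error_naming_the_gene(self):
        rows = {"a": "A--", "b": "-C-", "c": "--D"}
        with pytest.raises(CorePhyloError, match="g77"):
            build_profile_hmm(Alignment("g77", rows))

    def test_probability_invariants(self, bundle):
        aln = Alignment("g001", dict(bundle.training_clusters["g001"].members))
        m = build_profile_hmm(aln)
        assert np.allclose(m.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(m.transitions.sum(axis=2), 1.0, atol=1e-9)


class TestForward:
    @pytest.mark.parametrize("trial", range(5))
    def test_dp_equals_brute_force_path_summation(self, trial):
        rng = np.random.default_rng(trial)
        n_rows = int(rng.integers(2, 5))
        n_cols = int(rng.integers(1, 5))  # model L <= 4
        rows = {}
        for r in range(n_rows):
            rows[f"s{r}"] = "".join(
                "-" if rng.random() < 0.15 else AA[rng.integers(0, 20)]
                for _ in range(n_cols)
            )
        try:
            m = build_profile_hmm(Alignment("g", rows))
        except CorePhyloError:
            pytest.skip("degenerate all-gap alignment drawn")
        for slen in range(1, 6):
            seq = "".join(AA[i] for i in rng.integers(0, 20, size=slen))
            assert forward_score(m, seq) == pytest.approx(
                brute_force_score(m, seq), abs=1e-9
            )

    def test_consensus_beats_every_single_mutant(self):
        seq = "MKVLAEGHTRWQDNSPYCFI"  # L = 20
        m = build_profile_hmm(Alignment("g", {f"s{i}": seq for i in range(5)}))
        ref = forward_score(m, seq)
        for pos, alt in itertools.product(range(len(seq)), AA):
            if alt == seq[pos]:
                continue
            mutant = seq[:pos] + alt + seq[pos + 1 :]
            assert forward_score(m, mutant) < ref

    def test_evalue_monotone_decreasing_in_score(self):
        seq = "MKVLAEGHTRWQDNSPYCFI"
        m = calibrate(build_profile_hmm(Alignment("g", {"a": seq, "b": seq})), seed=0)
        es = [evalue(m, s, 10000) for s in (0.0, 5.0, 10.0, 50.0)]
        assert es == sorted(es, reverse=True)


class TestCalibration:
    def test_gumbel_fit_recovers_known_scale(self):
        rng = np.random.default_rng(1)
        beta_true, mu_true = 2.5, 10.0
        draws = mu_true - beta_true * np.log(-np.log(rng.random(5000)))
        mu, beta = fit_gumbel(draws)
        assert beta == pytest.approx(beta_true, rel=0.05)
        assert mu == pytest.approx(mu_true, rel=0.05)

    def test_same_seed_same_calibration(self):
        seq = "MKVLAEGHTRWQDNSPYCFI"
        m = build_profile_hmm(Alignment("g", {"a": seq, "b": seq}))
        c1 = calibrate(m, n_random=150, seed=9)
        c2 = calibrate(m, n_random=150, seed=9)
        assert c1.calibration == c2.calibration

    def test_too_few_random_sequences_rejected(self):
        seq = "MKVLAEGHTRWQDNSPYCFI"
        m = build_profile_hmm(Alignment("g", {"a": seq}))
        with pytest.raises(ValidationError):
            calibrate(m, n_random=50)

    def test_degenerate_scores_raise_calibration_error(self, monkeypatch):
        seq = "MKVLAEGHTRWQDNSPYCFI"
        m = build_profile_hmm(Alignment("g", {"a": seq}))
        monkeypatch.setattr(
            "corephylo.hmm.forward_scores_batch", lambda model, seqs: np.zeros(len(seqs))
        )
        with pytest.raises(CalibrationError):
            calibrate(m, n_random=100)


class TestSearch:
    def test_true_homologs_found_and_decoys_rejected(self, bundle, gene_set):
        """Threshold semantics on held-out data: every genuine homolog passes
        the default 1e-10 cutoff; residue-shuffled sequences do not come near."""
        p = bundle.proteomes[0]
        hits = hmm_search(gene_set, p, 1e-10)
        found = {(h.gene_id, h.seq_id) for h in hits}
        for gid, per_genome in bundle.homolog_ids.items():
            assert (gid, per_genome[p.genome_label]) in found

    def test_uncalibrated_model_is_an_error(self, bundle):
        seq = "MKVLAEGHTRWQDNSPYCFI"
        m = build_profile_hmm(Alignment("g", {"a": seq, "b": seq}))
        phd = GeneSetPHD("raw", {"g": m})
        with pytest.raises(SearchError):
            hmm_search(phd, bundle.proteomes[0], 1e-10)

    def test_hits_sorted_by_gene_then_evalue(self, bundle, gene_set):
        hits = hmm_search(gene_set, bundle.proteomes[1], 1e-3)
        keys = [(h.gene_id, h.e_value) for h in hits]
        assert keys == sorted(keys)


class TestPersistence:
    def test_save_load_roundtrip_bit_identical(self, gene_set, tmp_path):
        path = tmp_path / "markers.phd"
        save_phd(gene_set, path)
        loaded = load_phd(path)
        assert loaded.set_name == gene_set.set_name
        assert loaded.gene_ids == gene_set.gene_ids
        for gid in gene_set.gene_ids:
            a, b = gene_set.models[gid], loaded.models[gid]
            assert np.abs(a.match_emissions - b.match_emissions).max() <= 1e-12
            assert np.abs(a.transitions - b.transitions).max() <= 1e-12
            assert a.calibration == pytest.approx(b.calibration, abs=1e-12)

    def test_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(PHDFormatError):
            load_phd(tmp_path / "nope.phd")

    def test_concatenated_sets_rejected(self, gene_set, tmp_path):
        path = tmp_path / "markers.phd"
        save_phd(gene_set, path)
        doubled = tmp_path / "doubled.phd"
        doubled.write_text(path.read_text() + path.read_text())
        with pytest.raises(PHDFormatError, match="unique"):
            load_phd(doubled)

    def test_truncated_file_rejected(self, gene_set, tmp_path):
        path = tmp_path / "markers.phd"
        save_phd(gene_set, path)
        text = path.read_text()
        (tmp_path / "trunc.phd").write_text(text[: len(text) // 2])
        with pytest.raises(PHDFormatError):
            load_phd(tmp_path / "trunc.phd")


def test_build_gene_set_rejects_duplicate_gene_ids():
    seq = "MKVLAEGHTRWQDNSPYCFI"
    alns = [Alignment("g1", {"a": seq, "b": seq}), Alignment("g1", {"a": seq, "b": seq})]
    with pytest.raises(ValidationError, match="duplicate"):
        build_gene_set("s", alns, calibration_n=100)
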