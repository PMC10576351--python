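"""Profile HMMs of core-gene sets: build, calibrate, store, search.

One model per marker gene, built from a (training) cluster alignment. The
architecture is the classic match/insert/delete profile with glocal scoring:
the model is traversed in full (begin to end, deletions allowed) while the
target sequence's flanks are free, which suits full-length marker detection.
Scores are forward log-odds in bits against a fixed background (standard
amino-acid frequencies). E-values come from a Gumbel tail fitted to scores of
background-sampled random sequences at build time:

    E(score) = k * n_db_residues * exp(-lambda * score)

with lambda = 1/beta and k = exp(mu/beta)/L from the method-of-moments fit
(mu location, beta scale). These E-values carry the same *threshold
semantics* as an external hmmsearch run but are not numerically HMMER's; the
tblout reader in :mod:`corephylo.io` gives exact interop when real HMMER
output is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .align import Alignment
from .errors import CalibrationError, CorePhyloError, PHDFormatError, SearchError, ValidationError
from .io import HitRecord, ProteomeRecord

__all__ = [
    "ProfileHMM",
    "GeneSetPHD",
    "BACKGROUND",
    "build_profile_hmm",
    "build_gene_set",
    "calibrate",
    "fit_gumbel",
    "forward_score",
    "forward_scores_batch",
    "hmm_search",
    "save_phd",
    "load_phd",
    "DEFAULT_EVALUE",
]

DEFAULT_EVALUE = 1e-10
AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(AA)}
_EULER_GAMMA = 0.5772156649015329

# Robinson & Robinson (1991) amino-acid frequencies, normalized to sum 1
_RR = {
    "A": 0.078047, "C": 0.019246, "D": 0.053637, "E": 0.062949, "F": 0.038556,
    "G": 0.073772, "H": 0.021992, "I": 0.051420, "K": 0.057438, "L": 0.090191,
    "M": 0.022425, "N": 0.044873, "P": 0.052028, "Q": 0.042644, "R": 0.051269,
    "S": 0.071198, "T": 0.058413, "V": 0.064409, "W": 0.013298, "Y": 0.032165,
}
BACKGROUND = np.array([_RR[a] for a in AA])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

_M, _I, _D = 0, 1, 2  # state indices in transition tables


@dataclass
class ProfileHMM:
    """Match/insert/delete profile model of one marker gene.

    ``transitions`` has shape (L+1, 3, 3): row k holds the outgoing
    probabilities of M_k/I_k/D_k towards (M_{k+1}, I_k, D_{k+1}); k=0 is the
    begin state and k=L routes to the end state (its D destination is 0).
    """

    gene_id: str
    L: int
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (20,)
    transitions: np.ndarray  # (L+1, 3, 3)
    background: np.ndarray  # (20,)
    calibration: tuple[float, float] | None = None  # (lambda, k)
    trained_on: int = 0

    def __post_init__(self):
        if self.L < 1:
            raise CorePhyloError(f"gene '{self.gene_id}': L must be >= 1")
        me = np.asarray(self.match_emissions, float)
        if me.shape != (self.L, 20) or not np.allclose(me.sum(axis=1), 1.0, atol=1e-9):
            raise CorePhyloError(f"gene '{self.gene_id}': match emission rows must sum to 1")
        tr = np.asarray(self.transitions, float)
        if tr.shape != (self.L + 1, 3, 3) or not np.allclose(tr.sum(axis=2), 1.0, atol=1e-9):
            raise CorePhyloError(f"gene '{self.gene_id}': outgoing transitions must sum to 1")
        if self.calibration is not None and not self.calibration[0] > 0:
            raise CorePhyloError(f"gene '{self.gene_id}': lambda must be > 0")

    @property
    def is_calibrated(self) -> bool:
        return self.calibration is not None


@dataclass
class GeneSetPHD:
    """A named, ordered collection of per-gene profile HMMs."""

    set_name: str
    models: dict[str, ProfileHMM] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        if not self.models:
            raise ValidationError(f"gene set '{self.set_name}' is empty")
        for gid, m in self.models.items():
            if gid != m.gene_id:
                raise ValidationError(f"model key '{gid}' != model gene_id '{m.gene_id}'")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.models)


def build_profile_hmm(cluster_alignment: Alignment, pseudocount_weight: float = 1.0) -> ProfileHMM:
    """Estimate a profile HMM from a gene-cluster alignment.

    Match states are the columns with gap fraction <= 0.5 (in order); the
    match emission of residue a in column c is
    (count_a(c) + alpha * bg_a) / (residues(c) + alpha), alpha being the
    pseudocount weight. Transition probabilities come from the observed state
    paths with add-one smoothing. Insert emissions equal the background.
    """
    if pseudocount_weight <= 0:
        raise ValidationError("pseudocount_weight must be positive")
    rows = list(cluster_alignment.rows.values())
    if not rows:
        raise CorePhyloError(f"gene '{cluster_alignment.gene_id}': empty alignment")
    n_cols = cluster_alignment.length
    gapfrac = [sum(1 for r in rows if r[c] == "-") / len(rows) for c in range(n_cols)]
    match_cols = [c for c in range(n_cols) if gapfrac[c] <= 0.5]
    if not match_cols:
        raise CorePhyloError(
            f"gene '{cluster_alignment.gene_id}': all columns are >50% gaps; cannot build a model"
        )
    L = len(match_cols)
    alpha = pseudocount_weight

    emissions = np.zeros((L, 20))
    for k, c in enumerate(match_cols):
        counts = np.zeros(20)
        n_res = 0
        for r in rows:
            idx = _AA_IDX.get(r[c])
            if idx is not None:
                counts[idx] += 1
                n_res += 1
        emissions[k] = (counts + alpha * BACKGROUND) / (n_res + alpha)

    # observed state paths: match column -> M or D; inter-match residues -> I
    tcounts = np.zeros((L + 1, 3, 3))
    match_set = {c: k for k, c in enumerate(match_cols)}
    for r in rows:
        state, pos = _M, 0  # begin = M_0
        for c in range(n_cols):
            if c in match_set:
                k = match_set[c] + 1
                nxt = _M if r[c] != "-" else _D
                tcounts[pos, state, nxt] += 1
                state, pos = nxt, k
            elif r[c] != "-":
                tcounts[pos, state, _I] += 1
                state = _I
        tcounts[pos, state, _M] += 1  # exit to end

    tcounts += 1.0  # add-one smoothing
    tcounts[L, :, _D] = 0.0  # no delete state beyond the last match
    transitions = tcounts / tcounts.sum(axis=2, keepdims=True)

    return ProfileHMM(
        gene_id=cluster_alignment.gene_id,
        L=L,
        match_emissions=emissions,
        insert_emissions=BACKGROUND.copy(),
        transitions=transitions,
        background=BACKGROUND.copy(),
        trained_on=len(rows),
    )


def forward_scores_batch(model: ProfileHMM, seqs: list[str]) -> np.ndarray:
    """Glocal forward log-odds scores in bits for equal-length sequences.

    Sums over all alignments of the full model to any substring (flanks
    free); emission odds of non-standard residues (X, B, Z, U, *) are 1,
    i.e. they are scored as background. Batching over sequences of one length
    keeps the dynamic program vectorized in both the batch and the position
    dimension (the insert self-loop is a linear recurrence, solved with an
    IIR filter).
    """
    if not seqs:
        return np.empty(0)
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("forward_scores_batch needs equal-length sequences")
    B = len(seqs)
    if n == 0:
        return np.full(B, -np.inf)
    L, t = model.L, model.transitions
    odds = model.match_emissions / model.background  # (L, 20)
    sym = np.array([[_AA_IDX.get(ch, -1) for ch in s] for s in seqs])  # (B, n)
    valid = sym >= 0

    fM = np.ones((B, n + 1))  # level 0: begin reachable after any free flank
    fD = np.zeros((B, n + 1))
    # I_0 (inserts before the first match; redundant with the free flank but
    # part of the generative model)
    inflow = np.zeros((B, n + 1))
    inflow[:, 1:] = fM[:, :-1] * t[0, _M, _I]
    fI = lfilter([1.0], [1.0, -t[0, _I, _I]], inflow, axis=1)

    log_scale = np.zeros(B)
    for k in range(1, L + 1):
        eo_k = np.where(valid, odds[k - 1][np.clip(sym, 0, 19)], 1.0)  # (B, n)
        newM = np.zeros((B, n + 1))
        newM[:, 1:] = eo_k * (
            fM[:, :-1] * t[k - 1, _M, _M]
            + fI[:, :-1] * t[k - 1, _I, _M]
            + fD[:, :-1] * t[k - 1, _D, _M]
        )
        newD = fM * t[k - 1, _M, _D] + fI * t[k - 1, _I, _D] + fD * t[k - 1, _D, _D]
        inflow = np.zeros((B, n + 1))
        inflow[:, 1:] = newM[:, :-1] * t[k, _M, _I] + newD[:, :-1] * t[k, _D, _I]
        newI = lfilter([1.0], [1.0, -t[k, _I, _I]], inflow, axis=1)
        fM, fI, fD = newM, newI, newD
        peak = np.maximum(
            fM.max(axis=1), np.maximum(fI.max(axis=1), fD.max(axis=1))
        )
        needs = (peak > 0) & ((peak > 1e200) | (peak < 1e-200))
        if needs.any():
            scale = np.where(needs, peak, 1.0)[:, None]
            fM, fI, fD = fM / scale, fI / scale, fD / scale
            log_scale += np.where(needs, np.log2(np.where(needs, peak, 1.0)), 0.0)

    fE = fM * t[L, _M, _M] + fI * t[L, _I, _M] + fD * t[L, _D, _M]
    total = fE.sum(axis=1)  # free right flank: end at any position
    with np.errstate(divide="ignore"):
        return np.where(total > 0, np.log2(np.maximum(total, 1e-320)) + log_scale, -np.inf)


def forward_score(model: ProfileHMM, seq: str) -> float:
    """Glocal forward log-odds score of one sequence, in bits."""
    return float(forward_scores_batch(model, [seq])[0])


def calibrate(model: ProfileHMM, n_random: int = 200, seed: int = 0) -> ProfileHMM:
    """Fit the Gumbel E-value constants on background-sampled sequences.

    Scores ``n_random`` i.i.d. background sequences of length L and fits the
    Gumbel by the method of moments. Deterministic given ``seed``.
    """
    if n_random < 100:
        raise ValidationError(f"n_random must be >= 100, got {n_random}")
    rng = np.random.default_rng(seed)
    seqs = [
        "".join(rng.choice(list(AA), size=model.L, p=model.background))
        for _ in range(n_random)
    ]
    scores = forward_scores_batch(model, seqs)
    try:
        mu, beta = fit_gumbel(scores)
    except ValueError:
        raise CalibrationError(
            f"gene '{model.gene_id}': degenerate calibration score distribution"
        ) from None
    lam = 1.0 / beta
    k = math.exp(mu / beta) / model.L
    return replace(model, calibration=(lam, k))


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: (location mu, scale beta)."""
    scores = np.asarray(scores, float)
    sd = scores.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or non-finite score variance")
    beta = sd * math.sqrt(6.0) / math.pi
    mu = scores.mean() - _EULER_GAMMA * beta
    return float(mu), float(beta)


def evalue(model: ProfileHMM, score: float, n_db_residues: int) -> float:
    if not model.is_calibrated:
        raise SearchError(f"model '{model.gene_id}' is not calibrated")
    lam, k = model.calibration
    log_e = math.log(k) + math.log(max(n_db_residues, 1)) - lam * score
    return math.exp(min(max(log_e, -700.0), 700.0))


def hmm_search(
    phd: GeneSetPHD,
    proteome: ProteomeRecord,
    evalue_threshold: float = DEFAULT_EVALUE,
) -> list[HitRecord]:
    """Search every model of the set against every proteome sequence.

    Returns hits with E <= threshold, sorted by (gene_id, E ascending).
    """
    if not evalue_threshold > 0:
        raise ValidationError("evalue_threshold must be > 0")
    for m in phd.models.values():
        if not m.is_calibrated:
            raise SearchError(f"model '{m.gene_id}' in set '{phd.set_name}' is not calibrated")
    if not proteome.sequences:
        return []
    n_db = proteome.n_residues
    by_length: dict[int, list[str]] = {}
    for sid, seq in proteome.sequences.items():
        by_length.setdefault(len(seq), []).append(sid)
    hits = []
    for gid, model in phd.models.items():
        scored: list[tuple[str, float]] = []
        for length, sids in by_length.items():
            batch = forward_scores_batch(model, [proteome.sequences[s] for s in sids])
            scored.extend(zip(sids, batch))
        for sid, score in scored:
            if not math.isfinite(score):
                continue
            e = evalue(model, float(score), n_db)
            if e <= evalue_threshold:
                hits.append(
                    HitRecord(
                        genome_label=proteome.genome_label,
                        seq_id=sid,
                        gene_id=gid,
                        bit_score=float(score),
                        e_value=max(e, 5e-324),
                    )
                )
    hits.sort(key=lambda h: (h.gene_id, h.e_value, h.seq_id))
    return hits


def build_gene_set(
    set_name: str,
    cluster_alignments: list[Alignment],
    pseudocount_weight: float = 1.0,
    calibration_n: int = 200,
    seed: int = 0,
    provenance: str = "",
) -> GeneSetPHD:
    """Build + calibrate one model per training-cluster alignment."""
    models: dict[str, ProfileHMM] = {}
    for i, aln in enumerate(sorted(cluster_alignments, key=lambda a: a.gene_id)):
        if aln.gene_id in models:
            raise ValidationError(f"duplicate gene_id '{aln.gene_id}' in gene set '{set_name}'")
        m = build_profile_hmm(aln, pseudocount_weight)
        models[aln.gene_id] = calibrate(m, calibration_n, seed=(seed + 7919 * i) % 2**31)
    return GeneSetPHD(set_name=set_name, models=models, provenance=provenance)


# ------------------------------------------------------------------ persistence
_PHD_MAGIC = "#corephylo-phd v1"


def _fmt_row(row) -> str:
    return " ".join(f"{x:.17g}" for x in np.atleast_1d(row))


def save_phd(phd: GeneSetPHD, path) -> None:
    """Lossless, versioned text serialization of a gene set."""
    with open(path, "w") as fh:
        fh.write(_PHD_MAGIC + "\n")
        fh.write(f"set_name\t{phd.set_name}\n")
        fh.write(f"provenance\t{phd.provenance}\n")
        fh.write(f"n_genes\t{len(phd.models)}\n")
        for gid, m in phd.models.items():
            fh.write(f"GENE\t{gid}\n")
            fh.write(f"L\t{m.L}\n")
            fh.write(f"trained_on\t{m.trained_on}\n")
            if m.calibration is None:
                fh.write("calibration\tnone\n")
            else:
                fh.write(f"calibration\t{m.calibration[0]:.17g} {m.calibration[1]:.17g}\n")
            fh.write(f"background\t{_fmt_row(m.background)}\n")
            fh.write(f"insert\t{_fmt_row(m.insert_emissions)}\n")
            for k in range(m.L):
                fh.write(f"match\t{_fmt_row(m.match_emissions[k])}\n")
            for k in range(m.L + 1):
                fh.write(f"trans\t{_fmt_row(m.transitions[k].ravel())}\n")
        fh.write("END\n")


def load_phd(path) -> GeneSetPHD:
    p = Path(path)
    if not p.exists():
        raise PHDFormatError(f"PHD file '{path}' does not exist")
    lines = p.read_text().splitlines()
    if not lines or lines[0] != _PHD_MAGIC:
        raise PHDFormatError(f"'{path}' is not a corephylo PHD v1 file")
    if sum(1 for ln in lines if ln == _PHD_MAGIC) > 1 or sum(
        1 for ln in lines if ln.startswith("set_name\t")
    ) > 1:
        raise PHDFormatError(f"'{path}' contains multiple gene sets; set names must be unique")
    it = iter(lines[1:])

    def expect(tag: str) -> str:
        try:
            line = next(it)
        except StopIteration:
            raise PHDFormatError(f"'{path}' is truncated (expected '{tag}')") from None
        key, _, val = line.partition("\t")
        if key != tag:
            raise PHDFormatError(f"'{path}': expected '{tag}', found '{key}'")
        return val

    set_name = expect("set_name")
    provenance = expect("provenance")
    n_genes = int(expect("n_genes"))
    models: dict[str, ProfileHMM] = {}
    for _ in range(n_genes):
        gid = expect("GENE")
        L = int(expect("L"))
        trained_on = int(expect("trained_on"))
        cal_raw = expect("calibration")
        calibration = None if cal_raw == "none" else tuple(float(x) for x in cal_raw.split())
        background = np.array([float(x) for x in expect("background").split()])
        insert = np.array([float(x) for x in expect("insert").split()])
        match = np.array([[float(x) for x in expect("match").split()] for _ in range(L)])
        trans = np.array(
            [[float(x) for x in expect("trans").split()] for _ in range(L + 1)]
        ).reshape(L + 1, 3, 3)
        models[gid] = ProfileHMM(
            gene_id=gid,
            L=L,
            match_emissions=match,
            insert_emissions=insert,
            transitions=trans,
            background=background,
            calibration=calibration,
            trained_on=trained_on,
        )
    try:
        if next(it) != "END":
            raise PHDFormatError(f"'{path}': missing END marker")
    except StopIteration:
        raise PHDFormatError(f"'{path}' is truncated (missing END)") from None
    return GeneSetPHD(set_name=set_name, models=models, provenance=provenance)
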