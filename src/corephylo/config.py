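"""Run configuration: the full pipeline option surface with defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError
from .trim import TRIM_METHODS

__all__ = ["RunConfig", "validate_config", "TREE_MODES", "TREE_APPS"]

TREE_MODES = ("sm", "st", "cs")
TREE_APPS = ("internal", "fasttree", "iqtree")

# default command templates for the external tree programs
TREE_APP_TEMPLATES = {
    "fasttree": "fasttree -quiet -nopr {options} {input} > {output}",
    "iqtree": "iqtree2 -s {input} -m LG {options} --prefix {output}_iq -redo "
    "&& cp {output}_iq.treefile {output}",
}


@dataclass
class RunConfig:
    """Every pipeline option, with the documented defaults.

    ``hmm_set`` names a profile-HMM gene set: either a direct path to a .phd
    file or a set name resolved as ``<phd_dir>/<hmm_set>.phd``.
    """

    proteome_dir: str
    hmm_set: str = "bac120"
    phd_dir: str = "phd"
    evalue: float = 1e-10
    genome_cutoff: float = 0.8
    gene_cutoff: float = 0.8
    trim_method: str = "strict"
    tree_mode: str = "sm"
    tree_app: str = "internal"
    align_engine: str = "internal"
    align_command: str | None = None
    tree_command: str | None = None
    bootstrap_reps: int = 100
    threads: int = 1
    seed: int = 42
    outdir: str = "corephylo_out"

    def phd_path(self) -> Path:
        direct = Path(self.hmm_set)
        if direct.is_file():
            return direct
        return Path(self.phd_dir) / f"{self.hmm_set}.phd"


def validate_config(cfg: RunConfig) -> tuple[RunConfig, list[str]]:
    """Check invariants and cross-option consistency.

    Returns a normalized copy plus human-readable notices. Consensus mode
    silently forces gene_cutoff to 1 (with a notice) so every taxon is present
    in every gene tree.
    """
    notices: list[str] = []
    if not cfg.evalue > 0:
        raise ValidationError(f"evalue must be > 0, got {cfg.evalue}")
    for name in ("genome_cutoff", "gene_cutoff"):
        v = getattr(cfg, name)
        if not 0 <= v <= 1:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    if cfg.trim_method not in TRIM_METHODS:
        raise ValidationError(f"unknown trim method '{cfg.trim_method}' (choose from {TRIM_METHODS})")
    if cfg.tree_mode not in TREE_MODES:
        raise ValidationError(f"unknown tree mode '{cfg.tree_mode}' (choose from {TREE_MODES})")
    if cfg.tree_app not in TREE_APPS:
        raise ValidationError(f"unknown tree app '{cfg.tree_app}' (choose from {TREE_APPS})")
    if cfg.align_engine not in ("internal", "external"):
        raise ValidationError(f"unknown alignment engine '{cfg.align_engine}'")
    if cfg.bootstrap_reps < 1:
        raise ValidationError("bootstrap_reps must be >= 1")
    if cfg.threads < 1:
        raise ValidationError("threads must be >= 1")
    if not cfg.phd_path().is_file():
        raise ValidationError(
            f"unknown hmm set '{cfg.hmm_set}': no file at '{cfg.phd_path()}' "
            "(build one with 'corephylo phd build')"
        )
    out = dataclasses.replace(cfg)
    if cfg.tree_mode == "cs" and cfg.gene_cutoff != 1:
        out = dataclasses.replace(out, gene_cutoff=1.0)
        notices.append(
            f"consensus mode requires every taxon in every gene tree: "
            f"gene_cutoff {cfg.gene_cutoff} -> 1"
        )
    if cfg.tree_mode == "st" and cfg.gene_cutoff == 1:
        notices.append(
            "supertree mode does not require complete gene clusters; "
            "gene_cutoff=1 may discard usable genes"
        )
    return out, notices
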