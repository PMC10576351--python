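"""Hit screening and core-gene cluster extraction.

The central object is the :class:`PresenceTable` — a gene x genome matrix
holding at most the single best hit per cell. Prevalence cutoffs act on it in
two passes, genomes first: genomes detecting too small a fraction of the gene
set are dropped, then genes too rare among the *retained* genomes. Genome
fractions are not recomputed after gene exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConsistencyError, CutoffError
from .io import HitRecord, ProteomeRecord

__all__ = [
    "PresenceTable",
    "GeneCluster",
    "ExclusionReport",
    "select_top_hits",
    "apply_cutoffs",
    "extract_clusters",
    "prevalence_report",
    "MIN_RETAINED_GENOMES",
]

MIN_RETAINED_GENOMES = 4  # smallest informative unrooted phylogeny


@dataclass
class PresenceTable:
    genes: list[str]
    genomes: list[str]
    cells: dict[tuple[str, str], HitRecord] = field(default_factory=dict)

    def __post_init__(self):
        for (g, m) in self.cells:
            if g not in set(self.genes) or m not in set(self.genomes):
                raise ConsistencyError(f"cell ({g}, {m}) outside the declared gene/genome lists")

    def n_detected(self, genome: str) -> int:
        return sum(1 for (g, m) in self.cells if m == genome)

    def n_present(self, gene: str) -> int:
        return sum(1 for (g, m) in self.cells if g == gene)


@dataclass
class GeneCluster:
    gene_id: str
    members: dict[str, str]  # genome_label -> amino-acid sequence

    def __post_init__(self):
        for lab, seq in self.members.items():
            if not seq:
                raise ConsistencyError(f"empty sequence for genome '{lab}' in gene '{self.gene_id}'")


@dataclass
class ExclusionRow:
    kind: str  # "genome" | "gene"
    name: str
    fraction: float
    cutoff: float


@dataclass
class ExclusionReport:
    rows: list[ExclusionRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.kind, r.name, r.fraction, r.cutoff) for r in self.rows],
            columns=["kind", "name", "fraction", "cutoff"],
        )


def select_top_hits(
    hits: list[HitRecord],
    evalue_threshold: float,
    genes: list[str] | None = None,
    genomes: list[str] | None = None,
) -> PresenceTable:
    """Screen the top hit of each (gene, genome) cell at the E-value threshold.

    The best hit has the minimal E-value; ties break on higher bit score, then
    on the lexicographically smallest seq_id. ``genes``/``genomes`` fix the
    table universe (e.g. all genes of the HMM set, all input genomes); by
    default they are inferred from the hits themselves.
    """
    kept = [h for h in hits if h.e_value <= evalue_threshold]
    cells: dict[tuple[str, str], HitRecord] = {}
    for h in kept:
        key = (h.gene_id, h.genome_label)
        prev = cells.get(key)
        if prev is None or (h.e_value, -h.bit_score, h.seq_id) < (
            prev.e_value,
            -prev.bit_score,
            prev.seq_id,
        ):
            cells[key] = h
    gene_list = list(genes) if genes is not None else sorted({h.gene_id for h in kept})
    genome_list = list(genomes) if genomes is not None else sorted({h.genome_label for h in kept})
    cells = {
        k: v for k, v in cells.items() if k[0] in set(gene_list) and k[1] in set(genome_list)
    }
    return PresenceTable(gene_list, genome_list, cells)


def apply_cutoffs(
    table: PresenceTable, genome_cutoff: float, gene_cutoff: float
) -> tuple[PresenceTable, ExclusionReport]:
    """Two-pass prevalence filter (genomes, then genes over retained genomes)."""
    for name, v in (("genome_cutoff", genome_cutoff), ("gene_cutoff", gene_cutoff)):
        if not 0 <= v <= 1:
            raise CutoffError(f"{name} must be in [0, 1], got {v}")
    if not table.genes or not table.genomes:
        raise CutoffError("empty presence table")
    report = ExclusionReport()
    n_genes = len(table.genes)
    kept_genomes = []
    for m in table.genomes:
        frac = table.n_detected(m) / n_genes
        if frac < genome_cutoff:
            report.rows.append(ExclusionRow("genome", m, frac, genome_cutoff))
        else:
            kept_genomes.append(m)
    if not kept_genomes:
        raise CutoffError(
            f"genome_cutoff={genome_cutoff} excluded every genome; lower the cutoff"
        )
    if len(kept_genomes) < MIN_RETAINED_GENOMES:
        raise CutoffError(
            f"only {len(kept_genomes)} genome(s) retained (< {MIN_RETAINED_GENOMES}); "
            "no meaningful unrooted phylogeny — lower genome_cutoff"
        )
    kept_set = set(kept_genomes)
    kept_genes = []
    for g in table.genes:
        present = sum(1 for (gg, m) in table.cells if gg == g and m in kept_set)
        frac = present / len(kept_genomes)
        if frac < gene_cutoff:
            report.rows.append(ExclusionRow("gene", g, frac, gene_cutoff))
        else:
            kept_genes.append(g)
    cells = {
        (g, m): h
        for (g, m), h in table.cells.items()
        if g in set(kept_genes) and m in kept_set
    }
    return PresenceTable(kept_genes, kept_genomes, cells), report


def extract_clusters(
    table: PresenceTable, proteomes: list[ProteomeRecord]
) -> list[GeneCluster]:
    """One cluster per retained gene; each member is the proteome sequence of
    the cell's top hit. Clusters come back ordered by gene_id."""
    by_label = {p.genome_label: p for p in proteomes}
    clusters = []
    for gene in sorted(table.genes):
        members: dict[str, str] = {}
        for genome in table.genomes:
            hit = table.cells.get((gene, genome))
            if hit is None:
                continue
            prot = by_label.get(genome)
            if prot is None:
                raise ConsistencyError(f"cell ({gene}, {genome}): genome not among the proteomes")
            seq = prot.sequences.get(hit.seq_id)
            if seq is None:
                raise ConsistencyError(
                    f"cell ({gene}, {genome}): seq_id '{hit.seq_id}' not found in proteome"
                )
            members[genome] = seq
        if members:
            clusters.append(GeneCluster(gene, members))
    return clusters


def prevalence_report(table: PresenceTable) -> pd.DataFrame:
    """Per-gene and per-genome detection counts and fractions (TSV-ready)."""
    rows = []
    n_genomes, n_genes = len(table.genomes), len(table.genes)
    for g in table.genes:
        c = table.n_present(g)
        rows.append(("gene", g, c, c / n_genomes if n_genomes else 0.0))
    for m in table.genomes:
        c = table.n_detected(m)
        rows.append(("genome", m, c, c / n_genes if n_genes else 0.0))
    return pd.DataFrame(rows, columns=["kind", "name", "count", "fraction"])
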