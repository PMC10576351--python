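"""Concatenation of trimmed gene alignments into a supermatrix.

Genes are concatenated in lexicographic gene_id order; a taxon absent from a
gene cluster contributes a gap-only segment of that gene's trimmed length.
Partition coordinates are 1-based inclusive and tile [1, L] contiguously.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import Alignment
from .errors import CorePhyloError

__all__ = ["Supermatrix", "concatenate", "write_partitions", "read_partitions"]


@dataclass
class Partition:
    gene_id: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class Supermatrix:
    taxa: list[str]
    matrix: dict[str, str]
    partitions: list[Partition]

    @property
    def length(self) -> int:
        return self.partitions[-1].end if self.partitions else 0

    def to_alignment(self) -> Alignment:
        return Alignment("supermatrix", dict(self.matrix))


def concatenate(alignments: list[Alignment], taxa: list[str]) -> Supermatrix:
    if not alignments:
        raise CorePhyloError("no alignments to concatenate")
    if len(set(taxa)) != len(taxa):
        dups = sorted({t for t in taxa if taxa.count(t) > 1})
        raise CorePhyloError(f"duplicate taxa: {dups}")
    taxon_set = set(taxa)
    for aln in alignments:
        stray = set(aln.rows) - taxon_set
        if stray:
            raise CorePhyloError(
                f"alignment '{aln.gene_id}' contains labels not in the taxon list: {sorted(stray)}"
            )
    ordered = sorted(alignments, key=lambda a: a.gene_id)
    parts: list[Partition] = []
    segments: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for aln in ordered:
        glen = aln.length
        parts.append(Partition(aln.gene_id, pos, pos + glen - 1))
        pos += glen
        for t in taxa:
            segments[t].append(aln.rows.get(t, "-" * glen))
    return Supermatrix(list(taxa), {t: "".join(segments[t]) for t in taxa}, parts)


def write_partitions(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for p in sm.partitions:
            fh.write(f"PROT, {p.gene_id} = {p.start}-{p.end}\n")


def read_partitions(path) -> list[Partition]:
    parts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            _, rest = line.split(",", 1)
            gene, coords = rest.split("=")
            start, end = coords.strip().split("-")
            parts.append(Partition(gene.strip(), int(start), int(end)))
    return parts


def write_supermatrix_fasta(sm: Supermatrix, path) -> None:
    from .io import write_fasta

    write_fasta(sm.matrix, path)


def write_supermatrix_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: full labels, single space separator."""
    with open(path, "w") as fh:
        fh.write(f" {len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.matrix[t]}\n")
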