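"""Readers/writers and input validation.

FASTA parsing goes through Biopython; Newick parsing through dendropy (the
writer is ours, so lengths and supports are emitted with a fixed ``%.12g``
format and internal-node labels carry supports). HMMER3 per-target tabular
("tblout") files from an external ``hmmsearch`` run can be loaded directly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO

from .errors import (
    FormatError,
    NewickParseError,
    SequenceTypeError,
    TreeError,
    ValidationError,
)
from .tree import Node, PhyloTree

log = logging.getLogger("corephylo")

__all__ = [
    "ProteomeRecord",
    "HitRecord",
    "format_label",
    "format_labels",
    "read_proteome_dir",
    "write_proteome",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_hmmer_tblout",
    "MIN_PROTEOMES",
]

MIN_PROTEOMES = 5

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | set("XBZU*")
_NUC_CHARS = set("ACGTUN-")
_NUC_FRACTION = 0.90
_FASTA_EXTENSIONS = {"faa", "fa", "fasta", "fas", "pep", "aa", "txt"}
_LABEL_SAFE = re.compile(r"[^A-Za-z0-9_.\-]")


@dataclass
class ProteomeRecord:
    """All amino-acid sequences of one genome."""

    genome_label: str
    source_filename: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequences:
            raise ValidationError(f"proteome '{self.source_filename}' has no sequences")
        for sid, seq in self.sequences.items():
            bad = set(seq.upper()) - AA_ALPHABET
            if bad:
                raise SequenceTypeError(
                    f"sequence '{sid}' in '{self.source_filename}' has non-amino-acid "
                    f"characters: {sorted(bad)}"
                )

    @property
    def n_residues(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class HitRecord:
    """One profile-HMM hit of a gene model against a proteome sequence."""

    genome_label: str
    seq_id: str
    gene_id: str
    bit_score: float
    e_value: float

    def __post_init__(self):
        if not self.e_value > 0:
            raise ValidationError(f"e_value must be > 0, got {self.e_value}")


def format_label(filename: str) -> str:
    """Format a proteome file name into a Newick-safe genome label.

    Known FASTA extensions are stripped (repeatedly, so the function is
    idempotent) and every character outside ``[A-Za-z0-9_.-]`` becomes ``_``.
    """
    if not filename:
        raise ValidationError("empty filename")
    name = Path(filename).name
    while True:
        stem, dot, ext = name.rpartition(".")
        if dot and ext.lower() in _FASTA_EXTENSIONS and stem:
            name = stem
        else:
            break
    return _LABEL_SAFE.sub("_", name)


def format_labels(filenames: list[str]) -> dict[str, str]:
    """Map filename -> unique formatted label; collisions get _2, _3, ...

    Suffix assignment follows the (sorted) filename order so the mapping is
    deterministic for a directory listing.
    """
    mapping: dict[str, str] = {}
    used: dict[str, int] = {}
    for fn in filenames:
        base = format_label(fn)
        if base not in used:
            used[base] = 1
            mapping[fn] = base
        else:
            used[base] += 1
            candidate = f"{base}_{used[base]}"
            while candidate in used:
                used[base] += 1
                candidate = f"{base}_{used[base]}"
            used[candidate] = 1
            mapping[fn] = candidate
    return mapping


def _check_fasta_protein(path: Path) -> None:
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped or stripped[0] != ">":
        raise FormatError(f"'{path.name}' is not FASTA (first non-blank character is not '>')")
    residues = "".join(
        line.strip() for line in text.splitlines() if line and not line.startswith(">")
    ).upper()
    if residues:
        nuc = sum(1 for c in residues if c in _NUC_CHARS)
        if nuc / len(residues) > _NUC_FRACTION:
            raise SequenceTypeError(
                f"'{path.name}' looks like nucleotide data "
                f"({100 * nuc / len(residues):.1f}% of residues in ACGTUN-); "
                "a protein FASTA (proteome) is required"
            )


def read_fasta(path) -> dict[str, str]:
    """seq_id -> sequence, order preserved; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate sequence id '{rec.id}' in '{path}'")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_proteome_dir(path) -> list[ProteomeRecord]:
    """Read every file of a proteome directory as a protein multi-FASTA.

    Validation mirrors the pipeline's input checks: at least ``MIN_PROTEOMES``
    files, FASTA format, protein (not nucleotide) content. Records come back
    sorted by formatted genome label.
    """
    p = Path(path)
    if not p.is_dir():
        raise ValidationError(f"proteome directory '{path}' does not exist")
    files = sorted(f for f in p.iterdir() if f.is_file() and not f.name.startswith("."))
    if len(files) < MIN_PROTEOMES:
        raise ValidationError(f"input count {len(files)} < {MIN_PROTEOMES}")
    labels = format_labels([f.name for f in files])
    for old, new in labels.items():
        if Path(old).stem != new:
            log.info("label formatted: %s -> %s", old, new)
    records = []
    for f in files:
        _check_fasta_protein(f)
        records.append(
            ProteomeRecord(
                genome_label=labels[f.name],
                source_filename=f.name,
                sequences=read_fasta(f),
            )
        )
    records.sort(key=lambda r: r.genome_label)
    return records


# ---------------------------------------------------------------------- newick
def _prevalidate_newick(text: str) -> None:
    depth = 0
    last_close = None
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            last_close = i
            if depth < 0:
                raise NewickParseError("unbalanced parentheses", offset=i)
    if depth != 0:
        raise NewickParseError("unbalanced parentheses", offset=last_close if last_close is not None else len(text) - 1)
    if ";" not in text:
        raise NewickParseError("missing terminating ';'", offset=len(text) - 1)


def read_newick(text: str) -> PhyloTree:
    """Parse one Newick statement into a :class:`PhyloTree`.

    Numeric internal-node labels are read as branch supports; when any support
    exceeds 1 the whole set is taken to be on a 0-100 scale and divided by 100.
    """
    _prevalidate_newick(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"Newick parse failed: {exc}") from None

    def convert(dnode) -> Node:
        if not dnode.child_nodes():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return Node(label=label, length=dnode.edge.length)
        node = Node(length=dnode.edge.length, children=[convert(c) for c in dnode.child_nodes()])
        if dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                pass  # non-numeric internal label: ignored
        return node

    root = convert(dtree.seed_node)
    supports = [n.support for n in root.walk() if n.support is not None]
    if supports and max(supports) > 1.0:
        for n in root.walk():
            if n.support is not None:
                n.support /= 100.0
    try:
        return PhyloTree(root)
    except TreeError as exc:
        raise NewickParseError(str(exc)) from None


def write_newick(tree: PhyloTree) -> str:
    return tree.newick()


# ----------------------------------------------------------------- HMMER tblout
def read_hmmer_tblout(path, genome_label: str | None = None) -> list[HitRecord]:
    """Load an HMMER3 per-target table ('--tblout' of hmmsearch).

    Columns follow the HMMER3 convention: target name, target accession,
    query name, query accession, full-sequence E-value, full-sequence score.
    ``genome_label`` defaults to the file stem.
    """
    p = Path(path)
    label = genome_label if genome_label is not None else p.stem
    hits = []
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{p.name}:{lineno}: expected >= 6 columns, got {len(parts)}")
            try:
                evalue = float(parts[4])
                score = float(parts[5])
            except ValueError as exc:
                raise FormatError(f"{p.name}:{lineno}: unparseable E-value/score: {exc}") from None
            hits.append(
                HitRecord(
                    genome_label=label,
                    seq_id=parts[0],
                    gene_id=parts[2],
                    bit_score=score,
                    e_value=evalue,
                )
            )
    return hits


def write_hits_tsv(hits: list[HitRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tseq_id\tgene_id\tbit_score\te_value\n")
        for h in hits:
            fh.write(f"{h.genome_label}\t{h.seq_id}\t{h.gene_id}\t{h.bit_score:.4f}\t{h.e_value:.6g}\n")
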