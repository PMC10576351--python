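"""Pipeline orchestration: input -> gene calling -> clusters -> alignment ->
trimming -> supermatrix / supertree / consensus -> final Newick.

Every stage materializes its outputs under the run directory and logs its
in/out counts, so intermediate data can feed other tools directly and failed
runs keep their partial results for debugging.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import Alignment, align_cluster
from .combine import consensus_with_report, quartet_supertree
from .config import RunConfig, TREE_APP_TEMPLATES, validate_config
from .errors import CorePhyloError
from .hmm import hmm_search, load_phd
from .homolog import apply_cutoffs, extract_clusters, prevalence_report, select_top_hits
from .io import read_proteome_dir, write_fasta, write_hits_tsv
from .supermatrix import (
    concatenate,
    write_partitions,
    write_supermatrix_fasta,
    write_supermatrix_phylip,
)
from .treebuild import bootstrap_tree, external_tree
from .tree import PhyloTree
from .trim import trim_alignment

log = logging.getLogger("corephylo")

__all__ = ["RunResult", "run_pipeline", "open_run_log"]


@dataclass
class RunResult:
    config: RunConfig
    final_tree: PhyloTree
    final_tree_path: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    log_path: Path | None = None


def open_run_log(cfg: RunConfig, start_time: float) -> Path:
    """Attach a file handler named '<inputdirname>_<YYYYMMDD-HHMMSS>.log'."""
    outdir = Path(cfg.outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = time.strftime("%Y%m%d-%H%M%S", time.localtime(start_time))
        name = f"{Path(cfg.proteome_dir).name}_{stamp}.log"
        path = outdir / name
        handler = logging.FileHandler(path)
    except OSError as exc:
        raise CorePhyloError(f"cannot open run log in '{outdir}': {exc}") from None
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("corephylo %s", __version__)
    for key, value in vars(cfg).items():
        log.info("config %s = %r", key, value)
    return path


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CorePhyloError as exc:
                raise CorePhyloError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: RunConfig) -> RunResult:
    start = time.time()
    cfg, notices = validate_config(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = open_run_log(cfg, start)
    for n in notices:
        log.info("notice: %s", n)
    counts: dict[str, int] = {}
    artifacts: dict[str, Path] = {}

    # ---- input ----------------------------------------------------------
    proteomes = _stage("input")(read_proteome_dir)(cfg.proteome_dir)
    counts["proteomes"] = len(proteomes)
    log.info("stage complete: input (%d proteomes)", len(proteomes))

    # ---- gene calling ---------------------------------------------------
    phd = _stage("gene calling")(load_phd)(cfg.phd_path())
    hits_dir = outdir / "hits"
    hits_dir.mkdir(exist_ok=True)
    all_hits = []
    for p in proteomes:
        hits = _stage("gene calling")(hmm_search)(phd, p, cfg.evalue)
        write_hits_tsv(hits, hits_dir / f"{p.genome_label}.tsv")
        all_hits.extend(hits)
    counts["hits"] = len(all_hits)
    artifacts["hits"] = hits_dir
    log.info(
        "stage complete: gene calling (%d genes x %d genomes -> %d hits)",
        len(phd.models), len(proteomes), len(all_hits),
    )

    # ---- filtrate hits / clusters ---------------------------------------
    table = select_top_hits(
        all_hits, cfg.evalue,
        genes=phd.gene_ids, genomes=[p.genome_label for p in proteomes],
    )
    table, exclusions = _stage("filtrate")(apply_cutoffs)(
        table, cfg.genome_cutoff, cfg.gene_cutoff
    )
    prevalence = prevalence_report(table)
    prevalence.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)
    exclusions.to_frame().to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    artifacts["prevalence"] = outdir / "prevalence.tsv"
    artifacts["exclusions"] = outdir / "exclusions.tsv"
    counts["genes_retained"] = len(table.genes)
    counts["genomes_retained"] = len(table.genomes)
    clusters = _stage("filtrate")(extract_clusters)(table, proteomes)
    clusters_dir = outdir / "clusters"
    clusters_dir.mkdir(exist_ok=True)
    for c in clusters:
        write_fasta(c.members, clusters_dir / f"{c.gene_id}.faa")
    artifacts["clusters"] = clusters_dir
    log.info(
        "stage complete: filtrate (%d genes, %d genomes retained; %d excluded)",
        len(table.genes), len(table.genomes), len(exclusions.rows),
    )

    # ---- align ----------------------------------------------------------
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    alignments: list[Alignment] = []
    for c in clusters:
        aln = _stage("align")(align_cluster)(c, cfg.align_engine, cfg.align_command)
        write_fasta(aln.rows, aln_dir / f"{c.gene_id}.aln.faa")
        alignments.append(aln)
    artifacts["alignments"] = aln_dir
    log.info("stage complete: align (%d clusters)", len(alignments))

    # ---- trim -----------------------------------------------------------
    trim_dir = outdir / "trimmed"
    trim_dir.mkdir(exist_ok=True)
    trimmed: list[Alignment] = []
    with open(outdir / "trim_report.tsv", "w") as fh:
        fh.write("gene_id\tmethod\tcolumns_in\tcolumns_out\tgap_threshold\tsimilarity_threshold\n")
        for aln in alignments:
            taln, rep = _stage("trim")(trim_alignment)(aln, cfg.trim_method)
            write_fasta(taln.rows, trim_dir / f"{aln.gene_id}.trim.faa")
            trimmed.append(taln)
            fh.write(
                f"{aln.gene_id}\t{rep.method}\t{aln.length}\t{len(rep.retained)}"
                f"\t{rep.gap_threshold}\t{rep.similarity_threshold}\n"
            )
    artifacts["trimmed"] = trim_dir
    counts["trimmed_columns"] = sum(t.length for t in trimmed)
    log.info(
        "stage complete: trim (%d alignments, %d columns total)",
        len(trimmed), counts["trimmed_columns"],
    )

    # ---- phylogeny ------------------------------------------------------
    taxa = list(table.genomes)
    if cfg.tree_mode == "sm":
        final = _run_sm(cfg, trimmed, taxa, outdir, artifacts, counts)
    elif cfg.tree_mode == "st":
        final = _run_gene_tree_mode(cfg, trimmed, taxa, outdir, artifacts, counts, supertree=True)
    else:
        final = _run_gene_tree_mode(cfg, trimmed, taxa, outdir, artifacts, counts, supertree=False)

    final_path = outdir / "final_tree.nwk"
    final_path.write_text(final.newick() + "\n")
    artifacts["final_tree"] = final_path
    log.info("stage complete: phylogeny (%s mode, %d taxa)", cfg.tree_mode, final.n_leaves)
    log.info("run finished in %.1f s", time.time() - start)
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler) and Path(h.baseFilename) == log_path:
            h.close()
            log.removeHandler(h)
    return RunResult(
        config=cfg,
        final_tree=final,
        final_tree_path=final_path,
        artifacts=artifacts,
        stage_counts=counts,
        log_path=log_path,
    )


def _run_sm(cfg, trimmed, taxa, outdir, artifacts, counts) -> PhyloTree:
    sm = _stage("supermatrix")(concatenate)(trimmed, taxa)
    write_supermatrix_fasta(sm, outdir / "supermatrix.faa")
    write_supermatrix_phylip(sm, outdir / "supermatrix.phy")
    write_partitions(sm, outdir / "partitions.txt")
    artifacts["supermatrix"] = outdir / "supermatrix.faa"
    artifacts["partitions"] = outdir / "partitions.txt"
    counts["supermatrix_positions"] = sm.length
    log.info("stage complete: supermatrix (%d positions, %d partitions)", sm.length, len(sm.partitions))
    if cfg.tree_app == "internal":
        return _stage("tree inference")(bootstrap_tree)(
            sm.to_alignment(), cfg.bootstrap_reps, cfg.seed
        )
    template = cfg.tree_command or TREE_APP_TEMPLATES[cfg.tree_app]
    options = _passthrough_options()
    return _stage("tree inference")(external_tree)(
        outdir / "supermatrix.faa", template, options
    )


def _run_gene_tree_mode(cfg, trimmed, taxa, outdir, artifacts, counts, supertree: bool) -> PhyloTree:
    gt_dir = outdir / "gene_trees"
    gt_dir.mkdir(exist_ok=True)
    gene_trees = []
    for i, aln in enumerate(trimmed):
        if aln.n_rows < 3:
            log.warning("gene %s has <3 taxa after filtering; skipped for gene trees", aln.gene_id)
            continue
        tree = _stage("gene trees")(bootstrap_tree)(
            aln, cfg.bootstrap_reps, (cfg.seed + 101 * i) % 2**31
        )
        (gt_dir / f"{aln.gene_id}.nwk").write_text(tree.newick() + "\n")
        gene_trees.append(tree)
    artifacts["gene_trees"] = gt_dir
    counts["gene_trees"] = len(gene_trees)
    log.info("stage complete: gene trees (%d trees)", len(gene_trees))
    if supertree:
        return _stage("supertree")(quartet_supertree)(gene_trees, taxa)
    tree, rows = _stage("consensus")(consensus_with_report)(gene_trees)
    with open(outdir / "consensus_report.tsv", "w") as fh:
        fh.write("bipartition\tfrequency\trule\n")
        for r in rows:
            fh.write(f"{'|'.join(sorted(r.split))}\t{r.frequency:.6g}\t{r.rule}\n")
    artifacts["consensus_report"] = outdir / "consensus_report.tsv"
    return tree


def _passthrough_options() -> str:
    """Contents of a 'tree_app-options.txt' in the working directory, passed
    verbatim to the external tree command."""
    p = Path("tree_app-options.txt")
    if p.is_file():
        return p.read_text().strip()
    return ""
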