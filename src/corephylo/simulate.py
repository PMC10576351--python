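"""Synthetic data with known truth, for end-to-end verification.

The generator produces a complete study in miniature: a Yule species tree,
per-gene trees with controllable discordance (one random NNI per discordant
gene) and lognormal branch-length jitter, protein sequences evolved along the
gene trees under a Poisson substitution process with uniform replacement,
per-genome decoy sequences drawn from the background, and *held-out* training
clusters evolved on an independent copy of the tree with fresh taxon labels —
so profile-HMM search is a genuine generalization test, not memorization.

Everything is a pure function of the parameter record, including the seed.

What this emulates and what it does not: sequences are equal-length per gene
(no indel process), substitution is uniform over the 19 alternative residues
(no empirical exchangeability matrix), and decoys are i.i.d. background. That
is sufficient for topology-recovery and threshold-semantics tests; it says
nothing about alignment quality on real, indel-rich proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import Alignment
from .errors import ValidationError
from .homolog import GeneCluster
from .hmm import AA, BACKGROUND
from .io import ProteomeRecord, write_fasta
from .tree import Node, PhyloTree

__all__ = [
    "FixtureParams",
    "TruthBundle",
    "simulate_species_tree",
    "simulate_gene_trees",
    "evolve_proteome_set",
    "make_truth_bundle",
    "write_bundle",
]


@dataclass
class FixtureParams:
    n_taxa: int = 8
    n_genes: int = 15
    gene_length: int = 400  # typical conserved single-copy marker (EF-Tu class)
    rate: float = 0.2  # substitutions per site per unit branch length
    discordance: float = 0.0  # probability a gene tree differs by one NNI
    length_jitter: float = 0.0  # sigma of lognormal branch-length jitter
    n_decoys: int = 5  # background-random sequences per genome
    seed: int = 42


@dataclass
class TruthBundle:
    params: FixtureParams
    species_tree: PhyloTree
    gene_trees: dict[str, PhyloTree]
    proteomes: list[ProteomeRecord]
    training_clusters: dict[str, GeneCluster]
    homolog_ids: dict[str, dict[str, str]] = field(default_factory=dict)
    # gene_id -> genome_label -> seq_id of the true homolog


def simulate_species_tree(n_taxa: int, seed: int, mean_branch: float = 0.1) -> PhyloTree:
    """Yule topology (uniform random leaf split), exponential branch lengths.

    Returned unrooted (root of degree 3), so an n-taxon binary tree carries
    n - 3 non-trivial bipartitions.
    """
    if n_taxa < 4:
        raise ValidationError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    leaves = [Node(labels[0]), Node(labels[1])]
    root = Node(children=list(leaves))
    for lab in labels[2:]:
        split_leaf = leaves[rng.integers(0, len(leaves))]
        # the split leaf becomes an internal node with two fresh children
        a, b = Node(split_leaf.label), Node(lab)
        split_leaf.label = None
        split_leaf.children = [a, b]
        leaves.remove(split_leaf)
        leaves.extend([a, b])
    for node in root.walk():
        if node is not root:
            node.length = float(rng.exponential(mean_branch))
    return PhyloTree(root).deroot()


def _random_nni(tree: PhyloTree, rng) -> PhyloTree:
    """One uniformly chosen NNI move; changes exactly one bipartition (RF 2)."""
    t = tree.copy().deroot()
    moves = []
    nodes = list(t.root.walk())
    for node in nodes:
        for c in node.children:
            if c.is_leaf:
                continue
            for gi in range(len(c.children)):
                for si, sib in enumerate(node.children):
                    if sib is c:
                        continue
                    moves.append((node, c, gi, si))
    if not moves:
        return t
    parent, child, gi, si = moves[rng.integers(0, len(moves))]
    parent.children[si], child.children[gi] = child.children[gi], parent.children[si]
    # swapped subtrees keep their own edge lengths; supports are void
    return PhyloTree(t.root)


def simulate_gene_trees(
    species_tree: PhyloTree,
    n_genes: int,
    discordance: float,
    length_jitter: float,
    seed: int,
) -> dict[str, PhyloTree]:
    """Gene trees = species tree, NNI-perturbed with probability
    ``discordance``, branch lengths multiplied by i.i.d. lognormal jitter."""
    if not 0 <= discordance <= 1:
        raise ValidationError("discordance must be a probability")
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_genes):
        gid = f"g{i + 1:03d}"
        t = species_tree.copy()
        if rng.random() < discordance:
            t = _random_nni(t, rng)
        if length_jitter > 0:
            for node in t.root.walk():
                if node.length is not None:
                    node.length = float(node.length * rng.lognormal(0.0, length_jitter))
        out[gid] = t
    return out


def _evolve_along(tree: PhyloTree, root_seq: np.ndarray, rate: float, rng) -> dict[str, np.ndarray]:
    """Poisson substitution: along a branch of length t each site substitutes
    with probability 1 - exp(-rate * t), uniformly over the other 19 residues."""
    out: dict[str, np.ndarray] = {}

    def visit(node: Node, seq: np.ndarray):
        for c in node.children:
            t = c.length if c.length is not None else 0.0
            p = 1.0 - np.exp(-rate * t)
            child_seq = seq.copy()
            hit = rng.random(len(seq)) < p
            if hit.any():
                shifts = rng.integers(1, 20, size=int(hit.sum()))
                child_seq[hit] = (child_seq[hit] + shifts) % 20
            if c.is_leaf:
                out[c.label] = child_seq
            else:
                visit(c, child_seq)

    visit(tree.root, root_seq)
    return out


def _to_str(idx_seq: np.ndarray) -> str:
    return "".join(AA[i] for i in idx_seq)


def evolve_proteome_set(
    gene_trees: dict[str, PhyloTree],
    gene_length: int,
    rate: float,
    n_decoys: int,
    seed: int,
) -> tuple[list[ProteomeRecord], dict[str, GeneCluster], dict[str, dict[str, str]]]:
    """(proteomes, training clusters, true homolog seq_ids).

    Per genome: one evolved sequence per gene under an opaque seq_id, plus
    ``n_decoys`` i.i.d. background sequences. Training clusters are evolved on
    an independent copy of each gene tree relabeled with fresh taxa, so the
    training and test taxon sets are disjoint.
    """
    rng = np.random.default_rng(seed)
    gene_ids = sorted(gene_trees)
    taxa = sorted(next(iter(gene_trees.values())).leaf_labels)
    per_genome: dict[str, dict[str, str]] = {m: {} for m in taxa}
    homolog_ids: dict[str, dict[str, str]] = {g: {} for g in gene_ids}
    training: dict[str, GeneCluster] = {}

    for gid in gene_ids:
        tree = gene_trees[gid]
        root_seq = rng.choice(20, size=gene_length, p=BACKGROUND)
        leaf_seqs = _evolve_along(tree, root_seq, rate, rng)
        for m in taxa:
            per_genome[m][gid] = _to_str(leaf_seqs[m])
        # held-out training copy: same gene family (same root sequence), an
        # independent substitution realization, fresh taxon labels
        train_tree = tree.copy()
        mapping = {lab: f"train_{i + 1:02d}" for i, lab in enumerate(sorted(tree.leaf_labels))}
        for node in train_tree.root.walk():
            if node.is_leaf:
                node.label = mapping[node.label]
        train_seqs = _evolve_along(PhyloTree(train_tree.root), root_seq, rate, rng)
        training[gid] = GeneCluster(gid, {lab: _to_str(s) for lab, s in sorted(train_seqs.items())})

    proteomes = []
    for m in taxa:
        sequences: dict[str, str] = {}
        order = list(per_genome[m].items())
        for j, (gid, seq) in enumerate(order):
            sid = f"{m}_orf{j + 1:04d}"  # opaque: no gene_id visible downstream
            sequences[sid] = seq
            homolog_ids[gid][m] = sid
        for d in range(n_decoys):
            dl = int(rng.integers(int(gene_length * 0.6), int(gene_length * 1.6)))
            sequences[f"{m}_orf{len(order) + d + 1:04d}"] = _to_str(
                rng.choice(20, size=dl, p=BACKGROUND)
            )
        proteomes.append(
            ProteomeRecord(genome_label=m, source_filename=f"{m}.faa", sequences=sequences)
        )
    return proteomes, training, homolog_ids


def make_truth_bundle(params: FixtureParams) -> TruthBundle:
    sp = simulate_species_tree(params.n_taxa, params.seed)
    gt = simulate_gene_trees(
        sp, params.n_genes, params.discordance, params.length_jitter, seed=params.seed + 1
    )
    proteomes, training, homolog_ids = evolve_proteome_set(
        gt, params.gene_length, params.rate, params.n_decoys, seed=params.seed + 2
    )
    return TruthBundle(
        params=params,
        species_tree=sp,
        gene_trees=gt,
        proteomes=proteomes,
        training_clusters=training,
        homolog_ids=homolog_ids,
    )


def training_alignments(bundle: TruthBundle) -> list[Alignment]:
    """Training clusters as (trivially ungapped, equal-length) alignments."""
    return [
        Alignment(gid, dict(cluster.members))
        for gid, cluster in sorted(bundle.training_clusters.items())
    ]


def write_bundle(bundle: TruthBundle, out_dir) -> None:
    """Write proteome FASTAs, training cluster FASTAs, and truth Newick files."""
    out = Path(out_dir)
    (out / "proteomes").mkdir(parents=True, exist_ok=True)
    (out / "training_clusters").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for p in bundle.proteomes:
        write_fasta(p.sequences, out / "proteomes" / p.source_filename)
    for gid, cluster in bundle.training_clusters.items():
        write_fasta(cluster.members, out / "training_clusters" / f"{gid}.faa")
    (out / "truth" / "species_tree.nwk").write_text(bundle.species_tree.newick() + "\n")
    for gid, t in bundle.gene_trees.items():
        (out / "truth" / f"{gid}.nwk").write_text(t.newick() + "\n")
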