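import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from corephylo.config import RunConfig
from corephylo.hmm import build_gene_set, save_phd
from corephylo.pipeline import run_pipeline
from corephylo.simulate import (
    FixtureParams,
    make_truth_bundle,
    training_alignments,
    write_bundle,
)

# the canonical study conditions: 8 taxa, 15 genes, concordant gene trees,
# rate 0.2 subs/site/unit length, 5 decoys per genome, seed 42
STUDY_PARAMS = FixtureParams()


@pytest.fixture(scope="session")
def bundle():
    return make_truth_bundle(STUDY_PARAMS)


@pytest.fixture(scope="session")
def gene_set(bundle):
    return build_gene_set("markers", training_alignments(bundle), seed=7)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, bundle, gene_set):
    """On-disk layout: proteome FASTAs, truth trees, and a saved PHD."""
    root = tmp_path_factory.mktemp("study")
    write_bundle(bundle, root / "fix")
    (root / "phd").mkdir()
    save_phd(gene_set, root / "phd" / "markers.phd")
    return root


def _run(study_dir, mode, outname, seed=42):
    cfg = RunConfig(
        proteome_dir=str(study_dir / "fix" / "proteomes"),
        hmm_set="markers",
        phd_dir=str(study_dir / "phd"),
        tree_mode=mode,
        outdir=str(study_dir / outname),
        seed=seed,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def pipeline_runs(study_dir):
    """One full pipeline run per tree mode on the canonical fixture."""
    return {mode: _run(study_dir, mode, f"out_{mode}") for mode in ("sm", "cs", "st")}


@pytest.fixture(scope="session")
def repeat_sm_run(study_dir):
    """A second, independent sm-mode run with the identical configuration."""
    return _run(study_dir, "sm", "out_sm_repeat")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_binary_tree(labels, rng, min_len=0.05, max_len=1.0):
    """Random unrooted binary tree with uniform branch lengths (test helper)."""
    from corephylo.tree import Node, PhyloTree

    labels = list(labels)
    rng.shuffle(labels)
    nodes = [Node(lab) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [n for n in nodes if n is not a and n is not b]
        nodes.append(Node(children=[a, b]))
    root = Node(children=nodes)
    for n in root.walk():
        if n is not root:
            n.length = float(rng.uniform(min_len, max_len))
    return PhyloTree(root)
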