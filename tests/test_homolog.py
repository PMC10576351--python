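"""Top-hit screening, prevalence cutoffs, cluster extraction."""

import pytest

from corephylo.errors import ConsistencyError, CutoffError
from corephylo.homolog import (
    PresenceTable,
    apply_cutoffs,
    extract_clusters,
    prevalence_report,
    select_top_hits,
)
from corephylo.io import HitRecord, ProteomeRecord


def hit(gene, genome, e, score=50.0, seq_id="s1"):
    return HitRecord(genome_label=genome, seq_id=seq_id, gene_id=gene, bit_score=score, e_value=e)


class TestSelectTopHits:
    def test_minimal_evalue_wins(self):
        t = select_top_hits([hit("g", "x", 1e-12, seq_id="a"), hit("g", "x", 1e-30, seq_id="b")], 1e-10)
        assert t.cells[("g", "x")].seq_id == "b"

    def test_default_threshold_discards_weak_hit(self):
        t = select_top_hits([hit("g", "x", 1e-9)], 1e-10)
        assert ("g", "x") not in t.cells

    def test_ties_break_on_score_then_lexicographic_seq_id(self):
        hits = [
            hit("g", "x", 1e-20, score=50, seq_id="ctg2_5"),
            hit("g", "x", 1e-20, score=50, seq_id="ctg10_1"),
        ]
        t = select_top_hits(hits, 1e-10)
        assert t.cells[("g", "x")].seq_id == "ctg10_1"  # '1' < '2' stringwise
        hits2 = [
            hit("g", "x", 1e-20, score=60, seq_id="zzz"),
            hit("g", "x", 1e-20, score=50, seq_id="aaa"),
        ]
        assert select_top_hits(hits2, 1e-10).cells[("g", "x")].seq_id == "zzz"

    def test_universe_can_include_hitless_rows(self):
        t = select_top_hits([hit("g1", "x", 1e-20)], 1e-10, genes=["g1", "g2"], genomes=["x", "y"])
        assert t.genes == ["g1", "g2"] and t.genomes == ["x", "y"]
        assert t.n_present("g2") == 0


def _table_10x5(missing):
    """10 genomes x 5 genes, with (gene, genome) pairs in ``missing`` absent."""
    genes = [f"g{i}" for i in range(1, 6)]
    genomes = [f"m{i:02d}" for i in range(1, 11)]
    cells = {
        (g, m): hit(g, m, 1e-20)
        for g in genes
        for m in genomes
        if (g, m) not in missing
    }
    return PresenceTable(genes, genomes, cells)


class TestApplyCutoffs:
    def test_worked_example_genome_then_gene_exclusion(self):
        # genome m01 detects 2/5 genes; gene g5 present in 6/9 of the rest
        missing = {("g1", "m01"), ("g2", "m01"), ("g3", "m01")}
        missing |= {("g5", f"m{i:02d}") for i in (2, 3, 4)}
        table = _table_10x5(missing)
        out, report = apply_cutoffs(table, genome_cutoff=0.5, gene_cutoff=0.8)
        assert "m01" not in out.genomes and "g5" not in out.genes
        kinds = {(r.kind, r.name): r.fraction for r in report.rows}
        assert kinds[("genome", "m01")] == pytest.approx(2 / 5)
        assert kinds[("gene", "g5")] == pytest.approx(6 / 9)

    def test_zero_cutoffs_are_identity(self):
        table = _table_10x5({("g1", "m01")})
        out, report = apply_cutoffs(table, 0, 0)
        assert out.genes == table.genes and out.genomes == table.genomes
        assert report.rows == []

    def test_gene_cutoff_one_keeps_only_universal_genes(self):
        table = _table_10x5({("g3", "m05")})
        out, _ = apply_cutoffs(table, 0, 1)
        assert "g3" not in out.genes and len(out.genes) == 4

    def test_all_genomes_excluded_is_hard_error(self):
        table = _table_10x5({(g, m) for g in ("g1", "g2", "g3") for m in [f"m{i:02d}" for i in range(1, 11)]})
        with pytest.raises(CutoffError, match="lower"):
            apply_cutoffs(table, 0.9, 0)

    def test_fewer_than_four_retained_genomes_is_hard_error(self):
        genes = ["g1"]
        genomes = ["a", "b", "c", "d", "e"]
        cells = {("g1", m): hit("g1", m, 1e-20) for m in ("a", "b", "c")}
        with pytest.raises(CutoffError, match="4"):
            apply_cutoffs(PresenceTable(genes, genomes, cells), 0.5, 0)

    @pytest.mark.parametrize("axis", ["genome", "gene"])
    def test_monotone_raising_cutoffs_never_restores(self, axis, rng):
        genes = [f"g{i}" for i in range(6)]
        genomes = [f"m{i}" for i in range(8)]
        cells = {
            (g, m): hit(g, m, 1e-20)
            for g in genes
            for m in genomes
            if rng.random() < 0.8
        }
        table = PresenceTable(genes, genomes, cells)
        prev_genomes, prev_genes = None, None
        for cut in (0.0, 0.3, 0.6, 0.9):
            kw = dict(genome_cutoff=cut, gene_cutoff=0.0) if axis == "genome" else dict(
                genome_cutoff=0.0, gene_cutoff=cut
            )
            try:
                out, _ = apply_cutoffs(table, **kw)
            except CutoffError:
                break
            if prev_genomes is not None:
                assert set(out.genomes) <= prev_genomes
                assert set(out.genes) <= prev_genes
            prev_genomes, prev_genes = set(out.genomes), set(out.genes)


class TestExtractClusters:
    def _proteomes(self):
        return [
            ProteomeRecord(m, f"{m}.faa", {f"{m}_s1": "MKVL", f"{m}_s2": "GHTR"})
            for m in ("w", "x", "y", "z")
        ]

    def test_cluster_members_mirror_cells_exactly(self):
        genes, genomes = ["g1", "g2"], ["w", "x", "y", "z"]
        cells = {
            (g, m): hit(g, m, 1e-20, seq_id=f"{m}_s1")
            for g in genes
            for m in genomes
            if not (g == "g2" and m == "z")
        }
        clusters = extract_clusters(PresenceTable(genes, genomes, cells), self._proteomes())
        assert [c.gene_id for c in clusters] == ["g1", "g2"]
        assert len(clusters[0].members) == 4 and len(clusters[1].members) == 3
        assert clusters[0].members["w"] == "MKVL"

    def test_dangling_seq_id_is_a_consistency_error(self):
        cells = {("g1", "w"): hit("g1", "w", 1e-20, seq_id="w_missing")}
        table = PresenceTable(["g1"], ["w", "x", "y", "z"], cells)
        with pytest.raises(ConsistencyError, match="w_missing"):
            extract_clusters(table, self._proteomes())


class TestPrevalenceReport:
    def test_fractions(self):
        table = _table_10x5({("g2", f"m{i:02d}") for i in (1, 2, 3)})
        df = prevalence_report(table)
        g2 = df[(df.kind == "gene") & (df.name == "g2")].iloc[0]
        assert g2["count"] == 7 and g2.fraction == pytest.approx(0.7)
        full = df[(df.kind == "gene") & (df.name == "g1")].iloc[0]
        assert full.fraction == pytest.approx(1.0)

    def test_empty_table_header_only(self):
        df = prevalence_report(PresenceTable([], [], {}))
        assert list(df.columns) == ["kind", "name", "count", "fraction"]
        assert len(df) == 0
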