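import numpy as np
import pandas as pd
import pytest
from scipy import stats

from operonwave.operon_io import (
    AnnotationError,
    GeneRecord,
    GenomeAnnotation,
    PromoterRecord,
    TerminatorRecord,
    assign_first_gene_index,
    downstream_gap_stats,
    parse_annotation,
    read_expression_table,
    read_region_counts,
    structural_summary,
    tss_uniform_null,
    write_annotation,
)
from operonwave.synthetic_data import SyntheticConfig, generate_annotation


class TestParsing:
    def test_fixture_structure(self, tiny_annotation_tsv):
        ann = parse_annotation(tiny_annotation_tsv)
        assert len(ann.operons) == 3
        assert len(ann.genes) == 7
        assert len(ann.promoters) == 4
        assert ann.operons["op1"] == ["a1", "a2", "a3"]
        p2 = next(p for p in ann.promoters if p.promoter_id == "P2")
        assert p2.first_gene_index == 3 and p2.is_internal
        assert not ann.report["synthesized_primaries"]

    def test_minus_strand_positions_follow_transcription_order(self, tiny_annotation_tsv):
        ann = parse_annotation(tiny_annotation_tsv)
        b1, b2 = ann.gene_index["b1"], ann.gene_index["b2"]
        assert (b1.position, b2.position) == (1, 2)
        assert b1.tss_side_nt > b2.tss_side_nt  # 5' end of a minus-strand operon is downstream in coordinates

    def test_round_trip_is_record_identical(self, tmp_path, tiny_annotation):
        p1 = tmp_path / "a.tsv"
        write_annotation(tiny_annotation, p1)
        ann = parse_annotation(p1)
        key = lambda g: g.gene_id
        assert sorted(ann.genes, key=key) == sorted(tiny_annotation.genes, key=key)
        assert ann.promoters == tiny_annotation.promoters
        assert ann.terminators == tiny_annotation.terminators
        assert ann.genome_length_nt == tiny_annotation.genome_length_nt

    def test_gene_in_two_operons_rejected(self, tmp_path):
        rows = [
            "feature\tid\toperon_id\tstart\tend\tstrand\tattributes",
            "gene\tx\topA\t10\t100\t+\t",
            "gene\tx\topB\t200\t300\t+\t",
        ]
        path = tmp_path / "bad.tsv"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(AnnotationError, match="two operons|duplicate"):
            parse_annotation(path)

    def test_missing_primary_promoter_synthesized_and_flagged(self, tmp_path):
        rows = [
            "feature\tid\toperon_id\tstart\tend\tstrand\tattributes",
            "gene\tx1\topA\t100\t400\t+\t",
            "gene\tx2\topA\t500\t800\t+\t",
            "promoter\tPint\topA\t450\t450\t+\t",  # internal only
        ]
        path = tmp_path / "nopri.tsv"
        path.write_text("\n".join(rows) + "\n")
        ann = parse_annotation(path)
        assert ann.report["synthesized_primaries"] == ["opA"]
        primaries = [p for p in ann.promoters_by_operon["opA"] if p.first_gene_index == 1]
        assert len(primaries) == 1 and primaries[0].synthesized

    def test_tss_downstream_of_all_coding_starts_dropped(self, tmp_path):
        rows = [
            "feature\tid\toperon_id\tstart\tend\tstrand\tattributes",
            "gene\tx1\topA\t100\t400\t+\t",
            "promoter\tP1\topA\t80\t80\t+\t",
            "promoter\tPlate\topA\t390\t390\t+\t",  # past the only coding start
        ]
        path = tmp_path / "late.tsv"
        path.write_text("\n".join(rows) + "\n")
        ann = parse_annotation(path)
        assert ann.report["dropped_promoters"] == ["Plate"]
        assert [p.promoter_id for p in ann.promoters] == ["P1"]

    def test_first_gene_index_assignment_rule(self, tiny_annotation):
        genes = tiny_annotation.operon_genes("op1")
        assert assign_first_gene_index(genes, 80) == 1
        assert assign_first_gene_index(genes, 450) == 2
        assert assign_first_gene_index(genes, 1000) is None  # at/after last coding start


class TestExpressionTable:
    def _write(self, tmp_path, text):
        p = tmp_path / "expr.tsv"
        p.write_text(text)
        return p

    def test_reads_deseq2_aliases_and_counts_rows(self, tmp_path):
        p = self._write(tmp_path, "gene_id\tlog2FoldChange\tpvalue\na\t1.5\t0.01\nb\t-0.3\t0.2\nc\t0.0\t0.9\n")
        df = read_expression_table(p, condition_id="novobiocin")
        assert len(df) == 3
        assert set(df["condition_id"]) == {"novobiocin"}
        assert df.set_index("gene_id").loc["a", "lfc"] == 1.5

    def test_na_lfc_dropped_and_logged(self, tmp_path):
        p = self._write(tmp_path, "gene_id\tlfc\na\t1.0\nb\tNA\n")
        df = read_expression_table(p)
        assert list(df["gene_id"]) == ["a"]
        assert df.attrs["n_dropped"] == 1

    def test_non_numeric_lfc_raises_with_row(self, tmp_path):
        p = self._write(tmp_path, "gene_id\tlfc\na\t1.0\nb\toops\n")
        with pytest.raises(ValueError, match="row"):
            read_expression_table(p)

    def test_duplicate_gene_condition_raises(self, tmp_path):
        p = self._write(tmp_path, "gene_id\tlfc\na\t1.0\na\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_table(p)

    def test_genes_outside_annotation_flagged_not_dropped(self, tmp_path, tiny_annotation):
        p = self._write(tmp_path, "gene_id\tlfc\na1\t1.0\nzz\t0.5\n")
        df = read_expression_table(p, annotation=tiny_annotation)
        assert df.set_index("gene_id")["in_annotation"].to_dict() == {"a1": True, "zz": False}


class TestRegionCounts:
    def test_reads_and_shapes(self, tmp_path):
        lines = ["gene_id\treplicate\tcondition\treads_start\treads_end"]
        for g in ("a", "b"):
            for r in (1, 2, 3):
                lines.append(f"{g}\trep{r}\tctrl\t100\t80")
        p = tmp_path / "counts.tsv"
        p.write_text("\n".join(lines) + "\n")
        df = read_region_counts(p)
        assert len(df) == 6
        assert (df["reads_end"] <= df["reads_start"]).all()

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("gene_id\treplicate\tcondition\treads_start\treads_end\na\trep1\tctrl\t-5\t0\n")
        with pytest.raises(ValueError, match="negative"):
            read_region_counts(p)

    def test_missing_replicate_warns(self, tmp_path, caplog):
        p = tmp_path / "counts.tsv"
        p.write_text(
            "gene_id\treplicate\tcondition\treads_start\treads_end\n"
            "a\trep1\tctrl\t10\t8\na\trep2\tctrl\t12\t9\nb\trep1\tctrl\t10\t8\n"
        )
        with caplog.at_level("WARNING"):
            read_region_counts(p)
        assert any("replicate" in r.message for r in caplog.records)


class TestStructuralStats:
    def test_single_gene_operon(self):
        ann = GenomeAnnotation(
            genes=[GeneRecord("x", "op", 1, 10, 100, "+")],
            promoters=[PromoterRecord("P", "op", 5, 1)],
            terminators=[], genome_length_nt=200,
        )
        df = structural_summary(ann)
        assert df.loc["op", "n_genes"] == 1
        assert np.isnan(df.loc["op", "mean_intergenic_nt"])

    def test_intergenic_distance_arithmetic(self):
        ann = GenomeAnnotation(
            genes=[GeneRecord("x", "op", 1, 1, 100, "+"), GeneRecord("y", "op", 2, 151, 300, "+")],
            promoters=[PromoterRecord("P", "op", 1, 1)],
            terminators=[], genome_length_nt=400,
        )
        df = structural_summary(ann)
        assert df.loc["op", "mean_intergenic_nt"] == 50.0

    def test_synthetic_genome_summary_matches_generator(self, default_dataset):
        cfg, ann, _ = default_dataset
        df = structural_summary(ann)
        g = df.attrs["genome"]
        assert g["n_operons"] == cfg.n_operons
        assert g["n_tss"] == len(ann.promoters)
        assert g["n_internal_tss"] == sum(p.is_internal for p in ann.promoters)
        assert abs(g["mean_intergenic_nt"] - cfg.intergenic_mean_nt) < 10
        assert g["median_operon_size"] == 3

    def test_downstream_gap_two_group_construction(self):
        # operons alternate: gap ~100 nt with a TTS inside, ~200 nt without;
        # the genome is circular, so the wrap-around gap is laid out to match
        genes, proms, ttss = [], [], []
        pos = 1
        for i in range(20):
            oid = f"o{i}"
            genes.append(GeneRecord(f"g{i}", oid, 1, pos, pos + 499, "+"))
            proms.append(PromoterRecord(f"P{i}", oid, max(pos - 10, 1), 1))
            gap = 100 if i % 2 == 0 else 200
            if i % 2 == 0:
                ttss.append(TerminatorRecord(tts_nt=pos + 499 + 50))
            pos += 500 + gap
        last_end = pos - (500 + 200) + 499  # i=19 (odd): undo its increment, add its length
        ann = GenomeAnnotation(
            genes=genes, promoters=proms, terminators=ttss,
            genome_length_nt=last_end + 200,  # wrap gap back to gene at pos 1 is ~200
        )
        res = downstream_gap_stats(ann)
        assert res["mean_with_tts"] == pytest.approx(100, abs=5)
        assert res["mean_without_tts"] == pytest.approx(200, abs=5)
        assert res["ratio_without_over_with"] == pytest.approx(2.0, abs=0.1)
        assert res["p_value"] < 1e-6

    def test_no_terminators_gives_single_group(self, default_dataset):
        _, ann, _ = default_dataset
        bare = GenomeAnnotation(genes=list(ann.genes), promoters=list(ann.promoters),
                                terminators=[], genome_length_nt=ann.genome_length_nt)
        res = downstream_gap_stats(bare)
        assert res["n_with_tts"] == 0 and res["n_without_tts"] > 0
        assert np.isnan(res["p_value"])

    def test_generator_gap_ratio_recovered(self):
        cfg = SyntheticConfig(seed=3, n_operons=400, tts_fraction=0.5)
        ann = generate_annotation(cfg)
        res = downstream_gap_stats(ann)
        gaps = res["gaps"]
        se = np.sqrt(
            gaps.loc[gaps.has_tts, "gap_nt"].var() / res["n_with_tts"]
            + gaps.loc[~gaps.has_tts, "gap_nt"].var() / res["n_without_tts"]
        )
        truth = cfg.intergenic_operon_gap_nt[1] - cfg.intergenic_operon_gap_nt[0]
        observed = res["mean_without_tts"] - res["mean_with_tts"]
        assert abs(observed - truth) < 3 * se


class TestTssUniformNull:
    def _annotation(self, lengths, tss_counts):
        genes, proms = [], []
        pos = 100
        for i, (L, k) in enumerate(zip(lengths, tss_counts)):
            oid = f"o{i}"
            n = 4
            gl = L // n
            for j in range(n):
                genes.append(GeneRecord(f"o{i}g{j}", oid, j + 1, pos + j * gl, pos + (j + 1) * gl - 1, "+"))
            proms.append(PromoterRecord(f"P{i}", oid, pos - 5, 1))
            for t in range(k):
                proms.append(PromoterRecord(f"P{i}i{t}", oid, pos + gl, 2))
            pos += L + 200
        return GenomeAnnotation(genes=genes, promoters=proms, terminators=[], genome_length_nt=pos)

    def test_equal_lengths_give_symmetric_null(self):
        # identical operon lengths collapse to one bin; the observed total then
        # equals the null total exactly and its quantile sits mid-distribution
        ann = self._annotation([4000] * 20, [1] * 20)
        df = tss_uniform_null(ann, n_draws=300, seed=1, n_length_bins=4)
        assert len(df) == 1
        assert df["observed"].iloc[0] == df["null_mean"].iloc[0] == 20
        assert 0.2 < df["quantile"].iloc[0] < 0.8

    def test_tss_concentrated_in_long_operons_enriched(self):
        lengths = [2000] * 15 + [20000] * 5
        tss = [0] * 15 + [6] * 5
        df = tss_uniform_null(self._annotation(lengths, tss), n_draws=500, seed=2, n_length_bins=4)
        assert df.iloc[-1]["quantile"] > 0.975

    def test_self_consistency_quantiles_uniform(self):
        # observations drawn from the uniform-placement null itself
        rng = np.random.default_rng(7)
        lengths = list(rng.integers(2000, 20000, size=60))
        quantiles = []
        for seed in range(30):
            r2 = np.random.default_rng(1000 + seed)
            probs = np.array(lengths) / np.sum(lengths)
            placed = r2.multinomial(40, probs)
            ann = self._annotation(lengths, placed.tolist())
            df = tss_uniform_null(ann, n_draws=300, seed=seed, n_length_bins=3)
            quantiles.append(df["quantile"].iloc[1])
        p = stats.kstest(quantiles, "uniform").pvalue
        assert p > 0.05

    def test_requires_enough_draws(self, tiny_annotation):
        with pytest.raises(ValueError):
            tss_uniform_null(tiny_annotation, n_draws=10)


class TestGff3:
    def test_gff3_reader_maps_features(self, tmp_path):
        lines = [
            "##gff-version 3",
            "##sequence-region chr 1 6000",
            "chr\tsrc\tgene\t100\t400\t.\t+\t.\tID=a1;operon_id=op1",
            "chr\tsrc\tgene\t500\t900\t.\t+\t.\tID=a2;operon_id=op1",
            "chr\tsrc\tpromoter\t80\t80\t.\t+\t.\tID=P1;operon_id=op1",
            "chr\tsrc\tterminator\t950\t950\t.\t+\t.\tID=T1;operon_id=op1",
        ]
        path = tmp_path / "ann.gff3"
        path.write_text("\n".join(lines) + "\n")
        from operonwave.operon_io import parse_gff3

        ann = parse_gff3(path)
        assert ann.operons == {"op1": ["a1", "a2"]}
        assert len(ann.promoters) == 1 and len(ann.terminators) == 1
        assert ann.genome_length_nt == 6000


class TestSetReaders:
    def test_gene_sets_two_column_tsv(self, tmp_path, tiny_annotation):
        from operonwave.operon_io import read_gene_sets

        p = tmp_path / "sets.tsv"
        p.write_text("essential\ta1\nessential\tb2\ncold\tc1\n")
        sets = read_gene_sets(p)
        assert sets["essential"].members == {"a1", "b2"}
        sets["essential"].validate(tiny_annotation)

    def test_go_map_accepts_two_column_and_gaf_rows(self, tmp_path):
        from operonwave.operon_io import read_go_map

        p = tmp_path / "go.tsv"
        p.write_text(
            "!gaf-version: 2.2\n"
            "a1\tGO:0001\n"
            "db\ta2\ta2\t\tGO:0002\tref\tIEA\n"
            "a1\tGO:0003\n"
        )
        go = read_go_map(p)
        assert go["a1"] == ["GO:0001", "GO:0003"]
        assert go["a2"] == ["GO:0002"]
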