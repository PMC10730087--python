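import numpy as np
import pytest

from markdyn.genomic_io import (
    AbundanceRecord,
    ContrastStat,
    CoverageTrack,
    FormatError,
    GeneModel,
    GenomicInterval,
    read_abundance,
    read_coverage,
    read_gene_models,
    read_intervals,
    write_abundance,
    write_coverage,
    write_gene_models,
    write_intervals,
)


class TestIntervals:
    def test_bed_line_parses_with_score(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tp1\t5\n")
        (iv,) = read_intervals(p)
        assert (iv.chrom, iv.start, iv.end, iv.score, iv.name) == ("chr1", 100, 200, 5.0, "p1")

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert read_intervals(p) == []

    def test_inverted_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(FormatError, match=r":2"):
            read_intervals(p)

    def test_non_integer_coordinate_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\tx\t200\n")
        with pytest.raises(FormatError, match="non-integer"):
            read_intervals(p)

    def test_broadpeak_extras_kept_as_meta(self, tmp_path):
        p = tmp_path / "a.broadPeak"
        p.write_text("chr1\t0\t500\tpk1\t800\t.\t7.5\t3.2\t2.1\n")
        (iv,) = read_intervals(p, format="broadpeak")
        assert iv.meta == {"signal_value": 7.5, "p_value": 3.2, "q_value": 2.1}

    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        assert GenomicInterval("chr1", 0, 10).length == 10

    def test_round_trip(self, tmp_path):
        ivs = [
            GenomicInterval("chr1", 0, 50, strand="+", score=1.5, name="a"),
            GenomicInterval("chr2", 10, 99, strand="-", score=-0.25, name="b"),
        ]
        p = tmp_path / "rt.bed"
        write_intervals(p, ivs)
        assert read_intervals(p) == ivs


class TestCoverage:
    def test_stepwise_mean(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t10\t2.0\nchr1\t10\t20\t4.0\n")
        track = read_coverage(p)
        assert track.mean("chr1", 0, 20) == pytest.approx(3.0)

    def test_uncovered_positions_read_zero(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t10\t2.0\n")
        track = read_coverage(p)
        assert track.mean("chr1", 50, 60) == 0.0
        assert track.mean("chrX", 0, 10) == 0.0

    def test_overlapping_spans_rejected(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t2\n")
        with pytest.raises(FormatError, match="overlap"):
            read_coverage(p)

    def test_binned_means_partial_bins(self):
        track = CoverageTrack.from_records([("chr1", 0, 10, 2.0), ("chr1", 10, 20, 4.0)])
        np.testing.assert_allclose(
            track.binned_means("chr1", 5, 15, 2), [2.0, 4.0]
        )
        # bin straddling the step: mean of the two halves
        np.testing.assert_allclose(track.binned_means("chr1", 5, 15, 1), [3.0])

    def test_negative_coordinates_read_zero(self):
        track = CoverageTrack.from_records([("chr1", 0, 10, 2.0)])
        np.testing.assert_allclose(
            track.binned_means("chr1", -10, 10, 2), [0.0, 2.0]
        )

    def test_rpm_scaling_total(self, tmp_path):
        track = CoverageTrack.from_records([("chr1", 0, 100, 5.0)])
        rpm = track.to_rpm()
        assert rpm.total_signal == pytest.approx(1e6)
        p = tmp_path / "out.bedgraph"
        write_coverage(p, rpm)
        assert read_coverage(p).total_signal == pytest.approx(1e6)


class TestGeneModels:
    def test_minus_strand_tss_tes_convention(self):
        g = GeneModel(
            "g1", GenomicInterval("chr1", 1000, 5000, strand="-"), transcript_id="t1"
        )
        assert (g.tss, g.tes, g.length_bp) == (5000, 1000, 4000)

    def test_missing_strand_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t100\tg1\t0\t.\n")
        with pytest.raises(FormatError, match="strand"):
            read_gene_models(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t100\tg1\t0\t+\nchr1\t200\t300\tg1\t0\t-\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_gene_models(p)

    def test_gtf_one_based_conversion(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t1001\t5000\t.\t+\t.\tgene_id "g1";\n'
        )
        (g,) = read_gene_models(p, format="gtf")
        assert (g.start, g.end) == (1000, 5000)

    def test_bed12_round_trip_with_exons(self, tmp_path):
        g = GeneModel(
            "g1",
            GenomicInterval("chr1", 100, 1000, strand="+"),
            exons=((100, 300), (800, 1000)),
        )
        p = tmp_path / "g.bed12"
        write_gene_models(p, [g])
        (back,) = read_gene_models(p)
        assert back.exons == g.exons
        assert back.interval == g.interval


class TestAbundance:
    def _write(self, tmp_path, rows):
        p = tmp_path / "a.tsv"
        header = "transcript_id\tgene_id\ttpm\tq_value_m1\tlog2fc_m1\n"
        p.write_text(header + "".join(rows))
        return p

    def test_typed_record(self, tmp_path):
        p = self._write(tmp_path, ["t1\tg1\t3.2\t0.01\t-0.8\n"])
        (rec,) = read_abundance(p, ["m1"])
        assert rec.tpm == 3.2
        assert rec.contrasts["m1"] == ContrastStat(0.01, -0.8)

    def test_q_outside_unit_interval_rejected(self, tmp_path):
        p = self._write(tmp_path, ["t1\tg1\t3.2\t1.3\t-0.8\n"])
        with pytest.raises(FormatError, match="q_value"):
            read_abundance(p, ["m1"])

    def test_missing_column_error_lists_header(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("transcript_id\tgene_id\ttpm\n" "t1\tg1\t1.0\n")
        with pytest.raises(FormatError, match="q_value_m1"):
            read_abundance(p, ["m1"])

    def test_round_trip(self, tmp_path):
        rec = AbundanceRecord(
            "t1", "g1", 2.5, {"m1": ContrastStat(0.2, 1.25)}
        )
        p = tmp_path / "rt.tsv"
        write_abundance(p, [rec], ["m1"])
        assert read_abundance(p, ["m1"]) == [rec]
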