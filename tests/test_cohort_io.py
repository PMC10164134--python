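"""Format I/O: clinical TSV, VCF, SEG, BED annotations and gene-set tables."""
import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from wntgct.annotations import GeneAnnotation, default_arms, promoter_window
from wntgct.cn_burden import Segment, SegmentProfile
from wntgct.cohort_io import (Sample, default_wnt_geneset, read_clinical,
                              read_gene_annotations, read_geneset,
                              read_segments, read_variant_calls, vcf_header,
                              write_clinical, write_gene_beds, write_geneset,
                              write_segments)
from wntgct.config import VcfFieldNames


class TestClinical:
    SAMPLES = [
        Sample("S1", 3.5, "male", "testis", "YST", "I", False, 48.0, False),
        Sample("S2", 16.0, "female", "ovary", "SE", "II", True, 12.5, True),
        Sample("S3", 20.0, "male", "extragonadal", "MMGCT", "II", None, None, None),
    ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "clin.tsv"
        write_clinical(self.SAMPLES, path)
        back = read_clinical(path)
        assert back == self.SAMPLES

    def test_duplicate_id_names_offender(self, tmp_path):
        path = tmp_path / "clin.tsv"
        write_clinical([self.SAMPLES[0], self.SAMPLES[0]], path)
        with pytest.raises(ValueError, match="S1"):
            read_clinical(path)

    def test_event_without_time_rejected(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text(
            "sample_id\tage_years\tsex\tsite\thistology\tgct_type\t"
            "relapse\tsurvival_time\tevent\n"
            "S1\t3.0\tmale\ttestis\tYST\tI\t0\t\t1\n")
        with pytest.raises(ValueError, match="survival time"):
            read_clinical(path)

    def test_unknown_histology_names_row(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text(
            "sample_id\tage_years\tsex\tsite\thistology\tgct_type\t"
            "relapse\tsurvival_time\tevent\n"
            "S9\t3.0\tmale\ttestis\tCARCINOMA\tI\t\t\t\n")
        with pytest.raises(ValueError, match="S9"):
            read_clinical(path)


class TestSeg:
    PROFILES = {
        "S1": SegmentProfile("S1", [
            Segment("chr1", 0, 5_000_000, 0.01, loh=False, n_markers=100),
            Segment("chr1", 5_000_000, 9_000_000, 0.82, loh=True, n_markers=80),
        ]),
        "S2": SegmentProfile("S2", [
            Segment("chr2", 100, 4_000_000, -0.51, loh=False, n_markers=77),
        ]),
    }

    def test_round_trip_both_dialects(self, tmp_path):
        for dialect in ("1based_closed", "0based_halfopen"):
            path = tmp_path / f"{dialect}.seg"
            write_segments(self.PROFILES, path, dialect)
            back = read_segments(path, dialect)
            assert back["S1"].segments == self.PROFILES["S1"].segments
            assert back["S2"].segments == self.PROFILES["S2"].segments

    def test_dialect_shift_applied_at_boundary(self, tmp_path):
        path = tmp_path / "x.seg"
        path.write_text("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
                        "S1\tchr1\t1\t100\t10\t0.5\n")
        seg = read_segments(path, "1based_closed")["S1"].segments[0]
        assert (seg.start, seg.end) == (0, 100)
        seg0 = read_segments(path, "0based_halfopen")["S1"].segments[0]
        assert (seg0.start, seg0.end) == (1, 100)

    def test_abutting_segments_retained(self, tmp_path):
        path = tmp_path / "x.seg"
        prof = {"S1": SegmentProfile("S1", [Segment("chr1", 0, 50, 0.1),
                                            Segment("chr1", 50, 90, -0.1)])}
        write_segments(prof, path)
        assert len(read_segments(path)["S1"].segments) == 2

    def test_overlapping_segments_rejected(self, tmp_path):
        path = tmp_path / "x.seg"
        path.write_text("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
                        "S1\tchr1\t1\t100\t10\t0.5\n"
                        "S1\tchr1\t50\t150\t10\t0.5\n")
        with pytest.raises(ValueError, match="overlap"):
            read_segments(path)


@settings(max_examples=50, derandomize=True)
@given(start=st.integers(0, 10**8), length=st.integers(1, 10**6))
def test_coordinate_shift_is_self_inverse(start, length):
    """1-based closed -> 0-based half-open -> back is the identity."""
    one_start, one_end = start + 1, start + length
    zero_start, zero_end = one_start - 1, one_end
    assert (zero_start + 1, zero_end) == (one_start, one_end)
    assert zero_end - zero_start == length


class TestGeneset:
    def test_default_roles(self):
        gs = default_wnt_geneset()
        assert gs.role["APC"] == "repressor"
        assert gs.role["CTNNB1"] == "activator"
        assert len(gs.activators) >= 2 and len(gs.repressors) >= 2

    def test_round_trip(self, tmp_path):
        gs = default_wnt_geneset()
        write_geneset(gs, tmp_path / "gs.tsv")
        assert read_geneset(tmp_path / "gs.tsv").role == gs.role

    def test_same_role_duplicate_deduplicated(self, tmp_path):
        p = tmp_path / "gs.tsv"
        p.write_text("gene\trole\nAPC\trepressor\nAPC\trepressor\n")
        assert read_geneset(p).role == {"APC": "repressor"}

    def test_conflicting_roles_rejected(self, tmp_path):
        p = tmp_path / "gs.tsv"
        p.write_text("gene\trole\nAPC\tactivator\nAPC\trepressor\n")
        with pytest.raises(ValueError, match="conflict"):
            read_geneset(p)


class TestGeneBeds:
    def test_round_trip(self, tmp_path):
        ps, pe = promoter_window(1000, 5000, "-")
        genes = [GeneAnnotation("G1", "chr1", 1000, 5000, "-", ps, pe),
                 GeneAnnotation("G2", "chr2", 9000, 12_000, "+", 7500, 9500)]
        write_gene_beds(genes, tmp_path / "g.bed", tmp_path / "p.bed")
        back = read_gene_annotations(tmp_path / "g.bed", tmp_path / "p.bed")
        assert back == genes

    def test_promoter_window_strand_aware(self):
        assert promoter_window(10_000, 20_000, "+") == (8_500, 10_500)
        assert promoter_window(10_000, 20_000, "-") == (19_500, 21_500)


class TestVcf:
    @staticmethod
    def _write(tmp_path, records, name="x.vcf"):
        f = VcfFieldNames()
        header = vcf_header({"chr1": 249_000_000}, f)
        path = tmp_path / name
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for rec_kw in records:
                rec = vcf.new_record(contig="chr1", start=rec_kw["pos"] - 1,
                                     alleles=("A", "T"))
                info = rec_kw.get("info", {})
                rec.info[f.mapq] = info.get("mq", 50.0)
                rec.info[f.baseq] = info.get("bq", 30.0)
                rec.info[f.gene] = "KIT"
                rec.info[f.consequence] = info.get("csq", "missense")
                if "paf" in info:
                    rec.info[f.popaf] = info["paf"]
                rec.samples[f.tumor_sample][f.ad] = rec_kw["ad_t"]
                if rec_kw.get("with_strand", True):
                    rec.samples[f.tumor_sample][f.adf] = rec_kw.get("adf", (45, 5))
                    rec.samples[f.tumor_sample][f.adr] = rec_kw.get("adr", (45, 5))
                rec.samples[f.tumor_sample][f.dp] = sum(rec_kw["ad_t"])
                rec.samples[f.normal_sample][f.ad] = rec_kw.get("ad_n", (60, 0))
                rec.samples[f.normal_sample][f.adf] = (30, 0)
                rec.samples[f.normal_sample][f.adr] = (30, 0)
                rec.samples[f.normal_sample][f.dp] = sum(rec_kw.get("ad_n", (60, 0)))
                vcf.write(rec)
        return path

    def test_vaf_computed_from_allele_depths(self, tmp_path):
        path = self._write(tmp_path, [{"pos": 100, "ad_t": (90, 10)}])
        res = read_variant_calls(path, "S1")
        assert res.calls[0].tumor_vaf == pytest.approx(0.10)
        assert res.calls[0].pos == 100  # 1-based position preserved
        assert res.calls[0].pop_af is None

    def test_record_without_strand_counts_is_unscorable(self, tmp_path):
        path = self._write(tmp_path, [{"pos": 100, "ad_t": (90, 10),
                                       "with_strand": False},
                                      {"pos": 200, "ad_t": (50, 50)}])
        res = read_variant_calls(path, "S1")
        assert res.n_unscorable == 1
        assert len(res.calls) == 1 and res.calls[0].pos == 200

    def test_empty_vcf_body_yields_empty_list(self, tmp_path):
        path = self._write(tmp_path, [])
        res = read_variant_calls(path, "S1")
        assert res.calls == [] and res.n_unscorable == 0

    def test_population_af_read_when_present(self, tmp_path):
        path = self._write(tmp_path, [{"pos": 100, "ad_t": (50, 50),
                                       "info": {"paf": 0.05}}])
        res = read_variant_calls(path, "S1")
        assert res.calls[0].pop_af == pytest.approx(0.05)


def test_default_arm_table_is_well_formed():
    arms = default_arms()
    names = {a.name for a in arms}
    assert "chr12p" in names and "chr6q" in names
    for chrom in {a.chrom for a in arms}:
        per = sorted((a for a in arms if a.chrom == chrom), key=lambda a: a.start)
        assert len(per) == 2 and per[0].end == per[1].start  # p abuts q
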