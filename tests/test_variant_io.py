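import math

import pytest
from hypothesis import given, strategies as st

from somaclass.variant_io import (
    NON_SBS,
    CaptureFootprint,
    CopyNumberSegment,
    VariantCall,
    VariantParseError,
    compute_pop_max,
    merge_intervals,
    read_annotated_variants,
    read_footprint,
    read_segments,
    read_variants_tsv,
    write_variants_tsv,
    write_variants_vcf,
)
from conftest import make_variant

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=ONTOLOGY,Number=1,Type=String,Description="x">
##INFO=<ID=FPFILTER,Number=1,Type=String,Description="x">
##INFO=<ID=COSMIC_CNT,Number=1,Type=Integer,Description="x">
##INFO=<ID=TRI_CONTEXT,Number=1,Type=String,Description="x">
##INFO=<ID=dbNSFP_ExAC_AF,Number=1,Type=Float,Description="x">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tT1
"""


class TestReadAnnotatedVariants:
    def test_header_only_vcf_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(VCF_HEADER)
        assert read_annotated_variants(str(p), "T1") == []

    def test_single_snv_allele_depths(self, tmp_path):
        # AD=60,40 -> t_alt_freq 40/100, t_maj_allele 60/100
        p = tmp_path / "one.vcf"
        p.write_text(
            VCF_HEADER
            + "chr1\t101\t.\tC\tT\t.\tPASS\tONTOLOGY=missense;TRI_CONTEXT=ACG\tAD\t60,40\n"
        )
        (v,) = read_annotated_variants(str(p), "T1")
        assert v.t_alt_freq == pytest.approx(0.4)
        assert v.t_maj_allele == pytest.approx(0.6)
        assert v.variant_class == "SNV"
        assert v.pos == 100  # converted to 0-based
        assert v.ontology == "missense"

    def test_insertion_has_non_sbs_context(self, tmp_path):
        p = tmp_path / "ins.vcf"
        p.write_text(VCF_HEADER + "chr1\t101\t.\tC\tCAT\t.\tPASS\t.\tAD\t70,30\n")
        (v,) = read_annotated_variants(str(p), "T1")
        assert v.variant_class == "insertion"
        assert v.tri_context == NON_SBS

    def test_multiallelic_split(self, tmp_path):
        p = tmp_path / "multi.vcf"
        p.write_text(
            VCF_HEADER
            + "chr1\t101\t.\tC\tT,G\t.\tPASS\tTRI_CONTEXT=ACG\tAD\t50,30,20\n"
        )
        calls = read_annotated_variants(str(p), "T1")
        assert [c.alt for c in calls] == ["T", "G"]
        assert calls[0].t_alt_freq == pytest.approx(0.3)
        assert calls[1].t_alt_freq == pytest.approx(0.2)
        # major allele fraction computed over all observed alleles
        assert all(c.t_maj_allele == pytest.approx(0.5) for c in calls)

    def test_missing_ad_is_record_level_error(self, tmp_path):
        p = tmp_path / "noad.vcf"
        p.write_text(VCF_HEADER + "chr1\t101\t.\tC\tT\t.\tPASS\t.\t.\t.\n")
        with pytest.raises(VariantParseError, match="chr1:101"):
            read_annotated_variants(str(p), "T1")

    def test_db_annotation_parsed(self, tmp_path):
        p = tmp_path / "db.vcf"
        p.write_text(
            VCF_HEADER
            + "chr1\t101\t.\tC\tT\t.\tPASS\tdbNSFP_ExAC_AF=0.005;TRI_CONTEXT=ACG\tAD\t60,40\n"
        )
        (v,) = read_annotated_variants(str(p), "T1")
        assert v.db_freqs == {"ExAC_AF": pytest.approx(0.005)}

    def test_malformed_vcf_raises(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("this is not a vcf\n")
        with pytest.raises(VariantParseError):
            read_annotated_variants(str(p), "T1")


class TestComputePopMax:
    def test_empty_map_is_zero(self):
        assert compute_pop_max({}) == 0.0

    def test_maximum(self):
        assert compute_pop_max({"1000Gp3": 0.002, "ExAC": 0.005}) == 0.005
        assert compute_pop_max({"gnomAD_exomes": 0.5, "TWINSUK": 0.01}) == 0.5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_pop_max({"ExAC": 1.5})

    @given(
        st.dictionaries(st.text(min_size=1, max_size=5), st.floats(0, 1), max_size=6),
        st.floats(0, 1),
    )
    def test_monotone_in_added_entry(self, dbs, extra):
        before = compute_pop_max(dbs)
        augmented = dict(dbs)
        augmented["__new__"] = extra
        assert compute_pop_max(augmented) >= before


class TestVariantCallInvariants:
    def test_snv_iff_single_base(self):
        with pytest.raises(ValueError):
            make_variant(ref="C", alt="CAT", variant_class="SNV", tri_context="ACG")

    def test_tri_context_consistency(self):
        with pytest.raises(ValueError):
            VariantCall(
                sample_id="S", chrom="chr1", pos=1, ref="C", alt="T",
                variant_class="SNV", t_alt_freq=0.5, t_maj_allele=0.5,
                depth=10, tri_context=NON_SBS,
            )

    def test_bounds(self):
        with pytest.raises(ValueError):
            make_variant(t_alt_freq=1.2)
        with pytest.raises(ValueError):
            make_variant(depth=-1)


class TestSegments:
    def test_empty_body(self, tmp_path):
        p = tmp_path / "s.seg"
        p.write_text("chrom\tstart\tend\tlog2\n")
        assert read_segments(str(p)) == []

    def test_adjacent_segments_roundtrip(self, tmp_path):
        p = tmp_path / "s.seg"
        p.write_text("chrom\tstart\tend\tlog2\nchr1\t0\t1000\t0.0\nchr1\t1000\t5000\t-0.4\n")
        segs = read_segments(str(p))
        assert len(segs) == 2
        assert segs[0].end == segs[1].start == 1000
        assert segs[1].log2_ratio == pytest.approx(-0.4)

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "s.seg"
        p.write_text("chrom\tstart\tend\tlog2\nchr1\t0\t1000\t0.0\nchr1\t500\t2000\t0.1\n")
        with pytest.raises(ValueError, match="overlap"):
            read_segments(str(p))

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            CopyNumberSegment(sample_id="S", chrom="chr1", start=10, end=10, log2_ratio=0.0)


class TestFootprint:
    def test_single_interval_megabases(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t1000000\n")
        fp = read_footprint(str(p))
        assert fp.footprint_mb == pytest.approx(1.0)

    def test_overlapping_intervals_merged(self, tmp_path):
        # chr1 0-100 and 50-200 merge to 0-200: 200 bp = 2e-4 Mb
        p = tmp_path / "b.bed"
        p.write_text("chr1\t0\t100\nchr1\t50\t200\n")
        fp = read_footprint(str(p))
        assert fp.intervals == (("chr1", 0, 200),)
        assert fp.footprint_mb == pytest.approx(2e-4)

    def test_empty_bed_warns(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("")
        with pytest.warns(UserWarning):
            fp = read_footprint(str(p))
        assert fp.footprint_mb == 0.0

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "d.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(ValueError):
            read_footprint(str(p))

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 500),
                st.integers(1, 200),
            ),
            max_size=15,
        )
    )
    def test_merge_idempotent_and_order_independent(self, raw):
        intervals = [(c, s, s + w) for c, s, w in raw]
        merged = merge_intervals(intervals)
        assert merge_intervals(merged) == merged
        assert merge_intervals(list(reversed(intervals))) == merged

    def test_footprint_invariant(self):
        fp = CaptureFootprint("k", (("chr1", 0, 1_500_000),), 1.5)
        total = sum(e - s for _, s, e in fp.intervals)
        assert math.isclose(fp.footprint_mb, total / 1e6, abs_tol=1e-9)


class TestTsvRoundTrip:
    def test_round_trip_exact(self, tmp_path):
        variants = [
            make_variant(db_freqs={"ExAC_AF": 0.003, "UK10K_AF": 0.1}, cosmic_count=7),
            make_variant(pos=200, ref="A", alt="AT", variant_class="insertion",
                         ontology="frameshift_indel", truth_label=1),
            make_variant(pos=300, ref="T", alt="G", tri_context="ATA",
                         t_alt_freq=1 / 3, t_maj_allele=2 / 3, truth_label=0),
        ]
        p = tmp_path / "v.tsv"
        write_variants_tsv(variants, str(p))
        assert read_variants_tsv(str(p)) == variants

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("not-a-header\n")
        with pytest.raises(VariantParseError):
            read_variants_tsv(str(p))


class TestVcfRoundTrip:
    def test_vcf_write_read_preserves_core_fields(self, tmp_path):
        variants = [
            make_variant(db_freqs={"ExAC_AF": 0.004}, cosmic_count=3),
            make_variant(pos=500, ref="G", alt="GTC", variant_class="insertion",
                         ontology="inframe_indel"),
        ]
        p = tmp_path / "out.vcf"
        write_variants_vcf(variants, str(p), sample_id="S1")
        back = read_annotated_variants(str(p), "S1")
        assert len(back) == 2
        by_pos = {v.pos: v for v in back}
        assert by_pos[100].t_alt_freq == pytest.approx(0.4)
        assert by_pos[100].cosmic_count == 3
        assert by_pos[100].db_freqs["ExAC_AF"] == pytest.approx(0.004)
        assert by_pos[500].variant_class == "insertion"
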