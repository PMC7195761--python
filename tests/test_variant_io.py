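"""Variant model, normalization, VCF+sidecar reading, transcript ranking."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duohit.variant_io import (
    CohortPanel,
    Variant,
    VariantKey,
    normalize,
    rank_transcripts,
    read_variants,
    write_variants,
)


def v(chrom="1", pos=100, ref="A", alt="T", **kw):
    kw.setdefault("vaf", 0.5)
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


class TestVariantModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            v(pos=0)
        with pytest.raises(ValueError):
            v(ref="A", alt="A")
        with pytest.raises(ValueError):
            v(vaf=1.5)
        with pytest.raises(ValueError):
            v(cohort_freqs={"x": 2.0})

    def test_key_equality_across_individuals(self):
        a = v(gene="G1", qual=50)
        b = v(gene="G2", qual=80)
        assert a.key == b.key == VariantKey("1", 100, "A", "T")

    def test_key_string_round_trip(self):
        key = VariantKey("X", 12345, "AT", "A")
        assert VariantKey.parse(str(key)) == key


class TestNormalize:
    def test_shared_leading_base_trimmed(self):
        out = normalize(v(pos=100, ref="AT", alt="AC"))
        assert (out.pos, out.ref, out.alt) == (101, "T", "C")

    def test_minimal_snv_unchanged(self):
        x = v(pos=100, ref="A", alt="T")
        assert normalize(x) is x

    def test_padded_representations_collapse_to_one_key(self):
        # a fixed 3-bp deletion, re-padded every way with shared context
        minimal = v(pos=100, ref="ACGT", alt="A")
        prefix_pool = ["", "G", "GG", "TAG"]
        suffix_pool = ["", "C", "CC", "ACG"]
        keys = set()
        for pre, suf in itertools.product(prefix_pool, suffix_pool):
            padded = v(
                pos=100 - len(pre),
                ref=pre + minimal.ref + suf,
                alt=pre + minimal.alt + suf,
            )
            keys.add(normalize(padded).key)
        assert keys == {minimal.key}

    @given(
        pos=st.integers(1, 10_000),
        core=st.tuples(st.text("ACGT", min_size=1, max_size=4),
                       st.text("ACGT", min_size=1, max_size=4)).filter(lambda t: t[0] != t[1]),
        pad=st.text("ACGT", max_size=3),
    )
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, pos, core, pad):
        ref, alt = core
        x = v(pos=pos, ref=pad + ref, alt=pad + alt)
        once = normalize(x)
        assert normalize(once) == once

    def test_left_alignment_with_reference_context(self):
        # deletion inside a homopolymer shifts to its leftmost placement
        seq = "GGGAAAAAT"  # 1-based positions 1..9

        def ref_ctx(chrom, s0, e0):
            return seq[s0:e0]

        # delete one A, represented at the right edge of the run; the
        # left-aligned form anchors on the G preceding the homopolymer
        x = v(pos=7, ref="AA", alt="A")
        out = normalize(x, reference=ref_ctx)
        assert (out.pos, out.ref, out.alt) == (3, "GA", "G")
        assert normalize(out, reference=ref_ctx) == out


class TestRankTranscripts:
    def test_lof_beats_missense(self):
        records = [
            v(gene="G", transcript="NM_A", consequence="missense", cadd_scaled=25.0),
            v(gene="G", transcript="NM_B", consequence="nonsense"),
        ]
        assert rank_transcripts(records).transcript == "NM_B"

    def test_single_record_is_identity(self):
        x = v(transcript="NM_1", consequence="missense")
        assert rank_transcripts([x]) is x

    def test_refseq_curated_tie_break_under_all_orderings(self):
        records = [
            v(transcript="XM_1", consequence="missense"),
            v(transcript="NM_2", consequence="missense"),
        ]
        for perm in itertools.permutations(records):
            assert rank_transcripts(list(perm)).transcript == "NM_2"

    def test_lexicographic_tie_break(self):
        records = [v(transcript=t, consequence="missense") for t in ("NM_9", "NM_10", "NM_2")]
        for perm in itertools.permutations(records):
            assert rank_transcripts(list(perm)).transcript == "NM_10"

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            rank_transcripts([])

    def test_mixed_keys_rejected(self):
        with pytest.raises(ValueError):
            rank_transcripts([v(pos=1), v(pos=2)])


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##contig=<ID=5,length=120000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1
1\t100\t.\tA\tC,T\t60\t.\t.\tGT:AD\t1/2:2,9,9
1\t500\t.\tG\tT\t45\t.\t.\tGT:AD\t0/1:10,10
5\t112220000\t.\tT\tG\t99\t.\t.\tGT:AD\t0/1:30,30
"""

SIDECAR_TEXT = """\
chrom\tpos\tref\talt\tgene\ttranscript\tconsequence\tcadd_scaled\tgnomad
5\t112220000\tT\tG\tREEP5\tNM_005669.4\tnonsense\t31\t0.0
5\t112220000\tT\tG\tREEP5\tXM_0001.1\tother\t\t0.0
"""


class TestReadVariants:
    @pytest.fixture()
    def paths(self, tmp_path):
        vcf = tmp_path / "p1.vcf"
        vcf.write_text(VCF_TEXT)
        ann = tmp_path / "p1.tsv"
        ann.write_text(SIDECAR_TEXT)
        return vcf, ann

    def test_symmetric_depths_give_half_vaf(self, paths):
        vcf, ann = paths
        out = read_variants(vcf, ann, sample="P1")
        snv = next(x for x in out if x.pos == 500)
        assert snv.vaf == pytest.approx(0.5)

    def test_multiallelic_decomposed_into_n_minus_one_records(self, paths):
        vcf, ann = paths
        out = read_variants(vcf, ann, sample="P1")
        tri = [x for x in out if x.pos == 100]
        assert len(tri) == 2
        assert {x.alt for x in tri} == {"C", "T"}
        assert all(x.chrom == "1" and x.ref == "A" for x in tri)

    def test_nonsense_annotation_joined_with_best_transcript(self, paths):
        vcf, ann = paths
        out = read_variants(vcf, ann, sample="P1")
        reep5 = next(x for x in out if x.chrom == "5")
        assert reep5.gene == "REEP5"
        assert reep5.transcript == "NM_005669.4"
        assert reep5.consequence == "nonsense"
        assert reep5.cadd_scaled == 31
        assert reep5.cohort_freqs["gnomad"] == 0.0

    def test_unannotated_record_gets_other(self, paths):
        vcf, ann = paths
        out = read_variants(vcf, ann, sample="P1")
        plain = next(x for x in out if x.pos == 500)
        assert plain.consequence == "other"
        assert plain.cadd_scaled is None

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.vcf"):
            read_variants(tmp_path / "nope.vcf", None)

    def test_orphan_annotation_row_warns(self, tmp_path, paths):
        vcf, _ = paths
        ann = tmp_path / "orphan.tsv"
        ann.write_text(
            "chrom\tpos\tref\talt\tgene\ttranscript\tconsequence\tcadd_scaled\n"
            "9\t42\tA\tG\tGHOST\tNM_1\tmissense\t12\n"
        )
        with pytest.warns(UserWarning, match="matches no variant"):
            read_variants(vcf, ann, sample="P1")


class TestRoundTrip:
    def test_write_read_preserves_key_set(self, tmp_path):
        variants = [
            v(chrom="1", pos=10, ref="A", alt="G", gene="X", consequence="missense",
              qual=50, vaf=0.4, cadd_scaled=12.0, cohort_freqs={"gnomad": 1e-5}),
            v(chrom="2", pos=20, ref="CT", alt="C", gene="Y", consequence="frameshift",
              qual=70, vaf=0.3),
            v(chrom="X", pos=5, ref="G", alt="T", gene="Z", consequence="nonsense",
              qual=90, vaf=0.6),
        ]
        vcf = tmp_path / "rt.vcf"
        ann = tmp_path / "rt.tsv"
        write_variants(variants, vcf, ann)
        back = read_variants(vcf, ann)
        assert {x.key for x in back} == {x.key for x in variants}
        assert {x.consequence for x in back} == {"missense", "frameshift", "nonsense"}


class TestCohortPanel:
    def test_absent_key_is_absent_not_error(self):
        panel = CohortPanel("p", keys=[VariantKey("1", 1, "A", "T")])
        missing = VariantKey("2", 2, "C", "G")
        assert not panel.contains(missing)
        assert panel.frequency(missing) == 0.0

    def test_presence_without_frequency_counts_as_present(self):
        key = VariantKey("1", 1, "A", "T")
        panel = CohortPanel("p", keys=[key])
        assert panel.contains(key)
        assert panel.frequency(key) == 0.0

    def test_key_list_round_trip(self, tmp_path):
        path = tmp_path / "panel.keys"
        path.write_text("1:100:A:T\n2:200:G:C\t0.004\n")
        panel = CohortPanel.from_key_list("p", path)
        assert panel.contains(VariantKey("1", 100, "A", "T"))
        assert panel.frequency(VariantKey("2", 200, "G", "C")) == 0.004
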