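"""Published study tables for the familial appendiceal mucinous tumour duo.

The study sequenced the germline exomes of two affected relatives (P1, P2)
with appendiceal mucinous tumours / pseudomyxoma peritonei and profiled
their tumours on a copy-number/LOH array. Its published evidence surface —
the fifteen validated shared candidate variants, the per-tumour LOH /
copy-number-loss segment tables, and the tumour allele observations for the
four candidates falling in LOH — is encoded here as in-memory fixtures so
the pipeline's worked examples and regression tests run without any
external download.

Variant genomic coordinates: the publication identifies each candidate by
gene, transcript and cDNA change, not by genomic position. The positions
used here are synthetic placements at each gene's GRCh37 locus (correct
chromosome, position inside the gene's genomic span, alleles taken from the
cDNA change read on the forward strand). Every conclusion drawn from them —
which candidates fall inside which megabase-scale tumour segments — is
insensitive to the intra-gene offset.

Segment coordinates are encoded exactly as printed and declared 0-based
half-open: several rows start at 0 (whole p-arm-to-position events), which
makes the 0-based reading the natural one, and the run-together published
text of the P1 table is resolved so that its first row is chromosome 1,
0–26,948,921 — the only reading under which exactly one region of LOH is
common to both tumours, as the study reports.
"""

from __future__ import annotations

from .loh_segments import GenomeModel, Segment, SegmentSet, grch37_genome
from .two_hit import TumourObservation
from .variant_io import Variant

__all__ = [
    "candidate_variants",
    "tumour_segments",
    "tumour_allele_observations",
    "genome",
    "SHARED_LOH_REGION",
]

#: The one LOH region common to both tumours: chr2q, 1,771,307 bp.
SHARED_LOH_REGION = Segment("2", 241_428_066, 243_199_373, "LOH")

# gene, transcript, cDNA, protein, consequence, scaled CADD, gnomAD v2 freq,
# chrom, synthetic position inside the gene's GRCh37 span
_CANDIDATES = [
    ("REEP5", "NM_005669.4", "c.159T>G", "p.Tyr53*", "nonsense", 31.0, 0.0, "5", 112_220_000),
    ("RHBDL2", "NM_017821.3", "c.395C>G", "p.Gly132Ala", "missense", 29.8, 0.0, "1", 39_360_000),
    ("FGFR4", "NM_022963.2", "c.1988G>A", "p.Arg663Gln", "missense", 21.9, 4.42e-5, "5", 176_520_000),
    ("CNTN2", "NM_005076.3", "c.2263A>T", "p.Ser755Cys", "missense", 21.2, 3.98e-6, "1", 205_020_000),
    ("RANBP2", "NM_006267.4", "c.3683G>T", "p.Gly1228Val", "missense", 19.8, 0.0, "2", 109_370_000),
    ("ZNF747", "NM_023931.2", "c.254C>T", "p.Gly85Glu", "missense", 16.28, 5.70e-6, "16", 30_540_000),
    ("EXOG", "NM_005107.3", "c.178G>A", "p.Ala60Thr", "missense", 16.17, 0.0, "3", 38_550_000),
    ("BRINP3", "NM_199051.1", "c.809A>C", "p.Glu270Ala", "missense", 16.1, 1.60e-5, "1", 190_100_000),
    ("ASIC1", "NM_020039.3", "c.463C>T", "p.Arg155Cys", "missense", 16.05, 0.0, "12", 50_460_000),
    ("TNFRSF1B", "NM_001066.2", "c.1337A>G", "p.Glu446Gly", "missense", 15.46, 3.99e-6, "1", 12_250_000),
    ("RANBP6", "NM_001243202.1", "c.251A>C", "p.Glu84Ala", "missense", 14.87, 3.98e-6, "9", 6_015_000),
    ("LSR", "NM_205834.3", "c.725C>T", "p.Thr242Ile", "missense", 14.79, 3.20e-5, "19", 35_740_000),
    ("MTERFD3", "NM_001033050.1", "c.607C>T", "p.Ala203Thr", "missense", 12.04, 1.20e-5, "12", 107_380_000),
    ("PAX1", "NM_001257096.1", "c.1379G>T", "p.Arg460Leu", "missense", 11.57, 5.11e-5, "20", 21_690_000),
    ("EGFR", "NM_005228.3", "c.1915A>C", "p.Asn639His", "missense", 10.51, 0.0, "7", 55_240_000),
]


def candidate_variants() -> list[Variant]:
    """The fifteen validated shared candidates (1 LoF, 14 missense).

    QUAL and VAF are not part of the published table; representative
    in-band values (QUAL 99, VAF 0.5) are filled in so the records pass the
    heterozygous-quality stage they had already cleared in the study.
    """
    out = []
    for gene, tx, cdna, prot, csq, cadd, freq, chrom, pos in _CANDIDATES:
        ref, alt = _alleles_from_cdna(cdna)
        out.append(
            Variant(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=gene, transcript=tx, consequence=csq,
                qual=99.0, vaf=0.5,
                cadd_scaled=cadd,
                cohort_freqs={"gnomad": freq},
                hgvs_c=cdna, hgvs_p=prot,
            )
        )
    return out


def _alleles_from_cdna(cdna: str) -> tuple[str, str]:
    # e.g. "c.159T>G" -> ("T", "G"); forward-strand placement
    change = cdna.split(".")[-1]
    ref_alt = "".join(ch for ch in change if ch in "ACGT>")
    ref, alt = ref_alt.split(">")
    return ref, alt


# Per-tumour segment tables, exactly as printed (0-based half-open).
_P1_SEGMENTS = [
    ("1", 0, 26_948_921, "CN_LOSS_LOH"),
    ("1", 147_134_028, 147_825_662, "LOH"),
    ("1", 190_881_536, 191_887_248, "LOH"),
    ("2", 50_914_938, 51_446_707, "LOH"),
    ("2", 99_377_108, 243_199_373, "LOH"),
    ("3", 0, 48_040_095, "LOH"),
    ("3", 50_384_337, 52_768_237, "LOH"),
    ("3", 191_022_128, 191_856_841, "LOH"),
    ("4", 21_562_094, 22_526_745, "LOH"),
    ("6", 33_506_076, 171_115_067, "CN_LOSS_LOH"),
    ("7", 22_818_202, 23_530_679, "LOH"),
    ("9", 0, 33_946_637, "LOH"),
    ("9", 118_867_206, 119_530_524, "LOH"),
    ("10", 62_401_757, 63_554_609, "LOH"),
    ("10", 69_912_047, 70_990_019, "LOH"),
    ("11", 5_529_179, 6_091_608, "LOH"),
    ("11", 34_356_991, 35_043_999, "LOH"),
    ("12", 21_011_988, 22_928_787, "LOH"),
    ("12", 29_116_987, 29_816_788, "LOH"),
    ("12", 111_166_777, 112_632_998, "LOH"),
    ("14", 36_158_966, 36_786_121, "LOH"),
    ("15", 84_783_628, 85_501_061, "LOH"),
    ("17", 857_820, 1_452_131, "LOH"),
    ("18", 18_535_946, 19_513_726, "LOH"),
    ("19", 41_994_722, 48_382_347, "CN_LOSS_LOH"),
    ("21", 14_414_872, 48_129_895, "CN_LOSS_LOH"),
]

_P2_SEGMENTS = [
    ("2", 241_428_066, 243_199_373, "CN_LOSS_LOH"),
    ("8", 0, 33_395_041, "CN_LOSS_LOH"),
    ("8", 42_137_047, 49_106_261, "LOH"),
    ("10", 0, 29_922_641, "CN_LOSS"),
    ("11", 66_296_148, 135_006_516, "LOH"),
    ("11", 111_333_148, 117_815_955, "CN_LOSS"),
    ("11", 130_316_743, 135_006_516, "CN_LOSS"),
    ("X", 1, 155_270_560, "CN_LOSS_LOH"),
]


def tumour_segments(sample: str) -> SegmentSet:
    """LOH / copy-number segment table for tumour ``"P1"`` or ``"P2"``."""
    try:
        rows = {"P1": _P1_SEGMENTS, "P2": _P2_SEGMENTS}[sample]
    except KeyError:
        raise ValueError(f"unknown tumour sample {sample!r}; use 'P1' or 'P2'") from None
    return SegmentSet(
        sample,
        [Segment(c, s, e, ev) for c, s, e, ev in rows],
        provenance="published array segment table",
    ).normalized()


def tumour_allele_observations() -> list[TumourObservation]:
    """Tumour sequencing of the four candidates inside P1's LOH.

    The RANBP2 locus had lost the mutant allele; EXOG, RANBP6 and TNFRSF1B
    still showed both alleles in the sequenced (primary appendiceal) tumour
    tissue despite array LOH in the peritoneal tumour.
    """
    by_gene = {v.gene: v for v in candidate_variants()}
    return [
        TumourObservation(by_gene["RANBP2"].key, "wildtype_only", "tumour Sanger, P1"),
        TumourObservation(by_gene["EXOG"].key, "both", "tumour Sanger, P1"),
        TumourObservation(by_gene["RANBP6"].key, "both", "tumour Sanger, P1"),
        TumourObservation(by_gene["TNFRSF1B"].key, "both", "tumour Sanger, P1"),
    ]


def genome() -> GenomeModel:
    """GRCh37 genome model matching the segment tables."""
    return grch37_genome()
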