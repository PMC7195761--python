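"""Germline variant data model and I/O.

This module houses the normalized single-alternate variant record used by
every downstream stage, readers for VCF input joined against a tab-separated
annotation sidecar (consequence class, scaled CADD score, per-cohort allele
frequencies), cohort presence/frequency panels, and the transcript-ranking
rule that collapses multi-transcript annotations to the most deleterious one.

Coordinate convention: variant positions are 1-based (VCF convention)
throughout; tumour segment code converts at its own boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Consequence classes counted as loss-of-function. "Essential splice" means
#: a change within +/-2 bp of an exon boundary (the canonical donor/acceptor
#: dinucleotides); that width is an assumption recorded in the methods note.
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "essential_splice"})

CONSEQUENCES = LOF_CONSEQUENCES | {"missense", "other"}

#: Deleteriousness rank used by :func:`rank_transcripts`; lower is more
#: deleterious. All LoF classes tie at the top. Configurable because the
#: full ranking of milder classes is a project convention, not a law.
DEFAULT_CONSEQUENCE_RANK: Mapping[str, int] = {
    "nonsense": 0,
    "frameshift": 0,
    "essential_splice": 0,
    "missense": 1,
    "other": 2,
}

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort chromosomes 1..22, X, Y, MT, then anything else lexically."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (_CHROM_ORDER.get(c, 99), c)


class VariantKey(NamedTuple):
    """Identity of a normalized variant: two records from different
    individuals denote the same allele iff their keys are equal."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def sort_key(self):
        return (*chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.strip().split(":")
        return cls(chrom, int(pos), ref, alt)


@dataclass
class Variant:
    """One normalized germline variant call with its annotations.

    ``cadd_scaled`` may be ``None`` (typical for LoF calls, which bypass the
    CADD filter). ``cohort_freqs`` maps cohort name to allele frequency; a
    missing key means the variant was not observed in that cohort.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    transcript: str = ""
    consequence: str = "other"
    qual: float = 0.0
    vaf: float = 0.0
    cadd_scaled: float | None = None
    cohort_freqs: dict[str, float] = field(default_factory=dict)
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        for name, f in self.cohort_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"cohort frequency out of [0,1]: {name}={f}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_lof(self) -> bool:
        return self.consequence in LOF_CONSEQUENCES


def normalize(variant: Variant, reference: Callable[[str, int, int], str] | None = None) -> Variant:
    """Return the minimal representation of ``variant``.

    Shared trailing bases are trimmed first, then shared leading bases
    (advancing ``pos``), always keeping at least one base in each allele.
    When ``reference(chrom, start0, end0) -> str`` is supplied, indels are
    additionally left-aligned by the standard shift-left rule. Idempotent.
    """
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if reference is not None and len(ref) != len(alt):
        # left-align: while alleles end with the same base, prepend the
        # reference base to the left and drop the shared last base
        while ref[-1] == alt[-1] and pos > 1:
            prev = reference(variant.chrom, pos - 2, pos - 1).upper()
            if not prev:
                break
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
    if (ref, alt, pos) == (variant.ref, variant.alt, variant.pos):
        return variant
    return replace(variant, ref=ref, alt=alt, pos=pos)


def rank_transcripts(
    records: Sequence[Variant],
    consequence_rank: Mapping[str, int] = DEFAULT_CONSEQUENCE_RANK,
) -> Variant:
    """Pick the single most deleterious transcript annotation for one variant.

    All records must share the same :class:`VariantKey` and gene and differ
    in transcript (and possibly consequence). Order: LoF classes first, then
    missense, then other; ties broken by preferring RefSeq curated ("NM_")
    accessions, then the lexicographically smallest accession. Invariant
    under permutation of the input.
    """
    if not records:
        raise ValueError("rank_transcripts: empty input")
    keys = {r.key for r in records}
    if len(keys) != 1:
        raise ValueError(f"rank_transcripts: records span multiple variants {keys}")

    def sort_key(r: Variant):
        return (
            consequence_rank.get(r.consequence, max(consequence_rank.values()) + 1),
            0 if r.transcript.startswith("NM_") else 1,
            r.transcript,
        )

    return min(records, key=sort_key)


ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "transcript", "consequence", "cadd_scaled"]


def _read_annotation_sidecar(path: Path | str) -> tuple[dict[VariantKey, list[dict]], list[str]]:
    """Parse the tab-separated annotation sidecar.

    Mandatory columns: chrom, pos, ref, alt, gene, transcript, consequence,
    cadd_scaled. Every additional column is interpreted as a per-cohort
    allele frequency (empty cell = not observed in that cohort).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation sidecar lacks columns {missing}")
    cohort_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    rows: dict[VariantKey, list[dict]] = {}
    for rec in df.itertuples(index=False):
        d = rec._asdict()
        key = VariantKey(str(d["chrom"]), int(d["pos"]), d["ref"], d["alt"])
        cadd = d["cadd_scaled"]
        freqs = {c: float(d[c]) for c in cohort_cols if pd.notna(d[c])}
        rows.setdefault(key, []).append(
            {
                "gene": "" if pd.isna(d["gene"]) else str(d["gene"]),
                "transcript": "" if pd.isna(d["transcript"]) else str(d["transcript"]),
                "consequence": str(d["consequence"]),
                "cadd_scaled": None if pd.isna(cadd) else float(cadd),
                "cohort_freqs": freqs,
            }
        )
    return rows, cohort_cols


def read_variants(
    vcf_path: Path | str,
    annotation_path: Path | str | None,
    sample: str | None = None,
    reference: Callable[[str, int, int], str] | None = None,
) -> list[Variant]:
    """Read one individual's calls from a VCF, normalize them and join the
    annotation sidecar.

    Multi-allelic rows are decomposed into one record per alternate allele.
    VAF comes from a FORMAT ``AF`` field when present, else from allele
    depths (``AD``); calls with zero total depth are dropped with a warning.
    Records with no matching annotation row get ``consequence='other'`` and
    no CADD score; annotation rows matching no call raise a warning only.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(f"cannot read VCF: {vcf_path}")
    annotations: dict[VariantKey, list[dict]] = {}
    if annotation_path is not None:
        ann_path = Path(annotation_path)
        if not ann_path.exists():
            raise FileNotFoundError(f"cannot read annotation sidecar: {ann_path}")
        annotations, _ = _read_annotation_sidecar(ann_path)

    vcf = VCF(str(vcf_path))
    if sample is not None:
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} not in {vcf_path} (has {vcf.samples})")
        sidx = vcf.samples.index(sample)
    else:
        sidx = 0 if vcf.samples else None

    out: list[Variant] = []
    seen: set[VariantKey] = set()
    for rec in vcf:
        qual = float(rec.QUAL) if rec.QUAL is not None else 0.0
        n_alts = len(rec.ALT)
        afs = _format_field(rec, "AF", sidx)
        ads = _format_field(rec, "AD", sidx)
        for ai, alt in enumerate(rec.ALT):
            if alt in (".", "*", ""):
                continue
            vaf = None
            if afs is not None and ai < len(afs):
                vaf = float(afs[ai])
            elif ads is not None:
                total = float(sum(max(x, 0) for x in ads))
                if total <= 0:
                    warnings.warn(
                        f"{vcf_path}:{rec.CHROM}:{rec.POS} zero depth; record dropped"
                    )
                    continue
                vaf = float(max(ads[ai + 1], 0)) / total if ai + 1 < len(ads) else 0.0
            v = normalize(
                Variant(
                    chrom=rec.CHROM.removeprefix("chr"),
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    qual=qual,
                    vaf=min(max(vaf, 0.0), 1.0) if vaf is not None else 0.0,
                ),
                reference=reference,
            )
            ann_rows = annotations.get(v.key)
            if ann_rows:
                best = rank_transcripts(
                    [
                        replace(v, **{k: row[k] for k in ("gene", "transcript", "consequence", "cadd_scaled")},
                                cohort_freqs=dict(row["cohort_freqs"]))
                        for row in ann_rows
                    ]
                )
                v = best
            out.append(v)
            seen.add(v.key)
        del n_alts
    for key in annotations.keys() - seen:
        warnings.warn(f"annotation row {key} matches no variant in {vcf_path}")
    return out


def _format_field(rec, name: str, sidx: int | None):
    if sidx is None:
        return None
    try:
        arr = rec.format(name)
    except KeyError:
        return None
    if arr is None:
        return None
    row = arr[sidx]
    try:
        return [x for x in row]
    except TypeError:
        return [row]


def write_variants(
    variants: Sequence[Variant],
    vcf_path: Path | str,
    annotation_path: Path | str | None = None,
    sample: str = "SAMPLE",
    contig_lengths: Mapping[str, int] | None = None,
    cohort_columns: Sequence[str] | None = None,
    depth: int = 100,
) -> None:
    """Write variants as a single-sample VCF plus (optionally) a sidecar.

    The VCF carries QUAL and an AD field derived from ``vaf`` at the given
    synthetic read ``depth``, so ``read_variants`` round-trips the key set
    exactly and the VAF to within 1/depth. Output is deterministic: records
    sorted by genomic key, no timestamps.
    """
    variants = sorted(variants, key=lambda v: v.key.sort_key())
    if contig_lengths is None:
        contig_lengths = {}
        for v in variants:
            contig_lengths[v.chrom] = max(
                contig_lengths.get(v.chrom, 0), v.pos + len(v.ref) + 1000
            )
    lines = ["##fileformat=VCFv4.2"]
    for chrom in sorted(contig_lengths, key=chrom_sort_key):
        lines.append(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for v in variants:
        alt_depth = int(round(v.vaf * depth))
        ad = f"{depth - alt_depth},{alt_depth}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:g}\t.\t.\tGT:AD\t0/1:{ad}"
        )
    Path(vcf_path).write_text("\n".join(lines) + "\n")

    if annotation_path is not None:
        if cohort_columns is None:
            cols: list[str] = []
            for v in variants:
                for c in v.cohort_freqs:
                    if c not in cols:
                        cols.append(c)
            cohort_columns = cols
        rows = []
        for v in variants:
            row = {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "transcript": v.transcript,
                "consequence": v.consequence,
                "cadd_scaled": v.cadd_scaled,
            }
            for c in cohort_columns:
                row[c] = v.cohort_freqs.get(c)
            rows.append(row)
        pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + list(cohort_columns)).to_csv(
            annotation_path, sep="\t", index=False
        )


class CohortPanel:
    """A control cohort: membership (and optionally frequency) by VariantKey.

    Absent keys are simply absent — ``contains`` returns False and
    ``frequency`` returns 0.0, never an error.
    """

    def __init__(self, name: str, frequencies: Mapping[VariantKey, float] | None = None,
                 keys: Iterable[VariantKey] | None = None):
        self.name = name
        self._freqs: dict[VariantKey, float] = dict(frequencies or {})
        if keys is not None:
            for k in keys:
                self._freqs.setdefault(k, float("nan"))

    def contains(self, key: VariantKey) -> bool:
        """Presence means any record of the allele, regardless of frequency."""
        return key in self._freqs

    def frequency(self, key: VariantKey) -> float:
        f = self._freqs.get(key, 0.0)
        return 0.0 if f != f else f  # NaN (presence-only entry) -> 0.0

    def __len__(self) -> int:
        return len(self._freqs)

    @classmethod
    def from_key_list(cls, name: str, path: Path | str) -> "CohortPanel":
        """Load a panel from a chrom:pos:ref:alt-per-line key list.

        Lines may carry an optional tab-separated frequency column.
        """
        freqs: dict[VariantKey, float] = {}
        keys: list[VariantKey] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            key = VariantKey.parse(parts[0])
            if len(parts) > 1 and parts[1] != "":
                freqs[key] = float(parts[1])
            else:
                keys.append(key)
        return cls(name, frequencies=freqs, keys=keys)

    @classmethod
    def from_vcf(cls, name: str, path: Path | str, freq_info: str = "AF") -> "CohortPanel":
        """Load a panel from a sites VCF; AF INFO values become frequencies."""
        freqs: dict[VariantKey, float] = {}
        keys: list[VariantKey] = []
        for rec in VCF(str(path)):
            af = rec.INFO.get(freq_info)
            alts = rec.ALT
            for ai, alt in enumerate(alts):
                v = normalize(Variant(rec.CHROM.removeprefix("chr"), rec.POS, rec.REF, alt, vaf=0.5))
                if af is not None:
                    f = af[ai] if isinstance(af, tuple) else af
                    freqs[v.key] = float(f)
                else:
                    keys.append(v.key)
        return cls(name, frequencies=freqs, keys=keys)
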