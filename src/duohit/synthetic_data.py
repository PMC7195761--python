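"""Seeded synthetic study generator with recorded ground truth.

Emulates the discovery design end to end on a toy genome: two relatives'
annotated germline variant lists (VCF + annotation sidecar), three
discovery control-cohort panels, a verification frequency panel, a curator
blacklist, and two tumour segment tables with a planted shared LOH region.
Every planted variant belongs to exactly one category — destined to
survive the whole cascade, or to fail one named filter — and the ground
truth (key sets, expected per-stage ledger counts, expected LOH zones,
expected intersection) is recorded so recovery can be checked exactly.

The default configuration reproduces the count skeleton of the study this
package models — ~4.9k heterozygous coding calls per individual, ~110 after
the novelty filter, 40 shared (8 LoF / 32 missense), 9 removed by curation,
7 by CADD, 9 by the frequency check, 15 final (1 LoF / 14 missense), 4 of
them in one tumour's LOH — by construction: the generator plants those
counts, it does not re-derive them from sequence data.

What this emulates and what it does not: category-labelled annotations with
values drawn safely inside or outside each filter band, on a genome scaled
to 1/1000 of GRCh37 so per-base oracles are cheap. It does not simulate
reads, realistic site-frequency spectra, linkage, or annotation noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datasets import _P1_SEGMENTS, _P2_SEGMENTS, SHARED_LOH_REGION
from .filter_cascade import CandidateSet, FilterLedger
from .loh_segments import (
    GenomeModel,
    Segment,
    SegmentSet,
    _union_intervals,
    grch37_genome,
    loh_view,
)
from .two_hit import LohZone
from .variant_io import Variant, VariantKey, write_variants

DISCOVERY_COHORTS = ("thousand_genomes", "esp6500", "inhouse_breast")
VERIFICATION_COHORT = "gnomad"

#: planted categories; each shared variant belongs to exactly one
CATEGORIES = (
    "pass",            # survives every filter
    "qual_fail",       # Phred quality below the strict > 30 cut
    "vaf_fail",        # VAF outside the 0.15-0.8 heterozygous band
    "cohort_fail",     # present in a discovery cohort
    "blacklist_fail",  # removed by the curation blacklist
    "cadd_fail",       # missense with scaled CADD below 10
    "freq_fail",       # verification-cohort frequency above 1e-4
)


def _scaled_segments(rows, factor: float) -> list[tuple[str, int, int, str]]:
    out = []
    for chrom, start, end, event in rows:
        s, e = int(round(start * factor)), int(round(end * factor))
        if e > s:
            out.append((chrom, s, e, event))
    return out


@dataclass
class SyntheticConfig:
    """Generator knobs. Counts per category are (n_lof, n_missense) pairs
    for the shared categories and per-individual pairs for backgrounds.

    Defaults are the study-shaped configuration described in the module
    docstring; ``seed`` fully determines every output byte.
    """

    seed: int = 0
    sample_names: tuple[str, str] = ("P1", "P2")
    # shared planted variants, by fate: (n_lof, n_missense)
    n_pass: tuple[int, int] = (1, 14)
    n_qual_fail: tuple[int, int] = (0, 2)
    n_vaf_fail: tuple[int, int] = (0, 2)
    n_cohort_fail: tuple[int, int] = (0, 2)
    n_blacklist_fail: tuple[int, int] = (5, 4)
    n_cadd_fail: tuple[int, int] = (0, 7)
    n_freq_fail: tuple[int, int] = (2, 7)
    # per-individual backgrounds: private novel calls (pass the individual
    # filters, die at the sharing step) and cohort-member calls (die at the
    # novelty step)
    n_private_novel: tuple[int, int] = (66, 70)
    n_cohort_present: tuple[int, int] = (4785, 4861)
    # how many surviving shared candidates are placed inside LOH private to
    # the first tumour
    n_candidates_in_loh: int = 4
    # tumour segment tables on the toy genome, plus the planted shared region
    genome_scale: float = 1e-3
    loh: Mapping[str, Sequence[tuple[str, int, int, str]]] | None = None
    shared_loh_region: tuple[str, int, int] | None = None
    genome: GenomeModel | None = None
    #: place annotation values exactly on filter boundaries (off by default:
    #: boundary semantics are exercised by dedicated unit tests, not here)
    boundary_stress: bool = False

    def __post_init__(self) -> None:
        for name in ("n_pass", "n_qual_fail", "n_vaf_fail", "n_cohort_fail",
                     "n_blacklist_fail", "n_cadd_fail", "n_freq_fail",
                     "n_private_novel", "n_cohort_present"):
            pair = getattr(self, name)
            if len(pair) != 2 or any(int(x) < 0 for x in pair):
                raise ValueError(f"{name} must be a pair of non-negative counts")
        if self.genome is None:
            self.genome = grch37_genome().scaled(self.genome_scale)
        if self.loh is None:
            self.loh = {
                self.sample_names[0]: _scaled_segments(_P1_SEGMENTS, self.genome_scale),
                self.sample_names[1]: _scaled_segments(_P2_SEGMENTS, self.genome_scale),
            }
        if self.shared_loh_region is None:
            r = SHARED_LOH_REGION
            self.shared_loh_region = (
                r.chrom,
                int(round(r.start * self.genome_scale)),
                int(round(r.end * self.genome_scale)),
            )
        if self.n_candidates_in_loh > sum(self.n_pass):
            raise ValueError("n_candidates_in_loh exceeds surviving shared count")

    def segment_sets(self) -> dict[str, SegmentSet]:
        return {
            sid: SegmentSet(sid, [Segment(*row) for row in rows], "synthetic").normalized()
            for sid, rows in self.loh.items()
        }


@dataclass
class InputsBundle:
    """Paths of everything simulate_duo wrote."""

    out_dir: Path
    vcfs: dict[str, Path]
    sidecars: dict[str, Path]
    panel_paths: dict[str, Path]
    frequency_panel: Path
    segment_paths: dict[str, Path]
    blacklist: Path
    genome_file: Path
    truth_file: Path


@dataclass
class SyntheticTruth:
    """Planted ground truth, sufficient to check recovery exactly."""

    planted: dict[str, list[str]]  # category -> sorted VariantKey strings
    expected_ledger: dict
    expected_zones: dict[str, dict]  # key string -> {kind, sample_id}
    expected_intersection: list[tuple[str, int, int]]

    @property
    def survivor_keys(self) -> set[VariantKey]:
        return {VariantKey.parse(k) for k in self.planted["pass"]}

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: Path | str) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["expected_intersection"] = [tuple(x) for x in d["expected_intersection"]]
        return cls(**d)


# ---------------------------------------------------------------- placement

def _complement(intervals: dict[str, list[tuple[int, int]]], genome: GenomeModel):
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in genome.lengths.items():
        cur = 0
        free: list[tuple[int, int]] = []
        for s, e in intervals.get(chrom, []):
            if s > cur:
                free.append((cur, s))
            cur = max(cur, e)
        if cur < length:
            free.append((cur, length))
        if free:
            out[chrom] = free
    return out


def _subtract(a: dict[str, list[tuple[int, int]]], b: dict[str, list[tuple[int, int]]]):
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in a.items():
        cuts = b.get(chrom, [])
        rem: list[tuple[int, int]] = []
        for s, e in ivs:
            cur = s
            for cs, ce in cuts:
                if ce <= cur or cs >= e:
                    continue
                if cs > cur:
                    rem.append((cur, cs))
                cur = max(cur, ce)
            if cur < e:
                rem.append((cur, e))
        if rem:
            out[chrom] = rem
    return out


class _Placer:
    """Draws unique 1-based positions uniformly over interval territories."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def draw(self, territory: dict[str, list[tuple[int, int]]], n_attempts: int = 10_000):
        chroms = sorted(territory)
        weights = np.array([sum(e - s for s, e in territory[c]) for c in chroms], dtype=float)
        if not chroms or weights.sum() <= 0:
            raise ValueError("impossible placement: no territory available")
        for _ in range(n_attempts):
            c = chroms[self.rng.choice(len(chroms), p=weights / weights.sum())]
            ivs = territory[c]
            lens = np.array([e - s for s, e in ivs], dtype=float)
            s, e = ivs[self.rng.choice(len(ivs), p=lens / lens.sum())]
            pos0 = int(self.rng.integers(s, e))
            if (c, pos0) not in self.used:
                self.used.add((c, pos0))
                return c, pos0 + 1  # 1-based
        raise ValueError("impossible placement: territory exhausted")


# ------------------------------------------------------------- value draws

_BASES = np.array(list("ACGT"))


def _draw_alleles(rng: np.random.Generator, consequence: str) -> tuple[str, str]:
    if consequence == "frameshift":
        # 1-bp deletion, already minimal
        anchor, lost = (str(b) for b in rng.choice(_BASES, size=2))
        return anchor + lost, anchor
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


@dataclass
class _Draws:
    """Per-category annotation value ranges, kept clear of filter boundaries."""

    qual_pass: tuple[float, float] = (40.0, 95.0)
    qual_fail: tuple[float, float] = (5.0, 25.0)
    vaf_pass: tuple[float, float] = (0.25, 0.70)
    vaf_fail_high: tuple[float, float] = (0.86, 0.98)
    vaf_fail_low: tuple[float, float] = (0.02, 0.10)
    cadd_pass: tuple[float, float] = (12.0, 40.0)
    cadd_fail: tuple[float, float] = (1.0, 8.0)
    freq_pass: tuple[float, float] = (0.0, 8.0e-5)
    freq_fail: tuple[float, float] = (5.0e-4, 2.0e-2)


def _uniform(rng, lo_hi) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi))


# ------------------------------------------------------------------ driver

def simulate_duo(config: SyntheticConfig, out_dir: Path | str) -> tuple[InputsBundle, SyntheticTruth]:
    """Generate the full inputs bundle and its ground truth.

    Writes, under ``out_dir``: ``<sample>.vcf`` and ``<sample>.annotations.tsv``
    per individual, one key-list file per discovery cohort, a frequency panel
    (key + frequency), per-tumour SEG-dialect segment tables, the blacklist,
    the toy-genome lengths file, and ``truth.json``. Identical seeds yield
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    draws = _Draws()
    if config.boundary_stress:
        draws.qual_fail = (30.0, 30.0)
        draws.vaf_pass = (0.15, 0.8)
        draws.cadd_pass = (10.0, 10.0)
        draws.freq_pass = (1e-4, 1e-4)

    genome = config.genome
    seg_sets = config.segment_sets()
    s1, s2 = config.sample_names
    view1 = _union_intervals(loh_view(seg_sets[s1], include_pure_loss=True).segments)
    view2 = _union_intervals(loh_view(seg_sets[s2], include_pure_loss=True).segments)
    loh_any = {
        c: _union_intervals(
            [Segment(c, s, e, "LOH") for s, e in view1.get(c, []) + view2.get(c, [])]
        )[c]
        for c in set(view1) | set(view2)
    }
    territory_one = _subtract(view1, view2)   # first tumour only
    territory_out = _complement(loh_any, genome)
    placer = _Placer(rng)

    planted: dict[str, list[str]] = {cat: [] for cat in CATEGORIES}
    variants: dict[str, list[Variant]] = {s1: [], s2: []}
    panel_keys: dict[str, list[VariantKey]] = {c: [] for c in DISCOVERY_COHORTS}
    freq_panel: dict[VariantKey, float] = {}
    blacklist_keys: list[VariantKey] = []
    zones: dict[str, dict] = {}

    def passing_values(rng):
        return _uniform(rng, draws.qual_pass), _uniform(rng, draws.vaf_pass)

    def make_shared(category: str, consequence: str, in_loh: bool) -> None:
        if in_loh:
            chrom, pos = placer.draw(territory_one)
        else:
            chrom, pos = placer.draw(territory_out)
        ref, alt = _draw_alleles(rng, consequence)
        lof = consequence in ("nonsense", "frameshift", "essential_splice")
        cadd = None
        if not lof:
            cadd = _uniform(rng, draws.cadd_fail if category == "cadd_fail" else draws.cadd_pass)
        freq = _uniform(rng, draws.freq_fail if category == "freq_fail" else draws.freq_pass)
        gene = f"GENE_{chrom}_{pos}"
        tx = f"NM_{pos:07d}.1"
        for sample in (s1, s2):
            if category == "qual_fail":
                qual, vaf = _uniform(rng, draws.qual_fail), _uniform(rng, draws.vaf_pass)
            elif category == "vaf_fail":
                band = draws.vaf_fail_high if rng.random() < 0.5 else draws.vaf_fail_low
                qual, vaf = _uniform(rng, draws.qual_pass), _uniform(rng, band)
            else:
                qual, vaf = passing_values(rng)
            variants[sample].append(
                Variant(chrom, pos, ref, alt, gene=gene, transcript=tx,
                        consequence=consequence, qual=qual, vaf=vaf,
                        cadd_scaled=cadd,
                        cohort_freqs={VERIFICATION_COHORT: freq} if freq > 0 else {})
            )
        key = VariantKey(chrom, pos, ref, alt)
        planted[category].append(str(key))
        if freq > 0:
            freq_panel[key] = freq
        if category == "cohort_fail":
            panel_keys[DISCOVERY_COHORTS[int(rng.integers(len(DISCOVERY_COHORTS)))]].append(key)
        if category == "blacklist_fail":
            blacklist_keys.append(key)
        if category == "pass":
            zones[str(key)] = (
                {"kind": "loh_in_one", "sample_id": s1}
                if in_loh
                else {"kind": "none", "sample_id": None}
            )

    # shared variants, category by category (LoF first, then missense)
    category_counts = {
        "pass": config.n_pass,
        "qual_fail": config.n_qual_fail,
        "vaf_fail": config.n_vaf_fail,
        "cohort_fail": config.n_cohort_fail,
        "blacklist_fail": config.n_blacklist_fail,
        "cadd_fail": config.n_cadd_fail,
        "freq_fail": config.n_freq_fail,
    }
    n_in_loh_left = config.n_candidates_in_loh
    for category, (n_lof, n_mis) in category_counts.items():
        for i in range(n_lof + n_mis):
            lof = i < n_lof
            consequence = ("nonsense" if rng.random() < 0.5 else "frameshift") if lof else "missense"
            in_loh = False
            if category == "pass" and not lof and n_in_loh_left > 0:
                in_loh, n_in_loh_left = True, n_in_loh_left - 1
            make_shared(category, consequence, in_loh)
    if n_in_loh_left > 0:  # more in-LOH slots than missense survivors
        raise ValueError("impossible placement: not enough missense survivors for LOH slots")

    # per-individual backgrounds
    whole = _complement({}, genome)
    for idx, sample in enumerate((s1, s2)):
        for _ in range(config.n_private_novel[idx]):
            chrom, pos = placer.draw(whole)
            ref, alt = _draw_alleles(rng, "missense")
            qual, vaf = passing_values(rng)
            variants[sample].append(
                Variant(chrom, pos, ref, alt, gene=f"BG_{chrom}_{pos}",
                        transcript=f"NM_{pos:07d}.1", consequence="missense",
                        qual=qual, vaf=vaf, cadd_scaled=_uniform(rng, (0.5, 35.0)))
            )
        for _ in range(config.n_cohort_present[idx]):
            chrom, pos = placer.draw(whole)
            ref, alt = _draw_alleles(rng, "missense")
            qual, vaf = passing_values(rng)
            v = Variant(chrom, pos, ref, alt, gene=f"BG_{chrom}_{pos}",
                        transcript=f"NM_{pos:07d}.1", consequence="missense",
                        qual=qual, vaf=vaf, cadd_scaled=_uniform(rng, (0.5, 35.0)))
            variants[sample].append(v)
            panel_keys[DISCOVERY_COHORTS[int(rng.integers(len(DISCOVERY_COHORTS)))]].append(v.key)

    # ------------------------------------------------------------- outputs
    contigs = dict(genome.lengths)
    vcfs, sidecars = {}, {}
    for sample in (s1, s2):
        vcfs[sample] = out_dir / f"{sample}.vcf"
        sidecars[sample] = out_dir / f"{sample}.annotations.tsv"
        write_variants(variants[sample], vcfs[sample], sidecars[sample],
                       sample=sample, contig_lengths=contigs,
                       cohort_columns=[VERIFICATION_COHORT])

    panel_paths = {}
    for cohort in DISCOVERY_COHORTS:
        p = out_dir / f"panel_{cohort}.keys"
        p.write_text("".join(
            f"{k}\n" for k in sorted(set(panel_keys[cohort]), key=VariantKey.sort_key)
        ))
        panel_paths[cohort] = p

    frequency_panel = out_dir / f"panel_{VERIFICATION_COHORT}.keys"
    frequency_panel.write_text("".join(
        f"{k}\t{freq_panel[k]:.10g}\n"
        for k in sorted(freq_panel, key=VariantKey.sort_key)
    ))

    segment_paths = {}
    for sid, segset in seg_sets.items():
        p = out_dir / f"{sid}.segments.seg"
        with open(p, "w") as fh:
            fh.write("sample\tchrom\tstart\tend\tevent\n")
            for s in segset.segments:
                # SEG dialect is 1-based inclusive start
                fh.write(f"{sid}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{s.event}\n")
        segment_paths[sid] = p

    blacklist = out_dir / "blacklist.keys"
    blacklist.write_text("".join(
        f"{k}\n" for k in sorted(blacklist_keys, key=VariantKey.sort_key)
    ))

    genome_file = out_dir / "genome.tsv"
    genome.to_file(genome_file)

    truth = _build_truth(config, planted, zones, seg_sets)
    truth_file = out_dir / "truth.json"
    truth.to_json(truth_file)

    bundle = InputsBundle(out_dir, vcfs, sidecars, panel_paths, frequency_panel,
                          segment_paths, blacklist, genome_file, truth_file)
    return bundle, truth


def _build_truth(config: SyntheticConfig, planted, zones, seg_sets) -> SyntheticTruth:
    from .loh_segments import intersect_sets

    s1, s2 = config.sample_names
    n = {cat: tuple(map(int, getattr(config, f"n_{cat.replace('_fail', '')}_fail"
                                     if cat != "pass" else "n_pass")))
         for cat in CATEGORIES}
    shared_total = {cat: sum(n[cat]) for cat in CATEGORIES}
    n_shared_input = sum(shared_total.values())

    per_sample = {}
    for idx, sample in enumerate((s1, s2)):
        n_input = (n_shared_input + config.n_private_novel[idx]
                   + config.n_cohort_present[idx])
        n_het = n_input - shared_total["qual_fail"] - shared_total["vaf_fail"]
        n_novel = n_het - shared_total["cohort_fail"] - config.n_cohort_present[idx]
        per_sample[sample] = [
            {"step": "input", "count": n_input},
            {"step": "het_quality", "count": n_het},
            {"step": "novel", "count": n_novel},
        ]

    def stage(cats):
        lof = sum(n[c][0] for c in cats)
        mis = sum(n[c][1] for c in cats)
        return lof, mis

    shared_cats = ["pass", "blacklist_fail", "cadd_fail", "freq_fail"]
    steps = []
    for step, cats in [
        ("shared", shared_cats),
        ("blacklist", ["pass", "cadd_fail", "freq_fail"]),
        ("deleterious", ["pass", "freq_fail"]),
        ("rare", ["pass"]),
    ]:
        lof, mis = stage(cats)
        if step == "deleterious":
            # the CADD stage also drops LoF-free cadd_fail missense only;
            # cadd_fail LoF (normally zero) would survive it
            lof += n["cadd_fail"][0]
        steps.append({"step": step, "total": lof + mis, "lof": lof, "missense": mis})

    inter = intersect_sets(
        loh_view(seg_sets[s1], include_pure_loss=False),
        loh_view(seg_sets[s2], include_pure_loss=False),
    )
    return SyntheticTruth(
        planted={cat: sorted(keys) for cat, keys in planted.items()},
        expected_ledger={"per_sample": per_sample, "shared": steps},
        expected_zones=zones,
        expected_intersection=[(s.chrom, s.start, s.end) for s in inter.segments],
    )


def run_pipeline_on_bundle(bundle: InputsBundle):
    """Re-run the whole pipeline from a bundle's files, as a user would.

    Returns ``(candidates, ledger, zones, intersection)`` — the four
    outputs :func:`evaluate_recovery` compares against planted truth.
    """
    from .filter_cascade import FilterConfig, run_cascade
    from .loh_segments import intersect_sets as _isect
    from .loh_segments import read_segments
    from .two_hit import variants_in_segments
    from .variant_io import CohortPanel, read_variants

    samples = list(bundle.vcfs)
    lists = [
        read_variants(bundle.vcfs[s], bundle.sidecars[s], sample=s) for s in samples
    ]
    panels = [
        CohortPanel.from_key_list(name, path)
        for name, path in bundle.panel_paths.items()
    ]
    verification = CohortPanel.from_key_list(VERIFICATION_COHORT, bundle.frequency_panel)
    blacklist = frozenset(
        VariantKey.parse(line)
        for line in bundle.blacklist.read_text().splitlines()
        if line.strip()
    )
    candidates, ledger = run_cascade(
        lists[0], lists[1], panels, FilterConfig(curation_blacklist=blacklist),
        verification, sample_names=tuple(samples),
    )
    seg_sets = {
        sid: read_segments(path, dialect="SEG", sample_id=sid)
        for sid, path in bundle.segment_paths.items()
    }
    zones = variants_in_segments(candidates, seg_sets)
    views = [loh_view(seg_sets[s], include_pure_loss=False) for s in samples]
    intersection = _isect(views[0], views[1])
    return candidates, ledger, zones, intersection


# ---------------------------------------------------------------- recovery

@dataclass
class RecoveryReport:
    ledger_match: bool
    candidates_match: bool
    zones_match: bool
    intersection_match: bool
    precision: float
    recall: float

    @property
    def overall_pass(self) -> bool:
        return (self.ledger_match and self.candidates_match and self.zones_match
                and self.intersection_match and self.precision == 1.0
                and self.recall == 1.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["overall_pass"] = self.overall_pass
        return d


def evaluate_recovery(
    candidates: CandidateSet,
    ledger: FilterLedger,
    zones: Sequence[tuple[Variant, LohZone]],
    intersection: SegmentSet,
    truth: SyntheticTruth,
) -> RecoveryReport:
    """Compare pipeline outputs against planted truth, exactly."""
    got_keys = candidates.keys
    want_keys = truth.survivor_keys
    tp = len(got_keys & want_keys)
    precision = tp / len(got_keys) if got_keys else (1.0 if not want_keys else 0.0)
    recall = tp / len(want_keys) if want_keys else 1.0

    got_ledger = ledger.to_dict()
    ledger_match = got_ledger == truth.expected_ledger

    got_zones = {
        str(v.key): {"kind": z.kind, "sample_id": z.sample_id} for v, z in zones
    }
    zones_match = got_zones == truth.expected_zones

    got_inter = [(s.chrom, s.start, s.end) for s in intersection.segments]
    intersection_match = got_inter == list(truth.expected_intersection)

    return RecoveryReport(
        ledger_match=ledger_match,
        candidates_match=got_keys == want_keys,
        zones_match=zones_match,
        intersection_match=intersection_match,
        precision=precision,
        recall=recall,
    )
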