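"""Ordered prioritization cascade for shared germline candidates in a duo.

The cascade mirrors the discovery design for two affected relatives:

1. per individual — keep heterozygous-looking, well-supported coding calls
   (Phred quality strictly > 30, VAF in the inclusive 0.15–0.8 band,
   consequence LoF or missense);
2. per individual — keep only calls absent from every discovery control
   cohort (presence/absence, not a frequency cut);
3. intersect the two individuals' survivor sets on variant identity;
4. remove read-level artefacts via a curator-supplied blacklist;
5. keep LoF unconditionally, missense only with scaled CADD >= 10;
6. drop anything with verification-cohort frequency above 1e-4.

Every stage is a pure predicate over its input; a per-step survivor-count
ledger is a first-class output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variant_io import CohortPanel, Variant, VariantKey

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds and inputs of the cascade.

    Boundary semantics (each lifted from the stated wording, each
    configurable): quality strictly ``>``; VAF band inclusive on both ends;
    CADD inclusive ``>=``; frequency strictly ``>`` excludes, so equality
    with ``freq_max`` passes.
    """

    qual_min: float = 30.0
    vaf_low: float = 0.15
    vaf_high: float = 0.8
    cadd_min: float = 10.0
    freq_max: float = 1e-4
    discovery_cohorts: tuple[str, ...] = ()
    curation_blacklist: frozenset[VariantKey] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_low < self.vaf_high <= 1.0:
            raise ValueError(f"invalid VAF band [{self.vaf_low}, {self.vaf_high}]")
        for name in ("qual_min", "cadd_min", "freq_max"):
            v = getattr(self, name)
            if not (v >= 0 and v == v and v != float("inf")):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        self.curation_blacklist = frozenset(self.curation_blacklist)


@dataclass
class FilterLedger:
    """Ordered survivor counts after each cascade step.

    ``per_sample`` holds ``(step, count)`` pairs per individual (counts are
    non-increasing along the cascade); ``shared`` holds
    ``(step, total, n_lof, n_missense)`` for the shared-set stages.
    """

    per_sample: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    shared: list[tuple[str, int, int, int]] = field(default_factory=list)

    def record(self, sample: str, step: str, count: int) -> None:
        self.per_sample.setdefault(sample, []).append((step, count))

    def record_shared(self, step: str, variants: Sequence[Variant]) -> None:
        n_lof = sum(1 for v in variants if v.is_lof)
        self.shared.append((step, len(variants), n_lof, len(variants) - n_lof))

    def to_dict(self) -> dict:
        return {
            "per_sample": {
                s: [{"step": st, "count": c} for st, c in steps]
                for s, steps in self.per_sample.items()
            },
            "shared": [
                {"step": st, "total": t, "lof": l, "missense": m}
                for st, t, l, m in self.shared
            ],
        }

    def to_frame(self):
        import pandas as pd

        rows = [
            {"scope": s, "step": st, "count": c, "lof": None, "missense": None}
            for s, steps in self.per_sample.items()
            for st, c in steps
        ] + [
            {"scope": "shared", "step": st, "count": t, "lof": l, "missense": m}
            for st, t, l, m in self.shared
        ]
        return pd.DataFrame(rows, columns=["scope", "step", "count", "lof", "missense"])


@dataclass
class CandidateSet:
    """Final shared candidates (one representative record per individual)."""

    pairs: list[tuple[Variant, Variant]]

    @property
    def variants(self) -> list[Variant]:
        return [a for a, _ in self.pairs]

    @property
    def keys(self) -> set[VariantKey]:
        return {a.key for a, _ in self.pairs}

    @property
    def n_total(self) -> int:
        return len(self.pairs)

    @property
    def n_lof(self) -> int:
        return sum(1 for v in self.variants if v.is_lof)

    @property
    def n_missense(self) -> int:
        return sum(1 for v in self.variants if v.consequence == "missense")


def filter_het_quality(variants: Iterable[Variant], config: FilterConfig) -> list[Variant]:
    """Quality / heterozygous-band / coding-class filter (stage 1)."""
    return [
        v
        for v in variants
        if v.qual > config.qual_min
        and config.vaf_low <= v.vaf <= config.vaf_high
        and (v.is_lof or v.consequence == "missense")
    ]


def filter_novel(variants: Iterable[Variant], panels: Sequence[CohortPanel]) -> list[Variant]:
    """Keep variants absent from every discovery cohort panel (stage 2)."""
    return [v for v in variants if not any(p.contains(v.key) for p in panels)]


def shared_variants(a: Iterable[Variant], b: Iterable[Variant]) -> list[tuple[Variant, Variant]]:
    """Pair up variants present in both individuals, matched on identity.

    Output is deterministic: sorted by chromosome (1..22, X, Y), position,
    ref, alt. If one individual carries duplicate records of a key, the
    first is used.
    """
    b_by_key: dict[VariantKey, Variant] = {}
    for v in b:
        b_by_key.setdefault(v.key, v)
    pairs = []
    seen: set[VariantKey] = set()
    for v in a:
        if v.key in b_by_key and v.key not in seen:
            pairs.append((v, b_by_key[v.key]))
            seen.add(v.key)
    pairs.sort(key=lambda p: p[0].key.sort_key())
    return pairs


def apply_blacklist(
    pairs: Sequence[tuple[Variant, Variant]], config: FilterConfig
) -> list[tuple[Variant, Variant]]:
    """Drop curator-flagged artefact keys (stage 4)."""
    keys = {a.key for a, _ in pairs}
    for k in config.curation_blacklist - keys:
        logger.warning("blacklist key %s matches no candidate", k)
    return [(a, b) for a, b in pairs if a.key not in config.curation_blacklist]


def filter_deleterious(
    pairs: Sequence[tuple[Variant, Variant]], config: FilterConfig
) -> list[tuple[Variant, Variant]]:
    """LoF always retained; missense needs scaled CADD >= threshold (stage 5).

    Missense without a CADD score is excluded (conservative) with a warning.
    """
    out = []
    for a, b in pairs:
        if a.is_lof:
            out.append((a, b))
        elif a.consequence == "missense":
            if a.cadd_scaled is None:
                logger.warning("missense %s (%s) lacks a CADD score; excluded", a.key, a.gene)
            elif a.cadd_scaled >= config.cadd_min:
                out.append((a, b))
    return out


def filter_rare(
    pairs: Sequence[tuple[Variant, Variant]],
    config: FilterConfig,
    verification_cohort: CohortPanel | None,
) -> list[tuple[Variant, Variant]]:
    """Drop variants more common than ``freq_max`` in the verification
    cohort (stage 6). A variant absent from the cohort has frequency 0."""
    if verification_cohort is None:
        return list(pairs)
    return [
        (a, b)
        for a, b in pairs
        if verification_cohort.frequency(a.key) <= config.freq_max
    ]


def run_cascade(
    a: Sequence[Variant],
    b: Sequence[Variant],
    panels: Sequence[CohortPanel],
    config: FilterConfig,
    verification_cohort: CohortPanel | None = None,
    sample_names: tuple[str, str] = ("P1", "P2"),
) -> tuple[CandidateSet, FilterLedger]:
    """Run the full prioritization cascade and return candidates + ledger."""
    ledger = FilterLedger()
    per_sample = []
    for name, variants in zip(sample_names, (a, b)):
        ledger.record(name, "input", len(list(variants)))
        v1 = filter_het_quality(variants, config)
        ledger.record(name, "het_quality", len(v1))
        v2 = filter_novel(v1, panels)
        ledger.record(name, "novel", len(v2))
        per_sample.append(v2)

    pairs = shared_variants(per_sample[0], per_sample[1])
    ledger.record_shared("shared", [p[0] for p in pairs])
    pairs = apply_blacklist(pairs, config)
    ledger.record_shared("blacklist", [p[0] for p in pairs])
    pairs = filter_deleterious(pairs, config)
    ledger.record_shared("deleterious", [p[0] for p in pairs])
    pairs = filter_rare(pairs, config, verification_cohort)
    ledger.record_shared("rare", [p[0] for p in pairs])
    return CandidateSet(pairs), ledger
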