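"""Two-hit overlay: shared germline candidates vs tumour LOH.

Under a two-hit model of tumour-suppressor inactivation, a shared germline
variant gains support when the tumour has lost the wild-type allele over its
locus — either within LOH common to both tumours or within LOH private to
one. Allele observations from tumour sequencing then confirm (mutant
retained, wild type lost), contradict (mutant lost), or leave unresolved
(both alleles still seen — e.g. subclonal heterogeneity, or different
tumour tissue than the array) each candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .filter_cascade import CandidateSet
from .loh_segments import SegmentSet, intersect_sets, loh_view
from .variant_io import Variant, VariantKey

logger = logging.getLogger(__name__)

ALLELE_OBSERVATIONS = ("both", "mutant_only", "wildtype_only")

ZONE_SHARED = "shared_loh"
ZONE_ONE = "loh_in_one"
ZONE_NONE = "none"

#: observation vocabulary -> allele_status vocabulary
_STATUS_FROM_OBSERVATION = {
    "mutant_only": "mutant_retained_wt_lost",
    "wildtype_only": "mutant_lost",
    "both": "heterozygous_retained",
}


@dataclass(frozen=True)
class TumourObservation:
    """Which alleles tumour sequencing saw at a candidate locus."""

    key: VariantKey
    alleles_observed: str  # both | mutant_only | wildtype_only
    source: str = ""

    def __post_init__(self) -> None:
        if self.alleles_observed not in ALLELE_OBSERVATIONS:
            raise ValueError(
                f"alleles_observed must be one of {ALLELE_OBSERVATIONS}, "
                f"got {self.alleles_observed!r}"
            )


@dataclass(frozen=True)
class LohZone:
    """A candidate's relationship to tumour LOH territory."""

    kind: str  # shared_loh | loh_in_one | none
    sample_id: str | None = None  # set iff kind == loh_in_one


@dataclass(frozen=True)
class TwoHitCall:
    key: VariantKey
    gene: str
    zone: LohZone
    allele_status: str  # mutant_retained_wt_lost | mutant_lost | heterozygous_retained | unobserved
    candidacy: str  # supported | contradicted | unresolved


def _containing(segset: SegmentSet, chrom: str, pos0: int) -> bool:
    return any(s.chrom == chrom and s.start <= pos0 < s.end for s in segset)


def variants_in_segments(
    candidates: CandidateSet | Sequence[Variant],
    loh_by_sample: Mapping[str, SegmentSet],
    include_pure_loss: bool = True,
) -> list[tuple[Variant, LohZone]]:
    """Label each candidate with its LOH zone.

    ``shared_loh`` — inside the cross-tumour intersection of LOH views;
    ``loh_in_one`` — inside exactly one tumour's LOH view (sample recorded);
    ``none`` — otherwise, including chromosomes no segment set mentions.

    The candidate's 1-based position is converted to 0-based before the
    half-open containment test; an indel is "in" a segment iff its start
    position is (segments are megabases, indels are bases).
    ``include_pure_loss`` defaults to True here: a deletion spanning the
    variant removes one allele outright, the strongest second hit.
    """
    variants = candidates.variants if isinstance(candidates, CandidateSet) else list(candidates)
    views = {
        sid: loh_view(segs, include_pure_loss=include_pure_loss)
        for sid, segs in loh_by_sample.items()
    }
    shared: SegmentSet | None = None
    for view in views.values():
        shared = view if shared is None else intersect_sets(shared, view)

    out: list[tuple[Variant, LohZone]] = []
    for v in variants:
        pos0 = v.pos - 1
        if shared is not None and len(views) > 1 and _containing(shared, v.chrom, pos0):
            zone = LohZone(ZONE_SHARED)
        else:
            hits = [sid for sid, view in views.items() if _containing(view, v.chrom, pos0)]
            if len(hits) == 1:
                zone = LohZone(ZONE_ONE, hits[0])
            else:
                # 0 hits, or >1 without full sharing (possible only through
                # include_pure_loss asymmetries) -> not a clean second hit
                zone = LohZone(ZONE_NONE) if not hits else LohZone(ZONE_SHARED)
        out.append((v, zone))
    return out


def classify_two_hit(
    zones: Sequence[tuple[Variant, LohZone]],
    observations: Iterable[TumourObservation] = (),
) -> list[TwoHitCall]:
    """Combine LOH zones with tumour allele observations into candidacy calls.

    - ``contradicted`` iff the mutant allele was somatically lost;
    - ``supported`` iff the variant sits in an LOH zone and the tumour
      retained only the mutant allele;
    - everything else ``unresolved`` — including heterozygosity observed
      inside an LOH zone, which can reflect subclonal heterogeneity or a
      different tumour tissue and is never treated as an error.
    """
    obs_by_key: dict[VariantKey, TumourObservation] = {}
    zone_keys = {v.key for v, _ in zones}
    for o in observations:
        if o.key not in zone_keys:
            logger.warning("observation for %s matches no candidate", o.key)
            continue
        obs_by_key[o.key] = o

    calls: list[TwoHitCall] = []
    for v, zone in zones:
        o = obs_by_key.get(v.key)
        status = _STATUS_FROM_OBSERVATION[o.alleles_observed] if o else "unobserved"
        if status == "mutant_lost":
            candidacy = "contradicted"
        elif status == "mutant_retained_wt_lost" and zone.kind != ZONE_NONE:
            candidacy = "supported"
        else:
            candidacy = "unresolved"
        calls.append(TwoHitCall(v.key, v.gene, zone, status, candidacy))
    return calls


def read_observations(path: Path | str) -> list[TumourObservation]:
    """Read a tab-separated observations file: key, alleles_observed[, source]."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        out.append(
            TumourObservation(
                VariantKey.parse(parts[0]),
                parts[1],
                parts[2] if len(parts) > 2 else "",
            )
        )
    return out
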