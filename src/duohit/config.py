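"""Run configuration: one YAML file naming every input path and threshold.

Example::

    samples:
      P1: {vcf: p1.vcf, annotations: p1.annotations.tsv}
      P2: {vcf: p2.vcf, annotations: p2.annotations.tsv}
    discovery_panels:
      thousand_genomes: panel_thousand_genomes.keys
      esp6500: panel_esp6500.keys
      inhouse_breast: panel_inhouse_breast.keys
    verification_panel: {name: gnomad, path: panel_gnomad.keys}
    blacklist: blacklist.keys
    segments:
      P1: {path: P1.segments.seg, dialect: SEG}
      P2: {path: P2.segments.seg, dialect: SEG}
    genome: genome.tsv
    observations: observations.tsv
    filters: {qual_min: 30, vaf_low: 0.15, vaf_high: 0.8, cadd_min: 10, freq_max: 1.0e-4}

Relative paths are resolved against the YAML file's directory. Only
``samples`` is mandatory for prioritization; segment/observation entries are
needed for the two-hit overlay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .filter_cascade import FilterConfig
from .loh_segments import GenomeModel, SegmentSet, read_segments
from .two_hit import TumourObservation, read_observations
from .variant_io import CohortPanel, Variant, VariantKey, read_variants


@dataclass
class RunConfig:
    samples: dict[str, dict[str, Path]]
    discovery_panels: dict[str, Path] = field(default_factory=dict)
    verification_panel: tuple[str, Path] | None = None
    blacklist: Path | None = None
    segments: dict[str, tuple[Path, str]] = field(default_factory=dict)
    genome: Path | None = None
    observations: Path | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def p(x) -> Path:
            q = Path(x)
            return q if q.is_absolute() else base / q

        samples = {
            name: {"vcf": p(entry["vcf"]), "annotations": p(entry["annotations"])}
            for name, entry in raw.get("samples", {}).items()
        }
        if len(samples) != 2:
            raise ValueError(f"{path}: exactly two samples required, got {len(samples)}")
        panels = {name: p(f) for name, f in (raw.get("discovery_panels") or {}).items()}
        ver = raw.get("verification_panel")
        verification = (ver["name"], p(ver["path"])) if ver else None
        segments = {
            sid: (p(entry["path"]), entry.get("dialect", "SEG"))
            for sid, entry in (raw.get("segments") or {}).items()
        }
        filters_raw = dict(raw.get("filters") or {})
        blacklist_path = raw.get("blacklist")
        if blacklist_path is not None:
            keys = frozenset(
                VariantKey.parse(line)
                for line in p(blacklist_path).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            )
            filters_raw["curation_blacklist"] = keys
        filters_raw.setdefault("discovery_cohorts", tuple(panels))
        return cls(
            samples=samples,
            discovery_panels=panels,
            verification_panel=verification,
            blacklist=p(blacklist_path) if blacklist_path else None,
            segments=segments,
            genome=p(raw["genome"]) if raw.get("genome") else None,
            observations=p(raw["observations"]) if raw.get("observations") else None,
            filters=FilterConfig(**filters_raw),
        )

    # --- loaded views -----------------------------------------------------
    def load_variants(self) -> dict[str, list[Variant]]:
        return {
            name: read_variants(entry["vcf"], entry["annotations"], sample=name)
            for name, entry in self.samples.items()
        }

    def load_panels(self) -> list[CohortPanel]:
        return [
            CohortPanel.from_key_list(name, path)
            for name, path in self.discovery_panels.items()
        ]

    def load_verification(self) -> CohortPanel | None:
        if self.verification_panel is None:
            return None
        name, path = self.verification_panel
        return CohortPanel.from_key_list(name, path)

    def load_segments(self) -> dict[str, SegmentSet]:
        return {
            sid: read_segments(path, dialect=dialect, sample_id=sid)
            for sid, (path, dialect) in self.segments.items()
        }

    def load_genome(self) -> GenomeModel | None:
        return GenomeModel.from_file(self.genome) if self.genome else None

    def load_observations(self) -> list[TumourObservation]:
        return read_observations(self.observations) if self.observations else []
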