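"""Tumour copy-number / LOH segment tables and their interval algebra.

Segments are stored 0-based half-open internally. Readers accept BED
(pass-through), SEG exports (1-based inclusive start, shifted by -1), and a
plain three-column chrom/start/end(/event) table declared 0-based half-open.
Supported operations: per-sample normalization (sort + merge per event
class), the "LOH-bearing" view used for cross-tumour comparison, interval
intersection between two tumours, and the fraction of a genome model
covered by a segment set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .variant_io import chrom_sort_key

EVENTS = ("LOH", "CN_LOSS", "CN_LOSS_LOH", "CN_GAIN")

_EVENT_ALIASES = {
    "loh": "LOH",
    "cn loss": "CN_LOSS",
    "cn_loss": "CN_LOSS",
    "loss": "CN_LOSS",
    "cn loss/loh": "CN_LOSS_LOH",
    "cn_loss_loh": "CN_LOSS_LOH",
    "cn loss / loh": "CN_LOSS_LOH",
    "cn gain": "CN_GAIN",
    "cn_gain": "CN_GAIN",
    "gain": "CN_GAIN",
}

#: Event classes implying loss of heterozygosity over the segment. A pure
#: hemizygous deletion (CN_LOSS) removes one allele, so it implies LOH too,
#: but is kept behind a flag because array calls label it separately.
LOH_EVENTS = frozenset({"LOH", "CN_LOSS_LOH"})


def parse_event(label: str) -> str:
    norm = " ".join(str(label).strip().lower().split())
    if norm in _EVENT_ALIASES:
        return _EVENT_ALIASES[norm]
    raise ValueError(f"unknown segment event label: {label!r}")


@dataclass(frozen=True)
class Segment:
    """One copy-number/LOH interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    event: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment bounds [{self.start}, {self.end})")
        if self.event not in EVENTS:
            raise ValueError(f"unknown event {self.event!r} (use parse_event)")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self):
        return (*chrom_sort_key(self.chrom), self.start, self.end, self.event)


@dataclass
class SegmentSet:
    """A sample's segments; ``normalized()`` sorts and merges overlapping or
    book-ended segments of the same event class per chromosome."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)
    provenance: str = ""

    def normalized(self) -> "SegmentSet":
        merged: list[Segment] = []
        by_group: dict[tuple[str, str], list[Segment]] = {}
        for s in self.segments:
            by_group.setdefault((s.chrom, s.event), []).append(s)
        for (chrom, event), segs in by_group.items():
            segs = sorted(segs, key=lambda s: (s.start, s.end))
            cur_start, cur_end = segs[0].start, segs[0].end
            for s in segs[1:]:
                if s.start <= cur_end:  # overlap or book-ended: merge
                    cur_end = max(cur_end, s.end)
                else:
                    merged.append(Segment(chrom, cur_start, cur_end, event))
                    cur_start, cur_end = s.start, s.end
            merged.append(Segment(chrom, cur_start, cur_end, event))
        merged.sort(key=Segment.sort_key)
        return SegmentSet(self.sample_id, merged, self.provenance)

    def chromosomes(self) -> list[str]:
        return sorted({s.chrom for s in self.segments}, key=chrom_sort_key)

    def union_length(self) -> int:
        """Total bp covered by at least one segment (event-agnostic union)."""
        total = 0
        for _, ivs in _union_intervals(self.segments).items():
            total += sum(e - s for s, e in ivs)
        return total

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


@dataclass
class GenomeModel:
    """Ordered chromosome labels with lengths in bp."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for c, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {n}")
        self.lengths = {
            c: self.lengths[c] for c in sorted(self.lengths, key=chrom_sort_key)
        }

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def scaled(self, factor: float) -> "GenomeModel":
        return GenomeModel({c: max(1, int(round(n * factor))) for c, n in self.lengths.items()})

    @classmethod
    def from_file(cls, path: Path | str) -> "GenomeModel":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         dtype={"chrom": str})
        return cls(dict(zip(df["chrom"], df["length"].astype(int))))

    def to_file(self, path: Path | str) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{n}\n" for c, n in self.lengths.items())
        )


#: GRCh37 chromosome lengths (bp), autosomes plus X and Y.
GRCH37_LENGTHS: Mapping[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}


def grch37_genome() -> GenomeModel:
    return GenomeModel(dict(GRCH37_LENGTHS))


DIALECTS = ("BED", "SEG", "TABLE")


def read_segments(path: Path | str, dialect: str = "SEG", sample_id: str | None = None) -> SegmentSet:
    """Read a segment table into the internal half-open convention.

    Dialects: ``BED`` — ``chrom start end event``, 0-based half-open,
    no header; ``SEG`` — ``sample chrom start end event`` with header,
    1-based inclusive start (shifted by -1 on read); ``TABLE`` — ``chrom
    start end event`` with header, already 0-based half-open.
    """
    dialect = dialect.upper()
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    path = Path(path)
    if dialect == "BED":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "event"], dtype={"chrom": str})
        shift = 0
    elif dialect == "SEG":
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        required = {"sample", "chrom", "start", "end", "event"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: SEG needs columns {sorted(required)}")
        if sample_id is None and df["sample"].nunique() == 1:
            sample_id = df["sample"].iloc[0]
        elif sample_id is not None:
            df = df[df["sample"] == sample_id]
        shift = -1
    else:  # TABLE
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        if not {"chrom", "start", "end", "event"} <= set(df.columns):
            raise ValueError(f"{path}: TABLE needs columns chrom,start,end,event")
        shift = 0

    segments = []
    for i, row in enumerate(df.itertuples(index=False)):
        start = int(str(row.start).replace(",", "")) + shift
        end = int(str(row.end).replace(",", ""))
        if start >= end:
            raise ValueError(f"{path} row {i}: start >= end ({start} >= {end})")
        try:
            event = parse_event(row.event)
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
        segments.append(Segment(str(row.chrom).removeprefix("chr"), start, end, event))
    return SegmentSet(sample_id or path.stem, segments, provenance=f"{dialect}:{path}").normalized()


def write_segments(segset: SegmentSet, path: Path | str) -> None:
    """Emit BED4 (0-based half-open, tab-separated, no header)."""
    with open(path, "w") as fh:
        for s in sorted(segset.segments, key=Segment.sort_key):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.event}\n")


def loh_view(segset: SegmentSet, include_pure_loss: bool = False) -> SegmentSet:
    """Segments implying LOH: always LOH and CN Loss/LOH; plus pure CN Loss
    when ``include_pure_loss`` (a hemizygous deletion loses one allele)."""
    events = set(LOH_EVENTS) | ({"CN_LOSS"} if include_pure_loss else set())
    return SegmentSet(
        segset.sample_id,
        [s for s in segset.segments if s.event in events],
        provenance=segset.provenance,
    ).normalized()


def _union_intervals(segments: Iterable[Segment]) -> dict[str, list[tuple[int, int]]]:
    """Event-agnostic merged intervals per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [(s, e) for s, e in merged]
    return out


def intersect_sets(a: SegmentSet, b: SegmentSet) -> SegmentSet:
    """Per-chromosome interval intersection of two (LOH-view) segment sets.

    Output segments carry event ``LOH``; zero-length results are dropped;
    ordering is deterministic (chromosome, start).
    """
    ua, ub = _union_intervals(a.segments), _union_intervals(b.segments)
    out: list[Segment] = []
    for chrom in set(ua) & set(ub):
        ia, ib = ua[chrom], ub[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if s < e:
                out.append(Segment(chrom, s, e, "LOH"))
            if ia[i][1] <= ib[j][1]:
                i += 1
            else:
                j += 1
    out.sort(key=Segment.sort_key)
    return SegmentSet(f"{a.sample_id}&{b.sample_id}", out, provenance="intersection")


def genome_fraction(segset: SegmentSet, genome: GenomeModel) -> float:
    """Fraction of the genome model covered by the set (overlaps merged)."""
    covered = 0
    for chrom, ivs in _union_intervals(segset.segments).items():
        if chrom not in genome.lengths:
            raise ValueError(f"chromosome {chrom} absent from genome model")
        for s, e in ivs:
            if e > genome.lengths[chrom]:
                raise ValueError(
                    f"segment {chrom}:{s}-{e} extends past chromosome length "
                    f"{genome.lengths[chrom]}"
                )
            covered += e - s
    return covered / genome.total_length


def mb(length_bp: int) -> float:
    """Report a length in Mb, rounded half-away-from-zero to 2 decimals."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(
        Decimal(length_bp).scaleb(-6).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )
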