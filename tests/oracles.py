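"""Brute-force per-base oracles for interval algebra, independent of the
implementation under test. Only usable on toy genomes (kilobases)."""

from __future__ import annotations

import numpy as np

from duohit.loh_segments import GenomeModel, Segment, SegmentSet


def bitmap(segset: SegmentSet, genome: GenomeModel) -> dict[str, np.ndarray]:
    """Boolean per-base coverage mask per chromosome."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in genome.lengths.items()}
    for s in segset:
        masks[s.chrom][s.start : s.end] = True
    return masks


def bitmap_intersection_segments(a: SegmentSet, b: SegmentSet, genome: GenomeModel) -> list[tuple[str, int, int]]:
    """Maximal runs of the per-base AND of two coverage masks."""
    ma, mb_ = bitmap(a, genome), bitmap(b, genome)
    out = []
    for chrom in genome.lengths:
        both = ma[chrom] & mb_[chrom]
        if not both.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], both, [False]))))
        for start, end in edges.reshape(-1, 2):
            out.append((chrom, int(start), int(end)))
    return out


def bitmap_union_length(segset: SegmentSet, genome: GenomeModel) -> int:
    return int(sum(m.sum() for m in bitmap(segset, genome).values()))


def bitmap_contains(segset: SegmentSet, chrom: str, pos0: int) -> bool:
    return any(s.chrom == chrom and s.start <= pos0 < s.end for s in segset)


def random_segment_set(rng: np.random.Generator, genome: GenomeModel,
                       n_segments: int, events=("LOH", "CN_LOSS", "CN_LOSS_LOH", "CN_GAIN"),
                       sample_id: str = "toy") -> SegmentSet:
    chroms = list(genome.lengths)
    segs = []
    for _ in range(n_segments):
        c = chroms[int(rng.integers(len(chroms)))]
        length = genome.lengths[c]
        s = int(rng.integers(0, length))
        e = int(rng.integers(s + 1, length + 1))
        segs.append(Segment(c, s, e, events[int(rng.integers(len(events)))]))
    return SegmentSet(sample_id, segs)
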