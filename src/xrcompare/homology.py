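"""One-to-one homologous region extraction from whole-genome alignments.

The input is a table of alignment segments (ref <-> query interval plus
percent identity, as emitted by MUMmer show-coords).  Three successive
filters produce one-to-one homolog pairs:

1. length/identity thresholds (defaults: both sides >= 400 bp, >= 80 %
   identity, boundary values kept);
2. per (ref chrom, query chrom, orientation) group, the longest mutually
   consistent (co-linear, non-overlapping) chain of segments, found by
   weighted longest-increasing-subsequence dynamic programming;
3. removal of every pair whose region overlaps (>= 1 bp) another pair's
   region in either species — the "one-to-multiple" orthology filter.

The surviving pairs tile a small fraction of each genome and are the unit
of all downstream cross-species repair comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

import pandas as pd

from .io_core import AlignmentSegment, GenomicInterval

logger = logging.getLogger("xrcompare")


@dataclass(frozen=True)
class HomologPair:
    """A one-to-one orthologous region pair between species A and species B."""

    pair_id: str
    region_a: GenomicInterval
    region_b: GenomicInterval
    identity: float
    orientation: str = "same"  # "same" or "inverted"

    def __post_init__(self):
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"invalid orientation {self.orientation!r}")


def filter_segments(
    segments: Sequence[AlignmentSegment],
    min_length: int = 400,
    min_identity: float = 80.0,
) -> list[AlignmentSegment]:
    """Keep segments long enough on *both* sides and identical enough.

    Thresholds are inclusive: a 400-bp segment at exactly 80 % identity
    survives.
    """
    return [
        s
        for s in segments
        if s.ref.length >= min_length
        and s.query.length >= min_length
        and s.identity >= min_identity
    ]


def _group_key(s: AlignmentSegment):
    return (s.ref.chrom, s.query.chrom, s.query_strand)


def longest_consistent_chain(
    segments: Sequence[AlignmentSegment],
) -> list[AlignmentSegment]:
    """Maximum-weight mutually consistent subset of one alignment group.

    All segments must share ref chrom, query chrom and orientation.  Two
    segments are consistent when they do not overlap in either genome and
    preserve order: ref order equals query order for forward alignments and
    is reversed for inverted ones.  The returned subset maximizes total
    ref-aligned length (weighted LIS dynamic programming over segments
    sorted by ref start); score ties resolve toward smaller ref start for a
    deterministic result.
    """
    segs = list(segments)
    if not segs:
        return []
    if len({_group_key(s) for s in segs}) != 1:
        raise ValueError(
            "longest_consistent_chain requires one (ref chrom, query chrom, "
            "orientation) group"
        )
    strand = segs[0].query_strand
    order = sorted(
        range(len(segs)),
        key=lambda i: (segs[i].ref.start, segs[i].ref.end, segs[i].query.start),
    )
    segs = [segs[i] for i in order]
    n = len(segs)

    def consistent(j: int, i: int) -> bool:
        # segment j strictly before segment i along the ref
        a, b = segs[j], segs[i]
        if a.ref.end > b.ref.start:
            return False
        if strand == "+":
            return a.query.end <= b.query.start
        return b.query.end <= a.query.start

    weight = [s.ref.length for s in segs]
    best = list(weight)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if consistent(j, i) and best[j] + weight[i] > best[i]:
                best[i] = best[j] + weight[i]
                prev[i] = j
    # deterministic argmax: first index attaining the maximum score
    end = max(range(n), key=lambda i: (best[i], -i))
    chain = []
    while end != -1:
        chain.append(segs[end])
        end = prev[end]
    return chain[::-1]


def chain_all(segments: Sequence[AlignmentSegment]) -> list[AlignmentSegment]:
    """Apply longest_consistent_chain within every alignment group."""
    segs = sorted(segments, key=_group_key)
    out: list[AlignmentSegment] = []
    for _key, group in groupby(segs, key=_group_key):
        out.extend(longest_consistent_chain(list(group)))
    return out


def pairs_from_segments(
    segments: Sequence[AlignmentSegment], prefix: str = "hp"
) -> list[HomologPair]:
    """Materialize segments as homolog pairs with deterministic ids.

    Region coordinates keep the segment intervals; strand bookkeeping moves
    into the ``orientation`` field and both regions are emitted unstranded.
    """
    segs = sorted(
        segments,
        key=lambda s: (s.ref.chrom, s.ref.start, s.ref.end, s.query.chrom, s.query.start),
    )
    pairs = []
    for i, s in enumerate(segs):
        pairs.append(
            HomologPair(
                pair_id=f"{prefix}{i:05d}",
                region_a=GenomicInterval(s.ref.chrom, s.ref.start, s.ref.end),
                region_b=GenomicInterval(s.query.chrom, s.query.start, s.query.end),
                identity=s.identity,
                orientation="same" if s.query_strand == "+" else "inverted",
            )
        )
    return pairs


def _overlapping_ids(regions: list[tuple[str, int, int, str]]) -> set[str]:
    """ids of all regions overlapping (>= 1 bp) any other region; sweep over
    (chrom, start)-sorted intervals with an active set."""
    flagged: set[str] = set()
    regions = sorted(regions, key=lambda r: (r[0], r[1], r[2]))
    active: list[tuple[str, int, int, str]] = []  # same chrom, not yet closed
    for chrom, start, end, pid in regions:
        active = [a for a in active if a[0] == chrom and a[2] > start]
        if active:
            flagged.add(pid)
            flagged.update(a[3] for a in active)
        active.append((chrom, start, end, pid))
    return flagged


def remove_one_to_multiple(pairs: Sequence[HomologPair]) -> list[HomologPair]:
    """Drop every pair involved in a within-species overlap.

    If a pair's species-A region overlaps another pair's species-A region
    (or likewise on the B side), the locus aligns to multiple places —
    a one-to-multiple orthology relationship — and *all* pairs involved are
    removed, since the true ortholog cannot be identified.  The output
    regions are mutually disjoint within each species.
    """
    side_a = [(p.region_a.chrom, p.region_a.start, p.region_a.end, p.pair_id) for p in pairs]
    side_b = [(p.region_b.chrom, p.region_b.start, p.region_b.end, p.pair_id) for p in pairs]
    bad = _overlapping_ids(side_a) | _overlapping_ids(side_b)
    if bad:
        logger.info("remove_one_to_multiple: dropped %d pairs", len(bad))
    return [p for p in pairs if p.pair_id not in bad]


def extract_homologs(
    segments: Sequence[AlignmentSegment],
    min_length: int = 400,
    min_identity: float = 80.0,
) -> list[HomologPair]:
    """Full extraction pipeline: threshold filter -> per-group consistent
    chaining -> one-to-multiple removal."""
    kept = filter_segments(segments, min_length=min_length, min_identity=min_identity)
    chained = chain_all(kept)
    return remove_one_to_multiple(pairs_from_segments(chained))


def genome_fraction(pairs: Sequence[HomologPair], genome_sizes: dict) -> dict[str, float]:
    """Percent of each genome covered by one-to-one homolog regions.

    ``genome_sizes`` maps side ("a"/"b") to either a total bp count or a
    chrom -> length mapping.
    """
    totals = {}
    for side, size in genome_sizes.items():
        totals[side] = sum(size.values()) if isinstance(size, dict) else float(size)
    covered = {
        "a": sum(p.region_a.length for p in pairs),
        "b": sum(p.region_b.length for p in pairs),
    }
    return {side: 100.0 * covered[side] / totals[side] for side in totals}


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------

PAIR_COLUMNS = [
    "pair_id", "chrom_a", "start_a", "end_a",
    "chrom_b", "start_b", "end_b", "identity", "orientation",
]


def pairs_to_frame(pairs: Sequence[HomologPair]) -> pd.DataFrame:
    rows = [
        (p.pair_id, p.region_a.chrom, p.region_a.start, p.region_a.end,
         p.region_b.chrom, p.region_b.start, p.region_b.end,
         p.identity, p.orientation)
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(frame: pd.DataFrame) -> list[HomologPair]:
    return [
        HomologPair(
            pair_id=str(r.pair_id),
            region_a=GenomicInterval(r.chrom_a, int(r.start_a), int(r.end_a)),
            region_b=GenomicInterval(r.chrom_b, int(r.start_b), int(r.end_b)),
            identity=float(r.identity),
            orientation=str(r.orientation),
        )
        for r in frame.itertuples(index=False)
    ]


def write_pair_table(pairs: Sequence[HomologPair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> list[HomologPair]:
    return frame_to_pairs(pd.read_csv(path, sep="\t"))


def pairs_to_bed_frames(pairs: Sequence[HomologPair]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two BED6 frames (species A, species B) sharing pair_id in the name
    column, for export alongside the pair table."""
    a = pd.DataFrame(
        [(p.region_a.chrom, p.region_a.start, p.region_a.end, p.pair_id, "0", "+")
         for p in pairs],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    b = pd.DataFrame(
        [(p.region_b.chrom, p.region_b.start, p.region_b.end, p.pair_id, "0",
          "+" if p.orientation == "same" else "-")
         for p in pairs],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    return a, b
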