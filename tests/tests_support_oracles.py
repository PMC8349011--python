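"""Brute-force oracles shared by the end-to-end validation tests.

Deliberately naive (exhaustive subsets, O(n^2) scans) and independent of
the package's algorithms.
"""

from itertools import combinations

from xrcompare.io_core import AlignmentSegment, GenomicInterval


def random_segment_table(rng, n, rc="h1", qc="m1", strand="+"):
    segs = []
    for _ in range(n):
        rs = int(rng.integers(0, 30_000))
        qs = int(rng.integers(0, 30_000))
        rl = int(rng.integers(100, 2_000))
        ql = int(rng.integers(100, 2_000))
        segs.append(
            AlignmentSegment(
                ref=GenomicInterval(rc, rs, rs + rl),
                query=GenomicInterval(qc, qs, qs + ql),
                identity=float(rng.uniform(60, 100)),
                query_strand=strand,
            )
        )
    return segs


def bruteforce_filter(segs, min_length=400, min_identity=80.0):
    return [
        s for s in segs
        if s.ref.length >= min_length
        and s.query.length >= min_length
        and s.identity >= min_identity
    ]


def _consistent(a, b, strand):
    if a.ref.start > b.ref.start:
        a, b = b, a
    if a.ref.end > b.ref.start:
        return False
    if strand == "+":
        return a.query.end <= b.query.start
    return b.query.end <= a.query.start


def bruteforce_chain(segs, strand):
    """Best total ref length over all 2^n consistent subsets."""
    best = 0
    for k in range(1, len(segs) + 1):
        for subset in combinations(segs, k):
            if all(_consistent(a, b, strand) for a, b in combinations(subset, 2)):
                best = max(best, sum(s.ref.length for s in subset))
    return best


def bruteforce_one_to_multiple(pairs):
    """Surviving pair ids after removing every pair in a within-species
    overlap, by all-pairs comparison."""
    bad = set()
    for p, q in combinations(pairs, 2):
        if p.region_a.overlaps(q.region_a) or p.region_b.overlaps(q.region_b):
            bad |= {p.pair_id, q.pair_id}
    return {p.pair_id for p in pairs} - bad
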