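"""Simulated XR-seq null model.

Excised oligomers carry a strong sequence bias (the lesion must sit at a
fixed distance from the 3' incision), so raw read counts over regions mix
repair activity with sequence composition.  The null model removes the
composition part: candidate reads are drawn uniformly from the homologous
regions, scored against the position-specific nucleotide frequency matrix
of the real XR-seq library, and the best-scoring N are kept.  Counting the
selected reads per region yields the expected signal of a repair-blind
process with XR-like sequence preferences; dividing real by simulated RPKM
cancels the bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import GenomicInterval, fetch_sequences
from .readstats import FrequencyMatrix, encode_sequences, nucleotide_frequency

logger = logging.getLogger("xrcompare")

SCORE_EPS = 1e-6


@dataclass(frozen=True)
class ScoredRead:
    interval: GenomicInterval
    sequence: str
    score: float = float("nan")


def score_read(sequence: str, freq: FrequencyMatrix, eps: float = SCORE_EPS) -> float:
    """Sum over positions of log frequency of the observed base.

    Equivalent, for ranking, to the product of per-position frequencies;
    the log form is numerically safe.  A non-ACGT base scores -inf so the
    read can never be selected.
    """
    if len(sequence) != freq.L:
        raise ValueError(
            f"sequence length {len(sequence)} != matrix length {freq.L}"
        )
    return float(score_sequences([sequence], freq, eps=eps)[0])


def score_sequences(
    sequences: Sequence[str], freq: FrequencyMatrix, eps: float = SCORE_EPS
) -> np.ndarray:
    """Vectorized score_read over equal-length sequences."""
    if len(sequences) == 0:
        return np.empty(0)
    codes = encode_sequences([s.upper() for s in sequences], freq.L)
    logf = np.log(np.maximum(freq.values, eps))
    valid = codes >= 0
    safe = np.where(valid, codes, 0)
    per_pos = logf[np.arange(freq.L)[None, :], safe]
    scores = per_pos.sum(axis=1)
    scores[~valid.all(axis=1)] = -np.inf
    return scores


_RC = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _RC[_a] = _b


def _bulk_fetch(genome, chroms, starts, strands, L: int) -> list[str]:
    """Vectorized fixed-length sequence fetch with minus-strand reverse
    complement; falls back to fetch_sequences for non-array genomes."""
    seqs = np.empty(len(chroms), dtype=object)
    for chrom in pd.unique(chroms):
        arr = genome[chrom]
        idx = np.flatnonzero(chroms == chrom)
        if not isinstance(arr, np.ndarray):
            ivs = [
                GenomicInterval(chrom, int(starts[i]), int(starts[i]) + L, strands[i])
                for i in idx
            ]
            seqs[idx] = fetch_sequences(genome, ivs)
            continue
        mat = arr[starts[idx][:, None] + np.arange(L)]
        minus = strands[idx] == "-"
        mat[minus] = _RC[mat[minus]][:, ::-1]
        seqs[idx] = [row.tobytes().decode("ascii") for row in mat]
    return list(seqs)


def generate_candidates(
    regions: Sequence[GenomicInterval],
    genome,
    n: int,
    L: int = 26,
    seed=None,
) -> pd.DataFrame:
    """Draw ``n`` candidate reads uniformly over (region, offset, strand).

    Every L-mer start position on either strand of every usable region is
    equally likely (regions are weighted by their number of valid offsets).
    Regions shorter than L are skipped with a logged count.  Returns a
    frame with BED6 columns plus ``seq``; the ``score`` column is filled by
    :func:`score_sequences` downstream.
    """
    rng = np.random.default_rng(seed)
    usable = [r for r in regions if r.length >= L]
    skipped = len(regions) - len(usable)
    if skipped:
        logger.info("generate_candidates: skipped %d regions shorter than %d bp",
                    skipped, L)
    if not usable:
        raise ValueError(f"no regions of length >= {L}")
    n_offsets = np.array([r.length - L + 1 for r in usable], dtype=float)
    ridx = rng.choice(len(usable), size=n, p=n_offsets / n_offsets.sum())
    offsets = np.floor(rng.random(n) * n_offsets[ridx]).astype(int)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    starts = np.array([usable[i].start for i in ridx]) + offsets
    chroms = np.array([usable[i].chrom for i in ridx], dtype=object)
    seqs = _bulk_fetch(genome, chroms, starts, strands, L)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + L,
            "name": [f"sim{i}" for i in range(n)],
            "score": np.nan,
            "strand": strands,
            "seq": seqs,
        }
    )


def select_top(candidates: pd.DataFrame, n_select: int) -> pd.DataFrame:
    """The ``n_select`` highest-scoring candidates.

    Reads scoring -inf (non-ACGT content) are excluded before selection;
    ties break by (chrom, start, strand) so output is order-invariant.
    """
    if "score" not in candidates or candidates["score"].isna().any():
        raise ValueError("candidates must be scored before selection")
    finite = candidates[np.isfinite(candidates["score"])]
    if n_select > len(finite):
        raise ValueError(
            f"cannot select {n_select} reads from {len(finite)} scorable "
            "candidates; generate a larger candidate pool"
        )
    ordered = finite.sort_values(
        ["score", "chrom", "start", "strand"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    return ordered.head(n_select).reset_index(drop=True)


def simulate_null_reads(
    regions: Sequence[GenomicInterval],
    genome,
    freq: FrequencyMatrix,
    n_select: int,
    pool_factor: float = 3.0,
    seed=None,
) -> pd.DataFrame:
    """End-to-end null model: candidates -> scoring -> top-N selection.

    ``pool_factor`` controls how many candidates are generated per selected
    read; selection is only meaningful when the pool is larger than N.
    """
    n_pool = int(round(pool_factor * n_select))
    cands = generate_candidates(regions, genome, n_pool, L=freq.L, seed=seed)
    cands = cands.assign(score=score_sequences(cands["seq"].tolist(), freq))
    return select_top(cands, n_select)


def selection_shift(
    pool: pd.DataFrame, selected: pd.DataFrame, target: FrequencyMatrix
) -> tuple[float, float]:
    """Frobenius distances (pool -> target, selected -> target).

    Selection works when the second number is smaller: the chosen reads'
    composition has moved toward the real XR-seq library's.
    """
    f_pool = nucleotide_frequency(pool["seq"].tolist(), L=target.L)
    f_sel = nucleotide_frequency(selected["seq"].tolist(), L=target.L)
    d_pool = float(np.linalg.norm(f_pool.values - target.values))
    d_sel = float(np.linalg.norm(f_sel.values - target.values))
    return d_pool, d_sel
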