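"""Transcription-coupled repair profiles: TS/NTS metagene analysis.

Genes closer than 20 kb to any other gene are removed first, so opposing
signals from neighbours cannot cancel.  Reads are then pooled over genes
in 100-bp bins across 10 kb flanks around the TSS and TES, oriented 5'->3'
by gene strand and split by repair strand: a read mapping opposite to the
annotated gene strand reports transcribed-strand (TS, template) repair, a
read on the gene strand reports non-transcribed-strand (NTS) repair.
Binned counts become RPKM and are divided by the RPKM of the same reads
repositioned uniformly at random (shuffle normalization), cancelling
coverage artifacts.  Per-gene TS/NTS ratios over the TSS-downstream window
feed a two-sided Mann-Whitney U comparison between species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GeneModel, as_read_frame

logger = logging.getLogger("xrcompare")


def filter_isolated_genes(
    genes: Sequence[GeneModel], min_gap: int = 20_000
) -> list[GeneModel]:
    """Keep genes >= ``min_gap`` bp (body-to-body, any strand) from every
    other gene on the same chromosome; both members of a close pair go.
    Overlapping genes have distance 0 and are always removed.
    """
    genes = list(genes)
    keep = np.ones(len(genes), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    for idx in by_chrom.values():
        starts = np.array([genes[i].start for i in idx])
        ends = np.array([genes[i].end for i in idx])
        # pairwise interval distance: max(0, larger start - smaller end)
        gap = np.maximum(
            np.maximum(starts[:, None], starts[None, :])
            - np.minimum(ends[:, None], ends[None, :]),
            0,
        )
        np.fill_diagonal(gap, min_gap)
        close = (gap < min_gap).any(axis=1)
        for k, i in enumerate(idx):
            if close[k]:
                keep[i] = False
    return [g for i, g in enumerate(genes) if keep[i]]


def rpkm(count: float, length_bp: float, total_reads: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length must be > 0")
    if total_reads <= 0:
        raise ValueError("total mapped reads must be > 0")
    return count / ((length_bp / 1_000.0) * (total_reads / 1_000_000.0))


def shuffle_reads(reads, chrom_sizes: dict[str, int], seed=None) -> pd.DataFrame:
    """Reposition every read uniformly at random genome-wide.

    Read count and the length multiset are preserved; the chromosome is
    chosen proportional to its length, the start uniformly so the read
    stays inside, and the strand is redrawn uniformly (bedtools shuffle
    semantics).
    """
    rng = np.random.default_rng(seed)
    frame = as_read_frame(reads)
    n = len(frame)
    lengths = (frame["end"].to_numpy() - frame["start"].to_numpy()).astype(int)
    names = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in names], dtype=float)
    cidx = rng.choice(len(names), size=n, p=sizes / sizes.sum())
    span = np.maximum(sizes[cidx] - lengths, 1)
    starts = np.floor(rng.random(n) * span).astype(int)
    return pd.DataFrame(
        {
            "chrom": np.array(names, dtype=object)[cidx],
            "start": starts,
            "end": starts + lengths,
            "name": frame["name"].to_numpy() if "name" in frame else ".",
            "score": "0",
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        }
    )


@dataclass
class BinnedMetaProfile:
    """Pooled metagene profile around one anchor (TSS or TES).

    ``offsets`` give the bin-center position relative to the anchor in
    transcription direction; TS/NTS arrays hold pooled RPKM and their
    shuffle-normalized ratios.
    """

    anchor: str
    flank: int
    bin_size: int
    offsets: np.ndarray
    ts_rpkm: np.ndarray
    nts_rpkm: np.ndarray
    ts_norm: np.ndarray
    nts_norm: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor": self.anchor,
                "bin_index": np.arange(len(self.offsets)),
                "offset_bp": self.offsets,
                "TS_rpkm": self.ts_rpkm,
                "NTS_rpkm": self.nts_rpkm,
                "TS_norm": self.ts_norm,
                "NTS_norm": self.nts_norm,
            }
        )


def _read_midpoints_by_strand(frame: pd.DataFrame):
    """chrom -> {strand -> sorted midpoint array}."""
    mids = ((frame["start"].to_numpy() + frame["end"].to_numpy()) // 2).astype(np.int64)
    out: dict[str, dict[str, np.ndarray]] = {}
    chroms = frame["chrom"].to_numpy()
    strands = frame["strand"].to_numpy()
    df = pd.DataFrame({"chrom": chroms, "strand": strands, "mid": mids})
    for (chrom, strand), grp in df.groupby(["chrom", "strand"]):
        out.setdefault(chrom, {})[strand] = np.sort(grp["mid"].to_numpy())
    return out


def _binned_counts(
    frame: pd.DataFrame,
    genes: Sequence[GeneModel],
    anchor: str,
    flank: int,
    bin_size: int,
    chrom_sizes: dict[str, int] | None,
):
    """Pooled per-bin TS/NTS counts plus per-bin effective length (bp
    summed over genes, truncated at chromosome ends)."""
    n_bins = 2 * flank // bin_size
    ts = np.zeros(n_bins)
    nts = np.zeros(n_bins)
    eff_len = np.zeros(n_bins)
    index = _read_midpoints_by_strand(frame)
    for g in genes:
        pos = g.tss if anchor == "TSS" else g.tes
        w0, w1 = pos - flank, pos + flank
        lo = max(w0, 0)
        hi = min(w1, chrom_sizes[g.chrom]) if chrom_sizes else w1
        if hi <= lo:
            continue
        # per-bin effective bp given chromosome truncation
        edges = w0 + bin_size * np.arange(n_bins + 1)
        cover = np.maximum(
            np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0
        )
        if g.strand == "-":
            cover = cover[::-1]
        eff_len += cover
        for strand in ("+", "-"):
            mids = index.get(g.chrom, {}).get(strand)
            if mids is None or len(mids) == 0:
                continue
            sel = mids[np.searchsorted(mids, w0, "left"):np.searchsorted(mids, w1, "left")]
            if len(sel) == 0:
                continue
            if g.strand == "+":
                bins = (sel - w0) // bin_size
            else:
                bins = (w1 - 1 - sel) // bin_size
            counts = np.bincount(bins, minlength=n_bins)
            # read on the strand opposite the gene reports TS repair
            if strand != g.strand:
                ts += counts
            else:
                nts += counts
    return ts, nts, eff_len


def metagene_profile(
    reads,
    genes: Sequence[GeneModel],
    shuffled_reads,
    anchor: str = "TSS",
    flank: int = 10_000,
    bin_size: int = 100,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedMetaProfile:
    """Shuffle-normalized TS/NTS metagene profile around TSS or TES.

    ``genes`` should already have passed :func:`filter_isolated_genes`.
    Each read lands in at most one bin per gene window (midpoint rule).
    RPKM uses the full sample sizes as totals; normalized values divide
    real by shuffled RPKM, with zero shuffled bins floored at the
    one-read-equivalent RPKM so sparse bins cannot divide by zero.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    frame = as_read_frame(reads)
    shuf = as_read_frame(shuffled_reads)
    if len(shuf) == 0:
        raise ValueError("no shuffled reads given for normalization")
    genes = list(genes)
    total = len(frame)
    total_shuf = len(shuf)
    ts_c, nts_c, eff = _binned_counts(frame, genes, anchor, flank, bin_size, chrom_sizes)
    ts_s, nts_s, _ = _binned_counts(shuf, genes, anchor, flank, bin_size, chrom_sizes)

    def to_rpkm(counts, tot):
        out = np.zeros_like(counts, dtype=float)
        ok = eff > 0
        out[ok] = counts[ok] / ((eff[ok] / 1_000.0) * (tot / 1_000_000.0))
        return out

    ts_r, nts_r = to_rpkm(ts_c, total), to_rpkm(nts_c, total)
    ts_sr, nts_sr = to_rpkm(ts_s, total_shuf), to_rpkm(nts_s, total_shuf)
    floor = to_rpkm(np.ones_like(ts_s), total_shuf)
    n_floored = int((ts_sr <= 0).sum() + (nts_sr <= 0).sum())
    if n_floored:
        logger.info("metagene_profile: floored %d empty shuffled bins", n_floored)
    ts_sr = np.where(ts_sr > 0, ts_sr, floor)
    nts_sr = np.where(nts_sr > 0, nts_sr, floor)
    offsets = -flank + bin_size * np.arange(2 * flank // bin_size) + bin_size // 2
    return BinnedMetaProfile(
        anchor=anchor,
        flank=flank,
        bin_size=bin_size,
        offsets=offsets,
        ts_rpkm=ts_r,
        nts_rpkm=nts_r,
        ts_norm=np.divide(ts_r, ts_sr, out=np.zeros_like(ts_r), where=ts_sr > 0),
        nts_norm=np.divide(nts_r, nts_sr, out=np.zeros_like(nts_r), where=nts_sr > 0),
        n_genes=len(genes),
    )


def gene_asymmetry(
    reads,
    genes: Sequence[GeneModel],
    flank: int = 10_000,
    total: int | None = None,
) -> pd.DataFrame:
    """Per-gene TS and NTS RPKM over the TSS-downstream ``flank`` window.

    The TS/NTS ratio is NaN when the gene has zero NTS reads; such genes
    are excluded from ratio statistics downstream (their count is logged).
    """
    frame = as_read_frame(reads)
    total = len(frame) if total is None else total
    index = _read_midpoints_by_strand(frame)
    rows = []
    for g in genes:
        if g.strand == "+":
            w0, w1 = g.tss, g.tss + flank
        else:
            w0, w1 = g.tss - flank, g.tss
        counts = {"+": 0, "-": 0}
        for strand in ("+", "-"):
            mids = index.get(g.chrom, {}).get(strand)
            if mids is not None and len(mids):
                counts[strand] = int(
                    np.searchsorted(mids, w1, "left") - np.searchsorted(mids, w0, "left")
                )
        ts_count = counts["-" if g.strand == "+" else "+"]
        nts_count = counts[g.strand]
        ts_r = rpkm(ts_count, flank, total)
        nts_r = rpkm(nts_count, flank, total)
        rows.append(
            (g.gene_id, ts_r, nts_r, ts_r / nts_r if nts_r > 0 else np.nan)
        )
    out = pd.DataFrame(rows, columns=["gene_id", "ts_rpkm", "nts_rpkm", "ratio"])
    n_undef = int(out["ratio"].isna().sum())
    if n_undef:
        logger.info("gene_asymmetry: %d genes with zero NTS reads (ratio undefined)",
                    n_undef)
    return out


@dataclass(frozen=True)
class TsNtsTestResult:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def ts_nts_test(ratios_a, ratios_b) -> TsNtsTestResult:
    """Two-sided Mann-Whitney U on per-gene TS/NTS ratios of two samples
    (typically two species); undefined (NaN) ratios are dropped."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 defined TS/NTS ratios per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TsNtsTestResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
    )
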