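"""Cross-species comparison over one-to-one homologous regions.

Per region and species, three RPKM values are computed (real XR-seq,
simulated XR-seq null, RNA-seq); the normalized repair signal is
XR / simulated RPKM, cancelling the sequence-composition bias of excised
oligomers.  On top of that sit the Pearson correlation of log-normalized
repair between species, the expression-quartile bootstrap of that
correlation, sample clustering by PCA of region count matrices, and the
genic/intergenic partition of regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homology import HomologPair
from .io_core import GeneModel, as_read_frame

logger = logging.getLogger("xrcompare")


# ---------------------------------------------------------------------------
# Region-level signal aggregation
# ---------------------------------------------------------------------------

def _overlap_counts(regions: pd.DataFrame, reads) -> np.ndarray:
    """Reads overlapping (>= 1 bp, strand-blind) each region, counted once
    per region.  Regions must be mutually disjoint within a chromosome
    (guaranteed for one-to-one homologs), so sorted-array arithmetic works:
    overlaps(r) = #{start < region_end} - #{end <= region_start}.
    """
    frame = as_read_frame(reads)
    counts = np.zeros(len(regions), dtype=np.int64)
    for chrom, grp in frame.groupby("chrom"):
        sel = regions["chrom"] == chrom
        if not sel.any():
            continue
        starts = np.sort(grp["start"].to_numpy())
        ends = np.sort(grp["end"].to_numpy())
        r_start = regions.loc[sel, "start"].to_numpy()
        r_end = regions.loc[sel, "end"].to_numpy()
        counts[np.flatnonzero(sel)] = (
            np.searchsorted(starts, r_end, "left")
            - np.searchsorted(ends, r_start, "right")
        )
    return counts


def _signals_one_side(
    pairs: Sequence[HomologPair], side: str, xr_reads, sim_reads, rna_reads
) -> pd.DataFrame:
    region = {
        "a": lambda p: p.region_a,
        "b": lambda p: p.region_b,
    }[side]
    regions = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "chrom": [region(p).chrom for p in pairs],
            "start": [region(p).start for p in pairs],
            "end": [region(p).end for p in pairs],
        }
    )
    length = (regions["end"] - regions["start"]).to_numpy()
    out = pd.DataFrame({"pair_id": regions["pair_id"]})
    for label, reads in (("xr", xr_reads), ("sim", sim_reads), ("rna", rna_reads)):
        frame = as_read_frame(reads)
        total = len(frame)
        if total == 0:
            raise ValueError(f"{label} read set for side {side} is empty")
        counts = _overlap_counts(regions, frame)
        out[f"{label}_count"] = counts
        out[f"{label}_rpkm"] = counts / ((length / 1_000.0) * (total / 1_000_000.0))
    out["norm_repair"] = np.where(
        out["sim_rpkm"] > 0, out["xr_rpkm"] / out["sim_rpkm"], np.nan
    )
    return out


def region_signals(
    pairs: Sequence[HomologPair],
    reads_a: dict,
    reads_b: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region RPKM triples and normalized repair for both species.

    ``reads_a``/``reads_b`` map "xr", "sim" and "rna" to read sets (BED6
    frames or AlignedRead lists); totals are the full sample sizes, not
    only in-region reads.  A pair is dropped from *both* species when
    either side has zero XR or RNA reads, or zero simulated coverage
    (normalized repair undefined); the two returned frames are aligned row
    by row on pair_id.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty homolog pair list")
    sig_a = _signals_one_side(pairs, "a", reads_a["xr"], reads_a["sim"], reads_a["rna"])
    sig_b = _signals_one_side(pairs, "b", reads_b["xr"], reads_b["sim"], reads_b["rna"])

    def ok(sig):
        return (sig["xr_count"] > 0) & (sig["rna_count"] > 0) & (sig["sim_count"] > 0)

    keep = (ok(sig_a) & ok(sig_b)).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("region_signals: dropped %d/%d pairs failing the "
                    "zero-read filter", n_drop, len(pairs))
    return (
        sig_a[keep].reset_index(drop=True),
        sig_b[keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Cross-species correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str = "pearson"


def repair_correlation(
    signals_a, signals_b, method: str = "pearson", log_transform: bool = True
) -> CorrelationResult:
    """Correlation of normalized repair between species across paired
    regions.

    Accepts the aligned signal frames from :func:`region_signals` (their
    ``norm_repair`` columns) or bare arrays.  By default the correlation
    is Pearson on log10 values — the scale on which normalized repair is
    approximately normal; Spearman is available for sensitivity checks.
    """
    x = np.asarray(
        signals_a["norm_repair"] if isinstance(signals_a, pd.DataFrame) else signals_a,
        dtype=float,
    )
    y = np.asarray(
        signals_b["norm_repair"] if isinstance(signals_b, pd.DataFrame) else signals_b,
        dtype=float,
    )
    if len(x) != len(y):
        raise ValueError("signal vectors must be paired (equal length)")
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 paired regions with defined signal")
    if log_transform:
        x, y = np.log10(x), np.log10(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a signal vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(r=float(r), p_value=float(p), n=len(x), method=method)


def quartile_bootstrap(
    signals_a: pd.DataFrame,
    signals_b: pd.DataFrame,
    n_boot: int = 10,
    seed=None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Bootstrap of the repair correlation within expression quartiles.

    For each species' RNA RPKM, regions split into four rank-based
    quartiles (stable order breaks ties, sizes within one of each other);
    each quartile is resampled with replacement ``n_boot`` times at its own
    size and the repair correlation recomputed.  Returns a tidy frame
    (species_used, quartile, boot, r).
    """
    rng = np.random.default_rng(seed)
    if len(signals_a) != len(signals_b):
        raise ValueError("signal frames must be aligned")
    rows = []
    for species, sig in (("a", signals_a), ("b", signals_b)):
        order = np.argsort(sig["rna_rpkm"].to_numpy(), kind="stable")
        quartiles = np.array_split(order, 4)
        for qi, q_idx in enumerate(quartiles, start=1):
            if len(q_idx) < 3:
                raise ValueError(
                    f"quartile Q{qi} has {len(q_idx)} regions (< 3)"
                )
            for b in range(1, n_boot + 1):
                take = q_idx[rng.integers(0, len(q_idx), len(q_idx))]
                res = repair_correlation(
                    signals_a["norm_repair"].to_numpy()[take],
                    signals_b["norm_repair"].to_numpy()[take],
                    method=method,
                )
                rows.append((species, f"Q{qi}", b, res.r))
    return pd.DataFrame(rows, columns=["species_used", "quartile", "boot", "r"])


# ---------------------------------------------------------------------------
# Sample clustering
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: pd.DataFrame       # sample, PC1, PC2
    explained_variance_ratio: np.ndarray

    def distances(self) -> pd.DataFrame:
        """Pairwise sample distances over all retained components."""
        pc_cols = [c for c in self.coordinates.columns if c.startswith("PC")]
        xy = self.coordinates[pc_cols].to_numpy()
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        s = self.coordinates["sample"]
        return pd.DataFrame(d, index=s, columns=s)


def pca_counts(count_matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of samples from a regions x samples count matrix.

    Counts are stabilized by median-of-ratios size factors followed by
    log2(x + 1), then region-centered; PCA runs on the samples.  Component
    signs follow a fixed convention (the largest-magnitude region loading
    is positive) so output is reproducible across orderings.
    """
    from sklearn.decomposition import PCA

    counts = count_matrix.to_numpy(dtype=float)
    if counts.shape[1] < 3 or counts.shape[0] < 10:
        raise ValueError("need >= 3 samples and >= 10 regions")
    if np.allclose(counts, counts[:, :1]):
        raise ValueError("count matrix is constant across samples")
    # median-of-ratios size factors over rows positive in all samples
    pos = (counts > 0).all(axis=1)
    if pos.any():
        log_gm = np.log(counts[pos]).mean(axis=1, keepdims=True)
        size_factors = np.exp(np.median(np.log(counts[pos]) - log_gm, axis=0))
    else:
        size_factors = np.ones(counts.shape[1])
    transformed = np.log2(counts / size_factors + 1.0)
    x = transformed.T - transformed.mean(axis=1)  # samples x regions, centered
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1
    frame = pd.DataFrame(
        {"sample": list(count_matrix.columns),
         **{f"PC{k + 1}": coords[:, k] for k in range(n_components)}}
    )
    return PCAResult(coordinates=frame,
                     explained_variance_ratio=pca.explained_variance_ratio_)


def nearest_neighbors(result: PCAResult) -> dict[str, str]:
    """Each sample's nearest other sample in the retained PC space."""
    d = result.distances().to_numpy().copy()
    np.fill_diagonal(d, np.inf)
    names = list(result.coordinates["sample"])
    return {names[i]: names[int(np.argmin(d[i]))] for i in range(len(names))}


# ---------------------------------------------------------------------------
# Genic / intergenic partition
# ---------------------------------------------------------------------------

def genic_intergenic_split(
    pairs: Sequence[HomologPair],
    genes: Sequence[GeneModel],
    side: str = "a",
) -> tuple[list[HomologPair], list[HomologPair]]:
    """Partition pairs by >= 1 bp overlap with any gene body on the
    partitioning species' side; returns (genic, intergenic)."""
    get = {"a": lambda p: p.region_a, "b": lambda p: p.region_b}[side]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    starts_ends = {
        c: (np.sort(np.array([s for s, _ in v])), np.sort(np.array([e for _, e in v])))
        for c, v in by_chrom.items()
    }
    genic, intergenic = [], []
    for p in pairs:
        r = get(p)
        hit = False
        if r.chrom in starts_ends:
            starts, ends = starts_ends[r.chrom]
            n_overlap = (
                np.searchsorted(starts, r.end, "left")
                - np.searchsorted(ends, r.start, "right")
            )
            hit = n_overlap > 0
        (genic if hit else intergenic).append(p)
    return genic, intergenic
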