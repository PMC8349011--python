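"""Optional matplotlib figures for the main pipeline outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_metagene(profile, ax=None):
    """TS (red) vs NTS (blue) normalized profile around one anchor."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 3.5))
    kb = profile.offsets / 1_000.0
    ax.plot(kb, profile.ts_norm, color="crimson", label="TS")
    ax.plot(kb, profile.nts_norm, color="steelblue", label="NTS")
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(f"distance from {profile.anchor} (kb)")
    ax.set_ylabel("normalized repair (real / shuffled RPKM)")
    ax.legend(frameon=False)
    return ax


def plot_repair_scatter(signals_a, signals_b, ax=None):
    """Log-log scatter of normalized repair between species."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(4, 4))
    x = np.asarray(signals_a["norm_repair"], dtype=float)
    y = np.asarray(signals_b["norm_repair"], dtype=float)
    ok = (x > 0) & (y > 0)
    ax.scatter(x[ok], y[ok], s=6, alpha=0.4, color="black")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("normalized repair, species A")
    ax.set_ylabel("normalized repair, species B")
    return ax


def plot_pca(result, meta=None, ax=None):
    """PC1/PC2 scatter, optionally colored by cell type from a metadata
    frame with 'sample' and 'celltype' columns."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(4.5, 4))
    coords = result.coordinates
    colors = None
    if meta is not None:
        lut = dict(zip(meta["sample"], meta["celltype"]))
        palette = {"fibroblast": "tab:blue", "lymphocyte": "tab:red"}
        colors = [palette.get(lut.get(s), "grey") for s in coords["sample"]]
    ax.scatter(coords["PC1"], coords["PC2"], c=colors or "black", s=30)
    for _i, row in coords.iterrows():
        ax.annotate(row["sample"], (row["PC1"], row["PC2"]), fontsize=6)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    return ax
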