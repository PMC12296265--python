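"""Figure rendering from the statistical tables.

Every figure is a pure function of the tables it consumes, so regenerating
from saved tables reproduces it. Only presence, axes semantics, and the
highlighted-set membership are contractual; aesthetics are not.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .networks import CorrelationMatrix, FunctionalNetwork, PermutationResult

FIGURE_KINDS = ("heatmap", "network", "volcano", "parallel", "distribution")


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_heatmap(corr: CorrelationMatrix, path: str | Path, title: str = "") -> Path:
    """Region cross-correlation heatmap (r in [-1, 1], diverging scale)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.regions)), corr.regions, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.regions)), corr.regions, fontsize=6)
    ax.set_title(title or "regional cross-correlations")
    fig.colorbar(im, ax=ax, label="Pearson r")
    return _save(fig, path)


def plot_network(net: FunctionalNetwork, path: str | Path, title: str = "") -> Path:
    """Thresholded functional network; edge color encodes the sign of r."""
    fig, ax = plt.subplots(figsize=(6, 6))
    G = net.graph
    pos = nx.spring_layout(G, seed=0)
    colors = ["tab:red" if d["r"] < 0 else "tab:blue" for _, _, d in G.edges(data=True)]
    widths = [1 + 2 * abs(d["r"]) for _, _, d in G.edges(data=True)]
    nx.draw_networkx(G, pos=pos, ax=ax, node_size=120, font_size=6,
                     edge_color=colors, width=widths)
    ax.set_title(title or f"|r| > {net.r_min}, p < {net.alpha}")
    ax.set_axis_off()
    return _save(fig, path)


def volcano_significant_pairs(
    perm: pd.DataFrame, d_threshold: float = 1.0, alpha: float = 0.01
) -> pd.DataFrame:
    """The highlighted set of a volcano plot: |d| > threshold and p < alpha."""
    return perm[(perm["d"].abs() > d_threshold) & (perm["p"] < alpha)]


def plot_volcano(
    perm: PermutationResult | pd.DataFrame,
    path: str | Path,
    d_threshold: float = 1.0,
    alpha: float = 0.01,
    title: str = "",
) -> Path:
    """Correlation difference d = r_B − r_A against −log10 permutation p.

    Pairs with |d| above the threshold and p below alpha are highlighted.
    The file is produced even when the highlighted set is empty.
    """
    df = perm.to_frame() if isinstance(perm, PermutationResult) else perm
    fig, ax = plt.subplots(figsize=(6, 5))
    sig = volcano_significant_pairs(df, d_threshold, alpha)
    ax.scatter(df["d"], -np.log10(df["p"]), s=10, c="lightgray")
    if len(sig):
        ax.scatter(sig["d"], -np.log10(sig["p"]), s=16, c="tab:red")
    ax.axvline(d_threshold, ls="--", c="k", lw=0.7)
    ax.axvline(-d_threshold, ls="--", c="k", lw=0.7)
    ax.axhline(-np.log10(alpha), ls="--", c="k", lw=0.7)
    ax.set_xlabel("correlation difference d")
    ax.set_ylabel("-log10 permutation p")
    ax.set_title(title or "correlation differences")
    return _save(fig, path)


def plot_parallel(
    perm: PermutationResult,
    corr_a: CorrelationMatrix,
    corr_b: CorrelationMatrix,
    path: str | Path,
    d_threshold: float = 1.0,
    alpha: float = 0.01,
) -> Path:
    """Parallel-coordinate ribbons for significantly changed pairs: each
    ribbon joins a pair's r in group A to its r in group B."""
    sig = volcano_significant_pairs(perm.to_frame(), d_threshold, alpha)
    fig, ax = plt.subplots(figsize=(4, 5))
    for _, row in sig.iterrows():
        ia, ja = corr_a.index(row.region_a), corr_a.index(row.region_b)
        ib, jb = corr_b.index(row.region_a), corr_b.index(row.region_b)
        ra, rb = corr_a.r[ia, ja], corr_b.r[ib, jb]
        ax.plot([0, 1], [ra, rb], marker="o",
                label=f"{row.region_a}-{row.region_b}")
    ax.set_xticks([0, 1], [perm.group_a, perm.group_b])
    ax.set_ylabel("Pearson r")
    ax.set_ylim(-1.05, 1.05)
    if len(sig):
        ax.legend(fontsize=6)
    ax.set_title("significantly changed correlations")
    return _save(fig, path)


def plot_region_distribution(
    corr_a: CorrelationMatrix,
    corr_b: CorrelationMatrix,
    region: str,
    path: str | Path,
    labels: tuple[str, str] = ("A", "B"),
) -> Path:
    """Overlaid histograms of one region's correlation values per group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    bins = np.linspace(-1, 1, 21)
    ax.hist(corr_a.region_values(region), bins=bins, alpha=0.6, label=labels[0])
    ax.hist(corr_b.region_values(region), bins=bins, alpha=0.6, label=labels[1])
    ax.set_xlabel("Pearson r")
    ax.set_ylabel("count")
    ax.set_title(f"{region} correlation distribution")
    ax.legend()
    return _save(fig, path)
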