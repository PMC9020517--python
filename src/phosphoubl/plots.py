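"""Static figures: CSP bar plots, ZZ-exchange buildup, enrichment heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .csp import CSPProfile
from .enrichment import EnrichmentResult
from .zz import ExchangeFit, ZZSeries, exchange_ratio


def plot_csp_profile(profile: CSPProfile, path: str | Path) -> Path:
    """Per-residue bar plot with mean (solid) and mean+SD (dashed) lines."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.bar(profile.entries["residue_index"], profile.entries["delta_omega"], width=0.8)
    ax.axhline(profile.mean_threshold, color="k", lw=1)
    ax.axhline(profile.sd_threshold, color="k", lw=1, ls="--")
    ax.set_xlabel("residue")
    ax.set_ylabel(r"$\Delta\omega$ (ppm)")
    ax.set_title(f"{profile.query_spectrum} vs {profile.reference_spectrum}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_zz_ratio(series: list[ZZSeries], fit: ExchangeFit, path: str | Path) -> Path:
    """sqrt(ratio) vs mixing time with the fitted line per residue."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    for s in series:
        ratio, valid = exchange_ratio(s)
        ax.plot(s.t_mix[valid], np.sqrt(ratio[valid]), "o", label=str(s.residue))
        k = fit.per_residue_k.get(s.residue)
        if k is not None:
            tt = np.linspace(0, s.t_mix.max(), 50)
            ax.plot(tt, k * tt, "-", alpha=0.5)
    ax.set_xlabel(r"$t_\mathrm{mix}$ (s)")
    ax.set_ylabel(r"$\sqrt{R(t)}$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_enrichment_heatmap(result: EnrichmentResult, path: str | Path) -> Path:
    """Clustered z-score heatmap of significant proteins x baits."""
    path = Path(path)
    if result.z_matrix is None:
        raise ValueError("run cluster_and_zscore first")
    z = result.z_matrix
    order = result.row_clusters.sort_values().index if result.row_clusters is not None else z.index
    cols = result.column_order or list(z.columns)
    data = z.loc[order, cols]
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(len(cols)), [str(c) for c in cols], rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
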