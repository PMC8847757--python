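"""Figure helpers: cooperation surfaces, mean +/- sd curves, and
forcing/synchrony/spectrum panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["heatmap", "sweep_curves", "fluctuation_panels"]


def heatmap(summary: pd.DataFrame, value: str = "mean_prop_coop",
            out: str | Path | None = None):
    """Sweep-summary surface of ``value`` over R00 (x) and bK (y)."""
    pivot = summary.pivot_table(index="bK", columns="R00", values=value)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto",
                   cmap="viridis",
                   extent=(min(pivot.columns), max(pivot.columns),
                           min(pivot.index), max(pivot.index)))
    ax.set_xlabel("environmental resource availability $R_0^0$")
    ax.set_ylabel("cooperation efficiency $b_K$")
    fig.colorbar(im, ax=ax, label=value)
    if out:
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def sweep_curves(summary: pd.DataFrame, value: str = "mean_N",
                 out: str | Path | None = None):
    """``value`` vs. R00, one panel per bK, error bars = replicate sd."""
    bks = sorted(summary["bK"].unique())
    fig, axes = plt.subplots(1, len(bks), figsize=(4 * len(bks), 3.2),
                             sharey=True, squeeze=False)
    for ax, bk in zip(axes[0], bks):
        for scenario, sub in summary[summary["bK"] == bk].groupby("scenario"):
            sub = sub.sort_values("R00")
            ax.errorbar(sub["R00"], sub[value], yerr=sub.get(f"sd_{value}"),
                        marker="o", capsize=3, label=scenario)
        ax.set_title(f"$b_K$ = {bk:g}")
        ax.set_xlabel("$R_0^0$")
        ax.legend(fontsize=8)
    axes[0][0].set_ylabel(value)
    if out:
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def fluctuation_panels(env: np.ndarray, mean_N: dict, lag_corrs: dict,
                       spectra: dict, out: str | Path | None = None):
    """Forcing + population time series, TLCC, and spectra per scenario.

    ``mean_N``, ``lag_corrs`` and ``spectra`` map scenario labels to a mean
    population-size series, a LagCorrelation and a Spectrum respectively.
    """
    labels = list(mean_N)
    fig, axes = plt.subplots(3, len(labels), figsize=(5 * len(labels), 8),
                             squeeze=False)
    for j, lab in enumerate(labels):
        ax = axes[0][j]
        ax.plot(mean_N[lab], lw=0.8, label="mean N")
        ax2 = ax.twinx()
        ax2.plot(env, lw=0.6, color="tab:orange", alpha=0.6, label="$R_0(t)$")
        ax.set_title(lab)
        ax.set_xlabel("step")
        ax.set_ylabel("population size")

        lc = lag_corrs[lab]
        axes[1][j].plot(lc.lags, lc.r, lw=0.8)
        axes[1][j].axhline(0, color="grey", lw=0.5)
        axes[1][j].set_xlabel("lag (steps)")
        axes[1][j].set_ylabel("TLCC r")

        sp = spectra[lab]
        axes[2][j].plot(sp.freqs[1:], sp.amplitude[1:], lw=0.8)
        axes[2][j].set_xlabel("frequency (1/step)")
        axes[2][j].set_ylabel("amplitude")
        axes[2][j].set_xlim(0, 0.02)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
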