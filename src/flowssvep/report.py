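"""Topographic significance maps, amplitude bars and complex-vector plots.

Every figure has a CSV twin containing exactly the numbers rendered, so
plots are regenerable bit-identically from the CSV plus the channel map.
Maps are schematic head diagrams (no interpolation, no 3D rendering).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .channels import ChannelMap
from .spectral import rms_amplitude
from .stats import DEFAULT_THRESHOLDS

__all__ = [
    "significance_map",
    "top_channels",
    "rms_bar_plot",
    "vector_plot",
]


def _most_stringent(p: np.ndarray, thresholds: tuple) -> np.ndarray:
    """Smallest threshold each p-value passes (NaN if none; strict '<')."""
    thr = np.sort(np.asarray(thresholds))  # ascending = most stringent first
    out = np.full(p.shape, np.nan)
    for t in thr[::-1]:
        out[p < t] = t
    return out


def significance_map(
    results: pd.DataFrame,
    channel_map: ChannelMap,
    thresholds: tuple = DEFAULT_THRESHOLDS,
    out: str | Path | None = None,
):
    """Head-schematic maps of channel-wise p-values, one panel per effect.

    ``results`` needs columns channel, effect, p (e.g. a mass-univariate
    table).  Channel markers are coded by the most stringent threshold
    passed; unmarked channels are drawn as faint dots.  Returns
    (figure, plot_df); when ``out`` is given the figure is saved to
    ``<out>.svg`` and the plot data to ``<out>.csv``.
    """
    unknown = set(results.channel.unique()) - set(channel_map.channels)
    if unknown:
        raise ValueError(f"unknown channel indices: {sorted(unknown)}")
    effects = list(pd.unique(results.effect))
    coords = channel_map.frame[["x", "y"]]
    plot_rows = []
    fig, axes = plt.subplots(
        1, len(effects), figsize=(4 * len(effects), 4), squeeze=False
    )
    thr_sorted = tuple(sorted(thresholds, reverse=True))  # liberal -> strict
    cmap = plt.get_cmap("viridis", len(thr_sorted))
    for ax, effect in zip(axes[0], effects):
        sub = results[results.effect == effect]
        x = coords.loc[sub.channel, "x"].to_numpy()
        y = coords.loc[sub.channel, "y"].to_numpy()
        stringency = _most_stringent(sub.p.to_numpy(), thr_sorted)
        ax.add_patch(plt.Circle((0, 0), 1.05, fill=False, lw=1, color="gray"))
        ax.scatter(x, y, s=6, color="lightgray", zorder=1)
        for j, t in enumerate(thr_sorted):
            mask = stringency == t
            if mask.any():
                ax.scatter(
                    x[mask], y[mask], s=30 + 12 * j, color=cmap(j),
                    zorder=2 + j, label=f"p < {t:g}",
                )
        ax.set_title(effect)
        ax.set_aspect("equal")
        ax.set_xlim(-1.25, 1.25)
        ax.set_ylim(-1.25, 1.25)
        ax.axis("off")
        if np.isfinite(stringency).any():
            ax.legend(fontsize=7, loc="lower right")
        plot_rows.append(
            pd.DataFrame(
                {
                    "effect": effect,
                    "channel": sub.channel.to_numpy(),
                    "x": x,
                    "y": y,
                    "p": sub.p.to_numpy(),
                    "most_stringent_alpha": stringency,
                }
            )
        )
    plot_df = pd.concat(plot_rows, ignore_index=True)
    fig.tight_layout()
    if out is not None:
        out = Path(out)
        fig.savefig(out.with_suffix(".svg"))
        plot_df.to_csv(out.with_suffix(".csv"), index=False)
    return fig, plot_df


def top_channels(
    subject_components: pd.DataFrame,
    harmonic: str,
    k: int = 9,
) -> np.ndarray:
    """The k channels with the highest across-participant mean RMS amplitude.

    Per participant the RMS amplitude sqrt((re^2 + im^2)/2) is averaged over
    conditions, then averaged across participants per channel.  Ties are
    broken toward the lower channel index.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    d = subject_components[subject_components.harmonic == harmonic].copy()
    if d.empty:
        raise ValueError(f"no components at harmonic {harmonic!r}")
    d["rms"] = rms_amplitude(d.re, d.im)
    per_subject = d.groupby(["channel", "subject"], sort=True).rms.mean()
    mean_rms = per_subject.groupby("channel").mean()
    channels = mean_rms.index.to_numpy()
    order = np.lexsort((channels, -mean_rms.to_numpy()))
    return np.sort(channels[order[: min(k, channels.size)]])


def rms_bar_plot(
    subject_components: pd.DataFrame,
    harmonic: str,
    channels,
    by: str = "pattern",
    out: str | Path | None = None,
):
    """Across-participant mean (+1 SEM) RMS amplitude bars per condition.

    One panel per channel, one bar per level of ``by`` ('pattern' or
    'speed').  Returns (figure, plot_df) with the CSV twin of the bars.
    """
    d = subject_components[
        (subject_components.harmonic == harmonic)
        & subject_components.channel.isin(list(channels))
    ].copy()
    if d.empty:
        raise ValueError("no components for the requested channels")
    d["rms"] = rms_amplitude(d.re, d.im)
    per_subject = (
        d.groupby(["channel", by, "subject"], sort=True).rms.mean().reset_index()
    )
    summary = (
        per_subject.groupby(["channel", by])
        .rms.agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    chans = sorted(pd.unique(summary.channel))
    ncol = min(3, len(chans))
    nrow = int(np.ceil(len(chans) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3 * ncol, 2.4 * nrow), squeeze=False,
        sharey=True,
    )
    for ax, ch in zip(axes.ravel(), chans):
        sub = summary[summary.channel == ch]
        ax.bar(sub[by].astype(str), sub["mean"], yerr=sub["sem"], capsize=3)
        ax.set_title(f"ch {ch}", fontsize=9)
    for ax in axes.ravel()[len(chans):]:
        ax.axis("off")
    axes[0, 0].set_ylabel("RMS amplitude (uV)")
    fig.tight_layout()
    if out is not None:
        out = Path(out)
        fig.savefig(out.with_suffix(".svg"))
        summary.to_csv(out.with_suffix(".csv"), index=False)
    return fig, summary


def vector_plot(
    subject_components: pd.DataFrame,
    harmonic: str,
    channels,
    by: str = "pattern",
    out: str | Path | None = None,
):
    """Complex-domain vector plots: mean (re, im) with separate SEM bars.

    Distance from the origin is amplitude, angle is relative phase; error
    bars show +/-1 SEM of the real and imaginary components separately.
    Returns (figure, plot_df).
    """
    d = subject_components[
        (subject_components.harmonic == harmonic)
        & subject_components.channel.isin(list(channels))
    ].copy()
    if d.empty:
        raise ValueError("no components for the requested channels")
    per_subject = (
        d.groupby(["channel", by, "subject"], sort=True)[["re", "im"]]
        .mean()
        .reset_index()
    )
    def _sem(v):
        return v.std(ddof=1) / np.sqrt(len(v))
    summary = (
        per_subject.groupby(["channel", by])
        .agg(
            mean_re=("re", "mean"), mean_im=("im", "mean"),
            sem_re=("re", _sem), sem_im=("im", _sem), n=("re", "size"),
        )
        .reset_index()
    )
    chans = sorted(pd.unique(summary.channel))
    ncol = min(3, len(chans))
    nrow = int(np.ceil(len(chans) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False,
    )
    levels = sorted(pd.unique(summary[by]).tolist())
    colors = plt.get_cmap("tab10")
    lim = 1.2 * max(
        np.hypot(summary.mean_re, summary.mean_im).max(), 1e-6
    )
    for ax, ch in zip(axes.ravel(), chans):
        sub = summary[summary.channel == ch]
        ax.axhline(0, color="gray", lw=0.5)
        ax.axvline(0, color="gray", lw=0.5)
        for j, lev in enumerate(levels):
            row = sub[sub[by] == lev]
            if row.empty:
                continue
            r = row.iloc[0]
            ax.annotate(
                "", xy=(r.mean_re, r.mean_im), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color=colors(j)),
            )
            ax.errorbar(
                r.mean_re, r.mean_im, xerr=r.sem_re, yerr=r.sem_im,
                color=colors(j), fmt="o", ms=3, capsize=2, label=str(lev),
            )
        ax.set_xlim(-lim, lim)
        ax.set_ylim(-lim, lim)
        ax.set_aspect("equal")
        ax.set_title(f"ch {ch}", fontsize=9)
    for ax in axes.ravel()[len(chans):]:
        ax.axis("off")
    axes[0, 0].legend(fontsize=7)
    axes[0, 0].set_xlabel("re (uV)")
    axes[0, 0].set_ylabel("im (uV)")
    fig.tight_layout()
    if out is not None:
        out = Path(out)
        fig.savefig(out.with_suffix(".svg"))
        summary.to_csv(out.with_suffix(".csv"), index=False)
    return fig, summary
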