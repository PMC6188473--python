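"""Thin matplotlib helpers for the standard figures of the workflow."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_ecdf_comparison(comparison, labels=("set A", "set B"), ax=None):
    """Step ECDFs of two gene-set metric distributions with the KS annotation."""
    ax = ax or plt.gca()
    for which, label in zip(("a", "b"), labels):
        x, y = comparison.ecdf(which)
        ax.step(x, y, where="post", label=label)
    ax.set_xlabel("metric value")
    ax.set_ylabel("ECDF")
    ax.legend(frameon=False)
    ax.set_title(f"KS D = {comparison.statistic:.3f}, "
                 f"p = {comparison.pvalue:.2g}")
    return ax


def plot_metagene(profiles: dict[str, np.ndarray], ax=None):
    """Mean conservation across length-normalized peaks, one line per group."""
    ax = ax or plt.gca()
    for label, prof in profiles.items():
        x = np.linspace(0, 1, len(prof))
        ax.plot(x, prof, label=label)
    ax.set_xlabel("normalized peak position")
    ax.set_ylabel("mean conservation")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax


def plot_correlation_heatmap(corr: pd.DataFrame, ax=None):
    """Pairwise sample Pearson correlation matrix."""
    ax = ax or plt.gca()
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)))
    ax.set_xticklabels(corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.index)))
    ax.set_yticklabels(corr.index, fontsize=6)
    plt.colorbar(im, ax=ax, label="Pearson r")
    return ax


def plot_detection_curve(curves: dict[str, pd.DataFrame], ax=None):
    """Genes detected vs downsampled depth, one line per sample."""
    ax = ax or plt.gca()
    for label, df in curves.items():
        ax.plot(df["depth"], df["n_detected"], marker="o", label=label)
    ax.set_xlabel("reads sampled")
    ax.set_ylabel("genes detected")
    ax.legend(frameon=False, fontsize=7)
    return ax
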