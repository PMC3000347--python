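"""Optional figure helpers (matplotlib; install the ``plot`` extra).

Each function takes the corresponding analysis table and writes a PNG or
returns the axes for composition; nothing else in the package imports
matplotlib.
"""

from __future__ import annotations

import pandas as pd


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 3.2))
    return ax


def plot_conservation_profile(profile: pd.DataFrame, ax=None, label=None):
    """Mean conservation score vs signed offset (exonic left, intronic right)."""
    ax = _ax(ax)
    ax.plot(profile["offset"], profile["mean_score"], ".", ms=3, label=label)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("offset from splice site (bp)")
    ax.set_ylabel("mean conservation score")
    return ax


def plot_periodicity(profile: pd.DataFrame, ax=None):
    """Minor-site/opportunity ratio, frame-preserving offsets highlighted."""
    ax = _ax(ax)
    inf = profile[profile["in_frame"]]
    outf = profile[~profile["in_frame"]]
    ax.plot(outf["offset"], outf["ratio"], ".", color="black", ms=4,
            label="frame-disrupting")
    ax.plot(inf["offset"], inf["ratio"], ".", color="red", ms=4,
            label="frame-preserving")
    ax.set_xlabel("offset from major splice site (bp)")
    ax.set_ylabel("minor sites / opportunities")
    ax.legend(fontsize=7)
    return ax


def plot_binned_trend(binned: pd.DataFrame, covariate: str = "length", ax=None):
    """Binned error-rate means with the smoothing-spline overlay."""
    ax = _ax(ax)
    x = binned[f"mean_{covariate}"]
    ax.plot(x, binned["mean_error_rate"], "o", ms=3, color="black")
    if binned["spline"].notna().any():
        order = x.argsort()
        ax.plot(x.iloc[order], binned["spline"].iloc[order], "-", color="red")
    ax.set_xlabel(f"log10 {covariate}")
    ax.set_ylabel("mean splicing error rate")
    return ax
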