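"""Fingerprint figures: radar plot and per-parameter boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .maps import ANALYSIS_PARAMS

_COLORS = {"track": "tab:red", "frontal": "tab:blue", "central": "tab:green",
           "GM": "black"}


def radar_plot(table: pd.DataFrame, path: str | Path,
               params: list[str] | None = None) -> Path:
    """Polar plot of each subtype's mean fingerprint, axes scaled per parameter."""
    params = params or list(ANALYSIS_PARAMS)
    means = table.groupby("subtype")[params].mean()
    lo = means.min() - 0.1 * (means.max() - means.min() + 1e-9)
    span = means.max() - lo + 1e-9
    angles = np.linspace(0, 2 * np.pi, len(params), endpoint=False)

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    for subtype, row in means.iterrows():
        vals = ((row - lo) / span).to_numpy()
        closed = np.r_[vals, vals[:1]]
        ax.plot(np.r_[angles, angles[:1]], closed, label=str(subtype),
                color=_COLORS.get(str(subtype)))
    ax.set_xticks(angles)
    ax.set_xticklabels(params)
    ax.set_yticklabels([])
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    ax.set_title("Subtype fingerprints (per-axis scaled)", fontsize=10)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def fingerprint_boxplots(table: pd.DataFrame, path: str | Path,
                         params: list[str] | None = None) -> Path:
    """One box per subtype per parameter, subjects as the samples."""
    params = params or list(ANALYSIS_PARAMS)
    subtypes = [s for s in table["subtype"].unique()]
    fig, axes = plt.subplots(1, len(params), figsize=(2.2 * len(params), 3),
                             sharex=False)
    for ax, p in zip(np.atleast_1d(axes), params):
        data = [table[table.subtype == s][p].dropna() for s in subtypes]
        box = ax.boxplot(data, tick_labels=subtypes, patch_artist=True)
        for patch, s in zip(box["boxes"], subtypes):
            patch.set_facecolor(_COLORS.get(str(s), "grey"))
            patch.set_alpha(0.5)
        ax.set_title(p, fontsize=9)
        ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
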