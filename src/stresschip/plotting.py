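"""Line plots of average-gene and promoter profiles (one panel per species,
one line per condition), in the layout used throughout the analysis."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metagene import GroupProfile

__all__ = ["plot_group_profiles", "plot_promoter_profiles"]


def plot_group_profiles(
    profiles: Mapping[str, GroupProfile], path: str | Path, title: str = ""
) -> None:
    """One line per condition over the 9+20+9 bin axis; IGR/ORF boundaries
    marked with vertical rules."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, gp in profiles.items():
        ax.plot(np.arange(gp.bins.size), gp.bins, label=cond)
    first = next(iter(profiles.values()))
    bounds = np.flatnonzero(
        [a != b for a, b in zip(first.region_labels, first.region_labels[1:])]
    )
    for b in bounds:
        ax.axvline(b + 0.5, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("bin (5'IGR | ORF | 3'IGR)")
    ax.set_ylabel("mean signal (a.u.)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_promoter_profiles(
    offsets: np.ndarray,
    per_condition: Mapping[str, np.ndarray],
    path: str | Path,
    title: str = "",
) -> None:
    """Promoter bins against bp-relative-to-ATG offsets, one line per
    condition, ATG marked at zero."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, vals in per_condition.items():
        ax.plot(offsets, vals, label=cond)
    ax.axvline(0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("bp relative to ATG")
    ax.set_ylabel("signal (a.u.)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
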