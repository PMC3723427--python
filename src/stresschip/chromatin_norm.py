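"""Histone-density correction: factor or acetylation signal relative to H3.

Acetyl marks live on histones, so apparent changes in a mark can simply
track changes in nucleosome density.  Dividing by total H3 (or subtracting,
for log-scale tracks) removes that confound — with the caveat that where H3
approaches zero the ratio blows up.  The policy object makes that caveat
explicit: denominators below a floor are either masked (default) or clamped.

The pipeline normalises *group-averaged* profiles (average per cluster and
condition, then divide the averages); per-gene normalisation is available by
calling :func:`normalize_to_h3` on individual :class:`GeneProfile` objects.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .metagene import GeneProfile, GroupProfile
from .signal_io import TrackSet

__all__ = ["NormalizationPolicy", "normalize_to_h3", "default_floor", "normalize_bins"]


@dataclass(frozen=True)
class NormalizationPolicy:
    mode: str = "log_difference"          # or "ratio"
    floor: float | None = None            # minimal usable denominator signal
    on_below_floor: str = "missing"       # or "clamp"

    def __post_init__(self) -> None:
        if self.mode not in {"log_difference", "ratio"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.on_below_floor not in {"missing", "clamp"}:
            raise ValueError(f"unknown below-floor action {self.on_below_floor!r}")
        if self.mode == "ratio" and self.floor is not None and self.floor <= 0:
            raise ValueError("floor must be > 0 in ratio mode")


def default_floor(h3_tracks: TrackSet, percentile: float = 1.0) -> float:
    """Conservative default floor: the 1st percentile of genome-wide H3."""
    vals = np.concatenate([t.all_values() for t in h3_tracks.tracks.values()])
    return float(np.percentile(vals, percentile))


def normalize_bins(
    target: np.ndarray, h3: np.ndarray, policy: NormalizationPolicy
) -> np.ndarray:
    if target.shape != h3.shape:
        raise ValueError("bin structures differ between target and H3")
    h3 = h3.astype(float).copy()
    if policy.floor is not None:
        below = h3 < policy.floor
        if policy.on_below_floor == "missing":
            h3[below] = np.nan
        else:
            h3[below] = policy.floor
    with np.errstate(divide="ignore", invalid="ignore"):
        if policy.mode == "ratio":
            return target / h3
        return target - h3


def normalize_to_h3(target, h3, policy: NormalizationPolicy = NormalizationPolicy()):
    """H3-relative version of a :class:`GeneProfile` or :class:`GroupProfile`.

    Missing bins propagate; bins where H3 is below the floor follow the
    policy.  Returns a new profile of the same type.
    """
    if type(target) is not type(h3):
        raise ValueError("target and H3 profiles must be the same type")
    if isinstance(target, (GeneProfile, GroupProfile)):
        out = copy.deepcopy(target)
        out.bins = normalize_bins(target.bins, h3.bins, policy)
        if isinstance(out, GroupProfile):
            out.n = np.minimum(target.n, h3.n)
        return out
    return normalize_bins(np.asarray(target, float), np.asarray(h3, float), policy)
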