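"""Probe-level signal tracks: bedGraph / fixed-step wiggle I/O and median
equalisation across the five time-course samples.

Tracks hold log-scale signal at point probe positions.  A bedGraph interval
is collapsed to its (floored) midpoint, matching the short-probe tiling-array
origin of the data; fixed-step wiggle positions are taken as given.  Cross-
sample normalisation shifts every track additively so all per-track medians
equal the grand median of the original medians (a multiplicative mode exists
for linear-scale inputs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SignalTrack",
    "TrackSet",
    "TrackError",
    "read_track",
    "write_track",
    "median_normalize",
    "merge_tracks",
]


class TrackError(ValueError):
    pass


@dataclass
class SignalTrack:
    """One species x one condition: per-chromosome sorted (position, value)."""

    species: str = ""
    condition: str = ""
    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_chrom(self, chrom: str, positions: np.ndarray, values: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if positions.shape != values.shape:
            raise TrackError("positions and values differ in length")
        if not np.all(np.isfinite(values)):
            raise TrackError(f"{chrom}: non-finite signal value")
        if positions.size and np.any(np.diff(positions) < 0):
            warnings.warn(f"{chrom}: unsorted probe positions; sorting", stacklevel=2)
            order = np.argsort(positions, kind="stable")
            positions, values = positions[order], values[order]
        if positions.size and np.any(np.diff(positions) == 0):
            raise TrackError(f"{chrom}: duplicate probe position")
        self.data[chrom] = (positions, values)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    @property
    def n_probes(self) -> int:
        return sum(p.size for p, _ in self.data.values())

    def all_values(self) -> np.ndarray:
        if not self.data:
            return np.empty(0)
        return np.concatenate([v for _, v in self.data.values()])

    def probes_in(self, chrom: str, start: float, end: float) -> tuple[np.ndarray, np.ndarray]:
        """Probes with start <= position < end (real-valued bounds allowed)."""
        if chrom not in self.data:
            return np.empty(0, dtype=np.int64), np.empty(0)
        pos, val = self.data[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi], val[lo:hi]

    def shifted(self, delta: float) -> "SignalTrack":
        out = SignalTrack(self.species, self.condition)
        out.data = {c: (p, v + delta) for c, (p, v) in self.data.items()}
        return out

    def scaled(self, factor: float) -> "SignalTrack":
        out = SignalTrack(self.species, self.condition)
        out.data = {c: (p, v * factor) for c, (p, v) in self.data.items()}
        return out


@dataclass
class TrackSet:
    """All condition tracks of one species, sharing a chromosome namespace."""

    species: str
    tracks: dict[str, SignalTrack] = field(default_factory=dict)

    def __getitem__(self, condition: str) -> SignalTrack:
        return self.tracks[condition]

    def __iter__(self):
        return iter(self.tracks)

    @property
    def conditions(self) -> list[str]:
        return list(self.tracks)


def read_track(path: str | Path, dialect: str = "bedgraph") -> SignalTrack:
    """Read a ``bedgraph`` (4-column) or fixed-step ``wig`` file.

    bedGraph intervals become point probes at ``(start + end) // 2``;
    overlapping intervals and duplicate positions are rejected, NaN values
    are an error, unsorted input is sorted with a warning.
    """
    dialect = dialect.lower()
    if dialect not in {"bedgraph", "wig"}:
        raise ValueError(f"unknown track dialect {dialect!r}")
    per_chrom: dict[str, tuple[list[int], list[float]]] = {}
    if dialect == "bedgraph":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) != 4:
                    raise TrackError(f"{path}:{lineno}: expected 4 columns")
                chrom, s, e, v = fields
                try:
                    start, end, value = int(s), int(e), float(v)
                except ValueError as exc:
                    raise TrackError(f"{path}:{lineno}: {exc}") from exc
                if end <= start:
                    raise TrackError(f"{path}:{lineno}: empty interval")
                if np.isnan(value):
                    raise TrackError(f"{path}:{lineno}: NaN value")
                intervals.setdefault(chrom, []).append((start, end))
                pos = (start + end) // 2
                ps, vs = per_chrom.setdefault(chrom, ([], []))
                ps.append(pos)
                vs.append(value)
        for chrom, ivs in intervals.items():
            ordered = sorted(ivs)
            if any(b[0] < a[1] for a, b in zip(ordered, ordered[1:])):
                raise TrackError(f"{path}: {chrom}: overlapping intervals")
    else:
        chrom = None
        step = span = 1
        nextpos = 0
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    params = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = params["chrom"]
                    nextpos = int(params["start"]) - 1  # wig is 1-based
                    step = int(params.get("step", 1))
                    span = int(params.get("span", 1))
                    per_chrom.setdefault(chrom, ([], []))
                    continue
                if chrom is None:
                    raise TrackError(f"{path}:{lineno}: value before fixedStep header")
                try:
                    value = float(line)
                except ValueError as exc:
                    raise TrackError(f"{path}:{lineno}: {exc}") from exc
                if np.isnan(value):
                    raise TrackError(f"{path}:{lineno}: NaN value")
                ps, vs = per_chrom[chrom]
                ps.append(nextpos + (span - 1) // 2)
                vs.append(value)
                nextpos += step
    track = SignalTrack()
    for chrom, (ps, vs) in per_chrom.items():
        track.add_chrom(chrom, np.array(ps, dtype=np.int64), np.array(vs))
    return track


def write_track(track: SignalTrack, path: str | Path, dialect: str = "bedgraph",
                probe_width: int = 1) -> None:
    """Writer mirroring :func:`read_track`.

    In bedGraph mode each probe becomes an interval of ``probe_width`` bp
    centred so that the interval midpoint floors back to the probe position.
    """
    dialect = dialect.lower()
    with open(path, "w") as fh:
        if dialect == "bedgraph":
            half = probe_width // 2
            for chrom, (pos, val) in track.data.items():
                starts = pos - half
                ends = starts + probe_width
                for s, e, v in zip(starts, ends, val):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.9g}\n")
        elif dialect == "wig":
            for chrom, (pos, val) in track.data.items():
                if pos.size == 0:
                    continue
                steps = np.unique(np.diff(pos))
                if steps.size > 1:
                    raise TrackError(f"{chrom}: irregular spacing, cannot write fixed-step wig")
                step = int(steps[0]) if steps.size else 1
                fh.write(f"fixedStep chrom={chrom} start={pos[0] + 1} step={step} span=1\n")
                fh.write("\n".join(f"{v:.9g}" for v in val) + "\n")
        else:
            raise ValueError(f"unknown track dialect {dialect!r}")


def median_normalize(trackset: TrackSet, mode: str = "additive") -> TrackSet:
    """Equalise per-track medians to the grand median of the input medians.

    ``additive`` shifts log-scale tracks; ``multiplicative`` rescales
    linear-scale tracks.  Idempotent, and order-preserving within each track.
    """
    if len(trackset.tracks) < 2:
        raise TrackError("median normalisation needs at least two tracks")
    medians = {}
    for cond, track in trackset.tracks.items():
        vals = track.all_values()
        if vals.size == 0:
            raise TrackError(f"track {cond!r} is empty")
        medians[cond] = float(np.median(vals))
    grand = float(np.median(list(medians.values())))
    out = TrackSet(trackset.species)
    for cond, track in trackset.tracks.items():
        if mode == "additive":
            shifted = track.shifted(grand - medians[cond])
        elif mode == "multiplicative":
            if medians[cond] == 0:
                raise TrackError(f"track {cond!r} has zero median; cannot rescale")
            shifted = track.scaled(grand / medians[cond])
        else:
            raise ValueError(f"unknown normalisation mode {mode!r}")
        shifted.species = track.species
        shifted.condition = track.condition
        out.tracks[cond] = shifted
    return out


def merge_tracks(tracks: Iterable[SignalTrack]) -> SignalTrack:
    """Per-position mean of tracks sharing identical probe grids (utility
    for pre-merging replicate cultures; the pipeline assumes merged input)."""
    tracks = list(tracks)
    if not tracks:
        raise TrackError("no tracks to merge")
    first = tracks[0]
    out = SignalTrack(first.species, first.condition)
    for chrom, (pos, _) in first.data.items():
        stack = []
        for t in tracks:
            if chrom not in t.data or not np.array_equal(t.data[chrom][0], pos):
                raise TrackError(f"{chrom}: probe grids differ between tracks")
            stack.append(t.data[chrom][1])
        out.data[chrom] = (pos, np.mean(stack, axis=0))
    return out
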