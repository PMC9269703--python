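"""Segmentation of the b&r recording into movement cycles.

Each repetition of the bending-and-return movement leaves one pronounced
minimum in the Acc Z channel of the T12 sensor (SENS1), the channel with the
highest signal-to-noise ratio: at deep flexion the sensor's Z axis points
away from gravity.  The five-step algorithm:

1. smooth Acc Z with a rolling centred mean (width 25 samples = 0.25 s);
2. threshold = global minimum + 40% of the global amplitude of the smoothed
   series;
3. keep only the contiguous runs strictly below the threshold, which
   suppresses shallow local minima above it;
4. take one minimum per run (its argmin) and place a cycle limit at the
   rounded mean position of each pair of consecutive minima;
5. resample every cycle (the stretch between consecutive limits) to a fixed
   number of points (450) by linear interpolation; the normalised within-
   cycle index is called "itime".

Because the threshold is relative to the signal's own amplitude, the
segmentation is invariant to adding a constant and to positive rescaling.
K detected minima give K - 1 cycle limits and hence K - 2 between-limit
cycles; samples before the first limit and after the last belong to partial
cycles and are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imu_io import Recording, SensorId

__all__ = [
    "SegmentationParams",
    "CycleSet",
    "NoCyclesError",
    "rolling_centered_mean",
    "segment_cycles",
    "detect_minima",
    "normalize_cycles",
    "mean_cycle",
]


class NoCyclesError(ValueError):
    """The signal does not contain enough detectable movement cycles."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the cycle-segmentation algorithm.

    window
        Rolling centred-mean width in samples (25 = 0.25 s at 100 Hz).
    threshold_frac
        Threshold as a fraction of the global amplitude above the minimum
        of the smoothed series (0.40).
    n_points
        Normalised cycle length after linear interpolation (450).
    """

    window: int = 25
    threshold_frac: float = 0.40
    n_points: int = 450

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if not 0 < self.threshold_frac < 1:
            raise ValueError(
                f"threshold_frac must lie in (0, 1), got {self.threshold_frac}"
            )
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")


@dataclass
class CycleSet:
    """Length-normalised cycles for every channel of one recording.

    ``cycles`` maps ``(sensor_id, channel)`` to an array of shape
    ``(n_cycles, n_points)``; ``boundaries`` are the cycle limits (sample
    indices into the trimmed recording) that delimit them.
    """

    boundaries: np.ndarray
    cycles: dict[tuple[SensorId, str], np.ndarray]
    n_points: int
    subject_id: str = ""
    group: str = ""

    @property
    def n_cycles(self) -> int:
        if self.cycles:
            return next(iter(self.cycles.values())).shape[0]
        return len(self.boundaries) - 1

    @property
    def itime(self) -> np.ndarray:
        return np.arange(self.n_points)

    def channel(self, sensor_id: SensorId | str, name: str) -> np.ndarray:
        return self.cycles[(SensorId(sensor_id), name)]

    def to_tidy(self):
        """Long-format table: subject, group, cycle, itime, channel, value."""
        import pandas as pd

        frames = []
        for (sid, name), arr in self.cycles.items():
            n_cycles, n_points = arr.shape
            frames.append(pd.DataFrame({
                "subject": self.subject_id,
                "group": self.group,
                "cycle": np.repeat(np.arange(n_cycles), n_points),
                "itime": np.tile(np.arange(n_points), n_cycles),
                "channel": f"{name} {sid.value}",
                "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path, *, sep: str = ",") -> None:
        self.to_tidy().to_csv(path, sep=sep, index=False)


def rolling_centered_mean(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with a symmetrically shrinking edge window.

    At index i the window is ``[i - h, i + h]`` with
    ``h = min((width - 1) // 2, i, n - 1 - i)``, so no samples are invented
    at the edges and the output length equals the input length.  Even widths
    use the next-lower odd width (a centred window needs symmetry).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    if width > n:
        raise ValueError(f"width {width} exceeds series length {n}")
    half = (width - 1) // 2
    if half == 0:
        return x.copy()
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_minima(
    acc_z: np.ndarray, params: SegmentationParams | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Steps 1-4a: smoothed series, per-run minima indices, and threshold."""
    p = params or SegmentationParams()
    x = np.asarray(acc_z, dtype=float)
    smoothed = rolling_centered_mean(x, p.window)
    lo = float(smoothed.min())
    hi = float(smoothed.max())
    threshold = lo + p.threshold_frac * (hi - lo)

    below = smoothed < threshold
    # Contiguous runs strictly below the threshold; one argmin per run
    # (earliest sample on ties).
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = [0] if below[0] else []
    starts += [int(e) + 1 for e in edges if below[e + 1]]
    ends = [int(e) + 1 for e in edges if below[e]]
    if below[-1]:
        ends.append(len(x))
    minima = np.array(
        [s + int(np.argmin(smoothed[s:e])) for s, e in zip(starts, ends)],
        dtype=int,
    )
    return smoothed, minima, threshold


def segment_cycles(
    acc_z: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Cycle limits (sample indices) from the SENS1 Acc Z series.

    Each limit is the rounded mean position of two consecutive detected
    minima (half-sample ties round down); K minima yield K - 1 limits.
    """
    _, minima, _ = detect_minima(acc_z, params)
    if len(minima) < 2:
        raise NoCyclesError(
            f"found {len(minima)} below-threshold minima; "
            "need at least 2 to delimit a cycle"
        )
    boundaries = (minima[:-1] + minima[1:]) // 2
    return boundaries.astype(int)


def normalize_cycles(
    rec: Recording,
    boundaries: np.ndarray,
    params: SegmentationParams | None = None,
    *,
    include_derived: bool = False,
) -> CycleSet:
    """Step 5: cut every channel at *boundaries*, resample to n_points.

    The same limits (from SENS1 Acc Z) are applied to every channel of every
    sensor.  Each cycle is linearly interpolated over its own duration onto
    a common n_points grid; degenerate cycles (< 2 samples) are skipped with
    a warning.
    """
    p = params or SegmentationParams()
    boundaries = np.asarray(boundaries, dtype=int)
    if len(boundaries) < 2:
        raise NoCyclesError("need at least 2 cycle limits to extract a cycle")

    keep = []
    for k in range(len(boundaries) - 1):
        if boundaries[k + 1] - boundaries[k] >= 2:
            keep.append(k)
        else:
            warnings.warn(
                f"cycle {k} has fewer than 2 samples; skipped", stacklevel=2
            )
    grid = np.linspace(0.0, 1.0, p.n_points)
    cycles: dict[tuple[SensorId, str], np.ndarray] = {}
    for sid, name, series in rec.iter_channels(include_derived=include_derived):
        out = np.empty((len(keep), p.n_points))
        for row, k in enumerate(keep):
            seg = series[boundaries[k]:boundaries[k + 1]]
            src = np.linspace(0.0, 1.0, len(seg))
            out[row] = np.interp(grid, src, seg)
        cycles[(sid, name)] = out
    used = np.array([boundaries[k] for k in keep] + [boundaries[keep[-1] + 1]]) \
        if keep else boundaries[:1]
    return CycleSet(
        boundaries=used,
        cycles=cycles,
        n_points=p.n_points,
        subject_id=rec.subject_id,
        group=rec.group.value,
    )


def mean_cycle(
    cycles: CycleSet, sensor_id: SensorId | str, channel: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SD across cycles at each itime.

    This is the summary drawn as a mean trace with an SD band; with a single
    cycle the SD is identically zero.
    """
    arr = cycles.channel(sensor_id, channel)
    if arr.shape[0] < 1:
        raise NoCyclesError("empty cycle set")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    return mean, sd


def segment_recording(
    rec: Recording, params: SegmentationParams | None = None,
    *, include_derived: bool = False,
) -> CycleSet:
    """Convenience: detect limits on SENS1 Acc Z, then normalise all channels."""
    acc_z = rec.channel(SensorId.SENS1, "Acc Z")
    boundaries = segment_cycles(acc_z, params)
    return normalize_cycles(rec, boundaries, params, include_derived=include_derived)
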