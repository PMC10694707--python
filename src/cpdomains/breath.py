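"""Breath-by-breath gas-exchange processing.

Pulmonary oxygen uptake (VO2) measured breath by breath is irregularly
sampled and noisy, so peak values are conventionally defined on short
time-bin averages rather than on raw breaths.  This module provides the
three primitives the rest of the package builds on:

* :func:`bin_series` — contiguous fixed-width (default 5 s) bin means,
  anchored at exercise onset (t = 0), with linear interpolation across
  empty interior bins (breath gaps longer than the bin width).
* :func:`peak_15s` — the highest 15-s VO2 average, computed as the maximum
  mean of three consecutive 5-s bins (rolling over bin boundaries).
* :func:`ppo_from_incremental` — peak power output of a staged incremental
  test, interpolating a partially completed final stage pro rata.

Windows for the 15-s peak start only at bin boundaries; arbitrary-offset
windows can be had by changing ``bin_width_s`` (e.g. 1-s bins with a
15-bin window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDurationError, InvalidInputError

__all__ = [
    "BreathSeries",
    "VO2Peak",
    "IncrementalResult",
    "bin_series",
    "peak_15s",
    "ppo_from_incremental",
]


@dataclass
class BreathSeries:
    """Timestamped oxygen-uptake samples from one exercise bout.

    Parameters
    ----------
    time_s : array_like
        Sample times in seconds from exercise onset (non-negative).
        Records are sorted on construction; ties are rejected.
    vo2_l_min : array_like
        Oxygen uptake in L·min⁻¹, strictly positive.
    """

    time_s: np.ndarray
    vo2_l_min: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.time_s, dtype=float))
        v = np.atleast_1d(np.asarray(self.vo2_l_min, dtype=float))
        if t.size == 0:
            raise InvalidInputError("breath series is empty")
        if t.shape != v.shape:
            raise InvalidInputError("time_s and vo2_l_min must have equal length")
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        if not np.all(np.isfinite(t)) or t[0] < 0:
            raise InvalidInputError("sample times must be finite and non-negative")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("sample times must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise InvalidInputError("VO2 samples must be finite and positive")
        self.time_s, self.vo2_l_min = t, v

    def __len__(self) -> int:
        return int(self.time_s.size)

    @property
    def span_s(self) -> float:
        """Time between the first and the last sample, in seconds."""
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class VO2Peak:
    """Highest windowed VO2 average of a bout.

    ``window_s`` records the averaging window (15 s unless configured).
    """

    value_l_min: float
    window_s: float = 15.0

    def __post_init__(self) -> None:
        if not (self.value_l_min > 0 and math.isfinite(self.value_l_min)):
            raise InvalidInputError("VO2 peak must be positive")
        if self.window_s <= 0:
            raise InvalidInputError("averaging window must be positive")


@dataclass
class IncrementalResult:
    """Outcome of a staged incremental test.

    ``stages`` holds (power_W, completed duration_s) per stage, the final
    stage possibly partial.  ``ppo_W`` is never below the last *completed*
    stage power.
    """

    ppo_W: float
    vo2peak: VO2Peak | None = None
    stages: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ppo_W <= 0:
            raise InvalidInputError("PPO must be positive")
        completed = [p for p, d in self.stages[:-1]] if len(self.stages) > 1 else []
        if completed and self.ppo_W < max(completed) - 1e-9:
            raise InvalidInputError("PPO below a completed stage power")


def bin_series(series: BreathSeries, bin_width_s: float = 5.0) -> BreathSeries:
    """Average a breath series into contiguous fixed-width bins.

    Bins are ``[0, w), [w, 2w), ...`` covering ``[0, last sample]``; a
    sample landing exactly on the final edge is kept in the last bin.
    Empty interior bins are filled by linear interpolation between the
    neighbouring bin means; empty leading/trailing bins are dropped.

    Returns
    -------
    BreathSeries
        One record per bin, timestamped at the bin centre.
    """
    if bin_width_s <= 0:
        raise InvalidInputError("bin_width_s must be positive")
    t, v = series.time_s, series.vo2_l_min
    last = t[-1]
    nbins = max(1, int(math.ceil(last / bin_width_s))) if last > 0 else 1
    idx = np.minimum((t / bin_width_s).astype(int), nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=v, minlength=nbins)
    centers = (np.arange(nbins) + 0.5) * bin_width_s
    filled = counts > 0
    means = np.full(nbins, np.nan)
    means[filled] = sums[filled] / counts[filled]
    nz = np.nonzero(filled)[0]
    lo, hi = nz[0], nz[-1]
    centers, means, filled = centers[lo : hi + 1], means[lo : hi + 1], filled[lo : hi + 1]
    if not filled.all():
        means[~filled] = np.interp(centers[~filled], centers[filled], means[filled])
    return BreathSeries(centers, means)


def peak_15s(
    series: BreathSeries, bin_width_s: float = 5.0, window_bins: int = 3
) -> VO2Peak:
    """Highest 15-s VO2 average from rolling means of 5-s bins.

    The peak is the maximum, over every run of ``window_bins`` consecutive
    bins, of the mean of the bin means.  Requires the series to span at
    least one full window (15 s at the defaults).
    """
    window_s = bin_width_s * window_bins
    if series.span_s < window_s - 1e-9:
        raise InsufficientDurationError(
            f"series spans {series.span_s:.1f} s; {window_s:.0f} s required"
        )
    binned = bin_series(series, bin_width_s)
    if len(binned) < window_bins:
        raise InsufficientDurationError(
            f"{len(binned)} bins available; {window_bins} required"
        )
    kernel = np.full(window_bins, 1.0 / window_bins)
    rolling = np.convolve(binned.vo2_l_min, kernel, mode="valid")
    return VO2Peak(float(rolling.max()), window_s=window_s)


def ppo_from_incremental(
    prev_stage_power_W: float,
    increment_W: float,
    final_stage_duration_s: float,
    stage_duration_s: float = 180.0,
) -> float:
    """Peak power output with pro-rata credit for a partial final stage.

    ``PPO = previous stage power + increment × duration / stage length``;
    a full final stage therefore yields the final stage's power and a
    zero-duration final stage yields the previous stage's power.
    """
    if increment_W <= 0:
        raise InvalidInputError("increment_W must be positive")
    if prev_stage_power_W < 0:
        raise InvalidInputError("prev_stage_power_W must be non-negative")
    if not 0 <= final_stage_duration_s <= stage_duration_s:
        raise InvalidInputError(
            f"final stage duration must lie in [0, {stage_duration_s:g}] s"
        )
    return prev_stage_power_W + increment_W * final_stage_duration_s / stage_duration_s
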