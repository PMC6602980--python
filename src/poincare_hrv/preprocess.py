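"""Standardization of heart-rate input to a uniform grid, and artifact filtering.

Every analysis in this package runs on a uniformly sampled instantaneous
heart-rate signal (default 1 Hz).  Uniform sampling matters for the lag-1
return map: the Poincaré pair (HR(t), HR(t+1)) is only well defined when the
time difference between successive samples is constant.  This module converts
beat annotations to instantaneous HR, resamples arbitrary sample streams onto
the grid by linear interpolation, and removes ectopic/noise samples by the
±20 % rule (a sample deviating more than 20 % from the most recent accepted
sample is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import EmptySeriesError, InsufficientDataError, ValidationError
from .io import BeatAnnotationSeries, RawHrSamples

__all__ = [
    "HeartRateSeries",
    "FilterConfig",
    "beats_to_instantaneous_hr",
    "resample_uniform",
    "filter_ectopic",
]


@dataclass(frozen=True)
class HeartRateSeries:
    """Uniformly sampled instantaneous heart rate with a validity mask.

    Sample ``k`` sits at ``start_time + k * sampling_interval`` seconds.
    Invalid samples (filtered artifacts) keep their stored value; only the
    mask changes, so the filtering step is non-destructive and auditable.
    """

    start_time: float
    sampling_interval: float
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid_mask", mask)
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be positive")
        if values.ndim != 1 or mask.shape != values.shape:
            raise ValidationError("values and valid_mask must be 1-D and equal length")
        valid_values = values[mask]
        if len(valid_values) and (
            not np.all(np.isfinite(valid_values)) or np.any(valid_values <= 0)
        ):
            raise ValidationError("valid heart-rate values must be finite and positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(len(self.values)) * self.sampling_interval

    @property
    def end_time(self) -> float:
        return self.start_time + (len(self.values) - 1) * self.sampling_interval

    @property
    def duration(self) -> float:
        """Elapsed time from first to last sample, in seconds."""
        return (len(self.values) - 1) * self.sampling_interval

    def to_raw_samples(self, source_label: str = "") -> RawHrSamples:
        """Export the valid samples as a (possibly gappy) raw sample stream."""
        mask = self.valid_mask
        return RawHrSamples(
            times=self.times[mask], values=self.values[mask], source_label=source_label
        )


@dataclass(frozen=True)
class FilterConfig:
    """Configuration of the relative-deviation artifact filter.

    ``relative_threshold`` is the exclusive rejection bound as a fraction of
    the reference value; the reference is always the most recent *accepted*
    sample, so an artifact never contaminates the reference.
    """

    relative_threshold: float = 0.20
    reference: str = "previous_accepted"

    def __post_init__(self) -> None:
        if not 0 < self.relative_threshold < 1:
            raise ValidationError("relative_threshold must be in (0, 1)")
        if self.reference != "previous_accepted":
            raise ValidationError("only 'previous_accepted' referencing is supported")


def beats_to_instantaneous_hr(beats: BeatAnnotationSeries) -> RawHrSamples:
    """Convert beat times to instantaneous heart rate.

    For each consecutive beat pair ``(t_i, t_{i+1})`` the rate
    ``60 / (t_{i+1} - t_i)`` bpm is assigned to the time of the *later*
    beat, keeping the estimate causal for streaming use.
    """
    if len(beats) < 2:
        raise InsufficientDataError("need at least 2 beats to estimate heart rate")
    intervals = np.diff(beats.beat_times)
    return RawHrSamples(times=beats.beat_times[1:], values=60.0 / intervals)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge samples use the truncated window."""
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def resample_uniform(
    samples: RawHrSamples, fs: float = 1.0, smooth_window: int = 0
) -> HeartRateSeries:
    """Resample onto a uniform grid by linear interpolation.

    The grid is ``t_k = t_first + k / fs`` for
    ``k = 0 .. floor((t_last - t_first) * fs)``; no extrapolation beyond the
    raw sample span.  ``smooth_window`` > 1 applies a centered moving average
    of that many points after interpolation (odd window required; edges use
    the truncated window), emulating smoothed instantaneous-rate conversion
    of annotation-derived signals.  All output samples are marked valid.
    """
    if len(samples) < 2:
        raise InsufficientDataError("need at least 2 samples to resample")
    if fs <= 0:
        raise ValidationError("fs must be positive")
    if smooth_window < 0 or (smooth_window > 1 and smooth_window % 2 == 0):
        raise ValidationError("smooth_window must be 0/1 (off) or an odd integer")
    t0 = samples.times[0]
    span = samples.times[-1] - t0
    n = int(np.floor(span * fs + 1e-9)) + 1
    grid = t0 + np.arange(n) / fs
    values = np.interp(grid, samples.times, samples.values)
    if smooth_window > 1:
        values = _moving_average(values, smooth_window)
    return HeartRateSeries(
        start_time=float(t0),
        sampling_interval=1.0 / fs,
        values=values,
        valid_mask=np.ones(n, dtype=bool),
    )


def filter_ectopic(
    series: HeartRateSeries, cfg: Optional[FilterConfig] = None
) -> HeartRateSeries:
    """Mask ectopic/noise samples by relative deviation from the last accepted value.

    Single forward pass over the valid samples: the first valid sample is
    always accepted and seeds the reference ``r``; a later valid sample ``x``
    is rejected iff ``|x - r| / r > relative_threshold`` (strict), and
    accepted samples update ``r``.  Already-invalid samples are skipped and
    stay invalid.  Values are untouched — only the mask changes.
    """
    if cfg is None:
        cfg = FilterConfig()
    if not np.any(series.valid_mask):
        raise EmptySeriesError("series has no valid samples to filter")
    mask = series.valid_mask.copy()
    reference: Optional[float] = None
    for i in np.flatnonzero(series.valid_mask):
        x = series.values[i]
        if reference is None:
            reference = x
            continue
        if abs(x - reference) / reference > cfg.relative_threshold:
            mask[i] = False
        else:
            reference = x
    return replace(series, valid_mask=mask)
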