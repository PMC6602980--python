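"""Sliding-window SD1/SD2 computation: batch traces and an online engine.

The real-time autonomic index is the sequence of SD1/SD2 descriptors computed
over a sliding window (default 20 s, stepping 5 s).  Two implementations share
identical window semantics:

* :func:`sliding_trace` — batch computation over a complete series;
* :class:`StreamEngine` — push samples one at a time; after buffering one full
  window it emits descriptors every step.  Its emissions are exactly
  (element-wise, bit-identically) those of the batch trace on the same data.

A window labelled with end time ``T`` covers the half-open interval
``(T - W, T]`` and contains the pairs whose *later* member falls inside it;
labelling at the window end is the causal choice for a live display.  Windows
with fewer than ``min_pairs`` valid pairs are reported as missing records, not
dropped, so a trace is always a regular time grid.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import OrderingError, ValidationError
from .poincare import PoincareDescriptors, PoincarePairs, _pairs_no_raise, sd_descriptors
from .preprocess import FilterConfig, HeartRateSeries

__all__ = [
    "WindowSpec",
    "TraceEmission",
    "SlidingWindowTrace",
    "sliding_trace",
    "StreamEngine",
    "window_length_sweep",
]

logger = logging.getLogger(__name__)

# Window lengths investigated for the resolution/noise trade-off; outside this
# range the descriptors are either too noisy or too sluggish to interpret.
INVESTIGATED_WINDOW_RANGE = (5.0, 120.0)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: length and step in seconds, emission gate."""

    window_length: float = 20.0
    step: float = 5.0
    min_pairs: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_length:
            raise ValidationError("require 0 < step <= window_length")
        if self.min_pairs < 2:
            raise ValidationError("min_pairs must be >= 2")
        lo, hi = INVESTIGATED_WINDOW_RANGE
        if not lo <= self.window_length <= hi:
            warnings.warn(
                f"window_length {self.window_length} s is outside the investigated "
                f"range [{lo}, {hi}] s; descriptor quality is uncharacterized",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TraceEmission:
    """One sliding-window emission: end-time label and (possibly missing) descriptors."""

    t_end: float
    descriptors: Optional[PoincareDescriptors]


@dataclass(frozen=True, eq=False)
class SlidingWindowTrace:
    """Regular sequence of sliding-window descriptor emissions."""

    t_end: np.ndarray
    descriptors: tuple[Optional[PoincareDescriptors], ...]
    spec: WindowSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_end", np.asarray(self.t_end, dtype=float))
        object.__setattr__(self, "descriptors", tuple(self.descriptors))
        if len(self.t_end) != len(self.descriptors):
            raise ValidationError("t_end and descriptors must have equal length")

    def __len__(self) -> int:
        return len(self.t_end)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SlidingWindowTrace):
            return NotImplemented
        return (
            self.spec == other.spec
            and np.array_equal(self.t_end, other.t_end)
            and self.descriptors == other.descriptors
        )

    @property
    def emissions(self) -> tuple[TraceEmission, ...]:
        return tuple(TraceEmission(t, d) for t, d in zip(self.t_end, self.descriptors))

    def to_frame(self):
        """Tabular view (pandas DataFrame) with NaN for missing windows."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t_end_s": self.t_end,
                "sd1_bpm": [d.sd1 if d else np.nan for d in self.descriptors],
                "sd2_bpm": [d.sd2 if d else np.nan for d in self.descriptors],
                "n_pairs": [d.n_pairs if d else 0 for d in self.descriptors],
            }
        )


def _emission_times(start: float, duration: float, spec: WindowSpec) -> np.ndarray:
    """Emission labels start + W + k*step, k = 0 .. floor((D - W)/step)."""
    if duration < spec.window_length:
        return np.empty(0)
    k_max = int(np.floor((duration - spec.window_length) / spec.step + 1e-9))
    return start + spec.window_length + np.arange(k_max + 1) * spec.step


def _window_descriptors(
    pair_times: Sequence[float],
    x: Sequence[float],
    y: Sequence[float],
    t_end: float,
    spec: WindowSpec,
) -> Optional[PoincareDescriptors]:
    lo = bisect.bisect_right(pair_times, t_end - spec.window_length)
    hi = bisect.bisect_right(pair_times, t_end)
    n = hi - lo
    if n < spec.min_pairs:
        return None
    window_pairs = PoincarePairs(
        x=np.asarray(x[lo:hi], dtype=float),
        y=np.asarray(y[lo:hi], dtype=float),
        pair_times=np.asarray(pair_times[lo:hi], dtype=float),
    )
    return sd_descriptors(window_pairs)


def sliding_trace(series: HeartRateSeries, spec: Optional[WindowSpec] = None) -> SlidingWindowTrace:
    """Batch sliding-window SD1/SD2 over a complete series.

    A series shorter than one window yields an empty trace (not an error).
    """
    if spec is None:
        spec = WindowSpec()
    t_ends = _emission_times(series.start_time, series.duration, spec)
    pairs = _pairs_no_raise(series)
    pt = list(pairs.pair_times)
    xs = list(pairs.x)
    ys = list(pairs.y)
    descriptors = [_window_descriptors(pt, xs, ys, t, spec) for t in t_ends]
    return SlidingWindowTrace(t_end=t_ends, descriptors=tuple(descriptors), spec=spec)


class StreamEngine:
    """Online SD1/SD2 engine with the batch window semantics.

    Push uniformly spaced samples in strictly increasing time order; nothing
    is emitted until one full window has been buffered (the initial delay
    equals the window length), after which one emission falls due per elapsed
    step.  The ±20 % artifact filter, when enabled, is applied online with the
    same previous-accepted reference rule as the batch
    :func:`~poincare_hrv.preprocess.filter_ectopic`.

    ``push`` returns the list of emissions that fell due with that sample
    (at most one under the default 1 Hz cadence).
    """

    def __init__(
        self,
        spec: Optional[WindowSpec] = None,
        filter_config: Optional[FilterConfig] = None,
        sampling_interval: float = 1.0,
    ) -> None:
        if sampling_interval <= 0:
            raise ValidationError("sampling_interval must be positive")
        self.spec = spec if spec is not None else WindowSpec()
        self.filter_config = filter_config
        self.sampling_interval = sampling_interval
        self._start: Optional[float] = None
        self._prev_time: Optional[float] = None
        self._prev_value = 0.0
        self._prev_valid = False
        self._reference: Optional[float] = None
        self._pair_times: list[float] = []
        self._pair_x: list[float] = []
        self._pair_y: list[float] = []
        self._next_k = 0
        self.emissions: list[TraceEmission] = []

    def push(self, time_s: float, hr_bpm: float) -> list[TraceEmission]:
        """Ingest one sample; return emissions that fell due."""
        if self._prev_time is not None and time_s <= self._prev_time:
            raise OrderingError(
                f"sample at t={time_s} not after previous t={self._prev_time}"
            )
        if self._start is None:
            self._start = time_s

        valid = True
        if self.filter_config is not None:
            if self._reference is None:
                self._reference = hr_bpm
            elif abs(hr_bpm - self._reference) / self._reference > self.filter_config.relative_threshold:
                valid = False
                logger.debug("filter rejected sample at t=%s (%.3f bpm)", time_s, hr_bpm)
            else:
                self._reference = hr_bpm

        if (
            self._prev_time is not None
            and self._prev_valid
            and valid
            and abs((time_s - self._prev_time) - self.sampling_interval) <= 1e-9
        ):
            self._pair_times.append(time_s)
            self._pair_x.append(self._prev_value)
            self._pair_y.append(hr_bpm)

        self._prev_time = time_s
        self._prev_value = hr_bpm
        self._prev_valid = valid

        spec = self.spec
        due: list[TraceEmission] = []
        while True:
            t_emit = self._start + spec.window_length + self._next_k * spec.step
            if t_emit > time_s + 1e-9 * spec.step:
                break
            desc = _window_descriptors(
                self._pair_times, self._pair_x, self._pair_y, t_emit, spec
            )
            emission = TraceEmission(t_end=t_emit, descriptors=desc)
            due.append(emission)
            self.emissions.append(emission)
            logger.info("emission t=%s sd1=%s sd2=%s", t_emit,
                        getattr(desc, "sd1", None), getattr(desc, "sd2", None))
            self._next_k += 1
        return due

    def trace(self) -> SlidingWindowTrace:
        """All emissions so far as a :class:`SlidingWindowTrace`."""
        return SlidingWindowTrace(
            t_end=np.asarray([e.t_end for e in self.emissions]),
            descriptors=tuple(e.descriptors for e in self.emissions),
            spec=self.spec,
        )


def window_length_sweep(
    series: HeartRateSeries,
    lengths: Iterable[float],
    step: float = 5.0,
    min_pairs: int = 3,
) -> dict[float, SlidingWindowTrace]:
    """One sliding trace per window length, for side-by-side comparison.

    Used to study the resolution/noise trade-off across window lengths
    (e.g. 5–120 s): short windows emit more often but from few pairs, long
    windows smooth heavily at the cost of time resolution.
    """
    result: dict[float, SlidingWindowTrace] = {}
    for length in lengths:
        spec = WindowSpec(window_length=float(length), step=step, min_pairs=min_pairs)
        result[float(length)] = sliding_trace(series, spec)
    return result
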