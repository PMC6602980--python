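"""Poincaré (lag-1 return map) construction and SD1/SD2 ellipse descriptors.

The Poincaré plot scatters each heart-rate value HR(t) against the next one
HR(t+1).  Fitting an ellipse oriented along the line of identity (x = y)
summarizes the cloud with two dispersions:

* **SD1** — spread perpendicular to the identity line: short-term,
  beat-to-beat variability.  With d_i = x_i - y_i, SD1 = sqrt(Var(d) / 2).
* **SD2** — spread along the identity line: longer-term variability.  With
  s_i = x_i + y_i, SD2 = sqrt(Var(s) / 2).

Variances are unbiased sample variances (n - 1 denominator).  Equivalently,
SD1 and SD2 are the standard deviations of the point cloud after rotating it
by 45°, i.e. of (x - y)/sqrt(2) and (x + y)/sqrt(2); that equivalent form is
used as an independent cross-check in the test suite, never here.

Physiological attributions of SD1/SD2 to sympathetic versus parasympathetic
tone differ between sources; this module reports the descriptors numerically
and encodes no such mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InsufficientDataError
from .preprocess import HeartRateSeries

__all__ = [
    "PoincarePairs",
    "PoincareDescriptors",
    "PoincareEllipse",
    "make_pairs",
    "sd_descriptors",
    "ellipse_geometry",
]


@dataclass(frozen=True)
class PoincarePairs:
    """Lag-1 pairs (x, y) = (HR(t), HR(t+1)) with the time of the later member."""

    x: np.ndarray
    y: np.ndarray
    pair_times: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "pair_times"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.x) == len(self.y) == len(self.pair_times)):
            raise ValueError("x, y, pair_times must have equal length")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class PoincareDescriptors:
    """SD1/SD2 ellipse descriptors of one window of Poincaré pairs.

    ``ratio`` (SD1/SD2) is ``None`` when SD2 is zero (degenerate cloud).
    """

    sd1: float
    sd2: float
    ratio: Optional[float]
    centroid_x: float
    centroid_y: float
    n_pairs: int


@dataclass(frozen=True)
class PoincareEllipse:
    """Geometry of the fitted ellipse: center, semi-axes, orientation.

    The semi-axis along the identity line has length SD2, the perpendicular
    one SD1; the orientation is fixed at 45° to the x-axis by construction.
    """

    center: tuple[float, float]
    semi_axis_identity: float
    semi_axis_perpendicular: float
    orientation_deg: float = 45.0

    def outline(self, n_points: int = 200) -> np.ndarray:
        """Sample the ellipse boundary (n_points, 2), for plotting."""
        theta = np.linspace(0.0, 2.0 * np.pi, n_points)
        u = self.semi_axis_identity * np.cos(theta)
        v = self.semi_axis_perpendicular * np.sin(theta)
        c = np.cos(np.deg2rad(self.orientation_deg))
        s = np.sin(np.deg2rad(self.orientation_deg))
        xs = self.center[0] + u * c - v * s
        ys = self.center[1] + u * s + v * c
        return np.column_stack([xs, ys])


def make_pairs(series: HeartRateSeries) -> PoincarePairs:
    """Form lag-1 pairs from adjacent valid grid samples.

    A pair is formed for every adjacent index pair (i, i+1) where both
    samples are valid; filtered samples break adjacency, so no pair spans a
    removed artifact.
    """
    pairs = _pairs_no_raise(series)
    if len(pairs) < 1:
        raise InsufficientDataError("fewer than 2 valid adjacent samples; no pairs")
    return pairs


def _pairs_no_raise(series: HeartRateSeries) -> PoincarePairs:
    mask = series.valid_mask
    both = mask[:-1] & mask[1:]
    idx = np.flatnonzero(both)
    times = series.times
    return PoincarePairs(
        x=series.values[idx], y=series.values[idx + 1], pair_times=times[idx + 1]
    )


def sd_descriptors(pairs: PoincarePairs) -> PoincareDescriptors:
    """Compute SD1/SD2 descriptors from a set of Poincaré pairs.

    Requires at least 2 pairs (sample variance undefined below that).
    """
    n = len(pairs)
    if n < 2:
        raise InsufficientDataError("need at least 2 pairs for SD1/SD2")
    d = pairs.x - pairs.y
    s = pairs.x + pairs.y
    sd1 = float(np.sqrt(np.var(d, ddof=1) / 2.0))
    sd2 = float(np.sqrt(np.var(s, ddof=1) / 2.0))
    ratio = sd1 / sd2 if sd2 > 0 else None
    return PoincareDescriptors(
        sd1=sd1,
        sd2=sd2,
        ratio=ratio,
        centroid_x=float(np.mean(pairs.x)),
        centroid_y=float(np.mean(pairs.y)),
        n_pairs=n,
    )


def ellipse_geometry(desc: PoincareDescriptors) -> PoincareEllipse:
    """Ellipse parameters implied by a descriptor set."""
    return PoincareEllipse(
        center=(desc.centroid_x, desc.centroid_y),
        semi_axis_identity=desc.sd2,
        semi_axis_perpendicular=desc.sd1,
    )
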