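"""Reading and writing of heart-rate samples, beat annotations, and SD1/SD2 traces.

All on-disk formats are plain text: comma-separated with a mandatory header,
``.`` decimal separator, UTF-8.  Times are seconds from recording start.  The
one binary format supported is the MIT annotation format (read-only, beat-time
extraction only), so that beat files distributed with public ECG databases can
be consumed directly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, FormatError, OrderingError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .streaming import SlidingWindowTrace

__all__ = [
    "RawHrSamples",
    "BeatAnnotationSeries",
    "read_hr_csv",
    "write_hr_csv",
    "read_beat_annotations",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass(frozen=True)
class RawHrSamples:
    """A possibly non-uniform heart-rate sample stream.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, non-negative.
    values
        Heart rate in beats per minute; finite and positive.
    source_label
        Free-text provenance (file name, device, subject id).
    """

    times: np.ndarray
    values: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValidationError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise ValidationError("times and values must have equal length")
        if len(times) and times[0] < 0:
            raise ValidationError("sample times must be non-negative")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise OrderingError("sample times must be strictly increasing")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValidationError("heart-rate values must be finite and positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class BeatAnnotationSeries:
    """Ordered beat occurrence times, optionally labelled.

    Labels follow the convention ``normal`` / ``ectopic`` / ``unknown``.
    """

    beat_times: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        beat_times = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", beat_times)
        if beat_times.ndim != 1:
            raise ValidationError("beat_times must be one-dimensional")
        if len(beat_times) > 1 and not np.all(np.diff(beat_times) > 0):
            raise OrderingError("beat times must be strictly increasing")
        if self.labels is not None and len(self.labels) != len(beat_times):
            raise ValidationError("labels must match beat_times in length")

    def __len__(self) -> int:
        return len(self.beat_times)


def read_hr_csv(path: str | Path) -> RawHrSamples:
    """Read a heart-rate CSV with columns ``time_s`` and ``hr_bpm``.

    Rows are sorted by time; duplicate timestamps, non-finite or
    non-positive heart rates are rejected.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not a parseable CSV: {exc}") from exc
    for col in ("time_s", "hr_bpm"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    frame = frame.sort_values("time_s", kind="stable")
    times = frame["time_s"].to_numpy(dtype=float)
    if len(times) > 1 and np.any(np.diff(times) == 0):
        raise ValidationError(f"{path}: duplicate timestamps")
    return RawHrSamples(
        times=times,
        values=frame["hr_bpm"].to_numpy(dtype=float),
        source_label=str(path),
    )


def write_hr_csv(samples: RawHrSamples, path: str | Path) -> None:
    """Write heart-rate samples as a ``time_s,hr_bpm`` CSV (6 decimal places)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "hr_bpm"])
        for t, v in zip(samples.times, samples.values):
            writer.writerow([f"{t:.6f}", f"{v:.6f}"])


# MIT annotation type codes that denote a detected beat (QRS), per the
# published annotation code table.  Code 1 is a normal beat; 13 is a beat of
# unknown origin; the remainder are aberrant/ectopic beat classes.
_BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 30, 31, 34, 35, 38, 41})
_NORMAL_CODE = 1
_UNKNOWN_CODE = 13
# Pseudo-annotation codes that carry side information rather than an event.
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _read_mit_annotations(path: Path, sampling_frequency: float) -> BeatAnnotationSeries:
    """Decode an MIT-format annotation file, keeping beat annotations only.

    Each annotation is a 16-bit little-endian word: the high 6 bits are the
    annotation type code, the low 10 bits the time increment in samples.
    Pseudo-annotations (SKIP/NUM/SUB/CHN/AUX) are consumed and discarded;
    non-beat event annotations advance time but emit no beat.
    """
    data = path.read_bytes()
    times_samples: list[int] = []
    labels: list[str] = []
    t = 0
    i = 0
    n = len(data)
    while i + 1 < n:
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = (word >> 10) & 0x3F
        delta = word & 0x3FF
        if code == 0 and delta == 0:  # end of annotations
            break
        if code == _SKIP:
            if i + 3 >= n:
                raise FormatError(f"{path}: truncated SKIP pseudo-annotation")
            high = data[i] | (data[i + 1] << 8)
            low = data[i + 2] | (data[i + 3] << 8)
            i += 4
            long_delta = (high << 16) | low
            if long_delta >= 1 << 31:  # signed 32-bit
                long_delta -= 1 << 32
            t += long_delta
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += delta + (delta & 1)  # aux string, padded to even length
            continue
        t += delta
        if code in _BEAT_CODES:
            times_samples.append(t)
            if code == _NORMAL_CODE:
                labels.append("normal")
            elif code == _UNKNOWN_CODE:
                labels.append("unknown")
            else:
                labels.append("ectopic")
    if not times_samples:
        raise EmptySeriesError(f"{path}: no beat annotations found")
    beat_times = np.asarray(times_samples, dtype=float) / sampling_frequency
    return BeatAnnotationSeries(beat_times=beat_times, labels=labels)


def read_beat_annotations(
    path: str | Path,
    dialect: str = "plain",
    *,
    sampling_frequency: float = 250.0,
) -> BeatAnnotationSeries:
    """Read beat occurrence times from a file.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"plain"``: one beat time (seconds) per line; blank lines and lines
        starting with ``#`` are ignored.  ``"wfdb"``: MIT annotation format;
        only beat annotations are kept, all other content is discarded.
    sampling_frequency
        Samples per second of the record the annotations refer to (wfdb
        dialect only); converts annotation sample indices to seconds.
    """
    path = Path(path)
    if dialect == "wfdb":
        return _read_mit_annotations(path, sampling_frequency)
    if dialect != "plain":
        raise ValueError(f"unknown dialect {dialect!r}")
    times: list[float] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            times.append(float(line))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: not a number: {line!r}") from exc
    if not times:
        raise EmptySeriesError(f"{path}: no beat times found")
    return BeatAnnotationSeries(beat_times=np.asarray(times, dtype=float))


def write_trace_csv(trace: "SlidingWindowTrace", path: str | Path) -> None:
    """Write a sliding-window trace as CSV.

    Columns are ``t_end_s, sd1_bpm, sd2_bpm, n_pairs``; windows with missing
    descriptors are written with empty value fields so the time grid stays
    regular.  Values carry 6 decimal places and round-trip through
    :func:`read_trace_csv` to that precision.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_end_s", "sd1_bpm", "sd2_bpm", "n_pairs"])
        for t_end, desc in zip(trace.t_end, trace.descriptors):
            if desc is None:
                writer.writerow([f"{t_end:.6f}", "", "", ""])
            else:
                writer.writerow(
                    [f"{t_end:.6f}", f"{desc.sd1:.6f}", f"{desc.sd2:.6f}", desc.n_pairs]
                )


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    """Read a trace CSV back into a DataFrame (missing windows become NaN)."""
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("t_end_s", "sd1_bpm", "sd2_bpm", "n_pairs"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return frame
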