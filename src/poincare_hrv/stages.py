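"""Stage extraction and pre-/during-anesthesia comparison of SD1/SD2.

Two stages are cut from each continuous heart-rate recording: a baseline
segment of 150–300 s immediately preceding anesthetic induction ("stage 1")
and a 300 s maintenance segment within minutes 15–30 of surgery ("stage 2";
for resting controls the analogous windows are minutes 0–5 and 15–20).  Per
subject, SD1 and SD2 are computed for each stage; across subjects each metric
is summarized (mean, median, IQR) per stage and the two stages are compared
with a two-sided Mann–Whitney–Wilcoxon rank-sum test.

Quartiles use linear interpolation (so reported IQRs are reproducible); the
rank-sum test uses exact null enumeration when both groups have at most 8
observations and there are no ties, and otherwise the normal approximation
with midranks, tie correction, and continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError, WindowRangeError
from .poincare import PoincareDescriptors, make_pairs, sd_descriptors
from .preprocess import FilterConfig, HeartRateSeries, filter_ectopic

__all__ = [
    "StageSpec",
    "SummaryStats",
    "RankSumResult",
    "MetricComparison",
    "StageComparisonReport",
    "extract_stage",
    "summarize",
    "rank_sum_test",
    "compare_stages",
    "stage_descriptors",
    "cohort_report",
]

logger = logging.getLogger(__name__)

STAGE1_MIN_LENGTH = 150.0
STAGE1_MAX_LENGTH = 300.0
STAGE2_LENGTH = 300.0


@dataclass(frozen=True)
class StageSpec:
    """Absolute time windows (seconds from recording start) of the two stages."""

    stage1_window: Tuple[float, float]
    stage2_window: Tuple[float, float]

    def __post_init__(self) -> None:
        s1a, s1b = self.stage1_window
        s2a, s2b = self.stage2_window
        _check_stage_length("stage1", s1b - s1a)
        _check_stage_length("stage2", s2b - s2a)
        if max(s1a, s2a) < min(s1b, s2b):
            raise ValidationError("stage windows must not overlap")


def _check_stage_length(role: str, length: float) -> None:
    if role == "stage1":
        if not STAGE1_MIN_LENGTH <= length <= STAGE1_MAX_LENGTH:
            raise ValidationError(
                f"stage-1 window must be {STAGE1_MIN_LENGTH:.0f}-{STAGE1_MAX_LENGTH:.0f} s "
                f"long, got {length:.1f} s"
            )
    elif role == "stage2":
        if abs(length - STAGE2_LENGTH) > 1e-9:
            raise ValidationError(
                f"stage-2 window must be exactly {STAGE2_LENGTH:.0f} s long, got {length:.1f} s"
            )
    elif role is not None:
        raise ValueError(f"unknown stage role {role!r}")


@dataclass(frozen=True)
class SummaryStats:
    """Mean / median / IQR of a set of per-subject descriptor values."""

    mean: float
    median: float
    iqr: float
    n: int


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Mann–Whitney–Wilcoxon result (U of the first group)."""

    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"


@dataclass(frozen=True)
class MetricComparison:
    stage1: SummaryStats
    stage2: SummaryStats
    test: RankSumResult
    significant: bool


@dataclass(frozen=True)
class StageComparisonReport:
    """Per-metric stage summaries and tests, in the layout of a two-stage table."""

    metrics: Mapping[str, MetricComparison]
    alpha: float
    n_subjects: int
    excluded_subjects: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        out: dict = {
            "alpha": self.alpha,
            "n_subjects": self.n_subjects,
            "excluded_subjects": list(self.excluded_subjects),
            "metrics": {},
        }
        for name, cmp_ in self.metrics.items():
            out["metrics"][name] = {
                "stage1": vars(cmp_.stage1),
                "stage2": vars(cmp_.stage2),
                "u_statistic": cmp_.test.u_statistic,
                "p_value": cmp_.test.p_value,
                "test_method": cmp_.test.method,
                "significant": cmp_.significant,
            }
        return out

    def format_table(self) -> str:
        """Human-readable two-stage table, one block per metric."""
        lines = [
            f"{'':24s}{'Mean':>8s}{'Median':>8s}{'IQR':>8s}{'p':>10s}",
        ]
        for name, cmp_ in self.metrics.items():
            star = "*" if cmp_.significant else ""
            p_txt = f"{cmp_.test.p_value:.3g}{star}"
            lines.append(f"{name.upper()}")
            lines.append(
                f"  Stage 1 (baseline)    {cmp_.stage1.mean:8.2f}{cmp_.stage1.median:8.2f}"
                f"{cmp_.stage1.iqr:8.2f}{p_txt:>10s}"
            )
            lines.append(
                f"  Stage 2 (maintenance) {cmp_.stage2.mean:8.2f}{cmp_.stage2.median:8.2f}"
                f"{cmp_.stage2.iqr:8.2f}"
            )
        lines.append(f"n = {self.n_subjects} subjects; * p < {self.alpha:g} "
                     "(two-sided Mann-Whitney-Wilcoxon)")
        return "\n".join(lines)


def extract_stage(
    series: HeartRateSeries,
    window: Tuple[float, float],
    role: Optional[str] = None,
) -> HeartRateSeries:
    """Cut a sub-series on the same grid, restricted to [start_s, end_s].

    ``role`` ("stage1" / "stage2") additionally enforces the stage-length
    rules.  The validity mask is carried over unchanged.
    """
    start_s, end_s = window
    if end_s <= start_s:
        raise ValidationError("window end must be after window start")
    if role is not None:
        _check_stage_length(role, end_s - start_s)
    if start_s < series.start_time - 1e-9 or end_s > series.end_time + 1e-9:
        raise WindowRangeError(
            f"window [{start_s}, {end_s}] outside recording "
            f"[{series.start_time}, {series.end_time}]"
        )
    dt = series.sampling_interval
    i0 = int(np.ceil((start_s - series.start_time) / dt - 1e-9))
    i1 = int(np.floor((end_s - series.start_time) / dt + 1e-9))
    return HeartRateSeries(
        start_time=series.start_time + i0 * dt,
        sampling_interval=dt,
        values=series.values[i0 : i1 + 1],
        valid_mask=series.valid_mask[i0 : i1 + 1],
    )


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, median (midpoint), and IQR with linear-interpolation quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("cannot summarize an empty value list")
    q1, q3 = np.percentile(arr, [25.0, 75.0])  # linear interpolation
    return SummaryStats(
        mean=float(np.mean(arr)),
        median=float(np.median(arr)),
        iqr=float(q3 - q1),
        n=int(arr.size),
    )


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> Tuple[int, ...]:
    """Null distribution of the Mann-Whitney U statistic as counts over u=0..m*n.

    Classic recurrence N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1):
    the largest pooled observation belongs either to the first group
    (contributing n to U) or to the second.
    """
    if m == 0 or n == 0:
        return (1,)
    a = _u_counts(m - 1, n)
    b = _u_counts(m, n - 1)
    total = m * n
    out = [0] * (total + 1)
    for u, c in enumerate(a):  # largest value in group 1: U gains n
        out[u + n] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> RankSumResult:
    """Two-sided Mann–Whitney–Wilcoxon rank-sum test.

    Exact null enumeration when both groups have <= 8 observations and the
    pooled sample has no ties; otherwise the normal approximation with
    midranks, tie correction, and continuity correction.  Returns the U
    statistic of ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(np.sum(ranks[: a.size]) - a.size * (a.size + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < pooled.size
    if not has_ties and a.size <= 8 and b.size <= 8:
        counts = _u_counts(int(a.size), int(b.size))
        total = sum(counts)
        u_min = min(u_a, a.size * b.size - u_a)
        cdf = sum(counts[: int(round(u_min)) + 1])
        p = min(1.0, 2.0 * cdf / total)
        return RankSumResult(u_statistic=u_a, p_value=p, method="exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(u_statistic=u_a, p_value=float(res.pvalue), method="normal_approx")


def compare_stages(
    per_subject: Mapping[str, Tuple[Optional[PoincareDescriptors], Optional[PoincareDescriptors]]],
    alpha: float = 0.05,
) -> StageComparisonReport:
    """Build the two-stage comparison report from per-subject descriptors.

    Subjects missing either stage are excluded with a logged warning.  At
    least 2 complete subjects are required.
    """
    complete: dict[str, Tuple[PoincareDescriptors, PoincareDescriptors]] = {}
    excluded: list[str] = []
    for subject, (d1, d2) in per_subject.items():
        if d1 is None or d2 is None:
            excluded.append(str(subject))
            logger.warning("subject %s missing a stage; excluded from comparison", subject)
        else:
            complete[str(subject)] = (d1, d2)
    if len(complete) < 2:
        raise InsufficientDataError("need at least 2 subjects with both stages")
    metrics: dict[str, MetricComparison] = {}
    for metric in ("sd1", "sd2"):
        stage1_vals = [getattr(d1, metric) for d1, _ in complete.values()]
        stage2_vals = [getattr(d2, metric) for _, d2 in complete.values()]
        test = rank_sum_test(stage1_vals, stage2_vals)
        metrics[metric] = MetricComparison(
            stage1=summarize(stage1_vals),
            stage2=summarize(stage2_vals),
            test=test,
            significant=test.p_value < alpha,
        )
    return StageComparisonReport(
        metrics=metrics,
        alpha=alpha,
        n_subjects=len(complete),
        excluded_subjects=tuple(excluded),
    )


def stage_descriptors(
    series: HeartRateSeries,
    stage1_window: Tuple[float, float],
    stage2_window: Tuple[float, float],
    filter_config: Optional[FilterConfig] = None,
) -> Tuple[Optional[PoincareDescriptors], Optional[PoincareDescriptors]]:
    """Per-stage SD1/SD2 for one subject: extract, artifact-filter, describe.

    The artifact filter is applied within each extracted stage (its reference
    seeds from the stage's first sample).  A stage that cannot yield
    descriptors (out of range, too few pairs) is returned as ``None``.
    """
    if filter_config is None:
        filter_config = FilterConfig()
    out: list[Optional[PoincareDescriptors]] = []
    for window, role in ((stage1_window, "stage1"), (stage2_window, "stage2")):
        try:
            stage = extract_stage(series, window, role=role)
            filtered = filter_ectopic(stage, filter_config)
            out.append(sd_descriptors(make_pairs(filtered)))
        except (InsufficientDataError, WindowRangeError) as exc:
            logger.warning("stage %s unusable: %s", role, exc)
            out.append(None)
    return out[0], out[1]


def cohort_report(
    recordings: Mapping[str, HeartRateSeries],
    stage_windows: Mapping[str, StageSpec],
    alpha: float = 0.05,
    filter_config: Optional[FilterConfig] = None,
) -> StageComparisonReport:
    """Full cohort pipeline: per-subject stage descriptors, then comparison."""
    per_subject = {}
    for subject, series in recordings.items():
        spec = stage_windows[subject]
        per_subject[subject] = stage_descriptors(
            series, spec.stage1_window, spec.stage2_window, filter_config
        )
    return compare_stages(per_subject, alpha=alpha)
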