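"""Synthetic heart-rate generation with controlled Poincaré structure.

The generator produces instantaneous heart rate directly on the analysis grid
(default 1 Hz) as

    HR_t = baseline + A * sin(2*pi*f_rsa*t + phi) + e_t,

where ``e`` is a stationary first-order autoregressive (AR(1)) process with
stationary standard deviation sigma and lag-1 autocorrelation rho, and the
sinusoid is a respiratory-sinus-arrhythmia surrogate.  AR(1) noise is the
minimal model whose SD1 and SD2 are independently tunable: for the pure AR(1)
case the population descriptors are

    SD1 = sigma * sqrt(1 - rho),    SD2 = sigma * sqrt(1 + rho),

so rho sets the SD1/SD2 aspect ratio and sigma the overall size — a
closed-form oracle for the estimators.  An anesthesia induction is emulated
by multiplying all deviations from baseline after a known time t0 by a
suppression factor f in (0, 1], reproducing the abrupt collapse of both SD1
and SD2 seen at induction.

Default resting parameters (sigma = 3.9 bpm, rho = 0.85) are chosen so that
the population SD1/SD2 (~1.5 / ~5.3 bpm) sit in the range reported for young
resting adults; RSA defaults to 2 bpm at 0.25 Hz (15 breaths/min).  All
generation is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import UnsupportedConfigError, ValidationError, WindowRangeError
from .io import write_hr_csv
from .preprocess import HeartRateSeries

__all__ = [
    "SyntheticConfig",
    "TransitionConfig",
    "Cohort",
    "generate_hr",
    "expected_descriptors",
    "inject_transition",
    "inject_ectopics",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Resting heart-rate generator parameters.

    duration: recording length in seconds (the stage-2 window at minutes
    15-20 needs at least 1200 s, hence the default).
    noise_sd: stationary SD sigma of the AR(1) component, bpm.
    lag1_autocorr: rho in (-1, 1).
    rsa_amplitude / rsa_freq: respiratory sinusoid, bpm and Hz.
    """

    duration: float = 1200.0
    fs: float = 1.0
    baseline_hr: float = 70.0
    noise_sd: float = 3.9
    lag1_autocorr: float = 0.85
    rsa_amplitude: float = 2.0
    rsa_freq: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not -1 < self.lag1_autocorr < 1:
            raise ValidationError("lag1_autocorr must be in (-1, 1)")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.duration < 2.0 / self.fs:
            raise ValidationError("duration must cover at least 2 samples")
        if self.baseline_hr <= 0:
            raise ValidationError("baseline_hr must be positive")
        if self.rsa_amplitude < 0:
            raise ValidationError("rsa_amplitude must be >= 0")
        if self.rsa_amplitude > 0 and not 0 < self.rsa_freq < self.fs / 2:
            raise ValidationError("rsa_freq must lie in (0, fs/2) to be representable")


@dataclass(frozen=True)
class TransitionConfig:
    """Anesthesia-induction emulation: variability suppression at time t0."""

    t0: float = 300.0
    suppression_factor: float = 0.3
    baseline_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.suppression_factor <= 1:
            raise ValidationError("suppression_factor must be in (0, 1]")


def generate_hr(cfg: SyntheticConfig) -> HeartRateSeries:
    """Generate a resting heart-rate series (all samples valid).

    The AR(1) component is initialized from its stationary distribution, so
    the series is stationary from the first sample; the RSA phase is drawn
    from the seeded generator.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(np.floor(cfg.duration * cfg.fs + 1e-9)) + 1
    t = np.arange(n) / cfg.fs
    phi = rng.uniform(0.0, 2.0 * np.pi)
    rsa = cfg.rsa_amplitude * np.sin(2.0 * np.pi * cfg.rsa_freq * t + phi)
    z = rng.standard_normal(n)
    rho = cfg.lag1_autocorr
    # x[0] ~ N(0, sigma^2); innovations sigma*sqrt(1-rho^2) keep SD stationary.
    innovations = cfg.noise_sd * np.sqrt(1.0 - rho * rho) * z
    innovations[0] = cfg.noise_sd * z[0]
    noise = lfilter([1.0], [1.0, -rho], innovations)
    values = cfg.baseline_hr + rsa + noise
    if np.any(values <= 0):
        raise ValidationError(
            "generated heart rate is non-positive; reduce noise_sd/rsa_amplitude "
            "or raise baseline_hr"
        )
    return HeartRateSeries(
        start_time=0.0,
        sampling_interval=1.0 / cfg.fs,
        values=values,
        valid_mask=np.ones(n, dtype=bool),
    )


def expected_descriptors(cfg: SyntheticConfig) -> Tuple[float, float]:
    """Population SD1/SD2 of the pure-AR(1) generator (closed form).

    For a stationary process with variance sigma^2 and lag-1 autocorrelation
    rho, Var(x_t - x_{t+1})/2 = sigma^2 (1 - rho) and
    Var(x_t + x_{t+1})/2 = sigma^2 (1 + rho), hence
    SD1 = sigma*sqrt(1 - rho) and SD2 = sigma*sqrt(1 + rho).  Only stated for
    rsa_amplitude == 0 (a sinusoid adds a frequency-dependent, non-AR term).
    """
    if cfg.rsa_amplitude != 0:
        raise UnsupportedConfigError("closed form requires rsa_amplitude == 0")
    sigma, rho = cfg.noise_sd, cfg.lag1_autocorr
    return sigma * np.sqrt(1.0 - rho), sigma * np.sqrt(1.0 + rho)


def inject_transition(
    series: HeartRateSeries,
    cfg: TransitionConfig,
    baseline: Optional[float] = None,
) -> HeartRateSeries:
    """Suppress variability after t0: deviations from baseline scaled by f.

    For samples at t > t0, ``value -> baseline + f*(value - baseline) +
    baseline_shift``; earlier samples are untouched.  ``baseline`` defaults
    to the mean of the valid samples at t <= t0 when the generator's true
    baseline is not supplied.
    """
    times = series.times
    if not series.start_time <= cfg.t0 <= series.end_time:
        raise WindowRangeError(f"t0={cfg.t0} outside recording span")
    post = times > cfg.t0
    if baseline is None:
        pre_valid = series.valid_mask & ~post
        baseline = float(np.mean(series.values[pre_valid]))
    values = series.values.copy()
    values[post] = (
        baseline
        + cfg.suppression_factor * (values[post] - baseline)
        + cfg.baseline_shift
    )
    return replace(series, values=values)


def inject_ectopics(
    series: HeartRateSeries,
    rate: float,
    magnitude: float,
    seed: int,
) -> Tuple[HeartRateSeries, np.ndarray]:
    """Multiply randomly selected samples by (1 + magnitude); return ground truth.

    Index 0 is never selected: the artifact filter accepts the first valid
    sample unconditionally (it seeds the reference), so a spike there could
    not be rejected and would corrupt the reference instead.
    """
    if not 0 <= rate < 0.5:
        raise ValidationError("rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = len(series)
    selected = np.flatnonzero(rng.random(n) < rate)
    selected = selected[selected > 0]
    values = series.values.copy()
    values[selected] *= 1.0 + magnitude
    return replace(series, values=values), selected


@dataclass(frozen=True)
class Cohort:
    """Per-subject synthetic recordings plus the manifest describing them."""

    recordings: dict[str, HeartRateSeries]
    manifest: pd.DataFrame
    resting_config: SyntheticConfig
    transition_config: Optional[TransitionConfig]


def generate_cohort(
    n_subjects: int = 18,
    resting_cfg: Optional[SyntheticConfig] = None,
    transition_cfg: Optional[TransitionConfig] = None,
    seed: int = 0,
) -> Cohort:
    """Generate a cohort of recordings (default 18 subjects).

    Per-subject seeds are ``seed + subject_index``, so cohorts are
    reproducible piecewise.  With a ``transition_cfg`` every subject gets an
    induction event at its t0 (recorded in the manifest); without one the
    cohort is a resting control group and ``induction_time_s`` marks the end
    of the stage-1 analysis window (minutes 0-5 by convention).
    """
    if n_subjects < 2:
        raise ValidationError("a cohort needs at least 2 subjects")
    if resting_cfg is None:
        resting_cfg = SyntheticConfig()
    recordings: dict[str, HeartRateSeries] = {}
    rows = []
    for i in range(n_subjects):
        subject_id = f"S{i:02d}"
        cfg = replace(resting_cfg, seed=seed + i)
        series = generate_hr(cfg)
        induction = transition_cfg.t0 if transition_cfg is not None else 300.0
        if transition_cfg is not None:
            series = inject_transition(series, transition_cfg, baseline=cfg.baseline_hr)
        recordings[subject_id] = series
        rows.append(
            {
                "subject_id": subject_id,
                "recording_path": "",
                "induction_time_s": induction,
                "stage2_start_s": 900.0,
                "seed": seed + i,
            }
        )
    return Cohort(
        recordings=recordings,
        manifest=pd.DataFrame(rows),
        resting_config=resting_cfg,
        transition_config=transition_cfg,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject HR CSVs and a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for subject_id, series in cohort.recordings.items():
        path = out_dir / f"{subject_id}.csv"
        write_hr_csv(series.to_raw_samples(source_label=subject_id), path)
        paths.append(str(path))
    manifest["recording_path"] = paths
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
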