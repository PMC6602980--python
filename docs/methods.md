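# Methods

## Signal model and preprocessing

All analysis operates on instantaneous heart rate in beats per minute (bpm),
not on RR intervals: the tool targets pulse-derived rate streams (pulse rate
variability), and SD1/SD2 computed from HR and from RR intervals are not
directly comparable, so an RR-interval mode is deliberately not offered.

Input is standardized to a uniformly sampled series because the lag-1 return
map presumes a constant time step, and because mixing sampling rates across
recordings would bias the variability estimates. The grid is anchored at the
first raw sample, `t_k = t_first + k/fs` (default fs = 1 Hz), values filled
by linear interpolation between bracketing raw samples; the grid never
extends beyond the last raw sample (no extrapolation — we do not invent
data). Beat annotations are converted first: each consecutive beat pair
(tᵢ, tᵢ₊₁) contributes 60/(tᵢ₊₁ − tᵢ) bpm stamped at the *later* beat, which
keeps the estimate causal for streaming use. An optional centered moving
average (odd window; edges truncated) can smooth annotation-derived rate; it
is off by default for already-smooth device rate streams, and a 3-point
window is a reasonable choice for annotation-derived input.

### Artifact filter

Ectopic beats and noise are removed by a relative-deviation rule: in a single
forward pass over the valid samples, the first valid sample is accepted and
seeds the reference r; a later sample x is rejected iff |x − r|/r > 0.20
(strict inequality, so exactly 20 % passes), and accepted samples update r.
Referencing the most recent *accepted* value means an artifact never
contaminates the reference; this is the convention of the cited filtering
literature for HRV preprocessing. Rejected samples are masked, not deleted or
interpolated: values stay in place for audit, the mask creates gaps, and no
Poincaré pair is formed across a gap (pairing across a removed ectopic would
reintroduce the artifact the filter removed).

A consequence worth knowing: a spike at the very first valid sample cannot be
rejected — it seeds the reference, and subsequent normal samples would be
rejected instead. The synthetic ectopic injector therefore never places a
spike at index 0.

## Poincaré descriptors

With pairs (xᵢ, yᵢ) = (HR(t), HR(t+1)) over the uniform grid, dᵢ = xᵢ − yᵢ,
sᵢ = xᵢ + yᵢ:

* SD1 = sqrt(Var(d)/2) — dispersion perpendicular to the identity line,
  short-term (sample-to-sample) variability;
* SD2 = sqrt(Var(s)/2) — dispersion along the identity line, longer-term
  variability;
* centroid = (mean x, mean y); the fitted ellipse is centered there with
  semi-axes SD2 (along identity) and SD1 (perpendicular), orientation 45°.

Variances are unbiased (n − 1 denominator); the convention is stated because
the literature rarely does, and the independent rotation-form oracle in the
tests uses the same convention. At least 2 pairs are required; when SD2 = 0
the SD1/SD2 ratio is reported as undefined rather than raising. Published
attributions of SD1/SD2 to sympathetic versus parasympathetic tone are
mutually inconsistent across sources; the package reports the descriptors
numerically and hard-codes no physiological mapping.

## Sliding-window streaming

The real-time index is SD1/SD2 over a window of W = 20 s updated every
step = 5 s (both configurable; a 1 s step is supported). A window labelled
with its end time T covers the half-open interval (T − W, T] and contains the
pairs whose later member falls inside it; end-labelling is the causal choice
for a live display. Emissions form a regular grid starting at
series start + W — the initial buffering delay equals the window length.
Windows with fewer than `min_pairs` = 3 valid pairs are emitted as explicit
missing records (variance of ≤ 2 points is too unstable to display), keeping
the trace grid regular for downstream plotting and merging.

The online engine applies the same filter rule incrementally and shares the
window-selection and descriptor code with the batch path, so its emissions
are exactly — bit-identically — the batch trace of the same data; this
equivalence is asserted over randomized fixtures rather than assumed. W is
warned about outside 5–120 s, the range over which the resolution/noise
trade-off has been characterized (short windows are noisy, long windows
sluggish; 20 s is the default compromise). The `window_length_sweep` helper
reproduces that comparison on any recording.

## Stage comparison

Per subject, two segments are extracted on the analysis grid: stage 1, a
baseline of 150–300 s immediately preceding anesthetic induction, and
stage 2, exactly 300 s of anesthesia maintenance within minutes 15–30
(default placement minutes 15–20, matching the control-extraction
convention; resting controls use minutes 0–5 as stage 1). Windows must not
overlap. The artifact filter runs within each extracted stage (the reference
seeds from the stage's first sample). Subjects missing a usable stage are
excluded with a logged warning, never imputed.

Across subjects, each metric is summarized by mean, median, and IQR
(quartiles by linear interpolation — stated because IQRs are reported), and
the stage-1 and stage-2 value sets are compared with a two-sided
Mann–Whitney–Wilcoxon rank-sum test at α = 0.05. The test is unpaired even
though the stages come from the same subjects: fidelity to the named test
wins, and a paired alternative is out of scope. The exact null distribution
(count recurrence N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1)) is used when
both groups have ≤ 8 observations and the pooled sample is tie-free;
otherwise the normal approximation with midranks, tie correction, and
continuity correction (via scipy) applies. The exact branch is cross-checked
in the tests against brute-force enumeration of all C(m+n, m) labelings.

## Synthetic data

The generator emulates resting heart rate directly on the analysis grid:

    HR_t = baseline + A·sin(2π f_rsa t + φ) + e_t,

with e a stationary AR(1) process (stationary SD σ, lag-1 autocorrelation ρ,
innovation SD σ√(1−ρ²), initialized from the stationary distribution) and
the sinusoid a respiratory-sinus-arrhythmia surrogate. AR(1) is the minimal
model with independently tunable SD1/SD2: in the pure-AR case the population
descriptors are SD1 = σ√(1−ρ), SD2 = σ√(1+ρ), a closed-form oracle for the
estimators. Defaults — σ = 3.9 bpm, ρ = 0.85, baseline 70 bpm, RSA 2 bpm at
0.25 Hz (15 breaths/min), duration 1200 s — put the population SD1/SD2 at
≈ 1.5/5.3 bpm, in the range reported for young resting adults, and make room
for a maintenance window at minutes 15–20.

An anesthesia induction is emulated by scaling all deviations from the known
baseline after t₀ by a suppression factor f ∈ (0, 1] (default 0.3, an abrupt
collapse of both descriptors to 30 %); an optional baseline shift models the
rate change itself. Ectopics are emulated by multiplying randomly selected
samples (never index 0; see above) by 1 + magnitude. Cohorts derive
per-subject seeds as master seed + subject index, so they are reproducible
piecewise; the default cohort size is 18.

What the generator does **not** emulate: beat-level point-process structure
(it synthesizes rate, not beats), non-stationary drift, respiratory-rate
variation, movement artifacts with temporal structure, or pharmacokinetic
dynamics of induction (the transition is instantaneous). Passing tests on
synthetic cohorts therefore demonstrate correctness of the estimators,
filter, streaming semantics, and statistics under a controlled stochastic
model — not clinical validity on device data.

## Numerical choices and degenerate inputs

* Grid sizes and emission counts use floor with a 1e-9 relative guard against
  float-representation error; emission labels are computed as
  `start + W + k·step` (never by repeated addition) in both batch and online
  paths so they agree exactly.
* Constant series yield SD1 = SD2 = 0 and an undefined ratio; a series
  shorter than one window yields an empty trace, not an error; an
  all-invalid series is an error.
* Filter threshold comparisons are strict (> rejects); summaries use
  linear-interpolation quartiles; the rank-sum two-sided exact p is
  2·P(U ≤ min(U_a, U_b)) capped at 1, which equals the enumeration
  definition P(|U − mn/2| ≥ |u_obs − mn/2|) for the tie-free symmetric null.
* Problem sizes in the validation suite: 20,000-sample series × 30 replicates
  for parameter recovery; 100 replicate pairs of 18-subject, 1200 s cohorts
  for the stage-comparison properties; 100 randomized fixtures for streaming
  equivalence. These sizes give Monte-Carlo standard errors well below the
  effects being checked while keeping the whole suite fast.

## Known limitations

* HR-domain (PRV) descriptors only; no RR-interval mode by design.
* The stage comparison treats stage-1/stage-2 values as independent groups
  (the named test), which is conservative for same-subject designs.
* The MIT annotation reader extracts beat times only; all other annotation
  content (aux strings, sub/chn/num fields) is discarded.
* The streaming engine guarantees sample-ordered semantics, not wall-clock
  latency; it is a model of a real-time tool, not device software.
* No respiration-gated correction of HRV and no spectral (LF/HF) analysis.
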