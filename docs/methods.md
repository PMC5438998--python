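# Methods

This note documents the models, numerical choices and known limitations of
the `gripstiff` pipeline: what the synthetic generator emulates, how each
analysis stage is defined, and what passing tests do and do not establish
about real recordings.

## Measurement model

A pinch grip on a spring-loaded perturbator is a one-dimensional elastic
system around its operating point. The device elongates by a constant
`Δx = 7.5 mm` within a few milliseconds; because the spring force (100–140 N)
far exceeds any pinch force, the displacement is the same regardless of how
firmly the device is held. Intrinsic (a-reflexive) stiffness is the force
change per unit displacement measured before reflexive or voluntary feedback
can act:

```
k = ( E_TaP(f) − E_TbP(f) ) / Δx        [N/mm]
```

with `E_TbP`, `E_TaP` arithmetic means of the smoothed force over the
windows before and after the perturbation. Damping and inertia do not enter
because both windows lie on (near-)static plateaus.

### Window detection

* The force trace (10 kHz) is smoothed once with a centered 21-point moving
  average (edges: shrinking symmetric window); detection and averaging both
  use the smoothed trace.
* `t_peak` is the global maximum of the smoothed trace; the trace must span
  ≥ 250 ms before it.
* `T_bP` is the **latest** 10 ms window ending at or before `t_peak` whose
  sample SD (ddof = 1) falls below a threshold (default 5·10⁻⁴ N); its end
  defines `t_pert`. The scan uses single-sample stride.
* Threshold fallback: if no rung admits a quiet window the threshold is
  multiplied by 10 (flagged in `quality_flags`), up to a cap of 0.1 N — the
  force-sensor accuracy; a plateau noisier than the sensor is not quiet in
  any meaningful sense, and such traces raise a detection error (e.g. a
  monotone ramp). A rung is accepted only if at least 25 % of candidate
  windows pass it: smoothing leaves roughly `100/21 ≈ 5` effective degrees
  of freedom per window, so the sample-SD distribution is wide and a rung
  below the true noise floor still admits a few percent of windows by
  chance; demanding a plateau's worth of quiet windows makes the rule
  robust. Both knobs are configuration fields.
* Known property, by design: on a noise-free trace the detected `t_pert`
  leads the mechanical onset by up to half the smoothing width plus one
  sample (1.1 ms at the defaults), because the centered moving average
  spreads the onset backwards and the quiet-window criterion rejects any
  window touching that bleed. The stiffness quotient is unaffected — both
  averaging windows sit on constant plateaus — and the tests assert the
  lead bound explicitly.
* `T_aP` is placed at the configured optimum: duration 55/3 ms ending at
  `t_trust = t_pert + 100/3 ms` by default (the grid points print as
  18.3/33.3 ms), always respecting `t_trust ≤ t_pert + 40 ms`, the horizon
  within which neuromuscular feedback cannot contribute.

### Window-placement objective

`optimize_windows` recalibrates the `T_aP` placement on a dataset by
exhaustive grid search (default resolution ⅓ ms) over duration ∈ [5, 20] ms
and trust offset ∈ [duration, 40] ms, minimising

```
Z = (1/n_sub) Σ_i (1/n_level) Σ_j [ ẽ(k_task1,ij)
      + (1/n_trial) Σ_k ( ẽ(T_aP f_task1,ijk) + ẽ(T_aP f_task2,ijk) ) ]
```

where `ẽ(x) = s/(µ√n)` is the coefficient of standard error — the
coefficient of variation combined with the standard error, dimensionless,
penalising small samples. Only task 1 contributes stiffness terms: repeated
task-2 trials are not replicates of one condition because the cocontraction
level cannot be commanded. Implementation notes:

* `ẽ` over the repeated task-1 stiffnesses is computed per (subject, level)
  group; groups with fewer than two task-1 trials are excluded with a
  warning. The force-sample terms are averaged per task (the two tasks have
  different repetition counts) and use the smoothed trace, consistent with
  smoothing-before-everything.
* The grid evaluation uses centered cumulative sums (numerically stable
  windowed means/variances, vectorised over the grid); placements with `Z`
  within 1e-6 of the minimum are treated as ties — below that the cumsum
  evaluation has no resolving power — and ties break to the smallest trust
  offset, then the smallest duration (earliest trusted data, minimal
  reflex-contamination risk).

## EMG features

* Filtering: zero-phase (forward–backward) second-order Butterworth
  bandpass, 25–450 Hz at 4 kHz. Sample-and-hold duplicates from a faster
  acquisition grid are collapsed back to the native rate before filtering
  (`collapse_duplicated`).
* Activation: ARV (mean |·|) over 200 ms ending at `t_pert − 48 ms`; the
  48 ms is the constant delivery delay of the wireless electrodes, so the
  window holds the muscle state that actually preceded the perturbation.
  The delay is configurable.
* Base noise: per-electrode ARV of one 500 ms window of the relaxation
  recording, identical window for all electrodes. The window is chosen
  automatically as the stretch with minimal summed ARV (reproducible,
  overridable) where the original procedure was a manual pick. Baseline
  ARVs are subtracted subject-wise; small negative corrected values are
  kept (clipping would break affinity of the subsequent normalization) and
  flagged.
* Normalization, per subject and electrode: divide by the maximum, then by
  the SD of the max-normalized values. This two-step rule is exactly
  invariant to any positive per-electrode gain — electrode placement and
  skin impedance scale the signal multiplicatively — which is what makes
  pooling subjects in one regression meaningful. Degenerate inputs
  (non-positive maximum, zero SD) raise errors naming the electrode.

## Kinematics

* Cleaning order matters: (1) exact-zero frames are masked (a lost marker
  reports zero, and a zero would also defeat the proximity rule); (2) the
  index/thumb identities are restored per frame by distance to the
  perturbator body (the index marker sits nearer to it by construction);
  (3) frames jumping faster than 5 m/s (configurable; the value
  operationalises "unreasonably high") from the last valid frame are
  masked. Masking is emergent, not a quota — at default noise ≈ 2–3 % of
  frames end up masked.
* Digit displacement: positions are mapped to the time-varying wrist frame
  (`p_w = Rᵀ(p − t)`), so forearm drift does not masquerade as grip
  displacement; each digit's displacement is the Euclidean norm of the
  difference between its mean wrist-frame position over `T_bP` and over
  `T_aP` — the same windows as the stiffness quotient — expressed in % of
  7.5 mm. The 3-D norm (not a projection on the perturbator axis) is used.
  Trials with more than 50 % of window frames masked are rejected.
* `angular_distance(R₁, R₂) = arccos((trace(R₂R₁⁻¹) − 1)/2)` in degrees,
  argument clamped to [−1, 1]; inputs are validated as proper rotations
  (orthonormality tolerance 1e-6).

## Regression

* Models: `f = β₁ + β̄·EMG` (7 coefficients) and `k = β₁ + β̄·EMG + βₙ·f`
  (8 coefficients), ordinary least squares on subject-wise normalized data.
  Rank deficiency is detected up front and reported with the collinear
  column names. Coefficient tables carry significance codes from p-value
  bands {≤0.001: +++, ≤0.01: ++, ≤0.05: +, ≤0.1: ., else −}.
* Target normalization for pooling across subjects defaults to the same
  max-then-SD rule as the EMG features; divide-by-SD-only is available
  behind a config switch (`intersubject_normalization="sd"`), since either
  convention is defensible.
* Cross-validation. Intrasubject: leave-one-trial-out, one model per
  perturbation; the per-subject R² pools held-out predictions against the
  subject's own mean. Intersubject: leave-one-subject-out, one model per
  subject; R² per held-out subject against that subject's mean. R² may be
  negative (model worse than the held-out mean).
* Transform comparison: per subject, the quality of each EMG transform
  (plain, √, ²) is the correlation between the in-sample OLS prediction and
  the target; pairs are compared with Steiger's z for dependent
  correlations sharing one variable,
  `z = (z_jk − z_jh)·√((n−3)/(2−2s))` with the covariance term from the
  correlation between the two predictions. Per-subject z values are
  combined across subjects with Stouffer's method (the pooling rule is a
  package choice; per-subject values are reported alongside).
* Correlation table: per subject/electrode Pearson r to stiffness and to
  force, summarized as mean ± SD across subjects; a paired t-test on the
  Fisher-transformed coefficients asks per electrode whether the two
  correlations differ. |r| = 1 is clamped into the open interval before
  `arctanh`.
* Decoupling table: stiffness max-normalized per subject over **all** of
  that subject's trials (both tasks), pooled across subjects, binned by
  commanded force level with the fixed map {15→10, 25→20, 35→30, 45→40,
  55→50 % MVC} (the ±5 % MVC control band centres produced force below the
  command). Rows: per-task mean and SD, the difference row
  `mean(task2) − mean(task1)` — the average voluntary stiffness increase —
  and a ratio row computed as the mean over task-2 trials of each trial's
  normalized stiffness divided by its subject-and-bin task-1 mean. The
  pairing behind a trial-ratio statistic is not uniquely defined; this
  convention is documented as such and the ratio row carries no acceptance
  weight.

## Synthetic generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis assumes.

* Protocol: per subject 24 task-1 trials (6 levels × 4, 15–65 % MVC) and
  75 task-2 trials (5 levels × 15, 15–55 % MVC), randomized order, plus a
  5 s relaxation recording. All randomness flows from one root seed through
  named substreams (subject → trial → stream), so force samples do not
  change when EMG or marker synthesis is switched off.
* Force trace: pre-plateau ≥ 250 ms (default 500 ms) at
  `f_pre = level × MVC` with Gaussian tremor (SD 0.05 N), linear rise over
  3 ms, post-plateau at `f_pre + k·7.5 mm` overlaid with an exponentially
  damped 150 Hz sinusoid (amplitude 1 N, decay constant 5 ms — below
  tremor amplitude within 20 ms), clipped at zero. A 100 N sensor-range
  check rejects infeasible commands.
* Stiffness law: task 1 `k = k0 + slope·f`; task 2 adds
  `offset(level) × LogNormal(CV 0.4) × k_scale`, with the per-level offsets
  {15, 14, 21, 21, 26} % of the subject stiffness scale
  `k_scale = k0 + slope·0.65·MVC`, and the lognormal reflecting that
  cocontraction effort cannot be commanded, only encouraged. Subject
  parameters draw uniformly from configured ranges (MVC 40–80 N, k0
  0.2–0.6 N/mm, slope 0.04–0.08 N/mm per N, index share 0.6–0.8).
* EMG: per channel, amplitude envelope
  `noise + gain × (w_f·f/MVC + w_c·cocontraction)` with a per-trial
  lognormal gain (CV 0.5–0.6 extrinsic, 0.18 intrinsic) modulating a
  band-limited (25–450 Hz) unit-SD noise carrier at 4 kHz. The intrinsic
  channels (FDI, SDI) weight the cocontraction drive ≈ 1.0 versus ≈ 0.2–0.3
  for the extrinsic channels; with these defaults the intrinsic ARV–
  stiffness correlation over task-2 trials sits near 0.83 and the extrinsic
  ones near 0.5 with much larger between-subject spread — the correlation
  structure the analysis is meant to resolve. A deterministic sinusoidal
  carrier (`emg_carrier="sine"`) provides an exact noise-free limit in
  which the ARV is strictly proportional to the envelope; it exists for
  validation, not realism.
* Markers (400 Hz): index and thumb tips on opposite sides of the grip
  move apart by `share·7.5` and `(1−share)·7.5` mm along the device axis
  with the same 3 ms ramp; the perturbator marker sits off-centre towards
  the index so the proximity rule is well-posed. The whole scene undergoes
  a slow rigid drift (2 mm, 1°, 0.5 Hz) removed by the wrist-frame
  transformation; stored wrist orientation carries 0.1° pose noise; marker
  noise 0.05 mm; dropout probability 1 % per frame and label-swap segments
  (0.5 % start probability, mean 4 frames) emulate the documented tracking
  artifacts.

### What the generator does not emulate

Hill-type muscle dynamics, reflex loops, motor-unit interference structure
in the EMG, electrode crosstalk, fatigue and learning trends, and any
nonlinearity in the force–stiffness law. Passing recovery tests therefore
establishes that the *analysis chain* is faithful (windows, quotient,
normalizations, partitions, cross-validation bookkeeping) under realistic
noise amplitudes — not that real hands satisfy the generating law.

## Recovery studies and their problem sizes

`gripstiff.recovery` drives the generator with *imposed* ground truth and
measures what the full pipeline returns.

* Decoupling recovery: 10 subjects × 5 levels × (4 task-1 + 15 task-2
  trials) = 950 trials, default trace noise. Imposed truths are per-level
  normalized-stiffness distributions (mean/SD per task); each subject's
  physical scale draws from 2.5–4.5 N/mm and cancels in the normalization.
  Truth draws use stratified (quantile-balanced) normal sampling — one draw
  per probability stratum, shuffled — which preserves the marginal
  distribution while stabilising both the group means and the extreme order
  statistics; the latter matters because the per-subject *maximum* is the
  normalization denominator.
* Known bias, stated rather than hidden: real max-normalized data has
  per-subject maximum exactly 1, whereas Gaussian draws reach only ≈ 0.95
  at the top level, so recovered differences inflate by a few percent of
  their value. Stratified draws keep this inflation small and stable; it is
  part of what the recovery numbers mean.
* Digit-share recovery: 10 subjects × 24 task-1 trials = 240 trials with
  default marker noise, dropouts and swaps; imposed per-subject shares;
  averaging per subject first, then across subjects.
* Estimator bias: 1,000 single trials across the task-1 levels; mean
  relative error of `k̂` is ≈ −0.1 % at default noise (bound asserted:
  &lt; 2 %).

These sizes keep every recovery run within seconds on one CPU while the
pooled bins still hold 40–150 trials each.

## Numerical choices and degenerate inputs

* Rolling window statistics use (centered) cumulative sums with variance
  clipped at zero; windows are inclusive of their end sample; `T_bP` holds
  100 samples at 10 kHz.
* Moving-average edges shrink symmetrically, so the filter is exactly
  mean-preserving on constants.
* `ẽ` requires n ≥ 2 and a positive mean; Steiger's z requires n ≥ 4 and
  |r| &lt; 1; the ARV window must lie inside the trace; empty or reversed
  windows raise input errors rather than returning NaN.
* Lognormal multipliers are parameterized to have mean exactly 1
  (`µ = −σ²/2`), so effort variability does not shift expected stiffness.
* Cross-validation fits use `numpy.linalg.lstsq` (minimum-norm under rank
  deficiency, with failed folds counted and skipped); the user-facing model
  objects use statsmodels OLS and refuse rank-deficient designs up front.

## Limitations

* The quiet-window SD threshold of 5·10⁻⁴ N presumes very quiet hardware;
  on the generator's tremor amplitudes the fallback ladder always engages
  one or two rungs (flagged per trial). External data with different noise
  floors should set the threshold explicitly.
* The detected `t_pert` inherits the half-filter-width lead described
  above; analyses that need the mechanical onset itself should correct by
  `(ma_points−1)/2` samples.
* Stream synchronisation between force and markers is exact in the
  generator; for external data a per-trial time offset must be supplied in
  the configuration.
* The decoupling ratio row depends on an arbitrary pairing convention and
  should not be compared across implementations.
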