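# gripstiff

Analysis pipeline for **intrinsic pinch-grip stiffness** experiments, with a
synthetic-data generator that emulates the full measurement chain.

## The problem

When you pinch an object between index finger and thumb, the stiffness of the
grip rises linearly with the grip force — but by *cocontracting* antagonist
muscles you can raise stiffness above that baseline at the same net force
("decoupling"). Quantifying this matters both for motor control and for
variable-stiffness robotic hands, whose torque–stiffness envelopes engineers
would like to match to the human one, and for teleoperation, where grip
stiffness must be read continuously from muscle activity.

The measurement: a spring-loaded perturbator held in a pinch grip elongates by
a constant 7.5 mm within a few milliseconds. Taking the force change over that
displacement fast enough (&lt; 40 ms) excludes reflexive and voluntary
responses, so the quotient is the *intrinsic* (a-reflexive) stiffness

```
k = ( E_TaP(f) − E_TbP(f) ) / (x_aP − x_bP),      x_aP − x_bP = 7.5 mm
```

where `E_TbP`, `E_TaP` average the smoothed force over a 10 ms quiet window
`T_bP` just before the perturbation and a short trusted window `T_aP` after
it. `T_bP` is found by a quiet-window rule (latest 10 ms stretch before the
force peak with sample SD below a threshold); the placement of `T_aP` is
calibrated on a whole dataset by minimising an objective `Z` that sums
coefficients of standard error `ẽ = s/(µ√n)` of repeated stiffness
measurements and of the force samples inside `T_aP`.

Around the stiffness quotient the package implements:

* **EMG activation features** — zero-phase 25–450 Hz second-order Butterworth
  bandpass, average rectified value (ARV) over 200 ms before the perturbation,
  subject-wise base-noise subtraction, and per-subject/per-electrode
  max-then-SD normalization (invariant to electrode gain) for six muscles:
  FDP, FDS (extrinsic flexors), EIP, ED (extrinsic extensors), FDI, SDI
  (intrinsic interossei).
* **Digit kinematics** — marker cleaning (exact-zero dropouts, implausible
  jumps, perturbator-proximity label restoration), rotation-matrix angular
  distances, and the wrist-frame partition of the 7.5 mm displacement between
  index finger and thumb (the stiffer digit moves less).
* **Regression models** — `f = β₁ + β̄·EMG` and `k = β₁ + β̄·EMG + βₙ·f` by
  OLS, with leave-one-trial-out (within-subject) and leave-one-subject-out
  (across-subject) cross-validated R², EMG transform comparison
  (plain / √ / ²) via Steiger's z-test for dependent correlations, paired
  tests on Fisher-transformed correlations, and the per-force-level
  decoupling table of normalized stiffness differences between the
  cocontraction and pure-force tasks.
* **A synthetic generator** — per-subject linear force–stiffness coupling,
  additive cocontraction offsets with lognormal effort variability,
  amplitude-modulated band-limited EMG whose intrinsic channels load on the
  cocontraction drive, marker trajectories with dropouts/label swaps, all
  reproducible from a single seed.

## Worked example

```python
import gripstiff as gs
from gripstiff import generate_dataset, analyze_dataset, prepare_subject_table
from gripstiff.regression import (StiffnessFromEMG, crossval_intersubject,
                                  decoupling_table)

gen = gs.GeneratorConfig()
config = gs.PipelineConfig(generator=gen, n_subjects=5, seed=42)
ds = generate_dataset(5, gen, seed=42)          # 5 subjects x 99 trials
result = analyze_dataset(ds, config)            # windows, k, ARV, kinematics

table = prepare_subject_table(result.merged)
fit = StiffnessFromEMG.from_trials(table).fit()
print(fit.summary().round(3))
print(crossval_intersubject(table, target="stiffness").summary())
print(decoupling_table(result.merged).table.round(1))
```

prints

```
          coef     se      p code
const    0.780  0.042  0.000  +++
EMG_FDP  0.030  0.018  0.092    .
EMG_FDS  0.023  0.019  0.225    -
EMG_EIP  0.091  0.017  0.000  +++
EMG_ED   0.005  0.018  0.765    -
EMG_FDI  0.283  0.027  0.000  +++
EMG_SDI  0.289  0.027  0.000  +++
force    0.499  0.022  0.000  +++
stiffness [leave-one-subject-out]: R^2 = 83.5 +/- 17.8 % (5 models)
bin_pct_mvc       10    20    30    40    50
mean_task1_pct  27.4  36.7  45.9  55.2  64.5
mean_task2_pct  38.6  46.1  61.0  69.6  83.9
sd_task1_pct     4.9   5.1   5.3   5.4   5.6
sd_task2_pct     7.1   7.7   8.7   9.3   9.0
diff_pct        11.2   9.5  15.1  14.4  19.4
ratio            1.4   1.3   1.3   1.3   1.3
```

Reading it: the stiffness model puts its large, highly significant weights on
the two intrinsic hand muscles (FDI, SDI) and on force — the signature of
cocontraction-driven stiffening — while the extrinsic forearm channels carry
little weight. A model fitted on four subjects explains ~84 % of a held-out
subject's stiffness variance. The decoupling table pools all trials per
commanded force-level bin after per-subject max-normalization; its `diff_pct`
row is the average voluntary stiffness increase through cocontraction, in %
of each subject's maximum stiffness.

The same pipeline runs from the shell on on-disk datasets (CSV per trial +
JSON manifest):

```
gripstiff all --out run/ --seed 42          # simulate -> analyze -> report
gripstiff simulate --config my.yaml --out data/
gripstiff analyze  --data data/ --out analysis/
gripstiff report   --analysis analysis/ --out report/
```

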