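# Methods

This note documents the generative model behind the synthetic data, the
reduction and inference conventions, and the numerical choices made
throughout `fittslab`.

## 1. Generative model

### Design

The default `StudyDesign` is a fully crossed repeated-measures layout:

| field | default | units |
|---|---|---|
| `amplitudes` | 155, 190, 266, 380 | mm |
| `widths` | 20, 30, 40, 50 | mm |
| `trials_per_condition` | 10 | — |
| `sessions` | TF-Absent, TF-Present | — |
| `n_accuracy` / `n_speed` | 12 / 7 | participants |
| `sample_rate` | 200 | Hz |

Each session therefore contains 16 conditions × 10 trials = 160 experimental
trials, and the nominal index of difficulty `log2(2A/W)` spans 2.63–5.25
bits.

### Movement time

The planted mean movement duration follows Welford's two-part form

```
MT(A, W) = intercept + beta_amp·log2(A) + beta_width·log2(1/W) [+ tf_effect]
```

plus a Gaussian per-participant intercept offset (`participant_sd_ms`) and
Gaussian per-trial noise (`mt_trial_sd_ms`), truncated below at 100 ms to
avoid degenerate two-sample reaches. `tf_effect_ms` applies in the
TF-Present session only.

Calibration rationale (all decided up front, from the structure the analyses
are meant to detect, not from test outcomes):

- `beta_amp = 106`, `beta_width = 48` ms/bit for both groups — clearly
  unequal component slopes, so the decomposition has a real signal to
  recover, with the amplitude slope roughly twice the width slope.
- `tf_effect = −23` ms — a small MT advantage under terminal feedback.
- Group intercepts (−114 ms accuracy-prone, −223 ms speed-prone) were chosen
  so that the *detected* MT (after threshold trimming, §3) lands in the
  plausible 300–460 ms range for these IDs, with speed-prone performers
  faster overall.
- Between/within noise (85/40 ms accuracy, 45/30 ms speed) gives stable
  per-participant slope estimates at 10 trials per cell while keeping
  realistic between-subject spread.

### Endpoints

Primary-axis endpoints are `Normal(A + endpoint_bias, σ)` with a
strategy-dependent scatter model:

- accuracy-prone: `σ = width_utilization · W / 2` (default utilization 0.3),
  so scatter tracks the target width and stays far inside it — error rates
  near zero;
- speed-prone: `σ = noise_base + noise_amp_gain · A` (defaults 6.0 mm +
  0.008·A), so scatter grows with movement amplitude and is independent of
  the target, producing endpoint error rates of several percent that exceed
  the 5 % strategy cutoff in at least one session for almost every simulated
  speed-prone performer.

Orthogonal axes carry small independent endpoint jitter (SD 2 mm); all
reduced measures use the primary axis only.

### Trajectories

Each reach is a minimum-jerk quintic, `x(τ) = D·(10τ³ − 15τ⁴ + 6τ⁵)` with
`τ = t/MT`, sampled on the acquisition grid, flanked by 0.2 s of quiescent
padding on each side. The padding carries uniform measurement jitter bounded
by `6/fs` mm, which keeps the central-difference resultant speed in the
padding below ~10.4 mm/s — under half the 30 mm/s detection threshold — so
padding can never trigger movement detection. The quintic's speed profile is
`(D/T)·30τ²(1−τ)²`, peaking at `1.875·D/T` at mid-movement.

### Determinism

Every participant/session/condition/trial owns its own seed substream
(`SeedSequence` spawn keys), so regenerating any subset of the study
reproduces it exactly, and the truth-only fast path
(`simulate_study(trajectories=False)`) consumes identical draws and yields a
truth table identical to the fully rendered run.

### Realism limits

The generator is a validation instrument, not a behavioral model. Known
simplifications: no reaction-time variability or anticipation; no secondary
submovements or online corrections (one quintic per reach); endpoint noise
is Gaussian and homoscedastic within condition; MT noise is independent of
endpoint noise, so the generator plants no within-condition speed–accuracy
correlation; and the two strategy groups differ only in intercept and noise
model, sharing the same planted component slopes.

## 2. Reduction conventions

- Speed is obtained by first-order differentiation (central differences by
  default; forward differences available), as the resultant 3-D speed by
  default or `|dx/dt|` on request.
- Movement start is the first sample of the earliest run of 5 consecutive
  samples with speed strictly above 30 mm/s; movement end is the first
  sample of the earliest subsequent run strictly below it. Samples exactly
  at the threshold break a run in both directions. The `run_end` convention
  (report the fifth sample of the run instead) is available; the default
  `run_start` keeps onset and offset symmetric.
- Everything after the detected end is ignored, so delayed corrections or
  the return toward the home position never extend a trial.
- Trials with no detectable onset or offset are flagged with a reason and
  excluded from summaries; exclusion counts are logged and written to the
  report bundle (`dropped_trials.csv`), never imputed.

## 3. Threshold trimming and slope bias

Threshold segmentation cannot see the movement's sub-threshold head and
tail. For a minimum-jerk reach of duration `T` (s) and distance `D` (mm)
with threshold `v0 = 30` mm/s, the speed near each end is
`≈ 30·(D/T)·τ²`, so the time spent under threshold at each end is
`≈ T·sqrt(v0·T/(30·D)) = T^1.5/sqrt(D)` seconds, and the total trimmed
duration is about `2·T^1.5/sqrt(D)` — it *grows* with MT and *shrinks* with
distance. Consequently detected MT underestimates planted MT by ~25–35 ms in
this design, and the bias is not constant across conditions: along a width
manipulation (fixed `A`), slower movements at higher ID lose more, biasing
the recovered width slope several ms/bit downward, while along an amplitude
manipulation the larger `D` at higher ID roughly cancels the effect. The
residual displacement left untravelled at the detected end is
`≈ 10·sqrt(T³/D)` mm (well under 0.5 mm here), which bounds the endpoint
error of the detector. These are properties of the measurement convention
itself, shared by any threshold-based pipeline, and are asserted
quantitatively in the test suite.

## 4. Difficulty metrics

- `ID = log2(2A/W)`; the effective variant uses `We = 4.13 × SD(endpoints)`
  (sample SD, `ddof = 1`), the 95 % span of a normal endpoint distribution.
  A degenerate (zero-spread) cell has undefined effective ID and is skipped
  with a logged reason.
- Endpoint errors are `|endpoint − A| > W/2` on the primary axis; the target
  edge counts as a hit. Performers are accuracy-prone iff their error rate
  is at or below 5 % in *every* session.
- Published difficulty tables are reproduced with decimal **half-up**
  rounding (3.225 → 3.23), computed through a 10-decimal pre-round so binary
  floating-point noise cannot defeat the rule, and table margins are
  presented as means of the already-rounded cells — the construction such
  tables typically use — alongside the exact unrounded margins.

## 5. Slope decomposition

Component slopes are ordinary least squares on the four (ID, cell-mean MT)
points of each manipulation, per participant × session × basis. Group
summaries always take the **mean of per-participant slopes** (with a
t-based 95 % CI over participants); the slope of group-mean points is
computed separately and kept distinct, because the two differ whenever the
abscissas vary per participant (as effective IDs do). In the slopes ANOVA
the Average-ID factor enters by rank within basis × component, since its
numeric level values differ between the amplitude and width margins.

## 6. Inference conventions

The mixed repeated-measures ANOVA rotates the within-cell space onto
orthonormal contrast blocks (Kronecker products of Helmert contrasts and
uniform-average vectors — any orthonormal basis gives identical results) and
analyses each block as a small general linear model over subjects:

- **Type III sums of squares** with sum-to-zero group coding for the
  (optionally unequal-`n`) between factor: every effect is tested on
  unweighted marginal means. With unequal group sizes these tests are not an
  additive decomposition of the total sum of squares; the additive identity
  `SS_total = SS_subjects + Σ effects + Σ error strata` holds exactly for
  pure within-subject designs and for equal group sizes, and is asserted in
  the tests for those cases.
- **Greenhouse–Geisser epsilon** from the pooled *within-group* covariance
  of the contrast scores (the mixed-model convention), clipped to its
  theoretical range `[1/d, 1]`. The corrected p is always reported;
  `p_headline` switches to it when Mauchly's test rejects at α = 0.05 or
  cannot be computed (the conservative default).
- **Mauchly's test** uses Box's chi-square approximation including the
  second-order correction term.
- **Generalized eta-squared** adds every subject-level error stratum to the
  denominator, plus the sums of squares of effects involving *observed*
  (measured, e.g. strategy) factors, keeping effect sizes comparable across
  between- and within-subject designs.
- A zero-variance error term yields an undefined F (reported as not
  applicable), never infinity.
- Orthogonal polynomial contrasts for unequally spaced levels come from a QR
  factorization of the centered Vandermonde matrix with the sign fixed so
  leading coefficients are positive; single-df trend tests use the contrast's
  own between-subject variability as the error term (df = n − 1), the
  sphericity-robust choice. Bonferroni adjustment is `min(1, p·m)`.

Validation: the engine is checked against textbook cell-mean formulas
implemented independently in the tests, against `pingouin` (one- and two-way
within designs, including epsilon, Mauchly and generalized eta-squared),
against `statsmodels` `AnovaRM` (three-way within), and against frozen
reference values from an independent Type III mixed-model implementation for
an unbalanced two-group design; its null behavior is calibrated by a
1,000-replicate type-I-error simulation.

## 7. Problem sizes and performance

The full default study (19 participants × 2 sessions × 160 trials ≈ 1.05 M
trajectory samples) simulates and reduces in a few seconds; the acceptance
script's complete run — full pipeline, 1,000-trial detector comparison and a
16-study strategy-recovery sweep — completes in well under a minute. These
sizes were chosen so the entire validation suite runs quickly on a laptop
while still exercising the statistics at realistic scale.
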