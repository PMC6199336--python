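# Methods

## The force matching task and what this package computes

In the force matching task a lever driven by a torque motor presses on the
participant's left index finger with a target force (1.0, 1.5, 2.0 or
2.5 N, each presented once per cycle of four trials) for 2.5 s.  The force
is then removed — the go cue — and the participant reproduces the sensed
force during a 4.5 s matching period, either by pressing the lever
directly with the right index finger (*Direct*) or by moving a slider that
drives the motor (*Slider*).  Because a direct press is self-generated,
its predicted sensory consequences are attenuated, and participants
systematically *overcompensate*: matched force exceeds target force.  The
slider breaks the mapping between the pressing hand and the felt force, so
Slider matching is nearly veridical and serves as a bias/sensitivity
control.

Per trial, the **matched force** is the mean force inside the 500 ms
window of the matching period with the minimum force variability (sample
SD, ddof = 1), located by sliding a window one sample at a time.  Per
subject and condition the package computes mean overcompensation
(matched − target), the OLS slope/intercept/R²/residual variance of
matched against target force, mean within-trial SD and its correlation
with matched force, the within-window linear trend, and mean
initiation/stabilization times.  Group comparisons use two-tailed tests —
Mann-Whitney Z for patient-versus-control contrasts (unequal group
sizes), t tests and Wilcoxon signed-rank within patients — and the
clinical analysis regresses Direct overcompensation on disease severity
(UPDRS-III) and levodopa dose equivalent (LDE), with Slider slope,
within-trial SD and the matching fit's unexplained variance as covariates
of no interest, all variables Z-scaled before the fit.

## Synthetic cohorts

No public patient-level recordings exist for this task, so the
`simulate` module generates complete datasets with known ground truth.
One trial's trace is: target force during presentation; zero after the
go cue until a sampled initiation latency; a smoothstep ramp (0.35 s
default rise) to a plateau at the intended matched force

    plateau = baseline_bias + matching_gain * target (+ attenuation_bias in Direct)

plus, sample-by-sample, Gaussian noise with SD = `noise_floor` +
`noise_cv` * (intended force) — the signal-dependent motor-noise law that
makes force variability grow with force level — and optional linear drift
and sinusoidal tremor.  Attenuation is additive by default; a
multiplicative mode turns it into a slope effect.  A per-trial
`plateau_jitter_sd` adds motor-planning variability to the intended
plateau, which is what gives realistic (sub-unity) matching-fit R² values;
without it the only trial-to-trial variability would be the tiny
within-window noise.

Key generator defaults (all config-exposed; per-condition and per-group):

| parameter | controls | patients | why |
|---|---|---|---|
| Direct gain | 1.00 | 0.90 | patients slightly compressed |
| Slider gain | 0.85 | 0.65 | reduced force sensitivity in PD |
| Slider intercept (N) | 0.26 | 0.61 | chosen so mean Slider overcompensation ≈ 0 |
| attenuation mean / SD (N) | 1.5 / 0.9 | 1.5 / 0.9 | attenuation is robust and not group-different |
| noise floor / CV | 0.03 / 0.07 | 0.05 / 0.10 | higher within-trial variability in PD |
| plateau jitter SD (N) | 0.15 | 0.25 | trial-to-trial planning noise |
| tremor (N @ Hz) | 0 | 0.08 @ 5 | mild rest tremor |
| initiation latency (s) | 0.40 ± 0.10 | 0.45 ± 0.15 | slower initiation in PD |
| premature / late rate | 0.02 / 0.03 | 0.03 / 0.05 | task repeats failed trials |

The attenuation mean of 1.5 N follows from the reported one-sample t and
SD of Direct overcompensation at n = 18.  Patient attenuation is tied to
the clinical covariates as `attenuation = 1.5 − 0.5·z(severity) +
0.5·z(LDE) + N(0, 0.6)`, with corr(z-severity, z-LDE) = 0.46 — the
structure (worse disease → less attenuation; more dopamine → more
attenuation; the two covariates positively correlated) that the clinical
regression is meant to recover.  UPDRS-III and LDE marginals
(20 ± 6.5, 1020 ± 500) and the demographic distributions mirror the
packaged patient table.  Each cohort alternates condition order across
subjects, runs 8 familiarisation + 32 main trials per condition, flags
premature/late trials and appends one forced-valid replacement at the
same target (a bounded stand-in for "repeat until valid").  Everything is
reproducible byte-for-byte from the master seed via spawned per-subject
substreams.

The sampling rate of the force sensor is not documented for the original
apparatus; the default is 500 Hz, giving a 250-sample analysis window.

**What the generator does not emulate.** White within-trial noise (real
force output has low-frequency structure), no biomechanics of the finger
or lever, no slider-to-motor dynamics, no fatigue or learning across
trials, no off-medication state.  Consequently the within-trial SD versus
matched-force correlation is near-perfect in synthetic subjects (real
values are positive but noisier), and passing recovery tests demonstrates
correctness of the pipeline's estimators, not fidelity of any particular
neural interpretation.

## Numerical and procedural choices

* **Window search.** Variability = sample SD (ddof 1); stride = one
  sample; ties broken by earliest start.  The admissible windows start at
  or after the detected initiation time: the force is flat before movement
  onset, so an unrestricted minimum-variability search would select the
  silent gap after the go cue rather than the stabilised response.  When a
  very late response leaves less than one window after onset, the search
  falls back to the whole matching period (such trials are flagged late
  and excluded from metrics anyway).
* **Initiation.** First crossing of baseline + 5% of the target force
  sustained for 50 ms after the go cue (baseline 0 by default, or
  estimated from the first samples after the cue); absence is a value.
  No canonical onset criterion exists for this task; this is a standard
  onset-detection convention and is config-exposed.
* **Stabilization time** = selected-window start relative to the go cue;
  a window-centre alternative is exposed.
* **Premature detection** during presentation uses sustained force above
  target × 1.05, since the participant's press adds to the motor force.
* **Validity is re-derived from traces** during processing, so simulated
  and real datasets flow through identical code; on synthetic data the
  detector reproduces the generator's flags.
* **Unexplained variance** of the matching fit defaults to RSS/(n − 2)
  (an unbiased noise estimate usable as a covariate); RSS and 1 − R² are
  selectable, as the three differ as regression covariates.
* **Force-magnitude correlations** use the matched (not target) force;
  with a numerically constant partner variable (e.g. zero within-trial SD
  in noise-free data) the correlation is reported as 0 rather than NaN.
* **Mann-Whitney / Wilcoxon** are reported as tie-corrected
  normal-approximation Z without continuity correction, positive when the
  first sample ranks higher (or differences are predominantly positive);
  exact enumeration p-values are available for small samples and are used
  as test oracles.
* **KS normality** plugs the sample mean and SD into a one-sample KS test
  and uses the small-sample (exact) null distribution of D; no Lilliefors
  correction for estimated parameters is applied, so the test is
  conservative.  This matches the conventional reporting the package
  reproduces (an exact-null p of 0.26 at D = 0.228, n = 18).
* **Chi-square** (2×2) uses no continuity correction by default (Yates
  optional); this reproduces the published gender statistic from the raw
  counts.
* **Bonferroni family** for the slope/intercept group contrasts is m = 4
  (two parameters × two conditions), the most conservative consistent
  reading; m is configurable.
* **Standardized regression** z-scales the dependent variable together
  with all predictors (ddof 1), fits OLS with intercept, and reports
  per-coefficient t with df = n − k − 1; exactly collinear designs raise
  an error naming the offending columns.
* **Cohort summary rounding** is half-away-from-zero to integers,
  matching the printed average row.  Note the packaged patient table's
  printed mean disease duration (13) differs from the mean of its own
  per-patient values (12.44 → 12); the package reports the computed value
  and leaves the discrepancy documented rather than resolved.

## Problem sizes used in tests and the acceptance script

Shared test cohorts use 8 patients + 8 controls (default noise) and a
3 + 2 deterministic cohort; the window-search oracle is checked on
500–1000 randomised traces; estimator bias uses 150–200 independent
single-subject simulations of 32 valid trials; covariate sign recovery
uses 100 cohorts of 50 patients at the generator level plus one
full-trace 50-patient pipeline run; the acceptance script additionally
runs one full study-scale cohort (18 patients, 175 controls).  At n = 18
patients the five-predictor clinical model recovers both covariate signs
in roughly nine out of ten seeds (the within-trial SD covariate is
partially collinear with attenuation through the signal-dependent noise
law); at the 50-patient recovery scale the signs are essentially always
recovered.

## Known limitations

* Initiation/stabilization operationalizations are this package's
  decisions; reported group timing values cannot pin down the original
  definitions, so only their comparative behaviour is meaningful.
* The KS p-value is conservative for estimated parameters (no Lilliefors
  correction), matching convention rather than strict calibration.
* The normal-approximation Z for rank tests is inaccurate for very small
  groups; use `method="exact"` there.
* LDE is consumed as an input; conversion from drug regimens is out of
  scope, as are neuroimaging/EEG analyses and hardware control.
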