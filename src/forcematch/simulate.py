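"""Synthetic force-matching cohorts with known ground truth.

No public accession exists for patient-level force-matching data, so this
module generates complete, realistic datasets — force traces, trial
metadata and a clinical covariate table — from explicit generating
parameters, enabling parameter-recovery tests of every downstream stage.

The generating model for one trial: after a sampled initiation latency the
participant's force rises along a smoothstep ramp to a plateau at the
intended matched force

    plateau = baseline_bias + matching_gain * target (+ attenuation, Direct)

with attenuation entering additively (default) or multiplicatively on the
target.  Samples around the plateau carry signal-dependent Gaussian noise
with SD = noise_floor + noise_cv * force — the classic association between
generated force level and force variability — plus optional linear drift
and sinusoidal tremor.  Sensory attenuation appears only in the Direct
condition, where the self-generated press is predicted and hence perceived
as weaker; matching through the slider breaks that prediction, so the
Slider condition carries no attenuation term.

Patient attenuation is tied to simulated clinical covariates: more severe
motor signs (UPDRS-III) lower attenuation while a higher levodopa dose
equivalent (LDE) raises it, with the two covariates themselves positively
correlated — the structure the clinical regressions are meant to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .task import CONDITIONS, DIRECT, ForceTrace, TaskDesign, Trial, validate_condition

__all__ = [
    "SubjectProfile",
    "GroupBehavior",
    "CohortConfig",
    "CohortData",
    "generate_target_sequence",
    "simulate_trial",
    "draw_cohort_profiles",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Generating parameters for one simulated participant.

    ``matching_gain`` and ``baseline_bias`` are per-condition mappings
    (keys ``"direct"``/``"slider"``).  ``attenuation_bias`` (N) is the
    Direct-condition overcompensation at the plateau; with
    ``attenuation_mode="multiplicative"`` it instead scales the target's
    contribution, turning attenuation into a slope effect.
    ``plateau_jitter_sd`` is trial-to-trial variability of the intended
    plateau (motor-planning noise), distinct from the within-trial
    signal-dependent noise governed by ``noise_floor``/``noise_cv``.
    """

    subject_id: str
    group: str  # "patient" | "control"
    attenuation_bias: float
    matching_gain: dict
    baseline_bias: dict
    plateau_jitter_sd: float = 0.0
    noise_floor: float = 0.0
    noise_cv: float = 0.0
    drift_rate: float = 0.0
    tremor_amplitude: float = 0.0
    tremor_frequency: float = 5.0
    initiation_latency_mean: float = 0.4
    initiation_latency_sd: float = 0.1
    premature_rate: float = 0.0
    late_rate: float = 0.0
    rise_time: float = 0.35
    attenuation_mode: str = "additive"

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise InvalidArgumentError("group must be 'patient' or 'control'")
        for cond in CONDITIONS:
            if cond not in self.matching_gain or cond not in self.baseline_bias:
                raise InvalidArgumentError(
                    f"matching_gain and baseline_bias need a {cond!r} entry"
                )
        if self.noise_floor < 0 or self.noise_cv < 0:
            raise InvalidArgumentError("noise parameters must be >= 0")
        if self.plateau_jitter_sd < 0:
            raise InvalidArgumentError("plateau_jitter_sd must be >= 0")
        if not (0.0 <= self.premature_rate + self.late_rate < 1.0):
            raise InvalidArgumentError(
                "premature_rate + late_rate must lie in [0, 1)"
            )
        if self.tremor_amplitude > 0 and self.tremor_frequency <= 0:
            raise InvalidArgumentError(
                "tremor_frequency must be positive when tremor_amplitude > 0"
            )
        if self.rise_time <= 0:
            raise InvalidArgumentError("rise_time must be positive")
        if self.attenuation_mode not in ("additive", "multiplicative"):
            raise InvalidArgumentError(
                "attenuation_mode must be 'additive' or 'multiplicative'"
            )

    def intended_plateau(self, condition: str, target: float) -> float:
        """Noise-free intended matched force for one trial."""
        cond = validate_condition(condition)
        gain = self.matching_gain[cond]
        bias = self.baseline_bias[cond]
        if cond == DIRECT:
            if self.attenuation_mode == "additive":
                return bias + gain * target + self.attenuation_bias
            return bias + gain * (1.0 + self.attenuation_bias) * target
        return bias + gain * target


@dataclass(frozen=True)
class GroupBehavior:
    """Population-level behavioural parameters from which subject profiles
    are drawn.  ``*_sd`` fields are between-subject standard deviations."""

    direct_gain_mean: float = 1.0
    slider_gain_mean: float = 0.85
    gain_sd: float = 0.12
    direct_bias_mean: float = 0.0
    slider_bias_mean: float = 0.26
    bias_sd: float = 0.10
    attenuation_mean: float = 1.5
    attenuation_sd: float = 0.9
    plateau_jitter_sd: float = 0.15
    noise_floor: float = 0.03
    noise_floor_sd: float = 0.02
    noise_cv: float = 0.07
    noise_cv_sd: float = 0.03
    drift_rate: float = 0.0
    tremor_amplitude: float = 0.0
    tremor_frequency: float = 5.0
    initiation_latency_mean: float = 0.40
    initiation_latency_sd: float = 0.10
    premature_rate: float = 0.02
    late_rate: float = 0.03
    rise_time: float = 0.35


#: Control defaults: accurate gain in Direct, mildly compressed Slider gain,
#: low noise, no tremor.
CONTROL_BEHAVIOR = GroupBehavior()

#: Patient defaults: reduced Slider gain with compensating intercept
#: (reduced force sensitivity), larger within-trial and trial-to-trial
#: variability, mild rest tremor, slightly slower initiation.
PATIENT_BEHAVIOR = GroupBehavior(
    direct_gain_mean=0.9,
    slider_gain_mean=0.65,
    direct_bias_mean=0.0,
    slider_bias_mean=0.61,
    attenuation_mean=1.5,
    attenuation_sd=0.9,
    plateau_jitter_sd=0.25,
    noise_floor=0.05,
    noise_cv=0.10,
    tremor_amplitude=0.08,
    tremor_frequency=5.0,
    initiation_latency_mean=0.45,
    initiation_latency_sd=0.15,
    premature_rate=0.03,
    late_rate=0.05,
)


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for a synthetic cohort.

    The patient covariate model ties each patient's generating
    ``attenuation_bias`` to standardized disease severity (negative
    coefficient) and standardized LDE (positive coefficient):

        attenuation = attenuation_mean
                      + severity_coef * z_severity
                      + lde_coef * z_lde
                      + N(0, attenuation_noise_sd)

    with corr(z_severity, z_lde) = ``severity_lde_corr``.  Demographic
    distributions default to the published cohort (18 patients, 175
    controls drawn from the patients' 48-81 year age range).
    """

    n_patients: int = 18
    n_controls: int = 175
    design: TaskDesign = field(default_factory=TaskDesign)
    patient_behavior: GroupBehavior = field(default_factory=lambda: PATIENT_BEHAVIOR)
    control_behavior: GroupBehavior = field(default_factory=lambda: CONTROL_BEHAVIOR)
    # patient covariate model
    severity_coef: float = -0.5
    lde_coef: float = 0.5
    attenuation_noise_sd: float = 0.6
    severity_lde_corr: float = 0.46
    updrs_mean: float = 20.0
    updrs_sd: float = 6.5
    lde_mean: float = 1020.0
    lde_sd: float = 500.0
    # demographics
    patient_age_mean: float = 67.0
    patient_age_sd: float = 10.0
    control_age_mean: float = 65.0
    control_age_sd: float = 10.0
    age_range: tuple[float, float] = (48.0, 81.0)
    male_fraction_patients: float = 12.0 / 18.0
    male_fraction_controls: float = 89.0 / 175.0
    attenuation_mode: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 0:
            raise InvalidArgumentError("need n_patients >= 1 and n_controls >= 0")
        if self.severity_coef > 0 or self.lde_coef < 0:
            raise InvalidArgumentError(
                "default covariate model requires severity_coef <= 0 and "
                "lde_coef >= 0"
            )
        if not (-1.0 < self.severity_lde_corr < 1.0):
            raise InvalidArgumentError("severity_lde_corr must lie in (-1, 1)")

    def zero_noise(self) -> "CohortConfig":
        """A copy with every stochastic behavioural term switched off.

        Covariate draws remain random, but trials become deterministic
        functions of the generating parameters (used by closure tests).
        """
        quiet = dict(
            gain_sd=0.0,
            bias_sd=0.0,
            attenuation_sd=0.0,
            plateau_jitter_sd=0.0,
            noise_floor=0.0,
            noise_floor_sd=0.0,
            noise_cv=0.0,
            noise_cv_sd=0.0,
            drift_rate=0.0,
            tremor_amplitude=0.0,
            initiation_latency_sd=0.0,
            premature_rate=0.0,
            late_rate=0.0,
        )
        return replace(
            self,
            patient_behavior=replace(self.patient_behavior, **quiet),
            control_behavior=replace(self.control_behavior, **quiet),
            attenuation_noise_sd=0.0,
        )


def generate_target_sequence(
    n_cycles: int,
    rng: np.random.Generator,
    target_set: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5),
) -> np.ndarray:
    """Pseudo-random target schedule: each cycle of four trials presents
    each target force exactly once, in a freshly permuted order."""
    if n_cycles < 1:
        raise InvalidArgumentError("n_cycles must be >= 1")
    targets = np.asarray(target_set, dtype=float)
    return np.concatenate([rng.permutation(targets) for _ in range(n_cycles)])


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def simulate_trial(
    profile: SubjectProfile,
    design: TaskDesign,
    condition: str,
    target: float,
    rng: np.random.Generator,
    *,
    status: str | None = None,
) -> Trial:
    """Simulate one trial's force trace.

    The sensor reads the motor's target force during the presentation
    period and the participant's matching force afterwards; a premature
    response adds the participant's press on top of the motor force before
    the go cue.  ``status`` forces the outcome (used for replacements);
    otherwise premature/late outcomes are drawn from the profile's rates.
    """
    cond = validate_condition(condition)
    if not design.contains_target(target):
        raise InvalidArgumentError(
            f"target {target} N is not in the design's target set"
        )
    if status is None:
        u = rng.random()
        if u < profile.premature_rate:
            status = "premature"
        elif u < profile.premature_rate + profile.late_rate:
            status = "late"
        else:
            status = "valid"

    plateau = profile.intended_plateau(cond, target)
    if profile.plateau_jitter_sd > 0:
        plateau += rng.normal(0.0, profile.plateau_jitter_sd)
    plateau = max(plateau, 0.05)  # a participant always presses something

    pe = design.presentation_end
    if status == "premature":
        onset = pe - rng.uniform(0.2, min(1.0, design.presentation_duration - 0.1))
    elif status == "late":
        onset = pe + design.late_threshold + 0.05 + rng.exponential(0.2)
    else:
        latency = rng.normal(
            profile.initiation_latency_mean, profile.initiation_latency_sd
        )
        latency = float(np.clip(latency, 0.08, design.late_threshold - 0.05))
        onset = pe + latency

    sr = design.sampling_rate
    n = int(round(design.matching_end * sr)) + 1
    t = np.arange(n) / sr

    # participant's intended force: smoothstep ramp to the plateau
    intended = plateau * _smoothstep((t - onset) / profile.rise_time)
    active = t >= onset

    force = intended.copy()
    sd = profile.noise_floor + profile.noise_cv * intended
    if np.any(sd[active] > 0):
        noise = rng.standard_normal(n) * sd
        force = force + np.where(active, noise, 0.0)
    if profile.drift_rate != 0.0:
        ramp_end = onset + profile.rise_time
        force = force + np.where(
            t >= ramp_end, profile.drift_rate * (t - ramp_end), 0.0
        )
    if profile.tremor_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        tremor = profile.tremor_amplitude * np.sin(
            2.0 * math.pi * profile.tremor_frequency * (t - onset) + phase
        )
        force = force + np.where(active, tremor, 0.0)

    # motor applies the target force until the go cue
    force = force + np.where(t < pe, target, 0.0)
    np.clip(force, 0.0, None, out=force)

    trace = ForceTrace(
        force=force,
        sampling_rate=sr,
        presentation_end=pe,
        matching_end=design.matching_end,
    )
    return Trial(
        subject_id=profile.subject_id,
        group=profile.group,
        condition=cond,
        phase="main",
        trial_index=-1,
        cycle_index=-1,
        target_force=float(target),
        status=status,
        trace=trace,
        intended_plateau=plateau,
        initiation_latency=onset - pe,
    )


def _simulate_condition(
    profile: SubjectProfile,
    design: TaskDesign,
    condition: str,
    rng: np.random.Generator,
) -> list[Trial]:
    trials: list[Trial] = []
    index = 0
    for phase, cycles in (
        ("familiarisation", design.familiarisation_cycles),
        ("main", design.main_cycles),
    ):
        if cycles == 0:
            continue
        targets = generate_target_sequence(cycles, rng, design.target_set)
        for k, target in enumerate(targets):
            cycle = k // len(design.target_set)
            trial = simulate_trial(profile, design, condition, target, rng)
            trial.phase = phase
            trial.trial_index = index
            trial.cycle_index = cycle
            trials.append(trial)
            index += 1
            if trial.status != "valid":
                # the task warns and repeats the trial at the same target
                redo = simulate_trial(
                    profile, design, condition, target, rng, status="valid"
                )
                redo.phase = phase
                redo.trial_index = index
                redo.cycle_index = cycle
                redo.repeat_of = trial.trial_index
                trials.append(redo)
                index += 1
    return trials


def _draw_profile(
    subject_id: str,
    group: str,
    behavior: GroupBehavior,
    attenuation: float,
    rng: np.random.Generator,
    attenuation_mode: str,
) -> SubjectProfile:
    def draw(mean: float, sd: float, lo: float, hi: float) -> float:
        return float(np.clip(rng.normal(mean, sd) if sd > 0 else mean, lo, hi))

    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        attenuation_bias=attenuation,
        matching_gain={
            "direct": draw(behavior.direct_gain_mean, behavior.gain_sd, 0.2, 1.8),
            "slider": draw(behavior.slider_gain_mean, behavior.gain_sd, 0.2, 1.8),
        },
        baseline_bias={
            "direct": draw(behavior.direct_bias_mean, behavior.bias_sd, -1.0, 1.5),
            "slider": draw(behavior.slider_bias_mean, behavior.bias_sd, -1.0, 1.5),
        },
        plateau_jitter_sd=behavior.plateau_jitter_sd,
        noise_floor=draw(behavior.noise_floor, behavior.noise_floor_sd, 0.0, 0.5),
        noise_cv=draw(behavior.noise_cv, behavior.noise_cv_sd, 0.0, 0.5),
        drift_rate=behavior.drift_rate,
        tremor_amplitude=behavior.tremor_amplitude,
        tremor_frequency=behavior.tremor_frequency,
        initiation_latency_mean=behavior.initiation_latency_mean,
        initiation_latency_sd=behavior.initiation_latency_sd,
        premature_rate=behavior.premature_rate,
        late_rate=behavior.late_rate,
        rise_time=behavior.rise_time,
        attenuation_mode=attenuation_mode,
    )


# Hoehn-Yahr stage, dominant-side and cognition draws mirror the published
# patient table's empirical frequencies.
_HY_STAGES = (1.0, 1.5, 2.0, 2.5, 3.0)
_HY_PROBS = (4 / 18, 2 / 18, 5 / 18, 3 / 18, 4 / 18)
_SIDES = ("L", "R", "B")
_SIDE_PROBS = (11 / 18, 4 / 18, 3 / 18)


def draw_cohort_profiles(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[SubjectProfile], pd.DataFrame, pd.DataFrame]:
    """Draw subject profiles and the clinical covariate table.

    Returns ``(profiles, clinical, subject_truth)``.  ``clinical`` has the
    standard clinical.csv columns plus ``subject_id`` and ``group``;
    patient-only scores are missing (NaN) for controls, never zero.
    ``subject_truth`` records every generating parameter per subject.
    """
    profiles: list[SubjectProfile] = []
    clin_rows = []
    truth_rows = []

    corr = config.severity_lde_corr
    cov = np.array([[1.0, corr], [corr, 1.0]])
    chol = np.linalg.cholesky(cov)

    for i in range(config.n_patients):
        sid = f"P{i + 1:03d}"
        z = chol @ rng.standard_normal(2)
        z_sev, z_lde = float(z[0]), float(z[1])
        updrs = float(np.clip(round(config.updrs_mean + config.updrs_sd * z_sev), 5, 60))
        lde = float(np.clip(round(config.lde_mean + config.lde_sd * z_lde), 50, 3500))
        attenuation = (
            config.patient_behavior.attenuation_mean
            + config.severity_coef * z_sev
            + config.lde_coef * z_lde
        )
        if config.attenuation_noise_sd > 0:
            attenuation += rng.normal(0.0, config.attenuation_noise_sd)
        profile = _draw_profile(
            sid, "patient", config.patient_behavior, attenuation, rng,
            config.attenuation_mode,
        )
        profiles.append(profile)
        age = float(
            np.clip(
                round(rng.normal(config.patient_age_mean, config.patient_age_sd)),
                *config.age_range,
            )
        )
        clin_rows.append(
            {
                "subject_id": sid,
                "group": "patient",
                "patient_no": i + 1,
                "gender": "M" if rng.random() < config.male_fraction_patients else "F",
                "age": age,
                "disease_duration_y": float(round(np.clip(rng.lognormal(2.4, 0.5), 1, 30))),
                "dominant_side": rng.choice(_SIDES, p=_SIDE_PROBS),
                "hoehn_yahr": float(rng.choice(_HY_STAGES, p=_HY_PROBS)),
                "updrs_motor": updrs,
                "ace_r": float(np.clip(round(rng.normal(93, 4)), 84, 100)),
                "mmse": float(np.clip(round(rng.normal(28.6, 1.0)), 24, 30)),
                "lde": lde,
            }
        )
        truth_rows.append(_truth_row(profile, z_sev=z_sev, z_lde=z_lde))

    for i in range(config.n_controls):
        sid = f"C{i + 1:03d}"
        behavior = config.control_behavior
        attenuation = behavior.attenuation_mean
        if behavior.attenuation_sd > 0:
            attenuation += rng.normal(0.0, behavior.attenuation_sd)
        profile = _draw_profile(
            sid, "control", behavior, attenuation, rng, config.attenuation_mode
        )
        profiles.append(profile)
        age = float(
            np.clip(
                round(rng.normal(config.control_age_mean, config.control_age_sd)),
                *config.age_range,
            )
        )
        clin_rows.append(
            {
                "subject_id": sid,
                "group": "control",
                "patient_no": np.nan,
                "gender": "M" if rng.random() < config.male_fraction_controls else "F",
                "age": age,
                "disease_duration_y": np.nan,
                "dominant_side": None,
                "hoehn_yahr": np.nan,
                "updrs_motor": np.nan,
                "ace_r": np.nan,
                "mmse": np.nan,
                "lde": np.nan,
            }
        )
        truth_rows.append(_truth_row(profile, z_sev=np.nan, z_lde=np.nan))

    clinical = pd.DataFrame(clin_rows)
    truth = pd.DataFrame(truth_rows)
    return profiles, clinical, truth


def _truth_row(profile: SubjectProfile, *, z_sev: float, z_lde: float) -> dict:
    return {
        "subject_id": profile.subject_id,
        "group": profile.group,
        "attenuation_bias": profile.attenuation_bias,
        "direct_gain": profile.matching_gain["direct"],
        "slider_gain": profile.matching_gain["slider"],
        "direct_bias": profile.baseline_bias["direct"],
        "slider_bias": profile.baseline_bias["slider"],
        "plateau_jitter_sd": profile.plateau_jitter_sd,
        "noise_floor": profile.noise_floor,
        "noise_cv": profile.noise_cv,
        "z_severity": z_sev,
        "z_lde": z_lde,
    }


@dataclass
class CohortData:
    """A fully simulated cohort: trials with traces, the clinical table and
    the generating ground truth (per subject and per trial)."""

    trials: list[Trial]
    clinical: pd.DataFrame
    subject_truth: pd.DataFrame
    trial_truth: pd.DataFrame
    profiles: list[SubjectProfile]
    config: CohortConfig

    def trials_frame(self) -> pd.DataFrame:
        """Long-format trial metadata (the trials.csv dialect)."""
        rows = [
            {
                "subject_id": tr.subject_id,
                "group": tr.group,
                "condition": tr.condition,
                "phase": tr.phase,
                "trial_index": tr.trial_index,
                "cycle_index": tr.cycle_index,
                "target_force_N": tr.target_force,
                "status": tr.status,
                "repeat_of": tr.repeat_of,
            }
            for tr in self.trials
        ]
        return pd.DataFrame(rows)


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Simulate a complete cohort, reproducibly from ``config.seed``.

    Each subject performs both conditions in a counterbalanced order
    (alternating which comes first), with familiarisation cycles followed
    by the main trials; premature/late trials are flagged and immediately
    repeated at the same target force.
    """
    root = np.random.SeedSequence(config.seed)
    profile_seed, trial_seed = root.spawn(2)
    rng_profiles = np.random.default_rng(profile_seed)
    profiles, clinical, subject_truth = draw_cohort_profiles(config, rng_profiles)

    all_trials: list[Trial] = []
    subject_streams = trial_seed.spawn(len(profiles))
    for i, profile in enumerate(profiles):
        rng = np.random.default_rng(subject_streams[i])
        order = CONDITIONS if i % 2 == 0 else CONDITIONS[::-1]
        for condition in order:
            all_trials.extend(
                _simulate_condition(profile, config.design, condition, rng)
            )

    trial_truth = pd.DataFrame(
        [
            {
                "subject_id": tr.subject_id,
                "condition": tr.condition,
                "phase": tr.phase,
                "trial_index": tr.trial_index,
                "target_force_N": tr.target_force,
                "intended_plateau_N": tr.intended_plateau,
                "initiation_latency_s": tr.initiation_latency,
                "status": tr.status,
                "repeat_of": tr.repeat_of,
            }
            for tr in all_trials
        ]
    )
    return CohortData(
        trials=all_trials,
        clinical=clinical,
        subject_truth=subject_truth,
        trial_truth=trial_truth,
        profiles=profiles,
        config=config,
    )
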