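import numpy as np
import pytest

from forcematch import CohortConfig, GroupBehavior, TaskDesign, simulate_cohort
from forcematch.pipeline import analyze_cohort


@pytest.fixture(scope="session")
def design():
    return TaskDesign()


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small default-noise cohort shared across tests (read-only)."""
    return simulate_cohort(CohortConfig(n_patients=8, n_controls=8, seed=42))


@pytest.fixture(scope="session")
def noisy_results(noisy_cohort):
    report, trial_measures, subject_measures = analyze_cohort(noisy_cohort)
    return {
        "report": report,
        "trial_measures": trial_measures,
        "subject_measures": subject_measures,
    }


def make_zero_noise_config(
    n_patients=3, n_controls=2, seed=7, attenuation=1.0
) -> CohortConfig:
    """Deterministic cohort: unit gain, no biases, fixed attenuation."""
    flat = GroupBehavior(
        direct_gain_mean=1.0,
        slider_gain_mean=1.0,
        direct_bias_mean=0.0,
        slider_bias_mean=0.0,
        attenuation_mean=attenuation,
    )
    return CohortConfig(
        n_patients=n_patients,
        n_controls=n_controls,
        patient_behavior=flat,
        control_behavior=flat,
        severity_coef=0.0,  # break the covariate link so every subject
        lde_coef=0.0,       # shares the same generating attenuation
        seed=seed,
    ).zero_noise()


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return simulate_cohort(make_zero_noise_config())


@pytest.fixture(scope="session")
def zero_noise_results(zero_noise_cohort):
    report, trial_measures, subject_measures = analyze_cohort(zero_noise_cohort)
    return {
        "report": report,
        "trial_measures": trial_measures,
        "subject_measures": subject_measures,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
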