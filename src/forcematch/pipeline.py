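"""End-to-end orchestration: trial measures -> subject metrics -> report.

``analyze_measures`` runs the full battery of group comparisons and
clinical regressions on a subject_measures table plus a clinical table and
returns a structured :class:`AnalysisReport`; ``analyze_cohort`` runs the
whole chain on an in-memory synthetic cohort, and ``run_full_analysis``
does the same from files on disk.

Analysis battery (patients-only tests use parametric statistics after a
KS normality check; patient-versus-control contrasts use Mann-Whitney Z
because of the very unequal group sizes; the four slope/intercept group
contrasts share a Bonferroni family):

* demographics: age (Mann-Whitney), gender (2x2 chi-square);
* timing: initiation and stabilization times per condition across groups;
* attenuation: Direct overcompensation > 0, Direct vs Slider (paired),
  Slider vs 0, Direct-Slider correlation, group contrasts;
* matching fits: slope/intercept/R^2 group contrasts, Direct slope vs 1
  (Wilcoxon);
* motor-output checks: within-trial SD, window trend, trend-force and
  force-SD correlations;
* clinical regressions: standardized models for Direct overcompensation
  (severity + LDE + nuisance covariates), Slider overcompensation and
  Slider slope (severity + LDE).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .exceptions import InvalidArgumentError, SubjectMismatchError
from .metrics import summarize_trials
from .simulate import CohortData
from .stats import (
    RegressionResult,
    TestResult,
    bonferroni,
    chi_square_2x2,
    ks_normality,
    pearson_r,
    rank_test,
    standardized_regression,
    t_test,
)
from .task import TaskDesign
from .traces import process_trials

__all__ = ["AnalysisReport", "analyze_measures", "analyze_cohort", "run_full_analysis"]

REPORT_SCHEMA_VERSION = 1

#: Family size for the slope/intercept group contrasts: two parameters x
#: two conditions, the most conservative consistent reading.
BONFERRONI_FAMILY = 4


@dataclass
class AnalysisReport:
    """Structured results of all group tests and regressions."""

    cohort_summary: dict
    tests: dict[str, TestResult]
    regressions: dict[str, RegressionResult]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "cohort_summary": self.cohort_summary,
            "tests": {k: v.to_dict() for k, v in sorted(self.tests.items())},
            "regressions": {
                k: v.to_dict() for k, v in sorted(self.regressions.items())
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_json_default)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _wide(measures: pd.DataFrame) -> pd.DataFrame:
    """subject_measures in wide form: one row per subject, columns
    ``<metric>__<condition>`` plus group."""
    value_cols = [
        c
        for c in measures.columns
        if c not in ("subject_id", "condition", "group")
    ]
    wide = measures.pivot(index="subject_id", columns="condition", values=value_cols)
    wide.columns = [f"{m}__{c}" for m, c in wide.columns]
    groups = measures.groupby("subject_id")["group"].first()
    wide["group"] = groups
    return wide


def analyze_measures(
    measures: pd.DataFrame,
    clinical: pd.DataFrame,
    *,
    bonferroni_family: int = BONFERRONI_FAMILY,
) -> AnalysisReport:
    """Run the full statistical battery.

    ``measures``: subject_measures table (one row per subject x condition,
    with a ``group`` column).  ``clinical``: cohort clinical table with
    ``subject_id``, ``group``, ``gender``, ``age`` and, for patients,
    ``updrs_motor`` and ``lde``.
    """
    wide = _wide(measures)
    pats = wide[wide["group"] == "patient"]
    ctls = wide[wide["group"] == "control"]
    if len(pats) == 0:
        raise InvalidArgumentError("no patient rows in subject measures")
    have_controls = len(ctls) >= 2

    tests: dict[str, TestResult] = {}
    regressions: dict[str, RegressionResult] = {}
    skipped: dict[str, str] = {}

    def attempt(key: str, fn) -> None:
        """Run one test; degenerate inputs (tiny or noise-free cohorts)
        are recorded as skips, not failures."""
        from .exceptions import DegenerateInputError, InvalidArgumentError as IAE

        try:
            tests[key] = fn()
        except (DegenerateInputError, IAE) as exc:
            skipped[key] = str(exc)

    clin = clinical.set_index("subject_id")
    pat_clin = clin[clin["group"] == "patient"].loc[pats.index]

    # --- demographics -----------------------------------------------------
    if have_controls:
        ctl_clin = clin[clin["group"] == "control"]
        attempt(
            "age_group_mw",
            lambda: rank_test(
                pat_clin["age"], ctl_clin["age"], kind="mann_whitney",
                name="age_group_mw",
            ),
        )
        pm = int((pat_clin["gender"] == "M").sum())
        cm = int((ctl_clin["gender"] == "M").sum())
        attempt(
            "gender_chi2",
            lambda: chi_square_2x2(
                pm, len(pat_clin) - pm, cm, len(ctl_clin) - cm, name="gender_chi2"
            ),
        )

    # --- timing and group contrasts per metric ----------------------------
    def mw(metric: str, cond: str, key: str) -> None:
        if not have_controls:
            return
        col = f"{metric}__{cond}"
        attempt(
            key,
            lambda: rank_test(
                pats[col].dropna(), ctls[col].dropna(), kind="mann_whitney", name=key
            ),
        )

    mw("mean_initiation_s", "direct", "direct_initiation_group_mw")
    mw("mean_initiation_s", "slider", "slider_initiation_group_mw")
    mw("mean_stabilization_s", "direct", "direct_stabilization_group_mw")
    mw("mean_stabilization_s", "slider", "slider_stabilization_group_mw")

    # --- attenuation ------------------------------------------------------
    d_over = pats["mean_overcompensation_N__direct"]
    s_over = pats["mean_overcompensation_N__slider"]
    attempt(
        "direct_overcomp_normality_ks",
        lambda: ks_normality(d_over, name="direct_overcomp_normality_ks"),
    )
    attempt(
        "slider_overcomp_normality_ks",
        lambda: ks_normality(s_over, name="slider_overcomp_normality_ks"),
    )
    attempt(
        "direct_overcomp_gt_zero",
        lambda: t_test(d_over, mu=0.0, name="direct_overcomp_gt_zero"),
    )
    attempt(
        "slider_overcomp_vs_zero",
        lambda: t_test(s_over, mu=0.0, name="slider_overcomp_vs_zero"),
    )
    attempt(
        "direct_vs_slider_overcomp",
        lambda: t_test(
            s_over.to_numpy(), d_over.to_numpy(), mode="paired",
            name="direct_vs_slider_overcomp",
        ),
    )
    attempt(
        "direct_slider_overcomp_corr",
        lambda: pearson_r(d_over, s_over, name="direct_slider_overcomp_corr"),
    )
    mw("mean_overcompensation_N", "direct", "direct_overcomp_group_mw")
    mw("mean_overcompensation_N", "slider", "slider_overcomp_group_mw")

    # --- matching fits ----------------------------------------------------
    mw("r_squared", "direct", "direct_r2_group_mw")
    mw("r_squared", "slider", "slider_r2_group_mw")
    contrast_keys = [
        ("slope", "direct", "direct_slope_group_mw"),
        ("intercept_N", "direct", "direct_intercept_group_mw"),
        ("slope", "slider", "slider_slope_group_mw"),
        ("intercept_N", "slider", "slider_intercept_group_mw"),
    ]
    for metric, cond, key in contrast_keys:
        mw(metric, cond, key)
    if have_controls:
        done = [k for _, _, k in contrast_keys if k in tests]
        raw = np.array([tests[k].p for k in done])
        adj = bonferroni(raw, bonferroni_family)
        for key, p_adj in zip(done, adj):
            t = tests[key]
            tests[key] = TestResult(
                name=t.name,
                statistic_name=t.statistic_name,
                statistic=t.statistic,
                p=float(p_adj),
                df=t.df,
                n=t.n,
                correction="bonferroni",
                extra={**t.extra, "p_uncorrected": t.p, "m": bonferroni_family},
            )
    attempt(
        "direct_slope_vs_one_wilcoxon",
        lambda: rank_test(
            pats["slope__direct"], kind="wilcoxon_signed_rank", mu=1.0,
            name="direct_slope_vs_one_wilcoxon",
        ),
    )

    # --- motor-output checks ----------------------------------------------
    mw("mean_within_trial_sd", "direct", "within_trial_sd_group_mw")
    attempt(
        "direct_trend_vs_zero",
        lambda: t_test(
            pats["mean_trend__direct"], mu=0.0, name="direct_trend_vs_zero"
        ),
    )
    mw("mean_trend", "direct", "direct_trend_group_mw")
    attempt(
        "r_trend_force_vs_zero",
        lambda: t_test(
            pats["r_trend_force__direct"].dropna(), mu=0.0,
            name="r_trend_force_vs_zero",
        ),
    )
    mw("r_trend_force", "direct", "r_trend_force_group_mw")
    attempt(
        "r_force_sd_gt_zero",
        lambda: t_test(
            pats["r_force_sd__direct"].dropna(), mu=0.0, name="r_force_sd_gt_zero"
        ),
    )
    mw("r_force_sd", "direct", "r_force_sd_group_mw")

    # --- clinical regressions --------------------------------------------
    have_clinical = (
        pat_clin["updrs_motor"].notna().all() and pat_clin["lde"].notna().all()
    )
    if have_clinical and len(pats) >= 8:
        attempt(
            "updrs_lde_correlation",
            lambda: pearson_r(
                pat_clin["updrs_motor"], pat_clin["lde"],
                name="updrs_lde_correlation",
            ),
        )
        nuisance = pd.DataFrame(
            {
                "slider_slope": pats["slope__slider"],
                "within_trial_sd": pats["mean_within_trial_sd__direct"],
                "unexplained_variance": pats["residual_variance__direct"],
            }
        )
        X_full = pd.concat(
            [
                pd.DataFrame(
                    {
                        "updrs_motor": pat_clin["updrs_motor"],
                        "lde": pat_clin["lde"],
                    }
                ),
                nuisance,
            ],
            axis=1,
        )
        roles = {
            "updrs_motor": "of_interest",
            "lde": "of_interest",
            "slider_slope": "nuisance",
            "within_trial_sd": "nuisance",
            "unexplained_variance": "nuisance",
        }
        from .exceptions import DegenerateInputError

        X_two = X_full[["updrs_motor", "lde"]]
        for key, dep, X in (
            ("direct_overcomp_model", d_over, X_full),
            ("slider_overcomp_model", s_over, X_two),
            ("slider_slope_model", pats["slope__slider"], X_two),
        ):
            try:
                regressions[key] = standardized_regression(
                    dep, X, roles=roles, name=key
                )
            except (DegenerateInputError, InvalidArgumentError) as exc:
                skipped[key] = str(exc)

    summary = {
        "n_patients": int(len(pats)),
        "n_controls": int(len(ctls)),
        "patients": _group_summary(pats),
        "controls": _group_summary(ctls) if have_controls else {},
        "skipped_tests": skipped,
    }
    return AnalysisReport(cohort_summary=summary, tests=tests, regressions=regressions)


def _group_summary(wide: pd.DataFrame) -> dict:
    out = {}
    for col in wide.columns:
        if col == "group":
            continue
        vals = wide[col].dropna()
        if len(vals) and np.issubdtype(vals.dtype, np.number):
            out[col] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return out


def _config_hash(config) -> str:
    from dataclasses import asdict, is_dataclass

    if is_dataclass(config):
        payload = json.dumps(asdict(config), sort_keys=True, default=str)
    else:
        payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze_cohort(
    cohort: CohortData,
    *,
    bonferroni_family: int = BONFERRONI_FAMILY,
    residual_mode: str = "mse",
) -> tuple[AnalysisReport, pd.DataFrame, pd.DataFrame]:
    """Process a simulated cohort end to end.

    Returns ``(report, trial_measures, subject_measures)``.
    """
    trial_measures = process_trials(cohort.trials, cohort.config.design)
    subject_measures = summarize_trials(trial_measures, residual_mode=residual_mode)
    report = analyze_measures(
        subject_measures, cohort.clinical, bonferroni_family=bonferroni_family
    )
    report.provenance = {
        "software": f"forcematch {_pkg_version}",
        "seed": cohort.config.seed,
        "config_sha256": _config_hash(cohort.config),
        "n_trials": len(cohort.trials),
    }
    return report, trial_measures, subject_measures


def run_full_analysis(
    trials_dir,
    clinical_path,
    *,
    design: TaskDesign | None = None,
    out_dir=None,
    bonferroni_family: int = BONFERRONI_FAMILY,
) -> AnalysisReport:
    """File-based pipeline: read a trials directory and a clinical CSV,
    check that subject ids reconcile, then process -> metrics -> stats.

    Writes ``trial_measures.csv``, ``subject_measures.csv`` and
    ``analysis_report.json`` into ``out_dir`` when given.  Deterministic
    given identical inputs.
    """
    from .io import load_cohort_dir

    design = design or TaskDesign()
    trials, clinical = load_cohort_dir(trials_dir, clinical_path, design)

    trial_subjects = {t.subject_id for t in trials}
    clin_subjects = set(clinical["subject_id"].astype(str))
    orphans = sorted(trial_subjects ^ clin_subjects)
    if orphans:
        raise SubjectMismatchError(
            f"subject ids do not reconcile across inputs: {orphans}",
            tuple(orphans),
        )

    trial_measures = process_trials(trials, design)
    subject_measures = summarize_trials(trial_measures)
    report = analyze_measures(
        subject_measures, clinical, bonferroni_family=bonferroni_family
    )
    report.provenance = {
        "software": f"forcematch {_pkg_version}",
        "trials_dir": str(trials_dir),
        "clinical_path": str(clinical_path),
        "n_trials": len(trials),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trial_measures.to_csv(out / "trial_measures.csv", index=False)
        subject_measures.to_csv(out / "subject_measures.csv", index=False)
        report.to_json(out / "analysis_report.json")
    return report
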