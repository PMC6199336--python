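"""Per-subject, per-condition aggregation of trial measures.

For each participant and condition the analysis uses: mean force
overcompensation (matched minus target force, averaged across the four
target levels — positive values in the Direct condition index sensory
attenuation); the slope, intercept, R^2 and residual variance of a linear
regression of matched on target force (the Slider slope serving as a
sensory-sensitivity proxy); mean within-trial variability and its
correlation with the matched force magnitude; and the within-window linear
trend and its correlation with force magnitude (a fatigue check).

Only valid main-experiment trials enter any metric; familiarisation trials
and flagged premature/late responses are excluded, their replacements used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, EmptyInputError, InvalidArgumentError

__all__ = [
    "MatchingFit",
    "mean_overcompensation",
    "fit_matching",
    "force_variability_profile",
    "summarize_subject",
    "summarize_trials",
]


@dataclass(frozen=True)
class MatchingFit:
    """OLS fit of matched force on target force for one subject-condition."""

    slope: float
    intercept: float
    r_squared: float
    residual_variance: float
    n: int


def mean_overcompensation(matched, target) -> float:
    """Mean of (matched - target) force across valid trials, in N."""
    matched = np.asarray(matched, dtype=float)
    target = np.asarray(target, dtype=float)
    if matched.size == 0:
        raise EmptyInputError("no valid trials")
    if matched.shape != target.shape:
        raise InvalidArgumentError("matched and target must align")
    return float(np.mean(matched - target))


def fit_matching(matched, target, *, residual_mode: str = "mse") -> MatchingFit:
    """Regress matched force on target force (OLS with intercept).

    ``residual_mode`` selects the "unexplained variance" convention:
    ``"mse"`` = RSS/(n-2) (default, an unbiased noise estimate), ``"rss"``
    = raw residual sum of squares, ``"fraction"`` = 1 - R^2.  The three are
    monotonically related for fixed n but differ as regression covariates.
    """
    matched = np.asarray(matched, dtype=float)
    target = np.asarray(target, dtype=float)
    if matched.size < 2 or np.unique(target).size < 2:
        raise DegenerateDesignError(
            "need >= 2 trials at >= 2 distinct target levels"
        )
    tc = target - target.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ (matched - matched.mean()) / sxx)
    intercept = float(matched.mean() - slope * target.mean())
    resid = matched - (intercept + slope * target)
    rss = float(resid @ resid)
    tss = float(np.sum((matched - matched.mean()) ** 2))
    if rss <= 1e-300:
        r_squared = 1.0
    elif tss > 0:
        r_squared = max(0.0, 1.0 - rss / tss)
    else:
        r_squared = 0.0
    n = matched.size
    if residual_mode == "mse":
        residual_variance = rss / (n - 2) if n > 2 else rss
    elif residual_mode == "rss":
        residual_variance = rss
    elif residual_mode == "fraction":
        residual_variance = 1.0 - r_squared
    else:
        raise InvalidArgumentError(
            "residual_mode must be 'mse', 'rss' or 'fraction'"
        )
    return MatchingFit(slope, intercept, r_squared, residual_variance, n)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, returning 0.0 when either variable is (numerically)
    constant — e.g. within-trial SD identically zero in noise-free data —
    where the textbook formula is 0/0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std()
    sy = y.std()
    tol_x = 1e-12 * max(1.0, np.abs(x).max(initial=0.0))
    tol_y = 1e-12 * max(1.0, np.abs(y).max(initial=0.0))
    if sx <= tol_x or sy <= tol_y:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def force_variability_profile(trials: pd.DataFrame) -> dict:
    """Across-trial variability summaries for one subject-condition.

    Expects trial_measures columns.  Correlations use the matched force as
    the force-magnitude variable and are reported as NaN when fewer than 3
    trials are available.
    """
    out = {
        "mean_within_trial_sd": float(trials["within_trial_sd_N"].mean()),
        "mean_trend": float(trials["trend_slope_Nps"].mean()),
        "r_force_sd": np.nan,
        "r_trend_force": np.nan,
    }
    if len(trials) >= 3:
        matched = trials["matched_force_N"].to_numpy()
        out["r_force_sd"] = _safe_pearson(matched, trials["within_trial_sd_N"].to_numpy())
        out["r_trend_force"] = _safe_pearson(matched, trials["trend_slope_Nps"].to_numpy())
    return out


def summarize_subject(trials: pd.DataFrame, *, residual_mode: str = "mse") -> dict:
    """All metrics for one subject-condition block of valid main trials."""
    if len(trials) == 0:
        raise EmptyInputError("no valid trials for this subject/condition")
    matched = trials["matched_force_N"].to_numpy()
    target = trials["target_force_N"].to_numpy()
    fit = fit_matching(matched, target, residual_mode=residual_mode)
    row = {
        "mean_overcompensation_N": mean_overcompensation(matched, target),
        "slope": fit.slope,
        "intercept_N": fit.intercept,
        "r_squared": fit.r_squared,
        "residual_variance": fit.residual_variance,
        "mean_initiation_s": float(trials["initiation_s"].mean()),
        "mean_stabilization_s": float(trials["stabilization_s"].mean()),
        "n_valid_trials": int(len(trials)),
    }
    row.update(force_variability_profile(trials))
    return row


def summarize_trials(
    trial_measures: pd.DataFrame, *, residual_mode: str = "mse"
) -> pd.DataFrame:
    """Aggregate a trial_measures table into subject_measures.

    One row per subject x condition, computed from valid main-phase trials
    only.  Trial order within a block is irrelevant by construction.
    """
    use = trial_measures[
        (trial_measures["phase"] == "main")
        & (trial_measures["status"] == "valid")
    ]
    rows = []
    for (sid, cond), block in use.groupby(["subject_id", "condition"], sort=True):
        row = {"subject_id": sid, "condition": cond}
        if "group" in block.columns:
            row["group"] = block["group"].iloc[0]
        row.update(summarize_subject(block, residual_mode=residual_mode))
        rows.append(row)
    return pd.DataFrame(rows)
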