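"""Per-trial trace analysis.

The matched force on a trial is defined as the mean force inside the 500 ms
window of the matching period with the minimum force variability, found by
sliding a window across the matching period one sample at a time.  This
definition is robust to the irregular force output of parkinsonian
participants (overshoot, tremor, slow adjustment), because it anchors the
measurement to the most stable part of the response rather than to a fixed
time.  This module implements that window search plus the auxiliary
per-trial measures: response-initiation time, premature/late classification,
the within-window linear trend, and the stabilization time.

Conventions (configurable where noted):

* variability = sample standard deviation with ddof=1;
* window stride = one sample; ties broken by the earliest window;
* initiation = first sustained crossing of baseline + 5% of the target
  force after the go cue (50 ms sustain by default);
* the per-trial window search starts at the detected initiation, so the
  silent pre-movement gap can never be selected as the "stable" window;
* stabilization time = start of the selected window relative to the go cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InvalidArgumentError, TraceTooShortError
from .task import ForceTrace, TaskDesign, Trial

__all__ = [
    "WindowResult",
    "TrialMeasures",
    "find_stable_window",
    "detect_initiation",
    "premature_onset",
    "classify_response",
    "within_window_trend",
    "stabilization_time",
    "process_trial",
    "process_trials",
]


@dataclass(frozen=True)
class WindowResult:
    """The minimum-variability window selected for one trial."""

    start_time: float
    duration: float
    mean_force: float
    within_window_sd: float
    trend_slope: float
    start_index: int
    n_samples: int


@dataclass(frozen=True)
class TrialMeasures:
    """Scalar measures extracted from one trial's trace."""

    matched_force: float
    overcompensation: float
    within_trial_sd: float
    trend_slope: float
    initiation_time: float | None
    stabilization_time: float
    status: str
    window_start: float


def _window_length(trace: ForceTrace, window_duration: float) -> int:
    n = trace.sampling_rate * window_duration
    if abs(n - round(n)) > 1e-6 or round(n) < 2:
        raise InvalidArgumentError(
            "window_duration x sampling_rate must be an integer >= 2"
        )
    return int(round(n))


def find_stable_window(
    trace: ForceTrace,
    window_duration: float,
    *,
    earliest_start: float | None = None,
) -> WindowResult:
    """Locate the matching-period window with minimum force variability.

    Every window of ``window_duration`` starting at each sample of the
    matching period is considered; the one with the smallest sample standard
    deviation (ddof=1) wins, with ties going to the earliest start.  The
    window's sample mean is the trial's matched force.

    ``earliest_start`` (absolute time) restricts the search to windows
    starting at or after that moment.  The per-trial pipeline passes the
    response-initiation time here: the force is flat (and hence minimally
    variable) *before* the participant starts pressing, so an unrestricted
    search would select the silent gap between the go cue and movement
    onset instead of the stabilised response.

    Raises
    ------
    TraceTooShortError
        If the admissible part of the matching period holds less than one
        full window.
    """
    w = _window_length(trace, window_duration)
    i0, i1 = trace.matching_bounds()
    if earliest_start is not None and earliest_start > i0 / trace.sampling_rate:
        i0 = min(trace.index_at(earliest_start), i1)
    segment = trace.force[i0:i1]
    if segment.shape[0] < w:
        raise TraceTooShortError(
            f"matching period has {segment.shape[0]} samples; "
            f"window needs {w}"
        )
    views = sliding_window_view(segment, w)
    sds = views.std(axis=1, ddof=1)
    j = int(np.argmin(sds))  # argmin returns the earliest minimizer
    start_index = i0 + j
    start_time = start_index / trace.sampling_rate
    window = views[j]
    times = (start_index + np.arange(w)) / trace.sampling_rate
    slope = _ols_slope(times, window)
    return WindowResult(
        start_time=start_time,
        duration=w / trace.sampling_rate,
        mean_force=float(window.mean()),
        within_window_sd=float(sds[j]),
        trend_slope=slope,
        start_index=start_index,
        n_samples=w,
    )


def _ols_slope(t: np.ndarray, f: np.ndarray) -> float:
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        return 0.0
    return float(tc @ (f - f.mean()) / denom)


def within_window_trend(trace: ForceTrace, window: WindowResult) -> float:
    """OLS slope (N/s) of force against time over the selected window."""
    sl = slice(window.start_index, window.start_index + window.n_samples)
    times = np.arange(window.start_index, window.start_index + window.n_samples)
    return _ols_slope(times / trace.sampling_rate, trace.force[sl])


def _first_sustained_run(above: np.ndarray, run: int) -> int | None:
    """Index of the first run of at least ``run`` consecutive True values."""
    if run <= 1:
        hits = np.flatnonzero(above)
        return int(hits[0]) if hits.size else None
    counts = np.convolve(above.astype(int), np.ones(run, dtype=int), "valid")
    hits = np.flatnonzero(counts == run)
    return int(hits[0]) if hits.size else None


def detect_initiation(
    trace: ForceTrace,
    target: float,
    *,
    threshold_fraction: float = 0.05,
    sustain_duration: float = 0.05,
    baseline: float = 0.0,
    baseline_duration: float | None = None,
) -> float | None:
    """Time after the go cue at which force matching starts.

    The motor force is removed at the go cue, so the baseline of the
    matching period is zero unless the caller estimates it from the first
    ``baseline_duration`` seconds after the cue.  Initiation is the first
    time at which the force exceeds baseline + ``threshold_fraction`` x
    target for a sustained run of ``sustain_duration``.  Returns ``None``
    when the threshold is never crossed; absence is a value, not an error.
    """
    i0, i1 = trace.matching_bounds()
    segment = trace.force[i0:i1]
    if segment.size == 0:
        return None
    if baseline_duration is not None:
        nb = max(1, int(round(baseline_duration * trace.sampling_rate)))
        baseline = float(segment[:nb].mean())
    threshold = baseline + threshold_fraction * target
    run = max(1, int(round(sustain_duration * trace.sampling_rate)))
    hit = _first_sustained_run(segment > threshold, run)
    if hit is None:
        return None
    return (i0 + hit) / trace.sampling_rate - trace.presentation_end


def premature_onset(
    trace: ForceTrace,
    target: float,
    *,
    threshold_fraction: float = 0.05,
    sustain_duration: float = 0.05,
) -> float | None:
    """Onset of a response *during* the presentation period, if any.

    While the motor presses with the target force, any additional sustained
    force above target x (1 + ``threshold_fraction``) betrays a premature
    matching attempt.  Returns the absolute onset time, or ``None``.
    """
    i0 = trace.index_at(trace.presentation_end)
    segment = trace.force[:i0]
    if segment.size == 0:
        return None
    threshold = target * (1.0 + threshold_fraction)
    run = max(1, int(round(sustain_duration * trace.sampling_rate)))
    hit = _first_sustained_run(segment > threshold, run)
    if hit is None:
        return None
    return hit / trace.sampling_rate


def classify_response(
    trace: ForceTrace,
    target: float,
    initiation_time: float | None,
    design: TaskDesign,
    *,
    threshold_fraction: float = 0.05,
) -> str:
    """Classify a trial as ``premature``, ``late`` or ``valid``.

    Premature: force onset during the presentation period.  Late: no
    initiation, or initiation more than ``design.late_threshold`` (1 s)
    after the go cue.  In the experiment both outcomes triggered a warning
    and a repeat of the trial.
    """
    if premature_onset(trace, target, threshold_fraction=threshold_fraction) is not None:
        return "premature"
    if initiation_time is None or initiation_time > design.late_threshold:
        return "late"
    return "valid"


def stabilization_time(
    window: WindowResult,
    go_time: float,
    *,
    reference: str = "start",
) -> float:
    """Time after the go cue at which the force stabilised.

    Operationalised as the start (default) or centre of the selected
    minimum-variability window, relative to the go cue.
    """
    if reference == "start":
        return window.start_time - go_time
    if reference == "center":
        return window.start_time + window.duration / 2.0 - go_time
    raise InvalidArgumentError("reference must be 'start' or 'center'")


def process_trial(
    trial: Trial,
    design: TaskDesign,
    *,
    threshold_fraction: float = 0.05,
    sustain_duration: float = 0.05,
    stabilization_reference: str = "start",
) -> TrialMeasures:
    """Extract all per-trial measures from one trial's trace."""
    trace = trial.trace
    if trace is None:
        raise InvalidArgumentError(f"trial {trial.trial_id} has no trace")
    initiation = detect_initiation(
        trace,
        trial.target_force,
        threshold_fraction=threshold_fraction,
        sustain_duration=sustain_duration,
    )
    earliest = None
    if initiation is not None:
        earliest = trace.presentation_end + initiation
    try:
        window = find_stable_window(
            trace, design.window_duration, earliest_start=earliest
        )
    except TraceTooShortError:
        # very late responses can leave less than one window after onset;
        # fall back to the unrestricted search (the trial is flagged late
        # anyway and never enters metrics)
        window = find_stable_window(trace, design.window_duration)
    status = classify_response(
        trace,
        trial.target_force,
        initiation,
        design,
        threshold_fraction=threshold_fraction,
    )
    return TrialMeasures(
        matched_force=window.mean_force,
        overcompensation=window.mean_force - trial.target_force,
        within_trial_sd=window.within_window_sd,
        trend_slope=window.trend_slope,
        initiation_time=initiation,
        stabilization_time=stabilization_time(
            window, trace.presentation_end, reference=stabilization_reference
        ),
        status=status,
        window_start=window.start_time,
    )


#: Column order of the trial_measures table.
TRIAL_MEASURES_COLUMNS = [
    "subject_id",
    "group",
    "condition",
    "phase",
    "trial_index",
    "cycle_index",
    "target_force_N",
    "matched_force_N",
    "overcompensation_N",
    "window_start_s",
    "within_trial_sd_N",
    "trend_slope_Nps",
    "initiation_s",
    "stabilization_s",
    "status",
    "repeat_of",
]


def process_trials(
    trials: list[Trial],
    design: TaskDesign,
    **kwargs,
) -> pd.DataFrame:
    """Process a batch of trials into the long trial_measures table.

    The validity status written here is re-derived from each trace, making
    the table identical whether trials come from the simulator or from real
    recordings exported in the same dialect.
    """
    rows = []
    for trial in trials:
        m = process_trial(trial, design, **kwargs)
        rows.append(
            {
                "subject_id": trial.subject_id,
                "group": trial.group,
                "condition": trial.condition,
                "phase": trial.phase,
                "trial_index": trial.trial_index,
                "cycle_index": trial.cycle_index,
                "target_force_N": trial.target_force,
                "matched_force_N": m.matched_force,
                "overcompensation_N": m.overcompensation,
                "window_start_s": m.window_start,
                "within_trial_sd_N": m.within_trial_sd,
                "trend_slope_Nps": m.trend_slope,
                "initiation_s": np.nan if m.initiation_time is None else m.initiation_time,
                "stabilization_s": m.stabilization_time,
                "status": m.status,
                "repeat_of": trial.repeat_of,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_MEASURES_COLUMNS)
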