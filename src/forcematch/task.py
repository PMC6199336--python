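"""Task design and force-trace containers.

The force matching task: on each trial a torque motor presses a lever onto
the participant's left index finger with one of four target forces for a
fixed presentation period; the force is then removed (the "go cue") and the
participant reproduces the sensed force during a matching period, either by
pressing the lever directly with the right index finger (Direct condition)
or by moving a slider that drives the motor (Slider condition).  A sensor at
the lever records the force applied to the left finger throughout, so a
trial's trace covers both the presentation and the matching periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

#: Canonical condition labels used throughout the package.
CONDITIONS: tuple[str, str] = ("direct", "slider")

DIRECT = "direct"
SLIDER = "slider"


def validate_condition(condition: str) -> str:
    cond = str(condition).lower()
    if cond not in CONDITIONS:
        raise InvalidArgumentError(
            f"condition must be one of {CONDITIONS}, got {condition!r}"
        )
    return cond


@dataclass(frozen=True)
class TaskDesign:
    """Timing and schedule parameters of the force matching task.

    Defaults follow the standard protocol: four target forces of 1.0-2.5 N,
    2.5 s presentation, 4.5 s matching period, a 500 ms analysis window, a
    1 s late-response deadline, eight familiarisation trials (two cycles of
    the four targets) and 32 main trials per condition.
    """

    target_set: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
    presentation_duration: float = 2.5
    matching_duration: float = 4.5
    late_threshold: float = 1.0
    window_duration: float = 0.5
    sampling_rate: float = 500.0
    familiarisation_cycles: int = 2
    main_trials_per_condition: int = 32

    def __post_init__(self) -> None:
        targets = tuple(float(t) for t in self.target_set)
        object.__setattr__(self, "target_set", targets)
        if len(targets) != 4 or len(set(targets)) != 4:
            raise InvalidArgumentError("target_set must hold 4 distinct forces")
        if min(targets) <= 0:
            raise InvalidArgumentError("target forces must be positive")
        if self.presentation_duration <= 0:
            raise InvalidArgumentError("presentation_duration must be positive")
        if not (self.matching_duration > self.window_duration > 0):
            raise InvalidArgumentError(
                "need matching_duration > window_duration > 0"
            )
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        n_win = self.sampling_rate * self.window_duration
        if abs(n_win - round(n_win)) > 1e-9 or round(n_win) < 2:
            raise InvalidArgumentError(
                "sampling_rate x window_duration must be an integer >= 2"
            )
        if self.familiarisation_cycles < 0:
            raise InvalidArgumentError("familiarisation_cycles must be >= 0")
        if (
            self.main_trials_per_condition < len(targets)
            or self.main_trials_per_condition % len(targets) != 0
        ):
            raise InvalidArgumentError(
                "main_trials_per_condition must be a positive multiple of the "
                "number of target forces"
            )
        if self.late_threshold <= 0:
            raise InvalidArgumentError("late_threshold must be positive")

    @property
    def window_samples(self) -> int:
        return int(round(self.sampling_rate * self.window_duration))

    @property
    def presentation_end(self) -> float:
        """Time of the go cue, with trial time zero at presentation onset."""
        return self.presentation_duration

    @property
    def matching_end(self) -> float:
        return self.presentation_duration + self.matching_duration

    @property
    def main_cycles(self) -> int:
        return self.main_trials_per_condition // len(self.target_set)

    def contains_target(self, target: float) -> bool:
        return any(abs(target - t) < 1e-9 for t in self.target_set)


@dataclass
class ForceTrace:
    """Uniformly sampled force-versus-time record for one trial.

    Time zero is presentation onset; ``presentation_end`` marks the go cue
    and ``matching_end`` the end of the matching period.
    """

    force: np.ndarray
    sampling_rate: float
    presentation_end: float
    matching_end: float

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if self.force.ndim != 1:
            raise InvalidArgumentError("force must be a 1-D array")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if not self.presentation_end < self.matching_end:
            raise InvalidArgumentError(
                "presentation_end must precede matching_end"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.force.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the first sample at or after time ``t``."""
        return int(np.ceil(t * self.sampling_rate - 1e-9))

    def matching_bounds(self) -> tuple[int, int]:
        """Half-open sample-index range covering the matching period."""
        i0 = self.index_at(self.presentation_end)
        # matching_end itself is included when it falls on a sample
        last = int(np.floor(self.matching_end * self.sampling_rate + 1e-9))
        i1 = min(self.n_samples, last + 1)
        return i0, i1

    def matching_segment(self) -> np.ndarray:
        i0, i1 = self.matching_bounds()
        return self.force[i0:i1]


@dataclass
class Trial:
    """One trial: metadata plus its force trace.

    ``phase`` is ``"familiarisation"`` or ``"main"``; ``status`` is the
    generator- or detector-assigned validity flag; ``repeat_of`` holds the
    ``trial_index`` of the failed trial this one replaces, if any.
    """

    subject_id: str
    group: str
    condition: str
    phase: str
    trial_index: int
    cycle_index: int
    target_force: float
    status: str = "valid"
    repeat_of: int | None = None
    trace: ForceTrace | None = None
    # generator ground truth (absent for real recordings)
    intended_plateau: float | None = None
    initiation_latency: float | None = None

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}:{self.condition}:{self.trial_index}"
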