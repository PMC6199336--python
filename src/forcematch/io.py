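"""Reading and writing force-matching datasets.

Two trace dialects are supported, both plain text:

* ``per-trial``: ``trials.csv`` carries a ``trace_file`` column pointing at
  one two-column CSV per trial (``time_s, force_N``; time zero at
  presentation onset), stored under ``traces/``;
* ``bundle``: a single ``traces.csv`` with one row per trial —
  ``trial_id, sampling_rate, presentation_end, matching_end`` followed by
  the force samples.

``trials.csv`` is the long-format metadata table (subject_id, group,
condition, phase, trial_index, cycle_index, target_force_N, status,
repeat_of, trace_file).  Cohort configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidArgumentError
from .simulate import CohortConfig, CohortData, GroupBehavior
from .task import ForceTrace, TaskDesign, Trial

__all__ = [
    "save_cohort",
    "load_cohort_dir",
    "load_config",
    "save_config",
]

TRIALS_COLUMNS = [
    "subject_id",
    "group",
    "condition",
    "phase",
    "trial_index",
    "cycle_index",
    "target_force_N",
    "status",
    "repeat_of",
    "trace_file",
]


def _trial_id(t: Trial) -> str:
    return f"{t.subject_id}_{t.condition}_{t.trial_index:03d}"


def save_cohort(cohort: CohortData, out_dir, *, trace_format: str = "bundle") -> Path:
    """Write a cohort to ``out_dir``: trials.csv, clinical.csv,
    ground-truth tables and traces in the requested dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    design = cohort.config.design
    if trace_format == "per-trial":
        (out / "traces").mkdir(exist_ok=True)
    elif trace_format != "bundle":
        raise InvalidArgumentError("trace_format must be 'bundle' or 'per-trial'")

    bundle_rows = []
    for t in cohort.trials:
        tid = _trial_id(t)
        trace_file = ""
        if t.trace is not None:
            if trace_format == "per-trial":
                trace_file = f"traces/{tid}.csv"
                frame = pd.DataFrame(
                    {"time_s": t.trace.times, "force_N": t.trace.force}
                )
                frame.to_csv(out / trace_file, index=False, float_format="%.6g")
            else:
                bundle_rows.append(
                    [
                        tid,
                        t.trace.sampling_rate,
                        t.trace.presentation_end,
                        t.trace.matching_end,
                    ]
                    + [f"{v:.6g}" for v in t.trace.force]
                )
        rows.append(
            {
                "subject_id": t.subject_id,
                "group": t.group,
                "condition": t.condition,
                "phase": t.phase,
                "trial_index": t.trial_index,
                "cycle_index": t.cycle_index,
                "target_force_N": t.target_force,
                "status": t.status,
                "repeat_of": t.repeat_of,
                "trace_file": trace_file,
            }
        )
    pd.DataFrame(rows, columns=TRIALS_COLUMNS).to_csv(out / "trials.csv", index=False)
    if trace_format == "bundle" and bundle_rows:
        n_samples = len(bundle_rows[0]) - 4
        header = ["trial_id", "sampling_rate", "presentation_end", "matching_end"]
        header += [f"f{i}" for i in range(n_samples)]
        with open(out / "traces.csv", "w") as fh:
            fh.write(",".join(header) + "\n")
            for row in bundle_rows:
                fh.write(",".join(str(v) for v in row) + "\n")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.subject_truth.to_csv(out / "ground_truth_subjects.csv", index=False)
    cohort.trial_truth.to_csv(out / "ground_truth_trials.csv", index=False)
    save_config(cohort.config, out / "cohort_config.yaml")
    return out


def load_cohort_dir(
    trials_dir, clinical_path=None, design: TaskDesign | None = None
) -> tuple[list[Trial], pd.DataFrame]:
    """Read trials + traces (either dialect) and the clinical table."""
    root = Path(trials_dir)
    trials_csv = root / "trials.csv"
    if not trials_csv.exists():
        raise InvalidArgumentError(f"{trials_csv} not found")
    meta = pd.read_csv(trials_csv)

    bundle: dict[str, ForceTrace] = {}
    bundle_csv = root / "traces.csv"
    if bundle_csv.exists():
        with open(bundle_csv) as fh:
            next(fh)  # header
            for line in fh:
                parts = line.rstrip("\n").split(",")
                tid = parts[0]
                sr, pe, me = (float(v) for v in parts[1:4])
                force = np.array(parts[4:], dtype=float)
                bundle[tid] = ForceTrace(
                    force=force, sampling_rate=sr,
                    presentation_end=pe, matching_end=me,
                )

    trials: list[Trial] = []
    for row in meta.to_dict("records"):
        trace = None
        tf = row.get("trace_file")
        if isinstance(tf, str) and tf:
            frame = pd.read_csv(root / tf)
            t = frame["time_s"].to_numpy()
            sr = 1.0 / float(np.median(np.diff(t)))
            d = design or TaskDesign()
            trace = ForceTrace(
                force=frame["force_N"].to_numpy(),
                sampling_rate=sr,
                presentation_end=d.presentation_end,
                matching_end=d.matching_end,
            )
        else:
            tid = (
                f"{row['subject_id']}_{row['condition']}_{int(row['trial_index']):03d}"
            )
            trace = bundle.get(tid)
        repeat_raw = row.get("repeat_of")
        repeat = None if pd.isna(repeat_raw) else int(repeat_raw)
        trials.append(
            Trial(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                condition=str(row["condition"]),
                phase=str(row["phase"]),
                trial_index=int(row["trial_index"]),
                cycle_index=int(row["cycle_index"]),
                target_force=float(row["target_force_N"]),
                status=str(row["status"]),
                repeat_of=repeat,
                trace=trace,
            )
        )

    clinical_path = Path(clinical_path) if clinical_path else root / "clinical.csv"
    clinical = pd.read_csv(clinical_path)
    if "subject_id" not in clinical.columns:
        raise InvalidArgumentError(
            f"{clinical_path} must carry a subject_id column for pipeline use"
        )
    return trials, clinical


def save_config(config: CohortConfig, path) -> None:
    payload = asdict(config)
    payload["design"] = asdict(config.design)
    payload["design"]["target_set"] = list(config.design.target_set)
    payload["age_range"] = list(config.age_range)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if payload is None:
        raise InvalidArgumentError(f"{path}: empty config")
    design_d = payload.pop("design", None)
    design = TaskDesign(**{**design_d, "target_set": tuple(design_d["target_set"])}) if design_d else TaskDesign()
    for key in ("patient_behavior", "control_behavior"):
        if key in payload and isinstance(payload[key], dict):
            payload[key] = GroupBehavior(**payload[key])
    if "age_range" in payload:
        payload["age_range"] = tuple(payload["age_range"])
    return CohortConfig(design=design, **payload)
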