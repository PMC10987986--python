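"""Stylus-trajectory preprocessing and reaction-time extraction.

Position traces are sampled at 100 Hz.  The pipeline is: zero-phase
second-order Butterworth low-pass at 10 Hz (applied forward and
backward, so the effective magnitude response is the squared Butterworth
response and the phase shift is zero), speed by central finite
differences, movement onset as the upward 50 mm/s speed crossing nearest
the recorded start-point exit, and RT as onset minus the
experiment-specific reference event (stimulus onset for the standard and
reduced-demand tasks, release of the enforced hold for the delayed
task).  Cleaning applies four sequential exclusion rules, each computed
on the survivors of the previous: missing RT, RT < 100 ms, trial outside
2 SD of the participant-by-condition mean, and participant-condition
mean outside 2 SD of the group mean of such means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "TrajectoryTrace",
    "lowpass_filter",
    "movement_speed",
    "movement_onset",
    "compute_rt",
    "clean_rt",
    "ExclusionReport",
]

SAMPLE_RATE_HZ = 100.0
CUTOFF_HZ = 10.0
ONSET_SPEED_MM_S = 50.0
MIN_RT_MS = 100.0
SD_CRITERION = 2.0
_MIN_SAMPLES = 10  # filtfilt warm-up for a 2nd-order section


@dataclass
class TrajectoryTrace:
    """A 100 Hz stylus trace with its event timestamps (all in ms)."""

    samples: pd.DataFrame  # columns t_ms, x_mm, y_mm
    stimulus_onset_ms: float = 0.0
    exit_timestamp_ms: Optional[float] = None  # start-point exit per task log
    redbox_offset_ms: Optional[float] = None  # hold release (delayed task)

    def __post_init__(self) -> None:
        t = self.samples["t_ms"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError("trace timestamps must be strictly increasing")


def lowpass_filter(trace: TrajectoryTrace) -> TrajectoryTrace:
    """Dual-pass (zero-phase) 2nd-order Butterworth low-pass at 10 Hz."""
    df = trace.samples
    if len(df) <= _MIN_SAMPLES:
        raise ValueError(
            f"trace of {len(df)} samples is shorter than the filter warm-up"
        )
    b, a = signal.butter(2, CUTOFF_HZ, fs=SAMPLE_RATE_HZ)
    out = df.copy()
    out["x_mm"] = signal.filtfilt(b, a, df["x_mm"].to_numpy())
    out["y_mm"] = signal.filtfilt(b, a, df["y_mm"].to_numpy())
    return TrajectoryTrace(
        out, trace.stimulus_onset_ms, trace.exit_timestamp_ms, trace.redbox_offset_ms
    )


def movement_speed(trace: TrajectoryTrace) -> np.ndarray:
    """Tangential speed (mm/s) by central finite differences."""
    t_s = trace.samples["t_ms"].to_numpy() / 1000.0
    vx = np.gradient(trace.samples["x_mm"].to_numpy(), t_s)
    vy = np.gradient(trace.samples["y_mm"].to_numpy(), t_s)
    return np.hypot(vx, vy)


def movement_onset(
    trace: TrajectoryTrace, exit_timestamp_ms: Optional[float] = None
) -> Optional[float]:
    """Time (ms) of the upward 50 mm/s crossing nearest the start-point exit.

    The threshold comparison is strict (speed must rise above 50 mm/s).
    Returns ``None`` when no crossing exists; such trials are later
    excluded as having no RT.
    """
    if exit_timestamp_ms is None:
        exit_timestamp_ms = trace.exit_timestamp_ms
    if exit_timestamp_ms is None:
        raise ValueError("an exit timestamp is required to anchor onset detection")
    speed = movement_speed(trace)
    t = trace.samples["t_ms"].to_numpy()
    above = speed > ONSET_SPEED_MM_S
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.r_[0, crossings]
    if crossings.size == 0:
        return None
    times = t[crossings]
    return float(times[np.argmin(np.abs(times - exit_timestamp_ms))])


def compute_rt(experiment: int, trace: TrajectoryTrace, t_onset_ms: Optional[float]) -> Optional[float]:
    """RT (ms) from the experiment's reference event to movement onset.

    Experiments 1 and 3 reference the stimulus (obstacle) onset;
    experiment 2 references the release of the enforced hold.
    """
    if t_onset_ms is None:
        return None
    if experiment == 2:
        if trace.redbox_offset_ms is None:
            raise ValueError("experiment 2 requires the hold-release timestamp")
        ref = trace.redbox_offset_ms
    else:
        ref = trace.stimulus_onset_ms
    return float(t_onset_ms - ref)


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts from the sequential RT cleaning cascade."""

    n_input: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.counts.values())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * v / self.n_input for k, v in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "counts": dict(self.counts),
            "percentages": self.percentages(),
        }


def clean_rt(
    records: pd.DataFrame,
    rt_col: str = "rt_ms",
    participant_col: str = "participant_id",
    condition_col: str = "condition",
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the four-rule RT exclusion cascade.

    Rules, each applied to the survivors of the previous:

    1. ``missing``: no RT present;
    2. ``anticipation``: RT below 100 ms;
    3. ``trial_outlier``: RT outside 2 SD of the participant's mean RT
       in that condition;
    4. ``participant_condition_outlier``: participant-condition mean RT
       outside 2 SD of the group mean of participant-condition means
       (all that cell's trials removed).

    Returns the retained records (with an ``exclusion`` column recording
    the removing rule on the dropped rows of the annotated copy) and a
    per-rule report.
    """
    df = records.copy()
    df["exclusion"] = ""
    report = ExclusionReport(n_input=len(df))

    missing = df[rt_col].isna()
    df.loc[missing, "exclusion"] = "missing"
    report.counts["missing"] = int(missing.sum())

    alive = df["exclusion"] == ""
    fast = alive & (df[rt_col] < MIN_RT_MS)
    df.loc[fast, "exclusion"] = "anticipation"
    report.counts["anticipation"] = int(fast.sum())

    alive = df["exclusion"] == ""
    sub = df[alive]
    grp = sub.groupby([participant_col, condition_col])[rt_col]
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    outlier = (sub[rt_col] - mean).abs() > SD_CRITERION * sd
    outlier &= sd > 0
    df.loc[outlier.index[outlier], "exclusion"] = "trial_outlier"
    report.counts["trial_outlier"] = int(outlier.sum())

    alive = df["exclusion"] == ""
    sub = df[alive]
    cell_means = sub.groupby([participant_col, condition_col])[rt_col].mean()
    gmean = cell_means.mean()
    gsd = cell_means.std()
    if pd.notna(gsd) and gsd > 0:
        bad_cells = cell_means[(cell_means - gmean).abs() > SD_CRITERION * gsd].index
    else:
        bad_cells = []
    key = list(zip(sub[participant_col], sub[condition_col]))
    bad = pd.Series([k in set(bad_cells) for k in key], index=sub.index)
    df.loc[bad.index[bad], "exclusion"] = "participant_condition_outlier"
    report.counts["participant_condition_outlier"] = int(bad.sum())

    retained = df[df["exclusion"] == ""].drop(columns=["exclusion"])
    return retained, report
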