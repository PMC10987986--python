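"""Synthetic experiment designs, cohorts, error tables and trajectories.

The three experiments share one session layout: 4 example, 6 practice
and 9 baseline trials with the obstacle central, then 87 experimental trials
in three 29-trial blocks (rightwards: obstacle steps left-to-right
across the 29-position grid; leftwards: right-to-left; random: the grid
shuffled), with the block order randomized per participant.  Cohort
sizes in the study were 152 (experiment 1) and 20 each (experiments 2
and 3).

Everything here is reproducible from a seed, so the model-fitting,
posterior-predictive and statistics layers can be exercised end to end
without any external download.  Trajectories are generated for the
kinematic pipeline: a stationary hold of lognormal duration (the
reaction time), then a minimum-jerk traversal of the minimal parabolic
path, with additive Gaussian position noise, sampled at 100 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .choice_model import ModelParams, TrialRecord, simulate_session
from .geometry import (
    ActionSide,
    DEFAULT_GEOMETRY,
    TaskGeometry,
    _min_abs_coefficient,
    make_position_grid,
    min_parabola_path_length,
)

__all__ = [
    "TrialSpec",
    "ExperimentDesign",
    "ErrorRateTable",
    "SyntheticCohort",
    "make_design",
    "make_cohort",
    "default_error_table",
    "simulate_trajectory",
    "CONDITIONS",
    "N_PRACTICE",
    "N_BASELINE",
]

CONDITIONS = ("rightwards", "leftwards", "random")
N_EXAMPLE = 4
N_PRACTICE = 6
N_BASELINE = 9
SAMPLE_RATE_HZ = 100.0
#: movement time budget start -> checkpoint (the task allows < 500 ms)
DEFAULT_MOVE_TIME_MS = 400.0
#: lognormal RT defaults on the scale of the observed ~400 ms mean
DEFAULT_RT_MEDIAN_MS = 400.0
DEFAULT_RT_SIGMA = 0.25


@dataclass(frozen=True)
class TrialSpec:
    block_type: str  # practice | baseline | experimental
    condition: str  # rightwards | leftwards | random | none
    obstacle_x: float  # mm


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered trial specifications for one session."""

    experiment: int
    condition_order: tuple[str, ...]
    trials: tuple[TrialSpec, ...]

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3):
            raise ValueError(f"experiment must be 1, 2 or 3, got {self.experiment}")
        if sorted(self.condition_order) != sorted(CONDITIONS):
            raise ValueError(f"condition_order must permute {CONDITIONS}")
        n_exp = sum(t.block_type == "experimental" for t in self.trials)
        if n_exp != 87:
            raise ValueError(f"expected 87 experimental trials, got {n_exp}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def experimental_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if t.block_type == "experimental"]


def make_design(
    experiment: int,
    condition_order: Sequence[str] | str,
    rng: np.random.Generator,
) -> ExperimentDesign:
    """Build one session design.

    ``condition_order`` is a permutation of (rightwards, leftwards,
    random) or the string ``"random"`` to draw the order from ``rng``.
    The random block's positions are shuffled from the same stream.
    """
    grid = list(make_position_grid().positions_mm)
    if condition_order == "random":
        order = tuple(rng.permutation(CONDITIONS))
    else:
        order = tuple(condition_order)
    if sorted(order) != sorted(CONDITIONS):
        raise ValueError(f"invalid condition order {condition_order!r}")

    trials: list[TrialSpec] = []
    trials += [TrialSpec("example", "none", 0.0)] * N_EXAMPLE
    trials += [TrialSpec("practice", "none", 0.0)] * N_PRACTICE
    trials += [TrialSpec("baseline", "none", 0.0)] * N_BASELINE
    for cond in order:
        if cond == "rightwards":
            xs = grid
        elif cond == "leftwards":
            xs = grid[::-1]
        else:
            xs = list(rng.permutation(grid))
        trials += [TrialSpec("experimental", cond, float(x)) for x in xs]
    return ExperimentDesign(int(experiment), order, tuple(trials))


@dataclass(frozen=True)
class ErrorRateTable:
    """Failure probability per (experiment, obstacle position)."""

    rates: dict[tuple[int, float], float]

    def __post_init__(self) -> None:
        for key, p in self.rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"error rate {p} for {key} outside [0, 1]")

    def rate(self, experiment: int, obstacle_x: float) -> float:
        key = (experiment, round(float(obstacle_x), 6))
        try:
            return self.rates[key]
        except KeyError:
            raise KeyError(
                f"no error rate for experiment {experiment}, position {obstacle_x}"
            ) from None


def default_error_table(
    experiment: int,
    base_rate: float = 0.05,
    u_shape_extra: float = 0.0,
) -> ErrorRateTable:
    """Constant-rate table over the 29 positions (the study's empirical
    per-position rates are not published; this stands in for them).

    ``u_shape_extra`` optionally adds a component growing quadratically
    with |position| to emulate more failures near the screen edges.
    """
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError("base_rate must lie in [0, 1]")
    grid = make_position_grid()
    x_max = max(abs(x) for x in grid.positions_mm)
    rates = {}
    for x in grid.positions_mm:
        extra = u_shape_extra * (abs(x) / x_max) ** 2
        rates[(experiment, round(float(x), 6))] = min(1.0, base_rate + extra)
    return ErrorRateTable(rates)


@dataclass
class SyntheticCohort:
    """A simulated cohort with full generating provenance."""

    experiment: int
    participants: list[tuple[str, ModelParams]]
    trials: pd.DataFrame
    seed: int
    generating_params: ModelParams
    between_participant_sd: float = 0.0

    def provenance(self) -> dict:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "n_participants": len(self.participants),
            "generating_params": {
                "cost_scaler": self.generating_params.cost_scaler,
                "bias_scaler": self.generating_params.bias_scaler,
                "bias_rate": self.generating_params.bias_rate,
            },
            "between_participant_sd": self.between_participant_sd,
        }

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance(), fh, indent=2)


def _records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "experiment": r.experiment,
                "block_type": r.block_type,
                "condition": r.condition,
                "trial_index": r.trial_index,
                "obstacle_x_mm": r.obstacle_x,
                "coded_position": r.coded_position,
                "side": r.side_chosen if r.side_chosen is not None else "none",
                "outcome": r.outcome,
                "failure_type": r.failure_type if r.failure_type else "",
                "rt_ms": r.rt if r.rt is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def make_cohort(
    n_participants: int,
    params: ModelParams,
    rng: np.random.Generator,
    experiment: int = 1,
    error_table: Optional[ErrorRateTable] = None,
    between_participant_sd: float = 0.0,
    seed: int = -1,
    reset_between_blocks: bool = False,
) -> SyntheticCohort:
    """Simulate ``n_participants`` full sessions under shared parameters.

    Each participant gets a randomized condition order.  With
    ``between_participant_sd`` > 0 the scalers are jittered per
    participant by Gaussian noise (the bias rate is jittered then clipped
    to [0, 1]); the default 0 matches fitting one parameter set per
    experiment.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if between_participant_sd < 0:
        raise ValueError("between_participant_sd must be >= 0")
    participants: list[tuple[str, ModelParams]] = []
    all_records: list[TrialRecord] = []
    width = max(3, len(str(n_participants)))
    for i in range(n_participants):
        pid = f"p{i:0{width}d}"
        if between_participant_sd > 0:
            p_i = ModelParams(
                cost_scaler=params.cost_scaler
                + rng.normal(0, between_participant_sd * params.cost_scaler),
                bias_scaler=params.bias_scaler
                + rng.normal(0, between_participant_sd * max(params.bias_scaler, 1e-9)),
                bias_rate=float(
                    np.clip(
                        params.bias_rate + rng.normal(0, between_participant_sd * 0.1),
                        0.0,
                        1.0,
                    )
                ),
            )
        else:
            p_i = params
        design = make_design(experiment, "random", rng)
        all_records += simulate_session(
            design,
            p_i,
            rng,
            error_table=error_table,
            participant_id=pid,
            reset_between_blocks=reset_between_blocks,
        )
        participants.append((pid, p_i))
    return SyntheticCohort(
        experiment=experiment,
        participants=participants,
        trials=_records_to_frame(all_records),
        seed=seed,
        generating_params=params,
        between_participant_sd=between_participant_sd,
    )


def _min_jerk_profile(t: np.ndarray) -> np.ndarray:
    """Minimum-jerk position fraction for normalized time t in [0, 1]."""
    t = np.clip(t, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def simulate_trajectory(
    trial: TrialRecord,
    rng: np.random.Generator,
    noise_sd: float = 0.3,
    rt_median_ms: float = DEFAULT_RT_MEDIAN_MS,
    rt_sigma: float = DEFAULT_RT_SIGMA,
    move_time_ms: float = DEFAULT_MOVE_TIME_MS,
    geom: TaskGeometry = DEFAULT_GEOMETRY,
    hold_before_ms: float = 0.0,
) -> pd.DataFrame:
    """Sample a 100 Hz stylus trace for one trial with a chosen side.

    Columns: ``t_ms, x_mm, y_mm, phase`` plus trace-level attributes
    ``onset_ms`` (ground-truth movement onset) and ``rt_ms`` in
    ``DataFrame.attrs``.  The stylus holds at the start point for the
    drawn reaction time, then follows the minimal parabola for the
    chosen side with a minimum-jerk (bell-shaped-speed) time course,
    reaching the checkpoint in ``move_time_ms``.  ``hold_before_ms``
    models the enforced wait of the delayed-release task variant.
    """
    if trial.side_chosen is None or trial.side_chosen == "none":
        raise ValueError("cannot simulate a trajectory for a trial with no passage")
    side = ActionSide(trial.side_chosen)
    rt_ms = float(rng.lognormal(mean=np.log(rt_median_ms), sigma=rt_sigma))
    onset_ms = hold_before_ms + rt_ms

    dt = 1000.0 / SAMPLE_RATE_HZ
    total_ms = onset_ms + move_time_ms + 100.0  # short post-movement tail
    t = np.arange(0.0, total_ms + dt / 2, dt)

    a = _min_abs_coefficient(side, trial.obstacle_x, geom)
    length = geom.checkpoint_distance

    frac = np.zeros_like(t)
    moving = t >= onset_ms
    frac[moving] = _min_jerk_profile((t[moving] - onset_ms) / move_time_ms)
    y = frac * length
    x = a * y * (y - length)

    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, size=t.shape)
        y = y + rng.normal(0, noise_sd, size=t.shape)

    phase = np.where(t < onset_ms, "hold", np.where(frac < 1.0, "move", "end"))
    out = pd.DataFrame({"t_ms": t, "x_mm": x, "y_mm": y, "phase": phase})
    # ground-truth onset per the detection criterion: the first time the
    # noiseless speed profile exceeds 50 mm/s (the min-jerk ramp reaches
    # the threshold shortly after the hold ends)
    tt = np.linspace(0.0, 1.0, 4001)
    y_fine = _min_jerk_profile(tt) * length
    slope = a * (2.0 * y_fine - length)  # dx/dy along the parabola
    speed = (
        length / (move_time_ms / 1000.0) * 30.0 * tt**2 * (1.0 - tt) ** 2
        * np.hypot(1.0, slope)
    )  # tangential, mm/s
    above = np.flatnonzero(speed > 50.0)
    t_cross = tt[above[0]] * move_time_ms if above.size else np.nan
    out.attrs["move_start_ms"] = onset_ms
    out.attrs["onset_ms"] = onset_ms + t_cross
    out.attrs["rt_ms"] = rt_ms
    out.attrs["side"] = side.value
    out.attrs["path_length_mm"] = min_parabola_path_length(side, trial.obstacle_x, geom)
    return out
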