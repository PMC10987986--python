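"""Generative action-selection model with reinforcement-learned bias.

On each trial the agent chooses to pass the obstacle on the left or the
right.  Each action i has a value

    V_i = s_c * c_i + s_b * b_i

where c_i in (0, 1] is the normalized path cost (reciprocal of relative
path length, :mod:`motorhyst.geometry`), b_i in [0, 1] is a bias
accumulated over previous trials, and s_c, s_b are scaling parameters
bringing the two terms to a common scale.  The left action is chosen
with softmax probability

    p_L = exp(V_L) / (exp(V_L) + exp(V_R)),

and after the outcome is observed the biases update by a delta rule with
bias rate r:

    b_i <- b_i + r * (1 - b_i)   if i was selected and the trial succeeded,
    b_i <- b_i + r * (0 - b_i)   otherwise (unselected, failed, or no selection).

Biases start at 0, so with r in [0, 1] they remain in [0, 1] forever.
Successive successes on one side push its bias toward 1 and decay the
other toward 0 — which is what makes choice hysteresis emerge: at the
central obstacle position both costs are equal and any accumulated bias
tips the softmax toward the recently successful side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .geometry import (
    ActionSide,
    DEFAULT_GEOMETRY,
    TaskGeometry,
    code_position,
    normalized_cost,
)

__all__ = [
    "ModelParams",
    "BiasState",
    "ActionCosts",
    "ActionValues",
    "TrialRecord",
    "action_values",
    "choice_probability",
    "p_left",
    "update_biases",
    "simulate_trial",
    "simulate_session",
]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters: cost scaler s_c, bias scaler s_b, bias rate r."""

    cost_scaler: float
    bias_scaler: float
    bias_rate: float

    def __post_init__(self) -> None:
        vals = (self.cost_scaler, self.bias_scaler, self.bias_rate)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("model parameters must be finite")
        if not 0.0 <= self.bias_rate <= 1.0:
            raise ValueError(f"bias rate must lie in [0, 1], got {self.bias_rate}")


#: Posterior-mean parameter estimates per experiment (cost scaler, bias
#: scaler, bias rate).  Experiment 1 is the large-cohort task, experiment 2
#: eases temporal constraints (enforced 1.5 s wait), experiment 3 reduces
#: cognitive demands (single target).
EXPERIMENT_PARAMS: dict[int, ModelParams] = {
    1: ModelParams(39.26, 2.69, 0.32),
    2: ModelParams(41.96, 1.09, 0.43),
    3: ModelParams(37.63, 1.87, 0.35),
}


@dataclass(frozen=True)
class BiasState:
    """Accumulated action biases, one per side, each in [0, 1]."""

    left: float = 0.0
    right: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.left) and math.isfinite(self.right)):
            raise ValueError("biases must be finite")

    def get(self, side: ActionSide) -> float:
        return self.left if side is ActionSide.LEFT else self.right


@dataclass(frozen=True)
class ActionCosts:
    """Normalized costs c in (0, 1] for the two actions."""

    left: float
    right: float

    def __post_init__(self) -> None:
        for v in (self.left, self.right):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"costs must lie in (0, 1], got {v}")

    @classmethod
    def at_position(
        cls, obstacle_x: float, geom: TaskGeometry = DEFAULT_GEOMETRY
    ) -> "ActionCosts":
        return cls(
            left=normalized_cost(ActionSide.LEFT, obstacle_x, geom),
            right=normalized_cost(ActionSide.RIGHT, obstacle_x, geom),
        )


@dataclass(frozen=True)
class ActionValues:
    left: float
    right: float


@dataclass(frozen=True)
class TrialRecord:
    """One trial's design, choice, outcome and (optional) reaction time."""

    participant_id: str
    experiment: int
    block_type: str  # practice | baseline | experimental
    condition: str  # rightwards | leftwards | random | none
    trial_index: int  # 0-based within session
    obstacle_x: float  # mm
    side_chosen: Optional[str]  # left | right | None (failed before passage)
    outcome: str  # success | fail
    rt: Optional[float] = None  # ms
    failure_type: Optional[str] = None

    @property
    def coded_position(self) -> float:
        return code_position(self.obstacle_x)


def action_values(
    costs: ActionCosts, biases: BiasState, params: ModelParams
) -> ActionValues:
    """V_i = s_c * c_i + s_b * b_i for each side."""
    return ActionValues(
        left=params.cost_scaler * costs.left + params.bias_scaler * biases.left,
        right=params.cost_scaler * costs.right + params.bias_scaler * biases.right,
    )


def p_left(v_left: float, v_right: float) -> float:
    """Softmax probability of the left action, overflow-safe.

    Subtracting the larger value before exponentiating keeps the
    computation finite for arbitrarily large value differences.
    """
    m = max(v_left, v_right)
    el = math.exp(v_left - m)
    er = math.exp(v_right - m)
    return el / (el + er)


def choice_probability(values: ActionValues) -> float:
    """Probability of selecting the left action from its softmax value."""
    return p_left(values.left, values.right)


def update_biases(
    biases: BiasState,
    selected: Optional[ActionSide | str],
    outcome: str,
    bias_rate: float,
) -> BiasState:
    """Delta-rule bias update after one trial.

    The selected action's bias moves toward 1 on success; every other
    action/outcome combination (the unselected action, a failed trial, or
    no selection at all) decays toward 0 at the same rate.
    """
    if not 0.0 <= bias_rate <= 1.0:
        raise ValueError(f"bias rate must lie in [0, 1], got {bias_rate}")
    selected = ActionSide(selected) if selected is not None else None
    success = outcome == "success"

    def step(b: float, side: ActionSide) -> float:
        target = 1.0 if (selected is side and success) else 0.0
        return b + bias_rate * (target - b)

    return BiasState(
        left=step(biases.left, ActionSide.LEFT),
        right=step(biases.right, ActionSide.RIGHT),
    )


def simulate_trial(
    biases: BiasState,
    obstacle_x: float,
    params: ModelParams,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    geom: TaskGeometry = DEFAULT_GEOMETRY,
    costs: Optional[ActionCosts] = None,
    update: bool = True,
) -> tuple[Optional[ActionSide], str, BiasState]:
    """Simulate one trial; returns (side or None, outcome, new biases).

    A uniform draw below ``error_rate`` fails the trial before any action
    is selected (both biases decay).  Otherwise the side is sampled from
    the softmax probability (uniform draw below p_left selects left) and
    the trial succeeds.  With ``update=False`` the biases are returned
    unchanged (used for practice/baseline trials that do not feed the
    bias accumulator).
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error rate must lie in [0, 1], got {error_rate}")
    if rng.uniform() < error_rate:
        new = update_biases(biases, None, "fail", params.bias_rate) if update else biases
        return None, "fail", new
    c = costs if costs is not None else ActionCosts.at_position(obstacle_x, geom)
    pl = choice_probability(action_values(c, biases, params))
    side = ActionSide.LEFT if rng.uniform() < pl else ActionSide.RIGHT
    new = update_biases(biases, side, "success", params.bias_rate) if update else biases
    return side, "success", new


def simulate_session(
    design,
    params: ModelParams,
    rng: np.random.Generator,
    error_table=None,
    participant_id: str = "p000",
    geom: TaskGeometry = DEFAULT_GEOMETRY,
    propagate_practice: bool = False,
    reset_between_blocks: bool = False,
) -> list[TrialRecord]:
    """Simulate a full session following an :class:`ExperimentDesign`.

    Biases start at (0, 0) at the first experimental trial and by default
    propagate continuously across the three experimental blocks, which
    the participant experiences as one uninterrupted run.  Practice and
    baseline trials are simulated from the same value rule but excluded
    from bias accumulation unless ``propagate_practice``;
    ``reset_between_blocks`` zeroes the biases at each experimental block
    boundary instead.
    """
    from .synthetic_data import ErrorRateTable  # cycle-free at runtime

    if error_table is not None and not isinstance(error_table, ErrorRateTable):
        raise ValueError("error_table must be an ErrorRateTable")

    cost_cache: dict[float, ActionCosts] = {}
    records: list[TrialRecord] = []
    biases = BiasState()
    prev_condition = None
    for i, spec in enumerate(design.trials):
        if reset_between_blocks and spec.block_type == "experimental":
            if prev_condition is not None and spec.condition != prev_condition:
                biases = BiasState()
            prev_condition = spec.condition
        x = spec.obstacle_x
        if x not in cost_cache:
            cost_cache[x] = ActionCosts.at_position(x, geom)
        rate = 0.0
        if error_table is not None and spec.block_type == "experimental":
            rate = error_table.rate(design.experiment, x)
        experimental = spec.block_type == "experimental"
        side, outcome, biases = simulate_trial(
            biases,
            x,
            params,
            rng,
            error_rate=rate,
            costs=cost_cache[x],
            update=experimental or propagate_practice,
        )
        records.append(
            TrialRecord(
                participant_id=participant_id,
                experiment=design.experiment,
                block_type=spec.block_type,
                condition=spec.condition,
                trial_index=i,
                obstacle_x=x,
                side_chosen=None if side is None else side.value,
                outcome=outcome,
                failure_type="no_passage" if side is None else None,
            )
        )
    return records
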