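"""Bayesian estimation of the choice-model parameters.

The three parameters (cost scaler s_c, bias scaler s_b, bias rate r) are
fitted to trial-level choice data by MCMC.  The likelihood propagates
each participant's biases forward through their observed choices and
outcomes — the bias trajectory is a deterministic function of the data
and r — and each trial with an observed passage side contributes the
Bernoulli log-probability of that side under the softmax rule.  Failed
trials contribute no likelihood term but still decay the biases.

Priors (weakly informative, fixed to the scale of the parameters):

    s_c, s_b ~ Normal(0, sd 25)
    r        ~ Normal(0.5, sd 0.2) truncated to [0, 1]

Sampling uses the affine-invariant ensemble sampler (emcee), with the
walker ensemble initialized in a tight ball around a MAP estimate.
Walkers are treated as chains for the Gelman–Rubin statistic and
effective sample size (via arviz); a fit is flagged when any R-hat
reaches 1.1.  Posteriors are summarized by mean and 95% highest-density
interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .choice_model import ModelParams
from .geometry import ActionSide, code_position, make_position_grid, normalized_cost

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "ChoiceData",
    "PosteriorDraws",
    "HDISummary",
    "prepare_choice_data",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "sample_posterior",
    "hdi",
    "contrast_parameter",
    "posterior_predictive_ribbon",
]

PARAM_NAMES = ("cost_scaler", "bias_scaler", "bias_rate")
PRIOR_SCALER_SD = 25.0
PRIOR_RATE_MEAN = 0.5
PRIOR_RATE_SD = 0.2
RHAT_WARN = 1.1


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings.

    The full-scale profile used for the study-size fits is 8 chains of
    5000 warm-up and 5000 retained draws; the default here is a reduced
    profile suited to synthetic cohorts on one CPU.  ``n_chains`` maps
    to ensemble walkers (floored at 8, the minimum for a 3-parameter
    ensemble move).
    """

    n_chains: int = 8
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0
    reset_between_blocks: bool = False
    include_practice: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.n_draws < 1 or self.n_warmup < 0:
            raise ValueError("draw counts must be positive")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "FitConfig":
        return cls(n_chains=8, n_warmup=5000, n_draws=5000, seed=seed)


@dataclass
class ChoiceData:
    """Trial arrays ready for the likelihood, one row per participant.

    Rectangularized with a validity mask so ragged sessions are
    supported.  ``chose_left``/``chose_right`` are False on no-passage
    trials; ``active`` marks real (non-padding) trials, which update the
    biases whether or not a side was observed.
    """

    cost_left: np.ndarray  # (P, T)
    cost_right: np.ndarray
    chose_left: np.ndarray  # bool
    chose_right: np.ndarray  # bool
    success: np.ndarray  # bool
    active: np.ndarray  # bool
    block_start: np.ndarray  # bool, True where a new experimental block begins
    participant_ids: list[str] = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return self.cost_left.shape[0]

    @property
    def n_choices(self) -> int:
        return int((self.chose_left | self.chose_right).sum())


def _cost_lookup() -> dict[float, tuple[float, float]]:
    grid = make_position_grid()
    return {
        round(float(x), 6): (
            normalized_cost(ActionSide.LEFT, x),
            normalized_cost(ActionSide.RIGHT, x),
        )
        for x in grid.positions_mm
    }


def prepare_choice_data(
    trials: pd.DataFrame, include_practice: bool = False
) -> ChoiceData:
    """Build likelihood arrays from a trial table.

    Expects the project trial-table columns (``participant_id``,
    ``block_type``, ``condition``, ``trial_index``, ``obstacle_x_mm``,
    ``side``, ``outcome``).  Trials must be chronologically ordered per
    participant (ascending ``trial_index``); practice/baseline trials
    are dropped unless ``include_practice``.
    """
    df = trials
    if not include_practice:
        df = df[df["block_type"] == "experimental"]
    if df.empty:
        raise ValueError("no experimental trials in dataset")
    costs = _cost_lookup()

    per: list[pd.DataFrame] = []
    ids: list[str] = []
    for pid, g in df.groupby("participant_id", sort=True):
        if not g["trial_index"].is_monotonic_increasing:
            raise ValueError(f"trials for participant {pid} are not in order")
        per.append(g)
        ids.append(str(pid))
    T = max(len(g) for g in per)
    P = len(per)
    shape = (P, T)
    cl = np.ones(shape)
    cr = np.ones(shape)
    chose_l = np.zeros(shape, dtype=bool)
    chose_r = np.zeros(shape, dtype=bool)
    succ = np.zeros(shape, dtype=bool)
    active = np.zeros(shape, dtype=bool)
    block_start = np.zeros(shape, dtype=bool)
    for i, g in enumerate(per):
        n = len(g)
        xs = g["obstacle_x_mm"].to_numpy(dtype=float)
        for j, x in enumerate(xs):
            key = round(float(x), 6)
            if key in costs:
                cl[i, j], cr[i, j] = costs[key]
            else:
                cl[i, j] = normalized_cost(ActionSide.LEFT, x)
                cr[i, j] = normalized_cost(ActionSide.RIGHT, x)
        side = g["side"].to_numpy()
        chose_l[i, :n] = side == "left"
        chose_r[i, :n] = side == "right"
        succ[i, :n] = g["outcome"].to_numpy() == "success"
        active[i, :n] = True
        cond = g["condition"].to_numpy()
        block_start[i, 0] = True
        block_start[i, 1:n] = cond[1:] != cond[:-1]
    return ChoiceData(cl, cr, chose_l, chose_r, succ, active, block_start, ids)


def log_likelihood(
    data: ChoiceData | pd.DataFrame,
    params: ModelParams | Sequence[float],
    reset_between_blocks: bool = False,
) -> float:
    """Log-probability of the observed choices under the model.

    Biases start at (0, 0) on each participant's first experimental
    trial and are propagated forward from the observed choices and
    outcomes; with ``reset_between_blocks`` they are re-zeroed at each
    experimental block boundary.
    """
    if isinstance(data, pd.DataFrame):
        data = prepare_choice_data(data)
    if isinstance(params, ModelParams):
        s_c, s_b, r = params.cost_scaler, params.bias_scaler, params.bias_rate
    else:
        s_c, s_b, r = (float(v) for v in params)
    P, T = data.cost_left.shape
    b_l = np.zeros(P)
    b_r = np.zeros(P)
    total = 0.0
    for t in range(T):
        act = data.active[:, t]
        if reset_between_blocks:
            reset = act & data.block_start[:, t]
            b_l[reset] = 0.0
            b_r[reset] = 0.0
        dv = (
            s_c * (data.cost_left[:, t] - data.cost_right[:, t])
            + s_b * (b_l - b_r)
        )
        # log p_left = -log(1 + e^{-dv}); log p_right = -log(1 + e^{dv})
        lp_l = -np.logaddexp(0.0, -dv)
        lp_r = -np.logaddexp(0.0, dv)
        cl = data.chose_left[:, t]
        cr = data.chose_right[:, t]
        total += lp_l[cl].sum() + lp_r[cr].sum()
        # delta-rule update toward 1 for a successful selection, 0 otherwise
        tgt_l = (cl & data.success[:, t]).astype(float)
        tgt_r = (cr & data.success[:, t]).astype(float)
        upd = act
        b_l[upd] += r * (tgt_l[upd] - b_l[upd])
        b_r[upd] += r * (tgt_r[upd] - b_r[upd])
    return float(total)


def log_prior(theta: Sequence[float]) -> float:
    s_c, s_b, r = theta
    if not 0.0 <= r <= 1.0:
        return -np.inf
    lp = stats.norm.logpdf(s_c, 0.0, PRIOR_SCALER_SD)
    lp += stats.norm.logpdf(s_b, 0.0, PRIOR_SCALER_SD)
    # truncated normal on [0, 1]; the normalizing constant is parameter-free
    lp += stats.norm.logpdf(r, PRIOR_RATE_MEAN, PRIOR_RATE_SD)
    return float(lp)


def log_posterior(
    theta: Sequence[float], data: ChoiceData, reset_between_blocks: bool = False
) -> float:
    lp = log_prior(theta)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(data, theta, reset_between_blocks)


@dataclass
class HDISummary:
    """Posterior mean and 95% HDI per parameter."""

    summary: dict[str, tuple[float, float, float]]  # name -> (mean, lo, hi)

    def mean(self, name: str) -> float:
        return self.summary[name][0]

    def interval(self, name: str) -> tuple[float, float]:
        return self.summary[name][1:]

    def contains(self, name: str, value: float) -> bool:
        lo, hi = self.interval(name)
        return lo <= value <= hi

    def to_dict(self) -> dict:
        return {
            k: {"mean": m, "hdi_low": lo, "hdi_high": hi}
            for k, (m, lo, hi) in self.summary.items()
        }


@dataclass
class PosteriorDraws:
    """MCMC draws with convergence diagnostics.

    ``chains`` has shape (n_chains, n_draws, 3) in the order
    (cost_scaler, bias_scaler, bias_rate).
    """

    chains: np.ndarray
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool

    @property
    def flat(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    def parameter(self, name: str) -> np.ndarray:
        return self.flat[:, PARAM_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        n_chains, n_draws, _ = self.chains.shape
        rows = self.flat
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(n_chains), n_draws),
                "draw": np.tile(np.arange(n_draws), n_chains),
                "cost_scaler": rows[:, 0],
                "bias_scaler": rows[:, 1],
                "bias_rate": rows[:, 2],
            }
        )

    def summarize(self, mass: float = 0.95) -> HDISummary:
        out = {}
        for i, name in enumerate(PARAM_NAMES):
            x = self.flat[:, i]
            lo, hi = hdi(x, mass)
            out[name] = (float(x.mean()), lo, hi)
        return HDISummary(out)


def _map_estimate(data: ChoiceData, reset: bool) -> np.ndarray:
    def neg(theta):
        return -log_posterior(theta, data, reset)

    best = None
    for x0 in ([20.0, 1.0, 0.3], [40.0, 2.0, 0.5], [10.0, 0.5, 0.2]):
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-4, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.asarray(best.x, dtype=float)
    theta[2] = float(np.clip(theta[2], 1e-3, 1 - 1e-3))
    return theta


def sample_posterior(
    data: ChoiceData | pd.DataFrame,
    config: FitConfig = FitConfig(),
) -> tuple[PosteriorDraws, HDISummary]:
    """Draw from the posterior over (s_c, s_b, r) by ensemble MCMC.

    Returns the draws with R-hat / ESS diagnostics and their HDI
    summary.  A ``UserWarning`` is raised (and ``converged`` set False)
    if any parameter's R-hat reaches 1.1.  With an empty dataset the
    posterior is the prior.
    """
    import arviz as az
    import emcee

    empty = False
    if isinstance(data, pd.DataFrame):
        if len(data) == 0:
            empty = True
        else:
            data = prepare_choice_data(data, include_practice=config.include_practice)

    ndim = 3
    nwalkers = max(8, config.n_chains, 2 * ndim + 2)
    rng = np.random.default_rng(config.seed)

    if empty:
        logpost = lambda th: log_prior(th)
        center = np.array([0.0, 0.0, 0.5])
    else:
        logpost = lambda th: log_posterior(th, data, config.reset_between_blocks)
        center = _map_estimate(data, config.reset_between_blocks)

    scale = np.maximum(np.abs(center) * 0.05, [0.5, 0.05, 0.02])
    p0 = center + rng.normal(0, 1, size=(nwalkers, ndim)) * scale
    p0[:, 2] = np.clip(p0[:, 2], 1e-3, 1 - 1e-3)

    sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost)
    state = emcee.State(p0, random_state=np.random.RandomState(config.seed).get_state())
    sampler.run_mcmc(state, config.n_warmup + config.n_draws, progress=False)
    if np.mean(sampler.acceptance_fraction) < 0.05:
        raise RuntimeError(
            "MCMC acceptance fraction collapsed "
            f"({np.mean(sampler.acceptance_fraction):.3f}); sampler failed"
        )
    chain = sampler.get_chain(discard=config.n_warmup)  # (draws, walkers, dim)
    chains = np.moveaxis(chain, 0, 1)  # (walkers, draws, dim)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(
            {name: chains[:, :, i] for i, name in enumerate(PARAM_NAMES)}
        )
        rhat_ds = az.rhat(ds)
        ess_ds = az.ess(ds)
    rhat = {n: float(rhat_ds[n]) for n in PARAM_NAMES}
    ess = {n: float(ess_ds[n]) for n in PARAM_NAMES}
    converged = all(v < RHAT_WARN for v in rhat.values())
    if not converged:
        warnings.warn(
            f"MCMC convergence suspect: R-hat {rhat} (threshold {RHAT_WARN})",
            UserWarning,
            stacklevel=2,
        )
    draws = PosteriorDraws(chains=chains, rhat=rhat, ess=ess, converged=converged)
    return draws, draws.summarize()


def hdi(x: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the draws (sorted-window).

    Sorts the draws and slides a window of ceil(mass * n) consecutive
    order statistics, returning the narrowest one.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws for an HDI")
    m = int(np.ceil(mass * n))
    m = min(max(m, 1), n)
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def contrast_parameter(
    draws_a: PosteriorDraws | np.ndarray,
    draws_b: PosteriorDraws | np.ndarray,
    parameter: str = "bias_scaler",
    mass: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, tuple[float, float]]:
    """Posterior of the difference A - B for one parameter.

    Draw sets from independent fits are paired elementwise after
    resampling to a common length (subsampling the longer set, or
    resampling with replacement if an ``rng`` is given).
    """
    a = draws_a.parameter(parameter) if isinstance(draws_a, PosteriorDraws) else np.asarray(draws_a)
    b = draws_b.parameter(parameter) if isinstance(draws_b, PosteriorDraws) else np.asarray(draws_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty draw set")
    n = min(a.size, b.size)
    if rng is not None:
        a = rng.choice(a, size=n, replace=True)
        b = rng.choice(b, size=n, replace=True)
    else:
        a = a[:n]
        b = b[:n]
    diff = a - b
    return float(diff.mean()), hdi(diff, mass)


def _fit_logistic_curve(coded: np.ndarray, went_right: np.ndarray) -> tuple[float, float]:
    """Plain logistic fit of P(right) on coded position; returns (b0, b1).

    Uses a large-C L2 regularization — effectively unpenalized, but a
    small ridge keeps the fit finite under complete separation.
    """
    from sklearn.linear_model import LogisticRegression

    y = went_right.astype(int)
    if y.min() == y.max():  # single class: saturated curve
        return (np.inf if y[0] == 1 else -np.inf), 0.0
    m = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    m.fit(coded.reshape(-1, 1), y)
    return float(m.intercept_[0]), float(m.coef_[0, 0])


def posterior_predictive_ribbon(
    draws: PosteriorDraws,
    designs: Sequence,
    error_table,
    n_draws: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    by_prime: bool = False,
) -> pd.DataFrame:
    """Min/max predicted P(right) per (condition, position) across
    simulated datasets.

    For each posterior draw a full dataset is simulated over ``designs``
    (one design per participant), summarized by a pooled logistic fit of
    P(right) on coded position per condition, and evaluated at the 29
    grid positions; the ribbon is the pointwise min/max over draws.  If
    ``n_draws`` exceeds the available posterior draws, draws are sampled
    with replacement.  ``by_prime`` groups the random block by the
    previous trial's side instead of by condition.
    """
    from .choice_model import simulate_session

    rng = rng or np.random.default_rng(0)
    flat = draws.flat
    idx = (
        rng.choice(flat.shape[0], size=n_draws, replace=True)
        if n_draws > flat.shape[0]
        else rng.choice(flat.shape[0], size=n_draws, replace=False)
    )
    grid = make_position_grid()
    coded_grid = np.array(grid.coded)
    groups = ("left_previous", "right_previous") if by_prime else (
        "rightwards", "leftwards", "random"
    )
    p_min = {g: np.ones(len(coded_grid)) for g in groups}
    p_max = {g: np.zeros(len(coded_grid)) for g in groups}

    for k in idx:
        s_c, s_b, r = flat[k]
        params = ModelParams(float(s_c), float(s_b), float(np.clip(r, 0.0, 1.0)))
        frames = []
        for i, design in enumerate(designs):
            recs = simulate_session(
                design, params, rng, error_table=error_table,
                participant_id=f"sim{i:03d}",
            )
            frames.append(recs)
        rows = [
            (r_.participant_id, r_.condition, r_.coded_position, r_.side_chosen)
            for recs in frames
            for r_ in recs
            if r_.block_type == "experimental"
        ]
        df = pd.DataFrame(rows, columns=["pid", "condition", "coded", "side"])
        if by_prime:
            df = df[df["condition"] == "random"].copy()
            prev = df.groupby("pid")["side"].shift(1)
            df["group"] = np.where(
                prev.eq("left"), "left_previous",
                np.where(prev.eq("right"), "right_previous", "undefined"),
            )
            df = df[df["group"].ne("undefined")]
        else:
            df["group"] = df["condition"]
        df = df[df["side"].isin(["left", "right"])]
        for g in groups:
            sub = df[df["group"] == g]
            if len(sub) == 0:
                continue
            b0, b1 = _fit_logistic_curve(
                sub["coded"].to_numpy(), (sub["side"] == "right").to_numpy()
            )
            with np.errstate(over="ignore"):
                p = 1.0 / (1.0 + np.exp(-(b0 + b1 * coded_grid)))
            p_min[g] = np.minimum(p_min[g], p)
            p_max[g] = np.maximum(p_max[g], p)

    out = []
    for g in groups:
        for x, cx, lo, hi in zip(grid.positions_mm, coded_grid, p_min[g], p_max[g]):
            out.append(
                {"condition": g, "position_mm": x, "coded_position": cx,
                 "p_min": lo, "p_max": hi}
            )
    return pd.DataFrame(out)
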