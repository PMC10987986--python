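"""Behavioral statistics: choice contrasts, prime effects, RT models.

The central quantity is the log odds (LO) of passing the obstacle on the
right at the central obstacle position, where both actions cost the same
and any difference is attributable to accumulated bias.  Hysteresis is
the increase in this LO in the rightwards condition relative to the
leftwards condition.  Choice models are mixed-effect logistic
regressions with a participant random intercept (see
:mod:`motorhyst.glmm`); post hoc comparisons are Wald-based with
Bonferroni-Holm correction.  RT analyses model inverse RT (1/s, for
normality) with linear mixed models and report back-transformed
estimated marginal means (EMMs) at the middle trial of the block.

Kinematic preprocessing (filtering, onset detection, RT cleaning) lives
in :mod:`motorhyst.kinematics` and is re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import code_position
from .glmm import GLMMResult, fit_logistic_glmm
from .kinematics import (  # noqa: F401  (module surface)
    ExclusionReport,
    TrajectoryTrace,
    clean_rt,
    compute_rt,
    lowpass_filter,
    movement_onset,
    movement_speed,
)

__all__ = [
    "ContrastResult",
    "preprocess_choices",
    "fit_choice_glmm",
    "central_contrasts",
    "hysteresis_contrast",
    "holm_correct",
    "prime_analysis",
    "fit_rt_lmm",
    "rt_switch_analysis",
    "RTModelResult",
    "clean_rt",
    "compute_rt",
    "lowpass_filter",
    "movement_onset",
    "movement_speed",
    "TrajectoryTrace",
    "ExclusionReport",
]

CONDITIONS = ("rightwards", "leftwards", "random")


@dataclass
class ContrastResult:
    """One post hoc comparison on the log-odds scale."""

    label: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_holm: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_raw": self.p_raw,
            "p_holm": self.p_holm,
        }


def preprocess_choices(raw: pd.DataFrame) -> pd.DataFrame:
    """Clean a trial table for choice analysis.

    Removes trials with no passage (``side`` not left/right), attaches
    coded positions, and computes within-block prime (previous trial's
    side) and switch/repeat flags.  The prime flag is undefined on the
    first trial of a block and after a no-passage trial.
    """
    df = raw.copy()
    known = {"rightwards", "leftwards", "random", "none"}
    bad = set(df["condition"].unique()) - known
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    df["coded_position"] = [code_position(x) for x in df["obstacle_x_mm"]]
    df = df.sort_values(["participant_id", "trial_index"], kind="stable")
    exp_mask = df["block_type"] == "experimental"
    prev = (
        df[exp_mask]
        .groupby(["participant_id", "condition"], sort=False)["side"]
        .shift(1)
    )
    df["prime"] = pd.Series(pd.NA, index=df.index, dtype="string")
    df.loc[prev.index, "prime"] = prev.where(prev.isin(["left", "right"])).astype("string")
    passed = df["side"].isin(["left", "right"])
    df = df[passed].copy()
    df["switch"] = pd.Series(pd.NA, index=df.index, dtype="string")
    has_prime = df["prime"].notna()
    df.loc[has_prime, "switch"] = np.where(
        df.loc[has_prime, "side"] == df.loc[has_prime, "prime"], "repeated", "switched"
    )
    return df.reset_index(drop=True)


def _choice_design(
    df: pd.DataFrame, include_experiment: bool
) -> tuple[np.ndarray, list[str]]:
    pos = df["coded_position"].to_numpy(dtype=float)
    cols = [np.ones(len(df)), pos]
    names = ["intercept", "position"]
    cond_dummies = {}
    for c in ("leftwards", "rightwards"):
        d = (df["condition"] == c).to_numpy(dtype=float)
        cond_dummies[c] = d
        cols.append(d)
        names.append(f"cond[{c}]")
    for c in ("leftwards", "rightwards"):
        cols.append(pos * cond_dummies[c])
        names.append(f"position:cond[{c}]")
    if include_experiment:
        exp_dummies = {}
        for e in (2, 3):
            d = (df["experiment"] == e).to_numpy(dtype=float)
            exp_dummies[e] = d
            cols.append(d)
            names.append(f"exp[{e}]")
        for e in (2, 3):
            cols.append(pos * exp_dummies[e])
            names.append(f"position:exp[{e}]")
        for c in ("leftwards", "rightwards"):
            for e in (2, 3):
                cols.append(cond_dummies[c] * exp_dummies[e])
                names.append(f"cond[{c}]:exp[{e}]")
        for c in ("leftwards", "rightwards"):
            for e in (2, 3):
                cols.append(pos * cond_dummies[c] * exp_dummies[e])
                names.append(f"position:cond[{c}]:exp[{e}]")
    return np.column_stack(cols), names


def fit_choice_glmm(
    dataset: pd.DataFrame, include_experiment: Optional[bool] = None
) -> GLMMResult:
    """Mixed-effect logistic regression of going right.

    Fixed effects: zero-centred obstacle position, condition (reference
    random), experiment (reference 1, included automatically when the
    data span several experiments) and all their interactions; random
    intercept per participant.
    """
    df = dataset[dataset["condition"].isin(CONDITIONS)]
    if include_experiment is None:
        include_experiment = df["experiment"].nunique() > 1
    X, names = _choice_design(df, include_experiment)
    y = (df["side"] == "right").to_numpy(dtype=float)
    return fit_logistic_glmm(X, y, df["participant_id"].to_numpy(), names)


def _cell_vector(model: GLMMResult, condition: str, experiment: int) -> np.ndarray:
    """Contrast vector for LO(right) at coded position 0 in one cell."""
    c = np.zeros(len(model.column_names))

    def put(name: str) -> None:
        if name in model.column_names:
            c[model.column_names.index(name)] = 1.0

    put("intercept")
    if condition != "random":
        put(f"cond[{condition}]")
    if experiment != 1:
        put(f"exp[{experiment}]")
        if condition != "random":
            put(f"cond[{condition}]:exp[{experiment}]")
    return c


def _wald(label: str, est: float, se: float) -> ContrastResult:
    z = est / se if se > 0 else np.inf * np.sign(est)
    p = 2 * stats.norm.sf(abs(z))
    half = 1.959963984540054 * se
    return ContrastResult(label, est, se, est - half, est + half, float(p))


def central_contrasts(
    model: GLMMResult, experiments: Sequence[int] = (1,)
) -> list[ContrastResult]:
    """Pairwise condition comparisons of LO(right) at the central position.

    For each experiment: rightwards - random, leftwards - random and
    rightwards - leftwards (the hysteresis measure), with Wald 95%
    intervals and Holm-adjusted p-values over the whole family.
    """
    results = []
    pairs = [("rightwards", "random"), ("leftwards", "random"), ("rightwards", "leftwards")]
    for e in experiments:
        for a, b in pairs:
            vec = _cell_vector(model, a, e) - _cell_vector(model, b, e)
            est, se = model.contrast(vec)
            results.append(_wald(f"exp{e}: {a} - {b}", est, se))
    adj = holm_correct([r.p_raw for r in results])
    for r, p in zip(results, adj):
        r.p_holm = float(p)
    return results


def hysteresis_contrast(model: GLMMResult, experiment: int = 1) -> ContrastResult:
    """Rightwards - leftwards LO at the central position for one experiment."""
    vec = _cell_vector(model, "rightwards", experiment) - _cell_vector(
        model, "leftwards", experiment
    )
    est, se = model.contrast(vec)
    return _wald(f"exp{experiment}: rightwards - leftwards", est, se)


def holm_correct(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate(np.minimum((m - np.arange(m)) * p[order], 1.0))
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def prime_analysis(dataset: pd.DataFrame) -> tuple[GLMMResult, ContrastResult]:
    """Trial-level hysteresis in the random block.

    Mixed logistic regression on random-condition trials with fixed
    effects of position, prime condition (reference: left previous) and
    their interaction, and a participant random intercept.  Returns the
    fitted model and the LO(right) difference (right previous - left
    previous) at the central position.
    """
    df = dataset[(dataset["condition"] == "random") & dataset["prime"].notna()]
    if df.empty:
        raise ValueError("no primed random-condition trials in dataset")
    pos = df["coded_position"].to_numpy(dtype=float)
    prime_r = (df["prime"] == "right").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), pos, prime_r, pos * prime_r])
    names = ["intercept", "position", "prime[right]", "position:prime[right]"]
    y = (df["side"] == "right").to_numpy(dtype=float)
    model = fit_logistic_glmm(X, y, df["participant_id"].to_numpy(), names)
    vec = np.zeros(4)
    vec[2] = 1.0
    est, se = model.contrast(vec)
    res = _wald("right previous - left previous", est, se)
    res.p_holm = res.p_raw
    return model, res


# ---------------------------------------------------------------------------
# RT mixed models


@dataclass
class RTModelResult:
    """Linear mixed model on inverse RT with back-transformed EMMs."""

    params: pd.Series
    cov: pd.DataFrame
    emm_ms: dict[str, tuple[float, float, float]]  # level -> (emm, lo, hi)
    comparisons: list[ContrastResult]
    converged: bool
    model: object = None


def _add_trial_centred(df: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
    df = df.copy()
    ranks = df.groupby(group_cols)["trial_index"].rank(method="first") - 1
    n = df.groupby(group_cols)["trial_index"].transform("size")
    df["trial_c"] = ranks - (n - 1) / 2.0
    return df


def _inverse_rt(df: pd.DataFrame) -> np.ndarray:
    return 1000.0 / df["rt_ms"].to_numpy(dtype=float)  # 1/s


def _fit_mixedlm(df, X, names, re_X, re_names, groups):
    import statsmodels.api as sm

    model = sm.MixedLM(
        endog=_inverse_rt(df),
        exog=pd.DataFrame(X, columns=names),
        groups=groups,
        exog_re=pd.DataFrame(re_X, columns=re_names),
    )
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs", maxiter=500)
    return fit


def _emm_from_fit(fit, vec: np.ndarray, label: str) -> tuple[float, float, float]:
    k = len(vec)
    beta = np.asarray(fit.params)[:k]
    cov = np.asarray(fit.cov_params())[:k, :k]
    est = float(vec @ beta)
    se = float(np.sqrt(vec @ cov @ vec))
    lo, hi = est - 1.96 * se, est + 1.96 * se
    # back-transform 1/s -> ms; reciprocal is decreasing, so the interval flips
    return 1000.0 / est, 1000.0 / hi, 1000.0 / lo


def fit_rt_lmm(dataset: pd.DataFrame) -> RTModelResult:
    """Mixed linear model of inverse RT across conditions.

    Fixed effects: trial number centred on the middle trial of the
    block, condition (reference random) and their interaction; random
    intercept and random condition slopes per participant.  EMMs at the
    middle trial are back-transformed to ms; pairwise condition
    comparisons are reported on the inverse-RT scale with Holm
    correction.
    """
    df = dataset[dataset["condition"].isin(CONDITIONS) & dataset["rt_ms"].notna()]
    df = _add_trial_centred(df, ["participant_id", "condition"])
    t = df["trial_c"].to_numpy(dtype=float)
    d_l = (df["condition"] == "leftwards").to_numpy(dtype=float)
    d_r = (df["condition"] == "rightwards").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), t, d_l, d_r, t * d_l, t * d_r])
    names = ["intercept", "trial_c", "cond[leftwards]", "cond[rightwards]",
             "trial_c:cond[leftwards]", "trial_c:cond[rightwards]"]
    re_X = np.column_stack([np.ones(len(df)), d_l, d_r])
    re_names = ["re_intercept", "re_leftwards", "re_rightwards"]
    fit = _fit_mixedlm(df, X, names, re_X, re_names, df["participant_id"].to_numpy())

    vecs = {
        "random": np.array([1, 0, 0, 0, 0, 0], dtype=float),
        "leftwards": np.array([1, 0, 1, 0, 0, 0], dtype=float),
        "rightwards": np.array([1, 0, 0, 1, 0, 0], dtype=float),
    }
    emm = {k: _emm_from_fit(fit, v, k) for k, v in vecs.items()}

    comps = []
    k = len(names)
    beta = np.asarray(fit.params)[:k]
    cov = np.asarray(fit.cov_params())[:k, :k]
    for a, b in (("rightwards", "random"), ("leftwards", "random"), ("rightwards", "leftwards")):
        c = vecs[a] - vecs[b]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        comps.append(_wald(f"{a} - {b} (1/s)", est, se))
    for r, p in zip(comps, holm_correct([r.p_raw for r in comps])):
        r.p_holm = float(p)

    return RTModelResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        emm_ms=emm,
        comparisons=comps,
        converged=bool(getattr(fit, "converged", True)),
        model=fit,
    )


def rt_switch_analysis(dataset: pd.DataFrame) -> RTModelResult:
    """Switch/repeat RT analysis in the random block.

    Fixed effects: centred trial number, switch condition (reference
    repeated) and interaction; random intercept and switch slope per
    participant.  EMMs at the middle trial back-transformed to ms.
    """
    df = dataset[
        (dataset["condition"] == "random")
        & dataset["rt_ms"].notna()
        & dataset["switch"].notna()
    ]
    if df.empty:
        raise ValueError("no switch-classified random-condition trials")
    df = _add_trial_centred(df, ["participant_id"])
    t = df["trial_c"].to_numpy(dtype=float)
    sw = (df["switch"] == "switched").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), t, sw, t * sw])
    names = ["intercept", "trial_c", "switch[switched]", "trial_c:switch[switched]"]
    re_X = np.column_stack([np.ones(len(df)), sw])
    fit = _fit_mixedlm(df, X, names, re_X, ["re_intercept", "re_switch"],
                       df["participant_id"].to_numpy())
    vecs = {
        "repeated": np.array([1, 0, 0, 0], dtype=float),
        "switched": np.array([1, 0, 1, 0], dtype=float),
    }
    emm = {k: _emm_from_fit(fit, v, k) for k, v in vecs.items()}
    k = len(names)
    beta = np.asarray(fit.params)[:k]
    cov = np.asarray(fit.cov_params())[:k, :k]
    c = vecs["switched"] - vecs["repeated"]
    est = float(c @ beta)
    se = float(np.sqrt(c @ cov @ c))
    comp = _wald("switched - repeated (1/s)", est, se)
    comp.p_holm = comp.p_raw
    return RTModelResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        emm_ms=emm,
        comparisons=[comp],
        converged=bool(getattr(fit, "converged", True)),
        model=fit,
    )
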