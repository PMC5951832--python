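"""Maximum-likelihood fitting of RL models to condition-averaged DA responses.

Following the study design, the per-trial dopamine responses are first
averaged per condition — one cell per (reward volume, trial-in-block,
previous-block type) — and the model is fit to those averages: the model is
run forward over the mouse's full trial history, its predicted responses
are averaged over the same cells, and the Gaussian likelihood of the
observed averages is maximized with the residual variance profiled out
analytically (equivalent to least squares). Optimization is bounded local
search from 5 random interior starting points, with a gradient-free polish.

Parameter bounds: α ∈ [0, 0.3], σ² ∈ [0.01, 0.5], initial values V ∈ [0, 1],
priors p ∈ [0.001, 0.999], gain β ∈ [0, 100] (unstated elsewhere; starts are
log-spaced).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import _kernels
from .models import CTX_CODES, BeliefRLParams, StandardRLParams, make_params

KEY_COLS = ["reward_volume_ul", "trial_in_block", "prev_block_type"]

BOUNDS = {
    "learning_rate": (0.0, 0.3),
    "sensory_noise_var": (0.01, 0.5),
    "init_value": (0.0, 1.0),
    "prior": (0.001, 0.999),
    "gain": (0.0, 100.0),
}

#: free parameters of each variant, in optimization-vector order
PARAM_NAMES = {
    "std_single": ["learning_rate", "init_value", "gain"],
    "std_dual": ["learning_rate", "init_value_after_s1", "init_value_after_s2", "gain"],
    "bs_fixed": ["learning_rate", "sensory_noise_var", "gain"],
    "bs_one_prior": ["learning_rate", "sensory_noise_var", "prior_after_s1", "gain"],
    "bs_two_prior": [
        "learning_rate",
        "sensory_noise_var",
        "prior_after_s1",
        "prior_after_s2",
        "gain",
    ],
    "bs_three_state": [
        "learning_rate",
        "sensory_noise_var",
        "prior_after_s1",
        "prior_after_s2",
        "prior_intermediate",
        "gain",
    ],
}

_RSS_FLOOR = 1e-30
_PENALTY = 1e10


def _bound_of(name: str):
    if name == "learning_rate":
        return BOUNDS["learning_rate"]
    if name == "sensory_noise_var":
        return BOUNDS["sensory_noise_var"]
    if name.startswith("prior"):
        return BOUNDS["prior"]
    if name == "gain":
        return BOUNDS["gain"]
    return BOUNDS["init_value"]


def variant_bounds(variant: str) -> list[tuple[float, float]]:
    return [_bound_of(p) for p in PARAM_NAMES[variant]]


def condition_average(trials: pd.DataFrame, responses) -> pd.DataFrame:
    """Mean response per (reward volume, trial-in-block, previous block) cell."""
    df = trials[KEY_COLS].copy()
    df["da"] = np.asarray(responses, dtype=float)
    if df["da"].isna().any():
        raise ValueError("every trial needs a response")
    out = (
        df.groupby(KEY_COLS, sort=True, observed=True)["da"]
        .agg(mean_da="mean", n_trials="size")
        .reset_index()
    )
    return out


def params_from_vector(variant: str, theta) -> StandardRLParams | BeliefRLParams:
    kwargs = dict(zip(PARAM_NAMES[variant], np.asarray(theta, dtype=float)))
    return make_params(variant, **kwargs)


def params_to_vector(params, variant: str) -> np.ndarray:
    vals = []
    for name in PARAM_NAMES[variant]:
        if name == "init_value":
            vals.append(params.init_value_after_s1)
        else:
            vals.append(getattr(params, name))
    return np.asarray(vals, dtype=float)


class FitProblem:
    """Precomputed arrays binding one mouse's trials to condition averages."""

    def __init__(
        self,
        cond_avg: pd.DataFrame,
        trials: pd.DataFrame,
        weights_init=None,
        use_post_outcome_belief: bool = True,
    ):
        if len(cond_avg) == 0:
            raise ValueError("no condition averages to fit")
        self.cond_avg = cond_avg.reset_index(drop=True)
        self.observed = self.cond_avg["mean_da"].to_numpy(dtype=float)
        self.n_obs = len(self.cond_avg)
        self.weights_init = weights_init
        self.use_post = use_post_outcome_belief

        self.rewards = trials["reward_norm"].to_numpy(dtype=float)
        self.new_block = (trials["trial_in_block"].to_numpy() == 1)
        self.ctx = trials["prev_block_type"].map(CTX_CODES).to_numpy(dtype=np.int64)

        keyed = self.cond_avg[KEY_COLS].reset_index(names="key_id")
        merged = trials[KEY_COLS].merge(keyed, on=KEY_COLS, how="left")
        key = merged["key_id"].to_numpy()
        self.in_fit = ~np.isnan(key)
        self.key_id = np.where(self.in_fit, key, 0).astype(np.int64)
        counts = np.bincount(self.key_id[self.in_fit], minlength=self.n_obs)
        if np.any(counts == 0):
            raise ValueError("condition averages contain cells with no trials")
        self.counts = counts

    def predicted_means(self, params) -> np.ndarray:
        if isinstance(params, StandardRLParams):
            _, rpe = _kernels.standard_pass(
                self.rewards,
                self.new_block,
                self.ctx,
                params.init_by_ctx(),
                params.learning_rate,
            )
        else:
            _, rpe, _, _, _ = _kernels.belief_pass(
                self.rewards,
                self.new_block,
                self.ctx,
                params.priors_by_ctx(),
                np.asarray(params.state_means, dtype=float),
                params.sensory_noise_var,
                params.learning_rate,
                np.asarray(
                    self.weights_init
                    if self.weights_init is not None
                    else params.weights_init,
                    dtype=float,
                ),
                params.use_post_outcome_belief and self.use_post,
            )
        pred = params.gain * rpe + params.offset
        sums = np.bincount(
            self.key_id[self.in_fit], weights=pred[self.in_fit], minlength=self.n_obs
        )
        return sums / self.counts

    def nll(self, params) -> float:
        pred = self.predicted_means(params)
        if not np.all(np.isfinite(pred)):
            return _PENALTY
        resid = pred - self.observed
        rss = max(float(resid @ resid), _RSS_FLOOR)
        n = self.n_obs
        return 0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)

    def nll_vector(self, variant: str, theta) -> float:
        try:
            params = params_from_vector(variant, theta)
        except ValueError:
            return _PENALTY
        return self.nll(params)


def negative_log_likelihood(
    params,
    cond_avg: pd.DataFrame,
    trials: pd.DataFrame,
    weights_init=None,
) -> float:
    """Profiled-variance Gaussian NLL of one parameter set (see module docs)."""
    return FitProblem(cond_avg, trials, weights_init=weights_init).nll(params)


@dataclass
class FitResult:
    """Best fit of one model variant to one mouse."""

    model: str
    params: object
    nll: float
    n_obs: int
    n_params: int
    seed: int
    starts: list = field(default_factory=list)
    converged: bool = True

    @property
    def param_dict(self) -> dict:
        return {
            name: float(v)
            for name, v in zip(
                PARAM_NAMES[self.model], params_to_vector(self.params, self.model)
            )
        }

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.param_dict,
            "nll": float(self.nll),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "seed": int(self.seed),
            "converged": bool(self.converged),
            "starts": self.starts,
        }


def _random_start(rng: np.random.Generator, variant: str) -> np.ndarray:
    theta = []
    for name in PARAM_NAMES[variant]:
        lo, hi = _bound_of(name)
        if name == "gain":
            # log-spaced over a plausible gain range
            theta.append(10.0 ** rng.uniform(-1.0, 1.5))
        else:
            span = hi - lo
            theta.append(rng.uniform(lo + 0.01 * span, hi - 0.01 * span))
    return np.asarray(theta)


def fit_model(
    variant: str,
    cond_avg: pd.DataFrame,
    trials: pd.DataFrame,
    n_starts: int = 5,
    seed: int = 0,
    weights_init=None,
    polish: bool = True,
) -> FitResult:
    """Bounded multi-start MLE for one (mouse, model) pair.

    Runs L-BFGS-B from ``n_starts`` random interior points, then polishes
    the best solution with bounded Powell search (gradient-free, robust to
    the flat ridges a near-zero learning rate induces). Deterministic for a
    given seed.
    """
    if variant not in PARAM_NAMES:
        raise ValueError(f"unknown model variant {variant!r}")
    rng = np.random.default_rng(seed)
    problem = FitProblem(cond_avg, trials, weights_init=weights_init)
    bounds = variant_bounds(variant)
    fun = lambda th: problem.nll_vector(variant, th)

    starts = []
    best = None
    for _ in range(n_starts):
        x0 = _random_start(rng, variant)
        res = optimize.minimize(
            fun,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        starts.append(
            {
                "x0": [float(v) for v in x0],
                "x": [float(v) for v in res.x],
                "nll": float(res.fun),
                "converged": bool(res.success),
            }
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not any(s["converged"] for s in starts):
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"all {n_starts} starts failed for {variant}: {starts}")
    if polish:
        res = optimize.minimize(
            fun,
            best.x,
            method="Powell",
            bounds=bounds,
            options={"ftol": 1e-12, "xtol": 1e-10, "maxiter": 2000},
        )
        if res.fun < best.fun:
            best = res
    return FitResult(
        model=variant,
        params=params_from_vector(variant, best.x),
        nll=float(best.fun),
        n_obs=problem.n_obs,
        n_params=len(PARAM_NAMES[variant]),
        seed=seed,
        starts=starts,
        converged=any(s["converged"] for s in starts),
    )


def fit_all_models(
    cond_avg: pd.DataFrame,
    trials: pd.DataFrame,
    variants=tuple(PARAM_NAMES),
    n_starts: int = 5,
    seed: int = 0,
    **kwargs,
) -> dict[str, FitResult]:
    """Fit every variant to one mouse; per-variant child seeds from ``seed``."""
    child = np.random.SeedSequence(seed).generate_state(len(variants)) % (2**31)
    return {
        v: fit_model(v, cond_avg, trials, n_starts=n_starts, seed=int(s), **kwargs)
        for v, s in zip(variants, child)
    }
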