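"""Standard and belief-state RL models of trial-level dopamine responses.

Both model classes predict the dopamine reward response as a linear readout
of the reward prediction error, predicted_da = β·δ (+ optional offset).

Standard RL (observable state): δ_t = r_t − V(s_t), V ← V + αδ_t, with the
value resetting at each block start to an initial value that may depend on
the previous block's type (``dual_init``) or not (``single_init``).

Belief-state RL: the agent is uncertain which hidden state (small-reward s1,
big-reward s2, optionally a third intermediate state) the current block was
drawn from. The belief b(s) starts at a prior at block start and is updated
by Bayes' rule after each reward, with Gaussian likelihood N(r; r̄_s, σ²).
Value is linear in the belief, V(b) = Σ_s w_s·b(s); δ_t = r_t − V(b_t) uses
the pre-outcome belief; weights update by Δw = αδ_t·b_t.

Variant labels: ``std_single``, ``std_dual``, ``bs_fixed``, ``bs_one_prior``,
``bs_two_prior``, ``bs_three_state``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .task import SessionSchedule, normalize_reward

VARIANTS = (
    "std_single",
    "std_dual",
    "bs_fixed",
    "bs_one_prior",
    "bs_two_prior",
    "bs_three_state",
)

#: context codes used by the kernels
CTX_CODES = {"none": 0, "s1": 1, "s2": 2, "intermediate": 3}

ALPHA_MAX = 0.3
SIGMA2_MIN, SIGMA2_MAX = 0.01, 0.5
PRIOR_MIN, PRIOR_MAX = 0.001, 0.999


class BeliefState:
    """Probability vector over hypothesized hidden states."""

    __slots__ = ("probabilities",)

    def __init__(self, probabilities):
        p = np.asarray(probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("belief probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"belief must sum to 1, got {p.sum()!r}")
        self.probabilities = p

    def __len__(self):
        return self.probabilities.size

    def __repr__(self):
        return f"BeliefState({np.array2string(self.probabilities, precision=6)})"


def _as_prob(x) -> np.ndarray:
    return x.probabilities if isinstance(x, BeliefState) else np.asarray(x, dtype=float)


def standard_rpe(reward: float, value: float) -> float:
    """δ = r − V."""
    return reward - value


def standard_value_update(value: float, alpha: float, delta: float) -> float:
    """V ← V + αδ."""
    return value + alpha * delta


def belief_posterior(prior, reward: float, state_means, sigma2: float) -> BeliefState:
    """Bayes posterior over states given one observed reward.

    b(s) ∝ N(reward; r̄_s, σ²) · prior(s), renormalized. Computed in log
    space so extreme rewards never underflow to an all-zero posterior;
    states with exactly zero prior mass stay at zero.
    """
    p = _as_prob(prior)
    means = np.asarray(state_means, dtype=float)
    with np.errstate(divide="ignore"):
        logp = np.log(p) - (reward - means) ** 2 / (2.0 * sigma2)
    logp -= logp.max()
    post = np.exp(logp)
    return BeliefState(post / post.sum())


def belief_value(belief, weights) -> float:
    """V(b) = Σ_s w_s b(s)."""
    b = _as_prob(belief)
    w = np.asarray(weights, dtype=float)
    if b.shape != w.shape:
        raise ValueError(f"belief length {b.size} != weights length {w.size}")
    return float(b @ w)


def belief_weight_update(weights, alpha: float, delta: float, belief) -> np.ndarray:
    """Δw = αδ·b, applied elementwise."""
    b = _as_prob(belief)
    w = np.asarray(weights, dtype=float)
    if b.shape != w.shape:
        raise ValueError(f"belief length {b.size} != weights length {w.size}")
    return w + alpha * delta * b


@dataclass
class StandardRLParams:
    """Parameters of the observable-state delta-rule model."""

    learning_rate: float = 0.1
    init_value_after_s1: float = 0.5
    init_value_after_s2: float = 0.5
    gain: float = 1.0
    variant: str = "single_init"
    offset: float = 0.0

    def __post_init__(self):
        if self.variant not in ("single_init", "dual_init"):
            raise ValueError(f"unknown standard-RL variant {self.variant!r}")
        if not 0.0 <= self.learning_rate <= ALPHA_MAX:
            raise ValueError(f"learning rate {self.learning_rate} outside [0, {ALPHA_MAX}]")
        for v in (self.init_value_after_s1, self.init_value_after_s2):
            if not 0.0 <= v <= 1.0:
                raise ValueError("initial values must lie in [0, 1]")
        if self.variant == "single_init" and (
            self.init_value_after_s1 != self.init_value_after_s2
        ):
            raise ValueError("single_init requires equal initial values")

    @property
    def n_states(self) -> int:
        return 1

    def init_by_ctx(self) -> np.ndarray:
        v1, v2 = self.init_value_after_s1, self.init_value_after_s2
        neutral = 0.5 * (v1 + v2)
        return np.array([neutral, v1, v2, neutral])


@dataclass
class BeliefRLParams:
    """Parameters of the belief-state model family.

    ``prior_after_s1`` (p1) is the prior probability of state s1 when the
    previous block was s1; ``prior_after_s2`` (p2) the prior of s2 when the
    previous block was s2. ``fixed_half`` pins both at 0.5; ``one_free``
    uses a single context-independent prior (p1, 1−p1); ``two_free`` frees
    both; ``three_state`` adds an intermediate hidden state with prior mass
    ``prior_intermediate`` (p3) and reward mean 0.5.
    """

    learning_rate: float = 0.1
    sensory_noise_var: float = 0.05
    gain: float = 1.0
    prior_variant: str = "fixed_half"
    prior_after_s1: float = 0.5
    prior_after_s2: float = 0.5
    prior_intermediate: float = 0.1
    state_means: tuple = None
    weights_init: tuple = None
    use_post_outcome_belief: bool = True
    offset: float = 0.0

    def __post_init__(self):
        if self.prior_variant not in ("fixed_half", "one_free", "two_free", "three_state"):
            raise ValueError(f"unknown belief prior variant {self.prior_variant!r}")
        if not 0.0 <= self.learning_rate <= ALPHA_MAX:
            raise ValueError(f"learning rate {self.learning_rate} outside [0, {ALPHA_MAX}]")
        if not SIGMA2_MIN <= self.sensory_noise_var <= SIGMA2_MAX:
            raise ValueError(
                f"sensory noise variance {self.sensory_noise_var} outside "
                f"[{SIGMA2_MIN}, {SIGMA2_MAX}]"
            )
        for p in (self.prior_after_s1, self.prior_after_s2):
            if not PRIOR_MIN <= p <= PRIOR_MAX:
                raise ValueError(f"prior {p} outside [{PRIOR_MIN}, {PRIOR_MAX}]")
        if self.prior_variant == "three_state" and not (
            PRIOR_MIN <= self.prior_intermediate <= PRIOR_MAX
        ):
            raise ValueError("intermediate prior outside bounds")
        k = self.n_states
        if self.state_means is None:
            self.state_means = (0.0, 1.0) if k == 2 else (0.0, 1.0, 0.5)
        if len(self.state_means) != k:
            raise ValueError(f"state_means must have {k} entries")
        if self.weights_init is None:
            self.weights_init = tuple([0.5] * k)
        if len(self.weights_init) != k:
            raise ValueError(f"weights_init must have {k} entries")

    @property
    def n_states(self) -> int:
        return 3 if self.prior_variant == "three_state" else 2

    def priors_by_ctx(self) -> np.ndarray:
        """Prior belief at block start for each previous-block context.

        Rows follow :data:`CTX_CODES`; ``none`` and ``intermediate``
        contexts use the average of the two training-block priors.
        """
        if self.prior_variant == "fixed_half":
            after_s1 = after_s2 = np.array([0.5, 0.5])
        elif self.prior_variant == "one_free":
            p1 = self.prior_after_s1
            after_s1 = after_s2 = np.array([p1, 1.0 - p1])
        elif self.prior_variant == "two_free":
            after_s1 = np.array([self.prior_after_s1, 1.0 - self.prior_after_s1])
            after_s2 = np.array([1.0 - self.prior_after_s2, self.prior_after_s2])
        else:  # three_state: p3 mass on the intermediate state, rest split by p1/p2
            p1, p2, p3 = self.prior_after_s1, self.prior_after_s2, self.prior_intermediate
            after_s1 = np.array([(1 - p3) * p1, (1 - p3) * (1 - p1), p3])
            after_s2 = np.array([(1 - p3) * (1 - p2), (1 - p3) * p2, p3])
        neutral = 0.5 * (after_s1 + after_s2)
        return np.stack([neutral, after_s1, after_s2, neutral])


@dataclass
class ModelTrace:
    """Per-trial output of a forward model run."""

    trials: pd.DataFrame
    value_pre: np.ndarray
    rpe: np.ndarray
    predicted_da: np.ndarray
    belief_pre: np.ndarray | None = None
    belief_post: np.ndarray | None = None
    weights: np.ndarray | None = None
    params: object = None

    def to_frame(self) -> pd.DataFrame:
        out = self.trials.copy()
        out["value_pre"] = self.value_pre
        out["rpe"] = self.rpe
        out["predicted_da"] = self.predicted_da
        if self.belief_pre is not None:
            for k in range(self.belief_pre.shape[1]):
                out[f"belief_pre_s{k + 1}"] = self.belief_pre[:, k]
                out[f"belief_post_s{k + 1}"] = self.belief_post[:, k]
                out[f"w{k + 1}"] = self.weights[:, k]
        return out


def make_params(variant: str, **kwargs):
    """Build a parameter object from a variant label.

    Maps the six public variant names onto :class:`StandardRLParams` /
    :class:`BeliefRLParams` configurations.
    """
    if variant == "std_single":
        if "init_value" in kwargs:
            v = kwargs.pop("init_value")
            kwargs["init_value_after_s1"] = kwargs["init_value_after_s2"] = v
        return StandardRLParams(variant="single_init", **kwargs)
    if variant == "std_dual":
        return StandardRLParams(variant="dual_init", **kwargs)
    prior_variant = {
        "bs_fixed": "fixed_half",
        "bs_one_prior": "one_free",
        "bs_two_prior": "two_free",
        "bs_three_state": "three_state",
    }.get(variant)
    if prior_variant is None:
        raise ValueError(f"unknown model variant {variant!r}; choose from {VARIANTS}")
    return BeliefRLParams(prior_variant=prior_variant, **kwargs)


def _encode_trials(trials: pd.DataFrame):
    rewards = trials["reward_norm"].to_numpy(dtype=float)
    new_block = (trials["trial_in_block"].to_numpy() == 1)
    ctx = trials["prev_block_type"].map(CTX_CODES).to_numpy(dtype=np.int64)
    return rewards, new_block, ctx


def run_model(params, schedule) -> ModelTrace:
    """Forward pass of either model over a schedule or trial table.

    ``schedule`` may be a :class:`~beliefrl.task.SessionSchedule` or a trial
    table with columns ``trial_in_block``, ``reward_norm`` and
    ``prev_block_type``.
    """
    trials = (
        schedule.to_trial_table() if isinstance(schedule, SessionSchedule) else schedule
    )
    if len(trials) == 0:
        raise ValueError("empty schedule")
    rewards, new_block, ctx = _encode_trials(trials)

    if isinstance(params, StandardRLParams):
        value_pre, rpe = _kernels.standard_pass(
            rewards, new_block, ctx, params.init_by_ctx(), params.learning_rate
        )
        return ModelTrace(
            trials=trials,
            value_pre=value_pre,
            rpe=rpe,
            predicted_da=params.gain * rpe + params.offset,
            params=params,
        )
    if isinstance(params, BeliefRLParams):
        value_pre, rpe, b_pre, b_post, w = _kernels.belief_pass(
            rewards,
            new_block,
            ctx,
            params.priors_by_ctx(),
            np.asarray(params.state_means, dtype=float),
            params.sensory_noise_var,
            params.learning_rate,
            np.asarray(params.weights_init, dtype=float),
            params.use_post_outcome_belief,
        )
        return ModelTrace(
            trials=trials,
            value_pre=value_pre,
            rpe=rpe,
            predicted_da=params.gain * rpe + params.offset,
            belief_pre=b_pre,
            belief_post=b_post,
            weights=w,
            params=params,
        )
    raise TypeError(f"unsupported parameter object {type(params).__name__}")


def run_model_reference(params: BeliefRLParams, schedule) -> ModelTrace:
    """Pure-Python belief-model pass composed from the scalar operations.

    Slow; exists as an independent route against which the compiled kernel
    is verified.
    """
    trials = (
        schedule.to_trial_table() if isinstance(schedule, SessionSchedule) else schedule
    )
    rewards, new_block, ctx = _encode_trials(trials)
    priors = params.priors_by_ctx()
    means = np.asarray(params.state_means, dtype=float)
    w = np.asarray(params.weights_init, dtype=float).copy()
    n, k = rewards.size, means.size
    value_pre = np.empty(n)
    rpe = np.empty(n)
    b_pre = np.empty((n, k))
    b_post = np.empty((n, k))
    weights = np.empty((n, k))
    b = BeliefState(priors[0])
    for i in range(n):
        if new_block[i]:
            b = BeliefState(priors[ctx[i]])
        b_pre[i] = b.probabilities
        v = belief_value(b, w)
        value_pre[i] = v
        d = standard_rpe(rewards[i], v)
        rpe[i] = d
        b = belief_posterior(b, rewards[i], means, params.sensory_noise_var)
        b_post[i] = b.probabilities
        w = belief_weight_update(
            w,
            params.learning_rate,
            d,
            b if params.use_post_outcome_belief else b_pre[i],
        )
        weights[i] = w
    return ModelTrace(
        trials=trials,
        value_pre=value_pre,
        rpe=rpe,
        predicted_da=params.gain * rpe + params.offset,
        belief_pre=b_pre,
        belief_post=b_post,
        weights=weights,
        params=params,
    )


def probe_block_table(volume: float, prev_block_type: str = "none") -> pd.DataFrame:
    """Trial table for a single 5-trial block of the given reward volume."""
    return pd.DataFrame(
        {
            "mouse_id": "probe",
            "day": 0,
            "block_index": 0,
            "trial_in_block": np.arange(1, 6),
            "block_type": "probe",
            "reward_volume_ul": volume,
            "reward_norm": normalize_reward(volume),
            "prev_block_type": prev_block_type,
        }
    )


def rpe_curve(
    params, volumes, trial: int = 1, prev_block_type: str = "none"
) -> pd.DataFrame:
    """δ at a given trial-in-block across reward volumes, one probe block each.

    Runs the model on isolated single blocks (weights/values as configured in
    ``params``), mirroring the prediction curves for the first encounters
    with each volume.
    """
    rows = []
    for v in volumes:
        trace = run_model(params, probe_block_table(v, prev_block_type))
        i = trial - 1
        rows.append((v, normalize_reward(v), trace.value_pre[i], trace.rpe[i]))
    return pd.DataFrame(rows, columns=["reward_volume_ul", "reward_norm", "value_pre", "rpe"])
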