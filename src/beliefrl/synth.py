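"""Synthetic per-mouse datasets with the statistical structure the analysis assumes.

No public dataset accompanies the study this pipeline targets, so every
downstream stage (photometry extraction, condition averaging, fitting,
model selection, behavioral statistics) is exercised on data generated
here: a ground-truth RL model run over a generated task history, with
Gaussian observation noise on the dopamine response and an affine,
floor-clipped lick model on the pre-outcome value.

Defaults emulate the study conditions: 11 mice, full training histories
(~3980 trials per training block, ~42 per intermediate volume), trial-level
dopamine responses in dF/F-scale units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task
from .models import BeliefRLParams, ModelTrace, StandardRLParams, make_params, run_model

#: per-trial DA observation noise (dF/F-scale units) against true gains ~1-3
DEFAULT_NOISE_SD_DA = 0.5
#: lick model defaults (licks/s); the scale is arbitrary — see docs/methods.md
DEFAULT_LICK_SLOPE = 6.0
DEFAULT_LICK_INTERCEPT = 1.0
DEFAULT_LICK_NOISE_SD = 0.8

#: ranges that per-mouse ground-truth parameters are drawn from (inside the
#: fitting bounds, so generated data are always recoverable)
TRUE_PARAM_RANGES = {
    "learning_rate": (0.05, 0.25),
    "sensory_noise_var": (0.03, 0.15),
    "gain": (1.0, 3.0),
    # context-conditioned priors are stay-biased, so every simulated animal
    # carries the previous-block effect on trial-1 expectation that the
    # two-free-prior model family exists to capture
    "prior": (0.55, 0.85),
    "init_low": (0.1, 0.4),
    "init_high": (0.6, 0.9),
}


@dataclass
class SyntheticMouse:
    """One simulated animal: trials, ground truth, and noisy observables."""

    mouse_id: str
    generating_model: str
    true_params: object
    trials: pd.DataFrame
    trace: ModelTrace
    da_response: np.ndarray
    lick_rate: np.ndarray
    noise_sd_da: float
    lick_slope: float
    lick_intercept: float
    lick_noise_sd: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        out = self.trials.copy()
        out["predicted_da"] = self.trace.predicted_da
        out["da_response"] = self.da_response
        out["lick_rate"] = self.lick_rate
        out["value_pre"] = self.trace.value_pre
        return out


def _check_in_bounds(params) -> None:
    # parameter dataclasses validate bounds on construction; re-validate in
    # case fields were mutated after the fact
    type(params)(**{f: getattr(params, f) for f in params.__dataclass_fields__})


def default_true_params(variant: str, rng: np.random.Generator):
    """Draw ground-truth parameters uniformly from :data:`TRUE_PARAM_RANGES`."""
    r = TRUE_PARAM_RANGES
    u = lambda lo_hi: float(rng.uniform(*lo_hi))
    if variant == "std_single":
        v = u((r["init_low"][0], r["init_high"][1]))
        return make_params(variant, learning_rate=u(r["learning_rate"]), init_value=v,
                           gain=u(r["gain"]))
    if variant == "std_dual":
        return make_params(
            variant,
            learning_rate=u(r["learning_rate"]),
            init_value_after_s1=u(r["init_low"]),
            init_value_after_s2=u(r["init_high"]),
            gain=u(r["gain"]),
        )
    kwargs = dict(
        learning_rate=u(r["learning_rate"]),
        sensory_noise_var=u(r["sensory_noise_var"]),
        gain=u(r["gain"]),
    )
    if variant in ("bs_one_prior", "bs_two_prior", "bs_three_state"):
        kwargs["prior_after_s1"] = u(r["prior"])
    if variant in ("bs_two_prior", "bs_three_state"):
        kwargs["prior_after_s2"] = u(r["prior"])
    if variant == "bs_three_state":
        kwargs["prior_intermediate"] = float(rng.uniform(0.05, 0.3))
    return make_params(variant, **kwargs)


def generate_mouse(
    generating_model: str = "bs_two_prior",
    true_params=None,
    schedule_config: dict | None = None,
    noise_sd_da: float = DEFAULT_NOISE_SD_DA,
    lick_slope: float = DEFAULT_LICK_SLOPE,
    lick_intercept: float = DEFAULT_LICK_INTERCEPT,
    lick_noise_sd: float = DEFAULT_LICK_NOISE_SD,
    seed: int = 0,
    mouse_id: str | None = None,
) -> SyntheticMouse:
    """Simulate one mouse: task history → model run → noisy observables.

    ``schedule_config`` is forwarded to :func:`beliefrl.task.generate_full_history`
    (defaults give the study-scale exposure). The recorded dopamine response
    is predicted_da + N(0, noise_sd_da²); the anticipatory lick rate is
    max(0, slope·V_pre + intercept + noise). Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    if true_params is None:
        true_params = default_true_params(generating_model, rng)
    else:
        _check_in_bounds(true_params)
    schedule_config = dict(schedule_config or {})
    mouse_id = mouse_id or f"m{seed}"
    trials = task.generate_full_history(
        seed=int(rng.integers(2**31)), mouse_id=mouse_id, **schedule_config
    )
    trace = run_model(true_params, trials)
    n = len(trials)
    da = trace.predicted_da + rng.normal(0.0, noise_sd_da, size=n)
    lick = np.maximum(
        0.0,
        lick_slope * trace.value_pre
        + lick_intercept
        + rng.normal(0.0, lick_noise_sd, size=n),
    )
    return SyntheticMouse(
        mouse_id=mouse_id,
        generating_model=generating_model,
        true_params=true_params,
        trials=trials,
        trace=trace,
        da_response=da,
        lick_rate=lick,
        noise_sd_da=noise_sd_da,
        lick_slope=lick_slope,
        lick_intercept=lick_intercept,
        lick_noise_sd=lick_noise_sd,
        seed=seed,
    )


def generate_cohort(
    n_mice: int = 11,
    model_mix: str | list = "bs_two_prior",
    seed: int = 0,
    **mouse_kwargs,
) -> list[SyntheticMouse]:
    """Simulate a cohort; each mouse gets an independent child seed.

    ``model_mix`` is either one variant label for the whole cohort or a list
    of labels, one per mouse (recorded in ``generating_model`` for
    model-selection validation).
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    if isinstance(model_mix, str):
        model_mix = [model_mix] * n_mice
    if len(model_mix) != n_mice:
        raise ValueError("model_mix must have one label per mouse")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_mice) % (2**31)
    return [
        generate_mouse(
            generating_model=model_mix[i],
            seed=int(child_seeds[i]),
            mouse_id=f"m{i:02d}",
            **mouse_kwargs,
        )
        for i in range(n_mice)
    ]


# ---------------------------------------------------------------------------
# raw fluorescence fixtures


@dataclass
class RawTraceFixture:
    """Synthetic 1 kHz fluorescence trace with task event timestamps.

    Event amplitudes at reward delivery equal the generating model's β·δ up
    to indicator-kernel scaling; CS events scale with the pre-outcome value.
    """

    sampling_rate: float
    fluorescence: np.ndarray
    sound_onsets: np.ndarray  # s, one per block
    odor_onsets: np.ndarray  # s, one per trial
    us_onsets: np.ndarray  # s, one per trial
    trial_index: np.ndarray  # row index into the mouse's trial table
    bleach_tau: float
    kernel_rise: float
    kernel_decay: float
    baseline_f: float
    injected_us_amplitude: np.ndarray = field(default=None)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.fluorescence.size) / self.sampling_rate

    def save_npz(self, path) -> None:
        np.savez(
            path,
            fluorescence=self.fluorescence,
            sound_onsets=self.sound_onsets,
            odor_onsets=self.odor_onsets,
            us_onsets=self.us_onsets,
            trial_index=self.trial_index,
            sampling_rate=self.sampling_rate,
        )


def _kernel(fs: float, rise: float, decay: float, duration: float = 3.0) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, normalized to unit peak."""
    t = np.arange(int(duration * fs)) / fs
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def generate_raw_trace(
    mouse: SyntheticMouse,
    n_trials: int | None = None,
    sampling_rate: float = 1000.0,
    kernel_rise: float = 0.03,
    kernel_decay: float = 0.4,
    bleach_tau: float = np.inf,
    baseline_f: float = 2.0,
    noise_sd: float = 0.0,
    cs_gain: float = 0.5,
    iti_fixed: float = 4.0,
    iti_exp_mean: float = 4.7,
    seed: int = 0,
) -> RawTraceFixture:
    """Render the first ``n_trials`` of a mouse as a raw fluorescence trace.

    Timing per trial: 1 s odor, 1 s delay, reward; inter-trial interval is a
    fixed 4 s plus an Exponential(mean 4.7 s) tail (≈8.7 s on average). A
    2 s block-start tone precedes each block's first trial by 3 s.
    F(t) = baseline·exp(−t/τ_bleach)·(1 + Σ event kernels) + white noise.
    """
    rng = np.random.default_rng(seed)
    trials = mouse.trials if n_trials is None else mouse.trials.iloc[:n_trials]
    n = len(trials)
    kern = _kernel(sampling_rate, kernel_rise, kernel_decay)

    odor_onsets = np.empty(n)
    us_onsets = np.empty(n)
    sound_onsets = []
    t = 5.0  # lead-in
    for i, (_, row) in enumerate(trials.iterrows()):
        if row["trial_in_block"] == 1:
            sound_onsets.append(t)
            t += 5.0  # 2 s tone + 3 s gap before the block's first odor
        odor_onsets[i] = t
        us_onsets[i] = t + 2.0  # 1 s odor + 1 s delay
        t += 2.0 + iti_fixed + rng.exponential(iti_exp_mean)
    total = int((t + 5.0) * sampling_rate)

    modulation = np.zeros(total)
    cs_amp = cs_gain * mouse.trace.value_pre[: n]
    us_amp = mouse.trace.predicted_da[: n]

    def add_event(onset_s, amp):
        i0 = int(round(onset_s * sampling_rate))
        seg = modulation[i0 : i0 + kern.size]
        seg += amp * kern[: seg.size]

    for i in range(n):
        add_event(odor_onsets[i], cs_amp[i])
        add_event(us_onsets[i], us_amp[i])

    times = np.arange(total) / sampling_rate
    bleach = np.exp(-times / bleach_tau) if np.isfinite(bleach_tau) else 1.0
    f = baseline_f * bleach * (1.0 + modulation)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=total)
    return RawTraceFixture(
        sampling_rate=sampling_rate,
        fluorescence=f,
        sound_onsets=np.asarray(sound_onsets),
        odor_onsets=odor_onsets,
        us_onsets=us_onsets,
        trial_index=trials.index.to_numpy(),
        bleach_tau=bleach_tau,
        kernel_rise=kernel_rise,
        kernel_decay=kernel_decay,
        baseline_f=baseline_f,
        injected_us_amplitude=us_amp.copy(),
    )
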