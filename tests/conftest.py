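"""Shared fixtures.

Heavy artifacts (cohorts and their model fits) are session-scoped so the
acceptance tests and unit tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import beliefrl as brl
from beliefrl import fitting


@pytest.fixture(scope="session")
def small_history():
    """A compact multi-phase trial table (deterministic + probabilistic + probe)."""
    return brl.generate_full_history(
        seed=11, n_det_days=1, n_prob_days=1, n_probe_days=2, blocks_per_day=8
    )


@pytest.fixture(scope="session")
def small_mouse():
    """A short synthetic mouse suitable for raw-trace rendering."""
    return brl.generate_mouse(
        "bs_two_prior",
        seed=5,
        schedule_config=dict(n_det_days=1, n_prob_days=1, n_probe_days=1, blocks_per_day=6),
    )


@pytest.fixture(scope="session")
def zero_noise_fit_bs():
    """Ground truth + zero-noise refit of the two-free-prior belief model."""
    true = brl.make_params(
        "bs_two_prior",
        learning_rate=0.15,
        sensory_noise_var=0.06,
        prior_after_s1=0.6,
        prior_after_s2=0.7,
        gain=2.0,
    )
    mouse = brl.generate_mouse("bs_two_prior", true_params=true, noise_sd_da=0.0, seed=3)
    cond = brl.condition_average(mouse.trials, mouse.da_response)
    fit = brl.fit_model("bs_two_prior", cond, mouse.trials, seed=1)
    return mouse, fit


@pytest.fixture(scope="session")
def cohort_bs():
    """11 mice generated from the two-free-prior belief model at default noise."""
    return brl.generate_cohort(11, "bs_two_prior", seed=42)


@pytest.fixture(scope="session")
def cohort_bs_fits(cohort_bs):
    """Six-variant fits for every mouse of the belief-generated cohort."""
    fits = {}
    for i, mouse in enumerate(cohort_bs):
        cond = brl.condition_average(mouse.trials, mouse.da_response)
        fits[mouse.mouse_id] = brl.fit_all_models(cond, mouse.trials, seed=7000 + i)
    return fits


@pytest.fixture(scope="session")
def cohort_std_fits():
    """Six-variant fits for an 11-mouse cohort generated from standard RL."""
    cohort = brl.generate_cohort(11, "std_dual", seed=42)
    fits = {}
    for i, mouse in enumerate(cohort):
        cond = brl.condition_average(mouse.trials, mouse.da_response)
        fits[mouse.mouse_id] = brl.fit_all_models(cond, mouse.trials, seed=8000 + i)
    return fits


@pytest.fixture(scope="session")
def recovery_runs():
    """20 noisy synthetic mice refit with their generating model."""
    runs = []
    for i in range(20):
        mouse = brl.generate_mouse("bs_two_prior", seed=100 + i)
        cond = brl.condition_average(mouse.trials, mouse.da_response)
        fit = brl.fit_model("bs_two_prior", cond, mouse.trials, seed=i)
        runs.append((mouse, fit))
    return runs
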