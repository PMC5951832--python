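import numpy as np
import pandas as pd
import pytest

import beliefrl as brl
from beliefrl import fitting


def toy_trials():
    """Five single-trial conditions with known rewards/contexts."""
    return pd.DataFrame(
        {
            "mouse_id": "t",
            "day": 0,
            "block_index": np.arange(5),
            "trial_in_block": 1,
            "block_type": "s2",
            "reward_volume_ul": [10.0, 10.0, 1.0, 1.0, 4.0],
            "reward_norm": [1.0, 1.0, 0.0, 0.0, 1 / 3],
            "prev_block_type": ["none", "s1", "s2", "s1", "s2"],
        }
    )


class TestConditionAverage:
    def test_mean_per_key(self):
        trials = pd.concat([toy_trials(), toy_trials()], ignore_index=True)
        resp = np.array([0.4, 1.0, 0.0, 0.2, 0.3, 0.6, 1.2, 0.4, 0.0, 0.5])
        cond = brl.condition_average(trials, resp)
        row = cond[
            (cond.reward_volume_ul == 10.0) & (cond.prev_block_type == "s1")
        ].iloc[0]
        assert row.mean_da == pytest.approx((1.0 + 1.2) / 2)
        assert row.n_trials == 2

    def test_grand_mean_conserved(self):
        trials = toy_trials()
        resp = np.array([0.4, 1.0, 0.0, 0.2, 0.3])
        cond = brl.condition_average(trials, resp)
        weighted = (cond.mean_da * cond.n_trials).sum() / cond.n_trials.sum()
        assert weighted == pytest.approx(resp.mean())

    def test_missing_response_rejected(self):
        trials = toy_trials()
        with pytest.raises(ValueError):
            brl.condition_average(trials, [0.1, 0.2, np.nan, 0.4, 0.5])


class TestNegativeLogLikelihood:
    def test_matches_hand_computed_rss(self):
        """Profiled-variance NLL = n/2·(ln(2π·RSS/n) + 1) against a direct
        residual computation on a 5-condition toy table."""
        trials = toy_trials()
        params = brl.make_params("std_dual", learning_rate=0.1,
                                 init_value_after_s1=0.3, init_value_after_s2=0.8, gain=2.0)
        trace = brl.run_model(params, trials)
        obs = trace.predicted_da + np.array([0.1, -0.2, 0.05, 0.0, -0.1])
        cond = brl.condition_average(trials, obs)
        # every condition is a singleton here, so residuals are the offsets
        rss = float(np.sum(np.array([0.1, -0.2, 0.05, 0.0, -0.1]) ** 2))
        n = 5
        expected = 0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        got = fitting.negative_log_likelihood(params, cond, trials)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_perfect_fit_hits_floored_minimum(self):
        trials = toy_trials()
        params = brl.make_params("std_single", learning_rate=0.1, init_value=0.5, gain=1.0)
        trace = brl.run_model(params, trials)
        cond = brl.condition_average(trials, trace.predicted_da)
        nll0 = fitting.negative_log_likelihood(params, cond, trials)
        worse = brl.make_params("std_single", learning_rate=0.1, init_value=0.4, gain=1.0)
        assert nll0 < fitting.negative_log_likelihood(worse, cond, trials)

    def test_monotone_in_residual_scale(self):
        trials = toy_trials()
        params = brl.make_params("std_single", init_value=0.5)
        trace = brl.run_model(params, trials)
        resid = np.array([0.1, -0.1, 0.2, 0.05, -0.15])
        nll1 = fitting.negative_log_likelihood(
            params, brl.condition_average(trials, trace.predicted_da + resid), trials
        )
        nll2 = fitting.negative_log_likelihood(
            params, brl.condition_average(trials, trace.predicted_da + 2 * resid), trials
        )
        assert nll2 > nll1


class TestFitModel:
    def test_zero_noise_recovery_two_prior(self, zero_noise_fit_bs):
        mouse, fit = zero_noise_fit_bs
        truth = {
            "learning_rate": 0.15,
            "sensory_noise_var": 0.06,
            "prior_after_s1": 0.6,
            "prior_after_s2": 0.7,
            "gain": 2.0,
        }
        for name, true_val in truth.items():
            assert fit.param_dict[name] == pytest.approx(true_val, rel=0.02), name

    def test_zero_noise_recovery_std_dual(self):
        true = brl.make_params(
            "std_dual", learning_rate=0.12, init_value_after_s1=0.25,
            init_value_after_s2=0.8, gain=1.5,
        )
        mouse = brl.generate_mouse("std_dual", true_params=true, noise_sd_da=0.0, seed=6)
        cond = brl.condition_average(mouse.trials, mouse.da_response)
        fit = brl.fit_model("std_dual", cond, mouse.trials, seed=2)
        assert fit.param_dict["init_value_after_s1"] == pytest.approx(0.25, rel=0.02)
        assert fit.param_dict["init_value_after_s2"] == pytest.approx(0.8, rel=0.02)
        assert fit.param_dict["learning_rate"] == pytest.approx(0.12, rel=0.02)

    def test_seeded_determinism(self, small_history):
        params = brl.make_params("bs_fixed", gain=2.0, sensory_noise_var=0.08)
        trace = brl.run_model(params, small_history)
        rng = np.random.default_rng(0)
        cond = brl.condition_average(
            small_history, trace.predicted_da + rng.normal(0, 0.3, len(small_history))
        )
        a = brl.fit_model("bs_fixed", cond, small_history, seed=11)
        b = brl.fit_model("bs_fixed", cond, small_history, seed=11)
        assert a.to_dict() == b.to_dict()

    def test_params_within_bounds_and_best_start_reported(self, recovery_runs):
        for mouse, fit in recovery_runs:
            vec = fitting.params_to_vector(fit.params, fit.model)
            for v, (lo, hi) in zip(vec, fitting.variant_bounds(fit.model)):
                assert lo - 1e-12 <= v <= hi + 1e-12
            assert fit.nll <= min(s["nll"] for s in fit.starts) + 1e-9

    def test_recovery_bias_small_for_priors(self, recovery_runs):
        """Context priors are well identified at study-condition noise."""
        for name in ("prior_after_s1", "prior_after_s2"):
            errs = [
                fit.param_dict[name] - getattr(mouse.true_params, name)
                for mouse, fit in recovery_runs
            ]
            assert abs(np.median(errs)) < 0.05, name

    def test_unknown_variant_rejected(self, small_history):
        cond = brl.condition_average(small_history, np.zeros(len(small_history)))
        with pytest.raises(ValueError):
            brl.fit_model("bs_quantum", cond, small_history)


class TestModelMimicry:
    def test_standard_fit_leaves_nonmonotonic_trial2_residuals(self, cohort_bs, cohort_bs_fits):
        """The standard model cannot absorb the belief-state trial-2 pattern:
        its residuals on intermediate-volume trial-2 cells keep the
        positive-small / negative-large sign structure."""
        signs = []
        for mouse in cohort_bs:
            fit = cohort_bs_fits[mouse.mouse_id]["std_dual"]
            cond = brl.condition_average(mouse.trials, mouse.da_response)
            prob = fitting.FitProblem(cond, mouse.trials)
            resid = cond.mean_da.to_numpy() - prob.predicted_means(fit.params)
            sel = cond.assign(resid=resid)
            t2 = sel[(sel.trial_in_block == 2) & sel.reward_volume_ul.isin([2.0, 8.0])]
            lo = t2[t2.reward_volume_ul == 2.0].resid.mean()
            hi = t2[t2.reward_volume_ul == 8.0].resid.mean()
            signs.append(lo > hi)
        assert np.mean(signs) >= 0.8
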