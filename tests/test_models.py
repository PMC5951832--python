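import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beliefrl as brl
from beliefrl import models, task


def brute_force_posterior(prior, reward, means, sigma2):
    """Direct density evaluation and normalization (independent oracle)."""
    dens = np.array(
        [
            p * np.exp(-((reward - m) ** 2) / (2 * sigma2)) / np.sqrt(2 * np.pi * sigma2)
            for p, m in zip(prior, means)
        ]
    )
    return dens / dens.sum()


class TestScalarOps:
    @pytest.mark.parametrize(
        "r,v,expected", [(1.0, 0.5, 0.5), (0.0, 0.0, 0.0), (0.333, 0.5, -0.167)]
    )
    def test_standard_rpe(self, r, v, expected):
        assert brl.standard_rpe(r, v) == pytest.approx(expected)

    def test_standard_value_update(self):
        assert brl.standard_value_update(0.5, 0.1, 0.5) == pytest.approx(0.55)
        assert brl.standard_value_update(0.73, 0.2, 0.0) == 0.73  # fixed point

    def test_belief_value(self):
        assert brl.belief_value([1, 0], [0, 1]) == 0.0
        assert brl.belief_value([0.5, 0.5], [0, 1]) == 0.5
        assert brl.belief_value([0.2, 0.8], [0.1, 0.9]) == pytest.approx(0.74)
        with pytest.raises(ValueError):
            brl.belief_value([0.5, 0.5], [1, 2, 3])

    def test_belief_weight_update(self):
        np.testing.assert_allclose(
            brl.belief_weight_update([0, 1], 0.1, 0.5, [1, 0]), [0.05, 1.0]
        )
        np.testing.assert_allclose(
            brl.belief_weight_update([0.3, 0.7], 0.25, 0.0, [0.5, 0.5]), [0.3, 0.7]
        )
        np.testing.assert_allclose(
            brl.belief_weight_update([0, 1], 0.2, -0.2, [0.5, 0.5]), [-0.02, 0.98]
        )


class TestBeliefPosterior:
    def test_symmetric_reward_leaves_flat_prior(self):
        post = brl.belief_posterior([0.5, 0.5], 0.5, [0, 1], 0.1)
        np.testing.assert_allclose(post.probabilities, [0.5, 0.5], atol=1e-14)

    def test_matches_logistic_closed_form(self):
        # flat prior, means (0,1): b(s1) = 1/(1+exp((2r-1)/(2σ²)))
        post = brl.belief_posterior([0.5, 0.5], 0.0, [0, 1], 0.1)
        assert post.probabilities[0] == pytest.approx(1 / (1 + np.exp(-5)), abs=1e-12)

    def test_degenerate_prior_is_absorbing(self):
        for r in (0.0, 0.5, 1.0):
            post = brl.belief_posterior([1.0, 0.0], r, [0, 1], 0.05)
            np.testing.assert_allclose(post.probabilities, [1.0, 0.0])

    def test_extreme_rewards_never_underflow_to_nan(self):
        post = brl.belief_posterior([0.5, 0.5], 100.0, [0, 1], 0.01)
        assert np.all(np.isfinite(post.probabilities))
        assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tight_noise_concentrates_on_observed_state_mean(self):
        post = brl.belief_posterior([0.5, 0.5], 1.0, [0, 1], 0.01)
        assert post.probabilities[1] >= 1 - 1e-6

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        p1=st.floats(0.001, 0.999),
        reward=st.floats(0.0, 1.0),
        sigma2=st.floats(0.01, 0.5),
    )
    def test_agrees_with_brute_force_oracle(self, p1, reward, sigma2):
        prior = [p1, 1 - p1]
        post = brl.belief_posterior(prior, reward, [0, 1], sigma2)
        oracle = brute_force_posterior(prior, reward, [0, 1], sigma2)
        np.testing.assert_allclose(post.probabilities, oracle, atol=1e-10)
        assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(post.probabilities >= 0)


class TestBeliefStateValidation:
    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            brl.BeliefState([-0.1, 1.1])
        with pytest.raises(ValueError):
            brl.BeliefState([0.5, 0.6])


class TestRunModel:
    def test_trial1_rpe_affine_with_unit_slope_at_asymptote(self):
        params = brl.make_params(
            "bs_fixed", sensory_noise_var=0.05, weights_init=(0.0, 1.0)
        )
        curve = brl.rpe_curve(params, task.ALL_VOLUMES, trial=1)
        slope, intercept = np.polyfit(curve["reward_norm"], curve["rpe"], 1)
        assert slope == pytest.approx(1.0, abs=1e-12)
        resid = curve["rpe"] - (slope * curve["reward_norm"] + intercept)
        assert np.abs(resid).max() < 1e-12

    def test_trial2_rpe_matches_logistic_oracle(self):
        # closed form with frozen weights: δ2(r) = r − (1 − b(s1)),
        # b(s1) = 1/(1+exp((2r−1)/(2σ²)))
        params = brl.make_params(
            "bs_fixed", sensory_noise_var=0.05, weights_init=(0.0, 1.0), learning_rate=0.0
        )
        curve = brl.rpe_curve(params, [2, 8], trial=2)
        for r, rpe in zip(curve["reward_norm"], curve["rpe"]):
            b1 = 1 / (1 + np.exp((2 * r - 1) / (2 * 0.05)))
            assert rpe == pytest.approx(r - (1 - b1), abs=1e-12)
        assert curve["rpe"].iloc[0] == pytest.approx(0.111, abs=0.001)
        assert curve["rpe"].iloc[1] == pytest.approx(-0.218, abs=0.001)

    def test_standard_trial2_rpe_strictly_increasing(self):
        params = brl.make_params(
            "std_dual", learning_rate=0.2, init_value_after_s1=0.3, init_value_after_s2=0.7
        )
        curve = brl.rpe_curve(params, task.ALL_VOLUMES, trial=2, prev_block_type="s1")
        assert np.all(np.diff(curve["rpe"]) > 0)

    def test_standard_value_resets_by_context(self, small_history):
        params = brl.make_params(
            "std_dual", learning_rate=0.1, init_value_after_s1=0.2, init_value_after_s2=0.9
        )
        trace = brl.run_model(params, small_history)
        first = trace.trials["trial_in_block"].to_numpy() == 1
        ctx = trace.trials["prev_block_type"].to_numpy()
        v = trace.value_pre
        assert np.all(v[first & (ctx == "s1")] == 0.2)
        assert np.all(v[first & (ctx == "s2")] == 0.9)
        assert np.all(v[first & np.isin(ctx, ["none", "intermediate"])] == 0.55)

    def test_beliefs_are_probability_vectors_throughout(self, small_history):
        params = brl.make_params(
            "bs_three_state", prior_after_s1=0.7, prior_after_s2=0.6, prior_intermediate=0.2
        )
        trace = brl.run_model(params, small_history)
        for arr in (trace.belief_pre, trace.belief_post):
            assert np.all(arr >= 0)
            np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-12)

    def test_kernel_matches_scalar_composition(self, small_history):
        """Compiled pass reproduces the pure-Python composition of scalar ops."""
        for variant, kw in [
            ("bs_two_prior", dict(prior_after_s1=0.65, prior_after_s2=0.7)),
            ("bs_fixed", dict(use_post_outcome_belief=False)),
            ("bs_three_state", dict(prior_intermediate=0.15)),
        ]:
            params = brl.make_params(variant, sensory_noise_var=0.07, learning_rate=0.12, **kw)
            fast = brl.run_model(params, small_history)
            slow = models.run_model_reference(params, small_history)
            np.testing.assert_allclose(fast.rpe, slow.rpe, atol=1e-12)
            np.testing.assert_allclose(fast.belief_post, slow.belief_post, atol=1e-12)
            np.testing.assert_allclose(fast.weights, slow.weights, atol=1e-12)

    @pytest.mark.parametrize("alpha", [0.05, 0.15, 0.3])
    def test_weights_converge_to_analytic_equilibrium(self, alpha):
        """Repeated training blocks drive the weights toward (0, 1), up to the
        trial-1 credit-assignment offset.

        With post-outcome credit and alternating blocks the equilibrium is
        (−c, 1+c): each block's first trial is predicted under the mixed
        prior (δ1 = ∓1/2) but credited to the identified state, and the
        within-block decay (1−α)⁴ balances that kick at
        c = α(1−α)⁴ / [2(1 − (1−α)⁴)] — a closed form checked here as an
        independent oracle. Pre-outcome credit splits the kick across
        states and lands within 0.05 of (0, 1).
        """
        sched = task.generate_training_schedule(
            5, "deterministic", blocks_per_day=80, seed=0
        )
        params = brl.make_params("bs_fixed", learning_rate=alpha, sensory_noise_var=0.05)
        trace = brl.run_model(params, sched)
        decay = (1 - alpha) ** 4
        c = 0.5 * alpha * decay / (1 - decay)
        np.testing.assert_allclose(trace.weights[-1], [-c, 1 + c], atol=1e-3)
        np.testing.assert_allclose(trace.weights[-1], [0.0, 1.0], atol=c + 1e-3)

        params_pre = brl.make_params(
            "bs_fixed",
            learning_rate=alpha,
            sensory_noise_var=0.05,
            use_post_outcome_belief=False,
        )
        trace_pre = brl.run_model(params_pre, sched)
        # pre-outcome kick is α/4 per block start, decays within the block
        np.testing.assert_allclose(
            trace_pre.weights[-1], [0.0, 1.0], atol=max(0.05, 0.3 * alpha)
        )

    def test_training_asymptote_rpe_shrinks_after_trial1(self):
        """|δ| on trials 2–5 of a training block is below trial 1's |δ|."""
        sched = task.generate_training_schedule(4, "probabilistic", seed=3)
        params = brl.make_params("bs_two_prior", prior_after_s1=0.7, prior_after_s2=0.7)
        trace = brl.run_model(params, sched).to_frame()
        late = trace[trace["day"] >= 2]  # post-convergence
        mean_abs = late.groupby("trial_in_block")["rpe"].apply(lambda s: s.abs().mean())
        assert (mean_abs.loc[2:] <= mean_abs.loc[1]).all()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            brl.make_params("bs_unknown")
        with pytest.raises(ValueError):
            models.StandardRLParams(variant="triple_init")

    def test_empty_schedule_rejected(self, small_history):
        with pytest.raises(ValueError):
            brl.run_model(brl.make_params("std_single"), small_history.iloc[:0])

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError):
            brl.make_params("bs_fixed", learning_rate=0.5)
        with pytest.raises(ValueError):
            brl.make_params("bs_fixed", sensory_noise_var=0.005)
        with pytest.raises(ValueError):
            brl.make_params("bs_two_prior", prior_after_s1=0.9999)
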