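"""Compiled trial-loop kernels for the RL forward passes.

These loops are sequential (each trial's value depends on the previous
trial's update) and sit inside the maximum-likelihood objective, so they are
JIT-compiled. ``models.py`` holds readable scalar counterparts of every
update rule; the test suite checks the kernels against a pure-Python
composition of those scalar operations.

Context codes: 0 = none (first block of a history), 1 = previous block s1,
2 = previous block s2, 3 = previous block intermediate.
"""

import math

import numpy as np
from numba import njit

_NEG_INF = -1.0e300


@njit(cache=False)
def standard_pass(rewards, new_block, ctx, init_by_ctx, alpha):
    """Delta-rule pass with value reset at block start.

    V resets to ``init_by_ctx[ctx]`` at each block start, then follows
    V ← V + α(r − V) within the block.
    """
    n = rewards.size
    value_pre = np.empty(n)
    rpe = np.empty(n)
    v = init_by_ctx[0]
    for i in range(n):
        if new_block[i]:
            v = init_by_ctx[ctx[i]]
        value_pre[i] = v
        d = rewards[i] - v
        rpe[i] = d
        v = v + alpha * d
    return value_pre, rpe


@njit(cache=False)
def belief_pass(
    rewards, new_block, ctx, priors_by_ctx, means, sigma2, alpha, w_init, use_post
):
    """Belief-state pass: Bayes posterior over states, linear value in belief.

    At block start the belief resets to the context-conditioned prior. The
    pre-outcome value is V = w·b; δ = r − V; the posterior
    b(s) ∝ N(r; r̄_s, σ²)·b(s) (computed in log space) becomes the next
    trial's belief; weights update by Δw = αδb using the post-outcome
    belief when ``use_post`` else the pre-outcome one.
    """
    n = rewards.size
    k_states = means.size
    value_pre = np.empty(n)
    rpe = np.empty(n)
    belief_pre = np.empty((n, k_states))
    belief_post = np.empty((n, k_states))
    weights = np.empty((n, k_states))
    w = w_init.copy()
    b = np.empty(k_states)
    logp = np.empty(k_states)
    for k in range(k_states):
        b[k] = priors_by_ctx[0, k]
    for i in range(n):
        if new_block[i]:
            for k in range(k_states):
                b[k] = priors_by_ctx[ctx[i], k]
        for k in range(k_states):
            belief_pre[i, k] = b[k]
        v = 0.0
        for k in range(k_states):
            v += w[k] * b[k]
        value_pre[i] = v
        d = rewards[i] - v
        rpe[i] = d
        # Bayes update in log space; zero-prior states stay at zero mass
        maxlp = _NEG_INF
        for k in range(k_states):
            if b[k] > 0.0:
                logp[k] = math.log(b[k]) - (rewards[i] - means[k]) ** 2 / (2.0 * sigma2)
            else:
                logp[k] = _NEG_INF
            if logp[k] > maxlp:
                maxlp = logp[k]
        tot = 0.0
        for k in range(k_states):
            b[k] = math.exp(logp[k] - maxlp)
            tot += b[k]
        for k in range(k_states):
            b[k] /= tot
            belief_post[i, k] = b[k]
        for k in range(k_states):
            bw = b[k] if use_post else belief_pre[i, k]
            w[k] += alpha * d * bw
            weights[i, k] = w[k]
    return value_pre, rpe, belief_pre, belief_post, weights
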