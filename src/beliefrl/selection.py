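"""Cohort-level model comparison: BIC and random-effects Bayesian model selection.

Per-model evidence for each mouse is approximated as −BIC/2. The cohort is
then treated as a random-effects population over models: model frequencies
r ~ Dirichlet(α), each mouse's generating model m_n ~ Categorical(r). The
variational scheme of Stephan et al. (2009) yields the posterior Dirichlet;
the exceedance probability xp_k = P(r_k > r_j ∀ j≠k) is estimated by Monte
Carlo, and the protected exceedance probability of Rigoux et al. (2014)
hedges against the null of equal frequencies via the Bayes omnibus risk
(BOR): pxp = (1 − BOR)·xp + BOR/K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp


@dataclass
class BicScore:
    model: str
    k: int
    n: int
    nll: float

    @property
    def bic(self) -> float:
        return bic(self.nll, self.k, self.n)


def bic(nll: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, k·ln(n) + 2·NLL (lower is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * np.log(n) + 2.0 * nll


@dataclass
class CohortSelection:
    """Random-effects model-selection result for one cohort."""

    models: list
    log_evidence: np.ndarray  # mice × models
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance: np.ndarray
    protected_exceedance: np.ndarray
    bor: float
    posterior_assignment: np.ndarray  # mice × models (u_nk)
    mc_samples: int
    seed: int
    ranking: pd.DataFrame | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "exceedance": self.exceedance.tolist(),
            "protected_exceedance": self.protected_exceedance.tolist(),
            "bor": float(self.bor),
            "mc_samples": int(self.mc_samples),
            "seed": int(self.seed),
        }


def _dirichlet_neg_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """−KL( Dir(alpha) || Dir(alpha0) )."""
    a_sum, a0_sum = alpha.sum(), alpha0.sum()
    kl = (
        gammaln(a_sum)
        - gammaln(alpha).sum()
        - gammaln(a0_sum)
        + gammaln(alpha0).sum()
        + ((alpha - alpha0) * (digamma(alpha) - digamma(a_sum))).sum()
    )
    return -kl

def exceedance_mc(
    alpha: np.ndarray, mc_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo exceedance: fraction of Dirichlet draws where model k wins.

    Exact ties between sampled frequencies (probability-zero event) would be
    counted once per tied model; with continuous draws this never occurs,
    so argmax's first-index rule is an adequate deterministic tie-break.
    """
    k = alpha.size
    # chunked to bound memory at default 10^6 samples
    counts = np.zeros(k, dtype=np.int64)
    remaining = mc_samples
    while remaining > 0:
        m = min(remaining, 200_000)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    return counts / mc_samples


def bms_random_effects(
    log_evidence,
    alpha0: float = 1.0,
    mc_samples: int = 1_000_000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> CohortSelection:
    """Variational random-effects BMS over a mice × models evidence matrix."""
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2:
        raise ValueError("log_evidence must be 2-D (mice × models)")
    n, k = lme.shape
    if k < 2:
        raise ValueError("need at least 2 models")
    bad = ~np.isfinite(lme)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"non-finite log evidence for mouse {i}, model {j}")

    alpha0_vec = np.full(k, float(alpha0))
    alpha = alpha0_vec.copy()
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0_vec + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    expected_freq = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    xp = exceedance_mc(alpha, mc_samples, rng)

    # free energy of the random-effects model (at the variational optimum)
    log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
    log_u -= logsumexp(log_u, axis=1, keepdims=True)
    u = np.exp(log_u)
    f_rfx = (
        (u * lme).sum()
        + (u @ (digamma(alpha) - digamma(alpha.sum()))).sum()
        - (u * np.where(u > 0, np.log(np.where(u > 0, u, 1.0)), 0.0)).sum()
        + _dirichlet_neg_kl(alpha, alpha0_vec)
    )
    # null: all models equally frequent in the population
    f_null = logsumexp(lme - np.log(k), axis=1).sum()
    bor = float(1.0 / (1.0 + np.exp(f_rfx - f_null)))
    pxp = (1.0 - bor) * xp + bor / k

    return CohortSelection(
        models=list(range(k)),
        log_evidence=lme,
        dirichlet_alpha=alpha,
        expected_freq=expected_freq,
        exceedance=xp,
        protected_exceedance=pxp,
        bor=bor,
        posterior_assignment=u,
        mc_samples=mc_samples,
        seed=seed,
    )


def select_cohort(
    fits: dict,
    mc_samples: int = 1_000_000,
    seed: int = 0,
    alpha0: float = 1.0,
) -> CohortSelection:
    """BIC + random-effects selection over ``fits[mouse_id][model] -> FitResult``.

    Every mouse must have the same model set. Returns a
    :class:`CohortSelection` whose ``ranking`` table lists, per model, the
    mean BIC, ΔBIC to the best model, expected frequency, xp and pxp.
    """
    mice = list(fits)
    if not mice:
        raise ValueError("empty cohort")
    models = sorted(fits[mice[0]])
    missing = [
        (m, v) for m in mice for v in models if v not in fits[m]
    ] + [(m, v) for m in mice for v in fits[m] if v not in models]
    if missing:
        raise ValueError(f"missing (mouse, model) fits: {sorted(set(missing))}")

    bics = np.array(
        [
            [
                bic(fits[m][v].nll, fits[m][v].n_params, fits[m][v].n_obs)
                for v in models
            ]
            for m in mice
        ]
    )
    log_ev = -bics / 2.0
    sel = bms_random_effects(log_ev, alpha0=alpha0, mc_samples=mc_samples, seed=seed)
    sel.models = models
    mean_bic = bics.mean(axis=0)
    sel.ranking = (
        pd.DataFrame(
            {
                "model": models,
                "mean_bic": mean_bic,
                "delta_mean_bic": mean_bic - mean_bic.min(),
                "expected_freq": sel.expected_freq,
                "xp": sel.exceedance,
                "pxp": sel.protected_exceedance,
            }
        )
        .sort_values("mean_bic")
        .reset_index(drop=True)
    )
    return sel
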