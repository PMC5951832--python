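"""Self-contained statistics: exact Wilcoxon signed-rank, correlations with
one-tailed tests, polynomial fits with adjusted r², and anticipatory-lick
deltas.

The exact signed-rank test enumerates the full null distribution of the
rank-sum by dynamic programming over subset sums of {1..n} (2ⁿ equiprobable
sign assignments), with the reported statistic being min(W⁺, W⁻) — the
convention under which small-cohort paired comparisons print, e.g.,
(w = 9, n = 11) → p = 0.032.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class SignedRankResult:
    n: int
    w_statistic: float
    p_two_sided: float
    method: str = "exact"


def signed_rank_null_counts(n: int) -> np.ndarray:
    """counts[w] = number of subsets of {1..n} whose ranks sum to w.

    The null distribution of W⁺ assigns probability counts[w]/2ⁿ to each
    achievable rank-sum w ∈ [0, n(n+1)/2]. Integer arithmetic throughout,
    so the distribution sums to 2ⁿ exactly.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for rank in range(1, n + 1):
        counts[rank:] = counts[rank:] + counts[: total + 1 - rank]
    return counts


def wilcoxon_exact(
    differences=None, w: float | None = None, n: int | None = None
) -> SignedRankResult:
    """Exact two-sided Wilcoxon signed-rank test.

    Give either the paired ``differences`` (no zeros, no tied magnitudes —
    the exact null requires distinct ranks) or the statistic ``w`` (the
    smaller of W⁺/W⁻) with the pair count ``n``. Two-sided
    p = 2·P(W ≤ w), capped at 1.
    """
    if differences is not None:
        d = np.asarray(differences, dtype=float)
        n = d.size
        if np.any(d == 0):
            raise ValueError(
                "zero differences invalidate the exact test; drop them or use a "
                "mid-rank/approximate method"
            )
        mags = np.abs(d)
        if np.unique(mags).size != n:
            raise ValueError(
                "tied |differences| invalidate the exact test; consider mid-ranks "
                "with a normal approximation"
            )
        ranks = sps.rankdata(mags)
        w_pos = float(ranks[d > 0].sum())
        w_neg = float(ranks[d < 0].sum())
        w = min(w_pos, w_neg)
    elif w is None or n is None:
        raise ValueError("provide differences, or both w and n")
    if n > 30:
        raise ValueError("exact enumeration supported for n <= 30")

    counts = signed_rank_null_counts(n)
    lower_tail = int(sum(counts[: int(np.floor(w)) + 1]))
    p = 2.0 * lower_tail / float(2**n)
    return SignedRankResult(n=n, w_statistic=float(w), p_two_sided=min(p, 1.0))


def corr_with_test(x, y, alternative: str = "two_tailed") -> tuple[float, float]:
    """Pearson r with t-test p-value.

    ``alternative``: ``two_tailed`` or ``one_tailed_positive`` (tests r > 0,
    the directional hypothesis that value and behavior covary positively).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    if alternative == "one_tailed_positive":
        p = float(sps.t.sf(t, df=n - 2))
    elif alternative == "two_tailed":
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return r, p


def polyfit_adjusted_r2(x, y, degree: int) -> tuple[np.ndarray, float]:
    """Least-squares polynomial fit and adjusted r².

    adjusted r² = 1 − (1 − r²)(n − 1)/(n − degree − 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n <= degree + 1:
        raise ValueError("underdetermined: need n > degree + 1")
    coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - degree - 1)
    return coeffs, float(adj)


def delta_lick(
    trials: pd.DataFrame,
    lick_col: str = "lick_rate",
    within_block: bool = True,
) -> pd.DataFrame:
    """Δ lick rate between consecutive trials within a training day.

    Returns one row per transition with the originating trial's block
    context. ``within_block=True`` restricts to transitions inside a block
    (1→2 … 4→5), the groupings used for per-volume learning curves; when
    False, all consecutive same-day pairs are used. Missing (NaN) licks
    drop the affected transitions.
    """
    df = trials.reset_index(drop=True)
    if "mouse_id" not in df.columns:
        df = df.assign(mouse_id="")
    nxt = df.shift(-1)
    ok = (df["day"] == nxt["day"]) & (df["mouse_id"] == nxt["mouse_id"])
    if within_block:
        ok &= (df["block_index"] == nxt["block_index"]) & (
            nxt["trial_in_block"] == df["trial_in_block"] + 1
        )
    ok &= df[lick_col].notna() & nxt[lick_col].notna()
    out = pd.DataFrame(
        {
            "mouse_id": df["mouse_id"],
            "day": df["day"],
            "block_index": df["block_index"],
            "block_type": df["block_type"],
            "reward_volume_ul": df["reward_volume_ul"],
            "from_trial": df["trial_in_block"],
            "to_trial": nxt["trial_in_block"],
            "delta_lick": nxt[lick_col] - df[lick_col],
        }
    )[ok.to_numpy(dtype=bool)].reset_index(drop=True)
    out["from_trial"] = out["from_trial"].astype(int)
    out["to_trial"] = out["to_trial"].astype(int)
    return out
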