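"""Fluorescence → per-trial response scalars.

dF/F = (F − F0)/F0 with three interchangeable baseline (F0) definitions:

* ``pretrial`` — mean F over the 1 s before each trial's odor onset.
* ``preblock`` — mean F over the 1 s before each block's tone onset.
* ``running_median`` — median F over a 60 s window centered on each sample
  (truncated at trace edges).

CS and US responses are means over the 1 s after event onset (half-open
windows); US responses are additionally baseline-corrected by the mean dF/F
over the 100 ms centered on reward onset, because the CS transient need not
have decayed by reward time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synth import RawTraceFixture

BASELINE_METHODS = ("pretrial", "preblock", "running_median")


def _segment_baseline(f: np.ndarray, fs: float, anchors: np.ndarray, window: float = 1.0):
    """Per-segment F0: mean over ``window`` seconds before each anchor.

    Sample i belongs to the last anchor at or before it (samples before the
    first anchor use the first one). Windows that extend past the trace
    start are truncated with a warning.
    """
    f0 = np.empty(anchors.size)
    for j, a in enumerate(anchors):
        i1 = int(round(a * fs))
        i0 = i1 - int(round(window * fs))
        if i0 < 0:
            warnings.warn("baseline window truncated at trace start")
            i0 = 0
        if i1 <= i0:
            raise ValueError("no samples available for baseline window")
        f0[j] = f[i0:i1].mean()
    starts = np.round(anchors * fs).astype(int)
    seg = np.searchsorted(starts, np.arange(f.size), side="right") - 1
    seg = np.clip(seg, 0, anchors.size - 1)
    return f0[seg]


def compute_dff(trace: RawTraceFixture, method: str = "pretrial") -> np.ndarray:
    """Relative fluorescence change dF/F = (F − F0)/F0 for a whole trace."""
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline method {method!r}")
    f = np.asarray(trace.fluorescence, dtype=float)
    fs = trace.sampling_rate
    if method == "pretrial":
        f0 = _segment_baseline(f, fs, trace.odor_onsets)
    elif method == "preblock":
        f0 = _segment_baseline(f, fs, trace.sound_onsets)
    else:
        win = int(60.0 * fs) + 1
        f0 = (
            pd.Series(f)
            .rolling(window=win, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    return (f - f0) / f0


def _window(dff: np.ndarray, fs: float, start_s: float, dur_s: float) -> np.ndarray:
    i0 = int(round(start_s * fs))
    i1 = i0 + int(round(dur_s * fs))
    if i0 < 0 or i1 > dff.size:
        raise ValueError(
            f"window [{start_s:.3f}, {start_s + dur_s:.3f}] s exceeds trace bounds"
        )
    return dff[i0:i1]  # half-open [onset, onset + dur)


def quantify_us(dff: np.ndarray, fs: float, us_onset: float) -> tuple[float, float]:
    """US mean and single-sample peak over [onset, onset+1 s), baseline-corrected.

    The correction subtracts the mean dF/F over the 100 ms centered on
    reward onset, isolating the change in activity at reward delivery from
    any residual CS transient.
    """
    base = _window(dff, fs, us_onset - 0.05, 0.1).mean()
    resp = _window(dff, fs, us_onset, 1.0) - base
    return float(resp.mean()), float(resp.max())


def quantify_cs(dff: np.ndarray, fs: float, odor_onset: float) -> float:
    """CS response: mean dF/F over [odor onset, odor onset + 1 s)."""
    return float(_window(dff, fs, odor_onset, 1.0).mean())


def minmax_normalize(responses, trial1_responses) -> np.ndarray:
    """y = (x − min_trial1) / (max_trial1 − min_trial1).

    Rescales each animal's responses by its own trial-1 range for pooled
    display; values outside the trial-1 range map outside [0, 1]. Model
    fitting never uses these normalized values.
    """
    x = np.asarray(responses, dtype=float)
    t1 = np.asarray(trial1_responses, dtype=float)
    lo, hi = t1.min(), t1.max()
    if hi - lo == 0:
        raise ValueError("degenerate trial-1 range: min == max")
    return (x - lo) / (hi - lo)


def extract_trial_responses(
    trace: RawTraceFixture, method: str = "pretrial"
) -> pd.DataFrame:
    """Per-trial CS/US scalars for every trial in a raw trace fixture."""
    dff = compute_dff(trace, method)
    fs = trace.sampling_rate
    rows = []
    for i in range(trace.odor_onsets.size):
        us_mean, us_peak = quantify_us(dff, fs, trace.us_onsets[i])
        rows.append(
            (
                trace.trial_index[i],
                quantify_cs(dff, fs, trace.odor_onsets[i]),
                us_mean,
                us_peak,
                method,
            )
        )
    return pd.DataFrame(
        rows, columns=["trial_index", "cs_mean", "us_mean", "us_peak", "baseline_method"]
    )
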