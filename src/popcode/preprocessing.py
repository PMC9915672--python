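"""From raw fluorescence to windowed scalar responses, plus interneuron tagging.

Responses are expressed as dF/Fstd — the fluorescence change normalized by
the standard deviation of the one-second pre-stimulus baseline — and reduced
to a scalar per trial by averaging over a one-second window.  Two window
choices are supported:

* the *optimal* window, chosen per neuron and stimulus condition as the 1-s
  window (starting 0-4 s after onset) that maximizes the sensitivity index
  d' between windowed and baseline activity across trials;
* the *fixed* window, one start per recording, chosen to maximize the number
  of neurons with a significant response (paired t-test vs baseline,
  Bonferroni-corrected over the stimulus conditions, p < 0.01) to at least
  one condition.

Opsin-expressing interneurons are identified from two-channel summary
signals: the activity-independent red channel is regressed on the green
channel to remove GCaMP bleedthrough, and cells whose corrected red
fluorescence exceeds 2 background standard deviations are tagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import validate_response_table
from .traces import TraceSet

__all__ = [
    "WindowSpec",
    "DegenerateTraceError",
    "compute_dff",
    "window_response",
    "optimal_window",
    "fixed_window",
    "responses_from_traces",
    "identify_tagged_cells",
]

WINDOW_S = 1.0  # response windows are one second long
MAX_START_S = 4.0  # latest admissible window start after onset


class DegenerateTraceError(ValueError):
    """Raised when a baseline has zero variance and dF/Fstd is undefined."""


@dataclass(frozen=True)
class WindowSpec:
    """A one-second averaging window, start measured in seconds from onset."""

    start_s: float
    duration_s: float = WINDOW_S

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError("window start must be >= 0 s from onset")
        if self.start_s + self.duration_s > MAX_START_S + WINDOW_S:
            raise ValueError("window must end within 5 s of onset")


def compute_dff(trace: np.ndarray, baseline_window: tuple[int, int]) -> np.ndarray:
    """dF/Fstd = (F - mean(Fbaseline)) / std(Fbaseline), frames on the last axis.

    Invariant to positive affine rescaling of the raw fluorescence.
    """
    trace = np.asarray(trace, dtype=float)
    b0, b1 = baseline_window
    if b1 - b0 < 2:
        raise ValueError("baseline window must span >= 2 frames")
    base = trace[..., b0:b1]
    mu = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, keepdims=True, ddof=1)
    if np.any(sd == 0):
        raise DegenerateTraceError("zero baseline standard deviation")
    return (trace - mu) / sd


def _frames(frame_rate: float, seconds: float) -> int:
    return int(round(frame_rate * seconds))


def window_response(
    trace: np.ndarray, window: WindowSpec, frame_rate: float, onset_frame: int
) -> np.ndarray:
    """Mean over the window's frames; scalar per trace (frames on last axis)."""
    start = onset_frame + _frames(frame_rate, window.start_s)
    stop = start + _frames(frame_rate, window.duration_s)
    trace = np.asarray(trace, dtype=float)
    if start < 0 or stop > trace.shape[-1]:
        raise IndexError("window out of trace bounds")
    return trace[..., start:stop].mean(axis=-1)


def _sliding_window_stats(
    dff: np.ndarray, frame_rate: float, onset_frame: int
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed trial means for every candidate start on the frame grid.

    dff has trials on axis -2 and frames on axis -1.  Returns (starts_s,
    means) with means shaped (..., n_starts, n_trials).
    """
    wlen = _frames(frame_rate, WINDOW_S)
    n_starts = _frames(frame_rate, MAX_START_S) + 1
    cs = np.cumsum(np.concatenate([np.zeros(dff.shape[:-1] + (1,)), dff], axis=-1), axis=-1)
    idx = onset_frame + np.arange(n_starts)
    win_means = (cs[..., idx + wlen] - cs[..., idx]) / wlen  # (..., trials, starts)
    starts_s = np.arange(n_starts) / frame_rate
    return starts_s, np.moveaxis(win_means, -1, -2)


def optimal_window(
    dff_trials: np.ndarray, frame_rate: float, onset_frame: int
) -> WindowSpec:
    """Best 1-s window for one neuron and condition by the sensitivity index.

    d' = |mean_win - mean_base| / sqrt((var_win + var_base)/2) computed
    across trials, with the 1-s pre-stimulus baseline as reference; the scan
    covers every frame-grid start in [0, 4] s and ties break to the earliest
    start.
    """
    dff = np.asarray(dff_trials, dtype=float)
    if dff.ndim != 2 or dff.shape[0] < 2:
        raise ValueError("need >= 2 trials (trials x frames)")
    wlen = _frames(frame_rate, WINDOW_S)
    base = dff[:, onset_frame - wlen : onset_frame].mean(axis=1)
    starts_s, win = _sliding_window_stats(dff, frame_rate, onset_frame)
    mu_w, var_w = win.mean(axis=1), win.var(axis=1, ddof=1)
    mu_b, var_b = base.mean(), base.var(ddof=1)
    pooled = (var_w + var_b) / 2.0
    if np.all(pooled == 0):
        raise DegenerateTraceError("zero pooled variance across all windows")
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = np.abs(mu_w - mu_b) / np.sqrt(pooled)
    dprime[~np.isfinite(dprime)] = -np.inf
    # near-ties (within numerical roundoff of the max) resolve to the earliest start
    best = int(np.flatnonzero(dprime >= dprime.max() - 1e-12)[0])
    return WindowSpec(start_s=float(starts_s[best]))


def fixed_window(ts: TraceSet, alpha: float = 0.01) -> WindowSpec:
    """Recording-wide 1-s window maximizing the responsive-neuron count.

    For each candidate start, each neuron is tested per stimulus condition
    with a paired t-test of windowed vs baseline response across trials;
    p-values are Bonferroni-corrected over the conditions and a neuron
    counts as responsive if any corrected p < alpha.  Ties break to the
    earliest start.
    """
    starts_s, counts = _responsive_counts(ts, alpha)
    return WindowSpec(start_s=float(starts_s[int(np.argmax(counts))]))


def _responsive_counts(ts: TraceSet, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    conditions = ts.conditions()
    n_cond = len(conditions)
    wlen = _frames(ts.frame_rate, WINDOW_S)
    dff = compute_dff(ts.F, (ts.onset_frame - wlen, ts.onset_frame))
    base = dff[:, :, ts.onset_frame - wlen : ts.onset_frame].mean(axis=2)
    starts_s, win = _sliding_window_stats(dff, ts.frame_rate, ts.onset_frame)
    # win: (neurons, starts, trials); diff vs per-trial baseline
    diff = win - base[:, None, :]
    responsive = np.zeros((ts.n_neurons, len(starts_s)), dtype=bool)
    for level, laser in conditions:
        m = ts.trial_mask(level, laser)
        n = int(m.sum())
        if n < 2:
            raise ValueError("need >= 2 trials per condition for the paired t-test")
        d = diff[:, :, m]
        sd = d.std(axis=2, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d.mean(axis=2) / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        p[~np.isfinite(p)] = 1.0
        responsive |= (p * n_cond) < alpha
    return starts_s, responsive.sum(axis=0)


def responses_from_traces(ts: TraceSet, mode: str = "fixed") -> pd.DataFrame:
    """Windowed scalar responses for every neuron and trial, as a tidy table.

    mode="fixed" uses one recording-wide window; mode="optimal" picks the
    d'-optimal window per neuron and stimulus condition.  The returned
    DataFrame carries the window provenance in ``attrs``.
    """
    if mode not in ("fixed", "optimal"):
        raise ValueError(f"mode must be 'fixed' or 'optimal', got {mode!r}")
    wlen = _frames(ts.frame_rate, WINDOW_S)
    dff = compute_dff(ts.F, (ts.onset_frame - wlen, ts.onset_frame))
    levels = ts.labels["level_db"].to_numpy(dtype=float)
    lasers = ts.labels["laser"].to_numpy()
    trials_idx = _within_condition_trial_index(levels, lasers)

    rows = []
    windows: dict = {}
    if mode == "fixed":
        w = fixed_window(ts)
        windows["fixed"] = w.start_s
        resp = window_response(dff, w, ts.frame_rate, ts.onset_frame)
        for i in range(ts.n_neurons):
            for j in range(ts.n_trials):
                rows.append((i, levels[j], lasers[j], trials_idx[j], float(resp[i, j])))
    else:
        for i in range(ts.n_neurons):
            for level, laser in ts.conditions():
                m = ts.trial_mask(level, laser)
                w = optimal_window(dff[i, m], ts.frame_rate, ts.onset_frame)
                windows[(i, level, laser)] = w.start_s
                resp = window_response(dff[i, m], w, ts.frame_rate, ts.onset_frame)
                for k, j in enumerate(np.flatnonzero(m)):
                    rows.append((i, level, laser, trials_idx[j], float(resp[k])))
    table = pd.DataFrame(
        rows, columns=["neuron_id", "level_db", "laser", "trial", "response"]
    ).sort_values(["neuron_id", "laser", "level_db", "trial"], ignore_index=True)
    table.attrs["window_mode"] = mode
    table.attrs["windows"] = windows
    return validate_response_table(table)


def _within_condition_trial_index(levels: np.ndarray, lasers: np.ndarray) -> np.ndarray:
    df = pd.DataFrame({"level_db": levels, "laser": lasers})
    return df.groupby(["level_db", "laser"], observed=True).cumcount().to_numpy()


def identify_tagged_cells(
    green: np.ndarray,
    red: np.ndarray,
    background_sd: float,
    background_mean: float = 0.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Bleedthrough correction and 2-sigma interneuron tagging.

    A single least-squares slope of red on green (pooled over cells and
    frames, as the red channel is activity-independent and any shared
    modulation is bleedthrough) corrects the red signal; each cell's mean
    corrected red fluorescence is z-scored against the background red
    fluorescence (mean and sd) and cells above 2 are tagged.
    Returns (slope, tagged flags, z-scores).
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("green and red must have matching shapes")
    if background_sd <= 0:
        raise ValueError("background_sd must be > 0")
    g, r = green.ravel(), red.ravel()
    var_g = g.var()
    if var_g == 0:
        warnings.warn("constant green signal; bleedthrough slope set to 0", stacklevel=2)
        slope = 0.0
    else:
        slope = float(np.cov(g, r, bias=True)[0, 1] / var_g)
    corrected = red - slope * green
    means = corrected.mean(axis=tuple(range(1, corrected.ndim))) if corrected.ndim > 1 else corrected
    z = (means - background_mean) / background_sd
    return slope, z > 2.0, z
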