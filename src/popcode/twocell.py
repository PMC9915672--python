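"""Analytic two-cell model of sound-level coding under interneuron activation.

A minimal population of one monotonic (sigmoid) and one nonmonotonic
(Gaussian) cell, evaluated on a 1-dB grid from 0 to 90 dB SPL, illustrates
how SST or VIP interneuron activation reshapes the population code: SST
activation rotates population vectors apart (larger separation angles,
shorter vectors — a shift toward a localist code), VIP activation does the
opposite (a more distributed, rate-like code).

Condition parameter sets are the mean fitted parameters of the recorded
monotonic and nonmonotonic populations at no and high laser power; only the
parameters that change significantly under activation differ from the
no-laser values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import GaussianParams, SigmoidParams, evaluate_model

__all__ = [
    "CONDITIONS",
    "TwoCellConfig",
    "GainCurve",
    "model_responses",
    "angle_matrix",
    "length_matrix",
    "mean_condition_difference",
    "condition_difference_summary",
    "gain_curve",
    "two_cell_response_table",
]

CONDITIONS = ("none", "SST", "VIP")

_DEFAULT_SIGMOID = {
    "none": SigmoidParams(y0=-0.12, yrange=0.88, x0=55.0, dx=11.0),
    "SST": SigmoidParams(y0=-0.12, yrange=0.88, x0=68.0, dx=11.0),
    "VIP": SigmoidParams(y0=-0.12, yrange=1.43, x0=55.0, dx=11.0),
}
_DEFAULT_GAUSSIAN = {
    "none": GaussianParams(y0=-0.04, yrange=0.54, xmean=50.0, sigma=13.0),
    "SST": GaussianParams(y0=-0.07, yrange=0.27, xmean=50.0, sigma=13.0),
    "VIP": GaussianParams(y0=-0.04, yrange=0.86, xmean=54.0, sigma=17.0),
}


@dataclass(frozen=True)
class TwoCellConfig:
    """Per-condition parameters of the two model cells.

    sigmoid / gaussian map condition name ("none" | "SST" | "VIP") to the
    cell's curve parameters.  The level grid is 0..90 dB SPL in 1 dB steps.
    """

    sigmoid: dict[str, SigmoidParams] = field(
        default_factory=lambda: dict(_DEFAULT_SIGMOID)
    )
    gaussian: dict[str, GaussianParams] = field(
        default_factory=lambda: dict(_DEFAULT_GAUSSIAN)
    )
    levels: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 91.0), compare=False
    )

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            if cond not in self.sigmoid or cond not in self.gaussian:
                raise ValueError(f"missing parameters for condition {cond!r}")


def model_responses(
    config: TwoCellConfig, condition: str, subtract_silence: bool = False
) -> np.ndarray:
    """Responses of both cells across the level grid; shape (2, n_levels).

    Row 0 is the monotonic (sigmoid) cell, row 1 the nonmonotonic (Gaussian)
    cell.  With ``subtract_silence`` each cell's 0 dB response is subtracted,
    giving the trajectory form whose origin is the response to silence.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    r = np.vstack(
        [
            evaluate_model("sigmoid", config.sigmoid[condition], config.levels),
            evaluate_model("gaussian", config.gaussian[condition], config.levels),
        ]
    )
    if subtract_silence:
        i0 = int(np.argmin(np.abs(config.levels)))
        r = r - r[:, [i0]]
    return r


def _nonzero_grid(config: TwoCellConfig) -> np.ndarray:
    return config.levels[config.levels > 0]


def angle_matrix(config: TwoCellConfig, condition: str) -> np.ndarray:
    """Separation angles (degrees) between silence-referenced population vectors.

    Entry [i, j] is the angle between r(s_i) - r(0) and r(s_j) - r(0) for the
    nonzero grid levels (1..90 dB).  Zero-length vectors give NaN entries,
    which downstream means exclude.
    """
    r = model_responses(config, condition)
    i0 = int(np.argmin(np.abs(config.levels)))
    v = np.delete(r - r[:, [i0]], i0, axis=1)  # 2 x 90
    norms = np.linalg.norm(v, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (v.T @ v) / np.outer(norms, norms)
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    ang[norms == 0, :] = np.nan
    ang[:, norms == 0] = np.nan
    np.fill_diagonal(ang, np.where(norms == 0, np.nan, 0.0))
    return ang


def length_matrix(config: TwoCellConfig, condition: str) -> np.ndarray:
    """Euclidean distances between population responses to level pairs.

    Entry [i, j] is ||r(s_j) - r(s_i)|| over the nonzero grid levels; raw
    responses, not silence-referenced (the 0 dB offset cancels anyway).
    """
    r = model_responses(config, condition)
    i0 = int(np.argmin(np.abs(config.levels)))
    rr = np.delete(r, i0, axis=1)
    diff = rr[:, :, None] - rr[:, None, :]
    return np.linalg.norm(diff, axis=0)


def mean_condition_difference(
    matrix_cond: np.ndarray,
    matrix_none: np.ndarray,
    level_range: tuple[int, int] = (1, 90),
    levels: np.ndarray | None = None,
) -> float:
    """Mean of (condition - none) over unordered level pairs within a range.

    The diagonal is excluded and each unordered pair counts once; NaN entries
    (undefined angles at zero-length vectors) are dropped.
    """
    if matrix_cond.shape != matrix_none.shape:
        raise ValueError("matrices must share a grid")
    if levels is None:
        levels = np.arange(1, matrix_cond.shape[0] + 1)
    lo, hi = level_range
    sel = np.flatnonzero((levels >= lo) & (levels <= hi))
    if sel.size < 2:
        raise ValueError(f"level range {level_range} selects fewer than 2 levels")
    d = (matrix_cond - matrix_none)[np.ix_(sel, sel)]
    iu = np.triu_indices(sel.size, k=1)
    return float(np.nanmean(d[iu]))


def condition_difference_summary(config: TwoCellConfig | None = None) -> dict[str, float]:
    """The eight summary numbers of the model: mean angle and length changes.

    For each activated condition (SST, VIP) and each level range (1-90 and
    30-90 dB), the mean over unordered sound pairs of the change relative to
    no activation, in degrees (angles) and a.u. (vector lengths).
    """
    if config is None:
        config = TwoCellConfig()
    ang = {c: angle_matrix(config, c) for c in CONDITIONS}
    length = {c: length_matrix(config, c) for c in CONDITIONS}
    out: dict[str, float] = {}
    for cond in ("SST", "VIP"):
        for lo, hi in ((1, 90), (30, 90)):
            tag = f"{lo}-{hi}"
            out[f"angle_diff_{cond}_{tag}dB"] = mean_condition_difference(
                ang[cond], ang["none"], (lo, hi)
            )
            out[f"length_diff_{cond}_{tag}dB"] = mean_condition_difference(
                length[cond], length["none"], (lo, hi)
            )
    return out


@dataclass(frozen=True)
class GainCurve:
    """Paired (laser-off, laser-on) responses of one cell with a gain-regime label."""

    levels: np.ndarray
    off: np.ndarray
    on: np.ndarray
    slope: float
    intercept: float
    regime: str


# Regime thresholds: slope within +/-0.05 of 1 counts as unity; |intercept|
# within 0.02 a.u. counts as zero.  Labels combine when both axes deviate.
_SLOPE_TOL = 0.05
_INTERCEPT_TOL = 0.02


def _regime_label(slope: float, intercept: float) -> str:
    parts: list[str] = []
    if slope > 1 + _SLOPE_TOL:
        parts.append("multiplicative")
    elif slope < 1 - _SLOPE_TOL:
        parts.append("divisive")
    if intercept > _INTERCEPT_TOL:
        parts.append("additive")
    elif intercept < -_INTERCEPT_TOL:
        parts.append("subtractive")
    if not parts:
        return "identity"
    return " and ".join(parts)


def gain_curve(
    config: TwoCellConfig,
    cell: str,
    condition: str,
    level_range: tuple[float, float] | None = None,
) -> GainCurve:
    """Laser-on vs laser-off response of one cell, with its gain regime.

    The regime is read off a least-squares line fit of on-responses against
    off-responses over `level_range` (default: the whole grid).  A slope
    below 1 is divisive gain, above 1 multiplicative; a negative intercept is
    subtractive, positive additive; combinations are labelled jointly.
    """
    if cell not in ("monotonic", "nonmonotonic"):
        raise ValueError(f"cell must be 'monotonic' or 'nonmonotonic', got {cell!r}")
    row = 0 if cell == "monotonic" else 1
    levels = config.levels
    off = model_responses(config, "none")[row]
    on = model_responses(config, condition)[row]
    if level_range is not None:
        lo, hi = level_range
        sel = (levels >= lo) & (levels <= hi)
        lv, x, y = levels[sel], off[sel], on[sel]
    else:
        lv, x, y = levels, off, on
    if np.ptp(x) == 0:
        slope, intercept = 1.0, float(np.mean(y - x))
    else:
        slope, intercept = np.polyfit(x, y, 1)
    return GainCurve(
        levels=lv,
        off=x,
        on=y,
        slope=float(slope),
        intercept=float(intercept),
        regime=_regime_label(float(slope), float(intercept)),
    )


def two_cell_response_table(
    config: TwoCellConfig,
    condition: str,
    levels=(0, 30, 50, 60, 70, 80, 90),
    laser: str = "none",
    n_trials: int = 1,
):
    """Noise-free trial table for the two model cells at the experimental levels.

    Returns a tidy DataFrame (neuron_id, level_db, laser, trial, response)
    whose trial responses equal the model curves exactly — the bridge between
    the analytic model and the population-geometry pipeline.
    """
    import pandas as pd

    levels = np.asarray(levels, dtype=float)
    r = np.vstack(
        [
            evaluate_model("sigmoid", config.sigmoid[condition], levels),
            evaluate_model("gaussian", config.gaussian[condition], levels),
        ]
    )
    rows = [
        {
            "neuron_id": nid,
            "level_db": float(lv),
            "laser": laser,
            "trial": t,
            "response": float(r[nid, j]),
        }
        for nid in range(2)
        for j, lv in enumerate(levels)
        for t in range(n_trials)
    ]
    return pd.DataFrame(rows)
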