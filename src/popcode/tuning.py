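"""Response-level curve classification and model fitting.

Each neuron's mean response vs sound level (one curve per laser condition)
is classified by its monotonicity index

    MI = (response at 90 dB - response at 0 dB) / (max - min),

monotonic above 0.7, nonmonotonic below 0.3, ambiguous between.  Monotonic
curves are fit with a 4-parameter sigmoid, nonmonotonic with a 4-parameter
Gaussian, ambiguous curves with both (the better fit wins).  The objective
is 1 minus the McFadden pseudo R-squared, which weights each level's squared
error by the inverse squared s.e.m. and normalizes by the intercept-only
model — so unequal trial-to-trial variability across levels is accounted
for.  Minimization uses Powell's method from 16 random starting points; a
curve counts as characterized only when at least two starts converge.

Two acceptance gates guard the fits: the McFadden R-squared must exceed 0.8,
and the interpolated error — an R-squared comparing the analytic model
against a piecewise-linear interpolant of its own values at the sampled
levels, evaluated on a finer level grid — must be at least 0.25, rejecting
fits that thread the sampled levels but swing wildly between them.
Gaussian fits whose mean falls outside 10-80 dB are recharacterized with
the sigmoid, as a peak beyond the sampled range cannot be distinguished
from a monotonic curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .models import evaluate_model
from .tables import mean_responses

__all__ = [
    "ResponseLevelCurve",
    "FitResult",
    "monotonicity_index",
    "classify",
    "mcfadden_objective",
    "interpolated_error",
    "fit_curve",
    "fit_table",
    "INTERMEDIATE_LEVELS",
]

MI_NONMONOTONIC = 0.3
MI_MONOTONIC = 0.7
R2_THRESHOLD = 0.8
INTERP_THRESHOLD = 0.25
GAUSSIAN_MEAN_RANGE = (10.0, 80.0)
N_STARTS = 16
INTERMEDIATE_LEVELS = (15.0, 40.0, 55.0, 65.0, 75.0, 85.0)


@dataclass(frozen=True)
class ResponseLevelCurve:
    """Mean +/- s.e.m. response at each sound level for one neuron and laser."""

    levels: np.ndarray
    mean: np.ndarray
    sem: np.ndarray

    def __post_init__(self) -> None:
        for name in ("levels", "mean", "sem"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.levels) == len(self.mean) == len(self.sem)):
            raise ValueError("levels, mean and sem lengths differ")
        if np.any(self.sem < 0):
            raise ValueError("sem must be >= 0")


@dataclass(frozen=True)
class FitResult:
    """Outcome of classifying and fitting one response-level curve."""

    mi: float
    curve_class: str  # monotonic | nonmonotonic | ambiguous
    kind: str | None  # sigmoid | gaussian | None when no start converged
    params: tuple[float, float, float, float] | None
    mcfadden_r2: float
    interpolated_error: float
    n_successful_starts: int
    refit_from_gaussian: bool
    accepted: bool


def monotonicity_index(curve: ResponseLevelCurve) -> float:
    """MI of a curve; NaN for a flat curve (max == min).

    The curve is first normalized so that abs(max(response)) <= 1; the index
    itself is invariant under positive affine transforms, so normalization
    does not change it.
    """
    m = curve.mean.copy()
    peak = np.abs(m).max()
    if peak > 1.0:
        m = m / peak
    lo, hi = m.min(), m.max()
    if hi == lo:
        return float("nan")
    i_max = int(np.argmax(curve.levels))
    i_spont = int(np.argmin(curve.levels))
    return float((m[i_max] - m[i_spont]) / (hi - lo))


def classify(mi: float) -> str:
    if np.isnan(mi):
        raise ValueError("MI undefined (flat curve)")
    if mi < MI_NONMONOTONIC:
        return "nonmonotonic"
    if mi > MI_MONOTONIC:
        return "monotonic"
    return "ambiguous"


def _sem_weights(curve: ResponseLevelCurve) -> np.ndarray:
    floor = 1e-6 * max(float(np.abs(curve.mean).max()), 1.0)
    return np.maximum(curve.sem, floor)


def mcfadden_objective(params, kind: str, curve: ResponseLevelCurve) -> float:
    """1 - McFadden pseudo R-squared of a model against a curve.

    Weighted SSE of the model over weighted SSE of the intercept-only model
    (the grand mean of the level means); 0 for a perfect fit, exactly 1 for
    the intercept model.
    """
    sem = _sem_weights(curve)
    y = evaluate_model(kind, params, curve.levels)
    num = float(np.sum((y - curve.mean) ** 2 / sem**2))
    den = float(np.sum((curve.mean.mean() - curve.mean) ** 2 / sem**2))
    if den == 0:
        raise ValueError("degenerate objective: flat curve under the given sem")
    return num / den


def interpolated_error(kind: str, params, levels) -> float:
    """Overfitting diagnostic comparing the model with its own linear interpolant.

    The model is evaluated at the sampled levels and linearly interpolated;
    both the analytic model and the interpolant are then evaluated at the
    sampled plus intermediate levels and compared with an R-squared.  Near 1
    the fitted curve is as smooth as a line between the sampled levels; low
    (or negative) values flag curves that oscillate between them.
    """
    levels = np.asarray(levels, dtype=float)
    dense = np.sort(np.unique(np.concatenate([levels, np.asarray(INTERMEDIATE_LEVELS)])))
    anchors = evaluate_model(kind, params, levels)
    interp = np.interp(dense, levels, anchors)
    model = evaluate_model(kind, params, dense)
    den = float(np.sum((interp - interp.mean()) ** 2))
    if den == 0:
        return float("nan")
    return float(1.0 - np.sum((model - interp) ** 2) / den)


def _start_points(kind: str, curve: ResponseLevelCurve, rng: np.random.Generator, n: int):
    lo, hi = float(curve.mean.min()), float(curve.mean.max())
    span = max(hi - lo, 1e-3)
    starts = np.column_stack(
        [
            rng.uniform(lo - span, hi, n),
            rng.uniform(1e-3, 2 * span, n),
            rng.uniform(0.0, 90.0, n),
            rng.uniform(1.0, 45.0, n),
        ]
    )
    return starts


_WIDTH_PENALTY = 1e9  # objective value returned for non-positive widths


def _fast_objective(kind: str, curve: ResponseLevelCurve):
    """Closure form of the McFadden objective with precomputed weights.

    The model width (dx / sigma) is kept positive with a large penalty, so
    Powell can run unbounded.
    """
    x = curve.levels
    mean = curve.mean
    sem2 = _sem_weights(curve) ** 2
    den = float(np.sum((mean.mean() - mean) ** 2 / sem2))
    if den == 0:
        raise ValueError("degenerate objective: flat curve under the given sem")
    if kind == "sigmoid":

        def obj(p):
            if p[3] <= 0:
                return _WIDTH_PENALTY
            with np.errstate(over="ignore"):
                y = p[0] + p[1] / (1.0 + np.exp((p[2] - x) / p[3]))
            return float(np.sum((y - mean) ** 2 / sem2)) / den

    else:

        def obj(p):
            if p[3] <= 0:
                return _WIDTH_PENALTY
            y = p[0] + p[1] * np.exp(-((x - p[2]) ** 2) / (2.0 * p[3] ** 2))
            return float(np.sum((y - mean) ** 2 / sem2)) / den

    return obj


def _fit_single(
    kind: str, curve: ResponseLevelCurve, rng: np.random.Generator, n_starts: int
) -> tuple[tuple | None, float, int]:
    """Multi-start Powell minimization; returns (params, r2, n_converged)."""
    best, best_obj, n_ok = None, np.inf, 0
    obj = _fast_objective(kind, curve)
    for x0 in _start_points(kind, curve, rng, n_starts):
        res = optimize.minimize(obj, x0, method="Powell")
        if (
            res.success
            and np.all(np.isfinite(res.x))
            and np.isfinite(res.fun)
            and res.fun < _WIDTH_PENALTY
        ):
            n_ok += 1
            if res.fun < best_obj:
                best_obj, best = float(res.fun), tuple(float(v) for v in res.x)
    r2 = 1.0 - best_obj if best is not None else -np.inf
    return best, r2, n_ok


def fit_curve(
    curve: ResponseLevelCurve, seed: int | np.random.Generator = 0, n_starts: int = N_STARTS
) -> FitResult:
    """Classify a curve and fit the model(s) its class prescribes.

    Ambiguous curves are fit with both models and the higher McFadden
    R-squared wins; Gaussian winners with a mean outside 10-80 dB are
    recharacterized with the sigmoid fit.  A curve is accepted when at
    least two starts converged, the McFadden R-squared exceeds 0.8 and the
    interpolated error is at least 0.25.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mi = monotonicity_index(curve)
    if np.isnan(mi):
        return FitResult(mi, "flat", None, None, -np.inf, float("nan"), 0, False, False)
    cls = classify(mi)
    kinds = {"monotonic": ["sigmoid"], "nonmonotonic": ["gaussian"]}.get(cls, ["sigmoid", "gaussian"])
    fits = {k: _fit_single(k, curve, rng, n_starts) for k in kinds}
    # sigmoid fallback must exist whenever a gaussian may be recharacterized
    if "gaussian" in fits and "sigmoid" not in fits:
        fits["sigmoid"] = _fit_single("sigmoid", curve, rng, n_starts)

    candidates = {k: v for k, v in fits.items() if k in kinds and v[0] is not None}
    if not candidates:
        return FitResult(mi, cls, None, None, -np.inf, float("nan"), 0, False, False)
    kind = max(candidates, key=lambda k: candidates[k][1])
    params, r2, n_ok = fits[kind]
    refit = False
    if kind == "gaussian" and not (
        GAUSSIAN_MEAN_RANGE[0] <= params[2] <= GAUSSIAN_MEAN_RANGE[1]
    ):
        refit = True
        kind = "sigmoid"
        params, r2, n_ok = fits["sigmoid"]
        if params is None:
            return FitResult(mi, cls, None, None, -np.inf, float("nan"), 0, True, False)
    ie = interpolated_error(kind, params, curve.levels)
    accepted = bool(n_ok >= 2 and r2 > R2_THRESHOLD and ie >= INTERP_THRESHOLD)
    return FitResult(mi, cls, kind, params, float(r2), float(ie), n_ok, refit, accepted)


def curve_from_table(table: pd.DataFrame, neuron_id, laser: str) -> ResponseLevelCurve:
    """Build one neuron's response-level curve (trial mean and sem) at a laser power."""
    means = mean_responses(table)
    sub = means[(means["neuron_id"] == neuron_id) & (means["laser"] == laser)]
    if sub.empty:
        raise ValueError(f"no rows for neuron {neuron_id!r} at laser {laser!r}")
    sub = sub.sort_values("level_db")
    return ResponseLevelCurve(
        levels=sub["level_db"].to_numpy(),
        mean=sub["mean"].to_numpy(),
        sem=sub["sem"].to_numpy(),
    )


def fit_table(table: pd.DataFrame, seed: int = 0, n_starts: int = N_STARTS) -> pd.DataFrame:
    """Fit every (neuron, laser) curve in a tidy response table.

    Per-curve random starts come from substreams keyed by (seed, neuron,
    laser), so results are reproducible and independent of iteration order.
    """
    means = mean_responses(table)
    lasers = sorted(means["laser"].unique(), key=str)
    rows = []
    for (nid, laser), grp in means.groupby(["neuron_id", "laser"], observed=True):
        grp = grp.sort_values("level_db")
        curve = ResponseLevelCurve(
            grp["level_db"].to_numpy(), grp["mean"].to_numpy(), grp["sem"].to_numpy()
        )
        rng = np.random.default_rng([seed, int(nid), lasers.index(laser)])
        fit = fit_curve(curve, rng, n_starts)
        p = fit.params or (np.nan,) * 4
        rows.append(
            {
                "neuron_id": nid,
                "laser": laser,
                "mi": fit.mi,
                "curve_class": fit.curve_class,
                "kind": fit.kind,
                "y0": p[0],
                "yrange": p[1],
                "xmid": p[2],
                "width": p[3],
                "mcfadden_r2": fit.mcfadden_r2,
                "interpolated_error": fit.interpolated_error,
                "n_successful_starts": fit.n_successful_starts,
                "refit_from_gaussian": fit.refit_from_gaussian,
                "accepted": fit.accepted,
            }
        )
    return pd.DataFrame(rows)
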