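"""Parametric response-level curve models.

Two 4-parameter families describe how a neuron's mean response varies with
sound pressure level (dB SPL): a sigmoid for monotonic cells and a Gaussian
for nonmonotonic (intensity-tuned) cells.  Both are shared by the tuning-fit
machinery, the synthetic-data generator and the analytic two-cell model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SigmoidParams",
    "GaussianParams",
    "sigmoid",
    "gaussian",
    "evaluate_model",
    "MODEL_KINDS",
]

MODEL_KINDS = ("sigmoid", "gaussian")


@dataclass(frozen=True)
class SigmoidParams:
    """Sigmoid response-level curve y = y0 + yrange / (1 + exp((x0 - x)/dx)).

    y0      offset response (dF/F units)
    yrange  amplitude range (dF/F units)
    x0      midpoint (dB SPL)
    dx      width (dB); must be positive
    """

    y0: float
    yrange: float
    x0: float
    dx: float

    def __post_init__(self) -> None:
        if not self.dx > 0:
            raise ValueError(f"sigmoid width dx must be > 0, got {self.dx}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.y0, self.yrange, self.x0, self.dx)


@dataclass(frozen=True)
class GaussianParams:
    """Gaussian response-level curve y = y0 + yrange * exp(-(x - xmean)^2 / (2 sigma^2)).

    y0      offset response (dF/F units)
    yrange  peak amplitude above offset (dF/F units)
    xmean   preferred level (dB SPL); accepted fits require 10 <= xmean <= 80
    sigma   tuning width (dB); must be positive
    """

    y0: float
    yrange: float
    xmean: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"gaussian sigma must be > 0, got {self.sigma}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.y0, self.yrange, self.xmean, self.sigma)


def sigmoid(levels, y0: float, yrange: float, x0: float, dx: float):
    """Evaluate the 4-parameter sigmoid at `levels` (dB SPL)."""
    x = np.asarray(levels, dtype=float)
    with np.errstate(over="ignore"):  # far-below-midpoint levels saturate to y0
        return y0 + yrange / (1.0 + np.exp((x0 - x) / dx))


def gaussian(levels, y0: float, yrange: float, xmean: float, sigma: float):
    """Evaluate the 4-parameter Gaussian at `levels` (dB SPL)."""
    x = np.asarray(levels, dtype=float)
    return y0 + yrange * np.exp(-((x - xmean) ** 2) / (2.0 * sigma**2))


def evaluate_model(kind: str, params, levels):
    """Evaluate a named model at the given sound levels.

    `params` may be a SigmoidParams/GaussianParams or a 4-sequence.
    """
    p = params.as_tuple() if hasattr(params, "as_tuple") else tuple(params)
    if kind == "sigmoid":
        return sigmoid(levels, *p)
    if kind == "gaussian":
        return gaussian(levels, *p)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
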