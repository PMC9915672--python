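"""Lifetime sparseness of single neurons and activity sparseness of populations.

Lifetime sparseness is the normalized Rolls-Tovee measure of how
concentrated a neuron's responses are across the nonzero sound levels: 0
when it responds equally to all levels, 1 when it responds to exactly one.
Responses enter as the mean over each neuron's optimal window minus the
neuron's response to laser-and-silence, rectified at zero; neurons with no
positive response are excluded (the measure is undefined for them).

Activity sparseness is the complementary population measure: the fraction
of neurons NOT driven above threshold by a given sound level, where the
threshold is the standard deviation of the population's mean responses to
silence with no laser.  100% means no neuron is active.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import mean_responses

__all__ = [
    "neuron_sparseness",
    "lifetime_sparseness_table",
    "activity_sparseness",
    "sparseness_cdf",
]


def neuron_sparseness(r, n: int | None = None) -> float:
    """Lifetime sparseness S of one neuron's level-response vector.

    S = (1 - (sum(ri)/n)^2 / (sum(ri^2)/n)) / (1 - 1/n), with negative ri
    rectified to zero first.  Returns NaN when no ri is positive (the
    neuron is excluded from sparseness summaries).
    """
    r = np.maximum(np.asarray(r, dtype=float), 0.0)
    if n is None:
        n = r.size
    if r.size != n:
        raise ValueError(f"expected {n} responses, got {r.size}")
    if n < 2:
        raise ValueError("sparseness needs >= 2 levels")
    if not np.any(r > 0):
        return float("nan")
    num = (r.sum() / n) ** 2
    den = (r**2).sum() / n
    return float((1.0 - num / den) / (1.0 - 1.0 / n))


def lifetime_sparseness_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron, per-laser lifetime sparseness from a tidy response table.

    ri is the neuron's mean response at each nonzero level minus its mean
    response to silence at the same laser power (its response to laser and
    silence alone).  Neurons with no positive ri at a laser get NaN.
    """
    means = mean_responses(table)
    rows = []
    for (nid, laser), grp in means.groupby(["neuron_id", "laser"], observed=True):
        grp = grp.sort_values("level_db")
        silence = grp.loc[grp["level_db"] == 0.0, "mean"]
        if silence.empty:
            raise ValueError("table lacks the 0 dB silence condition")
        r = grp.loc[grp["level_db"] > 0.0, "mean"].to_numpy() - float(silence.iloc[0])
        rows.append({"neuron_id": nid, "laser": laser, "sparseness": neuron_sparseness(r)})
    return pd.DataFrame(rows)


def activity_sparseness(
    table: pd.DataFrame, laser: str, reference: str = "same-laser-0dB"
) -> pd.DataFrame:
    """Fraction of neurons not driven above threshold, per sound level.

    reference="same-laser-0dB" compares each neuron's mean response at a
    level to its own silence response at the same laser power;
    "no-laser-0dB" compares to its silence response with no laser.  The
    threshold is the sd across neurons of the mean response to silence with
    no laser.  With the no-laser reference the (laser=none, 0 dB) point is
    100% by construction and is omitted from the output.
    """
    if reference not in ("same-laser-0dB", "no-laser-0dB"):
        raise ValueError(f"unknown reference {reference!r}")
    means = mean_responses(table)
    if means.empty:
        raise ValueError("empty response table")
    silence_none = means[(means["level_db"] == 0.0) & (means["laser"] == "none")]
    if silence_none.empty:
        raise ValueError("table lacks the (0 dB, no laser) condition")
    threshold = float(silence_none["mean"].std(ddof=1))

    ref_laser = laser if reference == "same-laser-0dB" else "none"
    ref = (
        means[(means["level_db"] == 0.0) & (means["laser"] == ref_laser)]
        .set_index("neuron_id")["mean"]
    )
    rows = []
    sub = means[means["laser"] == laser]
    for level, grp in sub.groupby("level_db"):
        if reference == "no-laser-0dB" and laser == "none" and level == 0.0:
            continue  # 100% by construction
        resp = grp.set_index("neuron_id")["mean"]
        active = resp > (ref.loc[resp.index] + threshold)
        rows.append(
            {
                "level_db": float(level),
                "laser": laser,
                "activity_sparseness": float(1.0 - active.mean()),
            }
        )
    return pd.DataFrame(rows)


def sparseness_cdf(values) -> pd.DataFrame:
    """Empirical CDF of a sparseness sample (NaNs dropped)."""
    v = np.asarray(values, dtype=float)
    v = np.sort(v[~np.isnan(v)])
    if v.size == 0:
        raise ValueError("no defined sparseness values")
    return pd.DataFrame(
        {"sparseness": v, "cdf": np.arange(1, v.size + 1) / v.size}
    )
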