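"""Tidy response-table conventions and I/O.

The central exchange object of the pipeline is a long-format pandas
DataFrame with one row per (neuron, sound level, laser condition, trial) and
a scalar windowed dF/F response — ready for downstream mixed-effects fits
with per-cell grouping without reshaping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RESPONSE_COLUMNS = ["neuron_id", "level_db", "laser", "trial", "response"]

LASERS = ("none", "medium", "high")


def validate_response_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy schema and that the condition grid is complete.

    Every neuron must have the same number of trials at every
    (level, laser) combination, and all responses must be finite.
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    if not np.isfinite(table["response"].to_numpy(dtype=float)).all():
        raise ValueError("response table contains non-finite responses")
    counts = table.groupby(["neuron_id", "level_db", "laser"], observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("incomplete condition grid: unequal trial counts per cell")
    return table


def mean_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron trial means and sems for each (level, laser) condition."""
    g = table.groupby(["neuron_id", "laser", "level_db"], observed=True)["response"]
    out = g.agg(mean="mean", sem="sem", n="size").reset_index()
    out["sem"] = out["sem"].fillna(0.0)  # single-trial conditions
    return out


def response_matrix(
    table: pd.DataFrame, laser: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-by-neuron response matrix for one laser condition.

    Returns (X, y, neuron_ids): X has one row per trial of each sound level,
    y the level label per row. Trials are ordered by (level, trial); neurons
    (columns) by neuron_id.
    """
    sub = table[table["laser"] == laser]
    if sub.empty:
        raise ValueError(f"no trials for laser condition {laser!r}")
    wide = sub.pivot_table(
        index=["level_db", "trial"], columns="neuron_id", values="response"
    )
    if wide.isna().any().any():
        raise ValueError("incomplete trial grid for laser condition")
    X = wide.to_numpy(dtype=float)
    y = wide.index.get_level_values("level_db").to_numpy(dtype=float)
    return X, y, wide.columns.to_numpy()


def write_response_table(table: pd.DataFrame, path) -> None:
    table[RESPONSE_COLUMNS].to_csv(path, index=False)


def read_response_table(path) -> pd.DataFrame:
    return validate_response_table(pd.read_csv(path))
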