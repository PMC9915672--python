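"""Population-vector geometry: separation angles and vector lengths.

The population's mean response to a sound level is a vector with one entry
per neuron (fixed-window responses).  Two complementary geometric readouts
compare levels within a laser condition:

* the *separation angle* between silence-referenced vectors (origin at the
  same-laser 0 dB response) — larger angles mean less overlap between the
  neurons recruited by the two levels (a more localist code);
* the *vector length*, the Euclidean distance between the raw mean vectors
  of the two levels — a magnitude (rate-like) readout of discriminability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import mean_responses

__all__ = [
    "mean_population_vector",
    "separation_angle",
    "vector_length",
    "angle_matrix_from_table",
    "length_matrix_from_table",
    "geometry_summary",
    "pairwise_long_format",
]


def mean_population_vector(
    table: pd.DataFrame, level: float, laser: str, subtract_silence: bool = False
) -> np.ndarray:
    """Per-neuron trial-mean response at one condition, ordered by neuron_id.

    With ``subtract_silence`` the same-laser 0 dB vector is subtracted, so
    the vector at 0 dB itself becomes zero.
    """
    means = mean_responses(table)
    sub = means[(means["laser"] == laser) & (means["level_db"] == level)]
    if sub.empty:
        raise ValueError(f"no trials at ({level} dB, laser={laser!r})")
    v = sub.sort_values("neuron_id")["mean"].to_numpy()
    if subtract_silence:
        v = v - mean_population_vector(table, 0.0, laser, subtract_silence=False)
    return v


def separation_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two population vectors in degrees, in [0, 180].

    NaN when either vector has zero norm (the angle is undefined and such
    pairs are excluded from summaries).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vector dimensions differ")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def vector_length(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two population vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vector dimensions differ")
    return float(np.linalg.norm(b - a))


def _sorted_nonzero_levels(table: pd.DataFrame) -> np.ndarray:
    levels = np.sort(table["level_db"].unique())
    return levels[levels > 0]


def angle_matrix_from_table(table: pd.DataFrame, laser: str) -> tuple[np.ndarray, np.ndarray]:
    """Separation angles between all nonzero-level pairs at one laser power.

    Vectors are silence-referenced.  Returns (levels, matrix) with NaN where
    a vector is zero; diagonal 0.
    """
    levels = _sorted_nonzero_levels(table)
    vecs = [mean_population_vector(table, lv, laser, subtract_silence=True) for lv in levels]
    n = len(levels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = separation_angle(vecs[i], vecs[j])
        if np.linalg.norm(vecs[i]) == 0:
            mat[i, i] = np.nan
    return levels, mat


def length_matrix_from_table(table: pd.DataFrame, laser: str) -> tuple[np.ndarray, np.ndarray]:
    """Vector lengths between all nonzero-level pairs at one laser power (raw vectors)."""
    levels = _sorted_nonzero_levels(table)
    vecs = [mean_population_vector(table, lv, laser) for lv in levels]
    n = len(levels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = vector_length(vecs[i], vecs[j])
    return levels, mat


def pairwise_long_format(
    levels: np.ndarray, mat: np.ndarray, laser: str, value_name: str
) -> pd.DataFrame:
    """Unordered level pairs of a symmetric matrix as a tidy table."""
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                {
                    "laser": laser,
                    "s1": float(levels[i]),
                    "s2": float(levels[j]),
                    "delta_db": float(abs(levels[j] - levels[i])),
                    value_name: float(mat[i, j]),
                }
            )
    return pd.DataFrame(rows)


def geometry_summary(tables: pd.DataFrame | list[pd.DataFrame]) -> dict:
    """Angle/length matrices per laser with condition differences and
    per-|delta level| summaries.

    Accepts one tidy response table (one recording) or a list of them; the
    per-pair mean +/- sem is taken unweighted across recordings.  Difference
    matrices are (laser - none) per recording, then averaged.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not tables:
        raise ValueError("no recordings supplied")
    lasers = sorted(tables[0]["laser"].unique(), key=str)
    per_rec = []
    for table in tables:
        rec = {}
        for laser in lasers:
            levels, ang = angle_matrix_from_table(table, laser)
            _, length = length_matrix_from_table(table, laser)
            rec[laser] = {"levels": levels, "angle": ang, "length": length}
        per_rec.append(rec)
    levels = per_rec[0][lasers[0]]["levels"]

    def _stack(metric, laser):
        return np.stack([r[laser][metric] for r in per_rec])

    out = {"levels": levels, "per_laser": {}, "differences": {}, "pair_summary": []}
    for laser in lasers:
        out["per_laser"][laser] = {
            m: np.nanmean(_stack(m, laser), axis=0) for m in ("angle", "length")
        }
        if laser != "none" and "none" in lasers:
            out["differences"][laser] = {
                m: np.nanmean(_stack(m, laser) - _stack(m, "none"), axis=0)
                for m in ("angle", "length")
            }
    rows = []
    iu = np.triu_indices(len(levels), k=1)
    deltas = np.abs(levels[:, None] - levels[None, :])[iu]
    for laser in lasers:
        for metric in ("angle", "length"):
            vals = np.stack([r[laser][metric][iu] for r in per_rec])  # rec x pair
            for d in np.unique(deltas):
                sel = vals[:, deltas == d]
                rec_means = np.nanmean(sel, axis=1)
                rows.append(
                    {
                        "laser": laser,
                        "metric": metric,
                        "delta_db": float(d),
                        "mean": float(np.nanmean(rec_means)),
                        "sem": float(
                            np.nanstd(rec_means, ddof=1) / np.sqrt(len(rec_means))
                        )
                        if len(rec_means) > 1
                        else 0.0,
                    }
                )
    out["pair_summary"] = pd.DataFrame(rows)
    return out
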