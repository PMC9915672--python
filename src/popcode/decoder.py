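"""One-vs-rest linear SVM decoding of sound pressure level.

For each laser condition the trial-by-neuron response matrix (fixed-window
responses) is projected onto the leading principal components capturing 70%
of the variance.  Each sound level is then decoded against the remaining
six: the 10 trials of the target level are oversampled to 60 with a
Gaussian kernel density estimate so both classes are balanced at 60, and a
linear-kernel SVM is scored with stratified 10-fold cross-validation.
Chance performance for the balanced two-class problem is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .tables import response_matrix

__all__ = ["DecoderConfig", "project_pca", "oversample_kde", "decode_levels"]


@dataclass(frozen=True)
class DecoderConfig:
    variance_capture: float = 0.70
    n_oversample: int = 60
    n_folds: int = 10
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_capture <= 1.0:
            raise ValueError("variance_capture must be in (0, 1]")
        if self.n_oversample < 1 or self.n_folds < 2:
            raise ValueError("invalid oversample/fold counts")


def project_pca(responses: np.ndarray, variance_capture: float = 0.70) -> np.ndarray:
    """Project trials onto the fewest components reaching the variance target."""
    X = np.asarray(responses, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 trials for PCA")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate input: zero variance in every dimension")
    pca = PCA(svd_solver="full")
    Z = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n = int(np.searchsorted(cum, variance_capture - 1e-12) + 1)
    return Z[:, :n]


def oversample_kde(
    class_trials: np.ndarray, target: int = 60, rng: np.random.Generator | int = 0
) -> np.ndarray:
    """Draw `target` synthetic trials from a Gaussian KDE over the class trials.

    Bandwidth follows Scott's rule.  When the trial covariance is singular
    (duplicate-only trials, or more dimensions than trials) the full-
    covariance KDE cannot be formed and sampling falls back to a
    diagonal-bandwidth kernel: resampled trials jittered with independent
    Gaussian noise of Scott-scaled per-dimension bandwidth.
    """
    X = np.atleast_2d(np.asarray(class_trials, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need >= 2 trials to oversample")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    try:
        kde = stats.gaussian_kde(X.T, bw_method="scott")
        return kde.resample(target, seed=rng).T
    except (np.linalg.LinAlgError, ValueError):
        n, d = X.shape
        factor = n ** (-1.0 / (d + 4))  # Scott's factor
        sd = X.std(axis=0, ddof=1) * factor
        sd = np.where(sd > 0, sd, 1e-9 * max(1.0, np.abs(X).max()))
        picks = rng.integers(0, n, target)
        return X[picks] + rng.normal(0.0, 1.0, (target, d)) * sd


def decode_levels(
    table: pd.DataFrame,
    laser: str,
    config: DecoderConfig | None = None,
    shuffle_labels: bool = False,
) -> pd.DataFrame:
    """Per-level one-vs-rest decoding accuracy for one laser condition.

    Returns a DataFrame (level_db, accuracy, n_components); accuracy is the
    mean validation accuracy over the stratified folds.

    ``shuffle_labels`` runs the permutation baseline: the class labels of
    the balanced 120-trial set handed to the SVM are permuted, so the
    features carry no label information and accuracy sits at the 0.5 chance
    level of the balanced design.  (Shuffling upstream of the oversampling
    step would not give chance: the KDE-resampled class is more concentrated
    than the same number of independent trials, and that resampling
    footprint alone is decodable.)
    """
    if config is None:
        config = DecoderConfig()
    X, y, _ = response_matrix(table, laser)
    Z = project_pca(X, config.variance_capture)
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("need at least two sound levels to decode")
    counts = {lv: int((y == lv).sum()) for lv in levels}
    if len(set(counts.values())) != 1:
        raise ValueError(f"unequal trial counts per level: {counts}")
    rng = np.random.default_rng(config.seed)
    rows = []
    for level in levels:
        target = Z[y == level]
        rest = Z[y != level]
        n_min = target.shape[0]
        if n_min < 2:
            raise ValueError(f"missing or single-trial level {level}")
        over = oversample_kde(target, config.n_oversample, rng)
        Xb = np.vstack([over, rest])
        yb = np.concatenate([np.ones(len(over)), np.zeros(len(rest))])
        if shuffle_labels:
            yb = rng.permutation(yb)
        cv = StratifiedKFold(
            n_splits=config.n_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        clf = SVC(kernel="linear", C=config.svm_c)
        acc = cross_val_score(clf, Xb, yb, cv=cv, scoring="accuracy")
        rows.append(
            {
                "level_db": float(level),
                "laser": laser,
                "accuracy": float(acc.mean()),
                "n_components": Z.shape[1],
            }
        )
    return pd.DataFrame(rows)
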