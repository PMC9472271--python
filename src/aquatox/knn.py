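"""k-nearest-neighbor toxicity regressors.

Two similarity spaces are supported, matching standard read-across practice:

* ``mode="descriptor"`` — Manhattan (city-block) distance between z-scaled
  molecular descriptor vectors.  Scaling statistics are fitted on training
  rows only; columns with zero training variance are excluded from the
  distance so heterogeneous panels cannot be dominated by large-magnitude
  descriptors.
* ``mode="fingerprint"`` — Tanimoto similarity between binary fingerprints
  (neighbors ranked by descending similarity).

Predictions are the unweighted mean of the k neighbors' training targets
(distance-weighted mean behind ``weights="distance"``).  Ties in the ranking
always break toward the lower training index, so results are reproducible
across runs and platforms.  The cross-validated neighbor-count search
(:func:`select_k`) scans validation fractions between 5 and 30% with a
seeded splitter; the neighbor counts that emerged from the original
large-scale screen ship as :data:`FINAL_K_DESC` and :data:`FINAL_K_FPN`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.exceptions import NotFittedError
from sklearn.metrics import r2_score
from sklearn.model_selection import ShuffleSplit
from sklearn.pipeline import Pipeline

__all__ = [
    "KnnToxicityRegressor",
    "CvPlan",
    "tanimoto",
    "manhattan",
    "select_k",
    "FINAL_K_DESC",
    "FINAL_K_FPN",
]

#: Final neighbor counts selected by the original cross-validation screens.
FINAL_K_DESC: tuple[int, ...] = (2, 4, 5, 6, 8)
FINAL_K_FPN: tuple[int, ...] = (2, 5, 7, 12, 14)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a&b|/|a|b| between two binary vectors.

    Both inputs must have equal length.  Two all-zero vectors are defined to
    have similarity 1.0 (identical absence of features).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def manhattan(x: np.ndarray, y: np.ndarray) -> float:
    """City-block distance sum |x_i - y_i|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.abs(x - y).sum())


class KnnToxicityRegressor(RegressorMixin, BaseEstimator):
    """kNN regressor over descriptor or fingerprint space.

    Parameters
    ----------
    k : int
        Number of neighbors; must not exceed the training set size.
    mode : {"descriptor", "fingerprint"}
        Similarity space (see module docstring).
    weights : {"uniform", "distance"}
        Neighbor aggregation; "uniform" is the arithmetic mean.

    Attributes
    ----------
    train_X_ : ndarray
        Stored training matrix (z-scaled in descriptor mode).
    train_y_ : ndarray
        Training targets.
    scale_mean_, scale_sd_ : ndarray
        Per-retained-column scaling statistics (descriptor mode).
    retained_columns_ : ndarray
        Indices of columns with positive training variance.
    """

    def __init__(self, k: int = 5, mode: str = "descriptor", weights: str = "uniform"):
        self.k = k
        self.mode = mode
        self.weights = weights

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2D matrix")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if self.mode not in ("descriptor", "fingerprint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.weights not in ("uniform", "distance"):
            raise ValueError(f"unknown weights {self.weights!r}")
        if not (1 <= self.k <= len(X)):
            raise ValueError(f"k={self.k} outside [1, n_train={len(X)}]")
        if self.mode == "descriptor":
            X = X.astype(float)
            sd = X.std(axis=0)
            self.retained_columns_ = np.where(sd > 0)[0]
            if self.retained_columns_.size == 0:
                raise ValueError("all descriptor columns are constant")
            self.scale_mean_ = X[:, self.retained_columns_].mean(axis=0)
            self.scale_sd_ = sd[self.retained_columns_]
            self.train_X_ = (X[:, self.retained_columns_] - self.scale_mean_) / self.scale_sd_
        else:
            X = X.astype(bool)
            self.train_X_ = X
            self._train_pop = X.sum(axis=1)
        self.n_features_in_ = X.shape[1]
        self.train_y_ = y
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "train_y_"):
            raise NotFittedError("model is not fitted; call fit first")

    def _prepare_query(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        if self.mode == "descriptor":
            return (X[:, self.retained_columns_].astype(float) - self.scale_mean_) / self.scale_sd_
        return X.astype(bool)

    # -- neighbor search -----------------------------------------------------

    def _ranking_key(self, Q: np.ndarray) -> np.ndarray:
        """Per-query vector over training rows; smaller ranks earlier."""
        if self.mode == "descriptor":
            # (n_query, n_train) Manhattan distances.
            return np.abs(Q[:, None, :] - self.train_X_[None, :, :]).sum(axis=2)
        inter = (Q.astype(np.int64) @ self.train_X_.T.astype(np.int64)).astype(float)
        union = Q.sum(axis=1)[:, None] + self._train_pop[None, :] - inter
        with np.errstate(invalid="ignore"):
            sim = np.where(union == 0, 1.0, inter / np.where(union == 0, 1, union))
        return -sim  # descending similarity == ascending key

    def kneighbors(
        self, X, k: int | None = None, exclude: Sequence[int] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (indices, keys) of the k best training rows per query.

        ``keys`` are Manhattan distances (descriptor mode) or negated
        Tanimoto similarities (fingerprint mode).  Ties break toward the
        lower training index.  ``exclude`` lists one training index per
        query to skip — the leave-one-out flag for self-matching.
        """
        self._check_fitted()
        k = self.k if k is None else k
        Q = self._prepare_query(X)
        key = self._ranking_key(Q)
        if exclude is not None:
            key = key.copy()
            for row, idx in enumerate(exclude):
                if idx is not None:
                    key[row, idx] = np.inf
        n_eff = key.shape[1] - (0 if exclude is None else 1)
        if k > n_eff:
            raise ValueError(f"k={k} exceeds available training molecules ({n_eff})")
        order = np.argsort(key, axis=1, kind="stable")[:, :k]
        return order, np.take_along_axis(key, order, axis=1)

    def predict(self, X, exclude: Sequence[int] | None = None) -> np.ndarray:
        self._check_fitted()
        idx, keys = self.kneighbors(X, exclude=exclude)
        targets = self.train_y_[idx]
        if self.weights == "uniform":
            return targets.mean(axis=1)
        if self.mode == "fingerprint":
            w = -keys  # similarities
        else:
            with np.errstate(divide="ignore"):
                w = 1.0 / keys
        # Exact matches get full weight.
        w = np.where(np.isinf(w), 1e12, w)
        w = np.where(w <= 0, 1e-12, w)
        return (targets * w).sum(axis=1) / w.sum(axis=1)


# --- cross-validated k selection -------------------------------------------

def _spearman_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    rho = stats.spearmanr(y_true, y_pred).statistic
    return float(rho) if np.isfinite(rho) else 0.0


_SCORERS = {"r2": r2_score, "spearman": _spearman_score}


@dataclass
class CvPlan:
    """Grid for the neighbor-count search.

    ``validation_ratios`` must lie within [0.05, 0.30], the band scanned by
    the original screen; ``score`` selects the model-selection metric.
    """

    candidate_ks: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14)
    validation_ratios: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30)
    repeats: int = 10
    seed: int = 0
    score: str = "r2"

    def __post_init__(self) -> None:
        self.candidate_ks = tuple(sorted(int(k) for k in self.candidate_ks))
        if not self.candidate_ks or self.candidate_ks[0] < 1:
            raise ValueError("candidate_ks must be positive integers")
        self.validation_ratios = tuple(float(r) for r in self.validation_ratios)
        if not all(0.05 <= r <= 0.30 for r in self.validation_ratios):
            raise ValueError("validation ratios must lie in [0.05, 0.30]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.score not in _SCORERS:
            raise ValueError(f"score must be one of {sorted(_SCORERS)}")


def _k_param_name(model) -> str:
    if isinstance(model, Pipeline):
        return f"{model.steps[-1][0]}__k"
    return "k"


def select_k(
    model,
    X,
    y,
    plan: CvPlan | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick the neighbor count maximising mean validation score.

    For every (ratio, repeat, k) cell a fresh seeded shuffle split is made,
    the model refitted on the training part and scored on the validation
    part.  The full score table is returned for audit; ``best_k`` maximises
    the mean score over all cells (ties toward the smaller k).  The search
    is deterministic given ``plan.seed``.
    """
    plan = plan or CvPlan()
    y = np.asarray(y, dtype=float)
    X_arr = np.asarray(X, dtype=object) if isinstance(X, (list, tuple)) else np.asarray(X)
    scorer = _SCORERS[plan.score]
    param = _k_param_name(model)
    max_ratio = max(plan.validation_ratios)
    if len(y) - int(np.ceil(len(y) * max_ratio)) < max(plan.candidate_ks):
        raise ValueError(
            f"max candidate k={max(plan.candidate_ks)} infeasible for "
            f"n={len(y)} at validation ratio {max_ratio}"
        )
    rows = []
    for ri, ratio in enumerate(plan.validation_ratios):
        for rep in range(plan.repeats):
            split_seed = (plan.seed * 1_000_003 + ri * 1009 + rep) % (2**31)
            splitter = ShuffleSplit(n_splits=1, test_size=ratio, random_state=split_seed)
            (train_idx, val_idx), = splitter.split(np.arange(len(y)))
            X_tr = X_arr[train_idx]
            X_va = X_arr[val_idx]
            if X_arr.dtype == object:
                X_tr, X_va = list(X_tr), list(X_va)
            for k in plan.candidate_ks:
                est = clone(model).set_params(**{param: k})
                est.fit(X_tr, y[train_idx])
                score = scorer(y[val_idx], est.predict(X_va))
                rows.append({"ratio": ratio, "repeat": rep, "k": k, "score": score})
    table = pd.DataFrame(rows)
    means = table.groupby("k")["score"].mean()
    best_k = int(means.index[np.argmax(means.to_numpy())])
    return best_k, table
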