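"""Prior-knowledge hybridization schemes around the kNN predictors.

Four composable ways of injecting domain knowledge before, during and
around a kNN model, plus the plain pipelines they wrap:

* **H0** — training-set outlier removal on a single descriptor, molecular
  weight: molecules with MW strictly above a threshold (default 300 g/mol,
  where the MW-toxicity correlation is known to break down) are dropped
  before fitting the descriptor kNN.
* **H1** — descriptor selection: the kNN runs in the reduced space of the
  six literature-flagged descriptors (logP, AATSC0p, TPSA, ETA_dEpsilon_A,
  SHBd, Mi) instead of the full panel.
* **H2** — model routing on logP: queries with logP inside [1.5, 4.0]
  (closed interval) go to the fingerprint kNN, everything else to the
  prior-knowledge model.  The router adds no arithmetic of its own — each
  prediction is exactly the routed pure model's output.
* **H3** — PKM-guided neighbor selection: neighbors are the k training
  molecules whose PKM predictions are closest to the query's PKM
  prediction; the returned value is the mean of those neighbors' observed
  toxicities.

All estimators take sequences of SMILES strings as X and toxicity values
(-ln LC50 mg/L) as y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.exceptions import NotFittedError
from sklearn.pipeline import Pipeline

from .chemdata import DescriptorCalculator, FingerprintGenerator, FeatureSet, MoleculeRecord
from .descriptors import compute_descriptor
from .exceptions import FeatureError
from .knn import KnnToxicityRegressor
from .pkm import PriorKnowledgeModel, default_pkm

__all__ = [
    "HybridConfig",
    "DEFAULT_PK_DESCRIPTORS",
    "make_descriptor_knn",
    "make_fingerprint_knn",
    "h0_filter",
    "h1_select",
    "h2_predict",
    "h3_predict",
    "MwOutlierFilteredRegressor",
    "PkDescriptorKnnRegressor",
    "LogPRoutedRegressor",
    "PkmGuidedKnnRegressor",
    "make_hybrid",
]

#: Literature-flagged descriptors for the H1 reduced space.
DEFAULT_PK_DESCRIPTORS: tuple[str, ...] = (
    "LogP", "AATSC0p", "TPSA", "ETA_dEpsilon_A", "SHBd", "Mi"
)


@dataclass
class HybridConfig:
    """Shared configuration for the hybridization schemes."""

    scheme: str = "H0"
    mw_threshold: float = 300.0
    pk_descriptors: tuple[str, ...] = DEFAULT_PK_DESCRIPTORS
    logp_low: float = 1.5
    logp_high: float = 4.0
    k: int = 5

    def __post_init__(self) -> None:
        if self.scheme not in ("H0", "H1", "H2", "H3"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.mw_threshold <= 0:
            raise ValueError("mw_threshold must be positive")
        if not self.pk_descriptors:
            raise ValueError("pk_descriptors must be non-empty")
        if not self.logp_low < self.logp_high:
            raise ValueError("require logp_low < logp_high")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def make_descriptor_knn(k: int = 5, names: Sequence[str] | None = None) -> Pipeline:
    """SMILES -> descriptor matrix -> Manhattan kNN pipeline."""
    return Pipeline([
        ("features", DescriptorCalculator(names=names)),
        ("knn", KnnToxicityRegressor(k=k, mode="descriptor")),
    ])


def make_fingerprint_knn(k: int = 7, radius: int = 2, n_bits: int = 2048) -> Pipeline:
    """SMILES -> circular fingerprint -> Tanimoto kNN pipeline."""
    return Pipeline([
        ("features", FingerprintGenerator(radius=radius, n_bits=n_bits)),
        ("knn", KnnToxicityRegressor(k=k, mode="fingerprint")),
    ])


def _molecular_weights(smiles: Sequence[str | MoleculeRecord]) -> np.ndarray:
    out = np.empty(len(smiles))
    for i, s in enumerate(smiles):
        out[i] = compute_descriptor(s if isinstance(s, str) else s.smiles, "MW")
    return out


# --- H0 ---------------------------------------------------------------------

def h0_filter(
    records: Sequence[MoleculeRecord | str],
    mw_threshold: float = 300.0,
    mw: Sequence[float] | None = None,
) -> tuple[list, list]:
    """Partition molecules into (kept, outliers) by MW > threshold (strict).

    ``mw`` may pass precomputed molecular weights aligned with ``records``;
    otherwise they are computed from the structures.
    """
    weights = np.asarray(mw, dtype=float) if mw is not None else None
    if weights is None:
        try:
            weights = _molecular_weights(records)
        except ValueError as exc:
            raise FeatureError(f"cannot compute MW: {exc}") from exc
    if len(weights) != len(records):
        raise FeatureError("MW vector length does not match records")
    kept, outliers = [], []
    for rec, w in zip(records, weights):
        (outliers if w > mw_threshold else kept).append(rec)
    return kept, outliers


class MwOutlierFilteredRegressor(RegressorMixin, BaseEstimator):
    """H0: drop high-MW training outliers, then fit the base regressor.

    Attributes
    ----------
    n_outliers_ : int
        Training molecules removed by the MW rule.
    """

    def __init__(self, base_estimator=None, mw_threshold: float = 300.0):
        self.base_estimator = base_estimator
        self.mw_threshold = mw_threshold

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        mw = _molecular_weights(list(X))
        keep = mw <= self.mw_threshold
        self.n_outliers_ = int((~keep).sum())
        if not keep.any():
            raise ValueError("MW filter removed every training molecule")
        base = self.base_estimator if self.base_estimator is not None else make_descriptor_knn(k=3)
        self.estimator_ = clone(base).fit([x for x, m in zip(X, keep) if m], y[keep])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "estimator_"):
            raise NotFittedError("fit before predict")
        return self.estimator_.predict(list(X))


# --- H1 ---------------------------------------------------------------------

def h1_select(features: FeatureSet, pk_descriptors: Sequence[str] = DEFAULT_PK_DESCRIPTORS) -> FeatureSet:
    """Restrict a descriptor FeatureSet to the prior-knowledge panel."""
    return features.subset(list(pk_descriptors))


class PkDescriptorKnnRegressor(RegressorMixin, BaseEstimator):
    """H1: descriptor kNN in the reduced prior-knowledge descriptor space."""

    def __init__(self, pk_descriptors: Sequence[str] = DEFAULT_PK_DESCRIPTORS, k: int = 2):
        self.pk_descriptors = pk_descriptors
        self.k = k

    def fit(self, X, y):
        self.pipeline_ = make_descriptor_knn(k=self.k, names=list(self.pk_descriptors))
        self.pipeline_.fit(list(X), np.asarray(y, dtype=float))
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "pipeline_"):
            raise NotFittedError("fit before predict")
        return self.pipeline_.predict(list(X))


# --- H2 ---------------------------------------------------------------------

class LogPRoutedRegressor(RegressorMixin, BaseEstimator):
    """H2: route each query to the fingerprint kNN or the PKM by logP.

    Queries with logP in the closed band [logp_low, logp_high] use the kNN;
    the rest use the prior-knowledge model.  Routing is pure dispatch — the
    returned value is bitwise identical to the routed model's own output.
    """

    def __init__(
        self,
        knn_estimator=None,
        pk_model: PriorKnowledgeModel | None = None,
        logp_low: float = 1.5,
        logp_high: float = 4.0,
        logp_descriptor: str = "MolLogP",
    ):
        self.knn_estimator = knn_estimator
        self.pk_model = pk_model
        self.logp_low = logp_low
        self.logp_high = logp_high
        self.logp_descriptor = logp_descriptor

    def fit(self, X, y):
        if not self.logp_low < self.logp_high:
            raise ValueError("require logp_low < logp_high")
        base = self.knn_estimator if self.knn_estimator is not None else make_fingerprint_knn(k=7)
        self.knn_ = clone(base).fit(list(X), np.asarray(y, dtype=float))
        pk = self.pk_model if self.pk_model is not None else default_pkm()
        self.pk_ = pk.fit() if hasattr(pk, "fit") else pk
        return self

    def _routes(self, X) -> np.ndarray:
        try:
            logp = np.array([
                compute_descriptor(x if isinstance(x, str) else x.smiles, self.logp_descriptor)
                for x in X
            ])
        except ValueError as exc:
            raise FeatureError(f"cannot compute logP: {exc}") from exc
        in_band = (logp >= self.logp_low) & (logp <= self.logp_high)
        return np.where(in_band, "knn", "pkm")

    def predict_with_route(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return (predictions, route tags); tags are "knn" or "pkm"."""
        if not hasattr(self, "knn_"):
            raise NotFittedError("fit before predict")
        X = list(X)
        routes = self._routes(X)
        yhat = np.empty(len(X))
        knn_mask = routes == "knn"
        if knn_mask.any():
            yhat[knn_mask] = self.knn_.predict([x for x, m in zip(X, knn_mask) if m])
        if (~knn_mask).any():
            yhat[~knn_mask] = self.pk_.predict([x for x, m in zip(X, knn_mask) if not m])
        return yhat, routes

    def predict(self, X) -> np.ndarray:
        return self.predict_with_route(X)[0]


def h2_predict(
    query: str | MoleculeRecord,
    knn_model,
    pk_model: PriorKnowledgeModel,
    cfg: HybridConfig | None = None,
) -> tuple[float, str]:
    """Route a single query; returns (toxicity estimate, route tag)."""
    cfg = cfg or HybridConfig(scheme="H2")
    smiles = query if isinstance(query, str) else query.smiles
    logp = compute_descriptor(smiles, "MolLogP")
    if cfg.logp_low <= logp <= cfg.logp_high:
        return float(np.asarray(knn_model.predict([smiles]))[0]), "knn"
    return float(np.asarray(pk_model.predict([smiles]))[0]), "pkm"


# --- H3 ---------------------------------------------------------------------

class PkmGuidedKnnRegressor(RegressorMixin, BaseEstimator):
    """H3: neighbors are training molecules with the closest PKM estimate.

    For a query q the k training molecules minimising
    ``|pkm(train_i) - pkm(q)|`` (ties toward the lower index) are averaged
    over their *observed* toxicities.
    """

    def __init__(self, pk_model=None, k: int = 12):
        self.pk_model = pk_model
        self.k = k

    def fit(self, X, y):
        X = list(X)
        y = np.asarray(y, dtype=float)
        if not (1 <= self.k <= len(X)):
            raise ValueError(f"k={self.k} outside [1, n_train={len(X)}]")
        pk = self.pk_model if self.pk_model is not None else default_pkm()
        self.pk_ = pk.fit() if hasattr(pk, "fit") else pk
        self.train_y_ = y
        self.train_pkm_ = np.asarray(self.pk_.predict(X), dtype=float)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "train_pkm_"):
            raise NotFittedError("fit before predict")
        query_pkm = np.asarray(self.pk_.predict(list(X)), dtype=float)
        diffs = np.abs(self.train_pkm_[None, :] - query_pkm[:, None])
        order = np.argsort(diffs, axis=1, kind="stable")[:, : self.k]
        return self.train_y_[order].mean(axis=1)


def h3_predict(
    query: str | MoleculeRecord,
    train_records: Sequence[str | MoleculeRecord],
    train_tox: Sequence[float],
    pk_model: PriorKnowledgeModel,
    k: int,
) -> float:
    """Single-query H3 prediction (functional form of the estimator)."""
    est = PkmGuidedKnnRegressor(pk_model=pk_model, k=k).fit(list(train_records), train_tox)
    smiles = query if isinstance(query, str) else query.smiles
    return float(est.predict([smiles])[0])


def make_hybrid(cfg: HybridConfig, pk_model: PriorKnowledgeModel | None = None):
    """Instantiate the estimator for a scheme from a HybridConfig."""
    if cfg.scheme == "H0":
        return MwOutlierFilteredRegressor(
            base_estimator=make_descriptor_knn(k=cfg.k), mw_threshold=cfg.mw_threshold
        )
    if cfg.scheme == "H1":
        return PkDescriptorKnnRegressor(pk_descriptors=cfg.pk_descriptors, k=cfg.k)
    if cfg.scheme == "H2":
        return LogPRoutedRegressor(
            knn_estimator=make_fingerprint_knn(k=cfg.k),
            pk_model=pk_model,
            logp_low=cfg.logp_low,
            logp_high=cfg.logp_high,
        )
    return PkmGuidedKnnRegressor(pk_model=pk_model, k=cfg.k)
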