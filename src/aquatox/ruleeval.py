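"""Rule-based post-assessment of toxicity models (compliance audit).

Beyond accuracy, a screening model can be judged by whether its predictions
reproduce the monotone structure-toxicity trends reported across the
literature: toxicity rising with hydrophobicity, polarizability and size,
falling with polar surface area, hydrogen-bond-donor character, ionization
potential, branching and N-methylation.  This module encodes those trends
as signed :class:`Rule` objects, measures each model's per-rule Spearman
correlation between the rule feature and the model's predictions
(:func:`compliance_matrix`), and condenses the matrix into a single
*rule affinity* per model: per rule, sign-adjusted correlations are min-max
normalised across models (degenerate ranges map to 0.5) and the normalised
values are summed over rules.  Affinity therefore lives in
[0, n_scored_rules] and is invariant to model or rule relabeling.

Scoped rules (chain-length trends in amines and ethers, the N-CH3 count)
correlate only over the molecules satisfying their scope predicate.  The
observed-data column participates in the matrix as a reference but is
excluded from affinity scoring by default.

Standard regression (R², Spearman) and imbalance-aware classification
metrics (macro-recall balanced accuracy, support-weighted precision and
recall over the T/PT/NT labels) round out the assessment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import balanced_accuracy_score, precision_score, r2_score, recall_score

from .chemdata import MoleculeRecord, compute_descriptors, count_rule_fragments
from .descriptors import RULE_DESCRIPTORS
from .exceptions import UndefinedCorrelationError

logger = logging.getLogger(__name__)

__all__ = [
    "Rule",
    "ComplianceMatrix",
    "MetricsReport",
    "default_rules",
    "spearman_rho",
    "rule_feature_table",
    "compliance_matrix",
    "rule_affinity",
    "regression_metrics",
    "classification_metrics",
    "evaluate_predictions",
    "plot_affinity",
]

HAZARD_ORDER = ("T", "PT", "NT")


@dataclass(frozen=True)
class Rule:
    """One literature trend: a feature, its expected sign, optional scope."""

    rule_id: str
    feature: str
    expected_sign: int
    scope: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.expected_sign not in (1, -1):
            raise ValueError("expected_sign must be +1 or -1")


def default_rules() -> list[Rule]:
    """The 16 encoded toxicity trends used for the compliance audit."""
    return [
        Rule("MolLogP", "MolLogP", +1, note="toxicity increases with hydrophobicity"),
        Rule("MR", "MR", +1, note="toxicity increases with molar refractivity (polarizability)"),
        Rule("GATS1p", "GATS1p", -1, note="toxicity decreases with Geary polarizability autocorrelation"),
        Rule("AATSC0p", "AATSC0p", +1, note="toxicity increases with centered polarizability autocorrelation"),
        Rule("TPSA", "TPSA", -1, note="toxicity decreases with polar surface area"),
        Rule("SHBd", "SHBd", -1, note="toxic compounds have lower H-bond-donor E-state sum"),
        Rule("maxHBint2", "maxHBint2", -1, note="toxic compounds have lower H-bond interaction strength"),
        Rule("ETA_dEpsilon_A", "ETA_dEpsilon_A", -1, note="toxicity decreases with electronegative-atom measure"),
        Rule("Mi", "Mi", -1, note="toxicity decreases with mean ionization potential"),
        Rule("GATS1i", "GATS1i", -1, note="higher ionization autocorrelation, lower reactivity/toxicity"),
        Rule("MW", "MW", +1, note="toxicity increases with molecular weight"),
        Rule("ETA_Alpha", "ETA_Alpha", +1, note="toxicity increases with molecular bulk"),
        Rule("ETA_EtaP_B", "ETA_EtaP_B", -1, note="toxicity decreases with branching"),
        Rule("nC_amine", "nC", +1, scope="contains_N",
             note="amine toxicity increases with chain length"),
        Rule("nC_methoxy", "nC", +1, scope="has_methoxy",
             note="ether/ethoxylate toxicity increases with chain length"),
        Rule("n_NCH3", "n_NCH3", -1, scope="contains_N",
             note="N-methylation reduces amine toxicity"),
    ]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (ties averaged).

    Raises :class:`UndefinedCorrelationError` for n < 3 or a constant
    argument, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class ComplianceMatrix:
    """Per-rule, per-model Spearman coefficients and their sample sizes.

    Undefined cells (scope subset < 3 molecules, or constant input) are
    NaN, not zero.
    """

    rules: list[Rule]
    rho: pd.DataFrame
    n_used: pd.DataFrame

    @property
    def models(self) -> list[str]:
        return list(self.rho.columns)


def rule_feature_table(
    records: Sequence[MoleculeRecord | str],
    rules: Sequence[Rule] | None = None,
) -> pd.DataFrame:
    """Feature + scope-predicate columns needed to evaluate the rules."""
    rules = list(rules) if rules is not None else default_rules()
    desc_names = sorted({r.feature for r in rules if r.feature in RULE_DESCRIPTORS})
    fs = compute_descriptors(records, desc_names)
    table = fs.frame().reset_index(drop=True)
    frag_rows = [count_rule_fragments(r) for r in records]
    for key in ("nC", "n_NCH3", "has_amine", "has_methoxy", "contains_N"):
        table[key] = [row[key] for row in frag_rows]
    return table


def compliance_matrix(
    predictions_by_model: Mapping[str, Sequence[float]],
    features: pd.DataFrame,
    rules: Sequence[Rule] | None = None,
) -> ComplianceMatrix:
    """Spearman correlation of every rule feature with every model's output.

    ``features`` must carry one column per rule feature plus boolean/0-1
    columns named after the scope predicates.  All models must be predicted
    on the same molecule set (equal-length vectors aligned with the feature
    rows).
    """
    rules = list(rules) if rules is not None else default_rules()
    n = len(features)
    for name, pred in predictions_by_model.items():
        if len(pred) != n:
            raise ValueError(f"predictions for {name!r} have length {len(pred)}, expected {n}")
    model_names = list(predictions_by_model)
    rho = pd.DataFrame(index=[r.rule_id for r in rules], columns=model_names, dtype=float)
    n_used = pd.DataFrame(0, index=rho.index, columns=model_names, dtype=int)
    for rule in rules:
        if rule.feature not in features.columns:
            raise ValueError(f"rule feature {rule.feature!r} missing from feature table")
        if rule.scope is None:
            mask = np.ones(n, dtype=bool)
        else:
            if rule.scope not in features.columns:
                raise ValueError(f"scope column {rule.scope!r} missing from feature table")
            mask = features[rule.scope].to_numpy().astype(bool)
        x = features[rule.feature].to_numpy(dtype=float)[mask]
        for name in model_names:
            y = np.asarray(predictions_by_model[name], dtype=float)[mask]
            n_used.loc[rule.rule_id, name] = int(mask.sum())
            try:
                rho.loc[rule.rule_id, name] = spearman_rho(x, y)
            except UndefinedCorrelationError:
                rho.loc[rule.rule_id, name] = np.nan
    return ComplianceMatrix(rules=rules, rho=rho, n_used=n_used)


def rule_affinity(
    cm: ComplianceMatrix,
    exclude: Sequence[str] = ("Data",),
) -> pd.Series:
    """Sum of per-rule min-max-normalised, sign-adjusted correlations.

    Per rule r and model m, ``s = expected_sign_r * rho[r, m]`` measures
    directional compliance; within each rule, s is min-max normalised
    across the scored models (0.5 when all models agree exactly).  The
    affinity of a model is the sum of its normalised values over all rules
    with fully defined cells; rules with undefined cells are dropped and
    logged.  Reference columns in ``exclude`` (the observed data) are not
    scored.  At least two scored models are required.
    """
    models = [m for m in cm.models if m not in exclude]
    if len(models) < 2:
        raise ValueError("rule affinity requires at least two scored models")
    affinity = pd.Series(0.0, index=models)
    n_scored = 0
    for rule in cm.rules:
        row = cm.rho.loc[rule.rule_id, models].to_numpy(dtype=float)
        if np.isnan(row).any():
            logger.info("dropping rule %s from affinity: undefined cells", rule.rule_id)
            continue
        s = rule.expected_sign * row
        lo, hi = s.min(), s.max()
        u = np.full_like(s, 0.5) if hi == lo else (s - lo) / (hi - lo)
        affinity += pd.Series(u, index=models)
        n_scored += 1
    affinity.attrs["n_scored_rules"] = n_scored
    return affinity


# --- metrics ----------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Regression + classification summary for one model."""

    r2: float
    spearman: float
    balanced_accuracy: float
    precision: float
    recall: float
    label_counts: dict = field(default_factory=dict)


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> tuple[float, float]:
    """(R², Spearman) of predictions against observations."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need >= 2 observations")
    if np.ptp(y_true) == 0:
        raise UndefinedCorrelationError("R^2 undefined for constant y_true")
    r2 = r2_score(y_true, y_pred)
    rho = stats.spearmanr(y_true, y_pred).statistic
    return float(r2), float(rho) if np.isfinite(rho) else 0.0


def classification_metrics(
    labels_true: Sequence[str], labels_pred: Sequence[str]
) -> tuple[float, float, float]:
    """(balanced accuracy, precision, recall) over the T/PT/NT labels.

    Balanced accuracy is the unweighted mean of per-class recalls over the
    classes present in ``labels_true``; precision and recall are
    support-weighted averages, so the label imbalance of screening data is
    accounted for.
    """
    labels_true = list(labels_true)
    labels_pred = list(labels_pred)
    if not labels_true:
        raise ValueError("empty input")
    if len(labels_true) != len(labels_pred):
        raise ValueError("length mismatch")
    bal = balanced_accuracy_score(labels_true, labels_pred)
    prec = precision_score(labels_true, labels_pred, average="weighted", zero_division=0)
    rec = recall_score(labels_true, labels_pred, average="weighted", zero_division=0)
    return float(bal), float(prec), float(rec)


def evaluate_predictions(
    y_true_tox: Sequence[float],
    y_pred_tox: Sequence[float],
    thresholds=None,
) -> MetricsReport:
    """Full report: regression on tox, classification on derived labels."""
    from .chemdata import ThresholdConfig, classify_hazard

    cfg = thresholds or ThresholdConfig()
    r2, rho = regression_metrics(y_true_tox, y_pred_tox)
    lab_true = [classify_hazard(float(np.exp(-t)), cfg) for t in np.asarray(y_true_tox, float)]
    lab_pred = [classify_hazard(float(np.exp(-t)), cfg) for t in np.asarray(y_pred_tox, float)]
    bal, prec, rec = classification_metrics(lab_true, lab_pred)
    counts = {lab: lab_true.count(lab) for lab in HAZARD_ORDER}
    return MetricsReport(r2=r2, spearman=rho, balanced_accuracy=bal,
                         precision=prec, recall=rec, label_counts=counts)


def plot_affinity(
    affinity: pd.Series,
    spearman_by_model: Mapping[str, float],
    accuracy_by_model: Mapping[str, float],
):
    """Scatter rule affinity against Spearman and balanced accuracy."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    for ax, values, label in (
        (axes[0], spearman_by_model, "Spearman vs data"),
        (axes[1], accuracy_by_model, "balanced accuracy"),
    ):
        for model in affinity.index:
            ax.scatter(affinity[model], values[model])
            ax.annotate(model, (affinity[model], values[model]), fontsize=8,
                        xytext=(3, 3), textcoords="offset points")
        ax.set_xlabel("rule affinity")
        ax.set_ylabel(label)
    fig.tight_layout()
    return fig
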