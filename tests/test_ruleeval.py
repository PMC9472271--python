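"""Rule set, compliance matrix, rule affinity and performance metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aquatox.exceptions import UndefinedCorrelationError
from aquatox.ruleeval import (
    ComplianceMatrix,
    Rule,
    classification_metrics,
    compliance_matrix,
    default_rules,
    regression_metrics,
    rule_affinity,
    rule_feature_table,
    spearman_rho,
)


def rank_pearson_oracle(x, y):
    """Independent Spearman: Pearson correlation of average ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestDefaultRules:
    def test_sixteen_rules_with_expected_signs(self):
        rules = default_rules()
        assert len(rules) == 16
        signs = {r.rule_id: r.expected_sign for r in rules}
        assert signs["TPSA"] == -1
        assert signs["MW"] == +1
        assert signs["MolLogP"] == +1
        assert signs["n_NCH3"] == -1
        assert sum(1 for r in rules if r.expected_sign == 1) == 7

    def test_scoped_rules(self):
        scopes = {r.rule_id: r.scope for r in default_rules()}
        assert scopes["nC_amine"] == "contains_N"
        assert scopes["nC_methoxy"] == "has_methoxy"
        assert scopes["n_NCH3"] == "contains_N"
        assert scopes["MolLogP"] is None

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            Rule("x", "MW", 0)


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            ([1, 2, 3], [3, 1, 2], -0.5),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_too_short_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 2], [2, 1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=20, unique=True))
    def test_matches_rank_pearson_oracle_and_monotone_invariance(self, x):
        rng = np.random.default_rng(abs(hash(tuple(x))) % 2**31)
        y = rng.permutation(len(x)).astype(float)
        assert spearman_rho(x, y) == pytest.approx(rank_pearson_oracle(x, y), abs=1e-9)
        # invariance under strictly monotone transforms of either side
        x3 = np.asarray(x, dtype=float) ** 3
        assert spearman_rho(x3, y) == pytest.approx(spearman_rho(x, y), abs=1e-12)
        assert spearman_rho(x, np.exp(y / 10)) == pytest.approx(
            spearman_rho(x, y), abs=1e-12
        )


class TestComplianceMatrix:
    def test_model_equal_to_data_gives_identical_columns(self, small_records):
        table = rule_feature_table(small_records)
        tox = np.array([r.tox for r in small_records])
        cm = compliance_matrix({"Data": tox, "copy": tox.copy()}, table)
        pd.testing.assert_series_equal(
            cm.rho["Data"], cm.rho["copy"], check_names=False
        )

    def test_prediction_equal_to_feature_gives_rho_one(self, small_records):
        table = rule_feature_table(small_records)
        pred = table["MW"].to_numpy(dtype=float)
        cm = compliance_matrix({"m": pred}, table)
        assert cm.rho.loc["MW", "m"] == pytest.approx(1.0)

    def test_cells_match_hand_oracle(self, dataset):
        records = dataset.records[:20]
        table = rule_feature_table(records)
        preds = {"truth": dataset.truth[:20], "Data": dataset.tox[:20]}
        cm = compliance_matrix(preds, table)
        for rule in cm.rules:
            mask = (np.ones(20, dtype=bool) if rule.scope is None
                    else table[rule.scope].to_numpy().astype(bool))
            x = table[rule.feature].to_numpy(dtype=float)[mask]
            for model, vec in preds.items():
                cell = cm.rho.loc[rule.rule_id, model]
                y = np.asarray(vec)[mask]
                if mask.sum() < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                    assert np.isnan(cell)
                else:
                    assert cell == pytest.approx(rank_pearson_oracle(x, y), abs=1e-9)

    def test_small_scope_is_nan_not_zero(self):
        table = pd.DataFrame({
            "MW": [1.0, 2.0, 3.0, 4.0],
            "scopecol": [1, 1, 0, 0],
        })
        rules = [Rule("MW", "MW", 1, scope="scopecol")]
        cm = compliance_matrix({"m": [1.0, 2.0, 3.0, 4.0]}, table, rules)
        assert np.isnan(cm.rho.loc["MW", "m"])

    def test_length_mismatch_rejected(self, small_records):
        table = rule_feature_table(small_records)
        with pytest.raises(ValueError):
            compliance_matrix({"m": [1.0]}, table)


def _fixture_matrix():
    """3-model x 4-rule compliance matrix with hand-computed affinities."""
    rules = [
        Rule("r1", "f1", +1),
        Rule("r2", "f2", -1),
        Rule("r3", "f3", +1),
        Rule("r4", "f4", -1),
    ]
    rho = pd.DataFrame(
        {
            "A": [1.0, 0.8, 0.0, -0.9],
            "B": [0.5, -0.2, 0.0, -0.3],
            "C": [-1.0, 0.4, 0.0, 0.6],
        },
        index=["r1", "r2", "r3", "r4"],
    )
    n_used = pd.DataFrame(10, index=rho.index, columns=rho.columns)
    return ComplianceMatrix(rules=rules, rho=rho, n_used=n_used)


class TestRuleAffinity:
    def test_hand_computed_fixture(self):
        # r1 (+): s = (1, .5, -1)     -> u = (1, .75, 0)
        # r2 (-): s = (-.8, .2, -.4)  -> u = (0, 1, .4)
        # r3 (+): s = (0, 0, 0)       -> u = (.5, .5, .5)  degenerate
        # r4 (-): s = (.9, .3, -.6)   -> u = (1, .6, 0)
        affinity = rule_affinity(_fixture_matrix(), exclude=())
        assert affinity["A"] == pytest.approx(2.5, abs=1e-9)
        assert affinity["B"] == pytest.approx(2.85, abs=1e-9)
        assert affinity["C"] == pytest.approx(0.9, abs=1e-9)

    def test_bounds(self):
        affinity = rule_affinity(_fixture_matrix(), exclude=())
        n = affinity.attrs["n_scored_rules"]
        assert n == 4
        assert ((affinity >= 0) & (affinity <= n)).all()

    def test_identical_models_score_half_per_rule(self):
        cm = _fixture_matrix()
        cm.rho["B"] = cm.rho["A"]
        cm.rho["C"] = cm.rho["A"]
        affinity = rule_affinity(cm, exclude=())
        assert np.allclose(affinity, 2.0)  # 4 rules x 0.5

    def test_invariant_to_model_relabeling(self):
        cm = _fixture_matrix()
        base = rule_affinity(cm, exclude=())
        cm2 = ComplianceMatrix(
            rules=cm.rules, rho=cm.rho[["C", "A", "B"]], n_used=cm.n_used
        )
        relabeled = rule_affinity(cm2, exclude=())
        for m in ("A", "B", "C"):
            assert relabeled[m] == base[m]

    def test_sign_coherence_under_negation(self):
        # Negating every model's predictions flips s and reverses the
        # per-rule ordering of u.
        cm = _fixture_matrix()
        neg = ComplianceMatrix(rules=cm.rules, rho=-cm.rho, n_used=cm.n_used)
        for rule in cm.rules:
            s = rule.expected_sign * cm.rho.loc[rule.rule_id]
            s_neg = rule.expected_sign * neg.rho.loc[rule.rule_id]
            assert (s_neg == -s).all()
            if s.max() > s.min():
                assert list(s.sort_values().index) == list(
                    s_neg.sort_values(ascending=False).index
                )

    def test_undefined_rule_dropped(self):
        cm = _fixture_matrix()
        cm.rho.loc["r2", "B"] = np.nan
        affinity = rule_affinity(cm, exclude=())
        assert affinity.attrs["n_scored_rules"] == 3

    def test_single_model_rejected(self):
        cm = _fixture_matrix()
        with pytest.raises(ValueError):
            rule_affinity(cm, exclude=("B", "C"))

    def test_data_column_excluded_by_default(self):
        cm = _fixture_matrix()
        cm.rho = cm.rho.rename(columns={"C": "Data"})
        affinity = rule_affinity(cm)
        assert "Data" not in affinity.index


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        r2, rho = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r2 == 1.0 and rho == 1.0

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        r2, _ = regression_metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_ss_oracle(self, rng):
        y = rng.normal(size=30)
        p = y + rng.normal(scale=0.5, size=30)
        r2, _ = regression_metrics(y, p)
        ss_res = np.sum((y - p) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)

    def test_constant_truth_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClassificationMetrics:
    def test_perfect(self):
        bal, prec, rec = classification_metrics(["T", "PT", "NT"], ["T", "PT", "NT"])
        assert bal == prec == rec == 1.0

    def test_four_sample_confusion_example(self):
        bal, prec, rec = classification_metrics(
            ["T", "T", "PT", "NT"], ["T", "PT", "PT", "NT"]
        )
        assert bal == pytest.approx(2.5 / 3)
        assert rec == pytest.approx(0.75)  # support-weighted = accuracy here

    def test_single_class_all_correct(self):
        bal, _, _ = classification_metrics(["NT", "NT"], ["NT", "NT"])
        assert bal == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])
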