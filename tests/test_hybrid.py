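"""Hybridization schemes H0-H3."""

import numpy as np
import pytest

from aquatox.chemdata import compute_descriptors
from aquatox.descriptors import compute_descriptor
from aquatox.exceptions import FeatureError
from aquatox.hybrid import (
    DEFAULT_PK_DESCRIPTORS,
    HybridConfig,
    LogPRoutedRegressor,
    MwOutlierFilteredRegressor,
    PkDescriptorKnnRegressor,
    PkmGuidedKnnRegressor,
    h0_filter,
    h1_select,
    h2_predict,
    make_descriptor_knn,
    make_fingerprint_knn,
)
from aquatox.knn import KnnToxicityRegressor
from aquatox.pkm import default_pkm


class _StubPkm:
    """Predicts a fixed value per SMILES; stands in for a fitted PKM."""

    def __init__(self, mapping):
        self.mapping = mapping

    def fit(self, X=None, y=None):
        return self

    def predict(self, X):
        return np.array([self.mapping[x] for x in X])


class TestH0:
    def test_partition_exhaustive_and_disjoint(self):
        smiles = ["CCO", "CCCCCCCC", "CCCCCCCCCCCCCCCCCCCC"]
        kept, outliers = h0_filter(smiles, mw_threshold=150.0)
        assert set(kept) | set(outliers) == set(smiles)
        assert set(kept) & set(outliers) == set()

    def test_boundary_is_strict(self):
        kept, outliers = h0_filter(["CCO"], mw_threshold=46.069, mw=[46.069])
        assert kept == ["CCO"] and outliers == []
        kept, outliers = h0_filter(["CCO"], mw_threshold=46.0, mw=[46.069])
        assert outliers == ["CCO"]

    def test_counted_against_direct_comparison(self, rng):
        mw = rng.uniform(50, 400, size=50)
        smiles = [f"m{i}" for i in range(50)]
        kept, outliers = h0_filter(smiles, mw_threshold=300.0, mw=mw)
        assert len(outliers) == int((mw > 300.0).sum())

    def test_threshold_monotone_in_kept(self, rng):
        mw = rng.uniform(50, 400, size=50)
        smiles = [f"m{i}" for i in range(50)]
        kept_low, _ = h0_filter(smiles, 200.0, mw=mw)
        kept_high, _ = h0_filter(smiles, 350.0, mw=mw)
        assert set(kept_low) <= set(kept_high)

    def test_estimator_removes_outliers_and_predicts(self, benchmark):
        est = MwOutlierFilteredRegressor(mw_threshold=150.0)
        est.fit(benchmark.train_smiles[:100], benchmark.train_tox[:100])
        mw = [compute_descriptor(s, "MW") for s in benchmark.train_smiles[:100]]
        assert est.n_outliers_ == sum(1 for w in mw if w > 150.0)
        preds = est.predict(benchmark.test_smiles[:10])
        assert preds.shape == (10,)


class TestH1:
    def test_subset_in_config_order(self, small_records):
        features = compute_descriptors(small_records)
        sub = h1_select(features)
        assert sub.descriptor_names == ["MolLogP", "AATSC0p", "TPSA",
                                        "ETA_dEpsilon_A", "SHBd", "Mi"]
        assert sub.descriptors.shape == (len(small_records), 6)

    def test_identity_subset(self, small_records):
        features = compute_descriptors(small_records, ["MW", "TPSA"])
        sub = h1_select(features, ["MW", "TPSA"])
        assert np.array_equal(sub.descriptors, features.descriptors)

    def test_missing_descriptor_named_in_error(self, small_records):
        features = compute_descriptors(small_records, ["MW"])
        with pytest.raises(FeatureError, match="TPSA"):
            h1_select(features, ["TPSA"])

    def test_estimator_runs_in_reduced_space(self, benchmark):
        est = PkDescriptorKnnRegressor(k=2)
        est.fit(benchmark.train_smiles[:80], benchmark.train_tox[:80])
        names = est.pipeline_.named_steps["features"].feature_names_
        assert names == [
            "MolLogP", "AATSC0p", "TPSA", "ETA_dEpsilon_A", "SHBd", "Mi"
        ]
        assert est.predict(benchmark.test_smiles[:5]).shape == (5,)


class TestH2:
    @pytest.mark.parametrize(
        "logp_smiles, expected_route",
        [
            ("CCCCCC", "knn"),    # logP ~ 2.6, inside band
            ("CO", "pkm"),        # logP < 1.5
            ("CCCCCCCCCCCC", "pkm"),  # logP > 4
        ],
    )
    def test_routing_by_logp(self, benchmark, logp_smiles, expected_route):
        est = LogPRoutedRegressor(knn_estimator=make_fingerprint_knn(k=3))
        est.fit(benchmark.train_smiles[:60], benchmark.train_tox[:60])
        _, routes = est.predict_with_route([logp_smiles])
        assert routes[0] == expected_route

    def test_router_output_equals_pure_model_bitwise(self, benchmark):
        train_s, train_y = benchmark.train_smiles[:80], benchmark.train_tox[:80]
        test_s = benchmark.test_smiles[:30]
        est = LogPRoutedRegressor(knn_estimator=make_fingerprint_knn(k=3))
        est.fit(train_s, train_y)
        yhat, routes = est.predict_with_route(test_s)
        pure_knn = make_fingerprint_knn(k=3).fit(train_s, train_y).predict(test_s)
        pure_pkm = default_pkm().predict(test_s)
        for i, route in enumerate(routes):
            expected = pure_knn[i] if route == "knn" else pure_pkm[i]
            assert yhat[i] == expected  # bitwise, no arithmetic added

    def test_functional_form_boundary_inclusive(self, benchmark):
        knn_model = make_fingerprint_knn(k=3).fit(
            benchmark.train_smiles[:60], benchmark.train_tox[:60]
        )
        pk = default_pkm()
        # A stub query object is not needed: pick molecules and override the
        # band so their computed logP sits exactly on the boundary.
        smiles = "CCCCCC"
        logp = compute_descriptor(smiles, "MolLogP")
        cfg = HybridConfig(scheme="H2", logp_low=logp, logp_high=logp + 1)
        _, route = h2_predict(smiles, knn_model, pk, cfg)
        assert route == "knn"
        cfg_hi = HybridConfig(scheme="H2", logp_low=logp - 1, logp_high=logp)
        _, route_hi = h2_predict(smiles, knn_model, pk, cfg_hi)
        assert route_hi == "knn"


class TestH3:
    def test_constant_pkm_ties_break_to_lowest_indices(self):
        train = ["a", "b", "c", "d"]
        stub = _StubPkm({s: 1.0 for s in train} | {"q": 1.0})
        est = PkmGuidedKnnRegressor(pk_model=stub, k=2)
        est.fit(train, [10.0, 20.0, 30.0, 40.0])
        assert est.predict(["q"])[0] == pytest.approx(15.0)  # indices 0, 1

    def test_nearest_pkm_values_selected(self):
        stub = _StubPkm({"a": 1.0, "b": 2.0, "c": 5.0, "q": 1.9})
        est = PkmGuidedKnnRegressor(pk_model=stub, k=2)
        est.fit(["a", "b", "c"], [10.0, 20.0, 50.0])
        # |delta| = {0.9, 0.1, 3.1} -> neighbors b, a
        assert est.predict(["q"])[0] == pytest.approx(15.0)

    def test_k_equals_n_gives_global_mean(self):
        stub = _StubPkm({"a": 0.0, "b": 1.0, "c": 2.0, "q": 5.0})
        est = PkmGuidedKnnRegressor(pk_model=stub, k=3)
        est.fit(["a", "b", "c"], [1.0, 2.0, 6.0])
        assert est.predict(["q"])[0] == pytest.approx(3.0)

    def test_reduces_to_1d_descriptor_knn_with_identity_pkm(self, benchmark):
        # When the PKM returns a single descriptor, H3 neighbor selection is
        # 1-D kNN on that descriptor (z-scaling is monotone, so neighbor
        # sets agree).
        train_s = benchmark.train_smiles[:60]
        train_y = benchmark.train_tox[:60]
        test_s = benchmark.test_smiles[:15]
        logp = {s: compute_descriptor(s, "MolLogP") for s in set(train_s + test_s)}
        stub = _StubPkm(logp)
        h3 = PkmGuidedKnnRegressor(pk_model=stub, k=4).fit(train_s, train_y)
        X_train = np.array([[logp[s]] for s in train_s])
        X_test = np.array([[logp[s]] for s in test_s])
        knn_1d = KnnToxicityRegressor(k=4).fit(X_train, train_y)
        assert np.allclose(h3.predict(test_s), knn_1d.predict(X_test))

    def test_k_exceeding_train_raises(self):
        stub = _StubPkm({"a": 0.0, "b": 1.0})
        with pytest.raises(ValueError):
            PkmGuidedKnnRegressor(pk_model=stub, k=5).fit(["a", "b"], [0.0, 1.0])


def test_hybrid_config_validation():
    with pytest.raises(ValueError):
        HybridConfig(scheme="H9")
    with pytest.raises(ValueError):
        HybridConfig(logp_low=4.0, logp_high=1.5)
    with pytest.raises(ValueError):
        HybridConfig(mw_threshold=-1)
    with pytest.raises(ValueError):
        HybridConfig(pk_descriptors=())


def test_schemes_deterministic(benchmark):
    train_s, train_y = benchmark.train_smiles[:60], benchmark.train_tox[:60]
    test_s = benchmark.test_smiles[:10]
    for maker in (
        lambda: MwOutlierFilteredRegressor(base_estimator=make_descriptor_knn(k=3),
                                           mw_threshold=150.0),
        lambda: PkDescriptorKnnRegressor(k=2),
        lambda: LogPRoutedRegressor(knn_estimator=make_fingerprint_knn(k=3)),
        lambda: PkmGuidedKnnRegressor(k=5),
    ):
        a = maker().fit(train_s, train_y).predict(test_s)
        b = maker().fit(train_s, train_y).predict(test_s)
        assert np.array_equal(a, b)


def test_h2_with_generative_law_pkm_never_degrades_pure_knn(benchmark):
    # When the PKM is configured to the generative law itself it predicts
    # the noiseless truth, so routing part of the queries to it cannot hurt
    # held-out accuracy relative to the pure fingerprint kNN.
    from aquatox.pkm import DATASET_SCALE, GcModel, InterspeciesMap, PriorKnowledgeModel
    from aquatox.ruleeval import regression_metrics

    gc = GcModel(
        fragments=[("[CH3][#7]", -0.8)],
        descriptor_terms=[("MolLogP", 0.9), ("MW", 0.005)],
        intercept=-2.0,
        output_scale=DATASET_SCALE,
    )
    true_pkm = PriorKnowledgeModel(
        gc=gc,
        species_map=InterspeciesMap(input_scale=DATASET_SCALE, output_scale=DATASET_SCALE),
    ).fit()
    # Sanity: this PKM reproduces the generative truth on the test set.
    assert np.allclose(true_pkm.predict(benchmark.test_smiles), benchmark.truth_test)
    pure = make_fingerprint_knn(k=7).fit(benchmark.train_smiles, benchmark.train_tox)
    r2_pure, _ = regression_metrics(benchmark.test_tox, pure.predict(benchmark.test_smiles))
    h2 = LogPRoutedRegressor(knn_estimator=make_fingerprint_knn(k=7), pk_model=true_pkm)
    h2.fit(benchmark.train_smiles, benchmark.train_tox)
    r2_h2, _ = regression_metrics(benchmark.test_tox, h2.predict(benchmark.test_smiles))
    assert r2_h2 >= r2_pure
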