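"""ML stage: dataset preparation, stratified split, SMOTE, RFE, models."""

import numpy as np
import pandas as pd
import pytest

from aceid.design import generate_design
from aceid.manifest import DEFAULT_INFORMATIVE_FEATURES, feature_names
from aceid.ml import (
    MLDataset,
    prepare_dataset,
    rfe_select,
    smote_oversample,
    split_stratified,
    train_and_evaluate,
)
from aceid.simulate import simulate_feature_table


def toy_dataset(n_pos=20, n_neg=40, p=6, sep=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n_pos + n_neg, p))
    X[:n_pos, 0] += sep
    y = pd.Series(["increase"] * n_pos + ["no_effect"] * n_neg, name="label")
    ids = pd.DataFrame(
        {"condition_id": [f"C{i}" for i in range(n_pos + n_neg)], "replicate_id": 1}
    )
    return MLDataset(X=pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y=y, ids=ids)


@pytest.fixture(scope="module")
def sim_table(default_design):
    return simulate_feature_table(default_design, seed=4)


@pytest.fixture(scope="module")
def labels(default_design):
    pos = set(default_design.positive_conditions)
    return {
        c: ("increase" if c in pos else "no_effect")
        for c in default_design.condition_ids
    }


class TestPrepare:
    def test_study_scale_shape(self, sim_table, labels):
        """The default design prepares to 490 samples x 850 features."""
        ds = prepare_dataset(sim_table, labels)
        assert ds.X.shape == (490, 850)
        assert list(ds.X.columns) == feature_names()
        assert ds.y.value_counts()["increase"] == 36 * 5  # first 66 conds have 5 reps

    def test_missing_assay_features_zero_filled(self, sim_table, labels):
        partial = sim_table.drop(
            columns=[c for c in sim_table.columns if c.startswith("dextran_")]
        )
        missing_block = pd.DataFrame(
            {c: np.nan for c in feature_names() if c.startswith("dextran_")},
            index=partial.index,
        )
        ds = prepare_dataset(pd.concat([partial, missing_block], axis=1), labels)
        dex = [c for c in ds.X.columns if c.startswith("dextran_")]
        assert (ds.X[dex] == 0).all().all()
        assert len(ds) == 490

    def test_duplicate_replicates_aggregated(self, sim_table, labels):
        doubled = pd.concat([sim_table, sim_table], ignore_index=True)
        ds = prepare_dataset(doubled, labels)
        assert len(ds) == 490

    def test_join_error_lists_missing_conditions(self, sim_table, labels):
        labels = dict(labels)
        labels["C999"] = "increase"
        with pytest.raises(KeyError, match="C999"):
            prepare_dataset(sim_table, labels)

    def test_robust_z_normalized_against_controls(self, sim_table, labels):
        """Control rows define the zero point: a feature's control block has
        median 0 after preparation (checked via a shifted copy)."""
        shifted = sim_table.copy()
        f = DEFAULT_INFORMATIVE_FEATURES[0]
        shifted[f] = shifted[f] + 100.0  # common shift: robust-Z removes it
        a = prepare_dataset(sim_table, labels)
        b = prepare_dataset(shifted, labels)
        np.testing.assert_allclose(a.X[f], b.X[f], atol=1e-9)


class TestSplit:
    def test_proportional_allocation(self):
        ds = toy_dataset(n_pos=5, n_neg=15)
        train, test = split_stratified(ds, 0.8, seed=0)
        assert len(train) == 16 and len(test) == 4
        assert (train.y == "increase").sum() == 4
        assert (test.y == "increase").sum() == 1

    def test_disjoint_exhaustive(self):
        ds = toy_dataset()
        train, test = split_stratified(ds, 0.8, seed=1)
        ids = pd.concat([train.ids, test.ids]).sort_values("condition_id")
        assert sorted(ids.condition_id) == sorted(ds.ids.condition_id)
        assert not set(train.ids.condition_id) & set(test.ids.condition_id)

    def test_same_seed_identical(self):
        ds = toy_dataset()
        a1, b1 = split_stratified(ds, seed=5)
        a2, b2 = split_stratified(ds, seed=5)
        pd.testing.assert_frame_equal(a1.X, a2.X)
        pd.testing.assert_frame_equal(b1.X, b2.X)

    def test_single_class_rejected(self):
        ds = toy_dataset(n_pos=0, n_neg=10)
        with pytest.raises(ValueError):
            split_stratified(ds)


class TestSmote:
    def test_balanced_input_unchanged(self):
        ds = toy_dataset(n_pos=10, n_neg=10)
        out = smote_oversample(ds, seed=0)
        assert out is ds

    def test_counts_equalized(self):
        ds = toy_dataset(n_pos=8, n_neg=30)
        out = smote_oversample(ds, seed=0)
        counts = out.y.value_counts()
        assert counts["increase"] == counts["no_effect"] == 30

    def test_two_point_minority_synthesizes_on_segment(self):
        """Minority {(0,0),(1,1)} with k=1: every synthetic point is
        (lam, lam) for lam in [0,1]."""
        X = pd.DataFrame(
            [[0.0, 0.0], [1.0, 1.0]] + [[5.0, -5.0]] * 8, columns=["a", "b"]
        )
        y = pd.Series(["increase"] * 2 + ["no_effect"] * 8, name="label")
        ids = pd.DataFrame({"condition_id": list(range(10)), "replicate_id": 1})
        out = smote_oversample(MLDataset(X=X, y=y, ids=ids), k_neighbors=1, seed=3)
        synth = out.X.iloc[10:]
        np.testing.assert_allclose(synth["a"], synth["b"], atol=1e-12)
        assert ((synth["a"] >= 0) & (synth["a"] <= 1)).all()

    def test_minority_too_small_rejected(self):
        ds = toy_dataset(n_pos=3, n_neg=10)
        with pytest.raises(ValueError, match="minority"):
            smote_oversample(ds, k_neighbors=5)


class TestRFE:
    def test_selects_requested_count(self):
        ds = toy_dataset(n_pos=15, n_neg=30, p=20, sep=2.0)
        sel = rfe_select(ds, n_features=10, seed=0)
        assert len(sel) == 10
        assert "f0" in sel  # the separating feature survives

    def test_one_elimination_round(self):
        ds = toy_dataset(p=6)
        sel = rfe_select(ds, n_features=5, seed=0)
        assert len(sel) == 5

    def test_n_features_too_large_rejected(self):
        ds = toy_dataset(p=6)
        with pytest.raises(ValueError):
            rfe_select(ds, n_features=6)


class TestTrainEvaluate:
    def test_separable_data_perfect_f1(self):
        tr = toy_dataset(n_pos=20, n_neg=30, sep=8.0, seed=1)
        te = toy_dataset(n_pos=8, n_neg=12, sep=8.0, seed=2)
        report = train_and_evaluate(tr, te, seed=0)
        for entry in report.models.values():
            assert entry["f1_macro"] == 1.0

    def test_importances_normalized(self):
        tr = toy_dataset(sep=2.0, seed=1)
        te = toy_dataset(sep=2.0, seed=2)
        report = train_and_evaluate(tr, te, seed=0)
        for name in ("random_forest", "gradient_boosted"):
            imp = report.models[name]["importances"]
            assert imp is not None and all(v >= 0 for v in imp.values())
            assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
        assert report.models["knn"]["importances"] is None

    def test_metrics_consistent_with_confusion(self):
        tr = toy_dataset(sep=1.0, seed=3)
        te = toy_dataset(sep=1.0, seed=4)
        report = train_and_evaluate(tr, te, seed=0)
        for entry in report.models.values():
            (tp, fn), (fp, tn) = entry["confusion"]
            pc = entry["per_class"]["increase"]
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert pc["precision"] == pytest.approx(prec)
            assert pc["recall"] == pytest.approx(rec)
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert pc["f1"] == pytest.approx(f1)

    def test_single_class_test_rejected(self):
        tr = toy_dataset()
        te = toy_dataset(n_pos=0, n_neg=5, seed=9)
        with pytest.raises(ValueError, match="single class"):
            train_and_evaluate(tr, te)

    def test_no_leakage_from_test_labels(self):
        """Permuting test labels changes metrics but not the fitted models:
        identical feature importances and identical predictions."""
        tr = toy_dataset(sep=1.5, seed=5)
        te = toy_dataset(sep=1.5, seed=6)
        scrambled = MLDataset(
            X=te.X,
            y=te.y.sample(frac=1.0, random_state=0).reset_index(drop=True),
            ids=te.ids,
        )
        a = train_and_evaluate(tr, te, seed=0)
        b = train_and_evaluate(tr, scrambled, seed=0)
        for name in ("random_forest", "gradient_boosted"):
            assert a.models[name]["importances"] == b.models[name]["importances"]


def test_planted_feature_recovery_single_seed(default_design):
    """On one study-scale simulation, RFE recovers most of the 10 planted
    features and the gradient-boosted model generalizes."""
    pos = set(default_design.positive_conditions)
    labels = {
        c: ("increase" if c in pos else "no_effect") for c in default_design.condition_ids
    }
    table = simulate_feature_table(default_design, seed=20)
    ds = prepare_dataset(table, labels)
    train, test = split_stratified(ds, 0.8, seed=20)
    train = smote_oversample(train, seed=20)
    selected = rfe_select(train, n_features=10, seed=20)
    hits = len(set(selected) & set(DEFAULT_INFORMATIVE_FEATURES))
    assert hits >= 7
    report = train_and_evaluate(train, test, selected, seed=20)
    assert report.models["gradient_boosted"]["f1_macro"] >= 0.75
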