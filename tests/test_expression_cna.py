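"""Expression-based CNA prediction: features, training, calibration."""

import numpy as np
import pandas as pd
import pytest

from tmzpgx.expression_cna import (
    build_pathway_features,
    calibrate_cutoffs,
    collapse_to_three_classes,
    predict_cna_from_expression,
    train_cna_predictor,
)


@pytest.fixture
def dosage_data(rng):
    """Expression where the target tracks copy number with mild noise."""
    n = 120
    classes = rng.choice(["deletion", "neutral", "amplification"], n, p=[0.25, 0.5, 0.25])
    dosage = pd.Series(classes).map({"deletion": -2.0, "neutral": 0.0, "amplification": 2.0})
    genes = [f"g{i}" for i in range(12)] + ["TARGET"]
    expr = pd.DataFrame(
        rng.normal(0, 1, (len(genes), n)), index=genes,
        columns=[f"s{i}" for i in range(n)],
    )
    expr.loc["TARGET"] += dosage.values + rng.normal(0, 0.2, n)
    labels = pd.Series(classes, index=expr.columns)
    gene_sets = {"pathway": ["TARGET"] + genes[:6]}
    return expr, labels, gene_sets


class TestPathwayFeatures:
    def test_set_union_with_target(self):
        expr = pd.DataFrame(
            np.arange(20.0).reshape(5, 4), index=list("abcdT"),
            columns=[f"s{i}" for i in range(4)],
        )
        sets = {"s1": ["T", "a", "b"], "s2": ["T", "b", "c"], "s3": ["x", "y"]}
        fs = build_pathway_features(expr, "T", sets)
        assert sorted(fs.predictor_genes) == ["T", "a", "b", "c"]

    def test_no_containing_set_falls_back_to_target(self):
        expr = pd.DataFrame(
            [[1.0, 2.0], [5.0, 3.0]], index=["T", "a"], columns=["s0", "s1"]
        )
        with pytest.warns(UserWarning):
            fs = build_pathway_features(expr, "T", {"s": ["a"]})
        assert fs.predictor_genes == ["T"]

    def test_target_absent_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["a"], columns=["s"])
        with pytest.raises(ValueError):
            build_pathway_features(expr, "T", {})

    def test_features_z_scored(self, dosage_data):
        expr, _, sets = dosage_data
        fs = build_pathway_features(expr, "TARGET", sets)
        np.testing.assert_allclose(fs.features.mean(axis=0), 0, atol=1e-10)


class TestTraining:
    def test_separable_case_trains_perfectly(self, dosage_data, rng):
        expr, labels, sets = dosage_data
        # noiseless monotone dosage: perfect separation expected
        expr2 = expr.copy()
        expr2.loc["TARGET"] = labels.map(
            {"deletion": -3.0, "neutral": 0.0, "amplification": 3.0}
        ).values
        fs = build_pathway_features(expr2, "TARGET", sets)
        model = train_cna_predictor(fs, labels, seed=0)
        proba = model.predict_proba(fs.features)
        acc = (proba.idxmax(axis=1) == collapse_to_three_classes(labels)).mean()
        assert acc == 1.0

    def test_fixed_seed_reproducible(self, dosage_data):
        expr, labels, sets = dosage_data
        fs = build_pathway_features(expr, "TARGET", sets)
        p1 = train_cna_predictor(fs, labels, seed=3).predict_proba(fs.features)
        p2 = train_cna_predictor(fs, labels, seed=3).predict_proba(fs.features)
        pd.testing.assert_frame_equal(p1, p2)

    def test_single_class_rejected(self, dosage_data):
        expr, labels, sets = dosage_data
        fs = build_pathway_features(expr, "TARGET", sets)
        with pytest.raises(ValueError, match="one class"):
            train_cna_predictor(fs, pd.Series("neutral", index=labels.index))

    def test_label_shuffle_gives_chance_accuracy(self, dosage_data, rng):
        expr, labels, sets = dosage_data
        fs = build_pathway_features(expr, "TARGET", sets)
        shuffled = pd.Series(rng.permutation(labels.values), index=labels.index)
        train_idx = fs.features.index[:80]
        test_idx = fs.features.index[80:]
        fs_train = build_pathway_features(expr[train_idx], "TARGET", sets)
        model = train_cna_predictor(fs_train, shuffled[train_idx], seed=0)
        z_test = (expr[test_idx].loc[fs_train.predictor_genes].T - fs_train.gene_means) / fs_train.gene_sds
        pred = model.predict_proba(z_test).idxmax(axis=1)
        acc = (pred == collapse_to_three_classes(shuffled[test_idx])).mean()
        prior = collapse_to_three_classes(shuffled).value_counts(normalize=True).max()
        assert abs(acc - prior) < 0.25


class TestCalibration:
    def test_separated_probabilities_smallest_maximising_cutoff(self):
        proba = pd.DataFrame(
            {"gain/amplification": [0.9, 0.8, 0.1, 0.2], "neutral": [0.1, 0.2, 0.9, 0.8]},
            index=list("abcd"),
        )
        truth = pd.Series(
            ["amplification", "gain", "neutral", "neutral"], index=list("abcd")
        )
        cuts = calibrate_cutoffs(proba, truth)
        assert cuts["gain/amplification"] == pytest.approx(0.8)

    def test_all_neutral_truth_leaves_classes_uncalibrated(self):
        proba = pd.DataFrame(
            {"deletion/loss": [0.4, 0.1], "neutral": [0.6, 0.9]}, index=["a", "b"]
        )
        truth = pd.Series(["neutral", "neutral"], index=["a", "b"])
        assert calibrate_cutoffs(proba, truth)["deletion/loss"] is None

    def test_rows_must_sum_to_one(self):
        proba = pd.DataFrame({"neutral": [0.4], "gain/amplification": [0.4]})
        with pytest.raises(ValueError):
            calibrate_cutoffs(proba, pd.Series(["neutral"]))

    def test_calibration_never_below_default_cutoff_f1(self, dosage_data):
        from sklearn.metrics import f1_score

        expr, labels, sets = dosage_data
        fs = build_pathway_features(expr, "TARGET", sets)
        model = train_cna_predictor(fs, labels, seed=0)
        proba = model.predict_proba(fs.features)
        cuts = calibrate_cutoffs(proba, labels)
        truth3 = collapse_to_three_classes(labels)
        for cls, cut in cuts.items():
            if cut is None:
                continue
            f1_cal = f1_score(truth3 == cls, proba[cls] >= cut, zero_division=0)
            f1_default = f1_score(truth3 == cls, proba[cls] >= 0.5, zero_division=0)
            assert f1_cal >= f1_default - 1e-12


class TestPrediction:
    def test_strong_dosage_effect_f1(self, dosage_data):
        from sklearn.metrics import f1_score

        expr, labels, sets = dosage_data
        fs = build_pathway_features(expr, "TARGET", sets)
        model = train_cna_predictor(fs, labels, seed=0)
        model.cutoffs = calibrate_cutoffs(model.predict_proba(fs.features), labels)
        pred = predict_cna_from_expression(model, expr)
        truth3 = collapse_to_three_classes(labels)
        for cls in ("deletion/loss", "gain/amplification"):
            assert f1_score(truth3 == cls, pred == cls, zero_division=0) >= 0.9

    def test_below_all_cutoffs_is_neutral(self, dosage_data):
        expr, labels, sets = dosage_data
        fs = build_pathway_features(expr, "TARGET", sets)
        model = train_cna_predictor(fs, labels, seed=0)
        model.cutoffs = {c: 1.1 for c in model.classes if c != "neutral"}
        pred = predict_cna_from_expression(model, expr)
        assert (pred == "neutral").all()

    def test_sample_order_invariance(self, dosage_data):
        expr, labels, sets = dosage_data
        fs = build_pathway_features(expr, "TARGET", sets)
        model = train_cna_predictor(fs, labels, seed=0)
        model.cutoffs = calibrate_cutoffs(model.predict_proba(fs.features), labels)
        p1 = predict_cna_from_expression(model, expr)
        p2 = predict_cna_from_expression(model, expr[expr.columns[::-1]])
        pd.testing.assert_series_equal(p1.sort_index(), p2.sort_index())

    def test_missing_predictors_imputed_with_warning(self, dosage_data):
        expr, labels, sets = dosage_data
        fs = build_pathway_features(expr, "TARGET", sets)
        model = train_cna_predictor(fs, labels, seed=0)
        model.cutoffs = calibrate_cutoffs(model.predict_proba(fs.features), labels)
        reduced = expr.drop(index=[g for g in fs.predictor_genes if g != "TARGET"][:3])
        with pytest.warns(UserWarning, match="predictor genes missing"):
            predict_cna_from_expression(model, reduced)
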