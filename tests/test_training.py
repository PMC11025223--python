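import numpy as np
import pandas as pd
import pytest

from molclass import synth, training
from molclass.crn import ValidationError
from molclass.training import (
    ExpressionMatrix,
    PanelModel,
    differential_expression,
    rank_features,
    select_classifier,
    split_train_validation,
    train_panels,
)


def small_matrix(seed=0, n=60, effects=(3.0, -3.0), n_features=6, sigma=0.5):
    rng = np.random.default_rng(seed)
    names = [f"f{i}" for i in range(n_features)]
    base = rng.uniform(5, 9, n_features)
    eff = np.zeros(n_features)
    eff[: len(effects)] = effects
    X = np.vstack(
        [
            base + eff / 2 + rng.normal(0, sigma, (n // 2, n_features)),
            base - eff / 2 + rng.normal(0, sigma, (n // 2, n_features)),
        ]
    )
    idx = [f"s{i}" for i in range(n)]
    labels = pd.Series(["HCC"] * (n // 2) + ["healthy"] * (n // 2), index=idx)
    return ExpressionMatrix(pd.DataFrame(X, index=idx, columns=names), labels)


class TestExpressionMatrix:
    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan]}, index=["s1", "s2"])
        labels = pd.Series(["HCC", "healthy"], index=["s1", "s2"])
        with pytest.raises(ValidationError):
            ExpressionMatrix(df, labels)

    def test_unknown_labels_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]}, index=["s1", "s2"])
        labels = pd.Series(["HCC", "weird"], index=["s1", "s2"])
        with pytest.raises(ValidationError):
            ExpressionMatrix(df, labels)

    def test_csv_round_trip(self, tmp_path):
        mat = small_matrix()
        path = tmp_path / "expr.csv"
        mat.to_csv(path)
        back = ExpressionMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.values, mat.values)
        pd.testing.assert_series_equal(
            back.labels, mat.labels, check_names=False
        )


class TestDifferentialExpression:
    def test_fourfold_feature_retained_up(self):
        mat = small_matrix(effects=(4.0,), sigma=0.05)
        de = differential_expression(mat)
        assert de.loc["f0", "retained"]
        assert de.loc["f0", "direction"] == "up"
        assert de.loc["f0", "log2_fold_change"] == pytest.approx(4.0, abs=0.1)

    def test_null_feature_dropped(self):
        mat = small_matrix(effects=(), sigma=0.1)
        de = differential_expression(mat)
        assert not de["retained"].any()

    def test_single_class_rejected(self):
        mat = small_matrix()
        sub = mat.subset([s for s in mat.values.index if mat.labels[s] == "HCC"])
        with pytest.raises(ValidationError):
            differential_expression(sub)

    def test_planted_recovery_at_scale(self):
        # 20 up + 30 down planted at >= fourfold: all recovered at n=600/class
        effects = tuple([2.5] * 20 + [-2.5] * 30)
        config = synth.GeneratorConfig(
            seed=5,
            n_positive=600,
            n_negative=600,
            n_features=100,
            informative_effects=effects,
            noise_sigma=0.5,
        )
        matrix, truth = synth.generate_expression(config)
        de = differential_expression(matrix)
        retained = set(de.index[de["retained"]])
        assert set(truth.features) <= retained


class TestRanking:
    def test_informative_feature_ranked_first(self):
        # one strong signal among nulls must top the ranking
        mat = small_matrix(seed=3, n=200, effects=(3.0,), n_features=10, sigma=0.5)
        ranking = rank_features(mat, mat.features, seed=11, n_estimators=200)
        assert ranking.index[0] == "f0"

    def test_all_null_features_no_crash(self):
        mat = small_matrix(seed=4, effects=(), n_features=5, sigma=0.5)
        ranking = rank_features(mat, mat.features, seed=1, n_estimators=50)
        assert set(ranking.index) == set(mat.features)

    def test_empty_retained_rejected(self):
        mat = small_matrix()
        with pytest.raises(ValidationError):
            rank_features(mat, [], seed=0)

    def test_deterministic_given_seed(self):
        mat = small_matrix(seed=6, n=100, n_features=8)
        r1 = rank_features(mat, mat.features, seed=9, n_estimators=100)
        r2 = rank_features(mat, mat.features, seed=9, n_estimators=100)
        pd.testing.assert_frame_equal(r1, r2)


class TestPanels:
    def test_separable_data_perfect_training_auc(self):
        mat = small_matrix(seed=1, n=80, effects=(6.0, -6.0), sigma=0.2)
        train, val = split_train_validation(mat, seed=2)
        ranking = rank_features(train, ["f0", "f1"], seed=3, n_estimators=50)
        panels = train_panels(train, ranking, val, k_range=range(1, 3), seed=3)
        assert panels[-1].auc_train == 1.0

    def test_class_penalty_raises_positive_sensitivity(self):
        # on imbalanced data a 2:1 positive penalty cannot lower sensitivity
        rng = np.random.default_rng(12)
        n_pos, n_neg = 30, 120
        names = ["f0", "f1"]
        X = np.vstack(
            [
                rng.normal(1.0, 1.2, (n_pos, 2)),
                rng.normal(-1.0, 1.2, (n_neg, 2)),
            ]
        )
        idx = [f"s{i}" for i in range(n_pos + n_neg)]
        mat = ExpressionMatrix(
            pd.DataFrame(X, index=idx, columns=names),
            pd.Series(["HCC"] * n_pos + ["healthy"] * n_neg, index=idx),
        )
        train, val = split_train_validation(mat, seed=4)
        ranking = rank_features(train, names, seed=5, n_estimators=50)

        def sensitivity(ratio):
            panels = train_panels(
                train, ranking, val, k_range=[2], class_penalty_ratio=ratio, seed=5
            )
            p = panels[0]
            scores = val.values[list(p.features)].to_numpy() @ np.array(p.weights) + p.bias
            calls = scores > 0
            y = val.y.astype(bool)
            return (calls & y).sum() / y.sum()

        assert sensitivity(2.0) >= sensitivity(1.0)

    def test_degenerate_single_class_split_rejected(self):
        mat = small_matrix()
        pos_only = mat.subset([s for s in mat.values.index if mat.labels[s] == "HCC"])
        ranking = pd.DataFrame(index=pd.Index(["f0"], name="feature"))
        with pytest.raises(ValidationError):
            train_panels(pos_only, ranking, mat)

    def test_weights_are_one_decimal(self, trained):
        spec, panels, _ = trained
        for p in panels:
            for w in p.weights:
                assert abs(w * 10 - round(w * 10)) < 1e-9

    def test_rounding_changes_validation_auc_little(self, trained):
        # one-decimal rounding must not cost more than 0.01 AUC
        _, panels, _ = trained
        for p in panels:
            assert abs(p.auc_validation - p.auc_validation_unrounded) < 0.01


class TestSelection:
    def _panel(self, k, auc):
        return PanelModel(
            features=tuple(f"f{i}" for i in range(k)),
            weights=tuple([1.0] * k),
            bias=0.0,
            k=k,
            auc_train=auc,
            auc_validation=auc,
        )

    def test_tie_broken_toward_smaller_panel(self):
        spec = select_classifier([self._panel(5, 0.98), self._panel(3, 0.98)])
        assert len(spec.features) == 3

    def test_single_panel_returned(self):
        spec = select_classifier([self._panel(2, 0.9)])
        assert len(spec.features) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            select_classifier([])


class TestEndToEnd:
    def test_parameter_recovery_and_auc(self, hcc_cohort, trained):
        # selected panel contains every planted miRNA with the planted sign
        _, _, truth = hcc_cohort
        spec, panels, _ = trained
        assert set(truth.features) <= set(spec.features)
        for feature, effect in truth.effects.items():
            assert np.sign(spec.weight_map[feature]) == np.sign(effect)
        best = max(panels, key=lambda p: (p.auc_validation, -p.k))
        assert best.auc_validation > 0.95

    def test_reproducible_bit_for_bit(self, hcc_cohort):
        _, matrix, _ = hcc_cohort
        spec1, _, _ = training.train_classifier(matrix, seed=13)
        spec2, _, _ = training.train_classifier(matrix, seed=13)
        assert spec1.to_json() == spec2.to_json()
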