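"""Gentle boosting: stump search, weights, rules files, evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from spherotype import fgboost
from spherotype.fgboost import (BoostModel, Rule, evaluate, export_rules,
                                holdout_evaluate, import_rules, predict,
                                train, two_stage_classify)


def brute_force_best_stump(x, y_enc, w):
    """Enumerate every (feature, threshold) stump; weighted LSQ oracle."""
    n, p = x.shape
    best = None
    for j in range(p):
        for thr in sorted(np.unique(x[:, j])):
            gt = x[:, j] > thr
            err = 0.0
            scores = []
            for branch in (gt, ~gt):
                wb = w[branch]
                yb = y_enc[branch]
                if wb.sum(axis=0).min() > 0:
                    f = (wb * yb).sum(axis=0) / wb.sum(axis=0)
                else:
                    f = np.zeros(y_enc.shape[1])
                scores.append(f)
                err += (w[branch] * (y_enc[branch] - f) ** 2).sum()
            if best is None or err < best[0] - 1e-12:
                best = (err, j, thr, scores[0], scores[1])
    return best


class TestTraining:
    def test_four_point_stump_matches_enumeration(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        labels = np.array(["neg", "neg", "pos", "pos"])
        model = train(x, labels, n_rounds=1)
        rule = model.rules[0]
        y_enc = np.where(labels[:, None] == np.array(model.classes), 1.0,
                         -1.0)
        w = np.full((4, 2), 0.25)
        _, j, thr, s_gt, s_le = brute_force_best_stump(x, y_enc, w)
        assert 1.0 <= rule.threshold < 2.0
        assert rule.threshold == thr
        np.testing.assert_allclose(rule.scores_gt, s_gt)
        np.testing.assert_allclose(rule.scores_le, s_le)
        # pure branches: weighted label means are exactly +-1
        np.testing.assert_allclose(np.abs(rule.scores_gt), 1.0)

    def test_separable_data_one_round_is_perfect(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)][:, None]
        labels = np.array(["a"] * 50 + ["b"] * 50)
        model = train(x, labels, n_rounds=10)
        assert evaluate(model, x, labels).accuracy == 1.0
        assert len(model.rules) == 1  # early stop at zero training error

    def test_exponential_loss_non_increasing(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(20, 60))
            x = rng.normal(size=(n, 3))
            labels = np.where(x[:, 0] + rng.normal(0, 1.2, n) > 0, "a", "b")
            if len(set(labels)) < 2 or min(
                    (labels == c).sum() for c in set(labels)) < 2:
                continue
            model = train(x, labels, n_rounds=15)
            classes = np.array(model.classes)
            y_enc = np.where(labels[:, None] == classes, 1.0, -1.0)
            # independent accumulator of the exponential loss
            f_sum = np.zeros_like(y_enc)
            losses = [np.exp(-y_enc * f_sum).mean()]
            for r in model.rules:
                fx = np.where(x[:, int(r.feature[1:])][:, None] > r.threshold,
                              r.scores_gt, r.scores_le)
                f_sum += fx
                losses.append(np.exp(-y_enc * f_sum).mean())
            assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_branch_scores_bounded(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 4))
        labels = rng.choice(["a", "b", "c"], size=40)
        model = train(x, labels, n_rounds=10)
        for r in model.rules:
            assert np.all(np.abs(r.scores_gt) <= 1.0 + 1e-12)
            assert np.all(np.abs(r.scores_le) <= 1.0 + 1e-12)

    def test_constant_features_rejected(self):
        x = np.ones((10, 2))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="no informative split"):
            train(x, labels)

    def test_nan_features_rejected(self):
        x = np.ones((10, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(x, np.array(["a"] * 5 + ["b"] * 5))


class TestPredict:
    def test_empty_rule_list_gives_first_class(self):
        model = BoostModel(classes=["x", "y"])
        assert list(predict(model, np.zeros((3, 1)))) == ["x"] * 3

    def test_missing_feature_column_named_in_error(self):
        model = BoostModel(classes=["x", "y"], rules=[
            Rule("Solidity", 0.5, np.array([1., -1.]), np.array([-1., 1.]))])
        with pytest.raises(KeyError, match="Solidity"):
            predict(model, pd.DataFrame({"Area": [1.0]}))


class TestRulesFile:
    def test_roundtrip_preserves_predictions(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(120, 5))
        labels = np.where(x[:, 1] - x[:, 3] > 0, "hi", "lo")
        model = train(pd.DataFrame(x, columns=list("abcde")), labels,
                      n_rounds=12)
        back = import_rules(export_rules(model))
        xr = pd.DataFrame(rng.normal(size=(1000, 5)), columns=list("abcde"))
        assert (predict(model, xr) == predict(back, xr)).all()

    def test_hand_written_rules_match_manual_evaluation(self):
        text = ("classes: A, B\n"
                "IF (f > 2, [0.5, -0.5], [-0.5, 0.5])\n"
                "IF (g > 0, [-1, 1], [0.25, -0.25])\n")
        model = import_rules(text)
        df = pd.DataFrame({"f": [3.0, 1.0, 2.5], "g": [-1.0, 1.0, 1.0]})
        # manual score_A: 0.5+0.25=0.75; -0.5-1=-1.5; 0.5-1=-0.5
        assert list(predict(model, df)) == ["A", "B", "B"]

    def test_empty_rules_file_rejected(self):
        with pytest.raises(ValueError):
            import_rules("classes: A, B\n")
        with pytest.raises(ValueError):
            import_rules("")

    def test_malformed_line_reports_line_number(self):
        text = "classes: A, B\nIF (f > 2, [0.5, -0.5], [-0.5, 0.5])\nnot a rule\n"
        with pytest.raises(ValueError, match="line 3"):
            import_rules(text)


class TestEvaluate:
    def test_perfect_model_identity_confusion(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        labels = np.array(["a", "a", "b", "b"])
        model = train(x, labels, n_rounds=1)
        res = evaluate(model, x, labels)
        assert res.accuracy == 1.0
        assert np.all(np.diag(res.confusion.to_numpy()) == [2, 2])

    def test_majority_class_predictor_accuracy(self):
        # a constant rule voting for class "a" on 70/30 data
        model = BoostModel(classes=["a", "b"], rules=[
            Rule("f", 0.0, np.array([1.0, -1.0]), np.array([1.0, -1.0]))])
        labels = np.array(["a"] * 70 + ["b"] * 30)
        res = evaluate(model, pd.DataFrame({"f": np.zeros(100)}), labels)
        assert res.accuracy == pytest.approx(0.7)

    def test_accuracy_tracks_bayes_rate(self):
        # 1-D gaussians N(0,1) vs N(2,1): Bayes rule is x > 1
        rng = np.random.default_rng(4)
        n = 2000
        x_tr = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)][:, None]
        y_tr = np.array(["lo"] * n + ["hi"] * n)
        model = train(x_tr, y_tr, n_rounds=30)
        m = 4000
        x_te = np.r_[rng.normal(0, 1, m), rng.normal(2, 1, m)][:, None]
        y_te = np.array(["lo"] * m + ["hi"] * m)
        acc = evaluate(model, x_te, y_te).accuracy
        bayes_pred = np.where(x_te[:, 0] > 1, "hi", "lo")
        bayes_acc = (bayes_pred == y_te).mean()  # MC estimate of 1-Phi(-1)
        assert abs(acc - bayes_acc) < 0.03
        assert abs(bayes_acc - norm.cdf(1)) < 0.02

    def test_cross_validation_stratified(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 2))
        labels = np.where(x[:, 0] > 0.8, "rare", "common")
        if (labels == "rare").sum() < 5:
            labels[:5] = "rare"
        res = fgboost.cross_validate(x, labels, n_rounds=5, k_folds=5,
                                     seed=0)
        assert res.confusion.to_numpy().sum() == 60


class TestTwoStage:
    def _models(self):
        focus = BoostModel(classes=["InFocus", "OutOfFocus"], rules=[
            Rule("sharpness", 0.5, np.array([1.0, -1.0]),
                 np.array([-1.0, 1.0]))])
        pheno = BoostModel(classes=["Hyper-protrusive", "Spherical"], rules=[
            Rule("solidity", 0.8, np.array([-1.0, 1.0]),
                 np.array([1.0, -1.0]))])
        return focus, pheno

    def test_all_blurred_reach_no_phenotype_stage(self):
        focus, pheno = self._models()
        df = pd.DataFrame({"sharpness": [0.1] * 4, "solidity": [0.9] * 4})
        out = two_stage_classify(df, focus, pheno)
        assert (out["focus_label"] == "OutOfFocus").all()
        assert out["phenotype_label"].isna().all()
        assert len(out) == 4  # flagged, not dropped

    def test_no_blur_retains_all_rows(self):
        focus, pheno = self._models()
        df = pd.DataFrame({"sharpness": [0.9] * 5,
                           "solidity": [0.9, 0.9, 0.5, 0.5, 0.9]})
        out = two_stage_classify(df, focus, pheno)
        assert out["phenotype_label"].notna().all()
        assert list(out["phenotype_label"][:3]) == [
            "Spherical", "Spherical", "Hyper-protrusive"]

    def test_excluded_fraction_matches_truth(self):
        from scipy.stats import binom
        from spherotype import pipeline
        x, labels = pipeline.gallery_feature_table(40, "focus", seed=17)
        focus_model = train(x[pipeline.FOCUS_FEATURES][:60], labels[:60],
                            n_rounds=20)
        pheno = BoostModel(classes=["Hyper-protrusive", "Spherical"], rules=[
            Rule("Solidity", 0.9, np.array([-1.0, 1.0]),
                 np.array([1.0, -1.0]))])
        out = two_stage_classify(x[60:], focus_model, pheno)
        frac = (out["focus_label"] == "OutOfFocus").mean()
        truth_frac = (np.array(labels[60:]) == "OutOfFocus").mean()
        n = len(out)
        lo, hi = binom.interval(0.99, n, truth_frac)
        assert lo <= frac * n <= hi
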