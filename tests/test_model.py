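"""Linear screening classifier: training, prediction, LOO, fixed evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from conftest import synthetic_feature_table
from thermoscreen.errors import TrainingError
from thermoscreen.features import NormalizationStats
from thermoscreen.metrics import ConfusionMatrix, confusion_metrics
from thermoscreen.model import (
    LABEL_POSITIVE,
    LinearModel,
    TrainConfig,
    evaluate_fixed,
    loo_cross_validate,
    predict,
    sensitivity_threshold,
    train,
)


def _identity_stats(features):
    return NormalizationStats(mean={f: 0.0 for f in features}, sd={f: 1.0 for f in features})


def _manual_model(weights, bias, threshold, features=("f1", "f2", "f3")):
    return LinearModel(
        feature_ids=list(features),
        weights=np.asarray(weights, dtype=float),
        bias=bias,
        threshold=threshold,
        normalization=_identity_stats(features),
    )


def naive_loo(table, config=TrainConfig()):
    """Independent brute-force leave-one-out: explicit per-fold refit.

    Deliberately re-implements the fold pipeline with plain sklearn calls and
    python loops, sharing no code with loo_cross_validate.
    """
    tp = tn = fp = fn = 0
    for lesion in table.index:
        rest = table.drop(index=lesion)
        feats = [c for c in rest.columns if c not in ("diagnosis", "dog_id", "tumor_type")]
        mu = {c: rest[c].mean() for c in feats}
        sd = {c: rest[c].to_numpy().std() for c in feats}
        kept = [c for c in feats if sd[c] > 0]
        z = pd.DataFrame({c: (rest[c] - mu[c]) / sd[c] for c in kept})
        y = (rest["diagnosis"] == "malignant").to_numpy(dtype=int)
        corrs = sorted(
            ((abs(float(np.corrcoef(z[c], y)[0, 1])), c) for c in kept if z[c].std() > 0),
            key=lambda rc: (-rc[0], rc[1]),
        )
        sel = [c for _, c in corrs[:3]]
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-8, max_iter=10000)
        clf.fit(z[sel].to_numpy(), y)
        scores = clf.decision_function(z[sel].to_numpy())
        # threshold: max specificity subject to sensitivity floor, ties -> sensitivity
        thr, best = None, (-1.0, -1.0)
        for cand in sorted(set(scores)):
            sens = sum(s >= cand for s, yy in zip(scores, y) if yy == 1) / max((y == 1).sum(), 1)
            if sens < config.min_sensitivity - 1e-12:
                continue
            spec = sum(s < cand for s, yy in zip(scores, y) if yy == 0) / max((y == 0).sum(), 1)
            if (spec, sens) > best:
                best, thr = (spec, sens), cand
        x_hold = np.array([(table.loc[lesion, c] - mu[c]) / sd[c] for c in sel])
        flag = float(clf.decision_function(x_hold[None, :])[0]) >= thr
        truth = table.loc[lesion, "diagnosis"] == "malignant"
        tp += flag and truth
        fp += flag and not truth
        fn += (not flag) and truth
        tn += (not flag) and not truth
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


class TestTrain:
    def test_separable_cohort_perfect_training_fit(self):
        table = synthetic_feature_table(60, seed=1, effect=1.0, signal_sd=0.01)
        model = train(table)
        cm, _ = evaluate_fixed(model, table)
        m = confusion_metrics(cm)
        assert m.sensitivity == 1.0
        assert m.specificity == 1.0

    def test_signal_feature_gets_positive_weight(self):
        # malignant lesions have the larger differential decay rate
        table = synthetic_feature_table(120, seed=2)
        model = train(table)
        assert "cool_rate_diff" in model.feature_ids
        w = model.weights[model.feature_ids.index("cool_rate_diff")]
        assert w > 0

    def test_min_sensitivity_monotone(self):
        table = synthetic_feature_table(120, seed=3, effect=0.05)
        last = -1.0
        for ms in (0.6, 0.75, 0.9, 1.0):
            model = train(table, TrainConfig(min_sensitivity=ms))
            cm, _ = evaluate_fixed(model, table)
            sens = confusion_metrics(cm).sensitivity
            assert sens >= ms
            assert sens >= last
            last = sens

    def test_single_class_rejected(self):
        table = synthetic_feature_table(30, seed=4)
        table["diagnosis"] = "benign"
        with pytest.raises(TrainingError):
            train(table)

    def test_model_round_trips_through_json(self, tmp_path):
        table = synthetic_feature_table(60, seed=5)
        model = train(table)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = LinearModel.load(path)
        np.testing.assert_array_equal(loaded.weights, model.weights)
        assert loaded.feature_ids == model.feature_ids
        assert loaded.threshold == model.threshold
        cm1, p1 = evaluate_fixed(model, table)
        cm2, p2 = evaluate_fixed(loaded, table)
        assert cm1 == cm2
        np.testing.assert_allclose(p1["score"], p2["score"], atol=1e-12)


class TestPredict:
    def test_score_below_threshold_is_benign(self):
        model = _manual_model([1, 0, 0], 0.0, 0.5)
        row = pd.DataFrame({"f1": [0.4], "f2": [0.0], "f3": [0.0]}, index=["L0"])
        out = predict(model, row)
        assert out.loc["L0", "score"] == pytest.approx(0.4)
        assert out.loc["L0", "label"] == "benign"

    def test_score_at_threshold_flagged(self):
        model = _manual_model([1, 0, 0], 0.0, 0.5)
        row = pd.DataFrame({"f1": [0.5], "f2": [0.0], "f3": [0.0]}, index=["L0"])
        assert predict(model, row).loc["L0", "label"] == LABEL_POSITIVE

    def test_constant_positive_score_flags_everything(self):
        model = _manual_model([0, 0, 0], 1.0, 0.0)
        rows = pd.DataFrame(
            {"f1": [0, 1, 2], "f2": [0, 0, 0], "f3": [5, -5, 0]}, index=["a", "b", "c"]
        )
        assert (predict(model, rows)["label"] == LABEL_POSITIVE).all()

    def test_missing_feature_rejected(self):
        model = _manual_model([1, 0, 0], 0.0, 0.5)
        with pytest.raises(Exception):
            predict(model, pd.DataFrame({"f1": [0.1], "f2": [0.0]}))


class TestThreshold:
    def test_threshold_monotonicity_on_fixed_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 1, 300)
        y = (rng.random(300) < 0.3).astype(int)
        last_sens, last_spec = 2.0, -1.0
        for thr in np.linspace(-3, 3, 61):
            pred = scores >= thr
            sens = (pred & (y == 1)).sum() / (y == 1).sum()
            spec = (~pred & (y == 0)).sum() / (y == 0).sum()
            assert sens <= last_sens + 1e-12
            assert spec >= last_spec - 1e-12
            last_sens, last_spec = sens, spec

    def test_sensitivity_threshold_achieves_target(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 200)
        y = (rng.random(200) < 0.25).astype(int)
        for ms in (0.5, 0.85, 1.0):
            thr = sensitivity_threshold(scores, y, ms)
            sens = ((scores >= thr) & (y == 1)).sum() / (y == 1).sum()
            assert sens >= ms


class TestLeaveOneOut:
    def test_one_prediction_per_lesion(self):
        table = synthetic_feature_table(30, seed=6)
        cm, preds = loo_cross_validate(table)
        assert len(preds) == 30
        assert cm.total == 30

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_bruteforce_oracle(self, seed):
        table = synthetic_feature_table(30, seed=100 + seed, effect=0.05)
        cm, _ = loo_cross_validate(table)
        assert cm == naive_loo(table)

    def test_duplicated_lesions_recover_training_fit_accuracy(self):
        table = synthetic_feature_table(40, seed=8, effect=0.05)
        model = train(table)
        cm_fit, _ = evaluate_fixed(model, table)
        doubled = pd.concat([table, table.set_index(table.index + "_dup")])
        cm_loo, _ = loo_cross_validate(doubled)
        acc_fit = confusion_metrics(cm_fit).accuracy
        acc_loo = confusion_metrics(cm_loo).accuracy
        assert acc_loo >= acc_fit - 1e-12

    def test_dog_grouped_loo_runs(self):
        table = synthetic_feature_table(40, seed=9)
        cm, preds = loo_cross_validate(table, TrainConfig(group_by_dog=True))
        assert cm.total == 40

    def test_fold_losing_a_class_flagged(self):
        table = synthetic_feature_table(20, seed=10)
        table["diagnosis"] = ["malignant"] + ["benign"] * 19
        cm, preds = loo_cross_validate(table)
        assert preds["flagged"].sum() == 1
        assert cm.total == 19


class TestFixedEvaluation:
    def test_pure_function_of_model_and_table(self):
        table = synthetic_feature_table(50, seed=11)
        model = train(table)
        cm1, p1 = evaluate_fixed(model, table)
        cm2, p2 = evaluate_fixed(model, table)
        assert cm1 == cm2
        np.testing.assert_allclose(p1["score"], p2["score"], atol=1e-12)

    def test_row_order_invariance(self):
        table = synthetic_feature_table(50, seed=12)
        model = train(table)
        cm1, _ = evaluate_fixed(model, table)
        shuffled = table.sample(frac=1.0, random_state=0)
        cm2, _ = evaluate_fixed(model, shuffled)
        assert cm1 == cm2

    def test_bayes_rate_recovery_as_n_grows(self):
        """With a single-feature Gaussian signal the best achievable accuracy
        is known in closed form; LOO accuracy should approach it with n."""
        from scipy.stats import norm

        effect, sd, prevalence = 0.06, 0.03, 0.25
        # Bayes rule for equal-variance Gaussians: threshold where posterior
        # odds = 1; accuracy = pi*P(x>c|mal) + (1-pi)*P(x<c|ben)
        c = effect / 2 + (sd**2 / effect) * np.log((1 - prevalence) / prevalence)
        bayes_acc = prevalence * (1 - norm.cdf(c, effect, sd)) + (1 - prevalence) * norm.cdf(
            c, 0, sd
        )
        gaps = {}
        for n in (100, 400):
            table = synthetic_feature_table(
                n, seed=13, effect=effect, signal_sd=sd, prevalence=prevalence
            )
            cm, _ = loo_cross_validate(table, TrainConfig(min_sensitivity=0.5))
            gaps[n] = abs(confusion_metrics(cm).accuracy - bayes_acc)
        assert gaps[400] < 0.1
        assert gaps[400] <= gaps[100] + 0.05
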