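"""Forest training, prediction, metrics, baselines, leakage and subtype protocols."""

import numpy as np
import pandas as pd
import pytest

from flyp.classifier import (FLYPModel, covariate_baseline, evaluate,
                             leave_one_subtype_out, misclassification_analysis,
                             predict_flyp, train_flyp)

FAST = dict(cv_repeats=1, cv_folds=5, tune_budget=4, n_estimators=100)


@pytest.fixture(scope="module")
def three_class_data():
    gen = np.random.default_rng(8)
    n_per = 30
    X = pd.DataFrame(gen.normal(0, 1, (3 * n_per, 10)),
                     index=[f"s{i}" for i in range(3 * n_per)],
                     columns=[f"cg{i}" for i in range(10)])
    labels = pd.Series(["control"] * n_per + ["NHL_hi"] * n_per + ["NHL_lo"] * n_per,
                       index=X.index)
    X.iloc[n_per:2 * n_per, :5] += 2.0
    X.iloc[2 * n_per:, 5:] += 2.0
    return X, labels


class TestTrainPredict:
    def test_probabilities_sum_to_one_and_labels_argmax(self, three_class_data):
        X, labels = three_class_data
        model = train_flyp(X, labels, seed=1, **FAST)
        pred = predict_flyp(model, X.T)
        proba = pred[["p_control", "p_NHL_hi", "p_NHL_lo"]]
        assert np.abs(proba.sum(axis=1) - 1.0).max() < 1e-9
        argmax = proba.columns[np.argmax(proba.to_numpy(), axis=1)]
        assert (pred["label"] == pd.Index([c[2:] for c in argmax])).all()
        assert np.allclose(pred["risk"], pred["p_NHL_hi"] + pred["p_NHL_lo"])

    def test_save_load_bit_identical(self, three_class_data, tmp_path):
        X, labels = three_class_data
        model = train_flyp(X, labels, seed=1, **FAST)
        pred1 = predict_flyp(model, X.T)
        model.save(tmp_path / "model.joblib")
        model2 = FLYPModel.load(tmp_path / "model.joblib")
        pred2 = predict_flyp(model2, X.T)
        pd.testing.assert_frame_equal(pred1, pred2)
        assert model2.features == model.features and model2.best_mtry == model.best_mtry

    def test_missing_model_cpgs_error_and_imputation(self, three_class_data):
        X, labels = three_class_data
        model = train_flyp(X, labels, seed=1, **FAST)
        partial = X.drop(columns=["cg0"])
        with pytest.raises(KeyError, match="cg0"):
            predict_flyp(model, partial)
        pred = predict_flyp(model, partial, impute_missing=True)
        assert len(pred) == len(X)

    def test_shuffled_labels_near_chance(self, three_class_data):
        X, labels = three_class_data
        gen = np.random.default_rng(3)
        train = X.index[:60]
        test = X.index[60:]
        shuffled = pd.Series(gen.permutation(labels.to_numpy()), index=labels.index)
        model = train_flyp(X.loc[train], shuffled.loc[train], seed=2,
                           cv_repeats=1, cv_folds=3, tune_budget=3, n_estimators=100)
        pred = predict_flyp(model, X.loc[test].T)
        acc = (pred["label"] == shuffled.loc[test]).mean()
        # three balanced classes: chance 1/3, binomial 3-sigma band at n=30
        assert acc < 1 / 3 + 3 * np.sqrt((1 / 3) * (2 / 3) / len(test))

    def test_strong_signal_high_accuracy(self, three_class_data):
        X, labels = three_class_data
        train = list(X.index[::2])
        test = list(X.index[1::2])
        model = train_flyp(X.loc[train], labels.loc[train], seed=4, **FAST)
        pred = predict_flyp(model, X.loc[test].T)
        assert (pred["label"] == labels.loc[test]).mean() >= 0.9

    def test_small_class_vs_folds_error(self, three_class_data):
        X, labels = three_class_data
        few = list(X.index[:32])
        with pytest.raises(ValueError, match="folds"):
            train_flyp(X.loc[few], labels.loc[few], cv_folds=10, seed=0)

    def test_protocol_defaults(self):
        """Resampling defaults: 3 repeats of 10-fold CV, 30 tuning candidates."""
        import inspect
        sig = inspect.signature(train_flyp)
        assert sig.parameters["cv_repeats"].default == 3
        assert sig.parameters["cv_folds"].default == 10
        assert sig.parameters["tune_budget"].default == 30


class TestEvaluate:
    def test_confusion_8_2_hand_metrics(self):
        idx = [f"s{i}" for i in range(20)]
        y_true = pd.Series(["case"] * 10 + ["control"] * 10, index=idx)
        y_pred = pd.Series(["case"] * 8 + ["control"] * 2
                           + ["control"] * 8 + ["case"] * 2, index=idx)
        rep = evaluate(y_true, y_pred)
        for lv in ("case", "control"):
            assert rep.per_class.loc[lv, "sensitivity"] == pytest.approx(0.8)
            assert rep.per_class.loc[lv, "specificity"] == pytest.approx(0.8)
            assert rep.per_class.loc[lv, "f1"] == pytest.approx(0.8)
        assert rep.confusion.loc["case", "case"] == 8
        assert rep.confusion.sum(axis=1).tolist() == [10, 10]

    def test_perfect_predictions(self, three_class_data):
        X, labels = three_class_data
        rep = evaluate(labels, labels.copy())
        assert rep.accuracy == 1.0
        assert (rep.per_class[["sensitivity", "specificity", "f1"]] == 1.0).all().all()
        assert rep.stratum_accuracy == {"NHL_hi": 1.0, "NHL_lo": 1.0}

    def test_f1_formula_matches_hand_computation(self, rng):
        """F1 = 2*precision*recall/(precision+recall) on random confusion tables."""
        for _ in range(10):
            tp, fn, fp, tn = rng.integers(1, 50, 4)
            idx = range(tp + fn + fp + tn)
            y_true = pd.Series(["pos"] * (tp + fn) + ["neg"] * (fp + tn), index=idx)
            y_pred = pd.Series(["pos"] * tp + ["neg"] * fn + ["pos"] * fp
                               + ["neg"] * tn, index=idx)
            rep = evaluate(y_true, y_pred)
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
            assert rep.per_class.loc["pos", "f1"] == pytest.approx(
                2 * precision * recall / (precision + recall))

    def test_random_scores_auc_near_half(self, rng):
        n = 1000
        idx = [f"s{i}" for i in range(n)]
        y_true = pd.Series(rng.choice(["pos", "neg"], n), index=idx)
        p_pos = rng.uniform(0, 1, n)
        proba = pd.DataFrame({"p_pos": p_pos, "p_neg": 1 - p_pos}, index=idx)
        y_pred = pd.Series(np.where(p_pos > 0.5, "pos", "neg"), index=idx)
        rep = evaluate(y_true, y_pred, proba=proba)
        assert rep.per_class.loc["pos", "auc"] == pytest.approx(0.5, abs=0.05)


class TestBaselineAndLeakage:
    def test_covariate_baseline_null_near_chance(self, small_cohort):
        """Covariates independent of the outcome give ~chance accuracy."""
        pheno, truth = small_cohort["pheno"], small_cohort["truth"]
        gen = np.random.default_rng(0)
        labels = pd.Series(gen.permutation(
            ["control"] * 40 + ["NHL_hi"] * 20 + ["NHL_lo"] * 20), index=pheno.index)
        train = list(pheno.index[::2])
        test = list(pheno.index[1::2])
        _, rep = covariate_baseline(pheno, truth.true_fractions, labels, train, test,
                                    seed=0, cv_repeats=1, cv_folds=4, tune_budget=3,
                                    n_estimators=100)
        assert rep.accuracy < 0.5 + 3 * np.sqrt(0.25 / len(test))

    def test_feature_set_ignores_test_labels(self, small_cohort):
        """Moving a test sample's label must not change the selected features."""
        from flyp.selection import elastic_net_condense, moderated_lm, threshold_stage1
        from flyp.preprocess import beta_to_m
        beta, pheno = small_cohort["beta"], small_cohort["pheno"]
        m = beta_to_m(beta)
        labels = pheno["outcome"].copy()
        train = list(beta.columns[:60])
        test = list(beta.columns[60:])

        def select(lbl):
            dm = moderated_lm(m[train], lbl.loc[train])
            surv = threshold_stage1(dm, mode="bh_fdr", level=0.05)
            return elastic_net_condense(m.loc[surv, train], lbl.loc[train],
                                        alpha=0.5, folds=5, seed=1).cpgs

        flipped = labels.copy()
        flipped[test[0]] = ("control" if flipped[test[0]] == "future_NHL"
                            else "future_NHL")
        assert select(labels) == select(flipped)


class TestSubtypesAndMisclassification:
    def test_leave_one_subtype_out_shared_signal(self, small_cohort):
        """Shared causal CpGs across subtypes -> held-out subtypes beat chance."""
        from flyp.preprocess import beta_to_m
        beta, pheno = small_cohort["beta"], small_cohort["pheno"]
        m = beta_to_m(beta)
        labels = pheno["outcome"]
        reports = leave_one_subtype_out(
            m, pheno, labels, seed=0, selection_mode="bh_fdr", selection_level=0.05,
            enet_folds=4, cv_repeats=1, cv_folds=3, tune_budget=3, n_estimators=100)
        assert len(reports) >= 2
        accs = [r.accuracy for r in reports.values()]
        assert np.mean(accs) > 0.6   # chance is ~0.5 with proportional controls

    def test_misclassification_detects_low_clock_weak_effects(self):
        """Cases with weaker (low-clock) effects are the ones the model misses."""
        from flyp.simulate import SimConfig, generate_cohort, generate_reference_profiles
        from flyp.preprocess import beta_to_m
        from flyp.clocks import epitoc_score
        from flyp.selection import moderated_lm, threshold_stage1
        cfg = SimConfig(n_cpgs=2500, n_samples_per_class=60, n_causal_cpgs=60,
                        n_clock_cpgs=80, n_discriminative_per_type=20,
                        delta_beta=0.12, clock_effect_coupling=1.0, noise_sd=0.1,
                        batch_sd=0.0, seed=23)
        refs = generate_reference_profiles(cfg)
        beta, pheno, ann, truth = generate_cohort(cfg, refs)
        m = beta_to_m(beta)
        scores = epitoc_score(beta, truth.clock_cpg_ids)
        labels = pheno["outcome"]
        train = list(beta.columns[::2])
        test = list(beta.columns[1::2])
        dm = moderated_lm(m[train], labels.loc[train])
        surv = threshold_stage1(dm, mode="bh_fdr", level=0.05)
        model = train_flyp(m.loc[surv, train].T, labels.loc[train], seed=1,
                           cv_repeats=1, cv_folds=4, tune_budget=3, n_estimators=150)
        pred = predict_flyp(model, m.loc[surv, test])
        out = misclassification_analysis(labels.loc[test], pred["label"], scores,
                                         age=pheno["age"])
        if out is not None:   # needs at least one error of each kind
            raw = out.loc["epitoc_raw"]
            assert raw["misclassified_median"] < raw["correct_median"]

    def test_all_correct_analysis_skipped(self, three_class_data):
        X, labels = three_class_data
        scores = pd.Series(0.2, index=X.index)
        assert misclassification_analysis(labels, labels.copy(), scores) is None
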