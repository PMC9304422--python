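"""Three-class random-forest risk score (FLYP) and its evaluation protocols.

The classifier is a random forest over the elastic-net-selected CpG M
values with the three-level outcome {control, NHL_hi, NHL_lo}. The only
tuned hyperparameter is the per-split feature count (mtry), chosen by
repeated stratified cross-validation accuracy over a caret-style grid of
up to ``tune_budget`` candidate values; the final forest is refit on the
full training data. The per-subject FLYP score is the predicted class
probability vector, with P(NHL_hi) + P(NHL_lo) reported as a scalar risk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .selection import elastic_net_condense, moderated_lm, threshold_stage1
from .vocab import CLASS_LEVELS

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class FLYPModel:
    """A trained forest with its frozen feature order and class levels."""

    forest: RandomForestClassifier
    features: list[str]
    classes: list[str]
    seed: int
    n_estimators: int
    best_mtry: int
    tuning: pd.DataFrame = field(repr=False, default=None)
    feature_means: pd.Series = field(repr=False, default=None)

    def save(self, path) -> None:
        """Serialize to a single archive (JSON metadata + pickled trees)."""
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "metadata": json.dumps({
                "features": self.features,
                "classes": self.classes,
                "seed": self.seed,
                "n_estimators": self.n_estimators,
                "best_mtry": self.best_mtry,
            }, sort_keys=True),
            "forest": self.forest,
            "tuning": self.tuning,
            "feature_means": self.feature_means,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "FLYPModel":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {payload.get('format_version')}")
        meta = json.loads(payload["metadata"])
        return cls(forest=payload["forest"], features=meta["features"],
                   classes=meta["classes"], seed=meta["seed"],
                   n_estimators=meta["n_estimators"], best_mtry=meta["best_mtry"],
                   tuning=payload.get("tuning"), feature_means=payload.get("feature_means"))


@dataclass
class MetricsReport:
    """Per-class and per-stratum performance summary."""

    accuracy: float
    confusion: pd.DataFrame                 # rows = truth, columns = predicted
    per_class: pd.DataFrame                 # sensitivity/specificity/F1/AUC per class
    stratum_accuracy: dict[str, float]      # NHL_hi-vs-control, NHL_lo-vs-control
    n_per_class: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.to_dict(),
            "per_class": self.per_class.to_dict(),
            "stratum_accuracy": self.stratum_accuracy,
            "n_per_class": self.n_per_class,
        }


def _mtry_grid(n_features: int, tune_budget: int) -> list[int]:
    """caret-style grid: up to ``tune_budget`` distinct mtry values from 2..p."""
    if n_features <= 2:
        return [max(1, n_features)]
    if n_features <= tune_budget:
        return list(range(1, n_features + 1))
    grid = np.unique(np.round(np.linspace(2, n_features, tune_budget)).astype(int))
    return grid.tolist()


def _ordered_levels(labels: pd.Series) -> list[str]:
    present = list(pd.unique(labels.astype(str)))
    if set(present) <= set(CLASS_LEVELS):
        return [lv for lv in CLASS_LEVELS if lv in present]
    return sorted(present)


def train_flyp(x: pd.DataFrame, labels: pd.Series, cv_repeats: int = 3,
               cv_folds: int = 10, tune_budget: int = 30,
               n_estimators: int = 300, tune_n_estimators: int | None = 150,
               seed: int = 0) -> FLYPModel:
    """Tune mtry by repeated CV accuracy and refit the forest on all data.

    ``x`` is samples x features (M values of the selected CpGs). The
    resampling scheme defaults to three separate 10-fold cross-validations
    with up to 30 candidate parameter values. Tuning forests use
    ``tune_n_estimators`` trees (CV rank of mtry stabilises well below the
    final forest size); the chosen model is refit with ``n_estimators``.
    All randomness (fold assignment, tree bootstraps) derives from ``seed``.
    """
    if x.shape[1] == 0:
        raise ValueError("feature matrix is empty")
    labels = labels.loc[x.index].astype(str)
    levels = _ordered_levels(labels)
    if len(levels) < 2:
        raise ValueError("need at least two classes to train")
    counts = labels.value_counts()
    if (counts < cv_folds).any():
        small = counts[counts < cv_folds]
        raise ValueError(
            f"class(es) {dict(small)} have fewer members than cv_folds={cv_folds}; "
            "use fewer folds")

    xv = x.to_numpy(float)
    yv = labels.to_numpy()
    grid = _mtry_grid(x.shape[1], tune_budget)
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats,
                                 random_state=seed)
    splits = list(cv.split(xv, yv))
    tune_trees = min(n_estimators, tune_n_estimators or n_estimators)
    records = []
    for mtry in grid:
        correct = total = 0
        for fold_i, (tr, va) in enumerate(splits):
            forest = RandomForestClassifier(
                n_estimators=tune_trees, max_features=mtry,
                random_state=(seed * 100_003 + fold_i) % (2 ** 31))
            forest.fit(xv[tr], yv[tr])
            correct += int((forest.predict(xv[va]) == yv[va]).sum())
            total += len(va)
        records.append({"mtry": mtry, "cv_accuracy": correct / total})
    tuning = pd.DataFrame(records)
    best_mtry = int(tuning.sort_values(["cv_accuracy", "mtry"],
                                       ascending=[False, True]).iloc[0]["mtry"])
    forest = RandomForestClassifier(n_estimators=n_estimators, max_features=best_mtry,
                                    random_state=seed)
    forest.fit(xv, yv)
    logger.info("train_flyp: best mtry %d (cv accuracy %.3f) over %d candidates",
                best_mtry, tuning["cv_accuracy"].max(), len(grid))
    return FLYPModel(forest=forest, features=list(x.columns), classes=levels,
                     seed=seed, n_estimators=n_estimators, best_mtry=best_mtry,
                     tuning=tuning, feature_means=x.mean(axis=0))


def predict_flyp(model: FLYPModel, m: pd.DataFrame, impute_missing: bool = False) -> pd.DataFrame:
    """Score new samples: per-class probabilities, hard label, scalar risk.

    ``m`` may be a CpG x sample matrix or a samples x features table. All
    model CpGs must be present unless ``impute_missing`` fills absentees
    with the training means. Ties in probability break in fixed class order
    (control, NHL_hi, NHL_lo).
    """
    cpg_oriented = all(f in m.index for f in model.features)
    if cpg_oriented:
        x = m.loc[model.features].T            # CpG x sample orientation
    else:
        missing = [f for f in model.features if f not in m.columns]
        if missing and not impute_missing:
            raise KeyError(f"missing model CpGs: {missing[:10]}"
                           + (f" ... ({len(missing)} total)" if len(missing) > 10 else ""))
        x = m.reindex(columns=model.features)
        if missing:
            x[missing] = x[missing].fillna(model.feature_means[missing])
        x = x[model.features]
    proba = model.forest.predict_proba(x.to_numpy(float))
    cols = list(model.forest.classes_)
    proba_df = pd.DataFrame(proba, index=x.index, columns=cols)
    ordered = [c for c in CLASS_LEVELS if c in cols] + [c for c in cols if c not in CLASS_LEVELS]
    proba_df = proba_df[ordered]
    hard = proba_df.columns[np.argmax(proba_df.to_numpy(), axis=1)]
    out = proba_df.add_prefix("p_")
    out["label"] = hard
    risk_cols = [c for c in ("p_NHL_hi", "p_NHL_lo") if c in out.columns]
    out["risk"] = out[risk_cols].sum(axis=1) if risk_cols else np.nan
    return out


def evaluate(y_true: pd.Series, y_pred: pd.Series, proba: pd.DataFrame | None = None) -> MetricsReport:
    """One-vs-rest sensitivity/specificity/F1 (+AUC with probabilities),
    the confusion matrix, and per-stratum accuracies.

    The stratum accuracy for NHL_hi is the plain accuracy restricted to
    samples whose truth is NHL_hi or control (and likewise for NHL_lo),
    so a case predicted into the other stratum counts as an error.
    """
    y_true = y_true.astype(str)
    y_pred = y_pred.loc[y_true.index].astype(str)
    levels = _ordered_levels(y_true)
    extra = set(y_pred.unique()) - set(levels)
    if extra:
        levels = levels + sorted(extra)
    confusion = pd.crosstab(y_true, y_pred).reindex(index=levels, columns=levels,
                                                    fill_value=0)
    confusion.index.name, confusion.columns.name = "truth", "predicted"
    accuracy = float((y_true == y_pred).mean())

    rows = {}
    for lv in levels:
        tp = int(((y_true == lv) & (y_pred == lv)).sum())
        fn = int(((y_true == lv) & (y_pred != lv)).sum())
        fp = int(((y_true != lv) & (y_pred == lv)).sum())
        tn = int(((y_true != lv) & (y_pred != lv)).sum())
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        precision = tp / (tp + fp) if tp + fp else np.nan
        f1 = (2 * precision * sens / (precision + sens)
              if precision and sens and (precision + sens) > 0 else
              (0.0 if (tp + fn and tp + fp) else np.nan))
        auc = np.nan
        if proba is not None and f"p_{lv}" in proba.columns and y_true.nunique() > 1:
            truth_bin = (y_true == lv).astype(int)
            if truth_bin.nunique() > 1:
                auc = float(roc_auc_score(truth_bin, proba.loc[y_true.index, f"p_{lv}"]))
        rows[lv] = {"sensitivity": sens, "specificity": spec, "f1": f1, "auc": auc}
    per_class = pd.DataFrame(rows).T

    stratum_accuracy = {}
    for lv in ("NHL_hi", "NHL_lo"):
        if lv in levels and "control" in levels:
            mask = y_true.isin([lv, "control"])
            if mask.any():
                stratum_accuracy[lv] = float((y_true[mask] == y_pred[mask]).mean())
    return MetricsReport(accuracy=accuracy, confusion=confusion, per_class=per_class,
                         stratum_accuracy=stratum_accuracy,
                         n_per_class={lv: int((y_true == lv).sum()) for lv in levels})


def covariate_baseline(pheno: pd.DataFrame, fractions: pd.DataFrame,
                       labels: pd.Series, train_samples, test_samples,
                       seed: int = 0, **train_kwargs):
    """Identical forest protocol on covariates only (age, sex, BMI, fractions).

    Returns ``(model, MetricsReport)`` for comparison with the CpG model.
    """
    feats = pd.DataFrame(index=pheno.index)
    feats["age"] = pheno["age"].astype(float)
    feats["sex"] = (pheno["sex"].astype(str) == "M").astype(float)
    if "bmi" in pheno.columns:
        feats["bmi"] = pd.to_numeric(pheno["bmi"], errors="coerce").fillna(
            pd.to_numeric(pheno["bmi"], errors="coerce").mean())
    feats = feats.join(fractions.loc[pheno.index])
    train_samples = pd.Index(train_samples)
    test_samples = pd.Index(test_samples)
    model = train_flyp(feats.loc[train_samples], labels.loc[train_samples],
                       seed=seed, **train_kwargs)
    pred = predict_flyp(model, feats.loc[test_samples])
    report = evaluate(labels.loc[test_samples], pred["label"],
                      proba=pred[[c for c in pred.columns if c.startswith("p_")]])
    return model, report


def leave_one_subtype_out(m: pd.DataFrame, pheno: pd.DataFrame, labels: pd.Series,
                          seed: int = 0, selection_mode: str = "fixed_p",
                          selection_level: float = 0.05, enet_alpha: float = 0.5,
                          enet_folds: int = 5, covariates: pd.DataFrame | None = None,
                          **train_kwargs) -> dict[str, MetricsReport]:
    """Train the full pipeline on all-but-one subtype; test on the held-out one.

    For each case subtype s: training samples are the cases of every other
    subtype plus a proportional, seed-controlled random share of controls;
    the test set is the subtype-s cases plus the held-out controls. The
    whole selection (stage 1 + elastic net) reruns inside each training set.
    """
    labels = labels.loc[m.columns].astype(str)
    subtype = pheno.loc[m.columns, "subtype"].astype(str)
    case_mask = pheno.loc[m.columns, "outcome"] == "future_NHL"
    subtypes = sorted(s for s in subtype[case_mask].unique() if s != "none")
    if len(subtypes) < 2:
        raise ValueError("need at least two case subtypes")
    controls = np.asarray(m.columns[~case_mask])
    rng = np.random.default_rng(seed)
    reports: dict[str, MetricsReport] = {}
    for s in subtypes:
        test_cases = m.columns[case_mask & (subtype == s)]
        train_cases = m.columns[case_mask & (subtype != s)]
        ctrl_perm = rng.permutation(controls)
        n_test_ctrl = max(1, int(round(len(controls) * len(test_cases) / case_mask.sum())))
        test_ctrl, train_ctrl = ctrl_perm[:n_test_ctrl], ctrl_perm[n_test_ctrl:]
        train_idx = list(train_cases) + list(train_ctrl)
        test_idx = list(test_cases) + list(test_ctrl)

        dm = moderated_lm(m[train_idx], labels.loc[train_idx],
                          covariates=None if covariates is None else covariates.loc[train_idx])
        survivors = threshold_stage1(dm, mode=selection_mode, level=selection_level)
        if not survivors:
            logger.warning("leave_one_subtype_out(%s): no stage-1 survivors; skipped", s)
            continue
        features = elastic_net_condense(m.loc[survivors, train_idx],
                                        labels.loc[train_idx], alpha=enet_alpha,
                                        folds=enet_folds, seed=seed)
        model = train_flyp(m.loc[features.cpgs, train_idx].T, labels.loc[train_idx],
                           seed=seed, **train_kwargs)
        pred = predict_flyp(model, m.loc[features.cpgs, test_idx])
        reports[s] = evaluate(labels.loc[test_idx], pred["label"],
                              proba=pred[[c for c in pred.columns if c.startswith("p_")]])
    return reports


def misclassification_analysis(y_true: pd.Series, y_pred: pd.Series,
                               scores: pd.Series, age: pd.Series | None = None):
    """Do misclassified cases have different clock scores than correct ones?

    Compares epiTOC between correctly and incorrectly classified cases by
    two-sided rank-sum, raw and (when ``age`` is given) after residualising
    the scores on age. Returns None with a log message when either group is
    empty (e.g. a perfect classifier).
    """
    y_true = y_true.astype(str)
    cases = y_true.index[y_true != "control"]
    if len(cases) == 0:
        logger.info("misclassification_analysis: no cases to analyse")
        return None
    correct = y_pred.loc[cases].astype(str) == y_true.loc[cases]
    if correct.all() or (~correct).all():
        logger.info("misclassification_analysis: all cases %s classified; skipped",
                    "correctly" if correct.all() else "incorrectly")
        return None
    rows = []
    variants = [("epitoc_raw", scores.loc[cases])]
    if age is not None:
        a = age.loc[cases].astype(float)
        s = scores.loc[cases].astype(float)
        slope, intercept = np.polyfit(a, s, 1)
        variants.append(("epitoc_age_adjusted", s - (intercept + slope * a)))
    for name, values in variants:
        x = values[correct].to_numpy(float)
        y = values[~correct].to_numpy(float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"variable": name,
                     "correct_median": float(np.median(x)),
                     "misclassified_median": float(np.median(y)),
                     "statistic": float(res.statistic),
                     "p_value": float(res.pvalue),
                     "n_correct": len(x), "n_misclassified": len(y)})
    return pd.DataFrame(rows).set_index("variable")
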