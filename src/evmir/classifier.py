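"""Diagnostic classification of ALS vs healthy controls on dCq features.

Three orthogonal designs, matching the study's evaluation scheme:

* ``logistic_80_20`` — maximum-likelihood logistic regression on all
  eight fingerprint dCq features, random stratified 80/20 split,
  seed 375; coefficient table with deviance bookkeeping, held-out
  metric panel and ROC/AUC;
* ``forest_79_21`` — random forest on a 79/21 split, seed 375, with
  iterative removal of the least important feature, keeping the subset
  with the best held-out accuracy (ties favour fewer features);
* ``forest_cross_cohort`` — random forest trained wholly on one cohort
  and evaluated wholly on an independent one (seed 101), features
  aligned by miRNA name.

Metric conventions: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), accuracy, F1 — all reported as
percentages; AUC via the rank (Mann-Whitney) formulation with ties
contributing one half.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .errors import AlignmentError, StratificationError, ValidationError

POSITIVE_LABEL = "ALS"
DEFAULT_N_TREES = 500


@dataclass
class SplitPlan:
    design_id: str
    fraction: float
    seed: int
    stratified: bool
    train_ids: list[str]
    test_ids: list[str]


@dataclass
class ClassifierReport:
    design_id: str
    seed: int
    features: list[str]
    n_train: int
    n_test: int
    confusion: dict[str, int]  # tp, fp, tn, fn
    metrics: dict[str, float | None]  # percentages; None = not applicable
    auc: float | None
    roc_points: pd.DataFrame | None = None
    importances: pd.Series | None = None  # forest designs
    coefficients: pd.DataFrame | None = None  # logistic design
    deviance: dict[str, float] | None = None  # logistic design
    separation_flag: bool = False
    notes: list[str] = field(default_factory=list)


def stratified_split(
    sample_ids: Sequence[str],
    labels: Sequence[str],
    fraction: float,
    seed: int,
    design_id: str = "split",
) -> SplitPlan:
    """Deterministic stratified split; train size = ceil(fraction * n).

    Per-class train counts are allocated by largest remainder so the
    total matches the ceiling rule exactly.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    ids = np.asarray(sample_ids)
    labs = np.asarray(labels)
    if len(ids) != len(labs):
        raise ValidationError("sample_ids and labels differ in length")
    classes, counts = np.unique(labs, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("need two classes to stratify")
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise StratificationError(f"class {small!r} has fewer than 2 members")

    n = len(ids)
    n_train = math.ceil(fraction * n)
    ideal = {c: fraction * k for c, k in zip(classes, counts)}
    take = {c: int(math.floor(v)) for c, v in ideal.items()}
    remainder = n_train - sum(take.values())
    order = sorted(classes, key=lambda c: ideal[c] - take[c], reverse=True)
    for c in order[:remainder]:
        take[c] += 1

    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for c in classes:
        members = ids[labs == c]
        perm = rng.permutation(len(members))
        k = min(take[c], len(members))
        train_ids.extend(members[perm[:k]])
        test_ids.extend(members[perm[k:]])
    return SplitPlan(
        design_id=design_id,
        fraction=fraction,
        seed=seed,
        stratified=True,
        train_ids=train_ids,
        test_ids=test_ids,
    )


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    """Metric panel in percentages; zero-denominator metrics are None."""
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValidationError("counts must be >= 0 with a positive sum")

    def pct(num: float, den: float) -> float | None:
        return None if den == 0 else 100.0 * num / den

    sens = pct(tp, tp + fn)
    spec = pct(tn, tn + fp)
    ppv = pct(tp, tp + fp)
    npv = pct(tn, tn + fn)
    acc = pct(tp + tn, tp + fp + tn + fn)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f1 = None
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "accuracy": acc,
        "f1": f1,
    }


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> tuple[float, pd.DataFrame]:
    """AUC by the rank formulation (ties count one half) plus curve points."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both labels must be present for ROC")
    ranks = rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    tps = np.cumsum(y[order])
    fps = np.cumsum(~y[order])
    # collapse tied thresholds
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return float(auc), curve


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    return {
        "tp": int(np.sum(y_pred & y_true)),
        "fp": int(np.sum(y_pred & ~y_true)),
        "tn": int(np.sum(~y_pred & ~y_true)),
        "fn": int(np.sum(~y_pred & y_true)),
    }


def _check_features(features: pd.DataFrame, labels: pd.Series) -> None:
    if features.isna().any().any():
        raise ValidationError("classifier features contain missing values")
    if not features.index.equals(labels.index):
        raise ValidationError("features and labels must share an index")


def run_design_logistic(
    features: pd.DataFrame,
    labels: pd.Series,
    fraction: float = 0.8,
    seed: int = 375,
    threshold: float = 0.5,
) -> ClassifierReport:
    """Logistic-regression design: stratified split, ML fit, held-out panel."""
    _check_features(features, labels)
    plan = stratified_split(
        features.index, labels.to_numpy(), fraction, seed, design_id="logistic_80_20"
    )
    y = (labels == POSITIVE_LABEL).astype(float)
    x_train = sm.add_constant(features.loc[plan.train_ids], has_constant="add")
    x_test = sm.add_constant(features.loc[plan.test_ids], has_constant="add")

    separation = False
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y.loc[plan.train_ids], x_train, family=sm.families.Binomial())
        fit = model.fit()
        for w in caught:
            if "separat" in str(w.message).lower() or "converge" in str(w.message).lower():
                separation = True
                notes.append(str(w.message))
    # statsmodels evaluates deviance/aic lazily; keep numerical-edge
    # warnings (overflow at separation) out of user-facing output
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fitted = fit.fittedvalues
        if np.any(fitted > 1 - 1e-10) and np.any(fitted < 1e-10) and fit.deviance < 1e-6:
            separation = True
            notes.append("perfect separation suspected: near-zero residual deviance")

        coef = pd.DataFrame(
            {
                "estimate": fit.params,
                "std_error": fit.bse,
                "z": fit.tvalues,
                "p": fit.pvalues,
            }
        )
        deviance = {
            "null_deviance": float(fit.null_deviance),
            "df_null": int(fit.df_model + fit.df_resid),  # n_train - 1
            "residual_deviance": float(fit.deviance),
            "df_residual": int(fit.df_resid),  # n_train - (features + 1)
            "aic": float(fit.aic),
        }
        scores = np.asarray(fit.predict(x_test))
    y_test = (labels.loc[plan.test_ids] == POSITIVE_LABEL).to_numpy()
    y_pred = scores >= threshold
    conf = _confusion(y_test, y_pred)
    auc, curve = roc_auc(scores, y_test)
    return ClassifierReport(
        design_id="logistic_80_20",
        seed=seed,
        features=list(features.columns),
        n_train=len(plan.train_ids),
        n_test=len(plan.test_ids),
        confusion=conf,
        metrics=confusion_metrics(**conf),
        auc=auc,
        roc_points=curve,
        coefficients=None if separation else coef,
        deviance=deviance,
        separation_flag=separation,
        notes=notes,
    )


def _fit_forest(
    x_train: pd.DataFrame,
    y_train: np.ndarray,
    seed: int,
    n_trees: int,
) -> RandomForestClassifier:
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training fold contains a single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(x_train, y_train)
    return forest


def _forest_evaluate(
    train_x: pd.DataFrame,
    train_y: np.ndarray,
    test_x: pd.DataFrame,
    test_y: np.ndarray,
    seed: int,
    n_trees: int,
    iterative_removal: bool,
    min_features: int = 2,
) -> tuple[list[str], RandomForestClassifier]:
    """Drop the least important feature one at a time; keep the subset with
    the best held-out accuracy (ties -> fewer features)."""
    features = list(train_x.columns)
    best: tuple[float, int, list[str]] | None = None
    current = features
    while True:
        forest = _fit_forest(train_x[current], train_y, seed, n_trees)
        acc = float(np.mean(forest.predict(test_x[current]) == test_y))
        cand = (acc, -len(current), list(current))
        if best is None or cand > best:
            best = cand
        if not iterative_removal or len(current) <= min_features:
            break
        imp = pd.Series(forest.feature_importances_, index=current)
        current = [f for f in current if f != imp.idxmin()]
    selected = best[2]
    final = _fit_forest(train_x[selected], train_y, seed, n_trees)
    return selected, final


def _forest_report(
    design_id: str,
    seed: int,
    train_x: pd.DataFrame,
    train_y: np.ndarray,
    test_x: pd.DataFrame,
    test_y: np.ndarray,
    n_trees: int,
    iterative_removal: bool,
) -> ClassifierReport:
    selected, forest = _forest_evaluate(
        train_x, train_y, test_x, test_y, seed, n_trees, iterative_removal
    )
    scores = forest.predict_proba(test_x[selected])[:, 1]
    y_pred = forest.predict(test_x[selected]).astype(bool)
    conf = _confusion(test_y, y_pred)
    auc, curve = roc_auc(scores, test_y)
    importances = pd.Series(
        forest.feature_importances_, index=selected, name="mean_decrease_gini"
    ).sort_values(ascending=False)
    return ClassifierReport(
        design_id=design_id,
        seed=seed,
        features=selected,
        n_train=len(train_x),
        n_test=len(test_x),
        confusion=conf,
        metrics=confusion_metrics(**conf),
        auc=auc,
        roc_points=curve,
        importances=importances,
    )


def run_design_forest(
    features: pd.DataFrame,
    labels: pd.Series,
    fraction: float = 0.79,
    seed: int = 375,
    iterative_removal: bool = True,
    n_trees: int = DEFAULT_N_TREES,
) -> ClassifierReport:
    """Random-forest design on a random stratified split of one cohort."""
    _check_features(features, labels)
    plan = stratified_split(
        features.index, labels.to_numpy(), fraction, seed, design_id="forest_79_21"
    )
    y = labels == POSITIVE_LABEL
    return _forest_report(
        "forest_79_21",
        seed,
        features.loc[plan.train_ids],
        y.loc[plan.train_ids].to_numpy(),
        features.loc[plan.test_ids],
        y.loc[plan.test_ids].to_numpy(),
        n_trees,
        iterative_removal,
    )


def run_design_cross_cohort(
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    test_features: pd.DataFrame,
    test_labels: pd.Series,
    seed: int = 101,
    iterative_removal: bool = True,
    n_trees: int = DEFAULT_N_TREES,
) -> ClassifierReport:
    """Forest trained wholly on one cohort, evaluated wholly on another.

    Features are aligned by miRNA name (intersection, train order); no
    re-splitting occurs.
    """
    _check_features(train_features, train_labels)
    _check_features(test_features, test_labels)
    common = [f for f in train_features.columns if f in set(test_features.columns)]
    if not common:
        raise AlignmentError("train and test cohorts share no feature names")
    y_train = (train_labels == POSITIVE_LABEL).to_numpy()
    y_test = (test_labels == POSITIVE_LABEL).to_numpy()
    return _forest_report(
        "forest_cross_cohort",
        seed,
        train_features[common],
        y_train,
        test_features[common],
        y_test,
        n_trees,
        iterative_removal,
    )
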