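"""Supervised blood-brain-barrier penetration validation.

Trains four classifier families (random forest, gradient boosting, XGBoost
when available, RBF support-vector machine with Platt calibration) on five
physicochemical descriptors of compounds with experimentally verified CNS
penetration, evaluates them on a stratified held-out split, selects the best
model by balanced accuracy, and produces probabilistic predictions banded
into five penetration classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.svm import SVC

from .medchem import bbb_class_from_probability

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "StandardizationParams",
    "ConfusionMatrix",
    "MetricsReport",
    "stratified_split",
    "standardize",
    "train_models",
    "evaluate",
    "confusion_matrix_from_predictions",
    "auc_rank_statistic",
    "select_best",
    "predict_bbb",
    "run_validation",
]

#: Descriptor columns used for training and prediction, in order.
FEATURES = ["mw", "logp", "psa", "hbd", "hba"]

#: Fixed family order used as the final tie-break in model selection.
FAMILY_ORDER = ["random_forest", "gradient_boosting", "xgboost", "svm_rbf"]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature training mean and population standard deviation."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.std


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    balanced_accuracy: float | None
    auc_roc: float | None
    confusion: ConfusionMatrix


def stratified_split(
    data: pd.DataFrame,
    test_frac: float = 0.2,
    seed: int = 42,
    label_col: str = "cns_label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified partition into train and test sets.

    Per class, ``round(class_n * test_frac)`` rows go to the test set; the
    draw is seeded so the same seed always yields the same split. A 70/40
    two-class set at test_frac 0.2 therefore splits into 56/32 training and
    14/8 test compounds.
    """
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    classes = data[label_col].unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    test_idx: list = []
    for cls in sorted(classes):
        members = data.index[data[label_col] == cls].to_numpy()
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_test = int(round(len(members) * test_frac))
        test_idx.extend(rng.choice(members, size=n_test, replace=False))
    test_mask = data.index.isin(test_idx)
    return data.loc[~test_mask].copy(), data.loc[test_mask].copy()


def standardize(
    train_x: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, StandardizationParams]:
    """Z-score features using training-set parameters only.

    Uses the population (divide-by-n) standard deviation, so a two-point
    training feature {0, 10} scales exactly to {-1, +1}. Constant training
    features are rejected. The same parameters transform ``apply_to``,
    preventing information leakage from test data.
    """
    train_x = np.asarray(train_x, dtype=float)
    mean = train_x.mean(axis=0)
    std = train_x.std(axis=0)  # population convention
    constant = np.flatnonzero(std == 0)
    if constant.size:
        names = ", ".join(FEATURES[i] if i < len(FEATURES) else str(i) for i in constant)
        raise ValueError(f"constant training feature(s): {names}")
    params = StandardizationParams(mean=mean, std=std)
    scaled_train = params.transform(train_x)
    scaled_apply = None if apply_to is None else params.transform(apply_to)
    return scaled_train, scaled_apply, params


def _default_models(seed: int) -> dict[str, object]:
    models: dict[str, object] = {
        "random_forest": RandomForestClassifier(
            n_estimators=200, max_depth=10, random_state=seed
        ),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=100, max_depth=5, learning_rate=0.1, random_state=seed
        ),
    }
    try:
        from xgboost import XGBClassifier

        models["xgboost"] = XGBClassifier(
            n_estimators=100,
            max_depth=5,
            learning_rate=0.1,
            random_state=seed,
            eval_metric="logloss",
        )
    except ImportError:  # pragma: no cover - xgboost is present in CI images
        logger.warning("xgboost unavailable; falling back to the remaining families")
    # Platt-style sigmoid calibration gives the margin classifier the same
    # probabilistic output contract as the ensemble families.
    models["svm_rbf"] = CalibratedClassifierCV(
        SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed),
        method="sigmoid",
        ensemble=False,
    )
    return models


def train_models(
    x_train: np.ndarray, y_train: np.ndarray, seed: int = 42
) -> dict[str, object]:
    """Fit the four classifier families on standardized training data.

    All families expose calibrated class probabilities (the SVM via Platt
    scaling). Raises on a degenerate single-class training set.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    fitted = {}
    for name, model in _default_models(seed).items():
        model.fit(x_train, y_train)
        fitted[name] = model
    return fitted


def auc_rank_statistic(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """AUC-ROC by the Mann-Whitney rank statistic (ties share mid-ranks)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    r_pos = ranks[y_true == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_matrix_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def evaluate(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> MetricsReport:
    """Classification metrics from a confusion matrix, plus rank-based AUC.

    Metrics with an empty denominator (e.g. sensitivity when no positives
    exist) are reported as None with a warning rather than raising.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return None
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "ppv")
    npv = _ratio(cm.tn, cm.tn + cm.fn, "npv")
    balanced = (
        (sensitivity + specificity) / 2
        if sensitivity is not None and specificity is not None
        else None
    )
    auc = None
    if scores is not None and y_true is not None:
        auc = auc_rank_statistic(y_true, scores)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        npv=npv,
        balanced_accuracy=balanced,
        auc_roc=auc,
        confusion=cm,
    )


def select_best(reports: dict[str, MetricsReport]) -> str:
    """Pick the deployment model: balanced accuracy, then AUC, then family order.

    The fixed family order (random forest, gradient boosting, XGBoost, SVM)
    resolves exact ties deterministically.
    """
    if not reports:
        raise ValueError("no evaluated models")

    def sort_key(name: str) -> tuple:
        r = reports[name]
        ba = -1.0 if r.balanced_accuracy is None else r.balanced_accuracy
        auc = -1.0 if r.auc_roc is None else r.auc_roc
        order = FAMILY_ORDER.index(name) if name in FAMILY_ORDER else len(FAMILY_ORDER)
        return (-ba, -auc, order)

    return min(reports, key=sort_key)


def predict_bbb(
    model: object,
    params: StandardizationParams,
    profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Probabilistic BBB predictions for a table of descriptor profiles.

    Returns per-drug penetration probability, binary call at the inclusive
    0.5 threshold, and the five-band penetration class.
    """
    missing = [f for f in FEATURES if f not in profiles.columns]
    if missing:
        raise ValueError(f"missing descriptor column(s): {', '.join(missing)}")
    for feat in FEATURES:
        bad = profiles[profiles[feat].isna()]
        if len(bad):
            drug = bad.iloc[0].get("drug", bad.index[0])
            raise ValueError(f"missing descriptor {feat!r} for drug {drug!r}")
    x = params.transform(profiles[FEATURES].to_numpy(dtype=float))
    proba = model.predict_proba(x)[:, 1]
    out = pd.DataFrame(
        {
            "probability": proba,
            "binary": (proba >= 0.5).astype(int),
            "ml_class": [bbb_class_from_probability(p) for p in proba],
        }
    )
    if "drug" in profiles.columns:
        out.insert(0, "drug", profiles["drug"].to_numpy())
    return out


def run_validation(
    data: pd.DataFrame, test_frac: float = 0.2, seed: int = 42
) -> dict:
    """End-to-end supervised validation on a labeled compound table.

    Splits, standardizes on the training rows only, trains all families,
    evaluates each on the held-out set, and selects the best model. Returns
    the fitted models, standardization parameters, per-model reports, the
    best model id, and the split sizes.
    """
    train, test = stratified_split(data, test_frac=test_frac, seed=seed)
    x_train = train[FEATURES].to_numpy(dtype=float)
    x_test = test[FEATURES].to_numpy(dtype=float)
    y_train = train["cns_label"].to_numpy(dtype=int)
    y_test = test["cns_label"].to_numpy(dtype=int)
    x_train_s, x_test_s, params = standardize(x_train, x_test)
    models = train_models(x_train_s, y_train, seed=seed)
    reports = {}
    for name, model in models.items():
        proba = model.predict_proba(x_test_s)[:, 1]
        pred = (proba >= 0.5).astype(int)
        cm = confusion_matrix_from_predictions(y_test, pred)
        reports[name] = evaluate(cm, scores=proba, y_true=y_test)
    best = select_best(reports)
    return {
        "models": models,
        "params": params,
        "reports": reports,
        "best_model": best,
        "n_train": len(train),
        "n_test": len(test),
        "train_class_counts": train["cns_label"].value_counts().to_dict(),
        "test_class_counts": test["cns_label"].value_counts().to_dict(),
    }
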