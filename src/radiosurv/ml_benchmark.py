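"""Eight-classifier, four-feature-set survival-class benchmark with 5-fold CV.

Classifiers mirror a fixed set of off-the-shelf configurations: three SVMs
(linear; Gaussian with kernel scale sqrt(P); Gaussian with kernel scale
4*sqrt(P)), three KNNs (k=100 Euclidean; k=10 cosine; k=10 Euclidean), linear
discriminant analysis, and a random-subspace ensemble of discriminant
learners.  Feature sets are: all radiomics features; those plus clinical
factors; the LASSO-selected subset; and that subset plus clinical factors.

Evaluation is stratified 5-fold cross-validation with per-fold
standardization (scalers fitted on the training folds only), pooled
out-of-fold scores for one-vs-rest AUC per survival class, and pooled
out-of-fold accuracy.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_preprocess import (MISSING, RESECTION_CATEGORIES, SURVIVAL_CLASSES)
from .selection import SelectionResult

logger = logging.getLogger(__name__)

CLASSIFIER_FAMILIES = (
    "SVM_LINEAR", "SVM_GAUSS_MEDIUM", "SVM_GAUSS_COARSE",
    "KNN_COARSE", "KNN_COSINE", "KNN_MEDIUM",
    "LDA", "ENSEMBLE_SUBSPACE_DISCRIMINANT",
)
FEATURE_CONFIGS = ("ALL", "ALL+CLINICAL", "LASSO", "LASSO+CLINICAL")

SVM_C = 1.0
KNN_COARSE_K = 100
KNN_K = 10
ENSEMBLE_N_LEARNERS = 200


@dataclasses.dataclass
class ClassifierSpec:
    """One benchmark classifier configuration."""

    family: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")

    def build(self, n_features: int, n_train: int):
        """Instantiate the sklearn estimator for P features and a given fold size."""
        P = n_features
        fam = self.family
        if fam == "SVM_LINEAR":
            return SVC(kernel="linear", C=SVM_C, decision_function_shape="ovr")
        if fam == "SVM_GAUSS_MEDIUM":
            return SVC(kernel="rbf", C=SVM_C, gamma=1.0 / P,
                       decision_function_shape="ovr")
        if fam == "SVM_GAUSS_COARSE":
            return SVC(kernel="rbf", C=SVM_C, gamma=1.0 / (16.0 * P),
                       decision_function_shape="ovr")
        if fam == "KNN_COARSE":
            k = min(KNN_COARSE_K, n_train)
            if k < KNN_COARSE_K:
                logger.warning("KNN_COARSE k clamped to training size %d", k)
            return KNeighborsClassifier(n_neighbors=k)
        if fam == "KNN_COSINE":
            return KNeighborsClassifier(n_neighbors=min(KNN_K, n_train), metric="cosine")
        if fam == "KNN_MEDIUM":
            return KNeighborsClassifier(n_neighbors=min(KNN_K, n_train))
        if fam == "LDA":
            return LinearDiscriminantAnalysis()
        # random-subspace ensemble of discriminant learners: each learner sees
        # a random half of the features, all samples
        return BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=ENSEMBLE_N_LEARNERS,
            max_samples=1.0, bootstrap=False,
            max_features=max(1, math.ceil(P / 2)), bootstrap_features=False,
            random_state=self.seed)


@dataclasses.dataclass
class CvReport:
    """Pooled out-of-fold performance of one classifier x feature-set cell."""

    classifier: str
    feature_config: str
    auc: dict[str, float]          # per survival class, one-vs-rest
    overall_accuracy: float
    fold_assignments: np.ndarray   # per-patient fold id
    oof_scores: np.ndarray | None = None  # pooled out-of-fold class scores


# ------------------------------------------------------------- encoding


def encode_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """Numeric clinical covariates: age plus one-hot resection status.

    MISSING is a legal third category (about half the cohort), encoded as its
    own indicator rather than dropped or imputed.
    """
    bad = set(records["resection_status"].unique()) - set(RESECTION_CATEGORIES)
    if bad:
        raise ValueError(f"unknown resection status value(s): {sorted(bad)}")
    out = pd.DataFrame(index=records.index)
    out["age_years"] = records["age_years"].astype(float)
    for cat in RESECTION_CATEGORIES:
        out[f"resection_{cat}"] = (records["resection_status"] == cat).astype(float)
    return out


# ------------------------------------------------------------- AUC


def ovr_auc(scores: np.ndarray, labels: Sequence[str],
            classes: Sequence[str] = SURVIVAL_CLASSES) -> dict[str, float]:
    """One-vs-rest ranking AUC per class; tied scores count one half.

    ``scores`` has one column per class (same order as ``classes``).  A class
    without both a positive and a negative example gets NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, float] = {}
    for j, c in enumerate(classes):
        pos = labels == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[c] = float("nan")
            continue
        r = rankdata(scores[:, j])  # midranks handle ties as 1/2
        out[c] = float((r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return out


# ------------------------------------------------------------- CV harness


def _class_scores(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Per-class continuous scores aligned to SURVIVAL_CLASSES order."""
    if hasattr(model, "predict_proba"):
        s = model.predict_proba(X)
    else:
        s = model.decision_function(X)
        if s.ndim == 1:  # binary fold degenerate case
            s = np.column_stack([-s, s])
    aligned = np.full((X.shape[0], len(SURVIVAL_CLASSES)), -np.inf)
    for j, c in enumerate(classes):
        aligned[:, SURVIVAL_CLASSES.index(c)] = s[:, j]
    return aligned


def make_folds(labels: Sequence[str], folds: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold ids per patient; unstratified fallback for tiny classes."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    assign = np.empty(len(labels), dtype=int)
    if counts.min() < folds:
        logger.warning("a class has fewer than %d members; non-stratified folds used", folds)
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(labels)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(labels)), labels)
    for f, (_, te) in enumerate(split):
        assign[te] = f
    return assign


def cross_validate(table: pd.DataFrame, labels: Sequence[str],
                   spec: ClassifierSpec, folds: int = 5, seed: int = 0,
                   feature_config: str = "ALL",
                   fold_assignments: np.ndarray | None = None) -> CvReport:
    """Stratified k-fold CV of one classifier; pooled out-of-fold AUC/accuracy.

    Standardization is fitted inside each training fold only, so no test-fold
    statistic leaks into training.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    n = len(labels)
    if n < folds:
        raise ValueError("more folds than patients")
    X = table.to_numpy(dtype=float)
    if fold_assignments is None:
        fold_assignments = make_folds(labels, folds, seed)
    scores = np.zeros((n, len(SURVIVAL_CLASSES)))
    pred = np.empty(n, dtype=object)
    for f in range(folds):
        te = fold_assignments == f
        tr = ~te
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        model = spec.build(n_features=X.shape[1], n_train=int(tr.sum()))
        model.fit(Xtr, labels[tr])
        scores[te] = _class_scores(model, Xte, model.classes_)
        pred[te] = model.predict(Xte)
    return CvReport(
        classifier=spec.family, feature_config=feature_config,
        auc=ovr_auc(scores, labels),
        overall_accuracy=float((pred == labels).mean()),
        fold_assignments=fold_assignments, oof_scores=scores)


# ------------------------------------------------------------- benchmark


def resolve_feature_configs(feature_table: pd.DataFrame,
                            clinical: pd.DataFrame,
                            selection: SelectionResult | None
                            ) -> dict[str, pd.DataFrame]:
    """The four benchmark design matrices, aligned on patients."""
    clin = encode_clinical(clinical).set_index(clinical["patient_id"])
    clin = clin.loc[feature_table.index]
    configs = {
        "ALL": feature_table,
        "ALL+CLINICAL": pd.concat([feature_table, clin], axis=1),
    }
    if selection is not None:
        missing = [f for f in selection.kept_features if f not in feature_table.columns]
        if missing:
            raise ValueError(f"selected feature(s) not in table: {', '.join(missing)}")
        lasso = feature_table[selection.kept_features]
        configs["LASSO"] = lasso
        configs["LASSO+CLINICAL"] = pd.concat([lasso, clin], axis=1)
    return configs


def run_benchmark(feature_table: pd.DataFrame, clinical: pd.DataFrame,
                  labels: Sequence[str], selection: SelectionResult | None = None,
                  folds: int = 5, seed: int = 0,
                  feature_configs: Sequence[str] = FEATURE_CONFIGS
                  ) -> list[CvReport]:
    """All classifiers x feature configurations, shared folds, ranked report.

    LASSO configurations require a prior :class:`SelectionResult`.  Reports
    are sorted best-first by overall accuracy.
    """
    if any(c.startswith("LASSO") for c in feature_configs) and selection is None:
        raise ValueError("LASSO feature configs requested but no selection result given")
    matrices = resolve_feature_configs(feature_table, clinical, selection)
    labels = np.asarray(labels)
    fold_assignments = make_folds(labels, folds, seed)
    reports: list[CvReport] = []
    for config in feature_configs:
        table = matrices[config]
        for family in CLASSIFIER_FAMILIES:
            spec = ClassifierSpec(family=family, seed=seed)
            reports.append(cross_validate(table, labels, spec, folds=folds,
                                          seed=seed, feature_config=config,
                                          fold_assignments=fold_assignments))
    reports.sort(key=lambda r: -r.overall_accuracy)
    return reports


def report_frame(reports: Sequence[CvReport]) -> pd.DataFrame:
    """Flatten CV reports into the benchmark table (one row per cell)."""
    rows = []
    for r in reports:
        rows.append({
            "classifier": r.classifier,
            "feature_config": r.feature_config,
            "auc_short": r.auc.get("SHORT"),
            "auc_medium": r.auc.get("MEDIUM"),
            "auc_long": r.auc.get("LONG"),
            "overall_accuracy": r.overall_accuracy,
        })
    return pd.DataFrame(rows)
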