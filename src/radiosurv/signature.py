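"""Cox-coefficient risk signature: fit, score, cutoffs, stratification, evaluation.

The signature is the linear risk score sum_i beta_i * feature_i with beta the
Cox proportional-hazards coefficients of the LASSO-selected features (fitted
unpenalized, so per-feature Wald p-values are available).  Two fixed cutoffs
— half the median score of the short-survivor (high-risk) group and half the
median of the long-survivor (low-risk) group, both derived on the discovery
cohort — partition the score line into low/medium/high risk, mapped to
predicted long/medium/short survival.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

from .io_preprocess import LONG, MEDIUM, SHORT, SURVIVAL_CLASSES

logger = logging.getLogger(__name__)

LOW, MED_RISK, HIGH = "LOW", "MEDIUM", "HIGH"
RISK_TO_CLASS = {HIGH: SHORT, MED_RISK: MEDIUM, LOW: LONG}

#: published default cutoffs; replaced by derive_cutoffs on a discovery cohort
DEFAULT_LOW_CUTOFF = -0.505
DEFAULT_HIGH_CUTOFF = 0.122


@dataclasses.dataclass
class SignatureModel:
    """Selected feature names, Cox coefficients, Wald p-values and risk cutoffs."""

    feature_names: list[str]
    beta: np.ndarray
    p_values: np.ndarray
    low_cutoff: float = DEFAULT_LOW_CUTOFF
    high_cutoff: float = DEFAULT_HIGH_CUTOFF

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.feature_names) != len(self.beta):
            raise ValueError("feature_names and beta lengths differ")
        if not self.low_cutoff < self.high_cutoff:
            raise ValueError("low_cutoff must be below high_cutoff")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "feature_names": self.feature_names,
            "beta": self.beta.tolist(),
            "p_values": self.p_values.tolist(),
            "low_cutoff": self.low_cutoff,
            "high_cutoff": self.high_cutoff,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(feature_names=d["feature_names"], beta=np.asarray(d["beta"]),
                   p_values=np.asarray(d["p_values"]),
                   low_cutoff=d["low_cutoff"], high_cutoff=d["high_cutoff"])


@dataclasses.dataclass
class ConfusionStats:
    """Per-class sensitivity and false-positive rate with the 3x3 count matrix."""

    classes: tuple[str, ...]
    counts: np.ndarray            # rows = truth, cols = prediction
    sensitivity: dict[str, float]  # NaN where the class is absent from truth
    fpr: dict[str, float]


# ------------------------------------------------------------- fitting


def fit_cox(table: pd.DataFrame, os_days, event=None,
            ) -> tuple[pd.Series, pd.Series]:
    """Unpenalized Cox proportional-hazards fit of survival on the given columns.

    Returns (beta, wald_p) indexed by column name.  All observations are
    treated as events when no indicator is supplied.  On non-convergence a
    ridge-stabilized refit (small L2 penalty) is attempted and logged.
    """
    if table.shape[0] <= table.shape[1]:
        raise ValueError("need more patients than features for an unpenalized fit")
    sd = table.std(axis=0)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance covariate(s): {', '.join(zero)}")
    df = table.copy()
    df["os_days"] = np.asarray(os_days, dtype=float)
    df["event"] = 1 if event is None else np.asarray(event, dtype=int)
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_days", event_col="event")
    except ConvergenceError:
        logger.warning("Cox fit did not converge; refitting with ridge penalizer 0.1")
        cph = CoxPHFitter(penalizer=0.1, l1_ratio=0.0)
        cph.fit(df, duration_col="os_days", event_col="event")
    beta = cph.params_.reindex(table.columns)
    p = cph.summary["p"].reindex(table.columns)
    return beta, p


# ------------------------------------------------------------- scoring


def risk_score(features: Mapping[str, float] | pd.DataFrame | pd.Series,
               beta: pd.Series):
    """The linear radiomics signature score sum_i beta_i * feature_i.

    Accepts a single feature record (mapping/Series -> float) or a feature
    table (DataFrame -> Series per patient).  Raises KeyError naming any
    selected feature that is absent.
    """
    names = list(beta.index)
    if isinstance(features, pd.DataFrame):
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise KeyError(f"missing selected feature(s): {', '.join(missing)}")
        return features[names].to_numpy(dtype=float) @ beta.to_numpy(dtype=float)
    missing = [n for n in names if n not in features]
    if missing:
        raise KeyError(f"missing selected feature(s): {', '.join(missing)}")
    vals = np.array([float(features[n]) for n in names])
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite feature value in risk score input")
    return float(vals @ beta.to_numpy(dtype=float))


def derive_cutoffs(scores, true_class) -> tuple[float, float]:
    """Fixed risk cutoffs by the half-median rule on a discovery cohort.

    The per-group medians of the score overlap between survivor groups, so the
    thresholds are taken at half the short-survivor (high-risk) group median
    and half the long-survivor (low-risk) group median — the 25th-percentile
    approximation.  Returns (low_cutoff, high_cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    cls = np.asarray(true_class)
    present = set(cls.tolist())
    missing = set(SURVIVAL_CLASSES) - present
    if missing:
        raise ValueError(f"survival class(es) absent from cohort: {sorted(missing)}")
    med_short = float(np.median(scores[cls == SHORT]))
    med_long = float(np.median(scores[cls == LONG]))
    low, high = med_long / 2.0, med_short / 2.0
    if not low < high:
        raise ValueError(
            f"inverted cutoffs (low {low:.4g} >= high {high:.4g}): the score does "
            "not separate short from long survivors in the expected direction")
    return low, high


def stratify(score: float, model: SignatureModel) -> tuple[str, str]:
    """Map one score to (risk_group, predicted_class); boundary scores are MEDIUM."""
    if not np.isfinite(score):
        raise ValueError(f"non-finite risk score: {score}")
    if score > model.high_cutoff:
        group = HIGH
    elif score < model.low_cutoff:
        group = LOW
    else:
        group = MED_RISK
    return group, RISK_TO_CLASS[group]


def stratify_cohort(scores, model: SignatureModel,
                    patient_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-patient stratification table: score, risk_group, predicted_class."""
    scores = np.asarray(scores, dtype=float)
    rows = [stratify(s, model) for s in scores]
    df = pd.DataFrame(rows, columns=["risk_group", "predicted_class"])
    df.insert(0, "score", scores)
    if patient_ids is not None:
        df.insert(0, "patient_id", list(patient_ids))
    return df


# ------------------------------------------------------------- evaluation


def confusion_stats(predicted_class, true_class) -> ConfusionStats:
    """3x3 confusion counts with per-class sensitivity and false-positive rate."""
    pred = np.asarray(predicted_class)
    truth = np.asarray(true_class)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    for v in np.unique(np.concatenate([pred, truth])):
        if v not in SURVIVAL_CLASSES:
            raise ValueError(f"unknown class label {v!r}")
    k = len(SURVIVAL_CLASSES)
    idx = {c: i for i, c in enumerate(SURVIVAL_CLASSES)}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        counts[idx[t], idx[p]] += 1
    n = counts.sum()
    sens, fpr = {}, {}
    for c, i in idx.items():
        pos = counts[i].sum()
        sens[c] = counts[i, i] / pos if pos else float("nan")
        neg = n - pos
        fp = counts[:, i].sum() - counts[i, i]
        fpr[c] = fp / neg if neg else float("nan")
    return ConfusionStats(classes=SURVIVAL_CLASSES, counts=counts,
                          sensitivity=sens, fpr=fpr)


def association_test(os_days, risk_groups) -> float:
    """Welch two-sample t-test of survival between HIGH and LOW risk strata.

    Returns the two-sided p-value; the stronger the signature, the smaller.
    """
    os_days = np.asarray(os_days, dtype=float)
    groups = np.asarray(risk_groups)
    hi = os_days[groups == HIGH]
    lo = os_days[groups == LOW]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need at least 2 patients in each of the HIGH and LOW strata")
    return float(sps.ttest_ind(hi, lo, equal_var=False).pvalue)


def zscore_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score transform (population SD) of the selected features."""
    sd = table.std(axis=0, ddof=0)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero-SD column(s): {', '.join(zero)}")
    return (table - table.mean(axis=0)) / sd


# ------------------------------------------------------------- end to end


def build_signature(features: pd.DataFrame, os_days, true_class,
                    event=None) -> SignatureModel:
    """Fit the signature on a discovery cohort: Cox coefficients + cutoffs."""
    beta, p = fit_cox(features, os_days, event=event)
    scores = risk_score(features, beta)
    low, high = derive_cutoffs(scores, true_class)
    return SignatureModel(feature_names=list(features.columns),
                          beta=beta.to_numpy(), p_values=p.to_numpy(),
                          low_cutoff=low, high_cutoff=high)
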