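"""Two-step feature selection: zero-MAD filter, then cross-validated LASSO.

The median-absolute-deviation filter removes columns whose MAD (median of
|x - median(x)|) is exactly zero — uninformative for more than half the
cohort.  LASSO then fits an L1-penalized linear model of overall survival on
the standardized features over a descending penalty grid; the penalty is
chosen by k-fold cross-validated deviance (minimum mean), with the 1-SE
penalty also reported.  Features with non-zero coefficients at the optimum
are the selected subset.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold, StratifiedKFold

from .io_preprocess import survival_classes

logger = logging.getLogger(__name__)

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-3


@dataclasses.dataclass
class SelectionResult:
    """The LASSO path, its cross-validation curve, and the selected subset."""

    kept_features: list[str]
    lambda_path: np.ndarray
    cv_deviance: np.ndarray       # mean CV deviance per lambda
    cv_se: np.ndarray             # standard error per lambda
    lambda_opt: float
    lambda_1se: float
    coefficients_at_opt: dict[str, float]  # original scale, non-zero only

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kept_features": self.kept_features,
            "lambda_path": self.lambda_path.tolist(),
            "cv_deviance": self.cv_deviance.tolist(),
            "cv_se": self.cv_se.tolist(),
            "lambda_opt": self.lambda_opt,
            "lambda_1se": self.lambda_1se,
            "coefficients_at_opt": self.coefficients_at_opt,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(kept_features=d["kept_features"],
                   lambda_path=np.asarray(d["lambda_path"]),
                   cv_deviance=np.asarray(d["cv_deviance"]),
                   cv_se=np.asarray(d["cv_se"]),
                   lambda_opt=d["lambda_opt"], lambda_1se=d["lambda_1se"],
                   coefficients_at_opt=d["coefficients_at_opt"])


def mad_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Drop columns whose median absolute deviation is exactly zero.

    Columns like [1, 1, 1, 100] are removed despite non-zero variance: the
    median of |x - median| is 0.
    """
    if table.empty:
        raise ValueError("empty feature table")
    med = table.median(axis=0)
    mad = (table - med).abs().median(axis=0)
    dropped = mad.index[mad == 0.0].tolist()
    if dropped:
        logger.info("MAD filter removed %d zero-MAD column(s): %s",
                    len(dropped), ", ".join(dropped))
    kept = table.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("MAD filter removed every column")
    return kept


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column; run mad_filter first")
    return (X - mu) / sd, mu, sd


def _lambda_grid(Xs: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Descending log-spaced grid from lambda_max (empty model) downward."""
    n = Xs.shape[0]
    lam_max = np.abs(Xs.T @ yc).max() / n
    return np.geomspace(lam_max, lam_max * LAMBDA_MIN_RATIO, N_LAMBDA)


def _stratified_folds(outcome: np.ndarray, folds: int, seed: int):
    """Folds stratified by survival class so every group appears in each fold."""
    strata = survival_classes(outcome)
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < folds:
        logger.warning("a survival class has fewer members than folds; "
                       "falling back to unstratified folds")
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(kf.split(outcome))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(outcome), strata))


def lasso_select(table: pd.DataFrame, outcome, folds: int = 10,
                 seed: int = 0) -> SelectionResult:
    """LASSO feature selection with k-fold cross-validated deviance.

    Features are standardized (zero mean, unit SD) before penalization; the
    reported coefficients are mapped back to the original scale.  Fold
    assignment is stratified by survival class and drawn from ``seed``;
    identical table and seed reproduce the identical selection.
    """
    y = np.asarray(outcome, dtype=float)
    n, p = table.shape
    if n < folds or folds < 2:
        raise ValueError(f"need 2 <= folds <= n (folds={folds}, n={n})")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome")
    X = table.to_numpy(dtype=float)
    Xs, _, sd = _standardize(X)
    yc = y - y.mean()
    grid = _lambda_grid(Xs, yc)

    dev = np.zeros((folds, N_LAMBDA))
    for f, (tr, te) in enumerate(_stratified_folds(y, folds, seed)):
        _, coefs, _ = lasso_path(Xs[tr], yc[tr], alphas=grid)
        pred = Xs[te] @ coefs + yc[tr].mean()   # (n_te, n_lambda)
        dev[f] = ((yc[te, None] - pred) ** 2).mean(axis=0)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)

    i_opt = int(np.argmin(cv_mean))
    lambda_opt = float(grid[i_opt])
    within = cv_mean <= cv_mean[i_opt] + cv_se[i_opt]
    lambda_1se = float(grid[np.flatnonzero(within)[0]])  # grid descends; first = largest

    final = Lasso(alpha=lambda_opt, max_iter=50_000)
    final.fit(Xs, yc)
    nz = np.flatnonzero(final.coef_ != 0.0)
    kept = [table.columns[j] for j in nz]
    coeffs = {table.columns[j]: float(final.coef_[j] / sd[j]) for j in nz}
    logger.info("LASSO kept %d/%d features at lambda_opt=%.4g", len(kept), p, lambda_opt)
    return SelectionResult(kept_features=kept, lambda_path=grid,
                           cv_deviance=cv_mean, cv_se=cv_se,
                           lambda_opt=lambda_opt, lambda_1se=lambda_1se,
                           coefficients_at_opt=coeffs)


# ------------------------------------------------- penalized-Cox alternative


def cox_partial_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                       beta: np.ndarray) -> float:
    """Breslow partial log-likelihood of fixed coefficients on a data set."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # descending time
    eta_o, time_o, ev_o = eta[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    ll = 0.0
    for i in range(len(time_o)):
        if ev_o[i]:
            # risk set: all with time >= t_i -> prefix of the descending order
            j = np.searchsorted(-time_o, -time_o[i], side="right") - 1
            ll += eta_o[i] - log_cum[j]
    return float(ll)


def lasso_select_cox(table: pd.DataFrame, os_days, event=None, folds: int = 10,
                     seed: int = 0) -> SelectionResult:
    """Penalty selection with a Cox partial-likelihood deviance (alternative family).

    Same interface as :func:`lasso_select` but the penalized model is a Cox
    proportional-hazards elastic net (pure L1) and the CV criterion is the
    held-out partial deviance.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    t = np.asarray(os_days, dtype=float)
    e = np.ones_like(t, dtype=bool) if event is None else np.asarray(event, dtype=bool)
    n, p = table.shape
    if n < folds or folds < 2:
        raise ValueError(f"need 2 <= folds <= n (folds={folds}, n={n})")
    X = table.to_numpy(dtype=float)
    Xs, _, sd = _standardize(X)

    ref = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=N_LAMBDA,
                                 alpha_min_ratio=LAMBDA_MIN_RATIO)
    ref.fit(Xs, Surv.from_arrays(e, t))
    grid = np.asarray(ref.alphas_)

    dev = np.full((folds, len(grid)), np.nan)
    for f, (tr, te) in enumerate(_stratified_folds(t, folds, seed)):
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=grid, fit_baseline_model=False)
        model.fit(Xs[tr], Surv.from_arrays(e[tr], t[tr]))
        fitted = np.asarray(model.alphas_)
        coefs = model.coef_  # (p, n_fitted)
        for k, lam in enumerate(grid):
            j = int(np.argmin(np.abs(fitted - lam)))
            dev[f, k] = -2.0 * cox_partial_loglik(Xs[te], t[te], e[te], coefs[:, j])
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_opt = int(np.argmin(cv_mean))
    lambda_opt = float(grid[i_opt])
    within = cv_mean <= cv_mean[i_opt] + cv_se[i_opt]
    lambda_1se = float(grid[np.flatnonzero(within)[0]])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lambda_opt])
    final.fit(Xs, Surv.from_arrays(e, t))
    w = final.coef_[:, 0]
    nz = np.flatnonzero(w != 0.0)
    kept = [table.columns[j] for j in nz]
    coeffs = {table.columns[j]: float(w[j] / sd[j]) for j in nz}
    return SelectionResult(kept_features=kept, lambda_path=grid,
                           cv_deviance=cv_mean, cv_se=cv_se,
                           lambda_opt=lambda_opt, lambda_1se=lambda_1se,
                           coefficients_at_opt=coeffs)
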