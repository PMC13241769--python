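"""Cross-validated logistic biomarker models and permutation comparison.

Two logistic regressions are fitted by maximum likelihood and compared:
a clinical-predictors-only model and a clinical + qEEG model. Both are
evaluated with stratified 5-fold cross-validation (standardization
learned on training folds only), ROC/AUC, and six threshold metrics
(Sens, Spec, PPV, NPV, Acc, F1 at probability 0.5). The added value of
the qEEG block is tested by permuting its subject rows — breaking its
link to the outcome while preserving the clinical–outcome structure —
and comparing the cross-validated ΔAUC against that null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from netsig.errors import FitError, ParameterError, SeparationWarning


@dataclass
class LogisticFit:
    coef: np.ndarray               # [intercept, slopes...]
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n_iter: int
    ridge_fallback: bool = False

    @property
    def saliences(self) -> np.ndarray:
        """|β| of the slope coefficients (feature salience ordering)."""
        return np.abs(self.coef[1:])


@dataclass
class CvModelResult:
    fold_auc: np.ndarray
    auc_mean: float
    auc_sd: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    metrics_median: dict
    metrics_sd: dict
    fit: LogisticFit
    feature_names: list[str] = field(default_factory=list)
    seed: int | None = None


@dataclass
class ModelComparison:
    auc_clin: float
    auc_full: float
    delta_auc: float
    p: float
    n_perm: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# Maximum-likelihood logistic fit (IRLS / Newton-Raphson)
# ---------------------------------------------------------------------------

def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
          max_iter: int = 200, tol: float = 1e-8):
    """Newton-Raphson on the Bernoulli log-likelihood; X includes the
    intercept column. Returns (beta, loglik, n_iter, XtWX)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    XtWX = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        XtWX = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, grad, rcond=None)[0]
        beta = beta + step
        eta = np.clip(X @ beta, -35, 35)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        if abs(ll - ll_old) < tol:
            return beta, ll, it, XtWX
        ll_old = ll
    return beta, ll_old, max_iter, XtWX


def _separated(X, y, beta) -> bool:
    """Quasi-complete separation heuristic: diverging coefficients with
    every fitted probability saturated on the correct side."""
    if not np.all(np.isfinite(beta)):
        return True
    if np.max(np.abs(beta)) < 10:
        return False
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    saturated_correct = ((y == 1) & (mu > 0.99)) | ((y == 0) & (mu < 0.01))
    return bool(np.all(saturated_correct))


def fit_logistic_ml(X, y, max_iter: int = 200, tol: float = 1e-8,
                    ridge_fallback: float = 1e-4) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald statistics.

    An intercept is prepended. On detected (quasi-)separation or
    non-convergence the fit falls back to a ridge-stabilized solution
    (penalty ``ridge_fallback``) with a loud :class:`SeparationWarning`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or not np.all(np.isfinite(X)):
        raise ParameterError("X must be a finite 2-D matrix")
    classes = np.unique(y)
    if not (classes.size == 2 and set(classes) <= {0.0, 1.0}):
        raise ParameterError("y must be binary with both classes present")
    Xd = np.column_stack([np.ones(len(y)), X])

    beta, ll, it, XtWX = _irls(Xd, y, ridge=0.0, max_iter=max_iter, tol=tol)
    fallback = False
    if _separated(Xd, y, beta) or it >= max_iter:
        warnings.warn(
            "separation or non-convergence detected; refitting with ridge "
            f"penalty {ridge_fallback:g}", SeparationWarning)
        beta, ll, it, XtWX = _irls(Xd, y, ridge=ridge_fallback,
                                   max_iter=max_iter, tol=tol)
        fallback = True
        if not np.all(np.isfinite(beta)):
            raise FitError("logistic fit failed even with ridge stabilization")

    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(beta.shape, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = 2 * sps.norm.sf(np.abs(z))
    return LogisticFit(coef=beta, se=se, z=z, p=p, log_likelihood=ll,
                       n_iter=it, ridge_fallback=fallback)


# ---------------------------------------------------------------------------
# ROC / threshold metrics
# ---------------------------------------------------------------------------

def auc_mann_whitney(y, scores) -> float:
    """AUC as the normalized Mann-Whitney U (midranks for ties)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ParameterError("AUC needs both classes")
    ranks = sps.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classification_metrics(y, scores, threshold: float = 0.5) -> dict:
    """Sens, Spec, PPV, NPV, Acc and F1 from the confusion matrix at a
    probability threshold; undefined ratios are NaN with a warning."""
    y = np.asarray(y)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "PPV")
    npv = ratio(tn, tn + fn, "NPV")
    acc = (tp + tn) / len(y)
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "F1")
    return {"sens": sens, "spec": spec, "ppv": ppv, "npv": npv,
            "acc": acc, "f1": f1}


def _standardize(train, test):
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mean) / sd, (test - mean) / sd


def _roc_points(y, scores):
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(y)[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return fpr, tpr


def _screen_columns(X, y, alpha: float, n_perm: int, seed) -> np.ndarray:
    """Columns whose two-sided permutation p (mean difference) is < alpha
    on the given (training) data; falls back to all columns if none pass."""
    from netsig.stats import permutation_test

    keep = []
    for j in range(X.shape[1]):
        p = permutation_test(X[y == 1, j], X[y == 0, j], n_perm=n_perm,
                             seed=seed).p
        if p < alpha:
            keep.append(j)
    return np.array(keep if keep else range(X.shape[1]), dtype=int)


def crossval_roc(X, y, k: int = 5, seed: int | None = None,
                 stratified: bool = True, feature_names=None,
                 screen_alpha: float | None = None,
                 screen_n_perm: int = 200) -> CvModelResult:
    """Stratified k-fold CV of the logistic model.

    Standardization and fitting happen on training folds only;
    out-of-fold probabilities give per-fold AUC, the mean ROC (vertical
    averaging on a fixed FPR grid) and threshold metrics at 0.5
    (reported as median and sd across folds). Coefficients come from a
    full-data fit on standardized features.

    ``screen_alpha`` enables significance-gated feature selection: in
    each fold, only columns whose training-data permutation p is below
    alpha enter the model (nested in CV, so the screening never sees
    the test fold).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(np.sum(y == 1), np.sum(y == 0)) < k:
        raise ParameterError(f"each class needs at least k={k} members")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    grid = np.linspace(0, 1, 101)
    fold_auc, tprs, metric_rows = [], [], []
    for tr, te in splitter.split(X, y):
        if screen_alpha is not None:
            cols = _screen_columns(X[tr], y[tr], screen_alpha,
                                   screen_n_perm, seed)
        else:
            cols = np.arange(X.shape[1])
        Xtr, Xte = _standardize(X[np.ix_(tr, cols)], X[np.ix_(te, cols)])
        Xd = np.column_stack([np.ones(len(tr)), Xtr])
        beta, *_ = _irls(Xd, y[tr], ridge=1e-4)
        eta = np.clip(np.column_stack([np.ones(len(te)), Xte]) @ beta, -35, 35)
        prob = 1.0 / (1.0 + np.exp(-eta))
        fold_auc.append(auc_mann_whitney(y[te], prob))
        fpr, tpr = _roc_points(y[te], prob)
        tprs.append(np.interp(grid, fpr, tpr))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metric_rows.append(classification_metrics(y[te], prob))
    fold_auc = np.array(fold_auc)
    keys = metric_rows[0].keys()
    med = {m: float(np.nanmedian([r[m] for r in metric_rows])) for m in keys}
    sd = {m: float(np.nanstd([r[m] for r in metric_rows])) for m in keys}

    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        full_fit = fit_logistic_ml(Xs, y)
    return CvModelResult(fold_auc=fold_auc, auc_mean=float(fold_auc.mean()),
                         auc_sd=float(fold_auc.std()),
                         roc_fpr=grid, roc_tpr=np.mean(tprs, axis=0),
                         metrics_median=med, metrics_sd=sd, fit=full_fit,
                         feature_names=list(feature_names or []), seed=seed)


def _cv_auc(X, y, folds) -> float:
    aucs = []
    for tr, te in folds:
        Xtr, Xte = _standardize(X[tr], X[te])
        Xd = np.column_stack([np.ones(len(tr)), Xtr])
        beta, *_ = _irls(Xd, y[tr], ridge=1e-4)
        eta = np.column_stack([np.ones(len(te)), Xte]) @ beta
        aucs.append(auc_mann_whitney(y[te], eta))
    return float(np.mean(aucs))


def compare_models(X_clin, X_qeeg, y, k: int = 5, n_perm: int = 10_000,
                   seed: int | None = None,
                   scheme: str = "permute-qeeg") -> ModelComparison:
    """Permutation test of the added value of the qEEG feature block.

    ΔAUC_obs = CV-AUC([X_clin X_qeeg]) − CV-AUC(X_clin). Null
    (``scheme="permute-qeeg"``): subject rows of X_qeeg are permuted,
    breaking their link to the outcome while preserving the
    clinical–outcome structure; ``scheme="permute-labels"`` permutes y
    instead (sensitivity alternative). p = (1 + #{ΔAUC_perm >=
    ΔAUC_obs}) / (n_perm + 1).
    """
    X_clin = np.asarray(X_clin, dtype=float)
    X_qeeg = np.asarray(X_qeeg, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X_clin) != len(X_qeeg) or len(X_clin) != len(y):
        raise ParameterError("feature blocks must cover the same subjects")
    if scheme not in ("permute-qeeg", "permute-labels"):
        raise ParameterError(f"unknown permutation scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(splitter.split(X_clin, y))

    auc_clin = _cv_auc(X_clin, y, folds)
    X_full = np.column_stack([X_clin, X_qeeg])
    auc_full = _cv_auc(X_full, y, folds)
    delta_obs = auc_full - auc_clin

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        if scheme == "permute-qeeg":
            Xp = np.column_stack([X_clin, X_qeeg[perm]])
            delta = _cv_auc(Xp, y, folds) - auc_clin
        else:
            yp = y[perm]
            folds_p = list(StratifiedKFold(
                n_splits=k, shuffle=True, random_state=seed).split(X_clin, yp))
            delta = (_cv_auc(X_full, yp, folds_p)
                     - _cv_auc(X_clin, yp, folds_p))
        if delta >= delta_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return ModelComparison(auc_clin=auc_clin, auc_full=auc_full,
                           delta_auc=delta_obs, p=float(p), n_perm=n_perm,
                           seed=seed)
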