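"""Multiclass discrimination of ALS+B / ALS-B / HC from composite scores.

Mixture discriminant analysis (MDA) models each class as a mixture of K
Gaussian subclasses with a covariance matrix shared across all
subclasses of all classes, fit by EM with k-means initialization. It
accommodates within-class heterogeneity (e.g. varying bulbar severity
within a diagnostic group) while keeping the parameter count small for
modest cohorts. The RBF-kernel maximum-margin classifier is delegated to
a standard implementation. Evaluation uses leave-one-out
cross-validation with macro-averaged one-vs-rest metrics and pairwise
ROC/AUC on the held-out posterior scores.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ClassifierConfig

__all__ = [
    "MdaModel",
    "fit_mda",
    "predict_scores",
    "ClassificationReport",
    "loocv_evaluate",
    "pairwise_roc_auc",
]


@dataclass
class MdaModel:
    classes: np.ndarray
    centers: dict  # class -> (K, d) subclass means
    mixing: dict  # class -> (K,) proportions
    covariance: np.ndarray  # shared (d, d)
    priors: dict  # class -> prior
    log_likelihood: float = float("nan")
    n_iter: int = 0


def _log_gauss_multi(
    X: np.ndarray, mus: np.ndarray, cov_chol: np.ndarray, log_det: float
) -> np.ndarray:
    """Log N(x; mu_k, Sigma) for all rows x and all centers mu_k at once;
    returns (n, K)."""
    d = X.shape[1]
    Xw = np.linalg.solve(cov_chol, X.T).T  # whiten
    Mw = np.linalg.solve(cov_chol, mus.T).T
    maha = (
        (Xw**2).sum(axis=1)[:, None]
        - 2.0 * Xw @ Mw.T
        + (Mw**2).sum(axis=1)[None, :]
    )
    return -0.5 * (d * np.log(2 * np.pi) + log_det + maha)


def _chol(cov: np.ndarray) -> tuple[np.ndarray, float]:
    d = cov.shape[0]
    cov = cov + 1e-8 * np.trace(cov) / d * np.eye(d)
    L = np.linalg.cholesky(cov)
    log_det = 2.0 * np.log(np.diag(L)).sum()
    return L, log_det


def fit_mda(
    X: np.ndarray,
    y: np.ndarray,
    n_subclasses: int = 2,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MdaModel:
    """Fit mixture discriminant analysis by EM with shared covariance."""
    from sklearn.cluster import KMeans

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n, d = X.shape
    K = n_subclasses
    for c in classes:
        if (y == c).sum() < K:
            raise ValueError(
                f"class {c!r} has fewer samples than K={K}; use a smaller K"
            )
    centers, mixing, priors, resp = {}, {}, {}, {}
    for c in classes:
        Xc = X[y == c]
        km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(Xc)
        centers[c] = km.cluster_centers_.copy()
        counts = np.bincount(km.labels_, minlength=K).astype(float)
        mixing[c] = np.maximum(counts, 1.0) / np.maximum(counts, 1.0).sum()
        priors[c] = len(Xc) / n
    cov = np.cov(X, rowvar=False).reshape(d, d)
    class_rows = {c: np.flatnonzero(y == c) for c in classes}
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        chol, log_det = _chol(cov)
        ll = 0.0
        scatter = np.zeros((d, d))
        for c in classes:
            Xc = X[class_rows[c]]
            logp = _log_gauss_multi(Xc, centers[c], chol, log_det) + np.log(
                np.maximum(mixing[c], 1e-12)
            )
            mx = logp.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
            ll += float(lse.sum())
            r = np.exp(logp - lse[:, None])
            resp[c] = r
            nk = r.sum(axis=0)
            mixing[c] = nk / nk.sum()
            centers[c] = (r.T @ Xc) / np.maximum(nk, 1e-12)[:, None]
            # within-subclass scatter: sum_k sum_i r_ik (x_i - mu_k)(x_i - mu_k)'
            scatter += (Xc * r.sum(axis=1)[:, None]).T @ Xc
            scatter -= centers[c].T @ (nk[:, None] * centers[c])
        cov = scatter / n
        if abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            prev_ll = ll
            break
        prev_ll = ll
    return MdaModel(
        classes=classes,
        centers=centers,
        mixing=mixing,
        covariance=cov,
        priors=priors,
        log_likelihood=prev_ll,
        n_iter=n_iter,
    )


def predict_scores(model: MdaModel, X: np.ndarray) -> np.ndarray:
    """Posterior class probabilities (rows sum to 1), class order =
    ``model.classes``."""
    X = np.asarray(X, dtype=float)
    d = model.covariance.shape[0]
    if X.ndim != 2 or X.shape[1] != d:
        raise ValueError(f"expected {d}-dimensional rows, got shape {X.shape}")
    chol, log_det = _chol(model.covariance)
    log_joint = np.empty((X.shape[0], len(model.classes)))
    for j, c in enumerate(model.classes):
        logp = _log_gauss_multi(X, model.centers[c], chol, log_det) + np.log(
            np.maximum(model.mixing[c], 1e-12)
        )
        mx = logp.max(axis=1, keepdims=True)
        log_joint[:, j] = np.log(model.priors[c]) + mx[:, 0] + np.log(
            np.exp(logp - mx).sum(axis=1)
        )
    mx = log_joint.max(axis=1, keepdims=True)
    post = np.exp(log_joint - mx)
    return post / post.sum(axis=1, keepdims=True)


@dataclass
class ClassificationReport:
    classes: np.ndarray
    confusion: np.ndarray  # true x predicted
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    scores: np.ndarray  # held-out posterior scores, rows x classes
    y_true: np.ndarray
    roc: dict = field(default_factory=dict)  # (c1, c2) -> dict(fpr, tpr, auc)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": {f"{a} vs {b}": v["auc"] for (a, b), v in self.roc.items()},
        }


def _macro_metrics(conf: np.ndarray) -> tuple[float, float, float, float, float]:
    n = conf.sum()
    acc = np.trace(conf) / n
    sens, spec, ppv, npv = [], [], [], []
    for i in range(conf.shape[0]):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spec.append(tn / (tn + fp) if tn + fp else np.nan)
        ppv.append(tp / (tp + fp) if tp + fp else np.nan)
        npv.append(tn / (tn + fn) if tn + fn else np.nan)
    return (
        float(acc),
        float(np.nanmean(sens)),
        float(np.nanmean(spec)),
        float(np.nanmean(ppv)),
        float(np.nanmean(npv)),
    )


def _fit_predict(algo, Xtr, ytr, Xte, classes, config: ClassifierConfig, seed: int):
    if algo == "mda":
        model = fit_mda(
            Xtr,
            ytr,
            n_subclasses=config.n_subclasses,
            seed=seed,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        scores = predict_scores(model, Xte)
        # reorder to global class order
        order = [list(model.classes).index(c) for c in classes]
        return scores[:, order]
    if algo == "svm_rbf":
        from sklearn.svm import SVC

        clf = SVC(
            C=config.svm_c, kernel="rbf", gamma="scale", probability=True, random_state=seed
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr, ytr)
        scores = clf.predict_proba(Xte)
        order = [list(clf.classes_).index(c) for c in classes]
        return scores[:, order]
    raise ValueError(f"unknown algorithm {algo!r}")


def loocv_evaluate(
    X,
    y,
    algo: str = "mda",
    config: ClassifierConfig | None = None,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    groups=None,
) -> ClassificationReport:
    """Leave-one-out cross-validation with macro metrics and pairwise ROC.

    When ``covariates`` are given, confounder adjustment (residualization
    on age/sex/cognitive status) is re-fit on each training fold and
    applied to the held-out row. ``groups`` selects leave-one-subject-out
    folds instead of leave-one-recording-out."""
    from .cohort_stats import adjust_confounders

    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    for c in classes:
        if (y == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
    if groups is not None:
        groups = np.asarray(groups)
        folds = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    else:
        folds = [np.array([i]) for i in range(n)]
    scores = np.zeros((n, len(classes)))
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(np.unique(y[train_idx])) < len(classes):
            raise ValueError("a fold's training set lost a class")
        if covariates is not None:
            adj = adjust_confounders(
                pd.DataFrame(X), covariates, fit_rows=train_idx
            ).to_numpy()
            Xtr, Xte = adj[train_idx], adj[test_idx]
        else:
            Xtr, Xte = X[train_idx], X[test_idx]
        scores[test_idx] = _fit_predict(
            algo, Xtr, y[train_idx], Xte, classes, config, seed
        )
    y_pred = classes[np.argmax(scores, axis=1)]
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y, y_pred):
        conf[list(classes).index(t), list(classes).index(p)] += 1
    acc, sens, spec, ppv, npv = _macro_metrics(conf)
    roc = pairwise_roc_auc(scores, y, classes)
    return ClassificationReport(
        classes=classes,
        confusion=conf,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        scores=scores,
        y_true=y,
        roc=roc,
    )


def pairwise_roc_auc(scores: np.ndarray, y: np.ndarray, classes=None) -> dict:
    """Pairwise ROC/AUC from per-class scores.

    For each unordered class pair, rows of those two classes are kept and
    the contrast p(c1)/(p(c1)+p(c2)) scored against membership of c1; AUC
    uses the rank statistic with midranks for ties."""
    from sklearn.metrics import roc_curve

    y = np.asarray(y)
    classes = np.unique(y) if classes is None else np.asarray(classes)
    out = {}
    for i, j in itertools.combinations(range(len(classes)), 2):
        c1, c2 = classes[i], classes[j]
        sel = (y == c1) | (y == c2)
        if (y[sel] == c1).sum() == 0 or (y[sel] == c2).sum() == 0:
            warnings.warn(f"pair ({c1}, {c2}) missing a class; skipped")
            continue
        denom = scores[sel, i] + scores[sel, j]
        contrast = np.where(denom > 0, scores[sel, i] / np.where(denom > 0, denom, 1.0), 0.5)
        labels = (y[sel] == c1).astype(int)
        fpr, tpr, _ = roc_curve(labels, contrast)
        # rank-statistic AUC with midranks
        ranks = pd.Series(contrast).rank(method="average").to_numpy()
        n1 = labels.sum()
        n0 = len(labels) - n1
        auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        out[(c1, c2)] = {"fpr": fpr, "tpr": tpr, "auc": float(auc)}
    return out
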