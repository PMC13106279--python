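"""Cohort-level statistics: cleaning and CART imputation, mixed-model
group effects, factor-analytic composite scoring, reliability, the
integrated bulbar functional outcome, mediation paths, and confounder
adjustment.

The factor pipeline mirrors the exploratory-factor-analysis workflow for
questionnaire-style batteries: the number of factors is chosen by
parallel analysis, factors are extracted from the feature correlation
matrix by minimum-residual (minres) factoring, rotated obliquely
(promax, power 4), features with |loading| > 0.40 define each factor's
component list, and factor scores are computed with the Ten Berge
correlation-preserving method. Factor scores serve as the composite
measures in all downstream analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .config import StatsConfig

__all__ = [
    "clean_outliers",
    "cart_impute",
    "GroupEffect",
    "group_effect",
    "welch_t_from_summary",
    "chi2_2x2_yates",
    "parallel_analysis",
    "FactorModel",
    "fit_factor_model",
    "cronbach_alpha",
    "integrated_outcome",
    "MediationResult",
    "mediation_paths",
    "adjust_confounders",
]


# ---------------------------------------------------------------------------
# Cleaning / imputation


def clean_outliers(
    table: pd.DataFrame, columns=None, iqr_multiplier: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tukey-fence outlier removal: per column, values outside
    [Q1 - k*IQR, Q3 + k*IQR] are set missing and flagged. Fences are
    closed (boundary values kept); constant columns have IQR 0 and lose
    nothing."""
    out = table.copy()
    columns = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    flags = pd.DataFrame(False, index=table.index, columns=columns)
    for c in columns:
        x = out[c].astype(float)
        q1, q3 = x.quantile(0.25), x.quantile(0.75)
        iqr = q3 - q1
        lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
        bad = (x < lo) | (x > hi)
        flags[c] = bad.fillna(False)
        out.loc[bad.fillna(False), c] = np.nan
    return out, flags


def cart_impute(
    table: pd.DataFrame,
    columns=None,
    seed: int = 0,
    config: StatsConfig | None = None,
) -> pd.DataFrame:
    """Impute missing cells with iterated single-tree regression (CART).

    Each incomplete column is predicted from the other feature columns by
    a depth-limited regression tree fit on its observed rows; sweeps
    repeat until imputed values change less than a tolerance or the sweep
    cap is reached. Deterministic for a given seed."""
    from sklearn.tree import DecisionTreeRegressor

    config = config or StatsConfig()
    out = table.copy()
    columns = list(columns) if columns is not None else [
        c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])
    ]
    fully_missing = [c for c in columns if out[c].isna().all()]
    if fully_missing:
        raise ValueError(f"column(s) fully missing, cannot impute: {fully_missing}")
    missing_mask = out[columns].isna()
    incomplete = [c for c in columns if missing_mask[c].any()]
    if not incomplete:
        return out
    # initialize with column medians
    for c in incomplete:
        out.loc[missing_mask[c], c] = out[c].median()
    rng = np.random.default_rng(seed)
    for _ in range(config.impute_max_sweeps):
        max_change = 0.0
        for c in incomplete:
            others = [o for o in columns if o != c]
            obs = ~missing_mask[c]
            tree = DecisionTreeRegressor(
                max_depth=config.impute_max_depth,
                min_samples_leaf=config.impute_min_leaf,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(out.loc[obs, others].to_numpy(), out.loc[obs, c].to_numpy())
            pred = tree.predict(out.loc[missing_mask[c], others].to_numpy())
            old = out.loc[missing_mask[c], c].to_numpy()
            scale = max(float(out[c].std(ddof=0)), 1e-12)
            max_change = max(max_change, float(np.max(np.abs(pred - old))) / scale)
            out.loc[missing_mask[c], c] = pred
        if max_change < config.impute_tol:
            break
    return out


# ---------------------------------------------------------------------------
# Group effects


@dataclass
class GroupEffect:
    estimate: float
    cohens_d: float
    ci: tuple
    method: str = "mixed"


def group_effect(
    y: np.ndarray, group_is_als: np.ndarray, subject_ids: np.ndarray
) -> GroupEffect:
    """ALS-vs-HC effect on one feature from a random-intercept model.

    A linear mixed-effects model (REML) with group as fixed effect and a
    subject-dependent intercept; Cohen's d is the marginal group
    difference standardized by the total SD sqrt(var_subject +
    var_residual). Singular fits fall back to a pooled-variance
    two-sample d with a warning."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    g = np.asarray(group_is_als).astype(float)
    keep = np.isfinite(y)
    y, g = y[keep], g[keep]
    subj = np.asarray(subject_ids)[keep]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, sm.add_constant(g), groups=subj)
            fit = model.fit(reml=True)
        beta = float(np.asarray(fit.params)[1])
        se = float(np.asarray(fit.bse)[1])
        var_subj = float(np.asarray(fit.cov_re)[0, 0])
        var_resid = float(fit.scale)
        total_sd = np.sqrt(var_subj + var_resid)
        if not np.isfinite(total_sd) or total_sd <= 0:
            raise np.linalg.LinAlgError("degenerate variance components")
        d = beta / total_sd
        ci = (beta - 1.96 * se, beta + 1.96 * se)
        return GroupEffect(estimate=beta, cohens_d=float(d), ci=ci, method="mixed")
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("singular mixed-model fit; falling back to pooled two-sample d")
        a, h = y[g == 1], y[g == 0]
        diff = a.mean() - h.mean()
        sp = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(h) - 1) * h.var(ddof=1))
            / (len(a) + len(h) - 2)
        )
        se = sp * np.sqrt(1 / len(a) + 1 / len(h))
        return GroupEffect(
            estimate=float(diff),
            cohens_d=float(diff / sp) if sp > 0 else float("nan"),
            ci=(float(diff - 1.96 * se), float(diff + 1.96 * se)),
            method="pooled",
        )


def welch_t_from_summary(m1, s1, n1, m2, s2, n2) -> tuple[float, float, float]:
    """Welch's unequal-variance t test from summary statistics; returns
    (t, Satterthwaite df, two-sided p)."""
    if s1 < 0 or s2 < 0 or n1 < 2 or n2 < 2:
        raise ValueError("require s >= 0 and n >= 2 per group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("both groups have zero variance")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * spstats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi2_2x2_yates(a, b, c, d) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table
    [[a, b], [c, d]]; returns (chi2, p)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    n = table.sum()
    ad_bc = abs(a * d - b * c)
    corr = max(ad_bc - n / 2, 0.0)
    chi2 = n * corr**2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    p = float(spstats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# Factor analysis


def parallel_analysis(
    X: np.ndarray,
    n_sims: int = 100,
    seed: int = 0,
    percentile: float = 95.0,
) -> int:
    """Number of factors by parallel analysis.

    k is the number of leading eigenvalues of the observed correlation
    matrix exceeding the given percentile of the corresponding
    eigenvalues of Gaussian null data of the same shape."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 20:
        raise ValueError("parallel analysis requires at least 20 rows")
    sds = X.std(axis=0)
    constant = np.flatnonzero(sds == 0)
    if constant.size:
        raise ValueError(f"constant column(s) at index {constant.tolist()}")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_sims, p))
    for s in range(n_sims):
        Z = rng.standard_normal((n, p))
        null[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    thresh = np.percentile(null, percentile, axis=0)
    above = obs > thresh
    k = 0
    for flag in above:
        if flag:
            k += 1
        else:
            break
    return k


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations from the inverse correlation matrix."""
    Rinv = np.linalg.pinv(R)
    d = np.diag(Rinv)
    return 1.0 - 1.0 / np.maximum(d, 1e-12)


def _minres_loadings(R: np.ndarray, k: int, psi: np.ndarray) -> np.ndarray:
    Rs = R.copy()
    np.fill_diagonal(Rs, 1.0 - psi)
    vals, vecs = np.linalg.eigh(Rs)
    order = np.argsort(vals)[::-1][:k]
    lam = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return lam


def _minres_fit(R: np.ndarray, k: int) -> tuple[np.ndarray, dict]:
    """Minimum-residual factor extraction: minimize the off-diagonal
    residual sum of squares of R - LL' over uniquenesses."""
    from scipy.optimize import minimize

    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)

    def objective(psi):
        lam = _minres_loadings(R, k, psi)
        resid = R - lam @ lam.T
        return float(np.sum(resid[off] ** 2))

    psi0 = np.clip(1.0 - _smc(R), 0.05, 0.95)
    res = minimize(
        objective,
        psi0,
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": 1000},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"minres extraction failed to converge: {res.message}")
    lam = _minres_loadings(R, k, res.x)
    diag = {"n_iter": int(res.nit), "objective": float(res.fun), "converged": bool(res.success)}
    return lam, diag


def _varimax(L: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Varimax rotation (orthogonal), Kaiser-normalized."""
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    Rm = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        B = A @ Rm
        U, s, Vt = np.linalg.svd(A.T @ (B**3 - B * ((B**2).sum(axis=0) / p)))
        Rm = U @ Vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return (A @ Rm) * h[:, None]


def _promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation (power 4) after varimax; returns (pattern,
    factor correlation matrix)."""
    V = _varimax(L)
    k = V.shape[1]
    if k < 2:
        return V, np.eye(1)
    P = V * np.abs(V) ** (power - 1)
    U, *_ = np.linalg.lstsq(V, P, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)
    pattern = V @ U
    Uinv = np.linalg.inv(U)
    phi = Uinv @ Uinv.T
    # normalize to unit factor variances
    sd = np.sqrt(np.diag(phi))
    phi = phi / np.outer(sd, sd)
    pattern = pattern * sd
    return pattern, phi


def _mat_power(M: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    vals = np.maximum(vals, 1e-12)
    return (vecs * vals**power) @ vecs.T


@dataclass
class FactorModel:
    loadings: pd.DataFrame  # features x factors (pattern matrix)
    phi: np.ndarray  # factor correlations
    component_map: dict  # factor -> list of feature names
    scores: pd.DataFrame  # rows x factors (Ten Berge)
    variance_explained: float
    diagnostics: dict = field(default_factory=dict)


def fit_factor_model(
    X: pd.DataFrame, k: int, loading_cutoff: float = 0.40
) -> FactorModel:
    """Minres extraction + promax rotation + Ten Berge factor scores.

    Component features of each factor are those with |pattern loading|
    above the cutoff. Ten Berge scores are correlation-preserving: their
    sample correlation matrix approximates the rotated factor correlation
    matrix."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        idx = X.index
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        cols = [f"f{i}" for i in range(M.shape[1])]
        idx = pd.RangeIndex(M.shape[0])
    if np.isnan(M).any():
        raise ValueError("factor model requires a complete (imputed) matrix")
    R = np.corrcoef(M, rowvar=False)
    lam, diag = _minres_fit(R, k)
    pattern, phi = _promax(lam)
    # orient factors so each has positive mean loading among its salient features
    for j in range(pattern.shape[1]):
        sal = np.abs(pattern[:, j]) > loading_cutoff
        ref = pattern[sal, j].sum() if sal.any() else pattern[:, j].sum()
        if ref < 0:
            pattern[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    factor_names = [f"F{j + 1}" for j in range(pattern.shape[1])]
    loadings = pd.DataFrame(pattern, index=cols, columns=factor_names)
    component_map = {
        fn: [c for c in cols if abs(loadings.at[c, fn]) > loading_cutoff]
        for fn in factor_names
    }
    # Ten Berge correlation-preserving scores
    Z = (M - M.mean(axis=0)) / M.std(axis=0)
    L = pattern @ _mat_power(phi, 0.5)
    R_inv_sqrt = _mat_power(R, -0.5)
    inner = L.T @ np.linalg.pinv(R) @ L
    C = R_inv_sqrt @ L @ _mat_power(inner, -0.5)
    W = R_inv_sqrt @ C @ _mat_power(phi, 0.5)
    scores = pd.DataFrame(Z @ W, index=idx, columns=factor_names)
    # variance explained (oblique): sum over factors of pattern'structure
    structure = pattern @ phi
    var_per_factor = (pattern * structure).sum(axis=0)
    variance_explained = float(var_per_factor.sum() / len(cols))
    return FactorModel(
        loadings=loadings,
        phi=phi,
        component_map=component_map,
        scores=scores,
        variance_explained=variance_explained,
        diagnostics=diag,
    )


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an items matrix (rows = observations). Items
    should be sign-aligned beforehand (reverse negative loadings)."""
    X = np.asarray(items, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("alpha requires at least 2 items")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total variance")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def composite_alphas(table: pd.DataFrame, model: FactorModel) -> dict:
    """Cronbach's alpha per factor over its component features, with
    negatively loading features sign-reversed."""
    out = {}
    for fn, comps in model.component_map.items():
        if len(comps) < 2:
            out[fn] = float("nan")
            continue
        X = table[comps].to_numpy(dtype=float).copy()
        signs = np.sign(model.loadings.loc[comps, fn].to_numpy())
        out[fn] = cronbach_alpha(X * signs)
    return out


# ---------------------------------------------------------------------------
# Integrated outcome, mediation, confounders


def integrated_outcome(
    table: pd.DataFrame,
    weights: tuple = (1.0, 1.0, 1.0),
    hc_bulbar_score: float = 12.0,
) -> pd.Series:
    """Integrated bulbar functional outcome.

    Out = c1*z(Bulb_ALSFRS) + c2*z(log10(max(Intell)+1 - Intell))
        + c3*z(1/SR), with healthy controls assigned the maximum bulbar
    subscore (12) before z-scoring, the intelligibility ceiling taken
    within-cohort, and speaking rate inverted to mean word duration."""
    bulb = table["Bulb_ALSFRS"].astype(float).copy()
    bulb[table["group"] == "HC"] = hc_bulbar_score
    intell = table["Intell"].astype(float)
    sr = table["SR"].astype(float)
    if (intell < 0).any() or (intell > 100).any():
        raise ValueError("Intell must lie in [0, 100]")
    if (sr <= 0).any():
        raise ValueError("SR must be positive")
    log_term = np.log10(intell.max() + 1.0 - intell)
    inv_sr = 1.0 / sr
    terms = []
    for t in (bulb, log_term, inv_sr):
        sd = t.std(ddof=1)
        if sd <= 0:
            raise ValueError("zero variance in a transformed functional metric")
        terms.append((t - t.mean()) / sd)
    c1, c2, c3 = weights
    return c1 * terms[0] + c2 * terms[1] + c3 * terms[2]


def _ols2(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS coefficients with intercept prepended."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


@dataclass
class MediationResult:
    composite: str
    direct: float
    a_path: float
    b_path: float
    indirect: float
    indirect_ci: tuple


def mediation_paths(
    composites: pd.DataFrame,
    stiffness: pd.Series,
    outcome: pd.Series,
    subject_ids: pd.Series,
    n_boot: int = 500,
    seed: int = 0,
) -> list:
    """Per-composite path mediation through stiffness.

    For composite X, mediator M (stiffness) and outcome Y: a from M ~ X,
    (direct, b) from Y ~ X + M; indirect = a*b with a percentile
    bootstrap CI resampling subjects (not rows)."""
    subj = np.asarray(subject_ids)
    uniq = np.unique(subj)
    if len(uniq) < 10:
        raise ValueError("mediation requires at least 10 subjects")
    M = np.asarray(stiffness, dtype=float)
    Y = np.asarray(outcome, dtype=float)
    rng = np.random.default_rng(seed)
    subj_rows = {s: np.flatnonzero(subj == s) for s in uniq}
    boot_subjects = rng.choice(uniq, size=(n_boot, len(uniq)), replace=True)
    results = []
    for name in composites.columns:
        X = composites[name].to_numpy(dtype=float)
        a = _ols2(M, X[:, None])[1]
        coefs = _ols2(Y, np.column_stack([X, M]))
        direct, b = coefs[1], coefs[2]
        boots = np.empty(n_boot)
        for i in range(n_boot):
            rows = np.concatenate([subj_rows[s] for s in boot_subjects[i]])
            xb, mb, yb = X[rows], M[rows], Y[rows]
            try:
                ab = _ols2(mb, xb[:, None])[1]
                bb = _ols2(yb, np.column_stack([xb, mb]))[2]
                boots[i] = ab * bb
            except np.linalg.LinAlgError:
                boots[i] = np.nan
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        results.append(
            MediationResult(
                composite=name,
                direct=float(direct),
                a_path=float(a),
                b_path=float(b),
                indirect=float(a * b),
                indirect_ci=(float(lo), float(hi)),
            )
        )
    return results


def adjust_confounders(
    composites: pd.DataFrame,
    covariates: pd.DataFrame,
    fit_rows=None,
) -> pd.DataFrame:
    """Residualize composites on age, sex, and cognitive status.

    A linear model is fit per composite on the covariates (over
    ``fit_rows`` when supplied, e.g. the training fold of a
    cross-validation split) and residuals are returned for all rows.
    Collinear covariates are dropped with a warning."""
    cov = covariates.copy()
    for c in cov.columns:
        if not pd.api.types.is_numeric_dtype(cov[c]):
            cov[c] = pd.factorize(cov[c])[0]
    Xfull = cov.to_numpy(dtype=float)
    fit_idx = np.arange(len(cov)) if fit_rows is None else np.asarray(fit_rows)
    keep = []
    A = np.ones((len(fit_idx), 1))
    for j in range(Xfull.shape[1]):
        cand = np.column_stack([A, Xfull[fit_idx, j]])
        if np.linalg.matrix_rank(cand) > A.shape[1]:
            A = cand
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate {cov.columns[j]!r}")
    out = {}
    design_all = np.column_stack([np.ones(len(cov)), Xfull[:, keep]])
    design_fit = design_all[fit_idx]
    for name in composites.columns:
        y = composites[name].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(design_fit, y[fit_idx], rcond=None)
        out[name] = y - design_all @ coef
    return pd.DataFrame(out, index=composites.index)
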