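"""Downstream statistics on fitted parameters and attribution series.

Covers the four analysis families used with this task: Bayesian paired
contrasts of individual-level parameters between conditions, the
precision (inverse variance) of attribution series and its regression
on the likelihood weights, trial-wise attributional coupling (the
across-subject association of harmful-intent and self-interest ratings
at each trial, Dictator policy partialled out) and its decay, and
exploratory factor analysis of the parameter covariation with
cross-validated logistic discrimination between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

__all__ = [
    "ContrastResult",
    "RegressionResult",
    "CouplingResult",
    "FactorSolution",
    "DiscriminationResult",
    "bayesian_paired_contrast",
    "attribution_precision",
    "precision_regression",
    "trialwise_coupling",
    "coupling_contrast",
    "parameter_factor_analysis",
    "drug_discrimination_cv",
    "partial_correlation",
]


# ---------------------------------------------------------------------------
# Bayesian paired contrast
# ---------------------------------------------------------------------------


@dataclass
class ContrastResult:
    """Posterior summary of a paired condition difference."""

    median_diff: float
    hdi_low: float
    hdi_high: float
    effect_size: float
    effect_size_low: float
    effect_size_high: float
    n: int
    degenerate: bool = False


def bayesian_paired_contrast(
    x, y, *, seed: int | None = None, n_draws: int = 20_000, hdi_prob: float = 0.95
) -> ContrastResult:
    """Bayesian paired contrast of two matched condition vectors.

    The paired differences ``d = x - y`` are modelled as Gaussian with
    unknown location and scale under the Jeffreys reference prior. The
    posterior of the mean is then analytic (a scaled, shifted
    Student-t), which supplies the median difference and the central
    95% interval exactly; the posterior of Cohen's d (mean over sd) is
    summarized from conjugate Monte-Carlo draws.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("paired contrast requires n >= 3")
    d = x - y
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    lo_q = (1.0 - hdi_prob) / 2
    if sd == 0.0:
        return ContrastResult(mean, mean, mean, float("nan"), float("nan"),
                              float("nan"), n, degenerate=True)
    scale = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - lo_q, df=n - 1)
    rng = np.random.default_rng(seed)
    sig2 = (n - 1) * sd**2 / rng.chisquare(n - 1, size=n_draws)
    mu = mean + np.sqrt(sig2 / n) * rng.standard_normal(n_draws)
    es = mu / np.sqrt(sig2)
    es_q = np.quantile(es, [lo_q, 0.5, 1.0 - lo_q])
    return ContrastResult(
        median_diff=mean,
        hdi_low=mean - tcrit * scale,
        hdi_high=mean + tcrit * scale,
        effect_size=float(es_q[1]),
        effect_size_low=float(es_q[0]),
        effect_size_high=float(es_q[2]),
        n=n,
    )


# ---------------------------------------------------------------------------
# attribution precision
# ---------------------------------------------------------------------------


def attribution_precision(df: pd.DataFrame, *, by_policy: bool = False) -> pd.DataFrame:
    """Inverse variance of each subject-condition rating series.

    Returns one row per subject x condition x dimension (HI, SI), with
    the precision ``1 / var`` of the rating series pooled over all
    trials, or within each Dictator policy when ``by_policy`` is set.
    Zero-variance series are flagged (``degenerate = True``,
    ``precision = NaN``) rather than reported as infinite.
    """
    keys = ["subject", "condition"] + (["policy"] if by_policy else [])
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for dim, col in (("HI", "hi_rating"), ("SI", "si_rating")):
            series = grp[col].to_numpy(dtype=float)
            row = dict(zip(keys, key))
            row["dimension"] = dim
            row["n_trials"] = len(series)
            if len(series) < 2 or np.var(series, ddof=1) == 0.0:
                row["precision"] = float("nan")
                row["degenerate"] = True
            else:
                row["precision"] = 1.0 / float(np.var(series, ddof=1))
                row["degenerate"] = False
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    """Precision regression: coefficient table and model comparison."""

    coefficients: pd.DataFrame
    aic_quadratic: float
    aic_linear: float
    r_squared: float
    n: int
    flags: list[str] = field(default_factory=list)


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=1)
    if s <= 1e-10 * (np.abs(v).max() + 1.0):  # constant up to float dust
        return v - v.mean()
    return (v - v.mean()) / s


def precision_regression(
    precision_df: pd.DataFrame,
    params_df: pd.DataFrame,
    *,
    dimension: str = "HI",
) -> RegressionResult:
    """Regress attribution precision on the likelihood weights.

    Fits precision on wHI (linear), w0 (quadratic) and their
    interaction, with Dictator-policy terms when the precision records
    are within-policy; all regressors are centred and scaled. The AIC
    of this model is reported alongside the variant using w0 only
    linearly.
    """
    prec = precision_df[
        (precision_df["dimension"] == dimension) & (~precision_df["degenerate"])
    ]
    merged = prec.merge(params_df, on=["subject", "condition"])
    if len(merged) < 5:
        raise ValueError("too few non-degenerate records for regression")
    y = merged["precision"].to_numpy(dtype=float)
    whi = _zscore(merged["wHI"].to_numpy(dtype=float))
    w0 = _zscore(merged["w0"].to_numpy(dtype=float))

    def design(quadratic: bool) -> tuple[np.ndarray, list[str]]:
        cols = [whi, w0]
        names = ["wHI", "w0"]
        if quadratic:
            cols.append(w0**2)
            names.append("w0_sq")
        cols.append(whi * w0)
        names.append("wHI_x_w0")
        if "policy" in merged.columns:
            dummies = pd.get_dummies(merged["policy"], drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(f"policy_{c}")
                cols.append(whi * dummies[c].to_numpy(dtype=float))
                names.append(f"wHI_x_policy_{c}")
        return np.column_stack(cols), names

    flags: list[str] = []
    Xq, names_q = design(quadratic=True)
    Xl, _ = design(quadratic=False)
    mq = sm.OLS(y, sm.add_constant(Xq, has_constant="add")).fit()
    ml = sm.OLS(y, sm.add_constant(Xl, has_constant="add")).fit()
    if np.linalg.matrix_rank(Xq) < Xq.shape[1]:
        flags.append("rank-deficient design matrix")
    # standardized coefficients from a z-scored refit
    mz = sm.OLS(
        _zscore(y),
        sm.add_constant(np.column_stack([_zscore(c) for c in Xq.T]),
                        has_constant="add"),
    ).fit()
    ci = mq.conf_int()
    table = pd.DataFrame(
        {
            "term": ["intercept"] + names_q,
            "coef": mq.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "std_coef": mz.params,
        }
    )
    return RegressionResult(
        coefficients=table,
        aic_quadratic=float(mq.aic),
        aic_linear=float(ml.aic),
        r_squared=float(mq.rsquared),
        n=len(y),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# trial-wise attributional coupling
# ---------------------------------------------------------------------------


def partial_correlation(
    x, y, covariates: np.ndarray, *, method: str = "spearman"
) -> float:
    """Correlation of x and y with covariates partialled out.

    Residualizes both variables on the covariate columns (plus an
    intercept) by least squares and correlates the residuals; for the
    Spearman flavour all variables are rank-transformed first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != len(x):
        Z = Z.T
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
        Z = np.column_stack([stats.rankdata(c) for c in Z.T]) if Z.size else Z
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    D = np.column_stack([np.ones(len(x)), Z])
    rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
    ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass
class CouplingResult:
    """Trial-wise HI-SI coupling series and summaries per condition."""

    per_trial: pd.DataFrame
    summary: pd.DataFrame
    decay: pd.DataFrame
    method: str


def trialwise_coupling(df: pd.DataFrame, *, method: str = "spearman") -> CouplingResult:
    """Across-subject HI-SI coupling at each trial, policy partialled out.

    For each condition and global trial index, correlates harmful
    intent with self-interest ratings across subjects while
    controlling for the Dictator policy each subject faced on that
    trial (indicator coding). Also reports, per condition, the mean
    and sd of the per-trial coefficients and the decay statistic: the
    Pearson correlation of the coefficients with the trial index.
    """
    df = df.copy()
    df["global_trial"] = (df["partner"] - 1) * df.groupby(
        ["subject", "condition", "partner"]
    )["trial"].transform("max") + df["trial"]
    rows = []
    for cond, cgrp in df.groupby("condition", sort=True):
        for t, tgrp in cgrp.groupby("global_trial", sort=True):
            if len(tgrp) < 3:
                rows.append({"condition": cond, "trial": int(t), "rho": float("nan"),
                             "flagged": True})
                continue
            hi = tgrp["hi_rating"].to_numpy(dtype=float)
            si = tgrp["si_rating"].to_numpy(dtype=float)
            if hi.std() == 0 or si.std() == 0:
                rows.append({"condition": cond, "trial": int(t), "rho": float("nan"),
                             "flagged": True})
                continue
            dummies = pd.get_dummies(tgrp["policy"], drop_first=True).to_numpy(dtype=float)
            if dummies.size == 0:
                dummies = np.zeros((len(tgrp), 0))
            rho = partial_correlation(hi, si, dummies, method=method)
            rows.append({"condition": cond, "trial": int(t), "rho": rho,
                         "flagged": not np.isfinite(rho)})
    per_trial = pd.DataFrame(rows)

    summaries, decays = [], []
    for cond, grp in per_trial.groupby("condition", sort=True):
        ok = grp[~grp["flagged"]]
        summaries.append(
            {"condition": cond, "mean_rho": float(ok["rho"].mean()),
             "sd_rho": float(ok["rho"].std(ddof=1)), "n_trials": len(ok)}
        )
        if len(ok) >= 3:
            r, p = stats.pearsonr(ok["trial"], ok["rho"])
            decays.append({"condition": cond, "decay_r": float(r), "decay_p": float(p)})
        else:
            decays.append({"condition": cond, "decay_r": float("nan"),
                           "decay_p": float("nan")})
    return CouplingResult(
        per_trial=per_trial,
        summary=pd.DataFrame(summaries),
        decay=pd.DataFrame(decays),
        method=method,
    )


def coupling_contrast(
    result: CouplingResult, cond_a: str, cond_b: str, *, seed: int | None = None
) -> ContrastResult:
    """Paired contrast of per-trial coupling coefficients (A minus B)."""
    pt = result.per_trial
    a = pt[(pt["condition"] == cond_a) & ~pt["flagged"]].set_index("trial")["rho"]
    b = pt[(pt["condition"] == cond_b) & ~pt["flagged"]].set_index("trial")["rho"]
    common = a.index.intersection(b.index)
    return bayesian_paired_contrast(a.loc[common], b.loc[common], seed=seed)


# ---------------------------------------------------------------------------
# exploratory factor analysis
# ---------------------------------------------------------------------------


@dataclass
class FactorSolution:
    """Oblique factor solution over parameter covariation."""

    loadings: pd.DataFrame          # pattern matrix, parameters x factors
    structure: pd.DataFrame
    phi: np.ndarray                 # factor intercorrelations
    eigenvalues: np.ndarray         # of the correlation matrix (scree)
    communalities: pd.Series
    scores: pd.DataFrame            # regression-method factor scores
    residual_rms: float             # rms of off-diagonal reproduced-R residuals
    n_factors: int
    rotation: str
    converged: bool


def _varimax(L: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    p, k = L.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (Lr * (Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return L @ R


def _promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation: pattern matrix and factor correlations."""
    X = _varimax(L)
    P = X * np.abs(X) ** (power - 1)
    U = np.linalg.lstsq(X, P, rcond=None)[0]
    d = np.sqrt(np.diag(np.linalg.inv(U.T @ U)))
    U = U * d  # scale so factor variances are 1
    pattern = X @ U
    Tinv = np.linalg.inv(U)
    phi = Tinv @ Tinv.T
    return pattern, phi


def parameter_factor_analysis(
    table: pd.DataFrame,
    n_factors: int | None = None,
    *,
    rotation: str = "promax",
    max_iter: int = 200,
    tol: float = 1e-6,
) -> FactorSolution:
    """Principal-axis factoring of a parameter table with oblique rotation.

    Columns are standardized, the correlation matrix is factored by
    iterated principal axes (communalities initialized at squared
    multiple correlations) and the retained factors are obliquely
    rotated (promax). ``n_factors`` defaults to the Kaiser count
    (eigenvalues above one). Factor scores use the regression method.
    Each factor is sign-oriented so its largest-magnitude loading is
    positive.
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.isna().any().any():
        raise ValueError("parameter table must be complete (no NaNs)")
    Z = numeric.to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    p = Z.shape[1]
    R = np.corrcoef(Z, rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(R))[::-1]
    if n_factors is None:
        n_factors = max(int(np.sum(eigvals > 1.0)), 1)
    if not 1 <= n_factors < p:
        raise ValueError(f"n_factors must lie in 1..{p - 1}")
    Rinv = np.linalg.pinv(R)
    near_singular = np.min(np.linalg.eigvalsh(R)) < 1e-10

    # iterated principal-axis factoring
    h2 = np.clip(1.0 - 1.0 / np.clip(np.diag(Rinv), 1.0, None), 0.05, 0.999)
    converged = False
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:n_factors]
        L = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
        h2_new = np.clip((L**2).sum(axis=1), 0.0, 0.999)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            converged = True
            break
        h2 = h2_new

    if n_factors == 1 or rotation == "none":
        pattern, phi = L, np.eye(n_factors)
    elif rotation == "promax":
        pattern, phi = _promax(L)
    elif rotation == "varimax":
        pattern, phi = _varimax(L), np.eye(n_factors)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    # orient each factor so its dominant loading is positive
    signs = np.sign(pattern[np.argmax(np.abs(pattern), axis=0), np.arange(n_factors)])
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)

    structure = pattern @ phi
    weights = np.linalg.pinv(R) @ structure
    scores = Z @ weights
    reproduced = pattern @ phi @ pattern.T
    mask = ~np.eye(p, dtype=bool)
    residual_rms = float(np.sqrt(np.mean((R - reproduced)[mask] ** 2)))

    cols = [f"F{j + 1}" for j in range(n_factors)]
    return FactorSolution(
        loadings=pd.DataFrame(pattern, index=numeric.columns, columns=cols),
        structure=pd.DataFrame(structure, index=numeric.columns, columns=cols),
        phi=phi,
        eigenvalues=eigvals,
        communalities=pd.Series(h2, index=numeric.columns),
        scores=pd.DataFrame(scores, index=table.index, columns=cols),
        residual_rms=residual_rms,
        n_factors=n_factors,
        rotation="none" if n_factors == 1 else rotation,
        converged=converged or near_singular,
    )


# ---------------------------------------------------------------------------
# cross-validated condition discrimination
# ---------------------------------------------------------------------------


@dataclass
class DiscriminationResult:
    per_solution: pd.DataFrame      # n_factors, cv accuracy, AIC
    best_n_factors: int
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    sensitivity: float
    specificity: float
    flags: list[str] = field(default_factory=list)


def drug_discrimination_cv(
    param_table: pd.DataFrame,
    labels,
    *,
    max_factors: int = 3,
    k: int = 10,
    repeats: int = 3,
    seed: int | None = None,
) -> DiscriminationResult:
    """Repeated k-fold logistic discrimination of conditions from factors.

    For each candidate factor count, refits the factor analysis,
    cross-validates a logistic classifier of the (binary) condition
    labels on the factor scores with repeated stratified k-fold, and
    records the full-data AIC. The best solution (highest mean CV
    accuracy, ties broken by lower AIC) supplies the ROC curve, AUC
    and Youden-point sensitivity/specificity. Folds are re-stratified
    downward when a class is too small for ``k`` splits.
    """
    y = np.asarray(pd.factorize(np.asarray(labels))[0])
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    flags: list[str] = []
    min_class = int(np.bincount(y).min())
    n_splits = min(k, min_class)
    if n_splits < 2:
        raise ValueError("a class has fewer than 2 members; cannot stratify")
    if n_splits < k:
        flags.append(f"re-stratified from {k} to {n_splits} folds")

    rows = []
    solutions = {}
    for nf in range(1, max_factors + 1):
        sol = parameter_factor_analysis(param_table, n_factors=nf)
        X = sol.scores.to_numpy()
        cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=repeats,
                                     random_state=None if seed is None else seed)
        accs = cross_val_score(
            LogisticRegression(penalty=None, max_iter=1000), X, y, cv=cv,
            scoring="accuracy",
        )
        try:
            aic = float(sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200).aic)
        except Exception as exc:  # noqa: BLE001 - singular/perfect separation
            aic = float("nan")
            flags.append(f"AIC unavailable for {nf}-factor solution: "
                         f"{type(exc).__name__}")
        rows.append(
            {"n_factors": nf, "mean_accuracy": float(accs.mean()),
             "median_accuracy": float(np.median(accs)), "aic": aic}
        )
        solutions[nf] = X
    per_solution = pd.DataFrame(rows)
    order = per_solution.sort_values(
        ["mean_accuracy", "aic"], ascending=[False, True]
    )
    best_n = int(order.iloc[0]["n_factors"])

    Xb = solutions[best_n]
    clf = LogisticRegression(penalty=None, max_iter=1000).fit(Xb, y)
    prob = clf.predict_proba(Xb)[:, 1]
    fpr, tpr, thresh = roc_curve(y, prob)
    auc = float(roc_auc_score(y, prob))
    youden = int(np.argmax(tpr - fpr))
    return DiscriminationResult(
        per_solution=per_solution,
        best_n_factors=best_n,
        auc=auc,
        roc_fpr=fpr,
        roc_tpr=tpr,
        sensitivity=float(tpr[youden]),
        specificity=float(1.0 - fpr[youden]),
        flags=flags,
    )
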