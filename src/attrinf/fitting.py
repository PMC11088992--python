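"""Hierarchical random-effects fitting and comparison of the model space.

Per-subject parameters are estimated by multi-start quasi-Newton MAP in
an unconstrained native space under a Gaussian group prior, with the
model evidence approximated by Laplace's method at the mode. An
empirical-Bayes EM loop then alternates (a) subject fits under the
current group prior of each candidate model, (b) per-subject model
responsibilities proportional to model frequency times exp(evidence),
(c) responsibility-weighted updates of each model's group mean and
variance, and (d) a Dirichlet count update of the model frequencies.
Exceedance probabilities (the chance that one model is the most
frequent in the population) are Monte-Carlo estimates from the
Dirichlet posterior; the protected variant mixes with the null of
equal frequencies.

Fitting is run independently per condition, starting from the broad
native prior (mean 0, sd 6.5).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from . import transforms
from .model import (
    expected_reports,
    InvalidParameterError,
    InvalidRecordError,
    rating_to_bin,
    simulate_reports,
    trajectory_loglik,
)
from .transforms import NATIVE_PRIOR_MEAN, NATIVE_PRIOR_SD

__all__ = [
    "SubjectData",
    "SubjectFit",
    "GroupFit",
    "HBIResult",
    "RecoveryReport",
    "subject_data_from_frame",
    "split_by_condition",
    "map_fit_subject",
    "laplace_evidence",
    "hbi_fit",
    "exceedance_probabilities",
    "recovery_study",
]

logger = logging.getLogger(__name__)

_BOUND = 20.0
_HESS_STEP = 1e-4
_START_JITTER_CAP = 1.5


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """One subject-condition's trials, pre-binned for fast likelihoods."""

    outcomes: np.ndarray
    hi_bins: np.ndarray
    si_bins: np.ndarray
    block_starts: list[int]
    policies: list[str]
    subject: int | str = 0
    condition: str = ""

    @property
    def n_trials(self) -> int:
        return len(self.outcomes)

    @property
    def is_boundary(self) -> np.ndarray:
        mask = np.zeros(self.n_trials, dtype=np.bool_)
        for b in self.block_starts:
            if b != 0:
                mask[b] = True
        return mask


def subject_data_from_frame(df: pd.DataFrame) -> SubjectData:
    """Build :class:`SubjectData` from one subject-condition's rows."""
    df = df.sort_values(["partner", "trial"])
    blocks, policies = [], []
    pos = 0
    for partner, grp in df.groupby("partner", sort=True):
        blocks.append(pos)
        policies.append(str(grp["policy"].iloc[0]))
        pos += len(grp)
    return SubjectData(
        outcomes=df["outcome"].to_numpy(dtype=float),
        hi_bins=np.array([rating_to_bin(int(r)) for r in df["hi_rating"]]),
        si_bins=np.array([rating_to_bin(int(r)) for r in df["si_rating"]]),
        block_starts=blocks,
        policies=policies,
        subject=df["subject"].iloc[0],
        condition=str(df["condition"].iloc[0]),
    )


def split_by_condition(df: pd.DataFrame) -> dict[str, list[SubjectData]]:
    """Split a long-format dataset into per-condition subject lists."""
    out: dict[str, list[SubjectData]] = {}
    for (cond, _), grp in df.groupby(["condition", "subject"], sort=True):
        out.setdefault(str(cond), []).append(subject_data_from_frame(grp))
    return out


@dataclass
class SubjectFit:
    """MAP fit of one subject under one model variant."""

    variant: str
    x_map: np.ndarray
    neg_hessian: np.ndarray
    loglik: float
    log_posterior: float
    log_evidence: float
    converged: bool
    n_starts_ok: int
    responsibility: float = 1.0


@dataclass
class GroupFit:
    """Group-level result of the hierarchical fit."""

    models: list[str]
    group_means: dict[str, np.ndarray]
    group_vars: dict[str, np.ndarray]
    alphas: np.ndarray
    frequencies: np.ndarray
    exceedance: np.ndarray
    protected_exceedance: np.ndarray
    iterations: list[dict] = field(default_factory=list)
    converged: bool = True


@dataclass
class HBIResult:
    group: GroupFit
    subject_fits: dict[str, list[SubjectFit]]
    responsibilities: np.ndarray  # (n_subjects, n_models)

    def best_model(self) -> str:
        return self.group.models[int(np.argmax(self.group.frequencies))]


# ---------------------------------------------------------------------------
# subject-level estimation
# ---------------------------------------------------------------------------


from scipy.special import expit as _expit, gammaln as _gammaln

_K9 = np.arange(9)
_LOGCOEF9 = _gammaln(9) - _gammaln(_K9 + 1) - _gammaln(9 - _K9)
_XI9 = 0.02 / 81.0
_FLOOR = 1e-12


def _expand_native(x: np.ndarray, variant: str) -> tuple:
    """Native vector -> the nine model-space scalars of the full model."""
    if variant == "M1":
        return (_expit(x[0]), _expit(x[1]), np.exp(x[2]), np.exp(x[3]),
                x[6], x[7], x[8], np.exp(x[4]), _expit(x[5]))
    if variant == "M2":
        return (_expit(x[0]), _expit(x[1]), np.exp(x[2]), np.exp(x[3]),
                x[6], x[7], x[7], np.exp(x[4]), _expit(x[5]))
    if variant == "M3":
        return (_expit(x[0]), _expit(x[1]), np.exp(x[2]), np.exp(x[2]),
                x[5], x[6], x[7], np.exp(x[3]), _expit(x[4]))
    raise InvalidParameterError(f"unknown model variant {variant!r}")


def _neg_log_posterior(
    x: np.ndarray,
    data: SubjectData,
    variant: str,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
) -> float:
    from .model import _loglik_jit

    try:
        scalars = _expand_native(x, variant)
        if _loglik_jit is not None:
            ll = _loglik_jit(
                *scalars, data.outcomes, data.hi_bins - 1, data.si_bins - 1,
                data.is_boundary, 9, _XI9, _LOGCOEF9, _FLOOR,
            )
        else:  # pragma: no cover - exercised only without numba
            params = transforms.native_vector_to_params(x, variant)
            ll = trajectory_loglik(
                params, data.outcomes, data.hi_bins, data.si_bins, data.block_starts
            )
    except (InvalidParameterError, FloatingPointError, ZeroDivisionError):
        return 1e10
    lp = -0.5 * np.sum((x - prior_mean) ** 2 / prior_var) - 0.5 * np.sum(
        np.log(2 * np.pi * prior_var)
    )
    return -(ll + lp)


def _finite_diff_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                         step: float = _HESS_STEP) -> np.ndarray:
    d = len(x)
    H = np.zeros((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step**2)
    return H


def _regularize_pd(H: np.ndarray, jitter: float = 1e-6, max_tries: int = 6):
    """Force H positive-definite: diagonal jitter, then eigenvalue clipping.

    Returns the regularized matrix and a flag telling whether the
    original matrix was already (numerically) positive-definite.
    """
    d = H.shape[0]
    if d == 0:
        return H, True
    H = np.where(np.isfinite(H), H, 0.0)
    H = 0.5 * (H + H.T)
    try:
        np.linalg.cholesky(H)
        return H, True
    except np.linalg.LinAlgError:
        pass
    J = jitter
    M = H
    for _ in range(max_tries):
        M = M + J * np.eye(d)
        try:
            np.linalg.cholesky(M)
            return M, False
        except np.linalg.LinAlgError:
            J *= 10.0
    vals, vecs = np.linalg.eigh(H)
    vals = np.clip(vals, jitter, None)
    return (vecs * vals) @ vecs.T, False


def laplace_evidence(objective_at_map: float, neg_hessian: np.ndarray | None) -> float:
    """Laplace approximation to the log model evidence.

    ``objective_at_map`` is the log joint (log-likelihood plus log
    prior) at the mode and ``neg_hessian`` the negative Hessian of the
    log joint there. With no free parameters the evidence is the
    objective value itself.
    """
    if neg_hessian is None or neg_hessian.size == 0:
        return float(objective_at_map)
    d = neg_hessian.shape[0]
    sign, logdet = np.linalg.slogdet(neg_hessian)
    if sign <= 0:
        raise np.linalg.LinAlgError("negative Hessian must be positive-definite")
    return float(objective_at_map + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet)


def _multistart_minimize(fun, starts: Sequence[np.ndarray], bounds):
    """Coarse quasi-Newton pass over all starts, then polish the best."""
    best = None
    n_ok = 0
    coarse_iter = 80 if len(starts) > 1 else 400
    for x0 in starts:
        res = optimize.minimize(
            fun,
            np.clip(x0, -_BOUND, _BOUND),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": coarse_iter},
        )
        if np.isfinite(res.fun):
            # status 1 (iteration cap) still yields a usable point
            n_ok += bool(res.success or res.status == 1)
            if best is None or res.fun < best.fun:
                best = res
    if best is not None and len(starts) > 1:
        polished = optimize.minimize(
            fun, best.x, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 400},
        )
        if np.isfinite(polished.fun) and polished.fun <= best.fun:
            best = polished
    return best, n_ok


def map_fit_subject(
    data: SubjectData,
    variant: str,
    prior_mean: np.ndarray | float = NATIVE_PRIOR_MEAN,
    prior_var: np.ndarray | float = NATIVE_PRIOR_SD**2,
    *,
    n_starts: int = 10,
    rng: np.random.Generator | int | None = None,
    warm_start: np.ndarray | None = None,
) -> SubjectFit:
    """Multi-start quasi-Newton MAP fit of one subject under one variant.

    The objective is the report log-likelihood plus the Gaussian group
    log-prior in native space. Starts are the prior mean, an optional
    warm start and seeded Gaussian jitters around the prior mean (the
    jitter sd is capped so exp-transformed parameters start in a
    numerically sane range). The returned fit carries the
    finite-difference negative Hessian (regularized to positive
    definite) and the Laplace log evidence.
    """
    if data.n_trials < 1:
        raise InvalidRecordError("subject has no trials")
    d = len(transforms.free_names(variant))
    prior_mean = np.broadcast_to(np.asarray(prior_mean, dtype=float), (d,)).copy()
    prior_var = np.broadcast_to(np.asarray(prior_var, dtype=float), (d,)).copy()
    if np.any(prior_var <= 0):
        raise InvalidParameterError("prior variances must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    jitter_sd = np.minimum(np.sqrt(prior_var), _START_JITTER_CAP)
    starts: list[np.ndarray] = []
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float))
    if warm_start is None or n_starts > 1:
        starts.append(prior_mean)
    while len(starts) < max(n_starts, 1):
        starts.append(prior_mean + rng.normal(0.0, jitter_sd, size=d))

    from .model import _loglik_jit

    if _loglik_jit is not None:
        # cache the per-subject arrays outside the optimizer's hot loop
        outcomes = np.ascontiguousarray(data.outcomes, dtype=float)
        hi0 = np.ascontiguousarray(data.hi_bins - 1, dtype=np.int64)
        si0 = np.ascontiguousarray(data.si_bins - 1, dtype=np.int64)
        boundary = data.is_boundary
        log_var_term = 0.5 * np.sum(np.log(2 * np.pi * prior_var))

        def fun(x):
            try:
                ll = _loglik_jit(
                    *_expand_native(x, variant), outcomes, hi0, si0, boundary,
                    9, _XI9, _LOGCOEF9, _FLOOR,
                )
            except ZeroDivisionError:  # pragma: no cover - extreme corners
                return 1e10
            lp = -0.5 * np.sum((x - prior_mean) ** 2 / prior_var) - log_var_term
            return -(ll + lp)
    else:  # pragma: no cover - exercised only without numba
        fun = lambda x: _neg_log_posterior(x, data, variant, prior_mean, prior_var)
    bounds = [(-_BOUND, _BOUND)] * d
    best, n_ok = _multistart_minimize(fun, starts, bounds)
    converged = best is not None and n_ok > 0
    if best is None:  # pragma: no cover - all starts non-finite
        raise RuntimeError("all optimization starts failed")

    H = _finite_diff_hessian(fun, best.x)
    H, pd_ok = _regularize_pd(H)
    if not pd_ok:
        logger.debug(
            "Hessian regularized to positive-definite for subject %s", data.subject
        )
    log_post = -float(best.fun)
    params = transforms.native_vector_to_params(best.x, variant)
    ll = trajectory_loglik(
        params, data.outcomes, data.hi_bins, data.si_bins, data.block_starts
    )
    return SubjectFit(
        variant=variant,
        x_map=best.x.copy(),
        neg_hessian=H,
        loglik=float(ll),
        log_posterior=log_post,
        log_evidence=laplace_evidence(log_post, H),
        converged=bool(converged),
        n_starts_ok=int(n_ok),
    )


# ---------------------------------------------------------------------------
# hierarchical loop
# ---------------------------------------------------------------------------


def _responsibilities(log_evidence: np.ndarray, frequencies: np.ndarray) -> np.ndarray:
    """Per-subject model responsibilities (rows on the simplex)."""
    logw = log_evidence + np.log(frequencies)[None, :]
    return np.exp(logw - logsumexp(logw, axis=1, keepdims=True))


def exceedance_probabilities(
    alphas: np.ndarray,
    *,
    protected: bool = False,
    n_mc: int = 100_000,
    seed: int | np.random.Generator | None = None,
    null_weight: float = 0.5,
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities from Dirichlet counts.

    The exceedance probability of model k is the posterior chance that
    its population frequency exceeds every other model's. The
    protected variant mixes the estimate with the null of equal
    frequencies using ``null_weight``.
    """
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas <= 0):
        raise InvalidParameterError("Dirichlet counts must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.dirichlet(alphas, size=n_mc)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=len(alphas)) / n_mc
    if protected:
        return (1.0 - null_weight) * xp + null_weight / len(alphas)
    return xp


def hbi_fit(
    subjects: Sequence[SubjectData],
    models: Sequence[str] = ("M1", "M2", "M3"),
    *,
    seed: int | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    n_starts: int = 10,
    alpha0: float = 1.0,
    var_floor: float = 1e-3,
    n_mc: int = 100_000,
    null_weight: float = 0.5,
) -> HBIResult:
    """Empirical-Bayes hierarchical fit and comparison for one condition.

    Iterates subject MAP fits under each model's current group prior,
    responsibility updates, responsibility-weighted group moment
    updates (the variance update includes the Laplace posterior
    variance of each subject, preventing collapse onto the group mean)
    and a Dirichlet frequency update, until the largest change in any
    group mean falls below ``tol`` or ``max_iter`` is reached. Subjects
    are fitted with ``n_starts`` random starts on the first sweep and
    warm-started from their previous MAP afterwards.
    """
    if len(subjects) < 2:
        raise InvalidRecordError("hierarchical fitting requires >= 2 subjects")
    models = list(models)
    K, S = len(models), len(subjects)
    rng = np.random.default_rng(seed)

    means = {m: np.full(len(transforms.free_names(m)), NATIVE_PRIOR_MEAN) for m in models}
    variances = {m: np.full(len(transforms.free_names(m)), NATIVE_PRIOR_SD**2) for m in models}
    alphas = np.full(K, alpha0, dtype=float)
    freqs = alphas / alphas.sum()
    fits: dict[str, list[SubjectFit | None]] = {m: [None] * S for m in models}
    iterations: list[dict] = []
    converged = False
    # Model-comparison evidences are fixed at the first sweep, where every
    # model is evaluated under the stated broad prior (0, 6.5^2): there the
    # Laplace integral carries the classic Occam penalty for extra
    # parameters. Evidences under later, empirically adapted priors lose
    # that penalty (the adapted prior absorbs the model's flexibility), so
    # they serve parameter estimation only.
    ev_compare: np.ndarray | None = None

    for it in range(max_iter):
        t0 = time.perf_counter()
        log_ev = np.full((S, K), -np.inf)
        conv_mask = np.ones((S, K))
        for k, m in enumerate(models):
            for i, data in enumerate(subjects):
                prev = fits[m][i]
                fit = map_fit_subject(
                    data,
                    m,
                    means[m],
                    variances[m],
                    # full multistart on the first sweep; later sweeps keep a
                    # few fresh starts beside the warm start so subjects can
                    # escape stale local optima as the group prior tightens
                    n_starts=n_starts if it == 0 else min(4, n_starts),
                    rng=rng,
                    warm_start=None if prev is None else prev.x_map,
                )
                fits[m][i] = fit
                log_ev[i, k] = fit.log_evidence
                if not fit.converged:
                    conv_mask[i, k] = 0.0
                    logger.debug(
                        "flagged fit (subject %s, model %s): excluded from group update",
                        data.subject, m,
                    )

        if ev_compare is None:
            ev_compare = log_ev.copy()
        resp = _responsibilities(ev_compare, freqs)
        max_shift = 0.0
        for k, m in enumerate(models):
            r = resp[:, k] * conv_mask[:, k]
            weight = r.sum()
            X = np.stack([fits[m][i].x_map for i in range(S)])
            if weight < 1e-8:
                continue  # no subject supports this model; keep prior
            new_mean = (r[:, None] * X).sum(axis=0) / weight
            # Laplace posterior variances. An exact Hessian of the log
            # posterior would satisfy diag(inv(H)) <= prior variance in
            # every direction (the prior's curvature is part of H), so the
            # clip below only corrects finite-difference artefacts that
            # otherwise inflate inv(H) on flat directions.
            post_var = np.stack(
                [np.diag(np.linalg.inv(fits[m][i].neg_hessian)) for i in range(S)]
            )
            post_var = np.clip(post_var, 0.0, variances[m][None, :])
            dev2 = (X - new_mean[None, :]) ** 2 + post_var
            new_var = np.clip(
                (r[:, None] * dev2).sum(axis=0) / weight,
                var_floor,
                NATIVE_PRIOR_SD**2,
            )
            # convergence tracks each model's shift weighted by its
            # frequency: the group prior of a model that explains almost
            # no subjects may keep drifting without affecting the fit
            shift = float(np.max(np.abs(new_mean - means[m])))
            max_shift = max(max_shift, float(freqs[k]) * shift)
            means[m], variances[m] = new_mean, new_var

        alphas = alpha0 + resp.sum(axis=0)
        freqs = alphas / alphas.sum()
        iterations.append(
            {
                "iteration": it + 1,
                "max_mean_shift": max_shift,
                "frequencies": freqs.tolist(),
                "seconds": time.perf_counter() - t0,
            }
        )
        if max_shift < tol:
            converged = True
            break
    if not converged:
        logger.warning("hierarchical fit hit the iteration cap (%d)", max_iter)
    n_flagged = int((conv_mask == 0).sum())
    if n_flagged:
        logger.warning(
            "%d subject-model fits flagged non-converged in the final sweep", n_flagged
        )

    for k, m in enumerate(models):
        for i in range(S):
            fits[m][i].responsibility = float(resp[i, k])

    xp = exceedance_probabilities(alphas, n_mc=n_mc, seed=rng)
    pxp = (1.0 - null_weight) * xp + null_weight / K
    group = GroupFit(
        models=models,
        group_means=means,
        group_vars=variances,
        alphas=alphas,
        frequencies=freqs,
        exceedance=xp,
        protected_exceedance=pxp,
        iterations=iterations,
        converged=converged,
    )
    return HBIResult(group=group, subject_fits={m: list(fits[m]) for m in models},
                     responsibilities=resp)


# ---------------------------------------------------------------------------
# recovery study
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """True-vs-recovered parameter and attribution agreement."""

    variant: str
    n_pairs: int
    param_correlations: dict[str, float]
    param_pvalues: dict[str, float]
    min_param_r: float
    attribution_correlations: dict[str, dict[str, float]]
    min_attribution_r: float
    model_identification: dict | None
    flags: list[str]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_pairs": self.n_pairs,
            "param_correlations": self.param_correlations,
            "param_pvalues": self.param_pvalues,
            "min_param_r": self.min_param_r,
            "attribution_correlations": self.attribution_correlations,
            "min_attribution_r": self.min_attribution_r,
            "model_identification": self.model_identification,
            "flags": self.flags,
        }


def _fit_cohort(
    by_cond: dict[str, list[SubjectData]],
    models: Sequence[str],
    seed: int,
    stream: int,
    **fit_kw,
) -> dict[str, HBIResult]:
    results = {}
    for c_idx, cond in enumerate(sorted(by_cond)):
        fit_seed = int(
            np.random.SeedSequence([int(seed) % 2**31, stream, c_idx])
            .generate_state(1)[0] % 2**31
        )
        results[cond] = hbi_fit(by_cond[cond], models, seed=fit_seed, **fit_kw)
    return results


def recovery_study(
    spec,
    variant: str = "M3",
    seed: int = 0,
    *,
    models: Sequence[str] | None = None,
    n_starts: int = 10,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> RecoveryReport:
    """Two-stage parameter and generative recovery study.

    Stage 1 generates a reference cohort from ``spec`` and fits it
    hierarchically, per condition, yielding one individual-level
    parameter set per subject-condition (the stand-in for parameters
    approximated from experimental data). Stage 2 simulates a replica
    cohort from exactly those fitted parameter sets (same partners and
    outcome sequences) and re-estimates them with the same procedure.

    Parameter recovery correlates the stage-1 parameter sets with their
    stage-2 re-estimates in native space, pooled over all
    subject-condition pairs. Generative recovery compares the stage-1
    model's posterior-mean attribution series against the fitted-to
    ratings within every Dictator policy, separately per dimension.
    With more than one candidate model, stage 1 also reports model
    identification (best-model counts, mean frequencies, exceedance).
    """
    from .simulate import generate_cohort_dataset  # local to avoid cycle

    models = [variant] if models is None else list(models)
    dataset, _ = generate_cohort_dataset(spec, variant, seed)
    by_cond = split_by_condition(dataset)
    names = transforms.free_names(variant)
    flags: list[str] = []

    fit_kw = dict(n_starts=n_starts, max_iter=max_iter, tol=tol)
    stage1 = _fit_cohort(by_cond, models, seed, stream=7, **fit_kw)

    # generative recovery + replica construction from stage-1 fits
    attr_pools: dict[tuple[str, str], list[tuple[float, float]]] = {}
    model_counts: dict[str, int] = {m: 0 for m in models}
    freq_accum = np.zeros(len(models))
    xp_accum = np.zeros(len(models))
    replica_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, 101])
    )
    replica_by_cond: dict[str, list[SubjectData]] = {}
    stage1_rows = []
    for cond, subject_list in sorted(by_cond.items()):
        result = stage1[cond]
        freq_accum += result.group.frequencies
        xp_accum += result.group.exceedance
        replica_by_cond[cond] = []
        for i, data in enumerate(subject_list):
            best_k = int(np.argmax(result.responsibilities[i]))
            model_counts[models[best_k]] += 1
            fit = result.subject_fits[variant][i]
            stage1_rows.append(
                {"subject": data.subject, "condition": cond}
                | {f"native_{n}": fit.x_map[j] for j, n in enumerate(names)}
            )
            params = transforms.native_vector_to_params(fit.x_map, variant)
            predicted = expected_reports(
                params, data.outcomes, block_starts=data.block_starts
            )
            starts = list(data.block_starts) + [data.n_trials]
            for b, policy in enumerate(data.policies):
                for t in range(starts[b], starts[b + 1]):
                    orig_hi = (data.hi_bins[t] - 0.5) * 100 / 9
                    orig_si = (data.si_bins[t] - 0.5) * 100 / 9
                    attr_pools.setdefault((policy, "HI"), []).append(
                        (orig_hi, predicted[t, 0])
                    )
                    attr_pools.setdefault((policy, "SI"), []).append(
                        (orig_si, predicted[t, 1])
                    )
            replica = simulate_reports(
                params, data.outcomes, replica_rng, block_starts=data.block_starts
            )
            replica_by_cond[cond].append(
                SubjectData(
                    outcomes=data.outcomes.copy(),
                    hi_bins=np.array([rating_to_bin(r.hi_rating) for r in replica]),
                    si_bins=np.array([rating_to_bin(r.si_rating) for r in replica]),
                    block_starts=list(data.block_starts),
                    policies=list(data.policies),
                    subject=data.subject,
                    condition=cond,
                )
            )

    # stage 2: re-estimate the replica cohort (single generating variant)
    stage2 = _fit_cohort(replica_by_cond, [variant], seed, stream=13, **fit_kw)
    stage2_rows = []
    for cond, subject_list in sorted(replica_by_cond.items()):
        for i, data in enumerate(subject_list):
            fit = stage2[cond].subject_fits[variant][i]
            stage2_rows.append(
                {"subject": data.subject, "condition": cond}
                | {f"native_{n}": fit.x_map[j] for j, n in enumerate(names)}
            )

    merged = pd.DataFrame(stage1_rows).merge(
        pd.DataFrame(stage2_rows), on=["subject", "condition"],
        suffixes=("_true", "_fit"),
    )
    param_r, param_p = {}, {}
    for name in names:
        x = merged[f"native_{name}_true"].to_numpy()
        y = merged[f"native_{name}_fit"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            flags.append(f"constant series for parameter {name}; correlation undefined")
            param_r[name], param_p[name] = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(x, y)
            param_r[name], param_p[name] = float(r), float(p)

    attr_r: dict[str, dict[str, float]] = {}
    for (policy, dim), pairs in sorted(attr_pools.items()):
        arr = np.asarray(pairs)
        if np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
            flags.append(f"constant attribution series for {policy}/{dim}")
            r = float("nan")
        else:
            r = float(stats.pearsonr(arr[:, 0], arr[:, 1])[0])
        attr_r.setdefault(policy, {})[dim] = r

    finite_pr = [v for v in param_r.values() if np.isfinite(v)]
    finite_ar = [v for d in attr_r.values() for v in d.values() if np.isfinite(v)]
    ident = None
    if len(models) > 1:
        n_cond = len(by_cond)
        ident = {
            "best_model_counts": model_counts,
            "mean_frequencies": dict(zip(models, (freq_accum / n_cond).tolist())),
            "mean_exceedance": dict(zip(models, (xp_accum / n_cond).tolist())),
        }
    return RecoveryReport(
        variant=variant,
        n_pairs=len(merged),
        param_correlations=param_r,
        param_pvalues=param_p,
        min_param_r=float(min(finite_pr)) if finite_pr else float("nan"),
        attribution_correlations=attr_r,
        min_attribution_r=float(min(finite_ar)) if finite_ar else float("nan"),
        model_identification=ident,
        flags=flags,
    )
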