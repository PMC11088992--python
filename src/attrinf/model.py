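"""Generative model of paired intentional attributions in an iterated
Dictator game.

An observer repeatedly receives either a fair split (the partner takes
half the stake, ``rew = 0.5``) or an unfair outcome (the partner takes
everything, ``rew = 0``) and, after each trial, rates on a 1-100 scale
how strongly the partner seemed motivated by *harmful intent* (HI, a
self-relevant motive: wanting to reduce the observer's payoff) and by
*self-interest* (SI, an other-relevant motive: wanting to earn more).

The model represents the observer's belief as a joint probability table
over discretized HI x SI levels (``NB = 9`` bins per dimension):

* **Priors.** Each marginal starts as a binomial pmf ``B(k; NB-1, p0)``
  raised elementwise to ``1/u`` and renormalized, where ``p0`` sets the
  location of the prior and ``u > 0`` flattens it (large ``u`` tends to
  the uniform distribution). The joint prior is the outer product of
  the two marginals.
* **Policy likelihood.** The perceived probability that a partner of
  character (HI, SI) acts unfairly is a logistic function of the
  centred bin values: ``pi(rew=0; HI, SI) = sigma(w0 + wHI*(HI-delta) +
  wSI*(SI-delta))`` with ``delta = (NB+1)/2``; the fair probability is
  its complement.
* **Update.** Beliefs are revised by elementwise Bayes' rule with the
  observed outcome's likelihood slice.
* **Consistency.** The posterior is tempered, ``p^(1/u_pi)``, a small
  constant ``xi = 0.02 / NB**2`` is added to every cell, and the table
  is renormalized. Large ``u_pi`` washes out the impact of behaviour
  (the partner is not believed to act in character).
* **Change point.** On meeting a new partner the starting belief is a
  convex blend ``(1-eta) * prior + eta * last posterior``: ``eta = 0``
  resets fully to the prior, ``eta = 1`` carries the last encounter
  over unchanged.

Reported ratings are linked to the grid by equal-width bins: the
response log-likelihood is the log mass of the jointly indexed cell,
and simulated agents sample a cell from the joint table and report its
bin centres.

Three nested variants restrict the free parameters: M1 is the full
model, M2 shares one likelihood weight (``wHI = wSI``), and M3 shares
one prior uncertainty (``uPri_HI = uPri_SI``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "NB",
    "MODEL_VARIANTS",
    "VARIANT_FREE_PARAMS",
    "InvalidParameterError",
    "InvalidRecordError",
    "DegenerateGridError",
    "BeliefGrid",
    "ModelParams",
    "PolicyLikelihood",
    "TrialRecord",
    "SubjectTrajectory",
    "discretized_binomial_prior",
    "build_joint_prior",
    "build_policy_likelihood",
    "bayes_update",
    "apply_consistency",
    "partner_change_blend",
    "rating_to_bin",
    "bin_to_rating",
    "report_loglik",
    "run_subject",
    "trajectory_loglik",
    "simulate_reports",
    "expected_reports",
    "default_xi",
]

#: number of bins per attribution dimension
NB = 9

#: additive regularizer in the consistency rule, scaled by 1/NB**2
XI_NUMERATOR = 0.02

#: floor applied inside report_loglik to guard log(0)
LOG_FLOOR = 1e-12

_NORM_TOL = 1e-10

MODEL_VARIANTS = ("M1", "M2", "M3")

#: free (native-space) parameter names per model variant, in canonical order
VARIANT_FREE_PARAMS = {
    "M1": ("pHI0", "pSI0", "uPri_HI", "uPri_SI", "u_pi", "eta", "w0", "wHI", "wSI"),
    "M2": ("pHI0", "pSI0", "uPri_HI", "uPri_SI", "u_pi", "eta", "w0", "w"),
    "M3": ("pHI0", "pSI0", "uPri", "u_pi", "eta", "w0", "wHI", "wSI"),
}


class InvalidParameterError(ValueError):
    """A model parameter is non-finite or outside its admissible range."""


class InvalidRecordError(ValueError):
    """A trial record violates the task's schema (ratings, outcome, order)."""


class DegenerateGridError(RuntimeError):
    """A belief table lost all its mass (cannot happen with sigmoid slices)."""


def default_xi(nb: int = NB) -> float:
    """Regularizer added in the consistency rule: ``0.02 / nb**2``."""
    return XI_NUMERATOR / nb**2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class BeliefGrid:
    """Normalized joint probability table over (HI bin, SI bin).

    Rows index harmful-intent bins ``1..nb`` and columns self-interest
    bins ``1..nb``. Cells are nonnegative and sum to one within 1e-10;
    every public operation in this module returns a grid satisfying the
    same contract.
    """

    __slots__ = ("probs",)

    def __init__(self, probs: np.ndarray, *, check: bool = True):
        probs = np.asarray(probs, dtype=float)
        if check:
            if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
                raise InvalidParameterError("belief grid must be a square table")
            if not np.all(np.isfinite(probs)) or np.any(probs < 0):
                raise InvalidParameterError("belief grid cells must be finite and >= 0")
            if abs(probs.sum() - 1.0) > _NORM_TOL:
                raise InvalidParameterError(
                    f"belief grid must sum to 1 (got {probs.sum()!r})"
                )
        self.probs = probs

    @property
    def nb(self) -> int:
        return self.probs.shape[0]

    def marginal_hi(self) -> np.ndarray:
        """Marginal distribution over harmful-intent bins."""
        return self.probs.sum(axis=1)

    def marginal_si(self) -> np.ndarray:
        """Marginal distribution over self-interest bins."""
        return self.probs.sum(axis=0)

    def mean_bins(self) -> tuple[float, float]:
        """Expected (HI, SI) bin index, 1-based."""
        bins = np.arange(1, self.nb + 1)
        return float(self.marginal_hi() @ bins), float(self.marginal_si() @ bins)

    def copy(self) -> "BeliefGrid":
        return BeliefGrid(self.probs.copy(), check=False)

    def to_csv(self, path) -> None:
        """Export the table as a plain nb x nb CSV for inspection."""
        np.savetxt(path, self.probs, delimiter=",")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        hi, si = self.mean_bins()
        return f"BeliefGrid(nb={self.nb}, mean_bins=({hi:.2f}, {si:.2f}))"


@dataclass(frozen=True)
class ModelParams:
    """Model-space parameters of the attribution model.

    ``pHI0``/``pSI0`` locate the binomial priors in (0, 1); ``uPri_HI``/
    ``uPri_SI`` (> 0) flatten them. ``w0``, ``wHI``, ``wSI`` parametrize
    the policy likelihood; ``u_pi`` (> 0) is the consistency noise and
    ``eta`` in [0, 1] the change-point carry-over. The ``variant`` mask
    ties parameters together: M2 forces ``wHI == wSI`` and M3 forces
    ``uPri_HI == uPri_SI``.
    """

    pHI0: float
    pSI0: float
    uPri_HI: float
    uPri_SI: float
    w0: float
    wHI: float
    wSI: float
    u_pi: float
    eta: float
    variant: str = "M1"

    def __post_init__(self):
        vals = [self.pHI0, self.pSI0, self.uPri_HI, self.uPri_SI,
                self.w0, self.wHI, self.wSI, self.u_pi, self.eta]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("all parameters must be finite")
        for name in ("pHI0", "pSI0"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidParameterError(f"{name} must lie in (0, 1), got {v}")
        for name in ("uPri_HI", "uPri_SI", "u_pi"):
            v = getattr(self, name)
            if v <= 0.0:
                raise InvalidParameterError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.eta <= 1.0:
            raise InvalidParameterError(f"eta must lie in [0, 1], got {self.eta}")
        if self.variant not in MODEL_VARIANTS:
            raise InvalidParameterError(f"unknown model variant {self.variant!r}")
        if self.variant == "M2" and self.wHI != self.wSI:
            raise InvalidParameterError("variant M2 requires wHI == wSI")
        if self.variant == "M3" and self.uPri_HI != self.uPri_SI:
            raise InvalidParameterError("variant M3 requires uPri_HI == uPri_SI")

    @classmethod
    def from_free(cls, variant: str, **values: float) -> "ModelParams":
        """Build from the variant's free parameters.

        M2 accepts the shared weight as ``w``; M3 accepts the shared
        prior uncertainty as ``uPri``.
        """
        if variant not in MODEL_VARIANTS:
            raise InvalidParameterError(f"unknown model variant {variant!r}")
        names = VARIANT_FREE_PARAMS[variant]
        missing = set(names) - set(values)
        extra = set(values) - set(names)
        if missing or extra:
            raise InvalidParameterError(
                f"variant {variant} expects parameters {names}; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        kw = dict(values)
        if variant == "M2":
            w = kw.pop("w")
            kw["wHI"] = kw["wSI"] = w
        if variant == "M3":
            u = kw.pop("uPri")
            kw["uPri_HI"] = kw["uPri_SI"] = u
        return cls(variant=variant, **kw)

    def free_values(self) -> dict[str, float]:
        """Free parameters of this variant as an ordered dict."""
        out: dict[str, float] = {}
        for name in VARIANT_FREE_PARAMS[self.variant]:
            if name == "w":
                out[name] = self.wHI
            elif name == "uPri":
                out[name] = self.uPri_HI
            else:
                out[name] = getattr(self, name)
        return out

    @property
    def n_free(self) -> int:
        return len(VARIANT_FREE_PARAMS[self.variant])


@dataclass(frozen=True)
class PolicyLikelihood:
    """Perceived partner policy, ``pi_gen(rew; HI, SI)``.

    ``p_unfair[i, j]`` is the probability that a partner of character
    (HI bin i+1, SI bin j+1) takes everything; the fair probability is
    its exact complement, so the two slices sum to one cellwise.
    """

    p_unfair: np.ndarray

    @property
    def nb(self) -> int:
        return self.p_unfair.shape[0]

    @property
    def delta(self) -> float:
        """Grid centre ``(NB + 1) / 2`` used to centre the bin values."""
        return (self.nb + 1) / 2

    def slice(self, outcome: float) -> np.ndarray:
        """Likelihood table for one observed outcome (0 unfair, 0.5 fair)."""
        _check_outcome(outcome)
        return self.p_unfair if outcome == 0.0 else 1.0 - self.p_unfair


@dataclass(frozen=True)
class TrialRecord:
    """One Dictator trial: the partner's action and the two ratings."""

    partner_id: int
    trial_index: int
    outcome: float
    hi_rating: int
    si_rating: int

    def __post_init__(self):
        _check_outcome(self.outcome)
        for name in ("hi_rating", "si_rating"):
            r = getattr(self, name)
            if not (isinstance(r, (int, np.integer)) and 1 <= r <= 100):
                raise InvalidRecordError(f"{name} must be an integer in 1..100, got {r!r}")
        if self.trial_index < 1:
            raise InvalidRecordError(f"trial_index must be >= 1, got {self.trial_index}")


@dataclass
class SubjectTrajectory:
    """Output of :func:`run_subject`: belief sequence and likelihood."""

    grids: list[BeliefGrid]
    loglik: float
    trial_logliks: np.ndarray


def _check_outcome(outcome: float) -> None:
    if outcome not in (0.0, 0.5):
        raise InvalidRecordError(
            f"outcome must be 0 (unfair) or 0.5 (fair), got {outcome!r}"
        )


# ---------------------------------------------------------------------------
# grid operations
# ---------------------------------------------------------------------------


def _binomial_marginal(p0: float, u: float, nb: int) -> np.ndarray:
    # log pmf of B(k; nb-1, p0), tempered by 1/u, softmax-normalized.
    k = np.arange(nb)
    n = nb - 1
    logpmf = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * math.log(p0) + (n - k) * math.log1p(-p0)
    )
    w = logpmf / u
    w -= w.max()
    p = np.exp(w)
    return p / p.sum()


def discretized_binomial_prior(p0: float, u: float, nb: int = NB) -> np.ndarray:
    """Binomial prior marginal with uncertainty ``u`` over ``nb`` bins.

    Evaluates ``B(k; nb-1, p0)`` at ``k = bin - 1``, raises the pmf
    elementwise to ``1/u`` and renormalizes. ``u = 1`` recovers the
    plain binomial; ``u -> inf`` tends to the uniform distribution.
    """
    if not (math.isfinite(p0) and 0.0 < p0 < 1.0):
        raise InvalidParameterError(f"p0 must lie in (0, 1), got {p0!r}")
    if not (math.isfinite(u) and u > 0.0):
        raise InvalidParameterError(f"u must be positive, got {u!r}")
    if nb < 2:
        raise InvalidParameterError("nb must be >= 2")
    return _binomial_marginal(p0, u, nb)


def build_joint_prior(params: ModelParams, nb: int = NB) -> BeliefGrid:
    """Joint prior as the outer product of the HI and SI marginals."""
    hi = discretized_binomial_prior(params.pHI0, params.uPri_HI, nb)
    si = discretized_binomial_prior(params.pSI0, params.uPri_SI, nb)
    return BeliefGrid(np.outer(hi, si), check=False)


def build_policy_likelihood(
    w0: float, wHI: float, wSI: float, nb: int = NB
) -> PolicyLikelihood:
    """Logistic policy likelihood over the (HI, SI) grid.

    ``pi(rew=0; HI, SI) = sigma(w0 + wHI*(HI - delta) + wSI*(SI - delta))``
    with ``delta = (nb + 1) / 2`` so that ``w0`` is the log-odds of an
    unfair act at the grid centre.
    """
    if not all(math.isfinite(v) for v in (w0, wHI, wSI)):
        raise InvalidParameterError("likelihood weights must be finite")
    centred = np.arange(1, nb + 1) - (nb + 1) / 2
    logits = w0 + wHI * centred[:, None] + wSI * centred[None, :]
    return PolicyLikelihood(p_unfair=expit(logits))


def bayes_update(grid: BeliefGrid, lik: PolicyLikelihood, outcome: float) -> BeliefGrid:
    """Bayes' rule on the joint table with the observed outcome's slice."""
    post = grid.probs * lik.slice(outcome)
    total = post.sum()
    if total <= 0.0:
        raise DegenerateGridError("posterior lost all probability mass")
    return BeliefGrid(post / total, check=False)


def apply_consistency(
    grid: BeliefGrid, u_pi: float, xi: float | None = None
) -> BeliefGrid:
    """Temper the posterior and regularize it.

    Raises every cell to ``1/u_pi``, adds ``xi`` (default
    ``0.02/nb**2``) and renormalizes. Higher ``u_pi`` reduces
    consistency: the partner's behaviour has less impact on beliefs,
    and ``u_pi -> inf`` drives the table to uniform.

    The ``xi`` argument exists as a hook for exactness checks; the
    model itself always uses the fixed default.
    """
    if not (math.isfinite(u_pi) and u_pi > 0.0):
        raise InvalidParameterError(f"u_pi must be positive, got {u_pi!r}")
    if xi is None:
        xi = default_xi(grid.nb)
    g = grid.probs ** (1.0 / u_pi) + xi
    return BeliefGrid(g / g.sum(), check=False)


def partner_change_blend(
    prior: BeliefGrid, posterior_final: BeliefGrid, eta: float
) -> BeliefGrid:
    """Starting belief for a new partner: ``(1-eta)*prior + eta*posterior``."""
    if not (math.isfinite(eta) and 0.0 <= eta <= 1.0):
        raise InvalidParameterError(f"eta must lie in [0, 1], got {eta!r}")
    mixed = (1.0 - eta) * prior.probs + eta * posterior_final.probs
    return BeliefGrid(mixed, check=False)


def rating_to_bin(rating: int, nb: int = NB) -> int:
    """Map a 1-100 rating onto an equal-width bin index in ``1..nb``."""
    if not (1 <= rating <= 100):
        raise InvalidRecordError(f"rating must lie in 1..100, got {rating!r}")
    return min(max(math.ceil(rating * nb / 100), 1), nb)


def bin_to_rating(b: int, nb: int = NB) -> int:
    """Inverse map: the centre of bin ``b`` on the 1-100 rating scale."""
    if not (1 <= b <= nb):
        raise InvalidRecordError(f"bin must lie in 1..{nb}, got {b!r}")
    return int(round((b - 0.5) * 100 / nb))


def report_loglik(grid: BeliefGrid, hi_bin: int, si_bin: int) -> float:
    """Log joint mass of the reported (HI, SI) cell, floored at 1e-12."""
    nb = grid.nb
    if not (1 <= hi_bin <= nb and 1 <= si_bin <= nb):
        raise InvalidRecordError(f"bins must lie in 1..{nb}, got ({hi_bin}, {si_bin})")
    return math.log(max(grid.probs[hi_bin - 1, si_bin - 1], LOG_FLOOR))


# ---------------------------------------------------------------------------
# forward runs
# ---------------------------------------------------------------------------


def _blocks_from_partners(partner_ids: Sequence[int]) -> list[int]:
    starts = [0]
    for t in range(1, len(partner_ids)):
        if partner_ids[t] != partner_ids[t - 1]:
            starts.append(t)
    return starts


def _forward_engine(
    params: ModelParams,
    outcomes: np.ndarray,
    block_starts: Sequence[int],
    nb: int,
    *,
    hi_idx: np.ndarray | None = None,
    si_idx: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    collect: bool = False,
):
    """Shared trial loop.

    Scores reports when ``hi_idx``/``si_idx`` (0-based cell indices) are
    given; samples reports when ``rng`` is given; optionally collects
    the per-trial belief tables.
    """
    prior = build_joint_prior(params, nb).probs
    lik = build_policy_likelihood(params.w0, params.wHI, params.wSI, nb)
    lu, lf = lik.p_unfair, 1.0 - lik.p_unfair
    xi = default_xi(nb)
    inv_upi = 1.0 / params.u_pi
    boundary = set(b for b in block_starts if b != 0)

    g = prior.copy()
    n_trials = len(outcomes)
    logliks = np.zeros(n_trials)
    sampled = np.zeros((n_trials, 2), dtype=int) if rng is not None else None
    grids: list[np.ndarray] = []

    for t in range(n_trials):
        if t in boundary:
            g = (1.0 - params.eta) * prior + params.eta * g
        g = g * (lu if outcomes[t] == 0.0 else lf)
        total = g.sum()
        if total <= 0.0:
            raise DegenerateGridError("posterior lost all probability mass")
        g = g / total
        g = g ** inv_upi + xi
        g = g / g.sum()
        if collect:
            grids.append(g.copy())
        if hi_idx is not None:
            logliks[t] = math.log(max(g[hi_idx[t], si_idx[t]], LOG_FLOOR))
        if rng is not None:
            cum = np.cumsum(g.ravel())
            cell = int(np.searchsorted(cum, rng.random() * cum[-1]))
            sampled[t] = divmod(min(cell, nb * nb - 1), nb)

    return g, logliks, sampled, grids


def run_subject(
    params: ModelParams, trials: Sequence[TrialRecord], *, collect_grids: bool = True
) -> SubjectTrajectory:
    """Run the full generative model over one subject's trial sequence.

    Trials must be grouped by partner in presentation order. Each trial
    applies the Bayesian update with the observed outcome, then the
    consistency rule, and scores the reported ratings on the resulting
    grid; each partner boundary blends the raw prior with the previous
    partner's final belief using ``eta``.
    """
    if len(trials) == 0:
        raise InvalidRecordError("trial list must not be empty")
    partner_ids = [tr.partner_id for tr in trials]
    if len(set(partner_ids)) != len(_blocks_from_partners(partner_ids)):
        raise InvalidRecordError("trials must be grouped contiguously by partner")
    outcomes = np.array([tr.outcome for tr in trials])
    hi_idx = np.array([rating_to_bin(tr.hi_rating) - 1 for tr in trials])
    si_idx = np.array([rating_to_bin(tr.si_rating) - 1 for tr in trials])
    blocks = _blocks_from_partners(partner_ids)
    _, logliks, _, grids = _forward_engine(
        params, outcomes, blocks, NB, hi_idx=hi_idx, si_idx=si_idx, collect=collect_grids
    )
    return SubjectTrajectory(
        grids=[BeliefGrid(g, check=False) for g in grids],
        loglik=float(logliks.sum()),
        trial_logliks=logliks,
    )


def trajectory_loglik(
    params: ModelParams,
    outcomes: np.ndarray,
    hi_bins: np.ndarray,
    si_bins: np.ndarray,
    block_starts: Sequence[int],
    nb: int = NB,
) -> float:
    """Total report log-likelihood for pre-binned data (fast fitting path).

    ``hi_bins``/``si_bins`` are 1-based bin indices; ``block_starts``
    are 0-based indices of the first trial of each partner. Uses a
    compiled kernel when numba is available; the result is identical
    to scoring :func:`run_subject` on the same data.
    """
    if len(outcomes) == 0:
        raise InvalidRecordError("outcome sequence must not be empty")
    outcomes = np.asarray(outcomes, dtype=float)
    hi_idx = np.asarray(hi_bins, dtype=np.int64) - 1
    si_idx = np.asarray(si_bins, dtype=np.int64) - 1
    if _loglik_jit is not None:
        is_boundary = np.zeros(len(outcomes), dtype=np.bool_)
        for b in block_starts:
            if b != 0:
                is_boundary[b] = True
        n = nb - 1
        k = np.arange(nb)
        logcoef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        return float(
            _loglik_jit(
                params.pHI0, params.pSI0, params.uPri_HI, params.uPri_SI,
                params.w0, params.wHI, params.wSI, params.u_pi, params.eta,
                outcomes, hi_idx, si_idx, is_boundary, nb, default_xi(nb),
                logcoef, LOG_FLOOR,
            )
        )
    _, logliks, _, _ = _forward_engine(
        params, outcomes, block_starts, nb, hi_idx=hi_idx, si_idx=si_idx
    )
    return float(logliks.sum())


def _build_loglik_jit():
    """Compile the hot likelihood kernel; None when numba is unavailable."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba present in supported envs
        return None

    @njit(cache=True)
    def kernel(pHI0, pSI0, uHI, uSI, w0, wHI, wSI, u_pi, eta,
               outcomes, hi_idx, si_idx, is_boundary, nb, xi, logcoef, floor):
        n = nb - 1
        lp0 = np.log(pHI0)
        lq0 = np.log1p(-pHI0)
        lp1 = np.log(pSI0)
        lq1 = np.log1p(-pSI0)
        mhi = np.empty(nb)
        msi = np.empty(nb)
        mx0 = -1e300
        mx1 = -1e300
        for k in range(nb):
            mhi[k] = (logcoef[k] + k * lp0 + (n - k) * lq0) / uHI
            msi[k] = (logcoef[k] + k * lp1 + (n - k) * lq1) / uSI
            if mhi[k] > mx0:
                mx0 = mhi[k]
            if msi[k] > mx1:
                mx1 = msi[k]
        s0 = 0.0
        s1 = 0.0
        for k in range(nb):
            mhi[k] = np.exp(mhi[k] - mx0)
            msi[k] = np.exp(msi[k] - mx1)
            s0 += mhi[k]
            s1 += msi[k]
        prior = np.empty((nb, nb))
        for i in range(nb):
            for j in range(nb):
                prior[i, j] = (mhi[i] / s0) * (msi[j] / s1)
        delta = (nb + 1) / 2.0
        lu = np.empty((nb, nb))
        for i in range(nb):
            for j in range(nb):
                z = w0 + wHI * (i + 1 - delta) + wSI * (j + 1 - delta)
                if z >= 0.0:
                    lu[i, j] = 1.0 / (1.0 + np.exp(-z))
                else:
                    ez = np.exp(z)
                    lu[i, j] = ez / (1.0 + ez)
        g = prior.copy()
        inv_upi = 1.0 / u_pi
        ll = 0.0
        for t in range(len(outcomes)):
            if is_boundary[t]:
                for i in range(nb):
                    for j in range(nb):
                        g[i, j] = (1.0 - eta) * prior[i, j] + eta * g[i, j]
            tot = 0.0
            if outcomes[t] == 0.0:
                for i in range(nb):
                    for j in range(nb):
                        g[i, j] = g[i, j] * lu[i, j]
                        tot += g[i, j]
            else:
                for i in range(nb):
                    for j in range(nb):
                        g[i, j] = g[i, j] * (1.0 - lu[i, j])
                        tot += g[i, j]
            if tot <= 0.0:
                # all mass annihilated (possible only in extreme corners
                # of the parameter space where the likelihood slice
                # underflows to exactly zero on a one-hot belief)
                return -1e12
            tot2 = 0.0
            for i in range(nb):
                for j in range(nb):
                    g[i, j] = (g[i, j] / tot) ** inv_upi + xi
                    tot2 += g[i, j]
            for i in range(nb):
                for j in range(nb):
                    g[i, j] = g[i, j] / tot2
            cell = g[hi_idx[t], si_idx[t]]
            if cell < floor:
                cell = floor
            ll += np.log(cell)
        return ll

    return kernel


_loglik_jit = _build_loglik_jit()


def simulate_reports(
    params: ModelParams,
    outcomes: Sequence[float],
    seed: int | np.random.Generator,
    block_starts: Sequence[int] | None = None,
) -> list[TrialRecord]:
    """Simulate rating reports for a fixed outcome sequence.

    After each update + consistency step a (HI, SI) cell is sampled
    from the current joint belief and reported as the cell's bin
    centres on the 1-100 scale. Deterministic given the seed.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    for o in outcomes:
        _check_outcome(float(o))
    if block_starts is None:
        block_starts = [0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, _, sampled, _ = _forward_engine(params, outcomes, block_starts, NB, rng=rng)
    return _records_from_bins(outcomes, block_starts, sampled[:, 0] + 1, sampled[:, 1] + 1)


def expected_reports(
    params: ModelParams,
    outcomes: Sequence[float],
    block_starts: Sequence[int] | None = None,
) -> np.ndarray:
    """Deterministic posterior-mean ratings, shape (n_trials, 2).

    Column 0 is the expected HI rating, column 1 the expected SI
    rating, each the belief-weighted average of bin centres.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    if block_starts is None:
        block_starts = [0]
    _, _, _, grids = _forward_engine(params, outcomes, block_starts, NB, collect=True)
    centres = np.array([(b - 0.5) * 100 / NB for b in range(1, NB + 1)])
    out = np.zeros((len(outcomes), 2))
    for t, g in enumerate(grids):
        out[t, 0] = g.sum(axis=1) @ centres
        out[t, 1] = g.sum(axis=0) @ centres
    return out


def _records_from_bins(outcomes, block_starts, hi_bins, si_bins) -> list[TrialRecord]:
    starts = sorted(block_starts) + [len(outcomes)]
    records = []
    for p, (a, b) in enumerate(zip(starts[:-1], starts[1:]), start=1):
        for t in range(a, b):
            records.append(
                TrialRecord(
                    partner_id=p,
                    trial_index=t - a + 1,
                    outcome=float(outcomes[t]),
                    hi_rating=bin_to_rating(int(hi_bins[t])),
                    si_rating=bin_to_rating(int(si_bins[t])),
                )
            )
    return records
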