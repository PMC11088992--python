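"""Seeded synthetic cohorts for the three-partner Sharing Game.

Emulates the study design: each subject plays 6 trials against each of
three Dictators whose policies are "always take half" (fair), "50:50
chance" (partially fair) and "always take all" (unfair), under three
within-subject drug-like conditions, and rates harmful intent and
self-interest after every trial. Ratings are generated from the grid
model with per-subject parameters drawn around condition presets; the
haloperidol-like preset shifts the likelihood weight on harmful intent
(wHI) and the carry-over weight (eta) upward and pulls the policy
intercept (w0) toward zero relative to the placebo-like preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import transforms
from .model import (
    InvalidParameterError,
    ModelParams,
    simulate_reports,
)

__all__ = [
    "POLICY_LABELS",
    "DictatorPolicy",
    "ConditionPreset",
    "CohortSpec",
    "default_conditions",
    "generate_policy_sequence",
    "sample_cohort_params",
    "generate_cohort_dataset",
]

POLICY_LABELS = ("fair", "partially_fair", "unfair")

_P_UNFAIR = {"fair": 0.0, "partially_fair": 0.5, "unfair": 1.0}


class InvalidPolicyError(ValueError):
    """Unknown Dictator policy label."""


@dataclass(frozen=True)
class DictatorPolicy:
    """A Dictator's behavioural policy: per-trial probability of taking all."""

    label: str
    p_unfair: float

    @classmethod
    def from_label(cls, label: str) -> "DictatorPolicy":
        if label not in _P_UNFAIR:
            raise InvalidPolicyError(f"unknown policy {label!r}; expected {POLICY_LABELS}")
        return cls(label=label, p_unfair=_P_UNFAIR[label])


# Native-space generative presets. Means/spreads are chosen so the
# transformed parameters sit in a plausible region for this task (prior
# locations mildly below/above the midpoint, moderate prior and
# consistency uncertainty, an unfair-averse intercept and positive
# likelihood weights); the haloperidol-like preset shifts wHI and eta
# upward and w0 toward zero, the directions reported for the drug. The
# l-DOPA-like preset matches placebo (no consistent behavioural effect).
_PLACEBO_MEANS = {
    "pHI0": -0.8,
    "pSI0": 0.1,
    "uPri_HI": -0.6,
    "uPri_SI": -0.6,
    "u_pi": 0.0,
    "eta": 0.0,
    "w0": -1.0,
    "wHI": 0.8,
    "wSI": 0.8,
}
_DEFAULT_SDS = {
    "pHI0": 1.0,
    "pSI0": 1.0,
    "uPri_HI": 1.2,
    "uPri_SI": 1.2,
    "u_pi": 0.35,
    "eta": 2.2,
    "w0": 1.3,
    "wHI": 0.7,
    "wSI": 0.7,
}
_HALOPERIDOL_SHIFTS = {"wHI": 0.10, "eta": 0.65, "w0": 0.6}


@dataclass(frozen=True)
class ConditionPreset:
    """Native-space group means and spreads for one condition."""

    name: str
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self):
        if any(s < 0 for s in self.sds.values()):
            raise InvalidParameterError("parameter spreads must be >= 0")


def default_conditions() -> list[ConditionPreset]:
    """Placebo-, haloperidol- and l-DOPA-like presets."""
    halo = dict(_PLACEBO_MEANS)
    for k, dv in _HALOPERIDOL_SHIFTS.items():
        halo[k] = halo[k] + dv
    return [
        ConditionPreset("placebo", dict(_PLACEBO_MEANS), dict(_DEFAULT_SDS)),
        ConditionPreset("haloperidol", halo, dict(_DEFAULT_SDS)),
        ConditionPreset("ldopa", dict(_PLACEBO_MEANS), dict(_DEFAULT_SDS)),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort layout: 28 subjects x 3 conditions by default.

    The design is a within-subject crossover: each subject's native
    parameter vector is one draw around the first condition's preset,
    and other conditions add their preset's mean shift plus a smaller
    condition-specific jitter (``within_subject_sd_frac`` of the
    between-subject spread), so the same individual differences carry
    across conditions as they do for a real crossover cohort.
    """

    n_subjects: int = 28
    n_trials_per_partner: int = 6
    conditions: tuple[ConditionPreset, ...] = field(
        default_factory=lambda: tuple(default_conditions())
    )
    seed: int = 0
    balanced_partial: bool = False
    within_subject_sd_frac: float = 0.6

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InvalidParameterError("n_subjects must be >= 2")
        if self.n_trials_per_partner < 1:
            raise InvalidParameterError("n_trials_per_partner must be >= 1")
        if not 0.0 <= self.within_subject_sd_frac <= 1.0:
            raise InvalidParameterError(
                "within_subject_sd_frac must lie in [0, 1]"
            )


def generate_policy_sequence(
    policy: DictatorPolicy | str,
    n_trials: int,
    rng: int | np.random.Generator,
    *,
    balanced: bool = False,
) -> np.ndarray:
    """Outcome sequence (0 unfair / 0.5 fair) for one partner block.

    Fair and unfair policies are deterministic; the partially fair
    policy draws independent Bernoulli(0.5) outcomes, or a balanced
    half/half shuffle when ``balanced`` is set.
    """
    if isinstance(policy, str):
        policy = DictatorPolicy.from_label(policy)
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if policy.p_unfair == 0.0:
        return np.full(n_trials, 0.5)
    if policy.p_unfair == 1.0:
        return np.zeros(n_trials)
    if balanced:
        seq = np.array([0.0] * (n_trials // 2) + [0.5] * (n_trials - n_trials // 2))
        rng.shuffle(seq)
        return seq
    return np.where(rng.random(n_trials) < policy.p_unfair, 0.0, 0.5)


def sample_cohort_params(
    spec: CohortSpec, variant: str, rng: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-subject native-space parameters for every condition.

    Returns one row per subject x condition with ``native_<name>``
    columns for the variant's free parameters plus their model-space
    transforms under the plain parameter names.
    """
    rng = _as_rng(rng, spec.seed, "params")
    names = transforms.free_names(variant)
    ref_means, ref_sds = _preset_for_variant(spec.conditions[0], names)
    base = ref_means + ref_sds * rng.standard_normal((spec.n_subjects, len(names)))
    frac = spec.within_subject_sd_frac
    rows = []
    for c_idx, cond in enumerate(spec.conditions):
        means, sds = _preset_for_variant(cond, names)
        if c_idx == 0:
            draws = base
        else:
            # crossover: carry the subject effect, add the condition's mean
            # shift and a smaller condition-specific jitter
            draws = base + (means - ref_means) + frac * sds * rng.standard_normal(
                (spec.n_subjects, len(names))
            )
        for i in range(spec.n_subjects):
            row = {"subject": i + 1, "condition": cond.name, "variant": variant}
            for j, name in enumerate(names):
                row[f"native_{name}"] = draws[i, j]
                row[name] = transforms.to_model_space(name, draws[i, j])
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort_dataset(
    spec: CohortSpec,
    variant: str = "M3",
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full long-format dataset plus its truth table.

    Partner order is randomized per subject and condition; partner ids
    number the presentation order 1..3. Returns ``(dataset, truth)``
    where the truth table holds the generative parameters, one row per
    subject x condition.
    """
    seed = spec.seed if seed is None else seed
    spec = replace(spec, seed=seed)
    truth = sample_cohort_params(spec, variant, _as_rng(None, seed, "params"))
    order_rng = _as_rng(None, seed, "order")
    report_rng = _as_rng(None, seed, "reports")

    n = spec.n_trials_per_partner
    rows = []
    for _, prow in truth.iterrows():
        params = ModelParams.from_free(
            variant,
            **{name: prow[name] for name in transforms.free_names(variant)},
        )
        policy_order = list(order_rng.permutation(POLICY_LABELS))
        outcomes, policies = [], []
        for label in policy_order:
            outcomes.append(
                generate_policy_sequence(
                    label, n, order_rng, balanced=spec.balanced_partial
                )
            )
            policies.extend([label] * n)
        outcomes = np.concatenate(outcomes)
        blocks = [n * p for p in range(len(policy_order))]
        records = simulate_reports(params, outcomes, report_rng, block_starts=blocks)
        for rec, pol in zip(records, policies):
            rows.append(
                {
                    "subject": int(prow["subject"]),
                    "condition": prow["condition"],
                    "partner": rec.partner_id,
                    "policy": pol,
                    "trial": rec.trial_index,
                    "outcome": rec.outcome,
                    "hi_rating": rec.hi_rating,
                    "si_rating": rec.si_rating,
                }
            )
    return pd.DataFrame(rows), truth


def _preset_for_variant(cond: ConditionPreset, names) -> tuple[np.ndarray, np.ndarray]:
    """Map a preset over the full parameter set onto a variant's names."""
    means, sds = [], []
    for name in names:
        if name == "w":
            m = 0.5 * (cond.means["wHI"] + cond.means["wSI"])
            s = 0.5 * (cond.sds["wHI"] + cond.sds["wSI"])
        elif name == "uPri":
            m = 0.5 * (cond.means["uPri_HI"] + cond.means["uPri_SI"])
            s = 0.5 * (cond.sds["uPri_HI"] + cond.sds["uPri_SI"])
        else:
            m, s = cond.means[name], cond.sds[name]
        means.append(m)
        sds.append(s)
    return np.array(means), np.array(sds)


_STREAMS = {"params": 11, "order": 23, "reports": 37}


def _as_rng(rng, seed: int, stream: str) -> np.random.Generator:
    """Stage-namespaced generator derived from the cohort seed."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, _STREAMS[stream]]))
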