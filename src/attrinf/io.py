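"""Dataset schema validation, run configuration and end-to-end orchestration."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, fitting, transforms
from .simulate import (
    POLICY_LABELS,
    CohortSpec,
    ConditionPreset,
    default_conditions,
    generate_cohort_dataset,
)

__all__ = [
    "SCHEMA_COLUMNS",
    "SCHEMA_VERSION",
    "ValidationReport",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "run_end_to_end",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
SCHEMA_COLUMNS = [
    "subject", "condition", "partner", "policy", "trial",
    "outcome", "hi_rating", "si_rating",
]

_EXPECTED_OUTCOME = {"fair": {0.5}, "partially_fair": {0.0, 0.5}, "unfair": {0.0}}


class ValidationError(ValueError):
    """Dataset failed schema validation."""


@dataclass
class ValidationReport:
    ok: bool
    n_rows: int
    n_subjects: int
    issues: list[str] = field(default_factory=list)

    def raise_if_failed(self) -> None:
        if not self.ok:
            raise ValidationError("; ".join(self.issues[:10]))


def read_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def validate_dataset(
    data, *, n_trials_per_partner: int = 6, n_partners: int = 3
) -> ValidationReport:
    """Schema, range and completeness checks on a long-format dataset.

    Each violation is reported with a row (or subject/condition)
    pointer; completeness requires every subject-condition to hold
    ``n_partners`` partner blocks of ``n_trials_per_partner`` trials.
    """
    df = read_dataset(data) if not isinstance(data, pd.DataFrame) else data
    issues: list[str] = []
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        return ValidationReport(False, len(df), 0, [f"missing columns: {missing}"])

    for idx, row in enumerate(df.itertuples(index=False)):
        if not 1 <= row.hi_rating <= 100 or not 1 <= row.si_rating <= 100:
            issues.append(f"row {idx}: rating outside 1..100")
        if row.outcome not in (0.0, 0.5):
            issues.append(f"row {idx}: outcome not in {{0, 0.5}}")
        if row.policy not in POLICY_LABELS:
            issues.append(f"row {idx}: unknown policy {row.policy!r}")
        elif row.outcome in (0.0, 0.5) and row.outcome not in _EXPECTED_OUTCOME[row.policy]:
            issues.append(f"row {idx}: outcome inconsistent with policy {row.policy!r}")
        if not 1 <= row.trial <= n_trials_per_partner:
            issues.append(f"row {idx}: trial index outside 1..{n_trials_per_partner}")
        if len(issues) > 200:
            issues.append("... further issues suppressed")
            break

    for (subj, cond), grp in df.groupby(["subject", "condition"]):
        partners = grp["partner"].nunique()
        if partners != n_partners:
            issues.append(
                f"subject {subj} / condition {cond}: expected {n_partners} "
                f"partner blocks, found {partners}"
            )
            continue
        counts = grp.groupby("partner")["trial"].count()
        if not (counts == n_trials_per_partner).all():
            issues.append(
                f"subject {subj} / condition {cond}: incomplete partner block"
            )
    n_subjects = df["subject"].nunique()
    logger.info("validated %d rows, %d subjects, %d issues",
                len(df), n_subjects, len(issues))
    return ValidationReport(len(issues) == 0, len(df), n_subjects, issues)


@dataclass
class RunConfig:
    """Flat, fully serialized configuration for reproducible runs."""

    seed: int = 0
    n_subjects: int = 28
    n_trials_per_partner: int = 6
    conditions: list[str] = field(
        default_factory=lambda: ["placebo", "haloperidol", "ldopa"]
    )
    variant: str = "M3"
    models: list[str] = field(default_factory=lambda: ["M1", "M2", "M3"])
    n_starts: int = 10
    max_iter: int = 50
    tol: float = 1e-3
    contrast: list[str] = field(default_factory=lambda: ["haloperidol", "placebo"])
    balanced_partial: bool = False
    max_factors: int = 3
    schema_version: str = SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        presets = {c.name: c for c in default_conditions()}
        conds = []
        for name in self.conditions:
            if name not in presets:
                raise ValidationError(
                    f"unknown condition preset {name!r}; available: {sorted(presets)}"
                )
            conds.append(presets[name])
        return CohortSpec(
            n_subjects=self.n_subjects,
            n_trials_per_partner=self.n_trials_per_partner,
            conditions=tuple(conds),
            seed=self.seed,
            balanced_partial=self.balanced_partial,
        )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_artifact(payload: dict, config: RunConfig, path: Path) -> None:
    payload = {"config_hash": config.hash(), "seed": config.seed,
               "schema_version": config.schema_version, **payload}
    path.write_text(json.dumps(payload, default=_json_default, indent=1))


def _fit_payload(result: fitting.HBIResult,
                 subjects: list[fitting.SubjectData]) -> dict:
    g = result.group
    return {
        "models": g.models,
        "frequencies": g.frequencies,
        "exceedance": g.exceedance,
        "protected_exceedance": g.protected_exceedance,
        "alphas": g.alphas,
        "group_means": {m: v for m, v in g.group_means.items()},
        "group_vars": {m: v for m, v in g.group_vars.items()},
        "converged": g.converged,
        "iterations": g.iterations,
        "single_model": len(g.models) == 1,
        "subjects": {
            m: [
                {
                    "subject": str(d.subject),
                    "x_map": f.x_map,
                    "loglik": f.loglik,
                    "log_evidence": f.log_evidence,
                    "responsibility": f.responsibility,
                    "converged": f.converged,
                }
                for d, f in zip(subjects, fits)
            ]
            for m, fits in result.subject_fits.items()
        },
    }


def recovered_params_frame(
    result: fitting.HBIResult, subjects: list[fitting.SubjectData], variant: str
) -> pd.DataFrame:
    """Model-space recovered parameters, one row per subject."""
    names = transforms.free_names(variant)
    rows = []
    for data, fit in zip(subjects, result.subject_fits[variant]):
        row = {"subject": data.subject, "condition": data.condition}
        for j, name in enumerate(names):
            row[name] = transforms.to_model_space(name, fit.x_map[j])
            row[f"native_{name}"] = float(fit.x_map[j])
        rows.append(row)
    return pd.DataFrame(rows)


def run_end_to_end(config: RunConfig, outdir) -> dict[str, str]:
    """simulate -> fit (per condition) -> recover -> analyze -> report.

    Writes dataset.csv, truth.csv, one fit_<condition>.json per
    condition, recovery.json, analysis.json and run_log.json under
    ``outdir`` and returns the artifact paths. Stage failures abort
    with a stage-tagged exception.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.cohort_spec()
    stage_log: list[dict] = []
    paths: dict[str, str] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            stage_log.append({"stage": name, "seconds": time.perf_counter() - t0})
            return out
        return deco

    dataset, truth = stage("simulate")(
        lambda: generate_cohort_dataset(spec, config.variant, config.seed)
    )
    report = validate_dataset(
        dataset, n_trials_per_partner=config.n_trials_per_partner
    )
    report.raise_if_failed()
    write_dataset(dataset, outdir / "dataset.csv")
    write_dataset(truth, outdir / "truth.csv")
    paths["dataset"] = str(outdir / "dataset.csv")
    paths["truth"] = str(outdir / "truth.csv")

    by_cond = fitting.split_by_condition(dataset)
    fit_results: dict[str, fitting.HBIResult] = {}
    recovered_frames = []
    for c_idx, cond in enumerate(sorted(by_cond)):
        def run_fit(cond=cond, c_idx=c_idx):
            return fitting.hbi_fit(
                by_cond[cond],
                config.models,
                seed=(config.seed * 1000 + c_idx) % 2**31,
                n_starts=config.n_starts,
                max_iter=config.max_iter,
                tol=config.tol,
            )
        result = stage(f"fit:{cond}")(run_fit)
        fit_results[cond] = result
        fpath = outdir / f"fit_{cond}.json"
        _write_artifact(_fit_payload(result, by_cond[cond]), config, fpath)
        paths[f"fit_{cond}"] = str(fpath)
        if config.variant in result.subject_fits:
            recovered_frames.append(
                recovered_params_frame(result, by_cond[cond], config.variant)
            )

    recovery = stage("recover")(
        lambda: fitting.recovery_study(
            spec,
            config.variant,
            config.seed,
            models=[config.variant],
            n_starts=config.n_starts,
            max_iter=config.max_iter,
            tol=config.tol,
        )
    )
    _write_artifact({"recovery": recovery.to_dict()}, config, outdir / "recovery.json")
    paths["recovery"] = str(outdir / "recovery.json")

    params_df = pd.concat(recovered_frames, ignore_index=True)
    analysis_payload = stage("analyze")(
        lambda: _analysis_payload(config, dataset, params_df)
    )
    _write_artifact(analysis_payload, config, outdir / "analysis.json")
    paths["analysis"] = str(outdir / "analysis.json")

    _write_artifact(
        {"stages": stage_log, "config": config.to_dict(), "artifacts": paths},
        config,
        outdir / "run_log.json",
    )
    paths["run_log"] = str(outdir / "run_log.json")
    return paths


def _analysis_payload(config: RunConfig, dataset: pd.DataFrame,
                      params_df: pd.DataFrame) -> dict:
    cond_a, cond_b = config.contrast
    names = transforms.free_names(config.variant)
    payload: dict = {"contrast_conditions": [cond_a, cond_b]}

    a = params_df[params_df["condition"] == cond_a].sort_values("subject")
    b = params_df[params_df["condition"] == cond_b].sort_values("subject")
    contrasts = {}
    for name in names:
        res = analysis.bayesian_paired_contrast(
            a[name].to_numpy(), b[name].to_numpy(), seed=config.seed
        )
        contrasts[name] = vars(res)
    payload["parameter_contrasts"] = contrasts

    prec = analysis.attribution_precision(dataset)
    payload["precision_summary"] = (
        prec[~prec["degenerate"]]
        .groupby(["condition", "dimension"])["precision"]
        .mean()
        .unstack()
        .to_dict()
    )
    try:
        reg = analysis.precision_regression(prec, params_df)
        payload["precision_regression"] = {
            "coefficients": reg.coefficients,
            "aic_quadratic": reg.aic_quadratic,
            "aic_linear": reg.aic_linear,
            "r_squared": reg.r_squared,
            "flags": reg.flags,
        }
    except ValueError as exc:
        payload["precision_regression"] = {"flagged": str(exc)}

    coupling = analysis.trialwise_coupling(dataset)
    payload["coupling"] = {
        "per_trial": coupling.per_trial,
        "summary": coupling.summary,
        "decay": coupling.decay,
        "method": coupling.method,
    }
    try:
        cc = analysis.coupling_contrast(coupling, cond_a, cond_b, seed=config.seed)
        payload["coupling_contrast"] = vars(cc)
    except ValueError as exc:
        payload["coupling_contrast"] = {"flagged": str(exc)}

    pair = params_df[params_df["condition"].isin([cond_a, cond_b])]
    table = pair[list(names)]
    labels = pair["condition"].to_numpy()
    try:
        fa = analysis.parameter_factor_analysis(table)
        payload["factor_analysis"] = {
            "eigenvalues": fa.eigenvalues,
            "loadings": fa.loadings,
            "phi": fa.phi,
            "n_factors": fa.n_factors,
            "residual_rms": fa.residual_rms,
        }
        disc = analysis.drug_discrimination_cv(
            table, labels, max_factors=config.max_factors, seed=config.seed
        )
        payload["discrimination"] = {
            "per_solution": disc.per_solution,
            "best_n_factors": disc.best_n_factors,
            "auc": disc.auc,
            "sensitivity": disc.sensitivity,
            "specificity": disc.specificity,
            "flags": disc.flags,
        }
    except (ValueError, np.linalg.LinAlgError) as exc:
        payload["factor_analysis"] = {"flagged": str(exc)}
        payload["discrimination"] = {"flagged": str(exc)}
    return payload
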