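"""End-to-end study pipeline on synthetic or user-supplied tables.

Stages: derive the biomarker-related covariance pattern, regress lobar
cortical volumes on its expression block-wise with FDR correction, then —
for FDR-significant lobes — run the serial mediation models (two imaging
mediators for lobar volume; three mediators for each cognitive outcome)
across nested covariate tiers, a reversed-mediator sensitivity model, and
follow-up biomarker/risk-factor regressions.  Produces a structured,
reproducible report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm, mediation, ssm
from .cohort import CohortConfig, VolumeMatrix, generate_cohort

__all__ = ["StudyConfig", "StudyReport", "run_full_analysis", "hcy_riskfactor_followup"]

LOBES = ("frontal", "temporal", "parietal", "occipital")
COGNITIVE_OUTCOMES = ("tmta_log", "tmtb_resid", "srt_cltr")

#: nested covariate tiers, mirroring the incremental adjustment sequence
BASE_COVARIATES = ("tiv", "sex", "education")
EXTENDED_COVARIATES = ("apoe4", "hypertension", "smoking", "vo2max")
RISK_FACTORS = ("apoe4", "hypertension", "smoking", "vo2max")
DEMOGRAPHICS = ("age", "sex", "education")


@dataclass(frozen=True)
class StudyConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    pheno_path: str | None = None      # if set, load instead of simulating
    volumes_path: str | None = None
    biomarker: str = "hcy"
    preprocess_mode: str = "log_tiv_residual"
    n_boot: int = 500                  # scaled-down default; 10,000 for release runs
    ssm_boot: int = 0                  # 0 disables pattern reliability bootstrap
    seed: int = 0
    gate_alpha: float = 0.05
    force_mediation: bool = False      # override the FDR gate
    run_cognition: bool = True
    run_sensitivity: bool = True

    def tiers(self, cognition: bool) -> dict:
        base = BASE_COVARIATES + (("interval_days",) if cognition else ())
        extended = base + EXTENDED_COVARIATES
        tiers = {"base": base, "extended": extended, "extended_b12": extended + ("b12",)}
        if cognition:
            tiers["extended_b12_gds"] = extended + ("b12", "gds")
        return tiers


@dataclass
class StudyReport:
    config_hash: str
    seeds: dict
    pattern: dict
    regression: pd.DataFrame
    fdr: dict
    gated_lobes: list
    mediation_lobar: dict
    mediation_cognition: dict
    sensitivity: dict
    hcy_followup: pd.DataFrame
    notes: list

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "pattern": self.pattern,
            "regression": self.regression.to_dict(orient="records"),
            "fdr": self.fdr,
            "gated_lobes": self.gated_lobes,
            "mediation_lobar": self.mediation_lobar,
            "mediation_cognition": self.mediation_cognition,
            "sensitivity": self.sensitivity,
            "hcy_followup": self.hcy_followup.to_dict(orient="records"),
            "notes": self.notes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=float)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.regression.to_csv(out / "table2.csv", index=False)
        self.hcy_followup.to_csv(out / "hcy_followup.csv", index=False)
        (out / "pattern.json").write_text(
            json.dumps(self.pattern, indent=2, default=float)
        )


def _config_hash(config: StudyConfig) -> str:
    d = asdict(config)
    d["cohort"]["pattern_weights"] = list(
        np.asarray(d["cohort"]["pattern_weights"], dtype=float)
    )
    d["cohort"]["path_coefficients"] = {
        "->".join(k): v for k, v in d["cohort"]["path_coefficients"].items()
    }
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode("utf8")).hexdigest()[:16]


def _load_inputs(config: StudyConfig) -> tuple[pd.DataFrame, VolumeMatrix]:
    if config.pheno_path is not None and config.volumes_path is not None:
        df = pd.read_csv(config.pheno_path, index_col=0)
        volumes = VolumeMatrix.from_csv(config.volumes_path)
        return df, volumes
    return generate_cohort(config.cohort)


def _mediation_summary(result: mediation.MediationResult) -> dict:
    report = mediation.decompose_total(result)
    return {
        "n_used": result.n_used,
        "boot_failures": result.boot_failures,
        "total": report["total"],
        "total_std": report["total_std"],
        "direct": report["direct"],
        "direct_std": report["direct_std"],
        "total_p": report["total_inference"][1],
        "direct_p": report["direct_inference"][1],
        "path_std": {
            "a": result.paths.a_std,
            "d": {f"{i}->{j}": v for (i, j), v in result.paths.d_std.items()},
            "b": result.paths.b_std,
        },
        "indirects": [
            {
                "path": e.label,
                "raw": e.raw,
                "std": e.std,
                "boot_se": e.boot_se,
                "ci": e.ci,
                "std_ci": e.std_ci,
                "significant": e.significant,
            }
            for e in result.indirects
        ],
    }


def run_full_analysis(
    config: StudyConfig, out_dir=None
) -> StudyReport:
    """Execute every stage in order and return (optionally write) the report."""
    timings: dict[str, float] = {}
    notes: list[str] = []
    t0 = time.perf_counter()

    data, volumes = _load_inputs(config)
    required = {"age", "tiv", "sex", "education", "log_wmh", config.biomarker, *LOBES}
    missing = sorted(required - set(data.columns))
    if missing:
        raise KeyError(f"cohort table is missing required columns: {missing}")
    timings["inputs"] = time.perf_counter() - t0

    # --- pattern derivation -------------------------------------------------
    t0 = time.perf_counter()
    tiv = data["tiv"].to_numpy()
    biomarker = data[config.biomarker].to_numpy()
    model, decomposition, scores = ssm.derive_pattern(
        volumes, tiv, biomarker, mode=config.preprocess_mode
    )
    data = data.assign(expression=scores.z)
    pattern_summary = {
        "weights": dict(zip(volumes.region_names, model.weights.tolist())),
        "component_set": list(model.component_set),
        "aic_trace": model.aic_trace.tolist(),
        "sign_convention": model.sign_convention,
        "eigenvalues": decomposition.eigenvalues.tolist(),
        "preprocess_mode": config.preprocess_mode,
    }
    if config.ssm_boot >= 100:
        rel = ssm.bootstrap_pattern(
            volumes, tiv, biomarker, config.ssm_boot, config.seed,
            mode=config.preprocess_mode,
        )
        pattern_summary["reliability"] = {
            "weight_sd": rel.weight_sd.tolist(),
            "weight_z": rel.weight_z.tolist(),
            "ci_lower": rel.ci_lower.tolist(),
            "ci_upper": rel.ci_upper.tolist(),
        }
    timings["pattern"] = time.perf_counter() - t0

    # --- lobar regressions with FDR ----------------------------------------
    t0 = time.perf_counter()
    blocks = [["tiv"], ["age", "sex", "education"], ["expression"]]
    rows = []
    raw_p = {}
    for lobe in LOBES:
        results = glm.fit_blockwise(data, lobe, blocks)
        focal = glm.focal_result(results, "expression")
        raw_p[lobe] = focal.p
        rows.append(
            {
                "outcome": lobe,
                "beta": focal.beta,
                "B": focal.B,
                "SE": focal.SE,
                "ci_lower": focal.ci[0],
                "ci_upper": focal.ci[1],
                "p": focal.p,
            }
        )
    fdr = glm.bh_fdr(raw_p)
    table2 = pd.DataFrame(rows)
    table2["p_fdr"] = [fdr.adj_p[lobe] for lobe in table2["outcome"]]
    gated = [lobe for lobe in LOBES if fdr.adj_p[lobe] < config.gate_alpha]
    if config.force_mediation and not gated:
        gated = list(LOBES)
        notes.append("FDR gate overridden: no lobe survived, running all")
    if not gated:
        notes.append("no FDR-significant lobe; mediation stages skipped")
    timings["regression"] = time.perf_counter() - t0

    # --- serial mediation ---------------------------------------------------
    t0 = time.perf_counter()
    mediation_lobar: dict = {}
    mediation_cognition: dict = {}
    sensitivity: dict = {}
    for lobe in gated:
        mediation_lobar[lobe] = {}
        for tier, covs in config.tiers(cognition=False).items():
            spec = mediation.MediationSpec(
                x="age",
                y=lobe,
                mediators=("log_wmh", "expression"),
                covariates=covs,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            result = mediation.bootstrap_mediation(data, spec)
            mediation_lobar[lobe][tier] = _mediation_summary(result)

        if config.run_cognition:
            mediation_cognition[lobe] = {}
            for outcome in COGNITIVE_OUTCOMES:
                mediation_cognition[lobe][outcome] = {}
                for tier, covs in config.tiers(cognition=True).items():
                    spec = mediation.MediationSpec(
                        x="age",
                        y=outcome,
                        mediators=("log_wmh", "expression", lobe),
                        covariates=covs,
                        n_boot=config.n_boot,
                        seed=config.seed,
                    )
                    result = mediation.bootstrap_mediation(data, spec)
                    mediation_cognition[lobe][outcome][tier] = _mediation_summary(
                        result
                    )

        if config.run_sensitivity:
            covs = config.tiers(cognition=False)["extended_b12"]
            spec = mediation.MediationSpec(
                x="age",
                y=lobe,
                mediators=("log_wmh", "expression"),
                covariates=covs,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            reversed_spec = mediation.reverse_mediators(spec)
            result = mediation.bootstrap_mediation(data, reversed_spec)
            sensitivity[lobe] = _mediation_summary(result)
    timings["mediation"] = time.perf_counter() - t0

    # --- biomarker vs risk factors -----------------------------------------
    t0 = time.perf_counter()
    followup = hcy_riskfactor_followup(data, biomarker=config.biomarker)
    timings["followup"] = time.perf_counter() - t0

    report = StudyReport(
        config_hash=_config_hash(config),
        seeds={"study": config.seed, "cohort": config.cohort.seed},
        pattern=pattern_summary,
        regression=table2,
        fdr={"raw_p": fdr.raw_p, "adj_p": fdr.adj_p, "m": fdr.m},
        gated_lobes=gated,
        mediation_lobar=mediation_lobar,
        mediation_cognition=mediation_cognition,
        sensitivity=sensitivity,
        hcy_followup=followup,
        notes=notes,
    )
    if out_dir is not None:
        report.save(out_dir)
        log = "\n".join(f"{stage}: {dt:.3f}s" for stage, dt in timings.items())
        (Path(out_dir) / "log.txt").write_text(log + "\n")
    return report


def hcy_riskfactor_followup(
    data: pd.DataFrame,
    biomarker: str = "hcy",
    risk_factors=RISK_FACTORS,
    demographics=DEMOGRAPHICS,
) -> pd.DataFrame:
    """Simple and demographics-adjusted regressions of the biomarker on each
    risk factor."""
    rows = []
    for factor in risk_factors:
        if factor not in data.columns:
            raise KeyError(f"risk factor column {factor!r} not in data")
        simple = glm.fit_blockwise(data, biomarker, [[factor]])
        adjusted = glm.fit_blockwise(data, biomarker, [list(demographics), [factor]])
        s = glm.focal_result(simple, factor)
        a = glm.focal_result(adjusted, factor)
        rows.append(
            {
                "risk_factor": factor,
                "B_simple": s.B,
                "p_simple": s.p,
                "B_adjusted": a.B,
                "p_adjusted": a.p,
            }
        )
    return pd.DataFrame(rows)


def load_study_config(path) -> StudyConfig:
    """Build a StudyConfig from a YAML/JSON file (flat keys; cohort nested)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    cohort_kwargs = raw.pop("cohort", {})
    if "pattern_weights" in cohort_kwargs:
        cohort_kwargs["pattern_weights"] = np.asarray(
            cohort_kwargs["pattern_weights"], dtype=float
        )
    if "path_coefficients" in cohort_kwargs:
        cohort_kwargs["path_coefficients"] = {
            tuple(k.split("->")): float(v)
            for k, v in cohort_kwargs["path_coefficients"].items()
        }
    return StudyConfig(cohort=CohortConfig(**cohort_kwargs), **raw)
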