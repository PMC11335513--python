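"""Synthetic cohort generation.

Builds ROI-level tabular cohorts with configurable marginal distributions and
a planted linear causal chain (age -> white-matter lesion burden -> latent
subcortical-pattern expression -> parietal volume -> processing speed), plus a
subjects x regions subcortical volume matrix carrying the planted covariance
pattern.  Every downstream stage of the package can therefore be exercised
and validated against known ground truth without any external data.

Structural equations operate on sample-standardized parents with standardized
path coefficients; each generated variable is then affinely rescaled to its
target marginal, so planted coefficients are directly comparable to
standardized regression estimates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "CohortConfig",
    "VolumeMatrix",
    "generate_cohort",
    "plant_pattern",
    "DEFAULT_REGIONS",
    "lognormal_params",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation configuration."""


#: Seven bilateral subcortical structures, left then right.
DEFAULT_REGIONS = tuple(
    f"{region}_{hemi}"
    for region in (
        "hippocampus",
        "accumbens",
        "amygdala",
        "thalamus",
        "caudate",
        "putamen",
        "pallidum",
    )
    for hemi in ("left", "right")
)

#: Typical per-hemisphere volumes in mL used as the baseline regional profile.
_REGION_MEANS = {
    "hippocampus": 4.3,
    "accumbens": 0.6,
    "amygdala": 1.7,
    "thalamus": 7.4,
    "caudate": 3.6,
    "putamen": 5.0,
    "pallidum": 1.8,
}


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log of a lognormal with the given raw mean/sd."""
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("lognormal moments must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _default_pattern_weights() -> np.ndarray:
    # Contrast: volume loss in hippocampus/accumbens (and mildly amygdala)
    # with relative preservation of basal ganglia as expression increases.
    per_region = {
        "hippocampus": -0.45,
        "accumbens": -0.35,
        "amygdala": -0.10,
        "thalamus": 0.05,
        "caudate": 0.20,
        "putamen": 0.20,
        "pallidum": 0.20,
    }
    w = np.array([per_region[r.rsplit("_", 1)[0]] for r in DEFAULT_REGIONS])
    return w / np.linalg.norm(w)


_WMH_LOG_MU, _WMH_LOG_SD = lognormal_params(6.57, 10.53)
_TMTA_LOG_MU, _TMTA_LOG_SD = lognormal_params(32.18, 10.37)


def _default_marginals() -> dict:
    return {
        # continuous: (mean, sd)
        "age": (69.66, 9.95),
        "education": (15.98, 2.57),
        "tiv": (1450.0, 140.0),
        "vo2max": (24.0, 6.0),
        "b12": (450.0, 160.0),
        "gds": (2.0, 2.0),
        "interval_days": (58.56, 47.35),
        "hcy": (11.0, 3.5),
        "log_wmh": (_WMH_LOG_MU, _WMH_LOG_SD),
        "frontal": (164.83, 15.04),
        "temporal": (96.83, 9.62),
        "parietal": (115.52, 11.19),
        "occipital": (44.91, 5.46),
        "tmta_log": (_TMTA_LOG_MU, _TMTA_LOG_SD),
        "tmtb": (76.14, 30.50),
        "srt_cltr": (64.62, 37.07),
        # binary: {1: prevalence}
        "sex": {1: 86 / 160},
        "apoe4": {1: 0.30},
        "hypertension": {1: 0.35},
        "smoking": {1: 0.40},
    }


def _default_paths() -> dict:
    return {
        ("age", "log_wmh"): 0.526,
        ("log_wmh", "expression"): 0.241,
        ("age", "expression"): 0.0,
        ("tiv", "frontal"): 0.55,
        ("age", "frontal"): -0.35,
        ("expression", "frontal"): -0.116,
        ("tiv", "temporal"): 0.55,
        ("age", "temporal"): -0.30,
        ("expression", "temporal"): -0.096,
        ("tiv", "parietal"): 0.55,
        ("age", "parietal"): -0.30,
        ("expression", "parietal"): -0.186,
        ("tiv", "occipital"): 0.50,
        ("age", "occipital"): -0.15,
        ("expression", "occipital"): -0.092,
        ("age", "tmta_log"): 0.246,
        ("parietal", "tmta_log"): -0.409,
        ("age", "tmtb"): 0.30,
        ("tmta_log", "tmtb"): 0.60,
        ("age", "srt_cltr"): -0.436,
    }


# Structural equations in topological order: child -> ordered parent list.
# Variables absent here are exogenous.
_STRUCTURE: dict[str, tuple[str, ...]] = {
    "log_wmh": ("age",),
    "expression": ("age", "log_wmh"),
    "frontal": ("tiv", "age", "expression"),
    "temporal": ("tiv", "age", "expression"),
    "parietal": ("tiv", "age", "expression"),
    "occipital": ("tiv", "age", "expression"),
    "tmta_log": ("age", "parietal"),
    "tmtb": ("age", "tmta_log"),
    "srt_cltr": ("age",),
    "hcy": ("expression",),
}

_EXOGENOUS_CONTINUOUS = ("age", "tiv", "education", "vo2max", "b12", "gds", "interval_days")
_BINARY = ("sex", "apoe4", "hypertension", "smoking")

#: Minimum cohort size; the largest downstream mediation submodel fits about
#: a dozen parameters and needs residual degrees of freedom to spare.
MIN_SUBJECTS = 20


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_subjects: int = 160
    seed: int = 0
    marginal_specs: dict = field(default_factory=_default_marginals)
    path_coefficients: dict = field(default_factory=_default_paths)
    noise_sds: dict = field(default_factory=dict)  # equation -> sd; default auto
    pattern_weights: np.ndarray = field(default_factory=_default_pattern_weights)
    hcy_loading: float = 0.5
    pattern_scale: float = 0.05
    region_noise_sd: float = 0.02
    region_names: tuple = DEFAULT_REGIONS

    def validate(self) -> None:
        if self.n_subjects < MIN_SUBJECTS:
            raise ConfigurationError(
                f"n_subjects={self.n_subjects} is below the minimum of "
                f"{MIN_SUBJECTS} required by downstream model degrees of freedom"
            )
        for name, spec in self.marginal_specs.items():
            if isinstance(spec, dict):
                total = sum(spec.values())
                if not (0.0 < total <= 1.0 + 1e-12):
                    raise ConfigurationError(
                        f"proportions for {name!r} must lie in (0, 1]: got {total}"
                    )
            else:
                _, sd = spec
                if sd <= 0:
                    raise ConfigurationError(f"sd for {name!r} must be > 0, got {sd}")
        for eq, sd in self.noise_sds.items():
            if sd < 0:
                raise ConfigurationError(f"noise sd for {eq!r} must be >= 0, got {sd}")
        if self.region_noise_sd < 0:
            raise ConfigurationError("region_noise_sd must be >= 0")
        w = np.asarray(self.pattern_weights, dtype=float)
        if w.shape != (len(self.region_names),):
            raise ConfigurationError(
                f"pattern_weights must have length {len(self.region_names)}"
            )
        if not np.isclose(np.linalg.norm(w), 1.0, atol=1e-6):
            raise ConfigurationError("pattern_weights must have unit Euclidean norm")


@dataclass(frozen=True)
class VolumeMatrix:
    """Subjects x regions volume matrix with labels.

    ``log_scale`` marks matrices that have already been log-transformed (or
    residualized), for which strict positivity no longer applies.
    """

    values: np.ndarray
    region_names: tuple
    subject_ids: tuple
    log_scale: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_names", tuple(self.region_names))
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        if v.ndim != 2:
            raise ValueError("values must be 2-D (subjects x regions)")
        if v.shape != (len(self.subject_ids), len(self.region_names)):
            raise ValueError(
                f"shape {v.shape} inconsistent with {len(self.subject_ids)} "
                f"subjects and {len(self.region_names)} regions"
            )
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("duplicated region names")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicated subject ids")
        if len(self.region_names) < 2:
            raise ValueError("need at least 2 regions")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite volume entries")
        if not self.log_scale and np.any(v <= 0):
            bad = np.argwhere(v <= 0)
            cells = ", ".join(
                f"({self.subject_ids[i]}, {self.region_names[j]})" for i, j in bad[:10]
            )
            raise ValueError(f"non-positive volumes at cells: {cells}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=list(self.region_names)
        ).rename_axis("subject_id")

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, log_scale: bool = False) -> "VolumeMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            region_names=tuple(df.columns),
            subject_ids=tuple(str(i) for i in df.index),
            log_scale=log_scale,
        )

    @classmethod
    def from_csv(cls, path, log_scale: bool = False) -> "VolumeMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls.from_dataframe(df, log_scale=log_scale)


def _rng_for(seed: int, name: str) -> np.random.Generator:
    # Stable per-variable substream keyed by a name hash so that adding a new
    # variable never perturbs the draws of existing ones.
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=0)
    if s == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / s


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, VolumeMatrix]:
    """Simulate a cohort table and its subcortical volume matrix.

    Returns a per-subject :class:`pandas.DataFrame` (including the hidden
    ``true_expression`` column used by recovery tests) and a
    :class:`VolumeMatrix` of strictly positive volumes in mL.  Fully
    deterministic given ``config`` (which includes the seed).
    """
    config.validate()
    n = config.n_subjects
    seed = config.seed
    paths = config.path_coefficients

    z: dict[str, np.ndarray] = {}

    for name in _EXOGENOUS_CONTINUOUS:
        z[name] = _standardize(_rng_for(seed, name).standard_normal(n))

    for child, parents in _STRUCTURE.items():
        rng = _rng_for(seed, child)
        if child == "hcy":
            betas = np.array([config.hcy_loading])
        else:
            betas = np.array([paths.get((p, child), 0.0) for p in parents])
        X = np.column_stack([z[p] for p in parents])
        if child in config.noise_sds:
            sigma = float(config.noise_sds[child])
        else:
            # residual sd that leaves the child with (approximately) unit
            # variance given the sample correlation of its parents
            R = np.corrcoef(X, rowvar=False)
            R = np.atleast_2d(R)
            explained = float(betas @ R @ betas)
            sigma = float(np.sqrt(max(1e-12, 1.0 - explained)))
        v = X @ betas + sigma * rng.standard_normal(n)
        z[child] = _standardize(v)

    table = {}
    for name in (*_EXOGENOUS_CONTINUOUS, *_STRUCTURE):
        mean, sd = config.marginal_specs[name] if name != "expression" else (0.0, 1.0)
        table[name] = mean + sd * z[name]

    for name in _BINARY:
        prevalence = config.marginal_specs[name][1]
        table[name] = (_rng_for(seed, name).random(n) < prevalence).astype(int)

    df = pd.DataFrame(table, index=[f"s{i:04d}" for i in range(n)]).rename_axis(
        "subject_id"
    )

    # derived scores: executive function = TMT-B residualized on raw TMT-A
    tmta_raw = np.exp(df["tmta_log"].to_numpy())
    x = _standardize(tmta_raw)
    resid = df["tmtb"].to_numpy() - (
        df["tmtb"].mean() + np.cov(df["tmtb"], tmta_raw, ddof=0)[0, 1]
        / tmta_raw.var(ddof=0) * (tmta_raw - tmta_raw.mean())
    )
    df["tmtb_resid"] = _standardize(resid)
    df = df.rename(columns={"expression": "true_expression"})
    df = df.drop(columns=["tmtb"])

    volumes = _simulate_volumes(config, df)
    return df, volumes


def _simulate_volumes(config: CohortConfig, df: pd.DataFrame) -> VolumeMatrix:
    n = config.n_subjects
    rng = _rng_for(config.seed, "subcortical_volumes")
    names = config.region_names
    base = np.log(
        [_REGION_MEANS[r.rsplit("_", 1)[0]] for r in names]
    )
    tiv = df["tiv"].to_numpy()
    log_tiv_dev = np.log(tiv) - np.log(tiv).mean()
    expr = df["true_expression"].to_numpy()
    logv = (
        base[None, :]
        + log_tiv_dev[:, None]
        + config.pattern_scale * np.outer(expr, np.asarray(config.pattern_weights))
        + config.region_noise_sd * rng.standard_normal((n, len(names)))
    )
    return VolumeMatrix(
        values=np.exp(logv),
        region_names=names,
        subject_ids=tuple(df.index),
    )


def plant_pattern(
    matrix: VolumeMatrix,
    weights: np.ndarray,
    expression: np.ndarray,
    scale: float,
) -> VolumeMatrix:
    """Add ``scale * outer(expression, weights)`` on the log scale.

    The input matrix is left unmodified.
    """
    weights = np.asarray(weights, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if weights.shape != (matrix.n_regions,):
        raise ValueError(
            f"weights length {weights.shape[0]} != region count {matrix.n_regions}"
        )
    if expression.shape != (matrix.n_subjects,):
        raise ValueError(
            f"expression length {expression.shape[0]} != subject count "
            f"{matrix.n_subjects}"
        )
    logv = np.log(matrix.values) + scale * np.outer(expression, weights)
    return replace(matrix, values=np.exp(logv))


def null_config(n_subjects: int = 160, seed: int = 0, **kwargs) -> CohortConfig:
    """Config with every structural path set to zero (pure-noise chain)."""
    zeroed = {edge: 0.0 for edge in _default_paths()}
    return CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        path_coefficients=zeroed,
        hcy_loading=kwargs.pop("hcy_loading", 0.0),
        pattern_scale=kwargs.pop("pattern_scale", 0.0),
        **kwargs,
    )
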