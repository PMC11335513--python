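"""Covariance-pattern derivation from ROI volume matrices.

Implements the Scaled Subprofile Model workflow: log (and optionally
head-size-residualized) volumes are double-centered into subject residual
profiles, decomposed by PCA, and the leading sequential components are
combined — via an AIC-selected regression onto an external biomarker — into a
single unit-norm regional weight pattern.  Subjects are scored by projecting
their (column-centered) preprocessed profiles onto the pattern, and regional
weight reliability is estimated by a case-resampling bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import VolumeMatrix

__all__ = [
    "SSMDecomposition",
    "PatternModel",
    "ExpressionScores",
    "BootstrapReliability",
    "preprocess_volumes",
    "double_center",
    "derive_components",
    "select_component_set",
    "combine_pattern",
    "express_pattern",
    "bootstrap_pattern",
    "derive_pattern",
]

#: relative floor applied to regression RSS so AIC stays finite on perfect fits
_RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class SSMDecomposition:
    srp: np.ndarray            # subjects x regions, double-centered log data
    gis: np.ndarray            # regions x K orthonormal loading matrix
    ssf: np.ndarray            # subjects x K component scores (srp @ gis)
    eigenvalues: np.ndarray    # length K, nonincreasing

    @property
    def n_components(self) -> int:
        return self.gis.shape[1]


@dataclass(frozen=True)
class PreprocessingSpec:
    """Frozen record of the derivation-sample preprocessing, for re-scoring."""

    mode: str                       # "log_only" | "log_tiv_residual"
    region_names: tuple
    tiv_slopes: np.ndarray | None   # per-region slope on log TIV
    log_tiv_mean: float | None
    col_means: np.ndarray           # column means of preprocessed derivation data


@dataclass(frozen=True)
class PatternModel:
    weights: np.ndarray            # unit-norm regional weights (sign applied)
    component_set: tuple           # retained sequential components, 1-based
    combine_coefs: np.ndarray      # regression slopes merging the components
    aic_trace: np.ndarray          # AIC per candidate prefix 1..max_k
    sign_convention: int           # +1 or -1
    preprocessing: PreprocessingSpec
    reference_stats: tuple         # (mean, sd) of raw projections, derivation sample

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "component_set": list(self.component_set),
            "combine_coefs": self.combine_coefs.tolist(),
            "aic_trace": self.aic_trace.tolist(),
            "sign_convention": self.sign_convention,
            "preprocessing": {
                "mode": self.preprocessing.mode,
                "region_names": list(self.preprocessing.region_names),
                "tiv_slopes": None
                if self.preprocessing.tiv_slopes is None
                else self.preprocessing.tiv_slopes.tolist(),
                "log_tiv_mean": self.preprocessing.log_tiv_mean,
                "col_means": self.preprocessing.col_means.tolist(),
            },
            "reference_stats": list(self.reference_stats),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatternModel":
        p = d["preprocessing"]
        spec = PreprocessingSpec(
            mode=p["mode"],
            region_names=tuple(p["region_names"]),
            tiv_slopes=None if p["tiv_slopes"] is None else np.asarray(p["tiv_slopes"]),
            log_tiv_mean=p["log_tiv_mean"],
            col_means=np.asarray(p["col_means"]),
        )
        return cls(
            weights=np.asarray(d["weights"]),
            component_set=tuple(d["component_set"]),
            combine_coefs=np.asarray(d["combine_coefs"]),
            aic_trace=np.asarray(d["aic_trace"]),
            sign_convention=int(d["sign_convention"]),
            preprocessing=spec,
            reference_stats=tuple(d["reference_stats"]),
        )


@dataclass(frozen=True)
class ExpressionScores:
    raw: np.ndarray
    z: np.ndarray
    reference_stats: tuple


@dataclass(frozen=True)
class BootstrapReliability:
    n_iterations: int
    n_failures: int
    point_weights: np.ndarray
    weight_sd: np.ndarray
    weight_z: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    region_names: tuple = field(default=())


def _check_positive(matrix: VolumeMatrix, tiv: np.ndarray) -> None:
    if np.any(matrix.values <= 0):
        bad = np.argwhere(matrix.values <= 0)
        cells = ", ".join(
            f"({matrix.subject_ids[i]}, {matrix.region_names[j]})" for i, j in bad[:10]
        )
        raise ValueError(f"non-positive volumes at cells: {cells}")
    if np.any(tiv <= 0):
        raise ValueError("all TIV values must be positive")


def preprocess_volumes(
    matrix: VolumeMatrix, tiv: np.ndarray, mode: str = "log_tiv_residual"
) -> VolumeMatrix:
    """Natural-log volumes, optionally residualized on log TIV per region.

    In ``log_tiv_residual`` mode each log-region column is replaced by its
    simple-regression residual on log TIV plus the column mean, preserving
    location.  A constant TIV degenerates gracefully to ``log_only``.
    """
    tiv = np.asarray(tiv, dtype=float)
    if tiv.shape != (matrix.n_subjects,):
        raise ValueError("tiv length must equal the number of subjects")
    _check_positive(matrix, tiv)
    if mode not in ("log_only", "log_tiv_residual"):
        raise ValueError(f"unknown preprocessing mode {mode!r}")

    logv = np.log(matrix.values)
    if mode == "log_tiv_residual":
        logv, _, _ = _tiv_residualize(logv, tiv)
    return VolumeMatrix(
        values=logv,
        region_names=matrix.region_names,
        subject_ids=matrix.subject_ids,
        log_scale=True,
    )


def _tiv_residualize(logv: np.ndarray, tiv: np.ndarray):
    lt = np.log(tiv)
    lt_dev = lt - lt.mean()
    denom = float(lt_dev @ lt_dev)
    if denom == 0.0:
        warnings.warn("constant TIV: falling back to log_only preprocessing")
        return logv.copy(), np.zeros(logv.shape[1]), float(lt.mean())
    slopes = (lt_dev @ (logv - logv.mean(axis=0))) / denom
    out = logv - np.outer(lt_dev, slopes)
    return out, slopes, float(lt.mean())


def double_center(log_matrix: np.ndarray) -> np.ndarray:
    """Subject-residual profiles: remove row means, column means, add grand mean."""
    x = np.asarray(log_matrix, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite entries in log matrix")
    return x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()


def derive_components(srp: np.ndarray) -> SSMDecomposition:
    """PCA of the double-centered profiles via SVD.

    Loadings (``gis``) are the right singular vectors; scores (``ssf``) are
    the projections of the profiles onto them; eigenvalues are the squared
    singular values scaled by 1/(n-1).
    """
    srp = np.asarray(srp, dtype=float)
    n = srp.shape[0]
    scale = float(np.abs(srp).max()) if srp.size else 0.0
    if scale == 0.0:
        warnings.warn("all-zero subject residual profiles: empty decomposition")
        return SSMDecomposition(
            srp=srp,
            gis=np.zeros((srp.shape[1], 0)),
            ssf=np.zeros((n, 0)),
            eigenvalues=np.zeros(0),
        )
    _, s, vt = np.linalg.svd(srp, full_matrices=False)
    # drop null directions produced by the double centering
    keep = s > max(n, srp.shape[1]) * np.finfo(float).eps * s[0]
    gis = vt[keep].T
    ssf = srp @ gis
    eigenvalues = s[keep] ** 2 / max(n - 1, 1)
    return SSMDecomposition(srp=srp, gis=gis, ssf=ssf, eigenvalues=eigenvalues)


def _prefix_aic(ssf: np.ndarray, biomarker: np.ndarray, max_k: int):
    """AIC of OLS fits biomarker ~ ssf[:, :k] for k = 1..max_k.

    AIC_k = n ln(RSS_k / n) + 2 (k + 2): slopes, intercept, and the error
    variance all count as parameters.  RSS is floored to keep AIC finite.
    """
    n = len(biomarker)
    b = biomarker - biomarker.mean()
    floor = _RSS_FLOOR * float(b @ b if b @ b > 0 else 1.0)
    aic = np.empty(max_k)
    coefs: list[np.ndarray] = []
    for k in range(1, max_k + 1):
        X = np.column_stack([np.ones(n), ssf[:, :k]])
        beta, *_ = np.linalg.lstsq(X, biomarker, rcond=None)
        resid = biomarker - X @ beta
        rss = max(float(resid @ resid), floor)
        aic[k - 1] = n * np.log(rss / n) + 2 * (k + 2)
        coefs.append(beta[1:])
    return aic, coefs


def select_component_set(
    ssf: np.ndarray, biomarker: np.ndarray, max_k: int | None = None
):
    """Pick the sequential-component prefix minimizing AIC for the biomarker.

    Returns ``(component_set, combine_coefs, aic_trace)`` where the component
    set is the 1-based prefix ``(1, ..., k*)``.  Ties resolve to the smallest
    prefix.
    """
    ssf = np.asarray(ssf, dtype=float)
    biomarker = np.asarray(biomarker, dtype=float)
    if not np.all(np.isfinite(biomarker)):
        raise ValueError("biomarker contains non-finite values")
    if biomarker.std() == 0:
        raise ValueError("biomarker has zero variance")
    K = ssf.shape[1]
    if max_k is None:
        # smaller of 8 and the count of components explaining 90% of variance
        var = (ssf - ssf.mean(axis=0)).var(axis=0).cumsum()
        k90 = int(np.searchsorted(var / var[-1], 0.90) + 1) if K else 0
        max_k = min(8, max(k90, 1), K)
    if max_k < 1 or max_k > K:
        raise ValueError(f"max_k must be in [1, {K}], got {max_k}")
    aic, coefs = _prefix_aic(ssf, biomarker, max_k)
    k_best = int(np.argmin(aic)) + 1  # argmin takes the first minimum: smallest k
    return tuple(range(1, k_best + 1)), coefs[k_best - 1], aic


def _project(preprocessed: np.ndarray, col_means: np.ndarray, weights: np.ndarray):
    return (preprocessed - col_means) @ weights


def combine_pattern(
    decomposition: SSMDecomposition,
    component_set: tuple,
    combine_coefs: np.ndarray,
    biomarker: np.ndarray,
    *,
    preprocessed: np.ndarray | None = None,
    preprocessing: PreprocessingSpec | None = None,
    aic_trace: np.ndarray | None = None,
) -> PatternModel:
    """Merge the retained components into one unit-norm weight pattern.

    The sign convention is chosen so that pattern expression correlates
    non-negatively with the biomarker; the norm is absorbed into the
    expression scale (scores are z-scored downstream anyway).
    """
    idx = np.asarray(component_set, dtype=int) - 1
    weights = decomposition.gis[:, idx] @ np.asarray(combine_coefs, dtype=float)
    norm = float(np.linalg.norm(weights))
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError("combined pattern has zero norm")
    weights = weights / norm

    if preprocessed is None:
        # fall back to the srp (column means are zero there by construction)
        preprocessed = decomposition.srp
        col_means = np.zeros(decomposition.srp.shape[1])
    else:
        col_means = preprocessed.mean(axis=0)
    proj = _project(preprocessed, col_means, weights)
    r = np.corrcoef(proj, biomarker)[0, 1] if proj.std() > 0 else 0.0
    sign = -1 if r < 0 else 1
    weights = sign * weights

    if preprocessing is None:
        preprocessing = PreprocessingSpec(
            mode="precomputed",
            region_names=tuple(f"r{j}" for j in range(weights.shape[0])),
            tiv_slopes=None,
            log_tiv_mean=None,
            col_means=col_means,
        )
    raw = _project(preprocessed, preprocessing.col_means, weights)
    sd = float(raw.std(ddof=0))
    reference_stats = (float(raw.mean()), sd if sd > 0 else 1.0)
    return PatternModel(
        weights=weights,
        component_set=tuple(int(c) for c in component_set),
        combine_coefs=np.asarray(combine_coefs, dtype=float),
        aic_trace=np.zeros(0) if aic_trace is None else np.asarray(aic_trace),
        sign_convention=sign,
        preprocessing=preprocessing,
        reference_stats=reference_stats,
    )


def express_pattern(
    model: PatternModel, matrix: VolumeMatrix, tiv: np.ndarray
) -> ExpressionScores:
    """Score subjects on a derived pattern.

    Applies the stored preprocessing (including the derivation sample's TIV
    slopes and column means), projects onto the pattern weights, and z-scores
    against the derivation-sample reference statistics so that new samples
    are expressed on the derivation scale.
    """
    spec = model.preprocessing
    if tuple(matrix.region_names) != tuple(spec.region_names):
        missing = set(spec.region_names) - set(matrix.region_names)
        extra = set(matrix.region_names) - set(spec.region_names)
        if missing or extra:
            raise ValueError(
                f"region mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
            )
        # same set, different order: realign
        order = [matrix.region_names.index(r) for r in spec.region_names]
        matrix = VolumeMatrix(
            values=matrix.values[:, order],
            region_names=spec.region_names,
            subject_ids=matrix.subject_ids,
            log_scale=matrix.log_scale,
        )
    tiv = np.asarray(tiv, dtype=float)
    _check_positive(matrix, tiv)
    logv = np.log(matrix.values)
    if spec.mode == "log_tiv_residual" and spec.tiv_slopes is not None:
        logv = logv - np.outer(np.log(tiv) - spec.log_tiv_mean, spec.tiv_slopes)
    raw = _project(logv, spec.col_means, model.weights)
    mean, sd = model.reference_stats
    return ExpressionScores(raw=raw, z=(raw - mean) / sd, reference_stats=(mean, sd))


def derive_pattern(
    matrix: VolumeMatrix,
    tiv: np.ndarray,
    biomarker: np.ndarray,
    *,
    mode: str = "log_tiv_residual",
    max_k: int | None = None,
    log_biomarker: bool = False,
) -> tuple[PatternModel, SSMDecomposition, ExpressionScores]:
    """Full derivation: preprocess, decompose, AIC-select, combine, score."""
    biomarker = np.asarray(biomarker, dtype=float)
    if log_biomarker:
        if np.any(biomarker <= 0):
            raise ValueError("biomarker must be positive for log transform")
        biomarker = np.log(biomarker)
    tiv = np.asarray(tiv, dtype=float)
    _check_positive(matrix, tiv)
    if matrix.n_subjects < matrix.n_regions:
        warnings.warn(
            f"fewer subjects ({matrix.n_subjects}) than regions "
            f"({matrix.n_regions}); decomposition may be unstable"
        )

    logv = np.log(matrix.values)
    tiv_slopes = None
    log_tiv_mean = None
    if mode == "log_tiv_residual":
        pre, tiv_slopes, log_tiv_mean = _tiv_residualize(logv, tiv)
    elif mode == "log_only":
        pre = logv
    else:
        raise ValueError(f"unknown preprocessing mode {mode!r}")

    srp = double_center(pre)
    decomposition = derive_components(srp)
    if decomposition.n_components == 0:
        raise ValueError("degenerate data: no components")
    component_set, coefs, aic = select_component_set(
        decomposition.ssf, biomarker, max_k
    )
    spec = PreprocessingSpec(
        mode=mode,
        region_names=tuple(matrix.region_names),
        tiv_slopes=tiv_slopes,
        log_tiv_mean=log_tiv_mean,
        col_means=pre.mean(axis=0),
    )
    model = combine_pattern(
        decomposition,
        component_set,
        coefs,
        biomarker,
        preprocessed=pre,
        preprocessing=spec,
        aic_trace=aic,
    )
    scores = express_pattern(model, matrix, tiv)
    return model, decomposition, scores


def bootstrap_pattern(
    matrix: VolumeMatrix,
    tiv: np.ndarray,
    biomarker: np.ndarray,
    n_iterations: int = 10_000,
    seed: int = 0,
    *,
    mode: str = "log_tiv_residual",
    max_k: int | None = None,
    ci_level: float = 0.95,
) -> BootstrapReliability:
    """Case-resampling bootstrap of the regional pattern weights.

    Each replicate re-runs the full derivation on a resample of subjects and
    is sign-aligned to the point estimate by the sign of the dot product.
    Degenerate replicates are skipped and counted; more than 5% failures is
    an error.
    """
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    tiv = np.asarray(tiv, dtype=float)
    biomarker = np.asarray(biomarker, dtype=float)
    point, _, _ = derive_pattern(matrix, tiv, biomarker, mode=mode, max_k=max_k)
    n = matrix.n_subjects
    weights = np.empty((n_iterations, matrix.n_regions))
    failures = 0
    kept = 0
    for i in range(n_iterations):
        rng = np.random.default_rng([seed, i])  # per-replicate substream
        idx = rng.integers(0, n, size=n)
        sub = VolumeMatrix(
            values=matrix.values[idx],
            region_names=matrix.region_names,
            subject_ids=tuple(f"b{j}" for j in range(n)),
            log_scale=matrix.log_scale,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep, _, _ = derive_pattern(
                    sub, tiv[idx], biomarker[idx], mode=mode, max_k=max_k
                )
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        w = rep.weights
        if float(w @ point.weights) < 0:
            w = -w
        weights[kept] = w
        kept += 1
    if failures > 0.05 * n_iterations:
        raise RuntimeError(
            f"{failures}/{n_iterations} bootstrap replicates failed"
        )
    weights = weights[:kept]
    sd = weights.std(axis=0, ddof=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(weights, [alpha, 1.0 - alpha], axis=0)
    with np.errstate(divide="ignore"):
        z = np.where(sd > 0, point.weights / sd, np.inf * np.sign(point.weights))
    return BootstrapReliability(
        n_iterations=n_iterations,
        n_failures=failures,
        point_weights=point.weights,
        weight_sd=sd,
        weight_z=z,
        ci_lower=lo,
        ci_upper=hi,
        region_names=tuple(matrix.region_names),
    )
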