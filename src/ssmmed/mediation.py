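"""Serial mediation with 1-3 ordered mediators and percentile bootstrap.

Path coefficients come from a set of OLS submodels sharing one complete-case
sample and one covariate set: each mediator is regressed on the exposure and
all earlier mediators, the outcome on the exposure and all mediators, and the
total effect on the exposure alone (always with covariates).  Indirect
effects are products of unstandardized coefficients along every ordered
mediator subset; completely standardized effects rescale by sd(x)/sd(y),
which equals the product of the standardized path coefficients (telescoping
identity).  Confidence intervals are empirical percentiles over case
resamples.

All replicate fits are solved from one Gram matrix per resample, which keeps
10,000-iteration bootstraps fast at typical cohort sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import prod

import numpy as np
import pandas as pd

from .glm import inference

__all__ = [
    "MediationSpec",
    "PathEstimates",
    "IndirectEffect",
    "MediationResult",
    "fit_paths",
    "enumerate_indirect_paths",
    "indirect_effects",
    "bootstrap_mediation",
    "decompose_total",
    "reverse_mediators",
    "telescoped_std_effect",
]


@dataclass(frozen=True)
class MediationSpec:
    x: str
    y: str
    mediators: tuple
    covariates: tuple = ()
    n_boot: int = 10_000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mediators", tuple(self.mediators))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        k = len(self.mediators)
        if not 1 <= k <= 3:
            raise ValueError(f"need 1-3 mediators, got {k}")
        names = [self.x, self.y, *self.mediators]
        if len(set(names)) != len(names):
            raise ValueError("x, y, and mediators must be disjoint")
        if set(names) & set(self.covariates):
            raise ValueError("covariates overlap model variables")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    @property
    def k(self) -> int:
        return len(self.mediators)


@dataclass(frozen=True)
class PathEstimates:
    """OLS path coefficients; keys are 1-based mediator indices."""

    a: dict            # i -> x -> M_i coefficient
    d: dict            # (i, j), i<j -> M_i -> M_j coefficient
    b: dict            # i -> M_i -> Y coefficient
    c_prime: float     # direct x -> Y
    c: float           # total x -> Y
    a_std: dict
    d_std: dict
    b_std: dict
    c_prime_std: float
    c_std: float
    residual_sds: dict
    sds: dict          # variable -> sd on the analysis sample
    n_used: int
    c_inference: tuple       # (t, p, ci) of the total effect
    c_prime_inference: tuple


@dataclass(frozen=True)
class IndirectEffect:
    path: tuple              # 1-based mediator indices, in serial order
    label: str
    raw: float
    std: float
    boot_se: float | None = None
    ci: tuple | None = None
    std_boot_se: float | None = None
    std_ci: tuple | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class MediationResult:
    spec: MediationSpec
    paths: PathEstimates
    indirects: list
    total: float
    direct: float
    total_std: float
    direct_std: float
    n_used: int
    boot_failures: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.indirects:
            rows.append(
                {
                    "path": e.label,
                    "raw": e.raw,
                    "std": e.std,
                    "boot_se": e.boot_se,
                    "ci_lower": None if e.ci is None else e.ci[0],
                    "ci_upper": None if e.ci is None else e.ci[1],
                    "std_ci_lower": None if e.std_ci is None else e.std_ci[0],
                    "std_ci_upper": None if e.std_ci is None else e.std_ci[1],
                    "significant": e.significant,
                }
            )
        return pd.DataFrame(rows)


def enumerate_indirect_paths(k: int) -> list[tuple]:
    """All nonempty ordered mediator subsets respecting the serial order."""
    if not 1 <= k <= 3:
        raise ValueError(f"k must be in 1..3, got {k}")
    paths = []
    for mask in range(1, 2**k):
        paths.append(tuple(i + 1 for i in range(k) if mask >> i & 1))
    paths.sort(key=lambda p: (len(p), p))
    return paths


def _extract(data: pd.DataFrame, spec: MediationSpec) -> np.ndarray:
    cols = [spec.x, *spec.mediators, *spec.covariates, spec.y]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    sub = data[cols].dropna()
    n = len(sub)
    p_max = 2 + spec.k + len(spec.covariates)
    if n <= p_max:
        raise ValueError(f"n={n} too small for {p_max} parameters")
    A = np.column_stack([np.ones(n), sub.to_numpy(dtype=float)])
    return A


# column layout of the stacked array A:
#   0 const | 1 x | 2..1+k mediators | covariates | last y
def _submodel_indices(k: int, n_cov: int):
    cov = list(range(2 + k, 2 + k + n_cov))
    y_col = 2 + k + n_cov
    models = []
    for i in range(1, k + 1):
        models.append(([0, 1] + [1 + j for j in range(1, i)] + cov, 1 + i))
    models.append(([0, 1] + [1 + j for j in range(1, k + 1)] + cov, y_col))  # outcome
    models.append(([0, 1] + cov, y_col))  # total
    return models, y_col


def _solve_gram(G: np.ndarray, pred: list[int], target: int) -> np.ndarray:
    sub = G[np.ix_(pred, pred)]
    rhs = G[pred, target]
    beta = np.linalg.solve(sub, rhs)
    if not np.all(np.isfinite(beta)):
        raise np.linalg.LinAlgError("non-finite solution")
    return beta


def _coef_tables(G: np.ndarray, k: int, n_cov: int):
    """(a, d, b, c_prime, c) unstandardized coefficients from a Gram matrix."""
    models, _ = _submodel_indices(k, n_cov)
    a, d, b = {}, {}, {}
    betas = [_solve_gram(G, pred, tgt) for pred, tgt in models]
    for i in range(1, k + 1):
        beta = betas[i - 1]
        a[i] = float(beta[1])
        for j in range(1, i):
            d[(j, i)] = float(beta[1 + j])
    beta_y = betas[k]
    c_prime = float(beta_y[1])
    for i in range(1, k + 1):
        b[i] = float(beta_y[1 + i])
    c = float(betas[k + 1][1])
    return a, d, b, c_prime, c, betas, models


def _sd_from_gram(G: np.ndarray, n: int, col: int) -> float:
    mean = G[0, col] / n
    var = G[col, col] / n - mean**2
    return float(np.sqrt(max(var, 0.0)) * np.sqrt(n / (n - 1)))


def fit_paths(data: pd.DataFrame, spec: MediationSpec) -> PathEstimates:
    """Estimate all path coefficients on the shared complete-case sample."""
    A = _extract(data, spec)
    n = A.shape[0]
    k = spec.k
    n_cov = len(spec.covariates)
    G = A.T @ A
    _check_gram_rank(G, spec)
    a, d, b, c_prime, c, betas, models = _coef_tables(G, k, n_cov)

    var_cols = {spec.x: 1, spec.y: 2 + k + n_cov}
    for i, m in enumerate(spec.mediators, start=1):
        var_cols[m] = 1 + i
    sds = {name: _sd_from_gram(G, n, col) for name, col in var_cols.items()}
    for name in (spec.x, spec.y, *spec.mediators):
        if sds[name] == 0:
            raise ValueError(f"variable {name!r} is constant on the analysis sample")

    sd_m = {i: sds[m] for i, m in enumerate(spec.mediators, start=1)}
    a_std = {i: a[i] * sds[spec.x] / sd_m[i] for i in a}
    d_std = {(i, j): d[(i, j)] * sd_m[i] / sd_m[j] for (i, j) in d}
    b_std = {i: b[i] * sd_m[i] / sds[spec.y] for i in b}
    c_prime_std = c_prime * sds[spec.x] / sds[spec.y]
    c_std = c * sds[spec.x] / sds[spec.y]

    residual_sds = {}
    inferences = {}
    for (pred, tgt), beta, name in zip(
        models, betas, [*spec.mediators, spec.y, f"{spec.y}|total"]
    ):
        rss = float(G[tgt, tgt] - beta @ G[np.ix_(pred, [tgt])].ravel())
        df_resid = n - len(pred)
        rss = max(rss, 0.0)
        residual_sds[name] = float(np.sqrt(rss / df_resid))
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.inv(G[np.ix_(pred, pred)])
        se_x = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 1e-300)))
        inferences[name] = inference(float(beta[1]), se_x, df_resid)

    return PathEstimates(
        a=a,
        d=d,
        b=b,
        c_prime=c_prime,
        c=c,
        a_std=a_std,
        d_std=d_std,
        b_std=b_std,
        c_prime_std=c_prime_std,
        c_std=c_std,
        residual_sds=residual_sds,
        sds=sds,
        n_used=n,
        c_inference=inferences[f"{spec.y}|total"],
        c_prime_inference=inferences[spec.y],
    )


def _check_gram_rank(G: np.ndarray, spec: MediationSpec) -> None:
    # predictors only: a perfectly determined outcome is legal, a collinear
    # design is not
    eigvals = np.linalg.eigvalsh(G[:-1, :-1])
    if eigvals[0] <= eigvals[-1] * 1e-12:
        raise ValueError(
            "collinear design in mediation submodels "
            f"(variables: {[spec.x, *spec.mediators, *spec.covariates]})"
        )


def _path_product(a: dict, d: dict, b: dict, path: tuple) -> float:
    coefs = [a[path[0]]]
    coefs += [d[(path[s], path[s + 1])] for s in range(len(path) - 1)]
    coefs.append(b[path[-1]])
    return prod(coefs)


def _path_label(spec: MediationSpec, path: tuple) -> str:
    middle = "->".join(spec.mediators[i - 1] for i in path)
    return f"{spec.x}->{middle}->{spec.y}"


def indirect_effects(paths: PathEstimates, spec: MediationSpec) -> list[IndirectEffect]:
    """Point estimates of every serial indirect effect."""
    ratio = paths.sds[spec.x] / paths.sds[spec.y]
    out = []
    for path in enumerate_indirect_paths(spec.k):
        raw = _path_product(paths.a, paths.d, paths.b, path)
        out.append(
            IndirectEffect(
                path=path,
                label=_path_label(spec, path),
                raw=raw,
                std=raw * ratio,
            )
        )
    return out


def telescoped_std_effect(std_path_coefficients) -> float:
    """Completely standardized serial indirect effect from standardized paths.

    By the telescoping identity this is simply the product of the
    standardized coefficients along the chain.
    """
    return float(prod(float(c) for c in std_path_coefficients))


def bootstrap_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Percentile-bootstrap mediation analysis.

    Cases (full rows) are resampled with replacement; all submodels are refit
    per replicate.  Replicate standardized effects use the replicate's own
    sds; the point estimate uses the full-sample sds.  Per-replicate seed
    substreams make results invariant to growing ``n_boot``.
    """
    if spec.n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    point_paths = fit_paths(data, spec)
    point_indirects = indirect_effects(point_paths, spec)
    path_list = [e.path for e in point_indirects]

    A = _extract(data, spec)
    n = A.shape[0]
    k = spec.k
    n_cov = len(spec.covariates)
    x_col, y_col = 1, 2 + k + n_cov

    raw = np.empty((spec.n_boot, len(path_list)))
    std = np.empty_like(raw)
    failures = 0
    kept = 0
    for rep in range(spec.n_boot):
        rng = np.random.default_rng([spec.seed, rep])
        idx = rng.integers(0, n, size=n)
        Ab = A[idx]
        G = Ab.T @ Ab
        try:
            a, d, b, _, _, _, _ = _coef_tables(G, k, n_cov)
        except np.linalg.LinAlgError:
            failures += 1
            continue
        sd_x = _sd_from_gram(G, n, x_col)
        sd_y = _sd_from_gram(G, n, y_col)
        if sd_x == 0 or sd_y == 0:
            failures += 1
            continue
        for j, path in enumerate(path_list):
            raw[kept, j] = _path_product(a, d, b, path)
        std[kept] = raw[kept] * sd_x / sd_y
        kept += 1
    if failures > 0.05 * spec.n_boot:
        raise RuntimeError(f"{failures}/{spec.n_boot} bootstrap replicates failed")
    raw, std = raw[:kept], std[:kept]

    alpha = (1.0 - spec.ci_level) / 2.0
    q = [alpha, 1.0 - alpha]
    raw_ci = np.quantile(raw, q, axis=0)
    std_ci = np.quantile(std, q, axis=0)
    indirects = []
    for j, e in enumerate(point_indirects):
        ci = (float(raw_ci[0, j]), float(raw_ci[1, j]))
        indirects.append(
            replace(
                e,
                boot_se=float(raw[:, j].std(ddof=1)),
                ci=ci,
                std_boot_se=float(std[:, j].std(ddof=1)),
                std_ci=(float(std_ci[0, j]), float(std_ci[1, j])),
                significant=not (ci[0] <= 0.0 <= ci[1]),
            )
        )
    return MediationResult(
        spec=spec,
        paths=point_paths,
        indirects=indirects,
        total=point_paths.c,
        direct=point_paths.c_prime,
        total_std=point_paths.c_std,
        direct_std=point_paths.c_prime_std,
        n_used=point_paths.n_used,
        boot_failures=failures,
    )


def decompose_total(result: MediationResult, rtol: float = 1e-8) -> dict:
    """Verify and report the decomposition c = c' + sum of raw indirects."""
    indirect_sum = sum(e.raw for e in result.indirects)
    lhs = result.total
    rhs = result.direct + indirect_sum
    scale = max(abs(lhs), abs(rhs), 1e-12)
    if abs(lhs - rhs) > rtol * scale:
        raise ValueError(
            f"total-effect decomposition violated: c={lhs!r} vs "
            f"c'+sum(indirects)={rhs!r}; submodel samples may differ"
        )
    ratio = result.paths.sds[result.spec.x] / result.paths.sds[result.spec.y]
    return {
        "total": lhs,
        "direct": result.direct,
        "indirect_sum": indirect_sum,
        "total_std": result.total_std,
        "direct_std": result.direct_std,
        "indirect_sum_std": indirect_sum * ratio,
        "total_inference": result.paths.c_inference,
        "direct_inference": result.paths.c_prime_inference,
        "n_used": result.n_used,
    }


def reverse_mediators(spec: MediationSpec) -> MediationSpec:
    """Sensitivity variant with the mediator order reversed."""
    if spec.k < 2:
        raise ValueError("need at least 2 mediators to reverse")
    return replace(spec, mediators=tuple(reversed(spec.mediators)))
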