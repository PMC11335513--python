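"""Block-wise OLS, exact t-based inference, BH-FDR, score transformations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "FDRResult",
    "fit_blockwise",
    "focal_result",
    "standardized_beta",
    "inference",
    "bh_fdr",
    "residualize",
    "log_transform",
]


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    predictor: str
    B: float
    SE: float
    beta: float
    t: float
    df: int
    p: float
    ci: tuple
    block: int
    n: int


@dataclass(frozen=True)
class FDRResult:
    raw_p: dict
    adj_p: dict
    m: int

    def significant(self, alpha: float = 0.05) -> dict:
        return {k: v < alpha for k, v in self.adj_p.items()}


def _design(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors]
    )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        cols = [X[:, 0]]
        for j in range(1, X.shape[1]):
            candidate = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(candidate) == len(cols):
                collinear.append(names[j - 1])
            else:
                cols.append(X[:, j])
        raise ValueError(f"design matrix is rank deficient; collinear: {collinear}")


def fit_blockwise(
    data: pd.DataFrame,
    outcome: str,
    blocks: list[list[str]],
    level: float = 0.95,
) -> list[RegressionResult]:
    """Cumulative block-wise OLS of ``outcome`` on nested predictor blocks.

    Block *k* contains all predictors of blocks 1..k.  Returns a
    :class:`RegressionResult` for every predictor in every cumulative model,
    computed on the complete-case sample shared across blocks.
    """
    all_predictors = [p for block in blocks for p in block]
    missing = [c for c in [outcome, *all_predictors] if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    if outcome in all_predictors:
        raise ValueError(f"outcome {outcome!r} also appears as a predictor")
    sub = data[[outcome, *all_predictors]].dropna()
    n = len(sub)
    if n <= len(all_predictors) + 1:
        raise ValueError(
            f"n={n} too small for {len(all_predictors) + 1} parameters"
        )
    y = sub[outcome].to_numpy(dtype=float)
    sd_y = y.std(ddof=1)
    results: list[RegressionResult] = []
    cum: list[str] = []
    for k, block in enumerate(blocks, start=1):
        cum = cum + list(block)
        X = _design(sub, cum)
        _check_rank(X, cum)
        beta_hat, rss = _ols(X, y)
        df_resid = n - X.shape[1]
        perfect = rss <= 1e-12 * max(float(y @ y), 1.0)
        if perfect:
            # outcome-as-predictor duplicates are rejected above by name; a
            # genuinely deterministic relation is legal but has no error df
            warnings.warn(f"perfect fit in block {k}: zero residual variance")
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.inv(X.T @ X)
        for j, name in enumerate(cum, start=1):
            B = float(beta_hat[j])
            SE = float(np.sqrt(sigma2 * xtx_inv[j, j]))
            if perfect or SE == 0.0:
                t, p, ci = float(np.inf * np.sign(B)) if B else 0.0, 0.0 if B else 1.0, (B, B)
            else:
                t, p, ci = inference(B, SE, df_resid, level)
            sd_x = sub[name].to_numpy(dtype=float).std(ddof=1)
            results.append(
                RegressionResult(
                    outcome=outcome,
                    predictor=name,
                    B=B,
                    SE=SE,
                    beta=standardized_beta(B, sd_x, sd_y),
                    t=t,
                    df=df_resid,
                    p=p,
                    ci=ci,
                    block=k,
                    n=n,
                )
            )
    return results


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def focal_result(
    results: list[RegressionResult], predictor: str
) -> RegressionResult:
    """The focal predictor's row from the final (largest) block."""
    rows = [r for r in results if r.predictor == predictor]
    if not rows:
        raise KeyError(f"no results for predictor {predictor!r}")
    return max(rows, key=lambda r: r.block)


def standardized_beta(B: float, sd_x: float, sd_y: float) -> float:
    """beta = B * sd(x) / sd(y), sds taken over the analysis sample."""
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("standard deviations must be positive")
    return B * sd_x / sd_y


def inference(B: float, SE: float, df: int, level: float = 0.95):
    """Exact t statistic, two-sided p, and symmetric CI for a coefficient."""
    if SE <= 0:
        raise ValueError("SE must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = B / SE
    p = float(2.0 * stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(0.5 + level / 2.0, df) * SE)
    return float(t), p, (B - half, B + half)


def bh_fdr(pvalues) -> FDRResult:
    """Benjamini–Hochberg step-up adjusted p-values.

    Accepts a sequence or a mapping ``label -> p``; preserves input order in
    the returned dictionaries.  adj_(i) = min_{j >= i} p_(j) * m / j, capped
    at 1, with ties kept stable.
    """
    if isinstance(pvalues, dict):
        labels = list(pvalues.keys())
        p = np.asarray(list(pvalues.values()), dtype=float)
    else:
        p = np.asarray(list(pvalues), dtype=float)
        labels = list(range(len(p)))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return FDRResult(
        raw_p=dict(zip(labels, p.tolist())),
        adj_p=dict(zip(labels, adj.tolist())),
        m=m,
    )


def residualize(y, x) -> np.ndarray:
    """Z-scored OLS residuals of y on x (with intercept)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have the same length")
    if x.std(ddof=0) == 0:
        raise ValueError("x is constant; cannot residualize")
    xd = x - x.mean()
    slope = float(xd @ (y - y.mean())) / float(xd @ xd)
    resid = y - y.mean() - slope * xd
    s = resid.std(ddof=0)
    if s == 0:
        warnings.warn("residuals are identically zero; returning zeros")
        return np.zeros_like(resid)
    return resid / s


def log_transform(v) -> np.ndarray:
    """Natural log, elementwise; errors list the offending rows."""
    v = np.asarray(v, dtype=float)
    bad = np.flatnonzero(~(v > 0))
    if bad.size:
        raise ValueError(f"non-positive values at rows: {bad[:20].tolist()}")
    return np.log(v)
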