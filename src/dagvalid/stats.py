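"""Rank-correlation estimation for DAG validation.

Marginal associations are estimated with the Spearman rank correlation and a
bias-corrected accelerated (BCa) bootstrap interval; conditional
independencies with the partial Spearman correlation computed from the rank
correlation matrix of the complete cases of the variables involved, with a
Fisher-z interval using standard error 1/sqrt(n - k - 3) for a
conditioning-set size k.  All tests use testwise complete-case deletion, so
the effective sample size varies per test and is recorded on each estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationEstimate",
    "EstimationConfig",
    "InsufficientDataError",
    "spearman_rho",
    "bca_ci",
    "rank_correlation_matrix",
    "partial_correlation",
    "fisher_z_ci",
    "test_marginal",
    "test_conditional",
]


class InsufficientDataError(ValueError):
    """Too few complete cases, or a constant variable, for the requested test."""


@dataclass(frozen=True)
class EstimationConfig:
    level: float = 0.95
    replicates: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        if self.replicates < 200:
            raise ValueError("at least 200 bootstrap replicates are required")


@dataclass(frozen=True)
class CorrelationEstimate:
    x: str
    y: str
    conditioning_set: FrozenSet[str]
    rho: float
    ci_low: float
    ci_high: float
    n_effective: int
    method: str  # "spearman_bootstrap" | "partial_fisher_z"
    level: float = 0.95
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "given": sorted(self.conditioning_set),
            "rho": self.rho,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n_effective,
            "method": self.method,
            "level": self.level,
            "flags": list(self.flags),
        }


def _as_clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties (complete cases)."""
    x, y = _as_clean_pair(x, y)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("correlation undefined for a constant input")
    return float(sps.spearmanr(x, y).statistic)


def _rowwise_spearman(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Spearman of each row pair; NaN where a row is constant."""
    rx = sps.rankdata(xs, axis=1)
    ry = sps.rankdata(ys, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (rx * ry).sum(axis=1) / denom, np.nan)


_JACKKNIFE_EXACT_MAX = 500


def _jackknife_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out Spearman estimates for the BCa acceleration.

    Exact (chunked) leave-one-out up to n=500; beyond that a delete-d
    grouped jackknife with 200 groups, since the exact version is O(n^2)
    and the acceleration vanishes as n grows anyway.
    """
    n = x.size
    if n <= _JACKKNIFE_EXACT_MAX:
        out = np.empty(n)
        mask = ~np.eye(n, dtype=bool)
        chunk = max(1, int(2e6 // max(n, 1)))
        for start in range(0, n, chunk):
            rows = mask[start : start + chunk]
            k = rows.shape[0]
            xs = np.broadcast_to(x, (k, n))[rows].reshape(k, n - 1)
            ys = np.broadcast_to(y, (k, n))[rows].reshape(k, n - 1)
            out[start : start + k] = _rowwise_spearman(xs, ys)
        return out
    groups = 200
    bounds = np.linspace(0, n, groups + 1).astype(int)
    out = np.empty(groups)
    for g in range(groups):
        keep = np.ones(n, dtype=bool)
        keep[bounds[g] : bounds[g + 1]] = False
        out[g] = _rowwise_spearman(x[keep][None, :], y[keep][None, :])[0]
    return out


def bca_ci(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
    replicates: int = 2000,
    seed: int = 0,
) -> tuple[float, float, tuple[str, ...]]:
    """BCa bootstrap interval for the Spearman correlation of paired data.

    Pairs are resampled with replacement; the bias correction z0 comes from
    the fraction of replicate statistics below the point estimate, the
    acceleration a from the jackknife skewness of leave-one-out estimates, and
    the endpoints are the correspondingly adjusted quantiles of the replicate
    distribution.  Deterministic given ``seed``.  Returns (low, high, flags);
    flags record degenerate fallbacks (see below) that never occur on
    well-behaved data.
    """
    if replicates < 200:
        raise ValueError("at least 200 bootstrap replicates are required")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    x, y = _as_clean_pair(x, y)
    theta = spearman_rho(x, y)
    n = x.size
    rng = np.random.default_rng(seed)
    flags: list[str] = []

    idx = rng.integers(0, n, size=(replicates, n))
    boot = _rowwise_spearman(x[idx], y[idx])
    bad = ~np.isfinite(boot)
    if bad.any():
        flags.append("constant_resamples_dropped")
        boot = boot[~bad]
        if boot.size < replicates // 2:
            flags.append("degenerate")
            return theta, theta, tuple(flags)
    if np.ptp(boot) == 0:
        flags.append("degenerate")
        return theta, theta, tuple(flags)

    alpha = (1 - level) / 2
    frac_below = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / boot.size
    if frac_below <= 0 or frac_below >= 1:
        flags.append("percentile_fallback")
        lo, hi = np.quantile(boot, [alpha, 1 - alpha])
        return float(lo), float(hi), tuple(flags)
    z0 = sps.norm.ppf(frac_below)

    loo = _jackknife_spearman(x, y)
    if not np.all(np.isfinite(loo)):
        flags.append("percentile_fallback")
        lo, hi = np.quantile(boot, [alpha, 1 - alpha])
        return float(lo), float(hi), tuple(flags)
    d = loo.mean() - loo
    denom = 6.0 * (d**2).sum() ** 1.5
    if denom == 0:
        flags.append("percentile_fallback")
        a = 0.0
        lo, hi = np.quantile(boot, [alpha, 1 - alpha])
        return float(lo), float(hi), tuple(flags)
    a = (d**3).sum() / denom

    lo, hi = np.quantile(boot, _bca_adjusted_alphas(z0, a, alpha))
    return float(lo), float(hi), tuple(flags)


def _bca_adjusted_alphas(z0: float, a: float, alpha: float) -> np.ndarray:
    """BCa-adjusted quantile levels; reduces to (alpha, 1-alpha) at z0 = a = 0."""
    z_lo, z_hi = sps.norm.ppf([alpha, 1 - alpha])
    adj = [sps.norm.cdf(z0 + (z0 + zq) / (1 - a * (z0 + zq))) for zq in (z_lo, z_hi)]
    return np.clip(adj, 0.0, 1.0)


def rank_correlation_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix on the complete cases of all given columns.

    Complete cases are taken jointly over the full column set — not pooled
    pairwise — so the matrix is always positive semi-definite and corresponds
    to a single effective sample.
    """
    complete = data.dropna()
    if len(complete) < 3:
        raise InsufficientDataError(
            f"need >= 3 jointly complete rows, got {len(complete)}"
        )
    for col in complete.columns:
        if complete[col].nunique() < 2:
            raise InsufficientDataError(f"column {col!r} is constant on complete cases")
    return complete.corr(method="spearman")


def partial_correlation(
    corr: pd.DataFrame, x: str, y: str, z: Iterable[str] = ()
) -> float:
    """Partial correlation of x and y given z, from a correlation matrix.

    Computed by inverting the (x, y, z) submatrix and normalizing the negated
    off-diagonal entry; with empty z this is exactly the marginal entry.
    """
    zs = sorted(set(z))
    if x in zs or y in zs:
        raise ValueError("x and y may not be in the conditioning set")
    if not zs:
        return float(corr.loc[x, y])
    cols = [x, y] + zs
    sub = corr.loc[cols, cols].to_numpy(dtype=float)
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as err:
        raise InsufficientDataError(
            f"singular correlation submatrix for ({x}, {y} | {zs})"
        ) from err
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        raise InsufficientDataError("correlation submatrix is not positive definite")
    return float(-prec[0, 1] / np.sqrt(denom))


def _partial_correlation_recursive(corr: pd.DataFrame, x: str, y: str, z: Iterable[str]) -> float:
    """Reference implementation via the first-order recursion; O(3^|z|)."""
    zs = sorted(set(z))
    if not zs:
        return float(corr.loc[x, y])
    w, rest = zs[-1], zs[:-1]
    rxy = _partial_correlation_recursive(corr, x, y, rest)
    rxw = _partial_correlation_recursive(corr, x, w, rest)
    ryw = _partial_correlation_recursive(corr, y, w, rest)
    return (rxy - rxw * ryw) / np.sqrt((1 - rxw**2) * (1 - ryw**2))


def fisher_z_ci(rho: float, n: int, k: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z interval for a (partial) correlation with k conditioning variables."""
    if n - k - 3 <= 0:
        raise InsufficientDataError(f"need n - k - 3 > 0, got n={n}, k={k}")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1 for the Fisher transform")
    zq = sps.norm.ppf(0.5 + level / 2)
    se = 1.0 / np.sqrt(n - k - 3)
    zr = np.arctanh(rho)
    return float(np.tanh(zr - zq * se)), float(np.tanh(zr + zq * se))


def _complete_subframe(data: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in dataset: {missing}")
    return data.loc[:, list(columns)].dropna()


def test_marginal(
    data: pd.DataFrame,
    pair: tuple[str, str],
    config: EstimationConfig = EstimationConfig(),
) -> CorrelationEstimate:
    """Spearman correlation of a pair with a seeded BCa bootstrap interval."""
    x, y = pair
    complete = _complete_subframe(data, [x, y])
    rho = spearman_rho(complete[x], complete[y])
    lo, hi, flags = bca_ci(
        complete[x].to_numpy(),
        complete[y].to_numpy(),
        level=config.level,
        replicates=config.replicates,
        seed=config.seed,
    )
    return CorrelationEstimate(
        x=x, y=y, conditioning_set=frozenset(), rho=rho, ci_low=lo, ci_high=hi,
        n_effective=len(complete), method="spearman_bootstrap",
        level=config.level, flags=flags,
    )


def test_conditional(
    data: pd.DataFrame,
    statement,  # IndependenceStatement or (x, y, z)
    config: EstimationConfig = EstimationConfig(),
) -> CorrelationEstimate:
    """Partial Spearman correlation for an independence statement, Fisher-z CI."""
    if hasattr(statement, "conditioning_set"):
        x, y, z = statement.x, statement.y, statement.conditioning_set
    else:
        x, y, z = statement
    zs = sorted(z)
    complete = _complete_subframe(data, [x, y, *zs])
    n, k = len(complete), len(zs)
    if n < k + 4:
        raise InsufficientDataError(
            f"need >= {k + 4} complete cases for |z|={k}, got {n}"
        )
    corr = rank_correlation_matrix(complete)
    rho = partial_correlation(corr, x, y, zs)
    lo, hi = fisher_z_ci(rho, n, k, config.level)
    return CorrelationEstimate(
        x=x, y=y, conditioning_set=frozenset(zs), rho=rho, ci_low=lo, ci_high=hi,
        n_effective=n, method="partial_fisher_z", level=config.level,
    )
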