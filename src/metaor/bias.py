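"""Publication-bias diagnostics: Begg rank correlation, Egger regression,
and funnel-plot coordinates.

Begg's test rank-correlates the standardized deviates
t_i = (theta_i - theta_hat) / sqrt(v_i - v_pooled) with the sampling
variances v_i (Kendall's tau-b).  Three p-value variants are exposed:
the plain normal approximation on the Kendall score (default), the
continuity-corrected normal approximation, and the exact permutation
distribution (feasible for k <= 8).

Egger's test regresses the standard normal deviate theta_i/se_i on the
precision 1/se_i by OLS; the intercept measures small-study asymmetry and
is tested against a t distribution with k - 2 degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectEstimate, PooledResult, Z975

__all__ = [
    "BiasTestResult",
    "FunnelPoint",
    "begg_test",
    "egger_test",
    "funnel_coordinates",
    "funnel_table",
    "BEGG_METHODS",
]

logger = logging.getLogger(__name__)

BEGG_METHODS = ("normal", "normal-cc", "exact")

#: floor for the radicand v_i - v_pooled in the Begg deviates; the pooled
#: variance can only exceed a study variance through floating error.
RADICAND_FLOOR = 1e-12


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of a publication-bias test.

    ``statistic`` is Kendall's tau-b for Begg and the regression intercept
    for Egger; ``se`` is the intercept's standard error (Egger only);
    ``slope`` is Egger's precision slope, reported for context.
    """

    test: str
    statistic: float
    p: float
    k: int
    se: float | None = None
    slope: float | None = None
    method: str | None = None


@dataclass(frozen=True)
class FunnelPoint:
    """One study's funnel-plot coordinates (log OR vs standard error)."""

    study_id: str
    x: float
    y: float
    pooled_ref: float


def _kendall_score_and_var(x: np.ndarray, y: np.ndarray) -> tuple[int, float]:
    """Kendall S statistic and its tie-corrected null variance."""
    n = len(x)
    S = 0
    for i in range(n):
        for j in range(i + 1, n):
            S += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))

    def tie_terms(v: np.ndarray) -> tuple[float, float, float]:
        _, counts = np.unique(v, return_counts=True)
        t1 = float(sum(t * (t - 1) * (2 * t + 5) for t in counts))
        t2 = float(sum(t * (t - 1) * (t - 2) for t in counts))
        t3 = float(sum(t * (t - 1) for t in counts))
        return t1, t2, t3

    x1, x2, x3 = tie_terms(x)
    y1, y2, y3 = tie_terms(y)
    var = (
        (n * (n - 1) * (2 * n + 5) - x1 - y1) / 18.0
        + x2 * y2 / (9.0 * n * (n - 1) * (n - 2))
        + x3 * y3 / (2.0 * n * (n - 1))
    )
    return S, var


def begg_test(
    effects: Sequence[EffectEstimate],
    method: str = "normal",
) -> BiasTestResult:
    """Begg-Mazumdar rank-correlation test for funnel asymmetry.

    ``method``: ``"normal"`` (default) tests the Kendall score with the
    plain normal approximation, ``"normal-cc"`` applies the +/-1 continuity
    correction, ``"exact"`` enumerates the permutation distribution of the
    score (k <= 8 only).
    """
    if method not in BEGG_METHODS:
        raise ValueError(f"method must be one of {BEGG_METHODS}, got {method!r}")
    k = len(effects)
    if k < 3:
        raise ValueError("Begg's test needs at least 3 studies")
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    mu_fixed = float((w * theta).sum() / w.sum())
    v_pooled = float(1.0 / w.sum())
    radicand = v - v_pooled
    if (radicand < RADICAND_FLOOR).any():
        logger.warning(
            "Begg deviates: %d radicand(s) truncated at %g",
            int((radicand < RADICAND_FLOOR).sum()), RADICAND_FLOOR,
        )
    t = (theta - mu_fixed) / np.sqrt(np.maximum(radicand, RADICAND_FLOOR))
    if np.ptp(t) == 0 or np.ptp(v) == 0:
        raise ValueError("no rank variation in the Begg sequences")

    tau, _ = stats.kendalltau(t, v)
    S, var = _kendall_score_and_var(t, v)
    if method == "exact":
        if k > 8:
            raise ValueError("exact Begg permutation distribution limited to k <= 8")
        perms = np.array(list(itertools.permutations(range(k))))
        Y = v[perms]  # (k!, k)
        S_perm = np.zeros(len(perms))
        for i in range(k):
            for j in range(i + 1, k):
                S_perm += np.sign(t[j] - t[i]) * np.sign(Y[:, j] - Y[:, i])
        p = float(np.mean(np.abs(S_perm) >= abs(S) - 1e-9))
    else:
        shift = 1.0 if method == "normal-cc" else 0.0
        z = max(abs(S) - shift, 0.0) / math.sqrt(var)
        p = float(2 * stats.norm.sf(z))
    return BiasTestResult(test="begg", statistic=float(tau), p=min(p, 1.0),
                          k=k, method=method)


def egger_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's regression test: SND = a + b * precision, intercept tested.

    Two-sided p from a t distribution with k - 2 degrees of freedom.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("Egger's test needs at least 3 studies")
    theta = np.array([e.log_or for e in effects])
    se = np.array([e.se for e in effects])
    snd = theta / se
    prec = 1.0 / se
    if np.ptp(prec) == 0:
        raise ValueError("no precision variation among studies")
    X = np.column_stack([np.ones(k), prec])
    beta, *_ = np.linalg.lstsq(X, snd, rcond=None)
    resid = snd - X @ beta
    s2 = float(resid @ resid) / (k - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    se_int = math.sqrt(cov[0, 0])
    tstat = beta[0] / se_int
    p = float(2 * stats.t.sf(abs(tstat), k - 2))
    return BiasTestResult(test="egger", statistic=float(beta[0]), p=p, k=k,
                          se=se_int, slope=float(beta[1]))


def funnel_coordinates(
    effects: Sequence[EffectEstimate],
    pooled: PooledResult,
    n_grid: int = 50,
) -> tuple[list[FunnelPoint], dict]:
    """Funnel-plot data: one (log OR, se) point per study plus pseudo-95%
    confidence guide lines around the pooled log OR over an se grid."""
    points = [
        FunnelPoint(e.study_id, x=e.log_or, y=e.se, pooled_ref=pooled.log_or)
        for e in effects
    ]
    se_max = max((e.se for e in effects), default=1.0)
    grid = np.linspace(0.0, 1.05 * se_max, n_grid)
    guides = {
        "se_grid": grid.tolist(),
        "center": pooled.log_or,
        "low": (pooled.log_or - Z975 * grid).tolist(),
        "high": (pooled.log_or + Z975 * grid).tolist(),
    }
    return points, guides


def funnel_table(points: Sequence[FunnelPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"study_id": p.study_id, "log_or": p.x, "se": p.y} for p in points]
    )
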