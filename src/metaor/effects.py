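"""Per-study odds ratios and fixed/random-effects pooling.

The effect measure is the log odds ratio of methylation, cancer vs control.
Sparse tables are the norm here (five of the eight built-in control arms
contain zero methylated samples), so a continuity correction of 0.5 is
added to all four cells of any study with a zero cell before the Woolf log
OR and its variance are computed.

Two fixed-effect estimators are provided:

``"mh"`` (default)
    Mantel-Haenszel pooled odds ratio with the Robins-Breslow-Greenland
    variance, computed on the (corrected) cell counts.
``"iv"``
    Classic inverse-variance weighting of the per-study log ORs.

Heterogeneity is quantified by Cochran's Q (inverse-variance weights,
centered by default on the MH summary — the convention of the major
meta-analysis GUIs — or optionally on the IV summary), I^2, and the
DerSimonian-Laird moment estimator of the between-study variance tau^2.
The random-effects model re-weights by 1/(se_i^2 + tau^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import StudyCorpus, StudyRecord

__all__ = [
    "NonEstimableError",
    "EffectEstimate",
    "HetStats",
    "PooledResult",
    "continuity_correct",
    "log_odds_ratio",
    "effect_from_cells",
    "compute_effects",
    "pool_fixed",
    "heterogeneity_stats",
    "pool_random",
    "select_model",
    "pooling_table",
    "round_half_up",
]

logger = logging.getLogger(__name__)

#: 97.5% standard-normal quantile used for all Wald 95% CIs.
Z975 = stats.norm.ppf(0.975)

CC_POLICIES = ("affected-only", "all", "none")


class NonEstimableError(ValueError):
    """A study whose odds ratio is undefined even after correction."""

    def __init__(self, study_id: str, reason: str):
        self.study_id = study_id
        super().__init__(f"study {study_id!r} non-estimable: {reason}")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal-style half-up rounding, used when comparing to printed values."""
    scale = 10 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass
class EffectEstimate:
    """One study's log odds ratio with its Woolf standard error.

    ``cells`` holds the (possibly corrected) 2x2 cells (a, b, c, d) =
    (case_m, case_u, ctrl_m, ctrl_u); they are carried along because the
    Mantel-Haenszel pooled estimate needs them.  ``weight_fixed`` and
    ``weight_random`` are normalized inverse-variance weights, filled in
    by the pooling routines.
    """

    study_id: str
    log_or: float
    se: float
    corrected: bool
    cells: tuple[float, float, float, float] | None = None
    weight_fixed: float | None = None
    weight_random: float | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z975 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z975 * self.se)


@dataclass(frozen=True)
class HetStats:
    """Cochran's Q heterogeneity statistics with DL tau^2.

    ``i2`` is on the percent scale.  For a single study Q = 0, df = 0 and
    ``p_het`` is defined as 1.
    """

    Q: float
    df: int
    p_het: float
    i2: float
    tau2: float


@dataclass(frozen=True)
class PooledResult:
    """A pooled log odds ratio with Wald 95% CI on the OR scale."""

    model: str                 # "fixed" or "random"
    k: int
    log_or: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    het: HetStats
    method: str = "iv"         # fixed-effect estimator behind this result
    study_ids: tuple[str, ...] = ()

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)


def continuity_correct(
    counts: Sequence[int],
    increment: float = 0.5,
    policy: str = "affected-only",
    study_id: str = "?",
) -> tuple[tuple[float, float, float, float], bool]:
    """Apply the zero-cell continuity correction to a 2x2 table.

    Under ``"affected-only"`` (default) the increment is added to all four
    cells of a study containing at least one zero cell; under ``"all"`` to
    every study; under ``"none"`` never.  Returns (cells, corrected_flag).

    A study with an empty arm (zero methylated AND zero unmethylated) is
    never estimable; with ``policy="none"`` a zero cell is also
    non-estimable because the log OR diverges.
    """
    if policy not in CC_POLICIES:
        raise ValueError(f"policy must be one of {CC_POLICIES}, got {policy!r}")
    a, b, c, d = (float(x) for x in counts)
    if a + b == 0 or c + d == 0:
        raise NonEstimableError(study_id, "empty arm")
    has_zero = min(a, b, c, d) == 0
    if policy == "all" or (policy == "affected-only" and has_zero):
        return (a + increment, b + increment, c + increment, d + increment), True
    if has_zero:  # policy == "none"
        raise NonEstimableError(study_id, "zero cell and no continuity correction")
    return (a, b, c, d), False


def effect_from_cells(
    study_id: str,
    counts: Sequence[int],
    increment: float = 0.5,
    policy: str = "affected-only",
) -> EffectEstimate:
    """Woolf log odds ratio ln(ad/bc), se = sqrt(1/a+1/b+1/c+1/d)."""
    cells, corrected = continuity_correct(counts, increment, policy, study_id)
    a, b, c, d = cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    if corrected:
        logger.debug("study %s: continuity correction %.3g applied", study_id, increment)
    return EffectEstimate(study_id, log_or, se, corrected, cells=cells)


def log_odds_ratio(
    record: StudyRecord,
    increment: float = 0.5,
    policy: str = "affected-only",
) -> EffectEstimate:
    """Effect estimate for one study record (cancer vs control methylation)."""
    return effect_from_cells(record.study_id, record.counts, increment, policy)


def compute_effects(
    corpus: StudyCorpus | Iterable[StudyRecord],
    increment: float = 0.5,
    policy: str = "affected-only",
) -> list[EffectEstimate]:
    """Effects for every estimable study; non-estimable ones are dropped
    with a logged warning."""
    out = []
    for rec in corpus:
        try:
            out.append(log_odds_ratio(rec, increment, policy))
        except NonEstimableError as err:
            logger.warning("excluded from pooling: %s", err)
    corrected = [e.study_id for e in out if e.corrected]
    if corrected:
        logger.warning("continuity correction %.3g applied to: %s",
                       increment, ", ".join(corrected))
    return out


def _arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if not effects:
        raise ValueError("no effects to pool")
    theta = np.array([e.log_or for e in effects])
    se = np.array([e.se for e in effects])
    return theta, se


def _mh_log_or(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Mantel-Haenszel pooled log OR and its RBG standard error."""
    missing = [e.study_id for e in effects if e.cells is None]
    if missing:
        raise ValueError(
            f"Mantel-Haenszel pooling needs 2x2 cells; missing for {missing}"
        )
    R = S = sPR = sPSQR = sQS = 0.0
    for e in effects:
        a, b, c, d = e.cells
        n = a + b + c + d
        P, Qf = (a + d) / n, (b + c) / n
        Rr, Ss = a * d / n, b * c / n
        R += Rr
        S += Ss
        sPR += P * Rr
        sPSQR += P * Ss + Qf * Rr
        sQS += Qf * Ss
    if R == 0 or S == 0:
        raise ValueError("Mantel-Haenszel estimate undefined (all-zero margin)")
    log_or = math.log(R / S)
    var = sPR / (2 * R * R) + sPSQR / (2 * R * S) + sQS / (2 * S * S)
    return log_or, math.sqrt(var)


def _wald(model: str, k: int, mu: float, se: float, het: HetStats,
          method: str, study_ids: tuple[str, ...]) -> PooledResult:
    z = mu / se
    p = 2 * stats.norm.sf(abs(z))
    return PooledResult(
        model=model, k=k, log_or=mu, se=se,
        ci_low=math.exp(mu - Z975 * se), ci_high=math.exp(mu + Z975 * se),
        z=z, p=p, het=het, method=method, study_ids=study_ids,
    )


def pool_fixed(
    effects: Sequence[EffectEstimate],
    method: str = "mh",
) -> PooledResult:
    """Fixed-effects pooled odds ratio.

    ``method="mh"`` (default) is the Mantel-Haenszel estimator on the cell
    counts; ``method="iv"`` is inverse-variance weighting of the log ORs.
    Normalized fixed-effect (inverse-variance) weights are recorded on the
    effects under both methods.
    """
    theta, se = _arrays(effects)
    w = 1.0 / se**2
    for e, wi in zip(effects, w / w.sum()):
        e.weight_fixed = float(wi)
    het = heterogeneity_stats(effects, center=method)
    if method == "iv":
        mu = float((w * theta).sum() / w.sum())
        pooled_se = float(1.0 / math.sqrt(w.sum()))
    elif method == "mh":
        mu, pooled_se = _mh_log_or(effects)
    else:
        raise ValueError(f"unknown fixed-effect method {method!r}")
    ids = tuple(e.study_id for e in effects)
    return _wald("fixed", len(effects), mu, pooled_se, het, method, ids)


def heterogeneity_stats(
    effects: Sequence[EffectEstimate],
    center: str = "mh",
) -> HetStats:
    """Cochran's Q, I^2 (percent) and the DL moment estimate of tau^2.

    Q = sum w_i (theta_i - theta_hat)^2 with inverse-variance weights
    w_i = 1/se_i^2; ``center`` selects the fixed-effect summary theta_hat
    (``"mh"`` default, or ``"iv"``).  If cells are unavailable for the MH
    center it falls back to IV.  tau^2 = max(0, (Q - df)/(S1 - S2/S1))
    with S1 = sum w_i, S2 = sum w_i^2.
    """
    theta, se = _arrays(effects)
    k = len(effects)
    w = 1.0 / se**2
    if center == "mh" and all(e.cells is not None for e in effects):
        try:
            mu, _ = _mh_log_or(effects)
        except ValueError:
            mu = float((w * theta).sum() / w.sum())
    elif center in ("mh", "iv"):
        mu = float((w * theta).sum() / w.sum())
    else:
        raise ValueError(f"unknown Q center {center!r}")
    Q = float((w * (theta - mu) ** 2).sum())
    df = k - 1
    if df == 0:
        return HetStats(Q=0.0, df=0, p_het=1.0, i2=0.0, tau2=0.0)
    p_het = float(stats.chi2.sf(Q, df))
    i2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return HetStats(Q=Q, df=df, p_het=p_het, i2=i2, tau2=tau2)


def pool_random(
    effects: Sequence[EffectEstimate],
    center: str = "mh",
) -> PooledResult:
    """DerSimonian-Laird random-effects pooled odds ratio.

    tau^2 comes from :func:`heterogeneity_stats` (Q centered per
    ``center``); studies are weighted 1/(se_i^2 + tau^2).
    """
    theta, se = _arrays(effects)
    het = heterogeneity_stats(effects, center=center)
    w = 1.0 / (se**2 + het.tau2)
    for e, wi in zip(effects, w / w.sum()):
        e.weight_random = float(wi)
    mu = float((w * theta).sum() / w.sum())
    pooled_se = float(1.0 / math.sqrt(w.sum()))
    ids = tuple(e.study_id for e in effects)
    return _wald("random", len(effects), mu, pooled_se, het, "dl", ids)


def select_model(het: HetStats, alpha: float = 0.05) -> str:
    """Q-test model choice: random iff the heterogeneity P <= alpha.

    The boundary P = alpha counts as significant (the fixed model is used
    only when P > alpha).
    """
    return "random" if het.p_het <= alpha else "fixed"


def pooling_table(
    effects: Sequence[EffectEstimate],
    pooled: PooledResult,
) -> pd.DataFrame:
    """Forest-plot-equivalent table: one row per study plus a summary row."""
    wattr = "weight_random" if pooled.model == "random" else "weight_fixed"
    rows = []
    for e in effects:
        w = getattr(e, wattr)
        rows.append({
            "study_id": e.study_id, "or": e.odds_ratio,
            "ci_low": e.ci_low, "ci_high": e.ci_high,
            "weight_pct": 100 * w if w is not None else float("nan"),
            "corrected": e.corrected,
        })
    rows.append({
        "study_id": f"pooled ({pooled.model}, {pooled.method})",
        "or": pooled.odds_ratio, "ci_low": pooled.ci_low,
        "ci_high": pooled.ci_high, "weight_pct": 100.0, "corrected": None,
    })
    return pd.DataFrame(rows)
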