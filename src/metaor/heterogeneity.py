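"""Subgroup analysis, leave-one-out sensitivity, and meta-regression.

Subgroup analysis pools each level of a study-level covariate separately
(both fixed- and random-effects results are reported per level, as the
source tables do).  Leave-one-out sensitivity re-pools the corpus k times
under the random-effects model with tau^2 re-estimated on each (k-1)-subset.
Univariable meta-regression fits log OR on a scalar-coded covariate by
weighted least squares with a method-of-moments residual tau^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import CorpusError, StudyCorpus, subset
from .effects import (
    Z975,
    EffectEstimate,
    HetStats,
    PooledResult,
    compute_effects,
    heterogeneity_stats,
    pool_fixed,
    pool_random,
)

__all__ = [
    "SubgroupRow",
    "LooRow",
    "MetaRegResult",
    "subgroup_analysis",
    "leave_one_out",
    "meta_regress",
    "subgroup_table",
    "loo_table",
    "LEVEL_ORDER",
    "METAREG_COVARIATES",
]

#: canonical level ordering for subgroup tables (observed-but-unlisted
#: levels follow in order of first appearance).
LEVEL_ORDER: dict[str, tuple[str, ...]] = {
    "country": ("China", "Poland"),
    "sample_type": ("serum", "tissues"),
    "control_type": ("NT", "NT&BOT", "AT&NT"),
    "method": ("MSP", "CCP-based FRET", "restriction-enzyme"),
    "size_class": ("<100", ">=100"),
}

METAREG_COVARIATES = (
    "year", "country", "sample_type", "control_type", "method", "sample_size",
)


@dataclass(frozen=True)
class SubgroupRow:
    """One level of a subgroup analysis with both pooling models."""

    variable: str
    level: str
    k: int
    case_m: int
    case_u: int
    ctrl_m: int
    ctrl_u: int
    fixed: PooledResult
    random: PooledResult
    het: HetStats


@dataclass(frozen=True)
class LooRow:
    """Random-effects pooling of the corpus with one study omitted."""

    omitted_study_id: str
    result: PooledResult


@dataclass(frozen=True)
class MetaRegResult:
    """Univariable mixed-effects meta-regression slope on the log OR scale."""

    covariate: str
    coding: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    residual_tau2: float
    intercept: float
    k: int


def subgroup_analysis(
    corpus: StudyCorpus,
    variable: str,
    increment: float = 0.5,
    policy: str = "affected-only",
    fixed_method: str = "mh",
    center: str = "mh",
) -> list[SubgroupRow]:
    """Pool every observed level of ``variable`` separately.

    Levels appear in the canonical table order where one is defined;
    each row carries pooled counts, fixed and random results, and the
    level's heterogeneity statistics.
    """
    observed: list[str] = []
    for rec in corpus:
        lev = rec.covariate(variable)
        if lev not in observed:
            observed.append(lev)
    canon = [l for l in LEVEL_ORDER.get(variable, ()) if l in observed]
    levels = canon + [l for l in observed if l not in canon]
    rows = []
    for level in levels:
        sub = subset(corpus, variable, level)
        effects = compute_effects(sub, increment, policy)
        fixed = pool_fixed(effects, method=fixed_method)
        random = pool_random(effects, center=center)
        rows.append(SubgroupRow(
            variable=variable, level=level, k=len(sub),
            case_m=sum(r.case_m for r in sub), case_u=sum(r.case_u for r in sub),
            ctrl_m=sum(r.ctrl_m for r in sub), ctrl_u=sum(r.ctrl_u for r in sub),
            fixed=fixed, random=random, het=random.het,
        ))
    return rows


def leave_one_out(
    corpus: StudyCorpus,
    increment: float = 0.5,
    policy: str = "affected-only",
    center: str = "mh",
) -> list[LooRow]:
    """Random-effects pooling with each study omitted in turn.

    tau^2 is re-estimated on every (k-1)-subset.  Rows follow corpus order.
    """
    if len(corpus) < 2:
        raise ValueError("leave-one-out needs at least 2 studies")
    rows = []
    for sid in corpus.study_ids:
        effects = compute_effects(corpus.drop(sid), increment, policy)
        rows.append(LooRow(sid, pool_random(effects, center=center)))
    return rows


def _code_covariate(corpus: StudyCorpus, covariate: str) -> tuple[np.ndarray, str]:
    """Scalar coding for meta-regression.

    year and sample_size enter numerically as-is; a binary categorical as a
    0/1 indicator (reference = the first study's level); a categorical with
    more than two observed levels as the single indicator "is the majority
    level".  The coding description is echoed in the result.
    """
    if covariate not in METAREG_COVARIATES:
        raise CorpusError(
            f"unknown meta-regression covariate {covariate!r}; allowed: "
            f"{', '.join(METAREG_COVARIATES)}"
        )
    if covariate in ("year", "sample_size"):
        x = np.array([float(getattr(r, covariate)) for r in corpus])
        return x, f"{covariate} (numeric, as-is)"
    values = [getattr(r, covariate) for r in corpus]
    levels = sorted(set(values))
    if len(levels) < 2:
        raise CorpusError(f"covariate {covariate!r} is constant across studies")
    if len(levels) == 2:
        ref = values[0]
        other = next(l for l in levels if l != ref)
        x = np.array([0.0 if v == ref else 1.0 for v in values])
        return x, f"{covariate}: {other}=1 vs {ref}=0 (reference = first study)"
    counts = {l: values.count(l) for l in levels}
    majority = max(levels, key=lambda l: (counts[l], l))
    x = np.array([1.0 if v == majority else 0.0 for v in values])
    return x, f"{covariate}: is-majority-level ({majority})=1 vs rest=0"


def meta_regress(
    corpus: StudyCorpus,
    covariate: str | None,
    increment: float = 0.5,
    policy: str = "affected-only",
) -> MetaRegResult:
    """Univariable mixed-effects meta-regression of log OR on a covariate.

    Method of moments: a fixed-effect WLS fit (weights 1/se_i^2) yields the
    residual Q_E; the residual between-study variance is
    tau^2 = max(0, (Q_E - (k - p)) / tr(P)) with P the weighted residual
    projector; the final slope comes from WLS with weights
    1/(se_i^2 + tau^2), with a normal-approximation CI and two-sided p.
    ``covariate=None`` fits the intercept-only model, which reproduces the
    DerSimonian-Laird pooled log OR (IV-centered Q).
    """
    k = len(corpus)
    if k < 3 and covariate is not None:
        raise ValueError("meta-regression needs at least 3 studies")
    effects = compute_effects(corpus, increment, policy)
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.se**2 for e in effects])
    if covariate is None:
        X = np.ones((len(theta), 1))
        coding = "intercept-only"
    else:
        x, coding = _code_covariate(corpus, covariate)
        if np.ptp(x) == 0:
            raise CorpusError(f"covariate {covariate!r} is constant across studies")
        X = np.column_stack([np.ones_like(x), x])
    n, p = X.shape

    W = np.diag(1.0 / v)
    XtWX = X.T @ W @ X
    beta_fe = np.linalg.solve(XtWX, X.T @ W @ theta)
    resid = theta - X @ beta_fe
    QE = float(resid @ W @ resid)
    P = W - W @ X @ np.linalg.solve(XtWX, X.T @ W)
    trP = float(np.trace(P))
    tau2 = max(0.0, (QE - (n - p)) / trP) if trP > 0 else 0.0

    Wr = np.diag(1.0 / (v + tau2))
    XtWrX = X.T @ Wr @ X
    beta = np.linalg.solve(XtWrX, X.T @ Wr @ theta)
    cov = np.linalg.inv(XtWrX)
    j = p - 1  # slope index (0 for intercept-only)
    se = float(np.sqrt(cov[j, j]))
    coef = float(beta[j])
    z = coef / se
    return MetaRegResult(
        covariate=covariate or "(intercept)",
        coding=coding,
        coefficient=coef,
        se=se,
        ci_low=coef - Z975 * se,
        ci_high=coef + Z975 * se,
        p=float(2 * stats.norm.sf(abs(z))),
        residual_tau2=tau2,
        intercept=float(beta[0]),
        k=n,
    )


def subgroup_table(rows: Sequence[SubgroupRow]) -> pd.DataFrame:
    """Tabular mirror of the subgroup-analysis layout."""
    out = []
    for r in rows:
        out.append({
            "variable": r.variable, "level": r.level, "k": r.k,
            "case_m": r.case_m, "case_u": r.case_u,
            "ctrl_m": r.ctrl_m, "ctrl_u": r.ctrl_u,
            "fixed_or": r.fixed.odds_ratio,
            "fixed_ci_low": r.fixed.ci_low, "fixed_ci_high": r.fixed.ci_high,
            "random_or": r.random.odds_ratio,
            "random_ci_low": r.random.ci_low, "random_ci_high": r.random.ci_high,
            "i2_pct": r.het.i2, "p_het": r.het.p_het,
        })
    return pd.DataFrame(out)


def loo_table(rows: Sequence[LooRow]) -> pd.DataFrame:
    out = []
    for r in rows:
        out.append({
            "omitted_study_id": r.omitted_study_id,
            "or": r.result.odds_ratio,
            "ci_low": r.result.ci_low, "ci_high": r.result.ci_high,
            "tau2": r.result.het.tau2,
        })
    return pd.DataFrame(out)
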