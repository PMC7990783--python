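"""Within-case pooling of clinicopathological contrasts.

Each study may report, among its cancer cases only, methylated/total counts
for two levels of a clinical variable (FIGO stage III/IV vs I/II, serous vs
other histology, poorly vs well/moderately differentiated grade, older vs
younger age group).  Level A is the risk level, so the pooled OR is the
odds of methylation in the risk level versus the reference level.

The pooling model per variable follows the Q-test rule (fixed when the
heterogeneity P > alpha, random otherwise) unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .corpus import CorpusError, StratumPair, StudyCorpus, STRATUM_VARIABLES
from .effects import (
    EffectEstimate,
    PooledResult,
    effect_from_cells,
    heterogeneity_stats,
    pool_fixed,
    pool_random,
    select_model,
)

__all__ = ["FourfoldTable", "strata_to_table", "clinicopath_effects",
           "pool_clinicopath", "clinicopath_table"]


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 within-case table derived from a stratum pair.

    a/b: methylated/unmethylated in level A (risk level);
    c/d: methylated/unmethylated in level B.
    """

    study_id: str
    variable: str
    a: int
    b: int
    c: int
    d: int


def strata_to_table(pair: StratumPair, study_id: str = "?") -> FourfoldTable:
    """Expand methylated/total stratum counts into a fourfold table."""
    return FourfoldTable(
        study_id=study_id,
        variable=pair.variable,
        a=pair.a_m, b=pair.a_n - pair.a_m,
        c=pair.b_m, d=pair.b_n - pair.b_m,
    )


def clinicopath_effects(
    corpus: StudyCorpus,
    variable: str,
    increment: float = 0.5,
    policy: str = "affected-only",
    include_serum_duplicate: bool = True,
) -> list[EffectEstimate]:
    """Per-study within-case effects for one clinical variable.

    ``include_serum_duplicate=False`` drops the serum member of any article
    contributing both a tissue and a serum study (their strata describe
    overlapping patients).
    """
    if variable not in STRATUM_VARIABLES:
        raise CorpusError(
            f"unknown clinicopathological variable {variable!r}; allowed: "
            f"{', '.join(STRATUM_VARIABLES)}"
        )
    effects = []
    article_sample_types: dict[str, set[str]] = {}
    for rec in corpus:
        if rec.article_id:
            article_sample_types.setdefault(rec.article_id, set()).add(rec.sample_type)
    for rec in corpus:
        if (not include_serum_duplicate and rec.article_id
                and rec.sample_type == "serum"
                and article_sample_types.get(rec.article_id, set()) >= {"serum", "tissues"}):
            continue
        for pair in rec.strata:
            if pair.variable != variable:
                continue
            tab = strata_to_table(pair, rec.study_id)
            effects.append(effect_from_cells(
                rec.study_id, (tab.a, tab.b, tab.c, tab.d), increment, policy,
            ))
    return effects


def pool_clinicopath(
    corpus: StudyCorpus,
    variable: str,
    alpha: float = 0.05,
    model: str | None = None,
    increment: float = 0.5,
    policy: str = "affected-only",
    fixed_method: str = "mh",
    center: str = "mh",
    include_serum_duplicate: bool = True,
) -> PooledResult:
    """Pooled within-case OR for one clinical variable.

    The model is chosen by the Q-test rule at ``alpha`` unless ``model``
    ("fixed" or "random") forces one.
    """
    effects = clinicopath_effects(
        corpus, variable, increment, policy, include_serum_duplicate,
    )
    if not effects:
        raise CorpusError(f"no strata reported for variable {variable!r}")
    if model is None:
        het = heterogeneity_stats(effects, center=center)
        model = select_model(het, alpha)
    if model == "fixed":
        return pool_fixed(effects, method=fixed_method)
    if model == "random":
        return pool_random(effects, center=center)
    raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")


def clinicopath_table(
    corpus: StudyCorpus,
    variable: str,
    pooled: PooledResult,
    **effect_opts,
) -> pd.DataFrame:
    """Forest-style table for one clinical variable (per-study rows plus
    the pooled summary)."""
    effects = clinicopath_effects(corpus, variable, **effect_opts)
    rows = [
        {"study_id": e.study_id, "or": e.odds_ratio,
         "ci_low": e.ci_low, "ci_high": e.ci_high, "corrected": e.corrected}
        for e in effects
    ]
    rows.append({
        "study_id": f"pooled ({pooled.model})", "or": pooled.odds_ratio,
        "ci_low": pooled.ci_low, "ci_high": pooled.ci_high, "corrected": None,
    })
    return pd.DataFrame(rows)
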