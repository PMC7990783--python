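"""Full-pipeline report assembly.

``run_full_analysis`` chains every stage — overall pooling under both
models with Q-test model selection, subgroup analyses over all study-level
covariates, leave-one-out sensitivity, univariable meta-regressions,
Begg/Egger publication-bias tests with funnel coordinates, and the
clinicopathological within-case poolings — into one deterministic report
that serializes to JSON and a set of TSV tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__ as _version
from .bias import BiasTestResult, begg_test, egger_test, funnel_coordinates, funnel_table
from .clinicopath import clinicopath_table, pool_clinicopath
from .corpus import CorpusError, STRATUM_VARIABLES, SUBSET_VARIABLES, StudyCorpus
from .effects import (
    PooledResult,
    compute_effects,
    pool_fixed,
    pool_random,
    pooling_table,
    select_model,
)
from .heterogeneity import (
    METAREG_COVARIATES,
    leave_one_out,
    loo_table,
    meta_regress,
    subgroup_analysis,
    subgroup_table,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Conventions applied across the whole pipeline.

    The defaults reproduce the printed results of the source analysis:
    0.5 continuity correction on zero-cell studies, Mantel-Haenszel fixed
    effect, MH-centered Q for DL tau^2, heterogeneity alpha 0.05 with the
    boundary counted as significant, and the plain normal approximation
    for Begg's p.
    """

    cc_increment: float = 0.5
    cc_policy: str = "affected-only"
    fixed_method: str = "mh"
    q_center: str = "mh"
    alpha_het: float = 0.05
    begg_method: str = "normal"
    include_serum_duplicate: bool = True


@dataclass
class AnalysisReport:
    overall_fixed: PooledResult
    overall_random: PooledResult
    selected_model: str
    subgroups: dict
    loo: list
    metareg: dict
    bias: dict
    clinicopath: dict
    config: AnalysisConfig
    corpus_digest: str
    version: str = _version

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _plain(obj):
    """Make asdict output JSON-safe (tuples -> lists, numpy scalars -> float)."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_full_analysis(
    corpus: StudyCorpus,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """Run the complete meta-analytic pipeline on a validated corpus.

    Stages that are undefined for the given corpus size (leave-one-out
    with one study, bias tests with fewer than three) are reported as
    ``{"status": "not applicable", ...}`` rather than raising.
    """
    eff_opts = dict(increment=config.cc_increment, policy=config.cc_policy)
    effects = compute_effects(corpus, **eff_opts)
    if not effects:
        raise CorpusError("no estimable studies in corpus")

    try:
        overall_fixed = pool_fixed(effects, method=config.fixed_method)
    except ValueError as err:
        raise CorpusError(f"overall pooling (fixed): {err}") from err
    overall_random = pool_random(effects, center=config.q_center)
    selected = select_model(overall_random.het, config.alpha_het)

    subgroups = {}
    for variable in SUBSET_VARIABLES:
        try:
            subgroups[variable] = subgroup_analysis(
                corpus, variable,
                fixed_method=config.fixed_method, center=config.q_center,
                **eff_opts,
            )
        except (CorpusError, ValueError) as err:
            subgroups[variable] = {"status": "not applicable", "reason": str(err)}

    if len(corpus) >= 2:
        loo = leave_one_out(corpus, center=config.q_center, **eff_opts)
    else:
        loo = {"status": "not applicable", "reason": "fewer than 2 studies"}

    metareg = {}
    for cov in METAREG_COVARIATES:
        try:
            metareg[cov] = meta_regress(corpus, cov, **eff_opts)
        except (CorpusError, ValueError) as err:
            metareg[cov] = {"status": "not applicable", "reason": str(err)}

    bias: dict = {}
    if len(effects) >= 3:
        try:
            bias["begg"] = begg_test(effects, method=config.begg_method)
        except ValueError as err:
            bias["begg"] = {"status": "not applicable", "reason": str(err)}
        try:
            bias["egger"] = egger_test(effects)
        except ValueError as err:
            bias["egger"] = {"status": "not applicable", "reason": str(err)}
        points, guides = funnel_coordinates(
            effects, overall_random if selected == "random" else overall_fixed,
        )
        bias["funnel"] = {"points": points, "guides": guides}
    else:
        bias = {"status": "not applicable", "reason": "fewer than 3 studies"}

    clinicopath = {}
    for variable in STRATUM_VARIABLES:
        try:
            clinicopath[variable] = pool_clinicopath(
                corpus, variable, alpha=config.alpha_het,
                fixed_method=config.fixed_method, center=config.q_center,
                include_serum_duplicate=config.include_serum_duplicate,
                **eff_opts,
            )
        except (CorpusError, ValueError) as err:
            clinicopath[variable] = {"status": "not applicable", "reason": str(err)}

    return AnalysisReport(
        overall_fixed=overall_fixed,
        overall_random=overall_random,
        selected_model=selected,
        subgroups=subgroups,
        loo=loo,
        metareg=metareg,
        bias=bias,
        clinicopath=clinicopath,
        config=config,
        corpus_digest=corpus.digest(),
    )


def write_outputs(report: AnalysisReport, corpus: StudyCorpus, outdir) -> list[str]:
    """Write report.json plus TSV tables; returns the filenames written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    (outdir / "report.json").write_text(report.to_json())
    written.append("report.json")

    eff_opts = dict(increment=report.config.cc_increment,
                    policy=report.config.cc_policy)
    effects = compute_effects(corpus, **eff_opts)
    pooled = (report.overall_random if report.selected_model == "random"
              else report.overall_fixed)
    pool_random_refresh = pool_random(effects, center=report.config.q_center)
    pooling_table(effects, pooled).to_csv(outdir / "forest.tsv", sep="\t", index=False)
    written.append("forest.tsv")

    rows = []
    for variable, result in report.subgroups.items():
        if isinstance(result, dict):
            continue
        rows.append(subgroup_table(result))
    if rows:
        import pandas as pd
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "subgroups.tsv", sep="\t", index=False)
        written.append("subgroups.tsv")

    if not isinstance(report.loo, dict):
        loo_table(report.loo).to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
        written.append("leave_one_out.tsv")

    if isinstance(report.bias, dict) and "funnel" in report.bias:
        funnel_table(report.bias["funnel"]["points"]).to_csv(
            outdir / "funnel.tsv", sep="\t", index=False)
        written.append("funnel.tsv")

    for variable, result in report.clinicopath.items():
        if isinstance(result, dict):
            continue
        clinicopath_table(
            corpus, variable, result,
            increment=report.config.cc_increment, policy=report.config.cc_policy,
            include_serum_duplicate=report.config.include_serum_duplicate,
        ).to_csv(outdir / f"clinicopath_{variable}.tsv", sep="\t", index=False)
        written.append(f"clinicopath_{variable}.tsv")
    return written
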