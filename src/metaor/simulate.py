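"""Synthetic study corpora with known truth.

The generator emulates the count-level structure the meta-analysis
consumes: per-study 2x2 binomial tables under a common control methylation
probability, a true log odds ratio with Normal between-study heterogeneity
on the log-odds scale, and an optional small-study (publication-bias)
shift proportional to each study's anticipated standard error.  Default
parameters mirror the built-in eight-study corpus: k = 8 studies, a true
OR around 33.5, between-study SD tau ~ 1.0, a control methylation
probability of about 0.11, and arm sizes in the ranges the source studies
span — producing the characteristic zero-methylated control arms.

No methylation biology (CpG sites, beta values) is simulated; only the
statistical structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import (
    CONTROL_TYPES,
    COUNTRIES,
    METHODS,
    SAMPLE_TYPES,
    StudyCorpus,
    StudyRecord,
)
from .bias import begg_test, egger_test
from .effects import compute_effects, heterogeneity_stats

__all__ = ["SimParams", "simulate_corpus", "null_calibration"]


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class SimParams:
    """Generative settings for a synthetic corpus.

    ``n_case``/``n_ctrl`` may be a fixed int or an inclusive (low, high)
    range sampled uniformly per study.  ``bias_strength`` shifts each
    study's log OR by bias_strength * anticipated_se, the standard
    small-study-effect construction.
    """

    k: int = 8
    true_log_or: float = math.log(33.5)
    tau: float = 1.0
    p0: float = 0.11
    n_case: int | tuple[int, int] = (35, 102)
    n_ctrl: int | tuple[int, int] = (4, 123)
    bias_strength: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.p0 < 1.0):
            raise ValueError("p0 must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        for name, n in (("n_case", self.n_case), ("n_ctrl", self.n_ctrl)):
            lo = n[0] if isinstance(n, tuple) else n
            if lo < 1:
                raise ValueError(f"{name} must be >= 1")
        # the linear predictor keeps probabilities strictly inside (0,1)
        # for any finite theta, so only p0 itself needs checking.


def _draw_n(rng: np.random.Generator, n: int | tuple[int, int]) -> int:
    if isinstance(n, tuple):
        return int(rng.integers(n[0], n[1] + 1))
    return int(n)


def simulate_corpus(params: SimParams) -> StudyCorpus:
    """Draw one synthetic corpus, fully reproducible from ``params.seed``.

    For study i: theta_i ~ Normal(true_log_or, tau^2); the case methylation
    probability is expit(logit(p0) + theta_i + bias_strength * se_i) with
    se_i the Woolf standard error anticipated from the expected counts;
    counts are binomial.  Covariates are assigned round-robin so subgroup
    and meta-regression machinery is exercisable on synthetic data.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    records = []
    eta0 = _logit(params.p0)
    for i in range(params.k):
        n_case = _draw_n(rng, params.n_case)
        n_ctrl = _draw_n(rng, params.n_ctrl)
        theta = params.true_log_or + params.tau * rng.standard_normal()
        if params.bias_strength > 0:
            p1_exp = _expit(eta0 + theta)
            exp_cells = (
                max(n_case * p1_exp, 0.5), max(n_case * (1 - p1_exp), 0.5),
                max(n_ctrl * params.p0, 0.5), max(n_ctrl * (1 - params.p0), 0.5),
            )
            se_exp = math.sqrt(sum(1.0 / c for c in exp_cells))
            theta += params.bias_strength * se_exp
        p1 = _expit(eta0 + theta)
        case_m = int(rng.binomial(n_case, p1))
        ctrl_m = int(rng.binomial(n_ctrl, params.p0))
        records.append(StudyRecord(
            study_id=f"sim{i:03d}",
            year=2006 + (i % 15),
            country=COUNTRIES[i % len(COUNTRIES)],
            sample_type=SAMPLE_TYPES[i % len(SAMPLE_TYPES)],
            control_type=CONTROL_TYPES[i % len(CONTROL_TYPES)],
            method=METHODS[i % len(METHODS)],
            case_m=case_m, case_u=n_case - case_m,
            ctrl_m=ctrl_m, ctrl_u=n_ctrl - ctrl_m,
        ))
    return StudyCorpus(tuple(records),
                       provenance=f"simulated (seed={params.seed})")


def null_calibration(
    params: SimParams,
    replicates: int = 2000,
    alpha: float = 0.05,
) -> dict:
    """Monte-Carlo rejection rates of the Q-test, Egger, and Begg tests.

    Each replicate draws a fresh corpus from ``params`` (child seeds are
    derived deterministically from ``params.seed``) and applies the three
    tests at level ``alpha``.  Returns rates with binomial standard errors.
    With ``params.true_log_or = 0`` and ``tau = 0`` this estimates the
    empirical type-I error.
    """
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    child_seeds = np.random.SeedSequence(params.seed).generate_state(replicates)
    rej = {"q_test": 0, "egger": 0, "begg": 0}
    valid = {"q_test": 0, "egger": 0, "begg": 0}
    for s in child_seeds:
        corpus = simulate_corpus(replace(params, seed=int(s % (2**31))))
        effects = compute_effects(corpus)
        if len(effects) >= 2:
            het = heterogeneity_stats(effects)
            valid["q_test"] += 1
            rej["q_test"] += het.p_het <= alpha
        if len(effects) >= 3:
            try:
                valid["egger"] += 1
                rej["egger"] += egger_test(effects).p <= alpha
            except ValueError:
                valid["egger"] -= 1
            try:
                valid["begg"] += 1
                rej["begg"] += begg_test(effects).p <= alpha
            except ValueError:
                valid["begg"] -= 1
    out = {"replicates": replicates, "alpha": alpha}
    for name in ("q_test", "egger", "begg"):
        n = valid[name]
        rate = rej[name] / n if n else float("nan")
        se = math.sqrt(rate * (1 - rate) / n) if n else float("nan")
        out[name] = {"rate": rate, "se": se, "n": n}
    return out
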