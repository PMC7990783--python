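# Methods

## Effect measure and continuity correction

The unit of analysis is a study-level 2×2 table of methylated/unmethylated
counts in cancer vs control samples. The effect is the log odds ratio with
Woolf standard error. Because sparse control arms are the norm in this
literature (five of the eight built-in control arms have zero methylated
samples), a continuity correction is applied before estimation: under the
default `affected-only` policy, 0.5 is added to **all four cells** of any
study containing at least one zero cell; `all` corrects every study and
`none` disables correction (a zero-cell study is then non-estimable and is
excluded from pooling with a logged warning). A study with an empty arm is
never estimable. The increment is configurable; 0.5 is the convention of
the major meta-analysis packages.

## Fixed-effect estimator

Two estimators are provided and the default matters. The
**Mantel–Haenszel** pooled OR (computed on the corrected cells, variance
by Robins–Breslow–Greenland) is the default because it is what the
standard GUI tools (RevMan and kin) report as "fixed"; inverse-variance
weighting of the log ORs is available as `method="iv"`. On the built-in
corpus the two differ visibly (serum subgroup: MH 102.86 vs IV 98.42) and
only MH reproduces the reference results this corpus is known by.

## Heterogeneity and the random-effects model

Cochran's Q uses inverse-variance weights around a configurable center:
by default the MH summary (again the GUI convention; `center="iv"` gives
the textbook Q that minimizes the weighted sum of squares, so Q_MH ≥ Q_IV
always). I² = max(0, 100·(Q − df)/Q) and the DerSimonian–Laird moment
estimator τ² = max(0, (Q − df)/(S₁ − S₂/S₁)) derive from that same Q.
The random-effects model re-weights by 1/(vᵢ + τ²). No Knapp–Hartung
small-sample adjustment is applied. All 95% CIs are Wald intervals on
the log scale using Φ⁻¹(0.975) = 1.959964…, not 1.96.

Model selection follows the Q-test rule: the random model is used when
the heterogeneity P ≤ α (default α = 0.05, with the boundary counted as
significant — fixed is reserved for P strictly above α).

On the built-in corpus, MH-centering vs IV-centering shifts the DL pooled
OR from 33.47 to 33.35; the package reports both conventions but defaults
to MH-centering throughout (overall, subgroups, leave-one-out,
clinicopathological pooling).

## Subgroups, sensitivity, meta-regression

Subgroup analysis partitions the corpus by one covariate (country, sample
type, control type, method, or the derived size class "<100"/"≥100" total
subjects) and reports **both** fixed and random pooling per level, since
single-level subgroups make the distinction vacuous and the reference
tables print both. Leave-one-out sensitivity always uses the
random-effects model with τ² re-estimated on each (k−1)-subset.

Univariable meta-regression fits log OR on a scalar-coded covariate:
publication year and total sample size enter numerically; a binary
categorical becomes a 0/1 indicator with the first study's level as
reference; a categorical with more than two levels becomes the single
indicator "is the majority level". The coding is echoed in the result
object because coefficient values are meaningless without it — and
because reference analyses rarely state their coding, numeric
meta-regression coefficients should be compared qualitatively only.
Estimation is method-of-moments: a fixed-effect WLS fit yields the
residual Q_E, τ²_res = max(0, (Q_E − (k − p))/tr(P)) with P the weighted
residual projector, and the final WLS uses weights 1/(vᵢ + τ²_res) with a
normal-approximation CI and two-sided p (no permutation p, no t/KH
correction). The intercept-only model reproduces the classic DL pooled
log OR (IV-centered Q) exactly — a useful identity test.

## Publication-bias tests

**Begg**: standardized deviates tᵢ = (θᵢ − θ̂_IV)/√(vᵢ − v_pooled) are
rank-correlated (Kendall τ_b, tie-corrected variance) with the variances
vᵢ. The radicand is floored at 1e-12 (it can only go negative through
floating error) with a logged warning. Three p-value variants: plain
normal approximation on the Kendall score (**default**), continuity-
corrected normal approximation, and the exact permutation distribution
(enumerating all k! orderings, limited to k ≤ 8 where 8! = 40320 is
cheap). The default is the plain approximation because it is what the
reference value for this corpus (P = 0.458) corresponds to; on eight
studies the variants differ materially (0.458 / 0.536 / 0.548), which is
why all three are exposed.

**Egger**: OLS of θᵢ/seᵢ on 1/seᵢ; the intercept is the asymmetry
statistic, tested two-sided against t with k − 2 df; the slope is
reported for context.

## Clinicopathological pooling

Stratum counts are stored methylated/total per level, with level A the
risk level; they expand to within-case 2×2 tables (a = methylated at risk
level, b = unmethylated at risk level, …) and flow through the same
effect/pooling machinery, model chosen by the Q-test rule. Design
choices: heterogeneous age cut-offs (<60 vs <55 years) are pooled as a
single "older vs younger" contrast; the article contributing both tissue
and serum studies contributes both sets of strata by default although they
describe overlapping patients (`include_serum_duplicate=False` drops the
serum copy); grade recodings (high-grade serous → poorly differentiated,
G1+G2 → well/moderately differentiated) are applied in the shipped data.

Known deviation: for the age contrast the Q-test P is 0.049, so the rule
selects the random model (OR 0.93 [0.13, 6.80]); the commonly cited value
1.42 [0.61, 3.30] is the MH fixed estimate, reproducible via
`pool_clinicopath(corpus, "age", model="fixed")`. The stage, grade and
histology contrasts are insensitive to this: the rule reproduces the
reference values (4.20, 4.37, 1.46) directly.

## Built-in corpus

Eight studies, 476 cases / 385 controls. Transcription choices: one
article's tissue and serum cohorts enter as two independent studies
(sharing an `article_id`); multi-arm control groups within an article
(NT+BOT twice, AT+NT once) are summed into a single control arm — the
only reading consistent with the published marginal totals; 41 metastatic
samples reported by one article are excluded from all counts; one study's
control arm is used as printed (11/112) although the text describes a
43+80 benign/healthy composition. Publication years are taken from the
source articles and feed only meta-regression.

## Synthetic-data generator

`simulate_corpus` draws, for each study, θᵢ ~ Normal(true_log_or, τ²),
case probability expit(logit(p₀) + θᵢ + bias·seᵢ_exp), and binomial
counts; arm sizes are fixed or uniform over a range; covariates are
assigned round-robin purely so subgroup/meta-regression machinery can be
exercised. The small-study bias term shifts each study's effect by
`bias_strength` × its anticipated Woolf SE (computed from expected
counts floored at 0.5) — the standard construction that Egger's test is
designed to detect. One seeded NumPy generator per call; no global state.

Defaults mirror the built-in corpus: k = 8, true OR 33.5, τ = 1.0
(the corpus's estimated τ is 1.05), p₀ = 0.11 (43/385 pooled control
methylation), case arms 35–102 and control arms 4–123 subjects. The
generator emulates only the count-level structure the meta-analysis
consumes — no CpG-site resolution, no assay error, no correlated cohorts
— so passing recovery/calibration tests validates the statistical
machinery, not robustness to those real-data features.

`null_calibration` replays the pipeline over seeded replicates and
returns Q-test/Egger/Begg rejection rates with binomial standard errors.
Monte-Carlo checks in the test suite use k = 20 studies of 100 + 100
subjects at p₀ = 0.3 (2000 replicates for the size checks, 300–400 for
ordering checks) — sizes chosen so the whole suite stays interactive
while binomial tolerance bands remain tight.

## Numerical conventions

Reported values are compared to printed references after half-up rounding
to 2 decimals (`round_half_up`), since banker's rounding can flip a
printed digit. Q = 0 defines I² = 0; a single study has df = 0, P_het = 1,
τ² = 0. Pooled results carry normalized weights back onto the effect
objects. Full precision is kept in the JSON report; rounding happens only
in human-readable output.
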