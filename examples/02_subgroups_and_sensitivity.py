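"""Subgroup analysis and leave-one-out sensitivity.

Pools each level of every study-level covariate separately (both models,
as the source tables report), then re-pools with each study omitted in
turn to gauge the influence of any single study.
"""

from metaor import builtin_corpus
from metaor.heterogeneity import leave_one_out, subgroup_analysis

corpus = builtin_corpus()

for variable in ("country", "sample_type", "control_type", "method",
                 "size_class"):
    print(f"\n{variable}:")
    for row in subgroup_analysis(corpus, variable):
        print(f"  {row.level:<20s} k={row.k}  "
              f"fixed {row.fixed.odds_ratio:7.2f} "
              f"[{row.fixed.ci_low:6.2f}, {row.fixed.ci_high:7.2f}]  "
              f"random {row.random.odds_ratio:7.2f} "
              f"[{row.random.ci_low:6.2f}, {row.random.ci_high:7.2f}]  "
              f"I2={row.het.i2:3.0f}%")

print("\nleave-one-out (random effects, tau2 re-estimated per subset):")
rows = leave_one_out(corpus)
for row in rows:
    r = row.result
    print(f"  without {row.omitted_study_id:<20s} "
          f"OR {r.odds_ratio:6.2f} [{r.ci_low:6.2f}, {r.ci_high:7.2f}]")
ors = [r.result.odds_ratio for r in rows]
print(f"  range: {min(ors):.2f} to {max(ors):.2f}")

# Every omission leaves the pooled OR far above 1 (here 24.04-44.47), so
# no single study drives the overall association.
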