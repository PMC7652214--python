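"""Compare populations with the multi-aspect statistical battery.

Measures brightness across a reduced synthetic cohort and runs the full
battery: multi-way ANOVA, one-sided permutation tests on location (mean)
and scatter (variance) with Bonferroni-Holm-Shaffer adjustment, and the
dominance-counting population ranking.
"""

import pandas as pd

from corneaquant import (
    PipelineConfig,
    default_cohort_spec,
    generate_cohort,
    multiway_anova,
    pairwise_population_tests,
    process_section,
    summarize_population,
    tukey_posthoc,
)

sections = generate_cohort(default_cohort_spec(n_per_group=4, seed=2))
cfg = PipelineConfig()
table = pd.concat(
    [process_section(s.image, cfg, metadata=s.metadata)[0] for s in sections],
    ignore_index=True,
)
print(f"{len(sections)} sections -> {len(table)} brightness records\n")
print(summarize_population(table).round(2).to_string(index=False))

anova = multiway_anova(table)
print("\nANOVA fixed effects:")
for name, f, p in anova.terms:
    print(f"  {name:18s} F = {f:8.2f}   p = {p:.4g}")

battery = pairwise_population_tests(table, n_permutations=1999, seed=2)
print("\none-sided permutation tests (row > column), adjusted p:")
res = battery["results"]
for aspect in ("location", "scatter"):
    sub = res[res.aspect == aspect]
    print(f"  [{aspect}]")
    for r in sub.itertuples():
        print(f"    {r.population_a:8s} > {r.population_b:8s} "
              f"p_adj = {r.p_adjusted:.4f}")
    ranks = battery["rankings"][aspect].ranks
    print(f"    ranking (1 = largest): {ranks}")

print("\nTukey post-hoc (simultaneous 95% CIs):")
print(tukey_posthoc(table).round(3).to_string(index=False))
print("\nexpected pattern: injured brighter than both (location), "
      "treated indistinguishable from healthy in mean.  The treated "
      "scatter excess is a subtler effect; at this reduced demo size "
      "(4 corneas/group) it often stays below significance — the "
      "default 10-cornea cohort detects it reliably.")
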