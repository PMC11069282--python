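"""Derive ROC cutoffs for the glycemic indexes and tabulate 30-day mortality.

For each index (in-hospital SD, in-hospital CV, estimated pre-hospital CV)
the cutoff minimizing the distance to the top-left ROC corner splits the
cohort in two; mortality is compared across strata with an uncorrected
Pearson chi-square.
"""

from glycostrat import (
    CohortSpec,
    generate_cohort,
    mortality_table,
    optimal_cutoff_closest_to_corner,
    roc_curve,
    summarize_cohort,
)

cohort = generate_cohort(CohortSpec(seed=7))
summaries = summarize_cohort(cohort)
died = summaries["died_30d"].to_numpy(dtype=bool)

rules = []
for var in ("in_sd", "in_cv", "est_pre_cv"):
    roc = roc_curve(summaries[var].to_numpy(), died)
    rule = optimal_cutoff_closest_to_corner(roc, var)
    rules.append(rule)
    print(f"{var:11s} AUC {roc.auc():.3f}  cutoff {rule.cutoff:.2f}")

print()
print(mortality_table(summaries, rules).to_string(index=False))
# death_pct gives 30-day mortality per stratum; p_value is the chi-square
# comparison of the two strata for that rule.
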