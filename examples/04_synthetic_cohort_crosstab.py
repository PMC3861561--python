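"""Simulate a cohort with known ground truth, score it, and cross-tabulate.

The generator draws a true Ki-67 fraction per case, emits annotated fields
under the 1,000-nuclei stopping rule, and keeps the truth for comparison.
"""

from ki67kit import (
    CohortSimConfig,
    aggregate_annotations,
    classify_case,
    cohort_cross_tab,
    simulate_cohort,
)

cohort = simulate_cohort(CohortSimConfig(n_cases=24, seed=7))

results = []
errors = []
for case in cohort:
    ik = aggregate_annotations(list(case.fields))
    errors.append(abs(ik.ik_mean - case.truth.true_ik_pct))
    results.append(classify_case(ik, case.profile, case.clinical))

print(f"cases: {len(cohort)}; mean |IK error| vs ground truth: "
      f"{sum(errors) / len(errors):.2f} percentage points")

tab = cohort_cross_tab(results, "luminal", "ik_class")
print("\nIK class by luminal status (row % and counts):")
print(tab.formatted().to_string())
# Each cell shows the row percentage with the case count in parentheses,
# the layout used for published IK distribution tables.  Estimation error
# stays small because every case accumulates at least 1,000 nuclei.
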