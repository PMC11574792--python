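"""Generate a matched phantom case--control cohort and summarise it.

Builds a 300-subject phantom population (horseshoe mandible masks, Gaussian
dose lobes, clinical covariates at development-cohort prevalences), draws
ORN labels from the planted logistic NTCP, matches cases to controls on
primary site and treatment year, and prints a case-vs-control clinical
summary with Mann-Whitney/chi-squared p-values and Cohen's d effect sizes.
"""

import numpy as np

from dosemap_ntcp import synthetic_cohort as sc
from dosemap_ntcp.metrics import cohort_summary

config = sc.PhantomConfig(grid_shape=(16, 16, 16), seed=11)
population = sc.generate_population(config, sc.PlantedTruth(), 300)
matched = sc.match_case_control(population)

print(f"population: {len(population)} subjects, "
      f"ORN rate {population.labels().mean():.2f}")
print(f"matched cohort: {len(matched)} subjects "
      f"({int(matched.labels().sum())} cases), "
      f"{matched.exclusions} unmatchable cases dropped")

d30 = np.array([s.dose_summary for s in matched.subjects])
labels = matched.labels()
print(f"mandible D30%: cases {d30[labels == 1].mean():.1f} Gy, "
      f"controls {d30[labels == 0].mean():.1f} Gy "
      "(cases are hotter: the planted dose effect)")

print("\ncase-vs-control summary (matched cohort):")
print(cohort_summary(matched.clinical_table()).round(3).to_string())
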