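"""Simulate a 55-case cohort and inspect its heterogeneity structure.

Each case draws a level-probability vector per feature from a symmetric
Dirichlet; small concentrations give mostly homogeneous specimens with a
long tail of heterogeneous ones, mimicking the spread seen in real
thymectomy panels.  The manifest records the realized truth, so estimates
from the generated slide table can be checked against it.
"""

import numpy as np

from thymentropy import (
    CohortConfig,
    compute_profiles,
    profiles_to_frame,
    read_slide_table,
    simulate_cohort,
)

cohort = simulate_cohort(CohortConfig(seed=55))
print(f"cases: {cohort.manifest.n_cases}, slide rows: {len(cohort.slides)}")

truth = cohort.manifest.to_frame()
print("\nTrue per-case Shannon entropy of the follicle count:")
print(truth["H_shannon_n_follicle_cd23"].describe().round(3).to_string())

# round-trip through CSV and the reading/discretization path
cohort.slides.to_csv("scratch_slides.csv", index=False)
est = profiles_to_frame(compute_profiles(read_slide_table("scratch_slides.csv")))
r = np.corrcoef(est["H_pointsum_n_follicle_cd23"], truth["H_pointsum_n_follicle_cd23"])[0, 1]
print(f"\npipeline vs manifest point-sum entropy: Pearson r = {r:.6f}")
# r = 1: back-transforming levels to raw values and re-discretizing is
# lossless, so the pipeline recovers the generator's truth exactly.

import os
os.remove("scratch_slides.csv")
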