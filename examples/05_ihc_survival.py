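"""Classify an IHC cohort by TET2 localization and compare survival.

Simulates a cohort whose hazard decreases with the nuclear-TET2 fraction,
classifies each sample into the four localization categories, cross-
tabulates against Dukes stage, and runs Kaplan-Meier / log-rank analysis.
"""

import numpy as np

from tet2traj import (
    CATEGORIES,
    crosstab_stage,
    generate_ihc_cohort,
    km_median,
    logrank_test,
)

records = generate_ihc_cohort(n_samples=263, hazard_beta=1.5, censor_rate=0.2, seed=1)

print(f"{len(records)} samples classified:")
groups = {}
for cat in CATEGORIES:
    recs = [r for r in records if r.category == cat]
    times = np.array([r.time for r in recs])
    events = np.array([r.event for r in recs])
    groups[cat] = (times, events)
    print(f"  {cat:<16} n = {len(recs):3d}  median survival = {km_median(times, events):7.1f}")

stat, df, p = logrank_test([groups[c] for c in CATEGORIES])
print(f"log-rank across the four categories: chi2 = {stat:.2f} (df {df}), p = {p:.2e}")

xt = crosstab_stage(records)
print("category x Dukes-stage counts:")
print(xt.table.to_string())
print(f"chi-square = {xt.chi2:.2f} (df {xt.dof}), p = {xt.p_value:.3g}")
# The nucleus-only category should show the longest median survival: higher
# nuclear TET2 is protective in the simulated hazard, and late stages enrich
# for cytoplasmic categories.
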