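"""Recover the temporal order of module-activation events.

Runs the full pipeline (simulate -> QC -> normalize -> pseudotime -> 100
bins -> module scores -> logistic fits) and prints each module's fitted
event time t50 with bootstrap support for the pairwise order.
"""

from tet2traj import SimulationConfig, bootstrap_order, fit_logistic, order_events
from tet2traj.evaluation import run_pipeline

config = SimulationConfig(n_cells=2000, conditions=("FLAG",), seed=7)
res = run_pipeline(config)
profile = res["profile"]

fits = [
    fit_logistic(profile.module_scores[m.name], profile.bin_t, m.name)
    for m in res["modules"]
]
order = order_events(fits)
print("module fits (t50 = pseudotime of half-maximal change):")
for f in sorted(fits, key=lambda f: f.t50):
    true_mid = res["truth"].module_midpoints[f.module_name]
    print(f"  {f.module_name:<14} t50 = {f.t50:5.1f}  (true {true_mid:4.1f})  "
          f"amp = {f.amp:+.2f}  r2 = {f.r2:.3f}")
print("recovered order:", " -> ".join(order.ordered))

boot = bootstrap_order(res["normalized"], res["modules"], res["pseudotime"], B=30, seed=7)
print("bootstrap support (fraction of resamples preserving each pair):")
for (a, b), s in boot.bootstrap_support.items():
    print(f"  {a} before {b}: {s:.2f}")
# Metabolic modules (negative-amplitude OXPHOS, rising glycolysis) change
# first, TET2 targets last — the putative regulatory order the trajectory
# analysis is built to expose.
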