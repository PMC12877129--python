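# tet2traj

Trajectory analysis of TET2 cytoplasm–nucleus shuttling in colorectal cancer
progression.

In colorectal tumors the DNA demethylase TET2 relocates from cytoplasm to
nucleus as the disease progresses, and the fraction of tumor cells with
nuclear TET2 stratifies patient survival.  Single-cell profiling of
progression models suggests a fixed order of events along the progression
trajectory — metabolic reprogramming first, then WNT activation and EMT, with
TET2-target activation last — and a negative feedback loop in which nuclear
TET2 dampens further EMT/WNT activation.  `tet2traj` re-implements that
computational analysis as a tested, reusable Python library, exercisable end
to end on synthetic data with known ground truth:

- **synthetic data** (`tet2traj.simulate`) — negative-binomial single-cell
  counts along a latent progression coordinate t ∈ [0, 100], five gene
  modules (OXPHOS, glycolysis, WNT targets, EMT markers, TET2 targets) with
  staggered sigmoid programs, two conditions (FLAG vs TET2CD) with optional
  feedback coupling, bulk cohorts, and an IHC survival cohort;
- **trajectory** (`tet2traj.trajectory`) — QC, normalization, deterministic
  PC1-based pseudotime, 100 equal-count bins, gene-module scores;
- **event ordering** (`tet2traj.ordering`) — four-parameter logistic fits of
  binned module scores, s(t) = base + amp / (1 + e^(−k (t − t50))), with the
  event time of a module defined as t50 (the 0.5-crossing of its min–max
  normalized curve), plus bootstrap support for the pairwise order;
- **projection** (`tet2traj.projection`) — Spearman-correlation assignment of
  external single-cell/bulk profiles onto the reference bin centroids, ECDF
  summaries, and permutation KS comparison of groups;
- **feedback** (`tet2traj.feedback`) — TET2-high/low stratification and a
  windowed (bins 36–75) slope-difference permutation test of EMT/WNT response
  per unit TET2-target activation;
- **survival** (`tet2traj.survival`) — the four-category nuclear-TET2
  classifier (≥90 % nucleus only, 50–90 % nucleus major, 10–50 % cytoplasm
  major, <10 % cytoplasm only), stage cross-tabulation, Kaplan–Meier and
  log-rank analysis.

## Worked example

`examples/` holds one short script per capability.  Recovering the event
order (`python examples/02_event_ordering.py`):

```
module fits (t50 = pseudotime of half-maximal change):
  GLYCOLYSIS     t50 =  29.0  (true 30.0)  amp = +1.88  r2 = 0.990
  OXPHOS         t50 =  33.1  (true 30.0)  amp = -2.15  r2 = 0.997
  WNT_TARGETS    t50 =  44.3  (true 45.0)  amp = +1.58  r2 = 0.994
  EMT_MARKERS    t50 =  50.5  (true 50.0)  amp = +1.54  r2 = 0.995
  TET2_TARGETS   t50 =  65.8  (true 65.0)  amp = +1.75  r2 = 0.992
recovered order: GLYCOLYSIS -> OXPHOS -> WNT_TARGETS -> EMT_MARKERS -> TET2_TARGETS
```

Each line is one module's four-parameter logistic fit against the 100-bin
pseudotime course of 2000 simulated cells: t50 is the inferred event time
(within ~1–3 units of the generative midpoint), a negative amplitude marks a
deactivating module (OXPHOS switches off as glycolysis takes over), and the
recovered order reproduces the generative sequence — metabolism changes
first, TET2 targets last.  Bootstrap support for every pairwise order in this
run is 1.00.

The other examples print projection separation between early- and late-skewed
cohorts (permutation KS p = 0.001), the feedback slope difference between
FLAG and TET2CD cells (Δslope = 1.15, p = 0.001), and a 263-sample survival
analysis in which the nucleus-only category has the best median survival
(log-rank p ≈ 5 × 10⁻⁷).

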