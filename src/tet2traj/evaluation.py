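"""End-to-end study routines: recovery, calibration and power measurements.

Each function runs the full pipeline on freshly simulated data with known
ground truth and measures how well the analysis recovers it: event-order
recovery across seeds, projection accuracy, feedback-test calibration and
power, and survival-analysis power.  These are the quantities the package's
acceptance checks report; they are ordinary library functions and can be used
to re-validate the pipeline under modified generator settings.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .feedback import windowed_feedback_test
from .io import ExpressionMatrix, GeneModule
from .ordering import event_time, fit_logistic, order_events
from .projection import build_reference, compare_distributions, project_samples
from .simulate import (
    SimulationConfig,
    generate_cells,
    generate_cells_at,
    generate_ihc_cohort,
    module_definitions,
)
from .survival import CATEGORIES, km_estimate, km_median, logrank_test
from .trajectory import (
    bin_pseudotime,
    infer_pseudotime,
    normalize_median_ratios,
    qc_filter,
    score_modules,
)

__all__ = [
    "child_seeds",
    "run_pipeline",
    "event_order_study",
    "projection_study",
    "feedback_calibration",
    "feedback_power_curve",
    "survival_study",
    "km_oracle_check",
    "structural_check",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) derived from one master seed."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(
    config: SimulationConfig,
    n_bins: int = 100,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
):
    """Simulate, QC, normalize, infer pseudotime, bin and score modules.

    Returns a dict with the intermediate products keyed by stage; ``t_true``
    is aligned with the QC-surviving cells.
    """
    matrix, ann, truth = generate_cells(config)
    filtered = qc_filter(matrix, min_genes_per_cell, min_cells_per_gene)
    norm = normalize_median_ratios(filtered)
    modules = module_definitions(config)
    ordering_genes = [g for mod in modules for g in mod.genes]
    root = next(m for m in modules if m.name == "OXPHOS")
    pt = bin_pseudotime(infer_pseudotime(norm, ordering_genes, root), n_bins)
    profile, cell_scores = score_modules(norm, modules, pt)
    keep = ann["cell_id"].isin(set(norm.row_ids)).to_numpy()
    return {
        "matrix": matrix,
        "normalized": norm,
        "annotations": ann.loc[keep].reset_index(drop=True),
        "t_true": truth.t_true[keep],
        "truth": truth,
        "modules": modules,
        "pseudotime": pt,
        "profile": profile,
        "cell_scores": cell_scores,
    }


def _fit_all(profile, modules, r2_min: float = 0.3):
    return [
        fit_logistic(profile.module_scores[m.name], profile.bin_t, m.name, r2_min)
        for m in modules
    ]


def event_order_study(
    n_seeds: int = 20,
    n_cells: int = 2000,
    base_seed: int = 0,
    config: Optional[SimulationConfig] = None,
) -> dict:
    """Recover the event order over independent simulations.

    Per seed: 2000 cells at generator defaults, 100 bins, logistic fits,
    ordering.  Reports the fraction of seeds recovering the metabolic modules
    earliest and TET2 targets last, the fraction recovering the full
    generative order, and the per-module t50 bias (mean recovered minus true).
    """
    if config is None:
        config = SimulationConfig(n_cells=n_cells, conditions=("FLAG",))
    t50s: dict[str, list[float]] = {p.module_name: [] for p in config.module_params}
    n_endpoint_ok = 0
    n_full_ok = 0
    metabolic = {"OXPHOS", "GLYCOLYSIS"}
    for seed in child_seeds(base_seed, n_seeds):
        res = run_pipeline(replace(config, seed=seed))
        fits = _fit_all(res["profile"], res["modules"])
        order = order_events(fits)
        for f in fits:
            if f.converged:
                t50s[f.module_name].append(event_time(f))
        if set(order.ordered[:2]) == metabolic and order.ordered[-1] == "TET2_TARGETS":
            n_endpoint_ok += 1
        non_metabolic = [m for m in order.ordered if m not in metabolic]
        if (
            set(order.ordered[:2]) == metabolic
            and non_metabolic == ["WNT_TARGETS", "EMT_MARKERS", "TET2_TARGETS"]
        ):
            n_full_ok += 1
    true_mid = {p.module_name: p.midpoint for p in config.module_params}
    bias = {
        name: float(np.mean(vals) - true_mid[name]) if vals else float("nan")
        for name, vals in t50s.items()
    }
    return {
        "n_seeds": n_seeds,
        "endpoint_recovery_pct": 100.0 * n_endpoint_ok / n_seeds,
        "full_order_recovery_pct": 100.0 * n_full_ok / n_seeds,
        "t50_bias": bias,
        "t50_abs_bias_max": float(np.nanmax(np.abs(list(bias.values())))),
    }


def projection_study(
    base_seed: int = 0,
    n_seeds: int = 20,
    n_ref_cells: int = 2000,
    n_external: int = 500,
    n_group: int = 200,
    n_perm: int = 199,
) -> dict:
    """Projection accuracy and group-separation power.

    Builds one reference trajectory, then (i) self-projects every bin
    centroid, (ii) projects external cells simulated at known latent t and
    measures the median absolute bin error, and (iii) per seed simulates an
    early-skewed "primary tumor" and a late-skewed "metastatic" group and
    tests their pseudotime distributions by permutation KS.
    """
    seeds = child_seeds(base_seed, n_seeds + 2)
    config = SimulationConfig(n_cells=n_ref_cells, conditions=("FLAG",), seed=seeds[0])
    res = run_pipeline(config)
    ref = build_reference(res["normalized"], res["pseudotime"], res["modules"])

    centroids = ExpressionMatrix(
        ref.bin_centroids, [f"bin{b}" for b in range(1, ref.n_bins + 1)], ref.genes,
        kind="normalized",
    )
    self_proj = project_samples(ref, centroids)
    self_exact = all(p.assigned_bin == b + 1 for b, p in enumerate(self_proj))
    self_sim_min = min(p.similarity for p in self_proj)

    rng = np.random.default_rng(seeds[1])
    t_ext = rng.uniform(0.0, 100.0, size=n_external)
    ext, _ = generate_cells_at(config, t_ext, rng=rng)
    proj = project_samples(ref, normalize_median_ratios(ext))
    true_bin = np.clip(np.floor(t_ext).astype(int) + 1, 1, ref.n_bins)
    errors = np.array(
        [abs(p.assigned_bin - tb) for p, tb in zip(proj, true_bin) if p.ok], dtype=float
    )
    median_err = float(np.median(errors))

    n_sig = 0
    for seed in seeds[2:]:
        rng = np.random.default_rng(seed)
        t_pt = 100.0 * rng.beta(2.0, 4.0, size=n_group)
        t_mt = 100.0 * rng.beta(4.0, 2.0, size=n_group)
        pt_cells, _ = generate_cells_at(config, t_pt, rng=rng, prefix="pt")
        mt_cells, _ = generate_cells_at(config, t_mt, rng=rng, prefix="mt")
        proj_pt = project_samples(ref, normalize_median_ratios(pt_cells))
        proj_mt = project_samples(ref, normalize_median_ratios(mt_cells))
        _, p = compare_distributions(proj_pt, proj_mt, n_perm=n_perm, seed=seed)
        n_sig += p < 0.05
    return {
        "self_projection_exact": bool(self_exact),
        "self_projection_similarity_min": float(self_sim_min),
        "median_abs_bin_error": median_err,
        "separation_pct": 100.0 * n_sig / n_seeds,
        "n_seeds": n_seeds,
    }


def _feedback_p(config: SimulationConfig, n_perm: int, seed: int) -> float:
    res = run_pipeline(config)
    result = windowed_feedback_test(
        res["cell_scores"],
        res["pseudotime"].bin,
        res["annotations"]["condition"].to_numpy(),
        groups=("FLAG", "TET2CD"),
        n_perm=n_perm,
        seed=seed,
    )
    return result.p_perm


def feedback_calibration(
    n_runs: int = 100,
    n_cells: int = 400,
    base_seed: int = 0,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the windowed feedback test with no coupling.

    With ``feedback_gamma = 0`` the FLAG and TET2CD conditions are
    exchangeable, so the rejection rate should sit near alpha.
    """
    seeds = child_seeds(base_seed, n_runs)
    rejections = 0
    for seed in seeds:
        config = SimulationConfig(n_cells=n_cells, feedback_gamma=0.0, seed=seed)
        rejections += _feedback_p(config, n_perm, seed) <= alpha
    return {"n_runs": n_runs, "rejection_rate": rejections / n_runs}


def feedback_power_curve(
    gammas: Sequence[float] = (0.1, 0.3, 0.5),
    n_seeds: int = 20,
    n_cells: int = 2000,
    base_seed: int = 0,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Power of the feedback test as a function of the coupling strength."""
    seeds = child_seeds(base_seed, n_seeds)
    power = {}
    for gamma in gammas:
        hits = 0
        for seed in seeds:
            config = SimulationConfig(n_cells=n_cells, feedback_gamma=gamma, seed=seed)
            hits += _feedback_p(config, n_perm, seed) < alpha
        power[float(gamma)] = 100.0 * hits / n_seeds
    return {"n_seeds": n_seeds, "power_pct": power}


def survival_study(
    n_seeds: int = 20,
    n_samples: int = 500,
    hazard_beta: float = 1.5,
    censor_rate: float = 0.2,
    base_seed: int = 0,
) -> dict:
    """Log-rank power and survival direction on simulated IHC cohorts.

    Per seed: a cohort whose hazard decreases with nuclear-TET2 fraction is
    classified into the four localization categories; reports the fraction of
    seeds with log-rank p < 0.05 across categories, and the fraction in which
    the nucleus-only category has the best Kaplan-Meier median survival.
    """
    seeds = child_seeds(base_seed, n_seeds)
    n_sig = 0
    n_best = 0
    for seed in seeds:
        records = generate_ihc_cohort(n_samples, hazard_beta, censor_rate, seed=seed)
        groups = {}
        for cat in CATEGORIES:
            recs = [r for r in records if r.category == cat]
            groups[cat] = (
                np.array([r.time for r in recs]),
                np.array([r.event for r in recs]),
            )
        _, _, p = logrank_test([groups[c] for c in CATEGORIES])
        n_sig += p < 0.05
        medians = {c: km_median(*groups[c]) for c in CATEGORIES if groups[c][0].size}
        if max(medians, key=medians.get) == "nucleus_only":
            n_best += 1
    return {
        "n_seeds": n_seeds,
        "logrank_power_pct": 100.0 * n_sig / n_seeds,
        "nucleus_only_best_pct": 100.0 * n_best / n_seeds,
    }


def km_oracle_check() -> float:
    """Max |KM - hand-computed product-limit| over two toy inputs.

    times (1,2,3) all events -> S = 2/3, 1/3, 0; times (1, 2+, 3) with a
    censoring at 2 -> S(1) = 2/3, S(3) = 0.
    """
    c1 = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
    err1 = np.max(np.abs(c1.survival - np.array([2 / 3, 1 / 3, 0.0])))
    c2 = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
    err2 = np.max(np.abs(c2.survival - np.array([2 / 3, 0.0])))
    return float(max(err1, err2))


def structural_check(seed: int = 0) -> dict:
    """Default pipeline bin count and classifier category count."""
    from .survival import classify_sample

    config = SimulationConfig(n_cells=150, seed=seed)
    res = run_pipeline(config, min_genes_per_cell=0, min_cells_per_gene=0)
    n_bins = int(np.unique(res["pseudotime"].bin).size)
    cats = {classify_sample(f) for f in np.linspace(0.0, 1.0, 1001)}
    return {"n_pseudotime_bins": n_bins, "n_categories": len(cats)}
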