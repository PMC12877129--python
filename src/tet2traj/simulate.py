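"""Synthetic single-cell, bulk and clinical-cohort data with known ground truth.

The generator emulates the statistical structure of a long-term-culture (LTC)
colorectal-cancer progression experiment: cells carry a latent progression
coordinate t on [0, 100]; five gene modules (OXPHOS, glycolysis, WNT targets,
EMT markers, TET2 targets) switch on or off along t following four-parameter
sigmoids with staggered midpoints; counts are negative-binomial around the
exponentiated module means, scaled by a per-cell library size.  Two
experimental conditions (FLAG control vs TET2CD overexpression) optionally
differ through a negative-feedback coupling: in the TET2CD condition the
EMT/WNT amplitudes are damped in proportion to the normalized TET2-target
activity at the cell's t, so TET2-high cells up-regulate EMT/WNT less.

Bulk samples are averages of cells drawn around a sample-level latent t, and
the clinical cohort draws survival times whose hazard decreases with the
nuclear-TET2 fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneModule, write_gmt, write_mtx_triplet
from .survival import CohortRecord

__all__ = [
    "ModuleActivationParams",
    "SimulationConfig",
    "GroundTruth",
    "MODULE_NAMES",
    "TYPE_EDGES",
    "TYPE_LABELS",
    "default_module_params",
    "default_timepoint_mixture",
    "module_mean",
    "expected_module_curve",
    "type_label",
    "module_definitions",
    "generate_cells",
    "generate_cells_at",
    "generate_bulk_cohort",
    "generate_ihc_cohort",
    "write_dataset",
]

MODULE_NAMES = ("OXPHOS", "GLYCOLYSIS", "WNT_TARGETS", "EMT_MARKERS", "TET2_TARGETS")

#: Cell-type thresholds on the latent coordinate: [0,20) I, [20,40) II,
#: [40,60) III, [60,80) IV, [80,100] V.  Type III corresponds to the
#: mid-trajectory window where the feedback analysis operates.
TYPE_EDGES = np.array([20.0, 40.0, 60.0, 80.0])
TYPE_LABELS = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class ModuleActivationParams:
    """Sigmoid activation program of one gene module along the trajectory.

    Mean log-expression at latent time t is
    ``baseline + amplitude / (1 + exp(-steepness * (t - midpoint)))``.
    A negative amplitude describes a deactivating module (e.g. OXPHOS).
    """

    module_name: str
    baseline: float
    amplitude: float
    steepness: float
    midpoint: float

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError(f"module {self.module_name!r}: steepness must be > 0")
        if not 0.0 <= self.midpoint <= 100.0:
            raise ValueError(f"module {self.module_name!r}: midpoint must lie in [0, 100]")
        if self.amplitude == 0:
            raise ValueError(f"module {self.module_name!r}: amplitude must be non-zero")


def module_mean(t, p: ModuleActivationParams):
    """Expected log-expression of module ``p`` at latent time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    if ((t < 0) | (t > 100)).any():
        raise ValueError("t must lie in [0, 100]")
    with np.errstate(over="ignore"):
        return p.baseline + p.amplitude / (1.0 + np.exp(-p.steepness * (t - p.midpoint)))


def default_module_params() -> tuple[ModuleActivationParams, ...]:
    """Default activation programs: metabolism switches first (midpoint 30),
    then WNT (45), EMT (50), and TET2 targets last (65)."""
    return (
        ModuleActivationParams("OXPHOS", baseline=2.0, amplitude=-1.5, steepness=0.15, midpoint=30.0),
        ModuleActivationParams("GLYCOLYSIS", baseline=0.8, amplitude=1.5, steepness=0.15, midpoint=30.0),
        ModuleActivationParams("WNT_TARGETS", baseline=0.8, amplitude=1.2, steepness=0.15, midpoint=45.0),
        ModuleActivationParams("EMT_MARKERS", baseline=0.8, amplitude=1.2, steepness=0.15, midpoint=50.0),
        ModuleActivationParams("TET2_TARGETS", baseline=0.8, amplitude=1.5, steepness=0.15, midpoint=65.0),
    )


def default_timepoint_mixture() -> dict[str, tuple[float, float]]:
    """Beta(a, b) parameters of the latent coordinate per harvest day.

    Day 6 is early-skewed and day 15 late-skewed; with equal cells per day the
    pooled mixture Beta(k, 5-k), k=1..4 is exactly Uniform(0, 1), so the
    trajectory is evenly populated and rank-based pseudotime is an unbiased
    recovery of the latent scale.
    """
    return {"day6": (1.0, 4.0), "day9": (2.0, 3.0), "day12": (3.0, 2.0), "day15": (4.0, 1.0)}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the single-cell generator needs, including the seed."""

    n_cells: int = 2000                       # per condition
    n_genes_background: int = 200
    genes_per_module: int = 25
    module_params: tuple[ModuleActivationParams, ...] = field(default_factory=default_module_params)
    timepoint_mixture: Mapping[str, tuple[float, float]] = field(default_factory=default_timepoint_mixture)
    dispersion: float = 10.0                  # NB: var = mu + mu^2 / dispersion
    library_size_mean: float = 5000.0         # expected counts per cell
    feedback_gamma: float = 0.0               # EMT/WNT damping by TET2 activity, in [0, 1)
    conditions: tuple[str, ...] = ("FLAG", "TET2CD")
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("n_cells", self.n_cells),
            ("n_genes_background", self.n_genes_background),
            ("genes_per_module", self.genes_per_module),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if self.library_size_mean <= 0:
            raise ValueError(f"library_size_mean must be > 0, got {self.library_size_mean}")
        if not 0.0 <= self.feedback_gamma < 1.0:
            raise ValueError(f"feedback_gamma must be in [0, 1), got {self.feedback_gamma}")
        if not self.module_params:
            raise ValueError("module_params must not be empty")
        names = [p.module_name for p in self.module_params]
        if len(set(names)) != len(names):
            raise ValueError("module_params contains duplicate module names")
        for tp, ab in self.timepoint_mixture.items():
            a, b = ab
            if a <= 0 or b <= 0:
                raise ValueError(f"timepoint_mixture[{tp!r}] must have positive Beta parameters")
        if len(self.conditions) < 1 or len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be non-empty and unique")

    def params_for(self, module_name: str) -> ModuleActivationParams:
        for p in self.module_params:
            if p.module_name == module_name:
                return p
        raise KeyError(f"no module named {module_name!r} in config")


@dataclass
class GroundTruth:
    """Per-cell latent coordinates and the generative event structure."""

    t_true: np.ndarray                      # per cell, on [0, 100]
    type_label: np.ndarray                  # per cell, 'I'..'V'
    module_midpoints: dict[str, float]
    event_order: list[str]                  # modules sorted by midpoint

    @classmethod
    def from_t(cls, t_true: np.ndarray, config: SimulationConfig) -> "GroundTruth":
        midpoints = {p.module_name: p.midpoint for p in config.module_params}
        order = sorted(midpoints, key=midpoints.get)
        return cls(
            t_true=np.asarray(t_true, float),
            type_label=type_label(t_true),
            module_midpoints=midpoints,
            event_order=order,
        )


def type_label(t):
    """Map latent coordinates to cell types I..V by fixed thresholds."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(TYPE_EDGES, t, side="right")
    return np.asarray(TYPE_LABELS, dtype=object)[idx]


def module_definitions(config: SimulationConfig) -> list[GeneModule]:
    """The gene modules of a simulated dataset, as GMT-ready gene sets."""
    modules = []
    for p in config.module_params:
        genes = tuple(f"{p.module_name}_{i:03d}" for i in range(config.genes_per_module))
        modules.append(GeneModule(p.module_name, genes, provenance="synthetic"))
    return modules


def _tet2_activity(t, config: SimulationConfig):
    """Normalized TET2-target activation in [0, 1] at latent time t."""
    p = config.params_for("TET2_TARGETS")
    return 1.0 / (1.0 + np.exp(-p.steepness * (np.asarray(t, float) - p.midpoint)))


_FEEDBACK_MODULES = ("EMT_MARKERS", "WNT_TARGETS")


def expected_module_curve(config: SimulationConfig, module_name: str, condition: str, t):
    """Noiseless mean log-expression of a module at t, feedback included.

    Under the TET2CD condition with ``feedback_gamma > 0``, TET2-target
    activation is stronger (amplitude times ``1 + gamma``) while the EMT and
    WNT amplitudes are damped by ``1 - gamma * tet2_activity(t)`` — TET2-high
    cells up-regulate EMT/WNT less per unit progression.  The damping uses
    the baseline (un-boosted) TET2 activity curve.
    """
    p = config.params_for(module_name)
    t = np.asarray(t, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-p.steepness * (t - p.midpoint)))
    amp = np.full_like(sig, p.amplitude)
    has_tet2 = "TET2_TARGETS" in {q.module_name for q in config.module_params}
    if condition == "TET2CD" and config.feedback_gamma > 0 and has_tet2:
        if module_name in _FEEDBACK_MODULES:
            amp = amp * (1.0 - config.feedback_gamma * _tet2_activity(t, config))
        elif module_name == "TET2_TARGETS":
            amp = amp * (1.0 + config.feedback_gamma)
    return p.baseline + amp * sig


def _draw_t(config: SimulationConfig, n: int, rng: np.random.Generator):
    """Latent coordinates and timepoint labels for n cells of one condition."""
    timepoints = list(config.timepoint_mixture)
    tp_idx = np.arange(n) % len(timepoints)          # equal split across days
    t = np.empty(n)
    labels = np.empty(n, dtype=object)
    for i, tp in enumerate(timepoints):
        a, b = config.timepoint_mixture[tp]
        mask = tp_idx == i
        t[mask] = 100.0 * rng.beta(a, b, size=mask.sum())
        labels[mask] = tp
    return t, labels


def _gene_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Fixed per-gene parameters: module membership, baseline/amplitude jitter.

    Genes within a module share the activation program up to a small per-gene
    baseline offset and amplitude scale, so module genes are correlated but
    not identical.
    """
    rows = []
    for p in config.module_params:
        for i in range(config.genes_per_module):
            rows.append({
                "gene": f"{p.module_name}_{i:03d}",
                "module": p.module_name,
                "baseline": p.baseline + rng.normal(0.0, 0.1),
                "amp_scale": rng.uniform(0.8, 1.2),
            })
    for i in range(config.n_genes_background):
        rows.append({
            "gene": f"BG_{i:04d}",
            "module": None,
            "baseline": rng.uniform(0.0, 2.0),
            "amp_scale": 0.0,
        })
    return pd.DataFrame(rows)


def _log_means(config: SimulationConfig, genes: pd.DataFrame, t: np.ndarray, condition: str):
    """Cells x genes matrix of mean log-expression at the cells' t."""
    n, g = t.size, len(genes)
    log_mu = np.tile(genes["baseline"].to_numpy(), (n, 1))
    fb = (
        condition == "TET2CD"
        and config.feedback_gamma > 0
        and "TET2_TARGETS" in {p.module_name for p in config.module_params}
    )
    damp = 1.0 - config.feedback_gamma * _tet2_activity(t, config) if fb else None
    for p in config.module_params:
        cols = np.flatnonzero((genes["module"] == p.module_name).to_numpy())
        sig = 1.0 / (1.0 + np.exp(-p.steepness * (t - p.midpoint)))     # (n,)
        amp = p.amplitude * genes["amp_scale"].to_numpy()[cols]         # (k,)
        contrib = np.outer(sig, amp)
        if fb and p.module_name in _FEEDBACK_MODULES:
            contrib *= damp[:, None]
        elif fb and p.module_name == "TET2_TARGETS":
            contrib *= 1.0 + config.feedback_gamma
        log_mu[:, cols] += contrib
    return log_mu


def _nb_counts(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with mean mu and var mu + mu^2/theta."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p).astype(float)


def _sample_counts(config, genes, t, condition, rng):
    log_mu = _log_means(config, genes, t, condition)
    weights = np.exp(log_mu)
    rel = weights / weights.sum(axis=1, keepdims=True)
    # log-normal library-size factor with mean exactly 1
    sigma = 0.3
    lib = config.library_size_mean * rng.lognormal(-0.5 * sigma**2, sigma, size=t.size)
    mu = rel * lib[:, None]
    return _nb_counts(mu, config.dispersion, rng)


def generate_cells(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate ``n_cells`` per condition along the latent trajectory.

    Returns a counts :class:`ExpressionMatrix` (all conditions stacked), an
    annotation frame (cell_id, condition, timepoint, cell_type) and the
    :class:`GroundTruth`.  Identical configs (including seed) give identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config, rng)
    blocks, t_all, ann_rows = [], [], []
    for condition in config.conditions:
        t, tp = _draw_t(config, config.n_cells, rng)
        counts = _sample_counts(config, genes, t, condition, rng)
        blocks.append(counts)
        t_all.append(t)
        for i in range(config.n_cells):
            ann_rows.append({
                "cell_id": f"{condition}_c{i:05d}",
                "condition": condition,
                "timepoint": tp[i],
            })
    values = np.vstack(blocks)
    t_all = np.concatenate(t_all)
    ann = pd.DataFrame(ann_rows)
    ann["cell_type"] = type_label(t_all)
    truth = GroundTruth.from_t(t_all, config)
    matrix = ExpressionMatrix(values, ann["cell_id"].tolist(), genes["gene"].tolist(), kind="counts")
    return matrix, ann, truth


def generate_cells_at(
    config: SimulationConfig,
    t_values: Sequence[float],
    condition: str = "FLAG",
    rng: Optional[np.random.Generator] = None,
    prefix: str = "ext",
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate cells at caller-specified latent coordinates.

    Used to emulate external cohorts (patient cells, bulk constituents) whose
    progression states are known, so projection accuracy can be measured.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.asarray(t_values, dtype=float)
    if ((t < 0) | (t > 100)).any():
        raise ValueError("t_values must lie in [0, 100]")
    # gene-level parameters are a deterministic function of the config seed so
    # external cells share the reference dataset's genes
    genes = _gene_table(config, np.random.default_rng(config.seed))
    counts = _sample_counts(config, genes, t, condition, rng)
    ids = [f"{prefix}_c{i:05d}" for i in range(t.size)]
    matrix = ExpressionMatrix(counts, ids, genes["gene"].tolist(), kind="counts")
    return matrix, GroundTruth.from_t(t, config)


def generate_bulk_cohort(
    config: SimulationConfig,
    n_samples: int,
    cells_per_sample: int,
    stage_rule: Sequence[float] = (25.0, 50.0, 75.0),
    seed: Optional[int] = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Bulk samples as averages of cells drawn around a sample-level latent t.

    Each sample draws a latent t uniformly on [0, 100]; its constituent cells
    scatter around it (sd 5 t-units).  The bulk profile is the mean of the
    cells' log-CPM normalized profiles (a singleton sample therefore equals
    that cell's normalized profile).  Stage I-IV is assigned by the monotone
    ``stage_rule`` thresholds on the sample t.
    """
    from .trajectory import normalize_median_ratios  # deferred: trajectory imports io

    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if cells_per_sample < 1:
        raise ValueError("cells_per_sample must be >= 1")
    thresholds = np.asarray(stage_rule, dtype=float)
    if thresholds.size != 3 or not np.all(np.diff(thresholds) > 0):
        raise ValueError(f"stage_rule must be 3 strictly increasing thresholds, got {stage_rule}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gene_rng = np.random.default_rng(config.seed)
    genes = _gene_table(config, gene_rng)
    t_samples = rng.uniform(0.0, 100.0, size=n_samples)
    profiles = []
    for t_s in t_samples:
        t_cells = np.clip(rng.normal(t_s, 5.0, size=cells_per_sample), 0.0, 100.0)
        counts = _sample_counts(config, genes, t_cells, "FLAG", rng)
        cells = ExpressionMatrix(
            counts, [f"c{i}" for i in range(cells_per_sample)], genes["gene"].tolist(), "counts"
        )
        profiles.append(normalize_median_ratios(cells).values.mean(axis=0))
    stage_idx = np.searchsorted(thresholds, t_samples, side="right")
    stages = np.asarray(["I", "II", "III", "IV"], dtype=object)[stage_idx]
    ids = [f"bulk_{i:04d}" for i in range(n_samples)]
    matrix = ExpressionMatrix(np.vstack(profiles), ids, genes["gene"].tolist(), kind="normalized")
    ann = pd.DataFrame({"sample_id": ids, "stage": stages, "t_sample": t_samples})
    return matrix, ann, GroundTruth.from_t(t_samples, config)


def generate_ihc_cohort(
    n_samples: int,
    hazard_beta: float,
    censor_rate: float = 0.2,
    seed: int = 0,
    baseline_rate: float = 0.01,
) -> list[CohortRecord]:
    """Clinical cohort where the hazard decreases with nuclear-TET2 fraction.

    Nuclear fraction f ~ Uniform(0, 1); event time ~ Exponential with rate
    ``baseline_rate * exp(-hazard_beta * f)`` so higher nuclear TET2 means
    better survival; each sample is independently censored with probability
    ``censor_rate`` at a Uniform(0, T) time.  Stage worsens (A -> D) with
    decreasing f, plus noise.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if hazard_beta < 0:
        raise ValueError("hazard_beta must be >= 0")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, 1.0, size=n_samples)
    rate = baseline_rate * np.exp(-hazard_beta * f)
    event_time = rng.exponential(1.0 / rate)
    censored = rng.uniform(size=n_samples) < censor_rate
    obs_time = np.where(censored, rng.uniform(0.0, event_time), event_time)
    stage_score = np.clip((1.0 - f) + rng.normal(0.0, 0.25, size=n_samples), 0.0, 1.0)
    stage = np.asarray(["A", "B", "C", "D"], dtype=object)[
        np.searchsorted([0.25, 0.5, 0.75], stage_score, side="right")
    ]
    return [
        CohortRecord(
            sample_id=f"pt_{i:04d}",
            nuclear_fraction=float(f[i]),
            time=float(obs_time[i]),
            event=int(not censored[i]),
            stage_dukes=str(stage[i]),
        )
        for i in range(n_samples)
    ]


def write_dataset(
    directory: str | Path,
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    truth: GroundTruth,
    modules: Sequence[GeneModule],
) -> None:
    """Write a simulated dataset: MTX triplet, annotation/truth CSVs, GMT."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mtx_triplet(matrix, directory)
    annotations.to_csv(directory / "annotations.csv", index=False)
    pd.DataFrame({
        "cell_id": matrix.row_ids,
        "t_true": truth.t_true,
        "cell_type": truth.type_label,
    }).to_csv(directory / "ground_truth.csv", index=False)
    write_gmt(modules, directory / "modules.gmt")
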