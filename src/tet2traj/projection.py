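"""Projection of external profiles onto the reference pseudotime.

External single cells or bulk samples are assigned to the reference bin whose
centroid they most resemble under Spearman rank correlation over shared genes.
Rank correlation makes the projection invariant to monotone per-gene
transformations, so cross-platform and bulk-vs-single-cell scale differences
do not dominate.  Group-level pseudotime distributions are compared with a
two-sample Kolmogorov-Smirnov statistic whose p-value comes from label
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, GeneModule
from .trajectory import BinProfile, PseudotimeAssignment

__all__ = [
    "ReferenceProfile",
    "ProjectionResult",
    "build_reference",
    "project_samples",
    "cumulative_distribution",
    "compare_distributions",
]


@dataclass
class ReferenceProfile:
    """Bin centroids of the reference trajectory, restricted to module genes."""

    bin_centroids: np.ndarray      # n_bins x genes, mean normalized expression
    genes: list[str]
    bin_positions: np.ndarray      # mean pseudotime per bin

    @property
    def n_bins(self) -> int:
        return self.bin_centroids.shape[0]


@dataclass
class ProjectionResult:
    """One external sample's assignment onto the reference.

    A constant expression profile has no defined rank correlation; such
    samples are flagged (``ok = False``, similarity NaN, no bin) rather than
    silently assigned.
    """

    sample_id: str
    assigned_bin: Optional[int]
    similarity: float
    runner_up_margin: float
    ok: bool = True


def build_reference(
    m: ExpressionMatrix,
    pt: PseudotimeAssignment,
    modules: Sequence[GeneModule],
) -> ReferenceProfile:
    """Bin centroids over the union of module genes (the trajectory's signal)."""
    from .trajectory import score_modules

    profile, _ = score_modules(m, modules, pt)
    genes = list(profile.bin_centroids.columns)
    if len(genes) < 10:
        raise ValueError(f"only {len(genes)} module genes in the matrix; need >= 10")
    return ReferenceProfile(
        bin_centroids=profile.bin_centroids.to_numpy(),
        genes=genes,
        bin_positions=profile.bin_t.copy(),
    )


def _rank_standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks, centered and scaled to unit norm.

    Rows with zero rank variance (constant profiles) are flagged invalid.
    """
    ranks = stats.rankdata(values, axis=1, method="average")
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    out = np.zeros_like(centered)
    out[ok] = centered[ok] / norms[ok, None]
    return out, ok


def project_samples(ref: ReferenceProfile, external: ExpressionMatrix) -> list[ProjectionResult]:
    """Assign each external row to the bin with maximal Spearman correlation.

    Exact similarity ties resolve to the smallest bin index.  Requires >= 10
    shared genes.
    """
    shared = [g for g in ref.genes if g in set(external.gene_ids)]
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} genes shared between reference and external data; need >= 10"
        )
    ref_idx = {g: i for i, g in enumerate(ref.genes)}
    ext = external.subset_genes(shared).values
    cent = ref.bin_centroids[:, [ref_idx[g] for g in shared]]
    ext_r, ext_ok = _rank_standardize(ext)
    cent_r, cent_ok = _rank_standardize(cent)
    if not cent_ok.all():
        raise ValueError("reference contains constant bin centroids over shared genes")
    sim = ext_r @ cent_r.T          # rows x bins, Spearman correlations
    results = []
    for i, sid in enumerate(external.row_ids):
        if not ext_ok[i]:
            results.append(ProjectionResult(sid, None, float("nan"), float("nan"), ok=False))
            continue
        row = sim[i]
        best = int(np.argmax(row))  # argmax returns the smallest index on ties
        second = np.partition(row, -2)[-2] if row.size > 1 else -np.inf
        results.append(
            ProjectionResult(
                sample_id=sid,
                assigned_bin=best + 1,
                similarity=float(row[best]),
                runner_up_margin=float(row[best] - second),
            )
        )
    return results


def _assigned_bins(proj: Sequence[ProjectionResult]) -> np.ndarray:
    bins = np.array([p.assigned_bin for p in proj if p.ok], dtype=float)
    if bins.size == 0:
        raise ValueError("no valid projections")
    return bins


def cumulative_distribution(proj: Sequence[ProjectionResult], n_bins: int = 100) -> np.ndarray:
    """Right-continuous ECDF over bins 1..n_bins; entry b-1 is P(bin <= b)."""
    bins = _assigned_bins(proj)
    grid = np.arange(1, n_bins + 1)
    return np.searchsorted(np.sort(bins), grid, side="right") / bins.size


def compare_distributions(
    proj_a: Sequence[ProjectionResult],
    proj_b: Sequence[ProjectionResult],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample KS statistic on assigned bins with a permutation p-value."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = _assigned_bins(proj_a)
    b = _assigned_bins(proj_b)
    obs = float(stats.ks_2samp(a, b, method="asymp").statistic)
    pooled = np.concatenate([a, b])
    na = a.size
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = stats.ks_2samp(perm[:na], perm[na:], method="asymp").statistic
        if d >= obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return obs, float(p)
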