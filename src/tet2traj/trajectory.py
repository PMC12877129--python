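"""Pseudotime inference, 100-group binning and gene-module scoring.

The trajectory is recovered deterministically: ordering genes are z-scored
across cells, their first principal component is oriented so that the root
population sits early, and the component is rank-transformed onto [0, 100].
Cells are then split into equal-count bins (100 by default) and per-bin
module scores — means of gene-wise z-scored normalized expression — form the
substrate for the event-ordering regressions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneModule

__all__ = [
    "PseudotimeAssignment",
    "BinProfile",
    "qc_filter",
    "normalize_log_cpm",
    "normalize_median_ratios",
    "infer_pseudotime",
    "bin_pseudotime",
    "score_modules",
]

logger = logging.getLogger(__name__)

RootSpec = Union[GeneModule, Iterable[str]]


@dataclass
class PseudotimeAssignment:
    """Per-cell pseudotime on [0, 100] and (after binning) a bin in 1..n_bins.

    ``orientation_evidence`` records the signed statistic used to fix the
    trajectory direction (negative: root-high cells sit early, as requested).
    """

    cell_ids: list[str]
    t: np.ndarray
    orientation_evidence: float
    bin: Optional[np.ndarray] = None       # int, 1..n_bins
    n_bins: Optional[int] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.shape != (len(self.cell_ids),):
            raise ValueError("t must have one value per cell")
        if ((self.t < 0) | (self.t > 100)).any():
            raise ValueError("pseudotime must lie in [0, 100]")


@dataclass
class BinProfile:
    """Per-bin summaries along the trajectory.

    ``module_scores``: bins x modules mean z-scores; ``bin_centroids``: bins x
    genes mean normalized expression over the union of module genes;
    ``bin_t``: mean pseudotime per bin (the regression abscissa).
    """

    bins: np.ndarray
    bin_t: np.ndarray
    module_scores: pd.DataFrame
    bin_centroids: pd.DataFrame
    cells_per_bin: np.ndarray


def qc_filter(
    m: ExpressionMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
) -> ExpressionMatrix:
    """Remove low-coverage cells, then rarely detected genes, in that order."""
    if m.kind != "counts":
        raise ValueError("qc_filter expects a counts matrix")
    detected = m.values > 0
    keep_cells = detected.sum(axis=1) >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError(
            f"all {m.n_rows} cells removed at min_genes_per_cell={min_genes_per_cell}; "
            "lower the threshold"
        )
    vals = m.values[keep_cells]
    keep_genes = (vals > 0).sum(axis=0) >= min_cells_per_gene
    logger.info(
        "qc_filter: removed %d/%d cells and %d/%d genes",
        (~keep_cells).sum(), m.n_rows, (~keep_genes).sum(), m.n_genes,
    )
    return ExpressionMatrix(
        vals[:, keep_genes],
        [c for c, k in zip(m.row_ids, keep_cells) if k],
        [g for g, k in zip(m.gene_ids, keep_genes) if k],
        kind="counts",
    )


def normalize_log_cpm(m: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Scale each cell to ``scale`` total counts, then log(1 + x)."""
    if m.kind != "counts":
        raise ValueError("normalize_log_cpm expects a counts matrix")
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"{zero.size} cell(s) with zero total counts (e.g. {m.row_ids[zero[0]]!r}); "
            "run qc_filter first"
        )
    normed = np.log1p(m.values / totals[:, None] * scale)
    return ExpressionMatrix(normed, list(m.row_ids), list(m.gene_ids), kind="normalized")


def normalize_median_ratios(m: ExpressionMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    """Composition-robust normalization: median-of-ratios size factors.

    Per-cell total counts are a poor size factor when a substantial fraction
    of the transcriptome changes along the trajectory: the changing modules
    shift every cell's total, which imprints a shared spurious drift on all
    normalized curves and biases fitted event times.  The median over genes of
    the ratio to a per-gene geometric-mean reference tracks the stable
    (background) majority instead, as in bulk median-of-ratios size factors.
    Size factors are scaled to geometric mean 1; values are log(1 + x).
    """
    if m.kind != "counts":
        raise ValueError("normalize_median_ratios expects a counts matrix")
    counts = m.values
    ref = np.exp(np.mean(np.log(counts + pseudocount), axis=0))
    size = np.median((counts + pseudocount) / ref, axis=1)
    if (size <= 0).any():
        raise ValueError("non-positive size factor; run qc_filter first")
    size = size / np.exp(np.mean(np.log(size)))
    normed = np.log1p(counts / size[:, None])
    return ExpressionMatrix(normed, list(m.row_ids), list(m.gene_ids), kind="normalized")


def _zscore_columns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores (population sd); zero-variance columns map to 0."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(values)
    z[:, ok] = (values[:, ok] - mean[ok]) / sd[ok]
    return z, ok


def infer_pseudotime(
    m: ExpressionMatrix,
    ordering_genes: Sequence[str],
    root_spec: RootSpec,
) -> PseudotimeAssignment:
    """PC1-based pseudotime: z-score ordering genes, project on the first
    principal component, orient so the root is early, rank-transform to
    [0, 100] (average ranks for ties)."""
    if m.kind != "normalized":
        raise ValueError("infer_pseudotime expects a normalized matrix")
    present = set(m.gene_ids)
    shared = [g for g in ordering_genes if g in present]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} ordering genes found in the matrix; need >= 10")
    sub = m.subset_genes(shared).values
    z, ok = _zscore_columns(sub)
    if not ok.any():
        raise ValueError("ordering-gene submatrix is constant; no trajectory signal")
    z = z[:, ok]
    # first principal component via SVD of the centered (z-scored) submatrix
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pc1 = u[:, 0] * s[0]

    if isinstance(root_spec, GeneModule):
        root_genes = root_spec.shared_genes(m)
        if not root_genes:
            raise ValueError(f"root module {root_spec.name!r} shares no genes with the matrix")
        root_z, _ = _zscore_columns(m.subset_genes(root_genes).values)
        root_score = root_z.mean(axis=1)
        # high scorers of the root module are early -> want corr(score, t) < 0
        evidence = float(np.corrcoef(root_score, pc1)[0, 1])
    else:
        root_ids = set(root_spec)
        mask = np.array([c in root_ids for c in m.row_ids])
        if not mask.any():
            raise ValueError("no root cells found in the matrix")
        evidence = float(pc1[mask].mean() - pc1.mean())
    if evidence > 0:
        pc1 = -pc1
    # quantize before ranking so numerically identical cells (e.g. duplicated
    # rows, which SVD reproduces only to machine precision) tie exactly
    scale = np.max(np.abs(pc1)) or 1.0
    ranks = stats.rankdata(np.round(pc1 / scale, 9), method="average")
    n = ranks.size
    t = 100.0 * (ranks - 1.0) / (n - 1.0) if n > 1 else np.zeros(1)
    return PseudotimeAssignment(list(m.row_ids), t, orientation_evidence=evidence)


def bin_pseudotime(pt: PseudotimeAssignment, n_bins: int = 100) -> PseudotimeAssignment:
    """Assign equal-count bins 1..n_bins along t (sizes differ by at most 1).

    Ties in t are broken by lexicographic cell identifier for reproducibility;
    when the cell count is not divisible, the earliest bins take the extra
    cell.  Bin index increases with t.
    """
    n = len(pt.cell_ids)
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if n < n_bins:
        raise ValueError(f"cannot form {n_bins} bins from {n} cells")
    order = sorted(range(n), key=lambda i: (pt.t[i], pt.cell_ids[i]))
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    bins = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        for i in order[start:start + size]:
            bins[i] = b
        start += size
    return replace(pt, bin=bins, n_bins=n_bins)


def score_modules(
    m: ExpressionMatrix,
    modules: Sequence[GeneModule],
    pt: PseudotimeAssignment,
) -> tuple[BinProfile, pd.DataFrame]:
    """Per-cell and per-bin module scores plus bin centroids.

    Per-cell score: mean over module genes of gene-wise z-scored normalized
    expression (so scores average ~0 across all cells).  Per-bin score: mean
    of member cells' scores.  Centroids: per-bin mean normalized expression
    over the union of module genes (for projection references).
    """
    if m.kind != "normalized":
        raise ValueError("score_modules expects a normalized matrix")
    if pt.bin is None:
        raise ValueError("pseudotime must be binned first (bin_pseudotime)")
    if list(m.row_ids) != list(pt.cell_ids):
        raise ValueError("matrix rows and pseudotime cells do not match")
    z, _ = _zscore_columns(m.values)
    gene_idx = m.gene_indexer()
    cell_scores = {}
    union: list[str] = []
    seen = set()
    for mod in modules:
        shared = mod.shared_genes(m)
        if not shared:
            raise ValueError(f"module {mod.name!r} shares no genes with the matrix")
        cols = [gene_idx[g] for g in shared]
        cell_scores[mod.name] = z[:, cols].mean(axis=1)
        for g in shared:
            if g not in seen:
                seen.add(g)
                union.append(g)
    scores = pd.DataFrame(cell_scores, index=m.row_ids)

    n_bins = pt.n_bins
    bins = np.arange(1, n_bins + 1)
    bin_t = np.empty(n_bins)
    cells_per_bin = np.empty(n_bins, dtype=int)
    mod_scores = np.empty((n_bins, len(modules)))
    union_cols = [gene_idx[g] for g in union]
    centroids = np.empty((n_bins, len(union)))
    score_arr = scores.to_numpy()
    for b in bins:
        mask = pt.bin == b
        cells_per_bin[b - 1] = mask.sum()
        bin_t[b - 1] = pt.t[mask].mean()
        mod_scores[b - 1] = score_arr[mask].mean(axis=0)
        centroids[b - 1] = m.values[np.ix_(mask, union_cols)].mean(axis=0)
    profile = BinProfile(
        bins=bins,
        bin_t=bin_t,
        module_scores=pd.DataFrame(mod_scores, index=bins, columns=[mod.name for mod in modules]),
        bin_centroids=pd.DataFrame(centroids, index=bins, columns=union),
        cells_per_bin=cells_per_bin,
    )
    return profile, scores
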