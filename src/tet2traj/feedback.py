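"""Negative-feedback detection between TET2-target activation and EMT/WNT.

The feedback loop predicts that cells with high TET2-target activity (or
cells overexpressing TET2CD) up-regulate EMT/WNT less per unit of TET2-target
activation.  The detector regresses the EMT (or WNT) module score on the
TET2-target score per group, inside the mid-trajectory Type III window (bins
36-75 by default), and tests the slope difference by permuting group labels
within the window — no Gaussian assumption on the scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeedbackResult",
    "stratify_by_tet2",
    "windowed_feedback_test",
    "group_trajectory_summary",
]

DEFAULT_WINDOW = (36, 75)


@dataclass
class FeedbackResult:
    """Outcome of the windowed slope-difference test.

    ``delta_slope = slope_a - slope_b``; under feedback the control/TET2-low
    group (A) has the steeper EMT-vs-TET2 slope, so the one-sided test is
    'greater' by default.  ``group_means`` holds per-group within-window mean
    module scores.
    """

    window: tuple[int, int]
    group_a: str
    group_b: str
    slope_a: float
    slope_b: float
    delta_slope: float
    p_perm: float
    n_a: int
    n_b: int
    group_means: dict[str, dict[str, float]]


def stratify_by_tet2(scores: Sequence[float], cutoff_rule: str = "median") -> np.ndarray:
    """Split cells into 'high'/'low' TET2 strata (median split, ties to low)."""
    s = np.asarray(scores, dtype=float)
    if s.size < 20:
        raise ValueError(f"need >= 20 cells to stratify, got {s.size}")
    if cutoff_rule != "median":
        raise ValueError(f"unknown cutoff_rule {cutoff_rule!r}")
    if np.ptp(s) == 0:
        raise ValueError("all scores identical; no high/low split possible")
    cutoff = np.median(s)
    return np.where(s > cutoff, "high", "low").astype(object)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form OLS slope: cov(x, y) / var(x)."""
    vx = np.var(x)
    if vx == 0:
        raise ValueError("degenerate predictor: zero variance in TET2-target scores")
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def windowed_feedback_test(
    cell_scores: pd.DataFrame,
    bins: Sequence[int],
    labels: Sequence[str],
    groups: tuple[str, str],
    window: tuple[int, int] = DEFAULT_WINDOW,
    predictor: str = "TET2_TARGETS",
    response: str = "EMT_MARKERS",
    n_perm: int = 999,
    seed: int = 0,
    side: str = "greater",
) -> FeedbackResult:
    """Slope-difference permutation test inside the pseudotime window.

    ``cell_scores`` holds per-cell module scores (columns include
    ``predictor`` and ``response``); ``bins`` and ``labels`` align with its
    rows.  ``side='greater'`` tests slope(groups[0]) > slope(groups[1]).
    """
    if side not in ("greater", "less", "two-sided"):
        raise ValueError(f"side must be 'greater', 'less' or 'two-sided', got {side!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    bins = np.asarray(bins, dtype=int)
    labels = np.asarray(labels, dtype=object)
    if not (len(bins) == len(labels) == len(cell_scores)):
        raise ValueError("cell_scores, bins and labels must align")
    lo, hi = window
    if lo > hi or lo < 1:
        raise ValueError(f"invalid window {window}")
    in_win = (bins >= lo) & (bins <= hi)
    ga, gb = groups
    mask_a = in_win & (labels == ga)
    mask_b = in_win & (labels == gb)
    if mask_a.sum() < 10 or mask_b.sum() < 10:
        raise ValueError(
            f"need >= 10 cells per group inside the window; got {mask_a.sum()} ({ga}) "
            f"and {mask_b.sum()} ({gb})"
        )
    x = cell_scores[predictor].to_numpy()
    y = cell_scores[response].to_numpy()
    slope_a = _ols_slope(x[mask_a], y[mask_a])
    slope_b = _ols_slope(x[mask_b], y[mask_b])
    delta = slope_a - slope_b

    win_idx = np.flatnonzero(in_win & ((labels == ga) | (labels == gb)))
    xw, yw = x[win_idx], y[win_idx]
    is_a = labels[win_idx] == ga
    n_a_win = int(is_a.sum())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(win_idx.size)
        pa = perm[:n_a_win]
        pb = perm[n_a_win:]
        try:
            d = _ols_slope(xw[pa], yw[pa]) - _ols_slope(xw[pb], yw[pb])
        except ValueError:
            continue
        if side == "greater":
            count += d >= delta - 1e-12
        elif side == "less":
            count += d <= delta + 1e-12
        else:
            count += abs(d) >= abs(delta) - 1e-12
    p = (1 + count) / (1 + n_perm)

    module_cols = list(cell_scores.columns)
    group_means = {
        name: {c: float(cell_scores[c].to_numpy()[mask].mean()) for c in module_cols}
        for name, mask in ((ga, mask_a), (gb, mask_b))
    }
    return FeedbackResult(
        window=(lo, hi),
        group_a=ga,
        group_b=gb,
        slope_a=slope_a,
        slope_b=slope_b,
        delta_slope=delta,
        p_perm=float(p),
        n_a=int(mask_a.sum()),
        n_b=int(mask_b.sum()),
        group_means=group_means,
    )


def group_trajectory_summary(
    groups: Mapping[str, pd.DataFrame],
    order: Sequence[str] = ("PT", "MT_high", "MT_low"),
) -> pd.DataFrame:
    """Per-group mean module scores in a fixed presentation order.

    Mirrors the arrow plots connecting primary-tumor cells to TET2-high and
    TET2-low metastatic cells.  Every requested group must be present and
    non-empty.
    """
    rows = []
    for name in order:
        if name not in groups:
            raise ValueError(f"missing group {name!r}")
        df = groups[name]
        if len(df) == 0:
            raise ValueError(f"group {name!r} is empty")
        rows.append(df.mean(axis=0).rename(name))
    return pd.DataFrame(rows)
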