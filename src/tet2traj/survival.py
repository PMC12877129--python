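"""Four-category TET2-localization classifier and survival analysis.

Immunohistochemistry cohorts score, per tumor sample, the fraction of cells
with nuclear TET2.  Samples are classified into four localization categories
(nucleus only, nucleus major, cytoplasm major, cytoplasm only), cross-tabulated
against clinical stage, and compared by Kaplan-Meier / log-rank survival
analysis.  The Kaplan-Meier and log-rank machinery is delegated to lifelines;
this module owns the classification rule and the result containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "CATEGORIES",
    "CohortRecord",
    "SurvivalCurve",
    "CrosstabResult",
    "classify_sample",
    "crosstab_stage",
    "km_estimate",
    "km_median",
    "logrank_test",
]

#: Localization categories ordered from most to least nuclear TET2.
CATEGORIES = ("nucleus_only", "nucleus_major", "cytoplasm_major", "cytoplasm_only")

#: Default category boundaries on the nuclear fraction: below the first value
#: is "cytoplasm only", the last value and above is "nucleus only".  Lower
#: bounds are inclusive (0.9 -> nucleus_only, 0.5 -> nucleus_major, ...).
DEFAULT_BOUNDARIES = (0.1, 0.5, 0.9)


def classify_sample(
    nuclear_fraction: float,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> str:
    """Map a nuclear-TET2 fraction in [0, 1] to one of the four categories.

    The rule partitions [0, 1]: f >= b3 -> nucleus_only, b2 <= f < b3 ->
    nucleus_major, b1 <= f < b2 -> cytoplasm_major, f < b1 -> cytoplasm_only.
    Boundary values belong to the upper category (lower bound inclusive).
    """
    f = float(nuclear_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"nuclear_fraction must be in [0, 1], got {f}")
    b1, b2, b3 = boundaries
    if not 0.0 < b1 < b2 < b3 < 1.0:
        raise ValueError(f"boundaries must be strictly increasing within (0, 1), got {boundaries}")
    if f >= b3:
        return "nucleus_only"
    if f >= b2:
        return "nucleus_major"
    if f >= b1:
        return "cytoplasm_major"
    return "cytoplasm_only"


@dataclass
class CohortRecord:
    """One cohort sample: nuclear-TET2 fraction, stage and survival outcome.

    ``category`` is always consistent with ``nuclear_fraction`` under the
    classification rule; it is filled in automatically when omitted.  Extra
    per-sample annotations (e.g. a 5mC score) are passed through unmodified
    in ``extra``.
    """

    sample_id: str
    nuclear_fraction: float
    time: float
    event: int
    category: Optional[str] = None
    stage_dukes: Optional[str] = None
    stage_tnm: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.nuclear_fraction <= 1.0:
            raise ValueError(
                f"sample {self.sample_id!r}: nuclear_fraction {self.nuclear_fraction} outside [0, 1]"
            )
        if self.time < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative survival time {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample_id!r}: event flag must be 0 or 1, got {self.event}")
        expected = classify_sample(self.nuclear_fraction)
        if self.category is None:
            self.category = expected
        elif self.category != expected:
            raise ValueError(
                f"sample {self.sample_id!r}: category {self.category!r} inconsistent with "
                f"nuclear_fraction {self.nuclear_fraction} (expected {expected!r})"
            )


@dataclass
class CrosstabResult:
    """Category x stage contingency table with a chi-square test."""

    table: pd.DataFrame          # counts, categories x stages
    chi2: float                  # NaN when the test is undefined
    dof: int
    p_value: float
    n_skipped: int               # records without the requested stage field
    small_expected: bool         # any expected cell count < 5


def crosstab_stage(records: Sequence[CohortRecord], staging: str = "dukes") -> CrosstabResult:
    """Cross-tabulate localization category against clinical stage.

    Records missing the requested stage field are skipped with a warning and
    counted in ``n_skipped``.  The chi-square statistic (no continuity
    correction) is NaN, flagged via ``dof == 0``, for degenerate tables.
    """
    attr = {"dukes": "stage_dukes", "tnm": "stage_tnm"}.get(staging)
    if attr is None:
        raise ValueError(f"staging must be 'dukes' or 'tnm', got {staging!r}")
    kept = [r for r in records if getattr(r, attr) is not None]
    n_skipped = len(records) - len(kept)
    if n_skipped:
        warnings.warn(f"{n_skipped} record(s) missing the {staging} stage were skipped")
    if not kept:
        raise ValueError("no records carry the requested stage field")
    df = pd.DataFrame({
        "category": pd.Categorical(
            [r.category for r in kept],
            categories=[c for c in CATEGORIES if any(r.category == c for r in kept)],
        ),
        "stage": [getattr(r, attr) for r in kept],
    })
    table = pd.crosstab(df["category"], df["stage"])
    r, c = table.shape
    if r < 2 or c < 2:
        warnings.warn("degenerate contingency table: chi-square undefined")
        return CrosstabResult(table, float("nan"), 0, float("nan"), n_skipped, False)
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    small = bool((expected < 5).any())
    if small:
        warnings.warn("expected cell counts < 5; chi-square approximation may be poor")
    return CrosstabResult(table, float(chi2), int(dof), float(p), n_skipped, small)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``survival[i]`` is S(t) just after ``event_times[i]``; the estimate starts
    at 1 and is non-increasing.  Censored subjects remain at risk for events
    occurring at their own censoring time (events-first tie convention).
    """

    event_times: np.ndarray      # distinct times with >= 1 event
    at_risk: np.ndarray          # number at risk just before each event time
    n_events: np.ndarray         # events at each event time
    survival: np.ndarray         # S after each event time
    censor_times: np.ndarray     # times of censored observations


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Product-limit estimator S(t) = prod over event times (1 - d_i / n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table
    mask = tab["observed"].to_numpy() > 0
    event_times = tab.index.to_numpy(dtype=float)[mask]
    at_risk = tab["at_risk"].to_numpy(dtype=float)[mask]
    n_events = tab["observed"].to_numpy(dtype=float)[mask]
    survival = np.cumprod(1.0 - n_events / at_risk)
    return SurvivalCurve(
        event_times=event_times,
        at_risk=at_risk,
        n_events=n_events,
        survival=survival,
        censor_times=np.sort(t[e == 0]),
    )


def km_median(times: Sequence[float], events: Sequence[int]) -> float:
    """Median survival time (inf if the curve never drops below 0.5)."""
    kmf = KaplanMeierFitter().fit(np.asarray(times, float), np.asarray(events, int))
    return float(kmf.median_survival_time_)


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi-square statistic, df = k-1, p).

    Each group is a ``(times, events)`` pair.  Invariant to group order.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {i} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValueError("no events in any group; log-rank test undefined")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)
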