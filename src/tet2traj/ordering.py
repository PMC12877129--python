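"""Four-parameter logistic regression of binned module scores and event ordering.

Each module's per-bin score is fit against pseudotime with
``f(t) = base + amp / (1 + exp(-k (t - t50)))``; the event time of a module is
the pseudotime at which its min-max-normalized fitted curve crosses 0.5, which
for the logistic is exactly ``t50``.  Deactivating modules (negative ``amp``)
are reflected before comparison so every event is a "time of change" and
increasing and decreasing modules are comparable.  Modules are ordered by
event time, with bootstrap resampling of cells quantifying the stability of
each pairwise order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io import ExpressionMatrix, GeneModule
from .trajectory import PseudotimeAssignment, bin_pseudotime, score_modules

__all__ = [
    "LogisticFit",
    "EventOrder",
    "logistic4",
    "fit_logistic",
    "normalize_curve",
    "minmax_normalize",
    "event_time",
    "order_events",
    "bootstrap_order",
]


def logistic4(t, base, amp, k, t50):
    """Four-parameter logistic in pseudotime."""
    return base + amp / (1.0 + np.exp(-k * (np.asarray(t, float) - t50)))


@dataclass
class LogisticFit:
    """Result of fitting one module's binned scores.

    ``converged`` is False when the optimizer failed or the fit explains too
    little variance (r2 < r2_min); non-converged fits are excluded from event
    ordering rather than contributing spurious times.
    """

    module_name: str
    base: float
    amp: float
    k: float
    t50: float
    r2: float
    converged: bool

    def predict(self, t):
        return logistic4(t, self.base, self.amp, self.k, self.t50)


@dataclass
class EventOrder:
    """Modules sorted by event time, with optional bootstrap support.

    ``tied_pairs`` lists module pairs whose event times differ by less than
    the tie tolerance and are therefore not ordered with confidence.
    ``bootstrap_support[(a, b)]`` is the fraction of resamples in which module
    ``a``'s event precedes module ``b``'s (exact ties credit 0.5).
    """

    ordered: list[str]
    event_times: dict[str, float]
    tied_pairs: list[tuple[str, str]] = field(default_factory=list)
    bootstrap_support: Optional[dict[tuple[str, str], float]] = None
    n_dropped_resamples: int = 0


def _initial_guess(y: np.ndarray, t: np.ndarray) -> tuple[float, float, float, float]:
    """Data-driven starting point: base from early bins, amp from late-minus-
    early, t50 at the steepest smoothed change, k = 0.1."""
    n = y.size
    k_edge = max(3, n // 10)
    base0 = float(y[:k_edge].mean())
    amp0 = float(y[-k_edge:].mean() - base0)
    if amp0 == 0.0:
        amp0 = 1e-3
    win = min(5, n)
    kernel = np.ones(win) / win
    smooth = np.convolve(y, kernel, mode="valid")
    t_mid = np.convolve(t, kernel, mode="valid")
    d = np.diff(smooth)
    t50_0 = float(t_mid[np.argmax(np.abs(d))]) if d.size else float(t.mean())
    return base0, amp0, 0.1, float(np.clip(t50_0, 0.0, 100.0))


def fit_logistic(
    bin_scores: Sequence[float],
    bin_positions: Sequence[float],
    module_name: str = "",
    r2_min: float = 0.3,
) -> LogisticFit:
    """Least-squares four-parameter logistic fit of one module's bin scores.

    Bounds: k in (0, 10], t50 in [0, 100].  Requires >= 8 bins; non-finite
    scores are rejected.
    """
    y = np.asarray(bin_scores, dtype=float)
    t = np.asarray(bin_positions, dtype=float)
    if y.shape != t.shape:
        raise ValueError("bin_scores and bin_positions must have equal length")
    if y.size < 8:
        raise ValueError(f"need >= 8 bins to fit a logistic, got {y.size}")
    if not np.isfinite(y).all() or not np.isfinite(t).all():
        raise ValueError("non-finite bin scores or positions")
    p0 = _initial_guess(y, t)
    lower = [-np.inf, -np.inf, 1e-6, 0.0]
    upper = [np.inf, np.inf, 10.0, 100.0]
    p0 = tuple(np.clip(p0, lower, upper))
    try:
        popt, _ = curve_fit(
            logistic4, t, y, p0=p0, bounds=(lower, upper), maxfev=20_000
        )
        ok = True
    except (RuntimeError, ValueError):
        popt, ok = np.array(p0), False
    resid = y - logistic4(t, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else -np.inf
    converged = bool(ok and np.isfinite(r2) and r2 >= r2_min and popt[1] != 0)
    return LogisticFit(
        module_name=module_name,
        base=float(popt[0]),
        amp=float(popt[1]),
        k=float(popt[2]),
        t50=float(popt[3]),
        r2=r2,
        converged=converged,
    )


def minmax_normalize(y: np.ndarray) -> np.ndarray:
    """Scale a curve to range exactly [0, 1]; idempotent on [0, 1] curves."""
    y = np.asarray(y, dtype=float)
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant curve")
    return (y - lo) / (hi - lo)


def normalize_curve(fit: LogisticFit, grid: Sequence[float]) -> np.ndarray:
    """Fitted curve on ``grid``, min-max normalized to a rising [0, 1] scale.

    Deactivating modules (amp < 0) are reflected (1 - value) so every
    normalized curve climbs from 0 toward 1 as its change completes.
    """
    if not fit.converged:
        raise ValueError(f"cannot normalize a non-converged fit ({fit.module_name!r})")
    y = minmax_normalize(fit.predict(np.asarray(grid, float)))
    return 1.0 - y if fit.amp < 0 else y


def event_time(fit: LogisticFit) -> float:
    """Pseudotime at which the normalized curve crosses 0.5 (= t50 exactly)."""
    if not fit.converged:
        raise ValueError(f"no event time for non-converged fit ({fit.module_name!r})")
    return fit.t50


def order_events(fits: Sequence[LogisticFit], tie_eps: float = 1.0) -> EventOrder:
    """Sort converged fits by event time; near-ties are flagged unordered."""
    conv = [f for f in fits if f.converged]
    if len(conv) < 2:
        raise ValueError(f"need >= 2 converged fits to order events, got {len(conv)}")
    times = {f.module_name: event_time(f) for f in conv}
    ordered = sorted(times, key=lambda name: (times[name], name))
    tied = [
        (a, b)
        for i, a in enumerate(ordered)
        for b in ordered[i + 1:]
        if abs(times[a] - times[b]) < tie_eps
    ]
    return EventOrder(ordered=ordered, event_times=times, tied_pairs=tied)


def bootstrap_order(
    m: ExpressionMatrix,
    modules: Sequence[GeneModule],
    pt: PseudotimeAssignment,
    B: int = 50,
    seed: int = 0,
    r2_min: float = 0.3,
    tie_eps: float = 1.0,
) -> EventOrder:
    """Resample cells with replacement and re-run binning/scoring/fitting.

    ``bootstrap_support[(a, b)]`` is the fraction of usable resamples in which
    ``a``'s t50 precedes ``b``'s for each pair ordered (a before b) in the
    full-data result; exact t50 ties credit 0.5 to the pair.  Resamples with
    fewer than two converged fits are dropped and counted; more than 50%
    dropped is an error.
    """
    if B < 20:
        raise ValueError(f"B must be >= 20, got {B}")
    if pt.n_bins is None:
        raise ValueError("pseudotime must be binned before bootstrapping")
    full = _score_and_order(m, modules, pt, pt.n_bins, r2_min, tie_eps)
    pairs = [
        (a, b) for i, a in enumerate(full.ordered) for b in full.ordered[i + 1:]
    ]
    rng = np.random.default_rng(seed)
    n = m.n_rows
    support = {pair: 0.0 for pair in pairs}
    dropped = 0
    kept = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        ids = [f"{m.row_ids[i]}#{j}" for j, i in enumerate(idx)]
        mb = ExpressionMatrix(m.values[idx], ids, list(m.gene_ids), m.kind)
        ptb = PseudotimeAssignment(ids, pt.t[idx], pt.orientation_evidence)
        try:
            res = _score_and_order(mb, modules, ptb, pt.n_bins, r2_min, tie_eps)
        except ValueError:
            dropped += 1
            continue
        kept += 1
        for a, b in pairs:
            ta, tb = res.event_times.get(a), res.event_times.get(b)
            if ta is None or tb is None:
                support[(a, b)] += 0.5    # pair unresolved in this resample
            elif ta == tb:
                support[(a, b)] += 0.5
            elif ta < tb:
                support[(a, b)] += 1.0
    if dropped > B / 2:
        raise ValueError(f"{dropped}/{B} bootstrap resamples failed to converge")
    return EventOrder(
        ordered=full.ordered,
        event_times=full.event_times,
        tied_pairs=full.tied_pairs,
        bootstrap_support={p: s / kept for p, s in support.items()},
        n_dropped_resamples=dropped,
    )


def _score_and_order(m, modules, pt, n_bins, r2_min, tie_eps) -> EventOrder:
    ptb = bin_pseudotime(pt, n_bins)
    profile, _ = score_modules(m, modules, ptb)
    fits = [
        fit_logistic(profile.module_scores[mod.name], profile.bin_t, mod.name, r2_min)
        for mod in modules
    ]
    return order_events(fits, tie_eps)
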