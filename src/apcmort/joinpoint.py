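"""Joinpoint (continuous piecewise-linear) regression with BIC selection.

Fits y on the broken-line basis {1, x, (x - tau_j)_+} by exact least
squares, searches joinpoint positions exhaustively over a candidate grid
(the observed interior x-values by default), and selects the number of
joinpoints k by BIC_k = n ln(SSE_k / n) + p_k ln(n) with p_k = 2 + 2k
(intercept, slope, and a position plus a slope change per joinpoint);
smaller BIC wins, ties go to the smaller k.  Intended for trend-change
location in estimated cohort/period effect series (log-RR scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "JoinpointFit",
    "fit_fixed_joinpoints",
    "search_joinpoints",
    "select_by_bic",
    "joinpoint_analysis",
]

@dataclass
class JoinpointFit:
    """A fitted continuous broken-line model.

    ``tss`` (total sum of squares of y about its mean) only sets the scale
    below which an SSE counts as an exact fit.
    """

    joinpoint_positions: tuple[float, ...]
    intercept: float
    segment_slopes: tuple[float, ...]
    sse: float
    n: int
    tss: float = 1.0

    @property
    def n_joinpoints(self) -> int:
        return len(self.joinpoint_positions)

    @property
    def bic(self) -> float:
        """n ln(SSE/n) + p ln(n), p = 2 + 2k; -inf for an exact fit."""
        if self.sse <= 1e-12 * max(self.tss, 1e-30):
            return float("-inf")
        p = 2 + 2 * self.n_joinpoints
        return float(self.n * np.log(self.sse / self.n) + p * np.log(self.n))

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        base = self.segment_slopes[0]
        y = self.intercept + base * x
        for tau, s_prev, s_next in zip(
            self.joinpoint_positions, self.segment_slopes[:-1], self.segment_slopes[1:]
        ):
            y += (s_next - s_prev) * np.clip(x - tau, 0.0, None)
        return y


def _segment_counts(x: np.ndarray, positions: Sequence[float]) -> list[int]:
    bounds = [-np.inf, *positions, np.inf]
    return [
        int(np.sum((x > lo) & (x <= hi))) if np.isfinite(lo) else int(np.sum(x <= hi))
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]


def fit_fixed_joinpoints(
    x, y, positions: Sequence[float], min_obs: int = 2
) -> JoinpointFit:
    """Exact least-squares broken-line fit with fixed joinpoint positions.

    ``positions`` must be strictly inside (min x, max x), distinct, and
    leave at least ``min_obs`` observations in every induced segment.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    positions = tuple(sorted(float(t) for t in positions))
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate joinpoint positions")
    for tau in positions:
        if not (x[0] < tau < x[-1]):
            raise ValueError(f"joinpoint {tau} outside the interior of x")
    if any(c < min_obs for c in _segment_counts(x, positions)):
        raise ValueError("a segment has fewer than min_obs observations")

    cols = [np.ones_like(x), x] + [np.clip(x - tau, 0.0, None) for tau in positions]
    X = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("ill-conditioned broken-line basis")
    resid = y - X @ coef
    slopes = np.concatenate([[coef[1]], coef[1] + np.cumsum(coef[2:])])
    centred = y - y.mean()
    return JoinpointFit(
        joinpoint_positions=positions,
        intercept=float(coef[0]),
        segment_slopes=tuple(float(s) for s in slopes),
        sse=float(resid @ resid),
        n=len(x),
        tss=float(centred @ centred),
    )


def search_joinpoints(
    x,
    y,
    max_k: int = 3,
    candidate_grid: Optional[Sequence[float]] = None,
    min_obs: int = 2,
) -> list[JoinpointFit]:
    """SSE-minimal fit per k = 0..max_k by exhaustive grid search.

    Candidates default to the observed x-values minus the endpoints.  If
    ``max_k`` is infeasible under the ``min_obs`` constraint it is reduced
    (the returned list is simply shorter).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if candidate_grid is None:
        candidate_grid = x[1:-1]
    candidates = sorted(float(t) for t in candidate_grid)
    best: list[JoinpointFit] = [fit_fixed_joinpoints(x, y, (), min_obs)]
    for k in range(1, max_k + 1):
        best_k: Optional[JoinpointFit] = None
        for combo in combinations(candidates, k):
            try:
                fit = fit_fixed_joinpoints(x, y, combo, min_obs)
            except ValueError:
                continue
            if best_k is None or fit.sse < best_k.sse:
                best_k = fit
        if best_k is None:
            break  # min_obs makes k (and any larger k) infeasible
        best.append(best_k)
    return best


def select_by_bic(fits: Sequence[JoinpointFit]) -> JoinpointFit:
    """Smallest-BIC fit; exact ties (including -inf) go to the smaller k."""
    if not fits:
        raise ValueError("no fits to select from")
    ordered = sorted(fits, key=lambda f: f.n_joinpoints)
    best = ordered[0]
    for fit in ordered[1:]:
        if fit.bic < best.bic:
            best = fit
    return best


def joinpoint_analysis(
    x, y, max_k: int = 3, min_obs: int = 2, candidate_grid=None
) -> JoinpointFit:
    """Convenience: search 0..max_k joinpoints and select by BIC."""
    return select_by_bic(search_joinpoints(x, y, max_k, candidate_grid, min_obs))
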