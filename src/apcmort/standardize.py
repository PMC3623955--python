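"""Direct age standardisation to the WHO World Standard Population.

An age-standardised rate (ASR) is the weighted average of age-specific
rates, ASR = sum_a w_a r_a, with fixed standard-population weights w_a.
Because the study grid covers ages 30+ only, the full standard is
restricted to the grid's age range (collapsing 75-79/80-84/85+ into the
open-ended 75+ group) and renormalised; the result is reported as a 30+
age-standardised rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lexis import LexisGrid

__all__ = [
    "StandardPopulation",
    "who_world_standard",
    "restrict_weights",
    "direct_asr",
    "asr_from_draws",
]

# WHO World Standard Population (Ahmad et al. 2001, "Age standardization of
# rates: a new WHO standard", GPE Discussion Paper 31), percentages by
# 5-year age group 0-4 ... 80-84 plus 85+ (85-89/90-94/95-99/100+ collapsed).
_WHO_EDGES = tuple(range(0, 90, 5))
_WHO_WEIGHTS = (
    8.86, 8.69, 8.60, 8.47, 8.22, 7.93, 7.61, 7.15, 6.59,
    6.04, 5.37, 4.55, 3.72, 2.96, 2.21, 1.52, 0.91, 0.635,
)


@dataclass(frozen=True)
class StandardPopulation:
    """Age weights keyed by age-group lower edge; last group open-ended."""

    age_lower_edges: tuple[int, ...]
    weights: tuple[float, ...]
    label: str = "WHO World Standard"

    def __post_init__(self) -> None:
        if len(self.age_lower_edges) != len(self.weights):
            raise ValueError("edges and weights must have equal length")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()


def who_world_standard() -> StandardPopulation:
    """The full WHO World Standard in 5-year groups 0-4 ... 85+."""
    return StandardPopulation(age_lower_edges=_WHO_EDGES, weights=_WHO_WEIGHTS)


def restrict_weights(
    full_standard: StandardPopulation, grid: LexisGrid
) -> StandardPopulation:
    """Restrict a standard population to the grid's age range.

    Weights below the grid's first age group are dropped; weights at or
    above the open-ended top edge are collapsed into the top group; the
    result is renormalised to sum to 1.
    """
    lo = grid.age_lower_edges[0]
    top = grid.age_lower_edges[-1]
    out = np.zeros(grid.n_age, dtype=float)
    for edge, w in zip(full_standard.age_lower_edges, full_standard.weights):
        if edge < lo:
            continue
        a = grid.age_index_of(edge) if edge < top else grid.n_age
        if a is None:
            continue
        out[a - 1] += w
    if np.any(out <= 0):
        missing = [grid.age_label(i + 1) for i in np.nonzero(out <= 0)[0]]
        raise ValueError(f"standard has no weight covering grid groups {missing}")
    out /= out.sum()
    return StandardPopulation(
        age_lower_edges=grid.age_lower_edges,
        weights=tuple(out),
        label=f"{full_standard.label} (restricted {lo}+)",
    )


def direct_asr(age_rates, std: StandardPopulation) -> float:
    """Directly standardised rate: sum_a w_a r_a (same units as the rates)."""
    rates = np.asarray(age_rates, dtype=float)
    w = std.normalized_weights
    if rates.shape[-1] != w.shape[0]:
        raise ValueError(
            f"expected {w.shape[0]} age-specific rates, got {rates.shape[-1]}"
        )
    return float(rates @ w) if rates.ndim == 1 else rates @ w


def asr_from_draws(rate_draws, std: StandardPopulation):
    """Posterior mean and equal-tailed 95% credible interval of the ASR.

    ``rate_draws`` is draws x n_age; the ASR is computed per draw, then
    summarised by the mean and the 2.5%/97.5% empirical quantiles
    (linear-interpolation definition).
    """
    draws = np.asarray(rate_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need a draws x n_age matrix with >= 2 draws")
    asr = draws @ std.normalized_weights
    lo, hi = np.quantile(asr, [0.025, 0.975])
    return float(asr.mean()), float(lo), float(hi)
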