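"""Projection of mortality rates via the RW2 predictive distribution.

Period and cohort effects are extended beyond the observed window by
sampling the second-order random-walk forward predictive per posterior
draw: e_{K+j} = 2 e_{K+j-1} - e_{K+j-2} + eps, eps ~ N(0, sigma2_draw).
Innovations are included (not set to zero) so projected rates carry
predictive uncertainty, and each draw uses its own sigma2, propagating
hyperparameter uncertainty.  Projecting h extra periods needs exactly h
extra cohort effects: the youngest age group in the last projected period
sits on cohort diagonal K + h.

Age-standardised rates need no future population denominators (the ASR is
a function of rates alone); projected death counts are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .apc import APCPosterior
from .lexis import LexisGrid, cohort_index
from .standardize import StandardPopulation

__all__ = [
    "ProjectionResult",
    "extend_effects",
    "project_rates",
    "asr_projection_series",
]


@dataclass
class ProjectionResult:
    """Extended effect draws and (once projected) future age-specific rates."""

    grid: LexisGrid
    n_ahead: int
    extended_beta: np.ndarray  # draws x (n_period + n_ahead)
    extended_gamma: np.ndarray  # draws x (n_cohorts + n_ahead)
    projected_rates: Optional[np.ndarray] = None  # draws x n_age x n_ahead, per 1e5

    @property
    def future_period_start_years(self) -> list[int]:
        first = self.grid.period_start_years[-1] + self.grid.period_width
        return [first + j * self.grid.period_width for j in range(self.n_ahead)]

    @property
    def future_period_labels(self) -> list[str]:
        return [
            f"{s}-{s + self.grid.period_width - 1}"
            for s in self.future_period_start_years
        ]

    @property
    def future_period_centers(self) -> list[float]:
        return [
            s + (self.grid.period_width - 1) / 2.0
            for s in self.future_period_start_years
        ]


def _rw2_extend(draws: np.ndarray, sigma2: np.ndarray, n_ahead: int, rng) -> np.ndarray:
    """Append n_ahead RW2 predictive steps to each row of ``draws``."""
    nd, k = draws.shape
    out = np.empty((nd, k + n_ahead))
    out[:, :k] = draws
    sd = np.sqrt(sigma2)
    for j in range(n_ahead):
        eps = rng.standard_normal(nd) * sd
        out[:, k + j] = 2.0 * out[:, k + j - 1] - out[:, k + j - 2] + eps
    return out


def extend_effects(
    posterior: APCPosterior, n_ahead: int = 3, seed: int = 0
) -> ProjectionResult:
    """Sample RW2 predictive extensions of the period and cohort effects.

    Applied independently to beta and gamma, per retained draw, using that
    draw's own innovation variance.  With sigma2 = 0 the extension is the
    exact linear extrapolation of the last two effects.
    """
    if n_ahead < 1:
        raise ValueError("n_ahead must be >= 1")
    spec = posterior.spec
    if not (spec.include_period and spec.include_cohort):
        raise ValueError("projection requires a model with period and cohort effects")
    rng = np.random.default_rng(seed)
    sigma2 = posterior.sigma2_draws()
    ext_beta = _rw2_extend(posterior.beta_draws(), sigma2[:, 1], n_ahead, rng)
    ext_gamma = _rw2_extend(posterior.gamma_draws(), sigma2[:, 2], n_ahead, rng)
    return ProjectionResult(
        grid=spec.grid,
        n_ahead=n_ahead,
        extended_beta=ext_beta,
        extended_gamma=ext_gamma,
    )


def project_rates(
    posterior: APCPosterior, extension: ProjectionResult, grid: Optional[LexisGrid] = None
) -> ProjectionResult:
    """Projected age-specific rate draws (per 100,000) for future periods.

    For future period index p' = P + j and age a the log rate is
    mu + alpha_a + beta_{p'} + gamma_{A - a + p'}; the youngest age in the
    last projected period requires cohort K + n_ahead, so all projected
    cohort effects are consumed.
    """
    grid = grid or posterior.spec.grid
    A, P = grid.n_age, grid.n_period
    nd = posterior.n_draws
    if extension.extended_beta.shape[0] != nd:
        raise ValueError("extension is not aligned with the posterior draws")
    h = extension.n_ahead
    need_cohort = cohort_index(1, P + h, grid)
    if extension.extended_gamma.shape[1] < need_cohort:
        raise ValueError(
            f"projection needs cohort effects up to index {need_cohort}, "
            f"got {extension.extended_gamma.shape[1]}"
        )
    mu = posterior.mu_draws()
    alpha = posterior.alpha_draws()
    rates = np.empty((nd, A, h))
    for j in range(h):
        p1 = P + 1 + j  # 1-based future period index
        coh = np.array([cohort_index(a, p1, grid) - 1 for a in range(1, A + 1)])
        eta = (
            mu[:, None]
            + alpha
            + extension.extended_beta[:, p1 - 1][:, None]
            + extension.extended_gamma[:, coh]
        )
        rates[:, :, j] = 1e5 * np.exp(eta)
    extension.projected_rates = rates
    return extension


def asr_projection_series(
    posterior: APCPosterior,
    projection: ProjectionResult,
    std: StandardPopulation,
) -> pd.DataFrame:
    """Observed-plus-projected age-standardised rate series with 95% CrIs.

    Observed periods use the fitted rates from the posterior draws; future
    periods use the projected rate draws.  One row per period:
    ``sex,income,period,period_center,asr,asr_lo,asr_hi,observed_or_projected``.
    """
    if projection.projected_rates is None:
        raise ValueError("call project_rates before building the ASR series")
    grid = posterior.spec.grid
    w = std.normalized_weights
    fitted = posterior.fitted_rate_draws()  # draws x A x P
    asr_obs = np.einsum("dap,a->dp", fitted, w)
    asr_fut = np.einsum("dah,a->dh", projection.projected_rates, w)
    rows = []
    counts = posterior.counts
    for p in range(grid.n_period):
        draws = asr_obs[:, p]
        lo, hi = np.quantile(draws, [0.025, 0.975])
        rows.append(
            {
                "sex": counts.sex,
                "income": counts.income_group,
                "period": grid.period_label(p + 1),
                "period_center": grid.period_center(p + 1),
                "asr": float(draws.mean()),
                "asr_lo": float(lo),
                "asr_hi": float(hi),
                "observed_or_projected": "observed",
            }
        )
    for j in range(projection.n_ahead):
        draws = asr_fut[:, j]
        lo, hi = np.quantile(draws, [0.025, 0.975])
        rows.append(
            {
                "sex": counts.sex,
                "income": counts.income_group,
                "period": projection.future_period_labels[j],
                "period_center": projection.future_period_centers[j],
                "asr": float(draws.mean()),
                "asr_lo": float(lo),
                "asr_hi": float(hi),
                "observed_or_projected": "projected",
            }
        )
    return pd.DataFrame(rows)
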