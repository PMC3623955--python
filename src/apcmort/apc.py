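"""Bayesian Poisson age-period-cohort model with random-walk priors.

The model
---------
Deaths in Lexis cell (a, p) are Poisson,

    D_ap ~ Poisson(N_ap * lambda_ap),
    log lambda_ap = mu + alpha_a + beta_p + gamma_c,   c = A - a + p,

with second-order Gaussian autoregressive (RW2) priors on each effect
vector: each element's prior mean is the linear extrapolation of its two
predecessors, e_k | e_{k-1}, e_{k-2} ~ N(2 e_{k-1} - e_{k-2}, sigma^2),
flat on the first two elements.  Gamma hyperpriors sit on the RW2
precisions 1/sigma^2 and a diffuse normal prior on the intercept mu.

Because cohort = period - age, the three effect dimensions are linearly
aliased; identifiable estimates are obtained by fixing reference
categories: the second and penultimate period effects and the central
cohort effect are zero (and the age curve is centred against the
intercept).  The constraints are enforced by an exact affine transform that
leaves every fitted log-rate unchanged, applied to every retained state.

Inference is by MCMC: adaptive random-walk Metropolis updates for the
intercept and effects (one scalar at a time, all chains advanced in
lock-step), conjugate Gibbs updates for the RW2 precisions, five chains
from over-dispersed starting points by default, split-chain Gelman-Rubin
R-hat to set the burn-in, and DIC (posterior mean deviance plus effective
parameter count pD) for model comparison across age/period/cohort
submodels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .lexis import LexisGrid, StratumCounts, cohort_index

__all__ = [
    "APCModelSpec",
    "APCParameters",
    "MCMCConfig",
    "DICResult",
    "APCPosterior",
    "log_rate",
    "log_rate_matrix",
    "loglik",
    "rw2_logprior",
    "apply_constraints",
    "split_rhat",
    "sample_posterior",
    "dic",
    "relative_risks",
    "model_comparison",
    "save_posterior",
    "load_posterior",
]


# ---------------------------------------------------------------------------
# Model specification and parameter container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class APCModelSpec:
    """Which effect dimensions enter the model, plus priors and references.

    ``hyper_shape``/``hyper_rate`` parameterise the Gamma hyperprior on each
    RW2 precision (the weakly-informative Gamma(0.001, 0.001) convention by
    default); ``mu_prior_var`` is the variance of the diffuse normal prior
    on the intercept.
    """

    grid: LexisGrid
    include_age: bool = True
    include_period: bool = True
    include_cohort: bool = True
    hyper_shape: float = 1e-3
    hyper_rate: float = 1e-3
    mu_prior_var: float = 1e6

    def __post_init__(self) -> None:
        if not (self.include_age or self.include_period or self.include_cohort):
            raise ValueError("at least one effect dimension must be included")
        if self.include_period and self.grid.n_period < 3:
            raise ValueError("period constraints degenerate for n_period < 3")

    @property
    def ref_period_indices(self) -> tuple[int, int]:
        """1-based (second, penultimate) period reference categories."""
        return (2, self.grid.n_period - 1)

    @property
    def ref_cohort_index(self) -> int:
        """1-based central cohort (floor((K+1)/2) for even K)."""
        return (self.grid.n_cohorts + 1) // 2

    @property
    def label(self) -> str:
        parts = [
            name
            for flag, name in [
                (self.include_age, "age"),
                (self.include_period, "period"),
                (self.include_cohort, "cohort"),
            ]
            if flag
        ]
        return "+".join(parts)


@dataclass
class APCParameters:
    """One parameter state: intercept, effect vectors, RW2 variances."""

    mu: float
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    sigma2_alpha: float = 1.0
    sigma2_beta: float = 1.0
    sigma2_gamma: float = 1.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        for s in (self.sigma2_alpha, self.sigma2_beta, self.sigma2_gamma):
            if s <= 0:
                raise ValueError("RW2 variances must be positive")


# ---------------------------------------------------------------------------
# Likelihood and priors
# ---------------------------------------------------------------------------


def _cohort_cell_map(grid: LexisGrid) -> np.ndarray:
    """0-based cohort index per (age, period) cell."""
    a = np.arange(grid.n_age)[:, None]
    p = np.arange(grid.n_period)[None, :]
    return (grid.n_age - 1 - a) + p


def log_rate_matrix(
    params: APCParameters, grid: LexisGrid, spec: Optional[APCModelSpec] = None
) -> np.ndarray:
    """n_age x n_period matrix of log rates per person-year."""
    inc_a = spec.include_age if spec is not None else True
    inc_p = spec.include_period if spec is not None else True
    inc_c = spec.include_cohort if spec is not None else True
    eta = np.full((grid.n_age, grid.n_period), params.mu, dtype=float)
    if inc_a:
        eta += params.alpha[:, None]
    if inc_p:
        eta += params.beta[None, :]
    if inc_c:
        eta += params.gamma[_cohort_cell_map(grid)]
    return eta


def log_rate(
    params: APCParameters,
    age_idx: int,
    period_idx: int,
    grid: LexisGrid,
    spec: Optional[APCModelSpec] = None,
) -> float:
    """Log rate eta = mu + alpha_a + beta_p + gamma_c at a single cell."""
    inc_a = spec.include_age if spec is not None else True
    inc_p = spec.include_period if spec is not None else True
    inc_c = spec.include_cohort if spec is not None else True
    c = cohort_index(age_idx, period_idx, grid)
    eta = params.mu
    if inc_a:
        eta += float(params.alpha[age_idx - 1])
    if inc_p:
        eta += float(params.beta[period_idx - 1])
    if inc_c:
        eta += float(params.gamma[c - 1])
    return eta


def loglik(
    params: APCParameters,
    counts: StratumCounts,
    spec: Optional[APCModelSpec] = None,
) -> float:
    """Poisson log likelihood sum_cells [D log(N lambda) - N lambda - log D!]."""
    if counts.person_years is None:
        raise ValueError("counts must carry person_years")
    D = counts.deaths.astype(float)
    N = counts.person_years
    eta = log_rate_matrix(params, counts.grid, spec)
    return float(np.sum(D * (np.log(N) + eta) - N * np.exp(eta) - gammaln(D + 1)))


def rw2_logprior(effects, sigma2: float) -> float:
    """Log density of the forward second-order autoregressive prior.

    sum_{k>=3} log N(e_k | 2 e_{k-1} - e_{k-2}, sigma2), i.e. a Gaussian
    penalty on the second differences, flat (contribution 0) on the first
    two elements.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    e = np.asarray(effects, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 effects for an RW2 prior")
    d2 = np.diff(e, n=2)
    return float(
        -0.5 * d2.size * math.log(2 * math.pi * sigma2) - 0.5 * np.sum(d2**2) / sigma2
    )


# ---------------------------------------------------------------------------
# Identifiability constraints
# ---------------------------------------------------------------------------


def _constrain_arrays(mu, alpha, beta, gamma, spec: APCModelSpec):
    """Affine constraint transform on chain-stacked arrays, in place.

    Exploits c = A - a + p: an affine function u + v*p of period splits into
    v*a (absorbed by alpha), v*c (absorbed by gamma) and u - v*A (absorbed
    by mu), leaving every fitted log-rate unchanged.  The two-point period
    detilt applies only to the full model, where the trend aliasing exists;
    otherwise each included effect is only re-levelled.
    """
    grid = spec.grid
    A, P, K = grid.n_age, grid.n_period, grid.n_cohorts
    full = spec.include_age and spec.include_period and spec.include_cohort
    if full:
        r1, r2 = spec.ref_period_indices
        if r2 <= r1:
            raise ValueError("degenerate period references (grid too small)")
        v = (beta[:, r2 - 1] - beta[:, r1 - 1]) / (r2 - r1)
        u = beta[:, r1 - 1] - v * r1
        beta -= u[:, None] + v[:, None] * np.arange(1, P + 1)
        alpha += v[:, None] * np.arange(1, A + 1)
        gamma += v[:, None] * np.arange(1, K + 1)
        mu += u - v * A
    elif spec.include_period:
        r1 = spec.ref_period_indices[0]
        u = beta[:, r1 - 1].copy()
        beta -= u[:, None]
        mu += u
    if spec.include_cohort:
        g0 = gamma[:, spec.ref_cohort_index - 1].copy()
        gamma -= g0[:, None]
        mu += g0
    if spec.include_age:
        m = alpha.mean(axis=1)
        alpha -= m[:, None]
        mu += m
    return mu, alpha, beta, gamma


def apply_constraints(params: APCParameters, spec: APCModelSpec) -> APCParameters:
    """Return the constrained representative of a raw parameter state.

    After the transform beta[2] = beta[P-1] = 0, gamma[central] = 0 and
    mean(alpha) = 0 (full model), with all adjustments absorbed into mu,
    alpha and gamma so the fitted log-rate surface is bit-for-bit the same
    function of (a, p).
    """
    mu = np.array([params.mu], dtype=float)
    alpha = params.alpha[None, :].astype(float).copy()
    beta = params.beta[None, :].astype(float).copy()
    gamma = params.gamma[None, :].astype(float).copy()
    mu, alpha, beta, gamma = _constrain_arrays(mu, alpha, beta, gamma, spec)
    return replace(
        params, mu=float(mu[0]), alpha=alpha[0], beta=beta[0], gamma=gamma[0]
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def split_rhat(chains) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Each chain is halved; with m draws in each of k split sequences,
    R-hat = sqrt(((m-1)/m W + B/m) / W) with W the mean within-sequence
    variance and B = m x variance of sequence means.  Zero within-sequence
    variance is reported as 1.0 when the sequences agree and +inf (flagged
    degenerate) when they sit at distinct constants, never NaN.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    n = x.shape[1]
    half = n // 2
    seq = x[:, : 2 * half].reshape(-1, half)
    means = seq.mean(axis=1)
    W = float(seq.var(axis=1, ddof=1).mean())
    B = half * float(means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_plus = (half - 1) / half * W + B / half
    return float(math.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# MCMC sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_keep_total`` draws are retained in total across chains after an
    adaptive burn-in that runs (in blocks of ``check_every`` iterations,
    after at least ``min_burn_in``) until every monitored split R-hat drops
    below ``rhat_threshold``, or ``max_burn_in`` is reached.  Step sizes
    adapt toward ``target_accept`` during burn-in only.  ``init_jitter``
    scales the over-dispersion of chain starting points.
    """

    n_chains: int = 5
    n_keep_total: int = 40000
    thin: int = 1
    seed: int = 0
    max_burn_in: int = 20000
    min_burn_in: int = 1000
    check_every: int = 500
    rhat_threshold: float = 1.05
    target_accept: float = 0.44
    init_jitter: float = 0.3

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_keep_total < 1 or self.thin < 1:
            raise ValueError("invalid MCMC configuration")


@dataclass
class DICResult:
    """Deviance information criterion summary: dic = dbar + pd."""

    dbar: float
    d_at_mean: float

    @property
    def pd(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


@dataclass
class APCPosterior:
    """Multi-chain posterior draws with convergence and fit summaries.

    Effect arrays are chains x kept x dim; every retained state satisfies
    the reference-category constraints.  ``converged`` is False when the
    R-hat criterion was still unmet at ``max_burn_in`` (an explicit
    convergence-failure result carrying its diagnostics).
    """

    spec: APCModelSpec
    counts: StratumCounts
    mcmc: MCMCConfig
    mu: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    sigma2: np.ndarray  # chains x kept x 3 (alpha, beta, gamma)
    deviance: np.ndarray
    rhat: pd.Series
    burn_in_used: int
    converged: bool

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_kept(self) -> int:
        return self.mu.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_kept

    def mu_draws(self) -> np.ndarray:
        return self.mu.reshape(-1)

    def alpha_draws(self) -> np.ndarray:
        return self.alpha.reshape(-1, self.alpha.shape[-1])

    def beta_draws(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def gamma_draws(self) -> np.ndarray:
        return self.gamma.reshape(-1, self.gamma.shape[-1])

    def sigma2_draws(self) -> np.ndarray:
        return self.sigma2.reshape(-1, 3)

    def posterior_mean_params(self) -> APCParameters:
        """Posterior means of all parameters (constraints are linear, so the
        mean state is itself constrained)."""
        s2 = self.sigma2_draws()
        with np.errstate(invalid="ignore"):
            s2m = np.nanmean(s2, axis=0)
        s2m = np.where(np.isfinite(s2m) & (s2m > 0), s2m, 1.0)
        return APCParameters(
            mu=float(self.mu_draws().mean()),
            alpha=self.alpha_draws().mean(axis=0),
            beta=self.beta_draws().mean(axis=0),
            gamma=self.gamma_draws().mean(axis=0),
            sigma2_alpha=float(s2m[0]),
            sigma2_beta=float(s2m[1]),
            sigma2_gamma=float(s2m[2]),
        )

    def fitted_rate_draws(self) -> np.ndarray:
        """Draws x n_age x n_period fitted rates per 100,000 person-years."""
        grid = self.spec.grid
        cmap = _cohort_cell_map(grid)
        eta = self.mu_draws()[:, None, None] + np.zeros(
            (self.n_draws, grid.n_age, grid.n_period)
        )
        if self.spec.include_age:
            eta += self.alpha_draws()[:, :, None]
        if self.spec.include_period:
            eta += self.beta_draws()[:, None, :]
        if self.spec.include_cohort:
            eta += self.gamma_draws()[:, cmap]
        return 1e5 * np.exp(eta)

    def summaries(self) -> pd.DataFrame:
        """Per-parameter posterior mean, 95% CrI and R-hat."""
        rows = []
        for name, draws in _named_draws(self):
            lo, hi = np.quantile(draws, [0.025, 0.975])
            rows.append(
                {
                    "parameter": name,
                    "mean": float(draws.mean()),
                    "lo95": float(lo),
                    "hi95": float(hi),
                    "rhat": float(self.rhat.get(name, np.nan)),
                }
            )
        return pd.DataFrame(rows)


def _named_draws(post: APCPosterior):
    yield "mu", post.mu_draws()
    if post.spec.include_age:
        for a in range(post.alpha.shape[-1]):
            yield f"alpha[{a + 1}]", post.alpha_draws()[:, a]
    if post.spec.include_period:
        for p in range(post.beta.shape[-1]):
            yield f"beta[{p + 1}]", post.beta_draws()[:, p]
    if post.spec.include_cohort:
        for c in range(post.gamma.shape[-1]):
            yield f"gamma[{c + 1}]", post.gamma_draws()[:, c]
    for k, name in enumerate(("sigma2_alpha", "sigma2_beta", "sigma2_gamma")):
        if [post.spec.include_age, post.spec.include_period, post.spec.include_cohort][k]:
            yield name, post.sigma2_draws()[:, k]


def _penalty_matrix(k: int) -> np.ndarray:
    """RW2 penalty Q = D2' D2 (so e' Q e is the second-difference SS)."""
    if k < 3:
        return np.zeros((k, k))
    d2 = np.zeros((k - 2, k))
    for i in range(k - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d2.T @ d2


class _Sampler:
    """Metropolis-within-Gibbs kernel, all chains advanced in lock-step."""

    _KIND_TO_TAU = {"alpha": 0, "beta": 1, "gamma": 2}

    def __init__(self, counts: StratumCounts, spec: APCModelSpec, mcmc: MCMCConfig):
        if counts.person_years is None:
            raise ValueError("counts must carry person_years")
        self.spec = spec
        self.mcmc = mcmc
        grid = spec.grid
        self.A, self.P, self.K = grid.n_age, grid.n_period, grid.n_cohorts
        self.D = counts.deaths.astype(float)
        self.N = counts.person_years
        self.logN = np.log(self.N)
        self.DlogN = float((self.D * self.logN).sum())
        self.DlogfactD = float(gammaln(self.D + 1).sum())
        self.cmap = _cohort_cell_map(grid)
        self.coh_cells = [np.nonzero(self.cmap == c) for c in range(self.K)]
        self.rowD = self.D.sum(axis=1)
        self.colD = self.D.sum(axis=0)
        self.cohD = np.array([self.D[cells].sum() for cells in self.coh_cells])
        self.Dtot = float(self.D.sum())
        self.rng = np.random.default_rng(mcmc.seed)
        C = mcmc.n_chains
        self.C = C

        # over-dispersed, chain-specific starting points around crude rates
        mu0 = math.log((self.Dtot + 0.5) / self.N.sum())
        alpha0 = np.log((self.rowD + 0.5) / self.N.sum(axis=1)) - mu0
        alpha0 -= alpha0.mean()
        jit = mcmc.init_jitter * (0.2 + 0.8 * np.arange(C) / max(C - 1, 1))
        self.mu = mu0 + self.rng.normal(0, 1, C) * jit
        self.alpha = alpha0[None, :] + self.rng.normal(0, 1, (C, self.A)) * jit[:, None]
        if not spec.include_age:
            self.alpha[:] = 0.0
        self.beta = self.rng.normal(0, 1, (C, self.P)) * jit[:, None] * float(
            spec.include_period
        )
        self.gamma = self.rng.normal(0, 1, (C, self.K)) * jit[:, None] * float(
            spec.include_cohort
        )
        self.tau = self.rng.uniform(5.0, 200.0, (C, 3))
        self._constrain()
        self._refresh_cache()

        # scalar update schedule
        self.updates: list[tuple[str, int]] = [("mu", 0)]
        if spec.include_age:
            self.updates += [("alpha", a) for a in range(self.A)]
        if spec.include_period:
            self.updates += [("beta", p) for p in range(self.P)]
        if spec.include_cohort:
            self.updates += [("gamma", c) for c in range(self.K)]
        self.n_par = len(self.updates)
        self.ls = np.full((C, self.n_par), math.log(0.1))
        self.adapting = True
        self.t = 0

        # RW2 structure matrices (second-difference penalty) per effect block
        self.blocks: list[str] = []
        if spec.include_age:
            self.blocks.append("alpha")
        if spec.include_period:
            self.blocks.append("beta")
        if spec.include_cohort:
            self.blocks.append("gamma")
        self.Q = {
            name: _penalty_matrix({"alpha": self.A, "beta": self.P, "gamma": self.K}[name])
            for name in self.blocks
        }

        # monitored parameters: everything identified (refs excluded)
        self.monitor_names: list[str] = ["mu"]
        self._mon_cols: list[tuple[str, int]] = [("mu", 0)]
        if spec.include_age:
            for a in range(self.A):
                self.monitor_names.append(f"alpha[{a + 1}]")
                self._mon_cols.append(("alpha", a))
        if spec.include_period:
            refs = set()
            if spec.include_age and spec.include_cohort:
                refs = {r - 1 for r in spec.ref_period_indices}
            else:
                refs = {spec.ref_period_indices[0] - 1}
            for p in range(self.P):
                if p not in refs:
                    self.monitor_names.append(f"beta[{p + 1}]")
                    self._mon_cols.append(("beta", p))
        if spec.include_cohort:
            for c in range(self.K):
                if c != spec.ref_cohort_index - 1:
                    self.monitor_names.append(f"gamma[{c + 1}]")
                    self._mon_cols.append(("gamma", c))
        for k, name in enumerate(("sigma2_alpha", "sigma2_beta", "sigma2_gamma")):
            if [spec.include_age, spec.include_period, spec.include_cohort][k]:
                self.monitor_names.append(name)
                self._mon_cols.append(("logtau", k))

    # -- state maintenance --------------------------------------------------

    def _constrain(self) -> None:
        _constrain_arrays(self.mu, self.alpha, self.beta, self.gamma, self.spec)

    def _refresh_cache(self) -> None:
        eta = np.broadcast_to(
            self.mu[:, None, None], (self.C, self.A, self.P)
        ).copy()
        if self.spec.include_age:
            eta += self.alpha[:, :, None]
        if self.spec.include_period:
            eta += self.beta[:, None, :]
        if self.spec.include_cohort:
            eta += self.gamma[:, self.cmap]
        self.eta = eta
        with np.errstate(over="ignore"):
            self.W = self.N[None, :, :] * np.exp(eta)

    @staticmethod
    def _ss2(e: np.ndarray) -> np.ndarray:
        if e.shape[1] < 3:
            return np.zeros(e.shape[0])
        d2 = np.diff(e, n=2, axis=1)
        return (d2**2).sum(axis=1)

    def _monitor_vec(self) -> np.ndarray:
        out = np.empty((self.C, len(self._mon_cols)))
        for j, (kind, idx) in enumerate(self._mon_cols):
            if kind == "mu":
                out[:, j] = self.mu
            elif kind == "logtau":
                out[:, j] = -np.log(self.tau[:, idx])
            else:
                out[:, j] = getattr(self, kind)[:, idx]
        return out

    # -- one full sweep -----------------------------------------------------

    def iterate(self) -> None:
        self.t += 1
        z = self.rng.standard_normal((self.C, self.n_par))
        logu = np.log(self.rng.random((self.C, self.n_par)))
        for j, (kind, idx) in enumerate(self.updates):
            self._update_scalar(kind, idx, z[:, j], logu[:, j], j)
        for kind in self.blocks:
            self._update_block(kind)
        self._update_precisions()
        self._constrain()
        if self.t % 200 == 0:
            self._refresh_cache()

    def _group_sums(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        """Death totals (dim,) and current expected deaths (C, dim) per
        row/column/diagonal group of one effect dimension."""
        if kind == "alpha":
            return self.rowD, self.W.sum(axis=2)
        if kind == "beta":
            return self.colD, self.W.sum(axis=1)
        w = np.stack(
            [self.W[:, ar, pc].sum(axis=1) for ar, pc in self.coh_cells], axis=1
        )
        return self.cohD, w

    def _update_block(self, kind: str) -> None:
        """Joint Metropolis-Hastings update of one whole effect vector.

        The proposal is the Gaussian that matches the gradient and Hessian
        of the Poisson-plus-RW2 conditional at the current point (an IWLS /
        Taylor proposal); the acceptance ratio uses the exact target and
        the exact forward/reverse proposal densities, so the update is an
        exact MCMC kernel with near-independent moves when the conditional
        is close to Gaussian.
        """
        from scipy.linalg import cho_factor, cho_solve, solve_triangular

        e = getattr(self, kind)
        k = e.shape[1]
        tau = self.tau[:, self._KIND_TO_TAU[kind]]
        Q = self.Q[kind]
        d, w = self._group_sums(kind)
        z = self.rng.standard_normal((self.C, k))
        logu = np.log(self.rng.random(self.C))
        for ch in range(self.C):
            if not np.all(np.isfinite(w[ch])):
                continue
            tQ = tau[ch] * Q
            H0 = np.diag(w[ch]) + tQ
            g0 = (d - w[ch]) - tQ @ e[ch]
            try:
                c0, low0 = cho_factor(H0)
            except np.linalg.LinAlgError:
                continue
            m0 = cho_solve((c0, low0), g0)
            # delta ~ N(m0, H0^-1): m0 + L^-T z with H0 = L L^T
            L0 = np.tril(c0) if low0 else np.triu(c0).T
            delta = m0 + solve_triangular(L0.T, z[ch], lower=False)
            logdet0 = 2.0 * np.sum(np.log(np.diag(L0)))
            r0 = delta - m0
            logq_fwd = 0.5 * logdet0 - 0.5 * r0 @ H0 @ r0

            e_new = e[ch] + delta
            with np.errstate(over="ignore"):
                w_new = w[ch] * np.exp(delta)
            if not np.all(np.isfinite(w_new)):
                continue
            d_target = (
                d @ delta
                - np.sum(w_new - w[ch])
                - 0.5 * (e_new @ (tQ @ e_new) - e[ch] @ (tQ @ e[ch]))
            )
            H1 = np.diag(w_new) + tQ
            g1 = (d - w_new) - tQ @ e_new
            try:
                c1, low1 = cho_factor(H1)
            except np.linalg.LinAlgError:
                continue
            m1 = cho_solve((c1, low1), g1)
            L1 = np.tril(c1) if low1 else np.triu(c1).T
            logdet1 = 2.0 * np.sum(np.log(np.diag(L1)))
            r1 = -delta - m1
            logq_rev = 0.5 * logdet1 - 0.5 * r1 @ H1 @ r1

            if d_target + logq_rev - logq_fwd > logu[ch]:
                e[ch] = e_new
                if kind == "alpha":
                    self.eta[ch] += delta[:, None]
                    self.W[ch] *= np.exp(delta)[:, None]
                elif kind == "beta":
                    self.eta[ch] += delta[None, :]
                    self.W[ch] *= np.exp(delta)[None, :]
                else:
                    self.eta[ch] += delta[self.cmap]
                    self.W[ch] *= np.exp(delta[self.cmap])

    def _update_scalar(self, kind: str, idx: int, z, logu, j: int) -> None:
        delta = z * np.exp(self.ls[:, j])
        if kind == "mu":
            dsum = self.Dtot
            wsum = self.W.sum(axis=(1, 2))
        elif kind == "alpha":
            dsum = self.rowD[idx]
            wsum = self.W[:, idx, :].sum(axis=1)
        elif kind == "beta":
            dsum = self.colD[idx]
            wsum = self.W[:, :, idx].sum(axis=1)
        else:
            arows, pcols = self.coh_cells[idx]
            dsum = self.cohD[idx]
            wsum = self.W[:, arows, pcols].sum(axis=1)
        with np.errstate(over="ignore", invalid="ignore"):
            d_ll = delta * dsum - np.expm1(delta) * wsum
        if kind == "mu":
            new = self.mu + delta
            d_lp = -(new**2 - self.mu**2) / (2.0 * self.spec.mu_prior_var)
        else:
            e = getattr(self, kind)
            e_new = e.copy()
            e_new[:, idx] += delta
            tau = self.tau[:, self._KIND_TO_TAU[kind]]
            d_lp = -0.5 * tau * (self._ss2(e_new) - self._ss2(e))
        logr = d_ll + d_lp
        logr = np.where(np.isnan(logr), -np.inf, logr)
        acc = logr > logu
        hit = np.nonzero(acc)[0]
        if hit.size:
            dlt = delta[hit]
            mult = np.exp(dlt)
            if kind == "mu":
                self.mu[hit] += dlt
                self.eta[hit] += dlt[:, None, None]
                self.W[hit] *= mult[:, None, None]
            elif kind == "alpha":
                self.alpha[hit, idx] += dlt
                self.eta[hit, idx, :] += dlt[:, None]
                self.W[hit, idx, :] *= mult[:, None]
            elif kind == "beta":
                self.beta[hit, idx] += dlt
                self.eta[hit, :, idx] += dlt[:, None]
                self.W[hit, :, idx] *= mult[:, None]
            else:
                arows, pcols = self.coh_cells[idx]
                self.gamma[hit, idx] += dlt
                ii = hit[:, None]
                self.eta[ii, arows[None, :], pcols[None, :]] += dlt[:, None]
                self.W[ii, arows[None, :], pcols[None, :]] *= mult[:, None]
        if self.adapting:
            rate = min(0.25, 2.0 / max(self.t, 1) ** 0.6)
            acc_prob = np.exp(np.minimum(logr, 0.0))
            self.ls[:, j] += rate * (acc_prob - self.mcmc.target_accept)
            np.clip(self.ls[:, j], -12.0, 3.0, out=self.ls[:, j])

    def _update_precisions(self) -> None:
        for kind, k in self._KIND_TO_TAU.items():
            included = [
                self.spec.include_age,
                self.spec.include_period,
                self.spec.include_cohort,
            ][k]
            e = getattr(self, kind)
            if not included or e.shape[1] < 3:
                continue
            ss = self._ss2(e)
            shape = self.spec.hyper_shape + 0.5 * (e.shape[1] - 2)
            rate = self.spec.hyper_rate + 0.5 * ss
            self.tau[:, k] = self.rng.gamma(shape, 1.0 / rate)

    # -- deviance of the current states -------------------------------------

    def deviance_now(self) -> np.ndarray:
        core = (self.D[None] * self.eta).sum(axis=(1, 2)) + self.DlogN - self.W.sum(
            axis=(1, 2)
        )
        return -2.0 * core


def _deviance_at(params: APCParameters, counts: StratumCounts, spec: APCModelSpec) -> float:
    """Deviance -2 sum [D log(N lambda) - N lambda] (no saturated term)."""
    D = counts.deaths.astype(float)
    N = counts.person_years
    eta = log_rate_matrix(params, counts.grid, spec)
    return float(-2.0 * np.sum(D * (np.log(N) + eta) - N * np.exp(eta)))


def sample_posterior(
    counts: StratumCounts, spec: APCModelSpec, mcmc: MCMCConfig
) -> APCPosterior:
    """Fit the APC model by MCMC and return the constrained posterior.

    Burn-in length is set adaptively from split R-hat on all identified
    parameters; if the threshold is still unmet at ``max_burn_in`` the
    returned posterior has ``converged=False`` and carries the offending
    R-hat values (callers decide whether to fail hard).
    """
    s = _Sampler(counts, spec, mcmc)
    C = mcmc.n_chains
    n_mon = len(s.monitor_names)
    burn_rhat: Optional[np.ndarray] = None
    converged = C < 2  # single-chain runs cannot be monitored
    if C >= 2:
        buf = np.empty((C, mcmc.check_every, n_mon))
        while s.t < mcmc.max_burn_in:
            for i in range(mcmc.check_every):
                s.iterate()
                buf[:, i, :] = s._monitor_vec()
            if s.t >= mcmc.min_burn_in:
                burn_rhat = np.array(
                    [split_rhat(buf[:, :, k]) for k in range(n_mon)]
                )
                if np.all(burn_rhat < mcmc.rhat_threshold):
                    converged = True
                    break
    else:
        while s.t < mcmc.min_burn_in:
            s.iterate()
    burn_in_used = s.t
    s.adapting = False
    s._refresh_cache()

    nk = -(-mcmc.n_keep_total // C)  # ceil, so chains x kept >= budget
    A, P, K = s.A, s.P, s.K
    mu_s = np.empty((C, nk))
    alpha_s = np.empty((C, nk, A))
    beta_s = np.empty((C, nk, P))
    gamma_s = np.empty((C, nk, K))
    sigma2_s = np.empty((C, nk, 3))
    dev_s = np.empty((C, nk))
    for i in range(nk):
        for _ in range(mcmc.thin):
            s.iterate()
        mu_s[:, i] = s.mu
        alpha_s[:, i] = s.alpha
        beta_s[:, i] = s.beta
        gamma_s[:, i] = s.gamma
        sigma2_s[:, i] = 1.0 / s.tau
        dev_s[:, i] = s.deviance_now()

    # final split R-hat on the retained draws, per monitored parameter
    rhat_vals = {}
    if C >= 2 and nk >= 4:
        for name, (kind, idx) in zip(s.monitor_names, s._mon_cols):
            if kind == "mu":
                arr = mu_s
            elif kind == "logtau":
                arr = np.log(sigma2_s[:, :, idx])
            else:
                arr = {"alpha": alpha_s, "beta": beta_s, "gamma": gamma_s}[kind][
                    :, :, idx
                ]
            rhat_vals[name] = split_rhat(arr)
    rhat = pd.Series(rhat_vals, dtype=float)

    return APCPosterior(
        spec=spec,
        counts=counts,
        mcmc=mcmc,
        mu=mu_s,
        alpha=alpha_s,
        beta=beta_s,
        gamma=gamma_s,
        sigma2=sigma2_s,
        deviance=dev_s,
        rhat=rhat,
        burn_in_used=burn_in_used,
        converged=bool(converged),
    )


# ---------------------------------------------------------------------------
# DIC, relative risks, model comparison
# ---------------------------------------------------------------------------


def dic(posterior: APCPosterior, counts: Optional[StratumCounts] = None) -> DICResult:
    """DIC = Dbar + pD with pD = Dbar - D(posterior mean parameters).

    The deviance omits the data-only log D! term consistently across
    compared models, so DIC differences are unaffected by the omission.
    """
    counts = counts or posterior.counts
    dbar = float(posterior.deviance.mean())
    d_at_mean = _deviance_at(posterior.posterior_mean_params(), counts, posterior.spec)
    return DICResult(dbar=dbar, d_at_mean=d_at_mean)


def relative_risks(posterior: APCPosterior) -> pd.DataFrame:
    """Posterior mean and 95% CrI of exp(effect) per cohort and period.

    Reference categories have RR identically 1 with a zero-width interval.
    """
    grid = posterior.spec.grid
    rows = []
    specs = []
    if posterior.spec.include_cohort:
        specs.append(("cohort", posterior.gamma_draws()))
    if posterior.spec.include_period:
        specs.append(("period", posterior.beta_draws()))
    for dim, draws in specs:
        rr = np.exp(draws)
        mean = rr.mean(axis=0)
        lo, hi = np.quantile(rr, [0.025, 0.975], axis=0)
        for k in range(draws.shape[1]):
            if dim == "cohort":
                label: object = grid.cohort_center_year(k + 1)
                is_ref = k + 1 == posterior.spec.ref_cohort_index
            else:
                label = grid.period_label(k + 1)
                is_ref = (k + 1) in posterior.spec.ref_period_indices
            rows.append(
                {
                    "dimension": dim,
                    "index": k + 1,
                    "label": label,
                    "rr": float(mean[k]),
                    "lo95": float(lo[k]),
                    "hi95": float(hi[k]),
                    "is_reference": bool(is_ref),
                }
            )
    return pd.DataFrame(rows)


_SUBMODELS = [
    (True, False, False),
    (False, True, False),
    (False, False, True),
    (True, True, False),
    (True, False, True),
    (False, True, True),
    (True, True, True),
]


def model_comparison(
    counts: StratumCounts,
    mcmc: MCMCConfig,
    hyper_shape: float = 1e-3,
    hyper_rate: float = 1e-3,
    submodels=None,
) -> pd.DataFrame:
    """DIC table across the seven nonempty {age, period, cohort} submodels."""
    rows = []
    for k, (ia, ip, ic) in enumerate(submodels or _SUBMODELS):
        spec = APCModelSpec(
            grid=counts.grid,
            include_age=ia,
            include_period=ip,
            include_cohort=ic,
            hyper_shape=hyper_shape,
            hyper_rate=hyper_rate,
        )
        fit = sample_posterior(counts, spec, replace(mcmc, seed=mcmc.seed + 1000 * k))
        res = dic(fit)
        rows.append(
            {
                "model": spec.label,
                "dbar": res.dbar,
                "pd": res.pd,
                "dic": res.dic,
                "converged": fit.converged,
                "max_rhat": float(fit.rhat.max()) if len(fit.rhat) else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Posterior persistence (long-format delimited text + JSON sidecar)
# ---------------------------------------------------------------------------


def save_posterior(posterior: APCPosterior, draws_path, meta_path) -> None:
    """Write draws as `chain,draw,parameter,value` CSV plus a JSON sidecar."""
    frames = []
    C, nk = posterior.n_chains, posterior.n_kept
    chain_col = np.repeat(np.arange(1, C + 1), nk)
    draw_col = np.tile(np.arange(1, nk + 1), C)

    def add(name, values):  # values (C, nk)
        frames.append(
            pd.DataFrame(
                {
                    "chain": chain_col,
                    "draw": draw_col,
                    "parameter": name,
                    "value": values.reshape(-1),
                }
            )
        )

    add("mu", posterior.mu)
    for a in range(posterior.alpha.shape[-1]):
        add(f"alpha[{a + 1}]", posterior.alpha[:, :, a])
    for p in range(posterior.beta.shape[-1]):
        add(f"beta[{p + 1}]", posterior.beta[:, :, p])
    for c in range(posterior.gamma.shape[-1]):
        add(f"gamma[{c + 1}]", posterior.gamma[:, :, c])
    for k, name in enumerate(("sigma2_alpha", "sigma2_beta", "sigma2_gamma")):
        add(name, posterior.sigma2[:, :, k])
    add("deviance", posterior.deviance)
    pd.concat(frames, ignore_index=True).to_csv(draws_path, index=False)

    grid = posterior.spec.grid
    meta = {
        "grid": {
            "age_lower_edges": list(grid.age_lower_edges),
            "period_start_years": list(grid.period_start_years),
            "age_width": grid.age_width,
            "period_width": grid.period_width,
            "open_ended_top": grid.open_ended_top,
        },
        "spec": {
            "include_age": posterior.spec.include_age,
            "include_period": posterior.spec.include_period,
            "include_cohort": posterior.spec.include_cohort,
            "hyper_shape": posterior.spec.hyper_shape,
            "hyper_rate": posterior.spec.hyper_rate,
            "mu_prior_var": posterior.spec.mu_prior_var,
        },
        "mcmc": {
            "n_chains": posterior.mcmc.n_chains,
            "n_keep_total": posterior.mcmc.n_keep_total,
            "thin": posterior.mcmc.thin,
            "seed": posterior.mcmc.seed,
            "max_burn_in": posterior.mcmc.max_burn_in,
            "min_burn_in": posterior.mcmc.min_burn_in,
            "check_every": posterior.mcmc.check_every,
            "rhat_threshold": posterior.mcmc.rhat_threshold,
            "target_accept": posterior.mcmc.target_accept,
            "init_jitter": posterior.mcmc.init_jitter,
        },
        "sex": posterior.counts.sex,
        "income_group": posterior.counts.income_group,
        "deaths": posterior.counts.deaths.tolist(),
        "person_years": posterior.counts.person_years.tolist(),
        "burn_in_used": posterior.burn_in_used,
        "converged": posterior.converged,
        "rhat": {k: (None if not np.isfinite(v) else float(v)) for k, v in posterior.rhat.items()},
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def load_posterior(draws_path, meta_path) -> APCPosterior:
    meta = json.loads(Path(meta_path).read_text())
    grid = LexisGrid(
        age_lower_edges=tuple(meta["grid"]["age_lower_edges"]),
        period_start_years=tuple(meta["grid"]["period_start_years"]),
        age_width=meta["grid"]["age_width"],
        period_width=meta["grid"]["period_width"],
        open_ended_top=meta["grid"]["open_ended_top"],
    )
    spec = APCModelSpec(grid=grid, **meta["spec"])
    mcmc = MCMCConfig(**meta["mcmc"])
    counts = StratumCounts(
        grid=grid,
        sex=meta["sex"],
        income_group=meta["income_group"],
        deaths=np.asarray(meta["deaths"], dtype=int),
        person_years=np.asarray(meta["person_years"], dtype=float),
    )
    df = pd.read_csv(draws_path)
    C = int(df["chain"].max())
    nk = int(df["draw"].max())
    A, P, K = grid.n_age, grid.n_period, grid.n_cohorts

    by_par = {name: sub for name, sub in df.groupby("parameter", sort=False)}

    def get(name):
        sub = by_par[name].sort_values(["chain", "draw"])
        return sub["value"].to_numpy().reshape(C, nk)

    alpha = np.stack([get(f"alpha[{a + 1}]") for a in range(A)], axis=-1)
    beta = np.stack([get(f"beta[{p + 1}]") for p in range(P)], axis=-1)
    gamma = np.stack([get(f"gamma[{c + 1}]") for c in range(K)], axis=-1)
    sigma2 = np.stack(
        [get(n) for n in ("sigma2_alpha", "sigma2_beta", "sigma2_gamma")], axis=-1
    )
    rhat = pd.Series(
        {k: (np.inf if v is None else v) for k, v in meta["rhat"].items()}, dtype=float
    )
    return APCPosterior(
        spec=spec,
        counts=counts,
        mcmc=mcmc,
        mu=get("mu"),
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        sigma2=sigma2,
        deviance=get("deviance"),
        rhat=rhat,
        burn_in_used=int(meta["burn_in_used"]),
        converged=bool(meta["converged"]),
    )
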