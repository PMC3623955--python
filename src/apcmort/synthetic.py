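"""Synthetic study data with the structure the APC analysis assumes.

Generates, per sex x income stratum, a multiplicative age/period/cohort
log-rate surface on the default 10 x 6 grid and Poisson death counts from
realistic person-year denominators, plus individual-level death records,
TPU income tables and population tables so the classification and
aggregation stages can be exercised end-to-end.  The generating truth is
exported so recovery tests can compare posterior estimates against it.

Scenario shape (fixed defaults):

* age effects rise log-linearly with a positive slope jump at the 50-54
  group (IHD mortality accelerates around age 50);
* male cohort effects decline after an early peak, with a downturn around
  the 1910-15 cohorts and a marked upturn at the 1945-50 cohorts that is
  stronger for the low-income stratum; female cohort effects show a
  1920-25 downturn and no 1945 upturn (at most a slight high-income
  upturn around 1940);
* period effects are small, with a low-income-only dip in 1991-95 and
  recovery in the late 1990s;
* high-income strata start with higher age-standardised rates (ASR
  anchors 40 vs 33 per 100,000 for women, 65 vs 55 for men in 1976-80)
  but decline faster, so the ordering reverses within the observed window.

Expected deaths per cell span roughly 1-200, matching the sparse-to-
moderate counts a 30-75+ IHD grid produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .lexis import DeathRecord, LexisGrid, StratumCounts, default_grid
from .sep import SEPAssignment, TPUIncomeTable, classify_tpus, stratum_of
from .standardize import StandardPopulation, restrict_weights, who_world_standard

__all__ = [
    "ScenarioTruth",
    "SimulatedStratum",
    "StudyData",
    "default_scenario",
    "simulate_grid_counts",
    "simulate_records",
    "simulate_study",
    "save_truth",
    "load_truth",
]

# log-rate increments between consecutive age groups: constant 0.45 up to
# the 50-54 group, then constant 0.62 (the acceleration at ~age 50)
_AGE_SLOPES = (0.45, 0.45, 0.45, 0.45, 0.62, 0.62, 0.62, 0.62, 0.62)

# gamma increments between consecutive cohorts (14 steps across 15 cohorts)
_GAMMA_SLOPES = {
    ("female", "low"): (0.04, 0.02, 0.00, -0.04, -0.12, -0.14, -0.12, -0.11,
                        -0.10, -0.10, -0.09, -0.09, -0.08, -0.08),
    ("female", "high"): (0.02, -0.02, -0.06, -0.12, -0.20, -0.20, -0.18, -0.17,
                         -0.12, -0.15, -0.15, -0.15, -0.15, -0.14),
    ("male", "low"): (0.02, -0.02, -0.10, -0.14, -0.12, -0.11, -0.10, -0.10,
                      -0.10, 0.12, -0.02, -0.06, -0.08, -0.10),
    ("male", "high"): (0.00, -0.06, -0.14, -0.18, -0.16, -0.15, -0.14, -0.14,
                       -0.14, -0.02, -0.10, -0.14, -0.16, -0.18),
}

# period effects (already constrained: beta[2] = beta[5] = 0, 1-based);
# the low-income strata carry the early-1990s dip and late-1990s recovery
_BETA = {
    "low": (0.03, 0.0, -0.01, -0.08, 0.0, 0.05),
    "high": (0.01, 0.0, 0.00, -0.01, 0.0, 0.00),
}

# first-period (1976-80) 30+ age-standardised rate anchors, per 100,000
_ASR_ANCHORS = {
    ("female", "low"): 33.0,
    ("female", "high"): 40.0,
    ("male", "low"): 55.0,
    ("male", "high"): 65.0,
}

# annual mid-year population per stratum, thousands, by age group; periods
# scale with overall population growth
_POP_BASE_THOUSANDS = (110, 100, 90, 80, 70, 60, 46, 32, 18, 8)
_POP_GROWTH = (0.75, 0.85, 1.0, 1.1, 1.2, 1.3)

_ICD9_CODES = ("410", "4109", "411", "412", "4129", "413", "414", "4140", "414.9")
_ICD10_CODES = ("I20", "I21", "I21.4", "I21.9", "I22", "I23", "I24", "I25",
                "I25.1", "I25.9")


@dataclass
class ScenarioTruth:
    """The generating parameters of one sex x income stratum."""

    grid: LexisGrid
    sex: str
    income_group: str
    mu: float
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    sigma2: np.ndarray  # (alpha, beta, gamma) innovation variances
    population: np.ndarray  # person-years per cell (annual pop x width)
    expected_kink_cohort: Optional[int] = None  # male 1945-50 upturn index
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        g = self.grid
        r1, r2 = 2, g.n_period - 1
        ref_c = (g.n_cohorts + 1) // 2
        if abs(self.beta[r1 - 1]) > 1e-12 or abs(self.beta[r2 - 1]) > 1e-12:
            raise ValueError("truth beta must satisfy the reference constraints")
        if abs(self.gamma[ref_c - 1]) > 1e-12:
            raise ValueError("truth gamma must be zero at the central cohort")
        if np.any(self.population <= 0):
            raise ValueError("populations must be positive")

    # -- evaluation ----------------------------------------------------------

    def log_rate_matrix(self) -> np.ndarray:
        g = self.grid
        a = np.arange(g.n_age)[:, None]
        p = np.arange(g.n_period)[None, :]
        cmap = (g.n_age - 1 - a) + p
        return self.mu + self.alpha[:, None] + self.beta[None, :] + self.gamma[cmap]

    def rates_per_100k(self) -> np.ndarray:
        return 1e5 * np.exp(self.log_rate_matrix())

    def asr_series(self, std: Optional[StandardPopulation] = None) -> np.ndarray:
        """True 30+ age-standardised rate per observed period."""
        std = std or restrict_weights(who_world_standard(), self.grid)
        return self.rates_per_100k().T @ std.normalized_weights

    def future_log_rates(self, n_ahead: int = 3) -> np.ndarray:
        """Noiseless truth projection: linear extrapolation of beta/gamma."""
        g = self.grid
        beta_ext = _linear_extend(self.beta, n_ahead)
        gamma_ext = _linear_extend(self.gamma, n_ahead)
        A, P = g.n_age, g.n_period
        out = np.empty((A, n_ahead))
        for j in range(n_ahead):
            p1 = P + 1 + j
            for a in range(1, A + 1):
                c = g.n_age - a + p1
                out[a - 1, j] = (
                    self.mu + self.alpha[a - 1] + beta_ext[p1 - 1] + gamma_ext[c - 1]
                )
        return out

    def future_asr(
        self, n_ahead: int = 3, std: Optional[StandardPopulation] = None
    ) -> np.ndarray:
        std = std or restrict_weights(who_world_standard(), self.grid)
        rates = 1e5 * np.exp(self.future_log_rates(n_ahead))
        return rates.T @ std.normalized_weights


def _linear_extend(e: np.ndarray, n_ahead: int) -> np.ndarray:
    out = np.concatenate([e, np.zeros(n_ahead)])
    k = len(e)
    for j in range(n_ahead):
        out[k + j] = 2 * out[k + j - 1] - out[k + j - 2]
    return out


def default_scenario(sex: str, income_group: str) -> ScenarioTruth:
    """The documented study-like scenario for one stratum.

    The intercept is calibrated so the true 1976-80 30+ ASR equals the
    stratum's anchor; all other curves are fixed constants (module header).
    """
    grid = default_grid()
    key = (sex, income_group)
    if key not in _GAMMA_SLOPES:
        raise ValueError(f"unknown stratum: {key}")
    alpha = np.concatenate([[0.0], np.cumsum(_AGE_SLOPES)])
    alpha -= alpha.mean()
    gamma = np.concatenate([[0.0], np.cumsum(_GAMMA_SLOPES[key])])
    gamma -= gamma[(grid.n_cohorts + 1) // 2 - 1]
    beta = np.asarray(_BETA[income_group], dtype=float)

    population = 5.0 * 1000.0 * np.outer(_POP_BASE_THOUSANDS, _POP_GROWTH)

    # calibrate mu against the first-period ASR anchor
    std = restrict_weights(who_world_standard(), grid)
    w = std.normalized_weights
    first_cohorts = grid.n_age - 1 - np.arange(grid.n_age)  # 0-based c at p=1
    s = float(np.sum(w * np.exp(alpha + beta[0] + gamma[first_cohorts])))
    mu = float(np.log(_ASR_ANCHORS[key] / 1e5) - np.log(s))

    return ScenarioTruth(
        grid=grid,
        sex=sex,
        income_group=income_group,
        mu=mu,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        sigma2=np.array([0.005, 0.003, 0.008]),
        population=population,
        expected_kink_cohort=10 if sex == "male" else None,
    )


def simulate_grid_counts(truth: ScenarioTruth, seed: int = 0) -> StratumCounts:
    """Draw D_ap ~ Poisson(N_ap exp(eta_ap)) independently per cell."""
    lam = truth.population * np.exp(truth.log_rate_matrix())
    if not np.all(np.isfinite(lam)) or np.any(lam > 1e12):
        raise OverflowError("expected counts overflow the Poisson sampler")
    rng = np.random.default_rng(seed)
    deaths = rng.poisson(lam)
    return StratumCounts(
        grid=truth.grid,
        sex=truth.sex,
        income_group=truth.income_group,
        deaths=deaths,
        person_years=truth.population.copy(),
    )


# ---------------------------------------------------------------------------
# Record-level simulation
# ---------------------------------------------------------------------------


def _make_tpu_table(
    n_tpus: int, census_years, seed: int
) -> tuple[TPUIncomeTable, SEPAssignment]:
    """TPU income table whose labels straddle the median in every census.

    Relative income ranks are constant across censuses, so each TPU keeps
    one label throughout and record assignment is census-independent.
    """
    if n_tpus < 4:
        raise ValueError("need at least 4 TPUs for both strata to be populated")
    rng = np.random.default_rng(seed)
    base = 6000.0 * (0.55 + 0.9 * np.arange(n_tpus) / (n_tpus - 1))
    base *= 1.0 + rng.uniform(-0.02, 0.02, n_tpus)  # jitter, rank-preserving
    base.sort()
    income = {}
    for year in census_years:
        growth = 1.045 ** (year - census_years[0])
        for i, b in enumerate(base):
            income[(f"T{i + 1:03d}", int(year))] = round(b * growth, 2)
    table = TPUIncomeTable(census_years=tuple(int(y) for y in census_years), income=income)
    return table, classify_tpus(table)


def _icd_for_year(year: int, rng) -> tuple[int, str]:
    if year <= 1979:
        return 8, str(rng.choice(_ICD9_CODES))
    if year <= 2000:
        return 9, str(rng.choice(_ICD9_CODES))
    return 10, str(rng.choice(_ICD10_CODES))


@dataclass
class SimulatedStratum:
    """Record-level expansion of one stratum's simulated grid counts."""

    truth: ScenarioTruth
    counts: StratumCounts
    records: list[DeathRecord]
    population: pd.DataFrame
    tpu_table: TPUIncomeTable
    assignment: SEPAssignment


def simulate_records(
    truth: ScenarioTruth,
    tpu_table_size: int = 40,
    seed: int = 0,
    tpu_table: Optional[TPUIncomeTable] = None,
    assignment: Optional[SEPAssignment] = None,
) -> SimulatedStratum:
    """Individual death records, population and TPU tables for one stratum.

    Cell counts are drawn first (same stream as :func:`simulate_grid_counts`
    at ``seed + 1``), then expanded to records with ages and years uniform
    within their cell, era-appropriate ICD codes, and TPU ids drawn from
    the TPUs carrying this stratum's income label, so aggregation
    round-trips exactly to the grid counts.
    """
    from .sep import DEFAULT_CENSUS_YEARS

    if tpu_table is None or assignment is None:
        tpu_table, assignment = _make_tpu_table(
            tpu_table_size, DEFAULT_CENSUS_YEARS, seed
        )
    counts = simulate_grid_counts(truth, seed + 1)
    rng = np.random.default_rng(seed + 2)
    grid = truth.grid
    pool = sorted(
        {
            tpu
            for (tpu, year), lab in assignment.labels.items()
            if lab == truth.income_group
        }
    )
    if not pool:
        raise ValueError("no TPUs carry this stratum's income label")

    records: list[DeathRecord] = []
    for a in range(1, grid.n_age + 1):
        lo = grid.age_lower_edges[a - 1]
        hi = lo + (15 if a == grid.n_age else grid.age_width)  # 75+ drawn 75-89
        for p in range(1, grid.n_period + 1):
            start = grid.period_start(p)
            for _ in range(int(counts.deaths[a - 1, p - 1])):
                year = int(rng.integers(start, start + grid.period_width))
                rev, code = _icd_for_year(year, rng)
                records.append(
                    DeathRecord(
                        age_at_death=int(rng.integers(lo, hi)),
                        sex=truth.sex,
                        year_of_death=year,
                        icd_revision=rev,
                        icd_code=code,
                        tpu_id=str(rng.choice(pool)),
                    )
                )

    pop_rows = []
    for a in range(1, grid.n_age + 1):
        for year in grid.study_years:
            p = grid.period_index_of(year)
            annual = truth.population[a - 1, p - 1] / grid.period_width
            share = annual / len(pool)
            for tpu in pool:
                pop_rows.append(
                    {
                        "age_group": grid.age_label(a),
                        "sex": truth.sex,
                        "year": year,
                        "tpu_id": tpu,
                        "population": share,
                    }
                )
    return SimulatedStratum(
        truth=truth,
        counts=counts,
        records=records,
        population=pd.DataFrame(pop_rows),
        tpu_table=tpu_table,
        assignment=assignment,
    )


@dataclass
class StudyData:
    """All four strata simulated against one shared TPU geography."""

    truths: dict[tuple[str, str], ScenarioTruth]
    counts: dict[tuple[str, str], StratumCounts]
    records: list[DeathRecord]
    population: pd.DataFrame
    tpu_table: TPUIncomeTable
    assignment: SEPAssignment

    def stratum_of_record(self, record: DeathRecord) -> Optional[str]:
        try:
            return stratum_of(record.year_of_death, record.tpu_id, self.assignment)
        except KeyError:
            return None


def simulate_study(seed: int = 0, tpu_table_size: int = 40) -> StudyData:
    """Simulate the full four-stratum study from the default scenarios."""
    from .sep import DEFAULT_CENSUS_YEARS

    tpu_table, assignment = _make_tpu_table(tpu_table_size, DEFAULT_CENSUS_YEARS, seed)
    truths: dict[tuple[str, str], ScenarioTruth] = {}
    counts: dict[tuple[str, str], StratumCounts] = {}
    records: list[DeathRecord] = []
    pops = []
    for k, (sex, inc) in enumerate(
        [(s, i) for s in ("female", "male") for i in ("low", "high")]
    ):
        truth = default_scenario(sex, inc)
        truth.seed = seed + 10 * k
        sim = simulate_records(
            truth,
            tpu_table_size,
            seed + 10 * k,
            tpu_table=tpu_table,
            assignment=assignment,
        )
        truths[(sex, inc)] = truth
        counts[(sex, inc)] = sim.counts
        records.extend(sim.records)
        pops.append(sim.population)
    return StudyData(
        truths=truths,
        counts=counts,
        records=records,
        population=pd.concat(pops, ignore_index=True),
        tpu_table=tpu_table,
        assignment=assignment,
    )


# ---------------------------------------------------------------------------
# Truth persistence
# ---------------------------------------------------------------------------


def save_truth(truth: ScenarioTruth, path) -> None:
    g = truth.grid
    payload = {
        "grid": {
            "age_lower_edges": list(g.age_lower_edges),
            "period_start_years": list(g.period_start_years),
            "age_width": g.age_width,
            "period_width": g.period_width,
            "open_ended_top": g.open_ended_top,
        },
        "sex": truth.sex,
        "income_group": truth.income_group,
        "mu": truth.mu,
        "alpha": truth.alpha.tolist(),
        "beta": truth.beta.tolist(),
        "gamma": truth.gamma.tolist(),
        "sigma2": truth.sigma2.tolist(),
        "population": truth.population.tolist(),
        "expected_kink_cohort": truth.expected_kink_cohort,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_truth(path) -> ScenarioTruth:
    d = json.loads(Path(path).read_text())
    grid = LexisGrid(
        age_lower_edges=tuple(d["grid"]["age_lower_edges"]),
        period_start_years=tuple(d["grid"]["period_start_years"]),
        age_width=d["grid"]["age_width"],
        period_width=d["grid"]["period_width"],
        open_ended_top=d["grid"]["open_ended_top"],
    )
    return ScenarioTruth(
        grid=grid,
        sex=d["sex"],
        income_group=d["income_group"],
        mu=d["mu"],
        alpha=np.asarray(d["alpha"]),
        beta=np.asarray(d["beta"]),
        gamma=np.asarray(d["gamma"]),
        sigma2=np.asarray(d["sigma2"]),
        population=np.asarray(d["population"]),
        expected_kink_cohort=d.get("expected_kink_cohort"),
        seed=d.get("seed"),
    )
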