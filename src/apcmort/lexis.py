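"""Lexis grid primitives for age-period-cohort tabulation.

An age x period ("Lexis") grid discretises deaths and person-years into
5-year age groups and 5-year calendar periods.  Birth cohorts run along the
grid's diagonals: with 1-based indices and ``A`` age groups, cell ``(a, p)``
belongs to cohort ``c = A - a + p``, so an ``A x P`` grid contains exactly
``A + P - 1`` (overlapping, 10-year) cohorts.

The default study grid has ten age groups (30-34 ... 75+), six periods
(1976-1980 ... 2001-2005) and hence fifteen cohorts.  Ischaemic heart
disease deaths are identified from ICD codes (ICD-8/9 rubrics 410-414,
ICD-10 I20-I25).

All public indices (age, period, cohort) are 1-based, matching the usual
epidemiological tabulation convention.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LexisGrid",
    "DeathRecord",
    "StratumCounts",
    "CohortLabel",
    "AggregateResult",
    "ICDCodeError",
    "cohort_index",
    "icd_matches_ihd",
    "is_ihd",
    "filter_ihd",
    "aggregate",
    "aggregate_population",
    "crude_rates",
    "default_grid",
    "read_deaths",
    "read_population",
    "counts_to_frame",
    "frame_to_counts",
]

SEXES = ("female", "male")
INCOME_GROUPS = ("low", "high")


class ICDCodeError(ValueError):
    """Raised when an ICD code cannot be parsed for the stated revision."""


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LexisGrid:
    """Age x period discretisation with diagonal (cohort) index arithmetic.

    Parameters
    ----------
    age_lower_edges
        Lower bounds of the age groups in years, strictly increasing with
        constant spacing ``age_width``.  The last group is open-ended
        ("75 or above") when ``open_ended_top`` is true.
    period_start_years
        First calendar year of each period, strictly increasing with
        constant spacing ``period_width``.
    """

    age_lower_edges: tuple[int, ...] = tuple(range(30, 80, 5))
    period_start_years: tuple[int, ...] = tuple(range(1976, 2006, 5))
    age_width: int = 5
    period_width: int = 5
    open_ended_top: bool = True

    def __post_init__(self) -> None:
        ages = np.asarray(self.age_lower_edges)
        periods = np.asarray(self.period_start_years)
        if len(ages) < 2 or len(periods) < 2:
            raise ValueError("grid needs at least two age groups and periods")
        if not np.all(np.diff(ages) == self.age_width):
            raise ValueError("age_lower_edges must increase by age_width")
        if not np.all(np.diff(periods) == self.period_width):
            raise ValueError("period_start_years must increase by period_width")
        if self.age_width != self.period_width:
            raise ValueError(
                "cohort diagonal arithmetic requires age_width == period_width"
            )

    @property
    def n_age(self) -> int:
        return len(self.age_lower_edges)

    @property
    def n_period(self) -> int:
        return len(self.period_start_years)

    @property
    def n_cohorts(self) -> int:
        return self.n_age + self.n_period - 1

    # -- labels and centres -------------------------------------------------

    def age_label(self, age_idx: int) -> str:
        lo = self.age_lower_edges[age_idx - 1]
        if self.open_ended_top and age_idx == self.n_age:
            return f"{lo}+"
        return f"{lo}-{lo + self.age_width - 1}"

    @property
    def age_labels(self) -> list[str]:
        return [self.age_label(a) for a in range(1, self.n_age + 1)]

    def period_label(self, period_idx: int) -> str:
        start = self.period_start_years[0] + (period_idx - 1) * self.period_width
        return f"{start}-{start + self.period_width - 1}"

    @property
    def period_labels(self) -> list[str]:
        return [self.period_label(p) for p in range(1, self.n_period + 1)]

    def period_start(self, period_idx: int) -> int:
        """First calendar year of period ``period_idx`` (may exceed the
        observed window, for projected periods)."""
        return self.period_start_years[0] + (period_idx - 1) * self.period_width

    def period_center(self, period_idx: int) -> float:
        return self.period_start(period_idx) + (self.period_width - 1) / 2.0

    def age_center(self, age_idx: int) -> float:
        lo = self.age_lower_edges[age_idx - 1]
        if self.open_ended_top and age_idx == self.n_age:
            return lo + self.age_width / 2.0  # nominal centre 77.5 for 75+
        return lo + (self.age_width - 1) / 2.0 + 0.5

    def cohort_center_year(self, cohort_idx: int) -> int:
        """Nominal central birth year of a cohort diagonal.

        Defined as (period centre) - (age-group centre) along the diagonal's
        non-top cells, rounded to the nearest multiple of the grid width.
        Consecutive cohorts are therefore exactly ``age_width`` years apart.
        """
        if not 1 <= cohort_idx:
            raise ValueError("cohort_idx must be >= 1")
        raw = (
            self.period_center(1)
            - self.age_center(1)
            + self.age_width * (cohort_idx - self.n_age)
        )
        return int(round(raw / self.age_width)) * self.age_width

    def cohort_label(self, cohort_idx: int) -> "CohortLabel":
        center = self.cohort_center_year(cohort_idx)
        half = self.age_width  # overlapping 10-year cohorts: centre +/- 5
        return CohortLabel(
            index=cohort_idx, center_year=center, span_years=(center - half, center + half)
        )

    # -- cell lookup ---------------------------------------------------------

    def age_index_of(self, age: int) -> Optional[int]:
        """1-based age-group index of an exact age, or None if below range.

        Ages at or above the top edge map to the open-ended top group.
        """
        edges = self.age_lower_edges
        if age < edges[0]:
            return None
        if age >= edges[-1]:
            return self.n_age
        return int((age - edges[0]) // self.age_width) + 1

    def period_index_of(self, year: int) -> Optional[int]:
        start = self.period_start_years[0]
        end = self.period_start_years[-1] + self.period_width
        if year < start or year >= end:
            return None
        return int((year - start) // self.period_width) + 1

    @property
    def study_years(self) -> range:
        return range(
            self.period_start_years[0],
            self.period_start_years[-1] + self.period_width,
        )


def default_grid() -> LexisGrid:
    """The study grid: 10 age groups 30-34..75+, 6 periods 1976-80..2001-05."""
    return LexisGrid()


@dataclass(frozen=True)
class CohortLabel:
    index: int
    center_year: int
    span_years: tuple[int, int]


def cohort_index(age_idx: int, period_idx: int, grid: LexisGrid) -> int:
    """Cohort index of grid cell ``(age_idx, period_idx)``, both 1-based.

    ``c = (n_age - age_idx) + period_idx``: the oldest-age/earliest-period
    cell is cohort 1 and the youngest-age/latest-period cell is cohort
    ``n_age + n_period - 1``.  ``period_idx`` may exceed ``n_period`` for
    projected periods.
    """
    if not 1 <= age_idx <= grid.n_age:
        raise ValueError(f"age_idx {age_idx} outside 1..{grid.n_age}")
    if period_idx < 1:
        raise ValueError("period_idx must be >= 1")
    return grid.n_age - age_idx + period_idx


# ---------------------------------------------------------------------------
# Death records and ICD filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeathRecord:
    age_at_death: int
    sex: str
    year_of_death: int
    icd_revision: int
    icd_code: str
    tpu_id: str

    def __post_init__(self) -> None:
        if self.age_at_death < 0:
            raise ValueError("age_at_death must be >= 0")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")


_ICD10_RE = re.compile(r"^I(\d{2})(?:\.?\d*)?$")
_NUMERIC_RE = re.compile(r"^(\d{3})\d*$")


def icd_matches_ihd(icd_code: str, icd_revision: int) -> bool:
    """True iff the code falls in the ischaemic-heart-disease range.

    ICD-8 and ICD-9 match on the leading three-digit rubric 410-414 after
    stripping punctuation (so decimal subcodes such as 414.9 or 4149 inherit
    the parent rubric's status); ICD-10 matches I20-I25 including subcodes
    (I21.4, I25.9, ...).  Unparseable codes raise :class:`ICDCodeError`
    rather than silently returning False.
    """
    code = str(icd_code).strip().upper().replace(" ", "")
    if icd_revision in (8, 9):
        stripped = code.replace(".", "")
        m = _NUMERIC_RE.match(stripped)
        if m is None:
            # supplementary E/V chapters are valid codes outside 410-414
            if re.match(r"^[EV]\d{2,}$", stripped):
                return False
            raise ICDCodeError(f"unparseable ICD-{icd_revision} code: {icd_code!r}")
        return 410 <= int(m.group(1)) <= 414
    if icd_revision == 10:
        m = _ICD10_RE.match(code)
        if m is not None:
            return 20 <= int(m.group(1)) <= 25
        # other chapters (letter + two digits) are valid non-IHD codes;
        # anything else is malformed and must be flagged, never False
        if code.startswith("I") or not re.match(r"^[A-Z]\d{2}(\.?\d*)?$", code):
            raise ICDCodeError(f"unparseable ICD-10 code: {icd_code!r}")
        return False
    raise ICDCodeError(f"unknown ICD revision: {icd_revision!r}")


def is_ihd(record: DeathRecord) -> bool:
    return icd_matches_ihd(record.icd_code, record.icd_revision)


def filter_ihd(
    records: Iterable[DeathRecord],
) -> tuple[list[DeathRecord], list[DeathRecord]]:
    """Split records into (IHD deaths, flagged-invalid records).

    Records whose code parses but is not in the IHD range are silently
    excluded; records with unparseable codes are returned in the second list
    so callers can report them.
    """
    kept: list[DeathRecord] = []
    invalid: list[DeathRecord] = []
    for rec in records:
        try:
            if is_ihd(rec):
                kept.append(rec)
        except ICDCodeError:
            invalid.append(rec)
    return kept, invalid


# ---------------------------------------------------------------------------
# Counts on the grid
# ---------------------------------------------------------------------------


@dataclass
class StratumCounts:
    """Deaths and person-years on a Lexis grid for one sex x income stratum.

    ``person_years`` is the annualised mid-year population summed over the
    calendar years of each period (population x period_width when the
    population is constant within the period).  It may be None while deaths
    are being accumulated, but must be strictly positive once set.
    """

    grid: LexisGrid
    sex: str
    income_group: str
    deaths: np.ndarray
    person_years: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shape = (self.grid.n_age, self.grid.n_period)
        self.deaths = np.asarray(self.deaths)
        if self.deaths.shape != shape:
            raise ValueError(f"deaths must have shape {shape}")
        if np.any(self.deaths < 0):
            raise ValueError("deaths must be non-negative")
        if self.person_years is not None:
            self.person_years = np.asarray(self.person_years, dtype=float)
            if self.person_years.shape != shape:
                raise ValueError(f"person_years must have shape {shape}")
            if np.any(self.person_years <= 0):
                raise ValueError("person_years must be strictly positive")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.income_group not in INCOME_GROUPS:
            raise ValueError(f"income_group must be one of {INCOME_GROUPS}")


@dataclass
class AggregateResult:
    """Outcome of aggregating individual deaths onto the grid."""

    deaths: dict[tuple[str, str], np.ndarray]
    n_retained: int
    dropped: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def aggregate(
    records: Iterable[DeathRecord],
    stratum_of: Callable[[DeathRecord], Optional[str]],
    grid: LexisGrid,
) -> AggregateResult:
    """Tally death records into (sex, income) x age x period cells.

    Records below the grid's first age group, outside the period window, or
    without an income-stratum assignment are counted in the ``dropped``
    tally (keyed by reason) rather than silently discarded, so
    ``n_retained + n_dropped`` always equals the number of input records.
    """
    deaths = {
        (sex, inc): np.zeros((grid.n_age, grid.n_period), dtype=int)
        for sex in SEXES
        for inc in INCOME_GROUPS
    }
    dropped: Counter = Counter()
    n_retained = 0
    for rec in records:
        a = grid.age_index_of(rec.age_at_death)
        if a is None:
            dropped["age_below_range"] += 1
            continue
        p = grid.period_index_of(rec.year_of_death)
        if p is None:
            dropped["year_out_of_range"] += 1
            continue
        stratum = stratum_of(rec)
        if stratum not in INCOME_GROUPS:
            dropped["unassigned_sep"] += 1
            continue
        deaths[(rec.sex, stratum)][a - 1, p - 1] += 1
        n_retained += 1
    return AggregateResult(deaths=deaths, n_retained=n_retained, dropped=dropped)


def aggregate_population(
    population: pd.DataFrame,
    stratum_of_tpu: Callable[[int, str], Optional[str]],
    grid: LexisGrid,
) -> dict[tuple[str, str], np.ndarray]:
    """Sum annual mid-year populations into person-years per stratum cell.

    ``population`` has columns ``age_group, sex, year, tpu_id, population``
    where ``age_group`` is a lower edge (30) or a grid label ("30-34",
    "75+").  ``stratum_of_tpu(year, tpu_id)`` returns "low"/"high"/None.
    Each in-window year contributes its population once, so a constant
    population contributes population x period_width person-years.
    """
    py = {
        (sex, inc): np.zeros((grid.n_age, grid.n_period), dtype=float)
        for sex in SEXES
        for inc in INCOME_GROUPS
    }
    label_to_idx = {lab: i + 1 for i, lab in enumerate(grid.age_labels)}
    for row in population.itertuples(index=False):
        ag = row.age_group
        if isinstance(ag, str) and ag in label_to_idx:
            a: Optional[int] = label_to_idx[ag]
        else:
            a = grid.age_index_of(int(ag))
        if a is None:
            continue
        p = grid.period_index_of(int(row.year))
        if p is None:
            continue
        stratum = stratum_of_tpu(int(row.year), str(row.tpu_id))
        if stratum not in INCOME_GROUPS:
            continue
        py[(str(row.sex), stratum)][a - 1, p - 1] += float(row.population)
    return py


def crude_rates(counts: StratumCounts) -> np.ndarray:
    """Age x period mortality rates per 100,000 person-years."""
    if counts.person_years is None:
        raise ValueError("person_years not set")
    return 1e5 * counts.deaths / counts.person_years


# ---------------------------------------------------------------------------
# Delimited-text interfaces
# ---------------------------------------------------------------------------


def read_deaths(path) -> list[DeathRecord]:
    """Read `age,sex,year,icd_revision,icd_code,tpu_id` delimited text."""
    df = pd.read_csv(path, dtype={"icd_code": str, "tpu_id": str})
    required = {"age", "sex", "year", "icd_revision", "icd_code", "tpu_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"deaths file missing columns: {sorted(missing)}")
    return [
        DeathRecord(
            age_at_death=int(r.age),
            sex=str(r.sex),
            year_of_death=int(r.year),
            icd_revision=int(r.icd_revision),
            icd_code=str(r.icd_code),
            tpu_id=str(r.tpu_id),
        )
        for r in df.itertuples(index=False)
    ]


def read_population(path) -> pd.DataFrame:
    """Read `age_group,sex,year,tpu_id,population` delimited text."""
    df = pd.read_csv(path, dtype={"tpu_id": str})
    required = {"age_group", "sex", "year", "tpu_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"population file missing columns: {sorted(missing)}")
    return df


def counts_to_frame(strata: Sequence[StratumCounts]) -> pd.DataFrame:
    """Long-format `sex,income,age_group,period,deaths,person_years`."""
    rows = []
    for sc in strata:
        g = sc.grid
        for a in range(1, g.n_age + 1):
            for p in range(1, g.n_period + 1):
                rows.append(
                    {
                        "sex": sc.sex,
                        "income": sc.income_group,
                        "age_group": g.age_label(a),
                        "period": g.period_label(p),
                        "deaths": int(sc.deaths[a - 1, p - 1]),
                        "person_years": (
                            float(sc.person_years[a - 1, p - 1])
                            if sc.person_years is not None
                            else np.nan
                        ),
                    }
                )
    return pd.DataFrame(rows)


def frame_to_counts(df: pd.DataFrame, grid: LexisGrid) -> list[StratumCounts]:
    """Inverse of :func:`counts_to_frame` on the given grid."""
    a_idx = {lab: i for i, lab in enumerate(grid.age_labels)}
    p_idx = {lab: i for i, lab in enumerate(grid.period_labels)}
    out = []
    for (sex, inc), sub in df.groupby(["sex", "income"], sort=True):
        deaths = np.zeros((grid.n_age, grid.n_period), dtype=int)
        py = np.zeros((grid.n_age, grid.n_period), dtype=float)
        for row in sub.itertuples(index=False):
            try:
                i, j = a_idx[row.age_group], p_idx[row.period]
            except KeyError as exc:
                raise ValueError(f"unknown grid cell label: {exc}") from exc
            deaths[i, j] = int(row.deaths)
            py[i, j] = float(row.person_years)
        out.append(
            StratumCounts(
                grid=grid,
                sex=str(sex),
                income_group=str(inc),
                deaths=deaths,
                person_years=py if np.all(py > 0) else None,
            )
        )
    return out
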