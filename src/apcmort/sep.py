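"""Neighbourhood (TPU) income classification.

Tertiary Planning Units are classified low/high income by a contemporaneous
median split of TPU-level median household income per capita: within each
census year, TPUs below the all-TPU median are "low", those at or above it
are "high".  Deaths and populations are then assigned the label of their
TPU at the census year nearest the event year (ties broken to the earlier
census).  The cut point is relative, so it moves with each census.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = [
    "TPUIncomeTable",
    "SEPAssignment",
    "UnassignedTPUError",
    "classify_tpus",
    "nearest_census_year",
    "stratum_of",
    "read_income_table",
    "assignment_to_frame",
]

DEFAULT_CENSUS_YEARS = (1976, 1981, 1986, 1991, 1996, 2001, 2006)


class UnassignedTPUError(KeyError):
    """Raised when a TPU has no income-group assignment for the chosen census."""


@dataclass
class TPUIncomeTable:
    """Median household income per capita by (tpu_id, census_year)."""

    census_years: tuple[int, ...]
    income: dict[tuple[str, int], float]

    def incomes_for_year(self, year: int) -> dict[str, float]:
        return {
            tpu: v for (tpu, y), v in self.income.items() if y == year
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tpu_id": tpu, "census_year": y, "median_income_per_capita": v}
            for (tpu, y), v in sorted(self.income.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TPUIncomeTable":
        income = {
            (str(r.tpu_id), int(r.census_year)): float(r.median_income_per_capita)
            for r in df.itertuples(index=False)
        }
        years = tuple(sorted({y for _, y in income}))
        return cls(census_years=years, income=income)


@dataclass
class SEPAssignment:
    """Low/high labels per (tpu_id, census_year) with per-census cutoffs."""

    labels: dict[tuple[str, int], str]
    cutoffs: dict[int, float]
    unassigned: list[tuple[str, int]] = field(default_factory=list)

    @property
    def census_years(self) -> tuple[int, ...]:
        return tuple(sorted(self.cutoffs))


def _lower_median(values: list[float]) -> float:
    # Even count: lower of the two middle order statistics, so at least one
    # TPU sits exactly at the cutoff and is labelled high ("equal to or
    # above the median" stays non-vacuous and deterministic).
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def classify_tpus(table: TPUIncomeTable) -> SEPAssignment:
    """Median-split classification, independently per census year.

    The cutoff is the unweighted median across TPUs; income strictly below
    it is "low", at or above it "high".  TPU-years with missing income are
    listed in ``unassigned``.
    """
    labels: dict[tuple[str, int], str] = {}
    cutoffs: dict[int, float] = {}
    unassigned: list[tuple[str, int]] = []
    for year in table.census_years:
        incomes = table.incomes_for_year(year)
        valid = {t: v for t, v in incomes.items() if v == v and v is not None}
        if len(valid) < 2:
            raise ValueError(f"census {year}: need >= 2 TPUs with income")
        cutoff = _lower_median(list(valid.values()))
        cutoffs[year] = cutoff
        for tpu, v in valid.items():
            labels[(tpu, year)] = "low" if v < cutoff else "high"
        for tpu in set(incomes) - set(valid):
            unassigned.append((tpu, year))
    return SEPAssignment(labels=labels, cutoffs=cutoffs, unassigned=unassigned)


def nearest_census_year(year: int, census_years) -> int:
    """Census year nearest ``year``; equidistant ties go to the earlier one."""
    if not census_years:
        raise ValueError("no census years available")
    return min(census_years, key=lambda c: (abs(year - c), c))


def stratum_of(record_year: int, tpu_id: str, assignment: SEPAssignment) -> str:
    """Income group of a TPU at the census nearest the event year."""
    census = nearest_census_year(record_year, assignment.census_years)
    try:
        return assignment.labels[(str(tpu_id), census)]
    except KeyError:
        raise UnassignedTPUError(
            f"TPU {tpu_id!r} not classified in census {census}"
        ) from None


def read_income_table(path) -> TPUIncomeTable:
    """Read `tpu_id,census_year,median_income_per_capita` delimited text."""
    df = pd.read_csv(path, dtype={"tpu_id": str})
    required = {"tpu_id", "census_year", "median_income_per_capita"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"income file missing columns: {sorted(missing)}")
    return TPUIncomeTable.from_frame(df)


def assignment_to_frame(assignment: SEPAssignment) -> pd.DataFrame:
    """Long-format `tpu_id,census_year,income_group,cutoff`."""
    rows = [
        {
            "tpu_id": tpu,
            "census_year": year,
            "income_group": lab,
            "cutoff": assignment.cutoffs[year],
        }
        for (tpu, year), lab in sorted(assignment.labels.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    ]
    return pd.DataFrame(rows)
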