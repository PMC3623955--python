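"""Lexis grid arithmetic, ICD filtering and aggregation."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import apcmort as m
from apcmort.lexis import (
    LexisGrid,
    counts_to_frame,
    frame_to_counts,
    icd_matches_ihd,
    read_deaths,
)


def make_grid(n_age, n_period):
    return LexisGrid(
        age_lower_edges=tuple(range(30, 30 + 5 * n_age, 5)),
        period_start_years=tuple(range(1976, 1976 + 5 * n_period, 5)),
    )


class TestCohortIndex:
    def test_definition_corners(self, grid):
        assert m.cohort_index(1, 1, grid) == 10
        assert m.cohort_index(10, 1, grid) == 1
        assert m.cohort_index(1, 6, grid) == 15

    def test_default_grid_yields_15_cohorts(self, grid):
        seen = {
            m.cohort_index(a, p, grid)
            for a in range(1, grid.n_age + 1)
            for p in range(1, grid.n_period + 1)
        }
        assert seen == set(range(1, 16))

    def test_projection_cells_extend_the_diagonals(self, grid):
        # youngest age in the third projected period sits on cohort 18;
        # brute-force enumeration of the 10 x 9 extended grid agrees
        assert m.cohort_index(1, 9, grid) == 18
        seen = {
            m.cohort_index(a, p, grid)
            for a in range(1, 11)
            for p in range(1, 10)
        }
        assert seen == set(range(1, 19))

    def test_out_of_range_age_raises(self, grid):
        with pytest.raises(ValueError):
            m.cohort_index(0, 1, grid)
        with pytest.raises(ValueError):
            m.cohort_index(11, 1, grid)

    @given(st.integers(2, 12), st.integers(2, 12))
    def test_diagonal_structure_any_grid(self, n_age, n_period):
        g = make_grid(n_age, n_period)
        vals = np.array(
            [
                [m.cohort_index(a, p, g) for p in range(1, n_period + 1)]
                for a in range(1, n_age + 1)
            ]
        )
        assert vals.min() == 1 and vals.max() == n_age + n_period - 1
        assert len(np.unique(vals)) == g.n_cohorts
        # +1 along periods, -1 along ages
        assert np.all(np.diff(vals, axis=1) == 1)
        assert np.all(np.diff(vals, axis=0) == -1)


class TestCohortLabels:
    def test_centres_are_equally_spaced_grid_years(self, grid):
        centres = [grid.cohort_center_year(c) for c in range(1, 19)]
        assert np.all(np.diff(centres) == 5)
        assert centres[0] == 1900
        assert grid.cohort_center_year(10) == 1945  # the male-upturn cohort

    def test_overlapping_ten_year_spans(self, grid):
        lab = grid.cohort_label(8)
        assert lab.span_years[1] - lab.span_years[0] == 10
        nxt = grid.cohort_label(9)
        assert nxt.center_year - lab.center_year == grid.age_width


class TestICD:
    @pytest.mark.parametrize(
        "code,rev,expected",
        [
            ("4149", 9, True),  # rubric 414 with subdigit
            ("410", 8, True),
            ("414.9", 9, True),
            ("409", 9, False),
            ("415", 8, False),
            ("I26", 10, False),
            ("I20", 10, True),
            ("I21.9", 10, True),
            ("I25.1", 10, True),
            ("i21.4", 10, True),  # case-insensitive
            ("E810", 9, False),  # external-cause chapter
        ],
    )
    def test_code_ranges(self, code, rev, expected):
        assert icd_matches_ihd(code, rev) is expected

    def test_icd10_subcode_enumeration(self):
        fixture = [f"I{n}" for n in range(20, 26)] + [
            f"I{n}.{s}" for n in range(20, 26) for s in range(10)
        ]
        assert all(icd_matches_ihd(c, 10) for c in fixture)

    @pytest.mark.parametrize("code,rev", [("??", 9), ("", 10), ("I2", 10), ("41", 9)])
    def test_unparseable_codes_are_flagged_not_false(self, code, rev):
        with pytest.raises(m.ICDCodeError):
            icd_matches_ihd(code, rev)

    def test_filter_separates_invalid_records(self):
        recs = [
            m.DeathRecord(70, "male", 1990, 9, "410", "T1"),
            m.DeathRecord(70, "male", 1990, 9, "250", "T1"),
            m.DeathRecord(70, "male", 1990, 9, "garbled", "T1"),
        ]
        kept, invalid = m.filter_ihd(recs)
        assert len(kept) == 1 and len(invalid) == 1


class TestAggregate:
    @staticmethod
    def _stratum(_rec):
        return "low"

    def test_open_ended_top_group(self, grid):
        rec = m.DeathRecord(77, "male", 1990, 9, "410", "T1")
        agg = m.aggregate([rec], self._stratum, grid)
        mat = agg.deaths[("male", "low")]
        assert mat[grid.n_age - 1, grid.period_index_of(1990) - 1] == 1
        assert agg.n_retained == 1 and agg.n_dropped == 0

    def test_empty_input_gives_all_zero_matrices(self, grid):
        agg = m.aggregate([], self._stratum, grid)
        assert all(np.all(v == 0) for v in agg.deaths.values())

    def test_matches_dictionary_tally_oracle(self, grid, rng):
        recs = []
        for _ in range(1000):
            recs.append(
                m.DeathRecord(
                    age_at_death=int(rng.integers(25, 95)),
                    sex=["female", "male"][int(rng.integers(2))],
                    year_of_death=int(rng.integers(1974, 2008)),
                    icd_revision=9,
                    icd_code="410",
                    tpu_id="T1",
                )
            )
        stratum = lambda r: ["low", "high"][r.year_of_death % 2]
        agg = m.aggregate(recs, stratum, grid)
        oracle: Counter = Counter()
        dropped = 0
        for r in recs:
            a = grid.age_index_of(r.age_at_death)
            p = grid.period_index_of(r.year_of_death)
            if a is None or p is None:
                dropped += 1
                continue
            oracle[(r.sex, stratum(r), a, p)] += 1
        for (sex, inc, a, p), n in oracle.items():
            assert agg.deaths[(sex, inc)][a - 1, p - 1] == n
        assert agg.n_retained + agg.n_dropped == len(recs)
        assert agg.n_dropped == dropped

    def test_drop_reasons_are_reported(self, grid):
        recs = [
            m.DeathRecord(20, "male", 1990, 9, "410", "T1"),  # under 30
            m.DeathRecord(60, "male", 2010, 9, "410", "T1"),  # after window
            m.DeathRecord(60, "male", 1990, 9, "410", "T1"),  # unassigned
        ]
        agg = m.aggregate(recs, lambda r: None, grid)
        assert agg.dropped["age_below_range"] == 1
        assert agg.dropped["year_out_of_range"] == 1
        assert agg.dropped["unassigned_sep"] == 1


class TestCrudeRates:
    def test_scalar_examples(self, grid):
        deaths = np.zeros((grid.n_age, grid.n_period), dtype=int)
        py = np.full((grid.n_age, grid.n_period), 1e5)
        deaths[0, 0] = 5
        counts = m.StratumCounts(grid, "male", "low", deaths, py)
        rates = m.crude_rates(counts)
        assert rates[0, 0] == 5.0
        assert rates[3, 3] == 0.0

    def test_matches_scalar_loop_oracle(self, grid, rng):
        deaths = rng.integers(0, 50, (grid.n_age, grid.n_period))
        py = rng.uniform(1e3, 1e6, (grid.n_age, grid.n_period))
        counts = m.StratumCounts(grid, "female", "high", deaths, py)
        rates = m.crude_rates(counts)
        for a in range(grid.n_age):
            for p in range(grid.n_period):
                assert rates[a, p] == pytest.approx(1e5 * deaths[a, p] / py[a, p])

    def test_positive_person_years_enforced(self, grid):
        deaths = np.zeros((grid.n_age, grid.n_period), dtype=int)
        py = np.zeros((grid.n_age, grid.n_period))
        with pytest.raises(ValueError):
            m.StratumCounts(grid, "male", "low", deaths, py)


class TestIO:
    def test_counts_frame_round_trip(self, grid, rng):
        deaths = rng.integers(0, 30, (grid.n_age, grid.n_period))
        py = rng.uniform(1e4, 1e6, (grid.n_age, grid.n_period))
        counts = m.StratumCounts(grid, "male", "low", deaths, py)
        back = frame_to_counts(counts_to_frame([counts]), grid)
        assert len(back) == 1
        assert np.array_equal(back[0].deaths, counts.deaths)
        assert np.allclose(back[0].person_years, counts.person_years)

    def test_read_deaths_requires_header(self, tmp_path):
        path = tmp_path / "deaths.csv"
        path.write_text("age,sex,year\n60,male,1990\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_deaths(path)

    def test_read_deaths_parses_records(self, tmp_path):
        path = tmp_path / "deaths.csv"
        path.write_text(
            "age,sex,year,icd_revision,icd_code,tpu_id\n"
            "61,male,1990,9,4149,T007\n"
            "45,female,2003,10,I21.4,T010\n"
        )
        recs = read_deaths(path)
        assert recs[0].icd_code == "4149" and recs[1].icd_revision == 10
        assert all(m.is_ihd(r) for r in recs)
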