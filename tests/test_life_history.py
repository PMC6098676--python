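"""Registry invariants, stage classification, PFC computation, benchmarks."""

import datetime as dt

import pytest

from rhinopfc.life_history import (
    ADULT,
    CALF,
    FEMALE,
    MALE,
    SUBADULT,
    ConsistencyError,
    LifeHistoryRecord,
    OutOfRangeError,
    RegistryError,
    UndefinedPFCError,
    add_months,
    births_from_census,
    census_summary,
    census_totals,
    classify_benchmark,
    classify_stage,
    compute_pfc,
    registry_from_census_year,
)


def female(id="f1", born=dt.date(2000, 1, 1), calvings=(), **kw):
    return LifeHistoryRecord(
        individual_id=id,
        sex=FEMALE,
        birth_date=born,
        entry_date=kw.pop("entry", born),
        calving_dates=tuple(calvings),
        **kw,
    )


class TestRecordInvariants:
    def test_male_with_calvings_rejected(self):
        with pytest.raises(RegistryError):
            LifeHistoryRecord(
                individual_id="m1",
                sex=MALE,
                birth_date=dt.date(2000, 1, 1),
                entry_date=dt.date(2000, 1, 1),
                calving_dates=(dt.date(2008, 1, 1),),
            )

    def test_calvings_closer_than_gestation_rejected(self):
        with pytest.raises(RegistryError, match="closer than 15 months"):
            female(calvings=[dt.date(2008, 1, 1), dt.date(2009, 1, 1)])

    def test_calvings_at_exactly_gestation_spacing_accepted(self):
        rec = female(calvings=[dt.date(2008, 1, 1), dt.date(2009, 4, 1)])
        assert len(rec.calving_dates) == 2

    def test_calving_outside_lifespan_rejected(self):
        with pytest.raises(RegistryError):
            female(calvings=[dt.date(2008, 1, 1)], exit_date=dt.date(2007, 1, 1),
                   exit_cause="death")

    def test_add_months_clamps_day(self):
        assert add_months(dt.date(2003, 1, 31), 1) == dt.date(2003, 2, 28)
        assert add_months(dt.date(2000, 10, 1), 15) == dt.date(2002, 1, 1)


class TestClassifyStage:
    @pytest.mark.parametrize(
        "born, calvings, date, expected",
        [
            # seven-year rule: adult without ever calving
            (dt.date(2000, 1, 1), (), dt.date(2007, 1, 1), ADULT),
            # calving confers adulthood on the calving day
            (dt.date(1998, 1, 1), (dt.date(2003, 6, 1),), dt.date(2003, 6, 1), ADULT),
            # age < 7, never calved: not adult
            (dt.date(2000, 1, 1), (), dt.date(2006, 12, 31), SUBADULT),
            (dt.date(2000, 1, 1), (), dt.date(2002, 1, 1), CALF),
        ],
    )
    def test_female_stages(self, born, calvings, date, expected):
        assert classify_stage(female(born=born, calvings=calvings), date) == expected

    def test_date_outside_lifespan_errors(self):
        rec = female(exit_date=dt.date(2005, 1, 1), exit_cause="death")
        with pytest.raises(OutOfRangeError):
            classify_stage(rec, dt.date(2006, 1, 1))
        with pytest.raises(OutOfRangeError):
            classify_stage(rec, dt.date(1999, 12, 31))

    def test_import_uses_imputed_age(self):
        imp = LifeHistoryRecord(
            individual_id="i1", sex=FEMALE, birth_date=None,
            entry_date=dt.date(1990, 6, 1), entry_stage=SUBADULT,
        )
        # imputed 5.25 y at entry -> adult ~1.75 y later
        assert classify_stage(imp, dt.date(1990, 7, 1)) == SUBADULT
        assert classify_stage(imp, dt.date(1993, 6, 1)) == ADULT


class TestComputePFC:
    def test_two_adults_one_birth(self):
        reg = [
            female("a", dt.date(1990, 1, 1), [dt.date(2004, 6, 1)]),
            female("b", dt.date(1990, 1, 1)),
        ]
        out = compute_pfc(reg, range(2004, 2005))
        assert out.loc[2004, "pfc"] == 0.5

    def test_part_year_adult_counts_in_denominator(self):
        # one female adult all year + one turning seven on July 1, one birth
        reg = [
            female("a", dt.date(1990, 1, 1), [dt.date(2004, 6, 1)]),
            female("b", dt.date(1997, 7, 1)),
        ]
        out = compute_pfc(reg, range(2004, 2005))
        assert out.loc[2004, "adult_female_count"] == 2
        assert out.loc[2004, "pfc"] == 0.5

    def test_mid_year_death_still_counts(self):
        reg = [
            female("a", dt.date(1990, 1, 1), [dt.date(2004, 6, 1)]),
            female("b", dt.date(1990, 1, 1), exit_date=dt.date(2004, 3, 1),
                   exit_cause="death"),
        ]
        assert compute_pfc(reg, range(2004, 2005)).loc[2004, "pfc"] == 0.5

    def test_zero_adult_females_is_an_error_not_zero(self):
        reg = [female("a", dt.date(2000, 1, 1))]  # still subadult in 2004
        with pytest.raises(UndefinedPFCError):
            compute_pfc(reg, range(2004, 2005))

    def test_table1_1994_row_equivalent(self):
        reg = registry_from_census_year(1994, 5, 4)
        assert compute_pfc(reg, range(1994, 1995)).loc[1994, "pfc"] == 0.8

    def test_births_never_exceed_denominator(self, base_config):
        from rhinopfc.simulate import simulate

        out = simulate(base_config)
        assert (out.pfc["births"] <= out.pfc["adult_female_count"]).all()


class TestBirthsFromCensus:
    @pytest.mark.parametrize("pfc, n, expected", [(0.8, 5, 4), (0.0, 1, 0)])
    def test_examples(self, pfc, n, expected):
        assert births_from_census(pfc, n) == expected

    def test_rounded_proportion_recovers_brute_force_minimizer(self):
        # independent oracle: minimize |pfc - x/n| over all integer numerators
        pfc, n = 0.6471, 17
        oracle = min(range(n + 1), key=lambda x: abs(pfc - x / n))
        assert oracle == 11
        assert births_from_census(pfc, n) == oracle

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ConsistencyError):
            births_from_census(0.5, 17)  # 0.5 not representable as x/17 +- 0.5/17

    def test_fixture_pfc_column_round_trips(self, study_census):
        # census -> integer births -> synthetic registry -> PFC to 4 dp
        for year, row in study_census.dropna(subset=["pfc"]).iterrows():
            n = int(row["f_adult"])
            births = births_from_census(row["pfc"], n)
            reg = registry_from_census_year(year, n, births)
            got = compute_pfc(reg, range(year, year + 1)).loc[year, "pfc"]
            assert abs(got - row["pfc"]) < 0.5 / n
            assert round(abs(got - births / n), 4) == 0


class TestCensusSummary:
    def test_founders_1986_row(self):
        founders = [
            LifeHistoryRecord("f-sub", FEMALE, None, dt.date(1986, 7, 1), SUBADULT),
            LifeHistoryRecord("f-ad", FEMALE, None, dt.date(1986, 7, 1), ADULT),
            LifeHistoryRecord("m-ad", MALE, None, dt.date(1986, 7, 1), ADULT),
        ]
        table = census_summary(founders, range(1986, 1987))
        row = table.loc[1986]
        assert row["f_subadult"] == 1 and row["f_adult"] == 1 and row["m_adult"] == 1
        assert row["f_calf"] == row["m_calf"] == row["m_subadult"] == 0
        assert row["f_subadult_imports"] == 1 and row["f_adult_imports"] == 1

    def test_empty_registry_is_all_zero(self):
        table = census_summary([], range(2000, 2003))
        assert (table == 0).all().all()

    def test_fixture_2008_total(self, study_census):
        assert census_totals(study_census).loc[2008] == 110


class TestBenchmark:
    @pytest.mark.parametrize(
        "pfc, band",
        [
            (0.26, "very poor-poor"),
            (0.45, "good-excellent"),
            (0.335, "mod-good"),
            (0.29, "poor-mod"),
            (0.40, "mod-good"),  # 0.40 is not yet good-excellent
            (0.0, "very poor-poor"),
            (1.0, "good-excellent"),
        ],
    )
    def test_bands(self, pfc, band):
        assert classify_benchmark(pfc) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_benchmark(1.2)


class TestFixtureStructure:
    def test_pfc_mean(self, study_census):
        assert round(study_census["pfc"].dropna().mean(), 2) == 0.40

    def test_imports_sum_to_23(self, study_census):
        imports = study_census[[c for c in study_census.columns if c.endswith("_imports")]]
        assert imports.to_numpy().sum() == 23

    def test_exports_sum_to_5(self, study_census):
        exports = study_census[[c for c in study_census.columns if c.endswith("_exports")]]
        assert exports.to_numpy().sum() == 5

    def test_adult_females_monotone_1_to_29(self, study_census):
        fa = study_census["f_adult"]
        assert fa.iloc[0] == 1 and fa.iloc[-1] == 29
        assert fa.is_monotonic_increasing
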