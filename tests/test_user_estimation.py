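"""The numerator engine: conversions, carryover, back-casting, aggregation.

Expected values for the cohort arithmetic are frozen from a brute-force
per-cohort oracle (each insertion cohort followed through the curve by
explicit enumeration) computed independently of the estimator.
"""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ss2emu import (
    ContinuationCurve,
    HistoricScenario,
    ServiceStatisticsTable,
    cyp_credited,
    estimate_users,
    ltm_continuing_users,
    ltm_current_users,
    ltm_historic_users,
    short_term_users,
)


def brute_force_cohort_users(cohorts: dict, curve: tuple, t: int) -> float:
    """Oracle: enumerate each cohort's contribution in year t explicitly."""
    total = 0.0
    for y, c in cohorts.items():
        age = t - y + 1
        if 1 <= age <= len(curve):
            total += c * curve[age - 1]
    return total


class TestShortTermUsers:
    def test_four_injectable_doses_is_one_user(self):
        assert short_term_users(4, 4) == 1.0

    @pytest.mark.parametrize(
        "count, upc, expected",
        [(0, 4, 0.0), (120, 120, 1.0), (15, 15, 1.0), (30, 15, 2.0)],
    )
    def test_cyp_division(self, count, upc, expected):
        assert short_term_users(count, upc) == expected

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            short_term_users(10, 0)


class TestLtmCurrentUsers:
    def test_hundred_copper_t_gives_92(self, iud_curve):
        assert ltm_current_users(100, iud_curve) == 92.0

    def test_zero_and_identity_curve(self, iud_curve):
        assert ltm_current_users(0, iud_curve) == 0.0
        assert ltm_current_users(50, ContinuationCurve((1.0,))) == 50.0


class TestLtmContinuingUsers:
    def test_copper_t_cohort_years_two_and_three(self, iud_curve):
        assert ltm_continuing_users({2020: 100}, iud_curve, t=2021) == 77.0
        assert ltm_continuing_users({2020: 100}, iud_curve, t=2022) == 65.0

    def test_empty_cohorts(self, iud_curve):
        assert ltm_continuing_users({}, iud_curve, t=2025) == 0.0

    def test_two_cohorts_match_sum_rule(self, iud_curve):
        got = ltm_continuing_users({2019: 100, 2020: 100}, iud_curve, t=2021)
        expected = 100 * iud_curve.at(3) + 100 * iud_curve.at(2)
        assert got == expected

    def test_future_cohort_rejected(self, iud_curve):
        with pytest.raises(ValueError, match="2022"):
            ltm_continuing_users({2022: 10}, iud_curve, t=2021)

    @given(
        cohorts=st.dictionaries(
            st.integers(min_value=2010, max_value=2019),
            st.floats(min_value=0, max_value=1e6),
            max_size=8,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, cohorts, iud_curve):
        # oracle counts all non-current cohorts; estimator must agree for
        # any window starting at or before the earliest cohort
        t = 2020
        got = ltm_continuing_users(cohorts, iud_curve, t=t, t0=2010)
        want = brute_force_cohort_users(cohorts, iud_curve.values, t)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-9)


class TestLtmHistoricUsers:
    def test_no_historic_is_zero(self, iud_curve):
        assert ltm_historic_users(1e6, iud_curve, "no_historic", 2025, 2020, 10) == 0.0

    def test_at_scale_first_year_direct_sum(self, iud_curve):
        # oracle: C * (Con(2) + Con(3) + ... ) with terms past the curve zero
        want = 100 * sum(iud_curve.at(x + 2) for x in range(0, 11))
        got = ltm_historic_users(100, iud_curve, "at_scale", t=2020, t0=2020, l_max=10)
        assert got == pytest.approx(want)

    @given(
        c0=st.floats(min_value=0, max_value=1e6),
        dt=st.integers(min_value=0, max_value=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_scaling_up_is_half_at_scale(self, c0, dt, iud_curve):
        at_scale = ltm_historic_users(c0, iud_curve, "at_scale", 2020 + dt, 2020, 10)
        scaling = ltm_historic_users(c0, iud_curve, "scaling_up", 2020 + dt, 2020, 10)
        assert scaling == pytest.approx(0.5 * at_scale)

    @pytest.mark.parametrize("scenario", ["at_scale", "scaling_up"])
    def test_washout_beyond_duration(self, scenario, iud_curve):
        # once t - t0 >= L_max - 1 every summand is past the curve support
        for dt in range(9, 14):
            assert ltm_historic_users(1e5, iud_curve, scenario, 2020 + dt, 2020, 10) == 0.0


def _stats(rows):
    return ServiceStatisticsTable(
        pd.DataFrame(rows, columns=["year", "method", "ss_type", "count"])
    )


class TestEstimateUsers:
    def test_single_method_matches_unit_operations(self, registry, iud_curve, simple_stats):
        series = estimate_users(simple_stats, registry)
        ss = "commodities_clients"
        assert series.component(2020, "iud_copper_t", ss, "current") == 92.0
        assert series.component(2021, "iud_copper_t", ss, "continuing") == 77.0
        assert series.component(2022, "iud_copper_t", ss, "continuing") == 65.0
        assert series.component(2020, "iud_copper_t", ss, "historic") == 0.0

    def test_total_is_exact_component_sum(self, registry):
        stats = _stats(
            [(y, "iud_copper_t", "commodities_clients", 50 + 10 * i)
             for i, y in enumerate(range(2018, 2024))]
        )
        series = estimate_users(stats, registry, scenarios={"iud_copper_t": "at_scale"})
        df = series.data
        assert (df["total"] == df["current"] + df["continuing"] + df["historic"]).all()

    def test_short_term_has_no_carryover(self, registry):
        stats = _stats([(2020, "pill", "commodities_clients", 150),
                        (2021, "pill", "commodities_clients", 300)])
        df = estimate_users(stats, registry).data
        assert (df["continuing"] == 0).all() and (df["historic"] == 0).all()
        assert df["current"].tolist() == [10.0, 20.0]

    def test_users_ss_type_passes_through(self, registry):
        stats = _stats([(2020, "iud_copper_t", "users", 1234)])
        df = estimate_users(stats, registry).data
        assert df["current"].tolist() == [1234.0]
        assert df["continuing"].tolist() == [0.0]

    def test_exclusion_removes_method_from_totals(self, registry):
        stats = _stats(
            [(2020, "condom", "commodities_clients", 1200),
             (2020, "pill", "commodities_clients", 150)]
        )
        with_condoms = estimate_users(stats, registry)
        without = estimate_users(stats, registry, exclusions={"condom"})
        assert "condom" not in set(without.data["method"])
        num_with = with_condoms.numerator()["total"].sum()
        num_without = without.numerator()["total"].sum()
        assert num_with - num_without == pytest.approx(10.0)  # 1200/120

    def test_two_methods_additive(self, registry):
        a = _stats([(2020, "iud_copper_t", "commodities_clients", 100)])
        b = _stats([(2020, "implant", "commodities_clients", 200)])
        both = _stats(
            [(2020, "iud_copper_t", "commodities_clients", 100),
             (2020, "implant", "commodities_clients", 200)]
        )
        sep = (
            estimate_users(a, registry).numerator()["total"].sum()
            + estimate_users(b, registry).numerator()["total"].sum()
        )
        joint = estimate_users(both, registry).numerator()["total"].sum()
        assert joint == pytest.approx(sep)

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_counts(self, scale, registry):
        base = [(2019, "iud_copper_t", "commodities_clients", 80.0),
                (2020, "iud_copper_t", "commodities_clients", 120.0),
                (2020, "pill", "commodities_clients", 450.0)]
        s1 = estimate_users(_stats(base), registry,
                            scenarios={"iud_copper_t": "scaling_up"})
        scaled = [(y, m, s, c * scale) for y, m, s, c in base]
        s2 = estimate_users(_stats(scaled), registry,
                            scenarios={"iud_copper_t": "scaling_up"})
        assert s2.data["total"].to_numpy() == pytest.approx(
            scale * s1.data["total"].to_numpy(), rel=1e-12
        )

    def test_impulse_series_non_increasing_after_insertion(self, registry):
        rows = [(2020, "iud_copper_t", "commodities_clients", 500)]
        rows += [(y, "iud_copper_t", "commodities_clients", 0) for y in range(2021, 2032)]
        df = estimate_users(_stats(rows), registry).data.sort_values("year")
        totals = df["total"].tolist()
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        assert totals[-1] == 0.0  # beyond the 10-year curve everyone is gone

    def test_cohort_conservation_against_ledger(self, registry, iud_curve):
        # a single cohort's users, summed over all years, equal C * sum(Con)
        rows = [(2020, "iud_copper_t", "commodities_clients", 250)]
        rows += [(y, "iud_copper_t", "commodities_clients", 0) for y in range(2021, 2031)]
        df = estimate_users(_stats(rows), registry).data
        attributed = (df["current"] + df["continuing"]).sum()
        ledger = 250 * sum(iud_curve.values)
        assert attributed == pytest.approx(ledger, rel=1e-9)

    def test_gap_year_contributes_zero_current_but_no_historic(self, registry):
        rows = [(2018, "iud_copper_t", "commodities_clients", 100),
                (2020, "iud_copper_t", "commodities_clients", 100)]
        df = estimate_users(_stats(rows), registry).data.set_index("year")
        assert df.loc[2019, "current"] == 0.0
        assert df.loc[2019, "continuing"] == pytest.approx(77.0)
        assert (df["historic"] == 0).all()  # no scenario declared -> no_historic

    def test_historic_washout_with_ten_years_of_data(self, registry):
        rows = [(y, "iud_copper_t", "commodities_clients", 100) for y in range(2010, 2021)]
        df = estimate_users(
            _stats(rows), registry, scenarios={"iud_copper_t": "at_scale"}
        ).data.set_index("year")
        assert df.loc[2020, "historic"] == 0.0
        assert df.loc[2010, "historic"] > 0.0

    def test_unknown_method_raises(self, registry):
        with pytest.raises(KeyError, match="patch"):
            estimate_users(_stats([(2020, "patch", "visits", 5)]), registry)


def test_cyp_credit_examples(registry):
    iud = registry["iud_copper_t"]
    assert cyp_credited(10, iud, "commodities_clients") == pytest.approx(46.0)
    assert cyp_credited(1, iud, "commodities_clients") == pytest.approx(4.6)
    inj = registry["injectable_dmpa_im"]
    assert cyp_credited(4, inj, "commodities_clients") == 1.0
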