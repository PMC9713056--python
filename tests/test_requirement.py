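"""Requirement arithmetic: core term, allowance factors, total, rounding."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wisn import (
    ActivityStandard,
    AllowanceSummary,
    AvailableWorkingTime,
    AWTComponents,
    Category,
    ServiceStatistics,
    StandardWorkload,
    TimeUnit,
    WisnError,
    compute_awt,
    compute_caf,
    compute_core_requirement,
    compute_iaf,
    compute_requirement,
    compute_total_requirement,
    round_requirement,
)


def _sw(activity, clients):
    return StandardWorkload(cadre="N/M", activity=activity, clients_per_year=clients)


def _stats(counts):
    return ServiceStatistics(facility="F", year=2019, counts=counts)


class TestCoreRequirement:
    def test_all_zero_counts_need_no_staff(self):
        sw = {"antenatal care": _sw("Antenatal care", 9456)}
        assert compute_core_requirement(_stats({"Antenatal care": 0}), sw) == 0.0

    def test_exactly_one_annual_workload_is_one_staff(self):
        sw = {"antenatal care": _sw("Antenatal care", 9456)}
        assert compute_core_requirement(_stats({"Antenatal care": 9456}), sw) == pytest.approx(1.0)

    def test_two_half_workloads_sum_to_one(self):
        sw = {
            "antenatal care": _sw("Antenatal care", 9456),
            "delivery": _sw("Delivery", 1576),
        }
        stats = _stats({"Antenatal care": 4728, "Delivery": 788})
        assert compute_core_requirement(stats, sw) == pytest.approx(1.0)

    def test_positive_count_without_workload_names_the_activity(self):
        with pytest.raises(WisnError, match="delivery"):
            compute_core_requirement(_stats({"Delivery": 10}), {})

    def test_names_match_after_trim_and_casefold(self):
        sw = {"antenatal care": _sw("Antenatal care", 100)}
        assert compute_core_requirement(_stats({"  ANTENATAL CARE ": 50}), sw) == pytest.approx(0.5)


def _support(minutes_per_day):
    return ActivityStandard(
        cadre="N/M", activity="Documentation on patients", category=Category.SUPPORT,
        time_value=minutes_per_day, time_unit=TimeUnit.MINUTES_PER_DAY,
    )


def _individual(minutes_per_day, activity="General administration"):
    return ActivityStandard(
        cadre="N/M", activity=activity, category=Category.INDIVIDUAL,
        time_value=minutes_per_day, time_unit=TimeUnit.MINUTES_PER_DAY,
    )


class TestAllowances:
    def test_no_support_work_gives_neutral_factor(self, awt_198):
        cas, caf = compute_caf([], awt_198)
        assert cas == 0.0 and caf == 1.0

    def test_twenty_percent_support_inflates_by_1_25(self, awt_198):
        # 20% of an 8-hour day is 96 minutes/day
        cas, caf = compute_caf([_support(96)], awt_198)
        assert cas == pytest.approx(20.0)
        assert caf == pytest.approx(1.25)

    def test_support_consuming_whole_day_is_an_error(self, awt_198):
        with pytest.raises(WisnError, match="support"):
            compute_caf([_support(480)], awt_198)

    def test_no_individual_work_gives_zero_iaf(self, awt_198):
        ias, iaf = compute_iaf([], awt_198)
        assert ias == 0.0 and iaf == 0.0

    def test_full_year_of_individual_work_is_one_staff(self, awt_198):
        ias, iaf = compute_iaf([_individual(480)], awt_198)
        assert ias == pytest.approx(awt_198.awt_hours)
        assert iaf == pytest.approx(1.0)

    def test_quarter_time_individual_load(self, awt_198):
        # 396 h/year against 1584 available hours
        ias, iaf = compute_iaf([_individual(120)], awt_198)
        assert ias == pytest.approx(396.0)
        assert iaf == pytest.approx(0.25)


def _allow(caf=1.0, iaf=0.0):
    cas = 100.0 - 100.0 / caf
    return AllowanceSummary(cadre="N/M", total_cas=cas, caf=caf, total_ias=0.0, iaf=iaf)


class TestTotalRequirement:
    @pytest.mark.parametrize(
        "core,caf,iaf,expected_raw,expected",
        [
            (1.0, 1.0, 0.0, 1.0, 1),
            (4.0, 1.25, 0.5, 5.5, 6),      # allowances inflate then round half-up
            (0.0, 1.3, 0.4, 0.4, 0),       # allowance-only facility
        ],
    )
    def test_caf_core_plus_iaf(self, core, caf, iaf, expected_raw, expected):
        res = compute_total_requirement("F", core, _allow(caf, iaf))
        assert res.required_raw == pytest.approx(expected_raw)
        assert res.required == expected

    @pytest.mark.parametrize(
        "raw,expected", [(5.5, 6), (3.0, 3), (10.49, 10), (0.5, 1), (0.4999, 0)]
    )
    def test_half_up_rounding(self, raw, expected):
        assert round_requirement(raw) == expected

    def test_ceil_mode(self):
        assert round_requirement(3.01, mode="ceil") == 4
        assert round_requirement(3.0, mode="ceil") == 3

    def test_negative_requirement_rejected(self):
        with pytest.raises(WisnError):
            round_requirement(-0.1)

    @given(
        raw=st.floats(min_value=0, max_value=100),
        bump=st.floats(min_value=0, max_value=10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_rounding_is_monotone(self, raw, bump):
        assert round_requirement(raw + bump) >= round_requirement(raw)


# ------------------------------------------------------------------ oracle

instances = st.fixed_dictionaries(
    {
        "possible_days": st.floats(min_value=200, max_value=300),
        "days_off": st.floats(min_value=0, max_value=100),
        "hours_per_day": st.floats(min_value=4, max_value=12),
        "core": st.lists(
            st.tuples(
                st.floats(min_value=1, max_value=60),      # minutes/client
                st.integers(min_value=0, max_value=20000), # annual count
            ),
            min_size=1,
            max_size=5,
        ),
        "support_min_per_day": st.lists(
            st.floats(min_value=0, max_value=60), max_size=3
        ),
        "individual_min_per_day": st.lists(
            st.floats(min_value=0, max_value=60), max_size=3
        ),
    }
)


def _spreadsheet_oracle(inst) -> float:
    """Single fused expression, no intermediate types: the hand calculation
    a planner would do in one spreadsheet cell."""
    awt_h = (inst["possible_days"] - inst["days_off"]) * inst["hours_per_day"]
    awt_d = inst["possible_days"] - inst["days_off"]
    core = sum(count * minutes / 60.0 / awt_h for minutes, count in inst["core"])
    cas = 100.0 * sum(m * awt_d / 60.0 for m in inst["support_min_per_day"]) / awt_h
    iaf = sum(m * awt_d / 60.0 for m in inst["individual_min_per_day"]) / awt_h
    return (100.0 / (100.0 - cas)) * core + iaf


@given(inst=instances)
@settings(max_examples=100, derandomize=True, deadline=1000)
def test_requirement_matches_fused_spreadsheet_oracle(inst):
    """The typed pipeline and a one-expression recomputation must agree."""
    comp = AWTComponents(
        cadre="N/M",
        possible_working_days=inst["possible_days"],
        official_leave=inst["days_off"],
        hours_per_working_day=inst["hours_per_day"],
    )
    awt = compute_awt(comp)
    standards = [
        ActivityStandard(
            cadre="N/M", activity=f"core {i}", category=Category.CORE,
            time_value=minutes, time_unit=TimeUnit.MINUTES_PER_CLIENT,
        )
        for i, (minutes, _) in enumerate(inst["core"])
    ]
    standards += [
        ActivityStandard(
            cadre="N/M", activity=f"support {i}", category=Category.SUPPORT,
            time_value=m, time_unit=TimeUnit.MINUTES_PER_DAY,
        )
        for i, m in enumerate(inst["support_min_per_day"])
    ]
    standards += [
        ActivityStandard(
            cadre="N/M", activity=f"individual {i}", category=Category.INDIVIDUAL,
            time_value=m, time_unit=TimeUnit.MINUTES_PER_DAY,
        )
        for i, m in enumerate(inst["individual_min_per_day"])
    ]
    stats = ServiceStatistics(
        facility="F", year=2019,
        counts={f"core {i}": count for i, (_, count) in enumerate(inst["core"])},
    )
    result = compute_requirement(stats, standards, awt)
    assert result.required_raw == pytest.approx(_spreadsheet_oracle(inst), rel=1e-9, abs=1e-9)


@given(inst=instances, k=st.integers(min_value=2, max_value=5))
@settings(max_examples=50, derandomize=True, deadline=1000)
def test_scaling_counts_scales_core_term_exactly(inst, k):
    """Multiplying all annual counts by k multiplies (raw - IAF) by k."""
    base = _build_and_run(inst)
    scaled_inst = dict(inst)
    scaled_inst["core"] = [(m, c * k) for m, c in inst["core"]]
    scaled = _build_and_run(scaled_inst)
    assert scaled.required_raw - scaled.iaf == pytest.approx(
        k * (base.required_raw - base.iaf), rel=1e-9, abs=1e-9
    )


@given(inst=instances, extra=st.integers(min_value=1, max_value=1000))
@settings(max_examples=50, derandomize=True, deadline=1000)
def test_more_clients_never_need_fewer_staff(inst, extra):
    base = _build_and_run(inst)
    bumped_inst = dict(inst)
    m0, c0 = inst["core"][0]
    bumped_inst["core"] = [(m0, c0 + extra)] + inst["core"][1:]
    bumped = _build_and_run(bumped_inst)
    assert bumped.required_raw >= base.required_raw - 1e-12


def _build_and_run(inst):
    comp = AWTComponents(
        cadre="N/M",
        possible_working_days=inst["possible_days"],
        official_leave=inst["days_off"],
        hours_per_working_day=inst["hours_per_day"],
    )
    awt = compute_awt(comp)
    standards = (
        [
            ActivityStandard(
                cadre="N/M", activity=f"core {i}", category=Category.CORE,
                time_value=m, time_unit=TimeUnit.MINUTES_PER_CLIENT,
            )
            for i, (m, _) in enumerate(inst["core"])
        ]
        + [
            ActivityStandard(
                cadre="N/M", activity=f"support {i}", category=Category.SUPPORT,
                time_value=m, time_unit=TimeUnit.MINUTES_PER_DAY,
            )
            for i, m in enumerate(inst["support_min_per_day"])
        ]
        + [
            ActivityStandard(
                cadre="N/M", activity=f"individual {i}", category=Category.INDIVIDUAL,
                time_value=m, time_unit=TimeUnit.MINUTES_PER_DAY,
            )
            for i, m in enumerate(inst["individual_min_per_day"])
        ]
    )
    stats = ServiceStatistics(
        facility="F", year=2019,
        counts={f"core {i}": c for i, (_, c) in enumerate(inst["core"])},
    )
    return compute_requirement(stats, standards, awt)
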