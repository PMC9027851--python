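"""Avoided clinical events and their savings against the published grids."""

import pytest

from cmm_bia import event_savings_ledger
from cmm_bia.event_savings import (
    avoided_events,
    effective_risk_reduction,
    event_unit_cost,
    spec_risk_reduction,
)

DMT2_CVD = "DMT2+CVD"
CVD = "CVD"

# Published savings grid (EUR) per (event, group), frozen from the
# event-savings result table. Years 2022-2024.
PUBLISHED_SAVINGS = {
    ("Heart failure", DMT2_CVD): [424_072, 599_637, 778_672],
    ("Heart failure", CVD): [376_707, 532_664, 691_702],
    ("Stroke", DMT2_CVD): [147_328, 208_322, 270_521],
    ("Stroke", CVD): [321_921, 455_197, 591_105],
    ("Myocardial infarction - fatal", DMT2_CVD): [28_627, 40_479, 52_564],
    ("Myocardial infarction - fatal", CVD): [62_552, 88_448, 114_856],
    ("Myocardial infarction - nonfatal", DMT2_CVD): [44_213, 62_517, 81_183],
    ("Myocardial infarction - nonfatal", CVD): [45_176, 63_879, 82_952],
    ("Angina", DMT2_CVD): [34_352, 48_574, 63_077],
    ("Angina", CVD): [50_736, 71_741, 93_161],
    ("Revascularization - stenotic coronary arteries", DMT2_CVD): [6_123, 8_658, 11_243],
    ("Revascularization - stenotic coronary arteries", CVD): [13_379, 18_918, 24_567],
}
PUBLISHED_YEARLY_SAVINGS = [1_555_187, 2_199_035, 2_855_604]
PUBLISHED_TOTAL_SAVINGS = 6_609_827

# Published per-cell rounded avoided-event counts.
PUBLISHED_EVENTS = {
    ("Heart failure", DMT2_CVD): [88, 124, 161],
    ("Heart failure", CVD): [78, 110, 143],
    ("Stroke", DMT2_CVD): [47, 66, 86],
    ("Stroke", CVD): [103, 145, 189],
    ("Myocardial infarction - fatal", DMT2_CVD): [33, 47, 61],
    ("Myocardial infarction - fatal", CVD): [72, 102, 133],
    ("Myocardial infarction - nonfatal", DMT2_CVD): [51, 72, 94],
    ("Myocardial infarction - nonfatal", CVD): [52, 74, 96],
    ("Angina", DMT2_CVD): [40, 56, 73],
    ("Angina", CVD): [59, 83, 108],
    ("Revascularization - stenotic coronary arteries", DMT2_CVD): [7, 10, 13],
    ("Revascularization - stenotic coronary arteries", CVD): [15, 22, 28],
}


class TestEffectiveRiskReduction:
    def test_heart_failure_dmt2_cvd(self):
        assert effective_risk_reduction(23.86, 0.40, 0.9) == pytest.approx(0.0085896)

    def test_stroke_dmt2_cvd(self):
        assert effective_risk_reduction(14.60, 0.35, 0.9) == pytest.approx(0.0045990)

    def test_no_guideline_effect(self):
        assert effective_risk_reduction(50.0, 0.0, 0.9) == 0

    def test_efficiency_scales_guideline_percentages(self):
        # the 10% efficiency decrement multiplies the guideline percentage
        # before use: 40 -> 36, 35 -> 31.5, 20 -> 18
        assert effective_risk_reduction(1000, 0.40, 0.9) == pytest.approx(0.36)
        assert effective_risk_reduction(1000, 0.35, 0.9) == pytest.approx(0.315)
        assert effective_risk_reduction(1000, 0.20, 0.9) == pytest.approx(0.18)


class TestEventUnitCost:
    def test_heart_failure_includes_pacemaker(self, croatia):
        spec = next(
            e for e in croatia.event_specs
            if e.event == "Heart failure" and e.group == DMT2_CVD
        )
        assert event_unit_cost(spec) == pytest.approx(1_182.24 + 1_176.00 + 2_473.95)

    def test_fatal_mi_has_no_followup(self, croatia):
        spec = next(
            e for e in croatia.event_specs
            if e.event == "Myocardial infarction - fatal" and e.group == DMT2_CVD
        )
        assert event_unit_cost(spec) == pytest.approx(864.79)

    def test_override_takes_precedence(self, croatia):
        spec = next(
            e for e in croatia.event_specs
            if e.event == "Angina" and e.group == DMT2_CVD
        )
        assert spec.inpatient_cost + spec.followup_cost == pytest.approx(2_303.51)
        assert event_unit_cost(spec) == pytest.approx(864.79)

    def test_all_zero_components(self, croatia):
        spec = croatia.event_specs[0].model_copy(
            update={"inpatient_cost": 0.0, "followup_cost": 0.0, "device_cost": 0.0}
        )
        assert event_unit_cost(spec) == 0


class TestAvoidedEvents:
    def test_heart_failure_year1(self):
        expected, rounded = avoided_events(10_217, 0.0085896)
        assert expected == pytest.approx(87.76, abs=0.01)
        assert rounded == 88

    def test_stroke_cvd_override_year1(self):
        expected, rounded = avoided_events(22_325, 0.0045990)
        assert expected == pytest.approx(102.67, abs=0.01)
        assert rounded == 103

    def test_zero_enrolled(self):
        assert avoided_events(0, 0.5) == (0, 0)


class TestPublishedTablesLedger:
    def test_every_savings_cell(self, croatia, result):
        ledger = result.events
        for (event, group), cells in PUBLISHED_SAVINGS.items():
            for year, expected in zip(croatia.years, cells):
                got = ledger.savings.loc[(event, group), year]
                tol = max(abs(expected) * 1e-3, 5.0)
                assert got == pytest.approx(expected, abs=tol), (event, group, year)

    def test_every_rounded_event_cell(self, croatia, result):
        ledger = result.events
        for (event, group), cells in PUBLISHED_EVENTS.items():
            got = [int(ledger.rounded_events.loc[(event, group), y]) for y in croatia.years]
            assert got == cells, (event, group)

    def test_totals(self, croatia, result):
        ledger = result.events
        for year, expected in zip(croatia.years, PUBLISHED_YEARLY_SAVINGS):
            assert ledger.yearly_savings_totals[year] == pytest.approx(expected, rel=5e-4)
        assert ledger.grand_total_savings == pytest.approx(
            PUBLISHED_TOTAL_SAVINGS, rel=5e-4
        )

    def test_savings_use_unrounded_events(self, croatia, result):
        # pricing the rounded counts cannot reproduce every published cell;
        # pricing the unrounded expectations can (checked above)
        ledger = result.events
        mismatches = 0
        for (event, group), cells in PUBLISHED_SAVINGS.items():
            spec = next(
                e for e in croatia.event_specs
                if (e.event, e.group) == (event, group)
            )
            cost = event_unit_cost(spec)
            for year, expected in zip(croatia.years, cells):
                rounded_based = ledger.rounded_events.loc[(event, group), year] * cost
                if abs(rounded_based - expected) > max(abs(expected) * 1e-3, 5.0):
                    mismatches += 1
        assert mismatches > 0


class TestAsStatedLedger:
    def test_stroke_cvd_2022_from_literal_parameters(self, croatia_stated, result_stated):
        # independent recomputation from the literal parameter-table values
        enrolled_cvd_2022 = (765_687 - 240_398) * 0.85 * 0.05
        rr = 7.70 / 1000 * 0.35 * 0.9
        expected = enrolled_cvd_2022 * rr * 3_135.45
        got = result_stated.events.savings.loc[("Stroke", CVD), 2022]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(169_787, rel=2e-4)

    def test_mode_contrast_limited_to_override_families(self, result, result_stated):
        a = result.events.savings
        b = result_stated.events.savings
        differing = {
            idx for idx in a.index if abs(a.loc[idx, "total"] - b.loc[idx, "total"]) > 1e-6
        }
        assert differing == {
            ("Stroke", CVD),
            ("Myocardial infarction - fatal", CVD),
            ("Myocardial infarction - nonfatal", DMT2_CVD),
            ("Myocardial infarction - nonfatal", CVD),
            ("Angina", DMT2_CVD),
            ("Angina", CVD),
            ("Revascularization - stenotic coronary arteries", DMT2_CVD),
            ("Revascularization - stenotic coronary arteries", CVD),
        }


class TestLinearity:
    @pytest.mark.parametrize("scale", [0.5, 1.0, 1.3])
    def test_rate_scale(self, croatia, projection, scale):
        base = event_savings_ledger(croatia, projection).grand_total_savings
        scaled = event_savings_ledger(
            croatia, projection, rate_scale=scale
        ).grand_total_savings
        assert scaled == pytest.approx(scale * base, rel=1e-12)

    def test_linear_in_incidence(self, croatia, projection):
        s = croatia.model_copy(deep=True)
        for e in s.event_specs:
            e.incidence_per_1000 *= 2
            if e.override_risk_reduction is not None:
                e.override_risk_reduction *= 2
        base = event_savings_ledger(croatia, projection).grand_total_savings
        doubled = event_savings_ledger(s, projection).grand_total_savings
        assert doubled == pytest.approx(2 * base, rel=1e-12)
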