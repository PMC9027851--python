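"""Cost savings from reduced incidence of unwanted clinical events.

For each event and patient group, the per-patient effective risk reduction
is (incidence per 1000 / 1000) x guideline relative risk reduction x
efficiency. Expected avoided events are enrolled patients x effective risk
reduction; savings price the *unrounded* expected events at the event's
unit treatment cost. Half-up rounded per-cell counts are reported as event
headcounts and summed as such.

Scenario-level overrides (effective risk reduction, unit cost) replace the
computed values where a published-tables parameterisation requires
back-calculated effective values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._round import display_int
from .config_model import ClinicalEventSpec, Scenario
from .population import EnrollmentProjection

__all__ = [
    "effective_risk_reduction",
    "event_unit_cost",
    "avoided_events",
    "event_savings_ledger",
    "EventLedger",
]


def effective_risk_reduction(incidence_per_1000: float, guideline_rr: float,
                             efficiency: float = 0.9) -> float:
    """Per-patient absolute risk reduction attributable to the programme."""
    if incidence_per_1000 < 0:
        raise ValueError(f"incidence must be >= 0, got {incidence_per_1000}")
    if not 0.0 <= guideline_rr <= 1.0 or not 0.0 <= efficiency <= 1.0:
        raise ValueError("guideline reduction and efficiency must lie in [0, 1]")
    return incidence_per_1000 / 1000.0 * guideline_rr * efficiency


def event_unit_cost(spec: ClinicalEventSpec) -> float:
    """Unit cost of treating one event: inpatient + follow-up + device,
    unless an override unit cost is set."""
    if spec.override_unit_cost is not None:
        return spec.override_unit_cost
    return spec.inpatient_cost + spec.followup_cost + spec.device_cost


def spec_risk_reduction(spec: ClinicalEventSpec) -> float:
    """Effective risk reduction for a spec, honouring any override."""
    if spec.override_risk_reduction is not None:
        return spec.override_risk_reduction
    return effective_risk_reduction(
        spec.incidence_per_1000, spec.guideline_risk_reduction, spec.efficiency
    )


def avoided_events(enrolled_unrounded: float, risk_reduction: float) -> tuple[float, int]:
    """Avoided events in one cell as (unrounded expected, half-up rounded)."""
    if enrolled_unrounded < 0 or risk_reduction < 0:
        raise ValueError("avoided-event inputs must be >= 0")
    expected = enrolled_unrounded * risk_reduction
    return expected, display_int(expected)


@dataclass
class EventLedger:
    """Per event-group-year avoided events and savings.

    ``savings``, ``expected_events`` and ``rounded_events`` are indexed by
    (event, group) with one column per year plus ``total``. Savings are
    unrounded EUR from unrounded expected events; ``rounded_events`` holds
    the per-cell half-up integers whose sums are the reported headcounts.
    """

    savings: pd.DataFrame = field(repr=False)
    expected_events: pd.DataFrame = field(repr=False)
    rounded_events: pd.DataFrame = field(repr=False)

    @property
    def yearly_savings_totals(self) -> pd.Series:
        return self.savings.drop(columns="total").sum(axis=0)

    @property
    def grand_total_savings(self) -> float:
        return float(self.savings.drop(columns="total").sum().sum())

    @property
    def total_avoided_events(self) -> int:
        """Grand total of per-cell rounded avoided events."""
        return int(self.rounded_events.drop(columns="total").to_numpy().sum())


def event_savings_ledger(scenario: Scenario, projection: EnrollmentProjection,
                         rate_scale: float = 1.0) -> EventLedger:
    """Full avoided-event and savings grid for a scenario.

    ``rate_scale`` multiplies every effective risk reduction (the
    sensitivity-analysis hook); savings scale linearly with it.
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be >= 0")
    years = scenario.years
    if scenario.event_specs:
        idx = pd.MultiIndex.from_tuples(
            [(s.event, s.group) for s in scenario.event_specs], names=["event", "group"]
        )
    else:
        idx = pd.MultiIndex.from_arrays([[], []], names=["event", "group"])
    sav_rows, exp_rows, rnd_rows = [], [], []
    for spec in scenario.event_specs:
        rr = spec_risk_reduction(spec) * rate_scale
        cost = event_unit_cost(spec)
        enrolled = projection.col("enrolled", spec.group).to_numpy()
        cells = [avoided_events(e, rr) for e in enrolled]
        exp_rows.append([c[0] for c in cells])
        rnd_rows.append([c[1] for c in cells])
        sav_rows.append([c[0] * cost for c in cells])

    def _frame(rows: list[list[float]], dtype=float) -> pd.DataFrame:
        df = pd.DataFrame(rows, index=idx, columns=years, dtype=dtype)
        df["total"] = df.sum(axis=1)
        return df

    return EventLedger(
        savings=_frame(sav_rows),
        expected_events=_frame(exp_rows),
        rounded_events=_frame(rnd_rows, dtype=int),
    )
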