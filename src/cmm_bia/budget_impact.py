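"""Net budget impact, per-patient metrics and deterministic sensitivity.

Budget impact = total direct costs - (utilisation savings + event savings).
A negative budget impact means the programme is cost-saving (dominant).

The sensitivity analysis scales both savings-side rate families (per-visit
service rates and effective risk reductions) by a common multiplicative
factor f and re-runs the model. Because every savings ledger is linear in
its rates, the scanned budget impact equals costs - f x baseline savings;
"overestimation of the rates by x%" therefore corresponds to f = 1 - x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._round import display_int, round_half_up
from .config_model import Scenario
from .event_savings import EventLedger, event_savings_ledger
from .intervention_costs import YearlyCostLedger, cost_ledger
from .population import EnrollmentProjection, project_enrollment
from .utilization_savings import UtilizationLedger, utilization_ledger

__all__ = [
    "BudgetImpactResult",
    "SensitivityGrid",
    "aggregate",
    "per_patient_metrics",
    "sensitivity_scan",
    "breakeven_factor",
    "run_model",
]


@dataclass
class BudgetImpactResult:
    """Aggregated model outputs for one scenario run."""

    scenario: Scenario = field(repr=False)
    projection: EnrollmentProjection = field(repr=False)
    costs: YearlyCostLedger = field(repr=False)
    utilization: UtilizationLedger = field(repr=False)
    events: EventLedger = field(repr=False)

    total_costs: float = 0.0
    total_utilization_savings: float = 0.0
    total_event_savings: float = 0.0
    total_savings: float = 0.0
    budget_impact: float = 0.0
    enrolled_total: int = 0
    cost_per_patient_year: float = 0.0
    incremental_cost_per_patient: float = 0.0

    @property
    def per_year(self) -> pd.DataFrame:
        """Per-year costs, savings and budget impact (unrounded EUR)."""
        df = pd.DataFrame(index=pd.Index(self.scenario.years, name="year"))
        df["costs"] = self.costs.df["total"]
        df["utilization_savings"] = self.utilization.yearly_totals
        df["event_savings"] = self.events.yearly_savings_totals
        df["total_savings"] = df["utilization_savings"] + df["event_savings"]
        df["budget_impact"] = df["costs"] - df["total_savings"]
        return df


@dataclass
class SensitivityGrid:
    """Budget impact and per-patient incremental cost per scaling factor."""

    df: pd.DataFrame = field(repr=False)  # index: factor

    def budget_impact(self, factor: float) -> float:
        return float(self.df.loc[factor, "budget_impact"])


def per_patient_metrics(total_costs: float, budget_impact: float,
                        enrolled_total: float) -> tuple[float, float]:
    """(cost per treated patient-year, incremental cost per patient).

    Both are totals over the horizon divided by the total number of treated
    patients (sum of per-year enrolled headcounts); display conventions are
    nearest EUR and two decimals respectively.
    """
    if enrolled_total <= 0:
        raise ValueError("enrolled_total must be > 0")
    return total_costs / enrolled_total, budget_impact / enrolled_total


def aggregate(scenario: Scenario, projection: EnrollmentProjection,
              costs: YearlyCostLedger, utilization: UtilizationLedger,
              events: EventLedger) -> BudgetImpactResult:
    """Combine the three unrounded ledgers into the headline result."""
    total_costs = costs.grand_total
    util = utilization.grand_total
    ev = events.grand_total_savings
    total_savings = util + ev
    bi = total_costs - total_savings
    enrolled_total = projection.enrolled_rounded_total
    if enrolled_total > 0:
        cppy, inc = per_patient_metrics(total_costs, bi, enrolled_total)
    else:  # degenerate empty cohort: metrics undefined, reported as 0
        cppy, inc = 0.0, 0.0
    return BudgetImpactResult(
        scenario=scenario, projection=projection, costs=costs,
        utilization=utilization, events=events,
        total_costs=total_costs,
        total_utilization_savings=util,
        total_event_savings=ev,
        total_savings=total_savings,
        budget_impact=bi,
        enrolled_total=enrolled_total,
        cost_per_patient_year=cppy,
        incremental_cost_per_patient=inc,
    )


def run_model(scenario: Scenario, rate_scale: float = 1.0) -> BudgetImpactResult:
    """Run the full pipeline for a scenario.

    ``rate_scale`` multiplies both savings-side rate families (sensitivity
    hook); costs are unaffected.
    """
    projection = project_enrollment(scenario)
    costs = cost_ledger(scenario, projection)
    util = utilization_ledger(scenario, projection, rate_scale=rate_scale)
    events = event_savings_ledger(scenario, projection, rate_scale=rate_scale)
    return aggregate(scenario, projection, costs, util, events)


def sensitivity_scan(scenario: Scenario, factors: list[float] | None = None,
                     ) -> SensitivityGrid:
    """Re-run the model with every savings-side rate scaled by each factor."""
    factors = list(scenario.sensitivity_factors if factors is None else factors)
    if any(f <= 0 for f in factors):
        raise ValueError("sensitivity factors must be > 0")
    rows = []
    for f in factors:
        res = run_model(scenario, rate_scale=f)
        rows.append(
            {
                "factor": f,
                "budget_impact": res.budget_impact,
                "incremental_cost_per_patient": res.incremental_cost_per_patient,
                "budget_impact_display": display_int(res.budget_impact),
                "incremental_display": round_half_up(res.incremental_cost_per_patient, 0)
                if abs(res.incremental_cost_per_patient) >= 1
                else round_half_up(res.incremental_cost_per_patient, 2),
            }
        )
    df = pd.DataFrame(rows).set_index("factor")
    return SensitivityGrid(df=df)


def breakeven_factor(result: BudgetImpactResult) -> float:
    """The rate-scaling factor at which the budget impact is exactly zero."""
    if result.total_costs == 0:
        return 0.0
    if result.total_savings <= 0:
        raise ValueError("break-even factor undefined when total savings are zero")
    return result.total_costs / result.total_savings
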