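"""Cost savings from reduced healthcare-service utilisation.

Each service category carries a per-visit avoidance rate transferred from a
source utilisation study (avoided count / total encounters, optionally
adjusted for transferability) and a local unit price. Savings for a year are
rate x total visits x unit price, computed at full precision; the published
three-decimal rates are display rounding only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config_model import Scenario, ServiceRate
from .intervention_costs import annual_visits
from .population import EnrollmentProjection

__all__ = [
    "service_rate",
    "avoided_service_savings",
    "utilization_ledger",
    "UtilizationLedger",
]


def service_rate(avoided: float, adjustment: float = 1.0,
                 encounters: float = 33_706.0) -> float:
    """Per-visit rate of a service being avoided, unrounded."""
    if encounters <= 0:
        raise ValueError(f"encounters must be > 0, got {encounters}")
    if not 0.0 <= adjustment <= 1.0:
        raise ValueError(f"adjustment {adjustment} outside [0, 1]")
    if avoided < 0:
        raise ValueError(f"avoided count must be >= 0, got {avoided}")
    return avoided * adjustment / encounters


def avoided_service_savings(rate: float, visits: float, unit_price: float) -> float:
    """Savings from one service category in one year, unrounded EUR."""
    if rate < 0 or visits < 0 or unit_price < 0:
        raise ValueError("savings inputs must be >= 0")
    return rate * visits * unit_price


@dataclass
class UtilizationLedger:
    """Per-service, per-year utilisation savings.

    ``df`` is indexed by service name with one column per year plus a
    ``total`` column; ``rates`` maps service name to its unrounded per-visit
    rate (after any sensitivity scaling).
    """

    df: pd.DataFrame = field(repr=False)
    rates: dict[str, float]

    @property
    def yearly_totals(self) -> pd.Series:
        return self.df.drop(columns="total").sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.df["total"].sum())


def utilization_ledger(scenario: Scenario, projection: EnrollmentProjection,
                       rate_scale: float = 1.0) -> UtilizationLedger:
    """Full per-service per-year savings grid.

    ``rate_scale`` multiplies every per-visit rate; it is the hook used by
    the deterministic sensitivity analysis (savings are linear in the rates,
    so scaling rates scales this ledger by the same factor).
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be >= 0")
    enrolled = projection.enrolled_unrounded.to_numpy()
    visits = [annual_visits(e, scenario.cost_params.visits_per_patient_year)
              for e in enrolled]
    rows = {}
    rates: dict[str, float] = {}
    for svc in scenario.service_rates:
        r = service_rate(svc.avoided_count, svc.adjustment, svc.encounters_base) * rate_scale
        rates[svc.name] = r
        rows[svc.name] = [avoided_service_savings(r, v, svc.unit_price) for v in visits]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=scenario.years)
    df.index.name = "service"
    df["total"] = df.sum(axis=1)
    return UtilizationLedger(df=df, rates=rates)
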