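"""Direct programme costs: labour, training and therapy modification.

Annual patient visits (enrolled x visits/patient-year) determine the
pharmacist full-time-equivalent requirement (visits / yearly visit
capacity) and hence labour cost. Therapy-modification cost is the
per-patient-year medication cost increase times the enrolled count.

Two labour/training conventions are supported, selected by the scenario
mode:

- ``published_tables``: labour = unrounded FTE x annual cost per
  pharmacist, no separate training term. This is the model that reproduces
  the published per-year cost cells.
- ``as_stated``: fixed per-year labour/training totals from the scenario
  (if given), otherwise headcount x annual cost and new-hires x unit
  training cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._round import display_int
from .config_model import Mode, Scenario
from .population import EnrollmentProjection

__all__ = [
    "annual_visits",
    "pharmacist_fte",
    "labour_cost",
    "training_cost",
    "therapy_cost",
    "cost_ledger",
    "YearlyCostLedger",
]


def annual_visits(enrolled_unrounded: float, visits_per_patient: float) -> float:
    """Total patient visits in a year, unrounded."""
    if enrolled_unrounded < 0 or visits_per_patient < 0:
        raise ValueError("visits inputs must be >= 0")
    return enrolled_unrounded * visits_per_patient


def pharmacist_fte(visits: float, capacity: float) -> tuple[float, int]:
    """Pharmacist requirement as (unrounded FTE, half-up headcount)."""
    if capacity <= 0:
        raise ValueError(f"visit capacity must be > 0, got {capacity}")
    fte = visits / capacity
    return fte, display_int(fte)


def labour_cost(fte: float, annual_cost: float) -> float:
    """Labour cost from unrounded FTE (the published-tables convention)."""
    if fte < 0 or annual_cost < 0:
        raise ValueError("labour inputs must be >= 0")
    return fte * annual_cost


def training_cost(new_headcount: int, unit_cost: float) -> float:
    """One-off training cost for pharmacists newly hired this year."""
    if new_headcount < 0 or unit_cost < 0:
        raise ValueError("training inputs must be >= 0")
    return new_headcount * unit_cost


def therapy_cost(enrolled_unrounded: float, per_patient_year: float) -> float:
    """Therapy-modification cost for one year."""
    if enrolled_unrounded < 0 or per_patient_year < 0:
        raise ValueError("therapy inputs must be >= 0")
    return enrolled_unrounded * per_patient_year


@dataclass
class YearlyCostLedger:
    """Per-year direct costs with grand totals.

    ``df`` is indexed by year with columns ``visits``, ``fte``,
    ``headcount``, ``new_hires``, ``labour_cost``, ``training_cost``,
    ``therapy_cost`` and ``total`` (all unrounded EUR except the integer
    headcount columns).
    """

    df: pd.DataFrame = field(repr=False)

    @property
    def total_labour_and_training(self) -> float:
        return float(self.df["labour_cost"].sum() + self.df["training_cost"].sum())

    @property
    def total_therapy(self) -> float:
        return float(self.df["therapy_cost"].sum())

    @property
    def grand_total(self) -> float:
        return float(self.df["total"].sum())


def cost_ledger(scenario: Scenario, projection: EnrollmentProjection) -> YearlyCostLedger:
    """Compute the full direct-cost ledger for a scenario."""
    cp = scenario.cost_params
    enrolled = projection.enrolled_unrounded.to_numpy()
    visits = np.array([annual_visits(e, cp.visits_per_patient_year) for e in enrolled])
    fte_head = [pharmacist_fte(v, cp.visit_capacity_per_pharmacist_year) for v in visits]
    fte = np.array([f for f, _ in fte_head])
    head = np.array([h for _, h in fte_head], dtype=int)
    new_hires = np.maximum(np.diff(head, prepend=0), 0)

    if scenario.mode is Mode.published_tables:
        labour = np.array([labour_cost(f, cp.annual_cost_per_pharmacist) for f in fte])
        training = np.zeros_like(labour)
    else:
        if cp.labour_cost_by_year is not None:
            labour = np.asarray(cp.labour_cost_by_year, dtype=float)
        else:
            labour = head.astype(float) * cp.annual_cost_per_pharmacist
        if cp.training_cost_by_year is not None:
            training = np.asarray(cp.training_cost_by_year, dtype=float)
        else:
            training = np.array(
                [training_cost(int(n), cp.training_cost_per_pharmacist) for n in new_hires]
            )

    therapy = np.array([therapy_cost(e, cp.therapy_cost_per_patient_year) for e in enrolled])
    df = pd.DataFrame(
        {
            "visits": visits,
            "fte": fte,
            "headcount": head,
            "new_hires": new_hires,
            "labour_cost": labour,
            "training_cost": training,
            "therapy_cost": therapy,
            "total": labour + training + therapy,
        },
        index=pd.Index(scenario.years, name="year"),
    )
    return YearlyCostLedger(df=df)
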