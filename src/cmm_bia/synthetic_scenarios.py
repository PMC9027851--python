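"""Random valid scenarios for property testing.

The generator draws every model parameter from bounds that bracket the
built-in scenario's values, so each pipeline stage can be exercised on
inputs with the statistical structure the model assumes without any real
parameter set. A single integer seed drives one pseudo-random stream and
the draw order is append-only (documented inline), so adding parameters
never reshuffles existing draws and a fixed seed reproduces a scenario
exactly.

Bounds-only realism is intended: no epidemiologically realistic joint
distribution between, say, incidence and unit cost is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config_model import (
    GROUP_CVD,
    GROUP_DMT2_CVD,
    ClinicalEventSpec,
    CostParams,
    Mode,
    PopulationParams,
    Scenario,
    ServiceRate,
)

__all__ = ["GeneratorSpec", "random_scenario", "perturb_scenario"]

_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    # log-uniform national-scale population
    "population": (1e5, 1e7),
    # on-medication fractions of the population (DMT2 and combined excess)
    "on_medication_fraction": (0.01, 0.5),
    "growth_rate": (-0.02, 0.05),
    "polypharmacy_fraction": (0.5, 1.0),
    "enrollment_fraction": (0.0, 0.2),
    "visits_per_patient": (1.0, 4.0),
    "therapy_cost": (5.0, 100.0),
    "avoided_count": (0.0, 12_000.0),
    "unit_price": (5.0, 5_000.0),  # log-uniform
    "incidence_per_1000": (0.5, 50.0),
    "guideline_risk_reduction": (0.05, 0.6),
    "efficiency": (0.5, 1.0),
}


@dataclass
class GeneratorSpec:
    """Shape and parameter bounds for one random scenario."""

    seed: int = 0
    n_years: int = 3
    n_services: int = 8
    n_events: int = 6  # event types; each is drawn for both patient groups
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:  # collapsed range: keep the draw but return the exact bound
        rng.uniform(np.log(lo), np.log(hi))
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def random_scenario(spec: GeneratorSpec) -> Scenario:
    """Generate a random valid scenario, reproducible under ``spec.seed``.

    Draw order (append-only): population block, enrollment fractions, cost
    parameters, services, events.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.ranges

    # population block
    population = _log_uniform(rng, *R["population"])
    dmt2 = population * rng.uniform(*R["on_medication_fraction"])
    cvd_only = population * rng.uniform(*R["on_medication_fraction"])
    growth = rng.uniform(*R["growth_rate"])
    poly = rng.uniform(*R["polypharmacy_fraction"])

    # enrollment fractions, one per year
    fractions = [float(rng.uniform(*R["enrollment_fraction"])) for _ in range(spec.n_years)]

    # cost parameters
    visits_pp = float(rng.uniform(*R["visits_per_patient"]))
    therapy = float(rng.uniform(*R["therapy_cost"]))

    services = []
    for i in range(spec.n_services):
        avoided = float(rng.uniform(*R["avoided_count"]))
        price = _log_uniform(rng, *R["unit_price"])
        services.append(
            ServiceRate(name=f"service-{i:02d}", avoided_count=avoided,
                        adjustment=1.0, unit_price=price)
        )

    events = []
    for i in range(spec.n_events):
        for group in (GROUP_DMT2_CVD, GROUP_CVD):
            inc = float(rng.uniform(*R["incidence_per_1000"]))
            grr = float(rng.uniform(*R["guideline_risk_reduction"]))
            eff = float(rng.uniform(*R["efficiency"]))
            inpat = _log_uniform(rng, *R["unit_price"])
            follow = _log_uniform(rng, *R["unit_price"])
            events.append(
                ClinicalEventSpec(
                    event=f"event-{i:02d}", group=group, incidence_per_1000=inc,
                    guideline_risk_reduction=grr, efficiency=eff,
                    inpatient_cost=inpat, followup_cost=follow,
                )
            )

    base_year = 2022
    return Scenario(
        label=f"synthetic-seed-{spec.seed}",
        years=[base_year + k for k in range(spec.n_years)],
        mode=Mode.published_tables,
        population=PopulationParams(
            dmt2_on_medication=dmt2,
            combined_on_medication=dmt2 + cvd_only,
            growth_rate=growth,
            polypharmacy_fraction=poly,
        ),
        enrollment_fractions=fractions,
        cost_params=CostParams(
            visits_per_patient_year=visits_pp,
            therapy_cost_per_patient_year=therapy,
        ),
        service_rates=services,
        event_specs=events,
    )


def _scale(rng: np.random.Generator, value: float, noise: float,
           lo: float = 0.0, hi: float | None = None) -> float:
    out = value * (1.0 + rng.uniform(-noise, noise))
    out = max(out, lo)
    if hi is not None:
        out = min(out, hi)
    return out


def perturb_scenario(scenario: Scenario, relative_noise: float, seed: int) -> Scenario:
    """Multiply each numeric parameter by an independent (1 + u), u ~ U(+-noise).

    Fractions are clipped back into [0, 1] so the result always validates;
    the overlap invariant is preserved by perturbing the DMT2 count and the
    CVD-only excess separately.
    """
    if not 0.0 <= relative_noise <= 0.5:
        raise ValueError(f"relative_noise {relative_noise} outside [0, 0.5]")
    rng = np.random.default_rng(seed)
    d = scenario.to_dict()

    pop = d["population"]
    dmt2 = _scale(rng, pop["dmt2_on_medication"], relative_noise)
    excess = _scale(rng, pop["combined_on_medication"] - pop["dmt2_on_medication"],
                    relative_noise)
    pop["dmt2_on_medication"] = dmt2
    pop["combined_on_medication"] = dmt2 + excess
    pop["growth_rate"] = pop["growth_rate"] * (1.0 + rng.uniform(-relative_noise,
                                                                 relative_noise))
    pop["polypharmacy_fraction"] = _scale(rng, pop["polypharmacy_fraction"],
                                          relative_noise, hi=1.0)

    d["enrollment_fractions"] = [
        _scale(rng, f, relative_noise, hi=1.0) for f in d["enrollment_fractions"]
    ]

    cp = d["cost_params"]
    for key in ("visits_per_patient_year", "visit_capacity_per_pharmacist_year",
                "annual_cost_per_pharmacist", "training_cost_per_pharmacist",
                "therapy_cost_per_patient_year"):
        cp[key] = _scale(rng, cp[key], relative_noise, lo=1e-9)
    for key in ("labour_cost_by_year", "training_cost_by_year"):
        if cp.get(key) is not None:
            cp[key] = [_scale(rng, v, relative_noise) for v in cp[key]]

    for svc in d["service_rates"]:
        svc["avoided_count"] = _scale(rng, svc["avoided_count"], relative_noise)
        svc["adjustment"] = _scale(rng, svc["adjustment"], relative_noise, hi=1.0)
        svc["unit_price"] = _scale(rng, svc["unit_price"], relative_noise)

    for ev in d["event_specs"]:
        ev["incidence_per_1000"] = _scale(rng, ev["incidence_per_1000"], relative_noise)
        ev["guideline_risk_reduction"] = _scale(rng, ev["guideline_risk_reduction"],
                                                relative_noise, hi=1.0)
        ev["efficiency"] = _scale(rng, ev["efficiency"], relative_noise, hi=1.0)
        for key in ("inpatient_cost", "followup_cost", "device_cost"):
            ev[key] = _scale(rng, ev[key], relative_noise)
        for key in ("override_risk_reduction", "override_unit_cost"):
            if ev.get(key) is not None:
                hi = 1.0 if key == "override_risk_reduction" else None
                ev[key] = _scale(rng, ev[key], relative_noise, hi=hi)

    if relative_noise == 0.0:
        return Scenario.model_validate(scenario.to_dict())
    return Scenario.model_validate(d)
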