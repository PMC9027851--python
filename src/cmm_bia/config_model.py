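"""Scenario data model, validation and (de)serialisation.

A :class:`Scenario` is the complete parameter set for one budget-impact run:
the eligible-population inputs, programme cost parameters, the catalogue of
avoided healthcare services with their per-visit transfer rates and unit
prices, the catalogue of unwanted clinical events with incidence rates and
guideline risk reductions, and the deterministic sensitivity factors.

Two parameterisation modes exist for the built-in Croatia scenario:

``published_tables``
    Reproduces the published result tables. Where the published parameter
    tables are internally inconsistent with the published result tables,
    effective values back-calculated from the result tables are used
    (documented field by field in :func:`builtin_croatia_scenario`).

``as_stated``
    Uses the published parameter-table values literally, with no overrides,
    and the published per-year labour/training totals as fixed inputs.

Scenario documents are YAML (canonical) or JSON; unknown keys are rejected
so parameter typos fail fast rather than silently falling back to defaults.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "Mode",
    "GROUP_DMT2_CVD",
    "GROUP_CVD",
    "PopulationParams",
    "CostParams",
    "ServiceRate",
    "ClinicalEventSpec",
    "Scenario",
    "ScenarioFormatError",
    "ScenarioValidationError",
    "load_scenario",
    "write_scenario",
    "validate_scenario",
    "builtin_croatia_scenario",
    "scenario_json_schema",
]

GROUP_DMT2_CVD = "DMT2+CVD"
GROUP_CVD = "CVD"


class Mode(str, enum.Enum):
    """Parameterisation mode for scenarios that replicate published tables."""

    published_tables = "published_tables"
    as_stated = "as_stated"


class ScenarioFormatError(ValueError):
    """The scenario document is not parseable YAML/JSON."""


class ScenarioValidationError(ValueError):
    """The scenario document parsed but violates one or more invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid scenario:\n" + "\n".join(f"  - {v}" for v in violations))


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PopulationParams(_StrictModel):
    """On-medication patient counts and their projection parameters.

    ``combined_on_medication`` is the total number of prevalent DMT2 + CVD
    patients on medication after overlap correction (every DMT2 patient is
    assumed to also have a CVD, so the CVD-only group is the combined count
    minus the DMT2 count). The counts are model inputs, not derived from the
    prevalence chain; the chain (national population, prevalences,
    on-medication fractions) may be recorded in ``provenance`` as
    documentation but is never recomputed.
    """

    dmt2_on_medication: float = Field(ge=0)
    combined_on_medication: float = Field(ge=0)
    growth_rate: float = Field(gt=-1.0)
    polypharmacy_fraction: float = Field(ge=0, le=1)
    provenance: Optional[dict[str, Any]] = None

    @model_validator(mode="after")
    def _overlap(self) -> "PopulationParams":
        if self.combined_on_medication < self.dmt2_on_medication:
            raise ValueError(
                "combined_on_medication must be >= dmt2_on_medication "
                f"({self.combined_on_medication} < {self.dmt2_on_medication})"
            )
        return self


class CostParams(_StrictModel):
    """Programme cost parameters.

    ``visit_capacity_per_pharmacist_year`` defaults to 2904 = 11 visits/day
    x 264 working days/year. ``labour_cost_by_year`` / ``training_cost_by_year``
    are optional fixed per-year totals; when present they take precedence over
    the computed labour (FTE x annual cost) and training (new hires x unit
    cost) models.
    """

    visits_per_patient_year: float = Field(default=2.0, gt=0)
    visit_capacity_per_pharmacist_year: float = Field(default=2904.0, gt=0)
    annual_cost_per_pharmacist: float = Field(default=28_000.0, gt=0)
    training_cost_per_pharmacist: float = Field(default=200.0, gt=0)
    therapy_cost_per_patient_year: float = Field(default=37.4733, gt=0)
    labour_cost_by_year: Optional[list[float]] = None
    training_cost_by_year: Optional[list[float]] = None


class ServiceRate(_StrictModel):
    """One avoided-healthcare-service category.

    The per-visit transfer rate is ``avoided_count * adjustment /
    encounters_base``: the number of services avoided in the source
    utilisation study, optionally adjusted for context transferability,
    divided by the source study's total patient encounters.
    """

    name: str
    avoided_count: float = Field(ge=0)
    adjustment: float = Field(default=1.0, ge=0, le=1)
    encounters_base: float = Field(default=33_706.0, gt=0)
    unit_price: float = Field(ge=0)

    @property
    def rate(self) -> float:
        """Per-visit rate of this service being avoided, unrounded."""
        return self.avoided_count * self.adjustment / self.encounters_base

    @model_validator(mode="after")
    def _rate_bounds(self) -> "ServiceRate":
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"service {self.name!r}: rate {self.rate} outside [0, 1]")
        return self


class ClinicalEventSpec(_StrictModel):
    """One unwanted clinical event for one patient group.

    The effective per-patient risk reduction is
    ``incidence_per_1000 / 1000 * guideline_risk_reduction * efficiency``.
    ``efficiency`` (default 0.9) scales the guideline effect for the blood
    pressure reduction actually achieved in practice (9 rather than 10 mmHg
    systolic). The unit cost is inpatient + follow-up + device, unless
    ``override_unit_cost`` is set. Overrides hold back-calculated effective
    values and are only populated in ``published_tables`` mode.
    """

    event: str
    group: str
    incidence_per_1000: float = Field(ge=0)
    guideline_risk_reduction: float = Field(ge=0, le=1)
    efficiency: float = Field(default=0.9, ge=0, le=1)
    inpatient_cost: float = Field(ge=0)
    followup_cost: float = Field(default=0.0, ge=0)
    device_cost: float = Field(default=0.0, ge=0)
    override_risk_reduction: Optional[float] = Field(default=None, ge=0, le=1)
    override_unit_cost: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _group_valid(self) -> "ClinicalEventSpec":
        if self.group not in (GROUP_DMT2_CVD, GROUP_CVD):
            raise ValueError(
                f"event {self.event!r}: group {self.group!r} must be "
                f"{GROUP_DMT2_CVD!r} or {GROUP_CVD!r}"
            )
        return self


class Scenario(_StrictModel):
    """Complete parameter set for one budget-impact model run."""

    label: str
    years: list[int]
    mode: Mode = Mode.published_tables
    population: PopulationParams
    enrollment_fractions: list[float]
    cost_params: CostParams = Field(default_factory=CostParams)
    service_rates: list[ServiceRate] = Field(default_factory=list)
    event_specs: list[ClinicalEventSpec] = Field(default_factory=list)
    sensitivity_factors: list[float] = Field(default_factory=lambda: [1.05, 0.95, 0.80, 0.60])

    @model_validator(mode="after")
    def _consistent(self) -> "Scenario":
        problems: list[str] = []
        if not self.years:
            problems.append("years: must be nonempty")
        elif any(b <= a for a, b in zip(self.years, self.years[1:])):
            problems.append(f"years: must be strictly increasing, got {self.years}")
        if len(self.enrollment_fractions) != len(self.years):
            problems.append(
                "enrollment_fractions: need one entry per year "
                f"({len(self.enrollment_fractions)} != {len(self.years)})"
            )
        for i, f in enumerate(self.enrollment_fractions):
            if not 0.0 <= f <= 1.0:
                problems.append(f"enrollment_fractions[{i}]: {f} outside [0, 1]")
        for attr in ("labour_cost_by_year", "training_cost_by_year"):
            v = getattr(self.cost_params, attr)
            if v is not None and len(v) != len(self.years):
                problems.append(f"cost_params.{attr}: need one entry per year")
        for f in self.sensitivity_factors:
            if f <= 0:
                problems.append(f"sensitivity_factors: factor {f} must be > 0")
        if self.mode is Mode.as_stated:
            for spec in self.event_specs:
                if spec.override_risk_reduction is not None or spec.override_unit_cost is not None:
                    problems.append(
                        f"event_specs[{spec.event!r}/{spec.group!r}]: overrides are only "
                        "allowed in published_tables mode"
                    )
        if problems:
            raise ValueError("; ".join(problems))
        return self

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """Plain-python dict with enum values as strings (YAML/JSON ready)."""
        return self.model_dump(mode="json", exclude_none=True)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)


def _format_pydantic_errors(err: ValidationError) -> list[str]:
    out = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        msg = e["msg"]
        if "input" in e and not isinstance(e.get("input"), (dict, list)):
            msg += f" (got {e['input']!r})"
        out.append(f"{loc}: {msg}")
    return out


def validate_scenario(document: Mapping[str, Any] | Scenario) -> list[str]:
    """Check a scenario document against every invariant.

    Returns a list of human-readable violations (empty iff valid); violations
    are data, not exceptions, so callers can report all of them at once.
    """
    data = document.to_dict() if isinstance(document, Scenario) else document
    try:
        Scenario.model_validate(data)
    except ValidationError as err:
        return _format_pydantic_errors(err)
    return []


def load_scenario(document: str | Path) -> Scenario:
    """Load and validate a scenario from a YAML/JSON file path or text.

    Raises :class:`ScenarioFormatError` on a parse failure (naming the line
    where available) and :class:`ScenarioValidationError` listing every
    violated invariant otherwise.
    """
    if isinstance(document, Path) or (
        isinstance(document, str) and "\n" not in document and Path(document).suffix in
        (".yaml", ".yml", ".json")
    ):
        path = Path(document)
        if not path.exists():
            raise FileNotFoundError(f"scenario file not found: {path}")
        text = path.read_text(encoding="utf-8")
    else:
        text = str(document)
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as err:
        mark = getattr(err, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ScenarioFormatError(f"cannot parse scenario document{where}: {err}") from err
    if not isinstance(raw, Mapping):
        raise ScenarioFormatError("scenario document must be a mapping of parameters")
    violations = validate_scenario(raw)
    if violations:
        raise ScenarioValidationError(violations)
    return Scenario.model_validate(raw)


def write_scenario(scenario: Scenario, path: str | Path) -> Path:
    """Write a scenario to YAML (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(scenario.to_dict(), indent=2), encoding="utf-8")
    else:
        path.write_text(scenario.to_yaml(), encoding="utf-8")
    return path


def scenario_json_schema() -> dict[str, Any]:
    """JSON Schema for scenario documents (published in docs/)."""
    return Scenario.model_json_schema()


# ---------------------------------------------------------------------------
# Built-in Croatia scenario (2022-2024 nationwide CMM roll-out)
# ---------------------------------------------------------------------------

# Unit prices are the Croatian payer's DRG-catalogue prices (EUR).
_SERVICES = [
    # (name, avoided count in source study, adjustment, unit price EUR)
    # The clinic-outpatient count is reduced by 30% for transferability:
    # pharmacists in Croatia cannot prescribe, so a third of avoided GP
    # encounters still happen. The as-published source count stays visible.
    ("Clinic outpatient visit avoided", 10_313.0, 0.7, 10.40),
    ("Specialty office visit avoided", 1_346.0, 1.0, 18.93),
    ("Employee work days saved", 277.0, 1.0, 47.19),
    ("Laboratory service avoided", 240.0, 1.0, 8.10),
    ("Urgent care visit avoided", 355.0, 1.0, 54.13),
    ("Hospital admission avoided", 41.0, 1.0, 120.13),
    ("Nursing home admissions", 3.0, 1.0, 20.00),
    ("Home health visit", 1.0, 1.0, 16.02),
]

# (event, group, incidence/1000, guideline RR, inpatient, followup, device)
_EVENTS = [
    ("Heart failure", GROUP_DMT2_CVD, 23.86, 0.40, 1_182.24, 1_176.00, 2_473.95),
    ("Heart failure", GROUP_CVD, 9.70, 0.40, 1_182.24, 1_176.00, 2_473.95),
    ("Stroke", GROUP_DMT2_CVD, 14.60, 0.35, 1_959.45, 1_176.00, 0.0),
    ("Stroke", GROUP_CVD, 7.70, 0.35, 1_959.45, 1_176.00, 0.0),
    ("Myocardial infarction - fatal", GROUP_DMT2_CVD, 18.00, 0.20, 864.79, 0.0, 0.0),
    ("Myocardial infarction - fatal", GROUP_CVD, 8.70, 0.20, 864.79, 0.0, 0.0),
    ("Myocardial infarction - nonfatal", GROUP_DMT2_CVD, 27.8, 0.20, 1_806.20, 1_176.00, 0.0),
    ("Myocardial infarction - nonfatal", GROUP_CVD, 13.00, 0.20, 1_806.20, 1_176.00, 0.0),
    ("Angina", GROUP_DMT2_CVD, 21.60, 0.20, 1_127.51, 1_176.00, 0.0),
    ("Angina", GROUP_CVD, 14.60, 0.20, 1_127.51, 1_176.00, 0.0),
    ("Revascularization - stenotic coronary arteries",
     GROUP_DMT2_CVD, 3.85, 0.20, 1_061.83, 1_176.00, 0.0),
    ("Revascularization - stenotic coronary arteries",
     GROUP_CVD, 3.85, 0.20, 1_061.83, 1_176.00, 0.0),
]

# published_tables overrides, back-calculated from the published result
# tables where the parameter tables do not reproduce them:
#   - Stroke/CVD effective risk reduction: the published per-patient value
#     0.00243 does not reproduce the published avoided-event or savings
#     cells; 0.0146 * 0.315 = 0.0045990 (the DMT2+CVD stroke value) does.
#   - Fatal-MI/CVD: published 0.00157 does not reproduce; 0.018 * 0.18 =
#     0.00324 (the DMT2+CVD value) does.
#   - Nonfatal MI / angina / revascularization savings cells price events at
#     the fatal-MI unit cost 864.79 EUR rather than their own catalogue sums.
_FATAL_MI_COST = 864.79
_RR_OVERRIDES = {
    ("Stroke", GROUP_CVD): 0.0146 * 0.315,
    ("Myocardial infarction - fatal", GROUP_CVD): 0.018 * 0.18,
}
_COST_OVERRIDE_EVENTS = {
    "Myocardial infarction - nonfatal",
    "Angina",
    "Revascularization - stenotic coronary arteries",
}

# Published per-year labour and training totals, used verbatim as fixed
# inputs in as_stated mode (they are not reproducible as FTE x annual cost
# nor as new-hires x 200 EUR).
_STATED_LABOUR = [632_008.13, 889_177.20, 1_154_142.67]
_STATED_TRAINING = [4_482.27, 1_855.73, 1_892.40]

_PROVENANCE = {
    "national_population": 4_087_934,
    "dmt2_prevalence_2022": 0.0774,
    "dmt2_on_medication_fraction": 0.76,
    "cvd_prevalence_2022": 0.2602,
    "cvd_on_medication_fraction": 0.90,
    "note": (
        "On-medication counts are exogenous inputs; the prevalence chain "
        "shown here is documentation and does not reproduce them exactly."
    ),
}


def builtin_croatia_scenario(mode: Mode | str = Mode.published_tables) -> Scenario:
    """The built-in nationwide Croatia scenario (2022-2024).

    ``published_tables`` applies the back-calculated effective overrides that
    reproduce the published result tables; ``as_stated`` takes the published
    parameter tables literally (therapy cost 37.47 EUR, no event overrides,
    published labour/training totals as fixed inputs). The two scenarios
    differ in those documented fields only.
    """
    mode = Mode(mode)
    events = []
    for event, group, inc, grr, inpat, follow, device in _EVENTS:
        spec: dict[str, Any] = dict(
            event=event, group=group, incidence_per_1000=inc,
            guideline_risk_reduction=grr, efficiency=0.9,
            inpatient_cost=inpat, followup_cost=follow, device_cost=device,
        )
        if mode is Mode.published_tables:
            if (event, group) in _RR_OVERRIDES:
                spec["override_risk_reduction"] = _RR_OVERRIDES[(event, group)]
            if event in _COST_OVERRIDE_EVENTS:
                spec["override_unit_cost"] = _FATAL_MI_COST
        events.append(ClinicalEventSpec(**spec))

    if mode is Mode.published_tables:
        cost_params = CostParams(therapy_cost_per_patient_year=37.4733)
    else:
        cost_params = CostParams(
            therapy_cost_per_patient_year=37.47,
            labour_cost_by_year=list(_STATED_LABOUR),
            training_cost_by_year=list(_STATED_TRAINING),
        )

    return Scenario(
        label="croatia-cmm-2022-2024",
        years=[2022, 2023, 2024],
        mode=mode,
        population=PopulationParams(
            dmt2_on_medication=240_398,
            combined_on_medication=765_687,
            growth_rate=0.01,
            polypharmacy_fraction=0.85,
            provenance=dict(_PROVENANCE),
        ),
        enrollment_fractions=[0.05, 0.07, 0.09],
        cost_params=cost_params,
        service_rates=[
            ServiceRate(name=n, avoided_count=c, adjustment=a, unit_price=p)
            for n, c, a, p in _SERVICES
        ],
        event_specs=events,
        sensitivity_factors=[1.05, 0.95, 0.80, 0.60],
    )
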