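"""Eligible-population projection.

Projects the on-medication patient counts over the model horizon with a
constant yearly growth rate, splits them into the two patient groups
(DMT2 + CVD and CVD-only) under the full-overlap assumption, applies the
polypharmacy filter (patients on five or more medicines) and the per-year
enrollment fractions, and returns per-year per-group eligible and enrolled
counts.

All counts are carried forward unrounded; half-up rounded counts are kept
alongside for display and headcount purposes only. Downstream cost
computations must consume the unrounded counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._round import display_int
from .config_model import GROUP_CVD, GROUP_DMT2_CVD, Scenario

__all__ = [
    "grow_counts",
    "split_overlap",
    "eligible_counts",
    "enrolled_counts",
    "project_enrollment",
    "EnrollmentProjection",
]

GROUPS = (GROUP_DMT2_CVD, GROUP_CVD)


def grow_counts(base: float, growth_rate: float, n_years: int) -> np.ndarray:
    """Project a count over ``n_years`` with constant yearly growth.

    Year 1 equals ``base``; each following year multiplies the previous
    (unrounded) value by ``1 + growth_rate``.
    """
    if base < 0:
        raise ValueError(f"base count must be >= 0, got {base}")
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    out = np.empty(n_years, dtype=float)
    out[0] = base
    for k in range(1, n_years):
        out[k] = out[k - 1] * (1.0 + growth_rate)
    return out


def split_overlap(dmt2_on_med: float, combined_on_med: float) -> dict[str, float]:
    """Split the overlap-corrected combined count into the two groups.

    Every DMT2 patient is assumed to also have a CVD, so the DMT2+CVD group
    equals the DMT2 count and the CVD-only group is the remainder.
    """
    if combined_on_med < dmt2_on_med:
        raise ValueError(
            f"combined count {combined_on_med} < DMT2 count {dmt2_on_med}"
        )
    return {
        GROUP_DMT2_CVD: float(dmt2_on_med),
        GROUP_CVD: float(combined_on_med - dmt2_on_med),
    }


def eligible_counts(groups: dict[str, np.ndarray], polypharmacy_fraction: float,
                    ) -> dict[str, np.ndarray]:
    """Apply the polypharmacy (5+ medicines) filter to per-group counts."""
    if not 0.0 <= polypharmacy_fraction <= 1.0:
        raise ValueError(f"polypharmacy fraction {polypharmacy_fraction} outside [0, 1]")
    return {g: np.asarray(v, dtype=float) * polypharmacy_fraction for g, v in groups.items()}


@dataclass
class EnrollmentProjection:
    """Per-year, per-group eligible and enrolled counts.

    ``by_group`` is indexed by year with one column block per group:
    ``on_medication``, ``eligible``, ``enrolled`` (all unrounded) and
    ``enrolled_rounded``; column names are ``(quantity, group)`` tuples
    flattened as ``f"{quantity}|{group}"``. Totals across groups are under
    the pseudo-group ``"total"``.
    """

    years: list[int]
    by_group: pd.DataFrame = field(repr=False)

    def col(self, quantity: str, group: str = "total") -> pd.Series:
        return self.by_group[f"{quantity}|{group}"]

    @property
    def enrolled_unrounded(self) -> pd.Series:
        """Unrounded total enrolled patients per year (cost-model input)."""
        return self.col("enrolled")

    @property
    def enrolled_rounded_total(self) -> int:
        """Headcount of enrolled patients over the horizon (sum of per-year
        half-up rounded totals)."""
        return int(self.col("enrolled_rounded").sum())


def enrolled_counts(eligible: dict[str, np.ndarray], enrollment_fractions: list[float],
                    years: list[int], on_medication: dict[str, np.ndarray] | None = None,
                    ) -> EnrollmentProjection:
    """Apply per-year enrollment fractions to per-group eligible counts.

    Both unrounded and half-up rounded enrolled counts are retained; the
    unrounded values feed the cost model, the rounded ones are display/
    headcount figures.
    """
    fr = np.asarray(enrollment_fractions, dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError(f"enrollment fractions outside [0, 1]: {enrollment_fractions}")
    if len(fr) != len(years):
        raise ValueError("need one enrollment fraction per year")
    cols: dict[str, np.ndarray] = {}
    groups = list(eligible)
    for g in groups:
        el = np.asarray(eligible[g], dtype=float)
        en = el * fr
        if on_medication is not None:
            cols[f"on_medication|{g}"] = np.asarray(on_medication[g], dtype=float)
        cols[f"eligible|{g}"] = el
        cols[f"enrolled|{g}"] = en
        cols[f"enrolled_rounded|{g}"] = np.array([display_int(x) for x in en], dtype=int)
    for q in ("on_medication", "eligible", "enrolled"):
        parts = [cols[f"{q}|{g}"] for g in groups if f"{q}|{g}" in cols]
        if parts:
            cols[f"{q}|total"] = np.sum(parts, axis=0)
    cols["enrolled_rounded|total"] = np.array(
        [display_int(x) for x in cols["enrolled|total"]], dtype=int
    )
    df = pd.DataFrame(cols, index=pd.Index(years, name="year"))
    return EnrollmentProjection(years=list(years), by_group=df)


def project_enrollment(scenario: Scenario) -> EnrollmentProjection:
    """Full projection pipeline for a scenario."""
    pop = scenario.population
    n = len(scenario.years)
    split = split_overlap(pop.dmt2_on_medication, pop.combined_on_medication)
    on_med = {g: grow_counts(split[g], pop.growth_rate, n) for g in GROUPS}
    eligible = eligible_counts(on_med, pop.polypharmacy_fraction)
    return enrolled_counts(eligible, scenario.enrollment_fractions, scenario.years,
                           on_medication=on_med)
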