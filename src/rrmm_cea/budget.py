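"""Five-year budget impact of introducing DRd alongside KRd.

The budget impact analysis (BIA) projects the national population forward at
a constant growth rate, walks a patient funnel (multiple-myeloma patients ->
death-rate-adjusted survivors -> the ~20% reaching the relapsed/refractory
stage where a triplet is indicated), and costs two worlds: one where KRd
holds 100% market share and one where DRd captures a growing share
(5% -> 25% over five years).  No discounting or inflation is applied, and
the per-patient annual treatment costs are budget-year costs, distinct from
the Markov model's lifetime totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "BIAInputs",
    "BIAResult",
    "project_population",
    "patient_funnel",
    "scenario_costs",
    "run_bia",
    "impacts_from_scenario_totals",
]


@dataclass(frozen=True)
class BIAInputs:
    """Inputs for the budget impact model.

    ``funnel_mode`` selects how annual patient counts are derived:
    ``"anchor"`` scales the published first-year counts with population
    growth (matching the published table), ``"rates"`` recomputes counts
    from incidence + prevalence each year.
    """

    base_population: int = 85_345_667
    annual_growth: float = 0.012
    incidence_per_100k: float = 1.8
    prevalence_per_100k: float = 3.27
    mm_patients_anchor: int = 4_267
    survival_adjusted_anchor: int = 3_456
    eligible_fraction: float = 0.20
    years: int = 5
    start_year: int = 2022
    drd_market_share: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)
    per_patient_annual_cost_krd: float = 14_845.726483357
    per_patient_annual_cost_drd: float = 26_379.503617945
    funnel_mode: str = "anchor"
    reference_scenario_totals: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if any(not (0.0 <= s <= 1.0) for s in self.drd_market_share):
            raise ValidationError("market shares must lie in [0, 1]")
        if len(self.drd_market_share) != self.years:
            raise ValidationError("one DRd market share per projected year")
        if not (0.0 <= self.eligible_fraction <= 1.0):
            raise ValidationError("eligible_fraction must lie in [0, 1]")
        if self.annual_growth < 0:
            raise ValidationError("annual_growth must be >= 0")
        if min(self.per_patient_annual_cost_krd, self.per_patient_annual_cost_drd) <= 0:
            raise ValidationError("per-patient annual costs must be > 0")
        if self.funnel_mode not in ("anchor", "rates"):
            raise ValidationError("funnel_mode must be 'anchor' or 'rates'")

    @property
    def survival_adjustment(self) -> float:
        """Fraction of MM patients alive after the death-rate adjustment."""
        return self.survival_adjusted_anchor / self.mm_patients_anchor

    @classmethod
    def from_dict(cls, raw: Mapping) -> "BIAInputs":
        ref = raw.get("reference_scenario_totals")
        return cls(
            base_population=int(raw.get("base_population", 85_345_667)),
            annual_growth=float(raw.get("annual_growth", 0.012)),
            incidence_per_100k=float(raw.get("incidence_per_100k", 1.8)),
            prevalence_per_100k=float(raw.get("prevalence_per_100k", 3.27)),
            mm_patients_anchor=int(raw.get("mm_patients_anchor", 4_267)),
            survival_adjusted_anchor=int(raw.get("survival_adjusted_anchor", 3_456)),
            eligible_fraction=float(raw.get("eligible_fraction", 0.20)),
            years=int(raw.get("years", 5)),
            start_year=int(raw.get("start_year", 2022)),
            drd_market_share=tuple(
                float(s) for s in raw.get("drd_market_share", (0.05, 0.1, 0.15, 0.2, 0.25))
            ),
            per_patient_annual_cost_krd=float(
                raw.get("per_patient_annual_cost", {}).get("krd", 14_845.726483357)
            ),
            per_patient_annual_cost_drd=float(
                raw.get("per_patient_annual_cost", {}).get("drd", 26_379.503617945)
            ),
            funnel_mode=str(raw.get("funnel_mode", "anchor")),
            reference_scenario_totals=(
                tuple((float(a), float(b)) for a, b in ref) if ref else None
            ),
        )

    def to_dict(self) -> dict:
        return {
            "base_population": self.base_population,
            "annual_growth": self.annual_growth,
            "incidence_per_100k": self.incidence_per_100k,
            "prevalence_per_100k": self.prevalence_per_100k,
            "mm_patients_anchor": self.mm_patients_anchor,
            "survival_adjusted_anchor": self.survival_adjusted_anchor,
            "eligible_fraction": self.eligible_fraction,
            "years": self.years,
            "start_year": self.start_year,
            "drd_market_share": list(self.drd_market_share),
            "per_patient_annual_cost": {
                "krd": self.per_patient_annual_cost_krd,
                "drd": self.per_patient_annual_cost_drd,
            },
            "funnel_mode": self.funnel_mode,
            "reference_scenario_totals": (
                [list(pair) for pair in self.reference_scenario_totals]
                if self.reference_scenario_totals
                else None
            ),
        }


@dataclass
class BIAResult:
    """Yearly funnel, scenario totals and financial impact."""

    table: pd.DataFrame
    total_impact: float

    def __post_init__(self) -> None:
        impact = self.table["scenario2_cost"] - self.table["scenario1_cost"]
        if not np.allclose(impact, self.table["financial_impact"]):
            raise ValidationError("financial_impact must equal scenario2 - scenario1")


def project_population(base: int, growth: float, years: int) -> np.ndarray:
    """Population at the start of each of ``years`` consecutive years.

    pop[y] = round(base * (1+growth)^y), compounded unrounded.
    """
    if growth < 0:
        raise ValidationError("growth must be >= 0")
    y = np.arange(years)
    return np.rint(base * (1.0 + growth) ** y).astype(np.int64)


def patient_funnel(inputs: BIAInputs) -> pd.DataFrame:
    """Yearly patient counts: MM patients -> survival-adjusted -> eligible.

    The unrounded chain is carried through and each displayed count is
    rounded half-to-even at its own stage; the eligible count (the quantity
    that feeds the scenarios) is rounded from the unrounded chain.
    """
    pop = project_population(inputs.base_population, inputs.annual_growth, inputs.years)
    growth_factor = (1.0 + inputs.annual_growth) ** np.arange(inputs.years)
    if inputs.funnel_mode == "anchor":
        mm_exact = inputs.mm_patients_anchor * growth_factor
    else:
        rate = (inputs.incidence_per_100k + inputs.prevalence_per_100k) / 1e5
        mm_exact = pop * rate
    adjusted_exact = mm_exact * inputs.survival_adjustment
    eligible_exact = adjusted_exact * inputs.eligible_fraction
    return pd.DataFrame(
        {
            "year": inputs.start_year + np.arange(inputs.years),
            "population": pop,
            "mm_patients": np.rint(mm_exact).astype(np.int64),
            "adjusted_patients": np.rint(adjusted_exact).astype(np.int64),
            "eligible": np.rint(eligible_exact).astype(np.int64),
        }
    )


def scenario_costs(
    eligible: Sequence[int],
    shares: Sequence[float],
    cost_krd: float,
    cost_drd: float,
) -> pd.DataFrame:
    """Cost the with/without-DRd worlds for given eligible counts and shares.

    Scenario 1 keeps KRd at 100% share; scenario 2 displaces share_y of
    treatment to DRd in year y.
    """
    eligible = np.asarray(eligible, dtype=float)
    shares = np.asarray(shares, dtype=float)
    if eligible.shape != shares.shape:
        raise ValidationError("eligible and shares must have equal length")
    s1 = eligible * cost_krd
    s2 = eligible * (shares * cost_drd + (1.0 - shares) * cost_krd)
    return pd.DataFrame(
        {
            "eligible": eligible,
            "drd_share": shares,
            "krd_share": 1.0 - shares,
            "scenario1_cost": s1,
            "scenario2_cost": s2,
            "financial_impact": s2 - s1,
            "impact_pct": np.divide(
                s2 - s1, s1, out=np.zeros_like(s1), where=s1 > 0
            ),
        }
    )


def run_bia(inputs: BIAInputs) -> BIAResult:
    """Full BIA: funnel + scenarios + 5-year total impact."""
    funnel = patient_funnel(inputs)
    scen = scenario_costs(
        funnel["eligible"].to_numpy(),
        inputs.drd_market_share,
        inputs.per_patient_annual_cost_krd,
        inputs.per_patient_annual_cost_drd,
    )
    table = pd.concat([funnel, scen.drop(columns="eligible")], axis=1)
    return BIAResult(table=table, total_impact=float(table["financial_impact"].sum()))


def impacts_from_scenario_totals(
    scenario1: Sequence[float], scenario2: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Rebuild yearly and total financial impact from scenario cost totals."""
    s1 = np.asarray(scenario1, dtype=float)
    s2 = np.asarray(scenario2, dtype=float)
    if s1.shape != s2.shape:
        raise ValidationError("scenario vectors must have equal length")
    impacts = s2 - s1
    return impacts, float(impacts.sum())
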