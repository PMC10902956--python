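"""Incremental cost-effectiveness statistics (ICER/ICUR, ACER, NMB).

Conventions: NMB = WTP x effect - cost; the intervention is *dominant* when
it is cheaper and more effective, *dominated* when costlier and less
effective.  Ratios are reported unrounded; display rounding belongs to the
reporting layer.  Undefined ratios (zero effect difference) are flagged
rather than printed as infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .engine import ArmResult
from .errors import ComparisonError, ValidationError

__all__ = ["CEAComparison", "nmb", "compare"]


@dataclass(frozen=True)
class CEAComparison:
    """Incremental statistics between an intervention and a comparator."""

    intervention: str
    comparator: str
    wtp: float
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icur: float  # USD per QALY; NaN when undefined
    icer_ly: float  # USD per LYG; NaN when undefined
    icur_defined: bool
    icer_ly_defined: bool
    acer_intervention: float
    acer_comparator: float
    nmb_intervention: float
    nmb_comparator: float
    dominance: str  # none | intervention-dominant | intervention-dominated

    @property
    def incremental_nmb(self) -> float:
        return self.nmb_intervention - self.nmb_comparator

    def to_frame(self) -> pd.DataFrame:
        """Summary table mirroring the base-case results layout."""
        return pd.DataFrame(
            {
                "metric": ["cost", "qaly", "ly", "icur", "icer_ly", "acer", "nmb"],
                self.intervention: [
                    None, None, None, None, None,
                    self.acer_intervention, self.nmb_intervention,
                ],
                self.comparator: [
                    None, None, None, None, None,
                    self.acer_comparator, self.nmb_comparator,
                ],
                "increment": [
                    self.delta_cost, self.delta_qaly, self.delta_ly,
                    self.icur if self.icur_defined else None,
                    self.icer_ly if self.icer_ly_defined else None,
                    None, self.incremental_nmb,
                ],
            }
        )


def nmb(result: ArmResult, wtp: float) -> float:
    """Net monetary benefit of one arm: WTP x QALY - cost."""
    if wtp <= 0:
        raise ValidationError(f"wtp must be > 0, got {wtp}")
    return wtp * result.total_qaly - result.total_cost


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return math.nan, False
    return num / den, True


def compare(
    intervention: ArmResult, comparator: ArmResult, wtp: float
) -> CEAComparison:
    """Full incremental comparison of two arm results at a WTP threshold."""
    if intervention.trace.occupancy.shape != comparator.trace.occupancy.shape:
        raise ComparisonError("arm results were produced under different horizons")
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qaly - comparator.total_qaly
    dly = intervention.total_ly - comparator.total_ly
    icur, icur_ok = _safe_ratio(dc, dq)
    icer, icer_ok = _safe_ratio(dc, dly)
    if dc < 0 and dq > 0:
        dominance = "intervention-dominant"
    elif dc > 0 and dq < 0:
        dominance = "intervention-dominated"
    else:
        dominance = "none"
    acer_i, _ = _safe_ratio(intervention.total_cost, intervention.total_qaly)
    acer_c, _ = _safe_ratio(comparator.total_cost, comparator.total_qaly)
    return CEAComparison(
        intervention=intervention.arm,
        comparator=comparator.arm,
        wtp=wtp,
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dly,
        icur=icur,
        icer_ly=icer,
        icur_defined=icur_ok,
        icer_ly_defined=icer_ok,
        acer_intervention=acer_i,
        acer_comparator=acer_c,
        nmb_intervention=nmb(intervention, wtp),
        nmb_comparator=nmb(comparator, wtp),
        dominance=dominance,
    )
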