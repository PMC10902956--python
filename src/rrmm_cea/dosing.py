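"""Dosing calendars and per-cycle treatment costs.

Cycles are 28 days.  The canonical calendars encode the published regimens:

* daratumumab — once weekly in cycles 1–2, every 2 weeks in cycles 3–6,
  every 4 weeks thereafter (planned 25 cycles);
* carfilzomib — days 1, 2, 8, 9, 15, 16 in cycles 1–12 and days 1, 2, 15, 16
  in cycles 13–18 (planned 18 cycles);
* dexamethasone — days 1, 8, 15, 22 of every cycle;
* lenalidomide — days 1 through 21 of every cycle.

Each administration is charged ``units_per_administration`` times the unit
price of the referenced vial/tablet parameter; non-drug components
(administration, monitoring) are configured as per-cycle counts of cost
parameters.  Cycle costs are therefore linear in every unit price, which
the deterministic sensitivity analysis and price-threshold search rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnsupportedStrategyError, ValidationError
from .params import CostModelConfig, DrugSpec, StrategyArm

__all__ = [
    "CYCLE_DAYS",
    "DoseSchedule",
    "CycleCostSchedule",
    "administrations_per_cycle",
    "canonical_administrations",
    "build_dose_schedule",
    "build_cycle_costs",
    "schedules_to_frame",
]

CYCLE_DAYS = 28


def administrations_per_cycle(interval_days: int, first_day: int = 1) -> int:
    """Number of administrations in a 28-day cycle at a fixed interval."""
    if interval_days <= 0 or not (1 <= first_day <= CYCLE_DAYS):
        raise ValidationError("interval and first day must lie within the cycle")
    return len(range(first_day, CYCLE_DAYS + 1, interval_days))


def canonical_administrations(drug: str, duration: int) -> tuple[int, ...]:
    """Administrations per cycle for the published calendars."""
    counts: list[int] = []
    if drug == "daratumumab":
        for cycle in range(1, duration + 1):
            if cycle <= 2:
                counts.append(administrations_per_cycle(7))  # weekly
            elif cycle <= 6:
                counts.append(administrations_per_cycle(14))  # every 2 weeks
            else:
                counts.append(administrations_per_cycle(28))  # every 4 weeks
    elif drug == "carfilzomib":
        for cycle in range(1, duration + 1):
            days = (1, 2, 8, 9, 15, 16) if cycle <= 12 else (1, 2, 15, 16)
            counts.append(len(days))
    elif drug == "dexamethasone":
        counts = [len((1, 8, 15, 22))] * duration
    elif drug == "lenalidomide":
        counts = [len(range(1, 22))] * duration
    else:
        raise UnsupportedStrategyError(f"no canonical calendar for drug {drug!r}")
    return tuple(counts)


@dataclass(frozen=True)
class DoseSchedule:
    """Administrations of one drug over an arm's planned treatment period."""

    drug: str
    administrations_by_cycle: tuple[int, ...]
    units_per_administration: float
    unit_cost_ref: str

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.administrations_by_cycle):
            raise ValidationError(f"drug {self.drug!r}: administration counts >= 0")
        if self.units_per_administration <= 0:
            raise ValidationError(f"drug {self.drug!r}: units must be > 0")

    @property
    def total_administrations(self) -> int:
        return int(sum(self.administrations_by_cycle))


def build_dose_schedule(arm: StrategyArm) -> list[DoseSchedule]:
    """Expand an arm's regimen into per-cycle administration counts."""
    schedules = []
    for drug in arm.drugs:
        if drug.administrations_by_cycle is not None:
            counts = drug.administrations_by_cycle
            if len(counts) != arm.planned_duration_cycles:
                raise ValidationError(
                    f"arm {arm.name!r} drug {drug.name!r}: override length "
                    f"{len(counts)} != planned duration {arm.planned_duration_cycles}"
                )
        else:
            counts = canonical_administrations(drug.name, arm.planned_duration_cycles)
        schedules.append(
            DoseSchedule(
                drug=drug.name,
                administrations_by_cycle=counts,
                units_per_administration=drug.units_per_administration,
                unit_cost_ref=drug.unit_cost,
            )
        )
    return schedules


@dataclass(frozen=True)
class CycleCostSchedule:
    """Per-cycle USD costs for one arm (drug + administration + monitoring).

    ``on_treatment_cost_by_cycle`` covers the planned treatment period while
    progression-free; afterwards progression-free patients accrue
    ``post_treatment_pfs_cost_per_cycle`` (supportive care) and progressed
    patients ``pd_cost_per_cycle``.  ``ae_event_cost`` is charged per
    adverse event, i.e. expected cost per on-treatment cycle is the AE
    probability times this amount.
    """

    arm: str
    on_treatment_cost_by_cycle: tuple[float, ...]
    post_treatment_pfs_cost_per_cycle: float
    pd_cost_per_cycle: float
    ae_event_cost: float

    def __post_init__(self) -> None:
        entries = (
            *self.on_treatment_cost_by_cycle,
            self.post_treatment_pfs_cost_per_cycle,
            self.pd_cost_per_cycle,
            self.ae_event_cost,
        )
        if any(c < 0 for c in entries):
            raise ValidationError(f"arm {self.arm!r}: negative cycle cost")

    @property
    def planned_duration(self) -> int:
        return len(self.on_treatment_cost_by_cycle)

    def pfs_cost_vector(self, horizon: int) -> np.ndarray:
        """Cost of a progression-free cycle for cycles 1..horizon."""
        on = np.asarray(self.on_treatment_cost_by_cycle, dtype=float)[:horizon]
        post = np.full(max(horizon - on.size, 0), self.post_treatment_pfs_cost_per_cycle)
        return np.concatenate([on, post])

    def scaled(self, factor: float) -> "CycleCostSchedule":
        """Multiply every component by ``factor`` (cost-scale calibration)."""
        if factor < 0:
            raise ValidationError("cost scale must be >= 0")
        return CycleCostSchedule(
            arm=self.arm,
            on_treatment_cost_by_cycle=tuple(
                factor * c for c in self.on_treatment_cost_by_cycle
            ),
            post_treatment_pfs_cost_per_cycle=factor
            * self.post_treatment_pfs_cost_per_cycle,
            pd_cost_per_cycle=factor * self.pd_cost_per_cycle,
            ae_event_cost=factor * self.ae_event_cost,
        )


def _component_cost(block: Mapping[str, float], values: Mapping[str, float]) -> float:
    total = 0.0
    for pname, count in block.items():
        if pname not in values:
            raise ConfigurationError(f"missing unit cost {pname!r}")
        total += count * values[pname]
    return total


def build_cycle_costs(
    schedules: Sequence[DoseSchedule],
    values: Mapping[str, float],
    arm: StrategyArm,
    cost_model: CostModelConfig,
) -> CycleCostSchedule:
    """Combine dose schedules and unit prices into a cycle cost schedule.

    cycle cost = sum over drugs of administrations x units x unit price,
    plus the configured per-cycle administration/monitoring components.
    """
    duration = arm.planned_duration_cycles
    drug_cost = np.zeros(duration)
    for sched in schedules:
        if sched.unit_cost_ref not in values:
            raise ConfigurationError(f"missing unit cost {sched.unit_cost_ref!r}")
        counts = np.asarray(sched.administrations_by_cycle[:duration], dtype=float)
        drug_cost[: counts.size] += (
            counts * sched.units_per_administration * values[sched.unit_cost_ref]
        )
    on_treatment = drug_cost + _component_cost(cost_model.on_treatment, values)
    return CycleCostSchedule(
        arm=arm.name,
        on_treatment_cost_by_cycle=tuple(on_treatment),
        post_treatment_pfs_cost_per_cycle=_component_cost(
            cost_model.post_treatment_pfs, values
        ),
        pd_cost_per_cycle=_component_cost(cost_model.progressed, values),
        ae_event_cost=_component_cost(cost_model.ae_event, values),
    )


def schedules_to_frame(
    arm: StrategyArm,
    schedules: Sequence[DoseSchedule],
    values: Mapping[str, float],
) -> pd.DataFrame:
    """Tidy (arm, drug, cycle, administrations, cost) table for audit."""
    rows = []
    for sched in schedules:
        price = values[sched.unit_cost_ref]
        for cycle, n in enumerate(sched.administrations_by_cycle, start=1):
            rows.append(
                {
                    "arm": arm.name,
                    "drug": sched.drug,
                    "cycle": cycle,
                    "administrations": n,
                    "cost": n * sched.units_per_administration * price,
                }
            )
    return pd.DataFrame(rows)
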