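"""Monthly-cycle Markov cohort engine.

The cohort starts fully progression-free and is pushed through the
per-cycle transition matrices; state occupancy is multiplied by state
utilities and state costs each cycle, discounted, and accumulated into
lifetime totals per arm.  Life-years are reported undiscounted by default;
QALYs and costs are discounted at their respective annual rates, with the
compounding basis configurable (see :class:`~rrmm_cea.params.ModelSettings`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dosing import CycleCostSchedule, build_cycle_costs, build_dose_schedule
from .errors import EngineError, ValidationError
from .params import CostModelConfig, ModelSettings, StrategyArm

__all__ = [
    "discount_factors",
    "run_cohort",
    "accumulate_outcomes",
    "accumulate_costs",
    "life_years_from_matrices",
    "CohortTrace",
    "ArmResult",
    "run_arm",
]

_MONTHS_PER_YEAR = 12.0


def discount_factors(
    annual_rate: float, horizon: int, basis: str = "annual"
) -> np.ndarray:
    """End-of-cycle discount factors for cycles t = 1..horizon.

    ``basis='annual'`` compounds the annual rate over elapsed years,
    (1+r)^(-t/12); ``basis='per_cycle'`` applies the annual rate once per
    monthly cycle, (1+r)^(-t).
    """
    t = np.arange(1, horizon + 1, dtype=float)
    if basis == "annual":
        return (1.0 + annual_rate) ** (-t / _MONTHS_PER_YEAR)
    if basis == "per_cycle":
        return (1.0 + annual_rate) ** (-t)
    raise ValidationError(f"unknown discount basis {basis!r}")


def run_cohort(
    matrices: np.ndarray, initial: Sequence[float] = (1.0, 0.0, 0.0)
) -> np.ndarray:
    """State occupancy over time; row t is the distribution after t cycles.

    Returns an array of shape (horizon + 1, 3) whose first row is the
    initial distribution.
    """
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1:] != (3, 3):
        raise EngineError(f"matrices must have shape (horizon, 3, 3), got {matrices.shape}")
    x = np.asarray(initial, dtype=float)
    if x.shape != (3,):
        raise EngineError("initial distribution must have 3 entries")
    if abs(x.sum() - 1.0) > 1e-10 or np.any(x < 0):
        raise EngineError("initial distribution must be nonnegative and sum to 1")
    horizon = matrices.shape[0]
    occ = np.empty((horizon + 1, 3))
    occ[0] = x
    for t in range(horizon):
        x = x @ matrices[t]
        occ[t + 1] = x
    if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-10:
        raise EngineError("occupancy rows must stay stochastic")
    return occ


def _effective_occupancy(occ: np.ndarray, half_cycle: bool) -> np.ndarray:
    """Occupancy attributed to cycles 1..horizon.

    End-of-cycle accounting by default; the half-cycle (trapezoid) variant
    averages the start- and end-of-cycle occupancy.
    """
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[1:]


def accumulate_outcomes(
    occ: np.ndarray,
    u_pfs: float,
    u_pd: float,
    ae_prob: float,
    ae_disutility: float,
    on_treatment: np.ndarray,
    settings: ModelSettings,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Life-years and discounted QALYs from an occupancy trace.

    Per cycle: ly += alive fraction / 12; qaly += (occ_PFS*U_PFS +
    occ_PD*U_PD + on-treatment occ_PFS * p_AE * disutility_AE) / 12 *
    discount(t).  ``ae_disutility`` is negative.  Life-year discounting is
    off unless ``settings.discount_life_years``.
    """
    if not (0.0 <= u_pfs <= 1.0 and 0.0 <= u_pd <= 1.0):
        raise ValidationError("state utilities must lie in [0, 1]")
    if not (0.0 <= ae_prob <= 1.0):
        raise ValidationError("AE probability must lie in [0, 1]")
    horizon = occ.shape[0] - 1
    eff = _effective_occupancy(occ, settings.half_cycle_correction)
    on_treatment = np.asarray(on_treatment, dtype=bool)
    if on_treatment.shape != (horizon,):
        raise EngineError("on_treatment mask must have one entry per cycle")

    alive = eff[:, 0] + eff[:, 1]
    d_out = discount_factors(
        settings.discount_outcome_annual, horizon, settings.discount_basis
    )
    d_ly = d_out if settings.discount_life_years else np.ones(horizon)

    ly_by_cycle = alive / _MONTHS_PER_YEAR * d_ly
    utility = eff[:, 0] * u_pfs + eff[:, 1] * u_pd
    utility = utility + np.where(on_treatment, eff[:, 0] * ae_prob * ae_disutility, 0.0)
    qaly_by_cycle = utility / _MONTHS_PER_YEAR * d_out
    if np.any(qaly_by_cycle < -1e-12):
        raise ValidationError("negative per-cycle QALY increment")
    return float(ly_by_cycle.sum()), float(qaly_by_cycle.sum()), ly_by_cycle, qaly_by_cycle


def accumulate_costs(
    occ: np.ndarray,
    costs: CycleCostSchedule,
    ae_prob: float,
    on_treatment: np.ndarray,
    settings: ModelSettings,
) -> tuple[float, np.ndarray]:
    """Discounted lifetime cost from an occupancy trace.

    Per cycle: occ_PFS x (on-treatment or supportive PFS cost) + occ_PD x
    PD cost + on-treatment occ_PFS x p_AE x AE event cost, all discounted
    at the cost rate.
    """
    horizon = occ.shape[0] - 1
    eff = _effective_occupancy(occ, settings.half_cycle_correction)
    on_treatment = np.asarray(on_treatment, dtype=bool)
    pfs_cost = costs.pfs_cost_vector(horizon)
    per_cycle = (
        eff[:, 0] * pfs_cost
        + eff[:, 1] * costs.pd_cost_per_cycle
        + np.where(on_treatment, eff[:, 0] * ae_prob * costs.ae_event_cost, 0.0)
    )
    d_cost = discount_factors(
        settings.discount_cost_annual, horizon, settings.discount_basis
    )
    cost_by_cycle = per_cycle * d_cost
    return float(cost_by_cycle.sum()), cost_by_cycle


def life_years_from_matrices(matrices: np.ndarray, settings: ModelSettings) -> float:
    """Undiscounted restricted life-years implied by a matrix sequence."""
    occ = run_cohort(matrices)
    eff = _effective_occupancy(occ, settings.half_cycle_correction)
    return float((eff[:, 0] + eff[:, 1]).sum() / _MONTHS_PER_YEAR)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and accumulation increments."""

    occupancy: np.ndarray  # (horizon + 1, 3), row 0 = initial
    cost_by_cycle: np.ndarray
    qaly_by_cycle: np.ndarray
    ly_by_cycle: np.ndarray

    def __post_init__(self) -> None:
        if np.max(np.abs(self.occupancy.sum(axis=1) - 1.0)) > 1e-10:
            raise EngineError("occupancy rows must sum to 1")
        if np.any(np.diff(self.occupancy[:, 2]) < -1e-12):
            raise EngineError("death occupancy must be non-decreasing")
        for arr in (self.cost_by_cycle, self.qaly_by_cycle, self.ly_by_cycle):
            if not np.all(np.isfinite(arr)):
                raise EngineError("trace increments must be finite")

    def to_frame(self) -> pd.DataFrame:
        horizon = self.occupancy.shape[0] - 1
        return pd.DataFrame(
            {
                "cycle": np.arange(1, horizon + 1),
                "occ_pfs": self.occupancy[1:, 0],
                "occ_pd": self.occupancy[1:, 1],
                "occ_death": self.occupancy[1:, 2],
                "disc_cost": self.cost_by_cycle,
                "disc_qaly": self.qaly_by_cycle,
                "ly": self.ly_by_cycle,
            }
        )


@dataclass
class ArmResult:
    """Lifetime totals and trace for one strategy arm."""

    arm: str
    total_cost: float
    total_qaly: float
    total_ly: float
    trace: CohortTrace

    def __post_init__(self) -> None:
        for total, by_cycle in (
            (self.total_cost, self.trace.cost_by_cycle),
            (self.total_qaly, self.trace.qaly_by_cycle),
            (self.total_ly, self.trace.ly_by_cycle),
        ):
            if abs(total - by_cycle.sum()) > 1e-9 * max(1.0, abs(total)):
                raise EngineError("totals must equal summed trace increments")


def run_arm(
    arm: StrategyArm,
    base,  # BaselineHazards
    values: Mapping[str, float],
    settings: ModelSettings,
    cost_model: CostModelConfig,
    hr_pfs_includes_pfs_death: bool = False,
    cost_scale: float = 1.0,
) -> ArmResult:
    """Compose matrices, cohort, outcome and cost accumulation for one arm."""
    from .transitions import build_arm_matrices  # local import: avoids cycle

    hr_pfs = arm.hr_value("pfs", values)
    hr_os = arm.hr_value("os", values)
    matrices = build_arm_matrices(
        base, hr_pfs, hr_os, settings, hr_pfs_includes_pfs_death
    )
    occ = run_cohort(matrices)

    horizon = settings.horizon_cycles
    on_treatment = np.arange(1, horizon + 1) <= arm.planned_duration_cycles

    u_pfs = values["u_pfs"]
    u_pd = u_pfs + values["disutility_progression"]
    ae_prob = values[arm.ae_probability]
    schedules = build_dose_schedule(arm)
    costs = build_cycle_costs(schedules, values, arm, cost_model).scaled(cost_scale)

    ly, qaly, ly_c, qaly_c = accumulate_outcomes(
        occ, u_pfs, u_pd, ae_prob, values["disutility_ae"], on_treatment, settings
    )
    cost, cost_c = accumulate_costs(occ, costs, ae_prob, on_treatment, settings)
    trace = CohortTrace(
        occupancy=occ, cost_by_cycle=cost_c, qaly_by_cycle=qaly_c, ly_by_cycle=ly_c
    )
    return ArmResult(
        arm=arm.name, total_cost=cost, total_qaly=qaly, total_ly=ly, trace=trace
    )
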