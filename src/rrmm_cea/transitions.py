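"""Transition probabilities: exponential baselines, hazard-ratio transforms.

The cohort moves over three states (PFS, PD, Death).  Baseline monthly
cause-specific hazards for the comparator arm are time-homogeneous
(exponential survival); the intervention arm is derived by scaling those
hazards with the published hazard ratios.  Because no baseline survival
curves are published, the hazards are identified by structure (median time
to progression, post-progression excess-mortality ratio) plus a single
mortality scale calibrated so the comparator arm reproduces its published
undiscounted restricted life-years.

The PFS row composes the two competing exits with death taking precedence
within a cycle:

    P(PFS->Death)  = 1 - exp(-r_die_pfs)
    P(PFS->PD)     = exp(-r_die_pfs) * (1 - exp(-r_progress))
    P(PFS->PFS)    = exp(-(r_progress + r_die_pfs))

so staying put is governed by the joint exponentiated hazard and the
marginal death probability transforms exactly under a hazard ratio:
1 - (1 - p)^HR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import CalibrationError, EngineError, ValidationError
from .params import ModelSettings

__all__ = [
    "STATES",
    "BaselineHazards",
    "rate_to_prob",
    "prob_to_rate",
    "apply_hazard_ratio",
    "matrix_from_hazards",
    "build_arm_matrices",
    "validate_matrix",
    "calibrate_baseline",
    "calibrate_cost_scale",
]

STATES = ("PFS", "PD", "Death")
_ROW_TOL = 1e-12


@dataclass(frozen=True)
class BaselineHazards:
    """Monthly cause-specific hazards for the comparator arm."""

    r_progress: float
    r_die_pfs: float
    r_die_pd: float

    def __post_init__(self) -> None:
        for name, r in (
            ("r_progress", self.r_progress),
            ("r_die_pfs", self.r_die_pfs),
            ("r_die_pd", self.r_die_pd),
        ):
            if not math.isfinite(r) or r < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {r}")


def rate_to_prob(rate: float, dt: float = 1.0) -> float:
    """Probability of an event within ``dt`` under constant hazard ``rate``."""
    if rate < 0:
        raise ValidationError(f"rate must be >= 0, got {rate}")
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    return -math.expm1(-rate * dt)


def prob_to_rate(prob: float, dt: float = 1.0) -> float:
    """Inverse of :func:`rate_to_prob`."""
    if not (0.0 <= prob < 1.0):
        raise ValidationError(f"probability must lie in [0, 1), got {prob}")
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    return -math.log1p(-prob) / dt

def apply_hazard_ratio(p: float, hr: float) -> float:
    """Scale a per-cycle probability on the hazard scale: 1 - (1-p)^hr."""
    if hr <= 0:
        raise ValidationError(f"hazard ratio must be > 0, got {hr}")
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"probability must lie in [0, 1], got {p}")
    if p == 1.0:
        if hr != 1.0:
            raise ValidationError("p = 1 is degenerate under a hazard ratio != 1")
        return 1.0
    return -math.expm1(hr * math.log1p(-p))


def matrix_from_hazards(
    r_progress: float, r_die_pfs: float, r_die_pd: float, dt: float = 1.0
) -> np.ndarray:
    """One-cycle transition matrix over (PFS, PD, Death)."""
    p_die_pfs = rate_to_prob(r_die_pfs, dt)
    stay_pfs = math.exp(-(r_progress + r_die_pfs) * dt)
    p_prog = math.exp(-r_die_pfs * dt) - stay_pfs
    p_die_pd = rate_to_prob(r_die_pd, dt)
    m = np.array(
        [
            [stay_pfs, p_prog, p_die_pfs],
            [0.0, 1.0 - p_die_pd, p_die_pd],
            [0.0, 0.0, 1.0],
        ]
    )
    validate_matrix(m)
    return m


def validate_matrix(m: np.ndarray) -> None:
    """Row-stochasticity, no-recovery and absorbing-death invariants."""
    if m.shape != (3, 3):
        raise EngineError(f"transition matrix must be 3x3, got {m.shape}")
    if np.any(m < -_ROW_TOL) or np.any(m > 1 + _ROW_TOL):
        raise EngineError("transition probabilities must lie in [0, 1]")
    if np.max(np.abs(m.sum(axis=1) - 1.0)) > _ROW_TOL:
        raise EngineError("transition matrix rows must sum to 1")
    if m[1, 0] != 0.0:
        raise EngineError("PD -> PFS (recovery) is not allowed")
    if not (m[2, 0] == 0.0 and m[2, 1] == 0.0 and m[2, 2] == 1.0):
        raise EngineError("Death must be absorbing")


def build_arm_matrices(
    base: BaselineHazards,
    hr_pfs: float,
    hr_os: float,
    settings: ModelSettings,
    hr_pfs_includes_pfs_death: bool = False,
) -> np.ndarray:
    """Per-cycle matrices for one arm, shape (horizon, 3, 3).

    ``hr_pfs`` scales the progression hazard; ``hr_os`` scales both death
    hazards.  When ``hr_pfs_includes_pfs_death`` the progression HR is
    applied to PFS->Death instead of the OS HR (a stricter reading of a
    progression-or-death endpoint), with the OS HR then acting on PD->Death
    only.
    """
    if hr_pfs <= 0 or hr_os <= 0:
        raise ValidationError("hazard ratios must be > 0")
    dt = settings.cycle_length_months
    hr_death_pfs = hr_pfs if hr_pfs_includes_pfs_death else hr_os
    m = matrix_from_hazards(
        base.r_progress * hr_pfs,
        base.r_die_pfs * hr_death_pfs,
        base.r_die_pd * hr_os,
        dt=dt,
    )
    return np.broadcast_to(m, (settings.horizon_cycles, 3, 3)).copy()


def _krd_life_years(
    m_scale: float,
    r_progress: float,
    pd_ratio: float,
    settings: ModelSettings,
) -> float:
    from .engine import life_years_from_matrices  # local import: avoids cycle

    base = BaselineHazards(
        r_progress=r_progress,
        r_die_pfs=m_scale,
        r_die_pd=pd_ratio * m_scale,
    )
    matrices = build_arm_matrices(base, 1.0, 1.0, settings)
    return life_years_from_matrices(matrices, settings)


def calibrate_baseline(
    target_ly: float,
    settings: ModelSettings,
    progression_median_months: float = 26.0,
    pd_to_pfs_mortality_ratio: float = 2.0,
    bracket: tuple[float, float] = (1e-6, 5.0),
    tol: float = 1e-8,
) -> BaselineHazards:
    """Find baseline hazards whose comparator-arm restricted life-years
    match ``target_ly``.

    The progression hazard is fixed from the configured median time to
    progression (r = ln 2 / median); the two death hazards share one free
    mortality scale with a fixed PD/PFS ratio, and that scale is found by
    root finding (Brent on the log scale) against the cohort engine.
    """
    horizon_years = settings.horizon_cycles * settings.cycle_length_months / 12.0
    if not (0.0 < target_ly < horizon_years):
        raise CalibrationError(
            f"target life-years must lie in (0, {horizon_years}), got {target_ly}"
        )
    r_progress = math.log(2.0) / progression_median_months

    def residual(log_m: float) -> float:
        return (
            _krd_life_years(
                math.exp(log_m), r_progress, pd_to_pfs_mortality_ratio, settings
            )
            - target_ly
        )

    lo, hi = math.log(bracket[0]), math.log(bracket[1])
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"target {target_ly} LY not bracketed by mortality scales "
            f"{bracket}: residuals ({f_lo:.4g}, {f_hi:.4g})"
        )
    log_m = optimize.brentq(residual, lo, hi, xtol=tol, rtol=8.9e-16)
    m = math.exp(log_m)
    return BaselineHazards(
        r_progress=r_progress,
        r_die_pfs=m,
        r_die_pd=pd_to_pfs_mortality_ratio * m,
    )


def calibrate_cost_scale(unscaled_total_cost: float, target_cost: float) -> float:
    """Multiplier aligning an arm's discounted lifetime cost with a target.

    Total cost is linear in the scale, so the calibration is exact.
    """
    if unscaled_total_cost <= 0:
        raise CalibrationError("unscaled total cost must be > 0")
    if target_cost < 0:
        raise CalibrationError("target cost must be >= 0")
    return target_cost / unscaled_total_cost
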