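"""Model assembly: calibration plus deterministic evaluation.

``build_model`` turns a :class:`~rrmm_cea.params.Config` into a ready-to-run
:class:`DecisionModel`: baseline hazards are calibrated to the reference
(KRd) arm's published restricted life-years, and per-arm cost scales are
calibrated so discounted lifetime costs hit the published totals (when
``cost_target_usd`` is configured).  ``evaluate`` reruns the deterministic
pipeline at the base-case means or at overridden parameter values — the
single entry point used by the base case, the tornado analysis, the price
threshold search and every probabilistic draw.  Calibrated quantities are
*not* refitted per draw; parameter uncertainty propagates through hazards
(via the hazard ratios), utilities and unit costs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .engine import ArmResult, run_arm
from .errors import ConfigurationError
from .metrics import CEAComparison, compare
from .params import Config
from .transitions import BaselineHazards, calibrate_baseline, calibrate_cost_scale

__all__ = ["DecisionModel", "EvaluationResult", "build_model", "evaluate", "base_case"]


@dataclass
class DecisionModel:
    """A calibrated, evaluable decision model."""

    config: Config
    baseline: BaselineHazards
    cost_scales: dict[str, float]

    @property
    def intervention_name(self) -> str:
        others = [a for a in self.config.arms.values() if not a.reference]
        if len(others) != 1:
            raise ConfigurationError("expected exactly one non-reference arm")
        return others[0].name

    @property
    def comparator_name(self) -> str:
        return self.config.reference_arm().name


@dataclass
class EvaluationResult:
    """Arm results plus the incremental comparison for one parameter vector."""

    arms: dict[str, ArmResult]
    comparison: CEAComparison

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "arm": r.arm,
                "total_cost": r.total_cost,
                "total_qaly": r.total_qaly,
                "total_ly": r.total_ly,
            }
            for r in self.arms.values()
        ]
        return pd.DataFrame(rows)


def build_model(config: Config) -> DecisionModel:
    """Calibrate baseline hazards and cost scales for a configuration."""
    baseline = calibrate_baseline(
        config.hazards.krd_target_life_years,
        config.settings,
        progression_median_months=config.hazards.progression_median_months,
        pd_to_pfs_mortality_ratio=config.hazards.pd_to_pfs_mortality_ratio,
    )
    model = DecisionModel(config=config, baseline=baseline, cost_scales={})
    means = config.params.means()
    for arm in config.arms.values():
        scale = 1.0
        if arm.cost_target_usd is not None:
            unscaled = run_arm(
                arm,
                baseline,
                means,
                config.settings,
                config.cost_model,
                config.hazards.hr_pfs_includes_pfs_death,
                cost_scale=1.0,
            )
            scale = calibrate_cost_scale(unscaled.total_cost, arm.cost_target_usd)
        model.cost_scales[arm.name] = scale
    return model


def evaluate(
    model: DecisionModel, overrides: Mapping[str, float] | None = None
) -> EvaluationResult:
    """Run the full deterministic pipeline at given parameter values.

    ``overrides`` replaces base-case means for the named parameters;
    baseline hazards and cost scales stay at their calibrated values.
    """
    config = model.config
    values = config.params.means()
    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise ConfigurationError(f"unknown override parameters: {sorted(unknown)}")
        values.update(overrides)
    arms = {
        arm.name: run_arm(
            arm,
            model.baseline,
            values,
            config.settings,
            config.cost_model,
            config.hazards.hr_pfs_includes_pfs_death,
            cost_scale=model.cost_scales[arm.name],
        )
        for arm in config.arms.values()
    }
    comparison = compare(
        arms[model.intervention_name],
        arms[model.comparator_name],
        config.settings.wtp_usd_per_qaly,
    )
    return EvaluationResult(arms=arms, comparison=comparison)


def base_case(config: Config) -> tuple[DecisionModel, EvaluationResult]:
    """Calibrate and evaluate at the published point estimates."""
    model = build_model(config)
    return model, evaluate(model)
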