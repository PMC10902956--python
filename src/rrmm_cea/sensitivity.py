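"""Deterministic and probabilistic sensitivity analysis.

One-way DSA reruns the full pipeline with each varied parameter pinned to
its lower/upper 95% bound (tornado ordering by outcome range).  The price
threshold search exploits the linearity of lifetime cost in a unit price to
locate the price at which the intervention stops being cost-effective
(ICUR = WTP) or becomes dominant (zero incremental cost).  The PSA samples
every varied parameter independently from its fitted distribution,
reruns the model per draw, and summarizes acceptability as a CEAC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import CalibrationError, ValidationError
from .params import fit_distribution
from .pipeline import DecisionModel, evaluate

__all__ = [
    "DSAEntry",
    "one_way_dsa",
    "ThresholdResult",
    "price_threshold",
    "PSAResult",
    "run_psa",
    "ceac",
    "switch_point",
    "quadrant_fractions",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DSAEntry:
    """Tornado bar: outcome at a parameter's lower and upper bound."""

    parameter: str
    low_value: float
    high_value: float
    outcome_at_low: float
    outcome_at_high: float
    icur_at_low: float
    icur_at_high: float
    failed: bool = False

    @property
    def range(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _outcome(model: DecisionModel, overrides: dict[str, float]) -> tuple[float, float]:
    res = evaluate(model, overrides)
    return res.comparison.incremental_nmb, res.comparison.icur


def one_way_dsa(model: DecisionModel) -> list[DSAEntry]:
    """Tornado entries for every varied parameter, sorted by range.

    The primary outcome is the incremental net monetary benefit at the
    configured WTP; the ICUR at each bound is carried along.  Ties in range
    break alphabetically.  A pipeline failure at a bound flags the entry
    and the analysis continues.
    """
    entries = []
    for spec in model.config.params.varied():
        try:
            nmb_lo, icur_lo = _outcome(model, {spec.name: spec.low})
            nmb_hi, icur_hi = _outcome(model, {spec.name: spec.high})
            entries.append(
                DSAEntry(
                    parameter=spec.name,
                    low_value=spec.low,
                    high_value=spec.high,
                    outcome_at_low=nmb_lo,
                    outcome_at_high=nmb_hi,
                    icur_at_low=icur_lo,
                    icur_at_high=icur_hi,
                )
            )
        except Exception as exc:  # noqa: BLE001 - flagged, run continues
            logger.warning("DSA failed for %s: %s", spec.name, exc)
            entries.append(
                DSAEntry(
                    parameter=spec.name,
                    low_value=spec.low,
                    high_value=spec.high,
                    outcome_at_low=np.nan,
                    outcome_at_high=np.nan,
                    icur_at_low=np.nan,
                    icur_at_high=np.nan,
                    failed=True,
                )
            )
    return sorted(entries, key=lambda e: (-(e.range if e.range == e.range else -1), e.parameter))


def dsa_to_frame(entries: list[DSAEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "inmb_at_low": [e.outcome_at_low for e in entries],
            "inmb_at_high": [e.outcome_at_high for e in entries],
            "icur_at_low": [e.icur_at_low for e in entries],
            "icur_at_high": [e.icur_at_high for e in entries],
            "range": [e.range for e in entries],
            "failed": [e.failed for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Price threshold analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdResult:
    drug_parameter: str
    criterion: str
    base_price: float
    threshold_price: float | None  # None when never crossed in the bracket
    bracket: tuple[float, float]


def price_threshold(
    model: DecisionModel,
    drug_parameter: str,
    criterion: str = "icur=wtp",
    bracket_factor: float = 10.0,
    tol: float = 0.01,
) -> ThresholdResult:
    """Unit price at which a cost-effectiveness criterion switches.

    ``criterion='icur=wtp'`` finds the price where the incremental NMB at
    the configured WTP is zero (equivalently ICUR = WTP when the QALY gain
    is positive); ``criterion='dominance'`` finds the price where the
    incremental cost is zero.  Bisection to ``tol`` dollars over
    [0, bracket_factor x base price]; cost linearity in the unit price makes
    the root unique when it exists.
    """
    spec = model.config.params[drug_parameter]
    base_price = spec.mean

    def f(price: float) -> float:
        res = evaluate(model, {drug_parameter: price})
        if criterion == "icur=wtp":
            return res.comparison.incremental_nmb
        if criterion == "dominance":
            return res.comparison.delta_cost
        raise ValidationError(f"unknown criterion {criterion!r}")

    lo, hi = 0.0, bracket_factor * base_price
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        return ThresholdResult(drug_parameter, criterion, base_price, None, (lo, hi))
    root = optimize.brentq(f, lo, hi, xtol=tol)
    return ThresholdResult(drug_parameter, criterion, base_price, float(root), (lo, hi))


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Sampled parameter vectors and incremental outcomes per draw."""

    samples: pd.DataFrame  # one row per draw
    seed: int
    n_resampled: int

    @property
    def n(self) -> int:
        return len(self.samples)


def _psa_parameters(model: DecisionModel) -> list:
    specs = model.config.params.varied()
    if not model.config.hazards.vary_hazard_ratios_in_psa:
        specs = [s for s in specs if s.role != "hazard-ratio"]
    return specs


def _valid_draw(model: DecisionModel, values: dict[str, float]) -> bool:
    means = model.config.params.means()
    means.update(values)
    u_pd = means["u_pfs"] + means["disutility_progression"]
    if not (0.0 <= u_pd <= 1.0) or not (0.0 <= means["u_pfs"] <= 1.0):
        return False
    for arm in model.config.arms.values():
        if not (0.0 <= means[arm.ae_probability] <= 1.0):
            return False
    return True


def run_psa(
    model: DecisionModel, n_draws: int | None = None, seed: int | None = None
) -> PSAResult:
    """Second-order Monte Carlo over all varied parameters.

    Each draw samples every varied parameter independently from its fitted
    distribution and reruns the deterministic pipeline.  Reproducible for a
    given (seed, n_draws); draws producing invalid state (utilities or
    probabilities out of range) are resampled with a logged count, warning
    above a 1% resample rate.
    """
    cfg = model.config
    n = cfg.psa.n_draws if n_draws is None else int(n_draws)
    if n < 1:
        raise ValidationError("n_draws must be >= 1")
    seed = cfg.psa.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    specs = _psa_parameters(model)
    dists = {s.name: fit_distribution(s) for s in specs}
    names = [s.name for s in specs]

    rows = []
    n_resampled = 0
    for i in range(n):
        for _attempt in range(100):
            values = {name: float(dists[name].rvs(1, rng)[0]) for name in names}
            if _valid_draw(model, values):
                break
            n_resampled += 1
        else:
            raise CalibrationError(f"draw {i}: could not sample a valid parameter set")
        res = evaluate(model, values)
        c = res.comparison
        row = {"draw": i, **values}
        row.update(
            {
                "cost_intervention": res.arms[model.intervention_name].total_cost,
                "cost_comparator": res.arms[model.comparator_name].total_cost,
                "qaly_intervention": res.arms[model.intervention_name].total_qaly,
                "qaly_comparator": res.arms[model.comparator_name].total_qaly,
                "delta_cost": c.delta_cost,
                "delta_qaly": c.delta_qaly,
                "delta_ly": c.delta_ly,
            }
        )
        rows.append(row)
    if n_resampled > 0.01 * n:
        warnings.warn(
            f"PSA resampled {n_resampled} invalid draws out of {n}", stacklevel=2
        )
    return PSAResult(samples=pd.DataFrame(rows), seed=seed, n_resampled=n_resampled)


def ceac(psa: PSAResult | pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each WTP, the fraction of draws with positive incremental net
    monetary benefit: wtp x delta_qaly - delta_cost > 0.
    """
    df = psa.samples if isinstance(psa, PSAResult) else psa
    if len(df) == 0:
        raise ValidationError("CEAC requires a nonempty sample")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dq = df["delta_qaly"].to_numpy()
    dc = df["delta_cost"].to_numpy()
    frac = [(w * dq - dc > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": frac})


def switch_point(curve: pd.DataFrame, level: float = 0.5) -> float | None:
    """First WTP at which acceptability reaches ``level`` (linear interp)."""
    w = curve["wtp"].to_numpy()
    p = curve["probability_cost_effective"].to_numpy()
    above = np.nonzero(p >= level)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0 or p[i] == p[i - 1]:
        return float(w[i])
    t = (level - p[i - 1]) / (p[i] - p[i - 1])
    return float(w[i - 1] + t * (w[i] - w[i - 1]))


def quadrant_fractions(psa: PSAResult | pd.DataFrame) -> dict[str, float]:
    """Share of PSA draws per cost-effectiveness plane quadrant."""
    df = psa.samples if isinstance(psa, PSAResult) else psa
    dq = df["delta_qaly"].to_numpy()
    dc = df["delta_cost"].to_numpy()
    n = len(df)
    return {
        "NE": float(((dq > 0) & (dc > 0)).sum() / n),
        "SE": float(((dq > 0) & (dc <= 0)).sum() / n),
        "NW": float(((dq <= 0) & (dc > 0)).sum() / n),
        "SW": float(((dq <= 0) & (dc <= 0)).sum() / n),
    }
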