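"""Parameter registry, configuration I/O and sampling-distribution fitting.

Every quantity the decision model consumes — unit costs, per-cycle
adverse-event probabilities, health-state utilities, hazard ratios, discount
rates — is declared as a :class:`ParameterSpec` carrying its point estimate,
95% interval and sampling-distribution family.  The shipped default
configuration (``data/default_paper.yaml``) encodes the published base-case
inputs for the DRd (daratumumab/lenalidomide/dexamethasone) versus KRd
(carfilzomib/lenalidomide/dexamethasone) comparison in relapsed-refractory
multiple myeloma.

Distribution fitting matches the mean exactly and reproduces the 95%
interval in least squares over the remaining free parameter of the
two-parameter family (beta, gamma) or in closed form (lognormal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

from .budget import BIAInputs
from .errors import ConfigurationError, FittingError, ValidationError

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "ModelSettings",
    "DrugSpec",
    "StrategyArm",
    "CostModelConfig",
    "HazardStructure",
    "PSASettings",
    "Config",
    "FittedDistribution",
    "fit_distribution",
    "load_config",
    "config_from_dict",
    "default_config",
    "write_config",
]

FAMILIES = ("beta", "gamma", "lognormal", "fixed")
ROLES = (
    "cost-USD",
    "probability-per-cycle",
    "utility",
    "disutility",
    "hazard-ratio",
    "rate",
    "share",
)

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ParameterSpec:
    """A named scalar with uncertainty bounds and a sampling family.

    ``low``/``high`` are the lower/upper 95% bounds.  For ``family='fixed'``
    the bounds may coincide with the mean (the parameter is excluded from
    sensitivity analyses).
    """

    name: str
    mean: float
    low: float
    high: float
    family: str
    role: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"parameter {self.name!r}: unknown family {self.family!r}"
            )
        if self.role not in ROLES:
            raise ValidationError(f"parameter {self.name!r}: unknown role {self.role!r}")
        if self.family != "fixed":
            if not (self.low <= self.mean <= self.high):
                raise ValidationError(
                    f"parameter {self.name!r}: requires low <= mean <= high, "
                    f"got ({self.low}, {self.mean}, {self.high})"
                )
        if self.role in ("probability-per-cycle", "utility", "share"):
            if not (0.0 <= self.mean <= 1.0):
                raise ValidationError(
                    f"parameter {self.name!r}: role {self.role} must lie in [0, 1]"
                )
        if self.role == "disutility" and not (-1.0 <= self.mean <= 0.0):
            raise ValidationError(
                f"parameter {self.name!r}: disutility must lie in [-1, 0]"
            )
        if self.role == "cost-USD" and self.mean < 0:
            raise ValidationError(f"parameter {self.name!r}: cost must be >= 0")
        if self.family == "beta" and self.role not in (
            "probability-per-cycle",
            "utility",
            "disutility",
            "share",
        ):
            raise ValidationError(
                f"parameter {self.name!r}: beta family requires a [0,1]-bounded role"
            )
        if self.family == "gamma" and self.role in ("disutility",):
            raise ValidationError(
                f"parameter {self.name!r}: gamma family requires a nonnegative role"
            )

    @property
    def varied(self) -> bool:
        """Whether the parameter enters DSA/PSA."""
        return self.family != "fixed"


class ParameterSet:
    """Ordered mapping of parameter name to :class:`ParameterSpec`."""

    def __init__(self, specs: Sequence[ParameterSpec]):
        self._specs: dict[str, ParameterSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValidationError(f"duplicate parameter {spec.name!r}")
            self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> ParameterSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._specs == other._specs

    def names(self) -> list[str]:
        return list(self._specs)

    def means(self) -> dict[str, float]:
        """Base-case point estimates for every parameter."""
        return {name: spec.mean for name, spec in self._specs.items()}

    def varied(self) -> list[ParameterSpec]:
        """Parameters entering sensitivity analyses (family != fixed)."""
        return [s for s in self if s.varied]


@dataclass(frozen=True)
class ModelSettings:
    """Global run settings: horizon, cycle length, discounting, WTP.

    ``discount_basis`` selects how the annual rates are compounded over the
    monthly cycle index t: ``"annual"`` uses (1+r)^(-t/12); ``"per_cycle"``
    applies the annual rate each cycle, (1+r)^(-t).  The per-cycle basis is
    the shipped default because it reproduces the published discounted QALY
    totals (see docs/methods.md).
    """

    cycle_length_months: float = 1.0
    horizon_cycles: int = 120
    wtp_usd_per_qaly: float = 1290.0
    discount_cost_annual: float = 0.072
    discount_outcome_annual: float = 0.03
    discount_basis: str = "per_cycle"
    discount_life_years: bool = False
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        for r in (self.discount_cost_annual, self.discount_outcome_annual):
            if not (0.0 <= r < 1.0):
                raise ValidationError("discount rates must lie in [0, 1)")
        if self.wtp_usd_per_qaly <= 0:
            raise ValidationError("wtp must be > 0")
        if self.discount_basis not in ("annual", "per_cycle"):
            raise ValidationError("discount_basis must be 'annual' or 'per_cycle'")
        if self.cycle_length_months <= 0:
            raise ValidationError("cycle_length_months must be > 0")


@dataclass(frozen=True)
class DrugSpec:
    """One drug inside an arm's regimen."""

    name: str
    unit_cost: str  # ParameterSpec name
    units_per_administration: float = 1.0
    administrations_by_cycle: tuple[int, ...] | None = None  # override calendar

    def __post_init__(self) -> None:
        if self.units_per_administration <= 0:
            raise ValidationError(
                f"drug {self.name!r}: units_per_administration must be > 0"
            )
        if self.administrations_by_cycle is not None and any(
            a < 0 for a in self.administrations_by_cycle
        ):
            raise ValidationError(f"drug {self.name!r}: administration counts >= 0")


@dataclass(frozen=True)
class StrategyArm:
    """A treatment strategy: regimen, duration, HRs vs baseline, AE risk.

    ``hr_pfs``/``hr_os`` are either literal floats (the reference arm uses
    1.0) or names of hazard-ratio parameters in the :class:`ParameterSet`.
    ``cost_target_usd``, when set, calibrates a multiplicative cost scale so
    the arm's discounted lifetime cost matches the published total.
    """

    name: str
    planned_duration_cycles: int
    ae_probability: str  # ParameterSpec name
    drugs: tuple[DrugSpec, ...]
    hr_pfs: float | str = 1.0
    hr_os: float | str = 1.0
    cost_target_usd: float | None = None
    reference: bool = False

    def __post_init__(self) -> None:
        if self.planned_duration_cycles < 1:
            raise ValidationError(f"arm {self.name!r}: planned duration must be >= 1")

    def hr_value(self, which: str, values: Mapping[str, float]) -> float:
        ref = self.hr_pfs if which == "pfs" else self.hr_os
        return float(values[ref]) if isinstance(ref, str) else float(ref)


@dataclass(frozen=True)
class CostModelConfig:
    """Non-drug per-cycle cost components as {parameter name: count}."""

    on_treatment: dict[str, float] = field(default_factory=dict)
    post_treatment_pfs: dict[str, float] = field(default_factory=dict)
    progressed: dict[str, float] = field(default_factory=dict)
    ae_event: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class HazardStructure:
    """Structural choices for the exponential baseline hazards.

    Three monthly hazards underlie the transition matrix but only one
    published quantity (the comparator arm's restricted life-years)
    identifies them, so two ratios are fixed by configuration: the median
    time to progression (identifying the progression hazard) and the
    post-progression / progression-free excess-mortality ratio.  A single
    mortality scale is then calibrated by root finding.
    """

    progression_median_months: float = 26.0
    pd_to_pfs_mortality_ratio: float = 2.0
    krd_target_life_years: float = 3.52
    hr_pfs_includes_pfs_death: bool = False
    vary_hazard_ratios_in_psa: bool = True

    def __post_init__(self) -> None:
        if self.progression_median_months <= 0:
            raise ValidationError("progression_median_months must be > 0")
        if self.pd_to_pfs_mortality_ratio <= 0:
            raise ValidationError("pd_to_pfs_mortality_ratio must be > 0")


@dataclass(frozen=True)
class PSASettings:
    n_draws: int = 10_000
    seed: int = 20220810


@dataclass(frozen=True)
class Config:
    """Fully parsed configuration bundle."""

    params: ParameterSet
    settings: ModelSettings
    arms: dict[str, StrategyArm]
    cost_model: CostModelConfig
    hazards: HazardStructure
    bia: BIAInputs | None = None
    psa: PSASettings = field(default_factory=PSASettings)

    def reference_arm(self) -> StrategyArm:
        for arm in self.arms.values():
            if arm.reference:
                return arm
        raise ConfigurationError("no reference arm flagged in configuration")


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedDistribution:
    """A parameterized sampling distribution for one ParameterSpec.

    ``negate`` marks disutilities, which are fitted as beta on |value| and
    negated on sampling.
    """

    spec: ParameterSpec
    frozen: stats._distn_infrastructure.rv_frozen
    negate: bool = False

    @property
    def mean(self) -> float:
        m = float(self.frozen.mean())
        return -m if self.negate else m

    def rvs(self, size: int | tuple, rng: np.random.Generator) -> np.ndarray:
        x = self.frozen.rvs(size=size, random_state=rng)
        return -x if self.negate else x

    def interval95(self) -> tuple[float, float]:
        lo, hi = self.frozen.ppf(0.025), self.frozen.ppf(0.975)
        if self.negate:
            lo, hi = -hi, -lo
        return float(lo), float(hi)


def _quantile_loss(frozen, low: float, high: float) -> float:
    q = frozen.ppf([0.025, 0.975])
    return float((q[0] - low) ** 2 + (q[1] - high) ** 2)


def _fit_beta(mean: float, low: float, high: float):
    if not (0.0 < mean < 1.0):
        raise FittingError(f"beta mean must lie in (0, 1), got {mean}")

    def loss(log_nu: float) -> float:
        nu = math.exp(log_nu)
        return _quantile_loss(stats.beta(mean * nu, (1.0 - mean) * nu), low, high)

    res = optimize.minimize_scalar(loss, bounds=(-4.0, 20.0), method="bounded")
    nu = math.exp(res.x)
    return stats.beta(mean * nu, (1.0 - mean) * nu)


def _fit_gamma(mean: float, low: float, high: float):
    if mean <= 0:
        raise FittingError(f"gamma mean must be > 0, got {mean}")

    def loss(log_k: float) -> float:
        k = math.exp(log_k)
        return _quantile_loss(stats.gamma(k, scale=mean / k), low, high)

    res = optimize.minimize_scalar(loss, bounds=(-4.0, 25.0), method="bounded")
    k = math.exp(res.x)
    return stats.gamma(k, scale=mean / k)


def _fit_lognormal(mean: float, low: float, high: float):
    # sigma from the (log-symmetric) CI ratio; mu shifted so the arithmetic
    # mean matches exactly: E[X] = exp(mu + sigma^2/2).
    if mean <= 0 or low <= 0 or high <= 0:
        raise FittingError("lognormal requires strictly positive mean and bounds")
    sigma = math.log(high / low) / (2.0 * _Z975)
    mu = math.log(mean) - 0.5 * sigma**2
    return stats.lognorm(s=sigma, scale=math.exp(mu))


def fit_distribution(spec: ParameterSpec) -> FittedDistribution:
    """Parameterize the sampling distribution declared by ``spec``.

    The mean is matched exactly; the 95% interval is reproduced as closely
    as the two-parameter family allows (least squares on the 2.5% and 97.5%
    quantiles for beta/gamma; closed form for lognormal).
    """
    if spec.family == "fixed":
        raise FittingError(f"parameter {spec.name!r} is fixed; nothing to fit")
    if spec.low >= spec.high:
        raise FittingError(f"parameter {spec.name!r}: degenerate interval")

    negate = spec.role == "disutility"
    mean, low, high = spec.mean, spec.low, spec.high
    if negate:
        mean, low, high = -mean, -high, -low  # fit on |value|

    if spec.family == "beta":
        frozen = _fit_beta(mean, low, high)
    elif spec.family == "gamma":
        frozen = _fit_gamma(mean, low, high)
    elif spec.family == "lognormal":
        frozen = _fit_lognormal(mean, low, high)
    else:  # pragma: no cover - guarded above
        raise FittingError(f"unknown family {spec.family!r}")

    fitted = FittedDistribution(spec=spec, frozen=frozen, negate=negate)
    if not math.isclose(abs(fitted.mean), mean, rel_tol=1e-6):
        raise FittingError(
            f"parameter {spec.name!r}: fitted mean {fitted.mean} != {spec.mean}"
        )
    return fitted


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

_REQUIRED_TOP = ("settings", "parameters", "arms", "cost_model", "hazard_structure")
_REQUIRED_SETTINGS = (
    "cycle_length_months",
    "horizon_cycles",
    "wtp_usd_per_qaly",
    "discount_cost",
    "discount_outcome",
)


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ConfigurationError(f"missing key {key!r} in {where}")
    return mapping[key]


def config_from_dict(raw: Mapping) -> Config:
    """Build and validate a :class:`Config` from a parsed mapping."""
    for key in _REQUIRED_TOP:
        _require(raw, key, "configuration")

    s = raw["settings"]
    for key in _REQUIRED_SETTINGS:
        _require(s, key, "settings")
    settings = ModelSettings(
        cycle_length_months=float(s["cycle_length_months"]),
        horizon_cycles=int(s["horizon_cycles"]),
        wtp_usd_per_qaly=float(s["wtp_usd_per_qaly"]),
        discount_cost_annual=float(s["discount_cost"]),
        discount_outcome_annual=float(s["discount_outcome"]),
        discount_basis=str(s.get("discount_basis", "per_cycle")),
        discount_life_years=bool(s.get("discount_life_years", False)),
        half_cycle_correction=bool(s.get("half_cycle_correction", False)),
    )

    specs = []
    for name, p in raw["parameters"].items():
        family = str(_require(p, "family", f"parameter {name!r}"))
        mean = float(_require(p, "mean", f"parameter {name!r}"))
        low = p.get("low")
        high = p.get("high")
        if family != "fixed" and (low is None or high is None):
            # one-way bounds default to +/-20% when no 95% CI is available
            span = 0.2 * abs(mean)
            low = mean - span if low is None else low
            high = mean + span if high is None else high
        specs.append(
            ParameterSpec(
                name=name,
                mean=mean,
                low=float(low if low is not None else mean),
                high=float(high if high is not None else mean),
                family=family,
                role=str(_require(p, "role", f"parameter {name!r}")),
            )
        )
    params = ParameterSet(specs)

    arms: dict[str, StrategyArm] = {}
    for arm_name, a in raw["arms"].items():
        drugs = tuple(
            DrugSpec(
                name=str(_require(d, "name", f"arm {arm_name!r} drug")),
                unit_cost=str(_require(d, "unit_cost", f"arm {arm_name!r} drug")),
                units_per_administration=float(d.get("units_per_administration", 1.0)),
                administrations_by_cycle=(
                    tuple(int(x) for x in d["administrations_by_cycle"])
                    if d.get("administrations_by_cycle") is not None
                    else None
                ),
            )
            for d in _require(a, "drugs", f"arm {arm_name!r}")
        )
        arm = StrategyArm(
            name=arm_name,
            planned_duration_cycles=int(
                _require(a, "planned_duration_cycles", f"arm {arm_name!r}")
            ),
            ae_probability=str(_require(a, "ae_probability", f"arm {arm_name!r}")),
            drugs=drugs,
            hr_pfs=a.get("hr_pfs", 1.0),
            hr_os=a.get("hr_os", 1.0),
            cost_target_usd=(
                float(a["cost_target_usd"]) if a.get("cost_target_usd") else None
            ),
            reference=bool(a.get("reference", False)),
        )
        # referenced parameters must exist
        params[arm.ae_probability]
        for which in ("pfs", "os"):
            ref = arm.hr_pfs if which == "pfs" else arm.hr_os
            if isinstance(ref, str):
                params[ref]
        for d in drugs:
            params[d.unit_cost]
        arms[arm_name] = arm

    cm = raw["cost_model"]
    cost_model = CostModelConfig(
        on_treatment=dict(cm.get("on_treatment", {})),
        post_treatment_pfs=dict(cm.get("post_treatment_pfs", {})),
        progressed=dict(cm.get("progressed", {})),
        ae_event=dict(cm.get("ae_event", {})),
    )
    for block in (
        cost_model.on_treatment,
        cost_model.post_treatment_pfs,
        cost_model.progressed,
        cost_model.ae_event,
    ):
        for pname in block:
            params[pname]

    h = raw["hazard_structure"]
    hazards = HazardStructure(
        progression_median_months=float(h.get("progression_median_months", 26.0)),
        pd_to_pfs_mortality_ratio=float(h.get("pd_to_pfs_mortality_ratio", 2.0)),
        krd_target_life_years=float(
            _require(h, "krd_target_life_years", "hazard_structure")
        ),
        hr_pfs_includes_pfs_death=bool(h.get("hr_pfs_includes_pfs_death", False)),
        vary_hazard_ratios_in_psa=bool(h.get("vary_hazard_ratios_in_psa", True)),
    )

    bia = None
    if raw.get("budget_impact") is not None:
        bia = BIAInputs.from_dict(raw["budget_impact"])

    p = raw.get("psa", {})
    psa = PSASettings(
        n_draws=int(p.get("n_draws", 10_000)), seed=int(p.get("seed", 20220810))
    )

    return Config(
        params=params,
        settings=settings,
        arms=arms,
        cost_model=cost_model,
        hazards=hazards,
        bia=bia,
        psa=psa,
    )


def load_config(path) -> Config:
    """Read and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path} does not contain a configuration mapping")
    return config_from_dict(raw)


def default_config() -> Config:
    """The shipped base-case configuration (published Table of inputs)."""
    ref = resources.files("rrmm_cea.data").joinpath("default_paper.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)


def config_to_dict(config: Config) -> dict:
    """Serialize a Config back to the documented mapping schema."""
    raw: dict = {
        "settings": {
            "cycle_length_months": config.settings.cycle_length_months,
            "horizon_cycles": config.settings.horizon_cycles,
            "wtp_usd_per_qaly": config.settings.wtp_usd_per_qaly,
            "discount_cost": config.settings.discount_cost_annual,
            "discount_outcome": config.settings.discount_outcome_annual,
            "discount_basis": config.settings.discount_basis,
            "discount_life_years": config.settings.discount_life_years,
            "half_cycle_correction": config.settings.half_cycle_correction,
        },
        "parameters": {
            s.name: {
                "mean": s.mean,
                "low": s.low,
                "high": s.high,
                "family": s.family,
                "role": s.role,
            }
            for s in config.params
        },
        "arms": {
            a.name: {
                "planned_duration_cycles": a.planned_duration_cycles,
                "ae_probability": a.ae_probability,
                "hr_pfs": a.hr_pfs,
                "hr_os": a.hr_os,
                "cost_target_usd": a.cost_target_usd,
                "reference": a.reference,
                "drugs": [
                    {
                        "name": d.name,
                        "unit_cost": d.unit_cost,
                        "units_per_administration": d.units_per_administration,
                        "administrations_by_cycle": (
                            list(d.administrations_by_cycle)
                            if d.administrations_by_cycle is not None
                            else None
                        ),
                    }
                    for d in a.drugs
                ],
            }
            for a in config.arms.values()
        },
        "cost_model": {
            "on_treatment": dict(config.cost_model.on_treatment),
            "post_treatment_pfs": dict(config.cost_model.post_treatment_pfs),
            "progressed": dict(config.cost_model.progressed),
            "ae_event": dict(config.cost_model.ae_event),
        },
        "hazard_structure": {
            "progression_median_months": config.hazards.progression_median_months,
            "pd_to_pfs_mortality_ratio": config.hazards.pd_to_pfs_mortality_ratio,
            "krd_target_life_years": config.hazards.krd_target_life_years,
            "hr_pfs_includes_pfs_death": config.hazards.hr_pfs_includes_pfs_death,
            "vary_hazard_ratios_in_psa": config.hazards.vary_hazard_ratios_in_psa,
        },
        "psa": {"n_draws": config.psa.n_draws, "seed": config.psa.seed},
    }
    if config.bia is not None:
        raw["budget_impact"] = config.bia.to_dict()
    return raw


def write_config(config: Config, path) -> None:
    """Write a Config as YAML; ``load_config`` round-trips it."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
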