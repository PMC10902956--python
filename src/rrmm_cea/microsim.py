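"""Individual-level Monte-Carlo simulation over the cohort's transition
structure.

The microsimulation draws one categorical transition per patient per cycle
from the same per-cycle matrices the cohort engine uses, so the empirical
state occupancy is an unbiased estimate of the cohort trace — the package's
brute-force oracle.  The same machinery generates synthetic patient-level
time-to-progression / time-to-death datasets under the stated hazard
ratios, standing in for unavailable trial-level data.

Event times live on the cycle grid (discrete exponential waiting times), so
oracle equivalence with the cohort engine is exact in distribution.  All
randomness is drawn up front from a single seeded generator; results depend
only on (n, seed), never on execution order or chunking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .params import ModelSettings
from .transitions import BaselineHazards, build_arm_matrices

__all__ = ["SimulatedCohort", "simulate_patients", "generate_survival_dataset",
           "estimate_hazard_ratios"]

_PFS, _PD, _DEATH = 0, 1, 2


@dataclass
class SimulatedCohort:
    """Patient-level state paths on the cycle grid.

    ``states`` has shape (n_patients, horizon + 1); column 0 is the initial
    state (all progression-free).  Times are in cycles; NaN marks events
    not observed within the horizon (censoring).
    """

    states: np.ndarray

    def __post_init__(self) -> None:
        diffs = np.diff(self.states.astype(np.int8), axis=1)
        if np.any(diffs < 0):
            raise ValidationError("states may never move backwards (no recovery)")

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1] - 1

    def occupancy(self) -> np.ndarray:
        """Empirical state-occupancy fractions, shape (horizon + 1, 3)."""
        out = np.empty((self.states.shape[1], 3))
        for s in (_PFS, _PD, _DEATH):
            out[:, s] = (self.states == s).mean(axis=0)
        return out

    def _first_time(self, predicate: np.ndarray) -> np.ndarray:
        hit = predicate.any(axis=1)
        first = predicate.argmax(axis=1).astype(float)
        first[~hit] = np.nan
        return first

    def time_to_progression(self) -> np.ndarray:
        """First cycle in PD; NaN if never progressed (death or censoring)."""
        return self._first_time(self.states == _PD)

    def time_to_death(self) -> np.ndarray:
        """First cycle in Death; NaN if alive at the horizon."""
        return self._first_time(self.states == _DEATH)

    def life_years(self) -> np.ndarray:
        """Restricted life-years per patient (cycles alive / 12)."""
        return (self.states[:, 1:] != _DEATH).sum(axis=1) / 12.0

    def to_frame(self) -> pd.DataFrame:
        ttp = self.time_to_progression()
        ttd = self.time_to_death()
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "time_to_progression": ttp,
                "progressed": ~np.isnan(ttp),
                "time_to_death": ttd,
                "died": ~np.isnan(ttd),
            }
        )


def simulate_patients(n: int, matrices: np.ndarray, seed: int) -> SimulatedCohort:
    """Simulate ``n`` patients through a per-cycle matrix sequence."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    matrices = np.asarray(matrices, dtype=float)
    horizon = matrices.shape[0]
    rng = np.random.default_rng(seed)
    u = rng.random((n, horizon))

    states = np.empty((n, horizon + 1), dtype=np.int8)
    states[:, 0] = _PFS
    current = states[:, 0].copy()
    for t in range(horizon):
        cum = np.cumsum(matrices[t], axis=1)
        # next state = first column whose cumulative prob exceeds the draw
        thresholds = cum[current]  # (n, 3)
        nxt = (u[:, t : t + 1] >= thresholds).sum(axis=1)
        current = nxt.astype(np.int8)
        states[:, t + 1] = current
    return SimulatedCohort(states=states)


def generate_survival_dataset(
    n_per_arm: int,
    base: BaselineHazards,
    hrs: tuple[float, float],
    censor: int,
    seed: int,
    settings: ModelSettings | None = None,
    hr_pfs_includes_pfs_death: bool = False,
) -> pd.DataFrame:
    """Two-arm synthetic event table under the stated hazard ratios.

    The comparator arm follows the baseline hazards; the intervention arm
    applies ``hrs = (hr_pfs, hr_os)``.  Events beyond ``censor`` cycles are
    censored.  Returns one row per patient with arm, progression and death
    times (cycles) and event flags.
    """
    if n_per_arm < 2:
        raise ValidationError("need at least 2 patients per arm")
    if censor < 0:
        raise ValidationError("censoring time must be >= 0")
    if settings is None:
        settings = ModelSettings(horizon_cycles=max(censor, 1))
    frames = []
    for arm_name, (hr_pfs, hr_os), arm_seed in (
        ("comparator", (1.0, 1.0), seed),
        ("intervention", hrs, seed + 1),
    ):
        matrices = build_arm_matrices(
            base, hr_pfs, hr_os, settings, hr_pfs_includes_pfs_death
        )
        cohort = simulate_patients(n_per_arm, matrices, arm_seed)
        df = cohort.to_frame()
        df.insert(0, "arm", arm_name)
        if censor < cohort.horizon:
            for time_col, flag_col in (
                ("time_to_progression", "progressed"),
                ("time_to_death", "died"),
            ):
                late = df[time_col] > censor
                df.loc[late, time_col] = np.nan
                df.loc[late, flag_col] = False
        df["censor_time"] = censor
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _pfs_exposure(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-patient person-cycles in PFS, progression events, PFS-death events."""
    exit_time = df["time_to_progression"].fillna(df["time_to_death"]).fillna(
        df["censor_time"]
    )
    # a patient leaves PFS at the first of progression, death, censoring
    exposure = np.minimum(exit_time, df["censor_time"]).to_numpy(dtype=float)
    progressed = df["progressed"].to_numpy(dtype=bool)
    died_from_pfs = df["died"].to_numpy(dtype=bool) & ~progressed
    return exposure, progressed, died_from_pfs


def estimate_hazard_ratios(df: pd.DataFrame) -> dict[str, float]:
    """Recover the progression and mortality hazard ratios from an event table.

    Cause-specific rates are estimated within the progression-free state
    (events per person-cycle, discrete-time corrected via -log(1 - p)) and
    compared between arms, so the estimates target exactly the hazard
    ratios the generator applied.
    """
    rates: dict[str, dict[str, float]] = {}
    for arm, sub in df.groupby("arm"):
        exposure, progressed, died_pfs = _pfs_exposure(sub)
        total = exposure.sum()
        if total <= 0:
            raise ValidationError(f"arm {arm!r}: no person-time at risk")
        p_prog = progressed.sum() / total
        p_die = died_pfs.sum() / total
        rates[arm] = {
            "progression": -np.log1p(-min(p_prog, 1 - 1e-12)),
            "death_pfs": -np.log1p(-min(p_die, 1 - 1e-12)),
        }
    return {
        "hr_pfs": rates["intervention"]["progression"] / rates["comparator"]["progression"],
        "hr_os": rates["intervention"]["death_pfs"] / rates["comparator"]["death_pfs"],
    }
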