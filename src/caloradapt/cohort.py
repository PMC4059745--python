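"""Virtual rat cohorts with the study's measurement structure.

Generates groups of simulated animals (default 4 groups x 6 rats over 8
weeks with a 5-day ad-libitum lead-in), observed the way the experiment
observed them: weekly morning body weights, daily consumed food from
leftover weighing, and a terminal fat mass reported through a linear
retroperitoneal-fat (rWAT) proxy.  Gaussian measurement noise is added
to weights and intake; inter-individual variability enters as lognormal
perturbations of the expenditure and hunger parameters.

The rWAT-to-total-lipid regression used here is a synthetic stand-in
with realistic rat-scale coefficients; it is applied together with its
exact inverse, so estimation round trips do not depend on its values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import DIET_ENERGY_DENSITY, ModelParameters
from .schedules import FeedingSchedule, with_lead_in
from .simulate import (DEFAULT_WEIGH_OFFSET, equilibrium_state,
                       observe_daily_intake, observe_weekly_weights,
                       simulate)

__all__ = [
    "RatRecord", "CohortSpec", "sample_individual", "generate_cohort",
    "write_cohort", "read_cohort", "fat_from_rwat", "rwat_from_fat",
    "DEFAULT_INITIAL_BW_MEAN", "DEFAULT_INITIAL_BW_SD",
    "DEFAULT_INITIAL_FAT_FRACTION",
]

#: Synthetic rWAT -> total body lipid regression (g); slope and intercept
#: of rat-literature magnitude, used with its exact inverse.
RWAT_SLOPE = 5.5
RWAT_INTERCEPT = 7.5

DEFAULT_INITIAL_BW_MEAN = 400.0   #: g, 12-week Wistar scale
DEFAULT_INITIAL_BW_SD = 15.0      #: g
DEFAULT_INITIAL_FAT_FRACTION = 0.12

#: Parameters perturbed by inter-individual variability.
_INDIVIDUAL_FIELDS = ("lambda0", "hunger_ghrelin_coeff",
                      "hunger_leptin_coeff", "hunger_glucose_scale",
                      "hunger_relax")


def fat_from_rwat(rwat_g: float) -> float:
    """Total body lipid (g) predicted from the retroperitoneal depot."""
    return RWAT_SLOPE * rwat_g + RWAT_INTERCEPT


def rwat_from_fat(fat_g: float) -> float:
    """Inverse of :func:`fat_from_rwat`."""
    return (fat_g - RWAT_INTERCEPT) / RWAT_SLOPE


@dataclass
class RatRecord:
    """One animal's observations (plus generation metadata when synthetic)."""

    rat_id: str
    group: str
    weigh_days: np.ndarray        #: day indices of the weekly weighings
    weekly_bw: np.ndarray         #: g
    daily_consumed_g: np.ndarray  #: g/day over the full simulated span
    terminal_fat_g: float | None  #: g, through the rWAT proxy; may be absent
    initial_bw: float             #: g, at day 0
    initial_fat_g: float          #: g, from D0-style rWAT biometrics
    lead_in_days: int = 5
    energy_density: float = DIET_ENERGY_DENSITY
    true_params: ModelParameters | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.weigh_days = np.asarray(self.weigh_days, dtype=int)
        self.weekly_bw = np.asarray(self.weekly_bw, dtype=float)
        self.daily_consumed_g = np.asarray(self.daily_consumed_g, dtype=float)
        if np.any(self.weekly_bw <= 0):
            raise ValueError("body weights must be positive")
        if np.any(self.daily_consumed_g < 0):
            raise ValueError("consumed food must be >= 0")

    @property
    def daily_consumed_kj(self) -> np.ndarray:
        return self.daily_consumed_g * self.energy_density


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort."""

    n_per_group: int = 6
    param_cv: float = 0.05         #: inter-individual lognormal CV
    weight_noise_sd: float = 5.0   #: g, weekly weighing error
    intake_noise_sd: float = 0.5   #: g, daily leftover-weighing error
    rwat_noise_sd: float = 0.2     #: g, terminal depot weighing error
    initial_bw_mean: float = DEFAULT_INITIAL_BW_MEAN
    initial_bw_sd: float = DEFAULT_INITIAL_BW_SD
    initial_fat_fraction: float = DEFAULT_INITIAL_FAT_FRACTION
    lead_in_days: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("need at least one rat per group")
        for name in ("param_cv", "weight_noise_sd", "intake_noise_sd",
                     "rwat_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def sample_individual(base: ModelParameters, cv: float,
                      rng: np.random.Generator | int | None) -> ModelParameters:
    """Lognormal multiplicative perturbation of the individual-level
    parameters (expenditure rate and hunger coefficients); cv=0 returns
    ``base`` unchanged."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return base
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    factors = {name: float(np.exp(rng.normal(-sigma ** 2 / 2.0, sigma)))
               for name in _INDIVIDUAL_FIELDS}
    return base.with_(**{k: getattr(base, k) * f for k, f in factors.items()})


def generate_cohort(spec: CohortSpec, schedules: dict[str, FeedingSchedule],
                    base: ModelParameters, dt: float = 1.0,
                    memory_on: bool = True) -> list[RatRecord]:
    """Simulate one rat per (group, index) and observe it like the study.

    ``schedules`` maps group labels to restriction-span schedules (no
    lead-in); the ad-libitum lead-in is prepended here.  Intake noise is
    truncated into [0, allocated] on ration days.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[RatRecord] = []
    for group in schedules:
        sched = with_lead_in(schedules[group], spec.lead_in_days)
        for i in range(spec.n_per_group):
            params = sample_individual(base, spec.param_cv, rng)
            bw0 = rng.normal(spec.initial_bw_mean, spec.initial_bw_sd)
            bw0 = max(bw0, 100.0)
            f0 = spec.initial_fat_fraction * bw0
            init, _ = equilibrium_state(f0, bw0 - f0, params)
            tr = simulate(params, sched, init=init, dt=dt,
                          memory_on=memory_on)
            _, bw = observe_weekly_weights(tr)
            weeks = np.arange(len(bw))
            weigh_days = (sched.lead_in_days + DEFAULT_WEIGH_OFFSET
                          + 7 * weeks)
            bw_obs = bw + rng.normal(0.0, spec.weight_noise_sd, size=bw.shape)
            _, intake = observe_daily_intake(tr)
            intake_obs = intake + rng.normal(0.0, spec.intake_noise_sd,
                                             size=intake.shape)
            cap = np.array([np.inf if u else g
                            for g, u in zip(sched.daily_grams, sched.unlimited)])
            intake_obs = np.clip(intake_obs, 0.0, cap)
            rwat = rwat_from_fat(tr.final_state.F)
            rwat_obs = max(rwat + rng.normal(0.0, spec.rwat_noise_sd), 0.0)
            records.append(RatRecord(
                rat_id=f"{group}{i + 1}", group=group,
                weigh_days=weigh_days, weekly_bw=bw_obs,
                daily_consumed_g=intake_obs,
                terminal_fat_g=fat_from_rwat(rwat_obs),
                initial_bw=bw0, initial_fat_g=f0,
                lead_in_days=sched.lead_in_days,
                energy_density=sched.energy_density,
                true_params=params))
    return records


def write_cohort(records: list[RatRecord], measurements_path: str | Path,
                 metadata_path: str | Path) -> None:
    """Write a cohort as two CSV files (tidy measurements + per-rat metadata)."""
    rows = []
    for r in records:
        for d, v in zip(r.weigh_days, r.weekly_bw):
            rows.append((r.rat_id, int(d), "weight", v))
        for d, v in enumerate(r.daily_consumed_g, start=1):
            rows.append((r.rat_id, d, "intake", v))
        if r.terminal_fat_g is not None:
            rows.append((r.rat_id, len(r.daily_consumed_g), "terminal_fat",
                         r.terminal_fat_g))
    pd.DataFrame(rows, columns=["rat_id", "day", "kind", "value_g"]) \
        .to_csv(measurements_path, index=False, float_format="%.17g")
    meta = []
    for r in records:
        row = {"rat_id": r.rat_id, "group": r.group,
               "initial_bw": r.initial_bw, "initial_fat_g": r.initial_fat_g,
               "lead_in_days": r.lead_in_days,
               "energy_density": r.energy_density}
        if r.true_params is not None:
            row.update({f"param_{k}": v
                        for k, v in r.true_params.as_dict().items()})
        meta.append(row)
    pd.DataFrame(meta).to_csv(metadata_path, index=False, float_format="%.17g")


def read_cohort(measurements_path: str | Path,
                metadata_path: str | Path) -> list[RatRecord]:
    """Read a cohort written by :func:`write_cohort` (lossless round trip)."""
    mdf = pd.read_csv(measurements_path, float_precision="round_trip")
    expected = {"rat_id", "day", "kind", "value_g"}
    if set(mdf.columns) != expected:
        raise ValueError(f"measurements file needs columns {sorted(expected)}")
    bad = mdf[(mdf["kind"] == "weight") & (mdf["value_g"] <= 0)]
    if len(bad):
        raise ValueError(
            f"non-positive body weight at measurement row(s) "
            f"{[int(i) + 2 for i in bad.index[:5]]}")
    meta = pd.read_csv(metadata_path, float_precision="round_trip").set_index("rat_id")
    records = []
    for rat_id, sub in mdf.groupby("rat_id", sort=False):
        if rat_id not in meta.index:
            raise ValueError(f"rat {rat_id!r} missing from metadata")
        m = meta.loc[rat_id]
        w = sub[sub["kind"] == "weight"].sort_values("day")
        intake = sub[sub["kind"] == "intake"].sort_values("day")
        fat = sub[sub["kind"] == "terminal_fat"]
        pcols = {c[len("param_"):]: float(m[c]) for c in meta.columns
                 if c.startswith("param_") and pd.notna(m[c])}
        records.append(RatRecord(
            rat_id=rat_id, group=str(m["group"]),
            weigh_days=w["day"].to_numpy(),
            weekly_bw=w["value_g"].to_numpy(),
            daily_consumed_g=intake["value_g"].to_numpy(),
            terminal_fat_g=(float(fat["value_g"].iloc[0]) if len(fat) else None),
            initial_bw=float(m["initial_bw"]),
            initial_fat_g=float(m["initial_fat_g"]),
            lead_in_days=int(m["lead_in_days"]),
            energy_density=float(m["energy_density"]),
            true_params=ModelParameters(**pcols) if pcols else None))
    return records
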