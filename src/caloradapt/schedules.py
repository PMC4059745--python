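"""Feeding protocols: ad-libitum and the three hypocaloric patterns.

The experiment's design: an ad-libitum group (AL, ~25 g chow/rat/day)
and three hypocaloric groups fed 80% of the AL ration (20 g/day on
average) over 8 weeks, differing only in the temporal pattern:

* H0 — the same ration every day;
* H1 — a ration re-drawn each week (constant within a week);
* H4 — strong restriction for 4 weeks, then excess for 4 weeks.

Every hypocaloric builder conserves the 56-day group total (1120 g)
exactly, using integer-milligram arithmetic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import DIET_ENERGY_DENSITY

__all__ = [
    "FeedingSchedule", "build_AL", "build_H0", "build_H1", "build_H4",
    "with_lead_in", "read_schedule", "write_schedule",
    "AL_GRAMS_PER_DAY", "HYPO_FRACTION",
]

logger = logging.getLogger(__name__)

#: Ad-libitum ration, g/rat/day.
AL_GRAMS_PER_DAY = 25.0
#: Hypocaloric groups receive this fraction of the AL ration.
HYPO_FRACTION = 0.8

_MG = 1000  # milligrams per gram


@dataclass(frozen=True)
class FeedingSchedule:
    """Daily food allocations for one rat.

    ``unlimited`` marks days on which availability is effectively
    infinite (ad-libitum); ``daily_grams`` still records the nominal
    ration on those days.  ``lead_in_days`` counts prepended ad-libitum
    days, excluded from restriction totals.
    """

    daily_grams: tuple[float, ...]
    energy_density: float = DIET_ENERGY_DENSITY  #: kJ/g
    unlimited: tuple[bool, ...] = ()
    lead_in_days: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.daily_grams):
            raise ValueError("daily allocations must be >= 0")
        if self.energy_density <= 0:
            raise ValueError("energy density must be positive")
        if not self.unlimited:
            object.__setattr__(self, "unlimited",
                               tuple(False for _ in self.daily_grams))
        if len(self.unlimited) != len(self.daily_grams):
            raise ValueError("unlimited flags must match daily allocations")

    def __len__(self) -> int:
        return len(self.daily_grams)

    @property
    def n_days(self) -> int:
        return len(self.daily_grams)

    @property
    def daily_kj(self) -> np.ndarray:
        return np.asarray(self.daily_grams) * self.energy_density

    def total_grams(self, exclude_lead_in: bool = True) -> float:
        """Total allocated grams (over the restricted span by default)."""
        start = self.lead_in_days if exclude_lead_in else 0
        return float(sum(self.daily_grams[start:]))


def _from_milligrams(mg_per_day: list[int], **kwargs) -> FeedingSchedule:
    return FeedingSchedule(tuple(m / _MG for m in mg_per_day), **kwargs)


def build_AL(duration: int, grams_per_day: float = AL_GRAMS_PER_DAY) -> FeedingSchedule:
    """Ad-libitum schedule: a constant nominal ration, flagged unlimited."""
    if duration < 1:
        raise ValueError("duration must be >= 1 day")
    return FeedingSchedule(tuple([grams_per_day] * duration),
                           unlimited=tuple([True] * duration), label="AL")


def build_H0(duration: int = 56) -> FeedingSchedule:
    """Constant hypocaloric schedule: 80% of the AL ration every day."""
    if duration % 7:
        raise ValueError("duration must be a whole number of weeks")
    ration_mg = round(HYPO_FRACTION * AL_GRAMS_PER_DAY * _MG)
    return _from_milligrams([ration_mg] * duration, label="H0")


def build_H1(duration: int = 56, seed: int | None = 0,
             weekly_cv: float = 0.2) -> FeedingSchedule:
    """Weekly-randomized hypocaloric schedule.

    Weekly rations are drawn around the 20 g/day mean (lognormal with
    coefficient of variation ``weekly_cv``, constant within each week)
    and rescaled so the grand total equals the H0 total exactly.
    """
    if duration % 7:
        raise ValueError("duration must be a whole number of weeks")
    n_weeks = duration // 7
    rng = np.random.default_rng(seed)
    mean = HYPO_FRACTION * AL_GRAMS_PER_DAY
    if weekly_cv > 0:
        sigma = np.sqrt(np.log1p(weekly_cv ** 2))
        weekly = mean * rng.lognormal(-sigma ** 2 / 2.0, sigma, size=n_weeks)
    else:
        weekly = np.full(n_weeks, mean)
    # rescale to the exact group total, then settle rounding in milligrams
    target_mg = round(mean * duration * _MG)
    weekly *= (target_mg / _MG) / (weekly.sum() * 7)
    mg = [round(w * _MG) for w in weekly for _ in range(7)]
    mg[-1] += target_mg - sum(mg)
    return _from_milligrams(mg, label="H1")


def build_H4(duration: int = 56, restriction_fraction: float = 0.55) -> FeedingSchedule:
    """Restriction-then-refeeding schedule.

    First half: ``restriction_fraction`` of the AL ration per day (the
    restriction phase stays below 60% of AL); second half: the constant
    complement closing the total to the H0 value exactly.
    """
    if duration % 14:
        raise ValueError("duration must split into two equal whole-week halves")
    if restriction_fraction >= 0.6:
        warnings.warn("restriction fraction >= 0.6 leaves the documented "
                      "restriction regime (< 60% of ad libitum)")
    half = duration // 2
    total_mg = round(HYPO_FRACTION * AL_GRAMS_PER_DAY * duration * _MG)
    low_mg = round(restriction_fraction * AL_GRAMS_PER_DAY * _MG)
    high_mg = (total_mg - half * low_mg) // half
    mg = [low_mg] * half + [high_mg] * half
    mg[-1] += total_mg - sum(mg)
    return _from_milligrams(mg, label="H4")


def with_lead_in(s: FeedingSchedule, days: int = 5,
                 grams_per_day: float = AL_GRAMS_PER_DAY) -> FeedingSchedule:
    """Prepend ``days`` ad-libitum days (the experiment's lead-in)."""
    if days < 0:
        raise ValueError("lead-in length must be >= 0")
    if days == 0:
        return s
    return FeedingSchedule(
        tuple([grams_per_day] * days) + s.daily_grams,
        energy_density=s.energy_density,
        unlimited=tuple([True] * days) + s.unlimited,
        lead_in_days=days + s.lead_in_days,
        label=s.label,
    )


def write_schedule(s: FeedingSchedule, path: str | Path) -> None:
    """Write a schedule as CSV: day,grams,unlimited plus a density header."""
    lines = [f"# energy_density_kj_per_g = {s.energy_density}",
             f"# lead_in_days = {s.lead_in_days}",
             "day,grams,unlimited"]
    for i, (g, u) in enumerate(zip(s.daily_grams, s.unlimited), start=1):
        lines.append(f"{i},{g!r},{int(u)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_schedule(path: str | Path) -> FeedingSchedule:
    """Read a schedule CSV written by :func:`write_schedule`."""
    density = None
    lead_in = 0
    grams: list[float] = []
    unlimited: list[bool] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition("=")
            if key.strip() == "energy_density_kj_per_g":
                density = float(val)
            elif key.strip() == "lead_in_days":
                lead_in = int(val)
            continue
        if not header_seen:
            if [c.strip() for c in line.split(",")] != ["day", "grams", "unlimited"]:
                raise ValueError(f"{path}:{lineno}: expected header 'day,grams,unlimited'")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        try:
            day, g, u = int(parts[0]), float(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
        if g < 0:
            raise ValueError(f"{path}:{lineno}: negative gram allocation")
        if day != len(grams) + 1:
            raise ValueError(f"{path}:{lineno}: day index out of order")
        grams.append(g)
        unlimited.append(bool(u))
    if not header_seen:
        raise ValueError(f"{path}: missing header row")
    if density is None:
        logger.warning("schedule %s lacks an energy-density header; "
                       "defaulting to %.1f kJ/g", path, DIET_ENERGY_DENSITY)
        density = DIET_ENERGY_DENSITY
    return FeedingSchedule(tuple(grams), energy_density=density,
                           unlimited=tuple(unlimited), lead_in_days=lead_in)
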