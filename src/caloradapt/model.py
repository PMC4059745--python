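"""State variables and right-hand-side evaluators of the energy-balance model.

The model couples eight dynamical variables: fat mass ``F`` and fat-free
mass ``FFM`` (g), available food energy ``Favail`` (kJ), hunger ``H``
(kJ, the amount of food energy the organism would consume absent any
availability constraint), plasma leptin ``L`` (ng), plasma glucose ``G``
(g), plasma ghrelin ``Ghr`` (pg/mL) and the rate of energy expenditure
``lam`` (per min), which adapts to a memory of past intake through the
difference of two trailing means of consumed energy.

All evaluators here are pure scalar functions used both directly (unit
tests, single steps) and as the reference for the compiled integration
kernel in :mod:`caloradapt._kernel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import MIN_PER_DAY, ModelParameters

__all__ = [
    "ModelState", "IntakeHistory",
    "food_intake_rate", "energy_expenditure", "energy_balance",
    "partition_ffm", "rhs_body_composition", "rhs_food", "rhs_leptin",
    "rhs_glucose", "rhs_ghrelin", "rhs_hunger", "rhs_lambda",
    "moving_average_intake",
]

#: Reference time over which an amount min(H, Favail) translates into an
#: ingestion rate (the "per unit of time" of the intake rule), min.
#: Calibrated once so that the ad-libitum fixed point of the hunger
#: subsystem corresponds to ~25 g chow/day for a 400 g rat.
EATING_TIME_UNIT = 1.7

#: Reference body mass (g) scaling the hunger-relaxation rate
#: ``hunger_relax`` (units /min/g); fixed rather than live body weight so
#: ad-libitum demand stays stationary as an animal grows.
REF_MASS = 400.0


@dataclass(frozen=True)
class ModelState:
    """One snapshot of the eight dynamical variables."""

    F: float        #: fat mass, g
    FFM: float      #: fat-free mass, g
    Favail: float   #: available food energy, kJ
    H: float        #: hunger, kJ
    L: float        #: plasma leptin, ng
    G: float        #: plasma glucose, g
    Ghr: float      #: plasma ghrelin, pg/mL
    lam: float      #: rate of energy expenditure, /min

    def __post_init__(self) -> None:
        for name in ("F", "FFM", "Favail", "H", "L", "G", "Ghr", "lam"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"state variable {name} must be finite and >= 0, got {v}")
        if not self.F + self.FFM > 0.0:
            raise ValueError("body weight F + FFM must be positive")

    @property
    def BW(self) -> float:
        """Body weight, g."""
        return self.F + self.FFM

    def with_(self, **kwargs) -> "ModelState":
        return replace(self, **kwargs)

    def as_array(self) -> np.ndarray:
        return np.array([self.F, self.FFM, self.Favail, self.H,
                         self.L, self.G, self.Ghr, self.lam])

    @classmethod
    def from_array(cls, a) -> "ModelState":
        return cls(*(float(x) for x in a))


class IntakeHistory:
    """Ring buffer of per-step consumed energy (kJ) covering the long
    memory window.

    The buffer is pre-filled with a constant burn-in value (ad-libitum
    intake per step) so trailing means are defined from the first step.
    Running sums over the short and long windows are maintained
    incrementally, so each mean is O(1) per step and exact to quadrature
    order (rectangle rule on the step grid).
    """

    def __init__(self, dt: float, tau1_day: float, tau2_day: float,
                 fill_rate: float = 0.0):
        if not 0.0 < tau1_day < tau2_day:
            raise ValueError("need 0 < tau1 < tau2")
        self.dt = float(dt)
        self.w1 = max(1, round(tau1_day * MIN_PER_DAY / dt))
        self.w2 = round(tau2_day * MIN_PER_DAY / dt)
        if not self.w1 < self.w2:
            raise ValueError("memory windows collapse at this step size")
        per_step = fill_rate * dt
        self.buf = np.full(self.w2, per_step)
        self.s1 = per_step * self.w1
        self.s2 = per_step * self.w2
        self.n = 0  # steps pushed so far

    def means(self) -> tuple[float, float]:
        """Trailing mean intake rates (short, long), kJ/min."""
        return self.s1 / (self.w1 * self.dt), self.s2 / (self.w2 * self.dt)

    def push(self, eaten_kj: float) -> None:
        if eaten_kj < 0.0:
            raise ValueError("consumed energy must be >= 0")
        i = self.n % self.w2
        j = (self.n - self.w1) % self.w2
        self.s1 += eaten_kj - self.buf[j]
        self.s2 += eaten_kj - self.buf[i]
        self.buf[i] = eaten_kj
        self.n += 1


def _check_nonneg(**kwargs) -> None:
    for name, v in kwargs.items():
        if not math.isfinite(v) or v < 0.0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")


def food_intake_rate(H: float, Favail: float, p: ModelParameters) -> float:
    """Instantaneous food consumption, kJ/min.

    Consumption equals the minimum of hunger and available food per unit
    of time, capped by the maximal ingestion rate 1/``intake_rate_coeff``
    (the experimentally measured time needed to ingest one kJ of chow).
    It therefore vanishes whenever either hunger or available food is
    zero and depends on the two arguments only through their minimum.
    """
    _check_nonneg(H=H, Favail=Favail)
    m = min(H, Favail)
    return min(m / EATING_TIME_UNIT, 1.0 / p.intake_rate_coeff)


def energy_expenditure(F: float, FFM: float, lam: float, p: ModelParameters) -> float:
    """Energy lost per minute, kJ/min.

    Expenditure is the rate ``lam`` applied to the caloric content of
    the body, taken as the affine form ``rho_F*F + rho_FFM*FFM + K``
    where ``K`` (``maintenance_offset``, kJ) is a maintenance
    offset: the mass-independent share of basal expenditure (organ and
    neural upkeep) that does not scale with the energy stores.  At the
    reference rate this yields ~230-240 kJ/day for a 400 g rat.
    """
    _check_nonneg(F=F, FFM=FFM, lam=lam)
    return lam * (p.rho_F * F + p.rho_FFM * FFM + p.maintenance_offset)


def energy_balance(q: float, ee: float) -> float:
    """Instantaneous difference between intake and expenditure, kJ/min."""
    return q - ee


def partition_ffm(F: float, p: ModelParameters) -> float:
    """Fraction of the energy balance routed to the fat-free compartment.

    A Forbes-type companionship rule: at low adiposity most of an energy
    surplus (or deficit) is routed to the fat-free compartment; as fat
    mass grows the fat-free share decays monotonically toward the floor
    ``b/(1+b)``, so a fat animal stores (or mobilizes) mostly fat.
    Always in (0, 1) and strictly decreasing in F.
    """
    s = (p.partition_baseline
         + p.partition_juvenile_amp * math.exp(-p.partition_fat_decay * F))
    return s / (1.0 + s)


def rhs_body_composition(state: ModelState, E: float,
                         p: ModelParameters) -> tuple[float, float]:
    """Time derivatives (dF/dt, dFFM/dt), g/min, for energy balance ``E``.

    The balance is split between the two compartments by the partition
    function so that ``rho_F*dF/dt + rho_FFM*dFFM/dt == E`` identically.
    """
    if not math.isfinite(E):
        raise ValueError("energy balance must be finite")
    share_ffm = partition_ffm(state.F, p)
    dF = (1.0 - share_ffm) * E / p.rho_F
    dFFM = share_ffm * E / p.rho_FFM
    return dF, dFFM


def rhs_food(Favail: float, u: float, q: float) -> float:
    """dFavail/dt: food delivered minus food consumed, kJ/min."""
    _check_nonneg(Favail=Favail, u=u, q=q)
    return u - q


def rhs_leptin(L: float, F: float, p: ModelParameters) -> float:
    """dL/dt: production proportional to fat mass, first-order clearance."""
    _check_nonneg(L=L, F=F)
    return p.leptin_prod * F - p.leptin_clear * L


def rhs_glucose(G: float, q: float, p: ModelParameters) -> float:
    """dG/dt: rises with food intake, first-order clearance."""
    _check_nonneg(G=G, q=q)
    return p.glucose_yield * q - p.glucose_clear * G


def rhs_ghrelin(Ghr: float, q: float, p: ModelParameters) -> float:
    """dGhr/dt: production inhibited by food being eaten, linear clearance.

    The inhibition argument is the consumed-food flux ``q`` (a proxy for
    stomach content); ``intake_rate_coeff * q`` is dimensionless and lies
    in [0, 1] because ``q`` is capped at the maximal ingestion rate, so
    production runs at full rate when fasting and shuts off while the
    animal eats at full speed.
    """
    _check_nonneg(Ghr=Ghr, q=q)
    inhibition = min(p.intake_rate_coeff * q, 1.0)
    return p.ghrelin_prod * (1.0 - inhibition) - p.ghrelin_clear * Ghr


def rhs_hunger(H: float, L: float, G: float, Ghr: float,
               p: ModelParameters) -> float:
    """dH/dt, kJ/min.

    Hunger is driven by ghrelin and damped multiplicatively by leptin
    (adiposity signal, long time scale) and glucose (nutrient signal,
    short time scale); it relaxes at a rate proportional to body weight
    via ``hunger_relax``.  Because the relaxation term is proportional to
    H itself, hunger cannot become negative.
    """
    _check_nonneg(H=H, L=L, G=G, Ghr=Ghr)
    drive = (p.hunger_ghrelin_coeff * Ghr
             * math.exp(-p.hunger_leptin_coeff * L)
             * math.exp(-G / p.hunger_glucose_scale))
    return drive - p.hunger_relax * REF_MASS * H


def moving_average_intake(hist: IntakeHistory, window_day: float,
                          t_min: float | None = None) -> float:
    """Trailing mean of consumed energy over ``window_day``, kJ/day.

    The window must be one of the two maintained by ``hist`` (short or
    long); a constant intake of c kJ/day returns c for either window.
    """
    w = round(window_day * MIN_PER_DAY / hist.dt)
    if w == hist.w1:
        rate = hist.s1 / (hist.w1 * hist.dt)
    elif w == hist.w2:
        rate = hist.s2 / (hist.w2 * hist.dt)
    else:
        raise ValueError(f"window {window_day} day is not tracked by this history")
    return rate * MIN_PER_DAY


def rhs_lambda(lam: float, m_short: float, m_long: float,
               p: ModelParameters) -> float:
    """dlam/dt, /min^2: adaptation of the rate of energy expenditure.

    ``m_short`` and ``m_long`` are the trailing mean intake rates over
    the short and long memory windows (kJ/min).  The rate of energy
    expenditure rises under sustained overfeeding (recent mean above the
    long-run mean) and falls under restriction, with relative speed set
    by ``mem_gain``; it is constant whenever intake has not changed for
    the long window's duration.
    """
    if not lam > 0.0:
        raise ValueError("lam must be strictly positive")
    return p.mem_gain * lam * (m_short - m_long)
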