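"""Trajectory integration over feeding schedules.

The integrator is a fixed-step explicit scheme (RK4 on the smooth part
of the field; the min-rule intake flux and the once-daily food
deposition are resolved per step) at dt = 1 min by default: the fastest
clearance in the system (leptin, 0.074/min) is well resolved at that
step, and the daily deposition events make adaptive stiff solvers
awkward.  The distributed memory of past intake is evaluated from a
ring buffer of per-step consumed energy rather than by augmenting the
state with delay lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel
from .model import (EATING_TIME_UNIT, REF_MASS, IntakeHistory, ModelState,
                    energy_expenditure, food_intake_rate,
                    rhs_body_composition, rhs_ghrelin, rhs_glucose,
                    rhs_hunger, rhs_lambda, rhs_leptin)
from .params import MIN_PER_DAY, ModelParameters
from .schedules import FeedingSchedule

__all__ = [
    "Trajectory", "simulate", "step", "equilibrium_state",
    "observe_weekly_weights", "observe_daily_intake", "extend_scenario",
    "export_trajectory", "DEFAULT_WEIGH_OFFSET",
]

#: Day-of-week offset of the weekly weighing within each schedule week
#: (food changed on Tuesdays, rats weighed Friday mornings).
DEFAULT_WEIGH_OFFSET = 3

_STATE_COLS = ("F_g", "FFM_g", "Favail_kJ", "H_kJ", "L_ng", "G_g",
               "Ghr_pgml", "lambda_permin")


@dataclass
class Trajectory:
    """Simulation output.

    ``daily_states[d]`` is the state at the start of day ``d`` (morning,
    before that day's deposition); the last row is the final state.
    ``rec_*`` hold the dense (strided) output used for within-day
    structure and export.
    """

    dt: float
    schedule: FeedingSchedule
    params: ModelParameters
    memory_on: bool
    daily_states: np.ndarray      # (n_days+1, 8)
    eaten_day_kj: np.ndarray      # (n_days,)
    removed_day_kj: np.ndarray    # (n_days,)
    deposited_day_kj: np.ndarray  # (n_days,)
    rec_t_min: np.ndarray
    rec_states: np.ndarray
    rec_cum_eaten_kj: np.ndarray
    history: tuple = field(repr=False, default=None)  # (buf, s1, s2, pos)

    @property
    def n_days(self) -> int:
        return len(self.eaten_day_kj)

    @property
    def daily_bw(self) -> np.ndarray:
        """Body weight (g) at each day start, plus the final value."""
        return self.daily_states[:, 0] + self.daily_states[:, 1]

    @property
    def final_state(self) -> ModelState:
        return ModelState.from_array(self.daily_states[-1])

    @property
    def rec_bw(self) -> np.ndarray:
        return self.rec_states[:, 0] + self.rec_states[:, 1]


def equilibrium_state(F0: float, FFM0: float, p: ModelParameters,
                      lam: float | None = None) -> tuple[ModelState, float]:
    """Closed-form/fixed-point initialization under ad-libitum feeding.

    Leptin, glucose and ghrelin are set to their steady states for the
    self-consistent ad-libitum intake rate, and hunger to its fixed
    point; returns the state and the equilibrium intake rate (kJ/min),
    which also serves as the memory buffer's burn-in value.
    """
    lam = p.lambda0 if lam is None else lam
    L = p.leptin_prod * F0 / p.leptin_clear
    qmax = 1.0 / p.intake_rate_coeff
    q = 0.5 * qmax
    for _ in range(400):
        G = p.glucose_yield * q / p.glucose_clear
        Ghr = p.ghrelin_prod * (1.0 - p.intake_rate_coeff * q) / p.ghrelin_clear
        drive = (p.hunger_ghrelin_coeff * Ghr
                 * math.exp(-p.hunger_leptin_coeff * L)
                 * math.exp(-G / p.hunger_glucose_scale))
        H = drive / (p.hunger_relax * REF_MASS)
        q_new = min(H / EATING_TIME_UNIT, qmax)
        if abs(q_new - q) < 1e-14:
            q = q_new
            break
        q = 0.5 * q + 0.5 * q_new
    G = p.glucose_yield * q / p.glucose_clear
    Ghr = p.ghrelin_prod * (1.0 - p.intake_rate_coeff * q) / p.ghrelin_clear
    H = q * EATING_TIME_UNIT
    state = ModelState(F=F0, FFM=FFM0, Favail=0.0,
                       H=H, L=L, G=G, Ghr=Ghr, lam=lam)
    return state, q


def _fresh_history(p: ModelParameters, dt: float, fill_rate: float):
    w2 = round(p.tau2 * MIN_PER_DAY / dt)
    buf = np.full(w2, fill_rate * dt)
    w1 = max(1, round(p.tau1 * MIN_PER_DAY / dt))
    return buf, fill_rate * dt * w1, fill_rate * dt * w2, 0


def simulate(p: ModelParameters, s: FeedingSchedule,
             init: ModelState | None = None, dt: float = 1.0,
             memory_on: bool = True, record_stride: int | None = None,
             history: tuple | None = None) -> Trajectory:
    """Integrate the full system over a feeding schedule.

    ``init`` defaults to the ad-libitum equilibrium of a 400 g rat with
    12% body fat.  ``history`` may carry the intake ring buffer from a
    previous segment (see :func:`extend_scenario`); otherwise the buffer
    is burned in at the initial equilibrium intake rate.
    """
    if not (dt > 0 and abs(1440.0 / dt - round(1440.0 / dt)) < 1e-9):
        raise ValueError("dt must divide 1440 min")
    if init is None:
        bw0 = 400.0
        init, q0 = equilibrium_state(0.12 * bw0, 0.88 * bw0, p)
    else:
        _, q0 = equilibrium_state(init.F, init.FFM, p, lam=init.lam)
    if history is None:
        buf, s1, s2, pos = _fresh_history(p, dt, q0)
    else:
        buf, s1, s2, pos = history
        buf = buf.copy()
    if record_stride is None:
        record_stride = round(MIN_PER_DAY / dt)  # daily dense output

    pv = _kernel.pack_params(p)
    deposits = np.ascontiguousarray(s.daily_kj, dtype=np.float64)
    unlimited = np.array(s.unlimited, dtype=np.int8)
    out = _kernel.run_full(pv, deposits, unlimited, float(dt),
                           init.as_array(), buf, float(s1), float(s2),
                           int(pos), bool(memory_on), int(record_stride))
    (daily_y, eaten_day, removed_day, deposited_day,
     rec_t, rec_y, rec_cum, buf, s1, s2, pos, err_step) = out
    if err_step >= 0:
        raise RuntimeError(
            f"state became non-finite at t = {err_step * dt:.0f} min "
            f"(day {err_step * dt / MIN_PER_DAY:.2f})")
    return Trajectory(dt=dt, schedule=s, params=p, memory_on=memory_on,
                      daily_states=daily_y, eaten_day_kj=eaten_day,
                      removed_day_kj=removed_day,
                      deposited_day_kj=deposited_day,
                      rec_t_min=rec_t, rec_states=rec_y,
                      rec_cum_eaten_kj=rec_cum,
                      history=(buf, float(s1), float(s2), int(pos)))


def step(state: ModelState, hist: IntakeHistory, u: float,
         p: ModelParameters, dt: float,
         memory_on: bool = True) -> tuple[ModelState, IntakeHistory]:
    """One explicit integration step (pure-Python reference).

    ``u`` is the food-delivery flux over the step (kJ/min), deposited at
    the step start.  The amount consumed during the step never exceeds
    availability plus the deposit; non-negativity clamps are applied.
    """
    if u < 0:
        raise ValueError("delivery flux must be >= 0")
    fa = state.Favail + u * dt
    m1, m2 = hist.means()
    q = food_intake_rate(state.H, fa, p)
    eaten = min(q * dt, fa)
    q_eff = eaten / dt

    def deriv(y):
        F, FFM, H, L, G, Ghr, lam = y
        st = state.with_(F=max(F, 0.0), FFM=max(FFM, 0.0))
        E = q_eff - energy_expenditure(max(F, 0.0), max(FFM, 0.0), lam, p)
        dF, dFFM = rhs_body_composition(st, E, p)
        dH = rhs_hunger(max(H, 0.0), max(L, 0.0), max(G, 0.0),
                        max(Ghr, 0.0), p)
        dL = rhs_leptin(max(L, 0.0), max(F, 0.0), p)
        dG = rhs_glucose(max(G, 0.0), q_eff, p)
        dGhr = rhs_ghrelin(max(Ghr, 0.0), q_eff, p)
        dlam = rhs_lambda(lam, m1, m2, p) if memory_on else 0.0
        return np.array([dF, dFFM, dH, dL, dG, dGhr, dlam])

    y = np.array([state.F, state.FFM, state.H, state.L, state.G,
                  state.Ghr, state.lam])
    k1 = deriv(y)
    k2 = deriv(y + 0.5 * dt * k1)
    k3 = deriv(y + 0.5 * dt * k2)
    k4 = deriv(y + dt * k3)
    y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if not np.all(np.isfinite(y)):
        raise RuntimeError("state became non-finite during step")
    y = np.maximum(y, 0.0)
    new = ModelState(F=y[0], FFM=y[1], Favail=fa - eaten, H=y[2],
                     L=y[3], G=y[4], Ghr=y[5], lam=y[6])
    hist.push(eaten)
    return new, hist


def observe_weekly_weights(tr: Trajectory,
                           weigh_day_offset: int = DEFAULT_WEIGH_OFFSET
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Weekly body-weight samples (week index, grams).

    One sample per 7-day schedule week, taken ``weigh_day_offset`` days
    into the week (morning value), weeks counted from the end of any
    ad-libitum lead-in.
    """
    lead = tr.schedule.lead_in_days
    span = tr.n_days - lead
    if span < 7:
        raise ValueError("trajectory must cover at least one week")
    n_weeks = span // 7
    days = lead + weigh_day_offset + 7 * np.arange(n_weeks)
    bw = tr.daily_bw[days]
    return np.arange(1, n_weeks + 1), bw


def observe_daily_intake(tr: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-day consumed food in grams (day index starting at 1)."""
    grams = tr.eaten_day_kj / tr.schedule.energy_density
    return np.arange(1, tr.n_days + 1), grams


def extend_scenario(p: ModelParameters, schedules: list[FeedingSchedule],
                    init: ModelState | None = None, dt: float = 1.0,
                    memory_on: bool = True,
                    record_stride: int | None = None) -> Trajectory:
    """Simulate a concatenation of schedules with carried-over state and
    intake history (e.g. 8 weeks of one pattern followed by 8 of another)."""
    if not schedules:
        raise ValueError("need at least one schedule segment")
    tr = simulate(p, schedules[0], init=init, dt=dt, memory_on=memory_on,
                  record_stride=record_stride)
    for seg in schedules[1:]:
        if seg.energy_density != tr.schedule.energy_density:
            raise ValueError("segments must share the diet energy density")
        nxt = simulate(p, seg, init=tr.final_state, dt=dt,
                       memory_on=memory_on, record_stride=record_stride,
                       history=tr.history)
        tr = _concat(tr, nxt)
    return tr


def _concat(a: Trajectory, b: Trajectory) -> Trajectory:
    joined = FeedingSchedule(
        a.schedule.daily_grams + b.schedule.daily_grams,
        energy_density=a.schedule.energy_density,
        unlimited=a.schedule.unlimited + b.schedule.unlimited,
        lead_in_days=a.schedule.lead_in_days,
        label=(a.schedule.label + "+" + b.schedule.label).strip("+"),
    )
    t_off = a.n_days * MIN_PER_DAY
    cum_off = a.rec_cum_eaten_kj[-1] if len(a.rec_cum_eaten_kj) else 0.0
    return Trajectory(
        dt=a.dt, schedule=joined, params=a.params, memory_on=a.memory_on,
        daily_states=np.vstack([a.daily_states[:-1], b.daily_states]),
        eaten_day_kj=np.concatenate([a.eaten_day_kj, b.eaten_day_kj]),
        removed_day_kj=np.concatenate([a.removed_day_kj, b.removed_day_kj]),
        deposited_day_kj=np.concatenate([a.deposited_day_kj,
                                         b.deposited_day_kj]),
        rec_t_min=np.concatenate([a.rec_t_min, b.rec_t_min + t_off]),
        rec_states=np.vstack([a.rec_states, b.rec_states]),
        rec_cum_eaten_kj=np.concatenate([a.rec_cum_eaten_kj,
                                         b.rec_cum_eaten_kj + cum_off]),
        history=b.history,
    )


def export_trajectory(tr: Trajectory, path: str | Path) -> None:
    """Write the dense output as tidy CSV."""
    import pandas as pd

    df = pd.DataFrame(tr.rec_states, columns=_STATE_COLS)
    df.insert(0, "time_min", tr.rec_t_min)
    df["BW_g"] = df["F_g"] + df["FFM_g"]
    df["consumed_kJ"] = tr.rec_cum_eaten_kj
    df.to_csv(path, index=False)
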