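"""Compiled fixed-step integration kernels.

The full system is integrated with a classical RK4 step on the smooth
part of the vector field while the consumed-food flux (the min-rule
nonsmoothness) and the daily deposition events are resolved per step:
within each step the intake rate is frozen at its value at the step
start and capped so the amount eaten never exceeds availability, and
the available-food pool is updated exactly by the amount eaten.  The
distributed memory of past intake is a ring buffer of per-step consumed
energy with O(1) running sums for the two trailing windows.

The parameter vector layout must match the field order of
:class:`caloradapt.params.ModelParameters` (see ``pack_params``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: kJ deposited on an "unlimited" (ad-libitum) day; far above the
#: maximal daily ingestion (1440/theta ~ 950 kJ), so never exhausted.
UNLIMITED_DEPOSIT = 2000.0
#: min; the reference time of the intake rule (see model.EATING_TIME_UNIT).
EAT_UNIT = 1.7
#: g; reference body mass scaling the hunger relaxation (see model.REF_MASS).
REF_MASS = 400.0

# parameter-vector indices
_RHO_F, _RHO_FFM, _THETA = 0, 1, 2
_GHR_PROD, _GHR_CLEAR = 3, 4
_GLU_YIELD, _GLU_CLEAR = 5, 6
_LEP_PROD, _LEP_CLEAR = 7, 8
_PK, _PA, _PB, _PD = 9, 10, 11, 12
_LAM0 = 13
_H_GHR, _H_LEP, _H_GLU, _H_RELAX = 14, 15, 16, 17
_KMEM, _TAU1, _TAU2 = 18, 19, 20


def pack_params(p) -> np.ndarray:
    """Pack a ModelParameters instance into the kernel's flat vector."""
    return np.array([
        p.rho_F, p.rho_FFM, p.intake_rate_coeff,
        p.ghrelin_prod, p.ghrelin_clear,
        p.glucose_yield, p.glucose_clear,
        p.leptin_prod, p.leptin_clear,
        p.maintenance_offset, p.partition_juvenile_amp,
        p.partition_baseline, p.partition_fat_decay,
        p.lambda0,
        p.hunger_ghrelin_coeff, p.hunger_leptin_coeff,
        p.hunger_glucose_scale, p.hunger_relax,
        p.mem_gain, p.tau1, p.tau2,
    ])


@njit(cache=True, inline="always")
def _deriv7(F, FFM, H, L, G, Ghr, lam, q, dm, pv, mem_on):
    """Smooth part of the vector field as a scalar 7-tuple
    (Favail is handled exactly outside); ``dm = m1 - m2``."""
    ee = lam * (pv[_RHO_F] * F + pv[_RHO_FFM] * FFM + pv[_PK])
    E = q - ee
    s = pv[_PB] + pv[_PA] * np.exp(-pv[_PD] * F)
    p_ffm = s / (1.0 + s)
    dF = (1.0 - p_ffm) * E / pv[_RHO_F]
    dFFM = p_ffm * E / pv[_RHO_FFM]
    drive = (pv[_H_GHR] * Ghr * np.exp(-pv[_H_LEP] * L)
             * np.exp(-G / pv[_H_GLU]))
    dH = drive - pv[_H_RELAX] * REF_MASS * H
    dL = pv[_LEP_PROD] * F - pv[_LEP_CLEAR] * L
    dG = pv[_GLU_YIELD] * q - pv[_GLU_CLEAR] * G
    inh = pv[_THETA] * q
    if inh > 1.0:
        inh = 1.0
    dGhr = pv[_GHR_PROD] * (1.0 - inh) - pv[_GHR_CLEAR] * Ghr
    dlam = pv[_KMEM] * lam * dm if mem_on else 0.0
    return dF, dFFM, dH, dL, dG, dGhr, dlam


@njit(cache=True)
def run_full(pv, deposits_kj, unlimited, dt, y0, buf, s1, s2, pos,
             mem_on, rec_stride):
    """Integrate the full system over a schedule.

    Parameters
    ----------
    pv : packed parameter vector
    deposits_kj : per-day nominal ration, kJ
    unlimited : per-day ad-libitum flags (int8)
    dt : step, min (must divide 1440)
    y0 : initial state [F, FFM, Favail, H, L, G, Ghr, lam]
    buf, s1, s2, pos : intake-history ring buffer, its two running sums
        and the absolute step counter (carried across scenario segments)
    mem_on : adapt lam if true, else lam frozen
    rec_stride : record every this-many steps into the dense output

    Returns
    -------
    daily_y, eaten_day, removed_day, deposited_day, rec_t, rec_y,
    rec_cum, buf, s1, s2, pos, err_step
    """
    spd = int(round(1440.0 / dt))
    n_days = deposits_kj.shape[0]
    n_steps = n_days * spd
    w2 = buf.shape[0]
    w1 = int(round(pv[_TAU1] * 1440.0 / dt))
    if w1 < 1:
        w1 = 1
    if w1 >= w2:
        w1 = w2 - 1

    daily_y = np.zeros((n_days + 1, 8))
    eaten_day = np.zeros(n_days)
    removed_day = np.zeros(n_days)
    deposited_day = np.zeros(n_days)
    n_rec = n_steps // rec_stride + 1
    rec_t = np.zeros(n_rec)
    rec_y = np.zeros((n_rec, 8))
    rec_cum = np.zeros(n_rec)

    y = y0.copy()
    cum_eaten = 0.0
    qmax = 1.0 / pv[_THETA]
    i_rec = 0
    err_step = -1

    for step in range(n_steps):
        if step % spd == 0:
            day = step // spd
            daily_y[day] = y
            removed_day[day] = y[2]
            dep = UNLIMITED_DEPOSIT if unlimited[day] else deposits_kj[day]
            deposited_day[day] = dep
            y[2] = dep
        if step % rec_stride == 0:
            rec_t[i_rec] = step * dt
            rec_y[i_rec] = y
            rec_cum[i_rec] = cum_eaten
            i_rec += 1

        dm = s1 / (w1 * dt) - s2 / (w2 * dt)
        F, FFM, FA = y[0], y[1], y[2]
        H, L, G, GHR, LAM = y[3], y[4], y[5], y[6], y[7]
        m = H if H < FA else FA
        q = m / EAT_UNIT
        if q > qmax:
            q = qmax
        eaten = q * dt
        if eaten > FA:
            eaten = FA
        q_eff = eaten / dt

        h = 0.5 * dt
        a1, b1, c1, d1, e1, f1, g1 = _deriv7(F, FFM, H, L, G, GHR, LAM,
                                             q_eff, dm, pv, mem_on)
        a2, b2, c2, d2, e2, f2, g2 = _deriv7(F + h * a1, FFM + h * b1,
                                             H + h * c1, L + h * d1,
                                             G + h * e1, GHR + h * f1,
                                             LAM + h * g1, q_eff, dm, pv, mem_on)
        a3, b3, c3, d3, e3, f3, g3 = _deriv7(F + h * a2, FFM + h * b2,
                                             H + h * c2, L + h * d2,
                                             G + h * e2, GHR + h * f2,
                                             LAM + h * g2, q_eff, dm, pv, mem_on)
        a4, b4, c4, d4, e4, f4, g4 = _deriv7(F + dt * a3, FFM + dt * b3,
                                             H + dt * c3, L + dt * d3,
                                             G + dt * e3, GHR + dt * f3,
                                             LAM + dt * g3, q_eff, dm, pv, mem_on)
        w = dt / 6.0
        y[0] = F + w * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        y[1] = FFM + w * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        y[2] = FA - eaten
        y[3] = H + w * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
        y[4] = L + w * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        y[5] = G + w * (e1 + 2.0 * e2 + 2.0 * e3 + e4)
        y[6] = GHR + w * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
        y[7] = LAM + w * (g1 + 2.0 * g2 + 2.0 * g3 + g4)
        for j in range(8):
            if y[j] < 0.0:
                y[j] = 0.0
            if not np.isfinite(y[j]):
                err_step = step
        if err_step >= 0:
            break

        cum_eaten += eaten
        eaten_day[step // spd] += eaten
        i = pos % w2
        jj = (pos - w1) % w2
        s1 += eaten - buf[jj]
        s2 += eaten - buf[i]
        buf[i] = eaten
        pos += 1

    daily_y[n_days] = y
    return (daily_y, eaten_day, removed_day, deposited_day,
            rec_t[:i_rec], rec_y[:i_rec], rec_cum[:i_rec],
            buf, s1, s2, pos, err_step)


@njit(cache=True)
def run_body_only(pv, intake_kj_day, dt, F0, FFM0):
    """Integrate the two-compartment body subsystem driven by measured
    daily intake (spread uniformly within each day), with lam = lambda0.

    Returns the (n_days + 1, 2) array of daily (F, FFM) at day starts.
    """
    spd = int(round(1440.0 / dt))
    n_days = intake_kj_day.shape[0]
    daily = np.zeros((n_days + 1, 2))
    F, FFM = F0, FFM0
    lam = pv[_LAM0]
    for day in range(n_days):
        daily[day, 0] = F
        daily[day, 1] = FFM
        q = intake_kj_day[day] / 1440.0
        for _ in range(spd):
            # RK4 on (F, FFM)
            Fa, Ma = F, FFM
            k1F, k1M = _body_rhs(Fa, Ma, q, lam, pv)
            k2F, k2M = _body_rhs(Fa + 0.5 * dt * k1F, Ma + 0.5 * dt * k1M, q, lam, pv)
            k3F, k3M = _body_rhs(Fa + 0.5 * dt * k2F, Ma + 0.5 * dt * k2M, q, lam, pv)
            k4F, k4M = _body_rhs(Fa + dt * k3F, Ma + dt * k3M, q, lam, pv)
            F = Fa + (dt / 6.0) * (k1F + 2 * k2F + 2 * k3F + k4F)
            FFM = Ma + (dt / 6.0) * (k1M + 2 * k2M + 2 * k3M + k4M)
            if F < 0.0:
                F = 0.0
            if FFM < 0.0:
                FFM = 0.0
    daily[n_days, 0] = F
    daily[n_days, 1] = FFM
    return daily


@njit(cache=True)
def _body_rhs(F, FFM, q, lam, pv):
    ee = lam * (pv[_RHO_F] * F + pv[_RHO_FFM] * FFM + pv[_PK])
    E = q - ee
    s = pv[_PB] + pv[_PA] * np.exp(-pv[_PD] * F)
    p_ffm = s / (1.0 + s)
    return (1.0 - p_ffm) * E / pv[_RHO_F], p_ffm * E / pv[_RHO_FFM]
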