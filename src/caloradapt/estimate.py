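"""Three-step parameter estimation, AIC model comparison and ABC.

Step 1 fits the body-composition subsystem alone, driven per rat by the
measured daily intake, to each ad-libitum animal's weekly weights and
terminal fat mass; it estimates the expenditure/partition constants and
the baseline rate of energy expenditure, then averages the per-rat
estimates.  Step 2 fits the hunger coefficients on the same ad-libitum
animals with the full system (constant expenditure rate, unlimited
food).  Step 3 fits the memory constants (gain and the two trailing
windows) on the weekly-varying hypocaloric group with the whole system.

All fits minimize the residual sum of squares of weekly body weight and
terminal fat mass with Nelder-Mead on log-transformed parameters (which
enforces positivity); the window ordering tau1 < tau2 is enforced by
optimizing (log tau1, log(tau2 - tau1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _kernel
from .cohort import RatRecord
from .params import ModelParameters
from .schedules import FeedingSchedule, build_AL, with_lead_in
from .simulate import equilibrium_state, simulate

__all__ = ["FitResult", "ABCResult", "rss", "aic", "fit_step1", "fit_step2",
           "fit_step3", "fit_lambda_const", "compare_aic", "abc_sample"]

#: Sentinel AIC for a perfect fit (rss == 0).
AIC_PERFECT = -math.inf

STEP1_FIELDS = ("maintenance_offset", "partition_juvenile_amp",
                "partition_baseline", "partition_fat_decay", "lambda0")
STEP2_FIELDS = ("hunger_ghrelin_coeff", "hunger_leptin_coeff",
                "hunger_glucose_scale", "hunger_relax")
STEP3_FIELDS = ("mem_gain", "tau1", "tau2")


@dataclass
class FitResult:
    step: str
    params: dict[str, float]
    rss: float
    n_points: int
    n_params: int
    aic: float
    n_iter: int
    converged: bool
    restart_rss: list[float] = field(default_factory=list)
    per_rat: list[dict[str, float]] = field(default_factory=list)

    def apply(self, base: ModelParameters) -> ModelParameters:
        """Return ``base`` with the fitted values substituted."""
        return base.with_(**self.params)


@dataclass
class ABCResult:
    names: tuple[str, ...]
    draws: np.ndarray          #: accepted draws, (n_accepted, n_params)
    rss_values: np.ndarray     #: RSS of accepted draws
    threshold: float
    rss_min: float
    n_proposed: int

    @property
    def mean(self) -> dict[str, float]:
        return dict(zip(self.names, self.draws.mean(axis=0)))

    @property
    def sd(self) -> dict[str, float]:
        return dict(zip(self.names, self.draws.std(axis=0, ddof=1)))


def aic(rss_value: float, n_points: int, n_params: int) -> float:
    """Least-squares Akaike information criterion, n*ln(RSS/n) + 2k."""
    if n_params < 0 or n_points <= n_params:
        raise ValueError("need n_points > n_params >= 0")
    if rss_value < 0:
        raise ValueError("RSS must be >= 0")
    if rss_value == 0.0:
        return AIC_PERFECT
    return n_points * math.log(rss_value / n_points) + 2.0 * n_params


def rss(observed: list[RatRecord], simulated_bw: list[np.ndarray],
        simulated_fat: list[float] | None = None,
        weight: float = 1.0) -> float:
    """Residual sum of squares over rats and time points (g^2 scale).

    ``simulated_bw[i]`` must align with ``observed[i].weigh_days``; the
    terminal fat-mass residual is included for each record carrying one
    when ``simulated_fat`` is given.
    """
    if len(observed) != len(simulated_bw):
        raise ValueError("one simulated series per record required")
    total = 0.0
    for i, rec in enumerate(observed):
        sim = np.asarray(simulated_bw[i], dtype=float)
        if sim.shape != rec.weekly_bw.shape:
            raise ValueError(
                f"rat {rec.rat_id}: simulated series has {sim.shape} points, "
                f"observed has {rec.weekly_bw.shape}")
        total += float(np.sum((rec.weekly_bw - sim) ** 2))
        if simulated_fat is not None and rec.terminal_fat_g is not None:
            total += weight * (rec.terminal_fat_g - simulated_fat[i]) ** 2
    return total


def _safe_aic(rss_value: float, n_points: int, n_params: int) -> float:
    """AIC, or nan when the data cannot support the parameter count."""
    if n_points <= n_params:
        return math.nan
    return aic(max(rss_value, 1e-300), n_points, n_params)


def _count_points(records: list[RatRecord], use_fat: bool = True) -> int:
    n = sum(len(r.weekly_bw) for r in records)
    if use_fat:
        n += sum(1 for r in records if r.terminal_fat_g is not None)
    return n


def _nelder_mead(objective, x0: np.ndarray, n_restarts: int, jitter_sd: float,
                 seed: int, maxiter: int) -> tuple[np.ndarray, float, int, bool, list[float]]:
    """Nelder-Mead with jittered restarts; returns the best solution and
    the running-best RSS after each restart."""
    rng = np.random.default_rng(seed)
    best_x, best_f, n_iter, ok = None, math.inf, 0, False
    trace: list[float] = []
    for r in range(n_restarts):
        start = x0 if r == 0 else x0 + rng.normal(0.0, jitter_sd, size=x0.shape)
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-8,
                                "fatol": 1e-10, "adaptive": True})
        n_iter += res.nit
        if res.fun < best_f:
            best_x, best_f, ok = res.x, res.fun, bool(res.success) or ok
        else:
            ok = ok or bool(res.success)
        trace.append(best_f)
    return best_x, best_f, n_iter, ok, trace


def _rat_init(rec: RatRecord, p: ModelParameters):
    f0 = rec.initial_fat_g
    state, _ = equilibrium_state(f0, rec.initial_bw - f0, p)
    return state


# --------------------------------------------------------------------------
# step 1: body-composition subsystem driven by measured intake
# --------------------------------------------------------------------------

def _predict_body_only(pv: np.ndarray, rec: RatRecord, dt: float):
    daily = _kernel.run_body_only(pv, rec.daily_consumed_kj, dt,
                                  rec.initial_fat_g,
                                  rec.initial_bw - rec.initial_fat_g)
    bw = daily[:, 0] + daily[:, 1]
    return bw[rec.weigh_days], daily[-1, 0]


def fit_step1(al_records: list[RatRecord],
              base: ModelParameters,
              init_guess: ModelParameters | None = None,
              dt: float = 10.0, n_restarts: int = 3,
              jitter_sd: float = 0.1, seed: int = 0,
              maxiter: int = 2000) -> FitResult:
    """Estimate the expenditure/partition constants and lambda0 per
    ad-libitum rat, then aggregate by averaging the per-rat estimates."""
    if not al_records:
        raise ValueError("step 1 needs at least one ad-libitum record")
    init = init_guess or base
    x0 = np.log([getattr(init, f) for f in STEP1_FIELDS])
    per_rat, trace_all = [], []
    tot_iter, all_ok = 0, True
    for rec in al_records:
        if len(rec.daily_consumed_g) == 0:
            raise ValueError(f"rat {rec.rat_id} lacks measured intake")
        pv = _kernel.pack_params(base)

        def obj(x, rec=rec, pv=pv):
            pv = pv.copy()
            pv[9:14] = np.exp(x)
            bw, fat = _predict_body_only(pv, rec, dt)
            return rss([rec], [bw], [fat])

        x, f, nit, ok, trace = _nelder_mead(obj, x0, n_restarts, jitter_sd,
                                            seed, maxiter)
        per_rat.append({**dict(zip(STEP1_FIELDS, np.exp(x))), "rss": f})
        trace_all.append(trace)
        tot_iter += nit
        all_ok = all_ok and ok
    agg = {f: float(np.mean([r[f] for r in per_rat])) for f in STEP1_FIELDS}
    # population RSS at the aggregated parameter set
    pv = _kernel.pack_params(base)
    pv[9:14] = [agg[f] for f in STEP1_FIELDS]
    preds = [_predict_body_only(pv, rec, dt) for rec in al_records]
    total_rss = rss(al_records, [b for b, _ in preds], [f for _, f in preds])
    n = _count_points(al_records)
    return FitResult(step="step1", params=agg, rss=total_rss, n_points=n,
                     n_params=len(STEP1_FIELDS),
                     aic=_safe_aic(total_rss, n, len(STEP1_FIELDS)),
                     n_iter=tot_iter, converged=all_ok,
                     restart_rss=[min(t) for t in trace_all],
                     per_rat=per_rat)


# --------------------------------------------------------------------------
# steps 2-3: full-system cohort objectives
# --------------------------------------------------------------------------

def _predict_full(p: ModelParameters, rec: RatRecord,
                  schedule: FeedingSchedule, dt: float, memory_on: bool):
    tr = simulate(p, schedule, init=_rat_init(rec, p), dt=dt,
                  memory_on=memory_on)
    bw = tr.daily_bw[rec.weigh_days]
    return bw, tr.final_state.F


def _cohort_rss(p: ModelParameters, records: list[RatRecord],
                schedule: FeedingSchedule, dt: float, memory_on: bool) -> float:
    preds = [_predict_full(p, rec, schedule, dt, memory_on)
             for rec in records]
    return rss(records, [b for b, _ in preds], [f for _, f in preds])


def fit_step2(al_records: list[RatRecord], after_step1: ModelParameters,
              init_guess: ModelParameters | None = None,
              duration: int | None = None, dt: float = 1.0,
              n_restarts: int = 2, jitter_sd: float = 0.1, seed: int = 0,
              maxiter: int = 400) -> FitResult:
    """Estimate the four hunger coefficients on ad-libitum data with the
    full system minus the memory equation (constant expenditure rate)."""
    if not al_records:
        raise ValueError("step 2 needs at least one ad-libitum record")
    n_days = duration or len(al_records[0].daily_consumed_g)
    lead = al_records[0].lead_in_days
    sched = with_lead_in(build_AL(n_days - lead), lead) if lead else build_AL(n_days)
    init = init_guess or after_step1
    x0 = np.log([getattr(init, f) for f in STEP2_FIELDS])

    def obj(x):
        p = after_step1.with_(**dict(zip(STEP2_FIELDS, np.exp(x))))
        return _cohort_rss(p, al_records, sched, dt, memory_on=False)

    x, f, nit, ok, trace = _nelder_mead(obj, x0, n_restarts, jitter_sd,
                                        seed, maxiter)
    n = _count_points(al_records)
    return FitResult(step="step2", params=dict(zip(STEP2_FIELDS, np.exp(x))),
                     rss=f, n_points=n, n_params=len(STEP2_FIELDS),
                     aic=_safe_aic(f, n, len(STEP2_FIELDS)),
                     n_iter=nit, converged=ok, restart_rss=trace)


#: tau2 values (days) scanned before the continuous step-3 search.
TAU2_GRID = (3.0, 5.0, 8.0, 11.0, 14.0)


def fit_step3(h1_records: list[RatRecord], schedule: FeedingSchedule,
              after_step2: ModelParameters,
              init_guess: tuple[float, float, float] | None = None,
              dt: float = 1.0, n_restarts: int = 1, jitter_sd: float = 0.15,
              seed: int = 0, maxiter: int = 200) -> FitResult:
    """Estimate the memory constants (k, tau1, tau2) on the
    weekly-varying hypocaloric group with the whole system.

    A coarse grid over the long window precedes the continuous
    Nelder-Mead search; tau1 < tau2 is enforced through the
    (log tau1, log(tau2 - tau1)) parameterization.
    """
    if not h1_records:
        raise ValueError("step 3 needs hypocaloric records")
    if schedule.lead_in_days != h1_records[0].lead_in_days:
        schedule = with_lead_in(schedule, h1_records[0].lead_in_days
                                - schedule.lead_in_days)

    def cohort_rss_kt(k, t1, t2):
        p = after_step2.with_(mem_gain=k, tau1=t1, tau2=t2)
        return _cohort_rss(p, h1_records, schedule, dt, memory_on=True)

    if init_guess is None:
        k0, t10 = 5.0e-4, 1.0
        best_t2, best_f = None, math.inf
        for t2 in TAU2_GRID:
            f = cohort_rss_kt(k0, min(t10, t2 / 3.0), t2)
            if f < best_f:
                best_t2, best_f = t2, f
        init_guess = (k0, min(t10, best_t2 / 3.0), best_t2)
    k0, t10, t20 = init_guess
    if not t10 < t20:
        t10, t20 = min(t10, t20) / 2.0, max(t10, t20)
    x0 = np.log([k0, t10, t20 - t10])

    def obj(x):
        k, t1, gap = np.exp(x)
        if t1 + gap > 60.0:   # cap the long window at 60 days
            return 1e12
        return cohort_rss_kt(k, t1, t1 + gap)

    x, f, nit, ok, trace = _nelder_mead(obj, x0, n_restarts, jitter_sd,
                                        seed, maxiter)
    k, t1, gap = np.exp(x)
    n = _count_points(h1_records)
    return FitResult(step="step3",
                     params={"mem_gain": k, "tau1": t1, "tau2": t1 + gap},
                     rss=f, n_points=n, n_params=3,
                     aic=_safe_aic(f, n, 3),
                     n_iter=nit, converged=ok, restart_rss=trace)


def fit_lambda_const(records: list[RatRecord], schedule: FeedingSchedule,
                     params: ModelParameters, dt: float = 1.0,
                     n_restarts: int = 2, jitter_sd: float = 0.1,
                     seed: int = 0, maxiter: int = 120) -> FitResult:
    """Fit the constant-expenditure-rate model variant (no memory): a
    single rate replaces the whole adaptation equation."""
    if schedule.lead_in_days != records[0].lead_in_days:
        schedule = with_lead_in(schedule, records[0].lead_in_days
                                - schedule.lead_in_days)
    x0 = np.array([math.log(params.lambda0)])

    def obj(x):
        p = params.with_(lambda0=float(np.exp(x[0])))
        return _cohort_rss(p, records, schedule, dt, memory_on=False)

    x, f, nit, ok, trace = _nelder_mead(obj, x0, n_restarts, jitter_sd,
                                        seed, maxiter)
    n = _count_points(records)
    return FitResult(step="no_memory",
                     params={"lambda0": float(np.exp(x[0]))},
                     rss=f, n_points=n, n_params=1,
                     aic=_safe_aic(f, n, 1),
                     n_iter=nit, converged=ok, restart_rss=trace)


def compare_aic(records: list[RatRecord], schedule: FeedingSchedule,
                params: ModelParameters, dt: float = 1.0,
                seed: int = 0) -> dict[str, FitResult]:
    """Fit the memory and constant-rate variants on one cohort and
    return both results (AIC computed on identical data points)."""
    mem = fit_step3(records, schedule, params, dt=dt, seed=seed)
    nomem = fit_lambda_const(records, schedule, params, dt=dt, seed=seed)
    return {"memory": mem, "no_memory": nomem}


def abc_sample(records: list[RatRecord], schedule: FeedingSchedule,
               after_step2: ModelParameters,
               point_estimate: dict[str, float], rss_min: float,
               prior_halfwidth: float = 0.5, n_draws: int = 200,
               threshold_factor: float = 1.3, dt: float = 1.0,
               seed: int = 0) -> ABCResult:
    """Rejection ABC around the step-3 point estimate.

    Draws (k, tau1, tau2) uniformly within ``prior_halfwidth`` relative
    bounds of the point estimate (draws violating tau1 < tau2 are
    rejected upfront) and accepts runs whose RSS falls below
    ``threshold_factor`` times the optimized minimum.
    """
    if threshold_factor < 1.0:
        raise ValueError("threshold factor must be >= 1")
    if schedule.lead_in_days != records[0].lead_in_days:
        schedule = with_lead_in(schedule, records[0].lead_in_days
                                - schedule.lead_in_days)
    names = tuple(STEP3_FIELDS)
    center = np.array([point_estimate[n] for n in names])
    lo, hi = center * (1.0 - prior_halfwidth), center * (1.0 + prior_halfwidth)
    rng = np.random.default_rng(seed)
    accepted, rss_vals = [], []
    threshold = threshold_factor * rss_min
    for _ in range(n_draws):
        draw = rng.uniform(lo, hi)
        if not 0.0 < draw[1] < draw[2]:
            continue
        p = after_step2.with_(mem_gain=draw[0], tau1=draw[1], tau2=draw[2])
        f = _cohort_rss(p, records, schedule, dt, memory_on=True)
        if f < threshold:
            accepted.append(draw)
            rss_vals.append(f)
    if not accepted:
        raise RuntimeError("no accepted ABC draws; widen the prior or "
                           "raise the threshold factor")
    return ABCResult(names=names, draws=np.array(accepted),
                     rss_values=np.array(rss_vals), threshold=threshold,
                     rss_min=rss_min, n_proposed=n_draws)
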