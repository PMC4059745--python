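# Methods

## The model

`caloradapt` simulates body weight and food intake of a single rat under
a feeding protocol, at one-minute resolution, with eight coupled state
variables:

| symbol | meaning | unit |
|---|---|---|
| F | fat mass | g |
| FFM | fat-free mass | g |
| F_avail | food energy available in the cage | kJ |
| H | hunger — food energy the animal would consume absent constraint | kJ |
| L | plasma leptin | ng |
| G | plasma glucose | g |
| Ghr | plasma ghrelin | pg/mL |
| λ | rate of energy expenditure | /min |

**Intake.** The consumption flux is the min rule
`q = min( min(H, F_avail)/T_e , 1/θ )` kJ/min, with `T_e = 1.7 min` the
demand-conversion time and `θ = 1.52 min/kJ` the measured time to ingest
one kJ of chow (1/θ ≈ 0.66 kJ/min ≈ 3 g/h). Consumption vanishes when
either hunger or availability is zero and depends on the two only
through their minimum. `T_e` was calibrated once so that the ad-libitum
fixed point of the hunger subsystem is ~25 g chow/day for a 400 g rat,
matching the study design's ad-libitum ration.

**Energy balance and body composition.** The balance `E = q − EE`
drives the two body compartments with an exact energy partition:

    dF/dt   = (1 − p(F)) E / ρ_F        ρ_F  = 39.3 kJ/g
    dFFM/dt =      p(F)  E / ρ_FFM      ρ_FFM = 7.5 kJ/g

so `ρ_F·dF/dt + ρ_FFM·dFFM/dt = E` holds identically. The fat-free
share is a Forbes-type companionship rule, `p(F) = s/(1+s)` with
`s = b + a·exp(−dF)` (`a = 2.2`, `b = 0.16`, `d = 0.269 /g`): lean
juveniles route most of a surplus (or deficit) to the fat-free
compartment; fat adults mostly to fat.

**Expenditure.** `EE = λ·(ρ_F F + ρ_FFM FFM + K)` kJ/min with
`K = 1964.4 kJ` a mass-independent maintenance offset (organ and neural
upkeep that does not scale with the energy stores). At the baseline
rate `λ0 = 2.525×10⁻⁵ /min` this gives ~236 kJ/day for a 400 g rat with
12% body fat — rat-scale expenditure. Without the offset the same λ0
would spend only ~165 kJ/day and every feeding group would gain weight
without bound; the affine reading is the only one consistent with both
the printed rate constant and rat physiology.

**Hormones.** Linear production–clearance kinetics throughout:

    dL/dt   = 0.126·F − 0.074·L            (leptin tracks adiposity)
    dG/dt   = 0.039·q − 0.007·G            (glucose tracks intake)
    dGhr/dt = 0.4025·(1 − θq) − 0.007·Ghr  (ghrelin inhibited by eating)

`θq ∈ [0,1]` because q is capped at 1/θ, so ghrelin production runs at
full rate while fasting and shuts off while the animal eats at full
speed. The fasted ghrelin steady state (57.5 pg/mL) and the fed
ad-libitum value (~37 pg/mL) bracket plasma levels reported for rats.

**Hunger.**

    dH/dt = h_Ghr·Ghr·exp(−h_L·L)·exp(−G/h_G) − h_R·M_ref·H

with `h_Ghr = 4.02×10⁻³ mL·kJ/min/pg`, `h_L = 1.66×10⁻³ /ng`,
`h_G = 5.03 g`, `h_R = 5.99×10⁻⁴ /min/g` and `M_ref = 400 g` a fixed
reference mass. Ghrelin drives hunger; leptin (slow, adiposity) and
glucose (fast, nutrient) inhibit it multiplicatively, which keeps H
non-negative by construction (a clamp remains as a numerical safety
net). The reference mass, rather than live body weight, scales the
relaxation so that ad-libitum demand stays stationary as the animal
grows; with live weight, demand — and through the memory equation the
expenditure rate — drifts under ad libitum, contradicting the premise
that unrestricted feeding is the model's equilibrium regime.

**Memory-adapted expenditure.** λ adapts to the difference between the
trailing mean intake over a short window τ₁ = 1 day and a long window
τ₂ = 8 days (overlapping windows):

    dλ/dt = k · λ · ( m_τ₁ − m_τ₂ ),   k = 9.05×10⁻⁴ /kJ

with the means in kJ/min. The multiplicative form is the only one
dimensionally consistent with k in /kJ, and it keeps λ > 0. λ is at a
fixed point whenever intake has been constant for τ₂; a restriction
step lowers λ (log-shift ≈ k·Δm·(τ₂−τ₁)/2, Δm the intake step per
minute), refeeding raises it, and the ~8-day lag between intake and
expenditure is what lets a restriction-then-refeeding pattern gain
weight on less food. `memory_on=False` (or k = 0) freezes λ = λ0 — the
constant-rate model variant.

Several printed constants carry unreadable exponents in the available
parameter table; their mantissas were kept and the exponents fixed once
by a physiological calibration (ad-libitum intake ≈ 25 g/day, the
constant 20 g ration fully consumed, rat-scale expenditure), before any
test was written, and not revisited.

## Feeding protocols

Four schedules emulate the study design, each preceded by a 5-day
ad-libitum lead-in: AL (unlimited, nominal 25 g/day), H0 (constant
20 g/day), H1 (weekly re-drawn rations around 20 g/day, lognormal CV
0.2, constant within each week), H4 (restriction at 55% of the
ad-libitum ration — 13.75 g/day — for 4 weeks, then the constant
complement, 26.25 g/day). All hypocaloric builders conserve the 56-day
total of 1120 g exactly in integer-milligram arithmetic. The H4
restriction fraction is a free design choice below the documented 60%
bound; 0.55 was chosen because it reproduces the headline directions
(heavier on less food) — a much deeper restriction digs a nadir the
4-week refeed cannot recover within the experiment.

Rations enter availability as a single deposition at the start of each
simulated day, and uneaten food is removed at the next deposition
(daily cage servicing); availability therefore never accumulates across
days.

## Integration

A fixed-step explicit scheme at dt = 1 min: classical RK4 on the smooth
part of the field, with the intake flux frozen within each step, capped
so the amount eaten never exceeds availability, and the available-food
pool updated exactly. The fastest clearance (leptin, 0.074/min,
half-life ~9 min) is well resolved at this step; the min-rule
nonsmoothness and the daily deposition events are what rule out
adaptive stiff solvers. Halving the step to 0.25 min moves the 8-week
body-weight endpoint by well under 0.1 g. The distributed memory is a
ring buffer of per-step consumed energy with O(1) running sums for both
windows; before the simulation start the buffer is filled with the
ad-libitum equilibrium intake (the lead-in's pre-history, extended
backward as a constant). Window lengths are rounded to whole steps, so
the estimation objective is piecewise constant in τ at the 1/1440-day
scale — irrelevant at the day-scale tolerances of interest. Hormones
and hunger are initialized at their ad-libitum fixed point; fat mass
from initial biometrics through the rWAT regression, fat-free mass as
the remainder. A compiled (numba) kernel performs the stepping; a
pure-Python reference step is kept in `simulate.step` and cross-checked
against the kernel in the tests.

## Synthetic cohorts

`cohort.generate_cohort` emulates the study's measurement structure:
6 rats per group, initial body weight N(400 g, 15 g) (12-week Wistar
scale) with 12% initial body fat, weekly morning weighings 3 days into
each schedule week, daily consumed food from leftover weighing, and a
terminal fat mass reported through a linear rWAT (retroperitoneal
white adipose tissue) proxy. The rWAT regression
(`fat = 5.5·rWAT + 7.5 g`) is a synthetic stand-in of realistic
magnitude applied with its exact inverse, so estimation round trips do
not depend on its coefficients. Measurement noise defaults — weight sd
5 g, intake sd 0.5 g, rWAT sd 0.2 g — and the lognormal
inter-individual CV (5% on the expenditure rate and hunger
coefficients) are harness constants, chosen as plausible magnitudes,
not literature values.

Ad-libitum cohorts are generated with the memory equation off: under
unrestricted feeding the adaptation has nothing to adapt to, and the
estimation steps that use ad-libitum data (below) assume a constant
expenditure rate. Restricted cohorts (H0/H1/H4) are generated with the
full model.

What the generator does **not** emulate: within-day meal structure and
circadian feeding, hormone assay noise, growth-curve age effects,
leptin/insulin resistance, and any inter-individual variability in the
partition constants. Passing round-trip tests therefore show that the
pipeline is self-consistent under the study's design and noise scale —
not that the model is identifiable from arbitrary real data.

## Estimation pipeline

All fits minimize the residual sum of squares (RSS) of weekly body
weight plus terminal fat mass (unweighted sum, g² scale) with
Nelder-Mead on log-transformed parameters (positivity by construction).

* **Step 1** uses the body-composition subsystem alone, driven per rat
  by the measured daily intake (spread uniformly within each day), on
  ad-libitum animals: per-rat estimates of (K, a, b, d, λ0), averaged
  across rats. Three restarts (one from the initial guess, two
  jittered), best RSS kept.
* **Step 2** uses the full system minus the memory equation (λ = λ0,
  unlimited food, consumption hunger-driven) on the same animals to
  estimate the four hunger coefficients. Two restarts.
* **Step 3** uses the whole system on the weekly-varying hypocaloric
  group to estimate (k, τ₁, τ₂): a coarse grid over τ₂ ∈ {3, 5, 8, 11,
  14} days seeds a continuous Nelder-Mead search in
  (log k, log τ₁, log(τ₂−τ₁)) — the gap parameterization enforces
  τ₁ < τ₂ identically. Windows are reported rounded to whole days.

The restart counts are deliberately small: the objectives are smooth at
the relevant scale and the τ₂ grid pre-scan covers the one genuine
multimodality risk, and each full-system cohort evaluation costs a
6-rat × 61-day simulation.

**Model comparison.** The memory and constant-rate variants are
compared by the least-squares AIC, `n·ln(RSS/n) + 2k_params`, with
k = 3 for the memory variant (k, τ₁, τ₂) and k = 1 for the constant
rate (its λ is refit). RSS = 0 maps to −∞ as a documented sentinel.

**ABC.** Rejection sampling around the step-3 optimum: uniform priors
within ±50% of the point estimate (draws violating τ₁ < τ₂ discarded),
acceptance when RSS < 1.3 × the optimized minimum; accepted draws are
summarized by mean and standard deviation per parameter.

## Numerical choices and degenerate inputs

* Non-negativity clamps after each step; body weight must stay
  positive or the run aborts with the failure time.
* A non-finite state aborts the simulation with a diagnostic
  (`RuntimeError` naming the minute).
* `tau1` is floored at one step; window rounding collapses are
  rejected.
* Schedules must divide into whole weeks (H0/H1) or two equal
  whole-week halves (H4); milligram rounding residues are folded into
  the final day.
* The step-3 long window is capped at 60 days inside the optimizer.

## Known limitations

* The hunger subsystem's demand declines mildly with adiposity; over
  very long ad-libitum runs (≫ 16 weeks) intake and λ drift a few
  percent rather than being exactly stationary.
* τ estimates inherit a ±1 day scale of variability from weighing noise
  at the study's design (6 rats, 8 weekly points each); the pipeline
  reports day-rounded windows for that reason.
* The partition constants (a, d) are weakly identified by weekly
  weights plus one terminal fat mass; step 1 recovers them cleanly only
  because the fit starts from the reference values (noiseless data make
  the truth the global optimum, but the valley is flat).
* No circadian structure within the day beyond the single deposition
  event; no stomach compartment — ghrelin inhibition uses the consumed
  flux as the stomach-content proxy.
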