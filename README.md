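# caloradapt

Energy-balance dynamics of body weight and food intake in rats under
time-varying caloric restriction, with a memory-adapted rate of energy
expenditure.

## The problem

Restrict a rat's food to 80% of ad libitum and its weight depends not
only on *how much* it eats but on *when*: a month of severe restriction
followed by a month of plenty leaves the animal heavier than a constant
ration of the same total, even though it eats less overall. The
mechanism is adaptive thermogenesis with a lag — expenditure tracks a
memory of recent intake, so during refeeding the animal briefly eats a
lot while still spending little.

`caloradapt` implements a minute-resolution model of this system for
researchers in energy-balance physiology and anyone fitting
intake/weight time series from feeding experiments. Eight coupled
states — fat mass F, fat-free mass FFM, available food, hunger H,
leptin L, glucose G, ghrelin Ghr and the expenditure rate λ — evolve
under

* intake `q = min(H, F_avail)` per unit time, capped at the measured
  ingestion speed `1/θ`;
* body composition `ρ_F dF/dt = (1−p(F))·E`, `ρ_FFM dFFM/dt = p(F)·E`
  with energy balance `E = q − λ·(ρ_F F + ρ_FFM FFM + K)` and a
  Forbes-type partition p(F);
* linear production–clearance kinetics for leptin (from fat), glucose
  (from intake) and ghrelin (inhibited while eating), driving hunger;
* the memory equation `dλ/dt = k·λ·(m_τ₁ − m_τ₂)` comparing mean intake
  over the last τ₁ = 1 day against the last τ₂ = 8 days.

On top of the simulator sit the study's feeding protocols (AL, constant
H0, weekly-randomized H1, restriction-refeed H4 — each hypocaloric
variant conserving 1120 g over 8 weeks exactly), a synthetic-cohort
generator with the experiment's measurement structure, the three-step
Nelder-Mead estimation pipeline, AIC comparison of the memory vs.
constant-rate variants, and rejection-ABC posteriors for the memory
constants. See `docs/methods.md` for the full model statement.

## Worked example

```python
from caloradapt import (DEFAULT_PARAMS, build_H0, build_H4, build_H1,
                        with_lead_in, simulate, observe_daily_intake,
                        CohortSpec, generate_cohort, fit_step3)

p = DEFAULT_PARAMS

# the headline effect: same food budget, different temporal pattern
for name, sched in (("H0", build_H0(56)), ("H4", build_H4(56))):
    tr = simulate(p, with_lead_in(sched, 5))
    _, grams = observe_daily_intake(tr)
    print(name, round(tr.daily_bw[-1], 1), "g final,",
          round(grams[5:].sum()), "g eaten")
# H0 491.1 g final, 1120 g eaten
# H4 495.0 g final, 1107 g eaten

# recover the memory windows from a synthetic cohort
sched = build_H1(56, seed=1)
spec = CohortSpec(n_per_group=6, param_cv=0.0, weight_noise_sd=5.0,
                  intake_noise_sd=0.0, rwat_noise_sd=0.0, seed=1)
records = generate_cohort(spec, {"H1": sched}, p, memory_on=True)
fit = fit_step3(records, sched, p, seed=1)
print(fit.params)
# {'mem_gain': 0.000908, 'tau1': 0.9992, 'tau2': 7.9588}
```

The restriction-refeed group ends 3.9 g heavier than the constant
group while eating 13 g less — the weight difference runs opposite to
the intake difference. The step-3 fit, given six animals with 5 g
weighing noise, returns the generating memory gain (9.05e-4 /kJ) and
both windows (1 and 8 days) to within a few percent.

A thin CLI wraps the same functions
(`caloradapt simulate|synth|fit|abc|scenarios`, each writing CSVs plus
a re-run manifest); `caloradapt simulate --schedule H4 --out runs/h4`
reproduces the first half of the example from a shell.

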