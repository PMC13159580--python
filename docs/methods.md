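# Methods

## Model

`pretermcast` couples three deterministic components.

**Cohort-component population projection.** The female population is held
as single-year age counts N(a, t), a = 0..A_max (default A_max = 100,
with the top class an open interval "100 and older"). One annual step is

    N(a+1, t+1) = N(a, t) · s(a) + M(a+1, t+1),      0 ≤ a < A_max
    N(A_max, t+1) += N(A_max, t) · s(A_max)
    N(0, t+1)   = newborn girls + M(0, t+1)

where s(a) is the probability of surviving from age a to a+1 (treated as
time-invariant) and M(a, t) is net migration, indexed here at the arrival
age and arrival year. Counts that would turn negative after net
out-migration are floored at zero with a logged warning — person counts
cannot be negative, and the floor is the only non-linearity in the
update. Counts are carried as real numbers; rounding to whole persons
happens only at reporting boundaries (CSV output, recorded vital
series). Women of reproductive age are W(t) = Σ_{a=15}^{49} N(a, t).

**Fertility and preterm indicators.** From annual counts of live births
B(t) and preterm births PTB(t):

    GFR(t) = B(t) / W(t) × 1000        (general fertility rate)
    p(t)   = PTB(t) / B(t)             (preterm-birth proportion)

plus year-over-year percent change of any count series. Display values
are rounded half-away-from-zero to two decimals; this convention matches
16 of 22 derivable cells in the packaged national table exactly, and the
six remaining cells differ by exactly 0.01 in a pattern consistent with
truncation at the source rather than a different rounding rule (see
"Packaged data" below).

**Scenario projection.** A scenario fixes a GFR target (per 1,000) and a
preterm-share target (%) at a horizon year (default 2050). Each
assumption is expanded into a year-by-year path; the default
`linear_to_target` rule interpolates linearly from the last observed
value at the start year to the target at the horizon, endpoints
inclusive, so the horizon value hits the target exactly. (A `constant`
rule is offered: start value in the first year, target thereafter.) The
engine then iterates annually: W(t) is read from the current pyramid
*before* it is advanced — year-t births use year-t women — then

    B(t) = GFR(t) · W(t) / 1000,       PTB(t) = B(t) · p(t),

and the pyramid is advanced with the female share of B(t) entering age 0
in year t+1. The named scenarios pair assumptions as optimistic
(GFR → 90, p → 5.8%), baseline (80, 6.3%) and pessimistic (75, 7.2%);
`custom` specs may decouple them.

**Newborn feedback.** Girls born after the baseline year reach age 15
before a mid-century horizon, so projected births are fed back into the
pyramid by default, using a sex ratio at birth of 105.5 boys per 100
girls (female fraction 100/205.5 ≈ 0.4866). Feedback is configurable and
can be disabled for analyses of the standing population only.

**Back-testing.** `backtest` calibrates on an early window and scores a
later, disjoint holdout with MAE and RMSE (case units; RMSE ≥ MAE by
the quadratic-mean inequality, with equality iff all errors are equal).
The default predictor carries the calibration-mean preterm proportion
forward, applied to observed holdout live births ("proportion-only"
mode) or to births projected via the calibration-mean GFR and the
cohort engine when demographic inputs are supplied. The rule is
pluggable because published validation tables do not always state the
rule that produced their predicted column; such tables can be scored
directly from their observed/predicted pairs.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| A_max | 100 | years | standard open-interval top age |
| reproductive ages | 15–49 inclusive | years | definition of W(t) |
| female fraction at birth | 100/205.5 | proportion | sex ratio at birth 105.5:100 |
| path rule | linear_to_target | — | published outlooks state endpoints only; a straight line is the most transparent interpolant |
| horizon | 2050 | year | mid-century planning horizon |
| rounding | half-away-from-zero, 2 dp | — | matches the national table convention |

## Synthetic data generator

National single-year pyramids, survival columns and migration schedules
are not published alongside the vital series this package analyses, so
tests run on synthetic bundles generated by the same engine run
generatively. Defaults emulate the study conditions: an 11-year history
(2013–2023), a 9-million-woman pyramid whose 15–49 segment holds ~4.5
million, GFR declining linearly 95 → 85 per 1,000 (inside the observed
82–95 range), preterm share rising 5.4 → 6.8% (inside 5.3–6.9%),
survival in [0.99, 0.9999] declining smoothly with age, zero net
migration unless configured, and live-birth volumes of ~350–440
thousand. The pyramid is a Gaussian age profile (mean 36, spread 29 —
chosen so the reproductive-age share matches a mid-transition population
of this size) with a 2% seeded multiplicative wiggle.

Noise on recorded counts is multiplicative lognormal, default **off**:
registry counts are treated as exact, so the noiseless bundle is the
reference mode and estimators must recover the generating trajectories
up to integer rounding (the packaged recovery checks find errors of
order 10⁻⁴ on GFR, far below the 0.01 tolerance). Noise is implemented
as exp(noise_sd · z) with z drawn once per (seed, year), so at fixed
seed the recovery error is exactly monotone in noise_sd — the property
the convergence tests assert. All outputs are deterministic functions
of (config, seed); bundles written twice with the same seed are
byte-identical.

What the generator does **not** emulate: COVID-era shocks or
reporting-artifact structure (the abrupt post-2020 shift visible in the
real series), age-specific fertility, year-varying survival, or
correlated noise across years. Passing tests therefore demonstrate
internal consistency and correct arithmetic of the pipeline, not that
any particular national projection is right.

## Packaged data

Three small CSVs ship with the package: the Kazakhstan 2013–2023 live
and preterm birth counts, the derived indicator columns exactly as
printed at the source, and the published 2019–2023 back-test
observed/predicted pairs. Six printed indicator cells differ from
recomputation by exactly 0.01 (the 2013 and 2020 preterm rates, the 2021
preterm change, both 2022 changes' pattern — the 2022 live-birth and
preterm changes — and the 2023 live-birth change); the package asserts
the recomputed values and keeps the printed ones as metadata. The
published RMSE for the back-test pairs is 4.5; the pairs' own errors (2,
4, 5, 2, 7) give √19.6 ≈ 4.43, which is the value this package reports.
The predicted column itself (errors of 2–7 cases out of ~22–27 thousand)
is not derivable from any stated calibration rule, so it is treated as
data to be scored, not as a reproducible model output.

## Numerical choices and degenerate inputs

- Zero women → explicit division-by-zero error naming the year; zero
  births → preterm proportion undefined (error), never NaN.
- First year of any series has no percent change (empty CSV field).
- Scenario paths must be positive; a start value equal to the target
  yields a constant path under either rule.
- The multi-year projector is definitionally the fold of the single-step
  update; tests assert elementwise bit-equality between the two on
  random inputs rather than approximate agreement.
- Problem sizes: test bundles use the full 101-age pyramid and 11-year
  history; oracle property checks use 6–30 age classes and 5–8 steps,
  which exercise every branch (newborn edge, open top, flooring) at
  negligible cost.

## Known limitations

- Aggregate GFR only; no age-specific fertility or preterm risk, so
  maternal-age composition effects are outside the model.
- No uncertainty intervals: projections are deterministic scenario
  arithmetic, not probabilistic forecasts.
- Survival is time-invariant and migration defaults to a fixed age
  profile; both are configurable inputs, not estimated quantities.
- Actual published national projections for 2024–2050 (e.g. a baseline
  of ~30–33 thousand preterm births annually for Kazakhstan) cannot be
  reproduced without the unpublished national pyramid, survival and
  migration inputs; the scenario machinery is validated by construction
  (exact endpoint proportions, ordering, conservation) on synthetic
  bundles instead.
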