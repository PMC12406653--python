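# Methods

This note documents the models, the synthetic-data generator, the estimation
algorithm and the numerical choices in `tobrapk`, in the order the pipeline
uses them.

## Structural PK model

One-compartment disposition with zero-order (constant-rate) infusion input and
first-order elimination. For a single dose `D` infused over `D1` hours,

    C(t) = R0/CL · (1 − e^{−k t})                      0 ≤ t < D1
    C(t) = R0/CL · (1 − e^{−k D1}) · e^{−k (t − D1)}   t ≥ D1

with `R0 = D/D1` and `k = CL/V`. Repeated dosing superposes this solution over
administered doses; the steady-state profile applies the accumulation factor
`1/(1 − e^{−k τ})` to the within-interval terms (`pk_core.concentration`).
Both forms are exercised against a brute-force ODE integration in the tests.
Exposure at steady state uses the exact identity `AUC24,ss = dose/CL`, which
the test suite confirms numerically (trapezoidal integral of the profile over
one interval agrees to < 0.5 %).

Assumptions: linear (first-order) elimination over the observed concentration
range; no peripheral compartment (a deliberate restriction — tobramycin data
of this design do not support one stably); intravenous administration only.

The infusion duration is carried as a model parameter `D1` with its own
between-subject variability rather than taken from the charted value, because
charted 0.5 h durations in routine care are imprecise. Simulations of
*prospective* dosing use the nominal 0.5 h; simulated estimation datasets use
the fitted typical value (0.801 h) with its variability, and their `DUR`
column still records the nominal 0.5 h, exactly the discrepancy the fitted
parameter exists to absorb. `D1` does not affect AUC either way.

## Covariate model

Typical clearance combines three multiplicative effects on a 70 kg mature
reference (6.17 L/h):

* **Size** — allometric weight scaling `(WT/70)^0.663` on CL and
  `(WT/70)^0.744` on V (15.5 L reference);
* **Maturation** — a Hill function of post-menstrual age,
  `PMA^3.4/(47.7^3.4 + PMA^3.4)`, the published maturation profile of
  glomerular filtration (half-maximal at 47.7 weeks PMA, i.e. ~2 months after
  term birth; > 97 % by age 2);
* **Renal function** — `(eGFR/127.3)^0.4` with the bedside Schwartz estimate
  `eGFR = 41.3·HT(m)/SCr(mg/dL)`. The exponent is fixed at 0.4, not
  re-estimated, and the 127.3 mL/min centering constant equals the source
  cohort's median eGFR; both are plain configuration values
  (`PopulationParameters`) should a future cohort warrant re-centering.

Creatinine conversion uses 88.4 µmol/L per mg/dL. A creatinine value without
an explicit unit tag is an error everywhere in the package — silent unit
guessing is forbidden by design. Gestational age defaults to 40 weeks when
unrecorded; the maturation error from a wrong default is a few percent of GFR
at most beyond infancy. eGFR is used as computed, uncapped.

Age strata for reporting are `[0, 2)`, `[2, 12]`, `(12, …]` years; 12.0
belongs to the middle group (the boundary had to be closed on one side; this
choice is tested).

## Dosing rules

* **Standard arm**: 10 mg/kg once daily, uncapped by default so that the
  simulation arm isolates the flat-dosing policy itself (`cap_standard=True`
  restores clinical caps).
* **Individualized arm**: `dose = target_auc · CL_typical` with
  `target_auc = 95` mg·h/L, capped at `min(850 mg, 16 mg/kg)`, whichever is
  lowest; the binding cap is recorded in the recommendation. Doses are not
  rounded by default (`round_to` rounds to a clinical increment when wanted).
* The **theoretical-best** analysis uses a 93.8 mg·h/L target. The package
  treats 95 and 93.8 as independent configuration values; numerically 93.8 is
  the geometric midpoint of the 80–110 window, which is where a lognormally
  distributed exposure maximizes the attainment probability.

## Probability of target attainment

Per virtual patient: typical CL from covariates; dose per arm; individual
clearance `CL_i = CL_typical · e^{η}`, `η ~ N(0, 0.170²)`;
`AUC = dose/CL_i`; classify against 80–110 mg·h/L. Only the clearance random
effect enters — volume and infusion-duration variability cancel out of
`dose/CL` — and assay (residual) error is excluded because the target refers
to true exposure, not a measured concentration.

For the uncapped individualized and theoretical-best arms the attainment
probability has the closed form

    PTA = Φ(ln(target/80)/ω) − Φ(ln(target/110)/ω)

(≈ 0.651 at target 93.8, ω 0.170; ≈ 0.650 at target 95), which the
Monte-Carlo estimator must reproduce within binomial error — a permanent
cross-check between two routes to the same number. Arms are compared on
common random numbers: per-stratum substreams depend only on (seed, stratum),
so both arms see identical patients and identical ηs. Pooled results weight
strata by their cohort counts (equal, 1,000 each, by default — a design
choice mirroring the equal-allocation simulation layout, not the demographic
age distribution). An empty stratum reports `n=0` with NaN fractions rather
than a fabricated number.

## Synthetic cohort generator

The generator emulates a pediatric CF cohort aged 0.1–19.3 years with
age-appropriate anthropometry and age-related normal serum creatinine —
the role played in the original analysis by a private database of 704
children. Per patient:

* age uniform within its stratum (`[0.1,2)`, `[2,12]`, `(12,19.3]`);
* weight and height from sex-averaged growth-reference medians
  (piecewise-linear in age, vendored as a small table) with lognormal
  inter-child variability, CV 12 % and 4 % respectively, deviates truncated
  at ±3 SD;
* serum creatinine from an age-dependent normal median rising from
  ~20 µmol/L in infancy to ~60 µmol/L in late adolescence, lognormal CV 20 %
  truncated at ±2 SD (the "normal band"). The 20 % CV was chosen to match the
  width of published pediatric creatinine reference intervals, whose 2.5th–
  97.5th centile ratio is roughly 2.2–2.4; it also keeps the implied eGFR
  dispersion comparable to the source cohort's observed 58–265 mL/min range,
  which matters for the detectability of the eGFR covariate in the recovery
  study below;
* gestational age fixed at 40 weeks.

What this generator does **not** emulate: the joint age–weight–creatinine
correlation structure of real CF patients (each margin is sampled around its
age median independently), CF-specific growth faltering, sex differences, or
any disease-progression dynamics. Consequences: quantities that depend only
on the dosing rule's algebra (individualized-arm PTA, reference clearance)
are insensitive to the generator, while standard-arm PTA and dose-per-kg
medians inherit the synthetic covariate distribution and should be read as
approximate reproductions. In particular the under-2 standard-arm PTA runs a
few percentage points above the published figure because uniform infant ages
include more very young, maturation-limited infants than a clinical admission
database would.

TDM datasets are simulated by inverting the estimation model: draw
(η_CL, η_V, η_D1), evaluate the structural model at sampling times drawn
uniformly within the monitoring windows (defaults: 1–2 h and 4–8 h after the
start of the infusion, on dose occasions 1, 3 and 5 — six observations per
child, matching the source data's ~7 per child), apply
`y = f·(1+ε_prop) + ε_add`, and censor strictly below the 0.6 mg/L
quantification limit. A value exactly at the limit is quantifiable. Negative
simulated observations are clipped at zero before censoring. With the default
design ~1–3 % of observations fall below the limit (the source cohort: 6 %).

## BLQ handling (M6)

Within each dose interval, observations are scanned in time order. The first
below-quantification value of each consecutive run is imputed at half the
limit (0.3 mg/L) and retained as an ordinary observation; later values in the
run are discarded. A quantifiable observation terminates the run, so a
subsequent BLQ value starts a new run and is imputed again. (The narrower
reading — at most one imputed value per dose interval regardless of
intervening quantifiable observations — differs only when a BLQ → quantifiable
→ BLQ pattern occurs inside one interval, which the simulated designs
essentially never produce; the run-based reading is implemented and the full
length-3 truth table is pinned in the tests.) The preprocessor never modifies
quantifiable records and never increases the record count.

## Mixed-effects estimation

The per-subject marginal likelihood over the lognormal random effects is
approximated by a Laplace expansion at the conditional mode with Gauss–Newton
curvature — the same conditional-linearization family as FOCE with
interaction (the interaction enters through the prediction-dependent residual
variance `g = σ_add² + σ_prop²·f²`). Writing

    h(η) = Σ_j [(y_j − f_j)²/g_j + ln(2π g_j)] + η'Ω⁻¹η + ln det(2πΩ)

the subject's OFV contribution is
`h(η*) + ln det(J'G⁻¹J + Ω⁻¹) − q·ln 2π`, with `η*` the minimizer, `J` the
Jacobian of the prediction with respect to the active random effects
(computed analytically from the infusion solution), and `q` the number of
active effects. With all ω = 0 this reduces exactly to the weighted
least-squares deviance `Σ[(y−f)²/g + ln g] + n·ln 2π`, a closed form the
tests pin down. Replicating any specific NONMEM OFV value is a non-goal;
recovery of generating parameters is the contract.

**Inner problem.** Damped Newton on `η` (3-dimensional at most), vectorized
across subjects, with per-subject step halving where `h` would increase; the
improvement test is relative to |h| so floating-point round-off cannot stall
the line search. Convergence when the largest per-subject change in `h` falls
below 1e-8.

**Outer problem.** All scale/variance parameters are log-transformed
(positivity by construction); covariate exponents and candidate coefficients
are unconstrained. A soft trust region (±6 on the transformed scale around
the start) keeps line searches off the −∞ plateaus of unidentifiable
log-variances. Minimization is staged: a quasi-gradient stage (L-BFGS-B with
finite differences), then a derivative-free direction-set sweep (Powell)
which steps across the curvature kinks the end-of-infusion branch switch
induces. The objective seen by the optimizers warm-starts the inner Newton
from a *fixed* reference (the converged modes at the stage's start point,
refreshed between stages) so it is a deterministic function of the
parameters — finite-difference gradients and bracketing line searches both
require this. The reported OFV is always re-evaluated from a cold inner start
at every stage endpoint and the starting point, and the best is returned;
this makes OFVs of different fits comparable and guarantees a warm-started
nested fit never ends above its start.

**Defaults.** Free parameters: θ_CL, θ_V, θ_D1, ω_CL, ω_V, ω_D1, σ_add,
σ_prop. The allometric exponents, maturation constants and the 0.4 eGFR
exponent are fixed at their published values (all re-estimable by adding them
to `free`). Initial estimates are literature-plausible (CL 5 L/h, V 20 L,
D1 0.5 h, ω 0.2, σ 0.2/0.1). Non-convergence returns a flagged result with
the best estimates found. An exactly zero predicted concentration under
proportional-only error raises a diagnostic error naming the subject and
time.

**Covariate selection.** Forward stepwise: each candidate enters as one extra
parameter (power of the median-scaled covariate, or `exp(β·x)` for a flag) and
is accepted when the OFV drop strictly exceeds the χ² 5 % critical value
(3.84 for one degree of freedom; a drop of exactly 3.84 is not significant).
Two safeguards make the likelihood-ratio comparison robust to optimizer
noise: (i) a coarse profile of the candidate coefficient (cheap cold
evaluations on a fixed grid) chooses the warm start, so a shallow local basin
at zero cannot hide a real effect; (ii) because any trial fit with its
coefficient zeroed is a point of the current model, the round re-polishes the
current fit whenever a trial's shared parameters improve on it, eliminating
phantom drops from an under-converged base. A materially negative drop
between nested models is flagged as a suspected optimizer failure rather than
silently accepted.

## Problem sizes and expected operating characteristics

The simulation-estimation round trip in the test suite uses 63 subjects
(21 per age stratum) with the default TDM design — the size of the source
study — and 20 replicates. Under these conditions the suite verifies: median
relative bias of θ_CL and θ_V below 10 % (ω_CL within 40 %); the true eGFR
effect selected in ≥ 90 % of replicates; a purely null binary covariate
accepted in ≤ 3 of 20 (nominal 5 % test). PTA simulations use 1,000 virtual
patients per stratum and 10⁵ draws for the theoretical-best Monte Carlo.
These sizes keep the whole suite to a few minutes while leaving the
Monte-Carlo error well inside every asserted tolerance.

## Known limitations

* Two-compartment kinetics, nonlinear elimination, inter-occasion variability
  and omega correlations are out of scope (the first was rejected for
  instability in the source analysis; the others were not supported by the
  data design).
* The Laplace/Gauss-Newton OFV is an approximation; its small-sample bias is
  what the recovery study quantifies, not removes.
* Standard errors of estimates are not computed by default (curvature-based
  SEs are a planned extension; the `FitResult.se` slot exists).
* The synthetic generator's independence assumptions above; its growth and
  creatinine tables are compact references, not a growth standard.
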