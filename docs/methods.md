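# Methods

## Scope and data flow

The package models a batch-culture in-vitro gas production (IVGP)
experiment: feed samples fermented in buffered rumen fluid inside sealed
bottles whose headspace pressure is logged automatically, with endpoint
assays (residue masses, pH, methane fraction of collected gas, VFA
concentrations) taken after 48 h. The analysis chain is

    pressure log ──convert──▶ gas curves ──fit──▶ kinetics
    sample sheet ─┘                └───────metrics──▶ endpoint metrics
    endpoints ────────────────────────────┘            └──trends──▶ tables

All stages are pure functions of their tabular inputs plus a run
configuration; the synthetic generator inverts the same chain, so
simulator and analyzer validate each other.

## Pressure-to-volume conversion

Cumulative pressure p (PSI) converts to evolved gas at STP as

    V_stp = p · 6.89476 · headspace_ml · T_stp / (T · P_stp)

with T the incubation temperature in kelvin. The PSI→kPa factor 6.89476
is the exact standard conversion. Defaults: T = 39.5 °C (rumen
temperature; 39.0 °C is equally defensible and configurable — published
protocols report both and which one a given study used in its conversion
is usually unknowable), STP = 273.15 K / 101.325 kPa (the strict
thermodynamic convention; "STP" is used loosely in this field, so both
values are configurable). `headspace_ml` has **no default**: nominal
bottle volume minus inoculum volume understates the true headspace by
the bottle overcapacity and the sensor module's internal volume, and a
silently wrong V scales every volume linearly. The simulator uses 110 mL
as a plausible value for a nominal 100 mL bottle with 90 mL inoculum.

Blank correction subtracts the pointwise mean of blank-bottle *absolute*
volumes before per-g normalisation (blanks carry no substrate mass).
Blanks on shifted grids are combined by linear interpolation on the union
grid restricted to the common range. Negative corrected volumes are kept,
not clamped, so noise statistics stay unbiased; they are logged.
Normalisation divides by dry-matter mass (sample mass × DM fraction),
consistent with reporting in mL/g DM; per-as-fed normalisation would be a
one-line change in `BottleMeta.dm_mass_g`.

Fixed-hour gas productions (default 6, 9, 12, 24, 48 h) are linear
interpolations of the observed cumulative curve, never extrapolations,
and deliberately *not* fitted-curve values: observed values are the more
common reporting choice and remain meaningful when neither model fits
well. Fitted values are available through `KineticFit.predict`.

## Kinetic models and fitting

Families: sigmoidal Y(t) = A/(1 + (B/t)^C) (asymptote A mL/g DM,
half-time B h, shape C) and no-intercept exponential Y(t) = b(1 − e^(−ct)).
B is carried in hours throughout; reported Tmax is in minutes (the
closed-form inflection B·((C−1)/(C+1))^(1/C) × 60 for C > 1), H1 in
hours. Both parameterisations force Y(0) = 0.

Fitting is unweighted nonlinear least squares on log-parameters
(positivity without constrained solvers), Levenberg–Marquardt, xtol 1e-10,
capped at 500 iterations per parameter. Starting values: A₀ = max(y),
B₀ = first positive time with y ≥ A₀/2, C₀ = 1.5; b₀ = max(y),
c₀ = 0.1/h. An identically zero response raises a fit error; a constant
response returns a non-converged fit with a diagnostic message rather
than an exception, so batch runs survive degenerate bottles.

Model choice minimises AIC = n·ln(RSS/n) + 2k over converged fits, with
k counting the curve parameters plus the residual variance (the standard
least-squares Gaussian form; sources that name AIC rarely state the
variant, and any fixed variant preserves the ranking).

Derived quantities: sigmoid — A1 = A, H1 = B,
Tmax = B·((C−1)/(C+1))^(1/C), Vmax = dY/dt at Tmax from
dY/dt = A·C·B^C·t^(C−1)/(B^C + t^C)²; for C ≤ 1 the rate is monotone
decreasing, so Tmax is reported as 0 and Vmax as the rate at the first
recording interval (10 min by default) — the mathematical supremum at
t → 0⁺ is infinite for C < 1 and uninformative. Exponential — A1 = b,
H1 = ln 2/c, Tmax = 0, Vmax = b·c. Vmax is carried in mL/g/h; a per-min
display (`Vmax_ml_per_g_min`) exists because published tables sometimes
label Vmax "per min" while printing magnitudes only consistent with
per-hour — unit handling must be explicit, not guessed.

## Endpoint metrics

- degradation % = (initial − residue)/initial × 100, after subtracting
  the mean blank residue from treatment residues (blank microbial debris
  inflates residues). Residue > initial yields a logged negative value.
- PF48 = mg degraded DM / mL 48-h gas (absolute, per bottle).
- tVFA = 0.0222·GP24 − 0.00425 in mmol per **200 mg** DM; the published
  regression is on that basis, so per-g gas values are divided by 5 by a
  documented adapter. The prediction is left unclamped (the intercept
  makes it negative at zero gas; that is reported raw and logged).
  Note: published PF48/tVFA values in dose-titration tables are often
  not reproducible from the same tables' printed gas productions under
  the stated formulas and sample mass; this implementation follows the
  formulas, so its absolute PF48/tVFA scale can differ from such tables
  while ordering and trend statistics are unaffected.
- Methane: the bag concentration mixes substrate-derived and
  inoculum-derived gas, so the default blank correction is
  volume-weighted — (c_bag·V_total − c_blank·V_blank)/(V_total − V_blank) —
  which exactly inverts the mixing; plain concentration subtraction is
  available (`method="simple"`). Yield = TGP48 × CH₄%/100, mL/g DM.
- VFA: total = Σ concentrations, molar profile = 100·cᵢ/total (always
  summing to 100), acetate:propionate ratio flagged `None` when
  propionate is zero. Missing acids count as zero with a warning.

## Dose-response model

Y_ijk = µ + D_i + R_j + E_ijk, dose categorical and fixed, incubation
run a random intercept, fitted by REML (statsmodels MixedLM, cell-means
coding so the fixed-effect vector *is* the dose-mean vector). Trend
contrasts are orthogonal polynomials for the actual spacings, built by
Gram–Schmidt in exact rational arithmetic and scaled to smallest
integers with the last coefficient positive: doses (0, 20, 40, 100) give
linear (−2, −1, 0, 3) and quadratic (43, −17, −49, 23); equal spacing
recovers the textbook (−3, −1, 1, 3)/(1, −1, −1, 1). Contrast Wald
t-tests use containment denominator degrees of freedom
n − #doses − #incubations + 1 (conservative, reproducible; software
packages differ here and any choice must be stated). With only two runs
the REML run-variance estimate frequently hits the zero boundary; the
model then refits with incubation as a fixed (sum-coded) block, which
gives identical contrast inference in the balanced case. Two SEMs are
reported: residual-based √(σ̂²ₑ/n_per_dose) (the printed "pooled SEM"
convention) and model-based √((σ̂²ₑ + σ̂²_run)/n_per_dose). No
multiple-testing correction is applied across responses, matching
per-response reporting practice. Blanks never enter the statistical
model.

## Synthetic generator

The generator realises exactly the model above. Defaults encode a
dose-titration study of three tannin-rich fruit additives (BA, HA, TC)
at 20/40/100 % of DM in a maize-silage control: 10 treatments × 2
incubation runs × 4 bottles + 4 blanks/run, 500 mg samples, 48 h at
10-min resolution (289 points). Per-treatment kinetic truths use
asymptotes ≈72–197 mL/g and half-times ≈4.5–17 h spanning the range
reported for such substrates; shape parameters C (1.25–2.59) were solved
so each curve's inflection time sits at a realistic Tmax for its
half-time. Endpoint means follow the same gradient (pH 6.7–6.9, dDM
66–84 %, CH₄ 1.8–10 %, total VFA 47–68 mmol/L with a seven-acid molar
profile). Observation noise is additive iid Gaussian on cumulative gas
(default 5 mL/g — the simplest model consistent with mean ± SEM
reporting); endpoint residual SDs are sized so pooled SEMs over 8
bottles match typical published magnitudes. The run effect is
multiplicative on the gas asymptote (1 + e_j, e_j ~ N(0, 0.02²), keeping
curves positive) and additive on endpoints (2 % of the response's grand
mean per SD), reflecting modest day-to-day inoculum variation. Blank gas
follows a slow sigmoid to 8 mL with 12 h half-time; blank residue 5 mg,
blank CH₄ 6 % — free parameters, since blank magnitudes are essentially
never published. Pressure traces are produced by the exact inverse of
the analyzer's conversion (per-g curve × DM mass + blank gas profile),
so the round trip is the identity at zero noise. One `numpy` generator
seeded from a single integer drives all randomness: fixed seed ⇒
identical bytes; different seed ⇒ same structure, new noise.

What the simulator does *not* emulate: vent-release quantisation and
sensor resolution, heteroscedastic or autocorrelated gas noise,
temperature drift, CO₂ solubility in buffer, headspace composition
changes, or any mechanistic microbiology. Passing tests therefore
demonstrate correctness of the calculation chain and calibration of the
statistics under the stated noise model — not robustness to instrument
artifacts.

Ground truth is recorded per bottle as the treatment mean plus the
realized run effect (everything except iid residual noise): that is the
quantity an unbiased analyzer recovers as noise averages out, and it is
what end-to-end coverage checks compare against, using the
residual-based pooled SEM.

## Numerical choices and edge cases

- Interpolation everywhere is linear with no extrapolation (range
  errors instead).
- Results tables are written tab-separated at fixed precision with a
  deterministic (treatment, dose) sort: identical inputs give
  byte-identical files. Data CSVs are written at %.17g and read with
  round-trip float parsing, so write→read is bit-exact.
- RSS of 0 (perfect fits) is floored at 1e-300 inside the AIC logarithm.
- Validation rejects exactly the rows violating a stated invariant
  (doses outside {0, 20, 40, 100}, unknown treatment codes, non-positive
  DM fractions); nothing is silently dropped. Blank rows may omit mass
  fields.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: 289-point curves
for round-trip and recovery checks; 100 seeds for noisy recovery and per
family for model identification (noise 3–5 mL/g); 500 simulated
experiments for null calibration of the linear-trend test plus 200 per
effect size for power monotonicity; and one full default experiment (88
bottles) for end-to-end coverage. These sizes give Monte-Carlo standard
errors comfortably below the decision margins they support.

## Known limitations

- Unweighted least squares assumes homoscedastic curve noise; cumulative
  gas data are positively autocorrelated in reality, so reported RSS
  understates parameter uncertainty (point estimates are unaffected).
- The containment-df Wald t-test is approximate for unbalanced designs;
  the balance check only warns.
- With two incubation runs the run variance is essentially inestimable;
  inference leans on the fixed-block fallback, which conditions on runs
  rather than generalising over them.
- The volume-weighted CH₄ correction assumes the blank's gas volume in
  every treatment bottle equals the mean blank's — exact in the
  simulator, approximate in real bottles.
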