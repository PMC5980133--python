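# Methods

This note records the modelling assumptions, numerical choices and open
design decisions behind `cd38pkpd`, in the spirit of a model-description
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structural PK model

Two-compartment disposition with linear clearance `CL`, intercompartmental
clearance `Q`, central/peripheral volumes `VC`/`VP`, a first-order SC depot
(`KA`, bioavailability `F` parameterised on logit scale so estimates stay in
(0, 1)), and target-mediated drug disposition in the quasi-steady-state
(QSS) approximation.  The QSS reduction assumes drug–target binding
equilibrates instantly relative to every other process, so the free
concentration `C` is the positive root of
`C + rtot·C/(KSS + C) = ctot`, with `KSS = (KOFF + KINT)/KON` a composite
the individual on/off rates are absorbed into.  The target (CD38) is
synthesised at `KSYN` and degraded at `KDEG` in the central compartment
only; the drug–target complex is internalised at `KINT`.  Drug-free
equilibrium target is `KSYN/KDEG = 8.85 u/L`.

Unit conventions worth making explicit:

* Times are days throughout; amounts mg; concentrations μg/mL (= mg/L), so
  volumes in L and clearances in L/day need no conversion factors.
* `KSS` is concentration-dimensioned (μg/mL).  Its composite definition
  forces this even where secondary sources print a rate unit.
* The target uses an arbitrary unit "u" coupled 1:1 to drug concentration
  (1 u/L binds one μg/mL-equivalent).  No molar conversion is available for
  it, and the QSS quadratic requires `rtot` in concentration units, so the
  coupling is the only self-consistent reading.  A consequence worth
  knowing: the equilibrium binding capacity (8.85 μg/mL-equivalents) is
  comparable to the free Cmax of a ~1 mg/kg dose, so *free*-concentration
  AUC remains visibly super-proportional in dose even at doses where
  *total*-drug AUC is proportional to within a few percent.  The
  nonlinearity in the elimination itself is confined to low concentrations
  (clearly below ~0.5 μg/mL), which is what the data for such antibodies
  show.
* The model reports free concentration as "the" concentration (used for
  fitting, NCA and as the PD driver).  Whether the bioanalytical assay sees
  free or total drug is genuinely ambiguous; free is the self-consistent
  choice given that the PD models were calibrated against the same output.

Dosing: IV boluses increment the central amount; 30-minute (monkey) or
2-hour (human) infusions enter as zero-order input; SC doses place
`F × amount` into the depot at dose time — equivalent to fractional
first-order absorption but with simpler event handling.  The SC route also
scales the central volume by `(1 + THETA_ROUT)` with `THETA_ROUT = −0.697`
(a covariate effect, not a physiological volume change).

Integration uses LSODA with relative tolerance 1e−8 (1e−6 inside fitting
loops), absolute 1e−10, restarting at every dose and infusion boundary;
samples that coincide with a dose time report the pre-dose state.

## PD models

All three models are driven by the free central concentration through an
Emax term `E(c) = EMAX·c/(C50 + c)`; Hill exponents are fixed at 1 (a
config switch exists but is off by default, matching the final models).

* **NK** — turnover: production `KIN`, baseline elimination
  `KOUT = KIN/BL` (forced by the observed baseline), drug effect added to
  the elimination rate.  With `KOUT ≈ 20/day` the pool tracks the
  instantaneous equilibrium `BL·KOUT/(KOUT + E(c))` within hours.
* **B** — four transit compartments with
  `KTR = KPROL = KCIRC = 4/MTT` feeding the circulating pool; the drug
  stimulates circulating-cell loss.  Because `KPROL = KTR` and all
  compartments start at the baseline, the upstream chain is constant for
  all time — a structural quirk of the published equations that we
  preserve.  It makes the circulating pool a scalar linear ODE given the
  exposure, which the estimation layer exploits (below).
* **T** — memoryless direct response `T(c) = BL·(1 − E(c)/…)` with `EMAX`
  a depleted *fraction* (≈ 0.47: half of T cells cannot be depleted).

The typical-value predictions deliberately reproduce the published models,
including their known misfits: the typical NK curve at 0.3 mg/kg reaches
only ~33% of baseline (the quasi-equilibrium at the free Cmax), much
shallower than the near-complete depletion observed in animals at that
dose, and the T-cell model underestimates depletion after a first high
dose.  No correction is applied.

## Population layer and synthetic data

Individual parameters are lognormal, `PAR_i = TVPAR·exp(η_i)`, diagonal
random effects.  Printed %CV magnitudes are taken as ω (the SD of η)
directly; the exact conversion `ω² = ln(1+CV²)` differs by <9% at these
magnitudes and is available as an option.  Residual error is combined
additive+proportional for the drug assay (variances 3.17e−4 and 0.0677)
and proportional-only per cell type (0.2905 / 0.136 / 0.1343 for NK/B/T).
These magnitudes are interpreted as *variances* (the usual SIGMA
convention); a flag switches to the SD reading.  Negative observation
draws are floored at zero and counted.

Baselines are lognormal per cell type, calibrated so the theoretical
median and IQR match the observed population summaries (NK 685
[482.8–970.1], B 1279 [860.8–1890], T 3732 [2881–5176] cells/μL);
`σ = (ln q3 − ln q1)/(2·z₀.₇₅)` is the symmetrised estimate when the
printed IQR is not exactly log-symmetric.  CD38⁺ fractions are normal
truncated to [0, 1] with the location moment-matched so the truncated mean
equals the printed mean.  Body weights are uniform on the reported
2.1–4.7 kg range (only the range is available); each animal's dose is its
dose level (mg/kg) × body weight.

Eight study templates reproduce the historical program (doses
0.03–100 mg/kg; single, weekly and every-other-week dosing; IV infusion,
IV bolus and SC).  Only per-animal *sample counts* are documented, so the
sampling schedules are invented to match those counts; they are not data.
Per-subject BL columns are the mean of the simulated predose measurements,
mirroring how baselines enter such datasets.

The anti-drug-antibody (ADA) emergence model is **fabricated**: a subject
seroconverts with probability 0.3 (repeated dosing; 0.05 single dose) at a
time `28 d + Exponential(mean 28 d)`, and flags are monotone within
subject.  Only the qualitative facts (emergence over time in repeated-dose
studies; once positive, stays positive) are supported by observation; all
parameters are config-exposed and should not be mistaken for estimates.
Placebo-arm cell counts fluctuate with a 27% proportional CV (the reported
placebo B-cell statistic); treated arms use the model residuals.

What the generator does *not* emulate: sex- and study-level baseline
shifts, inter-occasion variability, correlated random effects, ADA titer
magnitudes, PD values below a quantification limit, and the one historical
dosing error.  Passing recovery tests therefore demonstrate estimator
correctness under the stated statistical model, not robustness to every
feature of real monkey data.

## Estimation

Staged ("sequential") strategy as in the original analysis: PK first —
optionally with the TMDD block frozen, mirroring how those parameters were
locked from the low-dose studies — then each PD model with PK fixed.
Modes: naive-pooled maximum likelihood, and two-stage (per-subject fits
summarised by the median, which targets the population *median* parameter
under lognormal variability).  A Laplace-type marginal likelihood is not
implemented.  BLQ samples are excluded (M1), as are ADA-flagged samples
and PD samples within 8 h of a dose.

Numerics, all of which earn their place:

* Parameters are log-transformed (logit for bioavailability and for the
  T-cell EMAX fraction).  The Gaussian −2LL with predicted variance
  `σ²(f) = add + prop·f²` is minimised by iteratively reweighted least
  squares with weights *frozen* at the previous iterate — letting the
  proportional weights track the parameters inside the solver biases the
  fit; frozen-weight refits are consistent.  Up to 6 reweighting rounds
  with a 1e−5 stopping rule.
* The inner solver is Levenberg–Marquardt with an explicit 1e−3
  finite-difference step: the default ~1e−8 step sits below ODE-solver
  noise, degrading the Jacobian to zero and silently freezing the fit at
  its starting values.
* A Nelder–Mead simplex pre-search runs before the gradient polish when
  the start is far from the data (always, for one-shot pooled PD fits);
  LM alone is local and can land in a secondary basin from a 10×
  mis-specified start.  First-pass weights come from the data, not from
  the (possibly absurd) initial predictions.
* NK/B predictions inside the optimizer use an exponential integrator on
  the tabulated concentration grid (both reduce to scalar linear ODEs
  given the exposure): exact per step for the averaged loss coefficient,
  unconditionally stable for the extreme trial parameters an optimizer
  probes, and ~0.3% from the reference LSODA solution on the default grid.
* For the B and T models the prediction is proportional to the baseline,
  so a per-subject baseline adjustment (the counterpart of the published
  baseline random effect) is profiled out in closed form each evaluation,
  bounded to [1/2, 2].  Without it, the two-predose-sample BL column
  (±26% noise at the B residual magnitude) dominates the C50 error.
* Standard errors, when requested, come from a finite-difference Hessian
  of −2LL on the transformed scale (the SD of a log-scale estimate is the
  relative SE of the natural-scale one).

Identifiability findings from the recovery experiments (all reproduced by
the test suite): C50 is unidentifiable from lowest-dose-only designs (its
curvature-based SE is >5× the multi-dose design's); the B-cell transit
delay is invisible to trough-only weekly sampling (a quasi-instantaneous
model then fits as well or better), which is why the B recovery design
includes early post-dose and washout samples like the historical
toxicology schedules; and under the NK model's large residual noise the
absolute turnover rates (KIN, EMAX) drift along a likelihood ridge while
C50 and all rate *ratios* remain well determined — consistent with the
original analysis's own caveats about NK parameter precision.

## Noncompartmental analysis

Linear-up/log-down trapezoidal AUC; terminal slope by log-linear
regression over the best-adjusted-R² window among the last 3–6
quantifiable points strictly after Tmax; `AUC_inf = AUC_last + C_last/λz`;
`CL = dose/AUC_inf` (apparent CL/F for extravascular dosing);
`Vz = CL/λz`; per-kg values on request.  Standard conventions chosen
because the original NCA settings are unstated.

## Human scaling and FIH simulation

`P_h = P_m·(BW_h/BW_m)^b` with b = 1.0 for volumes and 0.85 for
clearances, reference weights 3 and 70 kg — standard monoclonal-antibody
practice; the original exact exponents are not in the main text, so these
defaults are explicit assumptions and fully config-exposed.  Absorption,
bioavailability and the TMDD block carry over unchanged (conservative: no
human CD38 turnover data), as do the PD parameters and baselines;
percent-of-baseline outputs are exactly baseline-free for T cells and only
weakly baseline-sensitive for NK/B through `KOUT = KIN/BL`.  The SC route
covariate on VC is retained in the human model for consistency.  FIH
simulation: single doses as 2-h IV infusions or SC, reporting Cmax, nadir
percent-of-baseline, time to nadir and time to 50% recovery per cell
type.  Human depletion-profile *depths* depend on the unpublished scaling
details and are treated as qualitative outputs, not calibrated targets.

## Known limitations

* No full TMDD model (KON/KOFF separately) and no third compartment.
* No FOCE-I or Laplace marginal likelihood; recovery of typical values is
  the design goal, not reproduction of NONMEM objective-function values
  or standard-error tables (impossible without the original animal data).
* The covariate machinery implements only the final route-on-VC effect,
  not a stepwise covariate search.
* ADA affects only data *flags*, never the simulated kinetics; excluding
  flagged rows is the only supported remedy, as in the source analysis.
* Problem sizes in the test suite are reduced versions of the full
  recovery experiments run by `scripts/acceptance.py` (which uses 20
  replicate PK studies and 10 replicate PD studies at 30–40 animals).
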