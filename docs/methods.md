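# Methods

This note documents the model, its assumptions, the numerical choices
and the limits of what the test suite demonstrates.

## The kinetic model

DEHTP (di-(2-ethylhexyl) terephthalate, C24H38O4, 390.56 g/mol) is a
highly lipophilic plasticiser (log P_ow 9.54).  After a single oral
bolus the model routes the dose three ways, with the fractions summing
to one:

* a **hepatic/GI fraction** (`frac_dose_hep`) enters the stomach lumen
  and is absorbed into venous blood by first-order permeation from the
  stomach (`bellyperm`), a first intestinal phase (`giperm1`) and a
  second intestinal phase (`giperm2`), with a transit lag (`gutlag`)
  between the two intestinal phases;
* a **lymphatic fraction** (`frac_dose_lymph`) is taken up via the
  intestinal lacteals, transits the lymphatic system for `lymphlag`
  hours and then enters venous blood at the thoracic duct at rate
  `k1_lymph`, bypassing the liver entirely — the route by which highly
  lipophilic chemicals associated with chylomicrons escape first-pass
  metabolism;
* the remainder passes through the gut unabsorbed to faeces.

Hydrolysis of DEHTP to its monoester MEHTP (C16H22O4, 278.35 g/mol) is
ascribed to the first intestinal phase and to the liver, with
first-order rates derived from in vivo half-lives (`k = 60 ln2 / T½`
with `T½` in minutes).  MEHTP formed in the gut splits between direct
venous entry (fraction `escape_frac_gu`, representing incomplete
first-pass capture) and portal delivery; of the portal stream, a
fraction `escape_frac_li` escapes hepatic extraction to venous blood
and the rest enters the liver compartment.  Liver DEHTP is also
secreted into bile at `k1_dehtp_liver` and re-enters the *second*
intestinal phase after a transit delay, where it is available for
reabsorption (enterohepatic recirculation).

Both chemicals distribute flow-limited to liver, adipose, kidney, gut,
stomach, rapidly and slowly perfused tissues with tissue:blood
partition coefficients.  Binding is described in arterial blood: only
the unbound fraction `1 − FB` distributes to tissues and feeds
metabolism; the bound fraction bypasses to venous blood.  Tissues with
missing in-silico partition coefficients borrow a surrogate organ with
similar perfusion (stomach ← gut, rapidly perfused ← spleen, slowly
perfused ← muscle), resolved in a single hop.

MEHTP is cleared in the liver only, with an intrinsic clearance scaled
from the measured microsomal half-life (30.54 min, 1 ml incubation at
0.5 mg/ml microsomal protein) through the microsomal protein yield
(`MPY`, mg/g) and liver mass, acting on the unbound venous-equilibrated
liver concentration (`CL_int · (1 − FB_M) · C_liver / P_liver`).
Metabolised MEHTP splits instantaneously into three tracked urinary
metabolites — 5OH-MEHTP (294.34 g/mol), 2cx-MMHTP (294.30 g/mol) and
5cx-MEPTP (308.33 g/mol) — by the fractions `frac_metab_*`, and a
terminal terephthalic-acid/non-specific remainder pool with no
kinetics of its own (the prior construction constrains that remainder
to roughly 30–60 % of metabolised MEHTP, consistent with TPA being a
major though unmeasured product).  Each tracked metabolite occupies a
central pool in MEHTP-equivalent mass draining into urine at a
first-order rate (`k1_moh`, `k1_2cx`, `k1_5cx`); conversion to each
metabolite's own molar mass happens only at the urine output.
5oxo-MEHTP is not simulated (it is a product of 5OH-MEHTP); the model
does not describe distribution of the second-order metabolites to
tissues.  MEHTP itself is eliminated from the kidney compartment at a
small fixed rate (0.1 h⁻¹).

### Physiology

Organ volumes are fractions of body weight (density 1 kg/L) with
slowly perfused tissue acting as the balance compartment so the
vascularised total is 0.95 of body weight; flows are fractions of
cardiac output, renormalised to sum to the cardiac output
`QC = QCC · BW^0.74` L/h (allometric).  Blood is split one third
arterial / two thirds venous.  The plasma partition coefficients
`Pbab`/`PbaM` and red-cell:plasma ratios `Prbcb`/`PrbcM` enter only the
whole-blood → plasma concentration conversion (haematocrit 0.45) and
the red-cell/plasma term of the well-stirred clearance formula; they do
not affect urinary outputs.  This is a deliberate, documented wiring
choice — with urine-void data alone the blood-side partitioning is
structurally non-identifiable, and the calibration leaves those two
parameters at their priors.

### Delays and the integrator

All kinetics are first order, so the state obeys a linear ODE
`x' = A x` with impulsive dose events.  The default integrator is a
matrix-exponential propagator: exact for piecewise-constant linear
systems, it conserves parent-equivalent mass to machine precision
(~1e-12 relative) and makes a forward solve cheap enough for MCMC
(~1–2 ms per volunteer).  A stiff LSODA path (rtol 1e-8, atol 1e-10)
is retained as an independent numerical route and the two are compared
in tests.  Integration restarts at every dose event and delay-arrival
time.

The lymphatic lag is an **exact transport delay**: lymph inflow is
impulse-only, so each dose's lymph fraction is re-injected into the
thoracic-duct compartment exactly `lymphlag` hours after ingestion.
The gut-1 → gut-2 and liver → bile transits carry continuous inflows
and use 5-stage Erlang chains whose mean equals the stated lag
(`gutlag`; bile transit fixed at 1 h).  Gastric emptying into the
first intestinal phase is first order at a fixed 2 h⁻¹.  The fast
likelihood path evaluates cumulative urinary outputs by binary powers
of `expm(A·dt)` on the 0.05 h grid and therefore quantises the lymph
arrival to the nearest grid point; observation times generated by the
study generator lie on the same grid, so the generative and inference
models agree exactly.

## Observation model and calibration

Urine voids (time, volume, concentration per metabolite) are converted
to average bladder deposition rates: `rate_i = c_i · V_i / (t_i −
t_{i−1})`, associated with the interval midpoint, with the first
interval anchored at the dose time (the bladder is assumed emptied at
dosing).  The model-side observation operator is the matching interval
average of cumulative urinary output.  Rates are compared under
independent **zero-truncated normal** errors with per-output standard
deviations (σ_OH, σ_2cx, σ_5cx); the log-density includes the
truncation term `−log Φ(μ/σ)`.

Parameters split into 15 calibrated globals (binding, six partition
coefficients, two DEHTP half-lives, three urinary elimination rates,
two escape fractions) plus the three error SDs, and 19 locals per
volunteer (dose-route fractions, permeation rates, lags, biliary rate,
metabolite formation fractions, microsomal yields and five
physiological overrides).  Priors follow the tabulated distributions;
parameters without explicit distributions get uniforms back-solved
from their published prior median and 95 % interval (`width =
(hi − lo)/0.95`, centre at the median, negative lower endpoints
clamped at zero).  The five subject-level physiological overrides use
normals back-solved the same way (the population table's SDs are
between-study, not between-subject, and are too narrow to contain
realistic subjects), truncated at their 5th/95th percentiles.
Normal kinetic priors are truncated at zero; half-normals are
parameterised by their scale (HN(10) ⇒ σ = 10).  Remaining parameters
are fixed at baseline values during calibration.

Sampling is **Metropolis-within-Gibbs over parameter blocks**: the
global kinetic block, one block per volunteer's locals and the
error-SD block.  This keeps one iteration at six forward simulations —
a local proposal re-simulates only its volunteer, and an SD proposal
re-simulates nothing because per-volunteer predictions are cached.  (A
strictly component-wise scan would cost ~120 simulations per sweep for
no inferential benefit at this model size.)  During burn-in (the first
quarter of iterations) each block adapts a scaled empirical-covariance
proposal towards 20–30 % acceptance; proposals are frozen afterwards
and burn-in is excluded from summaries.  Chains start at the prior
medians, retain every 10th iteration, are exactly reproducible under a
fixed seed, and warn if any block stalls at zero acceptance.
Summaries are empirical medians and 2.5/97.5 percentiles; the
"posterior mode" is the retained sample with the highest log-posterior,
and pointwise 95 % predictive bands are percentiles over
chain-driven simulations (the mode trace may legitimately step outside
a pointwise band).  The measured-versus-predicted 48-h excretion table
applies the same void observation operator to the model — cumulative
excretion at the last void inside the window — because mass deposited
in the bladder after the final void is unobservable in the measured
total.

## Synthetic studies

The generator emulates the emulated study's design constants: three
volunteers, ~52.2 mg oral bolus each, body weights 85–95 kg, 20–23
voids over 48 h with 3.6–5.6 L total urine.  Void gaps are irregular
with a diurnal pattern (waking-hour slots seven times likelier than
night slots; dosing at 08:00), an invention — the emulated design
constrains only counts and totals.  Volumes split a uniform total via
a symmetric Dirichlet.  Noise is added on deposition rates
(zero-truncated normal, default SDs 0.0059/0.00057/0.023 mg/h for
5OH/2cx/5cx — the noise scale of real biomonitoring data of this kind)
and converted back to concentrations, so a round trip through the rate
derivation reproduces the noisy rates to floating-point precision.

The default ground truth is a calibrated reference set representative
of three adult volunteers, including one lymph-dominant subject
(lymphatic fraction 0.26, lag 4.7 h) whose deposition profile shows
the characteristic double peak; the package reproduces that morphology
and its disappearance when the lymphatic route is ablated.

**What passing tests do and do not show.**  Because the synthetic data
are generated by the same forward model and error model used in
inference, parameter-recovery results demonstrate the correctness and
internal consistency of the implementation — not that the model is
structurally right for real volunteers.  Real urine data carry model
error, assay LOD/LOQ censoring, creatinine/hydration effects and
secondary uptake events, none of which the generator emulates.

## Numerical choices and degenerate inputs

* Grid 0–48 h at 0.05 h; delays ≥ 0 (a zero gut lag caps the transit
  rate at 1e6 h⁻¹); doses must lie inside the grid.
* Matrix-exponential propagation is exact; the LSODA route uses
  rtol 1e-8 / atol 1e-10 and a tolerance sweep shows mass-balance
  degrading monotonically as tolerances loosen.
* Mass balance sums every compartment, urine, faecal and TPA pool in
  DEHTP-equivalents (molar-mass ratios applied once at each
  conversion) and closes to ≤ 1e-6 relative by construction.
* Rejection sampling enforces the joint constraints (dose fractions
  summing ≤ 1; tracked metabolite fractions ≤ 0.7) in prior draws; the
  same constraints return −inf from the log-prior.
* Depletion-series fits use ordinary least squares on
  log-concentration per replicate (replicates are never pooled); a
  non-positive fitted decay constant is an error, not a half-life.

## Problem sizes

Default problem sizes are chosen for desk-scale reproducibility: the
recovery experiment uses 20,000 MCMC iterations (thin 10, 25 %
burn-in), which converges well for this 78-parameter posterior (all
key identifiable parameters recovered inside their 95 % intervals;
~96 % coverage over the full vector) in a couple of minutes on one
CPU.  Longer chains sharpen the posterior-mode fit but do not change
the summaries materially.

## Known limitations

* The escape-fraction wiring (`escape_frac_gu` acting on gut-formed
  MEHTP, `escape_frac_li` on the portal stream at the liver inlet) and
  the re-entry point of biliary DEHTP (second intestinal phase) are
  choices among topologies the available description does not fully
  pin down; both are documented here and are robust targets for
  calibration rather than claims about anatomy.
* `Pbab`/`PbaM` (and with them blood-concentration outputs) are
  uninformed by urine data; blood-side predictions carry the full
  prior uncertainty.
* Binding gates distribution and metabolism identically; separate
  tissue-specific binding is not modelled.
* Only the oral route; no age or renal-function covariates; no
  LOD/LOQ censoring.
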