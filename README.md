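# dehtp-pbpk

A physiologically based pharmacokinetic (PBPK) model for the
plasticiser **DEHTP** (di-(2-ethylhexyl) terephthalate) and its first
metabolite **MEHTP**, with hierarchical Bayesian calibration against
urine-void biomonitoring data.

DEHTP is the terephthalate substitute for DEHP used in food-contact
materials, toys and medical devices.  Because it is extremely
lipophilic (log P_ow ≈ 9.5), its oral uptake is unusual: alongside
absorption into portal blood it enters the **lymphatic system** via the
intestinal lacteals — bypassing first-pass hepatic metabolism — and
liver DEHTP recirculates through **bile** back into the intestine.
Human exposure is monitored through the urinary excretion of the
side-chain-oxidised metabolites of MEHTP (5OH-MEHTP, 2cx-MMHTP,
5cx-MEPTP).  This package implements, for toxicokinetic modellers and
biomonitoring scientists:

* the compartmental ODE model — stomach and two-phase intestine,
  lymphatic route with transport delay, enterohepatic recirculation,
  flow-limited tissue distribution with plasma-protein binding, and
  first-order urinary elimination of three tracked metabolites plus a
  terephthalic-acid bookkeeping pool (all first order, solved exactly
  by a matrix-exponential propagator with machine-precision mass
  balance);
* in vitro / in silico parameter derivation: microsomal
  substrate-depletion half-lives (`T½ = ln2/k`), intrinsic clearance
  `CL_in vitro = (ln2/T½)·(ml incubation / mg microsomes)` scaled to
  the whole organ (`CL_int = CL_in vitro · MPY · V_organ · 60`), the
  well-stirred liver model
  `CL_H = Q_H·fu·CL_int / (Q_H + fu·CL_int/(C_RBC/C_P))`, and plasma
  binding from `fu = 1/(10^(0.4485·logP − 0.4782) + 1)`;
* the urine-void observation model: average bladder deposition rates
  `c_i·V_i/(t_i − t_{i−1})` associated with interval midpoints;
* hierarchical Bayesian calibration (15 shared kinetic parameters +
  3 error SDs + 19 volunteer-specific parameters per subject) under
  zero-truncated normal errors, sampled by adaptive block random-walk
  Metropolis with reproducible seeding; and
* a synthetic volunteer-study generator (3 volunteers, ~52 mg oral
  bolus, 20–23 irregular voids over 48 h) used for end-to-end testing
  and parameter-recovery experiments.

See `docs/methods.md` for the model description and design choices.

## Worked example

```python
from dehtp_pbpk import (DoseEvent, GlobalParams, LocalParams, Physiology,
                        build_model, mass_balance, simulate)
from dehtp_pbpk.synth import reference_truth

truth = reference_truth()                   # calibrated 3-volunteer reference set
ctx = build_model(truth.physiologies[1], truth.glob, truth.locs[1])
out = simulate(ctx, [DoseEvent(time=0.0, amount=52.2)])   # mg, 0-48 h
print({m: round(out.cumulative_urine[m][-1], 3) for m in ("5OH", "2cx", "5cx")})
print(round(mass_balance(out, 52.2), 15))
```

prints

```
{'5OH': 0.482, '2cx': 0.096, '5cx': 4.66}
2.77e-13
```

— of a 52.2 mg dose this volunteer excretes 4.66 mg as 5cx-MEPTP over
48 h, and the model accounts for the dose to 1e-13 mg.  The 5cx
deposition-rate trace for this subject is double-peaked (maxima near
1.8 h and 7.4 h): the first peak is gut/liver uptake, the second is
the lymph bolus arriving at the thoracic duct after its 4.7 h lag.
Setting `frac_dose_lymph = 0` removes the second peak.

The analysis pipeline runs as numbered scripts:

```sh
python analysis/01_derive_parameters.py    # IVIVE chain, fu, partition table
python analysis/02_forward_simulation.py   # baseline + ablations + 2nd uptake events
python analysis/03_generate_study.py       # synthetic 3-volunteer study
python analysis/04_calibrate.py            # 20,000-iteration MCMC (~90 s)
python analysis/05_posterior_summary.py    # summaries, bands, 48-h comparison
```

Each writes its tables under `results/`.  On the default seeds the
calibration recovers all thirteen key identifiable parameters (the
dose-route fractions, transit lags and the 5cx elimination rate, per
volunteer) inside their 95 % credible intervals, with ~96 % coverage
over the full 78-parameter vector, and estimates per-volunteer
absorbed dose fractions of 0.31, 0.30 and 0.21 (truth 0.35, 0.29,
0.23).

A thin CLI wraps the same functions:
`dehtp-pbpk simulate|rates|synth|calibrate|summarise --help`.

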