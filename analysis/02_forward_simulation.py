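"""Forward simulations: baseline kinetics, structural ablations and
secondary uptake events.

Simulates a 52.2 mg oral bolus for the lymph-dominant calibrated
volunteer, then repeats with (a) the lymphatic route removed,
(b) enterohepatic recirculation removed, and (c) two small secondary
boluses (emulating food-triggered uptake of chemical residing in the
lower gut).  Writes the deposition-rate and concentration traces to
results/ and prints what changed.
"""

import dataclasses
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from scipy.signal import argrelmax

from dehtp_pbpk import DoseEvent, build_model, mass_balance, simulate
from dehtp_pbpk.io import write_sim_output_csv
from dehtp_pbpk.synth import reference_truth

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

truth = reference_truth()
phys, glob, loc = truth.physiologies[1], truth.glob, truth.locs[1]
doses = [DoseEvent(0.0, 52.2)]

base = simulate(build_model(phys, glob, loc), doses)
write_sim_output_csv(base, RESULTS / "simulation_reference.csv")
peaks = base.time[argrelmax(base.deposition_rate["5cx"], order=5)[0]]
print(f"reference volunteer (lymphatic fraction {loc.frac_dose_lymph}, "
      f"lag {loc.lymphlag} h):")
print(f"  5cx deposition peaks at t = {np.round(peaks, 2)} h "
      f"(first: gut/liver uptake; second: thoracic-duct arrival)")
print(f"  48-h urinary excretion (mg): "
      + ", ".join(f"{m} {base.cumulative_urine[m][-1]:.3f}" for m in ("5OH", "2cx", "5cx")))
print(f"  mass-balance residual: {mass_balance(base, 52.2):.2e} mg")

no_lymph = simulate(
    build_model(phys, glob, dataclasses.replace(loc, frac_dose_lymph=0.0)), doses
)
write_sim_output_csv(no_lymph, RESULTS / "simulation_no_lymph.csv")
n_peaks = len(argrelmax(no_lymph.deposition_rate["5cx"], order=5)[0])
print(f"lymphatic route removed: {n_peaks} deposition peak(s) — the late peak is gone")

no_ehr = simulate(
    build_model(phys, glob, dataclasses.replace(loc, k1_dehtp_liver=0.0)), doses
)
write_sim_output_csv(no_ehr, RESULTS / "simulation_no_ehr.csv")
early = base.time <= 4.0
d_early = abs(base.cumulative_urine["5cx"][early][-1]
              - no_ehr.cumulative_urine["5cx"][early][-1]) / no_ehr.cumulative_urine["5cx"][early][-1]
d_late = np.max(np.abs(base.deposition_rate["5cx"][~early]
                       - no_ehr.deposition_rate["5cx"][~early])) / base.deposition_rate["5cx"].max()
print(f"enterohepatic recirculation removed: early (<4 h) cumulative output "
      f"changes {100*d_early:.2f} %, late-time deposition rate up to "
      f"{100*d_late:.2f} % of peak")

multi = simulate(
    build_model(phys, glob, loc),
    [DoseEvent(0.0, 52.2), DoseEvent(9.5, 3.0), DoseEvent(17.0, 3.0)],
)
write_sim_output_csv(multi, RESULTS / "simulation_secondary_uptake.csv")
mpeaks = multi.time[argrelmax(multi.deposition_rate["5cx"], order=5)[0]]
print(f"with secondary uptake events at 9.5 h and 17 h: deposition peaks at "
      f"t = {np.round(mpeaks, 2)} h")
print(f"traces -> {RESULTS}")
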