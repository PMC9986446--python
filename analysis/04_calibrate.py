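"""Calibrate the PBPK model against the synthetic study by MCMC.

Runs the adaptive block random-walk Metropolis sampler (default
20,000 iterations, every 10th retained, first quarter as adaptive
burn-in) on the study written by 03_generate_study.py and persists the
chain under results/chain/.
"""

import argparse
import pathlib
import sys
import time

import yaml

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from dehtp_pbpk.likelihood import CalibrationDataset, VolunteerData
from dehtp_pbpk.mcmc import MCMCConfig, run_mcmc, save_chain
from dehtp_pbpk.urine import read_voids_csv

parser = argparse.ArgumentParser()
parser.add_argument("--iters", type=int, default=20_000)
parser.add_argument("--thin", type=int, default=10)
parser.add_argument("--seed", type=int, default=11)
args = parser.parse_args()

root = pathlib.Path(__file__).resolve().parents[1] / "results"
study = yaml.safe_load((root / "synthetic_study" / "study.yaml").read_text())
by_vol = read_voids_csv(root / "synthetic_study" / "voids.csv")

volunteers = [
    VolunteerData.from_voids(vlist, dose_mg=float(study["dose_mg"]), body_weight=float(bw))
    for vlist, bw in zip(by_vol.values(), study["body_weights"])
]

t0 = time.time()
chain = run_mcmc(
    CalibrationDataset(volunteers),
    MCMCConfig(iterations=args.iters, thin=args.thin, seed=args.seed),
)
save_chain(chain, root / "chain")
print(f"{args.iters} iterations in {time.time() - t0:.0f} s; "
      f"retained {len(chain.samples)} samples")
print("block acceptance rates:",
      {k: round(v, 3) for k, v in chain.acceptance.items()})
print(f"chain -> {root / 'chain'}")
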