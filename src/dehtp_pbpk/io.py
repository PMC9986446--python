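"""Plain-text exchange formats: parameter configs, prior specs,
depletion series and simulation outputs."""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import pandas as pd
import yaml

from .chem import METABOLITES
from .clearance import DepletionSeries
from .model import SimOutput
from .parameters import GlobalParams, LocalParams, Physiology
from .priors import PriorSpec

__all__ = [
    "read_depletion_csv",
    "read_priors_yaml",
    "write_priors_yaml",
    "read_params_yaml",
    "write_params_yaml",
    "write_sim_output_csv",
]


def read_depletion_csv(path) -> list[DepletionSeries]:
    """Depletion series from delimited text with columns
    replicate, time_min, concentration; one series per replicate."""
    df = pd.read_csv(path)
    needed = {"replicate", "time_min", "concentration"}
    if not needed.issubset(df.columns):
        raise ValueError(f"depletion file needs columns {sorted(needed)}")
    series = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("time_min")
        series.append(
            DepletionSeries(
                time=grp["time_min"].to_numpy(float),
                concentration=grp["concentration"].to_numpy(float),
                replicate_id=int(rep),
            )
        )
    return series


# -- priors -----------------------------------------------------------------

def write_priors_yaml(priors: dict[str, PriorSpec], path) -> None:
    payload = {
        name: {
            "family": s.family,
            "params": list(s.params),
            "trunc": None if s.trunc is None else list(s.trunc),
        }
        for name, s in priors.items()
    }
    pathlib.Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_priors_yaml(path) -> dict[str, PriorSpec]:
    payload = yaml.safe_load(pathlib.Path(path).read_text())
    out = {}
    for name, rec in payload.items():
        trunc = rec.get("trunc")
        out[name] = PriorSpec(
            name, rec["family"], tuple(rec["params"]),
            None if trunc is None else tuple(trunc),
        )
    return out


# -- parameter sets ---------------------------------------------------------

def write_params_yaml(path, phys: Physiology, glob: GlobalParams, locs: list[LocalParams]) -> None:
    payload = {
        "physiology": dataclasses.asdict(phys),
        "globals": dataclasses.asdict(glob),
        "locals": [dataclasses.asdict(l) for l in locs],
    }
    pathlib.Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_params_yaml(path) -> tuple[Physiology, GlobalParams, list[LocalParams]]:
    payload = yaml.safe_load(pathlib.Path(path).read_text())
    phys = Physiology(**payload.get("physiology", {}))
    glob = GlobalParams(**payload.get("globals", {}))
    locs = [LocalParams(**rec) for rec in payload.get("locals", [{}])]
    return phys, glob, locs


# -- simulation output ------------------------------------------------------

def write_sim_output_csv(out: SimOutput, path) -> None:
    cols = {"time_h": out.time}
    for chem in ("DEHTP", "MEHTP"):
        cols[f"conc_blood_{chem}"] = out.conc_blood[chem]
        cols[f"conc_plasma_{chem}"] = out.conc_plasma[chem]
    for met in METABOLITES:
        cols[f"cum_urine_{met}"] = out.cumulative_urine[met]
        cols[f"deposition_{met}"] = out.deposition_rate[met]
    cols["mass_residual"] = out.mass_residual
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
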