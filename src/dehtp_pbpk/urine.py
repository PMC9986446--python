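"""Urine-void biomonitoring records and derived deposition rates.

A volunteer's record is a sequence of spot urine voids: time since
dose (h), void volume (L) and the concentration (mg/L) of each
measured metabolite.  The calibration consumes average bladder
deposition rates: mass in a void divided by the time since the
previous void, associated with the interval midpoint.  The first
interval is anchored at the dose time (t = 0), assuming an emptied
bladder at dosing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import METABOLITES

__all__ = [
    "UrineVoid",
    "DepositionObs",
    "voids_to_rates",
    "cumulative_excretion",
    "read_voids_csv",
    "write_voids_csv",
]

#: CSV column layout for void records
_COLUMNS = ["volunteer", "time_h", "volume_L", "conc_5OH", "conc_2cx", "conc_5cx"]


@dataclass(frozen=True)
class UrineVoid:
    """One urine void: time since dose (h), volume (L), concentrations (mg/L)."""

    volunteer: str
    time: float
    volume: float
    concentration: dict[str, float]

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("void volume must be positive")
        for met in METABOLITES:
            if met not in self.concentration:
                raise ValueError(f"missing concentration for {met}")
            if self.concentration[met] < 0:
                raise ValueError(f"negative concentration for {met}")


@dataclass(frozen=True)
class DepositionObs:
    """Average deposition rate (mg/h) over one inter-void interval."""

    volunteer: str
    metabolite: str
    t_start: float
    t_end: float
    rate: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


def voids_to_rates(voids: list[UrineVoid], t_dose: float = 0.0) -> list[DepositionObs]:
    """Derive per-interval deposition rates from a volunteer's voids.

    ``rate_i = conc_i * volume_i / (t_i - t_{i-1})`` with the first
    interval starting at the dose time.  Requires strictly increasing
    void times and at least two voids.
    """
    if len(voids) < 2:
        raise ValueError("need at least 2 voids")
    if len({v.volunteer for v in voids}) != 1:
        raise ValueError("voids must belong to one volunteer")
    times = np.array([v.time for v in voids], dtype=float)
    if np.any(np.diff(times) <= 0) or times[0] <= t_dose:
        raise ValueError("void times must be strictly increasing and after dosing")
    obs: list[DepositionObs] = []
    prev = t_dose
    for void in voids:
        dt = void.time - prev
        for met in METABOLITES:
            obs.append(
                DepositionObs(
                    volunteer=void.volunteer,
                    metabolite=met,
                    t_start=prev,
                    t_end=void.time,
                    rate=void.concentration[met] * void.volume / dt,
                )
            )
        prev = void.time
    return obs


def cumulative_excretion(voids: list[UrineVoid], window: float = 48.0) -> dict[str, float]:
    """Total excreted mass (mg) per metabolite over voids with time <= window."""
    if window <= 0:
        raise ValueError("window must be positive")
    totals = {met: 0.0 for met in METABOLITES}
    for void in voids:
        if void.time <= window:
            for met in METABOLITES:
                totals[met] += void.concentration[met] * void.volume
    return totals


def write_voids_csv(voids: list[UrineVoid], path) -> None:
    rows = [
        {
            "volunteer": v.volunteer,
            "time_h": v.time,
            "volume_L": v.volume,
            **{f"conc_{m}": v.concentration[m] for m in METABOLITES},
        }
        for v in voids
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_voids_csv(path) -> dict[str, list[UrineVoid]]:
    """Read void records grouped by volunteer; missing values are rejected."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"void file lacks columns: {missing}")
    if df[_COLUMNS].isna().any().any():
        raise ValueError("void file contains missing values; imputation is not supported")
    out: dict[str, list[UrineVoid]] = {}
    for vol, grp in df.groupby("volunteer", sort=False):
        grp = grp.sort_values("time_h")
        out[str(vol)] = [
            UrineVoid(
                volunteer=str(vol),
                time=float(r.time_h),
                volume=float(r.volume_L),
                concentration={m: float(getattr(r, f"conc_{m}")) for m in METABOLITES},
            )
            for r in grp.itertuples()
        ]
    return out
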