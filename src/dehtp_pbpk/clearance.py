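"""In vitro to in vivo extrapolation of intrinsic clearance.

The microsomal substrate-depletion method: a first-order decay constant
``k`` is fitted to log-concentration versus time, the in vitro half-life
is ``ln2 / k``, and the intrinsic clearance per mg microsomal protein is
scaled to the whole organ through the microsomal protein yield and organ
mass.  Whole-liver plasma clearance follows the well-stirred model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepletionSeries",
    "ClearanceContext",
    "fit_depletion_half_life",
    "intrinsic_clearance_invitro",
    "scale_clearance_to_organ",
    "hepatic_plasma_clearance",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class DepletionSeries:
    """One microsomal incubation: substrate amount versus time.

    times are minutes, concentrations are relative substrate amounts
    (any consistent unit; only the log-slope matters).  Replicate
    incubations are fitted independently, never pooled.
    """

    time: np.ndarray
    concentration: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "concentration", c)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("time and concentration must be 1-D and equal length")
        if len(t) < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class ClearanceContext:
    """Scaling constants for the in vitro to in vivo clearance chain.

    incubation_volume in ml, microsomal_protein in mg, MPY values in
    mg protein per g tissue, organ_mass in g, hepatic blood flow Q_H in
    L/h, and rbc_plasma_ratio is the red-cell to plasma concentration
    ratio C_RBC/C_P entering the well-stirred model.
    """

    incubation_volume: float = 1.0
    microsomal_protein: float = 0.5
    mpy: float = 34.0
    mpy_gut: float = 3.34
    organ_mass: float = 2750.0
    q_h: float = 90.0
    rbc_plasma_ratio: float = 1.0

    def __post_init__(self) -> None:
        for field in (
            "incubation_volume",
            "microsomal_protein",
            "mpy",
            "mpy_gut",
            "organ_mass",
            "q_h",
            "rbc_plasma_ratio",
        ):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be strictly positive")


def fit_depletion_half_life(series: DepletionSeries) -> float:
    """In vitro half-life (minutes) from a substrate-depletion series.

    Ordinary least squares of ln(concentration) on time; the decay
    constant is minus the slope and the half-life is ``ln2 / k``.
    Raises ``ValueError`` if the fitted decay constant is not positive
    (no measurable depletion).
    """
    slope = np.polyfit(series.time, np.log(series.concentration), 1)[0]
    k = -slope
    if k <= 0:
        raise ValueError("no measurable depletion: fitted decay constant <= 0")
    return LN2 / k


def intrinsic_clearance_invitro(t_half: float, ctx: ClearanceContext) -> float:
    """In vitro intrinsic clearance, ml min^-1 mg^-1 microsomal protein.

    ``(ln2 / T_half) * (incubation volume / mg microsomes)``.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    return (LN2 / t_half) * (ctx.incubation_volume / ctx.microsomal_protein)


def scale_clearance_to_organ(cl_invitro: float, mpy: float, organ_mass: float) -> float:
    """Whole-organ intrinsic clearance, L/h.

    ``cl_invitro * MPY * organ mass * 60``, divided by 1000 to convert
    ml/h to L/h.  Applies to liver (MPY, liver mass) or gut (gut MPY,
    gut mass).
    """
    if cl_invitro < 0 or mpy < 0 or organ_mass < 0:
        raise ValueError("inputs must be non-negative")
    return cl_invitro * mpy * organ_mass * 60.0 / 1000.0


def hepatic_plasma_clearance(
    q_h: float, fu: float, cl_int: float, rbc_plasma_ratio: float = 1.0
) -> float:
    """Whole-liver plasma clearance (L/h) under the well-stirred model.

    ``CL_H = Q_H * fu * CL_int / (Q_H + fu * CL_int / (C_RBC/C_P))``.
    """
    if q_h <= 0 or cl_int < 0 or rbc_plasma_ratio <= 0:
        raise ValueError("flows, clearances and the RBC/plasma ratio must be positive")
    if not 0.0 < fu <= 1.0:
        raise ValueError("fu must be in (0, 1]")
    return q_h * fu * cl_int / (q_h + fu * cl_int / rbc_plasma_ratio)
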