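"""Parameter containers for the DEHTP/MEHTP PBPK model.

Three layers:

* :class:`Physiology` — anatomy and perfusion of one subject (organ
  volume fractions of body weight, blood-flow fractions of cardiac
  output).  Stored as fractions (not percent).
* :class:`GlobalParams` — chemical-specific constants shared across
  subjects: blood binding, partition coefficients, metabolic
  half-lives, urinary elimination rates of the second-order
  metabolites, and the first-pass escape fractions.
* :class:`LocalParams` — subject-specific uptake and metabolism:
  dose-fraction split between the hepatic (GI) and lymphatic routes,
  first-order luminal absorption rates, transit lags, the
  liver-to-bile recirculation rate, metabolite formation fractions,
  microsomal protein yields, and a handful of subject-level
  physiological overrides.

Defaults are the baseline values of the source tables; where a
parameter has no tabulated baseline its prior median is used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["Physiology", "GlobalParams", "LocalParams", "DoseEvent"]


@dataclass(frozen=True)
class Physiology:
    """Subject anatomy and perfusion.  Volumes as fractions of body
    weight (density 1 kg/L), flows as fractions of cardiac output.
    Cardiac output is allometric: QC = qcc * BW**0.74 (L/h)."""

    body_weight: float = 89.0
    v_li: float = 0.0309
    v_ki: float = 0.0058
    v_fa: float = 0.195
    v_gu: float = 0.015
    v_st: float = 0.0022
    v_spd: float = 0.607
    v_rpd: float = 0.0371
    v_bld: float = 0.05
    qcc: float = 14.0
    q_hepart: float = 0.06
    q_ki: float = 0.20
    q_fa: float = 0.05
    q_gu: float = 0.149
    q_st: float = 0.011
    q_spd: float = 0.27
    q_rpd: float = 0.22

    #: upper bound on the summed vascularised-tissue volume fractions
    MAX_VASCULARISED = 0.95

    def volume_fractions(self) -> dict[str, float]:
        return {
            "liver": self.v_li,
            "kidney": self.v_ki,
            "adipose": self.v_fa,
            "gut": self.v_gu,
            "stomach": self.v_st,
            "slowly_perfused": self.v_spd,
            "rapidly_perfused": self.v_rpd,
            "blood": self.v_bld,
        }

    def flow_fractions(self) -> dict[str, float]:
        return {
            "hepatic_artery": self.q_hepart,
            "kidney": self.q_ki,
            "adipose": self.q_fa,
            "gut": self.q_gu,
            "stomach": self.q_st,
            "slowly_perfused": self.q_spd,
            "rapidly_perfused": self.q_rpd,
        }

    def validate(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if self.qcc <= 0:
            raise ValueError("qcc must be positive")
        for name, value in {**self.volume_fractions(), **self.flow_fractions()}.items():
            if value <= 0:
                raise ValueError(f"physiology fraction {name} must be positive")
        total_v = sum(self.volume_fractions().values())
        if total_v > self.MAX_VASCULARISED + 1e-9:
            raise ValueError(
                f"vascularised volume fractions sum to {total_v:.3f} > "
                f"{self.MAX_VASCULARISED}"
            )


@dataclass(frozen=True)
class GlobalParams:
    """Chemical constants shared across subjects.

    Half-lives in minutes; urinary elimination rates in 1/h; partition
    coefficients dimensionless tissue:blood; bound fractions
    dimensionless in [0, 1).
    """

    fb_dehtp: float = 0.9
    fb_mehtp: float = 0.9
    dehtp_half_life: float = 3.0
    dehtp_gut_half_life: float = 60.0
    t_half_mehtp: float = 30.54
    # DEHTP tissue:blood partition coefficients
    pbab: float = 15.5
    pfab: float = 47.2
    plib: float = 5.89
    pkib: float = 3.7
    prbcb: float = 3.0
    pgub: float = 7.4
    pstb: float = 3.7
    prpdb: float = 3.7
    pspdb: float = 3.3
    # MEHTP tissue:blood partition coefficients
    pbam: float = 25.23
    pfam: float = 20.3
    plim: float = 5.9
    pkim: float = 12.2
    prbcm: float = 6.67
    pgum: float = 7.4
    pstm: float = 7.4
    prpdm: float = 3.7
    pspdm: float = 3.3
    # urinary elimination of the tracked second-order metabolites (1/h)
    k1_moh: float = 2.49
    k1_2cx: float = 2.49
    k1_5cx: float = 2.49
    # first-pass escape fractions for gut-formed MEHTP
    escape_frac_gu: float = 0.49
    escape_frac_li: float = 0.49

    def validate(self) -> None:
        for name in ("fb_dehtp", "fb_mehtp"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("dehtp_half_life", "dehtp_gut_half_life", "t_half_mehtp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (minutes)")
        for field in dataclasses.fields(self):
            if field.name.startswith("p") and getattr(self, field.name) <= 0:
                raise ValueError(f"partition coefficient {field.name} must be > 0")
        for name in ("k1_moh", "k1_2cx", "k1_5cx"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("escape_frac_gu", "escape_frac_li"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class LocalParams:
    """Subject-specific uptake, transit and metabolism parameters.

    The maximum summed formation fraction of the three tracked
    metabolites is 0.7; the remainder of metabolised MEHTP is routed to
    the terephthalic-acid / non-specific pool (30-60 % of MEHTP by
    prior construction).  ``frac_dose_hep + frac_dose_lymph <= 1``,
    the remainder passing unabsorbed to faeces.  Rates in 1/h, lags in
    h, microsomal protein yields in mg/g; the volume/flow entries are
    subject-level overrides of :class:`Physiology` (fractions).
    """

    frac_metab_moh: float = 0.065
    frac_metab_2cx: float = 0.010
    frac_metab_5cx: float = 0.425
    k1_dehtp_liver: float = 1.0
    frac_dose_hep: float = 0.354
    frac_dose_lymph: float = 0.152
    bellyperm: float = 3.72
    giperm1: float = 4.98
    giperm2: float = 15.17
    gutlag: float = 1.98
    lymphlag: float = 3.00
    k1_lymph: float = 1.53
    mpy: float = 34.0
    mpy_gut: float = 3.34
    v_bld: float = 0.05
    v_li: float = 0.0309
    v_gu: float = 0.015
    v_ki: float = 0.0058
    q_gu: float = 0.149

    MAX_TRACKED_METAB_FRACTION = 0.7

    def validate(self) -> None:
        fractions = {
            "frac_metab_moh": self.frac_metab_moh,
            "frac_metab_2cx": self.frac_metab_2cx,
            "frac_metab_5cx": self.frac_metab_5cx,
            "frac_dose_hep": self.frac_dose_hep,
            "frac_dose_lymph": self.frac_dose_lymph,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        fm = self.frac_metab_moh + self.frac_metab_2cx + self.frac_metab_5cx
        if fm > self.MAX_TRACKED_METAB_FRACTION + 1e-12:
            raise ValueError(
                f"tracked metabolite fractions sum to {fm:.3f} > "
                f"{self.MAX_TRACKED_METAB_FRACTION}; the remainder must cover the "
                "TPA/non-specific route"
            )
        if self.frac_dose_hep + self.frac_dose_lymph > 1.0 + 1e-12:
            raise ValueError("frac_dose_hep + frac_dose_lymph must be <= 1")
        for name in ("k1_dehtp_liver", "bellyperm", "giperm1", "giperm2", "k1_lymph"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (1/h)")
        for name in ("gutlag", "lymphlag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (h)")
        for name in ("mpy", "mpy_gut", "v_bld", "v_li", "v_gu", "v_ki", "q_gu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DoseEvent:
    """A single oral bolus (mg) at a given time (h)."""

    time: float
    amount: float
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        if self.route != "oral":
            raise ValueError("only the oral route is modelled")
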