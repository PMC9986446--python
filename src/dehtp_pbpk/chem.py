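"""Chemical identities and in-silico property predictions.

DEHTP (di-(2-ethylhexyl) terephthalate) is hydrolysed to its monoester
MEHTP, which is oxidised further to the urinary biomarkers 5OH-MEHTP,
2cx-MMHTP and 5cx-MEPTP.  Terephthalic acid (TPA) is a major but
non-specific downstream product and is handled as a bookkeeping pool.

Plasma protein binding is predicted from log P_ow with the regression for
predominantly neutral chemicals at pH 7.4::

    fu = 1 / (10**x + 1),   x = 0.4485 * logP - 0.4782

For highly lipophilic chemicals this algorithm is known to be unreliable
(it predicts >99.99 % binding for DEHTP); in the kinetic model the bound
fractions are therefore calibrated parameters, and the predicted fu is
used only in the in-vitro-to-in-vivo clearance chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChemicalSpec",
    "DEHTP",
    "MEHTP",
    "MOLAR_MASS",
    "fraction_unbound",
    "fractions_metabolised",
]

#: Molar masses (g/mol) from molecular formulae:
#: DEHTP C24H38O4, MEHTP C16H22O4, 5OH-MEHTP C16H22O5,
#: 2cx-MMHTP C15H18O6, 5cx-MEPTP C16H20O6, TPA C8H6O4.
MOLAR_MASS = {
    "DEHTP": 390.56,
    "MEHTP": 278.35,
    "5OH": 294.34,
    "2cx": 294.30,
    "5cx": 308.33,
    "TPA": 166.13,
}

#: The three second-order metabolites tracked to urine, in canonical order.
METABOLITES = ("5OH", "2cx", "5cx")


def fraction_unbound(log_pow: float) -> float:
    """Predicted plasma fraction unbound from the octanol-water log P.

    Strictly decreasing in ``log_pow`` and bounded in (0, 1).
    """
    x = 0.4485 * float(log_pow) - 0.4782
    return 1.0 / (10.0**x + 1.0)


@dataclass(frozen=True)
class ChemicalSpec:
    """Identity and physico-chemical properties of one species.

    Parameters
    ----------
    name : str
        Species label (e.g. ``"DEHTP"``).
    molecular_weight : float
        Molar mass in g/mol; must be positive.
    log_pow : float
        Octanol-water partition coefficient (log10).
    fraction_unbound : float
        Plasma fraction unbound, in (0, 1).
    role : str
        One of ``"parent"``, ``"monoester"``, ``"secondary"``.
    """

    name: str
    molecular_weight: float
    log_pow: float
    fraction_unbound: float
    role: str

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular_weight must be > 0")
        if not 0.0 < self.fraction_unbound < 1.0:
            raise ValueError(f"{self.name}: fraction_unbound must be in (0, 1)")
        if self.role not in ("parent", "monoester", "secondary"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")


DEHTP = ChemicalSpec(
    name="DEHTP",
    molecular_weight=MOLAR_MASS["DEHTP"],
    log_pow=9.54,
    fraction_unbound=fraction_unbound(9.54),
    role="parent",
)

MEHTP = ChemicalSpec(
    name="MEHTP",
    molecular_weight=MOLAR_MASS["MEHTP"],
    log_pow=5.84,
    fraction_unbound=fraction_unbound(5.84),
    role="monoester",
)


def fractions_metabolised(molar_amounts: dict[str, float]) -> dict[str, float]:
    """Per-metabolite shares of the five measured urinary species.

    ``molar_amounts`` maps the five measured species (MEHTP, 5OH, 2cx,
    5cx, 5oxo) to molar amounts.  Returns the fractions of the measured
    total attributable to each of the three simulated metabolites
    (5OH, 2cx, 5cx); 5oxo contributes to the denominator only, as it is
    a product of 5OH and is not simulated separately.
    """
    required = ("MEHTP", "5OH", "2cx", "5cx", "5oxo")
    amounts = {}
    for key in required:
        if key not in molar_amounts:
            raise KeyError(f"missing molar amount for {key}")
        value = float(molar_amounts[key])
        if value < 0:
            raise ValueError(f"negative molar amount for {key}")
        amounts[key] = value
    total = sum(amounts.values())
    if total <= 0:
        raise ValueError("total molar amount must be positive")
    return {m: amounts[m] / total for m in METABOLITES}
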