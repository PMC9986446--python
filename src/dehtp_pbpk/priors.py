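"""Prior distributions for the PBPK parameters.

Four families are supported (normal, lognormal, half-normal, uniform),
optionally truncated.  Truncation is handled exactly by inverse-CDF
sampling between the CDF values of the bounds, so sampled quantiles
converge to the closed-form quantiles of the truncated law.

Three registries are provided:

* ``PHYSIO_PRIORS`` — population distributions of the anatomical and
  physiological parameters (percent body weight / percent cardiac
  output, as conventionally tabulated), truncated at their own 5th and
  95th percentiles.
* ``GLOBAL_PRIORS`` — the 15 calibrated global kinetic parameters plus
  the three observation-error standard deviations.
* ``LOCAL_PRIORS`` — the 19 volunteer-specific parameters.

Parameters that have no explicitly stated distribution are given
uniform priors whose endpoints are back-solved from a published prior
median m and 95 % interval (lo, hi): a U(a, b) sample has median
(a+b)/2 and central 95 % interval (a + 0.025 w, b - 0.025 w) with
w = b - a, hence w = (hi - lo)/0.95 and a = m - w/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PriorSpec",
    "uniform_from_median_interval",
    "sample_prior",
    "summarise_prior",
    "PHYSIO_PRIORS",
    "GLOBAL_PRIORS",
    "LOCAL_PRIORS",
    "SENSITIVITY_PRIORS",
]

_FAMILIES = ("normal", "lognormal", "halfnormal", "uniform")


@dataclass(frozen=True)
class PriorSpec:
    """One marginal prior: family, parameters, optional truncation.

    params are (loc, scale) for normal, (meanlog, sdlog) for lognormal,
    (scale,) for halfnormal and (a, b) for uniform.  ``trunc`` is an
    optional (lower, upper) pair; either side may be ``None``.
    """

    name: str
    family: str
    params: tuple
    trunc: tuple | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"{self.name}: unsupported family {self.family!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if self.family in ("normal", "lognormal") and len(p) != 2:
            raise ValueError(f"{self.name}: need (location, scale)")
        if self.family == "halfnormal" and len(p) != 1:
            raise ValueError(f"{self.name}: half-normal takes a single scale")
        if self.family == "uniform":
            if len(p) != 2 or p[0] >= p[1]:
                raise ValueError(f"{self.name}: uniform needs ordered bounds")
        if self.family in ("normal", "halfnormal", "lognormal") and p[-1] <= 0:
            raise ValueError(f"{self.name}: scale must be positive")
        if self.trunc is not None:
            lo, hi = self.trunc
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"{self.name}: truncation bounds must be ordered")

    # -- distribution plumbing ------------------------------------------------

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(*self.params)
        if self.family == "lognormal":
            meanlog, sdlog = self.params
            return stats.lognorm(s=sdlog, scale=np.exp(meanlog))
        if self.family == "halfnormal":
            return stats.halfnorm(scale=self.params[0])
        return stats.uniform(self.params[0], self.params[1] - self.params[0])

    def _cdf_bounds(self) -> tuple[float, float]:
        dist = self._frozen()
        lo, hi = (None, None) if self.trunc is None else self.trunc
        flo = 0.0 if lo is None else float(dist.cdf(lo))
        fhi = 1.0 if hi is None else float(dist.cdf(hi))
        if not flo < fhi:
            raise ValueError(f"{self.name}: truncation removes all mass")
        return flo, fhi

    @property
    def support(self) -> tuple[float, float]:
        dist = self._frozen()
        lo, hi = dist.support()
        if self.trunc is not None:
            tlo, thi = self.trunc
            lo = lo if tlo is None else max(lo, tlo)
            hi = hi if thi is None else min(hi, thi)
        return float(lo), float(hi)

    def truncated_at_percentiles(self, lower: float = 0.05, upper: float = 0.95) -> "PriorSpec":
        """A copy truncated at the given percentiles of the untruncated law."""
        dist = self._frozen()
        return PriorSpec(
            self.name, self.family, self.params, (float(dist.ppf(lower)), float(dist.ppf(upper)))
        )

    # -- queries --------------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        flo, fhi = self._cdf_bounds()
        u = rng.uniform(flo, fhi, size=n)
        return np.asarray(self._frozen().ppf(u), dtype=float)

    def quantile(self, q) -> np.ndarray | float:
        flo, fhi = self._cdf_bounds()
        return self._frozen().ppf(flo + np.asarray(q, dtype=float) * (fhi - flo))

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    def logpdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        flo, fhi = self._cdf_bounds()
        lo, hi = self.support
        out = np.where(
            (x < lo) | (x > hi),
            -np.inf,
            self._frozen().logpdf(x) - np.log(fhi - flo),
        )
        return out if out.ndim else float(out)


def uniform_from_median_interval(
    name: str, median: float, lo: float, hi: float
) -> PriorSpec:
    """Uniform prior back-solved from a median and central 95 % interval.

    If the solved lower endpoint is slightly negative for a
    non-negative quantity it is clamped to zero, preserving the width.
    """
    width = (hi - lo) / 0.95
    a = median - width / 2.0
    if a < 0 and lo >= 0:
        a = 0.0
    return PriorSpec(name, "uniform", (a, a + width))


def normal_from_median_interval(
    name: str, median: float, lo: float, hi: float
) -> PriorSpec:
    """Normal prior back-solved from a median and central 95 % interval,
    truncated at its 5th/95th percentiles (physiological convention)."""
    sd = (hi - lo) / (2.0 * 1.959964)
    return PriorSpec(name, "normal", (median, sd)).truncated_at_percentiles()


def sample_prior(spec: PriorSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` samples from one prior (``n`` >= 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return spec.sample(n, rng)


def summarise_prior(samples: np.ndarray) -> dict[str, float]:
    """Empirical median and central 95 % interval of a sample."""
    q = np.percentile(np.asarray(samples, dtype=float), [50, 2.5, 97.5])
    return {"median": float(q[0]), "q2.5": float(q[1]), "q97.5": float(q[2])}


# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

def _n(name, loc, scale):  # normal truncated at the 5th/95th percentiles
    return PriorSpec(name, "normal", (loc, scale)).truncated_at_percentiles()


#: Population physiology.  Units: BW kg; volumes % BW; cardiac output
#: L h^-1 kg^-0.26 (allometric coefficient); flows % cardiac output.
PHYSIO_PRIORS: dict[str, PriorSpec] = {
    "BW": _n("BW", 89.5, 24.6),
    "VLiC": _n("VLiC", 3.09, 0.8),
    "VKiC": _n("VKiC", 0.58, 0.15),
    "VFaC": PriorSpec("VFaC", "lognormal", (np.log(19.5), 0.43)).truncated_at_percentiles(),
    "VGuC": _n("VGuC", 1.50, 0.17),
    "VStC": _n("VStC", 0.22, 0.07),
    "VSpdC": _n("VSpdC", 60.7, 9.4),
    "VRpdC": _n("VRpdC", 3.7, 0.26),
    "VBldC": _n("VBldC", 5.0, 1.0),
    "QCC": _n("QCC", 13.8, 2.5),
    "QHepartC": _n("QHepartC", 6.89, 0.52),
    "QKiC": _n("QKiC", 20.0, 3.0),
    "QFaC": _n("QFaC", 5.3, 0.3),
    "QGuC": _n("QGuC", 14.9, 0.9),
    "QStC": _n("QStC", 1.1, 0.08),
    "QSpdC": _n("QSpdC", 28.7, 1.91),
    "QRpdC": _n("QRpdC", 23.1, 2.78),
}

#: Calibrated global kinetic parameters + observation-error SDs.
GLOBAL_PRIORS: dict[str, PriorSpec] = {
    "FB_DEHTP": PriorSpec("FB_DEHTP", "uniform", (0.8, 1.0)),
    "FB_MEHTP": PriorSpec("FB_MEHTP", "uniform", (0.8, 1.0)),
    "DEHTP_GUT_half_life": PriorSpec(
        "DEHTP_GUT_half_life", "normal", (30.0, 10.0), trunc=(0.0, None)
    ),
    "DEHTP_half_life": PriorSpec("DEHTP_half_life", "halfnormal", (10.0,)),
    "Pbab": PriorSpec("Pbab", "uniform", (1.0, 30.0)),
    "Pgub": PriorSpec("Pgub", "uniform", (1.0, 50.0)),
    "Plib": PriorSpec("Plib", "uniform", (1.0, 50.0)),
    "PbaM": PriorSpec("PbaM", "uniform", (1.0, 50.0)),
    "PliM": PriorSpec("PliM", "uniform", (1.0, 30.0)),
    "PguM": PriorSpec("PguM", "uniform", (1.0, 30.0)),
    "K1_2cx": uniform_from_median_interval("K1_2cx", 2.49, 0.12, 4.89),
    "K1_MOH": uniform_from_median_interval("K1_MOH", 2.49, 0.12, 4.89),
    "K1_5cx": uniform_from_median_interval("K1_5cx", 2.49, 0.12, 4.89),
    "escapeFracgu": PriorSpec("escapeFracgu", "uniform", (0.0, 1.0)),
    "escapeFracli": PriorSpec("escapeFracli", "uniform", (0.0, 1.0)),
    "sigma_OH_U": PriorSpec("sigma_OH_U", "halfnormal", (1.0,)),
    "sigma_2cx_U": PriorSpec("sigma_2cx_U", "halfnormal", (1.0,)),
    "sigma_5cx_U": PriorSpec("sigma_5cx_U", "halfnormal", (1.0,)),
}

#: Volunteer-specific (local) parameters.  Volume/flow entries are
#: fractions (not percent).
LOCAL_PRIORS: dict[str, PriorSpec] = {
    "FracMetabMOH": uniform_from_median_interval("FracMetabMOH", 0.065, 0.046, 0.084),
    "FracMetab2cx": uniform_from_median_interval("FracMetab2cx", 0.010, 0.005, 0.015),
    "FracMetab5cx": uniform_from_median_interval("FracMetab5cx", 0.425, 0.306, 0.543),
    "K1_DEHTP_Liver": PriorSpec("K1_DEHTP_Liver", "halfnormal", (2.0,)),
    "FracDOSEHep": uniform_from_median_interval("FracDOSEHep", 0.354, 0.018, 0.681),
    "BELLYPERM": uniform_from_median_interval("BELLYPERM", 3.72, 0.24, 7.30),
    "GIPERM1": uniform_from_median_interval("GIPERM1", 4.98, 0.28, 9.74),
    "GIPERM2": uniform_from_median_interval("GIPERM2", 15.17, 0.72, 29.20),
    "Gutlag": uniform_from_median_interval("Gutlag", 1.98, 0.11, 3.90),
    "FracDoseLymph": uniform_from_median_interval("FracDoseLymph", 0.152, 0.008, 0.293),
    "Lymphlag": uniform_from_median_interval("Lymphlag", 3.00, 1.09, 4.90),
    "K1_Lymph": uniform_from_median_interval("K1_Lymph", 1.53, 0.11, 2.92),
    "MPY": PriorSpec("MPY", "normal", (34.0, 10.0), trunc=(0.0, None)),
    "MPYgu": PriorSpec("MPYgu", "normal", (3.34, 1.67), trunc=(0.0, None)),
    # subject-level physiological overrides: normals back-solved from the
    # stated prior median and 95 % interval (the population-table SDs are
    # too narrow to admit realistic between-subject spread here)
    "VBldC": normal_from_median_interval("VBldC", 0.05, 0.031, 0.070),
    "VliC": normal_from_median_interval("VliC", 0.03, 0.011, 0.05),
    "VguC": normal_from_median_interval("VguC", 0.015, 0.010, 0.020),
    "VkiC": normal_from_median_interval("VkiC", 0.0058, 0.0028, 0.007),
    "QguC": normal_from_median_interval("QguC", 0.150, 0.089, 0.21),
}

#: Remaining partition coefficients (fixed at baseline in calibration,
#: retained here for uncertainty analysis and synthetic-truth draws).
SENSITIVITY_PRIORS: dict[str, PriorSpec] = {
    "Pfab": PriorSpec("Pfab", "uniform", (32.0, 125.0)),
    "Pkib": PriorSpec("Pkib", "uniform", (3.0, 12.0)),
    "Prbcb": PriorSpec("Prbcb", "uniform", (1.0, 10.0)),
    "Pstb": PriorSpec("Pstb", "uniform", (2.0, 8.0)),
    "Prpdb": PriorSpec("Prpdb", "uniform", (2.0, 8.0)),
    "Pspdb": PriorSpec("Pspdb", "uniform", (2.0, 8.0)),
    "PfaM": PriorSpec("PfaM", "uniform", (15.0, 60.0)),
    "PkiM": PriorSpec("PkiM", "uniform", (1.0, 30.0)),
    "PrbcM": PriorSpec("PrbcM", "uniform", (3.0, 12.0)),
    "PstM": PriorSpec("PstM", "uniform", (12.0, 50.0)),
    "PrpdM": PriorSpec("PrpdM", "uniform", (6.0, 24.0)),
    "PspdM": PriorSpec("PspdM", "uniform", (4.0, 15.0)),
    "T_half_MEHTP": PriorSpec("T_half_MEHTP", "normal", (30.54, 2.39), trunc=(0.0, None)),
}
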