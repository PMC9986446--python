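"""Hierarchical calibration target: parameter vector, priors, likelihood.

The calibrated unknowns are a global vector (15 kinetic parameters
shared across volunteers, plus three observation-error standard
deviations) and one 19-parameter local vector per volunteer.  The
observation model compares measured average bladder deposition rates
of 5OH-MEHTP, 2cx-MMHTP and 5cx-MEPTP with the model's interval
averages under independent zero-truncated normal errors:

    R_ij ~ N(mu_ij(theta, omega_j), sigma_out)[0, inf)

The truncated log-density includes the normalisation
``-log Phi(mu/sigma)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache as _lru_cache

import numpy as np
from scipy.special import log_ndtr
from scipy.stats import norm

from .chem import METABOLITES
from .model import build_model, cumulative_urine_at
from .parameters import DoseEvent, GlobalParams, LocalParams, Physiology
from .priors import GLOBAL_PRIORS, LOCAL_PRIORS, PriorSpec
from .urine import DepositionObs, UrineVoid, voids_to_rates

__all__ = [
    "GLOBAL_NAMES",
    "SIGMA_NAMES",
    "LOCAL_NAMES",
    "SIGMA_FOR",
    "VolunteerData",
    "CalibrationDataset",
    "ParameterVector",
    "truncnorm_logpdf",
    "log_prior",
    "log_likelihood",
    "predicted_rates",
    "volunteer_log_likelihood",
    "marginal_prior",
]

GLOBAL_NAMES = (
    "FB_DEHTP", "FB_MEHTP", "DEHTP_GUT_half_life", "DEHTP_half_life",
    "Pbab", "Pgub", "Plib", "PbaM", "PliM", "PguM",
    "K1_2cx", "K1_MOH", "K1_5cx", "escapeFracgu", "escapeFracli",
)
SIGMA_NAMES = ("sigma_OH_U", "sigma_2cx_U", "sigma_5cx_U")
LOCAL_NAMES = tuple(LOCAL_PRIORS)

SIGMA_FOR = {"5OH": "sigma_OH_U", "2cx": "sigma_2cx_U", "5cx": "sigma_5cx_U"}

_G_FIELD = {
    "FB_DEHTP": "fb_dehtp", "FB_MEHTP": "fb_mehtp",
    "DEHTP_GUT_half_life": "dehtp_gut_half_life",
    "DEHTP_half_life": "dehtp_half_life",
    "Pbab": "pbab", "Pgub": "pgub", "Plib": "plib",
    "PbaM": "pbam", "PliM": "plim", "PguM": "pgum",
    "K1_2cx": "k1_2cx", "K1_MOH": "k1_moh", "K1_5cx": "k1_5cx",
    "escapeFracgu": "escape_frac_gu", "escapeFracli": "escape_frac_li",
}
_L_FIELD = {
    "FracMetabMOH": "frac_metab_moh", "FracMetab2cx": "frac_metab_2cx",
    "FracMetab5cx": "frac_metab_5cx", "K1_DEHTP_Liver": "k1_dehtp_liver",
    "FracDOSEHep": "frac_dose_hep", "BELLYPERM": "bellyperm",
    "GIPERM1": "giperm1", "GIPERM2": "giperm2", "Gutlag": "gutlag",
    "FracDoseLymph": "frac_dose_lymph", "Lymphlag": "lymphlag",
    "K1_Lymph": "k1_lymph", "MPY": "mpy", "MPYgu": "mpy_gut",
    "VBldC": "v_bld", "VliC": "v_li", "VguC": "v_gu", "VkiC": "v_ki",
    "QguC": "q_gu",
}


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class VolunteerData:
    """One volunteer's dose, physiology and deposition-rate observations."""

    volunteer: str
    dose_mg: float
    body_weight: float
    t_start: dict[str, np.ndarray] = field(default_factory=dict)
    t_end: dict[str, np.ndarray] = field(default_factory=dict)
    rate: dict[str, np.ndarray] = field(default_factory=dict)
    dose_times: tuple[float, ...] = (0.0,)

    @classmethod
    def from_voids(
        cls, voids: list[UrineVoid], dose_mg: float, body_weight: float
    ) -> "VolunteerData":
        obs = voids_to_rates(voids)
        self = cls(volunteer=voids[0].volunteer, dose_mg=dose_mg, body_weight=body_weight)
        for met in METABOLITES:
            sel = [o for o in obs if o.metabolite == met]
            self.t_start[met] = np.array([o.t_start for o in sel])
            self.t_end[met] = np.array([o.t_end for o in sel])
            self.rate[met] = np.array([o.rate for o in sel])
        return self

    @property
    def doses(self) -> list[DoseEvent]:
        return [DoseEvent(t, self.dose_mg) for t in self.dose_times]

    def boundary_times(self) -> np.ndarray:
        times = np.concatenate(
            [self.t_start[m] for m in METABOLITES] + [self.t_end[m] for m in METABOLITES]
        )
        return np.unique(times)


@dataclass
class CalibrationDataset:
    volunteers: list[VolunteerData]

    def __post_init__(self) -> None:
        if not self.volunteers:
            raise ValueError("need at least one volunteer")


# ---------------------------------------------------------------------------
# parameter vector
# ---------------------------------------------------------------------------

def _vector_names(n_volunteers: int) -> tuple[str, ...]:
    names = list(GLOBAL_NAMES) + list(SIGMA_NAMES)
    for j in range(n_volunteers):
        names += [f"{n}[{j}]" for n in LOCAL_NAMES]
    return tuple(names)


@dataclass
class ParameterVector:
    """Flat calibration vector: globals, error SDs, then per-volunteer locals."""

    values: np.ndarray
    n_volunteers: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = len(GLOBAL_NAMES) + len(SIGMA_NAMES) + self.n_volunteers * len(LOCAL_NAMES)
        if self.values.shape != (expected,):
            raise ValueError(f"expected {expected} parameters, got {self.values.shape}")

    @property
    def names(self) -> tuple[str, ...]:
        return _vector_names(self.n_volunteers)

    # -- slicing -----------------------------------------------------------
    @property
    def n_global(self) -> int:
        return len(GLOBAL_NAMES)

    def sigma(self, metabolite: str) -> float:
        i = len(GLOBAL_NAMES) + SIGMA_NAMES.index(SIGMA_FOR[metabolite])
        return float(self.values[i])

    def local_slice(self, j: int) -> slice:
        base = len(GLOBAL_NAMES) + len(SIGMA_NAMES)
        k = len(LOCAL_NAMES)
        return slice(base + j * k, base + (j + 1) * k)

    def to_params(self, j: int, base_glob: GlobalParams | None = None) -> tuple[GlobalParams, LocalParams]:
        """Materialise (GlobalParams, LocalParams) for volunteer ``j``.

        Parameters outside the calibration vector stay at the baseline
        values of ``base_glob`` (defaults if omitted).
        """
        glob = base_glob or GlobalParams()
        glob = replace(glob, **{
            _G_FIELD[n]: float(self.values[i]) for i, n in enumerate(GLOBAL_NAMES)
        })
        vals = self.values[self.local_slice(j)]
        loc = LocalParams(**{
            _L_FIELD[n]: float(v) for n, v in zip(LOCAL_NAMES, vals)
        })
        return glob, loc

    @classmethod
    def from_params(
        cls,
        glob: GlobalParams,
        locs: list[LocalParams],
        sigmas: dict[str, float],
    ) -> "ParameterVector":
        values = [getattr(glob, _G_FIELD[n]) for n in GLOBAL_NAMES]
        values += [sigmas[n] for n in SIGMA_NAMES]
        for loc in locs:
            values += [getattr(loc, _L_FIELD[n]) for n in LOCAL_NAMES]
        return cls(np.array(values, dtype=float), n_volunteers=len(locs))

    @classmethod
    def at_prior_medians(cls, n_volunteers: int) -> "ParameterVector":
        values = [GLOBAL_PRIORS[n].median for n in GLOBAL_NAMES]
        values += [GLOBAL_PRIORS[n].median for n in SIGMA_NAMES]
        for _ in range(n_volunteers):
            values += [LOCAL_PRIORS[n].median for n in LOCAL_NAMES]
        return cls(np.array(values), n_volunteers=n_volunteers)


#: marginal prior for each vector entry, by bare name
def marginal_prior(name: str) -> PriorSpec:
    bare = name.split("[")[0]
    if bare in GLOBAL_PRIORS:
        return GLOBAL_PRIORS[bare]
    return LOCAL_PRIORS[bare]


@_lru_cache(maxsize=None)
def _fast_logpdf(spec: PriorSpec):
    """Closed-form scalar log-density closure for one prior.

    Avoids constructing scipy frozen distributions in the sampler's hot
    loop; agrees with ``PriorSpec.logpdf`` (tested against it).
    """
    flo, fhi = spec._cdf_bounds()
    lo, hi = spec.support
    log_z = np.log(fhi - flo)
    half_log_2pi = 0.5 * np.log(2.0 * np.pi)
    if spec.family == "uniform":
        a, b = spec.params
        c = -np.log(b - a) - log_z

        def f(x, lo=lo, hi=hi, c=c):
            return c if lo <= x <= hi else -np.inf
    elif spec.family == "normal":
        mu, sd = spec.params
        c = -np.log(sd) - half_log_2pi - log_z

        def f(x, lo=lo, hi=hi, c=c, mu=mu, sd=sd):
            return c - 0.5 * ((x - mu) / sd) ** 2 if lo <= x <= hi else -np.inf
    elif spec.family == "halfnormal":
        (sd,) = spec.params
        c = np.log(2.0) - np.log(sd) - half_log_2pi - log_z

        def f(x, lo=lo, hi=hi, c=c, sd=sd):
            return c - 0.5 * (x / sd) ** 2 if lo <= x <= hi else -np.inf
    else:  # lognormal
        ml, sl = spec.params
        c = -np.log(sl) - half_log_2pi - log_z

        def f(x, lo=lo, hi=hi, c=c, ml=ml, sl=sl):
            if x <= 0 or x < lo or x > hi:
                return -np.inf
            return c - np.log(x) - 0.5 * ((np.log(x) - ml) / sl) ** 2

    return f


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def truncnorm_logpdf(y, mu, sigma) -> np.ndarray:
    """Log-density of N(mu, sigma) truncated to [0, inf), elementwise.

    ``logpdf(y) = normal logpdf - log Phi(mu / sigma)``; -inf for y < 0.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = norm.logpdf(y, loc=mu, scale=sigma) - log_ndtr(mu / sigma)
    return np.where(y < 0, -np.inf, out)


def log_prior(p: ParameterVector) -> float:
    """Sum of independent marginal log-priors plus joint support constraints."""
    total = 0.0
    for name, value in zip(p.names, p.values):
        lp = _fast_logpdf(marginal_prior(name))(value)
        if lp == -np.inf:
            return -np.inf
        total += lp
    for j in range(p.n_volunteers):
        vals = dict(zip(LOCAL_NAMES, p.values[p.local_slice(j)]))
        if vals["FracDOSEHep"] + vals["FracDoseLymph"] > 1.0:
            return -np.inf
        fm = vals["FracMetabMOH"] + vals["FracMetab2cx"] + vals["FracMetab5cx"]
        if fm > LocalParams.MAX_TRACKED_METAB_FRACTION:
            return -np.inf
    return total


def predicted_rates(
    p: ParameterVector, vdata: VolunteerData, j: int, dt: float = 0.05
) -> dict[str, np.ndarray]:
    """Model interval-average deposition rates (mg/h) at the observation
    intervals of volunteer ``j``; matches the derivation applied to the
    measured voids."""
    boundaries = vdata.boundary_times()
    if boundaries.size == 0:
        return {met: np.array([]) for met in METABOLITES}
    glob, loc = p.to_params(j)
    ctx = build_model(Physiology(body_weight=vdata.body_weight), glob, loc)
    cum = cumulative_urine_at(ctx, vdata.doses, boundaries, dt=dt)
    lookup = {round(float(t), 9): i for i, t in enumerate(boundaries)}
    mu = {}
    for met in METABOLITES:
        i0 = [lookup[round(float(t), 9)] for t in vdata.t_start[met]]
        i1 = [lookup[round(float(t), 9)] for t in vdata.t_end[met]]
        c = cum[met]
        mu[met] = (c[i1] - c[i0]) / (vdata.t_end[met] - vdata.t_start[met])
    return mu


def volunteer_log_likelihood(
    mu: dict[str, np.ndarray], vdata: VolunteerData, sigmas: dict[str, float]
) -> float:
    total = 0.0
    for met in METABOLITES:
        total += float(np.sum(truncnorm_logpdf(vdata.rate[met], mu[met], sigmas[met])))
    return total


def log_likelihood(p: ParameterVector, data: CalibrationDataset, dt: float = 0.05) -> float:
    """Joint log-likelihood over volunteers, outputs and observations.

    Returns -inf (with a warning) if the forward model cannot be built
    or solved at ``p``.
    """
    import warnings

    sigmas = {met: p.sigma(met) for met in METABOLITES}
    total = 0.0
    for j, vdata in enumerate(data.volunteers):
        try:
            mu = predicted_rates(p, vdata, j, dt=dt)
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"forward model failed at parameter vector: {err}")
            return -np.inf
        total += volunteer_log_likelihood(mu, vdata, sigmas)
    return total
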