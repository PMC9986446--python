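"""Synthetic volunteer studies with the statistical structure the
calibration assumes.

The generator emulates a controlled single-oral-dose study: ~50 mg
DEHTP to each of three adult male volunteers (body weight 85-95 kg),
20-23 spot urine voids per volunteer over 48 h with 3.5-5.6 L total
urine, and metabolite concentrations produced by the forward model
plus zero-truncated normal noise on the interval-average deposition
rates.  Void times are irregular, denser in waking hours (a modelling
invention — only counts and totals are constrained by the emulated
study design), and lie on the 0.05 h simulation grid.

Default error SDs (mg/h): 5OH 0.0059, 2cx 0.00057, 5cx 0.023 — the
noise scale of real biomonitoring data of this kind.

``reference_truth`` provides a calibrated reference parameter set
(representative posterior medians for three adult volunteers) used as
the default ground truth for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .chem import METABOLITES
from .likelihood import CalibrationDataset, ParameterVector, VolunteerData
from .model import build_model, cumulative_urine_at
from .parameters import DoseEvent, GlobalParams, LocalParams, Physiology
from .priors import GLOBAL_PRIORS, LOCAL_PRIORS, PHYSIO_PRIORS, SENSITIVITY_PRIORS
from .urine import UrineVoid

__all__ = [
    "StudyDesign",
    "TruthRecord",
    "reference_truth",
    "draw_physiology",
    "draw_kinetics",
    "draw_void_schedule",
    "generate_study",
    "REFERENCE_GLOBALS",
    "REFERENCE_LOCALS",
    "REFERENCE_SIGMAS",
]


@dataclass(frozen=True)
class StudyDesign:
    """Design constants of the emulated volunteer study."""

    n_volunteers: int = 3
    dose_mg: float = 52.2
    body_weight_range: tuple[float, float] = (85.0, 95.0)
    void_count_range: tuple[int, int] = (20, 23)
    window_h: float = 48.0
    total_urine_range: tuple[float, float] = (3.62, 5.59)
    noise_sd: dict = field(
        default_factory=lambda: {"5OH": 0.0059, "2cx": 0.00057, "5cx": 0.023}
    )
    dt: float = 0.05
    dose_clock_hour: float = 8.0  # time of day of dosing, for the diurnal pattern

    def __post_init__(self) -> None:
        if self.n_volunteers < 1 or self.window_h <= 0:
            raise ValueError("counts and window must be positive")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth used to generate a synthetic study."""

    physiologies: list[Physiology]
    glob: GlobalParams
    locs: list[LocalParams]
    sigmas: dict[str, float]
    seed: int | None = None

    def parameter_vector(self) -> ParameterVector:
        sig = {"sigma_OH_U": self.sigmas["5OH"], "sigma_2cx_U": self.sigmas["2cx"],
               "sigma_5cx_U": self.sigmas["5cx"]}
        return ParameterVector.from_params(self.glob, self.locs, sig)


# -- calibrated reference set (three adult volunteers) ----------------------

REFERENCE_GLOBALS = GlobalParams(
    fb_dehtp=0.858, fb_mehtp=0.858, dehtp_half_life=2.71,
    dehtp_gut_half_life=33.60, pbab=24.26, pgub=41.50, plib=14.81,
    pbam=37.53, plim=18.64, pgum=12.18, k1_2cx=3.58, k1_moh=2.28,
    k1_5cx=3.91, escape_frac_gu=0.286, escape_frac_li=0.022,
)

REFERENCE_LOCALS = (
    LocalParams(frac_metab_moh=0.052, frac_metab_2cx=0.009, frac_metab_5cx=0.437,
                k1_dehtp_liver=0.554, frac_dose_hep=0.290, bellyperm=6.37,
                giperm1=5.61, giperm2=8.69, gutlag=3.52, frac_dose_lymph=0.058,
                lymphlag=2.55, k1_lymph=1.25, mpy=45.44, mpy_gut=3.35,
                v_bld=0.049, v_li=0.036, v_gu=0.016, v_ki=0.006, q_gu=0.14),
    LocalParams(frac_metab_moh=0.055, frac_metab_2cx=0.011, frac_metab_5cx=0.507,
                k1_dehtp_liver=0.196, frac_dose_hep=0.031, bellyperm=3.01,
                giperm1=2.666, giperm2=14.84, gutlag=2.05, frac_dose_lymph=0.26,
                lymphlag=4.72, k1_lymph=1.46, mpy=46.28, mpy_gut=2.66,
                v_bld=0.05, v_li=0.041, v_gu=0.015, v_ki=0.006, q_gu=0.185),
    LocalParams(frac_metab_moh=0.081, frac_metab_2cx=0.008, frac_metab_5cx=0.314,
                k1_dehtp_liver=1.80, frac_dose_hep=0.142, bellyperm=3.57,
                giperm1=3.63, giperm2=9.01, gutlag=1.94, frac_dose_lymph=0.09,
                lymphlag=3.65, k1_lymph=2.33, mpy=41.18, mpy_gut=3.44,
                v_bld=0.049, v_li=0.039, v_gu=0.014, v_ki=0.006, q_gu=0.168),
)

REFERENCE_BODY_WEIGHTS = (94.0, 85.0, 95.0)
REFERENCE_SIGMAS = {"5OH": 0.0059, "2cx": 0.00057, "5cx": 0.023}


def reference_truth(design: StudyDesign | None = None) -> TruthRecord:
    """The calibrated reference truth for a three-volunteer study."""
    design = design or StudyDesign()
    if design.n_volunteers != 3:
        raise ValueError("the reference truth describes exactly 3 volunteers")
    phys = [Physiology(body_weight=bw) for bw in REFERENCE_BODY_WEIGHTS]
    return TruthRecord(
        physiologies=phys, glob=REFERENCE_GLOBALS,
        locs=list(REFERENCE_LOCALS), sigmas=dict(REFERENCE_SIGMAS),
    )


# ---------------------------------------------------------------------------
# random draws
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_physiology(design: StudyDesign, seed) -> list[Physiology]:
    """Sample per-volunteer physiologies from the population priors.

    Distributions are truncated at their 5th/95th percentiles; body
    weight is additionally rejected into the design range.  Slowly
    perfused tissue balances the vascularised total to 0.95.
    """
    rng = _rng(seed)
    out = []
    pct = lambda name: float(PHYSIO_PRIORS[name].sample(1, rng)[0]) / 100.0
    for _ in range(design.n_volunteers):
        for _attempt in range(1000):
            bw = float(PHYSIO_PRIORS["BW"].sample(1, rng)[0])
            if design.body_weight_range[0] <= bw <= design.body_weight_range[1]:
                break
        else:
            raise RuntimeError("body-weight rejection sampling failed")
        draw = dict(
            body_weight=bw,
            v_li=pct("VLiC"), v_ki=pct("VKiC"), v_fa=pct("VFaC"),
            v_gu=pct("VGuC"), v_st=pct("VStC"), v_rpd=pct("VRpdC"),
            v_bld=pct("VBldC"), qcc=float(PHYSIO_PRIORS["QCC"].sample(1, rng)[0]),
            q_hepart=pct("QHepartC"), q_ki=pct("QKiC"), q_fa=pct("QFaC"),
            q_gu=pct("QGuC"), q_st=pct("QStC"), q_spd=pct("QSpdC"),
            q_rpd=pct("QRpdC"),
        )
        others = sum(draw[k] for k in ("v_li", "v_ki", "v_fa", "v_gu", "v_st", "v_rpd", "v_bld"))
        v_spd = Physiology.MAX_VASCULARISED - others
        if v_spd <= 0.1:
            continue  # anatomically implausible draw; resample volunteer
        out.append(Physiology(v_spd=v_spd, **draw))
    if len(out) < design.n_volunteers:
        raise RuntimeError("physiology sampling failed to produce enough volunteers")
    return out


def draw_kinetics(
    design: StudyDesign, seed, include_fixed: bool = False
) -> tuple[GlobalParams, list[LocalParams]]:
    """Independent draws of the calibrated kinetic parameters.

    The dose-fraction constraint (hepatic + lymphatic <= 1) and the
    tracked-metabolite-fraction cap are enforced by rejection; with
    ``include_fixed`` the baseline-fixed partition coefficients are
    sampled from their uncertainty ranges as well.
    """
    from .likelihood import _G_FIELD, _L_FIELD, GLOBAL_NAMES, LOCAL_NAMES

    rng = _rng(seed)
    gvals = {_G_FIELD[n]: float(GLOBAL_PRIORS[n].sample(1, rng)[0]) for n in GLOBAL_NAMES}
    if include_fixed:
        fixed_field = {
            "Pfab": "pfab", "Pkib": "pkib", "Prbcb": "prbcb", "Pstb": "pstb",
            "Prpdb": "prpdb", "Pspdb": "pspdb", "PfaM": "pfam", "PkiM": "pkim",
            "PrbcM": "prbcm", "PstM": "pstm", "PrpdM": "prpdm", "PspdM": "pspdm",
            "T_half_MEHTP": "t_half_mehtp",
        }
        gvals.update({
            f: float(SENSITIVITY_PRIORS[n].sample(1, rng)[0]) for n, f in fixed_field.items()
        })
    glob = GlobalParams(**gvals)
    locs = []
    rejections = 0
    while len(locs) < design.n_volunteers:
        lvals = {_L_FIELD[n]: float(LOCAL_PRIORS[n].sample(1, rng)[0]) for n in LOCAL_NAMES}
        loc = LocalParams(**lvals)
        try:
            loc.validate()
        except ValueError:
            rejections += 1
            if rejections > 10_000:
                raise RuntimeError("local-parameter rejection sampling stalled")
            continue
        locs.append(loc)
    return glob, locs


def draw_void_schedule(
    design: StudyDesign, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Void times (h since dose, on the dt grid) and volumes (L).

    Times are drawn without replacement from the simulation grid with a
    diurnal weighting (waking hours seven times likelier than night);
    volumes split a total in the design range via a symmetric Dirichlet.
    """
    rng = _rng(seed)
    n = int(rng.integers(design.void_count_range[0], design.void_count_range[1] + 1))
    slots = np.round(np.arange(0.5, design.window_h - 0.25 + 1e-9, design.dt), 10)
    clock = (slots + design.dose_clock_hour) % 24.0
    weights = np.where((clock >= 7.0) & (clock <= 23.0), 1.0, 1.0 / 7.0)
    weights /= weights.sum()
    times = np.sort(rng.choice(slots, size=n, replace=False, p=weights))
    total = rng.uniform(*design.total_urine_range)
    shares = rng.dirichlet(np.full(n, 4.0))
    volumes = np.maximum(shares, 0.02 / total) * total
    volumes *= total / volumes.sum()
    return times, volumes


def generate_study(
    design: StudyDesign,
    truth: TruthRecord | None = None,
    seed: int = 0,
) -> tuple[CalibrationDataset, TruthRecord, dict[str, list[UrineVoid]]]:
    """Forward-simulate a full synthetic study.

    For each volunteer: simulate the forward model under the truth
    parameters, average the urinary deposition rate over each
    inter-void interval, add zero-truncated normal noise with the
    design SDs, and convert back to void concentrations
    (rate x interval / volume).  Round-tripping the resulting voids
    through the rate derivation reproduces the noisy rates (up to
    floating-point arithmetic).
    """
    rng = _rng(seed)
    truth = truth or reference_truth(design)
    dataset_volunteers = []
    voids_by_volunteer: dict[str, list[UrineVoid]] = {}
    for j in range(design.n_volunteers):
        phys, loc = truth.physiologies[j], truth.locs[j]
        ctx = build_model(phys, truth.glob, loc)
        times, volumes = draw_void_schedule(design, rng)
        boundaries = np.concatenate([[0.0], times])
        cum = cumulative_urine_at(ctx, [DoseEvent(0.0, design.dose_mg)], boundaries, dt=design.dt)
        name = f"V{j + 1}"
        voids = []
        for i, (t, vol) in enumerate(zip(times, volumes)):
            dt_i = boundaries[i + 1] - boundaries[i]
            conc = {}
            for met in METABOLITES:
                mu = (cum[met][i + 1] - cum[met][i]) / dt_i
                sd = design.noise_sd[met]
                if sd > 0:
                    a = -mu / sd  # truncate at zero
                    rate = float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))
                else:
                    rate = float(mu)
                conc[met] = rate * dt_i / vol
            voids.append(UrineVoid(volunteer=name, time=float(t), volume=float(vol), concentration=conc))
        voids_by_volunteer[name] = voids
        dataset_volunteers.append(
            VolunteerData.from_voids(voids, dose_mg=design.dose_mg, body_weight=phys.body_weight)
        )
    return CalibrationDataset(dataset_volunteers), truth, voids_by_volunteer
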