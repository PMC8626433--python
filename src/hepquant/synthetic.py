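"""Synthetic cohorts and digital MR phantoms.

Two independent test surfaces for the pipeline:

* ``simulate_cohort`` draws per-lesion reduction rates directly from
  grade-conditional truncated normal distributions (defaults matching the
  reference cohort: G1 0.40 +/- 0.15, G2 0.26 +/- 0.07, G3 0.25 +/- 0.07,
  upper-truncated at 1), plus immunohistochemistry reads and log-normal
  lesion volumes, emitting tables with the reference cohort's column
  structure.

* ``simulate_phantom`` builds 3D flip-angle volumes by evaluating the SPGR
  forward model voxelwise on a piecewise-constant T1 ground truth (liver
  background with spherical lesions, separate native and hepatobiliary
  T1s), under a smooth multiplicative B1 field, with optional Gaussian or
  Rician acquisition noise — exercising the full fit/segment/quantify path.

All randomness flows through explicit integer seeds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .cohort import EligibilityFlags, LesionRecord
from .relaxometry import AcquisitionParams, B1Map, FlipAngleVolume, T1Map, spgr_signal
from .segmentation import VolumeMask

__all__ = [
    "GradeRR",
    "CohortModel",
    "LesionSpec",
    "PhantomSpec",
    "Phantom",
    "simulate_cohort",
    "simulate_phantom",
    "simulate_screening",
]

#: grade-conditional reduction-rate parameters of the reference cohort
DEFAULT_RR = {"G1": (0.40, 0.15), "G2": (0.26, 0.07), "G3": (0.25, 0.07)}

#: grade-conditional IRS-category frequencies of the reference cohort
DEFAULT_IRS_PROBS = {
    "G1": {"negative": 3 / 14, "low": 4 / 14, "medium": 5 / 14, "high": 2 / 14},
    "G2": {"negative": 8 / 14, "low": 4 / 14, "medium": 2 / 14, "high": 0.0},
    "G3": {"negative": 1.0, "low": 0.0, "medium": 0.0, "high": 0.0},
}

#: reference-cohort lesion volume mean/SD in cm3 (log-normal is fit to these)
DEFAULT_VOLUME_MEAN_SD = (170.94, 212.82)

#: (percent_score, intensity_score) pairs compatible with each IRS category
_CATEGORY_PAIRS = {
    "negative": [(0, 0), (1, 0), (2, 0), (0, 1), (0, 2), (0, 3)],
    "low": [(1, 1), (1, 2), (1, 3), (2, 1), (3, 1)],
    "medium": [(2, 2), (2, 3), (3, 2), (4, 1), (4, 2)],
    "high": [(3, 3), (4, 3)],
}
#: representative positive-cell fraction for each percent score
_SCORE_FRACTION = {0: 0.0, 1: 0.05, 2: 0.30, 3: 0.65, 4: 0.90}
_SCORE_LABEL = {0: "absent", 1: "weak", 2: "moderate", 3: "strong"}


@dataclass(frozen=True)
class GradeRR:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class CohortModel:
    """Generative model for a grade-labelled lesion cohort."""

    rr_params: dict[str, GradeRR] = field(
        default_factory=lambda: {g: GradeRR(*p) for g, p in DEFAULT_RR.items()}
    )
    irs_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_IRS_PROBS.items()}
    )
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"G1": 14, "G2": 14, "G3": 5}
    )
    volume_mean_sd: tuple[float, float] = DEFAULT_VOLUME_MEAN_SD

    def __post_init__(self) -> None:
        for g, probs in self.irs_probs.items():
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"IRS category probabilities for {g} sum to {total}")
            if any(p < 0 for p in probs.values()):
                raise ValueError("category probabilities must be >= 0")


def _draw_rr(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Reduction rates from a normal truncated above at 1 (RR <= 1 by
    construction of the statistic)."""
    if sd == 0:
        return np.full(size, mean)
    upper = (1.0 - mean) / sd
    return sps.truncnorm.rvs(-np.inf, upper, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_cohort(model: CohortModel, seed: int) -> tuple[list[LesionRecord], dict]:
    """Draw a cohort; returns the records and the generating ground truth.

    Deterministic for a fixed seed. Growth pattern is drawn with the
    reference cohort's marginal frequencies, independent of grade.
    """
    rng = np.random.default_rng(seed)
    mu_v, sig_v = _lognormal_params(*model.volume_mean_sd)
    records: list[LesionRecord] = []
    truth: dict = {"rr_by_grade": {}, "seed": seed}
    lesion_id = 1
    for grade in sorted(model.group_sizes):
        n = model.group_sizes[grade]
        if n <= 0:
            continue
        pars = model.rr_params[grade]
        rr = _draw_rr(rng, pars.mean, pars.sd, n)
        truth["rr_by_grade"][grade] = rr.tolist()
        cats = list(model.irs_probs[grade])
        probs = np.array([model.irs_probs[grade][c] for c in cats])
        drawn_cats = rng.choice(cats, size=n, p=probs)
        volumes = np.exp(rng.normal(mu_v, sig_v, size=n))
        growth = rng.choice(
            ["conventional", "macrotrabecular", "scirrhous", "steatohepatitic"],
            size=n,
            p=[27 / 33, 2 / 33, 1 / 33, 3 / 33],
        )
        ishak = rng.integers(0, 7, size=n)
        for i in range(n):
            pairs = _CATEGORY_PAIRS[drawn_cats[i]]
            ps, intensity = pairs[rng.integers(len(pairs))]
            records.append(
                LesionRecord(
                    lesion_id=lesion_id,
                    grade=grade,
                    pct_positive=_SCORE_FRACTION[ps],
                    intensity_label=_SCORE_LABEL[intensity],
                    reduction_rate=float(rr[i]),
                    growth_pattern=str(growth[i]),
                    volume_cm3=float(volumes[i]),
                    ishak=int(ishak[i]),
                )
            )
            lesion_id += 1
    return records, truth


# --------------------------------------------------------------------------
# digital phantom

@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: center in mm, radius in mm, per-phase T1 in ms."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    t1_plain_ms: float = 950.2
    t1_hbp_ms: float = 555.4


@dataclass
class PhantomSpec:
    """Piecewise-constant liver phantom under the reference SPGR protocol.

    Defaults: background-liver T1 720.7 ms native / 332.7 ms hepatobiliary;
    grid at the acquisition's interpolated resolution; B1 a smooth separable
    quadratic scaled into ``b1_range``; Gaussian magnitude noise of
    ``noise_sd`` (0 = noiseless; ``noise_model="rician"`` available).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 16)
    spacing_mm: tuple[float, float, float] = (1.3, 1.3, 3.0)
    liver_t1_plain_ms: float = 720.7
    liver_t1_hbp_ms: float = 332.7
    lesions: tuple[LesionSpec, ...] = ()
    b1_range: tuple[float, float] = (1.0, 1.0)
    noise_model: str = "gaussian"
    noise_sd: float = 0.0
    m0: float = 1000.0
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        extent = np.array(self.grid_shape) * np.array(self.spacing_mm)
        for les in self.lesions:
            c = np.array(les.center_mm)
            if np.any(c - les.radius_mm < 0) or np.any(c + les.radius_mm > extent):
                raise ValueError(f"lesion at {les.center_mm} extends outside the grid")
            if les.t1_plain_ms <= 0 or les.t1_hbp_ms <= 0:
                raise ValueError("lesion T1 values must be > 0")


@dataclass
class Phantom:
    """Simulated acquisition plus its generating ground truth."""

    plain_volumes: list[FlipAngleVolume]
    hbp_volumes: list[FlipAngleVolume]
    b1: B1Map
    truth_plain: T1Map
    truth_hbp: T1Map
    lesion_masks: list[VolumeMask]


def _smooth_b1(shape: tuple[int, int, int], lo: float, hi: float) -> np.ndarray:
    """Separable quadratic bump scaled into [lo, hi]: highest at the grid
    center, mimicking transmit-field smoothness."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    bump = (1 - gx**2 / 2) * (1 - gy**2 / 2) * (1 - gz**2 / 2)
    if hi == lo:
        return np.full(shape, lo)
    b = bump - bump.min()
    return lo + (hi - lo) * b / b.max()


def _voxel_centers(shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xs = (np.arange(shape[0]) + 0.5) * spacing[0]
    ys = (np.arange(shape[1]) + 0.5) * spacing[1]
    zs = (np.arange(shape[2]) + 0.5) * spacing[2]
    return np.meshgrid(xs, ys, zs, indexing="ij")


def simulate_phantom(spec: PhantomSpec, seed: int) -> Phantom:
    """Forward-simulate the two-phase VFA acquisition of a phantom."""
    rng = np.random.default_rng(seed)
    gx, gy, gz = _voxel_centers(spec.grid_shape, spec.spacing_mm)
    t1_plain = np.full(spec.grid_shape, spec.liver_t1_plain_ms)
    t1_hbp = np.full(spec.grid_shape, spec.liver_t1_hbp_ms)
    masks = []
    for les in spec.lesions:
        cx, cy, cz = les.center_mm
        inside = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= les.radius_mm**2
        t1_plain[inside] = les.t1_plain_ms
        t1_hbp[inside] = les.t1_hbp_ms
        masks.append(VolumeMask(inside, spec.spacing_mm))
    b1 = _smooth_b1(spec.grid_shape, *spec.b1_range)

    def acquire(t1_grid: np.ndarray) -> list[FlipAngleVolume]:
        vols = []
        for angle in spec.acquisition.flip_deg:
            sig = spgr_signal(spec.m0, t1_grid, spec.acquisition, angle, b1)
            if spec.noise_sd > 0:
                if spec.noise_model == "gaussian":
                    sig = sig + rng.normal(0.0, spec.noise_sd, size=sig.shape)
                else:  # rician: magnitude of complex signal + noise
                    re = sig + rng.normal(0.0, spec.noise_sd, size=sig.shape)
                    im = rng.normal(0.0, spec.noise_sd, size=sig.shape)
                    sig = np.hypot(re, im)
            vols.append(FlipAngleVolume(sig, spec.spacing_mm, angle))
        return vols

    return Phantom(
        plain_volumes=acquire(t1_plain),
        hbp_volumes=acquire(t1_hbp),
        b1=B1Map(b1),
        truth_plain=T1Map(t1_plain, spec.spacing_mm),
        truth_hbp=T1Map(t1_hbp, spec.spacing_mm),
        lesion_masks=masks,
    )


def simulate_screening(seed: int = 0) -> tuple[list[LesionRecord], list[EligibilityFlags]]:
    """A 56-lesion screening population with the study's per-reason
    exclusion counts (sub-cm 6, infiltrative 1, mixed 3, pretreated 1,
    repeat MRI 2, technical 10), leaving 33 eligible lesions.

    Per-lesion exclusion reasons are synthetic: the study reports only the
    counts. The 33 eligible lesions carry the reference cohort's values.
    """
    from .cohort import reference_cohort

    eligible = reference_cohort()
    reasons = (
        ["sub_cm"] * 6 + ["infiltrative"] * 1 + ["mixed_tumor"] * 3
        + ["pretreated"] * 1 + ["repeat_mri"] * 2 + ["technical_error"] * 10
    )
    rng = np.random.default_rng(seed)
    records = list(eligible)
    flags = [EligibilityFlags(lesion_id=r.lesion_id) for r in eligible]
    next_id = max(r.lesion_id for r in eligible) + 1
    for reason in reasons:
        grade = str(rng.choice(["G1", "G2", "G3"]))
        records.append(
            LesionRecord(
                lesion_id=next_id,
                grade=grade,
                pct_positive=float(np.round(rng.uniform(0, 0.9), 2)),
                intensity_label=str(rng.choice(["absent", "weak", "moderate", "strong"])),
                reduction_rate=float(np.round(rng.uniform(0.1, 0.7), 2)),
                growth_pattern="conventional",
                volume_cm3=float(np.round(rng.uniform(0.5, 500.0), 1)),
                ishak=int(rng.integers(0, 7)),
            )
        )
        flags.append(EligibilityFlags(lesion_id=next_id, **{reason: True}))
        next_id += 1
    return records, flags
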