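"""Variable-flip-angle (VFA / DESPOT1) T1 relaxometry.

A spoiled-gradient-echo (SPGR) acquisition at steady state gives, for a
nominal flip angle ``alpha`` scaled by the relative transmit field ``b1``:

    S = M0 * sin(b1*alpha) * (1 - E1) / (1 - E1 * cos(b1*alpha)),
    E1 = exp(-TR / T1)

Acquiring the same volume at several flip angles lets T1 be recovered per
voxel by the classical DESPOT1 linearization: plotting ``S/sin`` against
``S/tan`` of the effective angle is a line of slope E1, so
``T1 = -TR / ln(slope)``. A measured B1 map corrects the nominal angles
voxelwise, which is what keeps the fit accurate away from the coil center.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionParams",
    "FlipAngleVolume",
    "B1Map",
    "T1Map",
    "spgr_signal",
    "fit_t1_despot1",
    "fit_t1_map",
    "save_volume",
    "load_volume",
]

#: protocol of the reference acquisition: 3D SPGR, TR 5.79 ms, flips 1/7/14 deg
DEFAULT_TR_MS = 5.79
DEFAULT_FLIPS_DEG = (1.0, 7.0, 14.0)
DEFAULT_TE_MS = (2.46, 3.69)


@dataclass(frozen=True)
class AcquisitionParams:
    """SPGR protocol parameters. Angles are degrees at the interface; echo
    times are carried as metadata and unused by the fit."""

    tr_ms: float = DEFAULT_TR_MS
    flip_deg: tuple[float, ...] = DEFAULT_FLIPS_DEG
    te_ms: tuple[float, ...] = DEFAULT_TE_MS

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be > 0, got {self.tr_ms}")
        if len(set(self.flip_deg)) < 2:
            raise ValueError("need at least 2 distinct flip angles")
        for a in self.flip_deg:
            if not 0.0 < a <= 90.0:
                raise ValueError(f"flip angles must lie in (0, 90] deg, got {a}")

    @property
    def flip_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.flip_deg, dtype=float))


@dataclass
class FlipAngleVolume:
    """One 3D magnitude volume acquired at a single nominal flip angle."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    flip_deg: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")


@dataclass
class B1Map:
    """Relative transmit-field map; 1.0 means the nominal flip angle."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if np.any(self.voxels <= 0) or np.any(self.voxels >= 2):
            raise ValueError("B1 factors must lie in (0, 2)")


@dataclass
class T1Map:
    """Voxelwise T1 in ms; voxels where the fit failed are NaN."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    n_invalid: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        valid = self.voxels[np.isfinite(self.voxels)]
        if valid.size and np.any(valid <= 0):
            raise ValueError("valid T1 voxels must be strictly positive")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.voxels)


def spgr_signal(
    m0: float | np.ndarray,
    t1_ms: float | np.ndarray,
    params: AcquisitionParams,
    flip_deg: float,
    b1_rel: float | np.ndarray = 1.0,
) -> float | np.ndarray:
    """Steady-state SPGR signal magnitude at one nominal flip angle.

    ``b1_rel`` scales the nominal angle to the effective one. Broadcasts over
    array-valued ``m0``, ``t1_ms`` and ``b1_rel``.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be strictly positive")
    b1 = np.asarray(b1_rel, dtype=float)
    if np.any(b1 <= 0):
        raise ValueError("b1_rel must be strictly positive")
    alpha = np.deg2rad(flip_deg) * b1
    e1 = np.exp(-params.tr_ms / t1)
    sig = np.asarray(m0, dtype=float) * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))
    return float(sig) if np.ndim(sig) == 0 else sig


def fit_t1_despot1(
    signals: np.ndarray,
    params: AcquisitionParams,
    b1_rel: float = 1.0,
) -> tuple[float, float]:
    """DESPOT1 linearized T1/M0 fit at a single voxel.

    Regresses ``S/sin(alpha_eff)`` on ``S/tan(alpha_eff)``; the slope is E1
    and the intercept M0*(1-E1). Returns ``(nan, nan)`` — the invalid-result
    marker — when the signals carry no information (all non-positive) or the
    fitted slope falls outside (0, 1), where no positive T1 exists.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape != (len(params.flip_deg),):
        raise ValueError(
            f"expected {len(params.flip_deg)} signals, got shape {s.shape}"
        )
    if b1_rel <= 0:
        raise ValueError("b1_rel must be strictly positive")
    alpha = params.flip_rad * b1_rel
    if len(np.unique(alpha)) < 2:
        raise ValueError("degenerate design: effective flip angles coincide")
    if not np.any(s > 0):
        return (float("nan"), float("nan"))
    x = s / np.tan(alpha)
    y = s / np.sin(alpha)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    denom = n * (x * x).sum() - sx * sx
    if denom == 0:
        return (float("nan"), float("nan"))
    slope = (n * (x * y).sum() - sx * sy) / denom
    if not 0.0 < slope < 1.0:
        return (float("nan"), float("nan"))
    intercept = (sy - slope * sx) / n
    t1 = -params.tr_ms / np.log(slope)
    m0 = intercept / (1.0 - slope)
    if not (np.isfinite(t1) and t1 > 0):
        return (float("nan"), float("nan"))
    return (float(t1), float(m0))


def fit_t1_map(
    volumes: list[FlipAngleVolume],
    b1: B1Map | None,
    params: AcquisitionParams,
) -> T1Map:
    """Voxelwise DESPOT1 fit of a set of flip-angle volumes with B1 correction.

    ``b1=None`` fits with the nominal angles (no correction). Voxels whose
    linearized slope falls outside (0, 1), or with no positive signal, are
    marked NaN; their count is stored on the returned map.
    """
    if len(volumes) != len(params.flip_deg):
        raise ValueError("one volume per protocol flip angle is required")
    vol_by_angle = {v.flip_deg: v for v in volumes}
    if set(vol_by_angle) != set(params.flip_deg):
        raise ValueError(
            f"volume flip angles {sorted(vol_by_angle)} do not match protocol "
            f"{sorted(params.flip_deg)}"
        )
    shape = volumes[0].voxels.shape
    spacing = volumes[0].spacing_mm
    for v in volumes:
        if v.voxels.shape != shape or v.spacing_mm != spacing:
            raise ValueError("flip-angle volumes must share grid shape and spacing")
    if b1 is not None and b1.voxels.shape != shape:
        raise ValueError("B1 map grid does not match the flip-angle volumes")

    b1_flat = np.ones(np.prod(shape)) if b1 is None else b1.voxels.reshape(-1)
    sig = np.stack(
        [vol_by_angle[a].voxels.reshape(-1) for a in params.flip_deg]
    )  # (n_flip, n_vox)
    alpha = params.flip_rad[:, None] * b1_flat[None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        x = sig / np.tan(alpha)
        y = sig / np.sin(alpha)
        n = sig.shape[0]
        sx, sy = x.sum(axis=0), y.sum(axis=0)
        denom = n * (x * x).sum(axis=0) - sx * sx
        slope = np.where(denom != 0, (n * (x * y).sum(axis=0) - sx * sy) / denom, np.nan)
        t1 = np.where((slope > 0) & (slope < 1), -params.tr_ms / np.log(slope), np.nan)
    t1[~np.any(sig > 0, axis=0)] = np.nan
    t1[~np.isfinite(t1) | (t1 <= 0)] = np.nan
    n_invalid = int(np.sum(~np.isfinite(t1)))
    return T1Map(t1.reshape(shape), spacing, n_invalid=n_invalid)


def save_volume(voxels: np.ndarray, spacing_mm: tuple[float, float, float], path: str | Path) -> None:
    """Write a 3D array as NIfTI with a diagonal affine built from spacing."""
    affine = np.diag([*spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(voxels, dtype=np.float64), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume, returning the array and its voxel spacing in mm."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), spacing
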