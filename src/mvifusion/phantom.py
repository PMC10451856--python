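"""Synthetic four-phase liver MRI phantoms with planted MVI-correlated signal.

Each phantom patient is a roughly ellipsoidal "tumor" embedded in a uniform
liver-like background, imaged in four contrast phases (pre-contrast ``PreP``,
arterial ``AP``, portal ``PP``, hepatobiliary ``HBP``) that share one
coordinate frame.  MVI-positive cases carry the radiological correlates of
microvascular invasion:

* an irregular (lobulated) tumor margin in every phase, produced by a smooth
  band-limited radial perturbation of the tumor surface;
* a peritumoral hyperintense ring in the arterial phase;
* a peritumoral hypointense ring in the hepatobiliary phase.

All effect sizes are tunable through :class:`PhantomConfig`, so downstream
models can be exercised at any signal-to-noise level without real patient
data.
"""

from __future__ import annotations

import dataclasses
import math
import os
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

PHASES = ("PreP", "AP", "PP", "HBP")

# Piecewise-constant intensity model (arbitrary units).  Background imitates
# liver parenchyma: brightest in HBP (hepatocyte gadoxetate uptake); tumor is
# hyperintense in AP (arterial enhancement), washes out in PP and is
# hypointense in HBP.
BACKGROUND_MEAN: Mapping[str, float] = {"PreP": 100.0, "AP": 120.0, "PP": 130.0, "HBP": 150.0}
TUMOR_MEAN: Mapping[str, float] = {"PreP": 85.0, "AP": 150.0, "PP": 112.0, "HBP": 100.0}


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic cohort.

    Defaults are chosen so that the four-phase fusion task is learnable while
    each single phase alone is informative but imperfect: the margin
    irregularity is visible in every phase, the arterial ring only in AP and
    the (stronger) hypointense ring only in HBP.
    """

    n_patients: int = 120
    mvi_fraction: float = 1.0 / 3.0
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    tumor_radius_range: tuple[float, float] = (8.0, 13.0)
    margin_irregularity_amp: float = 2.5
    ap_ring_contrast: float = 40.0
    hbp_ring_contrast: float = 50.0
    ring_thickness: int = 2
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not (0.0 <= self.mvi_fraction <= 1.0):
            raise ValueError("mvi_fraction must lie in [0, 1]")
        for name in ("margin_irregularity_amp", "ap_ring_contrast", "hbp_ring_contrast", "noise_sd"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if min(self.volume_shape) < 48:
            raise ValueError("volume_shape must be at least 48 voxels per axis")
        if self.tumor_radius_range[0] > self.tumor_radius_range[1] or self.tumor_radius_range[0] <= 0:
            raise ValueError("tumor_radius_range must be a positive, ordered interval")

    @property
    def n_positive(self) -> int:
        return int(round(self.mvi_fraction * self.n_patients))


@dataclasses.dataclass
class MultiPhaseStudy:
    """Four co-registered phase volumes, one tumor mask and the MVI label."""

    patient_id: str
    volumes: dict[str, np.ndarray]
    mask: np.ndarray
    mvi_label: int

    def validate(self) -> None:
        shape = self.mask.shape
        for phase in PHASES:
            if self.volumes[phase].shape != shape:
                raise ValueError(f"phase {phase} shape {self.volumes[phase].shape} != mask shape {shape}")
        if not self.mask.any():
            raise ValueError("mask has no foreground voxels")
        _, n_comp = ndimage.label(self.mask)
        if n_comp != 1:
            raise ValueError(f"mask foreground has {n_comp} connected components, expected 1")


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    # Counter-based (Philox) stream keyed by (seed, patient index): studies are
    # reproducible independently of generation order.
    return np.random.Generator(np.random.Philox(key=[np.uint64(seed), np.uint64(patient_index + 1)]))


def _cohort_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[np.uint64(seed), np.uint64(0)]))


def _real_sph_harm_basis(theta: np.ndarray, phi: np.ndarray, l_max: int) -> np.ndarray:
    """Real spherical harmonics Y_lm(theta, phi) for l = 1..l_max, stacked.

    theta is the polar angle (from +z), phi the azimuth.  The l=0 term is
    omitted so the perturbation has zero mean radius change to first order.
    """
    from scipy.special import sph_harm_y

    rows = []
    for ell in range(1, l_max + 1):
        for m in range(-ell, ell + 1):
            y = sph_harm_y(ell, abs(m), theta, phi)
            if m < 0:
                rows.append(math.sqrt(2.0) * (-1.0) ** m * y.imag)
            elif m == 0:
                rows.append(y.real)
            else:
                rows.append(math.sqrt(2.0) * (-1.0) ** m * y.real)
    return np.stack(rows, axis=0)


_L_MAX = 3  # band limit of the margin perturbation: smooth lobulation, no fragmentation


def generate_study(config: PhantomConfig, patient_index: int, mvi_label: int) -> MultiPhaseStudy:
    """Generate one four-phase study.

    Deterministic for fixed ``(config.seed, patient_index)``.  The tumor is an
    ellipsoid with radii drawn from ``tumor_radius_range``; for MVI-positive
    cases the surface radius is perturbed by a band-limited random spherical
    field of amplitude ``margin_irregularity_amp`` (in voxels) and peritumoral
    rings are planted in AP (+) and HBP (-).
    """
    if not (0 <= patient_index < max(config.n_patients, patient_index + 1)):
        raise ValueError("patient_index must be >= 0")
    rng = _patient_rng(config.seed, patient_index)
    shape = np.asarray(config.volume_shape, dtype=int)

    radii = rng.uniform(*config.tumor_radius_range, size=3)
    amp = config.margin_irregularity_amp if mvi_label == 1 else 0.0
    # clearance: perturbed surface + ring + 2-voxel bbox margin must fit
    clearance = float(radii.max()) + amp + config.ring_thickness + 3.0
    lo = np.ceil(clearance)
    hi = shape - 1 - np.ceil(clearance)
    if np.any(hi < lo):
        raise ValueError(
            f"tumor with radii {np.round(radii, 2).tolist()} plus ring does not fit in volume {tuple(shape)}"
        )
    center = rng.uniform(lo, hi)

    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    d = np.stack([zz - center[0], yy - center[1], xx - center[2]])
    rho = np.sqrt((d**2).sum(axis=0))
    rho_safe = np.where(rho == 0, 1.0, rho)
    u = d / rho_safe  # unit directions

    # ellipsoid radius along each voxel's direction
    r_ell = 1.0 / np.sqrt((u[0] / radii[0]) ** 2 + (u[1] / radii[1]) ** 2 + (u[2] / radii[2]) ** 2)

    # draw perturbation coefficients unconditionally to keep the stream aligned
    n_coef = (_L_MAX + 1) ** 2 - 1
    coef = rng.standard_normal(n_coef)
    if amp > 0:
        theta = np.arccos(np.clip(u[0], -1.0, 1.0))
        phi = np.arctan2(u[2], u[1])
        basis = _real_sph_harm_basis(theta, phi, _L_MAX)
        # orthonormal harmonics: with unit-norm coefficients the field has RMS
        # 1/sqrt(4*pi) over the sphere, so rescale to unit RMS
        field = np.tensordot(coef / np.linalg.norm(coef), basis, axes=1) * math.sqrt(4.0 * math.pi)
        r_surface = r_ell + amp * field
    else:
        r_surface = r_ell
    mask = rho <= r_surface

    # peritumoral shell: Euclidean distance outside the mask
    shell = peritumoral_shell(mask, config.ring_thickness)

    volumes: dict[str, np.ndarray] = {}
    for phase in PHASES:
        vol = np.full(tuple(shape), BACKGROUND_MEAN[phase], dtype=np.float64)
        vol[mask] = TUMOR_MEAN[phase]
        if mvi_label == 1:
            if phase == "AP":
                vol[shell] += config.ap_ring_contrast
            elif phase == "HBP":
                vol[shell] -= config.hbp_ring_contrast
        if config.noise_sd > 0:
            vol += rng.normal(0.0, config.noise_sd, size=vol.shape)
        volumes[phase] = vol

    study = MultiPhaseStudy(
        patient_id=f"P{patient_index:04d}",
        volumes=volumes,
        mask=mask.astype(np.uint8),
        mvi_label=int(mvi_label),
    )
    study.validate()
    return study


def peritumoral_shell(mask: np.ndarray, thickness: int) -> np.ndarray:
    """Voxels outside the mask within Euclidean distance ``thickness`` of it."""
    dist = ndimage.distance_transform_edt(~mask.astype(bool))
    return (dist > 0) & (dist <= thickness)


def cohort_labels(config: PhantomConfig) -> np.ndarray:
    """MVI labels for the cohort: exactly round(mvi_fraction * n) positives, shuffled."""
    n_pos = config.n_positive
    labels = np.zeros(config.n_patients, dtype=int)
    labels[:n_pos] = 1
    _cohort_rng(config.seed).shuffle(labels)
    return labels


def generate_cohort(config: PhantomConfig, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Generate and write a full cohort; returns the roster table.

    One ``.nii.gz`` file per phase per patient plus one mask file, and a
    ``roster.csv`` with columns
    ``patient_id,mvi_label,prep_path,ap_path,pp_path,hbp_path,mask_path``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = cohort_labels(config)
    affine = np.eye(4)  # isotropic unit spacing
    rows = []
    for i, label in enumerate(labels):
        study = generate_study(config, i, int(label))
        row: dict[str, object] = {"patient_id": study.patient_id, "mvi_label": study.mvi_label}
        for phase in PHASES:
            path = out / f"{study.patient_id}_{phase}.nii.gz"
            nib.save(nib.Nifti1Image(study.volumes[phase].astype(np.float32), affine), path)
            row[f"{phase.lower()}_path"] = str(path)
        mask_path = out / f"{study.patient_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(study.mask.astype(np.uint8), affine), mask_path)
        row["mask_path"] = str(mask_path)
        rows.append(row)
    roster = pd.DataFrame(
        rows, columns=["patient_id", "mvi_label", "prep_path", "ap_path", "pp_path", "hbp_path", "mask_path"]
    )
    roster.to_csv(out / "roster.csv", index=False)
    return roster


def load_study(roster_row: Mapping[str, object]) -> MultiPhaseStudy:
    """Load one patient's study from roster file paths."""
    volumes = {
        phase: np.asarray(nib.load(str(roster_row[f"{phase.lower()}_path"])).dataobj, dtype=np.float64)
        for phase in PHASES
    }
    mask = np.asarray(nib.load(str(roster_row["mask_path"])).dataobj).astype(np.uint8)
    study = MultiPhaseStudy(
        patient_id=str(roster_row["patient_id"]),
        volumes=volumes,
        mask=mask,
        mvi_label=int(roster_row["mvi_label"]),  # type: ignore[arg-type]
    )
    study.validate()
    return study
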