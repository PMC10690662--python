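"""Synthetic paired T1w/PET brain phantoms.

Every downstream stage (preprocessing, MRI->PET translation, subtraction,
cluster detection, region scoring) is exercised on these phantoms, so the
whole pipeline is testable without any external data.

The phantom is an ellipsoidal "brain" with three concentric tissue shells
(CSF, grey matter, white matter, plus a CSF ventricle core).  The T1w and
PET volumes share this geometry exactly; each tissue class has its own mean
intensity in each modality, so the PET is a deterministic function of the
T1w tissue map in the noiseless limit -- the property an MRI->PET model is
expected to learn.  Gaussian voxel noise is added before smoothing, so the
PET noise is spatially correlated, as PSF-limited PET noise is.

A toy atlas of 18 bilateral regions (36 labels) is built by geometric
sectoring: hemispheres split on the world x coordinate, 18 lobe-like sectors
from the angular position within the ellipsoid.  It carries no anatomical
meaning; it exists so that label bookkeeping and cluster/region overlap
logic can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import BrainMask, Volume3D, gaussian_smooth, write_mask, write_volume
from .regions import REGION_CODES

__all__ = [
    "TissueIntensity",
    "PhantomSpec",
    "LesionSpec",
    "PhantomStudy",
    "generate_phantom",
    "inject_lesion",
    "lesion_mask",
    "write_phantom",
]

# tissue-class ids in the tissue map
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3


@dataclass(frozen=True)
class TissueIntensity:
    """Mean intensities (arbitrary units in [0, 1]) for one tissue class."""

    t1w: float
    pet: float

    def __post_init__(self) -> None:
        for v in (self.t1w, self.pet):
            if not 0.0 <= v <= 1.0:
                raise ValueError("tissue intensities must lie in [0, 1]")


#: Default per-class means.  T1w: WM bright, CSF dark.  PET: GM brightest
#: (cortical FDG uptake), WM intermediate, CSF near zero.
DEFAULT_TISSUES: dict[int, TissueIntensity] = {
    CSF: TissueIntensity(t1w=0.10, pet=0.05),
    GM: TissueIntensity(t1w=0.50, pet=0.90),
    WM: TissueIntensity(t1w=0.85, pet=0.35),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject.

    The output pair is a pure function of the spec (seed included): the same
    spec yields bit-identical volumes.

    Parameters
    ----------
    shape
        Grid size in voxels per axis.
    voxel_size_mm
        Isotropic voxel edge in mm.
    semi_axes_mm
        Brain ellipsoid semi-axes (a, b, c) in mm.
    tissues
        Per-class mean T1w/PET intensity, both scaled to [0, 1].
    noise_sd
        Standard deviation of additive Gaussian voxel noise, as a fraction
        of the [0, 1] intensity range.
    smooth_fwhm_mm
        FWHM of the Gaussian applied to the noisy PET (point-spread proxy).
    seed
        Seed for anatomy-linked noise.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    semi_axes_mm: tuple[float, float, float] = (50.0, 60.0, 50.0)
    tissues: dict[int, TissueIntensity] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )
    noise_sd: float = 0.02
    smooth_fwhm_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("grid shape must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """A focal hypometabolic lesion, the synthetic stand-in for the
    epileptogenic zone.

    PET intensity inside the lesion is multiplied by ``factor`` in (0, 1)
    (reduced uptake); ``softness_mm`` Gaussian-feathers the edge.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    factor: float = 0.7
    softness_mm: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.factor <= 1.0:
            raise ValueError("lesion factor must lie in (0, 1]")
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.softness_mm < 0:
            raise ValueError("edge softness must be >= 0")


@dataclass
class PhantomStudy:
    """One synthetic subject: paired volumes, mask, atlas, label table."""

    t1w: Volume3D
    pet: Volume3D
    mask: BrainMask
    atlas: Volume3D  # integer labels, 0 = background
    labels: pd.DataFrame  # label_id, region_code, hemisphere
    tissue_map: Volume3D  # integer tissue classes


def _affine(spec: PhantomSpec) -> np.ndarray:
    """Voxel->world affine centred on the grid, isotropic voxels."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spec.voxel_size_mm
    center = (np.array(spec.shape) - 1) / 2.0 * spec.voxel_size_mm
    aff[:3, 3] = -center
    return aff


def _world_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    aff = _affine(spec)
    axes = [
        np.arange(n) * spec.voxel_size_mm + aff[i, 3]
        for i, n in enumerate(spec.shape)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _tissue_map(spec: PhantomSpec) -> np.ndarray:
    """Concentric tissue shells inside the brain ellipsoid.

    Normalized ellipsoidal radius rho = sqrt(sum (x_i/a_i)^2):
    rho <= 0.18 ventricular CSF, <= 0.62 WM, <= 0.88 GM, <= 1 outer CSF.
    """
    x, y, z = _world_coords(spec)
    a, b, c = spec.semi_axes_mm
    half_extent = (np.array(spec.shape)) * spec.voxel_size_mm / 2.0
    if a > half_extent[0] or b > half_extent[1] or c > half_extent[2]:
        raise ValueError(
            f"brain ellipsoid (semi-axes {spec.semi_axes_mm} mm) does not fit "
            f"in the grid ({spec.shape} voxels at {spec.voxel_size_mm} mm)"
        )
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    tissue = np.full(spec.shape, BACKGROUND, dtype=np.int16)
    tissue[rho <= 1.0] = CSF
    tissue[rho <= 0.88] = GM
    tissue[rho <= 0.62] = WM
    tissue[rho <= 0.18] = CSF  # ventricles
    return tissue


def _fill_intensities(
    tissue: np.ndarray, spec: PhantomSpec, modality: str
) -> np.ndarray:
    out = np.zeros(tissue.shape, dtype=np.float64)
    for cls, ti in spec.tissues.items():
        out[tissue == cls] = ti.t1w if modality == "t1w" else ti.pet
    return out


def _build_atlas(spec: PhantomSpec, mask: np.ndarray) -> np.ndarray:
    """36 labels: 18 angular sectors x 2 hemispheres.

    Hemisphere from the world x sign (x < 0 -> left).  Sectors from 6
    azimuth bins (angle in the y-z plane) x 3 bands of polar angle.  Label
    ids are 1..36: sector s (0..17) in hemisphere h (0=L, 1=R) gets
    ``1 + s + 18 * h``.  Every in-mask voxel is labeled; background is 0.
    """
    x, y, z = _world_coords(spec)
    az = np.arctan2(z, y)  # [-pi, pi]
    az_bin = np.clip(((az + np.pi) / (2 * np.pi) * 6).astype(int), 0, 5)
    a, b, c = spec.semi_axes_mm
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    rho_bin = np.clip((rho / 1.0 * 3).astype(int), 0, 2)
    sector = az_bin * 3 + rho_bin  # 0..17
    hemi = (x >= 0).astype(int)  # 0 = left, 1 = right
    atlas = np.where(mask, 1 + sector + 18 * hemi, 0).astype(np.int16)
    return atlas


def atlas_label_table() -> pd.DataFrame:
    """Fixed mapping label_id -> (region_code, hemisphere).

    Sector s maps to the s-th canonical region code; the assignment is
    arbitrary but stable, which is all the overlap logic needs.
    """
    rows = []
    for h, hemi in enumerate("LR"):
        for s, code in enumerate(REGION_CODES):
            rows.append(
                {"label_id": 1 + s + 18 * h, "region_code": code, "hemisphere": hemi}
            )
    return pd.DataFrame(rows)


def generate_phantom(
    spec: PhantomSpec, pet_noise_seed: int | None = None
) -> PhantomStudy:
    """Generate one paired synthetic study.

    Parameters
    ----------
    spec
        Phantom description; the output is a pure function of it.
    pet_noise_seed
        If given, the PET noise field is drawn from this seed instead of
        ``spec.seed``, producing a second PET realization of the same
        anatomy (used e.g. as an error-bearing "predicted" volume in
        control false-positive analyses).

    Returns
    -------
    PhantomStudy
        T1w, PET, brain mask, 36-label atlas, label table and tissue map,
        all on the same lattice.
    """
    tissue = _tissue_map(spec)
    mask = tissue != BACKGROUND
    if not mask.any():
        raise ValueError("brain ellipsoid contains no voxels; grid too small")
    aff = _affine(spec)

    rng_t1 = np.random.default_rng(spec.seed)
    pet_seed = spec.seed if pet_noise_seed is None else pet_noise_seed
    # independent stream for PET noise (offset keeps it distinct from T1w)
    rng_pet = np.random.default_rng((pet_seed, 1))

    t1w = _fill_intensities(tissue, spec, "t1w")
    pet = _fill_intensities(tissue, spec, "pet")
    if spec.noise_sd > 0:
        t1w = t1w + rng_t1.normal(0.0, spec.noise_sd, size=spec.shape) * mask
        pet = pet + rng_pet.normal(0.0, spec.noise_sd, size=spec.shape) * mask

    pet_vol = Volume3D(pet, aff, modality="pet")
    if spec.smooth_fwhm_mm > 0:
        pet_vol = gaussian_smooth(pet_vol, spec.smooth_fwhm_mm)
        pet_vol.data[~mask] = 0.0  # keep background clean after smoothing

    atlas = _build_atlas(spec, mask)
    return PhantomStudy(
        t1w=Volume3D(t1w, aff, modality="t1w"),
        pet=pet_vol,
        mask=BrainMask(mask, aff),
        atlas=Volume3D(atlas, aff, modality="atlas"),
        labels=atlas_label_table(),
        tissue_map=Volume3D(tissue, aff, modality="tissue"),
    )


def lesion_mask(pet: Volume3D, lesion: LesionSpec) -> np.ndarray:
    """Boolean support of the lesion (feather included) on the PET lattice."""
    w = _lesion_weight(pet, lesion)
    return w > 0


def _lesion_weight(pet: Volume3D, lesion: LesionSpec) -> np.ndarray:
    """Multiplicative weight in [0, 1]: 1 inside the core radius, Gaussian
    fall-off over ``softness_mm``, exactly 0 beyond radius + 3*softness."""
    idx = np.indices(pet.shape).reshape(3, -1).T.astype(float)
    xyz = idx @ pet.affine[:3, :3].T + pet.affine[:3, 3]
    r = np.linalg.norm(xyz - np.asarray(lesion.center_mm), axis=1).reshape(pet.shape)
    w = np.zeros(pet.shape)
    w[r <= lesion.radius_mm] = 1.0
    if lesion.softness_mm > 0:
        edge = (r > lesion.radius_mm) & (r <= lesion.radius_mm + 3 * lesion.softness_mm)
        w[edge] = np.exp(
            -0.5 * ((r[edge] - lesion.radius_mm) / lesion.softness_mm) ** 2
        )
    return w


def inject_lesion(
    pet: Volume3D, lesion: LesionSpec, mask: BrainMask | None = None
) -> Volume3D:
    """Multiply PET intensity inside the lesion by its factor (feathered).

    Returns a copy; voxels outside the lesion support are unchanged
    bit-for-bit.

    Raises
    ------
    ValueError
        If a mask is given and the lesion center falls outside the brain.
    """
    if mask is not None:
        center_ijk = np.linalg.solve(
            pet.affine[:3, :3], np.asarray(lesion.center_mm) - pet.affine[:3, 3]
        )
        ijk = np.round(center_ijk).astype(int)
        if (
            np.any(ijk < 0)
            or np.any(ijk >= np.array(pet.shape))
            or not mask.data[tuple(ijk)]
        ):
            raise ValueError("lesion center lies outside the brain mask")
    w = _lesion_weight(pet, lesion)
    data = pet.data.copy()
    inside = w > 0
    # value -> value * (1 - (1 - factor) * w): factor at the core, ->1 at edge
    data[inside] = data[inside] * (1.0 - (1.0 - lesion.factor) * w[inside])
    return pet.with_data(data)


def write_phantom(study: PhantomStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the four volumes as NIfTI plus the atlas label table as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "t1w": write_volume(study.t1w, out_dir / "t1w.nii.gz"),
        "pet": write_volume(study.pet, out_dir / "pet.nii.gz"),
        "mask": write_mask(study.mask, out_dir / "mask.nii.gz"),
        "atlas": write_volume(study.atlas, out_dir / "atlas.nii.gz"),
    }
    labels_path = out_dir / "atlas_labels.csv"
    study.labels.to_csv(labels_path, index=False)
    paths["labels"] = labels_path
    return paths
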