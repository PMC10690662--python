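"""Volume I/O and preprocessing.

Volumes are assumed to be already co-registered on a common lattice
(template space); registration, bias correction and skull stripping are
upstream concerns.  This module provides the preprocessing steps that belong
to the subtraction pipeline itself: 0-1 intensity scaling, Gaussian PET
smoothing and brain-mask erosion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "BrainMask",
    "PrepConfig",
    "read_volume",
    "write_volume",
    "minmax_scale",
    "gaussian_smooth",
    "erode_mask",
    "check_same_lattice",
    "FWHM_TO_SIGMA",
]

# FWHM = sigma * sqrt(8 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume3D:
    """A 3D voxel grid with world geometry.

    Parameters
    ----------
    data : ndarray
        3D array of voxel values (finite reals).
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm transform (NIfTI convention).
    modality : str, optional
        Free-text tag ("t1w", "pet", ...).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume3D requires a 3D array, got {self.data.ndim}D "
                f"with shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("Volume3D values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return np.squeeze(xyz)

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Copy of this volume carrying new voxel data, same geometry."""
        return replace(self, data=np.asarray(data))


@dataclass
class BrainMask:
    """Boolean support of the brain on the same lattice as its volume."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("BrainMask requires a 3D array")
        if not self.data.any():
            raise ValueError("BrainMask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class PrepConfig:
    """Preprocessing applied before subtraction.

    smooth_fwhm_mm
        Gaussian smoothing of the PET, full width at half maximum in mm
        (0 disables).  Default 2 mm.
    scale
        Whether to rescale intensities to [0, 1] (min-max over the whole
        volume).
    smooth_before_scale
        Order of the two steps; smoothing first is the default.
    """

    smooth_fwhm_mm: float = 2.0
    scale: bool = True
    smooth_before_scale: bool = True


def check_same_lattice(*items: Volume3D | BrainMask) -> None:
    """Raise ValueError unless all items share shape and affine."""
    ref = items[0]
    for it in items[1:]:
        if it.shape != ref.shape:
            raise ValueError(f"lattice mismatch: shapes {ref.shape} vs {it.shape}")
        if not np.allclose(it.affine, ref.affine, atol=1e-6):
            raise ValueError("lattice mismatch: affines differ")


def read_volume(path: str | Path, modality: str | None = None) -> Volume3D:
    """Read a 3D NIfTI volume.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the image is not 3-dimensional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(
            f"expected a 3D image, got {img.ndim}D with shape {img.shape}: {path}"
        )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return Volume3D(data=data, affine=np.asarray(img.affine), modality=modality)


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz inferred from the path)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, str(path))
    return path


def write_mask(mask: BrainMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> BrainMask:
    vol = read_volume(path)
    return BrainMask(data=vol.data > 0.5, affine=vol.affine)


def minmax_scale(vol: Volume3D, mask: BrainMask | None = None) -> Volume3D:
    """Affine rescale of intensities to [0, 1].

    The scaling domain is the whole volume by default; when ``mask`` is
    given, min and max are taken over in-mask voxels only (the affine map is
    still applied everywhere).

    Raises
    ------
    ValueError
        If the scaling domain has zero dynamic range.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    domain = data[mask.data] if mask is not None else data
    lo, hi = float(domain.min()), float(domain.max())
    if hi - lo <= 0:
        raise ValueError("cannot min-max scale a constant volume (zero range)")
    return vol.with_data((data - lo) / (hi - lo))


def gaussian_smooth(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Separable Gaussian smoothing with a kernel specified by FWHM in mm.

    The per-axis sigma in voxels is ``fwhm / sqrt(8 ln 2) / voxel_size``.
    ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_size
    out = ndimage.gaussian_filter(
        np.asarray(vol.data, dtype=np.float64), sigma=sigma_vox, mode="constant"
    )
    return vol.with_data(out)


def _erosion_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")


def erode_mask(mask: BrainMask, n_voxels: int, connectivity: int = 6) -> BrainMask:
    """Erode the mask by ``n_voxels`` iterations of 1-voxel erosion.

    The structuring element is the 6-connected (face-adjacency) cross by
    default, configurable to 18 or 26 connectivity.  ``n_voxels == 0``
    returns an identical mask.

    Raises
    ------
    ValueError
        If erosion empties the mask (it is too small for the requested
        margin).
    """
    if n_voxels < 0:
        raise ValueError("n_voxels must be >= 0")
    if n_voxels == 0:
        return BrainMask(data=mask.data.copy(), affine=mask.affine)
    structure = _erosion_structure(connectivity)
    eroded = ndimage.binary_erosion(
        mask.data, structure=structure, iterations=n_voxels, border_value=0
    )
    if not eroded.any():
        raise ValueError(
            f"eroding by {n_voxels} voxels empties the mask; mask too small"
        )
    return BrainMask(data=eroded, affine=mask.affine)


def preprocess_pet(vol: Volume3D, config: PrepConfig) -> Volume3D:
    """Apply the PET preprocessing chain (smoothing and 0-1 scaling)."""
    out = vol
    steps = (
        ("smooth", "scale") if config.smooth_before_scale else ("scale", "smooth")
    )
    for step in steps:
        if step == "smooth" and config.smooth_fwhm_mm > 0:
            out = gaussian_smooth(out, config.smooth_fwhm_mm)
        elif step == "scale" and config.scale:
            out = minmax_scale(out)
    return out
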