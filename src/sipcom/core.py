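"""The subtraction anomaly map: mean-ratio scaling, subtraction,
Z standardization, eroded-mask thresholding and cluster extraction.

Given a patient's clinical PET and a pseudo-normal PET predicted from their
T1w MRI, the pipeline is

1. scale the predicted PET by the ratio of in-mask mean intensities, so the
   two volumes share a global mean (``scale_predicted``);
2. subtract and standardize the difference to Z-scores,
   ``Z_i = (D_i - mu) / sigma`` with mu, sigma over the brain mask
   (``difference_zmap``); by default the map is negated so that reduced
   clinical uptake (hypometabolism) appears as positive Z;
3. threshold the Z-map inside the brain mask eroded by three voxels (border
   artifact control), group supra-threshold voxels into connected
   components, and keep components at least 1 mL in volume
   (``extract_clusters``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_prep import (
    BrainMask,
    PrepConfig,
    Volume3D,
    check_same_lattice,
    erode_mask,
    preprocess_pet,
)

if TYPE_CHECKING:  # pragma: no cover
    from .gan import GeneratorState

__all__ = [
    "ZMap",
    "DetectionConfig",
    "Cluster",
    "ClusterTable",
    "scale_predicted",
    "difference_zmap",
    "extract_clusters",
    "run_sipcom",
]


@dataclass
class ZMap:
    """Standardized difference volume.

    ``volume.data`` holds Z scores; within ``mask`` they have mean 0 and
    (population) SD 1 by construction.  ``mu``/``sigma`` are the moments of
    the raw difference image that were removed; ``scale_ratio`` is the
    mean-intensity ratio applied to the predicted PET upstream (1.0 when
    unknown); ``hypometabolism_positive`` records the sign convention.
    """

    volume: Volume3D
    mask: BrainMask
    mu: float
    sigma: float
    scale_ratio: float = 1.0
    hypometabolism_positive: bool = True

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape

    @property
    def affine(self) -> np.ndarray:
        return self.volume.affine


@dataclass(frozen=True)
class DetectionConfig:
    """Cluster-detection parameters.

    z_threshold
        Voxel-level threshold on Z (one-tailed; default 2.33, the normal
        99th percentile).
    min_volume_ml
        Minimum cluster extent in millilitres (default 1 mL, i.e. 1000
        voxels at 1 mm^3; converted by the actual voxel volume).
    connectivity
        Voxel neighbourhood for components: 6, 18 or 26 (default 26).
    mask_erosion_voxels
        Iterations of 1-voxel erosion applied to the brain mask before
        thresholding (default 3).
    hypometabolism_positive
        If True (default) the Z-map is oriented so hypometabolism is
        positive and the threshold is applied to the positive tail.
    """

    z_threshold: float = 2.33
    min_volume_ml: float = 1.0
    connectivity: int = 26
    mask_erosion_voxels: int = 3
    hypometabolism_positive: bool = True

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.min_volume_ml <= 0:
            raise ValueError("min_volume_ml must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.mask_erosion_voxels < 0:
            raise ValueError("mask_erosion_voxels must be >= 0")


@dataclass
class Cluster:
    """One detected supra-threshold connected component."""

    cluster_id: int
    voxels: np.ndarray  # (n, 3) voxel indices
    n_voxels: int
    volume_ml: float
    peak_z: float
    mean_z: float
    centroid_ijk: tuple[float, float, float]
    centroid_xyz_mm: tuple[float, float, float]
    regions: frozenset = frozenset()
    region_fractions: dict = field(default_factory=dict)

    def mask_array(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = True
        return out


@dataclass
class ClusterTable:
    """Detected clusters sorted by peak Z (descending) plus lattice info."""

    clusters: list[Cluster]
    shape: tuple[int, int, int]
    affine: np.ndarray
    config: DetectionConfig

    def __len__(self) -> int:
        return len(self.clusters)

    def zmap_like(self) -> SimpleNamespace:
        """Lightweight lattice stand-in for shape/affine checks."""
        return SimpleNamespace(shape=self.shape, affine=self.affine)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "n_voxels": c.n_voxels,
                    "volume_ml": c.volume_ml,
                    "peak_z": c.peak_z,
                    "mean_z": c.mean_z,
                    "centroid_ijk": "({:.2f}, {:.2f}, {:.2f})".format(*c.centroid_ijk),
                    "centroid_xyz_mm": "({:.2f}, {:.2f}, {:.2f})".format(
                        *c.centroid_xyz_mm
                    ),
                    "regions": " + ".join(sorted(c.regions)) if c.regions else "",
                    "overlap_fractions": ";".join(
                        f"{k}:{v:.3f}" for k, v in sorted(c.region_fractions.items())
                    ),
                }
            )
        cols = [
            "cluster_id",
            "n_voxels",
            "volume_ml",
            "peak_z",
            "mean_z",
            "centroid_ijk",
            "centroid_xyz_mm",
            "regions",
            "overlap_fractions",
        ]
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)
        return path


def scale_predicted(
    predicted: Volume3D, clinical: Volume3D, mask: BrainMask
) -> tuple[Volume3D, float]:
    """Scale the predicted PET so its in-mask mean equals the clinical's.

    Returns the scaled volume and the ratio applied.  The ratio is computed
    within the brain mask (background would otherwise dominate it).

    Raises
    ------
    ValueError
        On lattice mismatch or zero predicted mean.
    """
    check_same_lattice(predicted, clinical, mask)
    m = mask.data
    mean_clin = float(clinical.data[m].mean())
    mean_pred = float(predicted.data[m].mean())
    if mean_pred == 0:
        raise ValueError("predicted PET has zero mean in the mask; cannot scale")
    ratio = mean_clin / mean_pred
    return predicted.with_data(predicted.data * ratio), ratio


def difference_zmap(
    clinical: Volume3D,
    scaled_predicted: Volume3D,
    mask: BrainMask,
    hypometabolism_positive: bool = True,
    scale_ratio: float = 1.0,
) -> ZMap:
    """Subtract and standardize: Z = (D - mu) / sigma over the brain mask.

    D = clinical - predicted; mu and sigma are the in-mask mean and
    population SD of D.  Under the default hypometabolism-positive
    convention the map is negated, so clinical < predicted (reduced uptake)
    yields positive Z.

    Raises
    ------
    ValueError
        On lattice mismatch or zero sigma (identical volumes).
    """
    check_same_lattice(clinical, scaled_predicted, mask)
    diff = np.asarray(clinical.data, dtype=np.float64) - np.asarray(
        scaled_predicted.data, dtype=np.float64
    )
    m = mask.data
    mu = float(diff[m].mean())
    sigma = float(diff[m].std())  # population (n-denominator) SD
    if sigma == 0:
        raise ValueError(
            "difference image has zero variance in the mask "
            "(clinical and predicted are identical up to a constant)"
        )
    z = (diff - mu) / sigma
    if hypometabolism_positive:
        z = -z
    z[~m] = 0.0
    return ZMap(
        volume=clinical.with_data(z),
        mask=mask,
        mu=mu,
        sigma=sigma,
        scale_ratio=scale_ratio,
        hypometabolism_positive=hypometabolism_positive,
    )


def _label_structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def extract_clusters(
    zmap: ZMap,
    config: DetectionConfig = DetectionConfig(),
    atlas: Volume3D | None = None,
    labels: pd.DataFrame | None = None,
) -> ClusterTable:
    """Threshold the Z-map inside the eroded mask and extract clusters.

    Supra-threshold voxels (Z > threshold, on the configured tail) within
    the eroded brain mask are grouped into connected components; components
    smaller than the minimum volume are discarded.  Clusters are sorted by
    peak Z descending.  When an atlas (and its label table) is given, each
    cluster is annotated with overlapping regions.

    Raises
    ------
    ValueError
        If erosion empties the mask.
    """
    eroded = (
        erode_mask(zmap.mask, config.mask_erosion_voxels)
        if config.mask_erosion_voxels > 0
        else zmap.mask
    )
    z = np.asarray(zmap.data, dtype=np.float64)
    # orient the map so the requested tail is positive before thresholding
    if zmap.hypometabolism_positive != config.hypometabolism_positive:
        z = -z
    supra = (z > config.z_threshold) & eroded.data

    voxel_ml = zmap.volume.voxel_volume_ml
    min_voxels = int(np.ceil(config.min_volume_ml / voxel_ml))

    labeled, n_comp = ndimage.label(supra, structure=_label_structure(config.connectivity))
    clusters: list[Cluster] = []
    if n_comp:
        sizes = np.bincount(labeled.ravel())
        for comp in range(1, n_comp + 1):
            if sizes[comp] < min_voxels:
                continue
            vox = np.argwhere(labeled == comp)
            zv = z[vox[:, 0], vox[:, 1], vox[:, 2]]
            centroid_ijk = vox.mean(axis=0)
            centroid_xyz = zmap.volume.voxel_to_world(centroid_ijk)
            clusters.append(
                Cluster(
                    cluster_id=0,  # assigned after sorting
                    voxels=vox,
                    n_voxels=int(sizes[comp]),
                    volume_ml=float(sizes[comp] * voxel_ml),
                    peak_z=float(zv.max()),
                    mean_z=float(zv.mean()),
                    centroid_ijk=tuple(centroid_ijk),
                    centroid_xyz_mm=tuple(np.atleast_1d(centroid_xyz)),
                )
            )
    clusters.sort(key=lambda c: c.peak_z, reverse=True)
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i
    table = ClusterTable(
        clusters=clusters,
        shape=zmap.shape,
        affine=zmap.affine,
        config=config,
    )
    if atlas is not None:
        from .evaluate import assign_cluster_regions

        if labels is None:
            from .phantom import atlas_label_table

            labels = atlas_label_table()
        assign_cluster_regions(table, atlas, labels)
    return table


def run_sipcom(
    clinical: Volume3D,
    mask: BrainMask,
    t1w: Volume3D | None = None,
    predicted: Volume3D | None = None,
    generator: "GeneratorState | None" = None,
    detection: DetectionConfig = DetectionConfig(),
    prep: PrepConfig = PrepConfig(),
    atlas: Volume3D | None = None,
    labels: pd.DataFrame | None = None,
) -> tuple[ZMap, ClusterTable, dict]:
    """Run the full subtraction pipeline on one patient.

    Either a ``predicted`` pseudo-normal PET is supplied directly, or a
    trained ``generator`` plus the patient's ``t1w`` is given and the
    prediction is computed.  The clinical PET is preprocessed per ``prep``
    (smooth then 0-1 scale by default); an externally supplied predicted
    volume receives the same preprocessing so the subtraction compares like
    with like, whereas a generator prediction is produced already in
    preprocessed space.

    Returns
    -------
    (zmap, clusters, provenance)
        Provenance is a JSON-serializable record of the configuration and
        the mu/sigma/ratio actually applied.
    """
    if predicted is None and (generator is None or t1w is None):
        raise ValueError("supply either `predicted`, or both `generator` and `t1w`")
    check_same_lattice(clinical, mask)

    clinical_p = preprocess_pet(clinical, prep)
    if predicted is not None:
        check_same_lattice(predicted, clinical)
        predicted_p = preprocess_pet(predicted, prep)
        predicted_source = "supplied"
    else:
        from .io_prep import minmax_scale

        t1w_p = minmax_scale(t1w) if prep.scale else t1w
        predicted_p = generator.predict_volume(t1w_p, mask)
        predicted_source = "generator"

    scaled, ratio = scale_predicted(predicted_p, clinical_p, mask)
    zmap = difference_zmap(
        clinical_p,
        scaled,
        mask,
        hypometabolism_positive=detection.hypometabolism_positive,
        scale_ratio=ratio,
    )
    table = extract_clusters(zmap, detection, atlas=atlas, labels=labels)
    provenance = {
        "predicted_source": predicted_source,
        "prep": {
            "smooth_fwhm_mm": prep.smooth_fwhm_mm,
            "scale": prep.scale,
            "smooth_before_scale": prep.smooth_before_scale,
        },
        "detection": {
            "z_threshold": detection.z_threshold,
            "min_volume_ml": detection.min_volume_ml,
            "connectivity": detection.connectivity,
            "mask_erosion_voxels": detection.mask_erosion_voxels,
            "hypometabolism_positive": detection.hypometabolism_positive,
        },
        "scale_ratio": ratio,
        "mu": zmap.mu,
        "sigma": zmap.sigma,
        "n_clusters": len(table),
    }
    return zmap, table, provenance


def write_provenance(provenance: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return path
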