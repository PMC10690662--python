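"""Predicted-vs-ground-truth PET image quality metrics.

Masked MAE, PSNR and SSIM for scoring a predicted pseudo-normal PET against
the subject's true PET.  All three accept a brain mask; MAE and PSNR are
computed over in-mask voxels, SSIM is a local-window statistic averaged over
windows centred in the mask (the volumes are zeroed outside the mask first,
so background never contributes structure).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_prep import BrainMask, Volume3D, check_same_lattice

__all__ = ["QualityMetrics", "masked_mae", "psnr", "ssim", "evaluate_pair"]


@dataclass(frozen=True)
class QualityMetrics:
    """MAE (intensity units), PSNR (dB; inf for identical images), SSIM."""

    mae: float
    psnr: float
    ssim: float

    def to_dict(self) -> dict:
        return asdict(self)


def _as_arrays(
    a: Volume3D | np.ndarray, b: Volume3D | np.ndarray, mask: BrainMask | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(a, Volume3D) and isinstance(b, Volume3D) and isinstance(mask, BrainMask):
        check_same_lattice(a, b, mask)
    aa = np.asarray(a.data if isinstance(a, Volume3D) else a, dtype=np.float64)
    bb = np.asarray(b.data if isinstance(b, Volume3D) else b, dtype=np.float64)
    mm = np.asarray(mask.data if isinstance(mask, BrainMask) else mask, dtype=bool)
    if aa.shape != bb.shape or aa.shape != mm.shape:
        raise ValueError(
            f"lattice mismatch: shapes {aa.shape}, {bb.shape}, {mm.shape}"
        )
    if not mm.any():
        raise ValueError("mask is empty")
    return aa, bb, mm


def masked_mae(
    a: Volume3D | np.ndarray, b: Volume3D | np.ndarray, mask: BrainMask | np.ndarray
) -> float:
    """Mean absolute error over in-mask voxels."""
    aa, bb, mm = _as_arrays(a, b, mask)
    return float(np.abs(aa[mm] - bb[mm]).mean())


def psnr(
    a: Volume3D | np.ndarray,
    b: Volume3D | np.ndarray,
    mask: BrainMask | np.ndarray,
    data_range: float = 1.0,
) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(range^2 / masked MSE).

    Identical images have zero MSE; ``inf`` is returned as the sentinel.
    """
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    aa, bb, mm = _as_arrays(a, b, mask)
    mse = float(((aa[mm] - bb[mm]) ** 2).mean())
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / mse)


def ssim(
    a: Volume3D | np.ndarray,
    b: Volume3D | np.ndarray,
    mask: BrainMask | np.ndarray,
    window: int = 7,
    data_range: float = 1.0,
    k1: float = 0.01,
    k2: float = 0.03,
    masked: bool = True,
) -> float:
    """Structural similarity index, averaged over local windows.

    Uses the standard uniform-window SSIM: per-window means, variances
    (sample, n-1 denominator) and covariance with stabilizing constants
    C1 = (k1 L)^2, C2 = (k2 L)^2 where L is the data range.  With
    ``masked=True`` (default) both volumes are zeroed outside the mask and
    the SSIM map is averaged over windows *centred* in the mask; with
    ``masked=False`` the mean is over the whole (valid) volume.
    """
    if window < 2 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    aa, bb, mm = _as_arrays(a, b, mask)
    if any(w > s for w, s in zip((window,) * 3, aa.shape)):
        raise ValueError(f"window {window} does not fit inside volume {aa.shape}")
    if masked:
        aa = np.where(mm, aa, 0.0)
        bb = np.where(mm, bb, 0.0)

    n = window**3
    filt = lambda x: ndimage.uniform_filter(x, size=window, mode="constant")
    mu_a = filt(aa)
    mu_b = filt(bb)
    mu_aa = filt(aa * aa)
    mu_bb = filt(bb * bb)
    mu_ab = filt(aa * bb)
    # unbiased (n-1) variance/covariance, matching the field's reference
    cov_norm = n / (n - 1)
    var_a = cov_norm * (mu_aa - mu_a * mu_a)
    var_b = cov_norm * (mu_bb - mu_b * mu_b)
    cov_ab = cov_norm * (mu_ab - mu_a * mu_b)

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov_ab + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    )
    if masked:
        return float(ssim_map[mm].mean())
    # exclude the border where the window leaves the volume
    pad = window // 2
    core = ssim_map[pad:-pad, pad:-pad, pad:-pad]
    return float(core.mean())


def evaluate_pair(
    predicted: Volume3D,
    truth: Volume3D,
    mask: BrainMask,
    data_range: float = 1.0,
) -> QualityMetrics:
    """All three metrics for one predicted/true pair."""
    return QualityMetrics(
        mae=masked_mae(predicted, truth, mask),
        psnr=psnr(predicted, truth, mask, data_range=data_range),
        ssim=ssim(predicted, truth, mask, data_range=data_range),
    )


def write_metrics(
    per_subject: dict[str, QualityMetrics], json_path: str | Path, csv_path: str | Path
) -> None:
    """Emit per-subject JSON records plus an aggregate mean +/- SD CSV."""
    json_path, csv_path = Path(json_path), Path(csv_path)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.write_text(
        json.dumps({k: m.to_dict() for k, m in per_subject.items()}, indent=2)
    )
    df = pd.DataFrame([m.to_dict() for m in per_subject.values()])
    agg = df.agg(["mean", "std"])
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    agg.to_csv(csv_path)
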