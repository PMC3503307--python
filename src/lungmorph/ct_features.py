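"""Micro-CT density descriptors from an HU volume and a given lung mask.

MLVI is the mean voxel intensity (HU) over the lung mask; VBT is the
percentage of in-mask voxels strictly below a threshold, -900 HU by default
(intensities below -900 HU are rare in healthy animals). The mask is taken
as given with airways already removed — lung and airway segmentation are
upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lungmorph.synthetic import HUVolume

__all__ = ["CTFeatures", "compute_ct_features"]


@dataclass
class CTFeatures:
    MLVI: float  # mean lung voxel intensity, HU
    VBT: float  # relative volume below threshold, percent
    n_voxels: int


def compute_ct_features(
    volume: HUVolume | np.ndarray,
    lung_mask: np.ndarray,
    threshold_hu: float = -900.0,
) -> CTFeatures:
    """Compute MLVI and VBT over the masked lung voxels.

    VBT counts voxels strictly below ``threshold_hu``; a voxel at exactly
    the threshold is not counted. Raises ``ValueError`` on an empty mask or
    a shape mismatch.
    """
    voxels = volume.voxels if isinstance(volume, HUVolume) else np.asarray(volume)
    mask = np.asarray(lung_mask, dtype=bool)
    if mask.shape != voxels.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {voxels.shape}"
        )
    values = voxels[mask]
    if values.size == 0:
        raise ValueError("lung mask is empty")
    return CTFeatures(
        MLVI=float(values.mean()),
        VBT=float(100.0 * np.count_nonzero(values < threshold_hu) / values.size),
        n_voxels=int(values.size),
    )
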