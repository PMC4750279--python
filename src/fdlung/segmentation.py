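"""Lung extraction from a chest attenuation volume.

The analysis pipeline only needs the set of voxels belonging to the lung; the
attenuation pattern inside that set is what gets binned and box-counted. The
segmenter here is deliberately simple and reproducible:

1. threshold: candidate voxels have attenuation below an air/parenchyma
   cut (default -300 relative HU);
2. exclude border air: candidate components connected to the volume
   boundary are ambient air, not lung;
3. keep the largest one or two remaining connected components above a
   minimum volume (two lungs may or may not be bridged by the airways);
4. morphological closing (spherical element) to smooth the boundary.

Interior holes (vessels, bronchi walls) are intentionally *not* filled: the
method analyses all lung-voxel attenuations, dense structures included, so
the mask must keep them. An externally produced mask can always be supplied
instead of running this segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError, SegmentationError, ValidationError
from .volume_io import AttenuationVolume, VoxelMask

__all__ = ["SegmentationParams", "segment_lung", "masked_values"]


@dataclass
class SegmentationParams:
    """Knobs of the threshold segmenter.

    threshold : air/parenchyma cut in relative HU; voxels strictly below it
        are lung candidates.
    min_volume : smallest connected component (in voxels) kept as lung.
    close_radius : radius (voxels) of the spherical closing element; 0
        disables closing.
    keep_components : how many of the largest candidate components to keep
        (1 or 2).
    """

    threshold: float = -300.0
    min_volume: int = 100
    close_radius: int = 2
    keep_components: int = 2

    def validate(self) -> None:
        if not np.isfinite(self.threshold):
            raise ParameterError("threshold must be finite")
        if self.min_volume < 1:
            raise ParameterError("min_volume must be >= 1")
        if self.close_radius < 0:
            raise ParameterError("close_radius must be >= 0")
        if self.keep_components not in (1, 2):
            raise ParameterError("keep_components must be 1 or 2")


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x * x + y * y + z * z) <= r * r


def segment_lung(volume: AttenuationVolume, params: SegmentationParams | None = None) -> VoxelMask:
    """Extract a lung mask from an attenuation volume.

    Raises
    ------
    SegmentationError
        If no candidate component of at least ``min_volume`` voxels survives
        ("no lung-like region").
    ParameterError
        For structurally invalid parameters.
    """
    params = params or SegmentationParams()
    params.validate()
    if volume.data.size < 1000:
        raise ValidationError("segmentation needs a volume of at least 10^3 voxels")

    below = volume.data < params.threshold
    structure = np.ones((3, 3, 3), bool)  # 26-connectivity
    labels, n_labels = ndi.label(below, structure=structure)
    if n_labels == 0:
        raise SegmentationError(
            f"no lung-like region: no voxel below threshold {params.threshold} relative HU"
        )

    # Components touching any face of the volume are ambient/border air.
    border = np.zeros(volume.shape, bool)
    for axis in range(3):
        sl: list = [slice(None)] * 3
        for end in (0, -1):
            sl[axis] = end
            border[tuple(sl)] = True
    border_labels = np.unique(labels[border & below])

    sizes = np.bincount(labels.ravel(), minlength=n_labels + 1)
    sizes[0] = 0
    sizes[border_labels] = 0
    candidates = np.flatnonzero(sizes >= params.min_volume)
    if candidates.size == 0:
        raise SegmentationError(
            "no lung-like region: every sub-threshold component is border air "
            f"or smaller than {params.min_volume} voxels"
        )

    keep = candidates[np.argsort(sizes[candidates])[::-1][: params.keep_components]]
    mask = np.isin(labels, keep)
    if params.close_radius > 0:
        mask = ndi.binary_closing(mask, structure=_ball(params.close_radius))
    if not mask.any():
        raise SegmentationError("no lung-like region: closing removed all voxels")
    return VoxelMask(mask)


def masked_values(volume: AttenuationVolume, mask: VoxelMask) -> tuple[np.ndarray, np.ndarray]:
    """Gather the attenuation values at mask-true voxels.

    Returns
    -------
    values : ndarray, shape (n,)
        Attenuation values in (x, y, z)-lexicographic voxel order.
    coords : ndarray, shape (n, 3)
        The corresponding voxel indices, same order.
    """
    if volume.shape != mask.shape:
        raise ValidationError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if not mask.data.any():
        raise ValidationError("mask is empty")
    coords = np.argwhere(mask.data)  # C-order scan == lexicographic (x, y, z)
    values = volume.data[mask.data]
    return values, coords
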