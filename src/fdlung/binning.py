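"""Cut-off ranges and per-range binarisation of a masked attenuation volume.

The attenuation scale (by default -3000 to +10000 relative HU) is divided
into ``n`` equal-width contiguous *cut-off ranges* — 100 ranges of 130
relative HU each at the defaults. Every masked voxel whose value falls
inside a range contributes a ``1`` to that range's binary pattern and a
``0`` everywhere else; the patterns partition the in-span masked voxel set.

Interior ranges are half-open ``[low, high)`` and the last range is closed,
so a value sitting exactly on an interior boundary belongs to the higher
range and the partition is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .volume_io import AttenuationVolume, VoxelMask

__all__ = [
    "CutoffRange",
    "BinaryPattern",
    "make_cutoff_ranges",
    "freedman_diaconis_width",
    "assign_ranges",
    "binarize_all",
    "DEFAULT_SPAN",
    "DEFAULT_N_RANGES",
]

logger = logging.getLogger(__name__)

#: Default attenuation span and range count (relative HU).
DEFAULT_SPAN = (-3000.0, 10000.0)
DEFAULT_N_RANGES = 100


class CutoffRange(NamedTuple):
    """One contiguous attenuation interval ``[low, high)`` (last range closed)."""

    low: float
    high: float
    index: int

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass
class BinaryPattern:
    """3D boolean occupancy grid for one cut-off range."""

    data: np.ndarray
    range: CutoffRange

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValidationError("binary pattern must be 3D")

    @property
    def n_occupied(self) -> int:
        return int(self.data.sum())


def make_cutoff_ranges(low: float, high: float, n: int) -> list[CutoffRange]:
    """Divide ``[low, high]`` into ``n`` equal, contiguous cut-off ranges."""
    if n < 2:
        raise ParameterError(f"need at least 2 cut-off ranges, got {n}")
    if not low < high:
        raise ParameterError(f"need low < high, got [{low}, {high}]")
    edges = np.linspace(low, high, n + 1)
    return [CutoffRange(float(edges[i]), float(edges[i + 1]), i) for i in range(n)]


def freedman_diaconis_width(values: np.ndarray) -> float:
    """Freedman–Diaconis bin width ``2 * IQR * n^(-1/3)``.

    Quartiles use the midpoint convention (``np.percentile`` with
    ``method="midpoint"``), i.e. for values 1..8 the IQR is 4 and the width
    ``2 * 4 * 8^(-1/3) = 4.0``.

    Raises
    ------
    ParameterError
        Fewer than 4 values, or zero interquartile range (use fixed-count
        binning instead).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        raise ParameterError("Freedman-Diaconis rule needs at least 4 values")
    q25, q75 = np.percentile(values, [25, 75], method="midpoint")
    iqr = float(q75 - q25)
    if iqr <= 0:
        raise ParameterError(
            "interquartile range is zero; Freedman-Diaconis width is undefined "
            "- use a fixed range count instead"
        )
    return 2.0 * iqr * values.size ** (-1.0 / 3.0)


def _check_ranges(ranges: Sequence[CutoffRange]) -> None:
    if not ranges:
        raise ParameterError("empty cut-off range set")
    for i, r in enumerate(ranges):
        if r.low >= r.high:
            raise ParameterError(f"range {i} has low >= high: {r}")
        if i and abs(r.low - ranges[i - 1].high) > 1e-9 * max(1.0, abs(r.low)):
            raise ParameterError("cut-off ranges must be contiguous and ascending")


def assign_ranges(values: np.ndarray, ranges: Sequence[CutoffRange]) -> np.ndarray:
    """Map each value to the index of its cut-off range, or -1 if out of span.

    Interior boundaries resolve upward; the top edge of the last range is
    included.
    """
    _check_ranges(ranges)
    values = np.asarray(values, dtype=float)
    edges = np.array([r.low for r in ranges] + [ranges[-1].high])
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(ranges) - 1  # last range closed
    out_of_span = (idx < 0) | (idx >= len(ranges))
    idx[out_of_span] = -1
    return idx


def binarize_all(
    volume: AttenuationVolume, mask: VoxelMask, ranges: Sequence[CutoffRange]
) -> list[BinaryPattern]:
    """Produce one binary pattern per cut-off range.

    A voxel is set in pattern ``i`` iff it is mask-true and its attenuation
    lies in range ``i``; masked voxels outside the overall span appear in no
    pattern (a warning is logged, since with the default span this should
    not happen).
    """
    if volume.shape != mask.shape:
        raise ValidationError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    _check_ranges(ranges)
    flat_mask = np.flatnonzero(mask.data.ravel())
    idx = assign_ranges(volume.data.ravel()[flat_mask], ranges)
    n_out = int(np.count_nonzero(idx == -1))
    if n_out:
        logger.warning(
            "%d masked voxel(s) fall outside the attenuation span [%g, %g] "
            "and belong to no cut-off range",
            n_out,
            ranges[0].low,
            ranges[-1].high,
        )
    patterns = []
    for i, r in enumerate(ranges):
        flat = np.zeros(volume.data.size, dtype=bool)
        flat[flat_mask[idx == i]] = True
        patterns.append(BinaryPattern(flat.reshape(volume.shape), r))
    return patterns
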