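"""Attenuation frequency distributions and single-Gaussian fits.

The frequency distribution of lung-voxel attenuations (the "density
histogram") is the conventional first-line summary of a chest CT volume. A
single Gaussian ``h * exp(-(x - p)^2 / (2 w^2))`` fitted to it yields three
parameters: height ``h``, position ``p`` (relative HU) and width ``w``
(reported as the Gaussian sigma, in relative HU). In the exposure-model
study design this histogram fit is the negative control: its width/position
do not separate the groups, while the fractal-dimension curve does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit as _scipy_curve_fit

from .errors import DegenerateFitError, ParameterError, ValidationError

__all__ = ["Histogram", "GaussianPeak", "gaussian", "compute_histogram", "fit_single_gaussian"]


def gaussian(x: np.ndarray, height: float, position: float, width: float) -> np.ndarray:
    """Unnormalised Gaussian ``height * exp(-(x-position)^2 / (2 width^2))``."""
    x = np.asarray(x, dtype=float)
    return height * np.exp(-((x - position) ** 2) / (2.0 * width**2))


@dataclass
class Histogram:
    """Binned frequency distribution with half-open bins, last bin closed."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_edges.ndim != 1 or self.counts.ndim != 1:
            raise ValidationError("bin_edges and counts must be 1D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValidationError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class GaussianPeak:
    """Height / position / width (sigma) of one fitted Gaussian component."""

    height: float
    position: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"Gaussian width must be positive, got {self.width}")
        if self.height < 0:
            raise ValidationError(f"Gaussian height must be non-negative, got {self.height}")


def compute_histogram(
    values: np.ndarray,
    *,
    edges: np.ndarray | None = None,
    bin_width: float | None = None,
    bins: int | None = None,
) -> Histogram:
    """Bin attenuation values into a frequency distribution.

    Exactly one of ``edges``, ``bin_width`` or ``bins`` must be given.
    Bins are half-open ``[low, high)`` with the last bin closed, so the total
    count always equals ``len(values)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValidationError("cannot histogram an empty value collection")
    given = sum(arg is not None for arg in (edges, bin_width, bins))
    if given != 1:
        raise ParameterError("specify exactly one of edges, bin_width or bins")

    if edges is None:
        lo, hi = float(values.min()), float(values.max())
        if bin_width is not None:
            if bin_width <= 0:
                raise ParameterError("bin_width must be positive")
            n = max(2, int(np.ceil(max(hi - lo, bin_width) / bin_width)))
            edges = lo + bin_width * np.arange(n + 1)
        else:
            assert bins is not None
            if bins < 2:
                raise ParameterError("need at least 2 bins")
            if hi == lo:
                hi = lo + 1.0  # degenerate spread; still produce >= 2 covering bins
            edges = np.linspace(lo, hi, bins + 1)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 3:
        raise ParameterError("edges must define at least 2 bins")
    if np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing")
    counts, _ = np.histogram(values, bins=edges)
    return Histogram(edges, counts)


def _fit_gaussian_xy(
    x: np.ndarray,
    y: np.ndarray,
    p0: tuple[float, float, float],
    bounds: tuple = ((0.0, -np.inf, 1e-12), (np.inf, np.inf, np.inf)),
) -> tuple[GaussianPeak, float]:
    """Least-squares single-Gaussian fit on (x, y) pairs; shared helper."""
    popt, _ = _scipy_curve_fit(
        gaussian, x, y, p0=p0, bounds=bounds, maxfev=20000, method="trf"
    )
    rss = float(np.sum((y - gaussian(x, *popt)) ** 2))
    rss0 = float(np.sum((y - gaussian(x, *p0)) ** 2))
    if rss > rss0:  # never return worse than the initial guess
        popt, rss = np.asarray(p0, dtype=float), rss0
    return GaussianPeak(float(popt[0]), float(popt[1]), abs(float(popt[2]))), rss


def gaussian_moments(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic moment-based initial guess (height, position, width)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    h0 = float(y.max())
    p0 = float(x[int(np.argmax(y))])
    w = y.clip(min=0)
    if w.sum() > 0:
        mean = float(np.average(x, weights=w))
        var = float(np.average((x - mean) ** 2, weights=w))
        w0 = float(np.sqrt(var)) if var > 0 else float(np.diff(x).mean() or 1.0)
    else:
        w0 = float(np.diff(x).mean() or 1.0)
    return h0, p0, max(w0, 1e-9)


def fit_single_gaussian(hist: Histogram) -> tuple[GaussianPeak, float]:
    """Fit one Gaussian to bin-centre/count pairs by unweighted least squares.

    Initialisation is deterministic (height = max count, position = argmax
    bin centre, width = count-weighted SD), so the fit is a pure function of
    the histogram.

    Returns the fitted peak and the residual sum of squares.

    Raises
    ------
    DegenerateFitError
        Fewer than 4 bins have nonzero counts.
    """
    occupied = int(np.count_nonzero(hist.counts))
    if occupied < 4:
        raise DegenerateFitError(
            f"single-Gaussian fit needs >= 4 occupied bins, histogram has {occupied}"
        )
    x, y = hist.centers, hist.counts.astype(float)
    return _fit_gaussian_xy(x, y, gaussian_moments(x, y))
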