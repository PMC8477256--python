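"""Image-quality metrics: RMSE, CNR, SNR and histogram-based gCNR.

RMSE compares a reconstruction against a known ground truth; CNR/SNR/gCNR
compare a circular target region against an equal-sized circular
background region when no ground truth exists.  gCNR is one minus the
overlap of the two regions' normalised intensity histograms, bounded in
[0, 1] and invariant to monotone remapping of the display range.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .grids import ImageGrid

__all__ = [
    "ROIPair",
    "MetricsReport",
    "rmse",
    "normalized_rmse",
    "cnr_snr",
    "gcnr",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given regions."""


@dataclasses.dataclass(frozen=True)
class ROIPair:
    """Equal-radius circular target and background regions (mm coordinates)."""

    target_center: tuple[float, float]
    background_center: tuple[float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("ROI radius must be positive")
        d = math.dist(self.target_center, self.background_center)
        if d < 2 * self.radius_mm:
            raise ValueError("target and background ROIs overlap")

    def validate_inside(self, grid: ImageGrid) -> None:
        half = grid.extent_mm / 2.0
        for c in (self.target_center, self.background_center):
            if max(abs(c[0]), abs(c[1])) + self.radius_mm > half:
                raise ValueError("ROI extends beyond the grid")

    def masks(self, grid: ImageGrid) -> tuple[np.ndarray, np.ndarray]:
        Y, X = grid.pixel_centers()

        def disc(c):
            return (Y - c[0]) ** 2 + (X - c[1]) ** 2 <= self.radius_mm**2

        return disc(self.target_center), disc(self.background_center)


@dataclasses.dataclass
class MetricsReport:
    cnr_db: float
    snr_db: float
    gcnr: float
    roi: ROIPair
    bins: int = 255
    rmse: float | None = None

    def as_dict(self) -> dict:
        out = {
            "cnr_db": self.cnr_db,
            "snr_db": self.snr_db,
            "gcnr": self.gcnr,
            "bins": self.bins,
            "roi": {
                "target_center": list(self.roi.target_center),
                "background_center": list(self.roi.background_center),
                "radius_mm": self.roi.radius_mm,
            },
        }
        if self.rmse is not None:
            out["rmse"] = self.rmse
        return out


def rmse(X: np.ndarray, Y: np.ndarray) -> float:
    """Root-mean-square pixel difference between two equally shaped images."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError(f"image shapes differ: {X.shape} vs {Y.shape}")
    return float(np.sqrt(np.mean((X - Y) ** 2)))


def normalized_rmse(X: np.ndarray, Y: np.ndarray) -> float:
    """RMSE after max-|value| normalising each image separately.

    Reconstruction output is in arbitrary units; dividing each image by
    its own peak magnitude puts both on the same [-1, 1] scale before
    comparing.  Ground-truth phantoms (already peaking at 1) are
    unchanged by this.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    mx, my = np.max(np.abs(X)), np.max(np.abs(Y))
    return rmse(X / mx if mx > 0 else X, Y / my if my > 0 else Y)


def cnr_snr(img: np.ndarray, roi: ROIPair, grid: ImageGrid) -> tuple[float, float]:
    """Contrast-to-noise and signal-to-noise ratios in dB.

    The target mean mu_i averages only pixels brighter than 50% of the
    peak inside the target ROI; the background mean/std use every pixel
    of the background ROI.  CNR = 20 log10(|mu_i - mu_o| / sigma_o),
    SNR = 20 log10(mu_i / sigma_o).
    """
    img = np.asarray(img, float)
    tmask, bmask = roi.masks(grid)
    if img.shape != tmask.shape:
        raise ValueError("image shape does not match the grid")
    tvals = img[tmask]
    bvals = img[bmask]
    if tvals.size == 0 or bvals.size == 0:
        raise UndefinedMetricError("an ROI contains no pixels")
    peak = tvals.max()
    signal = tvals[tvals > 0.5 * peak]
    if signal.size == 0:
        raise UndefinedMetricError("no target pixels above 50% of the ROI peak")
    mu_i = float(signal.mean())
    mu_o = float(bvals.mean())
    sigma_o = float(bvals.std())
    if sigma_o == 0.0:
        raise UndefinedMetricError("background standard deviation is zero")
    if mu_i == mu_o:
        raise UndefinedMetricError("zero contrast between target and background")
    if mu_i <= 0.0:
        raise UndefinedMetricError("non-positive target mean; SNR undefined")
    cnr_db = 20.0 * math.log10(abs(mu_i - mu_o) / sigma_o)
    snr_db = 20.0 * math.log10(mu_i / sigma_o)
    return cnr_db, snr_db


def gcnr(
    img: np.ndarray,
    roi: ROIPair,
    grid: ImageGrid,
    bins: int = 255,
) -> float:
    """Generalised CNR: 1 - sum_k min(h_i(x_k), h_o(x_k)).

    Histograms of the two ROIs share ``bins`` uniform bins spanning the
    pooled value range; each is normalised to unit sum.  A degenerate
    pooled range (all values identical) returns 0.
    """
    img = np.asarray(img, float)
    tmask, bmask = roi.masks(grid)
    if img.shape != tmask.shape:
        raise ValueError("image shape does not match the grid")
    tvals = img[tmask]
    bvals = img[bmask]
    if tvals.size == 0 or bvals.size == 0:
        raise UndefinedMetricError("an ROI contains no pixels")
    lo = min(tvals.min(), bvals.min())
    hi = max(tvals.max(), bvals.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    h_i, _ = np.histogram(tvals, bins=edges)
    h_o, _ = np.histogram(bvals, bins=edges)
    h_i = h_i / h_i.sum()
    h_o = h_o / h_o.sum()
    return float(1.0 - np.sum(np.minimum(h_i, h_o)))


def evaluate(
    img: np.ndarray,
    roi: ROIPair,
    grid: ImageGrid,
    truth: np.ndarray | None = None,
    bins: int = 255,
) -> MetricsReport:
    """Full metrics report for one image (RMSE only when truth is given)."""
    c, s = cnr_snr(img, roi, grid)
    g = gcnr(img, roi, grid, bins=bins)
    r = normalized_rmse(img, truth) if truth is not None else None
    return MetricsReport(cnr_db=c, snr_db=s, gcnr=g, roi=roi, bins=bins, rmse=r)
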