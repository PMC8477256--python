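"""Delay-and-sum (DAS) beamforming reconstruction.

For each pixel, the recorded pressure of every element is sampled at that
pixel's time of flight (fractional delays by linear interpolation) and
summed.  No apodization, envelope detection or depth compensation is
applied by default — the plain sum is what the iterative solver uses as
its initial image.  Under limited-view detection the result shows the
classic arc artifacts and lateral elongation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .forward import AcousticConfig, DirectivityProfile, Sinogram, directivity
from .geometry import DetectionGeometry
from .grids import ImageGrid

__all__ = ["ReconImage", "das_reconstruct", "combine_das"]


@dataclasses.dataclass
class ReconImage:
    """A reconstructed n x n image with its grid and provenance."""

    image: np.ndarray
    grid: ImageGrid
    method: str = "DAS"
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, float)
        if self.image.shape != (self.grid.n, self.grid.n):
            raise ValueError("image dimensions do not match the grid")

    def max_normalized(self) -> "ReconImage":
        """Divide by the maximum absolute value (no-op on an all-zero image)."""
        m = np.max(np.abs(self.image))
        img = self.image / m if m > 0 else self.image.copy()
        return ReconImage(img, self.grid, self.method, "max-normalized")


def das_reconstruct(
    s: Sinogram,
    geometry: DetectionGeometry,
    grid: ImageGrid,
    acoustics: AcousticConfig | None = None,
    profile: DirectivityProfile | None = None,
    use_directivity: bool = False,
    envelope: bool = False,
    normalize: bool = True,
) -> ReconImage:
    """Delay-and-sum image from a pressure sinogram.

    Delays beyond the record length contribute zero.  With
    ``use_directivity`` each element's contribution is weighted by the
    directivity profile at the subtended angle.  ``envelope`` beamforms
    the per-channel analytic (Hilbert) signals and returns the magnitude
    of the complex sum — the nonnegative display convention; the default
    signed sum is what the iterative solver's initialisation uses.
    """
    acoustics = acoustics if acoustics is not None else s.acoustics
    if profile is None:
        profile = DirectivityProfile()
    pos = geometry.all_positions()
    nrm = geometry.all_normals()
    if s.data.shape[0] != len(pos):
        raise ValueError("sinogram channel count does not match the geometry")
    T = acoustics.T
    n2 = grid.n * grid.n
    Y, X = grid.pixel_centers()
    yv, xv = Y.ravel(), X.ravel()
    if envelope:
        from scipy.signal import hilbert

        traces = hilbert(s.data, axis=1)
        acc = np.zeros(n2, dtype=complex)
    else:
        traces = s.data
        acc = np.zeros(n2)
    for i, (p, nv) in enumerate(zip(pos, nrm)):
        dy, dx = yv - p[0], xv - p[1]
        r = np.maximum(np.hypot(dy, dx), grid.pixel_size / 2.0)
        tau = r / acoustics.sample_distance_mm
        j0 = np.floor(tau).astype(np.int64)
        w1 = 1.0 - (tau - j0)
        valid = (j0 >= 0) & (j0 < T - 1)
        trace = traces[i]
        contrib = np.zeros(n2, dtype=acc.dtype)
        contrib[valid] = w1[valid] * trace[j0[valid]] + (1.0 - w1[valid]) * trace[
            j0[valid] + 1
        ]
        # delays landing exactly on the final sample
        last = j0 == T - 1
        contrib[last] = w1[last] * trace[T - 1]
        if use_directivity:
            angle = np.arccos(np.clip((dy * nv[0] + dx * nv[1]) / r, -1.0, 1.0))
            contrib *= directivity(profile, angle)
        acc += contrib
    img = np.abs(acc).reshape(grid.n, grid.n) if envelope else acc.reshape(
        grid.n, grid.n
    )
    out = ReconImage(img, grid, method="DAS", normalization="raw")
    return out.max_normalized() if normalize else out


def combine_das(images: list[ReconImage]) -> ReconImage:
    """Pixel-wise sum of DAS images (dual-probe combination), re-normalised."""
    if not images:
        raise ValueError("need at least one image to combine")
    grid = images[0].grid
    for im in images[1:]:
        if im.grid != grid:
            raise ValueError("cannot combine images on different grids")
    total = np.sum([im.image for im in images], axis=0)
    return ReconImage(total, grid, method="DAS", normalization="raw").max_normalized()
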