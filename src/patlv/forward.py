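"""Discrete photoacoustic forward model for linear-array detection.

The model maps a 2D initial-pressure image X (n x n, vectorised to n^2)
to the acoustic velocity potential recorded by each transducer element.
For element i, temporal sample j and pixel k at distance r from the
element, the sparse system block A_i has entries

    A_i(j, k) = (1 - |r/(c dt) - j|) * D(i, k) / (2 pi r)   if |r/(c dt) - j| < 1
              = 0                                            otherwise,

i.e. the pixel's arrival time is linearly interpolated between the two
neighbouring temporal samples, weighted by the element directivity D and
the 2D geometrical-spreading decay 1/(2 pi r).  Stacking the Q blocks
gives the full projection G = A vec(X).

Geometry is in mm and time in microseconds; the decay radius is
expressed in sample-travel units r/(c dt) — the same dimensionless
distance that indexes the temporal samples — which keeps the operator
norm compatible with the solver's fixed step sizes (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math
import numpy as np
import scipy.sparse as sp
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator

from .geometry import DetectionGeometry
from .grids import ImageGrid, Phantom

__all__ = [
    "AcousticConfig",
    "DirectivityProfile",
    "ProjectionOperator",
    "Sinogram",
    "PotentialData",
    "directivity",
    "build_submatrix",
    "build_projection",
    "pressure_to_potential",
    "simulate_data",
    "default_num_samples",
]

#: refuse to materialise a dense operator larger than this many entries
DENSE_ENTRY_BUDGET = int(5e7)


@dataclasses.dataclass(frozen=True)
class AcousticConfig:
    """Speed of sound, sampling rate and temporal record length.

    ``c`` is in m/s and ``fs`` in Hz as quoted on hardware datasheets;
    derived quantities are expressed in mm and microseconds.
    """

    c: float = 1500.0
    fs: float = 40e6
    T: int = 1000

    def __post_init__(self) -> None:
        if self.c <= 0 or self.fs <= 0 or self.T < 1:
            raise ValueError("need c > 0, fs > 0 and T >= 1")

    @property
    def dt_us(self) -> float:
        """Sampling period in microseconds."""
        return 1e6 / self.fs

    @property
    def c_mm_us(self) -> float:
        """Speed of sound in mm/us."""
        return self.c / 1000.0

    @property
    def sample_distance_mm(self) -> float:
        """Distance travelled per temporal sample, c * dt (mm)."""
        return self.c_mm_us * self.dt_us

    def with_T(self, T: int) -> "AcousticConfig":
        return AcousticConfig(self.c, self.fs, int(T))


def default_num_samples(geometry: DetectionGeometry, grid: ImageGrid,
                        acoustics: AcousticConfig) -> int:
    """Record length covering the farthest element-to-pixel travel time.

    Returns ceil(max distance / (c dt)) + 16; a small tail margin keeps the
    linear interpolation of the last arrivals inside the record.
    """
    pos = geometry.all_positions()
    half = (grid.extent_mm - grid.pixel_size) / 2.0
    corners = np.array([[sy * half, sx * half] for sy in (-1, 1) for sx in (-1, 1)])
    dmax = max(
        float(np.max(np.linalg.norm(corners - p, axis=1))) for p in pos
    )
    return int(math.ceil(dmax / acoustics.sample_distance_mm)) + 16


# ---------------------------------------------------------------------------
# directivity


@dataclasses.dataclass(frozen=True)
class DirectivityProfile:
    """Angle-dependent element sensitivity, normalised to 1 on axis.

    The default is a monotone (PCHIP) interpolant anchored at the
    datasheet sensitivities of the L14-5/38-class element — 95% at
    0.24 rad and 40% at 0.72 rad — falling to 0 at ``max_angle``.
    Alternatives: ``mode='cosine'`` (cos of the angle, clipped) and
    ``mode='none'`` (omnidirectional).
    """

    anchors: tuple[tuple[float, float], ...] = ((0.0, 1.0), (0.24, 0.95), (0.72, 0.40))
    max_angle: float = 1.2
    mode: str = "anchored-interpolant"

    def __post_init__(self) -> None:
        if self.mode not in ("anchored-interpolant", "cosine", "none"):
            raise ValueError(f"unknown directivity mode {self.mode!r}")
        if self.mode == "anchored-interpolant":
            a = np.asarray(self.anchors, float)
            if a[0, 0] != 0.0 or a[0, 1] != 1.0:
                raise ValueError("anchors must start with (0, 1)")
            if np.any(np.diff(a[:, 0]) <= 0) or np.any(np.diff(a[:, 1]) > 0):
                raise ValueError("anchor amplitudes must be non-increasing in angle")

    def _interp(self) -> PchipInterpolator:
        a = np.asarray(self.anchors, float)
        x = np.append(a[:, 0], self.max_angle)
        y = np.append(a[:, 1], 0.0)
        return PchipInterpolator(x, y, extrapolate=False)

    def __call__(self, angle_rad):
        return directivity(self, angle_rad)


def directivity(profile: DirectivityProfile, angle_rad) -> np.ndarray | float:
    """Evaluate the element sensitivity at (absolute) subtended angles."""
    ang = np.abs(np.asarray(angle_rad, float))
    if profile.mode == "none":
        out = np.ones_like(ang)
    elif profile.mode == "cosine":
        out = np.where(ang >= profile.max_angle, 0.0, np.clip(np.cos(ang), 0.0, 1.0))
    else:
        out = profile._interp()(np.minimum(ang, profile.max_angle))
        out = np.nan_to_num(out, nan=0.0)
        out = np.where(ang >= profile.max_angle, 0.0, np.clip(out, 0.0, 1.0))
    if np.isscalar(angle_rad):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# sparse system blocks


def _element_geometry(
    position: np.ndarray,
    normal: np.ndarray,
    grid: ImageGrid,
    acoustics: AcousticConfig,
    profile: DirectivityProfile,
):
    """Per-pixel distance (clamped), arrival time in samples and amplitude."""
    Y, X = grid.pixel_centers()
    dy = Y.ravel() - position[0]
    dx = X.ravel() - position[1]
    r = np.hypot(dy, dx)
    r = np.maximum(r, grid.pixel_size / 2.0)  # guard the 1/(2 pi r) singularity
    angle = np.arccos(
        np.clip((dy * normal[0] + dx * normal[1]) / r, -1.0, 1.0)
    )
    # 1/(2 pi r) decay with r expressed in sample-travel units r/(c dt) --
    # the same dimensionless distance that indexes the temporal samples.
    # This keeps the operator norm and the solver's step sizes well scaled.
    r_samples = r / acoustics.sample_distance_mm
    amp = directivity(profile, angle) / (2.0 * math.pi * r_samples)
    tau = r / acoustics.sample_distance_mm  # fractional sample index
    return tau, amp


def build_submatrix(
    i: int,
    geometry: DetectionGeometry,
    grid: ImageGrid,
    acoustics: AcousticConfig,
    profile: DirectivityProfile | None = None,
) -> sp.csr_matrix:
    """Sparse T x n^2 block A_i for element ``i`` (global element index)."""
    if profile is None:
        profile = DirectivityProfile()
    pos = geometry.all_positions()
    nrm = geometry.all_normals()
    if not 0 <= i < len(pos):
        raise IndexError(f"element index {i} out of range [0, {len(pos)})")
    return _submatrix_from_element(pos[i], nrm[i], grid, acoustics, profile)


def _submatrix_from_element(position, normal, grid, acoustics, profile) -> sp.csr_matrix:
    T = acoustics.T
    n2 = grid.n * grid.n
    tau, amp = _element_geometry(position, normal, grid, acoustics, profile)
    j0 = np.floor(tau).astype(np.int64)
    w1 = 1.0 - (tau - j0)  # weight of sample j0; 1 - w1 goes to j0 + 1
    cols = np.arange(n2, dtype=np.int64)

    rows_list, cols_list, vals_list = [], [], []
    for j, w in ((j0, w1), (j0 + 1, 1.0 - w1)):
        keep = (w > 0) & (j >= 0) & (j < T) & (amp > 0)
        rows_list.append(j[keep])
        cols_list.append(cols[keep])
        vals_list.append((w * amp)[keep])
    A = sp.csr_matrix(
        (np.concatenate(vals_list), (np.concatenate(rows_list), np.concatenate(cols_list))),
        shape=(T, n2),
    )
    A.sum_duplicates()
    return A


class ProjectionOperator:
    """Stacked sparse projection A = [A_1; ...; A_Q] with forward/adjoint apply.

    Blocks are kept separate so the stochastic solver can address single
    elements; ``forward`` returns the (Q, T) potential matrix G and
    ``adjoint`` maps a (Q, T) residual back to an n x n image.
    """

    def __init__(
        self,
        geometry: DetectionGeometry,
        grid: ImageGrid,
        acoustics: AcousticConfig,
        profile: DirectivityProfile | None = None,
    ):
        self.geometry = geometry
        self.grid = grid
        self.acoustics = acoustics
        self.profile = profile if profile is not None else DirectivityProfile()
        pos = geometry.all_positions()
        nrm = geometry.all_normals()
        self.blocks: list[sp.csr_matrix] = [
            _submatrix_from_element(p, nv, grid, acoustics, self.profile)
            for p, nv in zip(pos, nrm)
        ]
        self._blocks_T = [b.T.tocsr() for b in self.blocks]

    @property
    def Q(self) -> int:
        return len(self.blocks)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.Q * self.acoustics.T, self.grid.n * self.grid.n)

    @property
    def dense_size(self) -> int:
        """Entry count of the full operator if it were stored densely."""
        return self.Q * self.acoustics.T * self.grid.n * self.grid.n

    @property
    def block_dense_size(self) -> int:
        """Entry count of one dense block A_i (T x n^2)."""
        return self.acoustics.T * self.grid.n * self.grid.n

    @property
    def nnz(self) -> int:
        return sum(b.nnz for b in self.blocks)

    def _vec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if x.ndim == 2:
            if x.shape != (self.grid.n, self.grid.n):
                raise ValueError("image shape does not match the grid")
            x = x.ravel()
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """G = A vec(x), returned as a (Q, T) matrix."""
        xv = self._vec(x)
        out = np.empty((self.Q, self.acoustics.T))
        for i, b in enumerate(self.blocks):
            out[i] = b @ xv
        return out

    def forward_block(self, i: int, x: np.ndarray) -> np.ndarray:
        return self.blocks[i] @ self._vec(x)

    def adjoint(self, g: np.ndarray) -> np.ndarray:
        """A^T vec(G), returned as an n x n image."""
        g = np.asarray(g, float)
        if g.shape != (self.Q, self.acoustics.T):
            raise ValueError("data shape does not match (Q, T)")
        acc = np.zeros(self.grid.n * self.grid.n)
        for i, bt in enumerate(self._blocks_T):
            acc += bt @ g[i]
        return acc.reshape(self.grid.n, self.grid.n)

    def adjoint_block(self, i: int, g_i: np.ndarray) -> np.ndarray:
        return (self._blocks_T[i] @ np.asarray(g_i, float)).reshape(
            self.grid.n, self.grid.n
        )

    def to_dense(self) -> np.ndarray:
        """Materialise the stacked operator densely (guarded small cases only)."""
        if self.dense_size > DENSE_ENTRY_BUDGET:
            raise MemoryError(
                f"dense operator would hold {self.dense_size:.3g} entries, "
                f"budget is {DENSE_ENTRY_BUDGET:.3g}"
            )
        return sp.vstack(self.blocks).toarray()


def build_projection(
    geometry: DetectionGeometry,
    grid: ImageGrid,
    acoustics: AcousticConfig,
    profile: DirectivityProfile | None = None,
) -> ProjectionOperator:
    """Build the full sparse projection operator for a detection geometry."""
    return ProjectionOperator(geometry, grid, acoustics, profile)


# ---------------------------------------------------------------------------
# data containers


@dataclasses.dataclass
class Sinogram:
    """Per-element pressure time series p(t), shaped (Q, T)."""

    data: np.ndarray
    acoustics: AcousticConfig
    geometry: DetectionGeometry | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[1] != self.acoustics.T:
            raise ValueError("sinogram must be (Q, T) matching the acoustics")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")


@dataclasses.dataclass
class PotentialData:
    """Per-element acoustic velocity potential G, shaped (Q, T)."""

    data: np.ndarray
    acoustics: AcousticConfig
    geometry: DetectionGeometry | None = None
    provenance: str = "matrix-forward"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[1] != self.acoustics.T:
            raise ValueError("potential data must be (Q, T) matching the acoustics")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("potential data contains non-finite values")


def pressure_to_potential(s: Sinogram) -> PotentialData:
    """Cumulative time integral of the pressure, per channel (trapezoid rule)."""
    g = cumulative_trapezoid(s.data, dx=s.acoustics.dt_us, axis=1, initial=0.0)
    return PotentialData(
        data=g, acoustics=s.acoustics, geometry=s.geometry,
        provenance="integrated-from-pressure",
    )


def potential_to_pressure(g: PotentialData) -> Sinogram:
    """Central-difference time derivative of the potential, per channel."""
    p = np.gradient(g.data, g.acoustics.dt_us, axis=1)
    return Sinogram(data=p, acoustics=g.acoustics, geometry=g.geometry)


# ---------------------------------------------------------------------------
# synthetic data generation


def simulate_data(
    phantom: Phantom,
    geometry: DetectionGeometry,
    acoustics: AcousticConfig,
    profile: DirectivityProfile | None = None,
    refine: int = 2,
    noise_sd: float = 0.0,
    seed: int | None = None,
    antialias: bool = True,
) -> tuple[Sinogram, PotentialData]:
    """Simulate per-element data with the discrete forward model.

    The phantom is re-rasterised on a ``refine`` x finer grid and projected
    with the fine-grid operator, so that reconstruction on the original
    grid does not commit the inverse crime (refine >= 2); refine = 1
    reproduces the reconstruction-grid operator exactly.  The fine forward
    sum is weighted by the pixel-area ratio 1/refine^2, making the data
    amplitude resolution-independent.  Pressure is the time derivative of
    the potential.

    Differentiating a rasterised potential amplifies pixel-quantisation
    ripple at the sampling frequency, which a wave-propagation simulator
    would not produce; with ``antialias`` (the default) the pressure is
    smoothed by a Gaussian over the pixel-crossing time
    (sigma = pixel/(2 c dt) samples), suppressing exactly that
    rasterisation artifact.  Set ``antialias=False`` to obtain the raw
    sample-exact derivative (used by the model-property tests).  Optional
    white noise (std = ``noise_sd`` x peak |p|) is added to the pressure
    with the seeded generator; the returned potential is re-integrated
    from the noisy pressure in that case, and is otherwise the exact
    matrix-forward projection.
    """
    if profile is None:
        profile = DirectivityProfile()
    if refine < 1:
        raise ValueError("refine must be >= 1")
    fine_grid = phantom.grid.refined(refine)
    x = phantom.on_grid(fine_grid).ravel()

    pos = geometry.all_positions()
    nrm = geometry.all_normals()
    T = acoustics.T
    G = np.empty((len(pos), T))
    scale = 1.0 / (refine * refine)
    for idx, (p, nv) in enumerate(zip(pos, nrm)):
        tau, amp = _element_geometry(p, nv, fine_grid, acoustics, profile)
        j0 = np.floor(tau).astype(np.int64)
        w1 = 1.0 - (tau - j0)
        row = np.zeros(T + 2)
        np.add.at(row, np.clip(j0, 0, T + 1), w1 * amp * x)
        np.add.at(row, np.clip(j0 + 1, 0, T + 1), (1.0 - w1) * amp * x)
        G[idx] = row[:T] * scale

    potential = PotentialData(
        data=G, acoustics=acoustics, geometry=geometry, provenance="matrix-forward"
    )
    pressure = potential_to_pressure(potential)
    if antialias:
        from scipy.ndimage import gaussian_filter1d

        sigma = fine_grid.pixel_size / (2.0 * acoustics.sample_distance_mm)
        pressure = Sinogram(
            data=gaussian_filter1d(pressure.data, sigma, axis=1),
            acoustics=acoustics, geometry=geometry,
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_sd * np.max(np.abs(pressure.data))
        pressure = Sinogram(
            data=pressure.data + rng.normal(0.0, sigma, pressure.data.shape),
            acoustics=acoustics, geometry=geometry,
        )
        potential = pressure_to_potential(pressure)
    return pressure, potential
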