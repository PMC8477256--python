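"""Reconstruction grids and synthetic initial-pressure phantoms.

The image plane is a square n x n pixel grid centred on the physical
origin.  Physical coordinates are in millimetres; the first image axis is
depth (pointing away from the "top" transducer array), the second axis is
lateral.  Pixel index (i, j) maps to the physical pixel-centre coordinate
``(-(extent - pixel)/2 + i*pixel, -(extent - pixel)/2 + j*pixel)``.

Phantoms are nonnegative intensity maps normalised so the maximum is
exactly 1; they stand in for the initial acoustic pressure distribution
an optical pulse would deposit in a thin tissue slab.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ImageGrid",
    "Phantom",
    "make_grid",
    "forbild_phantom",
    "vessel_tree_phantom",
    "vessel_tree_segments",
    "dot_grid_phantom",
    "disc_phantom",
    "polygon_phantom",
]

#: supersampling factor used for anti-aliased rasterisation (per axis)
SUPERSAMPLE = 4


@dataclasses.dataclass(frozen=True)
class ImageGrid:
    """Square pixel grid with physical extent, centred at the origin."""

    n: int
    extent_mm: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"grid needs n >= 2 pixels per side, got {self.n}")
        if self.extent_mm <= 0:
            raise ValueError(f"grid extent must be positive, got {self.extent_mm}")

    @property
    def pixel_size(self) -> float:
        """Pixel side length in mm."""
        return self.extent_mm / self.n

    @property
    def origin(self) -> np.ndarray:
        """Physical coordinate of the grid centre (always the origin)."""
        return np.zeros(2)

    def axis_coords(self) -> np.ndarray:
        """Pixel-centre coordinates along one axis (identical for both axes)."""
        return (np.arange(self.n) - (self.n - 1) / 2.0) * self.pixel_size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (depth, lateral) coordinate maps, each shaped (n, n)."""
        c = self.axis_coords()
        return np.meshgrid(c, c, indexing="ij")

    def refined(self, factor: int) -> "ImageGrid":
        """Grid with the same extent and ``factor`` x more pixels per side."""
        if factor < 1:
            raise ValueError("refinement factor must be >= 1")
        return ImageGrid(self.n * factor, self.extent_mm)


@dataclasses.dataclass
class Phantom:
    """A synthetic initial-pressure map on an :class:`ImageGrid`.

    ``render`` regenerates the same object on another grid (used by the
    data simulator to rasterise on a finer grid than the reconstruction
    grid, avoiding the inverse crime).
    """

    image: np.ndarray
    grid: ImageGrid
    name: str
    seed: int | None = None
    render: Callable[[ImageGrid], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.shape != (self.grid.n, self.grid.n):
            raise ValueError("phantom image dimensions do not match the grid")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("phantom values must lie in [0, 1]")
        if not np.any(self.image):
            raise ValueError("phantom has no nonzero pixel")

    def on_grid(self, grid: ImageGrid) -> np.ndarray:
        """Rasterise this phantom on ``grid`` (re-render or resample)."""
        if grid.n == self.grid.n and grid.extent_mm == self.grid.extent_mm:
            return self.image.copy()
        if self.render is not None:
            return self.render(grid)
        # fallback: nearest-block resampling of the stored raster
        from scipy.ndimage import zoom

        out = zoom(self.image, grid.n / self.grid.n, order=1)
        return np.clip(out, 0.0, 1.0)


def make_grid(n: int, extent_mm: float) -> ImageGrid:
    """Build a centred square reconstruction grid.

    Parameters
    ----------
    n : pixels per side (the study default is 128).
    extent_mm : physical side length in mm (the study default is 38).
    """
    return ImageGrid(int(n), float(extent_mm))


# ---------------------------------------------------------------------------
# rasterisation helpers


def _fine_coords(grid: ImageGrid, ss: int = SUPERSAMPLE) -> np.ndarray:
    nf = grid.n * ss
    step = grid.extent_mm / nf
    return (np.arange(nf) - (nf - 1) / 2.0) * step


def _downsample(fine: np.ndarray, ss: int = SUPERSAMPLE) -> np.ndarray:
    n = fine.shape[0] // ss
    return fine.reshape(n, ss, n, ss).mean(axis=(1, 3))


def _normalize(img: np.ndarray) -> np.ndarray:
    m = img.max()
    if m <= 0:
        raise ValueError("rasterisation produced an empty image")
    out = img / m
    # guard against tiny negative round-off
    return np.clip(out, 0.0, 1.0)


def _paint_ellipse(canvas, Y, X, cy, cx, ry, rx, angle_deg, value):
    """Paint a (rotated) filled ellipse onto canvas, painter's order."""
    t = math.radians(angle_deg)
    dy, dx = Y - cy, X - cx
    u = math.cos(t) * dy + math.sin(t) * dx
    v = -math.sin(t) * dy + math.cos(t) * dx
    inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    canvas[inside] = value


# ---------------------------------------------------------------------------
# FORBILD-style head phantom


def _forbild_raster(grid: ImageGrid) -> np.ndarray:
    """Deterministic rendition of the public FORBILD head-phantom geometry.

    The analytic primitive list (ellipses/circles in a ~24 cm tall head)
    is scaled to the grid extent and painted in order; CT attenuation
    values are kept only as relative greys and affinely remapped to
    [0, 1] afterwards.
    """
    c = _fine_coords(grid)
    Y, X = np.meshgrid(c, c, indexing="ij")
    # nominal head half-height is 12 units; fit into 85% of the half-extent,
    # keeping a clear margin between the object and in-plane detector arrays
    # (the point-detector model diverges for sources adjacent to an element)
    s = (grid.extent_mm / 2.0) * 0.85 / 12.0

    canvas = np.zeros_like(Y)

    def ell(cx_u, cy_u, rx_u, ry_u, ang, val):
        # phantom "up" direction maps to negative depth (towards the top array)
        _paint_ellipse(canvas, Y, X, -cy_u * s, cx_u * s, ry_u * s, rx_u * s, ang, val)

    # outer skull shell and brain
    ell(0.0, 0.0, 9.6, 12.0, 0.0, 1.800)
    ell(0.0, 0.0, 9.0, 11.4, 0.0, 1.035)
    # frontal sinus: air pocket at the top of the skull
    ell(0.0, 9.2, 1.8, 1.8, 0.0, 0.0)
    # lateral ventricles: two tilted low-intensity ellipses
    ell(-2.2, 1.0, 1.7, 3.2, -25.0, 1.000)
    ell(2.2, 1.0, 1.7, 3.2, 25.0, 1.000)
    # internal bone disc and a small blood clot
    ell(1.9, -5.9, 1.8, 1.8, 0.0, 1.800)
    ell(-3.4, -4.2, 0.9, 1.4, 15.0, 1.100)
    # eyes with lenses, near the bottom of the head
    ell(-4.0, 7.0, 1.2, 1.2, 0.0, 1.050)
    ell(4.0, 7.0, 1.2, 1.2, 0.0, 1.050)
    ell(-4.0, 7.4, 0.45, 0.45, 0.0, 1.100)
    ell(4.0, 7.4, 0.45, 0.45, 0.0, 1.100)
    # sharp low-contrast resolution dots (ear-like insert)
    for k, r in enumerate((0.45, 0.35, 0.25)):
        ell(5.4, -1.8 + 1.3 * k, r, r, 0.0, 1.800)

    img = _downsample(canvas)
    return _normalize(img)


def forbild_phantom(grid: ImageGrid) -> Phantom:
    """FORBILD-style head phantom with sharp, distinguishable features."""
    return Phantom(
        image=_forbild_raster(grid),
        grid=grid,
        name="forbild",
        render=_forbild_raster,
    )


# ---------------------------------------------------------------------------
# procedural vessel-tree phantom


def vessel_tree_segments(
    grid: ImageGrid,
    seed: int = 0,
    depth: int = 5,
    root_width_px: float = 3.0,
) -> list[tuple[np.ndarray, np.ndarray, float, int]]:
    """Generate the branching-segment list of the vessel-tree phantom.

    Returns a list of ``(start, end, width_mm, level)`` tuples (levels are
    1-based; level ``depth`` segments are the tips).  A level-k parent
    spawns two level-(k+1) children with seeded random branching angles,
    shrinking length and width — a minimal mimic of a vascular tree.
    """
    if depth < 1:
        raise ValueError(f"tree depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    half = grid.extent_mm / 2.0
    start = np.array([-0.92 * half, 0.0])  # root enters from the top edge
    length0 = 0.30 * grid.extent_mm
    width0 = root_width_px * grid.pixel_size

    segments: list[tuple[np.ndarray, np.ndarray, float, int]] = []

    def grow(p0, direction, length, width, level):
        p1 = p0 + length * direction
        segments.append((p0, p1, width, level))
        if level == depth:
            return
        for sign in (-1.0, 1.0):
            ang = sign * math.radians(rng.uniform(15.0, 40.0))
            rot = np.array(
                [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
            )
            grow(p1, rot @ direction, 0.72 * length, 0.70 * width, level + 1)

    grow(start, np.array([1.0, 0.0]), length0, width0, 1)
    return segments


def _render_tree(grid, seed, depth, root_width_px):
    segs = vessel_tree_segments(grid, seed=seed, depth=depth, root_width_px=root_width_px)
    c = _fine_coords(grid)
    Y, X = np.meshgrid(c, c, indexing="ij")
    canvas = np.zeros_like(Y)
    for p0, p1, width, _level in segs:
        d = p1 - p0
        L2 = float(d @ d)
        t = np.clip(((Y - p0[0]) * d[0] + (X - p0[1]) * d[1]) / L2, 0.0, 1.0)
        dist2 = (Y - p0[0] - t * d[0]) ** 2 + (X - p0[1] - t * d[1]) ** 2
        canvas[dist2 <= (width / 2.0) ** 2] = 1.0
    return _normalize(_downsample(canvas))


def vessel_tree_phantom(
    grid: ImageGrid,
    seed: int = 0,
    depth: int = 5,
    root_width_px: float = 3.0,
) -> Phantom:
    """Seeded recursive branching phantom mimicking a blood-vessel tree."""
    if depth < 1:
        raise ValueError(f"tree depth must be >= 1, got {depth}")
    return Phantom(
        image=_render_tree(grid, seed, depth, root_width_px),
        grid=grid,
        name="tree",
        seed=seed,
        render=lambda g: _render_tree(g, seed, depth, root_width_px),
    )


# ---------------------------------------------------------------------------
# dot grids, discs, polygons


def _render_dots(grid, rows, cols, dot_diameter_mm, spacing_mm):
    c = _fine_coords(grid)
    Y, X = np.meshgrid(c, c, indexing="ij")
    canvas = np.zeros_like(Y)
    r = dot_diameter_mm / 2.0
    cy = (np.arange(rows) - (rows - 1) / 2.0) * spacing_mm
    cx = (np.arange(cols) - (cols - 1) / 2.0) * spacing_mm
    for y0 in cy:
        for x0 in cx:
            canvas[(Y - y0) ** 2 + (X - x0) ** 2 <= r**2] = 1.0
    return _normalize(_downsample(canvas))


def dot_grid_phantom(
    grid: ImageGrid,
    rows: int,
    cols: int,
    dot_diameter_mm: float = 0.1,
    spacing_mm: float = 1.0,
) -> Phantom:
    """Array of small discs, mimicking printed dots embedded in gelatin."""
    if rows < 1 or cols < 1 or dot_diameter_mm <= 0 or spacing_mm <= 0:
        raise ValueError("rows, cols, diameter and spacing must be positive")
    half_w = (cols - 1) / 2.0 * spacing_mm + dot_diameter_mm / 2.0
    half_h = (rows - 1) / 2.0 * spacing_mm + dot_diameter_mm / 2.0
    if max(half_h, half_w) > grid.extent_mm / 2.0:
        raise ValueError("dot array does not fit inside the grid extent")
    return Phantom(
        image=_render_dots(grid, rows, cols, dot_diameter_mm, spacing_mm),
        grid=grid,
        name="dots",
        render=lambda g: _render_dots(g, rows, cols, dot_diameter_mm, spacing_mm),
    )


def _render_discs(grid, centers, radii, values):
    c = _fine_coords(grid)
    Y, X = np.meshgrid(c, c, indexing="ij")
    canvas = np.zeros_like(Y)
    for (y0, x0), r, v in zip(centers, radii, values):
        canvas[(Y - y0) ** 2 + (X - x0) ** 2 <= r**2] = v
    return _normalize(_downsample(canvas))


def disc_phantom(
    grid: ImageGrid,
    centers: Sequence[Sequence[float]] = ((0.0, 0.0),),
    radii_mm: Sequence[float] | float = 5.0,
    values: Sequence[float] | None = None,
) -> Phantom:
    """One or more filled discs at given (depth, lateral) centres."""
    centers = [np.asarray(c, float) for c in centers]
    if np.isscalar(radii_mm):
        radii = [float(radii_mm)] * len(centers)
    else:
        radii = [float(r) for r in radii_mm]
    if values is None:
        values = [1.0] * len(centers)
    for c, r in zip(centers, radii):
        if np.max(np.abs(c)) + r > grid.extent_mm / 2.0:
            raise ValueError("disc extends beyond the grid")
    return Phantom(
        image=_render_discs(grid, centers, radii, values),
        grid=grid,
        name="discs",
        render=lambda g: _render_discs(g, centers, radii, values),
    )


def _render_polygon(grid, vertices):
    c = _fine_coords(grid)
    Y, X = np.meshgrid(c, c, indexing="ij")
    verts = np.asarray(vertices, float)
    inside = np.zeros(Y.shape, dtype=bool)
    # even-odd ray casting along the lateral axis
    for (y0, x0), (y1, x1) in zip(verts, np.roll(verts, -1, axis=0)):
        crosses = (y0 > Y) != (y1 > Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (x1 - x0) * (Y - y0) / (y1 - y0) + x0
        inside ^= crosses & (X < x_at)
    return _normalize(_downsample(inside.astype(float)))


def polygon_phantom(grid: ImageGrid, vertices: Sequence[Sequence[float]],
                    name: str = "polygon") -> Phantom:
    """Filled polygon phantom (e.g. an octagon test target)."""
    verts = np.asarray(vertices, float)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise ValueError("need at least 3 polygon vertices")
    return Phantom(
        image=_render_polygon(grid, verts),
        grid=grid,
        name=name,
        render=lambda g: _render_polygon(g, verts),
    )
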