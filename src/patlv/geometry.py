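"""Transducer-array detection geometries and the dual-probe rigid transform.

Coordinates follow the grid convention: 2-vectors are (depth, lateral) in
mm, with the grid centred at the origin and the reference ("top") array at
negative depth.  A linear array is a row of Q point-like element centres
with uniform pitch and a facing normal per element; multi-array geometries
are ordered lists of such arrays.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .grids import ImageGrid

__all__ = [
    "TransducerArray",
    "DetectionGeometry",
    "RigidTransform",
    "make_single",
    "make_dual",
    "make_parallel",
    "make_L",
    "make_square",
    "apply_rigid_transform",
    "max_roi_subtended_angle",
]


@dataclasses.dataclass(frozen=True)
class TransducerArray:
    """A linear array: element centres, facing normals and pitch (mm)."""

    positions: np.ndarray  # (Q, 2) in mm, (depth, lateral)
    normals: np.ndarray  # (Q, 2) unit vectors
    pitch: float

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, float))
        nrm = np.atleast_2d(np.asarray(self.normals, float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "normals", nrm)
        if pos.shape != nrm.shape or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValueError("positions and normals must both be (Q, 2) with Q >= 1")
        lengths = np.linalg.norm(nrm, axis=1)
        if not np.allclose(lengths, 1.0, atol=1e-9):
            raise ValueError("element normals must be unit vectors")
        if pos.shape[0] > 1:
            spacing = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            if not np.allclose(spacing, self.pitch, atol=1e-9):
                raise ValueError("element spacing must equal the pitch")

    @property
    def Q(self) -> int:
        return self.positions.shape[0]


@dataclasses.dataclass(frozen=True)
class DetectionGeometry:
    """One or more coplanar linear arrays around the imaging region."""

    arrays: tuple[TransducerArray, ...]
    label: str
    theta_deg: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "arrays", tuple(self.arrays))
        if not self.arrays:
            raise ValueError("a detection geometry needs at least one array")

    @property
    def total_elements(self) -> int:
        return sum(a.Q for a in self.arrays)

    def all_positions(self) -> np.ndarray:
        return np.concatenate([a.positions for a in self.arrays], axis=0)

    def all_normals(self) -> np.ndarray:
        return np.concatenate([a.normals for a in self.arrays], axis=0)


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: translation (h, k) composed with rotation theta.

    Maps coordinates expressed in a second probe's frame into the first
    probe's (imaging) frame through the inverse of ``T(h, k) @ R(theta)``.
    """

    h: float
    k: float
    theta: float  # radians

    def matrix(self) -> np.ndarray:
        """Forward homogeneous matrix T(h, k) @ R(theta)."""
        ct, st = math.cos(self.theta), math.sin(self.theta)
        T = np.array([[1.0, 0.0, self.h], [0.0, 1.0, self.k], [0.0, 0.0, 1.0]])
        R = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
        return T @ R

    def inverse(self) -> "RigidTransform":
        # (T R)^-1 = R(-theta) T(-h, -k); re-expressed as T(h', k') R(-theta)
        ct, st = math.cos(self.theta), math.sin(self.theta)
        hp = -(ct * self.h + st * self.k)
        kp = -(-st * self.h + ct * self.k)
        return RigidTransform(hp, kp, -self.theta)


def apply_rigid_transform(
    t: RigidTransform, coords_second_frame: Iterable[Sequence[float]]
) -> np.ndarray:
    """Map (i', j') points from the second probe's frame to the imaging frame.

    Computes ``(i, j, 1) = [T(h,k) @ R(theta)]^{-1} @ (i', j', 1)`` for each
    input point; returns an (N, 2) array.
    """
    pts = np.atleast_2d(np.asarray(list(coords_second_frame), float))
    hom = np.column_stack([pts, np.ones(len(pts))])
    out = hom @ np.linalg.inv(t.matrix()).T
    return out[:, :2]


# ---------------------------------------------------------------------------
# geometry constructors


def _top_array(grid: ImageGrid, Q: int, pitch_mm: float, standoff_mm: float) -> TransducerArray:
    if Q < 1 or pitch_mm <= 0:
        raise ValueError("need Q >= 1 elements and positive pitch")
    lateral = (np.arange(Q) - (Q - 1) / 2.0) * pitch_mm
    depth = np.full(Q, -grid.extent_mm / 2.0 - standoff_mm)
    positions = np.column_stack([depth, lateral])
    normals = np.tile([1.0, 0.0], (Q, 1))  # facing into the grid (+depth)
    return TransducerArray(positions=positions, normals=normals, pitch=pitch_mm)


def _rotate_array(a: TransducerArray, angle_rad: float) -> TransducerArray:
    ct, st = math.cos(angle_rad), math.sin(angle_rad)
    R = np.array([[ct, -st], [st, ct]])
    return TransducerArray(
        positions=a.positions @ R.T, normals=a.normals @ R.T, pitch=a.pitch
    )


def make_single(
    grid: ImageGrid, Q: int = 128, pitch_mm: float = 0.3, standoff_mm: float = 0.0
) -> DetectionGeometry:
    """Single linear array on the top edge, facing the grid interior."""
    return DetectionGeometry(
        arrays=(_top_array(grid, Q, pitch_mm, standoff_mm),), label="single"
    )


def make_dual(
    grid: ImageGrid,
    Q: int = 128,
    pitch_mm: float = 0.3,
    theta_deg: float = 90.0,
    standoff_mm: float = 0.0,
) -> DetectionGeometry:
    """Two identical arrays whose facing directions differ by ``theta_deg``.

    The first array sits on the top edge; the second is the first rotated
    by theta about the grid centre, so both are aimed at the centre.
    theta = 180 deg gives the parallel shape, theta = 90 deg the L shape.
    """
    if not 0.0 < theta_deg <= 180.0:
        raise ValueError(f"dual-probe angle must be in (0, 180] deg, got {theta_deg}")
    first = _top_array(grid, Q, pitch_mm, standoff_mm)
    second = _rotate_array(first, math.radians(theta_deg))
    label = {180.0: "parallel", 90.0: "L"}.get(float(theta_deg), "dual")
    return DetectionGeometry(arrays=(first, second), label=label, theta_deg=theta_deg)


def make_parallel(grid: ImageGrid, Q: int = 128, pitch_mm: float = 0.3,
                  standoff_mm: float = 0.0) -> DetectionGeometry:
    """Dual-probe parallel shape (theta = 180 deg, opposite sides)."""
    return make_dual(grid, Q, pitch_mm, theta_deg=180.0, standoff_mm=standoff_mm)


def make_L(grid: ImageGrid, Q: int = 128, pitch_mm: float = 0.3,
           standoff_mm: float = 0.0) -> DetectionGeometry:
    """Dual-probe L shape (theta = 90 deg, adjacent sides)."""
    return make_dual(grid, Q, pitch_mm, theta_deg=90.0, standoff_mm=standoff_mm)


def make_square(
    grid: ImageGrid, Q: int = 128, pitch_mm: float = 0.3, standoff_mm: float = 0.0
) -> DetectionGeometry:
    """Four arrays enclosing the grid on all sides (full-view reference)."""
    first = _top_array(grid, Q, pitch_mm, standoff_mm)
    arrays = tuple(
        _rotate_array(first, math.radians(a)) for a in (0.0, 90.0, 180.0, 270.0)
    )
    return DetectionGeometry(arrays=arrays, label="square")


def geometry_by_label(
    grid: ImageGrid,
    label: str,
    Q: int = 128,
    pitch_mm: float = 0.3,
    theta_deg: float | None = None,
    standoff_mm: float = 0.0,
) -> DetectionGeometry:
    """Dispatch constructor used by the CLI and study driver."""
    label = label.lower()
    if label == "single":
        return make_single(grid, Q, pitch_mm, standoff_mm)
    if label == "parallel":
        return make_parallel(grid, Q, pitch_mm, standoff_mm)
    if label in ("l", "l-shape"):
        return make_L(grid, Q, pitch_mm, standoff_mm)
    if label == "dual":
        if theta_deg is None:
            raise ValueError("dual geometry needs an explicit theta")
        return make_dual(grid, Q, pitch_mm, theta_deg, standoff_mm)
    if label == "square":
        return make_square(grid, Q, pitch_mm, standoff_mm)
    raise ValueError(f"unknown geometry label {label!r}")


# ---------------------------------------------------------------------------
# directivity-angle bookkeeping


def max_roi_subtended_angle(
    Q: int = 128,
    pitch_mm: float = 0.3,
    roi_width_mm: float = 15.0,
    roi_height_mm: float = 15.0,
    standoff_mm: float = 30.0,
    element: str = "end",
) -> float:
    """Largest in-plane angle (rad) between an element's normal and any ROI corner.

    The array lies along the lateral axis with end elements at
    +/-(Q-1)*pitch/2; a laterally centred rectangular ROI has its near face
    ``standoff_mm`` from the array.  For ``element='end'`` the worst-case
    (end) element is used, for ``'center'`` the central one.
    """
    if element == "end":
        ex = (Q - 1) * pitch_mm / 2.0
    elif element == "center":
        ex = 0.0
    else:
        raise ValueError("element must be 'end' or 'center'")
    corners_lat = (-roi_width_mm / 2.0, roi_width_mm / 2.0)
    corners_ax = (standoff_mm, standoff_mm + roi_height_mm)
    return max(
        math.atan(abs(lat - ex) / ax) for lat in corners_lat for ax in corners_ax
    )
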