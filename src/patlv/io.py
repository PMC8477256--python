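"""Serialization of phantoms, geometries, data and images.

Arrays are stored as 32-bit float ``.npz`` containers with a JSON sidecar
carrying the grid/acoustics/provenance metadata; geometries are plain
JSON.  PNG previews (8-bit, symmetric range for signed images) are
optional conveniences for visual inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .das import ReconImage
from .forward import AcousticConfig, PotentialData, Sinogram
from .geometry import DetectionGeometry, TransducerArray
from .grids import ImageGrid, Phantom


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_phantom(phantom: Phantom, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, image=phantom.image.astype(np.float32))
    meta = {
        "kind": "phantom",
        "name": phantom.name,
        "seed": phantom.seed,
        "grid": {"n": phantom.grid.n, "extent_mm": phantom.grid.extent_mm},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_phantom(path: str | Path) -> Phantom:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        image = np.asarray(z["image"], float)
    grid = ImageGrid(meta["grid"]["n"], meta["grid"]["extent_mm"])
    return Phantom(image=image, grid=grid, name=meta["name"], seed=meta.get("seed"))


def save_geometry(geom: DetectionGeometry, path: str | Path) -> None:
    payload = {
        "kind": "geometry",
        "label": geom.label,
        "theta_deg": geom.theta_deg,
        "arrays": [
            {
                "positions": a.positions.tolist(),
                "normals": a.normals.tolist(),
                "pitch": a.pitch,
            }
            for a in geom.arrays
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_geometry(path: str | Path) -> DetectionGeometry:
    payload = json.loads(Path(path).read_text())
    arrays = tuple(
        TransducerArray(
            positions=np.asarray(a["positions"], float),
            normals=np.asarray(a["normals"], float),
            pitch=a["pitch"],
        )
        for a in payload["arrays"]
    )
    return DetectionGeometry(
        arrays=arrays, label=payload["label"], theta_deg=payload.get("theta_deg")
    )


def save_timeseries(
    obj: Sinogram | PotentialData, path: str | Path, extra: dict | None = None
) -> None:
    path = Path(path)
    np.savez(path, data=obj.data.astype(np.float32))
    meta = {
        "kind": "potential" if isinstance(obj, PotentialData) else "sinogram",
        "acoustics": {"c": obj.acoustics.c, "fs": obj.acoustics.fs, "T": obj.acoustics.T},
    }
    if isinstance(obj, PotentialData):
        meta["provenance"] = obj.provenance
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_timeseries(path: str | Path) -> Sinogram | PotentialData:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        data = np.asarray(z["data"], float)
    ac = AcousticConfig(**meta["acoustics"])
    if meta["kind"] == "potential":
        return PotentialData(data=data, acoustics=ac,
                             provenance=meta.get("provenance", "matrix-forward"))
    return Sinogram(data=data, acoustics=ac)


def save_image(img: ReconImage, path: str | Path, extra: dict | None = None) -> None:
    path = Path(path)
    np.savez(path, image=img.image.astype(np.float32))
    meta = {
        "kind": "image",
        "method": img.method,
        "normalization": img.normalization,
        "grid": {"n": img.grid.n, "extent_mm": img.grid.extent_mm},
    }
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_image(path: str | Path) -> ReconImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        image = np.asarray(z["image"], float)
    grid = ImageGrid(meta["grid"]["n"], meta["grid"]["extent_mm"])
    return ReconImage(image, grid, meta.get("method", "DAS"),
                      meta.get("normalization", "raw"))


def export_png(image: np.ndarray, path: str | Path) -> None:
    """8-bit PNG preview; signed images use a symmetric grey scale."""
    import imageio.v3 as iio

    image = np.asarray(image, float)
    lo, hi = image.min(), image.max()
    if lo < 0:
        m = max(abs(lo), abs(hi)) or 1.0
        scaled = (image / m + 1.0) / 2.0
    else:
        scaled = image / (hi or 1.0)
    iio.imwrite(Path(path), (np.clip(scaled, 0, 1) * 255).astype(np.uint8))
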