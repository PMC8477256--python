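"""End-to-end geometry study: simulate, reconstruct, score, tabulate.

Reproduces the simulation-study design: one phantom, a list of detection
geometries, per-geometry data simulation on a refined grid, DAS and
VR-SGD reconstruction, and an RMSE table (both images max-normalised)
plus RMSE-versus-iteration traces for the iterative solver.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .das import ReconImage, das_reconstruct
from .forward import (
    AcousticConfig,
    DirectivityProfile,
    build_projection,
    default_num_samples,
    simulate_data,
)
from .geometry import geometry_by_label
from .grids import (
    Phantom,
    disc_phantom,
    dot_grid_phantom,
    forbild_phantom,
    make_grid,
    vessel_tree_phantom,
)
from .metrics import normalized_rmse
from .vrsgd import VRSGDConfig, vrsgd_reconstruct

logger = logging.getLogger("patlv")

__all__ = ["StudyConfig", "StudyResult", "run_geometry_study",
           "load_config", "save_config", "table1_config"]

GEOMETRY_LABELS = ("single", "parallel", "L", "square")


@dataclasses.dataclass
class StudyConfig:
    """Declarative description of one simulation study."""

    phantom: dict = dataclasses.field(
        default_factory=lambda: {"kind": "forbild", "n": 128, "extent_mm": 38.0}
    )
    geometries: tuple[str, ...] = GEOMETRY_LABELS
    elements_per_array: int = 128
    pitch_mm: float = 0.3
    standoff_mm: float = 0.0
    c: float = 1500.0
    fs: float = 40e6
    refine: int = 2
    noise_sd: float = 0.0
    sim_seed: int = 0
    directivity: str = "anchored-interpolant"
    solver: VRSGDConfig = dataclasses.field(default_factory=VRSGDConfig)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometries"] = list(self.geometries)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclasses.dataclass
class StudyResult:
    config: StudyConfig
    phantom: Phantom
    images: dict[tuple[str, str], ReconImage]  # (geometry, method) -> image
    rmse: dict[tuple[str, str], float]
    traces: dict[str, np.ndarray]  # geometry -> per-iteration RMSE

    def rmse_rows(self) -> list[tuple[str, str, float]]:
        return [(g, m, v) for (g, m), v in sorted(self.rmse.items())]

    def summary_csv(self) -> str:
        lines = ["geometry,method,rmse"]
        for g, m, v in self.rmse_rows():
            lines.append(f"{g},{m},{v:.6f}")
        return "\n".join(lines) + "\n"


def _build_phantom(spec: dict) -> Phantom:
    spec = dict(spec)
    kind = spec.pop("kind", "forbild")
    grid = make_grid(spec.pop("n", 128), spec.pop("extent_mm", 38.0))
    if kind == "forbild":
        return forbild_phantom(grid)
    if kind == "tree":
        return vessel_tree_phantom(grid, **spec)
    if kind == "dots":
        spec.setdefault("rows", 4)
        spec.setdefault("cols", 4)
        return dot_grid_phantom(grid, **spec)
    if kind == "discs":
        return disc_phantom(grid, **spec)
    raise ValueError(f"unknown phantom kind {kind!r}")


def run_geometry_study(
    cfg: StudyConfig,
    out_dir: str | Path | None = None,
    truth_trace: bool = True,
) -> StudyResult:
    """Run the full study described by ``cfg``; optionally write artifacts."""
    phantom = _build_phantom(cfg.phantom)
    grid = phantom.grid
    profile = DirectivityProfile(mode=cfg.directivity)
    truth = phantom.image / phantom.image.max()

    images: dict[tuple[str, str], ReconImage] = {}
    rmse_table: dict[tuple[str, str], float] = {}
    traces: dict[str, np.ndarray] = {}

    for label in cfg.geometries:
        geom = geometry_by_label(
            grid, label, Q=cfg.elements_per_array, pitch_mm=cfg.pitch_mm,
            standoff_mm=cfg.standoff_mm,
        )
        acoustics = AcousticConfig(cfg.c, cfg.fs, 1).with_T(
            default_num_samples(geom, grid, AcousticConfig(cfg.c, cfg.fs, 1))
        )
        logger.info("[%s] simulating data (Q=%d, T=%d, refine=%d)",
                    label, geom.total_elements, acoustics.T, cfg.refine)
        sino, potential = simulate_data(
            phantom, geom, acoustics, profile,
            refine=cfg.refine, noise_sd=cfg.noise_sd, seed=cfg.sim_seed,
        )
        logger.info("[%s] DAS reconstruction", label)
        # envelope-detected magnitude for the reported image, as in the
        # conventional nonnegative ultrasound display
        das_img = das_reconstruct(sino, geom, grid, acoustics, profile,
                                  envelope=True)
        images[(label, "DAS")] = das_img
        rmse_table[(label, "DAS")] = normalized_rmse(das_img.image, truth)

        logger.info("[%s] building projection operator", label)
        A = build_projection(geom, grid, acoustics, profile)
        logger.info("[%s] VR-SGD (%d outer iterations)", label, cfg.solver.N)
        result = vrsgd_reconstruct(
            potential, A, cfg.solver, X0=None,
            truth=phantom if truth_trace else None, sinogram=sino,
        )
        images[(label, "VR-SGD")] = result.image
        rmse_table[(label, "VR-SGD")] = normalized_rmse(result.image.image, truth)
        if result.trace.rmse is not None:
            traces[label] = result.trace.rmse
        logger.info(
            "[%s] RMSE: DAS %.3f, VR-SGD %.3f", label,
            rmse_table[(label, "DAS")], rmse_table[(label, "VR-SGD")],
        )

    result = StudyResult(cfg, phantom, images, rmse_table, traces)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": result.config.config_hash(),
        "sim_seed": result.config.sim_seed,
        "solver_seed": result.config.solver.seed,
    }
    (out_dir / "config.yaml").write_text(
        yaml.safe_dump(result.config.as_dict(), sort_keys=False)
    )
    (out_dir / "summary.csv").write_text(result.summary_csv())
    for (g, m), img in result.images.items():
        stem = f"{g}_{m.replace('-', '').lower()}"
        pio.save_image(img, out_dir / f"{stem}.npz", extra=provenance)
        pio.export_png(img.image, out_dir / f"{stem}.png")
    for g, tr in result.traces.items():
        lines = ["iteration,rmse"] + [
            f"{i + 1},{v:.6f}" for i, v in enumerate(tr)
        ]
        (out_dir / f"trace_{g}.csv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# config files


def table1_config() -> StudyConfig:
    """The simulation-study preset: 38 mm / 128 px grid, 128-element arrays,
    1500 m/s, 40 MHz, and solver settings lambda=1e-5, M=5, N=30,
    alpha0=5, a=1.05."""
    return StudyConfig()


_SOLVER_FIELDS = {f.name for f in dataclasses.fields(VRSGDConfig)}
_STUDY_FIELDS = {f.name for f in dataclasses.fields(StudyConfig)}


def load_config(path: str | Path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if raw.get("preset") == "table1":
        raw.pop("preset")
        base = table1_config().as_dict()
        base.update(raw)
        raw = base
    unknown = set(raw) - _STUDY_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    solver_raw = raw.pop("solver", {})
    if not isinstance(solver_raw, dict):
        raise ValueError(f"{path}: 'solver' must be a mapping")
    missing = {"lambda_tv", "M", "N", "alpha0", "decay_a"} - set(solver_raw)
    if solver_raw and missing:
        raise ValueError(
            f"{path}: solver section missing required fields {sorted(missing)}"
        )
    bad = set(solver_raw) - _SOLVER_FIELDS
    if bad:
        raise ValueError(f"{path}: unknown solver fields {sorted(bad)}")
    solver = VRSGDConfig(**solver_raw) if solver_raw else VRSGDConfig()
    if "geometries" in raw:
        raw["geometries"] = tuple(raw["geometries"])
    return StudyConfig(solver=solver, **raw)


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=False))
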