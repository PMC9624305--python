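"""Run configuration and the staged analysis pipeline.

The full workflow mirrors the experimental analysis chain:

    simulate -> track -> invert -> metrics -> hertz -> overlap -> report

Each stage reads and writes declared artifacts inside a working directory
and records itself in a JSON run manifest (config hash, seeds, package
version, outputs), so any output is regenerable from the manifest alone.
Deterministic stages reproduce their outputs bit-exactly under an
identical config.

Coordinate convention (package-wide): 0-based pixel indices with the
pixel-centre at integer coordinates; x = column (east), y = row (south);
lengths um, stresses Pa, forces nN, moduli kPa.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .colocalization import overlap_fraction
from .displacement import correct_drift, interpolate_to_grid, track_displacements
from .fttc import SubstrateProperties, fttc_invert
from .hertz import build_elasticity_map
from .io import (
    load_field_csv,
    load_force_volume,
    load_sparse_csv,
    read_image,
    save_elasticity_map,
    save_field_csv,
    save_force_volume,
    save_overlap_json,
    save_sparse_csv,
    write_image,
)
from .metrics import CellMask, force_area_table, integrate_force
from .synthetic import make_coloc_volume, make_scene

log = logging.getLogger("neuromech")

STAGES = ("simulate", "track", "invert", "metrics", "hertz", "overlap", "report")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; round-trips losslessly through YAML."""

    young_modulus: float = 470.0  # Pa, substrate
    poisson_ratio: float = 0.5
    pixel_size: float = 0.25  # um/px, bead images
    grid_spacing: float = 1.0  # um, inversion grid
    regularization: float = 0.0
    # Hertz
    half_angle: float = 30.0  # degrees
    poisson_cell: float = 0.5
    qc_threshold: float = 0.20
    # tracking
    max_displacement: float = 2.0  # um
    min_separation: float = 0.5  # um
    # overlap
    e_threshold: float = 1.0  # kPa
    # simulation
    mean_stress: float = 50.0  # Pa
    cell_area: float = 150.0  # um^2
    field_extent: float = 64.0  # um
    bead_density: float = 0.1  # beads/um^2
    noise: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "young_modulus",
            "pixel_size",
            "grid_spacing",
            "half_angle",
            "max_displacement",
            "min_separation",
            "e_threshold",
            "field_extent",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")

    @property
    def substrate(self) -> SubstrateProperties:
        return SubstrateProperties(self.young_modulus, self.poisson_ratio)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A stage is missing an upstream artifact or was misconfigured."""


def _require(workdir: Path, name: str, stage: str) -> Path:
    p = workdir / name
    if not p.exists():
        raise StageError(f"stage {stage!r} requires missing artifact {name!r}")
    return p


def run_pipeline(
    config: RunConfig,
    stages: tuple[str, ...] | list[str],
    workdir: str | Path,
) -> dict:
    """Run the requested stages in order and return the run manifest.

    Artifacts live in ``workdir`` under fixed names; each stage validates
    its inputs and raises :class:`StageError` naming the missing artifact
    otherwise.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    config.to_yaml(workdir / "config.yaml")

    for stage in stages:
        outputs = _run_stage(stage, config, workdir)
        manifest["stages"][stage] = outputs
        log.info("stage %s -> %s", stage, ", ".join(outputs))
    with open(workdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _run_stage(stage: str, config: RunConfig, workdir: Path) -> list[str]:
    sub = config.substrate
    if stage == "simulate":
        scene = make_scene(
            seed=config.seed,
            field_extent=config.field_extent,
            grid_spacing=config.grid_spacing,
            substrate=sub,
            mean_stress=config.mean_stress,
            cell_area=config.cell_area,
            bead_density=config.bead_density,
            pixel_size=config.pixel_size,
            noise=config.noise,
        )
        write_image(scene.bead_pair.reference, workdir / "beads_reference.tif")
        write_image(scene.bead_pair.loaded, workdir / "beads_loaded.tif")
        write_image(scene.cell_mask.mask.astype(np.float32), workdir / "cell_mask.tif")
        write_image(scene.actin_image, workdir / "actin.tif")
        save_field_csv(scene.truth_traction, workdir / "truth_traction.csv", sub)
        save_field_csv(scene.truth_displacement, workdir / "truth_displacement.csv", sub)
        scene.truth_beads.to_csv(workdir / "truth_beads.csv", index=False)
        volume = make_coloc_volume(seed=config.seed)[0]
        save_force_volume(volume, workdir / "force_volume")
        with open(workdir / "scene_truth.json", "w") as fh:
            json.dump(
                {
                    "mean_stress_Pa": scene.truth_mean_stress,
                    "total_force_nN": scene.truth_total_force,
                },
                fh,
                indent=2,
            )
        return [
            "beads_reference.tif",
            "beads_loaded.tif",
            "cell_mask.tif",
            "actin.tif",
            "truth_traction.csv",
            "truth_displacement.csv",
            "truth_beads.csv",
            "force_volume/",
            "scene_truth.json",
        ]

    if stage == "track":
        from .displacement import BeadImagePair

        ref = read_image(_require(workdir, "beads_reference.tif", stage))
        load = read_image(_require(workdir, "beads_loaded.tif", stage))
        pair = BeadImagePair(ref, load, config.pixel_size)
        sparse = track_displacements(
            pair,
            min_separation=config.min_separation,
        )
        mask_file = workdir / "cell_mask.tif"
        if mask_file.exists():
            sparse = correct_drift(
                sparse, read_image(mask_file) > 0.5, config.grid_spacing
            )
        save_sparse_csv(sparse, workdir / "displacements.csv")
        extent = config.field_extent - config.grid_spacing
        u = interpolate_to_grid(
            sparse, config.grid_spacing, (0.0, 0.0, extent, extent)
        )
        save_field_csv(u, workdir / "displacement_grid.csv", sub)
        return ["displacements.csv", "displacement_grid.csv"]

    if stage == "invert":
        u = load_field_csv(_require(workdir, "displacement_grid.csv", stage))
        traction = fttc_invert(u, sub, config.regularization)
        save_field_csv(traction, workdir / "traction.csv", sub)
        return ["traction.csv"]

    if stage == "metrics":
        traction = load_field_csv(_require(workdir, "traction.csv", stage))
        mask = read_image(_require(workdir, "cell_mask.tif", stage)) > 0.5
        cm = CellMask(mask=mask, pixel_area=config.grid_spacing**2, label="cell")
        summary = integrate_force(traction, cm)
        table = force_area_table([summary])
        table.to_csv(workdir / "summary.csv", index=False)
        return ["summary.csv"]

    if stage == "hertz":
        volume = load_force_volume(_require(workdir, "force_volume", stage))
        emap = build_elasticity_map(
            volume,
            grid_spacing=1.0,
            poisson_cell=config.poisson_cell,
            qc_threshold=config.qc_threshold,
        )
        save_elasticity_map(emap, workdir / "elasticity_map.csv")
        return ["elasticity_map.csv"]

    if stage == "overlap":
        from .io import load_elasticity_map

        emap = load_elasticity_map(_require(workdir, "elasticity_map.csv", stage))
        # the AFM map has its own (16x16) frame; the registered actin image
        # for it is produced by the simulate stage's coloc volume
        volume_actin = make_coloc_volume(seed=config.seed)[1]
        result = overlap_fraction(emap, volume_actin, e_threshold=config.e_threshold)
        save_overlap_json(result, workdir / "overlap.json")
        return ["overlap.json"]

    if stage == "report":
        digest: dict = {}
        for name in ("summary.csv", "overlap.json", "scene_truth.json"):
            p = workdir / name
            if not p.exists():
                continue
            if name.endswith(".json"):
                with open(p) as fh:
                    digest[name] = json.load(fh)
            else:
                import pandas as pd

                digest[name] = pd.read_csv(p).to_dict(orient="records")
        emap_file = workdir / "elasticity_map.csv"
        if emap_file.exists():
            from .io import load_elasticity_map

            digest["elasticity_map_stats"] = load_elasticity_map(emap_file).stats
        with open(workdir / "report.json", "w") as fh:
            json.dump(digest, fh, indent=2)
        return ["report.json"]

    raise ValueError(f"unhandled stage {stage!r}")
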