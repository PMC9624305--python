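"""File formats: CSV/TIFF fields, force curves, maps, JSON sidecars.

Tables are plain CSV with unit-suffixed column names (x_um, tx_Pa,
force_nN, ...); images and gridded fields are 32-bit float TIFF
(multi-page for 2-component fields); metadata rides in JSON sidecars named
``<stem>.meta.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .colocalization import OverlapResult
from .displacement import SparseDisplacements
from .fttc import DisplacementField, SubstrateProperties, TractionField
from .hertz import ElasticityMap, ForceCurve

__all__ = [
    "save_field_csv",
    "load_field_csv",
    "save_field_tiff",
    "load_field_tiff",
    "save_sparse_csv",
    "load_sparse_csv",
    "save_force_curve_csv",
    "load_force_curve_csv",
    "save_force_volume",
    "load_force_volume",
    "save_elasticity_map",
    "load_elasticity_map",
    "save_overlap_json",
    "read_image",
    "write_image",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if not str(path).endswith(
        ".meta.json"
    ) else path


def _write_meta(path: Path, meta: dict) -> None:
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2)


def _read_meta(path: Path) -> dict:
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            return json.load(fh)
    return {}


def _field_meta(field, substrate: SubstrateProperties | None) -> dict:
    meta = {
        "grid_spacing_um": field.grid_spacing,
        "origin_um": list(field.origin),
    }
    if isinstance(field, TractionField):
        meta["regularization"] = field.regularization_used
    if substrate is not None:
        meta["young_modulus_Pa"] = substrate.young_modulus
        meta["poisson_ratio"] = substrate.poisson_ratio
    return meta


def save_field_csv(
    field: DisplacementField | TractionField,
    path: str | Path,
    substrate: SubstrateProperties | None = None,
) -> None:
    """Write a gridded field as tidy CSV plus a JSON metadata sidecar."""
    path = Path(path)
    ny, nx = field.shape
    ys, xs = np.mgrid[0:ny, 0:nx].astype(float) * field.grid_spacing
    xs += field.origin[0]
    ys += field.origin[1]
    if isinstance(field, TractionField):
        df = pd.DataFrame(
            {
                "x_um": xs.ravel(),
                "y_um": ys.ravel(),
                "tx_Pa": field.tx.ravel(),
                "ty_Pa": field.ty.ravel(),
            }
        )
    else:
        df = pd.DataFrame(
            {
                "x_um": xs.ravel(),
                "y_um": ys.ravel(),
                "ux_um": field.ux.ravel(),
                "uy_um": field.uy.ravel(),
            }
        )
    df.to_csv(path, index=False)
    meta = _field_meta(field, substrate)
    meta["shape"] = [ny, nx]
    _write_meta(path, meta)


def load_field_csv(path: str | Path) -> DisplacementField | TractionField:
    """Read a field CSV written by :func:`save_field_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = _read_meta(path)
    ny, nx = meta.get("shape") or (
        df["y_um"].nunique(),
        df["x_um"].nunique(),
    )
    h = float(meta.get("grid_spacing_um", np.diff(np.unique(df["x_um"]))[0]))
    origin = tuple(meta.get("origin_um", (df["x_um"].min(), df["y_um"].min())))
    if "tx_Pa" in df.columns:
        return TractionField(
            grid_spacing=h,
            tx=df["tx_Pa"].to_numpy().reshape(ny, nx),
            ty=df["ty_Pa"].to_numpy().reshape(ny, nx),
            origin=origin,
            regularization_used=float(meta.get("regularization", 0.0)),
        )
    return DisplacementField(
        grid_spacing=h,
        ux=df["ux_um"].to_numpy().reshape(ny, nx),
        uy=df["uy_um"].to_numpy().reshape(ny, nx),
        origin=origin,
    )


def save_field_tiff(
    field: DisplacementField | TractionField,
    path: str | Path,
    substrate: SubstrateProperties | None = None,
) -> None:
    """Write a 2-component field as a 2-page 32-bit float TIFF."""
    path = Path(path)
    if isinstance(field, TractionField):
        stack = np.stack([field.tx, field.ty]).astype(np.float32)
    else:
        stack = np.stack([field.ux, field.uy]).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = _field_meta(field, substrate)
    meta["kind"] = "traction" if isinstance(field, TractionField) else "displacement"
    _write_meta(path, meta)


def load_field_tiff(path: str | Path) -> DisplacementField | TractionField:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    meta = _read_meta(path)
    h = float(meta.get("grid_spacing_um", 1.0))
    origin = tuple(meta.get("origin_um", (0.0, 0.0)))
    if meta.get("kind") == "traction":
        return TractionField(
            grid_spacing=h,
            tx=stack[0],
            ty=stack[1],
            origin=origin,
            regularization_used=float(meta.get("regularization", 0.0)),
        )
    return DisplacementField(grid_spacing=h, ux=stack[0], uy=stack[1], origin=origin)


def save_sparse_csv(sparse: SparseDisplacements, path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_um": sparse.positions[:, 0],
            "y_um": sparse.positions[:, 1],
            "ux_um": sparse.vectors[:, 0],
            "uy_um": sparse.vectors[:, 1],
            "quality": sparse.match_quality,
        }
    ).to_csv(path, index=False)


def load_sparse_csv(path: str | Path) -> SparseDisplacements:
    df = pd.read_csv(path)
    return SparseDisplacements(
        df[["x_um", "y_um"]].to_numpy(),
        df[["ux_um", "uy_um"]].to_numpy(),
        df["quality"].to_numpy(),
    )


def save_force_curve_csv(curve: ForceCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"z_um": curve.z_piezo, "force_nN": curve.deflection_force}
    ).to_csv(path, index=False)
    _write_meta(
        Path(path),
        {
            "spring_constant_N_per_m": curve.spring_constant,
            "half_angle_deg": curve.half_angle,
        },
    )


def load_force_curve_csv(
    path: str | Path,
    spring_constant: float | None = None,
    half_angle: float | None = None,
) -> ForceCurve:
    path = Path(path)
    df = pd.read_csv(path)
    meta = _read_meta(path)
    k = spring_constant or meta.get("spring_constant_N_per_m")
    if k is None:
        raise ValueError("spring_constant not given and not in sidecar")
    alpha = half_angle or meta.get("half_angle_deg", 30.0)
    return ForceCurve(
        z_piezo=df["z_um"].to_numpy(),
        deflection_force=df["force_nN"].to_numpy(),
        spring_constant=float(k),
        half_angle=float(alpha),
    )


def save_force_volume(volume, directory: str | Path) -> None:
    """Write a force-volume grid as per-curve CSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, row in enumerate(volume):
        names = []
        for i, curve in enumerate(row):
            name = f"curve_{j:02d}_{i:02d}.csv"
            save_force_curve_csv(curve, directory / name)
            names.append(name)
        rows.append(names)
    with open(directory / "volume.json", "w") as fh:
        json.dump({"curves": rows}, fh, indent=2)


def load_force_volume(directory: str | Path):
    directory = Path(directory)
    with open(directory / "volume.json") as fh:
        manifest = json.load(fh)
    return [
        [load_force_curve_csv(directory / name) for name in row]
        for row in manifest["curves"]
    ]


def save_elasticity_map(emap: ElasticityMap, path: str | Path) -> None:
    """Write moduli (kPa) as CSV grid; qc mask and stats in the sidecar."""
    path = Path(path)
    np.savetxt(path, emap.moduli, delimiter=",")
    _write_meta(
        path,
        {
            "grid_spacing_um": emap.grid_spacing,
            "qc_mask": emap.qc_mask.astype(int).tolist(),
            "unreliable": bool(emap.unreliable),
            "stats": emap.stats,
        },
    )


def load_elasticity_map(path: str | Path) -> ElasticityMap:
    path = Path(path)
    moduli = np.loadtxt(path, delimiter=",")
    meta = _read_meta(path)
    qc = np.asarray(meta.get("qc_mask", np.isfinite(moduli).astype(int)), dtype=bool)
    return ElasticityMap(
        moduli=moduli,
        grid_spacing=float(meta.get("grid_spacing_um", 1.0)),
        qc_mask=qc,
        unreliable=bool(meta.get("unreliable", False)),
        stats=meta.get("stats", {}),
    )


def save_overlap_json(result: OverlapResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "overlap_percent": result.overlap_percent,
                "reverse_overlap_percent": result.reverse_overlap_percent,
                "stiff_pixel_count": result.stiff_pixel_count,
                "actin_pixel_count": result.actin_pixel_count,
                "joint_count": result.joint_count,
                "e_threshold_kPa": result.e_threshold,
                "intensity_threshold_rule": result.intensity_threshold_rule,
            },
            fh,
            indent=2,
        )


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale (or float) TIFF as float array."""
    return tifffile.imread(path).astype(float)


def write_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))
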