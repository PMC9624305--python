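"""Per-cell traction summaries: stresses, integrated forces, trends.

A traction field is a stress (Pa = pN/um^2); the biologically quoted
quantity is the *force* the cell transmits through its contact area,
obtained by integrating the stress magnitude over the cell mask:

    F_total = sum_mask |T| * pixel_area,      1 Pa.um^2 = 1 fN = 1e-6 nN.

The vector (net) force is the same integral without the magnitude and is
near zero for a mechanically balanced cell.  Time-series and cohort
summaries reproduce the standard readouts of neuronal TFM experiments:
stress dynamics sampled every few minutes, stress vs. AFM-measured cell
modulus, and force vs. contact area (the contact-guidance signature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fttc import TractionField
from .hertz import ElasticityMap

__all__ = [
    "PA_UM2_TO_NN",
    "CellMask",
    "CellTractionSummary",
    "integrate_force",
    "contact_area",
    "summarize_time_series",
    "pair_stress_modulus",
    "force_area_table",
]

#: exact: 1 Pa * 1 um^2 = 1 N/m^2 * 1e-12 m^2 = 1 pN = 1e-3 nN
PA_UM2_TO_NN = 1e-3


@dataclass
class CellMask:
    """Boolean cell-contact mask aligned to a traction field grid."""

    mask: np.ndarray
    pixel_area: float  # um^2 per grid cell
    label: str = "cell"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.pixel_area > 0):
            raise ValueError("pixel_area must be > 0")


@dataclass
class CellTractionSummary:
    """Headline per-cell traction numbers at one timepoint."""

    label: str
    mean_stress: float  # Pa, over the mask
    peak_stress: float  # Pa
    total_force_magnitude: float  # nN
    net_force_vector: tuple[float, float]  # nN
    contact_area: float  # um^2
    timestamp: float = 0.0  # minutes


def contact_area(mask: CellMask) -> float:
    """Cell-substrate contact area in um^2 (true-pixel count x pixel area)."""
    n = int(mask.mask.sum())
    if n == 0:
        raise ValueError("empty cell mask")
    return n * mask.pixel_area


def integrate_force(
    traction: TractionField, mask: CellMask, timestamp: float = 0.0
) -> CellTractionSummary:
    """Integrate a traction field over a cell mask.

    Raises on an empty mask or shape mismatch.  Units: stresses Pa,
    forces nN (1 Pa.um^2 = 1 pN = 1e-3 nN).
    """
    if mask.mask.shape != traction.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} != traction shape {traction.shape}"
        )
    area = contact_area(mask)  # validates non-empty
    m = mask.mask
    mag = traction.magnitude()[m]
    total = float(mag.sum() * mask.pixel_area * PA_UM2_TO_NN)
    net = (
        float(traction.tx[m].sum() * mask.pixel_area * PA_UM2_TO_NN),
        float(traction.ty[m].sum() * mask.pixel_area * PA_UM2_TO_NN),
    )
    return CellTractionSummary(
        label=mask.label,
        mean_stress=float(mag.mean()),
        peak_stress=float(mag.max()),
        total_force_magnitude=total,
        net_force_vector=net,
        contact_area=area,
        timestamp=timestamp,
    )


def summarize_time_series(
    summaries: list[CellTractionSummary],
    growth_range_threshold: float = 15.0,
) -> dict:
    """Collapse an ordered stress time series into a trace plus statistics.

    Timestamps must be strictly increasing.  The growing/quiescent label is
    a convenience classifier: a cell whose stress range exceeds
    ``growth_range_threshold`` (Pa) is called "growing-like" (growing
    neurons alternate high/low-stress phases; quiescent ones hold a low,
    nearly constant stress).  A single-point series reports SEM 0 with
    ``sem_defined=False``.
    """
    if not summaries:
        raise ValueError("empty summary list")
    t = np.array([s.timestamp for s in summaries], dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    stress = np.array([s.mean_stress for s in summaries], dtype=float)
    sem_defined = len(stress) > 1
    sem = float(stress.std(ddof=1) / np.sqrt(len(stress))) if sem_defined else 0.0
    rng = float(stress.max() - stress.min())
    return {
        "label": summaries[0].label,
        "time_min": t,
        "mean_stress_Pa": stress,
        "mean": float(stress.mean()),
        "sem": sem,
        "sem_defined": sem_defined,
        "min": float(stress.min()),
        "max": float(stress.max()),
        "range": rng,
        "classification": (
            "growing-like" if rng > growth_range_threshold else "quiescent-like"
        ),
    }


def pair_stress_modulus(
    tfm_summaries: list[CellTractionSummary],
    elasticity_maps: dict[str, ElasticityMap],
    growth_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join per-cell traction stress with the AFM-measured mean modulus.

    One elasticity map per summary, keyed by cell label; the mean modulus
    is taken over qc-passing map pixels.  Raises ``KeyError`` naming any
    unmatched label.  Returns a DataFrame with columns
    (cell, mean_stress_Pa, mean_modulus_kPa, growth_label).
    """
    rows = []
    for s in tfm_summaries:
        if s.label not in elasticity_maps:
            raise KeyError(f"no elasticity map for cell label {s.label!r}")
        emap = elasticity_maps[s.label]
        if emap.qc_mask.any():
            mean_mod = float(emap.moduli[emap.qc_mask].mean())
        else:
            mean_mod = np.nan
        rows.append(
            {
                "cell": s.label,
                "mean_stress_Pa": s.mean_stress,
                "mean_modulus_kPa": mean_mod,
                "growth_label": (growth_labels or {}).get(s.label, ""),
            }
        )
    return pd.DataFrame(
        rows, columns=["cell", "mean_stress_Pa", "mean_modulus_kPa", "growth_label"]
    )


def force_area_table(summaries: list[CellTractionSummary]) -> pd.DataFrame:
    """Per-cell (contact area, total force) table — contact-guidance readout."""
    return pd.DataFrame(
        [
            {
                "cell": s.label,
                "contact_area_um2": s.contact_area,
                "force_nN": s.total_force_magnitude,
                "mean_stress_Pa": s.mean_stress,
            }
            for s in summaries
        ],
        columns=["cell", "contact_area_um2", "force_nN", "mean_stress_Pa"],
    )
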