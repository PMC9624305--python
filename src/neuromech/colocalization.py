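"""Overlap between stiff cell regions and high-actin regions.

Elasticity maps of neuronal somata show localized stiff regions
(E >= 1 kPa against a ~0.4 kPa background); actin staining shows where the
cytoskeleton is concentrated.  The headline readout is the fraction of
stiff pixels that also lie in the high-actin mask: values near 80% say
that cell stiffness is carried by the actin cytoskeleton.

The actin threshold rule is configurable because fluorescence intensity is
not calibrated: by default Otsu's method splits the actin image; a fixed
fraction-of-max rule is available.  Registration of the actin image onto
the AFM grid is an input, not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .hertz import ElasticityMap

__all__ = ["OverlapResult", "overlap_fraction"]


@dataclass
class OverlapResult:
    """Stiffness-actin overlap summary (percentages on 0-100 scale)."""

    overlap_percent: float  # |stiff & actin| / |stiff| * 100
    reverse_overlap_percent: float  # |stiff & actin| / |actin| * 100
    stiff_pixel_count: int
    actin_pixel_count: int
    joint_count: int
    e_threshold: float  # kPa
    intensity_threshold_rule: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.overlap_percent <= 100.0
        assert self.joint_count <= min(self.stiff_pixel_count, self.actin_pixel_count)


def _actin_mask(actin: np.ndarray, rule: str) -> tuple[np.ndarray, str]:
    if rule == "otsu":
        thr = threshold_otsu(actin)
        return actin >= thr, f"otsu({thr:.4g})"
    if rule.startswith("fraction:"):
        frac = float(rule.split(":", 1)[1])
        thr = actin.min() + frac * (actin.max() - actin.min())
        return actin >= thr, f"fraction_of_range({frac})"
    raise ValueError(f"unknown actin threshold rule {rule!r}")


def overlap_fraction(
    emap: ElasticityMap,
    actin_image: np.ndarray,
    e_threshold: float = 1.0,
    actin_rule: str = "otsu",
) -> OverlapResult:
    """Percent overlap of stiff map regions with high-actin regions.

    ``stiff = (moduli >= e_threshold [kPa]) & qc_mask``; the actin mask
    follows ``actin_rule`` ("otsu" or "fraction:<f>").  The denominator is
    the stiff-pixel count; the reverse fraction (actin pixels that are
    stiff) is reported alongside.  An empty stiff mask makes the overlap
    undefined and raises ``ValueError``.
    """
    actin = np.asarray(actin_image, dtype=float)
    if actin.shape != emap.shape:
        raise ValueError("actin image must be registered to the map grid")
    stiff = (np.nan_to_num(emap.moduli, nan=-np.inf) >= e_threshold) & emap.qc_mask
    n_stiff = int(stiff.sum())
    if n_stiff == 0:
        raise ValueError("empty stiff mask: overlap undefined")
    amask, rule_desc = _actin_mask(actin, actin_rule)
    n_actin = int(amask.sum())
    joint = int((stiff & amask).sum())
    return OverlapResult(
        overlap_percent=100.0 * joint / n_stiff,
        reverse_overlap_percent=(100.0 * joint / n_actin) if n_actin else 0.0,
        stiff_pixel_count=n_stiff,
        actin_pixel_count=n_actin,
        joint_count=joint,
        e_threshold=e_threshold,
        intensity_threshold_rule=rule_desc,
    )
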