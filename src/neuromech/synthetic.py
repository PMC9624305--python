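"""Ground-truth synthetic data for every pipeline stage.

The generator emulates the experimental platform end to end: sparse
focal-adhesion-like traction patches on a soft polyacrylamide substrate
(~470 Pa), the surface displacement they produce (computed with the same
Boussinesq forward model the inversion is tested against), fluorescent
fiducial beads imaged as diffraction-limited Gaussian spots with Poisson
photon noise, binary cell-contact masks, actin-like fluorescence images,
and conical-tip AFM force-volume grids.  Everything is seeded and
bit-reproducible, and every stage returns its ground truth so recovery can
be scored exactly.

Default conditions mirror the neuronal TFM/AFM experiments this package
analyses: traction stresses of tens of Pa (28-70 Pa for growing cells),
cell-substrate contact areas of order 10^2 um^2 (forces of a few nN),
cell moduli 0.4-2.3 kPa probed on 16 x 16 grids at 1 um pitch with a 30
degree cone, 200 nm beads at ~0.1 beads/um^2 of usable (in-focus)
density, and stress sampled every 10 min over 2 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .displacement import BeadImagePair
from .fttc import (
    DisplacementField,
    SubstrateProperties,
    TractionField,
    forward_displacement,
)
from .hertz import ForceCurve, hertz_cone_coefficient
from .metrics import CellMask

__all__ = [
    "SyntheticScene",
    "CohortSpec",
    "make_traction_pattern",
    "render_bead_pair",
    "simulate_force_curve",
    "simulate_force_volume",
    "make_scene",
    "make_coloc_volume",
    "make_cohort",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScene:
    """One cell at one timepoint, with full ground truth."""

    truth_traction: TractionField
    truth_displacement: DisplacementField
    bead_pair: BeadImagePair
    truth_beads: pd.DataFrame  # x_um, y_um, ux_um, uy_um
    cell_mask: CellMask
    actin_image: np.ndarray
    seed: int
    truth_mean_stress: float  # Pa over the cell mask
    truth_total_force: float  # nN over the cell mask


@dataclass
class CohortSpec:
    """Study-condition knobs for a multi-cell, multi-timepoint cohort.

    Defaults parameterize the conditions of the neuronal experiments:
    30 cells, growing-cell stresses spanning 28-70 Pa, contact areas
    100-250 um^2, modulus coupled to stress as E = base + slope * stress
    (0.4 kPa + 0.027 kPa/Pa, spanning ~0.4-2.3 kPa), 10-min sampling for
    2 h, and a 470 Pa incompressible substrate.
    """

    n_cells: int = 30
    stress_range: tuple[float, float] = (28.0, 70.0)  # Pa, growing cells
    quiescent_stress: float = 17.0  # Pa, mean for non-growing cells
    area_range: tuple[float, float] = (100.0, 250.0)  # um^2
    modulus_coupling: tuple[float, float] = (0.4, 0.027)  # (kPa, kPa/Pa)
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(0, 130, 10))
    growth_fraction: float = 0.5
    substrate: SubstrateProperties = field(
        default_factory=lambda: SubstrateProperties(470.0, 0.5)
    )
    bead_density: float = 0.1  # beads / um^2
    noise: str = "paper"  # "paper" (shot noise) or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.stress_range[0] <= self.stress_range[1]):
            raise ValueError("stress_range must be ordered")
        if not (self.area_range[0] <= self.area_range[1]):
            raise ValueError("area_range must be ordered")
        if not (0.0 <= self.growth_fraction <= 1.0):
            raise ValueError("growth_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Traction patterns
# ---------------------------------------------------------------------------


def make_traction_pattern(
    n_sites: int,
    stress_range: tuple[float, float] = (30.0, 70.0),
    site_radius: float = 5.0,
    field_extent: float = 64.0,
    balanced: bool = True,
    seed: int = 0,
    grid_spacing: float = 1.0,
    centers: np.ndarray | None = None,
    pattern_center: tuple[float, float] | None = None,
) -> TractionField:
    """Sparse Gaussian adhesion-site traction patches, in Pa.

    Each site is a radially symmetric Gaussian patch (sigma =
    ``site_radius``) whose peak magnitude is drawn uniformly from
    ``stress_range`` and whose direction points toward the common pattern
    centre — the centripetal morphology of a contracting growth cone.
    With ``balanced`` the mean traction is projected to zero (cells exert
    balanced force systems).  ``centers`` fixes the site positions
    explicitly; otherwise they are drawn uniformly in the central half of
    the field.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if site_radius <= 0:
        raise ValueError("site_radius must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(field_extent / grid_spacing))
    ys, xs = np.mgrid[0:n, 0:n] * grid_spacing
    tx = np.zeros((n, n))
    ty = np.zeros((n, n))
    if n_sites > 0:
        if centers is None:
            lo, hi = 0.25 * field_extent, 0.75 * field_extent
            centers = rng.uniform(lo, hi, size=(n_sites, 2))
        else:
            centers = np.atleast_2d(np.asarray(centers, dtype=float))
        if pattern_center is None:
            cx, cy = centers.mean(axis=0)
        else:
            cx, cy = pattern_center
        peaks = rng.uniform(stress_range[0], stress_range[1], size=len(centers))
        for (sx, sy), peak in zip(centers, peaks):
            dxc, dyc = cx - sx, cy - sy
            norm = np.hypot(dxc, dyc)
            if norm < 1e-9:
                ang = rng.uniform(0, 2 * np.pi)
                dxc, dyc = np.cos(ang), np.sin(ang)
            else:
                dxc, dyc = dxc / norm, dyc / norm
            prof = peak * np.exp(
                -((xs - sx) ** 2 + (ys - sy) ** 2) / (2 * site_radius**2)
            )
            tx += prof * dxc
            ty += prof * dyc
    if balanced:
        tx = tx - tx.mean()
        ty = ty - ty.mean()
    return TractionField(grid_spacing=grid_spacing, tx=tx, ty=ty)


# ---------------------------------------------------------------------------
# Bead image rendering
# ---------------------------------------------------------------------------


def _render_spots(
    shape: tuple[int, int],
    positions_px: np.ndarray,
    amplitude: float,
    sigma_px: float,
) -> np.ndarray:
    """Add Gaussian spots at sub-pixel positions onto a zero image."""
    img = np.zeros(shape)
    half = max(int(np.ceil(4 * sigma_px)), 2)
    ny, nx = shape
    for x, y in positions_px:
        c0, r0 = int(round(x)), int(round(y))
        rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, ny)
        clo, chi = max(c0 - half, 0), min(c0 + half + 1, nx)
        if rlo >= rhi or clo >= chi:
            continue
        rr = np.arange(rlo, rhi)
        cc = np.arange(clo, chi)
        gy = np.exp(-((rr - y) ** 2) / (2 * sigma_px**2))
        gx = np.exp(-((cc - x) ** 2) / (2 * sigma_px**2))
        img[rlo:rhi, clo:chi] += amplitude * np.outer(gy, gx)
    return img


def render_bead_pair(
    displacement: DisplacementField,
    bead_density: float = 0.1,
    psf_sigma: float = 0.2,
    photon_noise: dict | None = None,
    seed: int = 0,
    pixel_size: float = 0.25,
    drift: tuple[float, float] = (0.0, 0.0),
) -> tuple[BeadImagePair, pd.DataFrame]:
    """Render a reference/loaded fluorescence image pair from a field.

    Beads are planted uniformly at a Poisson-distributed count
    (``bead_density`` x field area), imaged as Gaussian spots of width
    ``psf_sigma`` (um; a warning-level check enforces >= 0.5 px sampling),
    and displaced by the field bilinearly sampled at each bead for the
    loaded image (plus any rigid stage ``drift``).  ``photon_noise`` is
    ``{"peak": photons/bead, "background": photons/px}`` (Poisson shot
    noise; ``None`` uses the defaults peak=200, background=10; pass
    ``{"peak": 0}`` for a noise-free pair).  Returns the pair plus a
    ground-truth bead table (x_um, y_um, ux_um, uy_um).
    """
    if bead_density <= 0:
        raise ValueError("bead_density must be > 0")
    if photon_noise is None:
        photon_noise = {"peak": 200.0, "background": 10.0}
    peak = float(photon_noise.get("peak", 200.0))
    bg = float(photon_noise.get("background", 10.0))
    sigma_px = psf_sigma / pixel_size
    if sigma_px < 0.5:
        import warnings

        warnings.warn("psf_sigma below 0.5 px: spots are undersampled")
    rng = np.random.default_rng(seed)
    ny_f, nx_f = displacement.shape
    h = displacement.grid_spacing
    extent_x = (nx_f - 1) * h
    extent_y = (ny_f - 1) * h
    area = extent_x * extent_y
    n_beads = rng.poisson(bead_density * area)
    pos = np.column_stack(
        [rng.uniform(0, extent_x, n_beads), rng.uniform(0, extent_y, n_beads)]
    )
    gx = np.arange(nx_f) * h
    gy = np.arange(ny_f) * h
    interp_x = RegularGridInterpolator(
        (gy, gx), displacement.ux, bounds_error=False, fill_value=0.0
    )
    interp_y = RegularGridInterpolator(
        (gy, gx), displacement.uy, bounds_error=False, fill_value=0.0
    )
    uxy = np.column_stack(
        [interp_x(pos[:, ::-1]), interp_y(pos[:, ::-1])]
    )  # sample at (y, x)
    loaded_pos = pos + uxy + np.asarray(drift)

    shape = (int(round(extent_y / pixel_size)), int(round(extent_x / pixel_size)))
    amp = peak if peak > 0 else 200.0
    ref = _render_spots(shape, pos / pixel_size, amp, sigma_px) + bg
    load = _render_spots(shape, loaded_pos / pixel_size, amp, sigma_px) + bg
    if peak > 0:
        ref = rng.poisson(ref).astype(float)
        load = rng.poisson(load).astype(float)
    pair = BeadImagePair(reference=ref, loaded=load, pixel_size=pixel_size)
    table = pd.DataFrame(
        {
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "ux_um": uxy[:, 0],
            "uy_um": uxy[:, 1],
        }
    )
    return pair, table


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------


def simulate_force_curve(
    E: float,
    contact_z: float = 2.0,
    half_angle: float = 30.0,
    poisson: float = 0.5,
    spring_constant: float = 0.03,
    noise_frac: float = 0.0,
    seed: int = 0,
    z_total: float = 3.0,
    n_samples: int = 240,
) -> ForceCurve:
    """Simulate a conical-indentation approach curve.

    Pre-contact the force is zero; post-contact it solves the coupled
    Sneddon + cantilever-bending system: the piezo advance past contact is
    shared between indentation and lever deflection,
    ``s = delta + F/k`` with ``F = C delta^2``, so
    ``delta = (-1 + sqrt(1 + 4 C kappa s)) / (2 C kappa)`` with
    ``kappa = 1/k``.  Multiplicative Gaussian noise of relative sd
    ``noise_frac`` is applied to the whole force channel.
    """
    if E <= 0:
        raise ValueError("E must be > 0")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, z_total, n_samples)
    s = np.clip(z - contact_z, 0.0, None)
    C = hertz_cone_coefficient(E, half_angle, poisson)  # nN / um^2
    kappa = 1.0 / (spring_constant * 1000.0)  # um / nN
    a = C * kappa
    delta = np.where(s > 0, (-1.0 + np.sqrt(1.0 + 4.0 * a * s)) / (2.0 * a), 0.0)
    force = C * delta**2
    if noise_frac > 0:
        force = force * (1.0 + noise_frac * rng.standard_normal(force.shape))
        # small additive floor so the pre-contact baseline has realistic noise
        floor = noise_frac * max(force.max(), 1e-9) * 0.02
        force = force + floor * rng.standard_normal(force.shape)
    return ForceCurve(
        z_piezo=z,
        deflection_force=force,
        spring_constant=spring_constant,
        half_angle=half_angle,
    )


def simulate_force_volume(
    E_map_pa: np.ndarray,
    contact_z: float = 2.0,
    half_angle: float = 30.0,
    poisson: float = 0.5,
    spring_constant: float = 0.03,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> list[list[ForceCurve]]:
    """Grid of force curves from a ground-truth modulus map (Pa).

    Non-finite map entries yield never-in-contact (flat baseline) curves.
    """
    E_map_pa = np.asarray(E_map_pa, dtype=float)
    rng = np.random.default_rng(seed)
    volume: list[list[ForceCurve]] = []
    for row in E_map_pa:
        curves = []
        for E in row:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if np.isfinite(E) and E > 0:
                curves.append(
                    simulate_force_curve(
                        E,
                        contact_z=contact_z,
                        half_angle=half_angle,
                        poisson=poisson,
                        spring_constant=spring_constant,
                        noise_frac=noise_frac,
                        seed=sub_seed,
                    )
                )
            else:
                z = np.linspace(0.0, 3.0, 240)
                f = (
                    0.001 * np.random.default_rng(sub_seed).standard_normal(z.shape)
                    if noise_frac > 0
                    else np.zeros_like(z)
                )
                curves.append(
                    ForceCurve(
                        z_piezo=z,
                        deflection_force=f,
                        spring_constant=spring_constant,
                        half_angle=half_angle,
                    )
                )
        volume.append(curves)
    return volume


# ---------------------------------------------------------------------------
# Whole scenes
# ---------------------------------------------------------------------------


def _ellipse_mask(
    shape: tuple[int, int],
    grid_spacing: float,
    center: tuple[float, float],
    area: float,
    aspect: float = 1.3,
) -> np.ndarray:
    """Boolean ellipse of the requested area (um^2) on the field grid."""
    ny, nx = shape
    ys, xs = np.mgrid[0:ny, 0:nx] * grid_spacing
    b = np.sqrt(area / (np.pi * aspect))
    a = aspect * b
    cx, cy = center
    return ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0


def make_scene(
    seed: int = 0,
    field_extent: float = 64.0,
    grid_spacing: float = 1.0,
    substrate: SubstrateProperties | None = None,
    mean_stress: float = 50.0,
    n_sites: int = 6,
    site_radius: float = 5.0,
    cell_area: float = 150.0,
    bead_density: float = 0.1,
    pixel_size: float = 0.25,
    psf_sigma: float = 0.2,
    noise: str = "paper",
) -> SyntheticScene:
    """Generate one full TFM scene with ground truth.

    Adhesion sites sit on the cell-mask periphery pulling toward the cell
    centre; the pattern is rescaled so the true mean stress magnitude over
    the mask equals ``mean_stress`` (Pa) exactly, then balanced.  The
    displacement truth is the Boussinesq forward solution; bead images are
    rendered from it (``noise="none"`` disables shot noise).  The actin
    image is a smoothed map of the adhesion-site layout inside the cell.
    """
    if substrate is None:
        substrate = SubstrateProperties(470.0, 0.5)
    rng = np.random.default_rng(seed)
    n = int(round(field_extent / grid_spacing))
    center = (field_extent / 2.0, field_extent / 2.0)
    mask = _ellipse_mask((n, n), grid_spacing, center, cell_area)

    # adhesion sites on the mask periphery
    b = np.sqrt(cell_area / (np.pi * 1.3))
    a = 1.3 * b
    angles = rng.uniform(0, 2 * np.pi, n_sites)
    radii = rng.uniform(0.7, 1.0, n_sites)
    centers = np.column_stack(
        [
            center[0] + a * radii * np.cos(angles),
            center[1] + b * radii * np.sin(angles),
        ]
    )
    traction = make_traction_pattern(
        n_sites,
        stress_range=(30.0, 70.0),
        site_radius=site_radius,
        field_extent=field_extent,
        balanced=False,
        seed=int(rng.integers(0, 2**31 - 1)),
        grid_spacing=grid_spacing,
        centers=centers,
        pattern_center=center,
    )
    # rescale to the target mean stress over the mask, re-balancing after
    # each rescale; the balance correction is small so this converges in
    # a few iterations to an exactly planted mean
    tx, ty = traction.tx, traction.ty
    for _ in range(8):
        cur = np.hypot(tx, ty)[mask].mean()
        if cur <= 0:
            break
        scale = mean_stress / cur
        tx = tx * scale - (tx * scale).mean()
        ty = ty * scale - (ty * scale).mean()
    traction = TractionField(grid_spacing=grid_spacing, tx=tx, ty=ty)

    u = forward_displacement(traction, substrate)
    photon = {"peak": 200.0, "background": 10.0} if noise == "paper" else {"peak": 0.0}
    pair, beads = render_bead_pair(
        u,
        bead_density=bead_density,
        psf_sigma=psf_sigma,
        photon_noise=photon,
        seed=int(rng.integers(0, 2**31 - 1)),
        pixel_size=pixel_size,
    )

    # actin-like image: adhesion sites + cell body texture, smoothed
    from scipy.ndimage import gaussian_filter

    actin = np.zeros((n, n))
    for sx, sy in centers:
        i, j = int(round(sy / grid_spacing)), int(round(sx / grid_spacing))
        if 0 <= i < n and 0 <= j < n:
            actin[i, j] = 1.0
    actin = gaussian_filter(actin, 2.0)
    actin = actin / max(actin.max(), 1e-12) * 800.0 + 100.0 * mask
    actin += 20.0 * rng.random((n, n))

    cm = CellMask(mask=mask, pixel_area=grid_spacing**2, label=f"cell{seed}")
    mag = np.hypot(traction.tx, traction.ty)
    truth_mean = float(mag[mask].mean())
    truth_force = float(mag[mask].sum() * grid_spacing**2 * 1e-3)  # Pa.um^2 -> nN
    return SyntheticScene(
        truth_traction=traction,
        truth_displacement=u,
        bead_pair=pair,
        truth_beads=beads,
        cell_mask=cm,
        actin_image=actin,
        seed=seed,
        truth_mean_stress=truth_mean,
        truth_total_force=truth_force,
    )


def make_coloc_volume(
    seed: int = 0,
    shape: tuple[int, int] = (16, 16),
    stiff_modulus: float = 2000.0,
    soft_modulus: float = 500.0,
    stiff_fraction: float = 0.35,
    miss_fraction: float = 0.18,
    noise_frac: float = 0.0,
) -> tuple[list[list[ForceCurve]], np.ndarray, np.ndarray]:
    """Force volume plus an actin image with calibrated stiffness overlap.

    A connected stiff region (``stiff_fraction`` of pixels at
    ``stiff_modulus`` Pa) is planted in a soft background; the actin image
    is bright on the stiff region except for a deterministic
    ``miss_fraction`` of its pixels (jitter), plus bright on an equal
    number of soft pixels.  The planted stiff-with-actin overlap is
    therefore ``(1 - miss_fraction) * 100`` percent, emulating the
    observed ~80% actin-stiffness colocalization.

    Returns (force_volume, actin_image, true_stiff_mask).
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    n_stiff = int(round(stiff_fraction * ny * nx))
    # grow a connected blob from a random seed pixel
    start = (rng.integers(3, ny - 3), rng.integers(3, nx - 3))
    blob = {tuple(start)}
    frontier = [tuple(start)]
    while len(blob) < n_stiff and frontier:
        j, i = frontier[rng.integers(0, len(frontier))]
        nbrs = [(j + dj, i + di) for dj, di in ((1, 0), (-1, 0), (0, 1), (0, -1))]
        rng.shuffle(nbrs)
        added = False
        for cand in nbrs:
            if 0 <= cand[0] < ny and 0 <= cand[1] < nx and cand not in blob:
                blob.add(cand)
                frontier.append(cand)
                added = True
                break
        if not added:
            frontier.remove((j, i))
    stiff = np.zeros(shape, dtype=bool)
    for j, i in blob:
        stiff[j, i] = True
    E_map = np.where(stiff, stiff_modulus, soft_modulus)

    stiff_idx = np.flatnonzero(stiff.ravel())
    soft_idx = np.flatnonzero(~stiff.ravel())
    n_miss = int(round(miss_fraction * len(stiff_idx)))
    missed = rng.choice(stiff_idx, size=n_miss, replace=False)
    extra = rng.choice(soft_idx, size=min(n_miss, len(soft_idx)), replace=False)
    actin_mask = stiff.ravel().copy()
    actin_mask[missed] = False
    actin_mask[extra] = True
    actin_mask = actin_mask.reshape(shape)
    actin = np.where(actin_mask, 900.0, 80.0) + 10.0 * rng.random(shape)

    volume = simulate_force_volume(E_map, noise_frac=noise_frac, seed=seed)
    return volume, actin, stiff


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def make_cohort(spec: CohortSpec) -> tuple[list[dict], pd.DataFrame]:
    """Multi-cell, multi-timepoint cohort with planted couplings.

    Per cell: a contact area drawn from ``area_range``; a growth state
    (growing cells alternate high/low stress phases across timepoints,
    quiescent cells hold a low constant stress); per timepoint a full
    :class:`SyntheticScene`; and a force-volume modulus coupled to the
    cell's characteristic stress via ``modulus_coupling``
    (E_kPa = base + slope * stress_Pa).

    Returns ``(cells, truth)`` where each cell dict carries label, growth
    state, the scene list, the per-timepoint true stresses, and the true
    modulus; ``truth`` is a tidy per-cell DataFrame (label, growth, area,
    time-averaged stress, force, modulus).
    """
    rng = np.random.default_rng(spec.seed)
    n_grow = int(round(spec.growth_fraction * spec.n_cells))
    cells: list[dict] = []
    rows = []
    for ci in range(spec.n_cells):
        growing = ci < n_grow
        area = rng.uniform(*spec.area_range)
        lo, hi = spec.stress_range
        if growing:
            # characteristic stress per cell, two-state alternation around
            # it (intermittent high-traction growth phases vs. low phases)
            char = rng.uniform(lo, hi)
            high, low = 1.3 * char, 0.7 * char
            stresses = []
            phase_high = bool(rng.integers(0, 2))
            dwell = int(rng.integers(2, 4))
            count = 0
            for _ in spec.timepoints:
                stresses.append(high if phase_high else low)
                count += 1
                if count >= dwell:
                    phase_high = not phase_high
                    dwell = int(rng.integers(2, 4))
                    count = 0
        else:
            # quiescent cells hold quiescent_stress up to small temporal
            # noise; the constant-stress cohort (growth_fraction = 0) is
            # the contact-guidance harness where force tracks area alone
            stresses = [
                spec.quiescent_stress * (1.0 + 0.05 * rng.standard_normal())
                for _ in spec.timepoints
            ]
        label = f"cell{ci:03d}"
        scenes = []
        for t, s_true in zip(spec.timepoints, stresses):
            scene = make_scene(
                seed=int(rng.integers(0, 2**31 - 1)),
                mean_stress=float(s_true),
                cell_area=float(area),
                substrate=spec.substrate,
                bead_density=spec.bead_density,
                noise=spec.noise,
            )
            scene.cell_mask.label = label
            scenes.append((float(t), scene))
        char_stress = float(np.mean(stresses))
        base, slope = spec.modulus_coupling
        modulus_kpa = base + slope * char_stress
        rows.append(
            {
                "cell": label,
                "growth": "growing" if growing else "quiescent",
                "area_um2": float(area),
                "mean_stress_Pa": char_stress,
                "force_nN": char_stress * float(area) * 1e-3,
                "modulus_kPa": float(modulus_kpa),
            }
        )
        cells.append(
            {
                "label": label,
                "growth": "growing" if growing else "quiescent",
                "area_um2": float(area),
                "scenes": scenes,
                "true_stresses_Pa": [float(s) for s in stresses],
                "true_modulus_kPa": float(modulus_kpa),
            }
        )
    truth = pd.DataFrame(rows)
    return cells, truth
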