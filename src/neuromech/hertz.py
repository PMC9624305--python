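"""AFM force-curve analysis: Hertz/Sneddon cone fits and elasticity maps.

In force-volume mode the AFM records, at each pixel of a (typically
16 x 16 um, 1 um resolution) grid, the cantilever force as the tip is
driven into the cell.  For a conical tip of half-opening angle ``alpha``
indenting an incompressible elastic body to depth ``delta`` the
Hertz/Sneddon model predicts

    F = (2 / pi) * tan(alpha) * E / (1 - nu^2) * delta^2,

with ``E`` the cell Young's modulus and ``nu`` its Poisson ratio
(default 0.5).  The measured axis is the z-piezo displacement, which is
shared between indentation and cantilever bending, so the corrected
indentation is ``delta = (z - z_contact) - F / k`` with spring constant
``k``.  Fitting each curve and assembling the fitted moduli yields the
elasticity map; fits whose relative residual exceeds a quality threshold
(default 20%) are masked out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ForceCurve",
    "HertzFit",
    "ElasticityMap",
    "NotInContactError",
    "find_contact_point",
    "fit_hertz_cone",
    "build_elasticity_map",
    "hertz_cone_coefficient",
]

#: nN per (Pa . um^2): F[N] = E[Pa] * delta[m]^2 * geometry
_PA_UM2_TO_NN = 1e-3  # E[Pa] * (delta[um])^2 * 1e-12 m^2/um^2 -> N, * 1e9 -> nN


class NotInContactError(RuntimeError):
    """Raised when a force curve never leaves its baseline (tip misses)."""


@dataclass
class ForceCurve:
    """Approach segment of an AFM force curve.

    ``z_piezo`` (um) increases toward the sample; ``deflection_force``
    (nN) is the cantilever force.  ``spring_constant`` in N/m,
    ``half_angle`` is the cone half-opening angle in degrees.
    """

    z_piezo: np.ndarray
    deflection_force: np.ndarray
    spring_constant: float
    half_angle: float = 30.0

    def __post_init__(self) -> None:
        self.z_piezo = np.asarray(self.z_piezo, dtype=float)
        self.deflection_force = np.asarray(self.deflection_force, dtype=float)
        if self.z_piezo.shape != self.deflection_force.shape:
            raise ValueError("z_piezo and deflection_force must have equal length")
        if self.z_piezo.size < 20:
            raise ValueError("force curve needs at least 20 samples")
        dz = np.diff(self.z_piezo)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z_piezo must be strictly monotonic on the approach")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")


@dataclass
class HertzFit:
    """Result of a single-cone Hertz fit."""

    young_modulus: float  # Pa
    contact_point: float  # um
    rms_residual: float  # nN
    relative_fit_error: float  # fraction of post-contact force RMS
    converged: bool


@dataclass
class ElasticityMap:
    """Per-pixel fitted Young's moduli (kPa) with a fit-quality mask."""

    moduli: np.ndarray
    grid_spacing: float
    qc_mask: np.ndarray
    unreliable: bool = False
    stats: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.moduli.shape


def hertz_cone_coefficient(
    young_modulus: float, half_angle: float, poisson: float
) -> float:
    """Force coefficient C (nN/um^2) such that F = C * delta^2."""
    alpha = np.deg2rad(half_angle)
    return (
        (2.0 / np.pi)
        * np.tan(alpha)
        * young_modulus
        / (1.0 - poisson**2)
        * _PA_UM2_TO_NN
    )


# ---------------------------------------------------------------------------
# Contact-point detection
# ---------------------------------------------------------------------------


def find_contact_point(
    curve: ForceCurve,
    noise_multiple: float = 4.0,
    baseline_fraction: float = 0.3,
) -> tuple[float, float]:
    """Locate the tip-sample contact point on an approach curve.

    The baseline force is the median over the first ``baseline_fraction``
    of samples (>= 10 required); the coarse contact point is the earliest z
    where the force exceeds baseline by ``noise_multiple`` times the
    baseline noise (robust MAD estimate), refined by minimising the
    residual of a flat-line + quadratic-branch piecewise model over z.

    Returns (contact_point um, baseline force nN); raises
    :class:`NotInContactError` if no crossing exists.
    """
    z = curve.z_piezo
    f = curve.deflection_force
    if z[0] > z[-1]:  # normalise to increasing z toward the sample
        z, f = z[::-1], f[::-1]
    n_base = max(int(len(z) * baseline_fraction), 10)
    if n_base > len(z):
        raise ValueError("curve too short for a pre-contact baseline")
    base = float(np.median(f[:n_base]))
    noise = float(1.4826 * np.median(np.abs(f[:n_base] - base)))
    floor = max(noise, 1e-6 * max(abs(f).max(), 1.0))
    above = f > base + noise_multiple * floor
    # require the crossing to persist: earliest index from which the force
    # stays above threshold (single noise spikes are not contact)
    idx = None
    run = 0
    for i in range(len(f) - 1, -1, -1):
        if above[i]:
            run += 1
            idx = i
        else:
            break
    if idx is None or run < 3:
        raise NotInContactError("force never rises above the baseline")

    # refine: piecewise (baseline | baseline + C (z - zc)^2) least squares in zc
    def sse(zc: float) -> float:
        post = z > zc
        d = z[post] - zc
        y = f[post] - base
        d4 = (d**4).sum()
        c = (d * d * y).sum() / d4 if d4 > 0 else 0.0
        c = max(c, 0.0)
        return float(((y - c * d * d) ** 2).sum())

    lo = z[max(idx - 5, 0)]
    hi = z[min(idx + 5, len(z) - 1)]
    if hi <= lo:
        return float(z[idx]), base
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded")
    return float(res.x), base


# ---------------------------------------------------------------------------
# Cone fit
# ---------------------------------------------------------------------------


def fit_hertz_cone(
    curve: ForceCurve,
    poisson_cell: float = 0.5,
    bending_correction: bool = True,
    max_indentation: float | None = None,
) -> HertzFit:
    """Fit the Sneddon cone model to a force curve.

    After contact-point detection the indentation is
    ``delta = (z - z_contact) - F/k`` (cantilever bending removed when
    ``bending_correction``); the modulus follows from a closed-form linear
    least-squares fit of ``F = C delta^2``.  ``max_indentation`` (um) caps
    the fitted depth to stay within small-deformation validity.  A fit with
    non-positive or non-finite modulus, or fewer than 15 post-contact
    samples, returns ``converged=False`` rather than raising.
    """
    try:
        zc0, base = find_contact_point(curve)
    except NotInContactError:
        return HertzFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    z = curve.z_piezo
    f = curve.deflection_force
    if z[0] > z[-1]:
        z, f = z[::-1], f[::-1]
    y = f - base
    bend = y / (curve.spring_constant * 1000.0) if bending_correction else 0.0

    def _fit_at(zc: float):
        delta = z - zc - bend  # spring constant N/m = 1000 nN/um
        post = (delta > 0) & (z > zc)
        if max_indentation is not None:
            post = post & (delta <= max_indentation)
        if post.sum() < 15:
            return None
        d = delta[post]
        yy = y[post]
        d4 = (d**4).sum()
        if d4 <= 0:
            return None
        coeff = (d * d * yy).sum() / d4
        sse = float(((yy - coeff * d * d) ** 2).sum())
        return coeff, d, yy, sse

    # the threshold-crossing contact estimate carries a small late bias;
    # refine zc jointly with the quadratic coefficient
    span = max(5.0 * float(np.median(np.diff(z))), 0.02)
    res = minimize_scalar(
        lambda zc: (_fit_at(zc) or (0, 0, 0, np.inf))[3],
        bounds=(zc0 - span, zc0 + span),
        method="bounded",
    )
    zc = float(res.x) if np.isfinite(res.fun) else zc0
    fit = _fit_at(zc)
    if fit is None:
        return HertzFit(np.nan, zc, np.nan, np.nan, converged=False)
    coeff, d, yy, _ = fit
    unit = hertz_cone_coefficient(1.0, curve.half_angle, poisson_cell)
    E = coeff / unit
    resid = yy - coeff * d * d
    rms_resid = float(np.sqrt((resid**2).mean()))
    rms_force = float(np.sqrt((yy**2).mean()))
    rel = rms_resid / rms_force if rms_force > 0 else np.inf
    ok = np.isfinite(E) and E > 0
    return HertzFit(
        young_modulus=float(E) if ok else np.nan,
        contact_point=zc,
        rms_residual=rms_resid,
        relative_fit_error=float(rel),
        converged=bool(ok),
    )


# ---------------------------------------------------------------------------
# Force-volume maps
# ---------------------------------------------------------------------------


def build_elasticity_map(
    force_volume,
    grid_spacing: float = 1.0,
    poisson_cell: float = 0.5,
    qc_threshold: float = 0.20,
    bending_correction: bool = True,
) -> ElasticityMap:
    """Fit every curve of a force-volume grid into an elasticity map.

    ``force_volume`` is a 2-D nested sequence of :class:`ForceCurve`.
    Moduli are reported in kPa; pixels whose fit failed or whose relative
    residual exceeds ``qc_threshold`` are masked False.  If more than half
    the fits fail the map is flagged ``unreliable`` (returned, not raised).
    """
    rows = list(force_volume)
    ny = len(rows)
    nx = len(rows[0])
    moduli = np.full((ny, nx), np.nan)
    qc = np.zeros((ny, nx), dtype=bool)
    for j, row in enumerate(rows):
        if len(row) != nx:
            raise ValueError("force_volume must be rectangular")
        for i, curve in enumerate(row):
            fit = fit_hertz_cone(
                curve,
                poisson_cell=poisson_cell,
                bending_correction=bending_correction,
            )
            if fit.converged:
                moduli[j, i] = fit.young_modulus / 1000.0  # Pa -> kPa
                qc[j, i] = fit.relative_fit_error <= qc_threshold
    n_ok = int(qc.sum())
    unreliable = n_ok < 0.5 * ny * nx
    stats = {}
    if n_ok:
        vals = moduli[qc]
        stats = {
            "mean_kPa": float(vals.mean()),
            "min_kPa": float(vals.min()),
            "max_kPa": float(vals.max()),
            "n_valid": n_ok,
        }
    return ElasticityMap(
        moduli=moduli,
        grid_spacing=grid_spacing,
        qc_mask=qc,
        unreliable=unreliable,
        stats=stats,
    )
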