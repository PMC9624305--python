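"""Elastic half-space solvers for Fourier Transform Traction Cytometry (FTTC).

The substrate is modelled as a linear-elastic, isotropic, semi-infinite
half-space (Boussinesq approximation).  A tangential traction field
``T(x, y)`` applied at the surface produces an in-plane surface displacement
field ``u(x, y)`` through a convolution with the Boussinesq surface Green
tensor.  In Fourier space the convolution becomes a per-wave-vector 2x2
linear system,

    u~(k) = G~(k) . T~(k),

with the kernel

    G~(k) = 2 (1 + sigma) / (E k^3)
            [[(1 - sigma) k^2 + sigma ky^2,  -sigma kx ky],
             [-sigma kx ky,  (1 - sigma) k^2 + sigma kx^2]],

where ``E`` is the substrate Young's modulus (Pa), ``sigma`` its Poisson
ratio, and ``k = |k|`` in rad/um.  This is the Fourier transform of the
classical real-space Boussinesq surface solution (implemented here as
:func:`boussinesq_point_displacement`, which doubles as an independent
oracle for the Fourier pipeline).

Conventions (used package-wide):
    * arrays are indexed ``[row, col]`` with ``x`` = column (east) and
      ``y`` = row (south); 0-based, pixel-centre;
    * lengths in um, stresses in Pa, forces in nN;
    * the discrete FFT approximates the continuous transform; with the
      kernel written in rad/um the grid-spacing factors cancel, so
      ``u = IFFT2(G~ . FFT2(T))`` directly.

The ``k = 0`` mode is singular (a uniform traction on an infinite half-space
produces unbounded displacement); both directions adopt the standard TFM
zero-net-force convention and null it.  Fields are zero-padded to twice the
linear size before transforming because the physical convolution is
aperiodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubstrateProperties",
    "DisplacementField",
    "TractionField",
    "FourierGreenTensor",
    "greens_tensor_hat",
    "forward_displacement",
    "fttc_invert",
    "boussinesq_point_displacement",
    "boussinesq_convolve",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstrateProperties:
    """Mechanical properties of the gel substrate.

    Parameters
    ----------
    young_modulus : float
        Young's modulus E of the substrate in Pa (e.g. ~470 Pa for the soft
        polyacrylamide gels used for neuronal TFM).
    poisson_ratio : float
        Poisson ratio sigma in [0, 0.5]; defaults to 0.5 (incompressible
        hydrogel).
    """

    young_modulus: float
    poisson_ratio: float = 0.5
    #: the solvers assume a semi-infinite elastic half-space
    thickness_assumption: str = field(default="semi-infinite half-space")

    def __post_init__(self) -> None:
        if not (self.young_modulus > 0):
            raise ValueError(f"young_modulus must be > 0, got {self.young_modulus}")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError(
                f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}"
            )


@dataclass
class DisplacementField:
    """Gridded 2-component substrate surface displacement, in um.

    ``ux``/``uy`` are 2-D arrays on a uniform rectangular grid with spacing
    ``grid_spacing`` (um); ``origin`` is the physical (x0, y0) of pixel
    (row 0, col 0) in um.  ``validity_mask`` is False where values were
    extrapolated rather than measured/interpolated.
    """

    grid_spacing: float
    ux: np.ndarray
    uy: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    validity_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ux = np.asarray(self.ux, dtype=float)
        self.uy = np.asarray(self.uy, dtype=float)
        if self.ux.shape != self.uy.shape or self.ux.ndim != 2:
            raise ValueError("ux and uy must be 2-D arrays of identical shape")
        if not (self.grid_spacing > 0):
            raise ValueError("grid_spacing must be > 0")
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.ux.shape, dtype=bool)
        else:
            self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
            if self.validity_mask.shape != self.ux.shape:
                raise ValueError("validity_mask shape mismatch")
        if not np.all(np.isfinite(self.ux[self.validity_mask])) or not np.all(
            np.isfinite(self.uy[self.validity_mask])
        ):
            raise ValueError("non-finite displacement inside validity_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ux.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy)


@dataclass
class TractionField:
    """Gridded 2-component traction stress field, in Pa."""

    grid_spacing: float
    tx: np.ndarray
    ty: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    regularization_used: float = 0.0

    def __post_init__(self) -> None:
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        if self.tx.shape != self.ty.shape or self.tx.ndim != 2:
            raise ValueError("tx and ty must be 2-D arrays of identical shape")
        if not (self.grid_spacing > 0):
            raise ValueError("grid_spacing must be > 0")
        if self.regularization_used < 0:
            raise ValueError("regularization must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tx.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)


@dataclass
class FourierGreenTensor:
    """Sampled Fourier-space Green tensor on an FFT frequency grid.

    ``gxy`` stores the (symmetric) off-diagonal component; the tensor at
    each wave vector is ``[[gxx, gxy], [gxy, gyy]]`` in um/Pa.
    """

    kx: np.ndarray
    ky: np.ndarray
    gxx: np.ndarray
    gxy: np.ndarray
    gyy: np.ndarray


# ---------------------------------------------------------------------------
# Fourier-space kernel
# ---------------------------------------------------------------------------


def greens_tensor_hat(
    kx: np.ndarray | float,
    ky: np.ndarray | float,
    substrate: SubstrateProperties,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boussinesq surface Green tensor in Fourier space.

    Parameters
    ----------
    kx, ky : array_like
        Wave-vector components in rad/um.  Must not both be zero anywhere
        (the k = 0 mode is singular and handled by the callers).
    substrate : SubstrateProperties

    Returns
    -------
    (gxx, gxy, gyy) : tuple of ndarray
        Tensor components in um/Pa; the full symmetric tensor is
        ``[[gxx, gxy], [gxy, gyy]]``.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k2 = kx * kx + ky * ky
    if np.any(k2 == 0):
        raise ValueError("greens_tensor_hat is singular at k = 0")
    k = np.sqrt(k2)
    E = substrate.young_modulus
    s = substrate.poisson_ratio
    pref = 2.0 * (1.0 + s) / (E * k2 * k)
    gxx = pref * ((1.0 - s) * k2 + s * ky * ky)
    gyy = pref * ((1.0 - s) * k2 + s * kx * kx)
    gxy = pref * (-s * kx * ky)
    return gxx, gxy, gyy


def _fft_wavevectors(shape: tuple[int, int], spacing: float):
    """Angular-frequency grids (rad/um) for a given padded shape."""
    ny, nx = shape
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing)
    return np.meshgrid(kx, ky)  # (KX, KY), each shaped (ny, nx)


def _green_grids(shape: tuple[int, int], spacing: float, substrate: SubstrateProperties):
    """Tensor components on the FFT grid, with the k = 0 entry set to 0."""
    KX, KY = _fft_wavevectors(shape, spacing)
    k2 = KX**2 + KY**2
    k2[0, 0] = 1.0  # avoids 0/0; the k = 0 entry is overwritten below
    k = np.sqrt(k2)
    E = substrate.young_modulus
    s = substrate.poisson_ratio
    pref = 2.0 * (1.0 + s) / (E * k2 * k)
    gxx = pref * ((1.0 - s) * k2 + s * KY * KY)
    gyy = pref * ((1.0 - s) * k2 + s * KX * KX)
    gxy = pref * (-s * KX * KY)
    gxx[0, 0] = gxy[0, 0] = gyy[0, 0] = 0.0
    return gxx, gxy, gyy


def _pad_shape(shape: tuple[int, int], pad_factor: int) -> tuple[int, int]:
    return (shape[0] * pad_factor, shape[1] * pad_factor)


# ---------------------------------------------------------------------------
# Forward problem: traction -> displacement
# ---------------------------------------------------------------------------


def forward_displacement(
    traction: TractionField,
    substrate: SubstrateProperties,
    pad_factor: int = 2,
) -> DisplacementField:
    """Surface displacement produced by a traction field (forward model).

    The traction is zero-padded to ``pad_factor`` times the linear grid
    size, transformed, multiplied by the Fourier Green tensor, and the
    result cropped back; padding suppresses periodic-image artifacts of the
    aperiodic physical convolution.  The k = 0 (net force) mode is nulled:
    only balanced force systems have a well-defined half-space solution, so
    the mean traction is effectively projected out.

    Linear in the traction: ``fwd(a T1 + b T2) = a fwd(T1) + b fwd(T2)``.
    """
    tx, ty = traction.tx, traction.ty
    if not (np.all(np.isfinite(tx)) and np.all(np.isfinite(ty))):
        raise ValueError("traction field contains NaN/Inf")
    ny, nx = tx.shape
    pny, pnx = _pad_shape((ny, nx), pad_factor)
    ptx = np.zeros((pny, pnx))
    pty = np.zeros((pny, pnx))
    ptx[:ny, :nx] = tx
    pty[:ny, :nx] = ty

    gxx, gxy, gyy = _green_grids((pny, pnx), traction.grid_spacing, substrate)
    ftx = np.fft.fft2(ptx)
    fty = np.fft.fft2(pty)
    fux = gxx * ftx + gxy * fty
    fuy = gxy * ftx + gyy * fty
    fux[0, 0] = fuy[0, 0] = 0.0
    ux = np.fft.ifft2(fux).real[:ny, :nx]
    uy = np.fft.ifft2(fuy).real[:ny, :nx]
    return DisplacementField(
        grid_spacing=traction.grid_spacing, ux=ux, uy=uy, origin=traction.origin
    )


# ---------------------------------------------------------------------------
# Inverse problem: displacement -> traction
# ---------------------------------------------------------------------------


def fttc_invert(
    displacement: DisplacementField,
    substrate: SubstrateProperties,
    regularization: float = 0.0,
    pad_factor: int = 2,
) -> TractionField:
    """Recover the traction field from a measured displacement field.

    With ``regularization == 0`` this is the exact per-wave-vector inversion
    ``T~ = G~^-1 u~``; with ``regularization = lam > 0`` it is the
    zeroth-order Tikhonov solution minimising
    ``|G~ T~ - u~|^2 + lam |T~|^2`` independently at each wave vector
    (``lam`` carries units of (um/Pa)^2).  The zero-frequency traction is
    set to zero (zero-net-force convention), and the mean displacement — a
    rigid translation carrying no traction information — is subtracted
    before padding.

    Raises
    ------
    ValueError
        For grids smaller than 4x4, negative ``regularization``, or a
        displacement field with unfilled gaps (``validity_mask`` not all
        True).
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    ny, nx = displacement.shape
    if ny < 4 or nx < 4:
        raise ValueError("displacement grid must be at least 4x4")
    if not (
        np.all(np.isfinite(displacement.ux)) and np.all(np.isfinite(displacement.uy))
    ):
        raise ValueError(
            "displacement field has unfilled gaps; interpolate before inversion"
        )

    ux = displacement.ux - displacement.ux.mean()
    uy = displacement.uy - displacement.uy.mean()
    pny, pnx = _pad_shape((ny, nx), pad_factor)
    pux = np.zeros((pny, pnx))
    puy = np.zeros((pny, pnx))
    pux[:ny, :nx] = ux
    puy[:ny, :nx] = uy

    gxx, gxy, gyy = _green_grids((pny, pnx), displacement.grid_spacing, substrate)
    fux = np.fft.fft2(pux)
    fuy = np.fft.fft2(puy)

    lam = float(regularization)
    # G~ is real symmetric 2x2 per wave vector; the Tikhonov normal
    # equations (G^2 + lam I) T~ = G u~ are solved in closed form.
    m11 = gxx * gxx + gxy * gxy + lam
    m22 = gyy * gyy + gxy * gxy + lam
    m12 = gxy * (gxx + gyy)
    det = m11 * m22 - m12 * m12
    det[0, 0] = 1.0  # k = 0 handled below
    if lam == 0.0:
        # guard exact zeros that can only occur at k = 0 (already patched)
        bad = det == 0
        det[bad] = 1.0
    rhs_x = gxx * fux + gxy * fuy
    rhs_y = gxy * fux + gyy * fuy
    ftx = (m22 * rhs_x - m12 * rhs_y) / det
    fty = (-m12 * rhs_x + m11 * rhs_y) / det
    ftx[0, 0] = fty[0, 0] = 0.0

    tx = np.fft.ifft2(ftx).real[:ny, :nx]
    ty = np.fft.ifft2(fty).real[:ny, :nx]
    return TractionField(
        grid_spacing=displacement.grid_spacing,
        tx=tx,
        ty=ty,
        origin=displacement.origin,
        regularization_used=lam,
    )


# ---------------------------------------------------------------------------
# Real-space reference solutions (independent of the FFT pipeline)
# ---------------------------------------------------------------------------


def boussinesq_point_displacement(
    x: np.ndarray,
    y: np.ndarray,
    fx: float,
    fy: float,
    substrate: SubstrateProperties,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface displacement of a tangential point force on a half-space.

    Classical Boussinesq/Cerruti solution evaluated in real space,

        u_i(r) = (1 + sigma) / (pi E r) [ (1 - sigma) delta_ij
                                          + sigma x_i x_j / r^2 ] F_j,

    with positions in um, force components in Pa.um^2 and displacements in
    um.  Kept free of any Fourier machinery so it can serve as an
    independent cross-check of the FTTC pipeline.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    if np.any(r2 == 0):
        raise ValueError("point-force solution is singular at r = 0")
    r = np.sqrt(r2)
    E = substrate.young_modulus
    s = substrate.poisson_ratio
    pref = (1.0 + s) / (np.pi * E * r)
    ux = pref * (((1.0 - s) + s * x * x / r2) * fx + (s * x * y / r2) * fy)
    uy = pref * ((s * x * y / r2) * fx + ((1.0 - s) + s * y * y / r2) * fy)
    return ux, uy


def boussinesq_convolve(
    traction: TractionField, substrate: SubstrateProperties
) -> DisplacementField:
    """Brute-force real-space convolution of the Boussinesq kernel.

    Direct O(N^4) summation of per-cell point forces ``F = T(r') dx^2``
    over all source cells; the (singular) self term uses the exact centre
    displacement of a uniformly loaded square patch.  Quadratic cost —
    intended for small validation grids only.
    """
    tx, ty = traction.tx, traction.ty
    ny, nx = tx.shape
    dx = traction.grid_spacing
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dx
    X, Y = np.meshgrid(xs, ys)
    ux = np.zeros_like(tx)
    uy = np.zeros_like(ty)
    E = substrate.young_modulus
    s = substrate.poisson_ratio
    # uniform square patch, tangential load: centre displacement along the
    # load direction. Integrating the Cerruti kernel over a square of side
    # dx = 2a gives int 1/r = 8a ln(1+sqrt2) and int x^2/r^3 = 4a ln(1+sqrt2),
    # hence u(0) = (1+s)/(pi E) * 4a (2 - s) ln(1+sqrt2) * q  (isotropic).
    a = dx / 2.0
    self_coeff = (1.0 + s) / (np.pi * E) * 4 * a * (2.0 - s) * np.log(1 + np.sqrt(2))
    for j in range(ny):
        for i in range(nx):
            fx = tx[j, i] * dx * dx
            fy = ty[j, i] * dx * dx
            if fx == 0.0 and fy == 0.0:
                continue
            rx = X - xs[i]
            ry = Y - ys[j]
            r2 = rx * rx + ry * ry
            r2[j, i] = 1.0  # self term handled analytically
            r = np.sqrt(r2)
            pref = (1.0 + s) / (np.pi * E * r)
            dux = pref * (((1 - s) + s * rx * rx / r2) * fx + (s * rx * ry / r2) * fy)
            duy = pref * ((s * rx * ry / r2) * fx + ((1 - s) + s * ry * ry / r2) * fy)
            dux[j, i] = self_coeff * tx[j, i]
            duy[j, i] = self_coeff * ty[j, i]
            ux += dux
            uy += duy
    return DisplacementField(
        grid_spacing=dx, ux=ux, uy=uy, origin=traction.origin
    )
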