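"""Substrate displacement measurement from fluorescent bead image pairs.

TFM measures substrate deformation by imaging fiducial beads embedded in
the gel twice: *loaded* (cell pulling) and *reference* (relaxed).  Each
bead's displacement is ``u = r' - r``, the difference between its loaded
and reference positions.  This module detects beads to sub-pixel
precision, links the two detections into per-bead displacement vectors,
optionally removes rigid stage drift, and interpolates the sparse vectors
onto the uniform rectangular grid the Fourier inversion requires.

Linking is the delicate stage: wherever the local displacement approaches
the bead spacing, nearest-neighbour matching suffers identity aliasing —
whole neighbourhoods can lock onto the wrong partners while remaining
mutually consistent, which no vector-median filter can repair.
:func:`track_displacements` therefore uses a hybrid scheme standard in
particle tracking: a coarse window-correlation *predictor* (immune to
bead identity, since it correlates all image texture) initialises an
iterative predictor-corrector loop in which matches are accepted only
when unambiguous (tight distance gate, or a looser gate guarded by a
nearest/second-nearest ratio test), with local-median and smoothness
filters between iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import (
    LinearNDInterpolator,
    NearestNDInterpolator,
    RBFInterpolator,
)
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

from .fttc import DisplacementField

__all__ = [
    "BeadImagePair",
    "SparseDisplacements",
    "detect_beads",
    "match_beads",
    "filter_vector_outliers",
    "track_displacements",
    "correct_drift",
    "interpolate_to_grid",
]


@dataclass
class BeadImagePair:
    """Reference/loaded fluorescence image pair with its pixel size (um/px)."""

    reference: np.ndarray
    loaded: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.loaded = np.asarray(self.loaded, dtype=float)
        if self.reference.shape != self.loaded.shape:
            raise ValueError("reference and loaded images must have the same shape")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        if self.reference.min() < 0 or self.loaded.min() < 0:
            raise ValueError("intensities must be nonnegative")


@dataclass
class SparseDisplacements:
    """Per-bead displacement vectors at scattered reference positions (um)."""

    positions: np.ndarray  # (n, 2) bead (x, y) in the reference frame, um
    vectors: np.ndarray  # (n, 2) displacement (ux, uy), um
    match_quality: np.ndarray  # (n,) score in [0, 1]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.match_quality = np.atleast_1d(np.asarray(self.match_quality, dtype=float))
        if len(self.positions) != len(self.vectors) or len(self.positions) != len(
            self.match_quality
        ):
            raise ValueError("positions, vectors and match_quality must align")

    def __len__(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# Bead detection
# ---------------------------------------------------------------------------


def _refine_centroid(
    image: np.ndarray, row: int, col: int, half: int = 2, n_iter: int = 2
) -> tuple[float, float]:
    """Background-subtracted intensity centroid, recentred iteratively.

    The window border median estimates the local background; recentring the
    window on the running estimate removes most of the truncation bias of a
    fixed window.  Returns (row, col) in float pixels.
    """
    ny, nx = image.shape
    r, c = float(row), float(col)
    for _ in range(n_iter):
        r0, c0 = int(round(r)), int(round(c))
        rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, ny)
        clo, chi = max(c0 - half, 0), min(c0 + half + 1, nx)
        win = image[rlo:rhi, clo:chi]
        border = np.concatenate([win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]])
        w = np.clip(win - np.median(border), 0.0, None)
        total = w.sum()
        if total <= 0:
            return r, c
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        r, c = float((w * rr).sum() / total), float((w * cc).sum() / total)
    return r, c


def _subtract_spot(
    image: np.ndarray, r: float, c: float, amp: float, sigma: float
) -> None:
    """Subtract a Gaussian spot in place (window of 4 sigma)."""
    ny, nx = image.shape
    half = max(int(np.ceil(4 * sigma)), 2)
    r0, c0 = int(round(r)), int(round(c))
    rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, ny)
    clo, chi = max(c0 - half, 0), min(c0 + half + 1, nx)
    if rlo >= rhi or clo >= chi:
        return
    rr = np.arange(rlo, rhi)
    cc = np.arange(clo, chi)
    gy = np.exp(-((rr - r) ** 2) / (2 * sigma**2))
    gx = np.exp(-((cc - c) ** 2) / (2 * sigma**2))
    image[rlo:rhi, clo:chi] -= amp * np.outer(gy, gx)


def _fit_amplitude(image: np.ndarray, r: float, c: float, sigma: float) -> float:
    """Least-squares Gaussian amplitude at a fixed centre."""
    ny, nx = image.shape
    half = max(int(np.ceil(2 * sigma)), 2)
    r0, c0 = int(round(r)), int(round(c))
    rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, ny)
    clo, chi = max(c0 - half, 0), min(c0 + half + 1, nx)
    rr = np.arange(rlo, rhi)
    cc = np.arange(clo, chi)
    g = np.outer(
        np.exp(-((rr - r) ** 2) / (2 * sigma**2)),
        np.exp(-((cc - c) ** 2) / (2 * sigma**2)),
    )
    win = image[rlo:rhi, clo:chi]
    denom = (g * g).sum()
    return float((win * g).sum() / denom) if denom > 0 else 0.0


def detect_beads(
    image: np.ndarray,
    pixel_size: float,
    min_separation: float = 1.0,
    intensity_threshold: float = 0.2,
    deblend_sigma: float | None = None,
) -> np.ndarray:
    """Detect fluorescent beads as sub-pixel (x, y) positions in um.

    Local maxima above ``intensity_threshold`` (a fraction of the image
    dynamic range above the minimum) and at least ``min_separation`` um
    apart are refined by an intensity-weighted centroid.  With
    ``deblend_sigma`` (the spot Gaussian width in um) the refinement is
    iterative: each spot's fitted Gaussian is subtracted before its
    neighbours are re-centroided (CLEAN-style), which removes the centroid
    bias that overlapping spots otherwise cause at high bead densities.
    A flat or empty image yields an empty (0, 2) array rather than an
    error.
    """
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 16 or image.shape[1] < 16:
        raise ValueError("image must be at least 16x16 pixels")
    lo, hi = image.min(), image.max()
    if hi <= lo:
        return np.empty((0, 2))
    thr = lo + intensity_threshold * (hi - lo)
    min_dist = max(int(round(min_separation / pixel_size)), 1)
    peaks = peak_local_max(
        image, min_distance=min_dist, threshold_abs=thr, exclude_border=2
    )
    if len(peaks) == 0:
        return np.empty((0, 2))

    if deblend_sigma is None:
        out = [_refine_centroid(image, row, col) for row, col in peaks]
        return np.asarray([(c * pixel_size, r * pixel_size) for r, c in out])

    sigma_px = deblend_sigma / pixel_size
    background = float(np.median(image))
    resid = image - background
    order = np.argsort(-image[peaks[:, 0], peaks[:, 1]])
    peaks = peaks[order]
    pos: list[tuple[float, float]] = []
    amps: list[float] = []
    for row, col in peaks:
        r, c = _refine_centroid(resid + background, row, col)
        a = _fit_amplitude(resid, r, c, sigma_px)
        _subtract_spot(resid, r, c, a, sigma_px)
        pos.append((r, c))
        amps.append(a)
    for _ in range(2):
        for i in range(len(pos)):
            r, c = pos[i]
            _subtract_spot(resid, r, c, -amps[i], sigma_px)  # add back
            r2, c2 = _refine_centroid(
                resid + background, int(round(r)), int(round(c))
            )
            a2 = _fit_amplitude(resid, r2, c2, sigma_px)
            _subtract_spot(resid, r2, c2, a2, sigma_px)
            pos[i] = (r2, c2)
            amps[i] = a2
    return np.asarray([(c * pixel_size, r * pixel_size) for r, c in pos])


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def match_beads(
    ref_positions: np.ndarray,
    loaded_positions: np.ndarray,
    max_displacement: float,
) -> SparseDisplacements:
    """Link reference beads to loaded beads by mutual nearest neighbours.

    A pair is kept only if each bead is the other's nearest neighbour and
    their separation is below ``max_displacement`` (um); unmatched beads
    are dropped.  ``match_quality`` is ``1 - d / max_displacement``.

    Reliable only while displacements stay well below the bead spacing;
    see :func:`track_displacements` for the robust pipeline entry point.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    ref = np.atleast_2d(np.asarray(ref_positions, dtype=float))
    load = np.atleast_2d(np.asarray(loaded_positions, dtype=float))
    if len(ref) == 0 or len(load) == 0:
        raise ValueError("both position lists must be nonempty")
    tree_load = cKDTree(load)
    tree_ref = cKDTree(ref)
    d_rl, j_rl = tree_load.query(ref)
    _, i_lr = tree_ref.query(load)
    keep = (i_lr[j_rl] == np.arange(len(ref))) & (d_rl <= max_displacement)
    pos = ref[keep]
    vec = load[j_rl[keep]] - pos
    qual = 1.0 - d_rl[keep] / max_displacement
    return SparseDisplacements(pos, vec, qual)


def filter_vector_outliers(
    sparse: SparseDisplacements,
    k: int = 12,
    abs_threshold: float = 0.3,
    mad_multiple: float = 5.0,
) -> SparseDisplacements:
    """Remove displacement vectors inconsistent with their neighbourhood.

    Normalised local-median test: a vector is discarded when its residual
    against the median of its ``k`` nearest neighbours exceeds
    ``max(abs_threshold, mad_multiple * local MAD)`` (um).  The absolute
    floor keeps steep-but-real gradients; only catastrophic mismatches
    (errors of order the bead spacing) are removed.
    """
    if len(sparse) <= k:
        return sparse
    tree = cKDTree(sparse.positions)
    _, idx = tree.query(sparse.positions, k=k + 1)
    nbr = sparse.vectors[idx[:, 1:]]
    med = np.median(nbr, axis=1)
    resid = np.linalg.norm(sparse.vectors - med, axis=1)
    mad = np.median(np.linalg.norm(nbr - med[:, None, :], axis=2), axis=1)
    keep = resid <= np.maximum(abs_threshold, mad_multiple * mad)
    return SparseDisplacements(
        sparse.positions[keep], sparse.vectors[keep], sparse.match_quality[keep]
    )


def _smoothness_filter(
    sparse: SparseDisplacements,
    threshold: float = 0.3,
    smoothing: float = 5.0,
    rounds: int = 2,
) -> SparseDisplacements:
    """Drop vectors far from a smoothing-spline fit of the whole field."""
    for _ in range(rounds):
        if len(sparse) < 16:
            return sparse
        fit = RBFInterpolator(
            sparse.positions,
            sparse.vectors,
            kernel="thin_plate_spline",
            neighbors=min(48, len(sparse)),
            smoothing=smoothing,
        )
        resid = np.linalg.norm(sparse.vectors - fit(sparse.positions), axis=1)
        keep = resid < threshold
        if keep.all():
            break
        sparse = SparseDisplacements(
            sparse.positions[keep], sparse.vectors[keep], sparse.match_quality[keep]
        )
    return sparse


def _coarse_window_predictor(
    pair: BeadImagePair,
    windows: tuple[float, ...] = (16.0, 12.0, 8.0),
    stride_frac: float = 0.5,
):
    """Multi-pass window-correlation displacement predictor (um -> um).

    Phase cross-correlation of corresponding sub-windows gives the bulk
    shift of each neighbourhood regardless of bead identity.  Passes run
    coarse to fine; from the second pass on, each loaded window is
    pre-shifted by the current prediction (window offsetting), so later,
    smaller windows measure only the residual and the predictor converges
    on displacement peaks larger than the bead spacing — exactly where
    per-bead linking is ambiguous and needs the prior.
    """
    px = pair.pixel_size
    ny, nx = pair.reference.shape
    predictor = None
    for wum in windows:
        w = max(int(round(wum / px)), 8)
        s = max(int(round(stride_frac * wum / px)), 4)
        cents, shifts = [], []
        for r0 in range(0, ny - w + 1, s):
            for c0 in range(0, nx - w + 1, s):
                cx, cy = (c0 + w / 2) * px, (r0 + w / 2) * px
                if predictor is None:
                    off_c = off_r = 0
                else:
                    off = predictor(np.array([[cx, cy]]))[0]
                    off_c = int(round(off[0] / px))
                    off_r = int(round(off[1] / px))
                r0l = min(max(r0 + off_r, 0), ny - w)
                c0l = min(max(c0 + off_c, 0), nx - w)
                rw = pair.reference[r0 : r0 + w, c0 : c0 + w]
                lw = pair.loaded[r0l : r0l + w, c0l : c0l + w]
                if rw.std() < 1e-12 or lw.std() < 1e-12:
                    continue
                shift, _, _ = phase_cross_correlation(
                    rw, lw, upsample_factor=10, normalization=None
                )
                # returned shift registers loaded onto reference; the
                # displacement is the opposite sign, (row, col) -> (x, y),
                # plus the integer window offset already applied
                cents.append((cx, cy))
                shifts.append(
                    (
                        -shift[1] * px + (c0l - c0) * px,
                        -shift[0] * px + (r0l - r0) * px,
                    )
                )
        if len(cents) < 4:
            continue
        predictor = RBFInterpolator(
            np.asarray(cents),
            np.asarray(shifts),
            kernel="thin_plate_spline",
            neighbors=min(16, len(cents)),
            smoothing=1e-3,
        )
    if predictor is None:
        return lambda p: np.zeros_like(np.atleast_2d(p))
    return predictor


def track_displacements(
    pair: BeadImagePair,
    min_separation: float = 0.5,
    intensity_threshold: float = 0.15,
    deblend_sigma: float | None = 0.2,
    n_iter: int = 8,
    tight_radius: float = 0.3,
    loose_radius: float = 0.9,
    ambiguity_ratio: float = 0.45,
) -> SparseDisplacements:
    """Measure per-bead displacements from a reference/loaded image pair.

    Hybrid predictor-corrector particle tracking: beads are detected in
    both frames (with overlap deblending); a coarse window-correlation
    predictor supplies the initial displacement estimate; then, for
    ``n_iter`` rounds, every reference bead is linked to the loaded bead
    nearest its *predicted* position, a link being accepted only when it
    is mutual and either within ``tight_radius`` (um) of the prediction or
    within ``loose_radius`` while beating the second-nearest candidate by
    ``ambiguity_ratio`` (a nearest/second-nearest distance ratio test).
    Accepted links pass a local-median outlier filter and refit the
    predictor; a final smoothness filter drops vectors inconsistent with a
    smoothing-spline fit of the whole field.

    The acceptance gates are deliberately conservative: a wrong but
    self-consistent neighbourhood (identity aliasing, arising wherever the
    displacement approaches the bead spacing) can pass any posterior
    vector filter, so it must be prevented from forming at all.
    """
    ref = detect_beads(
        pair.reference,
        pair.pixel_size,
        min_separation,
        intensity_threshold,
        deblend_sigma,
    )
    load = detect_beads(
        pair.loaded,
        pair.pixel_size,
        min_separation,
        intensity_threshold,
        deblend_sigma,
    )
    if len(ref) < 4 or len(load) < 4:
        return SparseDisplacements(
            np.empty((0, 2)), np.empty((0, 2)), np.empty((0,))
        )
    predictor = _coarse_window_predictor(pair)
    tree_load = cKDTree(load)
    sp = SparseDisplacements(np.empty((0, 2)), np.empty((0, 2)), np.empty((0,)))
    for _ in range(n_iter):
        pred = predictor(ref)
        corrected = ref + pred
        tree_pred = cKDTree(corrected)
        dd, jj = tree_load.query(corrected, k=2)
        d1, j1 = dd[:, 0], jj[:, 0]
        d2 = dd[:, 1]
        _, i_lr = tree_pred.query(load)
        mutual = i_lr[j1] == np.arange(len(ref))
        accept = mutual & (
            (d1 <= tight_radius)
            | ((d1 <= loose_radius) & (d1 <= ambiguity_ratio * d2))
        )
        if accept.sum() < 4:
            break
        sp = filter_vector_outliers(
            SparseDisplacements(
                ref[accept],
                load[j1[accept]] - ref[accept],
                np.clip(1.0 - d1[accept] / loose_radius, 0.0, 1.0),
            )
        )
        if len(sp) < 4:
            break
        predictor = RBFInterpolator(
            sp.positions,
            sp.vectors,
            kernel="thin_plate_spline",
            neighbors=min(32, len(sp)),
            smoothing=0.0,
        )
    return _smoothness_filter(sp)


def correct_drift(
    sparse: SparseDisplacements,
    cell_mask: np.ndarray | None,
    pixel_size: float = 1.0,
) -> SparseDisplacements:
    """Subtract rigid stage drift estimated from beads outside the cell.

    Drift is the median displacement of beads falling outside ``cell_mask``
    (a boolean image-aligned grid; position -> pixel via ``pixel_size``).
    With no mask, the median over all beads is used — appropriate only when
    most of the field of view is cell-free.
    """
    if len(sparse) == 0:
        return sparse
    if cell_mask is None:
        outside = np.ones(len(sparse), dtype=bool)
    else:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        cols = np.clip(
            (sparse.positions[:, 0] / pixel_size).round().astype(int),
            0,
            cell_mask.shape[1] - 1,
        )
        rows = np.clip(
            (sparse.positions[:, 1] / pixel_size).round().astype(int),
            0,
            cell_mask.shape[0] - 1,
        )
        outside = ~cell_mask[rows, cols]
    if not outside.any():
        return sparse
    drift = np.median(sparse.vectors[outside], axis=0)
    return SparseDisplacements(
        sparse.positions, sparse.vectors - drift, sparse.match_quality
    )


# ---------------------------------------------------------------------------
# Gridding
# ---------------------------------------------------------------------------


def interpolate_to_grid(
    sparse: SparseDisplacements,
    grid_spacing: float,
    extent: tuple[float, float, float, float],
    method: str = "thin_plate",
) -> DisplacementField:
    """Interpolate sparse bead displacements onto a uniform grid.

    ``method="thin_plate"`` (default) fits a thin-plate-spline surface —
    exact at the beads, smooth between, and markedly more faithful to
    curved elastic fields than piecewise-linear interpolation at realistic
    bead spacings.  ``method="linear"`` uses Delaunay linear interpolation
    inside the convex hull with nearest-neighbour extrapolation outside.
    In both cases cells outside the bead convex hull are marked False in
    the ``validity_mask``.  ``extent`` is (x_min, y_min, x_max, y_max) um.

    Raises
    ------
    ValueError
        With fewer than 3 non-collinear points.
    """
    if len(sparse) < 3:
        raise ValueError("need at least 3 sparse points to interpolate")
    x0, y0, x1, y1 = extent
    nx = max(int(np.floor((x1 - x0) / grid_spacing)) + 1, 2)
    ny = max(int(np.floor((y1 - y0) / grid_spacing)) + 1, 2)
    gx = x0 + np.arange(nx) * grid_spacing
    gy = y0 + np.arange(ny) * grid_spacing
    GX, GY = np.meshgrid(gx, gy)
    pts = sparse.positions
    span = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-12) < 2:
        raise ValueError("sparse points are collinear; cannot triangulate")
    # hull membership from the linear interpolant in either mode
    lin = LinearNDInterpolator(pts, sparse.vectors)
    lin_vals = lin(GX, GY)
    valid = np.isfinite(lin_vals[..., 0])
    if method == "linear":
        near = NearestNDInterpolator(pts, sparse.vectors)
        fill = near(GX, GY)
        vals = np.where(np.isfinite(lin_vals), lin_vals, fill)
    elif method == "thin_plate":
        rbf = RBFInterpolator(
            pts,
            sparse.vectors,
            kernel="thin_plate_spline",
            neighbors=min(64, len(sparse)),
        )
        vals = rbf(np.column_stack([GX.ravel(), GY.ravel()])).reshape(ny, nx, 2)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return DisplacementField(
        grid_spacing=grid_spacing,
        ux=vals[..., 0],
        uy=vals[..., 1],
        origin=(x0, y0),
        validity_mask=valid,
    )
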