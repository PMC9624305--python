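"""Bead detection, matching, tracking and gridding."""

import numpy as np
import pytest

from neuromech import (
    BeadImagePair,
    DisplacementField,
    SparseDisplacements,
    correct_drift,
    detect_beads,
    filter_vector_outliers,
    interpolate_to_grid,
    match_beads,
    render_bead_pair,
    track_displacements,
)
from neuromech.synthetic import _render_spots


class TestDetect:
    def test_single_spot_subpixel(self):
        img = _render_spots((64, 64), np.array([[10.3, 20.7]]), 200.0, 0.8) + 10
        det = detect_beads(img, pixel_size=1.0, min_separation=3.0)
        assert det.shape == (1, 2)
        assert np.hypot(det[0, 0] - 10.3, det[0, 1] - 20.7) < 0.05

    def test_flat_image_detects_nothing(self):
        assert detect_beads(np.full((32, 32), 7.0), 1.0).shape == (0, 2)

    def test_close_pair_suppressed_to_one(self):
        pos = np.array([[20.0, 20.0], [21.0, 20.3]])
        img = _render_spots((64, 64), pos, 200.0, 0.8) + 10
        det = detect_beads(img, pixel_size=1.0, min_separation=3.0)
        assert len(det) == 1

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError):
            detect_beads(np.zeros((8, 8)), 1.0)

    def test_deblending_reduces_neighbour_bias(self):
        # two resolvable but overlapping spots: plain centroids are pulled
        # together, deblended centroids are not
        pos = np.array([[20.0, 20.0], [24.5, 20.0]])
        img = _render_spots((64, 64), pos, 200.0, 1.5) + 10
        plain = detect_beads(img, 1.0, min_separation=2.0)
        deb = detect_beads(img, 1.0, min_separation=2.0, deblend_sigma=1.5)
        assert len(plain) == len(deb) == 2

        def err(d):
            d = d[np.argsort(d[:, 0])]
            return abs(d[0, 0] - 20.0) + abs(d[1, 0] - 24.5)

        assert err(deb) < err(plain)


class TestMatch:
    def test_identity(self):
        pos = np.array([[1.0, 2.0], [5.0, 7.0], [9.0, 3.0]])
        sp = match_beads(pos, pos, 1.0)
        assert len(sp) == 3
        assert np.allclose(sp.vectors, 0.0)

    def test_rigid_shift(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 50, size=(40, 2))
        sp = match_beads(pos, pos + [0.3, -0.2], 1.0)
        assert len(sp) == 40
        assert np.allclose(sp.vectors, [0.3, -0.2], atol=1e-12)

    def test_bead_beyond_cutoff_excluded(self):
        ref = np.array([[5.0, 5.0], [20.0, 20.0]])
        load = np.array([[5.1, 5.0], [28.0, 20.0]])  # second moved 8 um
        sp = match_beads(ref, load, max_displacement=1.0)
        assert len(sp) == 1
        assert np.allclose(sp.positions[0], [5.0, 5.0])

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            match_beads(np.zeros((2, 2)), np.zeros((2, 2)), 0.0)

    def test_outlier_filter_removes_catastrophic_vector(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 40, size=(60, 2))
        vec = np.tile([0.2, 0.1], (60, 1)) + rng.normal(0, 0.01, size=(60, 2))
        vec[7] = [1.8, -1.2]  # bead-spacing-scale mismatch
        sp = filter_vector_outliers(
            SparseDisplacements(pos, vec, np.ones(60))
        )
        assert len(sp) == 59
        assert not np.any(np.all(sp.positions == pos[7], axis=1))


class TestDrift:
    def test_median_drift_removed_outside_mask(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 40, size=(50, 2))
        drift = np.array([0.15, -0.08])
        vec = np.tile(drift, (50, 1))
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 10:20] = True
        out = correct_drift(
            SparseDisplacements(pos, vec, np.ones(50)), mask, pixel_size=1.0
        )
        assert np.allclose(out.vectors, 0.0, atol=1e-12)


class TestTracking:
    def test_rigid_shift_recovery_subpixel(self):
        # sub-pixel rigid shifts at SNR ~10 recovered to << 0.05 px
        px = 0.25
        n = 64
        shift = 0.4 * px
        u = DisplacementField(1.0, np.full((n, n), shift), np.full((n, n), -shift))
        pair, _ = render_bead_pair(
            u,
            bead_density=0.05,
            photon_noise={"peak": 110, "background": 10},
            seed=5,
        )
        sp = track_displacements(pair)
        mv = sp.vectors.mean(axis=0)
        assert np.hypot(mv[0] - shift, mv[1] + shift) / px < 0.05

    def test_end_to_end_field_correlation(self, substrate):
        # beads rendered from a traction scene, tracked and gridded:
        # the recovered field must correlate strongly with the truth
        from neuromech import make_scene

        sc = make_scene(seed=11, noise="paper")
        sp = track_displacements(sc.bead_pair)
        n = sc.truth_traction.shape[0]
        u = interpolate_to_grid(sp, 1.0, (0.0, 0.0, n - 1.0, n - 1.0))
        truth = sc.truth_displacement
        r = np.corrcoef(
            np.concatenate([u.ux.ravel(), u.uy.ravel()]),
            np.concatenate([truth.ux.ravel(), truth.uy.ravel()]),
        )[0, 1]
        assert r > 0.95


class TestInterpolate:
    def _sparse(self, vecs, n=30, seed=3):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 20, size=(n, 2))
        return SparseDisplacements(pos, vecs(pos), np.ones(n))

    @pytest.mark.parametrize("method", ["linear", "thin_plate"])
    def test_constant_field_reproduced(self, method):
        sp = self._sparse(lambda p: np.tile([0.4, -0.7], (len(p), 1)))
        u = interpolate_to_grid(sp, 1.0, (2, 2, 18, 18), method=method)
        inside = u.validity_mask
        assert np.allclose(u.ux[inside], 0.4, atol=1e-9)
        assert np.allclose(u.uy[inside], -0.7, atol=1e-9)

    @pytest.mark.parametrize("method", ["linear", "thin_plate"])
    def test_linear_field_exact_in_hull(self, method):
        a, b = 0.03, -0.05
        sp = self._sparse(lambda p: np.column_stack([a * p[:, 0], b * p[:, 1]]))
        u = interpolate_to_grid(sp, 1.0, (2, 2, 18, 18), method=method)
        ny, nx = u.shape
        ys, xs = np.mgrid[0:ny, 0:nx] * 1.0
        xs += 2
        ys += 2
        inside = u.validity_mask
        assert np.allclose(u.ux[inside], a * xs[inside], atol=1e-6)
        assert np.allclose(u.uy[inside], b * ys[inside], atol=1e-6)

    def test_forward_model_field_recovered(self, substrate):
        # sampling the forward-model displacement of an adhesion-patch
        # scene at the default bead density and re-gridding loses little
        # of the field
        from neuromech import forward_displacement, make_traction_pattern

        T = make_traction_pattern(5, site_radius=5.0, seed=2)
        truth = forward_displacement(T, substrate)
        rng = np.random.default_rng(4)
        n = truth.shape[0]
        pos = rng.uniform(0, n - 1.0, size=(int(0.1 * n * n), 2))
        from scipy.interpolate import RegularGridInterpolator

        g = np.arange(n) * 1.0
        fx = RegularGridInterpolator((g, g), truth.ux)
        fy = RegularGridInterpolator((g, g), truth.uy)
        vec = np.column_stack([fx(pos[:, ::-1]), fy(pos[:, ::-1])])
        sp = SparseDisplacements(pos, vec, np.ones(len(pos)))
        u = interpolate_to_grid(sp, 1.0, (0, 0, n - 1.0, n - 1.0))
        num = np.sqrt(((u.ux - truth.ux) ** 2 + (u.uy - truth.uy) ** 2).mean())
        den = np.sqrt((truth.ux**2 + truth.uy**2).mean())
        assert num / den < 0.05

    def test_too_few_points_rejected(self):
        sp = SparseDisplacements(np.zeros((2, 2)), np.zeros((2, 2)), np.ones(2))
        with pytest.raises(ValueError):
            interpolate_to_grid(sp, 1.0, (0, 0, 10, 10))

    def test_collinear_points_rejected(self):
        pos = np.column_stack([np.arange(5.0), np.arange(5.0)])
        sp = SparseDisplacements(pos, np.zeros((5, 2)), np.ones(5))
        with pytest.raises(ValueError):
            interpolate_to_grid(sp, 1.0, (0, 0, 10, 10))


class TestBeadImagePair:
    def test_validation(self):
        with pytest.raises(ValueError):
            BeadImagePair(np.zeros((4, 4)), np.zeros((5, 5)), 0.2)
        with pytest.raises(ValueError):
            BeadImagePair(np.zeros((4, 4)), np.zeros((4, 4)), -1.0)
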