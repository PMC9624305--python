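"""Traction summaries: integration, areas, time series, joins."""

import numpy as np
import pandas as pd
import pytest

from neuromech import (
    PA_UM2_TO_NN,
    CellMask,
    CellTractionSummary,
    ElasticityMap,
    TractionField,
    contact_area,
    force_area_table,
    integrate_force,
    pair_stress_modulus,
    summarize_time_series,
)


def _uniform_field(n=16, tx=50.0, ty=0.0, h=1.0):
    return TractionField(h, np.full((n, n), tx), np.full((n, n), ty))


class TestIntegrateForce:
    def test_uniform_stress_times_area(self):
        # 50 Pa over 150 um^2 -> 7.5 nN (1 Pa.um^2 = 1 pN)
        T = _uniform_field(16, 50.0)
        mask = np.zeros((16, 16), dtype=bool)
        mask.ravel()[:150] = True
        s = integrate_force(T, CellMask(mask, pixel_area=1.0))
        assert s.total_force_magnitude == pytest.approx(7.5)
        assert s.mean_stress == pytest.approx(50.0)
        assert s.peak_stress == pytest.approx(50.0)

    def test_opposite_patches_cancel_vectorially(self):
        tx = np.zeros((16, 16))
        tx[4:6, 4:6] = 30.0
        tx[10:12, 10:12] = -30.0
        T = TractionField(1.0, tx, np.zeros_like(tx))
        s = integrate_force(T, CellMask(np.ones((16, 16), bool), 1.0))
        assert abs(s.net_force_vector[0]) < 1e-12
        assert s.total_force_magnitude > 0

    def test_zero_field_all_zero(self):
        T = _uniform_field(8, 0.0)
        s = integrate_force(T, CellMask(np.ones((8, 8), bool), 1.0))
        assert s.total_force_magnitude == 0
        assert s.mean_stress == 0 and s.peak_stress == 0

    def test_unit_conversion_exact(self):
        # 1 Pa over 10^6 um^2 is exactly 1 uN = 1000 nN
        assert 1.0 * 1e6 * PA_UM2_TO_NN == pytest.approx(1000.0)

    def test_empty_mask_and_shape_mismatch(self):
        T = _uniform_field(8)
        with pytest.raises(ValueError):
            integrate_force(T, CellMask(np.zeros((8, 8), bool), 1.0))
        with pytest.raises(ValueError):
            integrate_force(T, CellMask(np.ones((9, 9), bool), 1.0))

    def test_additivity_over_disjoint_masks(self):
        rng = np.random.default_rng(0)
        T = TractionField(1.0, rng.normal(size=(16, 16)), rng.normal(size=(16, 16)))
        m1 = np.zeros((16, 16), bool)
        m2 = np.zeros((16, 16), bool)
        m1[:8] = True
        m2[8:] = True
        f1 = integrate_force(T, CellMask(m1, 1.0)).total_force_magnitude
        f2 = integrate_force(T, CellMask(m2, 1.0)).total_force_magnitude
        f12 = integrate_force(T, CellMask(m1 | m2, 1.0)).total_force_magnitude
        assert f12 == pytest.approx(f1 + f2)


class TestContactArea:
    def test_pixel_counting(self):
        m = np.zeros((16, 16), bool)
        m.ravel()[:100] = True
        assert contact_area(CellMask(m, 1.0)) == pytest.approx(100.0)
        assert contact_area(CellMask(np.ones((16, 16), bool), 1.0)) == 256.0

    def test_pixel_area_proportionality(self):
        m = np.ones((16, 16), bool)
        a1 = contact_area(CellMask(m, 1.0))
        a2 = contact_area(CellMask(m, 0.25))
        assert a2 == pytest.approx(0.25 * a1)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            contact_area(CellMask(np.zeros((4, 4), bool), 1.0))

    def test_force_monotone_in_area_at_constant_stress(self):
        # contact-guidance signature: at fixed mean stress, integrated
        # force strictly increases with contact area
        T = _uniform_field(32, 40.0, 10.0)
        forces = []
        for npix in (50, 120, 300, 700):
            m = np.zeros((32, 32), bool)
            m.ravel()[:npix] = True
            forces.append(
                integrate_force(T, CellMask(m, 1.0)).total_force_magnitude
            )
        assert all(a < b for a, b in zip(forces, forces[1:]))


def _summary(stress, t, label="c1", area=150.0):
    return CellTractionSummary(
        label=label,
        mean_stress=stress,
        peak_stress=stress,
        total_force_magnitude=stress * area * PA_UM2_TO_NN,
        net_force_vector=(0.0, 0.0),
        contact_area=area,
        timestamp=t,
    )


class TestTimeSeries:
    def test_constant_trace(self):
        out = summarize_time_series([_summary(30.0, t) for t in (0, 10, 20)])
        assert out["mean"] == pytest.approx(30.0)
        assert out["sem"] == 0.0
        assert out["classification"] == "quiescent-like"

    def test_alternating_growth_trace(self):
        # the alternating high/low stress phases of a growing neuron
        vals = [28.0, 70.0, 28.0, 70.0, 28.0, 70.0]
        out = summarize_time_series(
            [_summary(v, 10 * i) for i, v in enumerate(vals)]
        )
        assert out["min"] == 28.0 and out["max"] == 70.0
        assert out["classification"] == "growing-like"

    def test_single_point_degenerate(self):
        out = summarize_time_series([_summary(42.0, 0.0)])
        assert out["mean"] == 42.0
        assert out["sem"] == 0.0
        assert out["sem_defined"] is False

    def test_unsorted_timestamps_rejected(self):
        with pytest.raises(ValueError):
            summarize_time_series([_summary(30.0, 10.0), _summary(30.0, 0.0)])


def _uniform_map(kpa, n=8):
    return ElasticityMap(
        moduli=np.full((n, n), kpa),
        grid_spacing=1.0,
        qc_mask=np.ones((n, n), bool),
    )


class TestStressModulusJoin:
    def test_single_cell_join(self):
        df = pair_stress_modulus([_summary(50.0, 0.0)], {"c1": _uniform_map(1.0)})
        assert len(df) == 1
        row = df.iloc[0]
        assert row.mean_stress_Pa == 50.0
        assert row.mean_modulus_kPa == pytest.approx(1.0)

    def test_unmatched_label_named_in_error(self):
        with pytest.raises(KeyError, match="c1"):
            pair_stress_modulus([_summary(50.0, 0.0)], {})

    def test_empty_inputs_empty_table(self):
        df = pair_stress_modulus([], {})
        assert df.empty

    def test_planted_modulus_stress_coupling_recovered(self):
        # cohort with modulus = base + slope * stress: the joined table
        # must reproduce the planted monotone trend
        from scipy.stats import spearmanr

        from neuromech import build_elasticity_map, simulate_force_volume

        rng = np.random.default_rng(3)
        stresses = rng.uniform(20, 70, size=10)
        summaries, maps = [], {}
        for i, s in enumerate(stresses):
            label = f"c{i}"
            summaries.append(_summary(float(s), 0.0, label=label))
            E_pa = (0.4 + 0.027 * s) * 1000.0
            volume = simulate_force_volume(
                np.full((4, 4), E_pa), noise_frac=0.02, seed=i
            )
            maps[label] = build_elasticity_map(volume)
        df = pair_stress_modulus(summaries, maps)
        rho = spearmanr(df.mean_stress_Pa, df.mean_modulus_kPa).statistic
        assert rho > 0.9

    def test_force_area_table_columns(self):
        df = force_area_table([_summary(50.0, 0.0)])
        assert list(df.columns) == [
            "cell",
            "contact_area_um2",
            "force_nN",
            "mean_stress_Pa",
        ]
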