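import numpy as np
import pytest

from cestkit.axis import build_offset_axis, default_wassr_axis
from cestkit.pools import PoolSpec
from cestkit.synthetic import (PhantomConfig, PhantomConfigError,
                               default_demo_config, default_region_layout,
                               simulate_contrast_table, simulate_phantom,
                               simulate_wassr, simulate_zspectrum)

from conftest import tiny_config, truth_pools


class TestSimulateZspectrum:
    def test_single_pool_center_value(self, axis):
        pool = PoolSpec("glutamate", 3.0, 0.2, 1.0)
        z = simulate_zspectrum([pool], axis)
        assert z.values[np.where(axis == 3.0)[0][0]] == pytest.approx(0.8)

    def test_no_pools_all_ones(self, axis):
        assert np.allclose(simulate_zspectrum([], axis).values, 1.0)

    def test_amplitude_sum_validated(self, axis):
        pools = [PoolSpec("a", 0.0, 0.6, 1.0), PoolSpec("b", 2.0, 0.5, 1.0)]
        with pytest.raises(PhantomConfigError, match="invalid pool system"):
            simulate_zspectrum(pools, axis)

    def test_noiseless_range(self, axis):
        pools = truth_pools(a={"water": 0.6, "mt": 0.08, "creatine": 0.04,
                               "glutamate": 0.05, "noe": 0.06})
        z = simulate_zspectrum(pools, axis).values
        assert np.all(z <= 1.0) and np.all(z >= 1.0 - 0.83)

    def test_minimum_at_water_center(self):
        dense = build_offset_axis([(-5, 5, 0.01)])
        pools = truth_pools(a={"water": 0.6, "mt": 0.08, "creatine": 0.04,
                               "glutamate": 0.05, "noe": 0.06})
        z = simulate_zspectrum(pools, dense).values
        assert abs(dense[np.argmin(z)]) < 0.05

    def test_seeded_reproducibility(self, axis):
        pools = [PoolSpec("glutamate", 3.0, 0.2, 1.0)]
        z1 = simulate_zspectrum(pools, axis, noise_sigma=0.01, seed=42)
        z2 = simulate_zspectrum(pools, axis, noise_sigma=0.01, seed=42)
        assert np.array_equal(z1.values, z2.values)


class TestSimulateWassr:
    def test_minimum_at_b0(self):
        dense = build_offset_axis([(-1, 1, 0.001)])
        z = simulate_wassr(0.3, dense)
        assert dense[np.argmin(z.values)] == pytest.approx(0.3, abs=1e-3)

    def test_symmetric_about_zero(self):
        ax = default_wassr_axis()
        z = simulate_wassr(0.0, ax).values
        assert np.allclose(z, z[::-1], atol=1e-14)

    def test_noisy_b0_roundtrip(self):
        from cestkit.b0 import estimate_b0
        ax = default_wassr_axis()
        z = simulate_wassr(-0.4, ax, noise_sigma=0.01, seed=3)
        z2 = simulate_wassr(-0.4, ax, noise_sigma=0.01, seed=3)
        assert np.array_equal(z.values, z2.values)
        assert estimate_b0(z, ax) == pytest.approx(-0.4, abs=0.02)


class TestPhantomConfig:
    def test_default_demo_validates(self):
        default_demo_config().validate()

    def test_region_overlap_rejected(self):
        cfg = tiny_config()
        name0, name1 = list(cfg.region_layout)[:2]
        cfg.region_layout[name1] = cfg.region_layout[name0]
        with pytest.raises(PhantomConfigError, match="overlap"):
            cfg.validate()

    def test_region_outside_grid_rejected(self):
        cfg = tiny_config()
        cfg.region_layout["cortex"] = [(99, 99)]
        with pytest.raises(PhantomConfigError, match="outside grid"):
            cfg.validate()

    def test_b0_field_within_bound(self):
        cfg = tiny_config()
        assert np.max(np.abs(cfg._b0_field())) <= cfg.b0_bound


class TestSimulatePhantom:
    def test_zero_noise_flat_b0_region_uniform(self):
        cfg = tiny_config(noise=0.0)
        cfg.subject_cv = 0.0
        cfg.b0_coeffs = (0.0,) * 6
        ds = simulate_phantom(cfg)
        vox = cfg.region_layout["cortex"]
        spectra = np.stack([ds.z[0, i, j] for (i, j) in vox])
        assert np.ptp(spectra, axis=0).max() == 0.0

    def test_truth_amplitude_ratio_by_construction(self):
        cfg = tiny_config(noise=0.0)
        cfg.subject_cv = 0.0
        for region in cfg.region_layout:
            base = cfg.pool_truth[("baseline", region, "glutamate")]
            cfg.pool_truth[("wk12_vehicle", region, "glutamate")] = (
                base * (0.85 if region == "cortex" else 1.0))
            for pool in ("creatine", "noe"):
                cfg.pool_truth[("wk12_vehicle", region, pool)] = (
                    cfg.pool_truth[("baseline", region, pool)])
        ds = simulate_phantom(cfg)
        t = ds.truth.region_amplitudes
        g = t[t["pool"] == "glutamate"].groupby(["arm", "region"])["amplitude"].mean()
        for region in cfg.region_layout:
            ratio = g["wk12_vehicle", region] / g["baseline", region]
            assert ratio == pytest.approx(0.85 if region == "cortex" else 1.0)

    def test_bit_identical_under_same_seed(self):
        d1 = simulate_phantom(tiny_config(seed=5))
        d2 = simulate_phantom(tiny_config(seed=5))
        assert np.array_equal(d1.z, d2.z)
        assert np.array_equal(d1.wassr, d2.wassr)
        assert d1.subjects.equals(d2.subjects)

    def test_wassr_shares_b0_field(self):
        cfg = tiny_config(noise=0.0)
        ds = simulate_phantom(cfg)
        i, j = cfg.region_layout["thalamus"][0]
        ax = ds.wassr_axis
        assert ax[np.argmin(ds.wassr[0, i, j])] == pytest.approx(
            ds.truth.b0[i, j], abs=0.05)


def test_contrast_table_structure_and_determinism():
    cfg = tiny_config()
    t1 = simulate_contrast_table(cfg, seed=9)
    t2 = simulate_contrast_table(cfg, seed=9)
    assert t1.equals(t2)
    assert set(t1.columns) == {"subject", "arm", "region", "pool", "contrast"}
    n_sub = sum(cfg.n_subjects_per_arm.values())
    assert len(t1) == n_sub * len(cfg.region_layout) * 3
    assert (t1["contrast"] >= 0).all()
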