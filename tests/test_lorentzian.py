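import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cestkit.lorentzfit import (FitConfig, FitError, ZSpectrum, fit_stack,
                                fit_zspectrum, lorentzian, model_pools)
from cestkit.pools import PoolSpec, default_pools

from conftest import TRUTH_A, TRUTH_G, truth_pools


class TestLorentzianForm:
    def test_center_value(self):
        assert lorentzian(2.0, 0.3, 2.0, 1.0) == pytest.approx(0.3)

    def test_half_maximum_at_half_width(self):
        assert lorentzian(2.5, 0.3, 2.0, 1.0) == pytest.approx(0.15)

    def test_one_fwhm_from_center(self):
        # A * (G/2)^2 / ((G/2)^2 + 1) = 0.3 * 0.25 / 1.25
        assert lorentzian(3.0, 0.3, 2.0, 1.0) == pytest.approx(0.06)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            lorentzian(0.0, 0.3, 0.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0.001, 0.99), c=st.floats(-5, 5), g=st.floats(0.05, 10),
           x=st.floats(-20, 20))
    def test_bounded_by_amplitude(self, a, c, g, x):
        v = lorentzian(x, a, c, g)
        assert 0 < v <= a + 1e-15


class TestModel:
    def test_empty_pools_constant_one(self, axis):
        assert np.allclose(model_pools([], axis), 1.0)

    def test_superposition(self, axis):
        p1, p2 = truth_pools()[2], truth_pools()[3]
        both = model_pools([p1, p2], axis)
        assert np.allclose(both, model_pools([p1], axis) + model_pools([p2], axis) - 1.0,
                           atol=1e-15)

    def test_matches_independent_evaluation(self, axis):
        """Double implementation: straightforward loop vs the packaged model."""
        pools = truth_pools()
        expected = np.ones_like(axis)
        for p in pools:
            expected -= p.amplitude / (1.0 + ((axis - p.center) / (p.fwhm / 2.0)) ** 2)
        assert np.allclose(model_pools(pools, axis), expected, atol=1e-12)


class TestFit:
    def test_exact_recovery_noiseless(self, axis, clean_spectrum):
        res = fit_zspectrum(clean_spectrum, axis)
        assert res.converged
        assert res.rss < 1e-10
        for p in res.pools:
            assert p.amplitude == pytest.approx(TRUTH_A[p.name], abs=1e-4)
            assert p.fwhm == pytest.approx(TRUTH_G[p.name], abs=1e-4)

    def test_constant_one_all_solutes_at_zero(self, axis):
        res = fit_zspectrum(np.ones_like(axis), axis)
        for p in res.pools:
            assert p.amplitude <= 1e-5  # at the zero bound within solver tolerance

    def test_masked_points_never_influence_fit(self, axis, clean_spectrum):
        corrupted = clean_spectrum.copy()
        corrupted[40] = 10.0
        mask = np.ones_like(axis, dtype=bool)
        mask[40] = False
        res_masked = fit_zspectrum(ZSpectrum(corrupted, mask), axis)
        base_mask = np.ones_like(axis, dtype=bool)
        base_mask[40] = False  # same support, clean value
        res_clean = fit_zspectrum(ZSpectrum(clean_spectrum, base_mask), axis)
        for pm, pc in zip(res_masked.pools, res_clean.pools):
            assert pm.amplitude == pytest.approx(pc.amplitude, abs=1e-12)
            assert pm.fwhm == pytest.approx(pc.fwhm, abs=1e-12)

    def test_monotone_in_true_amplitude(self, axis):
        """Raising one pool's true amplitude raises its fitted amplitude."""
        fitted = []
        for a_glu in (0.03, 0.05, 0.08):
            a = dict(TRUTH_A, glutamate=a_glu)
            z = model_pools(truth_pools(a=a), axis)
            fitted.append(fit_zspectrum(z, axis).amplitude("glutamate"))
        assert fitted[0] < fitted[1] < fitted[2]

    def test_too_few_points_raises(self, axis, clean_spectrum):
        mask = np.zeros_like(axis, dtype=bool)
        mask[:10] = True
        with pytest.raises(FitError, match="usable points"):
            fit_zspectrum(ZSpectrum(clean_spectrum, mask), axis)

    def test_implausible_values_raise(self, axis):
        z = np.ones_like(axis)
        z[0] = 5.0
        with pytest.raises(FitError, match="plausible range"):
            fit_zspectrum(z, axis)

    def test_noisy_glutamate_recovery(self, axis, clean_spectrum):
        """Median glutamate amplitude error stays below 5% at sigma=0.005."""
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(50):
            z = clean_spectrum + rng.normal(0, 0.005, axis.size)
            errs.append(fit_zspectrum(z, axis).amplitude("glutamate")
                        - TRUTH_A["glutamate"])
        assert np.median(np.abs(errs)) / TRUTH_A["glutamate"] < 0.05

    def test_jacobian_full_column_rank_at_init(self, axis):
        """Identifiability: the default initialization is locally identifiable."""
        from cestkit.lorentzfit import _initial_pools, _model_and_jac, _pack

        cfg = FitConfig()
        z = model_pools(truth_pools(), axis)
        pools0 = _initial_pools(z, np.ones_like(axis, dtype=bool), cfg)
        x0, _, _, layout = _pack(pools0)
        _, jac = _model_and_jac(x0, axis, pools0, layout)
        assert np.linalg.matrix_rank(jac) == x0.size


class TestFitStack:
    def test_uniform_phantom_identical_fits(self, axis, clean_spectrum):
        stack = np.tile(clean_spectrum, (2, 3, 1))
        fits = fit_stack(stack, axis)
        amp = fits.amplitude["glutamate"]
        assert np.ptp(amp) < 1e-8
        assert fits.fitted.all() and fits.converged.all()

    def test_two_region_clustering(self, axis):
        lo = model_pools(truth_pools(a=dict(TRUTH_A, glutamate=0.03)), axis)
        hi = model_pools(truth_pools(), axis)
        stack = np.stack([np.tile(lo, (2, 1)), np.tile(hi, (2, 1))])
        fits = fit_stack(stack, axis)
        amp = fits.amplitude["glutamate"]
        assert np.all(amp[0] < 0.04) and np.all(amp[1] > 0.04)

    def test_mask_contract(self, axis, clean_spectrum):
        stack = np.tile(clean_spectrum, (2, 2, 1))
        mask = np.array([[True, False], [False, False]])
        fits = fit_stack(stack, axis, mask=mask)
        assert fits.fitted[0, 0]
        assert not fits.fitted[0, 1] and np.isnan(fits.amplitude["water"][0, 1])

    def test_all_masked_raises(self, axis, clean_spectrum):
        stack = np.tile(clean_spectrum, (2, 2, 1))
        with pytest.raises(FitError):
            fit_stack(stack, axis, mask=np.zeros((2, 2), dtype=bool))
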