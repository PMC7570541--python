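"""Masking, baseline subtraction, RLMSC and Savitzky-Golay filtering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import savgol_filter

import lactospec as ls
from lactospec.errors import DegenerateSampleError, ValidationError
from lactospec.preprocess import robust_affine_fit


def _make_set(axis, samples, concentrations, region="nir"):
    return ls.SpectraSet(axis=axis, samples=samples,
                         concentrations=concentrations, region=region)


@pytest.fixture()
def water_like_reference():
    """A smooth water-like NIR trace used as the RLMSC reference."""
    axis = np.arange(800.0, 2601.0)
    lib = ls.build_band_library("nir")
    ref = sum(b.evaluate(axis) for b in lib.water_bands)
    return axis, ref


class TestMasking:
    def test_empty_region_list_is_identity(self, nir_set_default):
        out = ls.mask_noise_regions(nir_set_default, [])
        np.testing.assert_array_equal(out.samples, nir_set_default.samples)

    def test_nir_default_masks_leave_1489_channels(self, nir_set_default):
        out = ls.mask_noise_regions(
            nir_set_default, [(1900, 1960), (2350, 2600)]
        )
        # 1801 - 61 - 251, closed intervals on the 1 nm grid
        assert out.n_channels == 1489

    def test_mir_mask_boundary_inclusive(self):
        plan = ls.build_sample_plan("hc6")
        spectra = ls.generate_spectra(
            plan, ls.build_band_library("mir"),
            ls.default_instrument("mir", seed=2),
        )
        out = ls.mask_noise_regions(spectra, [(500, 700)])
        assert out.axis[0] == 701.0

    def test_masking_everything_rejected(self, toy_set):
        with pytest.raises(ValidationError):
            ls.mask_noise_regions(toy_set, [(0.0, 1e6)])


class TestBaselineSubtract:
    def test_identical_samples_become_zero(self):
        axis = np.arange(10.0)
        row = np.sin(axis)
        spectra = _make_set(axis, np.tile(row, (4, 1)), [0.0, 1.0, 2.0, 3.0])
        out = ls.baseline_subtract(spectra)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-15)
        np.testing.assert_array_equal(
            out.concentrations, spectra.concentrations
        )

    def test_missing_zero_sample_rejected(self):
        axis = np.arange(5.0)
        spectra = _make_set(axis, np.ones((2, 5)), [1.0, 2.0])
        with pytest.raises(ValidationError):
            ls.baseline_subtract(spectra)

    def test_mean_of_several_zero_samples_used(self):
        axis = np.arange(6.0)
        base = np.cos(axis)
        eps = 0.01 * np.sin(3 * axis)
        samples = np.stack([base + eps, base - eps, base + 1.0])
        spectra = _make_set(axis, samples, [0.0, 0.0, 4.0])
        out = ls.baseline_subtract(spectra)
        # the two zero-level replicates land antisymmetrically about zero
        np.testing.assert_allclose(out.samples[0], eps, atol=1e-15)
        np.testing.assert_allclose(out.samples[0], -out.samples[1],
                                   atol=1e-15)
        np.testing.assert_allclose(out.samples[2], 1.0, atol=1e-15)

    def test_difference_spectrum_polarity(self, nir_set_noiseless):
        # after subtracting the pure-matrix spectrum, water bands go
        # negative (displacement) and lactate bands positive
        out = ls.baseline_subtract(nir_set_noiseless)
        top = out.samples[np.argmax(out.concentrations)]
        axis = out.axis
        assert top[np.argmin(np.abs(axis - 1450))] < 0
        assert top[np.argmin(np.abs(axis - 2259))] > 0

    def test_commutes_with_masking(self, nir_set_default):
        regions = [(1900, 1960), (2350, 2600)]
        a = ls.baseline_subtract(ls.mask_noise_regions(nir_set_default, regions))
        b = ls.mask_noise_regions(ls.baseline_subtract(nir_set_default), regions)
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-14)


class TestRlmsc:
    def test_sample_equal_to_reference_unchanged(self, water_like_reference):
        axis, ref = water_like_reference
        spectra = _make_set(axis, np.tile(ref, (2, 1)), [0.0, 1.0])
        out = ls.rlmsc(spectra, reference=ref)
        np.testing.assert_allclose(
            out.samples, np.tile(ref, (2, 1)), atol=1e-12
        )

    def test_exact_affine_transform_recovered(self, water_like_reference):
        axis, ref = water_like_reference
        spectra = _make_set(axis, (2.0 * ref + 0.1)[None, :], [1.0])
        out = ls.rlmsc(spectra, reference=ref)
        np.testing.assert_allclose(out.samples[0], ref, atol=1e-9)
        # closed-form OLS oracle agrees when there are no outliers
        a_ols, b_ols = np.polyfit(ref, spectra.samples[0], 1)
        assert (a_ols, b_ols) == pytest.approx((2.0, 0.1), abs=1e-9)

    def test_contaminated_fit_beats_ols(self, water_like_reference):
        axis, ref = water_like_reference
        rng = np.random.default_rng(42)
        x = 2.0 * ref + 0.1
        outliers = rng.choice(x.size, size=x.size // 20, replace=False)
        x = x.copy()
        x[outliers] += 10.0
        a, b = robust_affine_fit(x, ref)
        assert abs(a - 2.0) / 2.0 < 0.01
        assert abs(b - 0.1) / 0.1 < 0.01
        a_ols, b_ols = np.polyfit(ref, x, 1)
        assert max(abs(a_ols - 2.0) / 2.0, abs(b_ols - 0.1) / 0.1) > 0.05

    def test_degenerate_sample_rejected(self, water_like_reference):
        axis, ref = water_like_reference
        rng = np.random.default_rng(0)
        flat = 1e-15 * rng.normal(size=ref.size)
        spectra = _make_set(axis, flat[None, :], [0.0])
        with pytest.raises(DegenerateSampleError):
            ls.rlmsc(spectra, reference=ref)

    @given(seed=st.integers(0, 50))
    def test_idempotent_for_fixed_reference(self, seed):
        rng = np.random.default_rng(seed)
        axis = np.arange(200.0)
        ref = np.exp(-((axis - 100) / 30) ** 2)
        gain = 1.0 + 0.5 * rng.uniform()
        x = gain * ref + 0.2 * rng.uniform() + 0.01 * rng.normal(size=200)
        spectra = _make_set(axis, x[None, :], [1.0])
        once = ls.rlmsc(spectra, reference=ref)
        a, b = robust_affine_fit(once.samples[0], ref)
        assert a == pytest.approx(1.0, abs=1e-6)
        assert b == pytest.approx(0.0, abs=1e-6)


class TestSgCoefficients:
    def test_quadratic_smoothing_weights(self):
        # explicit normal-equations result for window 5, order 2
        w = ls.sg_coefficients(5, 2, 0, 1.0)
        np.testing.assert_allclose(
            w, np.array([-3, 12, 17, 12, -3]) / 35, atol=1e-12
        )

    @pytest.mark.parametrize("window,polyorder", [(5, 2), (21, 2), (31, 3)])
    def test_moment_identities(self, window, polyorder):
        w0 = ls.sg_coefficients(window, polyorder, 0, 1.0)
        assert w0.sum() == pytest.approx(1.0, abs=1e-12)
        w1 = ls.sg_coefficients(window, polyorder, 1, 1.0)
        assert w1.sum() == pytest.approx(0.0, abs=1e-12)

    def test_derivative_of_quadratic_exact(self):
        x = 0.5 * np.arange(100.0)
        y = x**2
        w = ls.sg_coefficients(21, 2, 1, 0.5)
        h = 10
        for i in range(h, 100 - h):
            val = w @ y[i - h : i + h + 1]
            assert val == pytest.approx(2 * x[i], abs=1e-9)

    def test_matches_independent_library_coefficients(self):
        from scipy.signal import savgol_coeffs

        for window, polyorder, deriv in [(21, 2, 1), (51, 2, 1), (31, 2, 0)]:
            mine = ls.sg_coefficients(window, polyorder, deriv, 1.0)
            # scipy returns weights for convolution (reversed order)
            ref = savgol_coeffs(window, polyorder, deriv=deriv, delta=1.0)[::-1]
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            ls.sg_coefficients(4, 2, 0)
        with pytest.raises(ValidationError):
            ls.sg_coefficients(3, 3, 0)
        with pytest.raises(ValidationError):
            ls.sg_coefficients(5, 2, 3)


class TestApplySavgol:
    def _config(self, window=5, polyorder=2, deriv=1):
        return ls.PreprocessConfig(
            region="nir", sg_window=window, sg_polyorder=polyorder,
            sg_deriv=deriv,
        )

    def test_constant_unchanged_by_smoothing(self):
        axis = np.arange(30.0)
        spectra = _make_set(axis, np.full((2, 30), 3.7), [0.0, 1.0])
        out = ls.apply_savgol(spectra, self._config(deriv=0))
        np.testing.assert_allclose(out.samples, 3.7, atol=1e-12)

    def test_linear_ramp_derivative_constant_including_edges(self):
        axis = np.arange(0.0, 50.0, 2.0)
        m = -0.37
        spectra = _make_set(axis, (m * axis + 5)[None, :], [1.0])
        out = ls.apply_savgol(spectra, self._config(window=7, deriv=1))
        np.testing.assert_allclose(out.samples[0], m, atol=1e-10)

    @given(coeffs=st.lists(st.floats(-2, 2), min_size=3, max_size=3))
    def test_quadratic_reproduction_everywhere(self, coeffs):
        axis = np.arange(40.0)
        y = np.polyval(coeffs, axis)
        spectra = _make_set(axis, y[None, :], [1.0])
        smoothed = ls.apply_savgol(spectra, self._config(window=9, deriv=0))
        np.testing.assert_allclose(smoothed.samples[0], y, atol=1e-7)
        deriv = ls.apply_savgol(spectra, self._config(window=9, deriv=1))
        dy = np.polyval(np.polyder(coeffs), axis)
        np.testing.assert_allclose(deriv.samples[0], dy, atol=1e-7)

    def test_agrees_with_independent_filter(self, nir_set_default):
        cfg = ls.PreprocessConfig.default("nir")
        mine = ls.apply_savgol(nir_set_default, cfg)
        ref = savgol_filter(
            nir_set_default.samples, cfg.sg_window, cfg.sg_polyorder,
            deriv=cfg.sg_deriv, delta=1.0, axis=1, mode="interp",
        )
        np.testing.assert_allclose(mine.samples, ref, atol=1e-9)

    def test_no_leakage_across_masked_gap(self, nir_set_default):
        cfg = ls.PreprocessConfig.default("nir")
        masked = ls.mask_noise_regions(nir_set_default, cfg.mask_regions)
        left = masked.axis < 1900
        out_a = ls.apply_savgol(masked, cfg)
        perturbed = masked.samples.copy()
        perturbed[:, ~left] += 5.0 * np.sin(np.arange((~left).sum()))
        out_b = ls.apply_savgol(masked.with_samples(perturbed), cfg)
        np.testing.assert_array_equal(
            out_a.samples[:, left], out_b.samples[:, left]
        )

    def test_block_shorter_than_window_rejected(self):
        axis = np.concatenate([np.arange(0.0, 60.0), np.arange(100.0, 110.0)])
        spectra = _make_set(axis, np.zeros((1, axis.size)), [1.0])
        with pytest.raises(ValidationError, match="block"):
            ls.apply_savgol(spectra, self._config(window=21))


class TestPipeline:
    def test_all_flags_off_is_identity(self, nir_set_default):
        cfg = ls.PreprocessConfig(
            region="nir", mask_regions=[], do_baseline_subtract=False,
            do_rlmsc=False, do_savgol=False, sg_window=51,
        )
        result = ls.preprocess_pipeline(nir_set_default, cfg)
        assert result.log == []
        np.testing.assert_array_equal(
            result.spectra.samples, nir_set_default.samples
        )

    def test_default_nir_dimensions(self, nir_set_default):
        result = ls.preprocess_pipeline(
            nir_set_default, ls.PreprocessConfig.default("nir")
        )
        assert result.spectra.samples.shape == (37, 1489)

    def test_default_mir_log_lists_four_ordered_steps(self):
        spectra = ls.generate_spectra(
            ls.build_sample_plan("main37"),
            ls.build_band_library("mir"),
            ls.default_instrument("mir", seed=3),
        )
        result = ls.preprocess_pipeline(
            spectra, ls.PreprocessConfig.default("mir")
        )
        assert len(result.log) == 4
        for line, stage in zip(
            result.log, ["mask", "baseline", "rlmsc", "savitzky"]
        ):
            assert stage in line

    def test_region_mismatch_rejected(self, nir_set_default):
        with pytest.raises(ValidationError):
            ls.preprocess_pipeline(
                nir_set_default, ls.PreprocessConfig.default("mir")
            )

    def test_concentrations_never_altered(self, nir_set_default):
        result = ls.preprocess_pipeline(
            nir_set_default, ls.PreprocessConfig.calibration_default("nir")
        )
        np.testing.assert_array_equal(
            result.spectra.concentrations, nir_set_default.concentrations
        )

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = ls.PreprocessConfig.default("nir")
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert ls.PreprocessConfig.from_yaml(path) == cfg
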