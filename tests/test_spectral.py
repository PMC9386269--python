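"""PC1 reduction, Welch PSD normalisation and band metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorkit import (
    average_spectra,
    band_metrics,
    pca_first_component,
    power_spectrum,
)
from tremorkit.errors import ConfigurationError, DataError

FS = 100.0


def _oracle_pca(xyz):
    """Brute-force covariance eigendecomposition (independent of the SVD path)."""
    c = xyz - xyz.mean(axis=0)
    cov = (c.T @ c) / (c.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


class TestPCA:
    def test_rank_one_signal_recovers_axis(self):
        t = np.arange(1000) / FS
        xyz = np.column_stack([np.sin(2 * np.pi * 5 * t), np.zeros(1000), np.zeros(1000)])
        res = pca_first_component(xyz)
        np.testing.assert_allclose(res.loading, [1, 0, 0], atol=1e-12)
        assert res.variance_fraction == pytest.approx(1.0)

    def test_isotropic_noise_gives_one_third_variance(self, rng):
        res = pca_first_component(rng.normal(size=(10_000, 3)))
        assert res.variance_fraction == pytest.approx(1 / 3, abs=0.05)

    def test_oblique_tremor_axis_recovered(self, rng):
        t = np.arange(2000) / FS
        axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        xyz = np.outer(np.sin(2 * np.pi * 5 * t), axis) + rng.normal(0, 0.02, (2000, 3))
        res = pca_first_component(xyz)
        assert abs(res.loading @ axis) > 0.99

    def test_matches_bruteforce_eigendecomposition(self, rng):
        for _ in range(20):
            xyz = rng.normal(size=(200, 3)) @ rng.normal(size=(3, 3))
            res = pca_first_component(xyz)
            vals, vecs = _oracle_pca(xyz)
            np.testing.assert_allclose(res.eigenvalues, vals, rtol=1e-9)
            assert abs(res.loading @ vecs[:, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sum_to_one(self, rng):
        res = pca_first_component(rng.normal(size=(500, 3)))
        fracs = res.eigenvalues / res.eigenvalues.sum()
        assert fracs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_rotation_leaves_pc1_spectrum_invariant(self, rng):
        t = np.arange(2800) / FS
        axis = np.array([0.6, 0.0, 0.8])
        xyz = np.outer(np.sin(2 * np.pi * 5 * t), axis) + rng.normal(0, 0.05, (2800, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        m1 = band_metrics(power_spectrum(pca_first_component(xyz).component_series, FS))
        m2 = band_metrics(power_spectrum(pca_first_component(xyz @ rot.T).component_series, FS))
        assert m2.total_power == pytest.approx(m1.total_power, rel=1e-6)
        assert m2.peak_frequency_hz == m1.peak_frequency_hz

    def test_deterministic_sign_convention(self):
        t = np.arange(1000) / FS
        xyz = np.outer(np.sin(2 * np.pi * 5 * t), [-1.0, 0.0, 0.0])
        res = pca_first_component(xyz)
        assert res.loading[0] > 0

    def test_all_zero_epoch_rejected(self):
        with pytest.raises(DataError):
            pca_first_component(np.zeros((100, 3)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_property_eigenpairs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xyz = rng.normal(size=(50, 3)) * rng.uniform(0.1, 3.0, size=3)
        res = pca_first_component(xyz)
        vals, vecs = _oracle_pca(xyz)
        np.testing.assert_allclose(res.eigenvalues, vals, rtol=1e-9, atol=1e-12)
        assert abs(res.loading @ vecs[:, 0]) == pytest.approx(1.0, abs=1e-9)


class TestPowerSpectrum:
    def test_zero_signal_zero_psd(self):
        spec = power_spectrum(np.zeros(2800), FS)
        assert np.all(spec.psd == 0)
        assert spec.delta_f == pytest.approx(0.1)

    def test_parseval_for_sinusoid(self):
        t = np.arange(2800) / FS
        x = 2.0 * np.sin(2 * np.pi * 5 * t)
        spec = power_spectrum(x, FS)
        total = np.trapezoid(spec.psd, spec.frequencies)
        assert total == pytest.approx(2.0, rel=0.03)  # A^2/2

    def test_parseval_for_white_noise(self, rng):
        x = rng.normal(0, 1.0, size=6000)
        spec = power_spectrum(x, FS)
        assert 0.9 <= np.trapezoid(spec.psd, spec.frequencies) <= 1.1

    def test_too_short_epoch_names_both_lengths(self):
        with pytest.raises(DataError, match="500 samples.*1000-sample"):
            power_spectrum(np.zeros(500), FS, segment_s=10.0)

    def test_segment_length_sets_resolution(self):
        spec = power_spectrum(np.zeros(4000), FS, segment_s=5.0)
        assert spec.delta_f == pytest.approx(0.2)
        assert spec.estimator_meta.n_segments == 1 + (4000 - 500) // 250


class TestBandMetrics:
    def _spec_for(self, x):
        return power_spectrum(x, FS)

    def test_sinusoid_peak_and_total(self):
        t = np.arange(2800) / FS
        spec = self._spec_for(2.0 * np.sin(2 * np.pi * 5 * t))
        m = band_metrics(spec)
        assert m.peak_frequency_hz == pytest.approx(5.0, abs=spec.delta_f)
        assert m.total_power == pytest.approx(2.0, rel=0.03)
        assert m.peak_power == spec.psd[np.argmin(np.abs(spec.frequencies - m.peak_frequency_hz))]

    def test_flat_spectrum_ties_break_to_band_low(self):
        spec = self._spec_for(np.zeros(2800))
        assert band_metrics(spec).peak_frequency_hz == pytest.approx(1.0)

    def test_larger_component_wins_peak(self):
        t = np.arange(2800) / FS
        x = 1.0 * np.sin(2 * np.pi * 4 * t) + 2.0 * np.sin(2 * np.pi * 8 * t)
        assert band_metrics(self._spec_for(x)).peak_frequency_hz == pytest.approx(8.0, abs=0.1)

    def test_sub_band_component_cannot_be_the_peak(self):
        t = np.arange(2800) / FS
        x = 5.0 * np.sin(2 * np.pi * 0.5 * t) + 0.5 * np.sin(2 * np.pi * 5 * t)
        m = band_metrics(self._spec_for(x))
        assert m.peak_frequency_hz == pytest.approx(5.0, abs=0.2)

    def test_band_outside_grid_rejected(self):
        spec = self._spec_for(np.zeros(2800))
        with pytest.raises(ConfigurationError):
            band_metrics(spec, band=(1.0, 80.0))

    @pytest.mark.parametrize("f0", [3.0, 5.0, 8.0, 12.0])
    def test_peak_recovery_at_high_snr(self, f0, rng):
        t = np.arange(2800) / FS
        x = 1.0 * np.sin(2 * np.pi * f0 * t) + rng.normal(0, 0.1, 2800)
        spec = self._spec_for(x)
        m = band_metrics(spec)
        assert abs(m.peak_frequency_hz - f0) <= spec.delta_f


class TestAverageSpectra:
    def test_mean_of_identical_spectra_is_identity(self):
        spec = power_spectrum(np.sin(np.arange(2800) * 0.3), FS)
        out = average_spectra([spec, spec, spec])
        np.testing.assert_allclose(out.psd, spec.psd, rtol=1e-15)

    def test_pointwise_arithmetic_mean(self):
        import dataclasses

        spec = power_spectrum(np.zeros(2800), FS)
        a = dataclasses.replace(spec, psd=np.ones_like(spec.psd))
        b = dataclasses.replace(spec, psd=3 * np.ones_like(spec.psd))
        np.testing.assert_allclose(average_spectra([a, b]).psd, 2.0)

    def test_mismatched_grids_rejected(self):
        a = power_spectrum(np.zeros(2800), FS, segment_s=10.0)
        b = power_spectrum(np.zeros(2800), FS, segment_s=5.0)
        with pytest.raises(ConfigurationError, match="grid"):
            average_spectra([a, b])
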