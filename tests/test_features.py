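"""Spectral energies, differential entropy, descriptors and the 59-feature set."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emoeeg.bands import MAIN_BANDS, SUB_BANDS, TOTAL_BAND, get_band
from emoeeg.features import (
    DegenerateBandError,
    EntropyParams,
    FeatureMatrix,
    FeatureNormalizer,
    band_energy,
    band_energy_ratio,
    build_feature_matrix,
    differential_entropy,
    extract_baseline_features,
    fractal_dimension,
    hjorth_parameters,
    instability_index,
    normalize_features,
    spectral_descriptors,
    time_domain_stats,
)

FS = 250.0
N = 250


def _sine(f, n=N, fs=FS, phase=0.0, amp=1.0):
    return amp * np.sin(2 * np.pi * f * np.arange(n) / fs + phase)


class TestBandEnergy:
    def test_parseval_identity_full_spectrum(self, rng):
        for x in (rng.standard_normal(N), _sine(10) + rng.standard_normal(N)):
            time_domain = float((x**2).sum())
            assert abs(band_energy(x, None, FS) - time_domain) <= 1e-9 * time_domain

    def test_single_tone_concentrates_in_alpha(self):
        x = _sine(10)
        total = band_energy(x, None, FS)
        assert band_energy(x, get_band("alpha"), FS) / total > 1 - 1e-6
        for name in ("delta", "theta", "beta", "gamma"):
            assert band_energy(x, get_band(name), FS) / total < 1e-6

    def test_white_noise_energy_proportional_to_bandwidth(self, rng):
        # 200-epoch mean; flat spectrum spreads energy evenly over frequency
        est = {name: 0.0 for name in ("theta", "alpha", "gamma")}
        for _ in range(200):
            x = rng.standard_normal(N)
            for name in est:
                est[name] += band_energy(x, get_band(name), FS)
        widths = {name: get_band(name).f_hi - get_band(name).f_lo for name in est}
        densities = [est[name] / widths[name] for name in est]
        assert max(densities) / min(densities) < 1.1

    def test_subband_energies_add_to_parent(self, rng):
        x = rng.standard_normal(N)
        for parent, lo, hi in (
            ("delta", "low_delta", "high_delta"),
            ("alpha", "low_alpha", "high_alpha"),
            ("beta", "low_beta", "high_beta"),
            ("gamma", "low_gamma", "high_gamma"),
        ):
            p = band_energy(x, get_band(parent), FS)
            s = band_energy(x, get_band(lo), FS) + band_energy(x, get_band(hi), FS)
            assert abs(p - s) / p < 1e-6

    def test_empty_band_rejected(self):
        from emoeeg.bands import BandDefinition

        narrow = BandDefinition("sliver", 10.05, 10.95)
        with pytest.raises(DegenerateBandError):
            band_energy(np.ones(10), narrow, 10.0)


class TestBandRatios:
    def test_pure_tone_ratio(self):
        assert band_energy_ratio(_sine(10), get_band("alpha"), FS) >= 0.99

    def test_five_equal_tones_split_evenly(self):
        x = sum(_sine(f) for f in (2.0, 6.0, 10.0, 20.0, 37.0))
        for band in MAIN_BANDS:
            assert abs(band_energy_ratio(x, band, FS) - 0.2) < 0.01

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_main_band_ratios_sum_to_one(self, seed):
        x = np.random.default_rng(seed).standard_normal(N)
        total = sum(band_energy_ratio(x, b, FS) for b in MAIN_BANDS)
        assert abs(total - 1.0) <= 1e-9


class TestDifferentialEntropy:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.floats(min_value=0.01, max_value=100.0),
        st.integers(min_value=0, max_value=10_000),
    )
    def test_scale_equivariance(self, a, seed):
        x = np.random.default_rng(seed).standard_normal(N)
        band = get_band("alpha")
        h0 = differential_entropy(x, band, FS)
        h1 = differential_entropy(a * x, band, FS)
        assert abs(h1 - (h0 + np.log(a))) < 1e-9

    def test_gaussian_closed_form(self, rng):
        """On band-limited Gaussian noise, 0.5*log(P_i) equals
        0.5*log(2*pi*e*sigma^2) - 0.5*log(2*pi*e/N) up to leakage (<0.05)."""
        band = get_band("alpha")
        freqs = np.fft.rfftfreq(N, d=1.0 / FS)
        keep = (freqs >= band.f_lo) & (freqs < band.f_hi)
        diffs = []
        for _ in range(100):
            spec = np.fft.rfft(rng.standard_normal(N))
            x = np.fft.irfft(np.where(keep, spec, 0.0), n=N)
            h_spec = differential_entropy(x, band, FS)
            sigma2 = x.var()
            h_gauss = 0.5 * np.log(2 * np.pi * np.e * sigma2) - 0.5 * np.log(
                2 * np.pi * np.e / N
            )
            diffs.append(h_spec - h_gauss)
        assert abs(np.mean(diffs)) < 0.05

    def test_class_difference_matches_half_log_effect(self):
        """A gamma-variance ratio of 4 between classes shifts the mean gamma
        DE by 0.5*log(4) ~ 0.693."""
        from emoeeg.preprocessing import segment_epochs
        from emoeeg.synthetic import SubjectProfile, synthesize_subject_recording

        prof = SubjectProfile(
            effect_channels=frozenset({"Fp1"}),
            effect_bands=frozenset({"gamma"}),
            effect_size=4.0,
            pink_power=1.0,
        )
        band = get_band("gamma")

        def mean_de(label, seed):
            rec = synthesize_subject_recording(
                prof, label, 150.0, FS, seed, channels=["Fp1", "Cz"]
            )
            return np.mean(
                [
                    differential_entropy(ep.data[0], band, FS)
                    for ep in segment_epochs(rec, 1.0)
                ]
            )

        diff = mean_de("positive", 41) - mean_de("negative", 42)
        assert abs(diff - 0.5 * np.log(4)) < 0.05

    def test_zero_energy_band_rejected(self):
        with pytest.raises(DegenerateBandError):
            differential_entropy(np.zeros(N), get_band("alpha"), FS)


class TestHjorth:
    def test_sine_mobility_matches_analytic_value(self):
        for f in (5.0, 10.0, 20.0):
            mob, _ = hjorth_parameters(_sine(f, n=2500))
            assert abs(mob - 2 * np.sin(np.pi * f / FS)) < 1e-3

    def test_single_tone_complexity_near_one(self):
        _, comp = hjorth_parameters(_sine(10, n=2500))
        assert abs(comp - 1.0) < 0.01

    def test_amplitude_scale_invariance(self, rng):
        x = rng.standard_normal(500)
        assert np.allclose(hjorth_parameters(x), hjorth_parameters(7.5 * x))

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            hjorth_parameters(np.full(100, 3.0))


class TestTimeDomainStats:
    def test_constant_signal(self):
        s = time_domain_stats(np.full(100, 5.0))
        assert s["mean"] == 5.0
        assert s["std"] == 0.0
        assert s["zero_crossings"] == 0.0
        assert s["amplitude"] == 0.0

    def test_sine_crossings_and_symmetry(self):
        k = 5
        x = _sine(k, n=1000, fs=1000.0, phase=0.1)  # k whole periods
        s = time_domain_stats(x)
        assert s["zero_crossings"] == 2 * k
        assert abs(s["skewness"]) < 0.01

    def test_normal_noise_excess_kurtosis_near_zero(self, rng):
        s = time_domain_stats(rng.standard_normal(10_000))
        assert abs(s["kurtosis"]) < 0.2


class TestSpectralDescriptors:
    def test_pure_tone_centroid(self):
        c, v = spectral_descriptors(_sine(10, n=2500), TOTAL_BAND, FS)
        assert abs(c - 10.0) < 0.5
        assert v < 0.5

    def test_two_tone_point_mass_formula(self):
        x = _sine(8, n=2500) + _sine(12, n=2500)
        c, v = spectral_descriptors(x, TOTAL_BAND, FS)
        assert abs(c - 10.0) < 0.5
        assert abs(v - 2.0) < 0.3

    def test_white_noise_centroid_at_band_midpoint(self, rng):
        cs = [
            spectral_descriptors(rng.standard_normal(2500), TOTAL_BAND, FS)[0]
            for _ in range(20)
        ]
        assert abs(np.mean(cs) - (0.5 + 45.0) / 2) < 1.0


class TestInstabilityIndex:
    def test_stationary_noise_is_low(self, rng):
        vals = [instability_index(rng.standard_normal(1000)) for _ in range(20)]
        assert max(vals) < 0.5

    def test_variance_step_exceeds_stationary_null(self, rng):
        null = [instability_index(rng.standard_normal(1000)) for _ in range(200)]
        q99 = np.quantile(null, 0.99)
        x = rng.standard_normal(1000)
        x[500:] *= np.sqrt(10)
        assert instability_index(x) > q99

    def test_amplitude_scale_invariance(self, rng):
        x = rng.standard_normal(1000)
        assert abs(instability_index(x) - instability_index(3 * x)) < 1e-9


class TestBaselineFeatureVector:
    def test_59_unique_stable_names(self, clean_epochs):
        ep = clean_epochs[0]
        f1 = extract_baseline_features(ep.data[0], ep.fs)
        f2 = extract_baseline_features(ep.data[0], ep.fs)
        assert len(f1) == 59
        assert list(f1) == list(f2)
        assert len(set(f1)) == 59

    def test_all_values_finite(self, clean_epochs):
        ep = clean_epochs[0]
        for ch in range(4):
            feats = extract_baseline_features(ep.data[ch], ep.fs)
            assert all(np.isfinite(v) for v in feats.values())

    def test_fractal_dimension_plausible_for_eeg(self, clean_epochs):
        ep = clean_epochs[0]
        assert 1.0 < fractal_dimension(ep.data[0]) < 2.0


class TestFeatureMatrix:
    def test_full_montage_baseline_is_1888_columns(self, clean_epochs):
        m = build_feature_matrix(clean_epochs[:1], "baseline")
        assert m.n_features == 59 * 32 == 1888

    def test_focused_set_widths(self, clean_epochs):
        eps = clean_epochs[:2]
        assert build_feature_matrix(eps, "ratio_de").n_features == 10 * 32
        assert build_feature_matrix(eps, "de").n_features == 5 * 32
        assert build_feature_matrix(eps, "ratio").n_features == 5 * 32
        assert build_feature_matrix(eps, "de_gamma").n_features == 32
        assert build_feature_matrix(eps, "dual20").n_features == 20

    def test_unknown_feature_set_rejected(self, clean_epochs):
        with pytest.raises(KeyError):
            build_feature_matrix(clean_epochs[:1], "wavelets")

    def test_csv_round_trip(self, clean_epochs, tmp_path):
        m = build_feature_matrix(clean_epochs[:3], "ratio_de", channels=["Fp1", "Cz"])
        path = tmp_path / "fm.csv"
        m.to_csv(path)
        back = FeatureMatrix.from_csv(path, feature_set="ratio_de")
        assert list(back.values.columns) == list(m.values.columns)
        assert np.allclose(back.values.to_numpy(), m.values.to_numpy())
        assert list(back.labels) == list(m.labels)


class TestNormalisation:
    def test_none_is_identity(self, clean_epochs):
        m = build_feature_matrix(clean_epochs[:3], "ratio", channels=["Fp1"])
        out = normalize_features(m, "none")
        assert np.array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_zscore_statistics(self, rng):
        X = rng.normal(5, 3, size=(200, 4))
        Z = FeatureNormalizer("zscore").fit(X).transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        assert np.abs(Z.std(axis=0) - 1).max() < 1e-9

    def test_minmax_idempotent(self, rng):
        X = rng.normal(size=(50, 3))
        n1 = FeatureNormalizer("minmax01").fit(X)
        Y = n1.transform(X)
        Z = FeatureNormalizer("minmax01").fit(Y).transform(Y)
        assert np.allclose(Y, Z)
        assert Y.min() >= 0.0 and Y.max() <= 1.0

    def test_zero_variance_column_warned_and_zeroed(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            norm = FeatureNormalizer("zscore").fit(X)
        Z = norm.transform(X)
        assert np.allclose(Z[:, 0], 0.0)
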