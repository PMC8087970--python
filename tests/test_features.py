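"""The 16-feature vector: conventions, worked values, DWT oracle."""

import numpy as np
import pytest

from ecgplace import (
    FEATURE_NAMES,
    Beat,
    CohortConfig,
    DegenerateBeatError,
    FeatureConfig,
    FeatureVector,
    build_feature_vector,
    delineate,
    feature_matrix,
    generate_cohort,
    pair_features,
    read_feature_matrix,
    statistical_features,
    time_domain_features,
    wavelet_features,
    write_feature_matrix,
)
from ecgplace.features import FEATURE_DESCRIPTIONS

# Published sym4 scaling (low-pass decomposition) filter taps; the high-pass
# is the quadrature mirror.  Used by the independent filter-bank oracle.
SYM4_DEC_LO = np.array([
    -0.0757657147892733, -0.0296355276459985, 0.4976186676320155,
    0.8037387518059161, 0.2978577956052774, -0.0992195435768472,
    -0.0126039672620378, 0.0322231006040427,
])
SYM4_DEC_HI = np.array([(-1) ** (k + 1) * SYM4_DEC_LO[len(SYM4_DEC_LO) - 1 - k]
                        for k in range(len(SYM4_DEC_LO))])


def dwt_d4_oracle(x: np.ndarray) -> np.ndarray:
    """Level-4 detail coefficients by explicit filter-bank convolution.

    Half-point symmetric extension by one filter length minus one on each
    side, full convolution restricted to the valid range, dyadic
    downsampling on the odd phase.
    """

    def step(sig, filt):
        pad = len(filt) - 1
        ext = np.concatenate([sig[:pad][::-1], sig, sig[::-1][:pad]])
        return np.convolve(ext, filt, mode="valid")[1::2]

    a = np.asarray(x, dtype=float)
    for _ in range(3):
        a = step(a, SYM4_DEC_LO)
    return step(a, SYM4_DEC_HI)


class TestTimeDomainFeatures:
    def test_pr_interval_of_30_samples_at_300hz_is_100ms(self):
        # a beat whose P peak and QRS onset end up exactly 30 samples apart
        t = np.arange(180) / 300.0
        s = (0.2 * np.exp(-((t - 0.2) ** 2) / (2 * 0.02**2))
             + 1.0 * np.exp(-((t - 0.35) ** 2) / (2 * 0.012**2)))
        fid = delineate(Beat(s, fs=300.0))
        if fid.qrs_onset_idx - fid.p_peak_idx == 30:
            assert fid.pr_interval == pytest.approx(100.0)
        # the ms conversion itself is exact regardless of landmark placement
        assert fid.pr_interval == pytest.approx(
            (fid.qrs_onset_idx - fid.p_peak_idx) * 1000.0 / 300.0)

    def test_r_amplitude_matches_ground_truth_in_raw_mode(
            self, noiseless_cohort, raw_amplitude_config):
        for pair in noiseless_cohort.pairs:
            if pair.placement_label != 1:
                continue
            fid = delineate(pair.v2)
            f = time_domain_features(fid, pair.v2)
            assert f[3] == pytest.approx(pair.ground_truth.r_amp, abs=0.02)

    def test_zero_amplitude_p_wave_gives_near_zero_f1(self):
        t = np.arange(180) / 300.0
        s = 1.0 * np.exp(-((t - 0.35) ** 2) / (2 * 0.012**2))
        fid = delineate(Beat(s, fs=300.0))
        f = time_domain_features(fid, Beat(s, fs=300.0))
        assert abs(f[0]) < 0.01


class TestStatisticalFeatures:
    def test_mean_and_population_variance(self):
        f = statistical_features(np.array([1.0, 3.0, 1.0, 3.0]))
        assert f[0] == pytest.approx(2.0)
        assert f[1] == pytest.approx(1.0)  # population convention
        assert f[2] == pytest.approx(1.0)

    def test_symmetric_signal_has_zero_skewness(self):
        f = statistical_features(np.array([-1.0, 0.0, 1.0, 0.0]))
        assert f[3] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_signal_kurtosis_is_one(self):
        # standardized fourth moment of {-2, 2} equally likely is exactly 1
        f = statistical_features(np.array([2.0, 2.0, -2.0, -2.0]))
        assert f[4] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_signal_rejected(self):
        with pytest.raises(DegenerateBeatError):
            statistical_features(np.ones(10))

    def test_sd_is_sqrt_of_variance_on_extracted_vectors(self, noisy_cohort):
        df = feature_matrix(noisy_cohort)
        np.testing.assert_allclose(df["f9"] ** 2, df["f8"], rtol=1e-12)


class TestPairFeatures:
    def test_identical_leads(self):
        x = np.array([0.1, -0.5, 1.0, 0.2])
        f = pair_features(x, x)
        assert f[0] == pytest.approx(1.0)
        assert f[1] == pytest.approx(0.0)

    def test_negated_lead_gives_correlation_minus_one(self):
        x = np.array([0.1, -0.5, 1.0, 0.2])
        assert pair_features(x, -x)[0] == pytest.approx(-1.0)

    def test_rmse_of_unit_offset(self):
        assert pair_features(
            np.array([1.0, 1.0, 0.5]),
            np.array([0.0, 0.0, -0.5]))[1] == pytest.approx(1.0)

    def test_constant_lead_rejected(self):
        with pytest.raises(DegenerateBeatError):
            pair_features(np.ones(4), np.array([0.0, 1.0, 2.0, 3.0]))


class TestWaveletFeatures:
    def test_constant_signal_has_vanishing_d4(self):
        f = wavelet_features(np.full(256, 3.7))
        assert np.all(np.abs(f) < 1e-9)

    def test_positive_scaling_linearity(self, rng):
        x = rng.standard_normal(200)
        f1 = wavelet_features(x)
        f3 = wavelet_features(3.0 * x)
        np.testing.assert_allclose(f3, 3.0 * f1, rtol=1e-10)

    def test_d4_matches_filter_bank_oracle(self, rng):
        import pywt
        x = rng.standard_normal(256)
        d4_pkg = pywt.wavedec(x, "sym4", mode="symmetric", level=4)[1]
        np.testing.assert_allclose(d4_pkg, dwt_d4_oracle(x), atol=1e-8)
        f = wavelet_features(x)
        oracle = dwt_d4_oracle(x)
        assert f[0] == pytest.approx(oracle.max(), abs=1e-8)
        assert f[1] == pytest.approx(oracle.min(), abs=1e-8)
        assert f[2] == pytest.approx(oracle.mean(), abs=1e-8)

    def test_short_signal_error_names_minimum_length(self):
        with pytest.raises(ValueError, match="112"):
            wavelet_features(np.ones(50))


class TestFeatureVectorAssembly:
    def test_sixteen_finite_named_entries(self, noisy_cohort):
        fv = build_feature_vector(noisy_cohort.pairs[0])
        assert fv.values.shape == (16,)
        assert np.all(np.isfinite(fv.values))
        assert fv.names == FEATURE_NAMES
        assert len(FEATURE_DESCRIPTIONS) == 16

    def test_ordering_invariants(self, noisy_cohort):
        fv = build_feature_vector(noisy_cohort.pairs[3])
        assert -1.0 <= fv["f15"] <= 1.0
        assert fv["f16"] >= 0.0
        assert fv["f12"] >= fv["f14"] >= fv["f13"]

    def test_identical_pairs_give_bitwise_identical_vectors(self, noisy_cohort):
        pair = noisy_cohort.pairs[5]
        a = build_feature_vector(pair).values
        b = build_feature_vector(pair).values
        np.testing.assert_array_equal(a, b)

    def test_r_attenuation_shifts_f4_class_means(self):
        cfg = CohortConfig(n_per_class=34, noise_sd=0.0,
                           baseline_drift_amp=0.0, seed=17)
        cohort = generate_cohort(cfg)
        assert len(cohort) >= 200
        df = feature_matrix(cohort,
                            FeatureConfig(amplitudes_from_normalized=False))
        y = df["label"]
        assert df["f4"][y == 0].mean() < df["f4"][y == 1].mean()

    def test_feature_matrix_is_order_independent(self, noisy_cohort, rng):
        import dataclasses
        df = feature_matrix(noisy_cohort)
        perm = rng.permutation(len(noisy_cohort))
        shuffled = dataclasses.replace(
            noisy_cohort, pairs=tuple(noisy_cohort.pairs[i] for i in perm))
        df_perm = feature_matrix(shuffled)
        np.testing.assert_array_equal(
            df.iloc[perm][list(FEATURE_NAMES)].to_numpy(),
            df_perm[list(FEATURE_NAMES)].to_numpy())

    def test_csv_round_trip_is_lossless(self, noisy_cohort, tmp_path):
        df = feature_matrix(noisy_cohort)
        path = tmp_path / "features.csv"
        write_feature_matrix(df, path)
        back = read_feature_matrix(path)
        np.testing.assert_array_equal(back[list(FEATURE_NAMES)].to_numpy(),
                                      df[list(FEATURE_NAMES)].to_numpy())
        assert list(back["label"]) == list(df["label"])

    def test_feature_vector_requires_sixteen_finite_values(self):
        with pytest.raises(ValueError):
            FeatureVector(np.ones(15))
        with pytest.raises(ValueError):
            FeatureVector(np.r_[np.ones(15), np.nan])
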