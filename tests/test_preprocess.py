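import numpy as np
import pytest
from scipy import signal

from neuroedge.eeg_io import EEGRecording, load_montage
from neuroedge.preprocess import (
    PreprocessConfig,
    SegmentSet,
    align_montage,
    bandpass_filter,
    consistency_score,
    quality_score,
    remove_eog,
    segment,
    spatial_filter,
    standardize,
)


def make_rec(data, fs=250.0, labels=None, eog_index=None):
    labels = labels or [f"C{i}" for i in range(data.shape[0])]
    return EEGRecording(np.asarray(data, float), fs, labels, eog_index=eog_index)


class TestRemoveEog:
    def test_fixed_beta_zero_is_identity(self, rng):
        data = rng.normal(size=(3, 500))
        rec = make_rec(data, labels=["a", "b", "EOG"], eog_index=2)
        cfg = PreprocessConfig(beta_mode="fixed", beta_value=0.0)
        out, beta = remove_eog(rec, cfg)
        np.testing.assert_array_equal(out.data, data[:2])
        assert np.all(beta == 0.0)

    def test_exact_cancellation(self, rng):
        eog = rng.normal(size=500)
        data = np.vstack([0.3 * eog, eog])
        rec = make_rec(data, labels=["a", "EOG"], eog_index=1)
        cfg = PreprocessConfig(beta_mode="fixed", beta_value=0.3)
        out, _ = remove_eog(rec, cfg)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_least_squares_recovers_beta(self, rng):
        # independent source + scaled EOG; normal-equations oracle
        n = 4000
        s = rng.normal(size=n)
        eog = rng.normal(size=n)
        mixed = s + 0.25 * eog
        rec = make_rec(np.vstack([mixed, eog]), labels=["a", "EOG"], eog_index=1)
        out, beta = remove_eog(rec, PreprocessConfig())
        eog_c = eog - eog.mean()
        oracle = ((mixed - mixed.mean()) @ eog_c) / (eog_c @ eog_c)
        assert beta[0] == pytest.approx(oracle, abs=1e-12)
        assert abs(beta[0] - 0.25) < 0.05
        r = np.corrcoef(out.data[0], eog)[0, 1]
        assert abs(r) < 0.05

    def test_residual_uncorrelated_noiseless(self, rng):
        n = 2000
        eog = rng.normal(size=n)
        s = rng.normal(size=n)
        s -= (s @ eog) / (eog @ eog) * eog  # exactly orthogonal source
        rec = make_rec(np.vstack([s + 0.4 * eog, eog]), labels=["a", "EOG"], eog_index=1)
        out, beta = remove_eog(rec, PreprocessConfig())
        c = np.corrcoef(out.data[0], eog)[0, 1]
        assert abs(c) < 1e-6

    def test_zero_variance_eog_raises(self):
        rec = make_rec(np.vstack([np.arange(10.0), np.ones(10)]), labels=["a", "EOG"], eog_index=1)
        with pytest.raises(ValueError, match="zero variance"):
            remove_eog(rec, PreprocessConfig())

    def test_no_eog_in_ls_mode_raises(self, rng):
        rec = make_rec(rng.normal(size=(2, 100)))
        with pytest.raises(ValueError, match="EOG"):
            remove_eog(rec, PreprocessConfig())


class TestStandardize:
    def test_fixed_point(self, rng):
        x = rng.normal(size=(1, 1000))
        x = (x - x.mean()) / x.std()
        out, _ = standardize(make_rec(x), PreprocessConfig())
        np.testing.assert_allclose(out.data, x, atol=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(2, 300))
        a, b = 3.7, -11.0
        out1, _ = standardize(make_rec(x), PreprocessConfig())
        out2, _ = standardize(make_rec(a * x + b), PreprocessConfig())
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-9)

    def test_matches_two_pass_oracle(self):
        x = np.array([[1.0, 2.0, 4.0, 8.0, 10.0]])
        mu = x.sum() / 5.0
        sigma = np.sqrt(((x - mu) ** 2).sum() / 5.0)  # population SD
        out, stats = standardize(make_rec(x), PreprocessConfig())
        np.testing.assert_allclose(out.data, (x - mu) / sigma, atol=1e-12)
        assert stats.mu[0] == pytest.approx(mu)
        assert stats.sigma[0] == pytest.approx(sigma)

    def test_output_moments(self, rng):
        x = rng.normal(3.0, 7.0, size=(4, 500))
        out, _ = standardize(make_rec(x), PreprocessConfig())
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.data.std(axis=1), 1.0, atol=1e-9)

    def test_sigma_zero_policy(self):
        rec = make_rec(np.ones((1, 50)))
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(rec, PreprocessConfig())
        out, _ = standardize(
            make_rec(np.ones((1, 50))), PreprocessConfig(sigma_zero_policy="zero_output")
        )
        np.testing.assert_array_equal(out.data, 0.0)


class TestBandpass:
    def test_dc_removed(self):
        rec = make_rec(np.full((1, 1000), 5.0) + 1e-6 * np.sin(np.arange(1000)))
        out = bandpass_filter(rec, PreprocessConfig(band=(0.5, 40.0)))
        assert (out.data**2).sum() < 0.01 * (rec.data**2).sum()

    def test_passband_sine_retained(self, sine_recording):
        out = bandpass_filter(sine_recording, PreprocessConfig(band=(0.5, 40.0)))
        fs = sine_recording.fs

        def peak_amp(x):  # periodogram-based amplitude estimate
            freqs, psd = signal.periodogram(x, fs=fs)
            df = freqs[1] - freqs[0]
            return np.sqrt(2 * psd.max() * df)

        amp_in = peak_amp(sine_recording.data[0])
        amp_out = peak_amp(out.data[0])
        assert amp_out == pytest.approx(amp_in, rel=0.05)

    def test_notch_attenuates_50hz(self):
        fs = 256.0
        t = np.arange(int(8 * fs)) / fs
        rec = make_rec(np.sin(2 * np.pi * 50.0 * t)[None, :], fs=fs)
        out = bandpass_filter(rec, PreprocessConfig(band=(0.5, 60.0), notch=50.0))

        def power_at(x, f):
            freqs, psd = signal.periodogram(x, fs=fs)
            return psd[np.argmin(np.abs(freqs - f))]

        att = 10 * np.log10(power_at(rec.data[0], 50.0) / power_at(out.data[0], 50.0))
        assert att >= 20.0

    def test_band_edge_at_nyquist_raises(self):
        rec = make_rec(np.zeros((1, 100)), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, PreprocessConfig(band=(0.5, 50.0)))

    def test_shape_preserved(self, small_recording):
        out = bandpass_filter(small_recording, PreprocessConfig())
        assert out.data.shape == small_recording.data.shape


class TestSpatial:
    def test_identical_channels_zeroed(self):
        x = np.tile(np.arange(100.0), (4, 1))
        out = spatial_filter(make_rec(x), PreprocessConfig(spatial_method="common_average"))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_cross_channel_mean_zero(self, rng):
        rec = make_rec(rng.normal(size=(5, 200)))
        out = spatial_filter(rec, PreprocessConfig(spatial_method="common_average"))
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_none_is_identity(self, small_recording):
        out = spatial_filter(small_recording, PreprocessConfig(spatial_method="none"))
        np.testing.assert_array_equal(out.data, small_recording.data)

    def test_laplacian_needs_positions(self, rng):
        rec = make_rec(rng.normal(size=(4, 100)))
        with pytest.raises(ValueError, match="positions"):
            spatial_filter(rec, PreprocessConfig(spatial_method="laplacian"))

    def test_laplacian_runs_with_montage(self, rng):
        m = load_montage("cap128")
        rec = EEGRecording(
            rng.normal(size=(128, 100)), 250.0, list(m.channel_labels)
        )
        out = spatial_filter(rec, PreprocessConfig(spatial_method="laplacian"), montage=m)
        assert out.data.shape == rec.data.shape
        assert not np.allclose(out.data, rec.data)


class TestAlign:
    def test_already_ordered_identity(self, small_recording):
        m = load_montage("wearable3")
        rec = EEGRecording(
            small_recording.data.copy(), 250.0, ["Fp1", "Fp2", "Fpz"]
        )
        out = align_montage(rec, m)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_permutation(self, rng):
        m = load_montage("wearable3")
        data = rng.normal(size=(3, 50))
        rec = EEGRecording(data, 250.0, ["Fpz", "Fp1", "Fp2"])
        out = align_montage(rec, m)
        assert out.channel_labels == ["Fp1", "Fp2", "Fpz"]
        np.testing.assert_array_equal(out.data[0], data[1])
        np.testing.assert_array_equal(out.data[1], data[2])
        np.testing.assert_array_equal(out.data[2], data[0])

    def test_extra_channel_dropped_with_warning(self, rng):
        m = load_montage("wearable3")
        rec = EEGRecording(rng.normal(size=(4, 50)), 250.0, ["Fp1", "Fp2", "Fpz", "X1"])
        with pytest.warns(UserWarning, match="dropping"):
            out = align_montage(rec, m)
        assert out.n_channels == 3

    def test_missing_label_raises(self, rng):
        m = load_montage("wearable3")
        rec = EEGRecording(rng.normal(size=(2, 50)), 250.0, ["Fp1", "Fp2"])
        with pytest.raises(ValueError, match="missing"):
            align_montage(rec, m)

    def test_case_insensitive(self, rng):
        m = load_montage("wearable3")
        rec = EEGRecording(rng.normal(size=(3, 50)), 250.0, ["FP1", "FP2", "FPZ"])
        out = align_montage(rec, m)
        assert out.n_channels == 3


class TestSegment:
    @pytest.mark.parametrize(
        "dur,win,hop,expected",
        [(10.0, 2.0, 2.0, 5), (10.0, 2.0, 1.0, 9), (10.0, 3.0, 2.0, 4)],
    )
    def test_counts(self, rng, dur, win, hop, expected):
        fs = 128.0
        rec = make_rec(rng.normal(size=(2, int(dur * fs))), fs=fs)
        segs = segment(rec, PreprocessConfig(window_s=win, hop_s=hop))
        assert segs.n_segments == expected
        assert segs.segments.shape[2] == round(win * fs)

    def test_too_short_gives_zero_with_warning(self, rng):
        rec = make_rec(rng.normal(size=(1, 1280)), fs=128.0)
        with pytest.warns(UserWarning, match="0 segments"):
            segs = segment(rec, PreprocessConfig(window_s=20.0, hop_s=1.0))
        assert segs.n_segments == 0

    def test_content_matches_slices(self, rng):
        fs = 100.0
        rec = make_rec(rng.normal(size=(2, 500)), fs=fs)
        segs = segment(rec, PreprocessConfig(window_s=1.0, hop_s=0.5))
        np.testing.assert_array_equal(segs.segments[3], rec.data[:, 150:250])


class TestScores:
    @pytest.mark.parametrize("flags,expected", [([1] * 5, 1.0), ([0] * 4, 0.0), ([1, 1, 1, 0], 0.75)])
    def test_consistency_ratios(self, flags, expected):
        assert consistency_score(np.array(flags, bool)) == expected

    def test_consistency_empty_raises(self):
        with pytest.raises(ValueError):
            consistency_score(np.array([], bool))

    def test_consistency_order_invariant(self, rng):
        flags = rng.random(20) > 0.5
        assert consistency_score(flags) == consistency_score(flags[::-1])

    def test_quality_all_pass(self, rng):
        segs = SegmentSet(segments=rng.normal(0, 5, size=(10, 2, 100)))
        rep = quality_score(segs, PreprocessConfig(validity_amp_uV=100.0))
        assert rep.quality_score == 1.0
        assert rep.n_valid_segments == 10

    def test_quality_spike_ratio(self, rng):
        segs_arr = rng.normal(0, 5, size=(10, 2, 100))
        segs_arr[3, 0, 50] = 500.0  # one spiked segment
        rep = quality_score(SegmentSet(segments=segs_arr), PreprocessConfig(validity_amp_uV=100.0))
        assert rep.quality_score == pytest.approx(0.9)

    def test_flatline_invalid(self, rng):
        segs_arr = rng.normal(0, 5, size=(4, 2, 100))
        segs_arr[1, 1, :] = 7.0  # flat channel
        rep = quality_score(SegmentSet(segments=segs_arr), PreprocessConfig())
        assert rep.n_valid_segments == 3

    def test_quality_order_invariant(self, rng):
        segs_arr = rng.normal(0, 40, size=(20, 2, 50))
        cfg = PreprocessConfig(validity_amp_uV=100.0)
        a = quality_score(SegmentSet(segments=segs_arr), cfg).quality_score
        b = quality_score(SegmentSet(segments=segs_arr[::-1].copy()), cfg).quality_score
        assert a == b


class TestChainShape:
    def test_shape_preserved_through_chain(self, rng):
        eog = rng.normal(size=1000)
        data = np.vstack([rng.normal(size=(3, 1000)) + 0.2 * eog, eog])
        rec = EEGRecording(data, 250.0, ["Fp1", "Fp2", "Fpz", "EOG"], eog_index=3)
        cfg = PreprocessConfig()
        out, _ = remove_eog(rec, cfg)
        assert out.data.shape == (3, 1000)  # EOG dropped, rest preserved
        out, _ = standardize(out, cfg)
        out = bandpass_filter(out, cfg)
        out = spatial_filter(out, cfg)
        out = align_montage(out, load_montage("wearable3"))
        assert out.data.shape == (3, 1000)
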