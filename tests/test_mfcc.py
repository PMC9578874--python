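"""The 7-step MFCC chain and its spectral building blocks."""

import numpy as np
import pytest

from fatiguekit.errors import InvalidArgumentError, InvalidDataError
from fatiguekit.mfcc import (
    AudioClip,
    MfccConfig,
    delta_features,
    frame_and_window,
    hamming_window,
    mel_filterbank,
    mel_scale,
    mel_to_hz,
    mfcc,
    n_frames_for,
    power_spectrum,
    preemphasize,
)

from oracles import oracle_mfcc


def clip_of(samples, sr=16000):
    return AudioClip(samples=np.asarray(samples, dtype=float), sample_rate=sr)


class TestPreemphasis:
    def test_alpha_zero_is_identity(self):
        x = np.sin(np.arange(100) * 0.1)
        assert np.array_equal(preemphasize(clip_of(x), 0.0).samples, x)

    def test_constant_signal_alpha_near_one(self):
        y = preemphasize(clip_of(np.full(50, 0.3)), 0.97).samples
        assert y[0] == pytest.approx(0.3)
        assert np.allclose(y[1:], 0.3 - 0.97 * 0.3)

    def test_hand_example(self):
        y = preemphasize(clip_of([1.0, 1.0, 0.0]), 0.97).samples
        assert np.allclose(y, [1.0, 0.03, -0.97])


class TestFraming:
    def test_frame_count_formula(self):
        frames = frame_and_window(clip_of(np.ones(512)), 256, 128, window=False)
        assert frames.shape == (3, 256)
        assert n_frames_for(512, 256, 128) == 3

    def test_all_ones_frame_is_the_window(self):
        frames = frame_and_window(clip_of(np.ones(256)), 256, 256)
        assert np.allclose(frames[0], hamming_window(256))

    def test_non_overlapping_frames_partition_signal(self, rng):
        x = rng.random(1024)
        frames = frame_and_window(clip_of(x), 256, 256, window=False)
        assert np.array_equal(frames.reshape(-1), x)

    def test_short_clip_rejected(self):
        with pytest.raises(InvalidDataError):
            frame_and_window(clip_of(np.ones(100)), 256, 128)


class TestPowerSpectrum:
    def test_zero_frame(self):
        assert np.all(power_spectrum(np.zeros((2, 64)), 64) == 0)

    def test_pure_cosine_concentrates_in_its_bin(self):
        n = 256
        k0 = 16
        x = np.cos(2 * np.pi * k0 * np.arange(n) / n)
        p = power_spectrum(x[None, :], n)[0]
        assert np.argmax(p) == k0
        assert p[k0] == pytest.approx((n / 2) ** 2, rel=1e-9)

    def test_parseval(self, rng):
        n = 512
        x = rng.standard_normal((10, n))
        p = power_spectrum(x, n)
        total = p[:, 0] + p[:, -1] + 2 * p[:, 1:-1].sum(axis=1)
        assert np.allclose(total / n, (x**2).sum(axis=1), rtol=1e-9)


class TestMelScale:
    @pytest.mark.parametrize("dialect", ["standard", "paper_printed"])
    def test_zero_maps_to_zero_and_monotone(self, dialect):
        assert mel_scale(0.0, dialect) == 0.0
        f = np.linspace(0, 8000, 2000)
        assert np.all(np.diff(mel_scale(f, dialect)) > 0)

    def test_standard_reference_point(self):
        assert mel_scale(700.0) == pytest.approx(2595 * np.log10(2), rel=1e-12)

    def test_round_trip(self):
        f = np.array([0.0, 123.4, 1000.0, 7999.0])
        for dialect in ("standard", "paper_printed"):
            assert np.allclose(mel_to_hz(mel_scale(f, dialect), dialect), f, atol=1e-8)


class TestFilterbank:
    def test_shape_positivity_and_ordering(self):
        cfg = MfccConfig()
        fb = mel_filterbank(cfg, 16000)
        assert fb.shape == (cfg.n_mels, cfg.n_fft // 2 + 1)
        assert np.all(fb >= 0)
        assert np.all(fb.sum(axis=1) > 0)
        centers = np.argmax(fb, axis=1)
        assert np.all(np.diff(centers) > 0)

    def test_adjacent_filters_overlap(self):
        fb = mel_filterbank(MfccConfig(), 16000)
        for i in range(fb.shape[0] - 1):
            assert np.any((fb[i] > 0) & (fb[i + 1] > 0))


class TestMfcc:
    def test_silence_gives_constant_rows(self):
        mat = mfcc(clip_of(np.zeros(4096)), MfccConfig())
        assert np.allclose(mat.coefficients, mat.coefficients[:, :1])

    def test_shape_for_7s_16khz(self):
        mat = mfcc(clip_of(np.random.default_rng(0).standard_normal(7 * 16000) * 0.1))
        assert mat.coefficients.shape == (20, 436)

    def test_global_gain_moves_only_coefficient_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4096) * 0.3
        cfg = MfccConfig(preemph_alpha=0.0)
        a = mfcc(clip_of(x), cfg).coefficients
        b = mfcc(clip_of(x * 2.0), cfg).coefficients
        diff = b - a
        # Orthonormal DCT-II maps a constant shift c on the mel axis to
        # c * sqrt(n_mels) in coefficient 0 and nothing elsewhere.
        expected_c0 = np.log(4.0) * np.sqrt(cfg.n_mels)
        assert np.allclose(diff[0], expected_c0, atol=1e-6)
        assert np.allclose(diff[1:], 0.0, atol=1e-6)

    def test_deltas_stack_and_vanish_on_static_input(self):
        cfg = MfccConfig(include_deltas=True)
        mat = mfcc(clip_of(np.zeros(4096)), cfg)
        assert mat.coefficients.shape[0] == 3 * cfg.n_coeffs
        assert np.allclose(mat.coefficients[cfg.n_coeffs :], 0.0)

    def test_matches_independent_reference(self, rng):
        cfg = MfccConfig()
        x = 0.5 * np.sin(2 * np.pi * 440 * np.arange(8000) / 16000)
        x += 0.05 * rng.standard_normal(x.size)
        ours = mfcc(clip_of(x), cfg).coefficients
        ref = oracle_mfcc(x, 16000, cfg.preemph_alpha, cfg.frame_len, cfg.hop_len,
                          cfg.n_fft, cfg.n_mels, cfg.n_coeffs)
        assert np.max(np.abs(ours - ref)) < 1e-6

    def test_config_validation(self):
        with pytest.raises(InvalidArgumentError):
            MfccConfig(preemph_alpha=1.5)
        with pytest.raises(InvalidArgumentError):
            MfccConfig(hop_len=600, frame_len=512)
        with pytest.raises(InvalidArgumentError):
            MfccConfig(n_coeffs=40, n_mels=26)

    def test_delta_width_validation(self):
        with pytest.raises(InvalidArgumentError):
            delta_features(np.zeros((3, 5)), width=0)
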