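"""The synthetic patch / queue / audio / corpus generators."""

import numpy as np
import pytest

from fatiguekit.errors import InvalidArgumentError
from fatiguekit.features import perclos
from fatiguekit.mfcc import MfccConfig, mfcc
from fatiguekit.synthetic import (
    ALERT_DEFAULTS,
    SessionParams,
    default_params,
    gen_audio_clip,
    gen_corpus,
    gen_eye_patch,
    gen_mouth_patch,
    gen_patch_dataset,
    gen_state_sequence,
)
from dataclasses import replace


class TestPatches:
    def test_open_eye_has_pupil_contrast(self):
        patch, label = gen_eye_patch(True, (26, 34), seed=1)
        assert label == 1
        assert patch.shape == (26, 34)
        assert patch.min() >= 0.0 and patch.max() <= 1.0
        interior = patch[4:-4, 6:-6]
        assert interior.max() - interior.min() >= 0.3

    def test_closed_eye_dark_area_small(self):
        patch, label = gen_eye_patch(False, (26, 34), seed=1)
        assert label == 0
        assert np.mean(patch < 0.3) < 0.15

    def test_mouth_aperture_larger_when_open(self):
        open_patch, _ = gen_mouth_patch(True, (80, 120), seed=7)
        closed_patch, _ = gen_mouth_patch(False, (80, 120), seed=7)
        assert np.mean(open_patch < 0.3) > np.mean(closed_patch < 0.3)

    def test_closed_mouth_line_is_thin(self):
        patch, _ = gen_mouth_patch(False, (80, 120), seed=7)
        dark_rows = np.flatnonzero((patch < 0.3).sum(axis=1) > 5)
        assert dark_rows.size <= 5

    @pytest.mark.parametrize("gen", [gen_eye_patch, gen_mouth_patch])
    def test_seed_determinism(self, gen):
        a, _ = gen(True, seed=42)
        b, _ = gen(True, seed=42)
        assert np.array_equal(a, b)

    def test_invalid_size_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gen_eye_patch(True, (0, 34), seed=0)


class TestStateSequences:
    def test_zero_rate_gives_all_open(self):
        params = replace(ALERT_DEFAULTS, blink_rate=0.0, seed=5)
        q = gen_state_sequence(params, "eye")
        assert np.all(q.states == 1)
        assert len(q) == round(params.fps * params.duration)

    def test_poisson_event_count(self):
        # 16 blinks/min over 15 s -> mean 4 events/clip.
        counts = []
        for seed in range(200):
            params = SessionParams(fps=25, duration=15, blink_rate=16,
                                   blink_dur_mean=0.2, blink_dur_sd=0.05, seed=seed)
            q = gen_state_sequence(params, "eye")
            closed_runs = np.sum(np.diff(np.concatenate(([1], q.states))) == -1)
            counts.append(closed_runs)
        mean = np.mean(counts)
        se = np.sqrt(4.0 / 200)
        assert abs(mean - 4.0) <= 3 * se

    def test_fatigued_perclos_exceeds_alert(self):
        gaps = []
        for seed in range(100):
            alert_q = gen_state_sequence(default_params("alert", seed), "eye")
            fat_q = gen_state_sequence(default_params("fatigued", seed + 1000), "eye")
            gaps.append(perclos(fat_q) - perclos(alert_q))
        assert np.mean(gaps) > 0

    def test_longer_fatigued_blinks_raise_perclos_monotonically(self):
        base = default_params("fatigued", seed=0)
        longer = replace(base, blink_dur_mean=base.blink_dur_mean * 2)
        p_base = np.mean([
            perclos(gen_state_sequence(replace(base, seed=s), "eye")) for s in range(60)
        ])
        p_long = np.mean([
            perclos(gen_state_sequence(replace(longer, seed=s), "eye")) for s in range(60)
        ])
        assert p_long > p_base

    def test_determinism(self):
        params = default_params("fatigued", seed=9)
        a = gen_state_sequence(params, "mouth")
        b = gen_state_sequence(params, "mouth")
        assert np.array_equal(a.states, b.states)


class TestAudio:
    def test_spectral_peak_at_f0_when_noiseless(self):
        params = replace(ALERT_DEFAULTS, audio_noise_sd=0.0, seed=2)
        clip = gen_audio_clip(params)
        spectrum = np.abs(np.fft.rfft(clip.samples))
        peak_hz = np.argmax(spectrum) * clip.sample_rate / len(clip)
        bin_width = clip.sample_rate / len(clip)
        assert abs(peak_hz - params.f0) <= bin_width + 1e-9

    def test_amplitude_bounded_and_deterministic(self):
        params = default_params("fatigued", seed=3)
        a = gen_audio_clip(params)
        b = gen_audio_clip(params)
        assert np.max(np.abs(a.samples)) <= 1.0
        assert np.array_equal(a.samples, b.samples)

    def test_classes_separate_in_mfcc_space(self):
        cfg = MfccConfig()
        means = {"alert": [], "fatigued": []}
        for cls in means:
            for seed in range(12):
                clip = gen_audio_clip(default_params(cls, seed))
                means[cls].append(mfcc(clip, cfg).coefficients.mean(axis=1))
        alert = np.array(means["alert"])
        fat = np.array(means["fatigued"])
        between = np.linalg.norm(alert.mean(0) - fat.mean(0))
        within = 0.5 * (np.linalg.norm(alert.std(0)) + np.linalg.norm(fat.std(0)))
        assert between > within

    def test_low_sample_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gen_audio_clip(ALERT_DEFAULTS, sample_rate=4000)


class TestCorpus:
    def test_size_balance_and_determinism(self):
        clips, manifest = gen_corpus(100, 0.5, seed=0)
        assert len(clips) == 100
        assert 0.35 <= manifest["label"].mean() <= 0.65
        _, manifest2 = gen_corpus(100, 0.5, seed=0)
        assert manifest.equals(manifest2)

    def test_minimum_corpus_has_both_classes(self):
        for seed in range(5):
            _, manifest = gen_corpus(2, 0.5, seed=seed)
            assert set(manifest["label"]) == {0, 1}

    def test_too_small_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gen_corpus(1, 0.5, seed=0)

    def test_queue_lengths_and_audio_length(self):
        clips, _ = gen_corpus(4, 0.5, seed=1)
        for clip in clips:
            p = clip.params
            assert len(clip.eye_queue) == round(p.fps * p.duration)
            assert len(clip.mouth_queue) == round(p.fps * p.duration)
            assert len(clip.audio) == round(p.audio_sample_rate * p.audio_duration)

    def test_patch_dataset_balanced(self):
        x, y = gen_patch_dataset("eye", 50, seed=0)
        assert x.shape == (50, 26, 34)
        assert abs(y.mean() - 0.5) <= 0.02
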