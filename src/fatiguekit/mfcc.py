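"""Mel-frequency cepstral coefficients via the classic 7-step chain.

The chain: (1) pre-emphasis y(n) = x(n) - a*x(n-1); (2) framing into
overlapping frames of ``frame_len`` samples at ``hop_len`` stride;
(3) Hamming windowing; (4) DFT magnitude-squared spectrum on bins
0..n_fft/2; (5) triangular mel filterbank and log energies; (6) orthonormal
DCT-II across the mel axis, keeping the first ``n_coeffs`` coefficients;
(7) optional delta and delta-delta features from a +/-2-frame regression
window.

Two mel-scale dialects are supported. ``standard`` is the common HTK-style
approximation mel(f) = 2595 log10(1 + f/700). ``paper_printed`` is an
alternative parameterisation, mel(f) = 2569 log10(1 + f/100), kept for
reproducibility of sources that use those constants. Both are monotone
with mel(0) = 0.

Everything here is deterministic; there is no randomness in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.fft

from .errors import InvalidArgumentError, InvalidDataError

MelDialect = Literal["standard", "paper_printed"]

LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class AudioClip:
    """Mono audio samples in [-1, 1] at a fixed sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidArgumentError("samples must be a nonempty 1-D sequence")
        if not np.isfinite(samples).all():
            raise InvalidArgumentError("samples must be finite")
        if not self.sample_rate > 0:
            raise InvalidArgumentError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class MfccConfig:
    preemph_alpha: float = 0.97
    frame_len: int = 512
    hop_len: int = 256
    n_fft: int = 512
    n_mels: int = 26
    n_coeffs: int = 20
    mel_dialect: MelDialect = "standard"
    include_deltas: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.preemph_alpha < 1:
            raise InvalidArgumentError("preemph_alpha must lie in [0, 1)")
        if not 0 < self.hop_len <= self.frame_len <= self.n_fft:
            raise InvalidArgumentError("need 0 < hop_len <= frame_len <= n_fft")
        if not 2 <= self.n_mels:
            raise InvalidArgumentError("n_mels must be >= 2")
        if not 0 < self.n_coeffs <= self.n_mels:
            raise InvalidArgumentError("need 0 < n_coeffs <= n_mels")
        if self.mel_dialect not in ("standard", "paper_printed"):
            raise InvalidArgumentError(f"unknown mel dialect {self.mel_dialect!r}")


@dataclass(frozen=True)
class MfccMatrix:
    """Cepstral coefficients, shape (n_coeffs [*3 with deltas], n_frames)."""

    coefficients: np.ndarray
    config: MfccConfig = field(compare=False)

    @property
    def n_frames(self) -> int:
        return int(self.coefficients.shape[1])


def n_frames_for(n_samples: int, frame_len: int, hop_len: int) -> int:
    """Frame count 1 + floor((len - frame_len)/hop_len); trailing partial
    frames are dropped."""
    if n_samples < frame_len:
        return 0
    return 1 + (n_samples - frame_len) // hop_len


def preemphasize(clip: AudioClip, alpha: float) -> AudioClip:
    """High-frequency emphasis filter y(n) = x(n) - alpha*x(n-1), y(0) = x(0)."""
    if not 0 <= alpha < 1:
        raise InvalidArgumentError("alpha must lie in [0, 1)")
    x = clip.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return AudioClip(samples=y, sample_rate=clip.sample_rate)


def hamming_window(length: int) -> np.ndarray:
    """w(n) = 0.54 - 0.46 cos(2 pi n / (L - 1)), the symmetric Hamming window."""
    if length < 1:
        raise InvalidArgumentError("window length must be >= 1")
    if length == 1:
        return np.ones(1)
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2 * np.pi * n / (length - 1))


def frame_and_window(
    clip: AudioClip, frame_len: int, hop_len: int, window: bool = True
) -> np.ndarray:
    """Slice the signal into overlapping frames, Hamming-windowed by default.

    Returns shape (n_frames, frame_len). ``window=False`` gives the raw
    frames (used by spectral tests that need an unwindowed path).
    """
    if not 0 < hop_len <= frame_len:
        raise InvalidArgumentError("need 0 < hop_len <= frame_len")
    x = clip.samples
    n = n_frames_for(x.size, frame_len, hop_len)
    if n == 0:
        raise InvalidDataError(
            f"clip of {x.size} samples is shorter than one frame ({frame_len})"
        )
    idx = hop_len * np.arange(n)[:, None] + np.arange(frame_len)[None, :]
    frames = x[idx]
    if window:
        frames = frames * hamming_window(frame_len)[None, :]
    return frames


def power_spectrum(frames: np.ndarray, n_fft: int) -> np.ndarray:
    """|DFT|^2 of each frame on bins 0..n_fft/2 (shape (n_frames, n_fft//2 + 1))."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if n_fft < frames.shape[1]:
        raise InvalidArgumentError("n_fft must be >= frame length")
    spectrum = np.fft.rfft(frames, n=n_fft, axis=1)
    return np.abs(spectrum) ** 2


def mel_scale(f, dialect: MelDialect = "standard"):
    """Perceptual mel value of a physical frequency in Hz."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise InvalidArgumentError("frequency must be nonnegative")
    if dialect == "standard":
        out = 2595.0 * np.log10(1.0 + f / 700.0)
    elif dialect == "paper_printed":
        out = 2569.0 * np.log10(1.0 + f / 100.0)
    else:
        raise InvalidArgumentError(f"unknown mel dialect {dialect!r}")
    return out if out.ndim else float(out)


def mel_to_hz(m, dialect: MelDialect = "standard"):
    """Inverse of :func:`mel_scale`."""
    m = np.asarray(m, dtype=np.float64)
    if dialect == "standard":
        out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    elif dialect == "paper_printed":
        out = 100.0 * (10.0 ** (m / 2569.0) - 1.0)
    else:
        raise InvalidArgumentError(f"unknown mel dialect {dialect!r}")
    return out if out.ndim else float(out)


def mel_filterbank(config: MfccConfig, sample_rate: int) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1).

    Filter centres are uniform on the chosen mel scale between 0 Hz and
    Nyquist; each triangle spans its two neighbouring centres and adjacent
    filters overlap. Peak height is 1 (no area normalisation).
    """
    nyquist = sample_rate / 2.0
    mel_points = np.linspace(
        mel_scale(0.0, config.mel_dialect),
        mel_scale(nyquist, config.mel_dialect),
        config.n_mels + 2,
    )
    hz_points = mel_to_hz(mel_points, config.mel_dialect)
    bin_freqs = np.arange(config.n_fft // 2 + 1) * sample_rate / config.n_fft

    fb = np.zeros((config.n_mels, bin_freqs.size))
    for i in range(config.n_mels):
        left, centre, right = hz_points[i], hz_points[i + 1], hz_points[i + 2]
        up = (bin_freqs - left) / (centre - left)
        down = (right - bin_freqs) / (right - centre)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def delta_features(coeffs: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression-slope deltas over a +/-``width``-frame window (edge-padded)."""
    if width < 1:
        raise InvalidArgumentError("width must be >= 1")
    padded = np.pad(coeffs, ((0, 0), (width, width)), mode="edge")
    denom = 2 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(coeffs)
    for n in range(1, width + 1):
        out += n * (padded[:, width + n :][:, : coeffs.shape[1]]
                    - padded[:, width - n :][:, : coeffs.shape[1]])
    return out / denom


def mfcc(clip: AudioClip, config: MfccConfig | None = None) -> MfccMatrix:
    """Full MFCC chain; returns coefficients x frames (deltas stacked below
    the static coefficients when ``include_deltas`` is set)."""
    config = config or MfccConfig()
    emphasized = preemphasize(clip, config.preemph_alpha)
    frames = frame_and_window(emphasized, config.frame_len, config.hop_len)
    power = power_spectrum(frames, config.n_fft)
    fb = mel_filterbank(config, clip.sample_rate)
    energies = power @ fb.T  # (n_frames, n_mels)
    log_energies = np.log(np.maximum(energies, LOG_FLOOR))
    cepstra = scipy.fft.dct(log_energies, type=2, norm="ortho", axis=1)
    coeffs = cepstra[:, : config.n_coeffs].T  # (n_coeffs, n_frames)
    if config.include_deltas:
        d1 = delta_features(coeffs)
        d2 = delta_features(d1)
        coeffs = np.vstack([coeffs, d1, d2])
    return MfccMatrix(coefficients=coeffs, config=config)


def paper_shape_config(sample_rate: int = 16000) -> MfccConfig:
    """Convenience config whose output keeps 20 static coefficients."""
    return MfccConfig(n_coeffs=20, include_deltas=False)
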