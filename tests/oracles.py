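"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the definition with the dumbest correct
algorithm (explicit scans, explicit transform matrices, all-pairs
counting) and shares no code with the package's vectorized paths.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Temporal features: single linear scan with an explicit state machine


def oracle_temporal_features(states, fps: float) -> dict:
    """blinks/ABT/ABTI/PERCLOS and open-fraction FOM by linear scan."""
    states = list(int(s) for s in states)
    n_total = len(states)
    n_close = sum(1 for s in states if s == 0)

    closed_runs = []
    run_len = 0
    for s in states:
        if s == 0:
            run_len += 1
        elif run_len:
            closed_runs.append(run_len)
            run_len = 0
    if run_len:
        closed_runs.append(run_len)
    blinks = len(closed_runs)

    # Open gaps strictly between consecutive closed runs.
    gaps = []
    seen_closed = False
    gap = 0
    for s in states:
        if s == 0:
            if seen_closed and gap:
                gaps.append(gap)
            seen_closed = True
            gap = 0
        elif seen_closed:
            gap += 1

    abt = 0.0 if blinks == 0 else (n_close / blinks) / fps
    abti = 0.0 if blinks < 2 else (sum(gaps) / (blinks - 1)) / fps
    return {
        "blinks": blinks,
        "abt": abt,
        "abti": abti,
        "perclos": n_close / n_total,
        "fom_open_fraction": sum(1 for s in states if s == 1) / n_total,
    }


def oracle_runs(states) -> list[tuple[int, int, int]]:
    """(value, start, length) runs by linear scan."""
    out = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append((int(states[start]), start, i - start))
            start = i
    return out


# ---------------------------------------------------------------------------
# MFCC: explicit transform matrices, no fft/dct library calls


def oracle_mfcc(
    samples: np.ndarray,
    sample_rate: int,
    preemph_alpha: float,
    frame_len: int,
    hop_len: int,
    n_fft: int,
    n_mels: int,
    n_coeffs: int,
    log_floor: float = 1e-10,
) -> np.ndarray:
    """Static MFCCs from first principles (standard mel dialect)."""
    x = np.asarray(samples, dtype=np.float64)
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, x.size):
        y[i] = x[i] - preemph_alpha * x[i - 1]

    n_frames = 1 + (y.size - frame_len) // hop_len
    window = np.array(
        [0.54 - 0.46 * np.cos(2 * np.pi * n / (frame_len - 1)) for n in range(frame_len)]
    )
    frames = np.stack(
        [y[i * hop_len : i * hop_len + frame_len] * window for i in range(n_frames)]
    )

    k = np.arange(n_fft // 2 + 1)
    n = np.arange(n_fft)
    dft = np.exp(-2j * np.pi * np.outer(k, n) / n_fft)  # explicit DFT matrix
    padded = np.zeros((n_frames, n_fft))
    padded[:, :frame_len] = frames
    power = np.abs(padded @ dft.T) ** 2

    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    edges = imel(np.linspace(mel(0.0), mel(sample_rate / 2.0), n_mels + 2))
    bin_freqs = k * sample_rate / n_fft
    fbank = np.zeros((n_mels, bin_freqs.size))
    for m in range(n_mels):
        lo, ce, hi = edges[m], edges[m + 1], edges[m + 2]
        for b, f in enumerate(bin_freqs):
            if lo <= f <= ce:
                fbank[m, b] = (f - lo) / (ce - lo)
            elif ce < f <= hi:
                fbank[m, b] = (hi - f) / (hi - ce)

    log_e = np.log(np.maximum(power @ fbank.T, log_floor))

    # Explicit orthonormal DCT-II matrix over the mel axis.
    dct = np.zeros((n_mels, n_mels))
    for kk in range(n_mels):
        for nn in range(n_mels):
            dct[kk, nn] = np.sqrt(2.0 / n_mels) * np.cos(
                np.pi * (nn + 0.5) * kk / n_mels
            )
    dct[0, :] /= np.sqrt(2.0)
    return (log_e @ dct.T)[:, :n_coeffs].T


# ---------------------------------------------------------------------------
# AUC: all positive-negative pairs


def oracle_pairwise_auc(labels, scores) -> float:
    """P(score+ > score-) + 0.5 P(tie) over all positive-negative pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = np.sum(pos[:, None] > neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    return (wins + 0.5 * ties) / (pos.size * neg.size)
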