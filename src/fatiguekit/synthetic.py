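"""Synthetic study-condition generator.

Real fatigue-monitoring corpora pair 15 s face video (for blink/yawn
dynamics) with 7 s speech clips. Such recordings are rarely shareable, so
this module fabricates the three ingredients every downstream stage needs:

* grayscale eye/mouth patches with unambiguous open/closed geometry, for
  training the closure classifiers;
* fixed-fps binary closure-state queues whose blink rate, blink duration
  and yawn frequency differ by fatigue class;
* class-conditioned audio clips — a harmonic carrier whose fundamental is
  lower and whose syllable-rate amplitude modulation is slower when
  fatigued, plus white noise.

Class defaults are physiology-flavoured: alert blinks ~15/min lasting
~0.15 s with rare yawns (0.2/min); fatigued blinks ~24/min lasting ~0.45 s
with frequent yawns (2/min). The generator DEFINES the ground-truth label
(the sampling class); everything is a pure function of (params, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .features import StateQueue
from .mfcc import AudioClip

logger = logging.getLogger(__name__)

FatigueClass = Literal["alert", "fatigued"]

EYE_PATCH_SHAPE = (26, 34)
MOUTH_PATCH_SHAPE = (80, 120)


@dataclass(frozen=True)
class SessionParams:
    """Sampling parameters for one synthetic clip.

    Rates are events/minute; durations are seconds. ``yawn_dur_sd`` scales
    the spread of yawn lengths the same way ``blink_dur_sd`` does for
    blinks.
    """

    fatigue_class: FatigueClass = "alert"
    fps: float = 25.0
    duration: float = 15.0
    blink_rate: float = 15.0
    blink_dur_mean: float = 0.15
    blink_dur_sd: float = 0.05
    yawn_rate: float = 0.2
    yawn_dur_mean: float = 4.0
    yawn_dur_sd: float = 1.0
    audio_sample_rate: int = 16000
    audio_duration: float = 7.0
    f0: float = 160.0
    syllable_rate: float = 5.0
    audio_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fatigue_class not in ("alert", "fatigued"):
            raise InvalidArgumentError(f"unknown class {self.fatigue_class!r}")
        if not self.fps > 0:
            raise InvalidArgumentError("fps must be positive")
        if not self.duration > 0:
            raise InvalidArgumentError("duration must be positive")
        if self.blink_rate < 0 or self.yawn_rate < 0:
            raise InvalidArgumentError("event rates must be nonnegative")
        if not self.blink_dur_mean > 0 or not self.yawn_dur_mean > 0:
            raise InvalidArgumentError("event durations must be positive")
        if self.audio_sample_rate < 8000:
            raise InvalidArgumentError("audio sample_rate must be >= 8000 Hz")

    @property
    def label(self) -> int:
        return 1 if self.fatigue_class == "fatigued" else 0


#: Class-conditional defaults. Fatigue lengthens and multiplies blinks,
#: adds yawns, lowers the voice fundamental and slows its syllable rhythm.
ALERT_DEFAULTS = SessionParams(fatigue_class="alert")
FATIGUED_DEFAULTS = SessionParams(
    fatigue_class="fatigued",
    blink_rate=24.0,
    blink_dur_mean=0.45,
    blink_dur_sd=0.15,
    yawn_rate=2.0,
    yawn_dur_mean=5.0,
    yawn_dur_sd=1.2,
    f0=110.0,
    syllable_rate=2.5,
)


def default_params(fatigue_class: FatigueClass, seed: int = 0) -> SessionParams:
    base = FATIGUED_DEFAULTS if fatigue_class == "fatigued" else ALERT_DEFAULTS
    return replace(base, seed=seed)


@dataclass(frozen=True)
class SyntheticClip:
    clip_id: str
    eye_queue: StateQueue
    mouth_queue: StateQueue
    audio: AudioClip
    label: int
    params: SessionParams = field(compare=False)


# ---------------------------------------------------------------------------
# Patches


def _patch_canvas(shape: tuple[int, int], rng: np.random.Generator) -> tuple:
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise InvalidArgumentError(f"patch size must be positive, got {shape}")
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    canvas = np.full((rows, cols), 0.62) + rng.normal(0.0, 0.02, (rows, cols))
    return yy, xx, canvas


def _finish(canvas: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
    return np.clip(canvas, 0.0, 1.0)


def gen_eye_patch(
    open: bool, size: tuple[int, int] = EYE_PATCH_SHAPE, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Render a grayscale eye patch.

    Open: bright sclera ellipse with a dark pupil disc. Closed: a thin dark
    lash arc on skin. Centre/axis jitter and additive noise make every
    patch unique; returns (matrix in [0, 1], label) with label 1 = open.
    """
    rng = np.random.default_rng(seed)
    rows, cols = size
    yy, xx, canvas = _patch_canvas(size, rng)
    cy = rows / 2 + rng.uniform(-rows * 0.06, rows * 0.06)
    cx = cols / 2 + rng.uniform(-cols * 0.06, cols * 0.06)
    if open:
        ay = rows * rng.uniform(0.26, 0.34)
        ax = cols * rng.uniform(0.32, 0.40)
        sclera = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        canvas[sclera] = 0.88
        pupil_r = rows * rng.uniform(0.15, 0.20)
        pupil = (yy - cy) ** 2 + (xx - cx) ** 2 <= pupil_r**2
        canvas[pupil] = 0.05
    else:
        # Lash line: a shallow downward arc ~2 px thick.
        span = cols * rng.uniform(0.30, 0.40)
        sag = rows * rng.uniform(0.05, 0.12)
        arc_y = cy + sag * (((xx - cx) / span) ** 2 - 0.5)
        on_arc = (np.abs(yy - arc_y) <= 1.0) & (np.abs(xx - cx) <= span)
        canvas[on_arc] = 0.15
    return _finish(canvas, rng, 0.03), int(open)


def gen_mouth_patch(
    open: bool, size: tuple[int, int] = MOUTH_PATCH_SHAPE, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Render a grayscale mouth patch.

    Open: a tall dark elliptical aperture (yawn) ringed by darker lips.
    Closed: a thin horizontal lip line. Returns (matrix, label), 1 = open.
    """
    rng = np.random.default_rng(seed)
    rows, cols = size
    yy, xx, canvas = _patch_canvas(size, rng)
    cy = rows / 2 + rng.uniform(-rows * 0.05, rows * 0.05)
    cx = cols / 2 + rng.uniform(-cols * 0.05, cols * 0.05)
    if open:
        ay = rows * rng.uniform(0.24, 0.32)
        ax = cols * rng.uniform(0.18, 0.26)
        r2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        canvas[r2 <= 1.45] = 0.38  # lip ring
        canvas[r2 <= 1.0] = 0.08  # dark aperture
    else:
        half_h = rng.uniform(0.8, 1.6)  # lip line <= ~4 rows total
        half_w = cols * rng.uniform(0.22, 0.30)
        line = (np.abs(yy - cy) <= half_h) & (np.abs(xx - cx) <= half_w)
        canvas[line] = 0.22
    return _finish(canvas, rng, 0.03), int(open)


# ---------------------------------------------------------------------------
# Closure-state sequences


def gen_state_sequence(
    params: SessionParams, channel: Literal["eye", "mouth"] = "eye"
) -> StateQueue:
    """Sample a binary open/closed queue for one clip.

    Event count ~ Poisson(rate * duration); each event is a closed run whose
    length (frames) is a truncated normal, minimum 1 frame. Events are
    placed uniformly without overlap (at least one open frame apart);
    events that cannot be placed or that run past the clip end are
    truncated or dropped with a logged warning. Flag 1 = open.
    """
    if channel not in ("eye", "mouth"):
        raise InvalidArgumentError(f"unknown channel {channel!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0 if channel == "eye" else 1])
    )
    n_frames = round(params.fps * params.duration)
    states = np.ones(n_frames, dtype=np.int64)

    rate = params.blink_rate if channel == "eye" else params.yawn_rate
    dur_mean = params.blink_dur_mean if channel == "eye" else params.yawn_dur_mean
    dur_sd = params.blink_dur_sd if channel == "eye" else params.yawn_dur_sd

    n_events = rng.poisson(rate * params.duration / 60.0) if rate > 0 else 0
    occupied = np.zeros(n_frames + 1, dtype=bool)  # sentinel keeps gaps open
    for _ in range(n_events):
        dur_s = max(rng.normal(dur_mean, dur_sd), 1.0 / params.fps)
        dur = max(1, round(dur_s * params.fps))
        placed = False
        for _attempt in range(20):
            start = int(rng.integers(0, n_frames))
            end = min(start + dur, n_frames)
            lo, hi = max(start - 1, 0), min(end + 1, n_frames)
            if not occupied[lo:hi].any():
                if end < start + dur:
                    logger.warning(
                        "event of %d frames truncated at clip end", dur
                    )
                states[start:end] = 0
                occupied[start:end] = True
                placed = True
                break
        if not placed:
            logger.warning("could not place a %d-frame closed event; dropped", dur)
    return StateQueue(states=states, fps=params.fps, channel=channel)


# ---------------------------------------------------------------------------
# Audio


def gen_audio_clip(
    params: SessionParams,
    sample_rate: int | None = None,
    duration: float | None = None,
) -> AudioClip:
    """Synthesize a speech-like clip: harmonic carrier at the class's
    fundamental, amplitude-modulated at its syllable rate, plus white
    noise; peak-normalised to |x| <= 1."""
    sr = sample_rate or params.audio_sample_rate
    dur = duration or params.audio_duration
    if sr < 8000:
        raise InvalidArgumentError("sample_rate must be >= 8000 Hz")
    if not dur > 0:
        raise InvalidArgumentError("duration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    n = round(sr * dur)
    t = np.arange(n) / sr
    phases = rng.uniform(0, 2 * np.pi, 5)
    voiced = np.zeros(n)
    for h, phase in enumerate(phases, start=1):
        voiced += (1.0 / h) * np.sin(2 * np.pi * h * params.f0 * t + phase)
    envelope = 0.6 + 0.4 * np.sin(2 * np.pi * params.syllable_rate * t)
    x = envelope * voiced + rng.normal(0.0, params.audio_noise_sd, n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return AudioClip(samples=x, sample_rate=sr)


# ---------------------------------------------------------------------------
# Corpus


def gen_clip(params: SessionParams, clip_id: str = "clip") -> SyntheticClip:
    """Generate one fully-paired clip (eye queue, mouth queue, audio, label)."""
    return SyntheticClip(
        clip_id=clip_id,
        eye_queue=gen_state_sequence(params, "eye"),
        mouth_queue=gen_state_sequence(params, "mouth"),
        audio=gen_audio_clip(params),
        label=params.label,
        params=params,
    )


def gen_corpus(
    n_clips: int,
    class_balance: float = 0.5,
    seed: int = 0,
    alert_params: SessionParams = ALERT_DEFAULTS,
    fatigued_params: SessionParams = FATIGUED_DEFAULTS,
) -> tuple[list[SyntheticClip], pd.DataFrame]:
    """Generate a labelled corpus plus its manifest.

    Labels are Bernoulli(class_balance); when the draw degenerates to a
    single class (and 0 < balance < 1) the first label is flipped so both
    classes stay representable. Per-clip seeds derive deterministically
    from the master seed.
    """
    if n_clips < 2:
        raise InvalidArgumentError("n_clips must be >= 2")
    if not 0 <= class_balance <= 1:
        raise InvalidArgumentError("class_balance must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    labels = (rng.random(n_clips) < class_balance).astype(int)
    if 0 < class_balance < 1 and labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    child_seeds = [
        int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n_clips)
    ]
    clips = []
    rows = []
    for i, (label, child_seed) in enumerate(zip(labels, child_seeds)):
        base = fatigued_params if label == 1 else alert_params
        params = replace(base, seed=child_seed)
        clip_id = f"clip{i:05d}"
        clips.append(gen_clip(params, clip_id))
        rows.append(
            {
                "clip_id": clip_id,
                "label": int(label),
                "fatigue_class": params.fatigue_class,
                "seed": child_seed,
            }
        )
    manifest = pd.DataFrame(rows)
    return clips, manifest


def gen_patch_dataset(
    channel: Literal["eye", "mouth"],
    n_patches: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labelled patch set for closure-classifier training.

    Returns (patches, labels): patches (n, rows, cols) in [0, 1], labels
    1 = open. Alternates open/closed so any prefix is near-balanced.
    """
    if n_patches < 2:
        raise InvalidArgumentError("n_patches must be >= 2")
    gen = gen_eye_patch if channel == "eye" else gen_mouth_patch
    shape = EYE_PATCH_SHAPE if channel == "eye" else MOUTH_PATCH_SHAPE
    seeds = np.random.SeedSequence(seed).generate_state(n_patches)
    patches = np.empty((n_patches, *shape), dtype=np.float64)
    labels = np.empty(n_patches, dtype=np.int64)
    for i in range(n_patches):
        is_open = i % 2 == 0
        patches[i], labels[i] = gen(is_open, shape, int(seeds[i] % (2**31)))
    return patches, labels
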