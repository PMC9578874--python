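"""Clip-level temporal features from binary closure-state queues.

A closure-state queue is the per-frame output of the eye or mouth
classifier: 1 means the eye/mouth is open on that frame, 0 means closed.
Five scalar features summarise a clip:

* ``blinks`` — number of maximal closed runs in the eye queue;
* ``abt`` — average blinking time, total closed frames per blink, in seconds;
* ``abti`` — average open interval strictly between consecutive blinks, seconds;
* ``perclos`` — fraction of frames with eyes closed (the classic drowsiness proxy);
* ``fom`` — frequency of open mouth, by default the open-mouth frame fraction
  (a yawn proxy); a ``closed_fraction_as_printed`` dialect reports the
  closed-mouth complement instead.

Conventions (degenerate denominators): ABT is 0 when there is no blink and
ABTI is 0 with fewer than two blinks; both cases are flagged in the vector's
``flags`` metadata. A closed run touching the clip boundary counts as a blink.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import InvalidArgumentError

Channel = Literal["eye", "mouth"]
FomConvention = Literal["open_fraction", "closed_fraction_as_printed"]

OPEN = 1
CLOSED = 0


@dataclass(frozen=True)
class StateQueue:
    """Fixed-fps binary open/closed sequence for one channel.

    ``states`` holds one flag per frame, 1 = open, 0 = closed.
    """

    states: np.ndarray
    fps: float
    channel: Channel

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int64)
        if states.ndim != 1 or states.size == 0:
            raise InvalidArgumentError("states must be a nonempty 1-D sequence")
        if not np.isin(states, (0, 1)).all():
            raise InvalidArgumentError("states must contain only 0/1 flags")
        if not self.fps > 0:
            raise InvalidArgumentError(f"fps must be positive, got {self.fps}")
        if self.channel not in ("eye", "mouth"):
            raise InvalidArgumentError(f"unknown channel {self.channel!r}")
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return int(self.states.size)


@dataclass(frozen=True)
class FacialFeatureVector:
    """The five clip-level facial features."""

    blinks: int
    abt: float
    abti: float
    perclos: float
    fom: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.blinks, self.abt, self.abti, self.perclos, self.fom], dtype=float
        )

    FIELD_NAMES = ("blinks", "abt", "abti", "perclos", "fom")


def segment_runs(queue: StateQueue) -> list[tuple[int, int, int]]:
    """Decompose a queue into maximal runs of equal value.

    Returns ``(value, start, length)`` triples whose concatenation
    reproduces the queue exactly.
    """
    states = queue.states
    boundaries = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [states.size]))
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _require_channel(queue: StateQueue, channel: Channel) -> None:
    if queue.channel != channel:
        raise InvalidArgumentError(
            f"expected a {channel} queue, got channel={queue.channel!r}"
        )


def _closed_runs(queue: StateQueue) -> list[tuple[int, int, int]]:
    return [r for r in segment_runs(queue) if r[0] == CLOSED]


def count_blinks(eye_queue: StateQueue) -> int:
    """Number of blinks = number of maximal closed runs in the eye queue."""
    _require_channel(eye_queue, "eye")
    return len(_closed_runs(eye_queue))


def average_blink_time(eye_queue: StateQueue) -> float:
    """Mean closed time per blink, in seconds: (n_close / N_blinks) / fps.

    Returns 0 when the clip contains no blink.
    """
    _require_channel(eye_queue, "eye")
    n_blinks = count_blinks(eye_queue)
    if n_blinks == 0:
        return 0.0
    n_close = int(np.sum(eye_queue.states == CLOSED))
    return (n_close / n_blinks) / eye_queue.fps


def average_blink_interval(eye_queue: StateQueue) -> float:
    """Mean open gap strictly between consecutive blinks, in seconds.

    With B blinks there are B - 1 inter-blink intervals; returns 0 when
    B < 2.
    """
    _require_channel(eye_queue, "eye")
    runs = segment_runs(eye_queue)
    closed_positions = [i for i, r in enumerate(runs) if r[0] == CLOSED]
    if len(closed_positions) < 2:
        return 0.0
    # Open runs strictly between consecutive closed runs are exactly the
    # interior runs; leading/trailing open runs are not intervals.
    first, last = closed_positions[0], closed_positions[-1]
    gap_frames = sum(r[2] for r in runs[first:last] if r[0] == OPEN)
    return (gap_frames / (len(closed_positions) - 1)) / eye_queue.fps


def perclos(eye_queue: StateQueue) -> float:
    """Fraction of frames with the eyes closed."""
    _require_channel(eye_queue, "eye")
    return float(np.mean(eye_queue.states == CLOSED))


def fom(
    mouth_queue: StateQueue,
    convention: FomConvention = "open_fraction",
) -> float:
    """Frequency of open mouth.

    Default: fraction of frames with the mouth open (yawn proxy). The
    ``closed_fraction_as_printed`` dialect returns the closed-mouth
    complement instead.
    """
    _require_channel(mouth_queue, "mouth")
    open_frac = float(np.mean(mouth_queue.states == OPEN))
    if convention == "open_fraction":
        return open_frac
    if convention == "closed_fraction_as_printed":
        return 1.0 - open_frac
    raise InvalidArgumentError(f"unknown FOM convention {convention!r}")


def facial_features(
    eye_queue: StateQueue,
    mouth_queue: StateQueue,
    fom_convention: FomConvention = "open_fraction",
) -> FacialFeatureVector:
    """Compute the five facial features for one clip."""
    _require_channel(eye_queue, "eye")
    _require_channel(mouth_queue, "mouth")
    if eye_queue.fps != mouth_queue.fps:
        raise InvalidArgumentError(
            f"eye and mouth queues disagree on fps: {eye_queue.fps} vs {mouth_queue.fps}"
        )
    blinks = count_blinks(eye_queue)
    flags: list[str] = []
    if blinks == 0:
        flags.append("zero_blinks")
    elif blinks == 1:
        flags.append("single_blink")
    return FacialFeatureVector(
        blinks=blinks,
        abt=average_blink_time(eye_queue),
        abti=average_blink_interval(eye_queue),
        perclos=perclos(eye_queue),
        fom=fom(mouth_queue, fom_convention),
        flags=tuple(flags),
    )
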