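"""Eye (E-CNN) and mouth (M-CNN) open/closed classifiers.

Both are small binary CNNs with exactly three convolution + max-pool
blocks, two fully connected layers and a sigmoid output. The eye network
consumes 26x34 grayscale patches, the mouth network 80x120. Applied to an
ordered patch stream they emit a closure-state queue: flag 1 = open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDataError, InvalidSpecError
from .features import StateQueue
from .nn import Conv2D, Dense, Flatten, MaxPool2D, ReLU, Sequential

logger = logging.getLogger(__name__)

EYE_INPUT = (26, 34, 1)
MOUTH_INPUT = (80, 120, 1)


@dataclass(frozen=True)
class CnnSpec:
    """Architecture spec: 3 conv blocks, 2 dense layers, sigmoid output."""

    channel: str  # "eye" or "mouth"
    input_shape: tuple[int, int, int] = None  # type: ignore[assignment]
    conv_blocks: tuple[tuple[int, int, int], ...] = ((8, 3, 2), (16, 3, 2), (32, 3, 2))
    dense_layers: tuple[int, ...] = (64, 32)

    def __post_init__(self) -> None:
        if self.channel not in ("eye", "mouth"):
            raise InvalidSpecError(f"unknown channel {self.channel!r}")
        default = EYE_INPUT if self.channel == "eye" else MOUTH_INPUT
        if self.input_shape is None:
            object.__setattr__(self, "input_shape", default)
        if len(self.input_shape) != 3 or self.input_shape[2] != 1:
            raise InvalidSpecError("input_shape must be (rows, cols, 1)")
        if tuple(self.input_shape) != default:
            raise InvalidSpecError(
                f"{self.channel} classifier input must be {default}, got {self.input_shape}"
            )
        if len(self.conv_blocks) != 3:
            raise InvalidSpecError("exactly 3 conv blocks required")
        if len(self.dense_layers) != 2:
            raise InvalidSpecError("exactly 2 fully connected layers required")
        for filters, kernel, pool in self.conv_blocks:
            if filters < 1 or kernel % 2 != 1 or pool < 2:
                raise InvalidSpecError("conv blocks need filters >= 1, odd kernel, pool >= 2")


@dataclass(frozen=True)
class TrainReport:
    epochs_run: int
    history: dict = field(compare=False)
    test_accuracy: float = float("nan")
    seed: int = 0


@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0
    split: float = 0.2  # held-out fraction


def build_closure_cnn(spec: CnnSpec, seed: int = 0) -> Sequential:
    """Instantiate the spec's layer stack with seeded He initialisation."""
    rng = np.random.default_rng(seed)
    rows, cols, _ = spec.input_shape
    layers = []
    in_ch = 1
    for filters, kernel, pool in spec.conv_blocks:
        layers += [Conv2D(in_ch, filters, kernel, rng), ReLU(), MaxPool2D(pool)]
        rows, cols = rows // pool, cols // pool
        in_ch = filters
    layers.append(Flatten())
    width = rows * cols * in_ch
    for dense_width in spec.dense_layers:
        layers += [Dense(width, dense_width, rng), ReLU()]
        width = dense_width
    layers.append(Dense(width, 1, rng))  # sigmoid applied by predict_proba
    return Sequential(layers)


def _as_batch(patches: np.ndarray, spec: CnnSpec) -> np.ndarray:
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[1:] != tuple(spec.input_shape):
        raise InvalidSpecError(
            f"patches of shape {x.shape[1:]} do not match spec input {spec.input_shape}"
        )
    return x


def train_closure_cnn(
    model: Sequential,
    patches: np.ndarray,
    labels: np.ndarray,
    spec: CnnSpec,
    config: TrainConfig | None = None,
) -> tuple[Sequential, TrainReport]:
    """Train on labelled patches (1 = open) with a seeded held-out split."""
    config = config or TrainConfig()
    x = _as_batch(patches, spec)
    y = np.asarray(labels).reshape(-1)
    if np.unique(y).size < 2:
        raise InvalidDataError("patch labels must contain both classes")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(x.shape[0])
    n_test = max(1, int(round(config.split * x.shape[0])))
    test_idx, train_idx = order[:n_test], order[n_test:]
    history = model.fit(
        x[train_idx],
        y[train_idx],
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.lr,
        seed=config.seed,
        validation=(x[test_idx], y[test_idx]),
    )
    test_accuracy = history["val_accuracy"][-1]
    report = TrainReport(
        epochs_run=len(history["loss"]),
        history=history,
        test_accuracy=test_accuracy,
        seed=config.seed,
    )
    return model, report


def combine_eye_queues(
    left: StateQueue, right: StateQueue, mode: str = "both"
) -> StateQueue:
    """Merge per-eye queues into one eye state.

    ``both`` (default): a frame is closed only when both eyes classify
    closed — open if either is open — which suppresses winks and
    one-sided landmark glitches. ``left``/``right`` select a single eye.
    """
    if mode == "left":
        return left
    if mode == "right":
        return right
    if mode != "both":
        raise InvalidDataError(f"unknown eye-combination mode {mode!r}")
    if len(left) != len(right) or left.fps != right.fps:
        raise InvalidDataError("eye queues must share length and fps")
    return StateQueue(states=np.maximum(left.states, right.states),
                      fps=left.fps, channel="eye")


def classify_sequence(
    model: Sequential,
    patches: np.ndarray,
    spec: CnnSpec,
    fps: float,
    threshold: float = 0.5,
    frame_indices: np.ndarray | None = None,
) -> StateQueue:
    """Threshold per-frame open probabilities into a closure-state queue.

    queue[i] = 1 (open) iff p_open >= threshold. When ``frame_indices``
    has gaps the last observed state is carried forward with a warning.
    """
    x = np.asarray(patches)
    if x.size == 0:
        raise InvalidDataError("empty patch stream")
    probs = model.predict_proba(_as_batch(x, spec))
    states = (probs >= threshold).astype(np.int64)
    if frame_indices is not None:
        frame_indices = np.asarray(frame_indices, dtype=np.int64)
        if np.any(np.diff(frame_indices) <= 0):
            raise InvalidDataError("frame_indices must be strictly increasing")
        n = int(frame_indices[-1] - frame_indices[0] + 1)
        full = np.empty(n, dtype=np.int64)
        pos = frame_indices - frame_indices[0]
        last = states[0]
        j = 0
        for i in range(n):
            if j < pos.size and pos[j] == i:
                last = states[j]
                j += 1
            full[i] = last
        if n != states.size:
            logger.warning(
                "filled %d missing frames by carrying the last state", n - states.size
            )
        states = full
    return StateQueue(states=states, fps=fps, channel=spec.channel)
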