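"""Eye/mouth regions of interest from 68-point facial landmarks.

Landmark indexing follows the standard 68-point annotation (0-based):
points 36-41 outline the left eye, 42-47 the right eye, 48-59 the outer
lip. The region boxes scale with the feature itself: the box width is
1.2x the feature's horizontal landmark span (a 20% margin) and the height
follows the classifier's input aspect ratio — eye patches are 34 px wide
by 26 px high, mouth patches 120 by 80. Boxes are centred on the feature's
landmark centroid, so they are equivariant under translation and uniform
scaling of the landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import DegenerateGeometryError, InvalidArgumentError, OutOfBoundsError

LEFT_EYE_IDX = np.arange(36, 42)
RIGHT_EYE_IDX = np.arange(42, 48)
OUTER_LIP_IDX = np.arange(48, 60)

EYE_TARGET = (26, 34)  # rows, cols
MOUTH_TARGET = (80, 120)
BOX_MARGIN = 1.2


@dataclass(frozen=True)
class LandmarkFrame:
    """68 ordered (x, y) pixel coordinates for one video frame."""

    frame_index: int
    points: np.ndarray
    image_size: tuple[int, int] | None = None  # (rows, cols)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.shape != (68, 2):
            raise InvalidArgumentError(
                f"expected 68 (x, y) points, got array of shape {pts.shape}"
            )
        if not np.isfinite(pts).all():
            raise InvalidArgumentError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class RoiBox:
    center: tuple[float, float]  # (x, y)
    width: float
    height: float
    channel: Literal["eye", "mouth"]

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise InvalidArgumentError("box extent must be positive")


@dataclass(frozen=True)
class Patch:
    pixels: np.ndarray
    source_frame: int
    channel: Literal["eye", "mouth"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _feature_box(
    pts: np.ndarray, aspect: float, channel: Literal["eye", "mouth"]
) -> RoiBox:
    span = float(pts[:, 0].max() - pts[:, 0].min())
    if span <= 0:
        raise DegenerateGeometryError(
            f"{channel} landmarks have zero horizontal span"
        )
    width = BOX_MARGIN * span
    height = width * aspect
    cx, cy = pts.mean(axis=0)
    return RoiBox(center=(float(cx), float(cy)), width=width, height=height, channel=channel)


def eye_box(frame: LandmarkFrame, side: Literal["left", "right"] = "left") -> RoiBox:
    """Eye ROI: width = 1.2x the eye's horizontal landmark span, height
    follows the 26:34 patch aspect, centred on the eye centroid."""
    if side == "left":
        idx = LEFT_EYE_IDX
    elif side == "right":
        idx = RIGHT_EYE_IDX
    else:
        raise InvalidArgumentError(f"side must be 'left' or 'right', got {side!r}")
    return _feature_box(frame.points[idx], EYE_TARGET[0] / EYE_TARGET[1], "eye")


def mouth_box(frame: LandmarkFrame) -> RoiBox:
    """Mouth ROI from the outer-lip landmarks, aspect 80:120."""
    return _feature_box(frame.points[OUTER_LIP_IDX], MOUTH_TARGET[0] / MOUTH_TARGET[1], "mouth")


def crop_patch(
    image: np.ndarray,
    box: RoiBox,
    target: tuple[int, int] | None = None,
    source_frame: int = 0,
) -> Patch:
    """Crop a box out of a grayscale image and resize to the classifier shape.

    The box is clipped to the image bounds; the crop is bilinearly resized
    to ``target`` (the channel's default classifier input when omitted) and
    rescaled to [0, 1] (8-bit images divided by 255).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise InvalidArgumentError("image must be a nonempty 2-D grayscale array")
    if target is None:
        target = EYE_TARGET if box.channel == "eye" else MOUTH_TARGET
    if target[0] <= 0 or target[1] <= 0:
        raise InvalidArgumentError("target shape must be positive")

    rows, cols = image.shape
    cx, cy = box.center
    left = int(round(cx - box.width / 2))
    right = int(round(cx + box.width / 2))
    top = int(round(cy - box.height / 2))
    bottom = int(round(cy + box.height / 2))
    left_c, right_c = max(left, 0), min(right, cols)
    top_c, bottom_c = max(top, 0), min(bottom, rows)
    if left_c >= right_c or top_c >= bottom_c:
        raise OutOfBoundsError("box lies entirely outside the image")

    crop = image[top_c:bottom_c, left_c:right_c]
    if image.max() > 1.0:
        crop = crop / 255.0
    crop = np.clip(crop, 0.0, 1.0)
    if crop.shape != tuple(target):
        crop = _sk_resize(crop, target, order=1, mode="edge", anti_aliasing=False)
    return Patch(pixels=crop, source_frame=source_frame, channel=box.channel)
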