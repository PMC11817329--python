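"""Normalized bounding boxes and intersection-over-union.

All coordinates are fractions of the image dimensions, stored in the YOLO
center convention ``(cx, cy, w, h)``.  Boxes are continuous real rectangles;
no pixel quantization is applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "Box",
    "Detection",
    "GroundTruthBox",
    "iou",
    "center_to_corner",
    "corner_to_center",
]


@dataclass(frozen=True)
class Box:
    """A normalized axis-aligned bounding box in center form.

    Parameters
    ----------
    cx, cy
        Box center as a fraction of image width / height, in ``[0, 1]``.
    w, h
        Box width / height fractions, strictly positive.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center ({self.cx}, {self.cy}) outside [0, 1]")
        if self.w <= 0.0 or self.h <= 0.0:
            raise ValueError(f"degenerate box: w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    def corners(self) -> tuple[float, float, float, float]:
        return center_to_corner(self)

    def clipped(self) -> "Box":
        """Clip the corner form to the image frame ``[0,1]²`` and rebuild.

        Detector output and jittered synthetic boxes occasionally overflow the
        frame; they are clipped rather than rejected.
        """
        x1, y1, x2, y2 = self.corners()
        cx1, cy1 = max(x1, 0.0), max(y1, 0.0)
        cx2, cy2 = min(x2, 1.0), min(y2, 1.0)
        if cx1 >= cx2 or cy1 >= cy2:
            raise ValueError("box lies entirely outside the image frame")
        if (cx1, cy1, cx2, cy2) != (x1, y1, x2, y2):
            warnings.warn(
                f"box {(x1, y1, x2, y2)} clipped to the image frame", stacklevel=2
            )
        return corner_to_center(cx1, cy1, cx2, cy2)


@dataclass(frozen=True)
class Detection:
    """One detector prediction: a box with a confidence score.

    ``model_id`` names the source detector (fused outputs use ``"fused"``);
    ``label`` is the integer class index (a single class in the impacted-tooth
    setting, but any number of classes is supported).
    """

    box: Box
    confidence: float
    label: int = 0
    model_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruthBox:
    """An expert-annotated reference box."""

    box: Box
    label: int = 0
    image_id: str = ""


def center_to_corner(b: Box) -> tuple[float, float, float, float]:
    """Convert center form to ``(x1, y1, x2, y2)`` corner form."""
    return (b.cx - b.w / 2.0, b.cy - b.h / 2.0, b.cx + b.w / 2.0, b.cy + b.h / 2.0)


def corner_to_center(x1: float, y1: float, x2: float, y2: float) -> Box:
    """Convert corner form to a center-form :class:`Box`.

    Raises
    ------
    ValueError
        If the corners are inverted (``x1 >= x2`` or ``y1 >= y2``).
    """
    if x1 >= x2 or y1 >= y2:
        raise ValueError(f"inverted corners: ({x1}, {y1}, {x2}, {y2})")
    return Box((x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when equal."""
    ax1, ay1, ax2, ay2 = center_to_corner(a)
    bx1, by1, bx2, by2 = center_to_corner(b)
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return min(inter / union, 1.0)  # guard float overshoot for equal boxes
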