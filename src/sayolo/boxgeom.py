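"""Axis-aligned box geometry in center/size parametrization.

All loss math in this package operates on boxes stored as
``(cx, cy, w, h)``: the center of the box and its strictly positive width
and height, in continuous pixel coordinates with x increasing rightward
and y increasing downward.  The corner view ``(left, top, right, bottom)``
is derived as ``left = cx - w/2`` etc. and both views are exposed through
:func:`convert`.

Vectorized helpers operating on ``(..., 4)`` arrays back the scalar API so
that the simulator can evaluate losses over whole anchor populations at
once; they share a single definition of intersection clamping and
enclosing-box extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "BoxPair",
    "EnclosureStats",
    "InvalidBoxError",
    "iou",
    "enclosing",
    "convert",
    "read_boxes",
    "write_boxes",
    "iou_xywh",
    "enclosing_wh_xywh",
]


class InvalidBoxError(ValueError):
    """Raised when a box has non-positive or non-finite width/height."""


@dataclass(frozen=True)
class Box:
    """An axis-aligned box: center ``(cx, cy)`` and size ``(w, h)`` in pixels.

    Width and height must be strictly positive; degenerate boxes are
    rejected at construction because every downstream loss term divides
    by ``max(w, w_gt)`` or by an enclosing extent.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        vals = (self.cx, self.cy, self.w, self.h)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidBoxError(f"box fields must be finite, got {vals}")
        if self.w <= 0 or self.h <= 0:
            raise InvalidBoxError(
                f"box width/height must be > 0, got w={self.w}, h={self.h}"
            )

    # corner view ------------------------------------------------------
    @property
    def left(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def right(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def top(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def bottom(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_array(self) -> np.ndarray:
        """Return the box as a ``(4,)`` float array ``[cx, cy, w, h]``."""
        return np.array([self.cx, self.cy, self.w, self.h], dtype=float)

    @classmethod
    def from_corners(
        cls, left: float, top: float, right: float, bottom: float
    ) -> "Box":
        return cls(
            cx=(left + right) / 2.0,
            cy=(top + bottom) / 2.0,
            w=right - left,
            h=bottom - top,
        )


@dataclass(frozen=True)
class BoxPair:
    """A (predicted, ground-truth) box pair, the unit of all loss math."""

    pred: Box
    gt: Box

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.pred.as_array(), self.gt.as_array()


@dataclass(frozen=True)
class EnclosureStats:
    """Extents of the minimum box enclosing a pair.

    ``wc``/``hc`` are the width and height of the smallest axis-aligned
    box covering both members; ``diag`` is its diagonal.  The diagonal is
    exposed because the enclosing-box diagonal appears in the classical
    DIoU/CIoU penalties; the iSD-IoU distance term normalizes by ``wc``
    and ``hc`` separately and does not use ``diag``.
    """

    wc: float
    hc: float
    diag: float


# ---------------------------------------------------------------------------
# vectorized core on (..., 4) arrays [cx, cy, w, h]
# ---------------------------------------------------------------------------

def iou_xywh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU of two broadcastable ``(..., 4)`` box arrays.

    Overlap extents are clamped at zero before multiplying so disjoint
    boxes score exactly 0 rather than a spurious positive product.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    iw = np.minimum(a[..., 0] + a[..., 2] / 2, b[..., 0] + b[..., 2] / 2) - np.maximum(
        a[..., 0] - a[..., 2] / 2, b[..., 0] - b[..., 2] / 2
    )
    ih = np.minimum(a[..., 1] + a[..., 3] / 2, b[..., 1] + b[..., 3] / 2) - np.maximum(
        a[..., 1] - a[..., 3] / 2, b[..., 1] - b[..., 3] / 2
    )
    inter = np.clip(iw, 0.0, None) * np.clip(ih, 0.0, None)
    union = a[..., 2] * a[..., 3] + b[..., 2] * b[..., 3] - inter
    # corner arithmetic on far-from-origin boxes can push the ratio a few
    # ulps outside [0, 1]
    return np.clip(inter / union, 0.0, 1.0)


def enclosing_wh_xywh(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Width and height of the minimum box enclosing each pair."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    wc = np.maximum(a[..., 0] + a[..., 2] / 2, b[..., 0] + b[..., 2] / 2) - np.minimum(
        a[..., 0] - a[..., 2] / 2, b[..., 0] - b[..., 2] / 2
    )
    hc = np.maximum(a[..., 1] + a[..., 3] / 2, b[..., 1] + b[..., 3] / 2) - np.minimum(
        a[..., 1] - a[..., 3] / 2, b[..., 1] - b[..., 3] / 2
    )
    return wc, hc


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def iou(pair: BoxPair) -> float:
    """Intersection over union of a box pair, in [0, 1]."""
    a, b = pair.as_arrays()
    return float(iou_xywh(a, b))


def enclosing(pair: BoxPair) -> EnclosureStats:
    """Minimum enclosing-box extents (and diagonal) of a pair."""
    a, b = pair.as_arrays()
    wc, hc = enclosing_wh_xywh(a, b)
    wc = float(wc)
    hc = float(hc)
    return EnclosureStats(wc=wc, hc=hc, diag=math.hypot(wc, hc))


def convert(
    values: Sequence[float], convention: str
) -> tuple[float, float, float, float]:
    """Convert a 4-tuple between the center/size and corner views.

    ``convention`` names the view of the *input*: ``"center"`` means
    ``values`` is ``(cx, cy, w, h)`` and corners are returned;
    ``"corner"`` means ``values`` is ``(left, top, right, bottom)`` and
    the center view is returned.  The round trip is exact to floating
    precision.
    """
    a, b, c, d = (float(v) for v in values)
    if convention == "center":
        return (a - c / 2.0, b - d / 2.0, a + c / 2.0, b + d / 2.0)
    if convention == "corner":
        return ((a + c) / 2.0, (b + d) / 2.0, c - a, d - b)
    raise ValueError(f"unknown convention {convention!r}; expected 'center' or 'corner'")


# ---------------------------------------------------------------------------
# plain-text serialization: one box per line, "cx cy w h"
# ---------------------------------------------------------------------------

def read_boxes(path) -> list[Box]:
    """Read whitespace-delimited ``cx cy w h`` lines into boxes.

    Blank lines and lines starting with ``#`` are skipped.
    """
    boxes: list[Box] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 fields 'cx cy w h', got {len(parts)}"
                )
            cx, cy, w, h = (float(p) for p in parts)
            boxes.append(Box(cx, cy, w, h))
    return boxes


def write_boxes(path, boxes: Iterable[Box]) -> None:
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{b.cx:.6g} {b.cy:.6g} {b.w:.6g} {b.h:.6g}\n")
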