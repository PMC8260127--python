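"""Axis-aligned bounding-box arithmetic.

All boxes use the package-internal convention: 0-based, half-open pixel
coordinates ``(xmin, ymin, xmax, ymax)`` with ``width = xmax - xmin``.
Array-valued helpers operate on ``(N, 4)`` float arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box; 0-based half-open, strictly positive area."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate box: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )
        if self.xmin < 0 or self.ymin < 0:
            raise ValueError(f"negative coordinates: ({self.xmin}, {self.ymin})")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_array(self) -> np.ndarray:
        return np.array([self.xmin, self.ymin, self.xmax, self.ymax], dtype=float)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 iff identical."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(a: np.ndarray, b: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Pairwise IoU between ``(N, 4)`` and ``(M, 4)`` box arrays -> ``(N, M)``.

    Computed in row chunks with in-place arithmetic so large anchor sets
    do not allocate multiple (N, M) temporaries.
    """
    a = np.ascontiguousarray(np.asarray(a, dtype=dtype).reshape(-1, 4))
    b = np.ascontiguousarray(np.asarray(b, dtype=dtype).reshape(-1, 4))
    n, m = a.shape[0], b.shape[0]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    out = np.empty((n, m), dtype=dtype)
    chunk = max(1, (1 << 22) // max(m, 1))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        ix = np.minimum(a[s:e, None, 2], b[None, :, 2])
        ix -= np.maximum(a[s:e, None, 0], b[None, :, 0])
        np.maximum(ix, 0.0, out=ix)
        iy = np.minimum(a[s:e, None, 3], b[None, :, 3])
        iy -= np.maximum(a[s:e, None, 1], b[None, :, 1])
        np.maximum(iy, 0.0, out=iy)
        ix *= iy  # intersection
        union = area_a[s:e, None] + area_b[None, :]
        union -= ix
        with np.errstate(divide="ignore", invalid="ignore"):
            np.divide(ix, union, out=out[s:e], where=union > 0)
        out[s:e][union <= 0] = 0.0
    return out


def clip_boxes(boxes: np.ndarray, width: float, height: float) -> np.ndarray:
    """Clip an ``(N, 4)`` array to ``[0, width] x [0, height]``."""
    boxes = np.asarray(boxes, dtype=float).copy()
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0.0, width)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0.0, height)
    return boxes


def flip_boxes(boxes: np.ndarray, width: int, height: int, axis: str) -> np.ndarray:
    """Reflect boxes across the image's vertical or horizontal mid-axis.

    ``axis='h'`` mirrors left-right (x' = W - x, endpoints swapped);
    ``axis='v'`` mirrors top-bottom. An involution: applying twice is identity.
    """
    boxes = np.asarray(boxes, dtype=float).copy()
    if axis == "h":
        x0 = width - boxes[:, 2]
        x1 = width - boxes[:, 0]
        boxes[:, 0], boxes[:, 2] = x0, x1
    elif axis == "v":
        y0 = height - boxes[:, 3]
        y1 = height - boxes[:, 1]
        boxes[:, 1], boxes[:, 3] = y0, y1
    else:
        raise ValueError(f"axis must be 'h' or 'v', got {axis!r}")
    return boxes


def union_box(a: BoundingBox, b: BoundingBox) -> BoundingBox:
    """Minimal box containing both inputs."""
    return BoundingBox(
        min(a.xmin, b.xmin), min(a.ymin, b.ymin), max(a.xmax, b.xmax), max(a.ymax, b.ymax)
    )


def mask_to_box(mask: np.ndarray) -> BoundingBox | None:
    """Tight half-open box around the True pixels of a 2-D mask; None if empty."""
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        return None
    return BoundingBox(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))
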