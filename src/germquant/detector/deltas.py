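"""Box regression targets: the four scalars (tx, ty, tw, th) per anchor.

Center offsets are normalized by anchor width/height; sizes are log
ratios, so ``decode(anchor, encode(anchor, g)) == g`` and
``encode(a, a) == (0, 0, 0, 0)``.
"""

from __future__ import annotations

import numpy as np


def _split(boxes: np.ndarray):
    boxes = np.asarray(boxes, dtype=float)
    w = boxes[..., 2] - boxes[..., 0]
    h = boxes[..., 3] - boxes[..., 1]
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("boxes must have strictly positive width and height")
    cx = boxes[..., 0] + w / 2
    cy = boxes[..., 1] + h / 2
    return cx, cy, w, h


def encode_delta(anchors: np.ndarray, gts: np.ndarray) -> np.ndarray:
    """Deltas carrying ``anchors`` onto ``gts``; broadcast over leading dims."""
    acx, acy, aw, ah = _split(anchors)
    gcx, gcy, gw, gh = _split(gts)
    return np.stack(
        [(gcx - acx) / aw, (gcy - acy) / ah, np.log(gw / aw), np.log(gh / ah)], axis=-1
    )


def decode_delta(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Apply deltas to anchors, returning (xmin, ymin, xmax, ymax) boxes."""
    acx, acy, aw, ah = _split(anchors)
    deltas = np.asarray(deltas, dtype=float)
    cx = acx + deltas[..., 0] * aw
    cy = acy + deltas[..., 1] * ah
    w = aw * np.exp(deltas[..., 2])
    h = ah * np.exp(deltas[..., 3])
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)
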