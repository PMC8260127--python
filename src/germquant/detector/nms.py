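"""Greedy non-maximum suppression."""

from __future__ import annotations

import numpy as np


def nms_indices(
    boxes: np.ndarray, scores: np.ndarray, iou_threshold: float, max_keep: int | None = None
) -> np.ndarray:
    """Indices kept by greedy NMS, in descending score order.

    Ties in score are broken by original index (stable), so the result is
    deterministic and idempotent. ``max_keep`` stops early once that many
    boxes survive (the prefix of the unbounded result).
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    b = boxes[order]
    areas = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    keep: list[int] = []
    cand = np.arange(len(order))
    while cand.size and (max_keep is None or len(keep) < max_keep):
        i = cand[0]
        keep.append(int(order[i]))
        rest = cand[1:]
        ix = np.minimum(b[i, 2], b[rest, 2]) - np.maximum(b[i, 0], b[rest, 0])
        np.maximum(ix, 0.0, out=ix)
        iy = np.minimum(b[i, 3], b[rest, 3]) - np.maximum(b[i, 1], b[rest, 1])
        np.maximum(iy, 0.0, out=iy)
        inter = ix * iy
        union = areas[i] + areas[rest] - inter
        iou = np.where(union > 0, inter / union, 0.0)
        cand = rest[iou <= iou_threshold]
    return np.array(keep, dtype=int)


def suppress_contained(detections: list, threshold: float) -> list:
    """Drop same-class boxes mostly contained in a higher-confidence box.

    A detection is removed when its intersection with an already-kept box
    of the same class covers at least ``threshold`` of its own area.
    Complements IoU-based NMS for elongated thin objects, where a partial
    segment of a stroke has low IoU with the full detection but is almost
    entirely contained in it. ``threshold >= 1`` disables the filter.
    """
    if threshold >= 1.0 or not detections:
        return list(detections)
    out = []
    for lab in sorted({d.label for d in detections}):
        kept: list = []
        for d in sorted((d for d in detections if d.label == lab),
                        key=lambda d: -d.confidence):
            a = d.box
            contained = any(
                max(0.0, min(a.xmax, k.box.xmax) - max(a.xmin, k.box.xmin))
                * max(0.0, min(a.ymax, k.box.ymax) - max(a.ymin, k.box.ymin))
                >= threshold * a.area
                for k in kept
            )
            if not contained:
                kept.append(d)
        out += kept
    out.sort(key=lambda d: -d.confidence)
    return out


def nms(detections: list, iou_threshold: float) -> list:
    """Per-class greedy suppression of :class:`Detection` lists.

    Keeps the highest-confidence box and drops same-class boxes overlapping
    a kept box above ``iou_threshold``; output sorted by confidence
    descending. Idempotent.
    """
    if not detections:
        return []
    labels = sorted({d.label for d in detections})
    kept = []
    for lab in labels:
        group = [d for d in detections if d.label == lab]
        boxes = np.array([d.box.as_array() for d in group])
        scores = np.array([d.confidence for d in group])
        for i in nms_indices(boxes, scores, iou_threshold):
            kept.append(group[i])
    kept.sort(key=lambda d: -d.confidence)
    return kept
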