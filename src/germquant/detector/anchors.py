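"""Anchor generation and ground-truth assignment for the proposal stage."""

from __future__ import annotations

import numpy as np

from ..boxes import iou_matrix
from .config import AnchorConfig

IGNORE = -1
NEGATIVE = 0
POSITIVE = 1


def generate_anchors(feature_shape: tuple[int, int], cfg: AnchorConfig) -> np.ndarray:
    """Tile 9 anchors at every feature-map location.

    Returns an ``(H*W*9, 4)`` array ordered row-major over locations, then
    scale-major / ratio-minor within a location. Each anchor is centered at
    ``(index + 0.5) * stride`` in image coordinates; an anchor of scale s
    and ratio r (width/height) has width ``s*sqrt(r)`` and height
    ``s/sqrt(r)`` (constant area s^2).
    """
    fh, fw = feature_shape
    if fh < 1 or fw < 1:
        raise ValueError("feature map must be at least 1x1")
    scales = np.asarray(cfg.scales, dtype=float)
    ratios = np.asarray(cfg.aspect_ratios, dtype=float)
    ws = (scales[:, None] * np.sqrt(ratios)[None, :]).ravel()  # scale-major
    hs = (scales[:, None] / np.sqrt(ratios)[None, :]).ravel()
    cy, cx = np.mgrid[0:fh, 0:fw].astype(float)
    cx = (cx.ravel() + 0.5) * cfg.stride
    cy = (cy.ravel() + 0.5) * cfg.stride
    anchors = np.empty((fh * fw, ws.size, 4), dtype=float)
    anchors[..., 0] = cx[:, None] - ws[None, :] / 2
    anchors[..., 1] = cy[:, None] - hs[None, :] / 2
    anchors[..., 2] = cx[:, None] + ws[None, :] / 2
    anchors[..., 3] = cy[:, None] + hs[None, :] / 2
    return anchors.reshape(-1, 4)


def assign_anchor_labels(
    anchors: np.ndarray,
    gt_boxes: np.ndarray,
    iou_positive: float = 0.7,
    iou_negative: float = 0.3,
    force_match: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Label each anchor positive / negative / ignore against ground truth.

    An anchor is positive when its best IoU over ground-truth boxes exceeds
    ``iou_positive`` (matched to the argmax box), negative below
    ``iou_negative``, and ignored in between (excluded from both loss
    terms). With ``force_match`` each ground-truth box additionally makes
    its highest-IoU anchor positive even below the threshold, so no object
    is left without a trainable anchor. With no ground truth all anchors
    are negative.

    Returns ``(labels, matched_gt)`` where ``labels`` is in {1, 0, -1}
    (POSITIVE/NEGATIVE/IGNORE) and ``matched_gt`` holds the matched
    ground-truth index for positives (-1 elsewhere).
    """
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 4)
    if anchors.shape[0] == 0:
        raise ValueError("anchors must be nonempty")
    n = anchors.shape[0]
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    labels = np.full(n, NEGATIVE, dtype=int)
    matched = np.full(n, -1, dtype=int)
    if gt_boxes.shape[0] == 0:
        return labels, matched

    ious = iou_matrix(anchors, gt_boxes)  # (n, g)
    best_iou = ious.max(axis=1)
    best_gt = ious.argmax(axis=1)

    labels[:] = IGNORE
    labels[best_iou < iou_negative] = NEGATIVE
    pos = best_iou > iou_positive
    labels[pos] = POSITIVE
    matched[pos] = best_gt[pos]

    if force_match:
        # every gt claims its best anchor (ties: all tied anchors), provided
        # the anchor overlaps it at all
        per_gt_best = ious.max(axis=0)
        rows, cols = np.nonzero(ious == per_gt_best[None, :])
        ok = per_gt_best[cols] > 0
        labels[rows[ok]] = POSITIVE
        matched[rows[ok]] = cols[ok]
    return labels, matched
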