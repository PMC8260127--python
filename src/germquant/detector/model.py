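"""The two-stage detector: proposal network, ROI head, losses, prediction.

Stage one slides a small network over the frozen backbone features and, at
each location, classifies 9 anchors as object/background (cross-entropy)
and regresses four scalars per positive anchor (smooth L1). Decoded,
score-ranked and NMS-filtered anchors become region proposals. Stage two
pools a fixed-size bilinear crop of the feature map around each proposal
and classifies it into the scheme's classes plus an explicit background
class (softmax cross-entropy), refining the box with a second smooth-L1
regression. Prediction keeps, per proposal, the highest-scoring
foreground class with its softmax confidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..boxes import BoundingBox, clip_boxes
from .anchors import generate_anchors
from .backbone import get_backbone
from .config import DetectorConfig
from .deltas import decode_delta
from .nms import nms, nms_indices, suppress_contained
from .nn import Conv3x3, Linear, relu, smooth_l1, softmax, softmax_cross_entropy

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class Detection:
    """One predicted object: box, foreground label, softmax confidence."""

    box: BoundingBox
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class LossComponents:
    rpn_cls: float
    rpn_reg: float
    head_cls: float
    head_reg: float

    @property
    def total(self) -> float:
        return self.rpn_cls + self.rpn_reg + self.head_cls + self.head_reg


def detector_losses(rpn_outputs, head_outputs, targets) -> LossComponents:
    """Loss components from (logits, deltas) pairs and assigned targets.

    ``rpn_outputs`` = (objectness logits (N, 2), deltas (N, 4)) for the
    sampled anchors; ``head_outputs`` = (class logits (M, K+1), deltas
    (M, 4)) for the sampled proposals; ``targets`` =
    (rpn_labels in {0, 1}, rpn_reg_targets (N, 4), head_classes in
    [0, K], head_reg_targets (M, 4)). Regression terms only see rows whose
    label/class is foreground; classification scores are softmax-normalized
    within each loss. All components are >= 0.
    """
    rpn_logits, rpn_deltas = rpn_outputs
    head_logits, head_deltas = head_outputs
    rpn_labels, rpn_reg_t, head_classes, head_reg_t = targets
    if rpn_logits.shape[0] != len(rpn_labels) or head_logits.shape[0] != len(head_classes):
        raise ValueError("output/target shape mismatch")
    comps, _ = _losses_with_grads(
        rpn_logits, rpn_deltas, np.asarray(rpn_labels), np.asarray(rpn_reg_t),
        head_logits, head_deltas, np.asarray(head_classes), np.asarray(head_reg_t),
        n_background=None,
    )
    return comps


def _losses_with_grads(
    rpn_logits, rpn_deltas, rpn_labels, rpn_reg_t,
    head_logits, head_deltas, head_classes, head_reg_t,
    n_background,
):
    rpn_cls, d_rpn_logits = softmax_cross_entropy(rpn_logits, rpn_labels.astype(int))
    pos = rpn_labels.astype(int) == 1
    d_rpn_deltas = np.zeros_like(rpn_deltas)
    rpn_reg, g = smooth_l1(rpn_deltas[pos], rpn_reg_t[pos] if rpn_reg_t.size else rpn_reg_t)
    if pos.any():
        d_rpn_deltas[pos] = g

    bg = head_logits.shape[1] - 1 if head_logits.size else 0
    head_cls, d_head_logits = softmax_cross_entropy(head_logits, head_classes.astype(int))
    fg = head_classes.astype(int) != bg
    d_head_deltas = np.zeros_like(head_deltas)
    head_reg, g = smooth_l1(head_deltas[fg], head_reg_t[fg] if head_reg_t.size else head_reg_t)
    if fg.any():
        d_head_deltas[fg] = g

    comps = LossComponents(rpn_cls, rpn_reg, head_cls, head_reg)
    grads = (d_rpn_logits, d_rpn_deltas, d_head_logits, d_head_deltas)
    return comps, grads


class FasterRCNN:
    """Two-stage detector over a frozen feature backbone.

    Trainable parameters: the proposal stage (3x3 conv + objectness and
    delta heads over 9 anchors per location) and the ROI head (hidden
    linear layer + class and delta heads).
    """

    def __init__(self, cfg: DetectorConfig, rng_seed: int = 0):
        self.cfg = cfg
        self.backbone = get_backbone(cfg.backbone)
        if self.backbone.stride != cfg.anchor.stride:
            raise ValueError(
                f"anchor stride {cfg.anchor.stride} != backbone stride {self.backbone.stride}"
            )
        rng = np.random.default_rng(rng_seed)
        c = self.backbone.n_channels
        a = cfg.anchor.n_anchors
        # two stacked 3x3 convs: 20 px receptive field at stride 4, enough
        # context to tell a thin radicle from seed-boundary halos
        self.rpn_conv = Conv3x3(c, cfg.rpn_hidden, rng)
        self.rpn_conv2 = Conv3x3(cfg.rpn_hidden, cfg.rpn_hidden, rng)
        self.rpn_obj = Linear(cfg.rpn_hidden, a * 2, rng)
        self.rpn_delta = Linear(cfg.rpn_hidden, a * 4, rng)
        n_roi_feat = cfg.roi_size * cfg.roi_size * c
        self.head_fc = Linear(n_roi_feat, cfg.head_hidden, rng)
        self.head_cls = Linear(cfg.head_hidden, len(cfg.classes) + 1, rng)
        self.head_delta = Linear(cfg.head_hidden, 4, rng)
        self._anchor_cache: dict[tuple[int, int], np.ndarray] = {}

    # ---- parameters ----

    @property
    def params(self):
        layers = [self.rpn_conv, self.rpn_conv2, self.rpn_obj, self.rpn_delta,
                  self.head_fc, self.head_cls, self.head_delta]
        return [p for layer in layers for p in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p.value[...] = w

    # ---- forward pieces ----

    def features(self, image: np.ndarray) -> np.ndarray:
        return self.backbone(image)

    def anchors_for(self, feat_shape: tuple[int, int]) -> np.ndarray:
        key = feat_shape
        if key not in self._anchor_cache:
            self._anchor_cache[key] = generate_anchors(feat_shape, self.cfg.anchor)
        return self._anchor_cache[key]

    def rpn_forward(self, feat: np.ndarray):
        """-> (objectness logits (H*W*9, 2), deltas (H*W*9, 4), cache)."""
        h, w, _ = feat.shape
        hidden1, mask1 = relu(self.rpn_conv.forward(feat))
        hidden2, mask2 = relu(self.rpn_conv2.forward(hidden1))
        flat = hidden2.reshape(h * w, -1)
        obj = self.rpn_obj.forward(flat).reshape(h * w * self.cfg.anchor.n_anchors, 2)
        dlt = self.rpn_delta.forward(flat).reshape(h * w * self.cfg.anchor.n_anchors, 4)
        return obj, dlt, {"mask1": mask1, "mask2": mask2, "hw": (h, w)}

    def rpn_backward(self, d_obj: np.ndarray, d_dlt: np.ndarray, cache) -> None:
        h, w = cache["hw"]
        d_flat = self.rpn_obj.backward(d_obj.reshape(h * w, -1))
        d_flat = d_flat + self.rpn_delta.backward(d_dlt.reshape(h * w, -1))
        d_hidden2 = d_flat.reshape(h, w, -1) * cache["mask2"]
        d_hidden1 = self.rpn_conv2.backward(d_hidden2, need_dx=True) * cache["mask1"]
        self.rpn_conv.backward(d_hidden1)

    def proposals(
        self, feat: np.ndarray, obj_logits: np.ndarray, rpn_deltas: np.ndarray,
        image_size: tuple[int, int],
        pre_nms: int | None = None, keep_count: int | None = None,
    ) -> np.ndarray:
        """Decode, clip, rank and NMS-filter anchors into proposal boxes.

        Budgets default to the training values; inference passes its own
        larger ones.
        """
        h, w, _ = feat.shape
        pre_nms = self.cfg.pre_nms_count if pre_nms is None else pre_nms
        keep_count = self.cfg.proposal_count if keep_count is None else keep_count
        anchors = self.anchors_for((h, w))
        scores = softmax(obj_logits)[:, 1]
        boxes = clip_boxes(decode_delta(anchors, rpn_deltas), image_size[0], image_size[1])
        valid = (boxes[:, 2] - boxes[:, 0] >= 2.0) & (boxes[:, 3] - boxes[:, 1] >= 2.0)
        boxes, scores = boxes[valid], scores[valid]
        if boxes.shape[0] == 0:
            return boxes
        k = min(pre_nms, scores.size)
        if k < scores.size:
            top = np.argpartition(-scores, k - 1)[:k]
        else:
            top = np.arange(scores.size)
        order = top[np.argsort(-scores[top], kind="stable")]
        boxes, scores = boxes[order], scores[order]
        keep = nms_indices(boxes, scores, self.cfg.rpn_nms_iou, max_keep=keep_count)
        return boxes[keep]

    def roi_pool(self, feat: np.ndarray, boxes: np.ndarray) -> np.ndarray:
        """Bilinear crop-and-resize of ``feat`` to (N, roi*roi*C).

        Each proposal is divided into a roi_size x roi_size grid and the
        feature map sampled bilinearly at each cell center (in feature-map
        coordinates, i.e. box / stride).
        """
        n = boxes.shape[0]
        r = self.cfg.roi_size
        h, w, c = feat.shape
        if n == 0:
            return np.zeros((0, r * r * c))
        b = np.asarray(boxes, dtype=float) / self.backbone.stride
        grid = (np.arange(r) + 0.5) / r
        xs = b[:, 0:1] + grid[None, :] * (b[:, 2:3] - b[:, 0:1])  # (N, r)
        ys = b[:, 1:2] + grid[None, :] * (b[:, 3:4] - b[:, 1:2])
        # convert to pixel-center coordinates and clamp
        xs = np.clip(xs - 0.5, 0.0, w - 1.0)
        ys = np.clip(ys - 0.5, 0.0, h - 1.0)
        x0 = np.floor(xs).astype(int); x1 = np.minimum(x0 + 1, w - 1)
        y0 = np.floor(ys).astype(int); y1 = np.minimum(y0 + 1, h - 1)
        fx = (xs - x0)[:, None, :, None]  # (N, 1, r, 1)
        fy = (ys - y0)[:, :, None, None]  # (N, r, 1, 1)
        Y0 = y0[:, :, None]; Y1 = y1[:, :, None]
        X0 = x0[:, None, :]; X1 = x1[:, None, :]
        v00 = feat[Y0, X0]; v01 = feat[Y0, X1]
        v10 = feat[Y1, X0]; v11 = feat[Y1, X1]
        out = (
            v00 * (1 - fy) * (1 - fx) + v01 * (1 - fy) * fx
            + v10 * fy * (1 - fx) + v11 * fy * fx
        )
        return out.reshape(n, r * r * c)

    def head_forward(self, roi_feats: np.ndarray):
        pre = self.head_fc.forward(roi_feats)
        hidden, mask = relu(pre)
        logits = self.head_cls.forward(hidden)
        deltas = self.head_delta.forward(hidden)
        return logits, deltas, {"mask": mask}

    def head_backward(self, d_logits: np.ndarray, d_deltas: np.ndarray, cache) -> None:
        d_hidden = self.head_cls.backward(d_logits) + self.head_delta.backward(d_deltas)
        self.head_fc.backward(d_hidden * cache["mask"])

    # ---- inference ----

    def predict_image(
        self, image: np.ndarray, score_threshold: float | None = None
    ) -> list[Detection]:
        """Detect objects; keep per-proposal argmax foreground class.

        Proposals whose highest-scoring class is background are dropped;
        survivors are box-refined, thresholded on softmax confidence and
        per-class NMS-filtered. Raising the threshold can only shrink the
        result.
        """
        thr = self.cfg.score_threshold if score_threshold is None else score_threshold
        h, w = image.shape[:2]
        feat = self.features(image)
        obj, dlt, _ = self.rpn_forward(feat)
        props = self.proposals(feat, obj, dlt, (w, h),
                               pre_nms=self.cfg.infer_pre_nms_count,
                               keep_count=self.cfg.infer_proposal_count)
        if props.shape[0] == 0:
            return []
        roi = self.roi_pool(feat, props)
        logits, deltas, _ = self.head_forward(roi)
        probs = softmax(logits)
        best = probs.argmax(axis=1)
        bg = len(self.cfg.classes)
        keep = best != bg
        if not keep.any():
            return []
        boxes = clip_boxes(decode_delta(props[keep], deltas[keep]), w, h)
        dets = []
        for box, cls_idx, conf in zip(boxes, best[keep], probs[keep, best[keep]]):
            if conf < thr:
                continue
            if box[2] - box[0] < 1 or box[3] - box[1] < 1:
                continue
            dets.append(
                Detection(
                    box=BoundingBox(*box),
                    label=self.cfg.classes[cls_idx],
                    confidence=float(conf),
                )
            )
        return suppress_contained(nms(dets, self.cfg.nms_iou),
                                  self.cfg.containment_threshold)

    # ---- persistence ----

    def save(self, path: str | Path) -> None:
        """Checkpoint: versioned .npz with weights and embedded config."""
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        meta = json.dumps({"version": CHECKPOINT_VERSION, "config": self.cfg.to_dict()})
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> FasterRCNN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = DetectorConfig.from_dict(meta["config"])
        model = FasterRCNN(cfg)
        weights = [data[f"w{i}"] for i in range(len(model.params))]
    model.set_weights(weights)
    return model
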