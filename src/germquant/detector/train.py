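"""Detector training: mini-batch loop, flip augmentation, validation-based
model selection.

Each iteration samples ``batch_size`` training images (optionally in
horizontally- or vertically-flipped form with boxes transformed
consistently), computes proposal-stage and ROI-head losses on balanced
anchor/proposal samples, and takes one Adam step. Every
``validation_interval`` iterations the current model is scored on the
validation split and the weights with the best (lowest) validation
counting error are retained, which is the overfitting guard used for the
full-scale recipe.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ..annotations import read_voc_xml, scheme_labels
from ..boxes import flip_boxes
from .anchors import NEGATIVE, POSITIVE, assign_anchor_labels
from .config import DetectorConfig, TrainConfig
from .deltas import encode_delta
from .model import FasterRCNN, _losses_with_grads, load_checkpoint
from .nn import Adam


def _load_split(manifest, split: str, classes: tuple[str, ...]) -> list[dict]:
    items = []
    for image_id in manifest.ids(split):
        ann = read_voc_xml(manifest.xml_path(image_id))
        if scheme_labels(ann.scheme) != tuple(classes):
            raise ValueError(
                f"annotation scheme {ann.scheme} ({scheme_labels(ann.scheme)}) does not "
                f"match detector classes {classes}"
            )
        boxes = np.array([b.as_array() for _, b in ann.objects], dtype=float).reshape(-1, 4)
        cls = np.array([classes.index(lab) for lab, _ in ann.objects], dtype=int)
        image = iio.imread(manifest.image_path(image_id))[..., :3]
        items.append({"id": image_id, "image": image, "boxes": boxes, "classes": cls})
    return items


def _sample_balanced(
    rng: np.random.Generator,
    labels: np.ndarray,
    total: int,
    positive_fraction: float,
    matched: np.ndarray | None = None,
    neg_scores: np.ndarray | None = None,
    hard_fraction: float = 0.5,
) -> np.ndarray:
    """Sample up to ``total`` anchor/proposal indices, at most a fraction
    positive.

    When ``matched`` (the matched ground-truth index per positive) is
    given, positives are drawn with weights inversely proportional to how
    many positive anchors their object owns, so small objects with a
    single force-matched anchor are seen as often as large ones with
    dozens. When ``neg_scores`` (current objectness per anchor) is given,
    half the negatives are the hardest (highest-scoring) ones, which
    concentrates background training on the false-positive tail.
    """
    pos = np.flatnonzero(labels == POSITIVE)
    neg = np.flatnonzero(labels == NEGATIVE)
    n_pos = min(len(pos), int(round(total * positive_fraction)))
    if n_pos < len(pos):
        if matched is not None:
            _, inverse, counts = np.unique(
                matched[pos], return_inverse=True, return_counts=True
            )
            w = 1.0 / counts[inverse]
            pos = rng.choice(pos, size=n_pos, replace=False, p=w / w.sum())
        else:
            pos = rng.choice(pos, size=n_pos, replace=False)
    n_neg = min(len(neg), total - len(pos))
    if n_neg < len(neg):
        if neg_scores is not None and hard_fraction > 0:
            n_hard = int(n_neg * hard_fraction)
            hard_order = neg[np.argsort(-neg_scores[neg], kind="stable")[:n_hard]]
            rest = np.setdiff1d(neg, hard_order, assume_unique=True)
            easy = rng.choice(rest, size=n_neg - n_hard, replace=False)
            neg = np.concatenate([hard_order, easy])
        else:
            neg = rng.choice(neg, size=n_neg, replace=False)
    return np.concatenate([pos, neg])


def train_detector(
    manifest,
    det_cfg: DetectorConfig,
    train_cfg: TrainConfig,
    log_path: str | Path | None = None,
) -> tuple[FasterRCNN, list[dict]]:
    """Train on the manifest's train split, select on the val split.

    Returns the model restored to its best-validation-mAE weights and the
    per-iteration training log (also written as CSV to ``log_path``:
    iteration, rpn_cls, rpn_reg, head_cls, head_reg, val_mAE, val_mAP).
    Fully deterministic given ``train_cfg.rng_seed``.
    """
    from ..metrics import evaluate_detector  # local import: avoids cycle

    train_items = _load_split(manifest, "train", det_cfg.classes)
    val_ids = manifest.ids("val")
    if not train_items:
        raise ValueError("training split is empty")
    if not val_ids:
        raise ValueError("validation split is empty")

    model = FasterRCNN(det_cfg, rng_seed=train_cfg.rng_seed)
    if train_cfg.init_weights:
        model.set_weights(load_checkpoint(train_cfg.init_weights).get_weights())
    if train_cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {train_cfg.optimizer!r}")
    opt = Adam(model.params, train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.rng_seed)
    flips = ("none", "h", "v") if train_cfg.flip_augmentation else ("none",)

    cache: dict[tuple[int, str], dict] = {}

    def prepared(idx: int, flip: str) -> dict:
        key = (idx, flip)
        if key in cache:
            return cache[key]
        item = train_items[idx]
        image, boxes = item["image"], item["boxes"]
        h, w = image.shape[:2]
        if flip == "h":
            image = image[:, ::-1]
            boxes = flip_boxes(boxes, w, h, "h") if boxes.size else boxes
        elif flip == "v":
            image = image[::-1]
            boxes = flip_boxes(boxes, w, h, "v") if boxes.size else boxes
        feat = model.features(np.ascontiguousarray(image))
        anchors = model.anchors_for(feat.shape[:2])
        labels, matched = assign_anchor_labels(
            anchors, boxes, det_cfg.iou_positive, det_cfg.iou_negative
        )
        entry = {
            "feat": feat, "boxes": boxes, "classes": item["classes"],
            "anchors": anchors, "rpn_labels": labels, "rpn_matched": matched,
            "size": (w, h),
        }
        cache[key] = entry
        return entry

    log: list[dict] = []
    best = {"mae": np.inf, "iteration": 0, "weights": model.get_weights(), "map": np.nan}
    n_bg = len(det_cfg.classes)

    for it in range(1, train_cfg.iterations + 1):
        opt.zero_grad()
        totals = np.zeros(4)
        for _ in range(train_cfg.batch_size):
            idx = int(rng.integers(len(train_items)))
            flip = flips[int(rng.integers(len(flips)))]
            e = prepared(idx, flip)
            feat, gt_boxes, gt_cls = e["feat"], e["boxes"], e["classes"]

            obj, dlt, rcache = model.rpn_forward(feat)
            sel = _sample_balanced(
                rng, e["rpn_labels"], train_cfg.rpn_batch,
                train_cfg.rpn_positive_fraction, matched=e["rpn_matched"],
                neg_scores=obj[:, 1] - obj[:, 0],
                hard_fraction=train_cfg.hard_negative_fraction,
            )
            sel_labels = (e["rpn_labels"][sel] == POSITIVE).astype(int)
            reg_t = np.zeros((len(sel), 4))
            pos_rows = np.flatnonzero(sel_labels == 1)
            if pos_rows.size:
                a_idx = sel[pos_rows]
                reg_t[pos_rows] = encode_delta(
                    e["anchors"][a_idx], gt_boxes[e["rpn_matched"][a_idx]]
                )

            props = model.proposals(feat, obj, dlt, e["size"])
            if gt_boxes.size:
                props = np.vstack([props, gt_boxes])
            p_labels, p_matched = assign_anchor_labels(
                props, gt_boxes, det_cfg.head_iou_positive, det_cfg.head_iou_negative,
                force_match=False,
            ) if gt_boxes.size else (np.zeros(len(props), dtype=int), np.full(len(props), -1))
            p_sel = _sample_balanced(
                rng, p_labels, train_cfg.head_batch,
                train_cfg.head_positive_fraction, matched=p_matched,
            )
            rois = props[p_sel]
            roi_feats = model.roi_pool(feat, rois)
            logits, deltas, hcache = model.head_forward(roi_feats)
            head_t = np.full(len(p_sel), n_bg, dtype=int)
            head_reg_t = np.zeros((len(p_sel), 4))
            fg_rows = np.flatnonzero(p_labels[p_sel] == POSITIVE)
            if fg_rows.size:
                g = p_matched[p_sel[fg_rows]]
                head_t[fg_rows] = gt_cls[g]
                head_reg_t[fg_rows] = encode_delta(rois[fg_rows], gt_boxes[g])

            comps, (d_obj_s, d_dlt_s, d_logits, d_deltas) = _losses_with_grads(
                obj[sel], dlt[sel], sel_labels, reg_t,
                logits, deltas, head_t, head_reg_t, n_background=n_bg,
            )
            d_obj = np.zeros_like(obj); d_obj[sel] = d_obj_s
            d_dlt = np.zeros_like(dlt); d_dlt[sel] = d_dlt_s
            model.head_backward(d_logits, d_deltas, hcache)
            model.rpn_backward(d_obj, d_dlt, rcache)
            totals += [comps.rpn_cls, comps.rpn_reg, comps.head_cls, comps.head_reg]

        opt.step()
        row = {
            "iteration": it,
            "rpn_cls": totals[0] / train_cfg.batch_size,
            "rpn_reg": totals[1] / train_cfg.batch_size,
            "head_cls": totals[2] / train_cfg.batch_size,
            "head_reg": totals[3] / train_cfg.batch_size,
            "val_mAE": "", "val_mAP": "",
        }

        if it % train_cfg.validation_interval == 0 or it == train_cfg.iterations:
            report = evaluate_detector(model, manifest, split="val")
            row["val_mAE"] = report.mAE
            row["val_mAP"] = report.mAP
            if report.mAE < best["mae"]:
                best = {"mae": report.mAE, "iteration": it,
                        "weights": model.get_weights(), "map": report.mAP}
        log.append(row)

    model.set_weights(best["weights"])
    model.best_validation = {k: best[k] for k in ("mae", "map", "iteration")}

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["iteration", "rpn_cls", "rpn_reg", "head_cls",
                                "head_reg", "val_mAE", "val_mAP"]
            )
            writer.writeheader()
            writer.writerows(log)
    return model, log
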