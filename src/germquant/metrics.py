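"""Detection (AP/mAP) and counting (AE/mAE) evaluation.

Detection quality: predictions are matched to ground truth greedily in
confidence order at an IoU threshold; sweeping the confidence cutoff over
all ranks yields a precision-recall curve whose all-points interpolated
area is the class AP, and mAP is the unweighted mean over classes.

Counting quality: per class, the relative absolute count error
``AE = |y - t| / y`` (ground truth ``y``, predicted ``t``); mAE is the
mean over the N classes. The two axes deliberately measure different
things — a detector can localize better (higher mAP) yet count worse
(higher mAE), and both are reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .annotations import read_voc_xml, scheme_labels
from .boxes import iou_matrix
from .census import ClassCounts, count_detections


@dataclass
class MatchResult:
    """Greedy one-to-one matching of ranked predictions to ground truth."""

    order: np.ndarray  # prediction indices in confidence-descending order
    is_tp: np.ndarray  # per ranked prediction: matched an unclaimed gt
    gt_matched: np.ndarray  # per gt box
    iou_threshold: float

    @property
    def n_fn(self) -> int:
        return int((~self.gt_matched).sum())


def match_predictions(
    pred_boxes: np.ndarray,
    confidences: np.ndarray,
    gt_boxes: np.ndarray,
    iou_threshold: float,
) -> MatchResult:
    """Classify each prediction of one class as TP or FP.

    In confidence-descending order, a prediction is a true positive when
    its best-IoU *unmatched* ground-truth box exceeds ``iou_threshold``
    (that box is then consumed); otherwise a false positive. Ground-truth
    boxes left unmatched are false negatives.
    """
    pred_boxes = np.asarray(pred_boxes, dtype=float).reshape(-1, 4)
    confidences = np.asarray(confidences, dtype=float)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    order = np.argsort(-confidences, kind="stable")
    n, g = pred_boxes.shape[0], gt_boxes.shape[0]
    is_tp = np.zeros(n, dtype=bool)
    gt_matched = np.zeros(g, dtype=bool)
    if n and g:
        ious = iou_matrix(pred_boxes, gt_boxes)
        for rank, i in enumerate(order):
            avail = ~gt_matched
            if not avail.any():
                break
            masked = np.where(avail, ious[i], -1.0)
            j = int(masked.argmax())
            if masked[j] > iou_threshold:
                is_tp[rank] = True
                gt_matched[j] = True
    return MatchResult(order=order, is_tp=is_tp, gt_matched=gt_matched,
                       iou_threshold=iou_threshold)


@dataclass
class PRCurve:
    """(recall, precision) at every confidence-rank cutoff."""

    recall: np.ndarray
    precision: np.ndarray


def precision_recall(match: MatchResult, n_gt: int) -> PRCurve:
    """Sweep the cutoff over ranks: precision TP/(TP+FP), recall TP/n_gt.

    With ``n_gt == 0`` the recall values are NaN-flagged.
    """
    cum_tp = np.cumsum(match.is_tp.astype(float))
    k = np.arange(1, len(cum_tp) + 1, dtype=float)
    precision = cum_tp / k
    recall = cum_tp / n_gt if n_gt > 0 else np.full_like(cum_tp, np.nan)
    return PRCurve(recall=recall, precision=precision)


def average_precision(curve: PRCurve) -> float:
    """All-points interpolated area under the precision-recall curve.

    Precision is replaced by its right-continuous envelope (the maximum
    precision at any recall >= r) and integrated over recall. An empty
    curve scores 0.
    """
    if curve.recall.size == 0 or np.isnan(curve.recall).any():
        return 0.0
    recall = np.concatenate([[0.0], curve.recall])
    envelope = np.maximum.accumulate(curve.precision[::-1])[::-1]
    return float(np.sum((recall[1:] - recall[:-1]) * envelope))


def mean_average_precision(per_class_ap: dict[str, float]) -> float:
    if not per_class_ap:
        raise ValueError("at least one class required")
    return float(np.mean(list(per_class_ap.values())))


def count_error(
    y: ClassCounts, t: ClassCounts
) -> tuple[dict[str, float], float]:
    """Per-class relative absolute count error and its mean.

    ``AE_i = |y_i - t_i| / y_i``. The formula is undefined at ``y_i = 0``:
    a class absent from both sides is skipped from the mean; a spurious
    count against zero ground truth contributes the absolute miscount
    ``t_i``.
    """
    if y.scheme != t.scheme:
        raise ValueError(f"scheme mismatch: {y.scheme} vs {t.scheme}")
    ae: dict[str, float] = {}
    contributing = []
    for lab in scheme_labels(y.scheme):
        yi, ti = y[lab], t[lab]
        if yi > 0:
            ae[lab] = abs(yi - ti) / yi
            contributing.append(ae[lab])
        elif ti > 0:
            ae[lab] = float(ti)
            contributing.append(ae[lab])
        else:
            ae[lab] = 0.0  # absent from both; skipped from the mean
    mae = float(np.mean(contributing)) if contributing else 0.0
    return ae, mae


@dataclass
class EvalReport:
    """Per-class AP and AE with their means over classes."""

    scheme: str
    per_class_ap: dict[str, float]
    per_class_ae: dict[str, float]
    mAP: float
    mAE: float
    iou_threshold: float
    score_threshold: float
    n_images: int = 0
    notes: dict = field(default_factory=dict)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(
                f"# iou_threshold={self.iou_threshold} "
                f"score_threshold={self.score_threshold} n_images={self.n_images}\n"
            )
            writer = csv.writer(fh)
            writer.writerow(["class", "AP", "AE"])
            for lab in scheme_labels(self.scheme):
                writer.writerow([lab, f"{self.per_class_ap[lab]:.6f}",
                                 f"{self.per_class_ae[lab]:.6f}"])
            writer.writerow(["mean", f"{self.mAP:.6f}", f"{self.mAE:.6f}"])


def evaluate_on_annotations(
    per_image: list[tuple[list, object]],
    scheme: str,
    iou_threshold: float = 0.5,
    per_image_counting: bool = True,
) -> EvalReport:
    """Score (detections, ground-truth annotation) pairs.

    ``per_image`` holds, per image, the thresholded detection list and its
    :class:`~germquant.annotations.AnnotatedImage`. AP pools predictions
    over all images per class, ranked by confidence (matching is within
    each prediction's own image). Counting error is computed per image and
    averaged over images, then over classes (set
    ``per_image_counting=False`` to pool counts over the whole set
    instead). A class absent from both ground truth and predictions scores
    AP 1.0.
    """
    labels = scheme_labels(scheme)
    per_class_ap: dict[str, float] = {}
    per_class_ae: dict[str, float] = {}

    for lab in labels:
        pooled: list[tuple[float, bool]] = []
        n_gt = 0
        for dets, ann in per_image:
            gts = np.array([b.as_array() for b in ann.boxes_of(lab)]).reshape(-1, 4)
            n_gt += gts.shape[0]
            group = [d for d in dets if d.label == lab]
            if not group:
                continue
            boxes = np.array([d.box.as_array() for d in group])
            confs = np.array([d.confidence for d in group])
            m = match_predictions(boxes, confs, gts, iou_threshold)
            for rank, i in enumerate(m.order):
                pooled.append((confs[i], bool(m.is_tp[rank])))
        if n_gt == 0 and not pooled:
            per_class_ap[lab] = 1.0  # correct silence
            continue
        if n_gt == 0:
            per_class_ap[lab] = 0.0
            continue
        pooled.sort(key=lambda x: -x[0])
        tp_flags = np.array([tp for _, tp in pooled], dtype=bool)
        cum_tp = np.cumsum(tp_flags.astype(float))
        k = np.arange(1, len(cum_tp) + 1, dtype=float)
        curve = PRCurve(recall=cum_tp / n_gt, precision=cum_tp / k)
        per_class_ap[lab] = average_precision(curve) if len(pooled) else 0.0

    if per_image_counting:
        per_image_ae: dict[str, list[float]] = {lab: [] for lab in labels}
        for dets, ann in per_image:
            y = ClassCounts(scheme, {lab: len(ann.boxes_of(lab)) for lab in labels})
            t = count_detections(dets, scheme)
            ae, _ = count_error(y, t)
            for lab in labels:
                if y[lab] > 0 or t[lab] > 0:
                    per_image_ae[lab].append(ae[lab])
        for lab in labels:
            vals = per_image_ae[lab]
            per_class_ae[lab] = float(np.mean(vals)) if vals else 0.0
    else:
        y_tot = {lab: 0 for lab in labels}
        t_tot = {lab: 0 for lab in labels}
        for dets, ann in per_image:
            for lab in labels:
                y_tot[lab] += len(ann.boxes_of(lab))
            t = count_detections(dets, scheme)
            for lab in labels:
                t_tot[lab] += t[lab]
        per_class_ae, _ = count_error(
            ClassCounts(scheme, y_tot), ClassCounts(scheme, t_tot)
        )

    contributing_ae = [per_class_ae[lab] for lab in labels]
    report = EvalReport(
        scheme=scheme,
        per_class_ap=per_class_ap,
        per_class_ae=per_class_ae,
        mAP=mean_average_precision(per_class_ap),
        mAE=float(np.mean(contributing_ae)),
        iou_threshold=iou_threshold,
        score_threshold=float("nan"),
        n_images=len(per_image),
    )
    return report


def evaluate_detector(
    model,
    manifest,
    split: str = "test",
    iou_threshold: float = 0.5,
    score_threshold: float | None = None,
    per_image_counting: bool = True,
) -> EvalReport:
    """Run the model over a manifest split and score it.

    Refuses to evaluate on the training split (the blind-test contract).
    AP integrates over all confidence cutoffs; the score threshold only
    affects the counting metric's detection lists.
    """
    if split == "train":
        raise ValueError("refusing to evaluate on the training split; use val or test")
    ids = manifest.ids(split)
    if not ids:
        raise ValueError(f"split {split!r} is empty")
    overlap = set(ids) & set(manifest.ids("train"))
    if overlap:
        raise ValueError(f"split {split!r} overlaps the training split: {sorted(overlap)}")
    scheme = None
    thr = model.cfg.score_threshold if score_threshold is None else score_threshold
    ap_pairs, count_pairs = [], []
    for image_id in ids:
        ann = read_voc_xml(manifest.xml_path(image_id))
        scheme = ann.scheme
        image = iio.imread(manifest.image_path(image_id))[..., :3]
        dets_all = model.predict_image(image, score_threshold=0.05)
        ap_pairs.append((dets_all, ann))
        count_pairs.append(([d for d in dets_all if d.confidence >= thr], ann))
    report_ap = evaluate_on_annotations(ap_pairs, scheme, iou_threshold)
    report_cnt = evaluate_on_annotations(count_pairs, scheme, iou_threshold,
                                         per_image_counting=per_image_counting)
    return EvalReport(
        scheme=scheme,
        per_class_ap=report_ap.per_class_ap,
        per_class_ae=report_cnt.per_class_ae,
        mAP=report_ap.mAP,
        mAE=report_cnt.mAE,
        iou_threshold=iou_threshold,
        score_threshold=thr,
        n_images=len(ids),
    )
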