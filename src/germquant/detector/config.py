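"""Detector and training configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class AnchorConfig:
    """Anchor geometry: 3 scales x 3 aspect ratios = 9 anchors per location.

    ``scales`` are anchor side lengths in pixels (the square-anchor base
    size); ``aspect_ratios`` are width/height ratios applied at constant
    area. ``stride`` is the feature-map stride in image pixels.
    """

    stride: int = 4
    scales: tuple[float, float, float] = (14.0, 22.0, 34.0)
    aspect_ratios: tuple[float, float, float] = (0.5, 1.0, 2.0)

    def __post_init__(self) -> None:
        if len(self.scales) != 3 or len(self.aspect_ratios) != 3:
            raise ValueError("anchor config requires exactly 3 scales and 3 aspect ratios")
        if any(s <= 0 for s in self.scales) or any(r <= 0 for r in self.aspect_ratios):
            raise ValueError("scales and aspect ratios must be positive")

    @property
    def n_anchors(self) -> int:
        return len(self.scales) * len(self.aspect_ratios)


@dataclass
class DetectorConfig:
    """Assignment thresholds, NMS and scoring defaults, and the class list.

    The RPN labels anchors positive above ``iou_positive`` (0.7) and
    negative below ``iou_negative`` (0.3); the band in between is ignored
    by both loss terms. The second-stage head reuses the same assignment
    rule with its own thresholds (default 0.5/0.5, i.e. no ignore band).
    ``classes`` is the ordered foreground label list; background is an
    implicit extra class of the head.

    Proposal budgets differ between training (``pre_nms_count`` /
    ``proposal_count``) and inference (``infer_*``): thin radicles rank
    lower in class-agnostic objectness than dark seeds, so inference digs
    deeper into the ranking and relies on the ROI head to discriminate.
    The final per-class NMS threshold (0.2) is deliberately aggressive
    because shifted duplicates of a thin diagonal box overlap far below
    the conventional 0.5.
    """

    anchor: AnchorConfig = field(default_factory=AnchorConfig)
    iou_positive: float = 0.7
    iou_negative: float = 0.3
    head_iou_positive: float = 0.5
    head_iou_negative: float = 0.5
    nms_iou: float = 0.2
    rpn_nms_iou: float = 0.7
    pre_nms_count: int = 6000
    proposal_count: int = 600
    infer_pre_nms_count: int = 20000
    infer_proposal_count: int = 1500
    containment_threshold: float = 0.6
    score_threshold: float = 0.5
    classes: tuple[str, ...] = ("S", "R")
    backbone: str = "small-conv"
    rpn_hidden: int = 32
    head_hidden: int = 128
    roi_size: int = 7

    def __post_init__(self) -> None:
        if not (0.0 <= self.iou_negative < self.iou_positive <= 1.0):
            raise ValueError(
                f"need 0 <= iou_negative < iou_positive <= 1, got "
                f"{self.iou_negative}, {self.iou_positive}"
            )
        if not self.classes:
            raise ValueError("at least one foreground class required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anchor"] = asdict(self.anchor)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        anchor = d.pop("anchor", {})
        ac = AnchorConfig(
            stride=int(anchor.get("stride", 4)),
            scales=tuple(anchor.get("scales", (14.0, 22.0, 34.0))),
            aspect_ratios=tuple(anchor.get("aspect_ratios", (0.5, 1.0, 2.0))),
        )
        d["classes"] = tuple(d.get("classes", ("S", "R")))
        return cls(anchor=ac, **d)


@dataclass
class TrainConfig:
    """Optimization schedule.

    Defaults follow the full-scale recipe: Adam, learning rate 0.01,
    batches of two images, 5,000 iterations (2,000 for fine-tuning), flip
    augmentation around both axes, and best-on-validation model selection.
    """

    iterations: int = 5000
    batch_size: int = 2
    learning_rate: float = 0.01
    optimizer: str = "adam"
    flip_augmentation: bool = True
    rng_seed: int = 0
    validation_interval: int = 100
    rpn_batch: int = 256
    rpn_positive_fraction: float = 0.5
    head_batch: int = 128
    head_positive_fraction: float = 0.25
    hard_negative_fraction: float = 0.0
    init_weights: str | None = None

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("iterations > 0, batch_size >= 1, learning_rate > 0 required")
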