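"""From detections to per-disk germination rates and the batch CSV report.

Under the S/R scheme every seed keeps a visible coat, so ``S`` counts all
seeds and ``R`` counts germinated ones; the germination rate is
``R / S`` clipped to 1 (undefined when no seed is detected). Under
NGS/GS the rate is ``GS / (GS + NGS)``. NGS detections nested inside GS
boxes are deliberately not suppressed — that double-count risk is an
inherent property of the NGS/GS labelling scheme and is reported as-is.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio

from .annotations import scheme_labels


@dataclass
class ClassCounts:
    """Per-label object counts under one scheme."""

    scheme: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = scheme_labels(self.scheme)
        full = {lab: 0 for lab in labels}
        for lab, v in self.counts.items():
            if lab not in labels:
                raise ValueError(f"label {lab!r} not in scheme {self.scheme}")
            if v < 0:
                raise ValueError(f"negative count for {lab!r}")
            full[lab] = int(v)
        self.counts = full

    def __getitem__(self, label: str) -> int:
        return self.counts[label]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_detections(detections: list, scheme: str) -> ClassCounts:
    """Tally detections by label; foreign labels are an error."""
    labels = scheme_labels(scheme)
    counts = {lab: 0 for lab in labels}
    for d in detections:
        if d.label not in counts:
            raise ValueError(f"detection label {d.label!r} not in scheme {scheme}")
        counts[d.label] += 1
    return ClassCounts(scheme=scheme, counts=counts)


def germination_rate(counts: ClassCounts) -> float | None:
    """Per-disk germinated fraction, or None when undefined.

    S_R: min(1, R/S), undefined when S = 0. NGS_GS: GS/(GS+NGS),
    undefined when both are 0.
    """
    if counts.scheme == "S_R":
        s, r = counts["S"], counts["R"]
        return None if s == 0 else min(1.0, r / s)
    ngs, gs = counts["NGS"], counts["GS"]
    total = ngs + gs
    return None if total == 0 else gs / total


@dataclass
class CensusRecord:
    """One image's census row; ``error`` set when processing failed."""

    image_name: str
    counts: ClassCounts | None
    germination_rate: float | None
    error: str | None = None


def census_batch(
    image_paths: list, model, scheme: str, score_threshold: float | None = None
) -> list[CensusRecord]:
    """Run the detector over a folder of disk images, one record per image.

    A failure on one image produces an error record instead of aborting
    the batch. The model's class list must match the requested scheme.
    """
    if tuple(model.cfg.classes) != scheme_labels(scheme):
        raise ValueError(
            f"model classes {model.cfg.classes} do not match scheme {scheme} "
            f"{scheme_labels(scheme)}"
        )
    records: list[CensusRecord] = []
    for path in image_paths:
        path = Path(path)
        try:
            image = iio.imread(path)
            if image.ndim == 2:
                image = image[..., None].repeat(3, axis=-1)
            dets = model.predict_image(image[..., :3], score_threshold)
            counts = count_detections(dets, scheme)
            records.append(CensusRecord(path.name, counts, germination_rate(counts)))
        except Exception as exc:  # per-row robustness, not batch abort
            records.append(CensusRecord(path.name, None, None, error=str(exc)))
    return records


def write_census_csv(records: list[CensusRecord], path: str | Path) -> None:
    """CSV report: image name, per-class counts, germination rate in %.

    The rate is formatted with two decimals and left empty when undefined
    or when the row errored.
    """
    path = Path(path)
    scheme = next((r.counts.scheme for r in records if r.counts is not None), "S_R")
    labels = scheme_labels(scheme)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["image_name", *[f"count_{lab}" for lab in labels],
             "germination_rate_percent", "error_message"]
        )
        for rec in records:
            if rec.counts is None:
                writer.writerow([rec.image_name, *[""] * len(labels), "", rec.error or ""])
                continue
            rate = "" if rec.germination_rate is None else f"{100 * rec.germination_rate:.2f}"
            writer.writerow(
                [rec.image_name, *[rec.counts[lab] for lab in labels], rate, ""]
            )


def read_census_csv(path: str | Path) -> list[CensusRecord]:
    """Parse a census CSV back into records (inverse of write for counts)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header, rows = rows[0], rows[1:]
    count_cols = [h for h in header if h.startswith("count_")]
    labels = tuple(h.removeprefix("count_") for h in count_cols)
    scheme = next(s for s, labs in
                  (("NGS_GS", ("NGS", "GS")), ("S_R", ("S", "R"))) if labs == labels)
    records = []
    for row in rows:
        d = dict(zip(header, row))
        if d.get("error_message"):
            records.append(CensusRecord(d["image_name"], None, None, d["error_message"]))
            continue
        counts = ClassCounts(scheme, {lab: int(d[f"count_{lab}"]) for lab in labels})
        rate_s = d["germination_rate_percent"]
        rate = None if rate_s == "" else float(rate_s) / 100.0
        records.append(CensusRecord(d["image_name"], counts, rate))
    return records
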