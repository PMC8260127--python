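"""Pascal VOC XML bounding-box annotations for germination-bioassay disks.

Two labelling schemes are supported:

* ``NGS_GS`` — each object is either a non-germinated seed (``NGS``, box
  around the seed alone) or a germinated seed (``GS``, box around the seed
  together with its radicle).
* ``S_R`` — every seed coat is boxed as ``S`` and every radicle separately
  as ``R``.

Coordinates are stored internally as 0-based half-open pixels; on disk the
VOC dialect is 1-based inclusive, so a pixel-identical box round-trips as
``xmin+1, ymin+1, xmax, ymax``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

from .boxes import BoundingBox

SCHEMES: dict[str, tuple[str, ...]] = {
    "NGS_GS": ("NGS", "GS"),
    "S_R": ("S", "R"),
}


def scheme_labels(scheme: str) -> tuple[str, ...]:
    """Ordered label set of a scheme; raises on unknown scheme names."""
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}") from None


def scheme_of_label(name: str) -> str:
    for scheme, labels in SCHEMES.items():
        if name in labels:
            return scheme
    raise ValueError(f"label {name!r} belongs to no known scheme")


class AnnotationError(ValueError):
    """Raised for malformed or scheme-inconsistent annotations."""


@dataclass
class AnnotatedImage:
    """One disk image plus its ground-truth boxes under a declared scheme."""

    image_id: str
    width: int
    height: int
    scheme: str
    objects: list[tuple[str, BoundingBox]] = field(default_factory=list)

    def boxes_of(self, label: str) -> list[BoundingBox]:
        return [b for lab, b in self.objects if lab == label]


def validate_annotation(ann: AnnotatedImage) -> list[str]:
    """Return a description of every invariant violation (empty when clean)."""
    violations: list[str] = []
    if ann.scheme not in SCHEMES:
        violations.append(f"scheme: unknown scheme {ann.scheme!r}")
        return violations
    labels = SCHEMES[ann.scheme]
    for i, (name, box) in enumerate(ann.objects):
        if name not in labels:
            violations.append(
                f"object {i}: scheme rule: label {name!r} not in scheme {ann.scheme} {labels}"
            )
        if box.xmin < 0 or box.ymin < 0 or box.xmax > ann.width or box.ymax > ann.height:
            violations.append(
                f"object {i}: bounds rule: box ({box.xmin}, {box.ymin}, {box.xmax}, "
                f"{box.ymax}) outside image {ann.width}x{ann.height}"
            )
    return violations


def read_voc_xml(path: str | Path, expected_scheme: str | None = None) -> AnnotatedImage:
    """Parse one VOC XML file into an :class:`AnnotatedImage`.

    VOC's 1-based inclusive coordinates are converted to the internal
    0-based half-open convention (``xmin - 1``; ``xmax`` unchanged). When
    ``expected_scheme`` is given, every object name must belong to it.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise AnnotationError(f"{path}: malformed XML: {exc}") from exc

    filename = root.findtext("filename") or path.stem
    size = root.find("size")
    if size is None:
        raise AnnotationError(f"{path}: missing <size>")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))

    objects: list[tuple[str, BoundingBox]] = []
    inferred_scheme: str | None = expected_scheme
    for i, obj in enumerate(root.iter("object")):
        name = obj.findtext("name")
        if name is None:
            raise AnnotationError(f"{path}: object {i} missing <name>")
        if expected_scheme is not None:
            if name not in scheme_labels(expected_scheme):
                raise AnnotationError(
                    f"{path}: object {i} label {name!r} not valid for scheme {expected_scheme}"
                )
        else:
            try:
                obj_scheme = scheme_of_label(name)
            except ValueError as exc:
                raise AnnotationError(f"{path}: object {i}: {exc}") from exc
            if inferred_scheme is None:
                inferred_scheme = obj_scheme
            elif inferred_scheme != obj_scheme:
                raise AnnotationError(
                    f"{path}: mixed schemes ({inferred_scheme} vs {obj_scheme})"
                )
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationError(f"{path}: object {i} missing <bndbox>")
        xmin = float(bnd.findtext("xmin")) - 1.0
        ymin = float(bnd.findtext("ymin")) - 1.0
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        if xmax <= xmin or ymax <= ymin:
            raise AnnotationError(
                f"{path}: object {i} degenerate box after conversion: "
                f"({xmin}, {ymin}, {xmax}, {ymax})"
            )
        objects.append((name, BoundingBox(xmin, ymin, xmax, ymax)))

    if inferred_scheme is None:
        # empty annotation with no scheme hint; default to S_R
        inferred_scheme = "S_R"
    return AnnotatedImage(
        image_id=Path(filename).stem,
        width=width,
        height=height,
        scheme=inferred_scheme,
        objects=objects,
    )


def write_voc_xml(ann: AnnotatedImage, path: str | Path) -> None:
    """Serialize to VOC XML (1-based inclusive coordinates).

    Refuses annotations that violate their invariants. ``read_voc_xml``
    applied to the output reproduces ``ann`` exactly.
    """
    violations = validate_annotation(ann)
    if violations:
        raise AnnotationError(f"refusing to write invalid annotation: {violations}")
    path = Path(path)
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = path.parent.name
    ET.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"
    for name, box in ann.objects:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = name
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = _fmt(box.xmin + 1.0)
        ET.SubElement(bnd, "ymin").text = _fmt(box.ymin + 1.0)
        ET.SubElement(bnd, "xmax").text = _fmt(box.xmax)
        ET.SubElement(bnd, "ymax").text = _fmt(box.ymax)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def _fmt(v: float) -> str:
    """Integers without a trailing .0 so files look like standard VOC."""
    return str(int(v)) if float(v).is_integer() else repr(v)
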