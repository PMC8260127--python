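"""Synthetic germination-bioassay disk images with exact ground truth.

Emulates the imaging conditions of a parasitic-seed (Striga/Orobanche type)
germination assay: a bright glass-fiber disk photographed top-down, bearing
50-100 dark ovoid seeds of which ~55% have germinated and show a thin,
bright, low-contrast radicle protruding from the seed coat. Radicles grow
to variable lengths and frequently cross neighbouring seeds and radicles,
which is the main difficulty of the counting task. Optional confusers
reproduce known failure modes of real assays: unlabeled plant debris, and a
small white seed-coat protuberance on non-germinated seeds that mimics a
freshly emerged radicle.

Ground truth is richer than either annotation scheme: the simulator knows
which radicle belongs to which seed, so both labelling schemes (and exact
per-disk germination fractions) derive from one :class:`DiskTruth`.

Every box is the tight axis-aligned box of the object's own rendered pixel
mask, so tightness is exact by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .annotations import AnnotatedImage, scheme_labels, write_voc_xml
from .boxes import BoundingBox, mask_to_box, union_box


@dataclass
class DiskSpec:
    """Parameters of one simulated disk.

    ``seed_axis_range`` bounds the ellipse semi-major axis in pixels (the
    semi-minor axis is drawn as 0.55-0.80 of it). ``radicle_contrast`` is
    the blending weight of the white radicle stroke against the disk: 0
    renders radicles invisible, 1 pure white. ``overlap_intensity`` shrinks
    the minimum seed-centre spacing towards heavy crowding as it approaches
    1. ``n_seeds=None`` draws the count uniformly in [50, 100] per disk.
    """

    image_size: tuple[int, int] = (512, 512)  # (width, height)
    n_seeds: int | None = None
    germination_fraction: float = 0.55
    exact_counts: bool = False
    seed_axis_range: tuple[float, float] = (9.0, 15.0)
    radicle_length_range: tuple[float, float] = (14.0, 42.0)
    radicle_width_range: tuple[float, float] = (2.0, 4.0)
    radicle_contrast: float = 0.5
    overlap_intensity: float = 0.3
    protuberance_probability: float = 0.0
    debris_count: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        w, h = self.image_size
        if w < 64 or h < 64:
            raise ValueError("image_size too small")
        for name in ("germination_fraction", "radicle_contrast", "overlap_intensity",
                     "protuberance_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("seed_axis_range", "radicle_length_range", "radicle_width_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a non-empty positive range, got ({lo}, {hi})")
        if self.debris_count < 0:
            raise ValueError("debris_count must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        for k in ("seed_axis_range", "radicle_length_range", "radicle_width_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DiskSpec":
        d = dict(d)
        for k in ("image_size", "seed_axis_range", "radicle_length_range",
                  "radicle_width_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SeedInstance:
    """One seed: ellipse geometry, germination state, and tight boxes."""

    center: tuple[float, float]  # (x, y)
    orientation: float  # radians, major-axis angle
    semi_axes: tuple[float, float]  # (major, minor)
    germinated: bool
    radicle_path: np.ndarray | None  # (P, 2) polyline (x, y) or None
    radicle_width: float
    protuberance: bool
    seed_box: BoundingBox
    radicle_box: BoundingBox | None


@dataclass
class DiskTruth:
    """Simulator ground truth: spec, seeds with paired radicles, debris."""

    spec: DiskSpec
    seeds: list[SeedInstance]
    debris: list[tuple[float, float, float]] = field(default_factory=list)  # (x, y, r)

    @property
    def n_germinated(self) -> int:
        return sum(s.germinated for s in self.seeds)

    @property
    def germinated_fraction(self) -> float:
        return self.n_germinated / len(self.seeds) if self.seeds else float("nan")


def seed_mask(inst: SeedInstance, shape: tuple[int, int]) -> np.ndarray:
    """Boolean pixel mask of the seed ellipse alone (rows, cols) = shape."""
    mask = np.zeros(shape, dtype=bool)
    cx, cy = inst.center
    a, b = inst.semi_axes
    # skimage rotates row/col ellipses counter-clockwise; orientation is the
    # major-axis angle in image (x right, y down) coordinates
    rr, cc = draw_ellipse(cy, cx, b, a, shape=shape, rotation=inst.orientation)
    mask[rr, cc] = True
    return mask


def radicle_mask(inst: SeedInstance, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the rendered radicle stroke; empty if not germinated."""
    mask = np.zeros(shape, dtype=bool)
    if inst.radicle_path is None:
        return mask
    r = max(inst.radicle_width / 2.0, 1.0)
    for x, y in inst.radicle_path:
        rr, cc = draw_disk((y, x), r, shape=shape)
        mask[rr, cc] = True
    return mask


def _protuberance_center(inst: SeedInstance) -> tuple[float, float]:
    cx, cy = inst.center
    a, _ = inst.semi_axes
    return (cx + a * np.cos(inst.orientation), cy + a * np.sin(inst.orientation))


def _sample_radicle_path(
    rng: np.random.Generator,
    inst_center: tuple[float, float],
    orientation: float,
    semi_major: float,
    length: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Cubic Bezier polyline leaving one pole of the seed ellipse."""
    sign = 1.0 if rng.random() < 0.5 else -1.0
    ux, uy = sign * np.cos(orientation), sign * np.sin(orientation)
    nx, ny = -uy, ux
    cx, cy = inst_center
    p0 = np.array([cx + semi_major * ux * 0.98, cy + semi_major * uy * 0.98])
    bend = rng.uniform(-0.35, 0.35, size=3).cumsum() * length
    ctrl = [
        p0,
        p0 + np.array([ux, uy]) * length * 0.35 + np.array([nx, ny]) * bend[0] * 0.3,
        p0 + np.array([ux, uy]) * length * 0.70 + np.array([nx, ny]) * bend[1] * 0.5,
        p0 + np.array([ux, uy]) * length * 1.00 + np.array([nx, ny]) * bend[2] * 0.6,
    ]
    t = np.linspace(0.0, 1.0, max(int(2 * length), 8))[:, None]
    b = (
        (1 - t) ** 3 * ctrl[0]
        + 3 * (1 - t) ** 2 * t * ctrl[1]
        + 3 * (1 - t) * t**2 * ctrl[2]
        + t**3 * ctrl[3]
    )
    h, w = shape
    b[:, 0] = np.clip(b[:, 0], 1.0, w - 2.0)
    b[:, 1] = np.clip(b[:, 1], 1.0, h - 2.0)
    return b


def sample_disk(spec: DiskSpec) -> DiskTruth:
    """Draw one disk layout; deterministic given ``spec.rng_seed``.

    Seed centres are rejection-sampled inside the disk with a minimum
    pairwise distance that shrinks as ``overlap_intensity`` approaches 1.
    Raises ``RuntimeError`` when the requested count cannot be packed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    w, h = spec.image_size
    shape = (h, w)
    disk_cx, disk_cy = w / 2.0, h / 2.0
    disk_r = 0.47 * min(w, h)

    n_seeds = int(spec.n_seeds) if spec.n_seeds is not None else int(rng.integers(50, 101))

    lo, hi = spec.seed_axis_range
    mean_major = (lo + hi) / 2.0
    min_dist = (1.9 * mean_major) * (1.0 - spec.overlap_intensity) + 4.0 * spec.overlap_intensity

    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 400 * n_seeds
    while len(centers) < n_seeds:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"infeasible packing: placed {len(centers)}/{n_seeds} seeds "
                f"after {max_attempts} attempts (image {w}x{h}, min spacing {min_dist:.1f})"
            )
        r = disk_r * 0.92 * np.sqrt(rng.random())
        phi = rng.uniform(0, 2 * np.pi)
        x, y = disk_cx + r * np.cos(phi), disk_cy + r * np.sin(phi)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_dist**2 for px, py in centers):
            centers.append((x, y))

    if spec.exact_counts:
        n_germ = int(round(n_seeds * spec.germination_fraction))
        germ_flags = np.zeros(n_seeds, dtype=bool)
        germ_flags[rng.permutation(n_seeds)[:n_germ]] = True
    else:
        germ_flags = rng.random(n_seeds) < spec.germination_fraction

    seeds: list[SeedInstance] = []
    for (x, y), germ in zip(centers, germ_flags):
        a = rng.uniform(lo, hi)
        b = a * rng.uniform(0.55, 0.80)
        theta = rng.uniform(0, np.pi)
        path = None
        width = float(rng.uniform(*spec.radicle_width_range))
        if germ:
            length = rng.uniform(*spec.radicle_length_range)
            path = _sample_radicle_path(rng, (x, y), theta, a, length, shape)
        prot = (not germ) and (rng.random() < spec.protuberance_probability)
        inst = SeedInstance(
            center=(x, y),
            orientation=theta,
            semi_axes=(a, b),
            germinated=bool(germ),
            radicle_path=path,
            radicle_width=width,
            protuberance=prot,
            seed_box=BoundingBox(0, 0, 1, 1),  # placeholder, set below
            radicle_box=None,
        )
        sbox = mask_to_box(seed_mask(inst, shape))
        rbox = mask_to_box(radicle_mask(inst, shape)) if germ else None
        inst.seed_box = sbox
        inst.radicle_box = rbox
        seeds.append(inst)

    debris = []
    for _ in range(spec.debris_count):
        r = disk_r * 0.9 * np.sqrt(rng.random())
        phi = rng.uniform(0, 2 * np.pi)
        debris.append((disk_cx + r * np.cos(phi), disk_cy + r * np.sin(phi),
                       float(rng.uniform(2.0, 6.0))))

    return DiskTruth(spec=spec, seeds=seeds, debris=debris)


def render_disk(truth: DiskTruth) -> np.ndarray:
    """Render an 8-bit RGB image; a pure function of the truth.

    Bright circular glass-fiber disk on a neutral background, dark textured
    seed ellipses, thin bright radicle strokes alpha-blended with weight
    ``radicle_contrast`` (0 leaves the disk pixels untouched), bright
    protuberance nubs, gray debris blobs.
    """
    spec = truth.spec
    w, h = spec.image_size
    shape = (h, w)
    rng = np.random.default_rng(np.uint32(spec.rng_seed) ^ np.uint32(0x5EED))

    img = np.full((h, w, 3), 0.45, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    disk_r = 0.47 * min(w, h)
    disk = (xx - w / 2.0) ** 2 + (yy - h / 2.0) ** 2 <= disk_r**2
    fiber = 0.82 + 0.035 * rng.standard_normal(shape)
    for c in range(3):
        img[..., c][disk] = fiber[disk]

    for x, y, r in truth.debris:
        rr, cc = draw_disk((y, x), r, shape=shape)
        img[rr, cc] = (0.52, 0.50, 0.46)

    seed_color = np.array([0.26, 0.19, 0.13])
    for inst in truth.seeds:
        m = seed_mask(inst, shape)
        tex = 0.05 * rng.standard_normal(int(m.sum()))
        for c in range(3):
            img[..., c][m] = seed_color[c] + tex

    alpha = spec.radicle_contrast
    radicle_color = np.array([0.99, 0.98, 0.94])
    if alpha > 0:
        for inst in truth.seeds:
            if inst.radicle_path is None:
                continue
            m = radicle_mask(inst, shape)
            for c in range(3):
                img[..., c][m] = (1 - alpha) * img[..., c][m] + alpha * radicle_color[c]

    for inst in truth.seeds:
        if inst.protuberance:
            px, py = _protuberance_center(inst)
            rr, cc = draw_disk((py, px), 2.5, shape=shape)
            img[rr, cc] = 0.2 * img[rr, cc] + 0.8 * radicle_color

    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def truth_to_annotation(truth: DiskTruth, scheme: str, image_id: str = "disk") -> AnnotatedImage:
    """Project the paired ground truth onto one of the two labelling schemes.

    ``S_R``: one ``S`` box per seed plus one ``R`` box per radicle.
    ``NGS_GS``: ``NGS`` = seed box for non-germinated seeds; ``GS`` = union
    of seed and radicle boxes for germinated ones.
    """
    scheme_labels(scheme)
    w, h = truth.spec.image_size
    objects: list[tuple[str, BoundingBox]] = []
    if scheme == "S_R":
        for inst in truth.seeds:
            objects.append(("S", inst.seed_box))
        for inst in truth.seeds:
            if inst.radicle_box is not None:
                objects.append(("R", inst.radicle_box))
    else:
        for inst in truth.seeds:
            if inst.germinated:
                objects.append(("GS", union_box(inst.seed_box, inst.radicle_box)))
            else:
                objects.append(("NGS", inst.seed_box))
    return AnnotatedImage(image_id=image_id, width=w, height=h, scheme=scheme, objects=objects)


@dataclass
class DatasetManifest:
    """Train/val/test membership of a generated dataset rooted at ``root``."""

    root: Path
    entries: list[tuple[str, str]]  # (image_id, split)

    def ids(self, split: str | None = None) -> list[str]:
        return [i for i, s in self.entries if split is None or s == split]

    def image_path(self, image_id: str) -> Path:
        return self.root / "images" / f"{image_id}.png"

    def xml_path(self, image_id: str) -> Path:
        return self.root / "annotations" / f"{image_id}.xml"

    def save(self, path: Path | None = None) -> Path:
        path = path or self.root / "manifest.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_id", "split"])
            writer.writerows(self.entries)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if rows and rows[0] == ["image_id", "split"]:
            rows = rows[1:]
        return cls(root=path.parent, entries=[(r[0], r[1]) for r in rows if r])


def split_indices(n_images: int) -> list[str]:
    """60/20/20 train/validation/test membership by image index."""
    n_train = int(round(0.6 * n_images))
    n_val = int(round(0.2 * n_images))
    return ["train"] * n_train + ["val"] * n_val + ["test"] * (n_images - n_train - n_val)


def generate_dataset(
    spec: DiskSpec, n_images: int, scheme: str, out_dir: str | Path
) -> DatasetManifest:
    """Write ``n_images`` disks (PNG + VOC XML) plus a split manifest.

    Image ``i`` uses ``rng_seed = spec.rng_seed + i`` so the dataset is
    fully reproducible; the resolved spec is echoed to ``spec.yaml``.
    """
    scheme_labels(scheme)
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    splits = split_indices(n_images)
    entries = []
    for i in range(n_images):
        sub = DiskSpec.from_dict({**spec.to_dict(), "rng_seed": spec.rng_seed + i})
        truth = sample_disk(sub)
        image_id = f"disk_{i:04d}"
        iio.imwrite(out_dir / "images" / f"{image_id}.png", render_disk(truth))
        ann = truth_to_annotation(truth, scheme, image_id=image_id)
        write_voc_xml(ann, out_dir / "annotations" / f"{image_id}.xml")
        entries.append((image_id, splits[i]))
    with open(out_dir / "spec.yaml", "w") as fh:
        yaml.safe_dump({**spec.to_dict(), "scheme": scheme, "n_images": n_images}, fh,
                       sort_keys=True)
    manifest = DatasetManifest(root=out_dir, entries=entries)
    manifest.save()
    return manifest
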