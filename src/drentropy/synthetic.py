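"""Synthetic fundus-like image generation.

Real severity-graded retinal photographs are large and access-controlled, so
the package ships a generator that emulates the statistical structure the
downstream features measure: five classes whose gray-level texture
randomness — and hence histogram entropy — differs by a controllable effect
size.  Each image is a dark circular "fundus" disc containing a smooth
illumination gradient, a few bright curvilinear vessel-like strokes,
class-dependent bright/dark lesion speckle, and Gaussian texture noise whose
standard deviation is the main entropy dial.  Pixels outside the disc stay
at a constant low value, mimicking the black border of a fundus photograph.

The generator makes no attempt at photorealism (no optic disc, macula or
color pathology): class separation is carried entirely by histogram texture,
which is exactly what the entropy features quantify.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_ops import round_half_away

__all__ = [
    "ClassParams",
    "SyntheticConfig",
    "LabeledImageSet",
    "DEFAULT_CLASSES",
    "generate_dataset",
    "inject_duplicates",
    "save_dataset",
    "load_dataset",
]

#: Canonical severity labels, mildest to most severe lesion load.
SEVERITY_LABELS = ("NoDR", "mild", "moderate", "proliferate", "severe")


@dataclass(frozen=True)
class ClassParams:
    """Texture parameters of one image class.

    lesion_density is the expected number of speckle blobs per pixel of
    image area; noise_sigma is the gray-level standard deviation of the
    additive texture noise (the dominant driver of histogram entropy);
    vessel_count is the number of curvilinear bright strokes drawn.
    """

    label: str
    lesion_density: float = 0.0
    noise_sigma: float = 8.0
    vessel_count: int = 6

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lesion_density) and self.lesion_density >= 0):
            raise ValueError("lesion_density must be finite and >= 0")
        if not (math.isfinite(self.noise_sigma) and self.noise_sigma >= 0):
            raise ValueError("noise_sigma must be finite and >= 0")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")


#: Default study conditions: entropy rises with severity through noise_sigma,
#: lesion load rises through lesion_density.  Illustrative, not calibrated to
#: any real dataset (no per-class texture statistics are published for one).
DEFAULT_CLASSES = (
    ClassParams("NoDR", lesion_density=0.0, noise_sigma=6.0, vessel_count=6),
    ClassParams("mild", lesion_density=2e-4, noise_sigma=10.0, vessel_count=6),
    ClassParams("moderate", lesion_density=5e-4, noise_sigma=14.0, vessel_count=6),
    ClassParams("proliferate", lesion_density=9e-4, noise_sigma=18.0, vessel_count=8),
    ClassParams("severe", lesion_density=1.4e-3, noise_sigma=24.0, vessel_count=8),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic image set."""

    image_size: tuple[int, int] = (64, 64)
    classes: tuple[ClassParams, ...] = DEFAULT_CLASSES
    n_per_class: int = 50
    seed: int = 0
    n_duplicates: int = 0
    levels: int = 256

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.n_duplicates < 0:
            raise ValueError("n_duplicates must be >= 0")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("class labels must be unique")


@dataclass
class LabeledImageSet:
    """Parallel lists of images, class labels and provenance records.

    provenance[i] is "generated" for a fresh image or the integer index of
    the earlier image that image i is a pixel-exact copy of.
    """

    images: list[np.ndarray]
    labels: list[str]
    provenance: list[object] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if not self.provenance:
            self.provenance = ["generated"] * len(self.images)
        if len(self.provenance) != len(self.images):
            raise ValueError("provenance must parallel images")
        for i, p in enumerate(self.provenance):
            if isinstance(p, (int, np.integer)):
                if not 0 <= p < i:
                    raise ValueError(f"duplicate-of index {p} at {i} is not earlier")
                if not np.array_equal(self.images[i], self.images[p]):
                    raise ValueError(f"image {i} is not pixel-identical to source {p}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_duplicates(self) -> int:
        return sum(isinstance(p, (int, np.integer)) for p in self.provenance)


def _disc_mask(h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = 0.47 * min(h, w)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _render_image(
    params: ClassParams, size: tuple[int, int], levels: int, rng: np.random.Generator
) -> np.ndarray:
    h, w = size
    mask = _disc_mask(h, w)
    yy, xx = np.mgrid[0:h, 0:w]

    # smooth illumination gradient across the disc
    theta = rng.uniform(0, 2 * np.pi)
    base = 90.0 + 30.0 * (
        np.cos(theta) * (xx / w - 0.5) + np.sin(theta) * (yy / h - 0.5)
    )

    img = base.copy()

    # vessel-like curvilinear bright strokes: biased random walks
    for _ in range(params.vessel_count):
        y = rng.uniform(0.25 * h, 0.75 * h)
        x = rng.uniform(0.25 * w, 0.75 * w)
        ang = rng.uniform(0, 2 * np.pi)
        steps = int(0.9 * max(h, w))
        for _ in range(steps):
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < h and 0 <= ix < w:
                img[max(0, iy - 1): iy + 1, max(0, ix - 1): ix + 1] += 45.0
            ang += rng.normal(0.0, 0.25)
            y += np.sin(ang)
            x += np.cos(ang)

    # lesion speckle: Poisson number of small bright/dark blobs
    n_lesions = rng.poisson(params.lesion_density * h * w)
    for _ in range(n_lesions):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        radius = rng.uniform(1.0, 3.0)
        amp = rng.choice([-60.0, 80.0])
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img += amp * np.exp(-d2 / (2 * radius**2))

    img += rng.normal(0.0, params.noise_sigma, size=(h, w))

    out = np.clip(round_half_away(img), 0, levels - 1)
    out[~mask] = 2  # constant dark border outside the fundus disc
    return out.astype(np.uint8 if levels <= 256 else np.int64)


def generate_dataset(config: SyntheticConfig) -> LabeledImageSet:
    """Generate ``n_per_class`` images for each configured class.

    Deterministic given ``config.seed``: one global RNG stream drives the
    whole call, so equal configs produce byte-identical image sets.
    """
    rng = np.random.default_rng(config.seed)
    images: list[np.ndarray] = []
    labels: list[str] = []
    for cls in config.classes:
        for _ in range(config.n_per_class):
            images.append(_render_image(cls, config.image_size, config.levels, rng))
            labels.append(cls.label)
    out = LabeledImageSet(images=images, labels=labels)
    if config.n_duplicates:
        out = inject_duplicates(out, config.n_duplicates, seed=config.seed + 1)
    return out


def inject_duplicates(image_set: LabeledImageSet, k: int, seed: int) -> LabeledImageSet:
    """Append k exact pixel copies of images chosen uniformly without replacement.

    Each copy keeps its source's label and records the source index in its
    provenance, providing ground truth for duplicate-removal tests.
    """
    n = len(image_set)
    if k > n:
        raise ValueError(f"cannot duplicate {k} of {n} images")
    if k == 0:
        return LabeledImageSet(
            images=list(image_set.images),
            labels=list(image_set.labels),
            provenance=list(image_set.provenance),
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False)
    images = list(image_set.images)
    labels = list(image_set.labels)
    prov = list(image_set.provenance)
    for src in chosen:
        images.append(image_set.images[int(src)].copy())
        labels.append(image_set.labels[int(src)])
        prov.append(int(src))
    return LabeledImageSet(images=images, labels=labels, provenance=prov)


def save_dataset(image_set: LabeledImageSet, out_dir: str | Path) -> Path:
    """Write 8-bit grayscale PNGs into per-class subdirectories plus a manifest.

    Layout: ``<out>/<label>/img_<idx>.png`` and ``<out>/manifest.csv`` with
    columns ``filename,label,provenance``.
    """
    from PIL import Image as PILImage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "provenance"])
        for idx, (img, label, prov) in enumerate(
            zip(image_set.images, image_set.labels, image_set.provenance)
        ):
            cls_dir = out_dir / label
            cls_dir.mkdir(exist_ok=True)
            fname = f"{label}/img_{idx:05d}.png"
            PILImage.fromarray(img.astype(np.uint8), mode="L").save(out_dir / fname)
            writer.writerow([fname, label, prov])
    return manifest


def load_dataset(in_dir: str | Path) -> LabeledImageSet:
    """Read a dataset written by :func:`save_dataset` (or any manifest dir)."""
    from PIL import Image as PILImage

    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.csv"
    images: list[np.ndarray] = []
    labels: list[str] = []
    prov: list[object] = []
    if manifest.exists():
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                images.append(np.asarray(PILImage.open(in_dir / row["filename"]).convert("L")))
                labels.append(row["label"])
                p = row["provenance"]
                prov.append(int(p) if p.isdigit() else p)
        return LabeledImageSet(images=images, labels=labels, provenance=prov)
    # fall back to per-class subdirectories of PNG/JPEG files
    for cls_dir in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        for f in sorted(cls_dir.iterdir()):
            if f.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                images.append(np.asarray(PILImage.open(f).convert("L")))
                labels.append(cls_dir.name)
    return LabeledImageSet(images=images, labels=labels)
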