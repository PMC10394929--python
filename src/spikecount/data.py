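"""Dataset pipeline: annotation conversion, normalization, augmentation, splits.

Images are RGB photographs of single wheat-ear sides; labels are two-class
rasters (0 = background, 1 = grain) converted from polygon annotations in the
Labelme JSON dialect (``shapes[].points`` as [x, y] float pairs).  All images
and masks are normalized to a square working size (default 480) before
augmentation; masks are resampled with nearest-neighbor so the label set stays
categorical.  Pixel indexing is row-major with the origin at the top-left; a
pixel (r, c) has its center at (x, y) = (c + 0.5, r + 0.5) in annotation
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import measure

__all__ = [
    "AnnotationError",
    "RawEarImage",
    "GrainMask",
    "AnnotatedSample",
    "DatasetSplit",
    "AugmentationSpec",
    "load_polygon_annotation",
    "normalize_size",
    "augment",
    "split_dataset",
    "kfold_splits",
    "blur_sigma",
    "read_image",
    "read_mask",
    "write_mask",
    "write_split_manifest",
]


class AnnotationError(ValueError):
    pass


@dataclass
class RawEarImage:
    """RGB photograph of one wheat-ear side, with acquisition metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8, channel order R,G,B
    variety: str = ""
    treatment: str = ""
    background: str = ""  # "field" | "white"
    side: str = "A"  # "A" | "B"
    device: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be HxWx3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")


@dataclass
class GrainMask:
    """Two-class label raster: 0 = background, 1 = grain."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be HxW")
        if not np.all(np.isin(np.unique(self.labels), (0, 1))):
            raise ValueError("mask values must be 0 or 1")


@dataclass
class AnnotatedSample:
    image: RawEarImage
    mask: GrainMask
    manual_counts: tuple | None = None

    def __post_init__(self):
        if self.image.pixels.shape[:2] != self.mask.labels.shape:
            raise ValueError("image and mask dimensions must match")


@dataclass
class DatasetSplit:
    train_ids: list
    test_ids: list
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids must be disjoint")


@dataclass
class AugmentationSpec:
    """Independent single transforms: rotations, flips, and image-only blur."""

    rotations: tuple = (90, 180, 270)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    gaussian_blur_kernel: int = 5

    def __post_init__(self):
        bad = set(self.rotations) - {90, 180, 270}
        if bad:
            raise ValueError(f"unsupported rotations: {sorted(bad)}")
        k = self.gaussian_blur_kernel
        if k is not None and (k < 1 or k % 2 == 0):
            raise ValueError("gaussian_blur_kernel must be odd and >= 1")


def blur_sigma(kernel: int) -> float:
    """Gaussian sigma from kernel size, 0.3*((k-1)/2 - 1) + 0.8."""
    return 0.3 * ((kernel - 1) / 2.0 - 1.0) + 0.8


def load_polygon_annotation(json_doc, height: int, width: int,
                            grain_labels=("grain",)) -> GrainMask:
    """Rasterize a polygon-annotation document into a grain mask.

    ``json_doc`` may be a dict already parsed, a JSON string, or a path.
    Pixels whose centers fall inside any polygon whose label is in
    ``grain_labels`` are set to 1; overlapping polygons rasterize to their
    union.
    """
    if isinstance(json_doc, (str, Path)) and Path(str(json_doc)).exists():
        with open(json_doc) as fh:
            doc = json.load(fh)
    elif isinstance(json_doc, str):
        try:
            doc = json.loads(json_doc)
        except json.JSONDecodeError as e:
            raise AnnotationError(f"malformed annotation document: {e}") from e
    elif isinstance(json_doc, dict):
        doc = json_doc
    else:
        raise AnnotationError(f"unsupported annotation input {type(json_doc)!r}")
    shapes = doc.get("shapes", [])
    mask = np.zeros((height, width), dtype=np.uint8)
    for i, shape in enumerate(shapes):
        if not isinstance(shape, dict) or "points" not in shape:
            raise AnnotationError(f"shape {i} is malformed (no points)")
        if shape.get("label", "grain") not in grain_labels:
            continue
        pts = np.asarray(shape["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise AnnotationError(f"shape {i} ({shape.get('label')!r}): bad point list")
        if len(pts) < 3:
            raise AnnotationError(
                f"shape {i} ({shape.get('label')!r}): polygon needs >= 3 vertices"
            )
        # bounding box of candidate pixels, then exact point-in-polygon test
        c0 = max(int(np.floor(pts[:, 0].min() - 0.5)), 0)
        c1 = min(int(np.ceil(pts[:, 0].max() + 0.5)), width - 1)
        r0 = max(int(np.floor(pts[:, 1].min() - 0.5)), 0)
        r1 = min(int(np.ceil(pts[:, 1].max() + 0.5)), height - 1)
        if c1 < c0 or r1 < r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        centers = np.stack([cols.ravel() + 0.5, rows.ravel() + 0.5], axis=1)
        inside = measure.points_in_poly(centers, pts)
        mask[rows.ravel()[inside], cols.ravel()[inside]] = 1
    return GrainMask(mask)


def normalize_size(image: RawEarImage, mask: GrainMask | None = None,
                   target_edge: int = 480):
    """Resize to a square working size (bilinear image, nearest-neighbor mask)."""
    if target_edge < 1:
        raise ValueError("target_edge must be >= 1")
    h, w = image.pixels.shape[:2]
    if (h, w) == (target_edge, target_edge):
        out_img = image
        out_mask = mask
    else:
        pil = Image.fromarray(image.pixels)
        resized = np.asarray(pil.resize((target_edge, target_edge), Image.BILINEAR))
        out_img = RawEarImage(resized, image.variety, image.treatment,
                              image.background, image.side, image.device)
        out_mask = None
        if mask is not None:
            pil_m = Image.fromarray(mask.labels.astype(np.uint8))
            out_mask = GrainMask(
                np.asarray(pil_m.resize((target_edge, target_edge), Image.NEAREST))
            )
    return out_img if mask is None else (out_img, out_mask)


def _transformed(sample: AnnotatedSample, fn) -> AnnotatedSample:
    img = fn(sample.image.pixels)
    msk = fn(sample.mask.labels)
    im = sample.image
    return AnnotatedSample(
        RawEarImage(np.ascontiguousarray(img), im.variety, im.treatment,
                    im.background, im.side, im.device),
        GrainMask(np.ascontiguousarray(msk)),
        sample.manual_counts,
    )


def augment(sample: AnnotatedSample, spec: AugmentationSpec,
            seed: int = 0) -> list[AnnotatedSample]:
    """Expand one sample into [original] + independent single transforms.

    Geometric transforms are applied identically to image and mask; the
    Gaussian blur touches the image only.  The transform list is deterministic
    (``seed`` is accepted for interface uniformity).
    """
    h, w = sample.image.pixels.shape[:2]
    if h != w and any(r in (90, 270) for r in spec.rotations):
        raise ValueError("90/270 degree rotations require a square sample")
    out = [sample]
    for rot in spec.rotations:
        k = rot // 90
        out.append(_transformed(sample, lambda a, k=k: np.rot90(a, k=k, axes=(0, 1))))
    if spec.horizontal_flip:
        out.append(_transformed(sample, lambda a: a[:, ::-1]))
    if spec.vertical_flip:
        out.append(_transformed(sample, lambda a: a[::-1]))
    if spec.gaussian_blur_kernel:
        k = spec.gaussian_blur_kernel
        sigma = blur_sigma(k)
        radius = (k - 1) / 2.0
        blurred = np.stack(
            [
                ndimage.gaussian_filter(
                    sample.image.pixels[..., c].astype(float),
                    sigma=sigma,
                    truncate=max(radius, 1e-9) / sigma,
                )
                for c in range(3)
            ],
            axis=2,
        )
        im = sample.image
        out.append(
            AnnotatedSample(
                RawEarImage(np.clip(np.rint(blurred), 0, 255).astype(np.uint8),
                            im.variety, im.treatment, im.background, im.side,
                            im.device),
                GrainMask(sample.mask.labels.copy()),
                sample.manual_counts,
            )
        )
    return out


def split_dataset(sample_ids, train_fraction: float = 0.9, seed: int = 0) -> DatasetSplit:
    """Shuffle ids by ``seed`` and split; train size = round(fraction * n)."""
    ids = list(sample_ids)
    if not ids:
        raise ValueError("sample_ids must be non-empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids) + 0.5))
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return DatasetSplit(train_ids=train, test_ids=test, seed=seed)


def kfold_splits(sample_ids, k: int = 10, seed: int = 0) -> list[DatasetSplit]:
    """k folds with pairwise-disjoint test sets covering all ids; sizes differ <= 1."""
    ids = list(sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2 (a single fold has no training set)")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of samples ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, k)
    folds = []
    for chunk in chunks:
        test = [ids[i] for i in chunk]
        test_set = set(chunk.tolist())
        train = [ids[i] for i in order if i not in test_set]
        folds.append(DatasetSplit(train_ids=train, test_ids=test, seed=seed))
    return folds


# -- small I/O helpers ------------------------------------------------------

def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def read_mask(path) -> np.ndarray:
    """Read a mask PNG with values {0, 255} into internal labels {0, 1}."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def write_mask(path, labels: np.ndarray) -> None:
    Image.fromarray((np.asarray(labels) * 255).astype(np.uint8)).save(path)


def write_split_manifest(path, splits) -> None:
    """CSV manifest (id, partition, fold) for one split or a list of folds."""
    if isinstance(splits, DatasetSplit):
        splits = [splits]
    rows = []
    for fold, sp in enumerate(splits):
        rows += [{"id": i, "partition": "train", "fold": fold} for i in sp.train_ids]
        rows += [{"id": i, "partition": "test", "fold": fold} for i in sp.test_ids]
    pd.DataFrame(rows).to_csv(path, index=False)
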