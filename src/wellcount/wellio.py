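"""Dataset model and image conditioning for well images.

Plates of 3984 wells are the unit of data management ("subsets"); samples are
single 8-bit grayscale well frames.  Conditioning is deliberately minimal,
matching how the counting network consumes raw wells: a per-image min-max
rescale to [0, 255] that cancels illumination offsets between acquisitions,
and a light geometric augmentation (mirror or 90/180/270-degree rotation in
about 20% of training draws).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .synth import CATEGORY_LABELS, read_manifest


@dataclass
class WellImage:
    """One well frame plus provenance and (optionally) its true category.

    ``category`` is the integer code 0..3 (3 = more than two cells) or None
    when unknown.
    """

    pixels: np.ndarray
    plate_id: str = ""
    well_index: int = -1
    well_id: str = ""
    time_index: Optional[int] = None
    category: Optional[int] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"well image must be square 2-D, got shape {p.shape}")
        if p.size == 0:
            raise ValueError("well image is empty")
        if float(p.min()) < 0 or float(p.max()) > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if self.category is not None and self.category not in range(len(CATEGORY_LABELS)):
            raise ValueError(f"invalid category code {self.category}")
        self.pixels = p


@dataclass(frozen=True)
class SubsetPartition:
    """Assignment of plates (subsets) to training / validation / test roles.

    The reference protocol uses 24 training, 4 validation and 2 test plates;
    any disjoint assignment is accepted.
    """

    train_subsets: Tuple[str, ...]
    validation_subsets: Tuple[str, ...] = ()
    test_subsets: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        groups = (set(self.train_subsets), set(self.validation_subsets), set(self.test_subsets))
        if groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2]:
            raise ValueError("train/validation/test subset lists must be disjoint")
        if not self.train_subsets:
            raise ValueError("train_subsets must be non-empty")


def normalize_image(image, per_image: bool = True):
    """Min-max rescale so the minimum maps to 0 and the maximum to 255.

    Accepts a :class:`WellImage` (returns a new one, pixels float32) or a bare
    array.  A constant image has no contrast to recover and maps to all
    zeros.  Idempotent: an image already spanning [0, 255] is unchanged.
    The ``per_image`` flag exists for symmetry with batch-level callers; the
    rescale itself is always computed from the given image's own extrema.
    """
    if isinstance(image, WellImage):
        out = normalize_image(image.pixels)
        return replace(image, pixels=out)
    p = np.asarray(image, dtype=np.float32)
    lo, hi = float(p.min()), float(p.max())
    if hi == lo:
        return np.zeros_like(p)
    return (p - lo) * (255.0 / (hi - lo))


#: the four augmentation transforms: mirror flip then the three rotations
_TRANSFORMS = ("mirror", "rot90", "rot180", "rot270")


def apply_transform(pixels: np.ndarray, name: str, invert: str = "mirror") -> np.ndarray:
    """Apply one named transform.  Rotations are counter-clockwise.

    ``invert`` selects the reading of the "inverted" augmentation: a mirror
    (left-right) reflection, or photometric inversion 255 - p.
    """
    if name == "mirror":
        if invert == "intensity":
            return 255.0 - np.asarray(pixels)
        return pixels[:, ::-1]
    if name == "rot90":
        return np.rot90(pixels, 1)
    if name == "rot180":
        return np.rot90(pixels, 2)
    if name == "rot270":
        return np.rot90(pixels, 3)
    raise ValueError(f"unknown transform {name!r}")


def augment_image(image, rng: np.random.Generator, transform_prob: float = 0.2,
                  invert: str = "mirror"):
    """With probability ``transform_prob`` apply one of the four transforms.

    The transform is drawn uniformly from {mirror, rot90, rot180, rot270};
    otherwise the image is returned unchanged.  Labels are untouched: every
    transform permutes pixels (or, with ``invert="intensity"``, remaps
    intensities) without changing the cell count.
    """
    if not 0.0 <= transform_prob <= 1.0:
        raise ValueError("transform_prob must lie in [0, 1]")
    if isinstance(image, WellImage):
        return replace(image, pixels=augment_image(image.pixels, rng, transform_prob, invert))
    if rng.random() >= transform_prob:
        return image
    name = _TRANSFORMS[rng.integers(len(_TRANSFORMS))]
    return np.ascontiguousarray(apply_transform(image, name, invert=invert))


def load_dataset(manifest_paths: Sequence, image_side: Optional[int] = None
                 ) -> Dict[str, List[WellImage]]:
    """Load plates from manifest TSVs (one per plate) and their PNG images.

    Returns ``{plate_id: [WellImage, ...]}`` in manifest order.  Any missing
    file, malformed row, non-square or non-8-bit image is reported with the
    offending record.
    """
    from PIL import Image

    plates: Dict[str, List[WellImage]] = {}
    for path in manifest_paths:
        path = Path(path)
        manifest = read_manifest(path)
        base = path.parent
        wells: List[WellImage] = []
        for i, row in manifest.records.iterrows():
            img_path = base / row["filename"]
            if not img_path.exists():
                raise FileNotFoundError(
                    f"{path} row {i} ({row['well_id']}): image file {img_path} not found"
                )
            with Image.open(img_path) as im:
                if im.mode != "L":
                    raise ValueError(
                        f"{path} row {i} ({row['well_id']}): image is {im.mode}, expected "
                        "8-bit grayscale"
                    )
                pixels = np.asarray(im)
            if pixels.shape[0] != pixels.shape[1]:
                raise ValueError(
                    f"{path} row {i} ({row['well_id']}): image is {pixels.shape}, not square"
                )
            if image_side is not None and pixels.shape[0] != image_side:
                raise ValueError(
                    f"{path} row {i} ({row['well_id']}): image side {pixels.shape[0]} != "
                    f"expected {image_side}"
                )
            wells.append(
                WellImage(
                    pixels=pixels,
                    plate_id=manifest.plate_id,
                    well_index=i,
                    well_id=row["well_id"],
                    category=CATEGORY_LABELS.index(row["category"]),
                )
            )
        plates[manifest.plate_id] = wells
    return plates


def plates_from_manifest(manifest) -> List[WellImage]:
    """Wrap an in-memory :class:`~wellcount.synth.PlateManifest` (with images)."""
    if manifest.images is None:
        raise ValueError("manifest has no in-memory images; use load_dataset on files")
    wells = []
    for i, row in manifest.records.iterrows():
        wells.append(
            WellImage(
                pixels=manifest.images[i],
                plate_id=manifest.plate_id,
                well_index=i,
                well_id=row["well_id"],
                category=CATEGORY_LABELS.index(row["category"]),
            )
        )
    return wells
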