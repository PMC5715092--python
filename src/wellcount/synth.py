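"""Synthetic nanoliter-well plates with known per-well cell counts.

Real plates image each well as one 8-bit grayscale frame (natively 511x511
pixels, 3984 wells per plate) and cells are loaded at a Poisson-like
occupancy with mean around 0.2 cells/well, with a mild excess of multi-cell
wells attributed to cell division and adhesion.  This module draws labeled
images with that statistical structure so the classifier, the triage logic
and the evaluation statistics can all be exercised end to end without any
microscope data: bright roughly circular cells inside a square or round well
wall, per-image illumination offsets (the reason the pipeline min-max
normalizes), plus occasional debris blobs and defocus blur — the two failure
modes that make real wells hard to call.

Everything is a pure function of its inputs and the supplied seed; a plate
generated twice from the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

#: category codes: index 0..3 <-> labels "0", "1", "2", "gt2"
CATEGORY_LABELS: Tuple[str, ...] = ("0", "1", "2", "gt2")
MANIFEST_COLUMNS = ("well_id", "filename", "count", "category", "debris", "defocus")


def count_to_category(count: int) -> int:
    """Clip a cell count into the four-way category code (3 means >2)."""
    if count < 0:
        raise ValueError("cell count must be non-negative")
    return min(int(count), 3)


@dataclass(frozen=True)
class WellGeometry:
    """Shape and intensity of the empty well.

    ``wall_thickness`` and the cell radii below are expressed at the native
    511-pixel scale and rescaled proportionally for smaller images, so a
    64-pixel well looks like a shrunken 511-pixel one.
    """

    shape: str = "square"  # "square" | "round"
    image_side: int = 511
    wall_thickness: int = 8
    wall_intensity: int = 40
    background_intensity: int = 96

    def __post_init__(self) -> None:
        if self.shape not in ("square", "round"):
            raise ValueError(f"unknown well shape {self.shape!r}")
        if self.image_side < 64:
            raise ValueError("image_side must be >= 64")
        for name in ("wall_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.wall_thickness < 1 or 2 * self.scale(self.wall_thickness) >= self.image_side // 2:
            raise ValueError("wall does not fit inside the image")

    def scale(self, pixels_at_511: float) -> float:
        return pixels_at_511 * self.image_side / 511.0


@dataclass(frozen=True)
class OccupancyModel:
    """Cells per well: Poisson(lambda) with an adhesion/division excess.

    A draw ``k ~ Poisson(lambda)`` is incremented by one with probability
    ``cluster_excess`` when ``k > 0``, shifting mass from each nonzero count
    to the next — the simplest mechanism that reproduces the observed excess
    of multi-cell wells over the Poisson expectation.  ``max_render`` caps how
    many cells are physically drawn (wells beyond the cap are all labeled
    ``gt2`` anyway).
    """

    lam: float = 0.2
    cluster_excess: float = 0.05
    max_render: int = 5

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.cluster_excess <= 1.0:
            raise ValueError("cluster_excess must lie in [0, 1]")
        if self.max_render < 1:
            raise ValueError("max_render must be >= 1")


@dataclass(frozen=True)
class ArtifactModel:
    """Nuisance structure: debris, defocus, illumination offset, sensor noise.

    ``intensity_offset_range`` is the per-image uniform shift in gray levels
    emulating illumination differences between acquisitions; ``noise_sigma``
    is i.i.d. Gaussian pixel noise.  ``defocus_blur_sigma`` is at the native
    511-pixel scale and is rescaled with the image.
    """

    debris_prob: float = 0.04
    defocus_prob: float = 0.02
    defocus_blur_sigma: float = 6.0
    intensity_offset_range: Tuple[float, float] = (-25.0, 25.0)
    noise_sigma: float = 4.0

    def __post_init__(self) -> None:
        for name in ("debris_prob", "defocus_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.defocus_blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur/noise sigma must be >= 0")
        lo, hi = self.intensity_offset_range
        if lo > hi:
            raise ValueError("intensity_offset_range must be (low, high)")


#: Cell appearance at the native 511-pixel scale: bright disk, darker rim.
CELL_RADIUS_RANGE = (8.0, 20.0)
CELL_PEAK_RANGE = (150.0, 230.0)


@dataclass(frozen=True)
class PlateManifest:
    """Labels and provenance for one generated plate.

    ``records`` has one row per well with columns
    ``well_id filename count category debris defocus``; ``images`` optionally
    holds the rendered frames in well order (omitted when written to disk).
    """

    plate_id: str
    n_wells: int
    seed: int
    records: pd.DataFrame
    images: Optional[List[np.ndarray]] = None

    def __post_init__(self) -> None:
        if len(self.records) != self.n_wells:
            raise ValueError("manifest record count != n_wells")

    @property
    def counts(self) -> np.ndarray:
        return self.records["count"].to_numpy()

    @property
    def categories(self) -> np.ndarray:
        labels = self.records["category"]
        return np.array([CATEGORY_LABELS.index(c) for c in labels])


def sample_cell_count(model: OccupancyModel, rng: np.random.Generator) -> int:
    """One occupancy draw: Poisson(lambda), then the cluster-excess increment."""
    k = int(rng.poisson(model.lam))
    if k > 0 and model.cluster_excess > 0 and rng.random() < model.cluster_excess:
        k += 1
    return k


def sample_cell_counts(model: OccupancyModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`sample_cell_count` (same marginal distribution)."""
    k = rng.poisson(model.lam, size=n)
    if model.cluster_excess > 0:
        bump = (k > 0) & (rng.random(n) < model.cluster_excess)
        k = k + bump
    return k.astype(np.int64)


def _well_interior(geometry: WellGeometry) -> Tuple[np.ndarray, np.ndarray, float]:
    """(wall mask, interior mask, interior inset radius/half-side)."""
    side = geometry.image_side
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    c = (side - 1) / 2.0
    margin = geometry.scale(10.0)
    thick = max(1.0, geometry.scale(geometry.wall_thickness))
    if geometry.shape == "square":
        d = np.maximum(np.abs(yy - c), np.abs(xx - c))
        outer = c - margin
        wall = (d <= outer) & (d > outer - thick)
        interior = d <= outer - thick
        inset = outer - thick
    else:
        d = np.hypot(yy - c, xx - c)
        outer = c - margin
        wall = (d <= outer) & (d > outer - thick)
        interior = d <= outer - thick
        inset = outer - thick
    return wall, interior, inset


def _draw_cell(img: np.ndarray, cy: float, cx: float, radius: float, peak: float,
               background: float) -> None:
    """Additively draw one cell: bright disk with a soft edge and darker rim."""
    side = img.shape[0]
    r_out = radius * 1.35
    y0, y1 = max(0, int(cy - r_out - 2)), min(side, int(cy + r_out + 3))
    x0, x1 = max(0, int(cx - r_out - 2)), min(side, int(cx + r_out + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    d = np.hypot(yy - cy, xx - cx)
    edge = max(1.0, radius * 0.15)
    body = np.clip((radius - d) / edge, 0.0, 1.0)  # 1 inside, soft fall-off
    rim = np.clip(1.0 - np.abs(d - radius * 1.15) / (radius * 0.2), 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch += body * (peak - background)
    patch -= rim * 0.35 * background


def _draw_debris(img: np.ndarray, interior: np.ndarray, rng: np.random.Generator,
                 geometry: WellGeometry) -> None:
    """Small irregular low-contrast polygons inside the well."""
    from skimage.draw import polygon as sk_polygon

    side = geometry.image_side
    ys, xs = np.nonzero(interior)
    n_pieces = int(rng.integers(1, 4))
    for _ in range(n_pieces):
        i = int(rng.integers(len(ys)))
        cy, cx = float(ys[i]), float(xs[i])
        r = geometry.scale(rng.uniform(4.0, 12.0))
        nv = int(rng.integers(3, 8))
        ang = np.sort(rng.uniform(0, 2 * np.pi, nv))
        rad = rng.uniform(0.4, 1.0, nv) * r
        py = np.clip(cy + rad * np.sin(ang), 0, side - 1)
        px = np.clip(cx + rad * np.cos(ang), 0, side - 1)
        rr, cc = sk_polygon(py, px, shape=img.shape)
        img[rr, cc] += rng.uniform(-35.0, 35.0)


def render_well(
    count: int,
    geometry: WellGeometry,
    artifacts: Optional[ArtifactModel] = None,
    rng: Optional[np.random.Generator] = None,
    max_render: int = 5,
    placement_attempts: int = 200,
) -> Tuple[np.ndarray, dict]:
    """Render one well image containing ``min(count, max_render)`` cells.

    Returns ``(image, flags)`` where ``image`` is uint8 of shape
    ``(image_side, image_side)`` and ``flags`` records whether debris or
    defocus were applied.  Cells are placed uniformly inside the well wall,
    rejecting overlaps; placement failure after ``placement_attempts`` tries
    per cell raises ``RuntimeError`` (only reachable for tiny wells or large
    ``max_render``).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    artifacts = artifacts or ArtifactModel()
    rng = rng if rng is not None else np.random.default_rng()
    side = geometry.image_side

    offset = rng.uniform(*artifacts.intensity_offset_range)
    img = np.full((side, side), float(geometry.background_intensity) + offset)
    wall, interior, _ = _well_interior(geometry)
    img[wall] = geometry.wall_intensity + offset

    n_draw = min(count, max_render)
    lo, hi = (geometry.scale(r) for r in CELL_RADIUS_RANGE)
    placed: List[Tuple[float, float, float]] = []
    c = (side - 1) / 2.0
    for _ in range(n_draw):
        radius = rng.uniform(lo, hi)
        ok = False
        for _attempt in range(placement_attempts):
            cy = rng.uniform(0, side - 1)
            cx = rng.uniform(0, side - 1)
            iy, ix = int(round(cy)), int(round(cx))
            # strictly inside the well: whole disk on interior pixels
            rr = radius * 1.4 + 2
            box = interior[
                max(0, int(cy - rr)) : int(cy + rr) + 1, max(0, int(cx - rr)) : int(cx + rr) + 1
            ]
            if not interior[iy, ix] or box.size == 0 or not box.all():
                continue
            if all(np.hypot(cy - py, cx - px) >= radius + pr + 2 for py, px, pr in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {n_draw} non-overlapping cells in a "
                f"{side}px {geometry.shape} well after {placement_attempts} attempts"
            )
        placed.append((cy, cx, radius))
        _draw_cell(img, cy, cx, radius, rng.uniform(*CELL_PEAK_RANGE) + offset,
                   geometry.background_intensity + offset)

    has_debris = rng.random() < artifacts.debris_prob
    if has_debris:
        _draw_debris(img, interior, rng, geometry)
    has_defocus = rng.random() < artifacts.defocus_prob
    if has_defocus:
        img = ndimage.gaussian_filter(img, geometry.scale(artifacts.defocus_blur_sigma))
    if artifacts.noise_sigma > 0:
        img = img + rng.normal(0.0, artifacts.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), {
        "debris": bool(has_debris),
        "defocus": bool(has_defocus),
    }


def generate_plate(
    geometry: Optional[WellGeometry] = None,
    occupancy: Optional[OccupancyModel] = None,
    artifacts: Optional[ArtifactModel] = None,
    n_wells: int = 3984,
    seed: int = 0,
    plate_id: str = "plate0",
    out_dir: Optional[str] = None,
) -> PlateManifest:
    """Generate one labeled plate.

    Each well gets an independent random stream spawned from ``seed``, so the
    plate is reproducible and insensitive to evaluation order.  With
    ``out_dir`` set, images are written as 8-bit PNG files next to a
    tab-separated manifest (`<plate_id>.tsv`); otherwise images are returned
    in memory on the manifest.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    geometry = geometry or WellGeometry()
    occupancy = occupancy or OccupancyModel()
    artifacts = artifacts or ArtifactModel()

    streams = np.random.SeedSequence(seed).spawn(n_wells)
    rows, images = [], []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        count = sample_cell_count(occupancy, rng)
        img, flags = render_well(count, geometry, artifacts, rng,
                                 max_render=occupancy.max_render)
        well_id = f"{plate_id}_w{i:04d}"
        filename = f"{well_id}.png"
        rows.append(
            {
                "well_id": well_id,
                "filename": filename,
                "count": count,
                "category": CATEGORY_LABELS[count_to_category(count)],
                "debris": flags["debris"],
                "defocus": flags["defocus"],
            }
        )
        if out_path is not None:
            from PIL import Image

            Image.fromarray(img, mode="L").save(out_path / filename)
        else:
            images.append(img)
    records = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest = PlateManifest(plate_id, n_wells, seed, records,
                             images if out_path is None else None)
    if out_path is not None:
        write_manifest(manifest, out_path / f"{plate_id}.tsv")
    return manifest


def write_manifest(manifest: PlateManifest, path) -> None:
    df = manifest.records.copy()
    df["debris"] = df["debris"].astype(int)
    df["defocus"] = df["defocus"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path, plate_id: Optional[str] = None, seed: int = -1) -> PlateManifest:
    """Read a manifest TSV back; inverse of :func:`write_manifest`."""
    df = pd.read_csv(path, sep="\t", dtype={"category": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    bad = ~df["category"].isin(CATEGORY_LABELS)
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"manifest {path}: row {row} has invalid category {df.loc[row, 'category']!r}"
        )
    df["debris"] = df["debris"].astype(bool)
    df["defocus"] = df["defocus"].astype(bool)
    if plate_id is None:
        plate_id = Path(path).stem
    return PlateManifest(plate_id, len(df), seed, df.reset_index(drop=True))
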