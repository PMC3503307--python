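"""Airspace segmentation with vessel and bronchiole exclusion.

The pipeline follows a fixed stage order on a calibrated RGB section
raster:

1. extract the 8-bit green channel (greatest tissue/background contrast on
   H&E stains);
2. threshold with the maximum-deviation (corner) unimodal rule — section
   histograms are monomodal, so bimodal methods such as Otsu's drop thin
   walls;
3. invert the tissue mask and label luminal structures by connected
   components (border-connected components are slide background, not
   airspaces);
4. erode the tissue mask with a size-7 structuring element so that only the
   thickest walls — vessels and bronchioles — survive;
5. take the convex hull of each surviving wall component on a 4x
   OR-downsampled raster (hulls close the wall ring around a lumen);
6. delete every labeled lumen whose centroid falls inside or on a hull.

Descriptor extraction downstream always runs at full resolution; only the
hull/centroid intersection is downsampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from skimage.measure import block_reduce, regionprops
from skimage.morphology import disk
from skimage.segmentation import clear_border, relabel_sequential

__all__ = [
    "GrayRaster",
    "TissueMask",
    "LabeledAirspaceMap",
    "WallHullSet",
    "SegmentationParams",
    "SegmentationError",
    "extract_green_channel",
    "unimodal_threshold",
    "binarize_tissue",
    "label_lumina",
    "extract_thick_walls",
    "wall_convex_hulls",
    "remove_vessels",
    "segment_section",
]

REGION_COLUMNS = ["label", "area_px", "centroid_row", "centroid_col"]


@dataclass
class GrayRaster:
    """An 8-bit grayscale raster with physical pixel calibration."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class TissueMask:
    """Boolean raster; True marks parenchyma tissue (walls)."""

    pixels: np.ndarray


@dataclass
class LabeledAirspaceMap:
    """Labeled lumina plus a per-region table.

    ``label_map`` holds 0 for non-lumen pixels and contiguous positive
    labels otherwise; ``regions`` has one row per label with pixel area and
    full-resolution centroid.
    """

    label_map: np.ndarray
    regions: pd.DataFrame
    pixel_size_um: float

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass
class WallHullSet:
    """Convex hulls of thick-wall components, in downsampled coordinates.

    Each hull is an (n, 2) float array of (row, col) vertices. Degenerate
    components (single pixels, collinear runs) keep their point/segment
    vertices; the containment test handles them as such.
    """

    hulls: list[np.ndarray] = field(default_factory=list)
    downsample_factor: int = 4

    def geometries(self):
        """Shapely geometries in (x=col, y=row) convention."""
        geoms = []
        for verts in self.hulls:
            pts = [(float(c), float(r)) for r, c in verts]
            if len(pts) >= 3:
                geoms.append(Polygon(pts))
            elif len(pts) == 2:
                geoms.append(LineString(pts))
            else:
                geoms.append(Point(pts[0]))
        return geoms


@dataclass
class SegmentationParams:
    """Tunable parameters of :func:`segment_section`."""

    pixel_size_um: float = 0.725
    threshold: int | None = None  # None = automatic unimodal threshold
    se_size: int = 7
    se_shape: str = "square"  # or "disk"
    downsample_factor: int = 4
    min_airspace_area_px: int = 0
    min_wall_area_px: int = 0


class SegmentationError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def extract_green_channel(image: np.ndarray, pixel_size_um: float) -> GrayRaster:
    """Return the green channel of a 24-bit RGB raster, verbatim.

    Raises ``ValueError`` for inputs that do not have exactly 3 channels.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an RGB image with 3 channels, got shape {image.shape}"
        )
    return GrayRaster(pixels=image[:, :, 1], pixel_size_um=pixel_size_um)


def unimodal_threshold(histogram: np.ndarray) -> int:
    """Maximum-deviation (corner) threshold of a unimodal histogram.

    A straight line is drawn from the histogram peak to the last nonzero bin
    on the tail side (the side of the peak with the longer support). The
    returned threshold is the bin between them with the greatest
    perpendicular distance to that line; ties are broken toward the peak.
    Degenerate cases (peak at the tail end) return the peak index.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 1:
        raise ValueError("histogram must be a 1-D array of bin counts")
    if np.any(h < 0):
        raise ValueError("histogram counts must be nonnegative")
    nonzero = np.flatnonzero(h)
    if nonzero.size == 0:
        raise ValueError("histogram is all zero")
    peak = int(np.argmax(h))
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    tail = hi if (hi - peak) >= (peak - lo) else lo
    if tail == peak:
        return peak
    x1, y1 = float(peak), h[peak]
    x2, y2 = float(tail), h[tail]
    a, b = min(peak, tail), max(peak, tail)
    idx = np.arange(a, b + 1)
    # distance from (x, y) to the line through (x1, y1)-(x2, y2)
    num = np.abs((y2 - y1) * idx - (x2 - x1) * h[a : b + 1] + x2 * y1 - y2 * x1)
    dist = num / np.hypot(x2 - x1, y2 - y1)
    best = dist.max()
    candidates = idx[dist == best]
    return int(candidates[np.argmin(np.abs(candidates - peak))])


def binarize_tissue(gray: GrayRaster, threshold: int) -> TissueMask:
    """Tissue = pixels with intensity <= threshold (tissue is dark in green)."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return TissueMask(pixels=gray.pixels <= threshold)


def _region_table(label_map: np.ndarray) -> pd.DataFrame:
    rows = [
        {
            "label": int(p.label),
            "area_px": int(p.area),
            "centroid_row": float(p.centroid[0]),
            "centroid_col": float(p.centroid[1]),
        }
        for p in regionprops(label_map)
    ]
    if not rows:
        return pd.DataFrame(columns=REGION_COLUMNS).astype(
            {"label": int, "area_px": int, "centroid_row": float, "centroid_col": float}
        )
    return pd.DataFrame(rows).sort_values("label", ignore_index=True)


def label_lumina(tissue: TissueMask, pixel_size_um: float) -> LabeledAirspaceMap:
    """Connected-component labeling of the inverted tissue mask.

    Lumina use 4-connectivity so that one-pixel diagonal wall contacts still
    separate neighboring airspaces. Components touching the image border are
    slide background and are dropped; surviving labels are contiguous.
    """
    inverted = ~np.asarray(tissue.pixels, dtype=bool)
    labeled, _ = ndimage.label(inverted, structure=ndimage.generate_binary_structure(2, 1))
    labeled = clear_border(labeled)
    labeled, _, _ = relabel_sequential(labeled)
    labeled = labeled.astype(np.int32)
    return LabeledAirspaceMap(
        label_map=labeled, regions=_region_table(labeled), pixel_size_um=pixel_size_um
    )


def extract_thick_walls(
    tissue: TissueMask, se_size: int = 7, se_shape: str = "square"
) -> TissueMask:
    """Binary erosion keeping only walls thicker than the structuring element.

    ``se_size`` is the side length of a square element (the default) or the
    diameter of a disk element; it must be odd and >= 3.
    """
    if se_size % 2 == 0 or se_size < 3:
        raise ValueError(f"se_size must be odd and >= 3, got {se_size}")
    if se_shape == "square":
        footprint = np.ones((se_size, se_size), dtype=bool)
    elif se_shape == "disk":
        footprint = disk(se_size // 2).astype(bool)
    else:
        raise ValueError(f"unknown structuring element shape: {se_shape!r}")
    eroded = ndimage.binary_erosion(
        np.asarray(tissue.pixels, dtype=bool), structure=footprint
    )
    return TissueMask(pixels=eroded)


def wall_convex_hulls(
    thick_walls: TissueMask,
    downsample_factor: int = 4,
    min_wall_area_px: int = 0,
) -> WallHullSet:
    """Convex hull of each thick-wall component, at downsampled resolution.

    Downsampling is OR-pooling over ``factor x factor`` blocks so no
    surviving wall pixel can vanish. ``min_wall_area_px`` optionally drops
    small wall components (in downsampled pixels) before hull computation;
    by default none are dropped.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    mask = np.asarray(thick_walls.pixels, dtype=bool)
    if downsample_factor > 1:
        mask = block_reduce(mask, (downsample_factor, downsample_factor), np.max)
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    hulls: list[np.ndarray] = []
    for k in range(1, n + 1):
        coords = np.argwhere(labeled == k)
        if min_wall_area_px and coords.shape[0] < min_wall_area_px:
            continue
        geom = MultiPoint([(float(c), float(r)) for r, c in coords]).convex_hull
        xy = np.asarray(geom.exterior.coords if geom.geom_type == "Polygon" else geom.coords)
        hulls.append(xy[:, ::-1].copy())  # back to (row, col)
    return WallHullSet(hulls=hulls, downsample_factor=downsample_factor)


def remove_vessels(
    lumina: LabeledAirspaceMap, hulls: WallHullSet
) -> LabeledAirspaceMap:
    """Delete labeled regions whose centroid lies inside or on any wall hull.

    Centroids are computed at full resolution and scaled by the hull set's
    downsample factor before the point-in-polygon test; boundary hits count
    as inside (conservative vessel exclusion). Remaining regions are
    relabeled contiguously.
    """
    if lumina.n_regions == 0 or not hulls.hulls:
        return lumina
    geoms = hulls.geometries()
    factor = float(hulls.downsample_factor)
    keep: list[int] = []
    for row in lumina.regions.itertuples(index=False):
        pt = Point(row.centroid_col / factor, row.centroid_row / factor)
        if not any(g.intersects(pt) for g in geoms):
            keep.append(int(row.label))
    return _subset_regions(lumina, keep)


def _subset_regions(lumina: LabeledAirspaceMap, keep: list[int]) -> LabeledAirspaceMap:
    """Keep only the listed labels, relabeling contiguously in label order."""
    old_max = int(lumina.label_map.max(initial=0))
    lut = np.zeros(old_max + 1, dtype=np.int32)
    for new, old in enumerate(sorted(keep), start=1):
        lut[old] = new
    new_map = lut[lumina.label_map]
    table = lumina.regions[lumina.regions["label"].isin(keep)].copy()
    table["label"] = table["label"].map({old: new for new, old in enumerate(sorted(keep), 1)})
    table = table.sort_values("label", ignore_index=True)
    return LabeledAirspaceMap(
        label_map=new_map, regions=table, pixel_size_um=lumina.pixel_size_um
    )


def segment_section(
    image: np.ndarray, params: SegmentationParams | None = None
) -> LabeledAirspaceMap:
    """Run the full airspace segmentation pipeline on an RGB section raster.

    Stage failures are re-raised as :class:`SegmentationError` carrying the
    stage name. The final label map is at full resolution.
    """
    params = params or SegmentationParams()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except SegmentationError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and propagate
            raise SegmentationError(name, str(exc)) from exc

    gray = _stage("green_channel", extract_green_channel, image, params.pixel_size_um)
    if params.threshold is None:
        hist = np.bincount(gray.pixels.ravel(), minlength=256)
        threshold = _stage("unimodal_threshold", unimodal_threshold, hist)
    else:
        threshold = params.threshold
    tissue = _stage("binarize", binarize_tissue, gray, threshold)
    lumina = _stage("label_lumina", label_lumina, tissue, params.pixel_size_um)
    thick = _stage(
        "thick_walls", extract_thick_walls, tissue, params.se_size, params.se_shape
    )
    hulls = _stage(
        "wall_hulls",
        wall_convex_hulls,
        thick,
        params.downsample_factor,
        params.min_wall_area_px,
    )
    result = _stage("remove_vessels", remove_vessels, lumina, hulls)
    if params.min_airspace_area_px > 0:
        keep = result.regions.loc[
            result.regions["area_px"] >= params.min_airspace_area_px, "label"
        ]
        result = _subset_regions(result, [int(k) for k in keep])
    return result
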