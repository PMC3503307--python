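"""Synthetic test data with exactly known ground truth.

Three generators are provided:

- :func:`render_scene` draws a histology-like RGB raster (near-white
  background and lumina, red-dominant tissue walls that are dark in the
  green channel) from a parametric :class:`SceneSpec`, together with a
  :class:`GroundTruth` label map of every airspace and vessel lumen.
- :func:`render_hu_volume` builds an HU-calibrated voxel volume plus a lung
  mask in which the fraction of voxels below -900 HU and the in-mask mean
  are controlled exactly.
- :func:`simulate_cohort` draws a two-group per-animal feature table from
  stated Gaussians.

Rasterization rule: a pixel belongs to a shape iff its *center* lies inside
the analytic boundary, and ground-truth areas are measured on the rasterized
region so that downstream segmentation can be compared without
discretization slack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Ellipse",
    "SceneSpec",
    "GroundTruth",
    "HUVolume",
    "render_scene",
    "random_scene_spec",
    "render_hu_volume",
    "simulate_cohort",
    "write_scene",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: Default calibration (µm/pixel) of a 10x whole-slide mosaic.
DEFAULT_PIXEL_SIZE_UM = 0.725


@dataclass(frozen=True)
class Ellipse:
    """A rotated ellipse with a surrounding tissue wall.

    ``center`` and ``semi_axes`` are in pixel units, ``(row, col)`` order for
    the center. The lumen is the ellipse interior; the wall is the ring
    between the lumen boundary and the ellipse grown by ``wall_thickness_px``
    along both semi-axes.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0
    wall_thickness_px: float = 2.0

    def outer_semi_axes(self) -> tuple[float, float]:
        return (
            self.semi_axes[0] + self.wall_thickness_px,
            self.semi_axes[1] + self.wall_thickness_px,
        )

    def bounding_radius(self) -> float:
        return max(self.outer_semi_axes())


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of a synthetic section image."""

    image_size: tuple[int, int]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    airspaces: tuple[Ellipse, ...] = ()
    vessels: tuple[Ellipse, ...] = ()
    background_level: int = 230
    tissue_level: int = 40
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "airspaces", tuple(self.airspaces))
        object.__setattr__(self, "vessels", tuple(self.vessels))


@dataclass
class GroundTruth:
    """Exact geometry of a rendered scene.

    ``label_map`` assigns 0 to walls/background and label ``k`` to the k-th
    lumen (airspaces first, then vessel lumina). ``vessel_labels`` holds the
    labels that a correct segmentation must exclude.
    """

    label_map: np.ndarray
    true_areas_um2: np.ndarray
    true_diameters_um: np.ndarray
    vessel_labels: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_airspaces(self) -> int:
        return int(self.true_areas_um2.size) - len(self.vessel_labels)


@dataclass
class HUVolume:
    """A 3D voxel array calibrated in Hounsfield units."""

    voxels: np.ndarray
    voxel_size_um: float = 50.0


class SceneValidationError(ValueError):
    """Raised when a SceneSpec violates its geometric invariants."""


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    rotation: float,
) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the ellipse."""
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise SceneValidationError(f"semi-axes must be positive, got {semi_axes}")
    cr, cc = center
    # restrict to the bounding box for speed
    rad = max(a, b)
    r0 = max(int(np.floor(cr - rad)) - 1, 0)
    r1 = min(int(np.ceil(cr + rad)) + 2, shape[0])
    c0 = max(int(np.floor(cc - rad)) - 1, 0)
    c1 = min(int(np.ceil(cc + rad)) + 2, shape[1])
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cc_ - cc
    ct, st = np.cos(rotation), np.sin(rotation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = local
    return mask


def _validate_spec(spec: SceneSpec) -> None:
    rows, cols = spec.image_size
    if rows <= 0 or cols <= 0:
        raise SceneValidationError("image_size must be positive")
    if spec.pixel_size_um <= 0:
        raise SceneValidationError("pixel_size_um must be positive")
    for shape in (*spec.airspaces, *spec.vessels):
        cr, cc = shape.center
        rad = shape.bounding_radius()
        if cr - rad < 0 or cc - rad < 0 or cr + rad > rows - 1 or cc + rad > cols - 1:
            raise SceneValidationError(
                f"shape at {shape.center} with outer radius {rad:.1f} exceeds the image"
            )
    if spec.vessels and spec.airspaces:
        max_air_wall = max(s.wall_thickness_px for s in spec.airspaces)
        min_ves_wall = min(s.wall_thickness_px for s in spec.vessels)
        if min_ves_wall <= max_air_wall:
            raise SceneValidationError(
                "vessel wall thickness must strictly exceed airspace wall thickness"
            )


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the scene and return ``(rgb_image, ground_truth)``.

    The returned image is ``uint8`` of shape ``(rows, cols, 3)``. Tissue
    walls are red-dominant with a low green value; background and lumina are
    near-white, so green-channel extraction separates the two populations.
    Additive Gaussian noise (``spec.noise_sd``) is applied per channel after
    rasterization and clipped to [0, 255].

    Raises
    ------
    SceneValidationError
        If shapes leave the image, a vessel wall is not thicker than every
        airspace wall, or two lumen interiors overlap.
    """
    _validate_spec(spec)
    shape = spec.image_size
    label_map = np.zeros(shape, dtype=np.int32)
    tissue = np.zeros(shape, dtype=bool)
    occupied = np.zeros(shape, dtype=bool)

    label = 0
    vessel_labels: set[int] = set()
    all_shapes = [(s, False) for s in spec.airspaces] + [(s, True) for s in spec.vessels]
    for ell, is_vessel in all_shapes:
        label += 1
        lumen = _ellipse_mask(shape, ell.center, ell.semi_axes, ell.rotation)
        outer = _ellipse_mask(shape, ell.center, ell.outer_semi_axes(), ell.rotation)
        if np.any(occupied & outer):
            raise SceneValidationError(
                f"shape {label} overlaps a previously drawn shape"
            )
        occupied |= outer
        label_map[lumen] = label
        tissue |= outer & ~lumen
        if is_vessel:
            vessel_labels.add(label)

    counts = np.bincount(label_map.ravel(), minlength=label + 1)[1:]
    areas_um2 = counts.astype(float) * spec.pixel_size_um**2
    diameters_um = 2.0 * np.sqrt(areas_um2 / np.pi)

    bg = float(spec.background_level)
    tl = float(spec.tissue_level)
    rgb = np.empty((*shape, 3), dtype=float)
    rgb[..., 0] = np.where(tissue, min(tl + 140.0, 255.0), bg)
    rgb[..., 1] = np.where(tissue, tl, bg)
    rgb[..., 2] = np.where(tissue, min(tl + 60.0, 255.0), bg)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    image = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        label_map=label_map,
        true_areas_um2=areas_um2,
        true_diameters_um=diameters_um,
        vessel_labels=frozenset(vessel_labels),
    )
    return image, truth


def random_scene_spec(
    n_airspaces: int,
    n_vessels: int = 0,
    image_size: tuple[int, int] = (768, 768),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_sd: float = 0.0,
    seed: int = 0,
    airspace_radius_px: tuple[float, float] = (8.0, 30.0),
    vessel_lumen_radius_px: tuple[float, float] = (15.0, 30.0),
    airspace_wall_px: float = 2.0,
    vessel_wall_px: float = 12.0,
    max_tries: int = 20000,
) -> SceneSpec:
    """Draw a valid random scene by rejection-sampling shape placements.

    Shapes are mildly eccentric rotated ellipses; two shapes are accepted
    only when their bounding circles are at least 3 px apart, which
    guarantees disjoint extents.
    """
    rng = np.random.default_rng(seed)
    rows, cols = image_size
    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)
    shapes: list[Ellipse] = []

    def _place(radius_range: tuple[float, float], wall: float) -> Ellipse:
        for _ in range(max_tries):
            r_mean = rng.uniform(*radius_range)
            ecc = rng.uniform(0.75, 1.0)
            a, b = r_mean / np.sqrt(ecc), r_mean * np.sqrt(ecc)
            rot = rng.uniform(0, np.pi)
            rad = max(a, b) + wall
            cr = rng.uniform(rad + 2, rows - rad - 3)
            cc = rng.uniform(rad + 2, cols - rad - 3)
            if all(
                np.hypot(cr - pr, cc - pc) > rad + prad + 3.0
                for pr, pc, prad in placed
            ):
                placed.append((cr, cc, rad))
                return Ellipse((cr, cc), (a, b), rot, wall)
        raise SceneValidationError(
            "could not place all shapes; reduce counts or radii"
        )

    for _ in range(n_vessels):
        shapes.append(_place(vessel_lumen_radius_px, vessel_wall_px))
    vessels = tuple(shapes)
    shapes = []
    for _ in range(n_airspaces):
        shapes.append(_place(airspace_radius_px, airspace_wall_px))

    return SceneSpec(
        image_size=image_size,
        pixel_size_um=pixel_size_um,
        airspaces=tuple(shapes),
        vessels=vessels,
        noise_sd=noise_sd,
        seed=seed,
    )


def render_hu_volume(
    shape: tuple[int, int, int],
    lung_fraction_below_thresh: float,
    mean_hu: float,
    seed: int = 0,
    threshold_hu: float = -900.0,
    voxel_size_um: float = 50.0,
) -> tuple[HUVolume, np.ndarray]:
    """Build an HU volume and lung mask with controlled density statistics.

    Exactly ``round(fraction * N)`` in-mask voxels are strictly below
    ``threshold_hu`` and the in-mask mean equals ``mean_hu`` up to floating
    point rounding. The mask is a centered ellipsoid; voxels outside it are
    set to a soft-tissue level (+40 HU).

    Raises
    ------
    ValueError
        If the fraction is outside [0, 1] or the requested mean is not
        attainable with the requested below-threshold fraction.
    """
    if not 0.0 <= lung_fraction_below_thresh <= 1.0:
        raise ValueError(
            f"lung_fraction_below_thresh must be in [0, 1], got {lung_fraction_below_thresh}"
        )
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.indices(shape, dtype=float)
    ctr = [(s - 1) / 2.0 for s in shape]
    ax = [max(s * 0.4, 1.0) for s in shape]
    mask = (
        ((zz - ctr[0]) / ax[0]) ** 2
        + ((yy - ctr[1]) / ax[1]) ** 2
        + ((xx - ctr[2]) / ax[2]) ** 2
    ) <= 1.0
    n = int(mask.sum())
    if n == 0:
        raise ValueError("volume too small: empty lung mask")

    n_below = int(round(lung_fraction_below_thresh * n))
    n_above = n - n_below
    floor_hu = threshold_hu - 100.0

    below = rng.uniform(floor_hu, threshold_hu - 1.0, size=n_below)
    if n_above > 0:
        target_above = (mean_hu * n - below.sum()) / n_above
        if target_above <= threshold_hu:
            raise ValueError(
                f"mean {mean_hu} HU unattainable with fraction "
                f"{lung_fraction_below_thresh} below {threshold_hu} HU"
            )
        spread = min(100.0, (target_above - threshold_hu) / 2.0)
        noise = rng.uniform(-spread, spread, size=n_above)
        noise -= noise.mean()
        above = target_above + noise
        values = np.concatenate([below, above])
    else:
        if not floor_hu < mean_hu < threshold_hu:
            raise ValueError(
                f"with fraction 1.0 the mean must lie in ({floor_hu}, {threshold_hu}) HU"
            )
        spread = 0.49 * min(threshold_hu - mean_hu, mean_hu - floor_hu)
        noise = rng.uniform(-spread, spread, size=n_below)
        if n_below > 1:
            noise -= noise.mean()
        values = mean_hu + noise

    rng.shuffle(values)
    voxels = np.full(shape, 40.0)
    voxels[mask] = values
    return HUVolume(voxels=voxels, voxel_size_um=voxel_size_um), mask


#: Plausible healthy-animal baselines for the standard feature panel.
DEFAULT_BASELINES: dict[str, float] = {
    "MLVI": -450.0,
    "VBT": 3.0,
    "RMBR": 290.0,
    "LMBR": 260.0,
    "R": 0.6,
    "C": 0.06,
    "IL6": 1.0,
    "IP10": 1.0,
    "KC": 1.0,
    "MCP1": 1.0,
    "D2": 90.0,
}


def simulate_cohort(
    n_per_group: int,
    effect_sizes: Mapping[str, float],
    noise_sd: Mapping[str, float] | float = 1.0,
    seed: int = 0,
    baselines: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a two-group ("control"/"treated") per-animal feature table.

    Each feature named in ``effect_sizes`` is drawn from a Gaussian: controls
    at the baseline, treated shifted by the effect size. ``noise_sd`` may be
    a scalar or a per-feature mapping. Deterministic for a fixed seed.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    features = list(effect_sizes)
    if not features:
        raise ValueError("effect_sizes must name at least one feature")
    base = dict(DEFAULT_BASELINES)
    if baselines:
        base.update(baselines)
    if isinstance(noise_sd, Mapping):
        sds = {f: float(noise_sd.get(f, 1.0)) for f in features}
    else:
        sds = {f: float(noise_sd) for f in features}

    rng = np.random.default_rng(seed)
    records = []
    for group, shift_on in (("control", 0.0), ("treated", 1.0)):
        for i in range(n_per_group):
            row: dict[str, object] = {
                "animal_id": f"{group[:4]}{i + 1:03d}",
                "group": group,
            }
            for f in features:
                mu = base.get(f, 0.0) + shift_on * effect_sizes[f]
                row[f] = rng.normal(mu, sds[f])
            records.append(row)
    return pd.DataFrame.from_records(records)


def write_scene(
    prefix: str | Path, spec: SceneSpec, image: np.ndarray, truth: GroundTruth
) -> dict[str, Path]:
    """Write a rendered scene: PNG image, 16-bit label PNG, JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    image_path = prefix.with_suffix(".png")
    labels_path = Path(str(prefix) + "_labels.png")
    sidecar_path = prefix.with_suffix(".json")
    iio.imwrite(image_path, image)
    iio.imwrite(labels_path, truth.label_map.astype(np.uint16))
    sidecar = {
        "spec": {
            "image_size": list(spec.image_size),
            "pixel_size_um": spec.pixel_size_um,
            "background_level": spec.background_level,
            "tissue_level": spec.tissue_level,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
            "airspaces": [
                {
                    "center": list(s.center),
                    "semi_axes": list(s.semi_axes),
                    "rotation": s.rotation,
                    "wall_thickness_px": s.wall_thickness_px,
                }
                for s in spec.airspaces
            ],
            "vessels": [
                {
                    "center": list(s.center),
                    "semi_axes": list(s.semi_axes),
                    "rotation": s.rotation,
                    "wall_thickness_px": s.wall_thickness_px,
                }
                for s in spec.vessels
            ],
        },
        "ground_truth": {
            "true_areas_um2": truth.true_areas_um2.tolist(),
            "true_diameters_um": truth.true_diameters_um.tolist(),
            "vessel_labels": sorted(truth.vessel_labels),
        },
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {"image": image_path, "labels": labels_path, "sidecar": sidecar_path}
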