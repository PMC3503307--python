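"""Airspace-enlargement descriptors: Lm and the diameter moments D0-D2.

Each labeled airspace of area A_i (µm²) has equivalent diameter
``d_i = 2*sqrt(A_i/pi)`` — the diameter of the circle with equal area. The
weighted mean diameters are consecutive-moment ratios of the d
distribution, ``D_v = <d^(v+1)> / <d^v>``: D0 is the arithmetic mean and
higher orders weight large airspaces progressively more, which is what
makes D2 sensitive to heterogeneous enlargement that leaves Lm almost
unchanged.

The mean linear intercept Lm is approximated by raster scanning the labeled
image: each maximal run of airspace pixels bounded on both ends by wall
pixels contributes one intercept of length ``run_length * pixel_size``, and
Lm is the mean over all intercepts pooled across the section. Runs touching
the image border have no bounding wall on one side and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lungmorph.segmentation import LabeledAirspaceMap

__all__ = [
    "DiameterSample",
    "DescriptorSet",
    "equivalent_diameters",
    "weighted_mean_diameter",
    "d_v_from_central_moments",
    "mean_linear_intercept",
    "compute_descriptors",
]


@dataclass
class DiameterSample:
    """Equivalent diameters (µm) and their source areas (µm²), label order."""

    diameters_um: np.ndarray
    areas_um2: np.ndarray

    def __len__(self) -> int:
        return int(self.diameters_um.size)


@dataclass
class DescriptorSet:
    """The four descriptors of one section plus sample counts."""

    Lm_um: float
    D0_um: float
    D1_um: float
    D2_um: float
    n_airspaces: int
    n_intercepts: int


def equivalent_diameters(regions: LabeledAirspaceMap) -> DiameterSample:
    """Per-region area (µm²) and equivalent diameter d = 2*sqrt(A/pi) (µm)."""
    if regions.pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    areas_px = regions.regions["area_px"].to_numpy(dtype=float)
    areas_um2 = areas_px * regions.pixel_size_um**2
    return DiameterSample(
        diameters_um=2.0 * np.sqrt(areas_um2 / np.pi), areas_um2=areas_um2
    )


def weighted_mean_diameter(sample: DiameterSample | np.ndarray, v: int) -> float:
    """Moment-ratio diameter ``D_v = <d^(v+1)> / <d^v>`` of the sample."""
    d = np.asarray(
        sample.diameters_um if isinstance(sample, DiameterSample) else sample,
        dtype=float,
    )
    if d.size == 0:
        raise ValueError("D_v is undefined for an empty diameter sample")
    if v < 0:
        raise ValueError("moment order v must be nonnegative")
    return float(np.mean(d ** (v + 1)) / np.mean(d**v))


def d_v_from_central_moments(mu: float, sigma2: float, gamma: float, v: int) -> float:
    """D1 or D2 expressed through central moments of the diameters.

    D1 = mu * (1 + sigma2/mu²) and D2 = (mu³ + 3*mu*sigma2 + gamma*sigma³)
    / (mu² + sigma2), with sigma = sqrt(sigma2). With the population (1/n)
    moment convention both match :func:`weighted_mean_diameter` exactly on
    empirical samples.
    """
    if mu <= 0:
        raise ValueError("mean diameter must be positive")
    if sigma2 < 0:
        raise ValueError("variance must be nonnegative")
    if v == 1:
        return float(mu * (1.0 + sigma2 / mu**2))
    if v == 2:
        sigma = np.sqrt(sigma2)
        return float((mu**3 + 3.0 * mu * sigma2 + gamma * sigma**3) / (mu**2 + sigma2))
    raise ValueError(f"central-moment form available for v in (1, 2), got {v}")


def _intercept_lengths(binary: np.ndarray) -> np.ndarray:
    """Lengths of interior airspace runs along rows of a boolean raster."""
    padded = np.zeros((binary.shape[0], binary.shape[1] + 2), dtype=np.int8)
    padded[:, 1:-1] = binary
    diff = np.diff(padded, axis=1)
    start_r, start_c = np.nonzero(diff == 1)
    end_r, end_c = np.nonzero(diff == -1)
    # starts and ends pair up in scan order within each row
    interior = (start_c > 0) & (end_c < binary.shape[1])
    return (end_c - start_c)[interior]


def mean_linear_intercept(
    regions: LabeledAirspaceMap, scan: str = "horizontal"
) -> tuple[float, int]:
    """Mean linear intercept (µm) and the number of intercepts pooled.

    ``scan`` is "horizontal" (default), "vertical", or "both" (pooling the
    two directions). Raises ``ValueError`` when no interior run exists.
    """
    binary = regions.label_map > 0
    if scan == "horizontal":
        lengths = _intercept_lengths(binary)
    elif scan == "vertical":
        lengths = _intercept_lengths(binary.T)
    elif scan == "both":
        lengths = np.concatenate(
            [_intercept_lengths(binary), _intercept_lengths(binary.T)]
        )
    else:
        raise ValueError(f"scan must be horizontal/vertical/both, got {scan!r}")
    if lengths.size == 0:
        raise ValueError("no wall-bounded intercepts found; Lm is undefined")
    return float(lengths.mean() * regions.pixel_size_um), int(lengths.size)


def compute_descriptors(
    regions: LabeledAirspaceMap, scan: str = "horizontal"
) -> DescriptorSet:
    """Bundle Lm, D0, D1, D2 and the sample counts for one section."""
    if regions.n_regions == 0:
        raise ValueError("descriptor set undefined for an empty airspace map")
    sample = equivalent_diameters(regions)
    lm, n_intercepts = mean_linear_intercept(regions, scan=scan)
    return DescriptorSet(
        Lm_um=lm,
        D0_um=weighted_mean_diameter(sample, 0),
        D1_um=weighted_mean_diameter(sample, 1),
        D2_um=weighted_mean_diameter(sample, 2),
        n_airspaces=len(sample),
        n_intercepts=n_intercepts,
    )
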