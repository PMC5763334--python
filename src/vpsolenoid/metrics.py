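"""ROI sampling and B1 homogeneity / sensitivity metrics.

The figure of merit for a coil geometry is computed over the *inner coil
volume*: a cylindrical region of interest (ROI) coaxial with the winding.
Sensitivity is the mean B1 amplitude over the ROI; homogeneity is its
standard deviation (population, since the ROI grid is exhaustive, not a
sample).  The coefficient of variation std/mean is the scale-free
combination used for ranking geometries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MM, InvalidSpecError
from .solver import AxisProfile, FieldMap

__all__ = [
    "RoiSpec",
    "MetricsResult",
    "sample_roi",
    "homogeneity_sensitivity",
    "edge_dropoff",
]


@dataclass(frozen=True)
class RoiSpec:
    """Cylindrical ROI: radius and axial half-extent, regular grid sampling.

    Defaults match the 28 mm bore / 56 mm winding of the reference coil:
    radius 14 mm, half-length 28 mm, 1 mm isotropic spacing.
    """

    radius_mm: float = 14.0
    z_half_extent_mm: float = 28.0
    grid_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.z_half_extent_mm <= 0:
            raise InvalidSpecError("ROI radius and z_half_extent must be > 0")
        if not (0 < self.grid_spacing_mm <= self.radius_mm):
            raise InvalidSpecError(
                "grid_spacing_mm must be positive and at most the ROI radius"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Bounding-grid shape (nx, ny, nz) of the sampling lattice."""
        nr = int(np.floor(self.radius_mm / self.grid_spacing_mm + 1e-9))
        nz = int(np.floor(self.z_half_extent_mm / self.grid_spacing_mm + 1e-9))
        return (2 * nr + 1, 2 * nr + 1, 2 * nz + 1)


@dataclass(frozen=True)
class MetricsResult:
    """Homogeneity/sensitivity summary of one geometry over an ROI."""

    alpha_deg: float
    beta_deg: float
    mean_b1: float  # tesla (per reference ampere) -- sensitivity
    std_b1: float  # tesla -- homogeneity (population std)
    cv: float  # std_b1 / mean_b1, dimensionless
    n_points: int


def sample_roi(roi: RoiSpec) -> np.ndarray:
    """All lattice points of the cylindrical ROI, in metres.

    Axis-aligned grid with the ROI spacing; a point is kept when its
    radial distance is <= radius and |z| <= z_half_extent.  Ordering is
    deterministic: z-major, then y, then x.
    """
    h = roi.grid_spacing_mm
    nx, _, nz = roi.grid_shape
    nr = (nx - 1) // 2
    nzh = (nz - 1) // 2
    xy = np.arange(-nr, nr + 1) * h
    zs = np.arange(-nzh, nzh + 1) * h
    zz, yy, xx = np.meshgrid(zs, xy, xy, indexing="ij")
    pts = np.column_stack((xx.ravel(), yy.ravel(), zz.ravel()))
    keep = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= roi.radius_mm**2 + 1e-9
    pts = pts[keep]
    if len(pts) == 0:
        raise InvalidSpecError("ROI contains no grid points")
    return pts * MM


def homogeneity_sensitivity(
    field: FieldMap, spec_angles: tuple[float, float] = (np.nan, np.nan)
) -> MetricsResult:
    """Mean, std and CV of the B1 proxy over the points of ``field``.

    ``spec_angles`` are carried through into the result for bookkeeping
    in grid searches.
    """
    if len(field) == 0:
        raise ValueError("field map is empty")
    b1 = field.b1
    mean = float(np.mean(b1))
    std = float(np.std(b1))  # population std: the ROI is exhaustive
    return MetricsResult(
        alpha_deg=float(spec_angles[0]),
        beta_deg=float(spec_angles[1]),
        mean_b1=mean,
        std_b1=std,
        cv=std / mean,
        n_points=len(b1),
    )


def edge_dropoff(profile: AxisProfile) -> float:
    """Relative B1 dropoff at the coil edges on the central axis.

    ``1 - min(b1(+edge), b1(-edge)) / b1(0)``, where the edges are the
    first and last profile samples; sample the profile over exactly
    [-L/2, +L/2] (with an odd sample count so z = 0 is hit) to obtain the
    coil-edge statistic.
    """
    return profile.dropoff
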