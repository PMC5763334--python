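"""Quasi-static Biot-Savart field solver for polyline conductors.

For a coil that is small compared with the RF wavelength, the transmit
field B1 is well approximated by the static field of the winding current,
so the full-wave problem reduces to a Biot-Savart sum over the
discretized conductor:

    B(p) = (mu0 * I / 4 pi) * sum_s  dl_s x (p - m_s) / |p - m_s|^3

with ``m_s`` the segment midpoint and ``dl_s`` the segment vector
(midpoint rule, second-order accurate in the segment length).

Everything in this module is SI: positions in metres, fields in tesla,
currents in amperes.  The per-point scalar ``b1`` reported alongside the
field vectors is a proxy for the rotating-frame B1 amplitude; by default
it is the vector magnitude ``|B|`` (see :data:`B1_PROXIES`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import mu_0

from ._kernels import HAVE_NUMBA, accumulate_field
from .geometry import ConductorPath

__all__ = [
    "FieldMap",
    "AxisProfile",
    "NearSingularityError",
    "B1_PROXIES",
    "biot_savart_field",
    "axial_profile",
    "analytic_loop_axis",
]

#: Available reductions from the field vector to the scalar B1 proxy.
#: ``magnitude`` is |B|; ``axial`` is |Bz| (the coil-frame axial component,
#: which is transverse to B0 when the solenoid is used with its axis
#: perpendicular to the main field); ``transverse`` is half the magnitude
#: of the projection onto the plane perpendicular to an assumed B0 along
#: +x -- the rotating-frame B1+ amplitude of a linearly polarized coil.
B1_PROXIES = ("magnitude", "axial", "transverse")

_CHUNK = 4096  # evaluation points per vectorized block


class NearSingularityError(ValueError):
    """An evaluation point lies too close to the conductor.

    The midpoint-rule Biot-Savart sum diverges near the filament; rather
    than returning a huge, discretization-dependent number the solver
    refuses points closer to a segment midpoint than half that segment's
    length.
    """


@dataclass(frozen=True)
class FieldMap:
    """Field vectors and the scalar B1 proxy at a set of points.

    Attributes
    ----------
    points : (N, 3) ndarray, metres
    b_vectors : (N, 3) ndarray, tesla
    b1 : (N,) ndarray, tesla -- scalar proxy per ``b1_proxy``
    b1_proxy : str
    source : ConductorPath that generated the field
    """

    points: np.ndarray
    b_vectors: np.ndarray
    b1: np.ndarray
    b1_proxy: str = "magnitude"
    source: ConductorPath | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        b = np.atleast_2d(np.asarray(self.b_vectors, dtype=float))
        if p.shape != b.shape or p.shape[1] != 3:
            raise ValueError("points and b_vectors must both be (N, 3)")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "b_vectors", b)
        object.__setattr__(self, "b1", np.asarray(self.b1, dtype=float))

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class AxisProfile:
    """B1 proxy sampled along the coil axis (x = y = 0)."""

    z: np.ndarray
    b1: np.ndarray

    @property
    def dropoff(self) -> float:
        """Relative edge dropoff ``1 - min(b1[first], b1[last]) / b1(z=0)``.

        The first and last samples are taken as the coil edges; the
        profile must contain a sample at z = 0 (within half a step).
        """
        z = np.asarray(self.z, float)
        i0 = int(np.argmin(np.abs(z)))
        step = np.median(np.abs(np.diff(z))) if len(z) > 1 else 0.0
        if abs(z[i0]) > max(step / 2.0, 1e-12):
            raise ValueError("profile has no sample at the coil centre z = 0")
        b0 = self.b1[i0]
        if b0 == 0.0:
            raise ValueError("central B1 is zero; dropoff undefined")
        return float(1.0 - min(self.b1[0], self.b1[-1]) / b0)


def _reduce_b1(b: np.ndarray, proxy: str) -> np.ndarray:
    if proxy == "magnitude":
        return np.linalg.norm(b, axis=-1)
    if proxy == "axial":
        return np.abs(b[..., 2])
    if proxy == "transverse":
        return 0.5 * np.hypot(b[..., 1], b[..., 2])
    raise ValueError(f"unknown b1_proxy {proxy!r}; choose from {B1_PROXIES}")


def _raise_near_singularity(pts, mid, excl2) -> None:
    """Locate and report the first point violating the exclusion distance."""
    for i, p in enumerate(pts):
        r2 = np.einsum("sk,sk->s", p - mid, p - mid)
        bad = np.nonzero(r2 < excl2)[0]
        if len(bad):
            j = int(bad[0])
            raise NearSingularityError(
                f"evaluation point {p} is within the exclusion distance of "
                f"conductor segment {j} (midpoint {mid[j]})"
            )
    raise AssertionError("exclusion violation flagged but not found")


def _field_numpy(pts, mid, dl, excl2) -> np.ndarray:
    """Chunked numpy Biot-Savart sum (unscaled); reference vectorized path."""
    dlx, dly, dlz = dl[:, 0], dl[:, 1], dl[:, 2]
    b = np.empty_like(pts)
    for lo in range(0, len(pts), _CHUNK):
        p = pts[lo : lo + _CHUNK]
        d = p[:, None, :] - mid[None, :, :]  # (P, S, 3)
        r2 = np.einsum("psk,psk->ps", d, d)
        if (r2 < excl2[None, :]).any():
            _raise_near_singularity(p, mid, excl2)
        d *= (r2 ** (-1.5))[:, :, None]  # d now holds (p - m) / |p - m|^3
        # B = sum_s dl_s x d_s, expanded per component as matrix-vector products
        b[lo : lo + _CHUNK, 0] = d[:, :, 2] @ dly - d[:, :, 1] @ dlz
        b[lo : lo + _CHUNK, 1] = d[:, :, 0] @ dlz - d[:, :, 2] @ dlx
        b[lo : lo + _CHUNK, 2] = d[:, :, 1] @ dlx - d[:, :, 0] @ dly
    return b


def biot_savart_field(
    path: ConductorPath,
    points: np.ndarray,
    b1_proxy: str = "magnitude",
    exclusion_factor: float = 0.5,
    engine: str = "auto",
) -> FieldMap:
    """Evaluate the Biot-Savart field of ``path`` at ``points`` (metres).

    Parameters
    ----------
    path : ConductorPath
        Current-carrying polyline (current taken from ``path.current_a``).
    points : (N, 3) array_like, metres
    b1_proxy : str
        Reduction from field vector to scalar B1, see :data:`B1_PROXIES`.
    exclusion_factor : float
        Points closer to a segment midpoint than ``exclusion_factor``
        times that segment's length raise :class:`NearSingularityError`.
    engine : {"auto", "numba", "numpy"}
        Summation backend.  Both compute the same sum; the compiled numba
        kernel is roughly an order of magnitude faster and is selected
        automatically when available.

    Returns
    -------
    FieldMap
    """
    if b1_proxy not in B1_PROXIES:
        raise ValueError(f"unknown b1_proxy {b1_proxy!r}; choose from {B1_PROXIES}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array")
    mid, dl = path.segments()
    if len(mid) == 0:
        raise ValueError("conductor path has no segments")

    excl2 = (exclusion_factor**2) * np.einsum("sk,sk->s", dl, dl)
    if engine == "auto":
        engine = "numba" if HAVE_NUMBA else "numpy"
    if engine == "numba":
        b, margin = accumulate_field(mid, dl, pts, excl2)
        if margin.min() < 0.0:
            _raise_near_singularity(pts[margin < 0.0], mid, excl2)
    elif engine == "numpy":
        b = _field_numpy(pts, mid, dl, excl2)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    b *= mu_0 * path.current_a / (4.0 * np.pi)
    return FieldMap(pts, b, _reduce_b1(b, b1_proxy), b1_proxy=b1_proxy, source=path)


def axial_profile(
    path: ConductorPath,
    n_samples: int = 57,
    z_min: float = -0.028,
    z_max: float = 0.028,
    b1_proxy: str = "magnitude",
) -> AxisProfile:
    """Sample the B1 proxy at ``n_samples`` uniform points on the coil axis.

    ``z_min``/``z_max`` are in metres; the defaults span the edges of the
    56 mm reference coil.  Use an odd ``n_samples`` with a symmetric range
    so z = 0 is sampled exactly (required for the dropoff statistic).
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    z = np.linspace(float(z_min), float(z_max), int(n_samples))
    pts = np.column_stack((np.zeros_like(z), np.zeros_like(z), z))
    fm = biot_savart_field(path, pts, b1_proxy=b1_proxy)
    return AxisProfile(z=z, b1=fm.b1)


def analytic_loop_axis(radius_m: float, z_m, current_a: float = 1.0):
    """Closed-form on-axis field of an ideal circular loop (tesla).

    ``B_z(z) = mu0 I R^2 / (2 (R^2 + z^2)^{3/2})`` for a loop of radius
    ``R`` in the plane z = 0.  Validation oracle for the polyline solver.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be > 0")
    z = np.asarray(z_m, dtype=float)
    out = mu_0 * current_a * radius_m**2 / (2.0 * (radius_m**2 + z**2) ** 1.5)
    return out if out.ndim else float(out)
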