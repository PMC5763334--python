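"""Variable-pitch solenoid conductor geometry.

A solenoid RF coil can be made axially more homogeneous by winding it
denser at the ends and sparser in the centre.  The winding of each coil
half (measured from the coil end inward, in winding angle theta) is split
into three segments:

* ``theta < alpha`` -- zero pitch: the conductor forms a flat ring,
* ``alpha <= theta < alpha + beta`` -- the pitch ramps up linearly,
* ``theta >= alpha + beta`` -- constant pitch, as in a regular solenoid.

The two halves are mirror images about the coil midplane, so the full
geometry is parametrized by the pair of segment angles ``(alpha, beta)``.
The special case ``alpha = beta = 0`` is the regular constant-pitch
solenoid.

Lengths at this interface are millimetres (the natural unit for coil
hardware); generated :class:`ConductorPath` vertices are in metres, the
unit used by the field solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SolenoidSpec",
    "ConductorPath",
    "InvalidSpecError",
    "pitch_profile",
    "plateau_pitch",
    "build_variable_pitch_solenoid",
    "build_regular_solenoid",
    "build_circular_loop",
    "check_strip_clearance",
]

#: millimetres per metre
MM = 1e-3


class InvalidSpecError(ValueError):
    """Raised when a coil specification violates its geometric constraints."""


@dataclass(frozen=True)
class SolenoidSpec:
    """Design parameters of one (variable-pitch) solenoid geometry.

    Parameters
    ----------
    winding_diameter_mm : float
        Diameter of the winding centerline cylinder. Default 34 mm
        (28 mm inner housing bore + 3 mm wall on each side).
    n_turns : float
        Number of windings. Default 3.
    winding_length_mm : float
        Axial span of the winding centerline. Default 56 mm.
    alpha_deg : float
        Angular range of the zero-pitch end segment, per coil half,
        in degrees of winding angle. Allowed range [0, 180].
    beta_deg : float
        Angular range of the linear pitch ramp, per coil half, in
        degrees. Allowed range [0, 180].
    current_a : float
        Reference current in amperes. All fields scale linearly with it.
    segments_per_turn : int
        Polyline discretization of the winding (vertices per turn).
    """

    winding_diameter_mm: float = 34.0
    n_turns: float = 3.0
    winding_length_mm: float = 56.0
    alpha_deg: float = 0.0
    beta_deg: float = 0.0
    current_a: float = 1.0
    segments_per_turn: int = 360

    def __post_init__(self) -> None:
        if not (self.winding_diameter_mm > 0):
            raise InvalidSpecError("winding_diameter_mm must be > 0")
        if not (self.winding_length_mm > 0):
            raise InvalidSpecError("winding_length_mm must be > 0")
        if not (self.n_turns > 0):
            raise InvalidSpecError("n_turns must be > 0")
        if not (0.0 <= self.alpha_deg <= 180.0):
            raise InvalidSpecError(
                f"alpha_deg={self.alpha_deg} outside the supported range [0, 180]"
            )
        if not (0.0 <= self.beta_deg <= 180.0):
            raise InvalidSpecError(
                f"beta_deg={self.beta_deg} outside the supported range [0, 180]"
            )
        if self.alpha_deg + self.beta_deg > self.theta_half_deg:
            raise InvalidSpecError(
                f"alpha + beta = {self.alpha_deg + self.beta_deg} deg exceeds the "
                f"half-winding angle {self.theta_half_deg} deg"
            )
        if int(self.segments_per_turn) != self.segments_per_turn or self.segments_per_turn < 8:
            raise InvalidSpecError("segments_per_turn must be an integer >= 8")

    @property
    def theta_half_deg(self) -> float:
        """Winding angle of one coil half, ``n_turns * 360 / 2`` degrees."""
        return self.n_turns * 360.0 / 2.0

    @property
    def radius_mm(self) -> float:
        return self.winding_diameter_mm / 2.0

    def with_angles(self, alpha_deg: float, beta_deg: float) -> "SolenoidSpec":
        """Return a copy with different segment angles."""
        return replace(self, alpha_deg=alpha_deg, beta_deg=beta_deg)


@dataclass(frozen=True)
class ConductorPath:
    """A discretized current-carrying polyline (vertices in metres).

    ``closed=True`` means the segment from the last back to the first
    vertex also carries the current (a loop); for open paths (solenoids)
    current enters at the first vertex and leaves at the last.
    """

    vertices: np.ndarray
    closed: bool = False
    current_a: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
            raise InvalidSpecError("vertices must be an (N>=2, 3) array")
        object.__setattr__(self, "vertices", v)
        step = np.diff(v, axis=0)
        if np.any(np.all(step == 0.0, axis=1)):
            raise InvalidSpecError("consecutive vertices must be distinct")
        if self.closed and np.all(v[0] == v[-1]):
            raise InvalidSpecError(
                "closed paths must not repeat the first vertex; the closing "
                "segment is implied"
            )

    @property
    def n_segments(self) -> int:
        return len(self.vertices) if self.closed else len(self.vertices) - 1

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment midpoints and direction vectors ``(mid, dl)``, each (S, 3)."""
        v = self.vertices
        if self.closed:
            nxt = np.roll(v, -1, axis=0)
            return (v + nxt) / 2.0, nxt - v
        return (v[:-1] + v[1:]) / 2.0, np.diff(v, axis=0)

    def with_current(self, current_a: float) -> "ConductorPath":
        return ConductorPath(self.vertices, closed=self.closed, current_a=current_a)


def plateau_pitch(spec: SolenoidSpec) -> float:
    """Constant-segment pitch ``p_c`` in mm per degree of winding angle.

    The unique plateau value for which the half-profile integrates to half
    the winding length:  ``p_c = (L/2) / (theta_half - alpha - beta/2)``.
    """
    denom = spec.theta_half_deg - spec.alpha_deg - spec.beta_deg / 2.0
    if denom <= 0:
        raise InvalidSpecError(
            "flat and ramp segments leave no room for the constant-pitch segment"
        )
    return (spec.winding_length_mm / 2.0) / denom


def pitch_profile(spec: SolenoidSpec, theta_deg):
    """Axial pitch (mm per degree) at winding angle ``theta_deg`` from the
    nearer coil end.

    Defined on the half-winding ``[0, theta_half]``; the other half is the
    mirror image.  Zero on the flat segment, linear on the ramp, constant
    (``p_c``) beyond.  ``beta = 0`` degenerates to a step at ``alpha``.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta > spec.theta_half_deg):
        raise InvalidSpecError(
            f"theta must lie in [0, {spec.theta_half_deg}] deg (half-winding)"
        )
    a, b = spec.alpha_deg, spec.beta_deg
    pc = plateau_pitch(spec)
    if b == 0.0:
        out = np.where(theta < a, 0.0, pc)
    else:
        # errstate: the ramp expression is evaluated (then discarded) even
        # where the np.where mask selects another branch
        with np.errstate(over="ignore", invalid="ignore"):
            ramp = pc * (theta - a) / b
            out = np.where(theta < a, 0.0, np.where(theta < a + b, ramp, pc))
    return out if out.ndim else float(out)


def _half_axial_mm(spec: SolenoidSpec, theta: np.ndarray) -> np.ndarray:
    """Closed-form integral of :func:`pitch_profile` from 0 to ``theta`` (mm)."""
    a, b = spec.alpha_deg, spec.beta_deg
    pc = plateau_pitch(spec)
    if b == 0.0:
        return pc * np.clip(theta - a, 0.0, None)
    with np.errstate(over="ignore", invalid="ignore"):
        ramp = pc * (theta - a) ** 2 / (2.0 * b)
        plateau = pc * (b / 2.0 + (theta - a - b))
        return np.where(theta <= a, 0.0, np.where(theta <= a + b, ramp, plateau))


def build_variable_pitch_solenoid(spec: SolenoidSpec) -> ConductorPath:
    """Discretize the variable-pitch solenoid winding into a polyline.

    The path is a right-handed helix starting at azimuth 0, uniformly
    sampled in winding angle with ``n_turns * segments_per_turn`` segments,
    centred at ``z = 0``.  Axial positions are evaluated from the
    closed-form integral of the mirrored pitch profile, and the second half
    is produced by reflecting the first so the path is mirror-symmetric
    about the midplane to machine precision.
    """
    n_seg = spec.n_turns * spec.segments_per_turn
    if abs(n_seg - round(n_seg)) > 1e-9:
        raise InvalidSpecError(
            "n_turns * segments_per_turn must be an integer number of segments"
        )
    n_seg = int(round(n_seg))
    theta_tot = spec.n_turns * 360.0

    k = np.arange(n_seg + 1)
    phi = k * (theta_tot / n_seg)  # winding angle, degrees

    half = n_seg // 2
    theta_lo = phi[: half + 1]  # first half incl. midpoint (or mid-segment)
    z_lo = _half_axial_mm(spec, theta_lo) - spec.winding_length_mm / 2.0
    z = np.empty(n_seg + 1)
    z[: half + 1] = z_lo
    # mirror the first half exactly: z[n_seg - k] = -z[k]
    z[n_seg - half :] = -z_lo[::-1]
    if n_seg % 2 == 0:
        z[half] = 0.0  # exact midplane vertex

    rad = np.deg2rad(phi)
    r = spec.radius_mm
    verts_mm = np.column_stack((r * np.cos(rad), r * np.sin(rad), z))
    return ConductorPath(verts_mm * MM, closed=False, current_a=spec.current_a)


def build_regular_solenoid(spec: SolenoidSpec) -> ConductorPath:
    """The constant-pitch reference solenoid (``alpha = beta = 0``).

    Other fields of ``spec`` (dimensions, turns, current, discretization)
    are used unchanged.
    """
    return build_variable_pitch_solenoid(spec.with_angles(0.0, 0.0))


def build_circular_loop(
    radius_mm: float,
    z_offset_mm: float = 0.0,
    n_segments: int = 3600,
    current_a: float = 1.0,
) -> ConductorPath:
    """Closed regular polygon approximating a circular loop.

    Lies in the plane ``z = z_offset_mm``; mainly an analytic validation
    fixture for the field solver (the on-axis loop field has a closed
    form).
    """
    if radius_mm <= 0:
        raise InvalidSpecError("radius_mm must be > 0")
    if int(n_segments) != n_segments or n_segments < 8:
        raise InvalidSpecError("n_segments must be an integer >= 8")
    phi = 2.0 * np.pi * np.arange(int(n_segments)) / int(n_segments)
    verts_mm = np.column_stack(
        (
            radius_mm * np.cos(phi),
            radius_mm * np.sin(phi),
            np.full(int(n_segments), float(z_offset_mm)),
        )
    )
    return ConductorPath(verts_mm * MM, closed=True, current_a=current_a)


def check_strip_clearance(
    spec: SolenoidSpec, path: ConductorPath | None = None, strip_width_mm: float = 5.0
) -> float:
    """Smallest axial gap between adjacent turn centerlines, in mm.

    The physical coil is wound from flat copper strip; if adjacent turn
    centerlines approach closer than the strip width the strips would
    overlap.  This emits a warning but does not reject the geometry (end
    rings of extreme flat-segment designs legitimately stack).
    """
    if path is None:
        path = build_variable_pitch_solenoid(spec)
    spt = int(spec.segments_per_turn)
    z = path.vertices[:, 2] / MM
    if len(z) <= spt:
        return float("inf")
    gaps = np.abs(z[spt:] - z[:-spt])  # same azimuth, one turn apart
    min_gap = float(gaps.min())
    if min_gap < strip_width_mm:
        warnings.warn(
            f"adjacent turn centerlines come within {min_gap:.2f} mm "
            f"(< strip width {strip_width_mm} mm); strips would overlap",
            stacklevel=2,
        )
    return min_gap
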