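"""Numba-accelerated Biot-Savart accumulation kernel.

The kernel sums the midpoint-rule Biot-Savart contributions of all
segments at all points and records, per point, the minimal clearance
margin ``r^2 - excl2`` so the caller can diagnose near-singular points
without a branch in the hot loop.  Importing this module is optional; the
solver falls back to a chunked numpy implementation when numba is
unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def deco(f):
            return f

        return deco


@njit(cache=True, fastmath=True)
def _accumulate(mid, dl, pts, excl2, out, margin):  # pragma: no cover - jitted
    n_pts = pts.shape[0]
    n_seg = mid.shape[0]
    for i in range(n_pts):
        px = pts[i, 0]
        py = pts[i, 1]
        pz = pts[i, 2]
        bx = 0.0
        by = 0.0
        bz = 0.0
        m = 1.0e300
        for s in range(n_seg):
            dx = px - mid[s, 0]
            dy = py - mid[s, 1]
            dz = pz - mid[s, 2]
            r2 = dx * dx + dy * dy + dz * dz
            g = r2 - excl2[s]
            if g < m:
                m = g
            w = 1.0 / (r2 * np.sqrt(r2))
            bx += (dl[s, 1] * dz - dl[s, 2] * dy) * w
            by += (dl[s, 2] * dx - dl[s, 0] * dz) * w
            bz += (dl[s, 0] * dy - dl[s, 1] * dx) * w
        out[i, 0] = bx
        out[i, 1] = by
        out[i, 2] = bz
        margin[i] = m


def accumulate_field(
    mid: np.ndarray, dl: np.ndarray, pts: np.ndarray, excl2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled Biot-Savart sum (no mu0*I/4pi prefactor) and clearance margin.

    Returns ``(out, margin)`` where ``out`` is the (N, 3) per-point sum of
    ``dl x d / |d|^3`` and ``margin[i] = min_s(|p_i - m_s|^2 - excl2[s])``
    (negative when point i violates the exclusion distance).
    """
    out = np.empty((pts.shape[0], 3))
    margin = np.empty(pts.shape[0])
    _accumulate(
        np.ascontiguousarray(mid),
        np.ascontiguousarray(dl),
        np.ascontiguousarray(pts),
        np.ascontiguousarray(excl2),
        out,
        margin,
    )
    return out, margin
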