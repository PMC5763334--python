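"""Independent reference implementations used only to check the package.

These deliberately avoid the package's vectorized/compiled code paths:
plain Python loops and ``math`` only, so they cannot share a bug with the
implementation under test.
"""

import math

# the vacuum permeability is a shared physical constant, not part of the
# algorithm under test (post-2019 SI: measured, not exactly 4pi e-7)
from scipy.constants import mu_0 as MU0


def naive_biot_savart(vertices, closed, current, points):
    """Per-point, per-segment double-loop midpoint-rule Biot-Savart sum."""
    segs = []
    n = len(vertices)
    last = n if closed else n - 1
    for i in range(last):
        a = vertices[i]
        b = vertices[(i + 1) % n]
        mid = [(a[k] + b[k]) / 2.0 for k in range(3)]
        dl = [b[k] - a[k] for k in range(3)]
        segs.append((mid, dl))
    pref = MU0 * current / (4.0 * math.pi)
    out = []
    for p in points:
        bx = by = bz = 0.0
        for mid, dl in segs:
            dx, dy, dz = p[0] - mid[0], p[1] - mid[1], p[2] - mid[2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            w = 1.0 / r**3
            bx += (dl[1] * dz - dl[2] * dy) * w
            by += (dl[2] * dx - dl[0] * dz) * w
            bz += (dl[0] * dy - dl[1] * dx) * w
        out.append([pref * bx, pref * by, pref * bz])
    return out


def loop_centre_field(radius_m, current=1.0):
    """|B| at the centre of an ideal circular loop: mu0 I / 2R."""
    return MU0 * current / (2.0 * radius_m)


def loop_axis_field(radius_m, z_m, current=1.0):
    """On-axis field of an ideal circular loop (independent closed form)."""
    return MU0 * current * radius_m**2 / (2.0 * (radius_m**2 + z_m**2) ** 1.5)
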