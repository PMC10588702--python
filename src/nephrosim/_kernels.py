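"""Compiled Gauss-Seidel projection sweeps.

The solver projects constraints sequentially and in place (Gauss-Seidel),
which cannot be vectorized without changing the iteration semantics; these
numba kernels keep the per-constraint loop exact while running at native
speed.  The scalar numpy projections in :mod:`nephrosim.pbd` are the
reference implementations; the test suite asserts kernel/scalar agreement.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sweep_stretch", "sweep_bend", "sweep_planes"]


@njit(cache=False)
def sweep_stretch(p, w, ij, rest, kprime, alive):  # pragma: no cover - compiled
    for c in range(ij.shape[0]):
        if not alive[c]:
            continue
        i = ij[c, 0]
        j = ij[c, 1]
        wi = w[i]
        wj = w[j]
        ws = wi + wj
        if ws == 0.0:
            continue
        dx = p[i, 0] - p[j, 0]
        dy = p[i, 1] - p[j, 1]
        dz = p[i, 2] - p[j, 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        if dist == 0.0:
            continue
        s = kprime[c] * (dist - rest[c]) / (ws * dist)
        p[i, 0] -= wi * s * dx
        p[i, 1] -= wi * s * dy
        p[i, 2] -= wi * s * dz
        p[j, 0] += wj * s * dx
        p[j, 1] += wj * s * dy
        p[j, 2] += wj * s * dz


@njit(cache=False)
def _cross(ax, ay, az, bx, by, bz):  # pragma: no cover - compiled
    return ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx


@njit(cache=False)
def sweep_bend(p, w, quads, rest_angle, kprime, alive):  # pragma: no cover
    eps = 1e-12
    for c in range(quads.shape[0]):
        if not alive[c]:
            continue
        i1 = quads[c, 0]
        i2 = quads[c, 1]
        i3 = quads[c, 2]
        i4 = quads[c, 3]
        # edge vectors relative to p1
        e2x = p[i2, 0] - p[i1, 0]
        e2y = p[i2, 1] - p[i1, 1]
        e2z = p[i2, 2] - p[i1, 2]
        e3x = p[i3, 0] - p[i1, 0]
        e3y = p[i3, 1] - p[i1, 1]
        e3z = p[i3, 2] - p[i1, 2]
        e4x = p[i4, 0] - p[i1, 0]
        e4y = p[i4, 1] - p[i1, 1]
        e4z = p[i4, 2] - p[i1, 2]
        # u1 = e3 x e2 (normal of triangle (p1, p3, p2)); u2 = e2 x e4
        u1x, u1y, u1z = _cross(e3x, e3y, e3z, e2x, e2y, e2z)
        u2x, u2y, u2z = _cross(e2x, e2y, e2z, e4x, e4y, e4z)
        l1 = np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
        l2 = np.sqrt(u2x * u2x + u2y * u2y + u2z * u2z)
        if l1 < eps or l2 < eps:
            continue
        n1x, n1y, n1z = u1x / l1, u1y / l1, u1z / l1
        n2x, n2y, n2z = u2x / l2, u2y / l2, u2z / l2
        d = n1x * n2x + n1y * n2y + n1z * n2z
        if d > 1.0:
            d = 1.0
        elif d < -1.0:
            d = -1.0
        cval = np.arccos(d) - rest_angle[c]
        if cval == 0.0:
            continue
        s2 = 1.0 - d * d
        if s2 < eps:
            continue
        # q1 = (n2 - d n1)/l1 ; q2 = (n1 - d n2)/l2  (grad of dot wrt u1, u2)
        q1x = (n2x - d * n1x) / l1
        q1y = (n2y - d * n1y) / l1
        q1z = (n2z - d * n1z) / l1
        q2x = (n1x - d * n2x) / l2
        q2y = (n1y - d * n2y) / l2
        q2z = (n1z - d * n2z) / l2
        # grad of dot wrt the points, via u1 = e3 x e2, u2 = e2 x e4
        g3x, g3y, g3z = _cross(e2x, e2y, e2z, q1x, q1y, q1z)
        g4x, g4y, g4z = _cross(q2x, q2y, q2z, e2x, e2y, e2z)
        a2x, a2y, a2z = _cross(q1x, q1y, q1z, e3x, e3y, e3z)
        b2x, b2y, b2z = _cross(e4x, e4y, e4z, q2x, q2y, q2z)
        g2x = a2x + b2x
        g2y = a2y + b2y
        g2z = a2z + b2z
        g1x = -(g2x + g3x + g4x)
        g1y = -(g2y + g3y + g4y)
        g1z = -(g2z + g3z + g4z)
        # dC/dp = -grad(dot)/sqrt(1-d^2)
        inv = -1.0 / np.sqrt(s2)
        g1x *= inv
        g1y *= inv
        g1z *= inv
        g2x *= inv
        g2y *= inv
        g2z *= inv
        g3x *= inv
        g3y *= inv
        g3z *= inv
        g4x *= inv
        g4y *= inv
        g4z *= inv
        denom = (
            w[i1] * (g1x * g1x + g1y * g1y + g1z * g1z)
            + w[i2] * (g2x * g2x + g2y * g2y + g2z * g2z)
            + w[i3] * (g3x * g3x + g3y * g3y + g3z * g3z)
            + w[i4] * (g4x * g4x + g4y * g4y + g4z * g4z)
        )
        if denom < eps:
            continue
        s = kprime[c] * cval / denom
        p[i1, 0] -= s * w[i1] * g1x
        p[i1, 1] -= s * w[i1] * g1y
        p[i1, 2] -= s * w[i1] * g1z
        p[i2, 0] -= s * w[i2] * g2x
        p[i2, 1] -= s * w[i2] * g2y
        p[i2, 2] -= s * w[i2] * g2z
        p[i3, 0] -= s * w[i3] * g3x
        p[i3, 1] -= s * w[i3] * g3y
        p[i3, 2] -= s * w[i3] * g3z
        p[i4, 0] -= s * w[i4] * g4x
        p[i4, 1] -= s * w[i4] * g4y
        p[i4, 2] -= s * w[i4] * g4z


@njit(cache=False)
def sweep_planes(p, w, vidx, points, normals):  # pragma: no cover - compiled
    for c in range(vidx.shape[0]):
        i = vidx[c]
        if w[i] == 0.0:
            continue
        cval = (
            (p[i, 0] - points[c, 0]) * normals[c, 0]
            + (p[i, 1] - points[c, 1]) * normals[c, 1]
            + (p[i, 2] - points[c, 2]) * normals[c, 2]
        )
        if cval < 0.0:
            p[i, 0] -= cval * normals[c, 0]
            p[i, 1] -= cval * normals[c, 1]
            p[i, 2] -= cval * normals[c, 2]
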