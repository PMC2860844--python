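"""Internal-coordinate geometry: atom placement (NeRF) and torsion measurement."""

from __future__ import annotations

import math

import numpy as np

from .errors import PmhcError

__all__ = ["place_atom", "dihedral", "bond_angle", "rotation_about_axis"]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d from three reference atoms and internal coordinates.

    ``bond`` is |c-d|, ``angle_deg`` the b-c-d angle and ``torsion_deg`` the
    a-b-c-d dihedral (natural extension reference frame).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)

    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nbc < 1e-8 or nn < 1e-8:
        raise PmhcError("degenerate reference frame for atom placement")
    bc /= nbc
    n /= nn
    m = np.cross(n, bc)

    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cross3(u, v):
    return (u[1] * v[2] - u[2] * v[1], u[2] * v[0] - u[0] * v[2], u[0] * v[1] - u[1] * v[0])


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    # scalar math on purpose: this sits in the minimizer's inner loop
    b0 = (p0[0] - p1[0], p0[1] - p1[1], p0[2] - p1[2])
    b1 = (p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2])
    b2 = (p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2])
    nb1 = math.sqrt(b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2)
    if nb1 < 1e-10:
        raise PmhcError("degenerate dihedral (zero-length central bond)")
    b1u = (b1[0] / nb1, b1[1] / nb1, b1[2] / nb1)
    d0 = b0[0] * b1u[0] + b0[1] * b1u[1] + b0[2] * b1u[2]
    d2 = b2[0] * b1u[0] + b2[1] * b1u[1] + b2[2] * b1u[2]
    v = (b0[0] - d0 * b1u[0], b0[1] - d0 * b1u[1], b0[2] - d0 * b1u[2])
    w = (b2[0] - d2 * b1u[0], b2[1] - d2 * b1u[1], b2[2] - d2 * b1u[2])
    x = v[0] * w[0] + v[1] * w[1] + v[2] * w[2]
    cv = _cross3(b1u, v)
    y = cv[0] * w[0] + cv[1] * w[1] + cv[2] * w[2]
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if abs(ang + 180.0) < 1e-9 else ang


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u = (a[0] - b[0], a[1] - b[1], a[2] - b[2])
    v = (c[0] - b[0], c[1] - b[1], c[2] - b[2])
    nu = math.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    nv = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    cosang = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise PmhcError("zero rotation axis")
    x, y, z = axis / n
    c, s = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    C = 1.0 - c
    return np.array([
        [x * x * C + c, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, y * y * C + c, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, z * z * C + c],
    ])
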