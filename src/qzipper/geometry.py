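"""Internal-coordinate geometry: NeRF atom placement, dihedral/angle
measurement, and circular statistics for dihedral populations.

All distances are in nm internally; angles cross the interface in degrees.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "measure_angle",
    "measure_dihedral",
    "circular_mean",
    "circular_mode",
    "wrap_angle",
    "rotation_about_axis",
]


def wrap_angle(deg):
    """Wrap angles into (-180, 180]."""
    a = np.asarray(deg, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w if w.ndim else float(w)


def place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D bonded to C given reference atoms A-B-C (NeRF).

    ``bond`` = |C-D|, ``angle_deg`` = angle(B,C,D), ``torsion_deg`` =
    dihedral(A,B,C,D) in the IUPAC sign convention.
    """
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_angle(a, b, c):
    """Planar angle A-B-C in degrees."""
    v1 = a - b
    v2 = c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def measure_dihedral(p0, p1, p2, p3):
    """Signed dihedral angle (deg) of the four points, IUPAC convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def circular_mean(deg):
    """Mean direction (deg) of angular samples."""
    rad = np.radians(np.asarray(deg, dtype=float))
    s = np.mean(np.sin(rad))
    c = np.mean(np.cos(rad))
    return wrap_angle(np.degrees(np.arctan2(s, c)))


def circular_mode(deg, kappa: float = 50.0, grid: int = 1440):
    """Mode of an angular sample via a von Mises kernel density estimate.

    Robust against multimodality, unlike the circular mean.  Returns the
    grid angle (deg, in (-180, 180]) with maximum density.
    """
    rad = np.radians(np.asarray(deg, dtype=float))
    if rad.size == 0:
        raise ValueError("circular_mode of empty sample")
    g = np.linspace(-np.pi, np.pi, grid, endpoint=False)
    dens = np.exp(kappa * np.cos(g[:, None] - rad[None, :])).sum(axis=1)
    return wrap_angle(np.degrees(g[int(np.argmax(dens))]))


def rotation_about_axis(axis, angle_deg):
    """3x3 rotation matrix about a unit axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(th) * k + (1.0 - np.cos(th)) * (k @ k)
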