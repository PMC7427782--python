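"""Low-level vector geometry: angles, torsions, internal-coordinate placement."""

from __future__ import annotations

import numpy as np

__all__ = ["unit", "bond_angle", "dihedral_angle", "place_atom", "rotation_about_axis"]


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral_angle(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Torsion p0-p1-p2-p3 with IUPAC sign convention, degrees in (-180, 180]."""
    b0 = p0 - p1
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom d from internal coordinates (NeRF).

    d satisfies |c-d| = bond_length, angle(b,c,d) = angle_deg and
    dihedral(a,b,c,d) = torsion_deg under the convention of
    :func:`dihedral_angle`.
    """
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    w = unit(c - b)
    n = unit(np.cross(b - a, w))
    m = np.cross(n, w)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * w + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    k = unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * kx + (1 - np.cos(t)) * (kx @ kx)
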