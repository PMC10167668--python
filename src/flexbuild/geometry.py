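"""Low-level 3-D geometry: dihedral measurement, axis rotations, atom placement.

All angles are in degrees.  Dihedrals follow the signed IUPAC convention and
are reported in the half-open interval [-180, 180).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "normalize_angle",
    "dihedral",
    "rotate_about_axis",
    "set_dihedral",
    "place_atom",
]


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees onto [-180, 180)."""
    return float(((angle + 180.0) % 360.0) - 180.0)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in [-180, 180).

    Looking along the p1->p2 bond, a clockwise rotation of p3 relative to p0
    is positive (IUPAC convention).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        raise ValueError("degenerate dihedral: coincident axis atoms")
    b1 = b1 / nb1
    # components of b0/b2 perpendicular to the bond axis
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return normalize_angle(math.degrees(math.atan2(y, x)))


def rotate_about_axis(points: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate points (N,3) about the axis through `origin` along `axis`.

    Right-handed rotation by `angle_deg` (Rodrigues formula).  Rotating the
    distal atom of a dihedral quadruple about its central bond by +delta
    increases the measured dihedral by +delta.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    origin = np.asarray(origin, dtype=float)
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    rel = pts - origin
    rot = (rel * c
           + np.cross(u, rel) * s
           + np.outer(np.dot(rel, u), u) * (1.0 - c))
    out = rot + origin
    return out if np.asarray(points).ndim == 2 else out[0]


def set_dihedral(coords: dict, quadruple, moving_atoms, target_deg: float) -> None:
    """Rotate `moving_atoms` rigidly so dihedral(quadruple) == target_deg.

    `coords` maps atom name -> (3,) array and is modified in place.  Bond
    lengths and bond angles of the moved atoms relative to the axis are
    preserved exactly (rigid rotation about the central bond).
    """
    a, b, c, d = (coords[name] for name in quadruple)
    current = dihedral(a, b, c, d)
    delta = normalize_angle(target_deg - current)
    axis = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
    names = list(moving_atoms)
    pts = np.array([coords[n] for n in names], dtype=float)
    newpts = rotate_about_axis(pts, b, axis, delta)
    for name, p in zip(names, newpts):
        coords[name] = p


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to c with |cD| = bond, angle(b,c,D) = angle_deg and
    dihedral(a,b,c,D) = torsion_deg (natural extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local
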