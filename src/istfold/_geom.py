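"""Small vector-geometry helpers shared across modules.

Everything here operates on plain numpy arrays in Angstroms; no knowledge
of residues or chains.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "rotation_about_axis",
    "rotation_aligning",
    "place_atom",
    "principal_axis",
    "segment_segment_distance",
    "fibonacci_sphere",
    "angle_deg",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return v normalised to unit length."""
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about `axis` (Rodrigues)."""
    a = unit(np.asarray(axis, dtype=float))
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(a, a)


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying unit vector a onto unit vector b."""
    a = unit(np.asarray(a, dtype=float))
    b = unit(np.asarray(b, dtype=float))
    c = float(np.dot(a, b))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any axis perpendicular to a
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(a, helper))
        return rotation_about_axis(axis, np.pi)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    return rotation_about_axis(axis / s, np.arctan2(s, c))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg_: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position atom d bonded to c, given chain a-b-c.

    `bond` is the c-d length, `angle_deg_` the b-c-d angle and
    `dihedral_deg` the a-b-c-d torsion.
    """
    ang = np.deg2rad(angle_deg_)
    tor = np.deg2rad(dihedral_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and dominant principal direction of a point cloud.

    The direction is undirected; callers orient it as needed.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    return centroid, vt[0]


def segment_segment_distance(p1: np.ndarray, q1: np.ndarray,
                             p2: np.ndarray, q2: np.ndarray) -> float:
    """Minimum distance between finite segments p1-q1 and p2-q2."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(np.dot(d1, d1))
    e = float(np.dot(d2, d2))
    f = float(np.dot(d2, r))
    EPS = 1e-12
    if a <= EPS and e <= EPS:
        return float(np.linalg.norm(r))
    if a <= EPS:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(np.dot(d1, r))
        if e <= EPS:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(np.dot(d1, d2))
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > EPS else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t = 1.0
                s = np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    c = np.clip(np.dot(unit(u), unit(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))
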