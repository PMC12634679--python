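"""Internal Cartesian/internal-coordinate helpers (NeRF atom placement)."""
from __future__ import annotations

import numpy as np

__all__ = ["bond_angle", "dihedral", "place_atom"]


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    a = p0 - p1
    b = p2 - p1
    c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom X bonded to ``a`` such that |X-a| = length, the angle
    X-a-b equals ``angle`` (deg) and the dihedral X-a-b-c equals
    ``torsion`` (deg).  Standard natural-extension (NeRF) construction.
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    ab = a - b
    cb = b - c

    n_ab = ab / np.linalg.norm(ab)
    # orthonormal frame at a
    n = np.cross(cb, n_ab)
    n /= np.linalg.norm(n)
    m = np.cross(n, n_ab)

    d = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(tor),
        length * np.sin(ang) * np.sin(tor),
    ])
    rot = np.column_stack([n_ab, m, n])
    return a + rot @ d
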