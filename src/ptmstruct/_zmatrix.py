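"""Internal-coordinate atom placement (NeRF) and dihedral measurement."""

from __future__ import annotations

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom D given atoms A, B, C and internal coordinates.

    *bond* = |C-D| in Angstroms, *angle* = B-C-D in degrees, *torsion* =
    dihedral A-B-C-D in degrees (right-handed about the B->C bond).
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # A, B, C collinear: any perpendicular reference works
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral A-B-C-D in degrees, in (-180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    return ang if ang > -180.0 else ang + 360.0
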