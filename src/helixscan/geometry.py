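"""Internal Cα-trace geometry: internal coordinates, chain construction, rotations.

All coordinates are in nanometres; angles are in radians unless a function
name says otherwise.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "bond_lengths",
    "bond_angles",
    "dihedrals",
    "build_chain",
    "rotate_about_axis",
]


def bond_lengths(coords: np.ndarray) -> np.ndarray:
    """Consecutive Cα–Cα distances, shape (n-1,)."""
    return np.linalg.norm(np.diff(coords, axis=0), axis=1)


def bond_angles(coords: np.ndarray) -> np.ndarray:
    """Pseudo-bond angles at residues 1..n-2, shape (n-2,)."""
    b = np.diff(coords, axis=0)
    u = b[:-1]
    v = b[1:]
    cosang = -np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def dihedrals(coords: np.ndarray) -> np.ndarray:
    """Signed Cα pseudo-dihedrals over atom quadruples (k..k+3), shape (n-3,).

    IUPAC sign convention: positive for a right-handed twist.
    """
    b = np.diff(coords, axis=0)
    b0, b1, b2 = b[:-2], b[1:-1], b[2:]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def _place_atom(a, b, c, bond: float, theta: float, phi: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    # sign of the n-component chosen so the measured signed dihedral
    # (IUPAC convention, see dihedrals()) equals phi
    d = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            -bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_chain(bond: float, angles: np.ndarray, dihs: np.ndarray) -> np.ndarray:
    """Cartesian chain from internal coordinates.

    ``angles`` has n-2 entries, ``dihs`` n-3; the first three atoms are placed
    canonically in the xy-plane.
    """
    angles = np.asarray(angles, dtype=float)
    dihs = np.asarray(dihs, dtype=float)
    n = len(angles) + 2
    if len(dihs) != n - 3:
        raise ValueError("need len(dihedrals) == len(angles) - 1")
    coords = np.zeros((n, 3))
    coords[1] = [bond, 0.0, 0.0]
    coords[2] = coords[1] + [
        -bond * np.cos(angles[0]),
        bond * np.sin(angles[0]),
        0.0,
    ]
    for i in range(3, n):
        coords[i] = _place_atom(
            coords[i - 3], coords[i - 2], coords[i - 1], bond, angles[i - 2], dihs[i - 3]
        )
    return coords


def rotate_about_axis(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle: float
) -> np.ndarray:
    """Rodrigues rotation of ``points`` about a line through ``origin``."""
    k = axis / np.linalg.norm(axis)
    p = points - origin
    cos, sin = np.cos(angle), np.sin(angle)
    rotated = (
        p * cos
        + np.cross(k, p) * sin
        + np.outer(p @ k, k) * (1.0 - cos)
    )
    return rotated + origin
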