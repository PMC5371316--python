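"""Numerical hot-path kernels for the Monte Carlo sampler.

Plain-loop implementations compiled with numba when available; the module
degrades to equivalent NumPy code otherwise.  Only the sampler inner loop
goes through here — public functions keep their NumPy reference
implementations as the behavioural contract.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False, fastmath=False)
def energy_kernel(
    coords: np.ndarray,
    helix_bias: np.ndarray,
    contact_strength: float,
    excluded_radius: float,
    angle_k: float,
    theta0: float,
    sigma: float,
    phi_helix: float,
    phi_ext: float,
    ext_depth: float,
    contact_cutoff: float,
    repulsion_k: float,
) -> tuple[float, float]:
    """Total model energy (kBT) and the minimum pairwise distance."""
    n = coords.shape[0]
    e = 0.0
    min_dist = 1e30

    # angles and dihedrals from bond vectors
    for i in range(1, n - 1):
        ux = coords[i - 1, 0] - coords[i, 0]
        uy = coords[i - 1, 1] - coords[i, 1]
        uz = coords[i - 1, 2] - coords[i, 2]
        vx = coords[i + 1, 0] - coords[i, 0]
        vy = coords[i + 1, 1] - coords[i, 1]
        vz = coords[i + 1, 2] - coords[i, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        e += 0.5 * angle_k * (theta - theta0) ** 2

    two_pi = 2.0 * np.pi
    for k in range(n - 3):
        b0x = coords[k + 1, 0] - coords[k, 0]
        b0y = coords[k + 1, 1] - coords[k, 1]
        b0z = coords[k + 1, 2] - coords[k, 2]
        b1x = coords[k + 2, 0] - coords[k + 1, 0]
        b1y = coords[k + 2, 1] - coords[k + 1, 1]
        b1z = coords[k + 2, 2] - coords[k + 1, 2]
        b2x = coords[k + 3, 0] - coords[k + 2, 0]
        b2y = coords[k + 3, 1] - coords[k + 2, 1]
        b2z = coords[k + 3, 2] - coords[k + 2, 2]
        n1x = b0y * b1z - b0z * b1y
        n1y = b0z * b1x - b0x * b1z
        n1z = b0x * b1y - b0y * b1x
        n2x = b1y * b2z - b1z * b2y
        n2y = b1z * b2x - b1x * b2z
        n2z = b1x * b2y - b1y * b2x
        nb1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        m1x = (n1y * b1z - n1z * b1y) / nb1
        m1y = (n1z * b1x - n1x * b1z) / nb1
        m1z = (n1x * b1y - n1y * b1x) / nb1
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = m1x * n2x + m1y * n2y + m1z * n2z
        phi = np.arctan2(y, x)
        dh = (phi - phi_helix + np.pi) % two_pi - np.pi
        de = (phi - phi_ext + np.pi) % two_pi - np.pi
        e -= helix_bias[k + 1] * np.exp(-0.5 * (dh / sigma) ** 2)
        e -= ext_depth * np.exp(-0.5 * (de / sigma) ** 2)

    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < min_dist:
                min_dist = d
            if j - i >= 4:
                if d < contact_cutoff:
                    e -= contact_strength
                if d < excluded_radius:
                    e += repulsion_k * (excluded_radius - d) ** 2
    return e, min_dist


@njit(cache=False, fastmath=False)
def drmsd_kernel(coords: np.ndarray, pairs: np.ndarray, d0: np.ndarray) -> float:
    s = 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        s += (d - d0[p]) ** 2
    return np.sqrt(s / pairs.shape[0])


@njit(cache=False, fastmath=False)
def rotate_tail_kernel(
    coords: np.ndarray, start: int, o0: int, o1: int, angle: float
) -> np.ndarray:
    """Rotate coords[start:] about the axis through atoms o0 -> o1."""
    out = coords.copy()
    ax = coords[o1, 0] - coords[o0, 0]
    ay = coords[o1, 1] - coords[o0, 1]
    az = coords[o1, 2] - coords[o0, 2]
    norm = np.sqrt(ax * ax + ay * ay + az * az)
    ax /= norm
    ay /= norm
    az /= norm
    c = np.cos(angle)
    s = np.sin(angle)
    ox = coords[o1, 0]
    oy = coords[o1, 1]
    oz = coords[o1, 2]
    for i in range(start, coords.shape[0]):
        px = coords[i, 0] - ox
        py = coords[i, 1] - oy
        pz = coords[i, 2] - oz
        dot = px * ax + py * ay + pz * az
        cx = ay * pz - az * py
        cy = az * px - ax * pz
        cz = ax * py - ay * px
        out[i, 0] = ox + px * c + cx * s + ax * dot * (1.0 - c)
        out[i, 1] = oy + py * c + cy * s + ay * dot * (1.0 - c)
        out[i, 2] = oz + pz * c + cz * s + az * dot * (1.0 - c)
    return out


@njit(cache=False, fastmath=False)
def rotate_span_kernel(
    coords: np.ndarray, lo: int, hi: int, o0: int, o1: int, angle: float
) -> np.ndarray:
    """Rotate coords[lo:hi] about the axis through atoms o0 -> o1."""
    out = coords.copy()
    ax = coords[o1, 0] - coords[o0, 0]
    ay = coords[o1, 1] - coords[o0, 1]
    az = coords[o1, 2] - coords[o0, 2]
    norm = np.sqrt(ax * ax + ay * ay + az * az)
    ax /= norm
    ay /= norm
    az /= norm
    c = np.cos(angle)
    s = np.sin(angle)
    ox = coords[o0, 0]
    oy = coords[o0, 1]
    oz = coords[o0, 2]
    for i in range(lo, hi):
        px = coords[i, 0] - ox
        py = coords[i, 1] - oy
        pz = coords[i, 2] - oz
        dot = px * ax + py * ay + pz * az
        cx = ay * pz - az * py
        cy = az * px - ax * pz
        cz = ax * py - ay * px
        out[i, 0] = ox + px * c + cx * s + ax * dot * (1.0 - c)
        out[i, 1] = oy + py * c + cy * s + ay * dot * (1.0 - c)
        out[i, 2] = oz + pz * c + cz * s + az * dot * (1.0 - c)
    return out
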