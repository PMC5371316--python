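"""dRMSD reaction coordinate, its gradient, and the quadratic umbrella restraint.

The coordinate is

    R(d_1 .. d_N) = sqrt( (1/N) * sum_i (d_i - d_i0)^2 )

over a fixed list of intra-chain distance pairs with reference values d_i0.
For the helicity coordinate the pairs are every (j, j+3) Cα pair with
d_i0 = 0.5 nm, so R = 0 is the fully helical chain and larger R means
increasing departure from the helix.  The umbrella restraint is
V(R) = 1/2 k0 (R - R0)^2 in kJ/mol.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cg_model import ChainConformation
from .errors import (
    InvalidLengthError,
    ShapeMismatchError,
    SingularGradientError,
)

HELICAL_REFERENCE_DISTANCE = 0.5  # nm, Cα(j)–Cα(j+3) in the helical state


@dataclass(frozen=True)
class DrmsdReference:
    """Pair list and per-pair reference distances defining the coordinate."""

    pairs: np.ndarray  # (N, 2) int
    d0: np.ndarray     # (N,) nm

    def __post_init__(self):
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        d0 = np.atleast_1d(np.asarray(self.d0, dtype=float))
        if len(d0) != len(pairs):
            raise ShapeMismatchError("d0 length must match the pair list")
        if np.any(d0 <= 0):
            raise ValueError("reference distances must be positive")
        if np.any(pairs < 0):
            raise ValueError("pair indices must be non-negative")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "d0", d0)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"pairs": self.pairs.tolist(), "d0": self.d0.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DrmsdReference":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["pairs"]), np.array(obj["d0"]))


@dataclass(frozen=True)
class RestraintSpec:
    """Quadratic dRMSD restraint: centre R0 (nm) and force constant k0
    (kJ mol^-1 nm^-2)."""

    r0: float
    k0: float

    def __post_init__(self):
        if self.r0 < 0:
            raise ValueError("R0 must be >= 0")
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")

    def to_dict(self) -> dict:
        return {"r0": self.r0, "k0": self.k0}


def make_helical_reference(
    n_residues: int, d0: float = HELICAL_REFERENCE_DISTANCE
) -> DrmsdReference:
    """All (j, j+3) pairs of an n-residue chain, each at reference ``d0``."""
    if n_residues < 4:
        raise InvalidLengthError("need at least 4 residues for a (j, j+3) pair")
    j = np.arange(n_residues - 3)
    return DrmsdReference(np.column_stack([j, j + 3]), np.full(n_residues - 3, d0))


def _coords_of(conf) -> np.ndarray:
    return conf.coords if isinstance(conf, ChainConformation) else np.asarray(conf, float)


def drmsd(conf, ref: DrmsdReference) -> float:
    """Distance-RMSD R in nm of a conformation from the reference distances."""
    from ._kernels import drmsd_kernel

    coords = _coords_of(conf)
    if np.max(ref.pairs) >= len(coords):
        raise ShapeMismatchError("pair index beyond chain length")
    return float(
        drmsd_kernel(np.ascontiguousarray(coords), ref.pairs, ref.d0)
    )


def drmsd_gradient(conf, ref: DrmsdReference) -> np.ndarray:
    """Analytic per-residue gradient dR/dx, shape (n, 3).

    Undefined at R = 0 (the square root is singular there); callers needing a
    force at the helical reference should use :func:`drmsd_squared_gradient`,
    which is regular everywhere.
    """
    coords = _coords_of(conf)
    r = drmsd(coords, ref)
    if r < 1e-12:
        raise SingularGradientError(
            "dR/dx is singular at R = 0; use drmsd_squared_gradient"
        )
    return drmsd_squared_gradient(coords, ref) / (2.0 * r)


def drmsd_squared_gradient(conf, ref: DrmsdReference) -> np.ndarray:
    """Gradient of R^2 — regular at R = 0; dR/dx = grad(R^2) / (2R)."""
    coords = _coords_of(conf)
    if np.max(ref.pairs) >= len(coords):
        raise ShapeMismatchError("pair index beyond chain length")
    grad = np.zeros_like(coords)
    i, j = ref.pairs[:, 0], ref.pairs[:, 1]
    vec = coords[i] - coords[j]
    d = np.linalg.norm(vec, axis=1)
    # d(R^2)/dx_i = (2/N) (d - d0) * (x_i - x_j)/d
    w = (2.0 / ref.n_pairs) * (d - ref.d0) / d
    np.add.at(grad, i, w[:, None] * vec)
    np.add.at(grad, j, -w[:, None] * vec)
    return grad


def restraint_energy(r: float, spec: RestraintSpec) -> float:
    """Umbrella energy V = 1/2 k0 (R - R0)^2 in kJ/mol."""
    if r < 0:
        raise ValueError("R must be >= 0")
    return 0.5 * spec.k0 * (r - spec.r0) ** 2
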