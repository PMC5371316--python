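"""Structural observables on Cα-trace ensembles.

Helicity here is a geometric criterion, not hydrogen-bond based secondary
structure assignment: a residue counts as helical when its Cα pseudo-dihedral
sits in the helical band [30, 80] deg and (where defined) its Cα(j)–Cα(j+3)
distance lies in [0.44, 0.56] nm.  The criterion is calibrated so an ideal
helix scores 1.0 and an extended chain 0.0.  The hydrogen-bond surrogate
counts medium/long-range Cα contacts (sequence separation >= 4 closer than
0.62 nm), which an ideal helix forms once per i,i+4 pair.

Clustering follows the greedy neighbour-count algorithm of Daura and
co-workers under a pairwise least-RMSD cutoff after optimal (Kabsch)
superposition.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import geometry
from .cg_model import ChainConformation
from .errors import InvalidLengthError, ShapeMismatchError
from .umbrella import WindowedSamples

HELICAL_DIHEDRAL_BAND = (30.0, 80.0)   # deg
HELICAL_D13_BAND = (0.44, 0.56)        # nm, Cα(j)–Cα(j+3)
HBOND_CUTOFF = 0.62                    # nm, Cα contact surrogate
HBOND_MIN_SEPARATION = 4


@dataclass(frozen=True)
class HelicityAssignment:
    """Per-residue helical flags; terminal residues lacking geometric context
    are non-assignable and excluded from the fraction's denominator."""

    flags: np.ndarray        # bool per residue
    assignable: np.ndarray   # bool per residue

    @property
    def fraction(self) -> float:
        n = np.count_nonzero(self.assignable)
        if n == 0:
            return 0.0
        return float(np.count_nonzero(self.flags & self.assignable) / n)


def assign_helicity(conf: ChainConformation) -> HelicityAssignment:
    """Geometric helicity assignment (see module docstring).

    Residue j (0-based, 1 <= j <= n-3) is assignable; it owns the
    pseudo-dihedral over atoms (j-1 .. j+2), and additionally must satisfy
    the d(j, j+3) distance test where that distance exists.
    """
    coords = conf.coords
    n = len(coords)
    if n < 4:
        raise InvalidLengthError("need at least 4 residues")
    phi = np.rad2deg(geometry.dihedrals(coords))  # phi[k] for atoms k..k+3
    lo, hi = HELICAL_DIHEDRAL_BAND
    flags = np.zeros(n, dtype=bool)
    assignable = np.zeros(n, dtype=bool)
    d13 = np.linalg.norm(coords[3:] - coords[:-3], axis=1)
    for j in range(1, n - 2):
        assignable[j] = True
        ok = lo <= phi[j - 1] <= hi
        if ok and j <= n - 4:
            ok = HELICAL_D13_BAND[0] <= d13[j] <= HELICAL_D13_BAND[1]
        flags[j] = ok
    return HelicityAssignment(flags=flags, assignable=assignable)


@dataclass
class HelicityCurve:
    """Mean helicity fraction binned on the dRMSD coordinate."""

    bin_centers: np.ndarray
    mean_fraction: np.ndarray
    counts: np.ndarray
    crossing: float | None  # R where the curve crosses 0.5, None if absent


def helicity_vs_r(
    samples: WindowedSamples, bin_width: float = 0.02
) -> HelicityCurve:
    """Helicity-fraction-versus-R calibration curve over all windows.

    Reports the R at which linear interpolation between bin centres crosses
    a fraction of 0.5 (``crossing=None`` when the curve never crosses).
    """
    rs, fracs = [], []
    for w in range(samples.n_windows):
        for conf, r in zip(samples.window_conformations(w), samples.r_values[w]):
            rs.append(r)
            fracs.append(assign_helicity(conf).fraction)
    rs = np.asarray(rs)
    fracs = np.asarray(fracs)
    edges = np.arange(0.0, rs.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(rs, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=fracs, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    crossing = None
    good = counts > 0
    c, m = centers[good], mean[good]
    for i in range(len(m) - 1):
        if (m[i] - 0.5) * (m[i + 1] - 0.5) <= 0 and m[i] != m[i + 1]:
            t = (0.5 - m[i]) / (m[i + 1] - m[i])
            crossing = float(c[i] + t * (c[i + 1] - c[i]))
            break
    return HelicityCurve(centers, mean, counts, crossing)


def radius_of_gyration(conf: ChainConformation | np.ndarray) -> float:
    """Unit-mass radius of gyration in nm."""
    coords = conf.coords if isinstance(conf, ChainConformation) else np.asarray(conf, float)
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def count_hbond_surrogate(conf: ChainConformation) -> int:
    """Number of Cα pairs (i, j), j >= i+4, closer than 0.62 nm."""
    coords = conf.coords
    if len(coords) < 5:
        raise InvalidLengthError("need at least 5 residues for an i,i+4 contact")
    count = 0
    for i in range(len(coords)):
        d = np.linalg.norm(coords[i + HBOND_MIN_SEPARATION :] - coords[i], axis=1)
        count += int(np.count_nonzero(d < HBOND_CUTOFF))
    return count


def _as_coords(x) -> np.ndarray:
    return x.coords if isinstance(x, ChainConformation) else np.asarray(x, float)


def kabsch_rmsd(a, b) -> float:
    """Least RMSD (nm) after optimal superposition with a proper rotation."""
    ca, cb = _as_coords(a), _as_coords(b)
    if ca.shape != cb.shape:
        raise ShapeMismatchError("conformations must have equal lengths")
    pa = ca - ca.mean(axis=0)
    pb = cb - cb.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(len(pa)))


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-pairs Kabsch RMSD for an (m, n, 3) stack of conformations.

    Batched closed-form Kabsch via SVD of the 3x3 covariance matrices, with
    the determinant sign fix restricting to proper rotations.
    """
    x = coords - coords.mean(axis=1, keepdims=True)
    m, n, _ = x.shape
    sq = np.einsum("mij,mij->m", x, x)
    out = np.zeros((m, m))
    ii, jj = np.triu_indices(m, k=1)
    # chunk the pair list to bound memory
    chunk = 200_000
    for s in range(0, len(ii), chunk):
        a = x[ii[s : s + chunk]]
        b = x[jj[s : s + chunk]]
        h = np.einsum("pni,pnj->pij", b, a)
        u, sv, vt = np.linalg.svd(h)
        sign = np.sign(np.linalg.det(np.einsum("pij,pjk->pik", u, vt)))
        sv[:, -1] *= sign
        e = sq[ii[s : s + chunk]] + sq[jj[s : s + chunk]] - 2.0 * sv.sum(axis=1)
        out[ii[s : s + chunk], jj[s : s + chunk]] = np.sqrt(np.maximum(e, 0.0) / n)
    return out + out.T


@dataclass
class ClusterSet:
    """Daura clusters: (center, members) lists sorted by decreasing size."""

    clusters: list[tuple[int, np.ndarray]]
    labels: list[str] | None
    cutoff: float

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for _, m in self.clusters])

    def membership(self) -> np.ndarray:
        n = sum(len(m) for _, m in self.clusters)
        out = np.empty(n, dtype=int)
        for cid, (_, members) in enumerate(self.clusters):
            out[members] = cid
        return out


def daura_cluster(
    structures: Sequence[ChainConformation] | np.ndarray,
    cutoff: float = 0.1,
    labels: Sequence[str] | None = None,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterSet:
    """Greedy neighbour-count clustering under a pairwise RMSD cutoff.

    Repeatedly the structure with the most neighbours within ``cutoff``
    (ties: lowest index) becomes a cluster centre; it and its neighbours are
    removed.  Clusters are reported sorted by decreasing size, ties by centre
    index.
    """
    if isinstance(structures, np.ndarray):
        stack = structures
    else:
        if len(structures) == 0:
            raise ValueError("need at least one structure")
        stack = np.array([s.coords for s in structures])
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(stack)
    m = len(stack)
    neighbor = rmsd_matrix <= cutoff
    np.fill_diagonal(neighbor, True)
    alive = np.ones(m, dtype=bool)
    clusters: list[tuple[int, np.ndarray]] = []
    while alive.any():
        counts = (neighbor & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest tied index
        members = np.flatnonzero(neighbor[center] & alive)
        clusters.append((center, members))
        alive[members] = False
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return ClusterSet(
        clusters=clusters,
        labels=list(labels) if labels is not None else None,
        cutoff=cutoff,
    )


def dominance_analysis(
    clusters: ClusterSet,
    min_size: int = 100,
    dominate_frac: float = 0.8,
    neglect_frac: float = 0.01,
) -> pd.DataFrame:
    """Per-(cluster, variant) dominance table for significant clusters.

    A cluster is significant when it holds strictly more than ``min_size``
    structures.  Within one, a variant's status is "dominated" when its share
    exceeds ``dominate_frac``, "neglected" below ``neglect_frac``, otherwise
    "neutral".  ``expected_share`` is each variant's share of all clustered
    structures, the uniform-contribution baseline.
    """
    if clusters.labels is None:
        raise ValueError("clusters carry no variant labels")
    labels = np.asarray(clusters.labels)
    variants = sorted(set(labels))
    if len(variants) < 2:
        raise ValueError("dominance analysis needs at least 2 variants")
    total_by_variant = {v: int(np.count_nonzero(labels == v)) for v in variants}
    n_total = len(labels)
    rows = []
    for cid, (center, members) in enumerate(clusters.clusters):
        size = len(members)
        if size <= min_size:
            continue
        member_labels = labels[members]
        for v in variants:
            share = float(np.count_nonzero(member_labels == v) / size)
            if share > dominate_frac:
                status = "dominated"
            elif share < neglect_frac:
                status = "neglected"
            else:
                status = "neutral"
            rows.append(
                {
                    "cluster_id": cid,
                    "size": size,
                    "center": center,
                    "variant": v,
                    "share": share,
                    "expected_share": total_by_variant[v] / n_total,
                    "status": status,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size", "center", "variant",
            "share", "expected_share", "status",
        ],
    )
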