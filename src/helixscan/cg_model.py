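"""Coarse-grained Cα helix–coil peptide model and synthetic NMR-shift generator.

The model represents a peptide as its Cα trace with a fixed virtual bond of
0.38 nm.  Its energy function (in units of kBT) is deliberately minimal:

* a harmonic pseudo-bond-angle term centred at 91 deg,
* a double-well potential in each Cα pseudo-dihedral with a helical minimum
  at +48 deg whose depth is the per-residue ``helix_bias`` h_j (kBT) and a
  fixed extended minimum at −170 deg,
* a square-well attraction of depth ``contact_strength`` between residues at
  sequence separation >= 4 closer than 0.62 nm, plus a harmonic soft-core
  repulsion inside ``excluded_radius``.

The helical geometry (91 deg / +48 deg) is calibrated so that an ideal helix
has every Cα(j)–Cα(j+3) distance at 0.50 nm — the reference distance of the
dRMSD reaction coordinate — and every Cα(j)–Cα(j+4) distance inside the
0.62 nm contact cutoff.

Four named parameter presets ("variants") emulate the qualitative behaviour
of four water force fields used for disordered-protein simulation: they
differ only in how strongly they stabilise helices (a multiplier on
``helix_bias``) and how compact they make the chain (``contact_strength``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .errors import (
    InvalidLengthError,
    SingularGeometryError,
    UnknownResidueError,
)

logger = logging.getLogger(__name__)

# -- fixed Cα-trace geometry (nm, degrees) ----------------------------------
BOND_LENGTH = 0.38
BOND_ANGLE_DEG = 91.0
HELIX_DIHEDRAL_DEG = 48.0
EXTENDED_DIHEDRAL_DEG = -170.0

# -- energy-function constants (kBT at 300 K, nm) ---------------------------
#: all model energies are expressed in units of kBT at this temperature;
#: sampling at another temperature rescales the Metropolis criterion
REFERENCE_TEMPERATURE = 300.0
ANGLE_FORCE_CONSTANT = 400.0    # kBT / rad^2; keeps Cα(j)-Cα(j+3) distances
                                # tight enough for geometric helix assignment
DIHEDRAL_WELL_SIGMA_DEG = 15.0  # width of both dihedral wells
EXTENDED_WELL_DEPTH = 0.9       # kBT, fixed depth of the coil well; kept
                                # below 1 so a unit helix_bias already makes
                                # the helix the global minimum
CONTACT_CUTOFF = 0.62           # nm, i,i+4-and-beyond attraction range
REPULSION_CONSTANT = 200.0      # kBT / nm^2 soft-core
BASE_WELL_DEPTH = 5.0           # kBT, helical well depth for Ala at scale 1

# -- synthetic chemical-shift constants (ppm) -------------------------------
FULL_HELIX_DELTA_CA = 3.1   # Cα secondary shift of a 100% helical residue
FULL_HELIX_DELTA_CB = -0.4  # Cβ secondary shift of a 100% helical residue


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("helixscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def random_coil_shifts() -> pd.DataFrame:
    """Packaged random-coil Cα/Cβ reference shifts (ppm), indexed by residue."""
    return _load_table("random_coil_shifts.csv").set_index("residue")


def helix_propensity_weights() -> dict[str, float]:
    """Per-residue intrinsic helix-propensity weights in [0, 1].

    Derived from an experimental helix-propensity free-energy scale
    (alanine = 1, proline/glycine ~ 0); used to map a sequence onto the
    per-residue well depths ``helix_bias``.
    """
    df = _load_table("helix_propensity.csv")
    return dict(zip(df["residue"], df["weight"].astype(float)))


@dataclass(frozen=True)
class ChainConformation:
    """Ordered Cα coordinates (nm) of one peptide segment."""

    coords: np.ndarray
    segment_id: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(coords) < 4:
            raise InvalidLengthError("chain needs at least 4 residues")
        bl = geometry.bond_lengths(coords)
        if np.any(np.abs(bl - BOND_LENGTH) > 1e-9):
            raise ValueError(
                f"virtual bond lengths deviate from {BOND_LENGTH} nm "
                f"(max |err| = {np.max(np.abs(bl - BOND_LENGTH)):.3e})"
            )
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.coords)


VARIANTS: dict[str, dict[str, float]] = {
    # helix_scale multiplies the sequence-derived well depths; contact_strength
    # (kBT) sets compaction.  Only the orderings are contractual: helix
    # stabilisation V-TIP4P-ws >= V-TIP3P > V-TIP4P-s > V-TIP4P-D, and
    # V-TIP4P-D the most extended / V-TIP3P the most compact.
    "V-TIP4P-ws": {"helix_scale": 1.15, "contact_strength": 0.8},
    "V-TIP3P": {"helix_scale": 1.00, "contact_strength": 1.2},
    "V-TIP4P-s": {"helix_scale": 0.70, "contact_strength": 0.8},
    "V-TIP4P-D": {"helix_scale": 0.30, "contact_strength": 0.1},
}


@dataclass(frozen=True)
class ModelParameters:
    """Energy-function parameters of the coarse-grained peptide model.

    ``helix_bias`` holds the per-residue helical well depth h_j in kBT
    (dimensionless energies; >= 0).  ``contact_strength`` is the depth of the
    square-well attraction in kBT.
    """

    helix_bias: np.ndarray
    contact_strength: float = 1.0
    excluded_radius: float = 0.40
    temperature: float = 300.0
    variant_name: str = "custom"

    def __post_init__(self):
        hb = np.atleast_1d(np.asarray(self.helix_bias, dtype=float))
        if np.any(hb < 0):
            raise ValueError("helix_bias entries must be >= 0")
        if self.contact_strength < 0:
            raise ValueError("contact_strength must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "helix_bias", hb)

    @property
    def n_residues(self) -> int:
        return len(self.helix_bias)

    def with_temperature(self, temperature: float) -> "ModelParameters":
        return replace(self, temperature=temperature)


def variant_parameters(
    variant_name: str,
    sequence: str | None = None,
    n_residues: int | None = None,
    temperature: float = 300.0,
) -> ModelParameters:
    """Build :class:`ModelParameters` for one of the packaged variants.

    With a ``sequence``, per-residue well depths are
    ``BASE_WELL_DEPTH * helix_scale * w(aa_j)`` using the packaged propensity
    weights; otherwise a uniform profile of length ``n_residues``.
    """
    if variant_name not in VARIANTS:
        raise KeyError(
            f"unknown variant {variant_name!r}; choose from {sorted(VARIANTS)}"
        )
    preset = VARIANTS[variant_name]
    if sequence is not None:
        weights = helix_propensity_weights()
        try:
            w = np.array([weights[aa] for aa in sequence.upper()])
        except KeyError as exc:
            raise UnknownResidueError(f"no propensity weight for {exc}") from exc
    elif n_residues is not None:
        w = np.ones(n_residues)
    else:
        raise ValueError("provide sequence or n_residues")
    return ModelParameters(
        helix_bias=BASE_WELL_DEPTH * preset["helix_scale"] * w,
        contact_strength=preset["contact_strength"],
        temperature=temperature,
        variant_name=variant_name,
    )


def build_ideal_helix(n_residues: int, segment_id: str = "") -> ChainConformation:
    """Ideal Cα-trace helix: every Cα(j)–Cα(j+3) distance is 0.50 nm.

    Raises :class:`InvalidLengthError` for fewer than 4 residues.
    """
    if n_residues < 4:
        raise InvalidLengthError("a helix needs at least 4 residues")
    coords = geometry.build_chain(
        BOND_LENGTH,
        np.full(n_residues - 2, np.deg2rad(BOND_ANGLE_DEG)),
        np.full(n_residues - 3, np.deg2rad(HELIX_DIHEDRAL_DEG)),
    )
    return ChainConformation(coords, segment_id=segment_id)


def build_extended_chain(n_residues: int, segment_id: str = "") -> ChainConformation:
    """Fully extended chain (all pseudo-dihedrals at the −170 deg minimum)."""
    if n_residues < 4:
        raise InvalidLengthError("need at least 4 residues")
    coords = geometry.build_chain(
        BOND_LENGTH,
        np.full(n_residues - 2, np.deg2rad(BOND_ANGLE_DEG)),
        np.full(n_residues - 3, np.deg2rad(EXTENDED_DIHEDRAL_DEG)),
    )
    return ChainConformation(coords, segment_id=segment_id)


def potential_energy_raw(coords: np.ndarray, params: ModelParameters) -> float:
    """Model energy in kBT for a raw (n, 3) coordinate array."""
    from ._kernels import energy_kernel

    coords = np.ascontiguousarray(coords, dtype=float)
    n = len(coords)
    h = params.helix_bias
    if len(h) == 1:
        h = np.full(n, h[0])
    elif len(h) != n:
        raise ValueError("helix_bias length does not match chain length")
    e, min_dist = energy_kernel(
        coords,
        np.ascontiguousarray(h),
        params.contact_strength,
        params.excluded_radius,
        ANGLE_FORCE_CONSTANT,
        np.deg2rad(BOND_ANGLE_DEG),
        np.deg2rad(DIHEDRAL_WELL_SIGMA_DEG),
        np.deg2rad(HELIX_DIHEDRAL_DEG),
        np.deg2rad(EXTENDED_DIHEDRAL_DEG),
        EXTENDED_WELL_DEPTH,
        CONTACT_CUTOFF,
        REPULSION_CONSTANT,
    )
    if min_dist < 1e-6:
        raise SingularGeometryError("two residues overlap (distance < 1e-6 nm)")
    return float(e)


def potential_energy(conf: ChainConformation, params: ModelParameters) -> float:
    """Model energy of a conformation in kBT (see module docstring)."""
    return potential_energy_raw(conf.coords, params)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

#: fraction of dihedral proposals drawn fresh from the full circle, so the
#: sampler hops between the helical and extended wells
_JUMP_FRACTION = 0.25
_DIHEDRAL_STEP = np.deg2rad(35.0)
_CRANK_STEP = np.deg2rad(45.0)


class MonteCarloSampler:
    """Metropolis sampler over Cα-trace conformations.

    One "sweep" attempts one dihedral move per pseudo-dihedral plus
    ``(n-3)//2`` crankshaft moves.  An optional ``bias`` callable (coords ->
    energy in kBT) is added to the model energy; umbrella windows use it for
    their dRMSD restraint.
    """

    def __init__(
        self,
        params: ModelParameters,
        rng: np.random.Generator,
        initial: np.ndarray | None = None,
        bias: Callable[[np.ndarray], float] | None = None,
    ):
        self.params = params
        self.rng = rng
        self.bias = bias
        # model energies are kBT at 300 K; at temperature T each model
        # energy difference is scaled by 300/T in the acceptance criterion
        self.temp_scale = REFERENCE_TEMPERATURE / params.temperature
        n = params.n_residues
        if n < 4:
            raise InvalidLengthError("need at least 4 residues")
        if initial is None:
            initial = build_ideal_helix(n).coords
        self.coords = np.array(initial, dtype=float)
        self.energy = self._total_energy(self.coords)
        self.n_attempted = 0
        self.n_accepted = 0

    def _total_energy(self, coords: np.ndarray) -> float:
        """Dimensionless action: scaled model energy plus bias (already in
        units of kBT at the sampling temperature)."""
        e = potential_energy_raw(coords, self.params) * self.temp_scale
        if self.bias is not None:
            e += self.bias(coords)
        return e

    def _metropolis(self, new_coords: np.ndarray) -> bool:
        try:
            e_new = self._total_energy(new_coords)
        except SingularGeometryError:
            self.rng.random()  # keep the stream aligned with accepted branches
            return False
        u = self.rng.random()
        if e_new <= self.energy or u < np.exp(self.energy - e_new):
            self.coords = new_coords
            self.energy = e_new
            return True
        return False

    def _dihedral_move(self, k: int) -> bool:
        if self.rng.random() < _JUMP_FRACTION:
            dphi = self.rng.uniform(-np.pi, np.pi)
        else:
            dphi = self.rng.normal(0.0, _DIHEDRAL_STEP)
        from ._kernels import rotate_tail_kernel

        new = rotate_tail_kernel(self.coords, k + 3, k + 1, k + 2, dphi)
        return self._metropolis(new)

    def _crankshaft_move(self) -> bool:
        n = len(self.coords)
        i = int(self.rng.integers(0, n - 3))
        j = i + 3
        from ._kernels import rotate_span_kernel

        dphi = self.rng.normal(0.0, _CRANK_STEP)
        new = rotate_span_kernel(self.coords, i + 1, j, i, j, dphi)
        return self._metropolis(new)

    def sweep(self) -> None:
        n = len(self.coords)
        for k in range(n - 3):
            self.n_attempted += 1
            self.n_accepted += self._dihedral_move(k)
        for _ in range((n - 3) // 2):
            self.n_attempted += 1
            self.n_accepted += self._crankshaft_move()

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(self.n_attempted, 1)


def sample_unbiased(
    params: ModelParameters,
    n_steps: int,
    seed: int,
    initial: ChainConformation | None = None,
    save_every: int = 1,
    segment_id: str = "",
) -> list[ChainConformation]:
    """Unbiased Metropolis Monte Carlo trajectory of the model.

    ``n_steps`` counts MC sweeps; conformations are recorded every
    ``save_every`` sweeps.  The same seed reproduces the trajectory exactly.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng([seed, 0])
    sampler = MonteCarloSampler(
        params, rng, initial=None if initial is None else initial.coords
    )
    frames: list[ChainConformation] = []
    for step in range(1, n_steps + 1):
        sampler.sweep()
        if step % save_every == 0:
            frames.append(ChainConformation(sampler.coords.copy(), segment_id))
    logger.info(
        "sample_unbiased: %d sweeps, acceptance %.3f",
        n_steps,
        sampler.acceptance_rate,
    )
    return frames


# ---------------------------------------------------------------------------
# Synthetic chemical shifts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HelixProfile:
    """Ground-truth per-residue helical populations p_j in [0, 1]."""

    sequence: str
    populations: np.ndarray
    first_residue: int = 1

    def __post_init__(self):
        p = np.asarray(self.populations, dtype=float)
        if len(p) != len(self.sequence):
            raise ValueError("populations and sequence lengths differ")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("populations must lie in [0, 1]")
        object.__setattr__(self, "populations", p)


def generate_shift_table(
    profile: HelixProfile, noise_sd: float = 0.0, seed: int = 0
):
    """Synthesise a Cα/Cβ chemical-shift table from a helical-population profile.

    Shifts follow a two-state model: δ = random-coil reference +
    p_j · (full-helix secondary shift) + Gaussian noise, with packaged
    full-helix offsets +3.1 ppm (Cα) and −0.4 ppm (Cβ).  Glycine has no Cβ.
    """
    from .ssp import ShiftTable  # deferred: ssp does not import cg_model

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rc = random_coil_shifts()
    rng = np.random.default_rng([seed, 1])
    rows = []
    for offset, (aa, p) in enumerate(zip(profile.sequence.upper(), profile.populations)):
        if aa not in rc.index:
            raise UnknownResidueError(
                f"residue {aa!r} at position {profile.first_residue + offset} "
                "has no random-coil reference"
            )
        ca = rc.loc[aa, "CA_ppm"] + p * FULL_HELIX_DELTA_CA
        cb = rc.loc[aa, "CB_ppm"] + p * FULL_HELIX_DELTA_CB
        if noise_sd > 0:
            ca += rng.normal(0.0, noise_sd)
            cb = cb if np.isnan(cb) else cb + rng.normal(0.0, noise_sd)
        rows.append(
            {
                "residue_number": profile.first_residue + offset,
                "residue_type": aa,
                "CA_shift_ppm": ca,
                "CB_shift_ppm": cb,
            }
        )
    return ShiftTable(pd.DataFrame(rows))
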