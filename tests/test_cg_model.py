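"""Coarse-grained peptide model: geometry, energy function, sampler,
synthetic shifts."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import helixscan as hx
from helixscan import geometry
from helixscan.cg_model import (
    ANGLE_FORCE_CONSTANT,
    BOND_ANGLE_DEG,
    BOND_LENGTH,
    CONTACT_CUTOFF,
    DIHEDRAL_WELL_SIGMA_DEG,
    EXTENDED_DIHEDRAL_DEG,
    EXTENDED_WELL_DEPTH,
    HELIX_DIHEDRAL_DEG,
    REPULSION_CONSTANT,
    ChainConformation,
    HelixProfile,
    ModelParameters,
    potential_energy_raw,
    random_coil_shifts,
)
from helixscan.errors import (
    InvalidLengthError,
    SingularGeometryError,
    UnknownResidueError,
)
from .conftest import random_chain


class TestIdealHelix:
    @pytest.mark.parametrize("n, n_pairs", [(10, 7), (4, 1)])
    def test_i_i3_distances(self, n, n_pairs):
        helix = hx.build_ideal_helix(n)
        d13 = np.linalg.norm(helix.coords[3:] - helix.coords[:-3], axis=1)
        assert len(d13) == n_pairs
        assert np.all((d13 >= 0.49) & (d13 <= 0.51))

    def test_bond_lengths_exact(self):
        helix = hx.build_ideal_helix(12)
        assert np.allclose(
            geometry.bond_lengths(helix.coords), BOND_LENGTH, atol=1e-12
        )

    def test_drmsd_against_helical_reference_is_tiny(self):
        helix = hx.build_ideal_helix(10)
        ref = hx.make_helical_reference(10)
        assert hx.drmsd(helix, ref) < 0.01

    def test_too_short_raises(self):
        with pytest.raises(InvalidLengthError):
            hx.build_ideal_helix(3)

    def test_chain_invariant_enforced(self):
        coords = hx.build_ideal_helix(6).coords.copy()
        coords[2] += 0.01
        with pytest.raises(ValueError):
            ChainConformation(coords)


class TestPotentialEnergy:
    def test_helix_below_extended_with_uniform_bias(self):
        p = ModelParameters(helix_bias=np.ones(10), contact_strength=0.0)
        e_helix = hx.potential_energy(hx.build_ideal_helix(10), p)
        e_ext = hx.potential_energy(hx.build_extended_chain(10), p)
        assert e_helix < e_ext

    def test_linearity_in_contact_strength(self, rng):
        conf = random_chain(rng, 12)
        p0 = ModelParameters(helix_bias=np.ones(12), contact_strength=0.0)
        p1 = ModelParameters(helix_bias=np.ones(12), contact_strength=1.0)
        d = conf.coords[:, None, :] - conf.coords[None, :, :]
        dist = np.linalg.norm(d, axis=-1)
        i, j = np.triu_indices(12, k=4)
        n_contacts = np.count_nonzero(dist[i, j] < CONTACT_CUTOFF)
        diff = hx.potential_energy(conf, p1) - hx.potential_energy(conf, p0)
        assert diff == pytest.approx(-n_contacts, abs=1e-10)

    def test_matches_independent_term_sum_oracle(self, rng):
        """Re-derive the energy as an explicit sum over terms, written
        independently of the production kernel."""

        def oracle(coords, params):
            n = len(coords)
            e = 0.0
            for i in range(1, n - 1):
                u = coords[i - 1] - coords[i]
                v = coords[i + 1] - coords[i]
                th = np.arccos(
                    np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                )
                e += 0.5 * ANGLE_FORCE_CONSTANT * (th - np.deg2rad(BOND_ANGLE_DEG)) ** 2
            sig = np.deg2rad(DIHEDRAL_WELL_SIGMA_DEG)
            phis = geometry.dihedrals(coords)
            for k, phi in enumerate(phis):
                for centre, depth in (
                    (HELIX_DIHEDRAL_DEG, params.helix_bias[k + 1]),
                    (EXTENDED_DIHEDRAL_DEG, EXTENDED_WELL_DEPTH),
                ):
                    delta = phi - np.deg2rad(centre)
                    delta = np.arctan2(np.sin(delta), np.cos(delta))
                    e -= depth * np.exp(-0.5 * (delta / sig) ** 2)
            for i in range(n):
                for j in range(i + 4, n):
                    d = np.linalg.norm(coords[i] - coords[j])
                    if d < CONTACT_CUTOFF:
                        e -= params.contact_strength
                    if d < params.excluded_radius:
                        e += REPULSION_CONSTANT * (params.excluded_radius - d) ** 2
            return e

        p = ModelParameters(
            helix_bias=rng.uniform(0, 5, 11), contact_strength=0.7
        )
        for _ in range(3):
            conf = random_chain(rng, 11)
            assert hx.potential_energy(conf, p) == pytest.approx(
                oracle(conf.coords, p), abs=1e-10
            )

    def test_rigid_motion_invariance(self, rng):
        p = ModelParameters(helix_bias=np.full(10, 2.0), contact_strength=1.0)
        conf = random_chain(rng, 10)
        e0 = potential_energy_raw(conf.coords, p)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(0, 3, 3)
            moved = conf.coords @ rot.T + shift
            assert potential_energy_raw(moved, p) == pytest.approx(e0, abs=1e-9)

    def test_overlapping_residues_raise(self):
        # square loop: valid 0.38 bonds but residues 0 and 3 coincide
        b = BOND_LENGTH
        coords = np.array(
            [[0, 0, 0], [b, 0, 0], [b, b, 0], [0, 0, 0]], dtype=float
        )
        p = ModelParameters(helix_bias=np.ones(4))
        with pytest.raises(SingularGeometryError):
            potential_energy_raw(coords, p)


class TestSampler:
    def test_same_seed_reproduces_trajectory(self):
        p = ModelParameters(helix_bias=np.full(8, 2.0), contact_strength=0.5)
        a = hx.sample_unbiased(p, 50, seed=1)
        b = hx.sample_unbiased(p, 50, seed=1)
        assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))

    def test_coil_baseline_and_helix_limit(self):
        """Zero bias stays coil-like; a deep (6 kBT) helical well dominates."""
        fractions = {}
        for h in (0.0, 6.0):
            p = ModelParameters(helix_bias=np.full(10, h), contact_strength=0.0)
            frames = hx.sample_unbiased(p, 2500, seed=2, save_every=2)[250:]
            fractions[h] = np.mean(
                [hx.assign_helicity(f).fraction for f in frames]
            )
        assert fractions[0.0] < 0.2
        assert fractions[6.0] > 0.8

    def test_helicity_monotone_in_uniform_bias(self):
        levels = [0.0, 1.5, 3.0, 4.5, 6.0]
        means = []
        for h in levels:
            p = ModelParameters(helix_bias=np.full(10, h), contact_strength=0.0)
            frames = hx.sample_unbiased(p, 1200, seed=3, save_every=2)[120:]
            means.append(
                np.mean([hx.assign_helicity(f).fraction for f in frames])
            )
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_mean_energy_increases_with_temperature(self):
        es = {}
        for t in (200.0, 500.0):
            p = ModelParameters(
                helix_bias=np.full(10, 3.0), contact_strength=1.0, temperature=t
            )
            frames = hx.sample_unbiased(p, 2000, seed=5, save_every=2)[200:]
            es[t] = np.mean([hx.potential_energy(f, p) for f in frames])
        assert es[200.0] < es[500.0]

    def test_bond_lengths_preserved_along_trajectory(self):
        p = ModelParameters(helix_bias=np.full(10, 2.0), contact_strength=1.0)
        frames = hx.sample_unbiased(p, 300, seed=6, save_every=100)
        for f in frames:
            assert np.allclose(
                geometry.bond_lengths(f.coords), BOND_LENGTH, atol=1e-9
            )


class TestShiftGenerator:
    def test_zero_population_reproduces_random_coil(self):
        prof = HelixProfile("ARNDQEK", np.zeros(7))
        table = hx.generate_shift_table(prof, noise_sd=0.0).data
        rc = random_coil_shifts()
        for _, row in table.iterrows():
            assert row["CA_shift_ppm"] == pytest.approx(
                rc.loc[row["residue_type"], "CA_ppm"]
            )
            assert row["CB_shift_ppm"] == pytest.approx(
                rc.loc[row["residue_type"], "CB_ppm"]
            )

    def test_full_helix_secondary_difference_is_3p5(self):
        prof = HelixProfile("ARNDQEK", np.ones(7))
        table = hx.generate_shift_table(prof, noise_sd=0.0).data
        rc = random_coil_shifts()
        dca = table["CA_shift_ppm"].to_numpy() - rc.loc[
            list(prof.sequence), "CA_ppm"
        ].to_numpy()
        dcb = table["CB_shift_ppm"].to_numpy() - rc.loc[
            list(prof.sequence), "CB_ppm"
        ].to_numpy()
        assert np.allclose(dca - dcb, 3.5)

    def test_partial_population_scales_linearly(self):
        prof = HelixProfile("A", np.array([0.4]))
        table = hx.generate_shift_table(prof, noise_sd=0.0).data
        rc = random_coil_shifts()
        assert table.loc[0, "CA_shift_ppm"] - rc.loc["A", "CA_ppm"] == pytest.approx(
            1.24
        )

    def test_glycine_has_no_cb(self):
        prof = HelixProfile("AGA", np.full(3, 0.5))
        table = hx.generate_shift_table(prof, noise_sd=0.0).data
        assert np.isnan(table.loc[1, "CB_shift_ppm"])

    def test_unknown_residue_raises(self):
        with pytest.raises(UnknownResidueError):
            hx.generate_shift_table(HelixProfile("AXA", np.zeros(3)))

    def test_noise_is_seed_reproducible(self):
        prof = HelixProfile("ARNDQEK", np.full(7, 0.3))
        a = hx.generate_shift_table(prof, noise_sd=0.2, seed=9).data
        b = hx.generate_shift_table(prof, noise_sd=0.2, seed=9).data
        assert a.equals(b)
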