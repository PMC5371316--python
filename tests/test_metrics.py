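"""Structural observables, Kabsch RMSD, Daura clustering, dominance."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import helixscan as hx
from helixscan import geometry
from helixscan.cg_model import BOND_LENGTH, ChainConformation, variant_parameters
from helixscan.metrics import (
    ClusterSet,
    daura_cluster,
    helicity_vs_r,
    pairwise_rmsd_matrix,
)
from .conftest import random_chain


def _chain_from_dihedrals(dihs_deg, angle_deg=91.0):
    n = len(dihs_deg) + 3
    return ChainConformation(
        geometry.build_chain(
            BOND_LENGTH,
            np.full(n - 2, np.deg2rad(angle_deg)),
            np.deg2rad(dihs_deg),
        )
    )


class TestAssignHelicity:
    def test_ideal_helix_is_fully_helical(self):
        assert hx.assign_helicity(hx.build_ideal_helix(10)).fraction == 1.0

    def test_extended_chain_has_no_helicity(self):
        assert hx.assign_helicity(hx.build_extended_chain(10)).fraction == 0.0

    def test_six_residue_toy_matches_manual_geometry_checks(self):
        """Independent re-evaluation of the dihedral-band and d(j, j+3) tests
        on a mixed helical/extended 6-mer."""
        conf = _chain_from_dihedrals([48.0, -170.0, 48.0])
        coords = conf.coords
        expected = []
        for j in (1, 2, 3):  # assignable interior residues
            b0 = coords[j] - coords[j - 1]
            b1 = coords[j + 1] - coords[j]
            b2 = coords[j + 2] - coords[j + 1]
            n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
            phi = np.rad2deg(
                np.arctan2(
                    np.dot(np.cross(n1, b1 / np.linalg.norm(b1)), n2),
                    np.dot(n1, n2),
                )
            )
            ok = 30.0 <= phi <= 80.0
            if ok and j + 3 < len(coords):
                d = np.linalg.norm(coords[j + 3] - coords[j])
                ok = 0.44 <= d <= 0.56
            expected.append(ok)
        got = hx.assign_helicity(conf)
        assert got.flags[[1, 2, 3]].tolist() == expected
        assert got.assignable.sum() == 3

    def test_terminal_residues_not_assignable(self):
        a = hx.assign_helicity(hx.build_ideal_helix(8))
        assert not a.assignable[0] and not a.assignable[-1]
        assert not a.assignable[-2]


class TestHelicityVsR:
    @staticmethod
    def _partial_helix_samples():
        """Partial helices: m helical dihedrals then extended tail."""
        import pandas as pd

        from helixscan.drmsd import RestraintSpec
        from helixscan.umbrella import WindowSpec, WindowedSamples

        confs = []
        for m in range(0, 8):
            dihs = [48.0] * m + [-170.0] * (7 - m)
            confs.append(_chain_from_dihedrals(dihs).coords)
        ref = hx.make_helical_reference(10)
        rs = np.array([hx.drmsd(c, ref) for c in confs])
        order = np.argsort(rs)
        stack = np.array(confs)[order]
        return WindowedSamples(
            windows=[WindowSpec(0, RestraintSpec(0.0, 1.0))],
            steps=[np.arange(1, len(stack) + 1)],
            r_values=[rs[order]],
            conformations=[stack],
            exchange_log=pd.DataFrame(
                columns=["step", "window_a", "window_b", "accepted"]
            ),
        )

    def test_crossing_matches_brute_force_bin_scan(self):
        samples = self._partial_helix_samples()
        curve = helicity_vs_r(samples, bin_width=0.02)
        # independent scan over the binned means
        good = curve.counts > 0
        c, m = curve.bin_centers[good], curve.mean_fraction[good]
        expected = None
        for i in range(len(m) - 1):
            if (m[i] - 0.5) * (m[i + 1] - 0.5) <= 0 and m[i] != m[i + 1]:
                expected = c[i] + (0.5 - m[i]) / (m[i + 1] - m[i]) * (c[i + 1] - c[i])
                break
        assert curve.crossing == pytest.approx(expected)

    def test_curve_decreases_on_sampled_ensembles(self, hremd_samples):
        curve = helicity_vs_r(hremd_samples.discard_equilibration(0.2))
        good = curve.counts > 30
        m = curve.mean_fraction[good]
        # monotone non-increasing, allowing one-bin noise violations
        violations = sum(b > a + 0.05 for a, b in zip(m, m[1:]))
        assert violations <= 1
        assert curve.crossing is not None
        assert 0.05 < curve.crossing < 0.3


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        assert hx.radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points_one_nm_apart(self):
        assert hx.radius_of_gyration(
            np.array([[0.0, 0, 0], [1.0, 0, 0]])
        ) == pytest.approx(0.5)

    def test_matches_definition_oracle(self, rng):
        conf = random_chain(rng, 10)
        centred = conf.coords - conf.coords.mean(axis=0)
        expected = np.sqrt((centred**2).sum(axis=1).mean())
        assert hx.radius_of_gyration(conf) == pytest.approx(expected, abs=1e-12)


class TestHbondSurrogate:
    def test_extended_chain_has_none(self):
        assert hx.count_hbond_surrogate(hx.build_extended_chain(12)) == 0

    def test_ideal_helix_counts_every_i_i4_pair(self):
        helix = hx.build_ideal_helix(10)
        d = helix.coords
        d4 = np.linalg.norm(d[4:] - d[:-4], axis=1)
        d5 = np.linalg.norm(d[5:] - d[:-5], axis=1)
        assert np.all(d4 < 0.62) and np.all(d5 > 0.62)
        assert hx.count_hbond_surrogate(helix) == 6

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            conf = random_chain(rng, 12)
            expected = sum(
                np.linalg.norm(conf.coords[i] - conf.coords[j]) < 0.62
                for i in range(12)
                for j in range(i + 4, 12)
            )
            assert hx.count_hbond_surrogate(conf) == expected


class TestKabschRmsd:
    def test_rigid_copy_is_zero(self, rng):
        conf = random_chain(rng, 10)
        moved = conf.coords @ Rotation.random(rng=rng).as_matrix().T + [1, 2, 3]
        assert hx.kabsch_rmsd(conf.coords, moved) <= 1e-9

    def test_mirror_image_cannot_be_superposed(self, rng):
        conf = random_chain(rng, 10)
        mirror = conf.coords * np.array([1.0, 1.0, -1.0])
        assert hx.kabsch_rmsd(conf.coords, mirror) > 0.01

    def test_agrees_with_rotation_grid_search_on_four_point_toys(self, rng):
        """SVD-free oracle: numeric minimisation over Euler angles from a
        coarse grid of starts."""
        a = rng.normal(0, 0.5, (4, 3))
        b = rng.normal(0, 0.5, (4, 3))
        pa = a - a.mean(axis=0)
        pb = b - b.mean(axis=0)

        def rmsd_of(angles):
            rot = Rotation.from_euler("zyx", angles).as_matrix()
            return np.sqrt(np.mean(np.sum((pb @ rot.T - pa) ** 2, axis=1)))

        best = np.inf
        grid = np.linspace(-np.pi, np.pi, 7)
        for z in grid:
            for y in grid[:4]:
                for x in grid:
                    res = minimize(rmsd_of, [z, y, x], method="Nelder-Mead")
                    best = min(best, res.fun)
        assert hx.kabsch_rmsd(a, b) == pytest.approx(best, abs=1e-3)

    def test_pairwise_matrix_consistent_with_single_pairs(self, rng):
        stack = np.array([random_chain(rng, 8).coords for _ in range(6)])
        mat = pairwise_rmsd_matrix(stack)
        for i in range(6):
            for j in range(i + 1, 6):
                assert mat[i, j] == pytest.approx(
                    hx.kabsch_rmsd(stack[i], stack[j]), abs=1e-10
                )


def _bundle(rng, centre_coords, n, spread=0.002):
    """Tight bundle of near-identical conformations around a centre."""
    out = [centre_coords]
    for _ in range(n - 1):
        rot = Rotation.from_rotvec(rng.normal(0, spread, 3)).as_matrix()
        out.append(centre_coords @ rot.T + rng.normal(0, spread, 3))
    return out


class TestDauraClustering:
    def test_identical_structures_form_one_cluster(self):
        helix = hx.build_ideal_helix(8).coords
        cs = daura_cluster(np.array([helix] * 7), cutoff=0.1)
        assert len(cs.clusters) == 1
        assert cs.sizes[0] == 7

    def test_two_separated_bundles_give_two_clusters(self, rng):
        a = _bundle(rng, hx.build_ideal_helix(10).coords, 6)
        b = _bundle(rng, hx.build_extended_chain(10).coords, 4)
        cs = daura_cluster(np.array(a + b), cutoff=0.1)
        assert len(cs.clusters) == 2
        assert list(cs.sizes) == [6, 4]

    def test_matches_exhaustive_brute_force_on_small_sets(self, rng):
        stack = np.array(
            [random_chain(rng, 8).coords for _ in range(20)]
            + _bundle(rng, hx.build_ideal_helix(8).coords, 10, spread=0.02)
        )
        cutoff = 0.12
        cs = daura_cluster(stack, cutoff=cutoff)

        # independent greedy re-implementation with plain loops
        m = len(stack)
        neigh = [
            {j for j in range(m) if hx.kabsch_rmsd(stack[i], stack[j]) <= cutoff}
            for i in range(m)
        ]
        alive = set(range(m))
        expected = []
        while alive:
            best, best_count = None, -1
            for i in sorted(alive):
                c = len(neigh[i] & alive)
                if c > best_count:
                    best, best_count = i, c
            members = sorted(neigh[best] & alive)
            expected.append((best, members))
            alive -= set(members)
        expected.sort(key=lambda c: (-len(c[1]), c[0]))
        got = [(c, sorted(mem)) for c, mem in cs.clusters]
        assert got == [(c, mem) for c, mem in expected]

    def test_deterministic_across_runs(self, rng):
        stack = np.array([random_chain(rng, 8).coords for _ in range(15)])
        a = daura_cluster(stack, cutoff=0.15)
        b = daura_cluster(stack, cutoff=0.15)
        assert [(c, m.tolist()) for c, m in a.clusters] == [
            (c, m.tolist()) for c, m in b.clusters
        ]

    def test_cluster_count_non_increasing_in_cutoff(self, rng):
        stack = np.array([random_chain(rng, 8).coords for _ in range(25)])
        counts = [
            len(daura_cluster(stack, cutoff=c).clusters) for c in (0.05, 0.15, 0.4)
        ]
        assert counts[0] >= counts[1] >= counts[2]


def _labelled_clusters(sizes_by_variant):
    """ClusterSet with one cluster per spec: {variant: n_members} dicts."""
    labels = []
    clusters = []
    idx = 0
    for spec in sizes_by_variant:
        members = []
        for variant, n in spec.items():
            labels.extend([variant] * n)
            members.extend(range(idx, idx + n))
            idx += n
        clusters.append((members[0], np.array(members)))
    clusters.sort(key=lambda c: -len(c[1]))
    return ClusterSet(clusters=clusters, labels=labels, cutoff=0.1)


class TestDominance:
    def test_eighty_five_percent_share_is_dominated(self):
        cs = _labelled_clusters([{"A": 170, "B": 30}])
        table = hx.dominance_analysis(cs)
        row = table[(table.variant == "A")].iloc[0]
        assert row.status == "dominated"
        assert row.share == pytest.approx(0.85)

    def test_half_percent_share_is_neglected(self):
        cs = _labelled_clusters([{"A": 199, "B": 1}])
        table = hx.dominance_analysis(cs)
        assert table[table.variant == "B"].iloc[0].status == "neglected"

    def test_exactly_one_hundred_structures_excluded(self):
        cs = _labelled_clusters([{"A": 60, "B": 40}, {"A": 150, "B": 51}])
        table = hx.dominance_analysis(cs, min_size=100)
        assert set(table["size"]) == {201}

    def test_shares_sum_to_one_per_cluster(self):
        cs = _labelled_clusters([{"A": 120, "B": 44, "C": 37}])
        table = hx.dominance_analysis(cs)
        assert table.groupby("cluster_id")["share"].sum().iloc[0] == pytest.approx(1.0)


class TestVariantContrast:
    def test_extended_variant_larger_rg_fewer_contacts(self):
        """The most helix-destabilising preset samples larger Rg and fewer
        surrogate H-bonds than the compact preset at matched windows."""
        windows = hx.build_windows(6, 0.0, 0.5, 1000.0)
        stats = {}
        for v in ("V-TIP3P", "V-TIP4P-D"):
            params = variant_parameters(v, sequence="ARLREALKAQ")
            s = hx.run_hremd(params, windows, 1200, 100, seed=13, save_every=2)
            s = s.discard_equilibration(0.2)
            rg, hb = [], []
            for w in range(s.n_windows):
                for conf in s.window_conformations(w):
                    rg.append(hx.radius_of_gyration(conf))
                    hb.append(hx.count_hbond_surrogate(conf))
            stats[v] = (np.array(rg), np.array(hb))
        rng = np.random.default_rng(0)

        def ci(x):
            means = [
                np.mean(rng.choice(x, len(x), replace=True)) for _ in range(200)
            ]
            return np.percentile(means, [2.5, 97.5])

        rg3, hb3 = stats["V-TIP3P"]
        rgd, hbd = stats["V-TIP4P-D"]
        assert ci(rgd)[0] > ci(rg3)[1]  # Rg strictly larger
        assert ci(hbd)[1] < ci(hb3)[0]  # contacts strictly fewer
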