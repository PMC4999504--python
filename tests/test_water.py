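"""Water-structure metrics against direct-sum oracles and closed forms."""

import numpy as np
import pytest
from scipy.special import sph_harm_y

from hydrafibre.core import (Atom, Frame, Topology, Trajectory,
                             minimum_image_displacement, pair_distances,
                             select)
from hydrafibre.mapping import reinsert_water
from hydrafibre.synth import (gen_ideal_gas, gen_lattice, gen_pa_bundle,
                              gen_solvation_shell, marsaglia_sphere)
from hydrafibre.water import (compute_density_profile, compute_q6,
                              compute_rdf, compute_tetrahedral_order,
                              compute_translational_order, find_hbonds,
                              radial_number_distribution,
                              steinhardt_q6_from_vectors,
                              tetrahedral_q_from_vectors)


def oracle_q6(unit_vectors):
    """Direct evaluation of sqrt(4π/13 Σ_{m=-6..6} |⟨Y_6m⟩|²)."""
    v = np.asarray(unit_vectors, dtype=float)
    v = v / np.linalg.norm(v, axis=1)[:, None]
    theta = np.arccos(np.clip(v[:, 2], -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    total = 0.0
    for m in range(-6, 7):
        total += np.abs(np.mean(sph_harm_y(6, abs(m), theta, phi)
                                * ((-1) ** m if m < 0 else 1))) ** 2
    return np.sqrt(4 * np.pi / 13 * total)


def oracle_qtet(vectors):
    u = np.asarray(vectors, dtype=float)
    u = u / np.linalg.norm(u, axis=1)[:, None]
    s = sum((np.dot(u[j], u[k]) + 1 / 3) ** 2
            for j in range(3) for k in range(j + 1, 4))
    return 1 - 3 / 8 * s


def water_only_topology(n):
    return Topology([Atom(k, "O", "O", 15.999, "HOH", k, k, "water")
                     for k in range(n)])


class TestRDF:
    def test_ideal_gas_flat(self, ideal_gas_traj):
        rdf = compute_rdf(ideal_gas_traj, "all", "all", r_max=12.0, dr=0.25)
        sel = (rdf.r >= 2.0) & (rdf.r <= 10.0)
        assert np.abs(rdf.g[sel] - 1.0).max() < 0.1
        # mean within 3 standard errors of 1
        se = np.std(rdf.g[sel]) / np.sqrt(sel.sum())
        assert abs(rdf.g[sel].mean() - 1.0) < 3 * se + 1e-3

    def test_pair_count_conservation(self, ideal_gas_traj):
        rdf = compute_rdf(ideal_gas_traj, "all", "all", r_max=12.0, dr=0.25)
        # ordered pairs within r_max, counted per frame, via direct loop
        total = 0
        for fr in ideal_gas_traj.frames[:3]:
            d = pair_distances(fr.coordinates, fr.coordinates, fr.box)
            np.fill_diagonal(d, np.inf)
            total += int((d < 12.0 - 1e-12).sum())
        partial = compute_rdf(
            Trajectory(ideal_gas_traj.topology, ideal_gas_traj.frames[:3]),
            "all", "all", r_max=12.0, dr=0.25)
        assert partial.pair_counts.sum() == total

    def test_two_particles_single_bin(self):
        top = water_only_topology(2)
        frame = Frame(0.0, [20, 20, 20],
                      np.array([[5.0, 5.0, 5.0], [10.0, 5.0, 5.0]]))
        rdf = compute_rdf((top, frame), "all", "all", r_max=8.0, dr=0.1)
        nz = np.flatnonzero(rdf.pair_counts)
        assert len(nz) == 1
        assert rdf.bin_edges[nz[0]] <= 5.0 <= rdf.bin_edges[nz[0] + 1]

    def test_shell_fixture_first_peak(self, shell_fixture):
        rdf = compute_rdf(shell_fixture, "group hydrophilic_head",
                          "group water", r_max=8.0, dr=0.05)
        assert rdf.first_peak() == pytest.approx(2.85, abs=0.05)

    @pytest.mark.parametrize("radius", [2.5, 3.0, 3.5])
    def test_peak_recovery_across_radii(self, radius):
        top, frame = gen_solvation_shell(
            n_sites=60, shell_radii=(radius, 6.0), shell_counts=(6, 0),
            jitter_sigma=0.05, seed=21)
        rdf = compute_rdf((top, frame), "group hydrophilic_head",
                          "group water", r_max=8.0, dr=0.05)
        assert rdf.first_peak() == pytest.approx(radius, abs=0.05)

    def test_minimum_image_bound_enforced(self, shell_fixture):
        top, frame = shell_fixture
        with pytest.raises(ValueError, match="minimum-image"):
            compute_rdf((top, frame), "all", "all",
                        r_max=float(frame.box[0]), dr=0.1)

    def test_empty_selection_error(self, shell_fixture):
        with pytest.raises(ValueError, match="empty"):
            compute_rdf(shell_fixture, "group bead", "group water",
                        r_max=5.0, dr=0.1)

    def test_against_brute_force_histogram(self, rng):
        n = 60
        box = np.array([15.0, 15.0, 15.0])
        top = water_only_topology(n)
        frame = Frame(0.0, box, rng.uniform(0, 1, (n, 3)) * box)
        r_max, dr = 6.0, 0.2
        rdf = compute_rdf((top, frame), "all", "all", r_max=r_max, dr=dr)
        counts = np.zeros(int(r_max / dr))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = np.linalg.norm(minimum_image_displacement(
                    frame.coordinates[i], frame.coordinates[j], box))
                if d < r_max:
                    b = int(d / dr)
                    if b < len(counts):
                        counts[b] += 1
        assert np.array_equal(rdf.pair_counts, counts.astype(int))


class TestDensityProfile:
    def test_uniform_water_box_1_g_cc(self):
        top, frame = reinsert_water(
            None, Frame(0.0, [40, 40, 40],
                        np.array([[20.0, 20.0, 20.0]]) * 0 + 20.0),
            overall_density=1.0, seed=4)
        prof = compute_density_profile((top, frame), "group water",
                                       axis="x", dr=10.0)
        assert np.all(np.abs(prof.density - 1.0) < 0.05)

    def test_vacuum_slab_zero(self):
        top = water_only_topology(50)
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 1, (50, 3)) * [10, 20, 20]
        frame = Frame(0.0, [40, 20, 20], coords)   # x in [0,10] only
        prof = compute_density_profile((top, frame), "all", axis="x", dr=5.0)
        assert np.all(prof.density[2:] == 0.0)
        assert prof.density[:2].sum() > 0

    def test_bundle_contour_spacing(self):
        top, frame = gen_pa_bundle(n_fibres=3, pas_per_fibre=50,
                                   centroid_spacing=50.0, seed=2)
        prof = compute_density_profile(
            (top, frame), "group hydrophobic_tail or group hydrophilic_head",
            axis="x", dr=2.0)
        spacings = prof.peak_spacings(min_frac=0.5)
        assert len(spacings) >= 1
        assert np.allclose(spacings, 50.0, atol=4.0)


class TestQ6:
    def test_fcc_matches_direct_sum(self, fcc):
        top, frame = fcc
        series = compute_q6((top, frame), "all", {"k_nearest": 12})
        # oracle over the 12 exact fcc neighbour directions
        dirs = []
        for axes in [(0, 1), (0, 2), (1, 2)]:
            for s1 in (1, -1):
                for s2 in (1, -1):
                    v = np.zeros(3)
                    v[axes[0]], v[axes[1]] = s1, s2
                    dirs.append(v)
        expect = oracle_q6(np.array(dirs))
        assert series.values[0] == pytest.approx(expect, abs=1e-8)
        assert expect == pytest.approx(0.57452, abs=1e-4)

    def test_sc_matches_direct_sum(self):
        top, frame = gen_lattice("sc", 4.0, (3, 3, 3))
        series = compute_q6((top, frame), "all", {"k_nearest": 6})
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1], [0, 0, -1]], dtype=float)
        assert series.values[0] == pytest.approx(oracle_q6(dirs), abs=1e-8)

    def test_random_directions_annihilate(self, rng):
        v = marsaglia_sphere(rng, 512)
        assert steinhardt_q6_from_vectors(v) < 0.1

    def test_rotation_invariance_of_invariant(self, rng):
        v = marsaglia_sphere(rng, 24) * 2.5
        q = steinhardt_q6_from_vectors(v)
        from scipy.stats import special_ortho_group
        rot = special_ortho_group.rvs(3, random_state=7)
        assert steinhardt_q6_from_vectors(v @ rot.T) == pytest.approx(
            q, abs=1e-10)

    def test_lattice_90_degree_rotation(self, fcc):
        top, frame = fcc
        q0 = compute_q6((top, frame), "all", {"k_nearest": 12}).values[0]
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        coords = frame.coordinates @ rot.T
        coords += frame.box * (coords < 0)         # PBC-compatible rewrap
        frame2 = Frame(0.0, frame.box, coords)
        q1 = compute_q6((top, frame2), "all", {"k_nearest": 12}).values[0]
        assert q1 == pytest.approx(q0, abs=1e-8)

    def test_global_mode_on_lattice(self, fcc):
        top, frame = fcc
        per = compute_q6((top, frame), "all", {"k_nearest": 12},
                         mode="per_particle")
        glo = compute_q6((top, frame), "all", {"k_nearest": 12},
                         mode="global")
        assert glo.values[0] == pytest.approx(per.values[0], abs=1e-8)

    def test_full_path_vs_brute_force(self, rng):
        """compute_q6 with a cutoff equals a brute-force neighbour search +
        direct Y_6m sum on a random 100-particle frame."""
        n, box = 100, np.array([12.0, 12.0, 12.0])
        top = water_only_topology(n)
        frame = Frame(0.0, box, rng.uniform(0, 1, (n, 3)) * box)
        cutoff = 3.0
        series = compute_q6((top, frame), "all", {"cutoff": cutoff})
        qs = []
        for i in range(n):
            vecs = []
            for j in range(n):
                if j == i:
                    continue
                d = minimum_image_displacement(frame.coordinates[i],
                                               frame.coordinates[j], box)
                if np.linalg.norm(d) <= cutoff:
                    vecs.append(d)
            if vecs:
                qs.append(oracle_q6(np.array(vecs)))
        assert series.values[0] == pytest.approx(np.mean(qs), abs=1e-8)


class TestTetrahedralOrder:
    def test_diamond_ice_is_one(self, diamond_ice):
        series = compute_tetrahedral_order(diamond_ice, "all")
        assert series.values[0] == pytest.approx(1.0, abs=1e-10)

    def test_collinear_neighbours_give_minus_three(self):
        # centre + 4 nearly-collinear close neighbours + padding far away;
        # all six pair cosines → 1, so q = 1 − (3/8)·6·(4/3)² = −3
        coords = [[10.0, 10, 10]]
        for k, r in enumerate([1.0, 1.2, 1.4, 1.6]):
            coords.append([10.0 + r, 10, 10])
        for k in range(4):                       # distant padding particles
            coords.append([2.0 + k, 3.0, 4.0])
        top = water_only_topology(len(coords))
        frame = Frame(0.0, [20, 20, 20], np.array(coords))
        v = frame.coordinates[1:5] - frame.coordinates[0]
        assert oracle_qtet(v) == pytest.approx(-3.0, abs=1e-12)
        series = compute_tetrahedral_order((top, frame), "all")
        per_centre = tetrahedral_q_from_vectors(v)
        assert per_centre == pytest.approx(-3.0, abs=1e-12)

    def test_random_neighbours_mean_zero(self, rng):
        """Monte-Carlo oracle: E[q] = 0 for uniformly random directions."""
        n_particles = 3000
        qs = np.array([oracle_qtet(marsaglia_sphere(rng, 4))
                       for _ in range(n_particles)])
        se = qs.std() / np.sqrt(n_particles)
        assert abs(qs.mean()) < 3 * se
        # the implementation's per-particle kernel agrees with the oracle
        v = marsaglia_sphere(rng, 4)
        assert tetrahedral_q_from_vectors(v) == pytest.approx(
            oracle_qtet(v), abs=1e-12)

    def test_full_path_vs_brute_force(self, rng):
        n, box = 80, np.array([10.0, 10.0, 10.0])
        top = water_only_topology(n)
        frame = Frame(0.0, box, rng.uniform(0, 1, (n, 3)) * box)
        series = compute_tetrahedral_order((top, frame), "all")
        qs = []
        for i in range(n):
            d = [minimum_image_displacement(frame.coordinates[i],
                                            frame.coordinates[j], box)
                 for j in range(n) if j != i]
            d = np.array(d)
            order = np.argsort(np.linalg.norm(d, axis=1))
            qs.append(oracle_qtet(d[order[:4]]))
        assert series.values[0] == pytest.approx(np.mean(qs), abs=1e-8)


class TestTranslationalOrder:
    def test_ideal_gas_small(self):
        traj = gen_ideal_gas(4000, [24.0, 24.0, 24.0], n_frames=10, seed=2)
        t = compute_translational_order(traj, "all", xi_cutoff=2.0)
        assert t.values[0] < 0.06

    def test_lattice_large(self):
        top, frame = gen_lattice("sc", 4.0, (6, 6, 6))
        t = compute_translational_order((top, frame), "all",
                                        xi_cutoff=2.843, dr=0.02)
        assert t.values[0] > 1.0

    def test_jitter_monotonicity(self, rng):
        top, frame = gen_lattice("fcc", 4.0, (4, 4, 4))
        ts = []
        for sigma in (0.05, 0.2, 0.5):
            noisy = Frame(0.0, frame.box, frame.coordinates
                          + rng.normal(0, sigma, frame.coordinates.shape))
            t = compute_translational_order((top, noisy), "all",
                                            xi_cutoff=2.0, dr=0.05)
            ts.append(t.values[0])
        assert ts[0] > ts[1] > ts[2]

    def test_q6_jitter_monotonicity(self, rng):
        top, frame = gen_lattice("fcc", 4.0, (4, 4, 4))
        qs = []
        for sigma in (0.05, 0.2, 0.5):
            noisy = Frame(0.0, frame.box, frame.coordinates
                          + rng.normal(0, sigma, frame.coordinates.shape))
            qs.append(compute_q6((top, noisy), "all",
                                 {"k_nearest": 12}).values[0])
        assert qs[0] > qs[1] > qs[2]

    def test_box_too_small_raises(self):
        top, frame = gen_lattice("sc", 4.0, (3, 3, 3))
        with pytest.raises(ValueError, match="larger box"):
            compute_translational_order((top, frame), "all",
                                        xi_cutoff=2.843)


def _water(aid0, mol, o_pos, h1_off, h2_off):
    atoms = [Atom(aid0, "OH2", "O", 15.999, "HOH", mol, mol, "water"),
             Atom(aid0 + 1, "H1", "H", 1.008, "HOH", mol, mol, "water"),
             Atom(aid0 + 2, "H2", "H", 1.008, "HOH", mol, mol, "water")]
    coords = [o_pos, np.add(o_pos, h1_off), np.add(o_pos, h2_off)]
    bonds = [(aid0, aid0 + 1), (aid0, aid0 + 2)]
    return atoms, coords, bonds


class TestHydrogenBonds:
    def _dimer(self, angle_deg):
        """Donor water with one H pointing at ``angle`` off the O–O axis;
        acceptor O–O distance 2.85 Å."""
        a = np.deg2rad(angle_deg)
        h1 = 0.9572 * np.array([np.cos(a), np.sin(a), 0.0])
        atoms1, c1, b1 = _water(0, 0, [5.0, 5.0, 5.0], h1, [-0.24, -0.93, 0])
        atoms2, c2, b2 = _water(3, 1, [7.85, 5.0, 5.0],
                                [0.76, 0.59, 0], [0.76, -0.59, 0])
        top = Topology(atoms1 + atoms2, b1 + b2)
        frame = Frame(0.0, [20, 20, 20], np.array(c1 + c2))
        return top, frame

    def test_linear_dimer_single_bond(self):
        top, frame = self._dimer(0.0)
        bonds = find_hbonds(top, frame, "molid 0", "molid 1")
        assert len(bonds) == 1
        assert bonds[0][0] == 0 and bonds[0][2] == 3

    def test_angle_cut_excludes(self):
        top, frame = self._dimer(35.0)        # angle_cut (30°) + 5°
        assert find_hbonds(top, frame, "molid 0", "molid 1") == []

    def test_donor_without_hydrogen_error(self):
        # bond-less topology: donor oxygens have no attached hydrogens
        top, frame = self._dimer(0.0)
        bare = Topology([top.atom(i) for i in range(top.n_atoms)])
        with pytest.raises(ValueError, match="hydrogen"):
            find_hbonds(bare, frame, "molid 0", "molid 1")

    def test_count_matches_triple_loop(self, rng):
        box = np.array([16.0, 16.0, 16.0])
        atoms, coords, bonds = [], [], []
        for m in range(50):
            o = rng.uniform(2, 14, 3)
            d1, d2 = marsaglia_sphere(rng, 2)
            a, c, b = _water(3 * m, m, o, 0.9572 * d1, 0.9572 * d2)
            atoms += a
            coords += c
            bonds += b
        top = Topology(atoms, bonds)
        frame = Frame(0.0, box, np.array(coords))
        got = find_hbonds(top, frame, "group water and element O",
                          "group water and element O")
        # exhaustive oracle
        expect = 0
        cos_cut = np.cos(np.deg2rad(30.0))
        for d in range(0, 150, 3):
            for acc in range(0, 150, 3):
                if acc == d:
                    continue
                v_da = minimum_image_displacement(frame.coordinates[d],
                                                  frame.coordinates[acc],
                                                  box)
                if np.linalg.norm(v_da) > 3.5:
                    continue
                for h in (d + 1, d + 2):
                    v_dh = minimum_image_displacement(
                        frame.coordinates[d], frame.coordinates[h], box)
                    cosang = (v_da @ v_dh
                              / np.linalg.norm(v_da) / np.linalg.norm(v_dh))
                    if cosang >= cos_cut:
                        expect += 1
        assert len(got) == expect


class TestRadialNumberDistribution:
    def test_single_fibre_tails_within_10(self):
        top, frame = gen_pa_bundle(n_fibres=1, pas_per_fibre=50,
                                   fibre_radius=20.0, box_z=45.5, seed=3)
        axis_point = [*(frame.box[:2] / 2), 0.0]
        dist = radial_number_distribution(
            (top, frame), axis_point, [0, 0, 1],
            {"tail": "group hydrophobic_tail", "head":
             "group hydrophilic_head"}, dr=1.0, r_max=30.0)
        tail = dist.counts["tail"]
        assert tail[dist.r < 10.0].sum() == pytest.approx(tail.sum())

    def test_cylinder_single_annulus(self):
        n = 64
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        coords = np.stack([25 + 20.5 * np.cos(ang), 25 + 20.5 * np.sin(ang),
                           np.linspace(1, 49, n)], axis=1)
        top = water_only_topology(n)
        frame = Frame(0.0, [50, 50, 50], coords)
        dist = radial_number_distribution((top, frame), [25, 25, 0],
                                          [0, 0, 1], {"w": "all"}, dr=1.0,
                                          r_max=25.0)
        nz = np.flatnonzero(dist.counts["w"])
        assert len(nz) == 1
        assert dist.bin_edges[nz[0]] <= 20.5 <= dist.bin_edges[nz[0] + 1]

    def test_totals_conserved(self, bundle):
        top, frame = bundle
        dist = radial_number_distribution(
            (top, frame), [*(frame.box[:2] / 2), 0.0], [0, 0, 1],
            {"tail": "group hydrophobic_tail"}, dr=2.0,
            r_max=float(np.linalg.norm(frame.box[:2])))
        n_tail = len(select(top, frame, "group hydrophobic_tail"))
        assert dist.counts["tail"].sum() == pytest.approx(n_tail)
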