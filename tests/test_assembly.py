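"""Aggregate census, fibre metrics, Ramachandran and chirality."""

import numpy as np
import pytest

from hydrafibre.assembly import (chirality, classify_aggregate,
                                 cluster_molecules, dihedral, end_to_end,
                                 fibre_metrics, lattice_spacing,
                                 ramachandran)
from hydrafibre.core import (Atom, Frame, Topology, pair_distances, select,
                             wrap_coordinates)
from hydrafibre.synth import (build_backbone, gen_micelle, gen_pa_bundle)

# ideal L-alanine backbone + Cβ (standard amino-acid geometry; improper
# dihedral N–Cα–C–Cβ ≈ +120°, the textbook L anchor)
L_ALA = {"N": (-0.966, 0.493, 1.500), "CA": (0.257, 0.418, 0.692),
         "C": (-0.094, 0.017, -0.716), "CB": (1.204, -0.620, 1.296)}


def _chain(spacing=2.0, n=12, start=(5.0, 5.0, 5.0), box=(100, 100, 100),
           fold_at=None):
    atoms, coords, bonds = [], [], []
    pos = np.array(start, dtype=float)
    step = np.array([spacing, 0.0, 0.0])
    for k in range(n):
        atoms.append(Atom(k, f"B{k + 1}", "C", 12.0, "CHN", 0, 0, "other"))
        coords.append(pos.copy())
        if fold_at is not None and k + 1 == fold_at:
            step = np.array([0.0, spacing, 0.0])
        pos = pos + step
        if k:
            bonds.append((k - 1, k))
    top = Topology(atoms, bonds)
    frame = Frame(0.0, box, wrap_coordinates(np.array(coords), box))
    return top, frame


class TestEndToEnd:
    def test_straight_chain(self):
        top, frame = _chain()
        _, mean, sd = end_to_end((top, frame), ("B1", "B12"))
        assert mean[0] == pytest.approx(22.0, abs=1e-12)
        assert sd[0] == 0.0

    def test_folded_chain_shorter(self):
        top, frame = _chain(fold_at=6)
        _, mean, _ = end_to_end((top, frame), ("B1", "B12"))
        assert mean[0] < 22.0

    def test_pbc_crossing_equals_centred_oracle(self):
        top, frame = _chain(start=(95.0, 5.0, 5.0))   # crosses x boundary
        _, mean, _ = end_to_end((top, frame), ("B1", "B12"))
        top2, frame2 = _chain(start=(30.0, 5.0, 5.0))  # whole-box translate
        _, mean2, _ = end_to_end((top2, frame2), ("B1", "B12"))
        assert mean[0] == pytest.approx(mean2[0], abs=1e-9)

    def test_missing_endpoint_names_molecule(self):
        top, frame = _chain()
        with pytest.raises(ValueError, match="molecule 0"):
            end_to_end((top, frame), ("B1", "B99"))


def _two_pa_system(gap):
    """Two 2-bead tail chains with closest beads ``gap`` apart."""
    atoms, coords = [], []
    for m, x0 in enumerate([10.0, 10.0 + 2.0 + gap]):
        for k in range(2):
            atoms.append(Atom(2 * m + k, f"B{k}", "C", 12.0, "TAIL", m, m,
                              "hydrophobic_tail"))
            coords.append([x0 + 2.0 * k - 2.0 * m * 2.0 * 0, 10.0, 10.0])
    # closest pair: atom1 (x0a+2) and atom2 (x0b)
    top = Topology(atoms, [(0, 1), (2, 3)])
    return top, Frame(0.0, [50, 50, 50], np.array(coords))


def brute_force_clusters(topology, frame, sel_expr, cutoff):
    """Exhaustive union–find over all selected bead pairs."""
    ids = select(topology, frame, sel_expr)
    mols = sorted(set(int(m) for m in topology.molecule_ids[ids]))
    parent = {m: m for m in mols}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d = pair_distances(frame.coordinates[ids], frame.coordinates[ids],
                       frame.box)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if d[i, j] <= cutoff:
                a = find(int(topology.molecule_ids[ids[i]]))
                b = find(int(topology.molecule_ids[ids[j]]))
                if a != b:
                    parent[a] = b
    groups = {}
    for m in mols:
        groups.setdefault(find(m), set()).add(m)
    return sorted((sorted(g) for g in groups.values()),
                  key=lambda g: (-len(g), g[0]))


class TestClustering:
    def test_cutoff_boundary(self):
        cutoff = 6.0
        top, frame = _two_pa_system(gap=cutoff - 0.01)
        assert cluster_molecules(top, frame, "group hydrophobic_tail",
                                 cutoff).n_clusters == 1
        top, frame = _two_pa_system(gap=cutoff + 0.01)
        assert cluster_molecules(top, frame, "group hydrophobic_tail",
                                 cutoff).n_clusters == 2

    def test_bundle_census_matches_construction(self, bundle):
        top, frame = bundle
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        assert asn.n_clusters == 6
        assert np.all(asn.sizes == 50)

    def test_matches_exhaustive_union_find(self, bundle):
        top, frame = bundle
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        expect = brute_force_clusters(top, frame, "group hydrophobic_tail",
                                      6.0)
        got = [sorted(int(m) for m in c.molecule_ids) for c in asn.clusters]
        assert got == expect

    def test_random_system_matches_union_find(self, rng):
        atoms, coords = [], []
        box = np.array([30.0, 30.0, 30.0])
        for m in range(60):
            centre = rng.uniform(0, 1, 3) * box
            for k in range(3):
                atoms.append(Atom(3 * m + k, f"B{k}", "C", 12.0, "TAIL",
                                  m, m, "hydrophobic_tail"))
                coords.append(centre + rng.normal(0, 1.0, 3))
        top = Topology(atoms)
        frame = Frame(0.0, box, wrap_coordinates(np.array(coords), box))
        asn = cluster_molecules(top, frame, "all", 4.0)
        expect = brute_force_clusters(top, frame, "all", 4.0)
        got = [sorted(int(m) for m in c.molecule_ids) for c in asn.clusters]
        assert got == expect

    def test_translation_invariance(self, bundle, rng):
        top, frame = bundle
        shift = rng.uniform(0, 50, 3)
        frame2 = Frame(0.0, frame.box,
                       wrap_coordinates(frame.coordinates + shift,
                                        frame.box))
        a = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        b = cluster_molecules(top, frame2, "group hydrophobic_tail", 6.0)
        assert np.array_equal(a.sizes, b.sizes)
        assert np.array_equal(a.labels, b.labels)

    def test_empty_selection(self, bundle):
        top, frame = bundle
        with pytest.raises(ValueError, match="empty"):
            cluster_molecules(top, frame, "group bead", 6.0)


class TestClassification:
    def test_fibres_classified_and_axis_aligned(self, bundle):
        top, frame = bundle
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        for lab in range(asn.n_clusters):
            info = classify_aggregate(asn, top, frame, lab)
            assert info.kind == "fibre"
            angle = np.degrees(np.arccos(abs(info.axis[2])))
            assert angle < 5.0

    def test_micelle_classified(self, micelle):
        top, frame = micelle
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        info = classify_aggregate(asn, top, frame, 0)
        assert info.kind == "micelle"
        # compact blob: axial extent comparable to twice its radius scale
        assert info.axial_extent < 4 * info.radius

    def test_radius_recovers_construction(self):
        r_f = 25.0
        top, frame = gen_pa_bundle(n_fibres=1, pas_per_fibre=50,
                                   fibre_radius=r_f, seed=6)
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        info = classify_aggregate(asn, top, frame, 0)
        # tail beads sit at radii (k+0.5)/12·r_f, k<4: exact RMS below
        expect = r_f / 12.0 * np.sqrt(np.mean([0.5 ** 2, 1.5 ** 2,
                                               2.5 ** 2, 3.5 ** 2]))
        assert info.radius == pytest.approx(expect, rel=0.10)
        assert info.radius < 0.5 * r_f

    def test_fission_bookkeeping(self):
        """A fibre broken into two half-clusters conserves molecules and
        the children sizes sum to the parent's."""
        top, frame = gen_pa_bundle(n_fibres=1, pas_per_fibre=50, seed=9)
        parent = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        assert parent.n_clusters == 1 and parent.sizes[0] == 50
        coords = frame.coordinates.copy()
        upper = coords[:, 2] >= frame.box[2] / 2
        coords[upper, 0] = (coords[upper, 0] + 30.0) % frame.box[0]
        split = cluster_molecules(top, Frame(0.0, frame.box, coords),
                                  "group hydrophobic_tail", 6.0)
        assert split.n_clusters == 2
        assert split.sizes.sum() == parent.sizes[0]
        assert np.all(split.sizes >= 20)          # ~25 PAs per child
        for lab in range(2):
            info = classify_aggregate(split, top,
                                      Frame(0.0, frame.box, coords), lab)
            assert info.kind == "micelle"


class TestFibreMetrics:
    def _classified_bundle(self, bundle):
        top, frame = bundle
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        infos = [classify_aggregate(asn, top, frame, lab)
                 for lab in range(asn.n_clusters)]
        return top, frame, asn, infos

    def test_printed_linear_density(self, bundle):
        top, frame, asn, infos = self._classified_bundle(bundle)
        ld, diam = fibre_metrics(asn, top, frame, 0)
        assert ld == pytest.approx(50 / 4.55, abs=1e-9)
        assert round(ld) == 11

    def test_density_halves_with_doubled_box(self):
        top, frame = gen_pa_bundle(n_fibres=1, pas_per_fibre=50,
                                   box_z=91.0, seed=2)
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        classify_aggregate(asn, top, frame, 0)
        ld, _ = fibre_metrics(asn, top, frame, 0)
        assert ld == pytest.approx(50 / 9.1, abs=1e-9)

    def test_diameter_recovers_construction(self, bundle):
        top, frame, asn, infos = self._classified_bundle(bundle)
        _, diam = fibre_metrics(asn, top, frame, 0)
        max_radial = 25.0 * (12 - 0.5) / 12.0     # outermost head bead
        assert diam == pytest.approx(2 * max_radial, rel=0.10)

    def test_micelle_input_rejected(self, micelle):
        top, frame = micelle
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        classify_aggregate(asn, top, frame, 0)
        with pytest.raises(ValueError, match="micelle"):
            fibre_metrics(asn, top, frame, 0)


class TestLatticeSpacing:
    def test_default_bundle_spacing(self, bundle):
        top, frame = bundle
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        cents = [classify_aggregate(asn, top, frame, lab).centroid
                 for lab in range(asn.n_clusters)]
        spacing, coord = lattice_spacing(np.array(cents), frame.box,
                                         axis=[0, 0, 1])
        assert spacing == pytest.approx(50.0, abs=0.5)
        assert np.all((coord >= 2) & (coord <= 4))   # 2x3 hexagonal patch

    @pytest.mark.parametrize("s", [40.0, 50.0, 60.0])
    def test_spacing_scales_with_generator(self, s):
        top, frame = gen_pa_bundle(n_fibres=6, pas_per_fibre=10,
                                   fibre_radius=s / 2.5,
                                   centroid_spacing=s, seed=3)
        asn = cluster_molecules(top, frame, "group hydrophobic_tail", 6.0)
        cents = [classify_aggregate(asn, top, frame, lab).centroid
                 for lab in range(asn.n_clusters)]
        spacing, _ = lattice_spacing(np.array(cents), frame.box,
                                     axis=[0, 0, 1])
        assert spacing == pytest.approx(s, abs=0.5)

    def test_needs_two_fibres(self):
        with pytest.raises(ValueError, match="2"):
            lattice_spacing(np.array([[1.0, 2.0, 3.0]]), [10, 10, 10])


class TestDihedralsAndRamachandran:
    def test_planar_cases(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0],
                        [1, 1, 0]) == pytest.approx(0.0, abs=1e-12)
        assert abs(dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0],
                            [1, -1, 0])) == pytest.approx(180.0, abs=1e-12)

    def test_sign_flips_under_mirror(self, rng):
        pts = rng.normal(size=(4, 3))
        d = dihedral(*pts)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral(*mirrored) == pytest.approx(-d, abs=1e-9)

    def test_p2_construction_round_trip(self):
        top, frame = build_backbone([-65.0] * 4, [145.0] * 4)
        rs = ramachandran((top, frame))
        assert np.allclose(rs.phi, -65.0, atol=1e-6)
        assert np.allclose(rs.psi, 145.0, atol=1e-6)
        assert np.all(rs.regions == "P_II")

    def test_region_table(self):
        from hydrafibre.assembly import classify_region
        assert classify_region(-65.0, 145.0) == "P_II"
        assert classify_region(-120.0, 130.0) == "beta"
        assert classify_region(-60.0, -45.0) == "alpha_R"
        assert classify_region(60.0, 45.0) == "alpha_L"
        assert classify_region(10.0, -170.0) == "other"

    def test_missing_backbone_atom_skipped(self, caplog):
        top, frame = build_backbone([-65.0] * 3, [145.0] * 3)
        # drop one CA: that residue (and only its angles) disappears
        keep = [i for i in range(top.n_atoms)
                if not (top.names[i] == "CA" and top.residue_indices[i] == 1)]
        atoms = [top.atom(i) for i in keep]
        for new_id, a in enumerate(atoms):
            a.atom_id = new_id
        sub = Topology(atoms)
        rs = ramachandran((sub, Frame(0.0, frame.box,
                                      frame.coordinates[keep])))
        assert len(rs.phi) == 0


class TestChirality:
    def test_ideal_l_alanine(self):
        assert chirality(L_ALA["N"], L_ALA["CA"], L_ALA["C"],
                         L_ALA["CB"]) == "L"
        assert dihedral(L_ALA["N"], L_ALA["CA"], L_ALA["C"],
                        L_ALA["CB"]) == pytest.approx(120.0, abs=1.0)

    def test_mirror_gives_d(self):
        mirror = {k: (v[0], v[1], -v[2]) for k, v in L_ALA.items()}
        assert chirality(mirror["N"], mirror["CA"], mirror["C"],
                         mirror["CB"]) == "D"

    def test_builder_produces_l_residues(self):
        top, frame = build_backbone([-65.0] * 3, [145.0] * 3)
        rs = ramachandran((top, frame))
        assert np.all(rs.chirality == "L")
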