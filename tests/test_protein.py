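"""Structural geometry: ASA/RSA, distances, secondary structure, chemistry."""

import math

import numpy as np
import pytest

from onkointerp.errors import ConfigError, FormatError, ValidationError
from onkointerp.fixtures import generate_synthetic_structure
from onkointerp.protein import (assign_secondary_structure, build_feature_tracks,
                                calpha_distances, compute_asa, compute_rsa,
                                detect_bridges, load_maxasa, read_structure,
                                spatial_neighbors, substitution_features)
from onkointerp.protein.structure import Atom, Residue, StructureModel


def _point_model(spec):
    """Residues of single or multiple named atoms at given coordinates.

    spec: list of (index, aa, [(atom_name, element, xyz, radius), ...])
    """
    residues = []
    for idx, aa, atoms in spec:
        adict = {}
        for name, element, xyz, radius in atoms:
            adict[name] = Atom(name, element, np.array(xyz, float), radius)
        residues.append(Residue(idx, aa, adict))
    return StructureModel(residues)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestStructureIO:
    def test_minimal_fixture_roundtrip(self, tmp_path):
        p = tmp_path / "h.pdb"
        generate_synthetic_structure("helix", 5, 0, p)
        m = read_structure(p)
        assert len(m) == 5
        assert all(r.calpha is not None for r in m.residues)
        # PDB stores 3 decimals; a rewrite must agree to that precision
        text2 = generate_synthetic_structure("helix", 5, 0)
        assert text2 == p.read_text()

    def test_hetatm_only_rejected(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\nEND\n")
        with pytest.raises(FormatError, match="ATOM"):
            read_structure(p)

    def test_confidence_from_bfactor(self, helix_model):
        assert helix_model.residues[0].confidence == pytest.approx(90.0)


class TestComputeAsa:
    def test_isolated_atom_matches_analytic_sphere(self):
        """Single atom: ASA = 4 pi (r + probe)^2 exactly (no occlusion)."""
        m = _point_model([(1, "G", [("CA", "C", (0, 0, 0), 1.9)])])
        asa = compute_asa(m, probe_radius=1.4, n_points=960)
        analytic = 4 * math.pi * 3.3 ** 2
        assert asa[1] == pytest.approx(analytic, rel=1e-6)
        assert analytic == pytest.approx(136.85, abs=0.01)

    def test_total_occlusion(self):
        m = _point_model([
            (1, "G", [("CA", "C", (0, 0, 0), 3.0)]),
            (2, "G", [("CA", "C", (0, 0, 0.1), 1.2)]),
        ])
        asa = compute_asa(m)
        assert asa[2] == 0.0

    def test_dipeptide_close_to_highres_rerun(self, tmp_path):
        """Gly-Gly dipeptide: 960-point quadrature within 2% of a 10000-point
        rerun (self-convergence oracle)."""
        p = tmp_path / "gg.pdb"
        generate_synthetic_structure("helix", 4, 0, p)
        m = read_structure(p)
        coarse = compute_asa(m, n_points=960)
        fine = compute_asa(m, n_points=10000)
        for idx in coarse:
            assert coarse[idx] == pytest.approx(fine[idx], rel=0.02)

    def test_matches_independent_biotite_sasa(self, tmp_path):
        """Cross-check against an independent Shrake-Rupley implementation
        with matched radii on the helix fixture."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        p = tmp_path / "helix.pdb"
        generate_synthetic_structure("helix", 8, 0, p)
        m = read_structure(p)
        ours = compute_asa(m, n_points=960)
        arr = pdb.PDBFile.read(str(p)).get_structure(model=1)
        radii = np.array([{"N": 1.55, "C": 1.70, "O": 1.52}[e]
                          for e in arr.element])
        per_atom = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                              point_number=1000)
        for i, r in enumerate(np.unique(arr.res_id)):
            theirs = per_atom[arr.res_id == r].sum()
            assert ours[int(r)] == pytest.approx(theirs, rel=0.03)

    def test_additivity_bound(self, helix_model):
        """Total ASA never exceeds the sum of isolated-atom spheres."""
        asa = compute_asa(helix_model)
        coords, radii, _ = helix_model.atom_table()
        isolated = float(np.sum(4 * np.pi * (radii + 1.4) ** 2))
        assert sum(asa.values()) < isolated

    def test_convergence_on_helix(self, helix_model):
        """Doubling the quadrature points changes per-residue ASA by < 1%
        (binary point counting converges ~ n^-1/2, so the check doubles from
        a fine base)."""
        a = compute_asa(helix_model, n_points=3840)
        b = compute_asa(helix_model, n_points=7680)
        for idx in a:
            if b[idx] > 1.0:  # relative change meaningful only off zero
                assert abs(a[idx] - b[idx]) / b[idx] < 0.01

    def test_parameter_validation(self, helix_model):
        with pytest.raises(ConfigError):
            compute_asa(helix_model, probe_radius=0)
        with pytest.raises(ConfigError):
            compute_asa(helix_model, n_points=50)


class TestComputeRsa:
    def test_identity_and_clamp(self):
        maxasa = load_maxasa()
        assert compute_rsa(maxasa["G"], "G") == 1.0
        assert compute_rsa(0.0, "G") == 0.0
        assert compute_rsa(1.1 * maxasa["G"], "G") == 1.0

    def test_unknown_residue_type(self):
        with pytest.raises(ValidationError):
            compute_rsa(10.0, "X")

    def test_burial_monotone_in_growing_cluster(self, tmp_path):
        """Adding surrounding residues never increases residue 1's RSA."""
        maxasa = load_maxasa()
        rsas = []
        for n in (4, 10, 18, 26):
            p = tmp_path / f"c{n}.pdb"
            generate_synthetic_structure("cluster", n, seed=3, path=p)
            m = read_structure(p)
            asa = compute_asa(m, n_points=480)
            rsas.append(compute_rsa(asa[1], "G", maxasa))
        assert all(b <= a + 1e-9 for a, b in zip(rsas, rsas[1:]))


class TestCalphaDistances:
    def test_self_distance_zero(self, helix_model):
        assert calpha_distances(helix_model, 5)[5] == 0.0

    def test_three_four_five(self):
        m = _point_model([
            (1, "G", [("CA", "C", (0, 0, 0), 1.7)]),
            (2, "G", [("CA", "C", (3, 4, 0), 1.7)]),
        ])
        assert calpha_distances(m, 1)[2] == pytest.approx(5.0)

    def test_matches_elementwise_recomputation(self, helix_model):
        """Brute-force recomputation of every pairwise distance agrees."""
        cas = {r.index: r.calpha.coord for r in helix_model.residues}
        for mut in (1, 7, 20):
            d = calpha_distances(helix_model, mut)
            for idx, ca in cas.items():
                expected = math.sqrt(sum((ca[k] - cas[mut][k]) ** 2
                                         for k in range(3)))
                assert d[idx] == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_triangle_inequality(self, helix_model):
        idx = [r.index for r in helix_model.residues][:10]
        dist = {i: calpha_distances(helix_model, i) for i in idx}
        for i in idx:
            for j in idx:
                assert dist[i][j] == pytest.approx(dist[j][i], abs=1e-9)
                for k in idx:
                    assert dist[i][j] <= dist[i][k] + dist[k][j] + 1e-9

    def test_missing_calpha_is_error(self):
        m = _point_model([(1, "G", [("N", "N", (0, 0, 0), 1.55)])])
        with pytest.raises(ValidationError):
            calpha_distances(m, 1)


class TestSecondaryStructure:
    def test_ideal_helix_interior_h(self, helix_model):
        ss = assign_secondary_structure(helix_model)
        interior = [ss[i] for i in range(3, 19)]
        assert set(interior) == {"H"}

    def test_antiparallel_pair_interior_e(self, strand_pair_model):
        ss = assign_secondary_structure(strand_pair_model)
        indices = sorted(ss)
        first = indices[:8]
        second = indices[8:]
        assert set(ss[i] for i in first[1:-1]) == {"E"}
        assert set(ss[i] for i in second[1:-1]) == {"E"}

    def test_three_residue_fragment_all_coil(self, tmp_path):
        p = tmp_path / "frag.pdb"
        generate_synthetic_structure("helix", 4, 0, p)
        m = read_structure(p)
        m = StructureModel(m.residues[:3])
        ss = assign_secondary_structure(m)
        assert set(ss.values()) == {"C"}

    def test_rigid_motion_invariance(self, helix_model):
        rng = np.random.default_rng(12)
        rot = _random_rotation(rng)
        moved = helix_model.transformed(rot, np.array([5.0, -3.0, 11.0]))
        assert assign_secondary_structure(moved) == \
            assign_secondary_structure(helix_model)


class TestSubstitutionFeatures:
    def test_identity_substitution_all_zero(self):
        prof = substitution_features("G", "G")
        assert prof.delta_weight == 0.0
        assert prof.charge_change == ("neutral", "neutral")
        assert not prof.polarity_change and not prof.aromaticity_change
        assert prof.blosum62 == 6  # BLOSUM62 diagonal for glycine

    def test_gly_to_asp_charge_and_blosum(self):
        prof = substitution_features("G", "D")
        assert prof.charge_change == ("neutral", "negative")
        assert prof.blosum62 == -1  # canonical BLOSUM62 G->D entry

    def test_leu_to_pro_introduces_helix_breaker(self):
        assert substitution_features("L", "P").helix_breaker_introduced
        assert not substitution_features("G", "P").helix_breaker_introduced

    def test_new_cysteine_flag(self):
        assert substitution_features("R", "C").new_cys
        assert not substitution_features("C", "C").new_cys

    def test_non_canonical_rejected(self):
        with pytest.raises(ValidationError):
            substitution_features("B", "A")


class TestBridges:
    def test_gained_disulfide(self):
        m = _point_model([
            (1, "A", [("CB", "C", (0, 0, 0), 1.7)]),
            (5, "C", [("SG", "S", (2.1, 0, 0), 1.8)]),
        ])
        out = detect_bridges(m, 1, "A", "C")
        assert [(b.kind, b.change, b.partner_index) for b in out] == \
            [("disulfide", "gained", 5)]
        assert out[0].distance == pytest.approx(2.1)

    def test_gained_salt_bridge(self):
        m = _point_model([
            (1, "A", [("CB", "C", (0, 0, 0), 1.7)]),
            (9, "E", [("OE1", "O", (3.5, 0, 0), 1.52)]),
        ])
        out = detect_bridges(m, 1, "A", "K")
        assert [(b.kind, b.change, b.partner_index) for b in out] == \
            [("salt_bridge", "gained", 9)]

    def test_apolar_alt_no_candidates(self):
        m = _point_model([
            (1, "A", [("CB", "C", (0, 0, 0), 1.7)]),
            (5, "C", [("SG", "S", (2.1, 0, 0), 1.8)]),
        ])
        assert detect_bridges(m, 1, "G", "A") == []

    def test_lost_salt_bridge(self):
        m = _point_model([
            (1, "K", [("NZ", "N", (0, 0, 0), 1.55)]),
            (9, "D", [("OD1", "O", (3.0, 0, 0), 1.52)]),
        ])
        out = detect_bridges(m, 1, "K", "A")
        assert [(b.kind, b.change) for b in out] == [("salt_bridge", "lost")]


class TestSpatialNeighbors:
    def test_hairpin_far_in_sequence_close_in_space(self, hairpin_model):
        """Across the hairpin, residue i+14 is 3D-closer than i+2."""
        known = [(4, "v_close_seq"), (16, "v_far_seq")]
        out = spatial_neighbors(hairpin_model, 2, known, radius=10.0)
        assert [e["aa_pos"] for e in out] == [16, 4]
        assert out[0]["seq_separation"] > out[1]["seq_separation"]

    def test_radius_smaller_than_everything(self, hairpin_model):
        assert spatial_neighbors(hairpin_model, 2, [(16, "x")], 0.5) == []

    def test_sorted_ascending(self, helix_model):
        known = [(i, f"v{i}") for i in range(1, 21) if i != 10]
        out = spatial_neighbors(helix_model, 10, known, radius=1e6)
        d = [e["calpha_dist"] for e in out]
        assert d == sorted(d)
        assert len(out) == 19


class TestFeatureTracks:
    def test_all_tracks_populated(self, helix_model):
        rows, summary = build_feature_tracks(
            helix_model, 10, domain_table=[(5, 15, "ToyDomain")],
            known_variants=[(3, "v3")], binding_table={10: 0.7},
            predictor_score=0.8, n_points=480)
        assert len(rows) == 20
        site = next(r for r in rows if r.index == 10)
        assert site.calpha_dist == 0.0
        assert site.domain == "ToyDomain"
        assert site.binding_prob == 0.7
        assert all(r.ss_state in "HEC" for r in rows)
        assert all(0 <= r.rsa <= 1 for r in rows)
        assert "residue 10" in summary

    def test_benign_leaning_summary(self, hairpin_model):
        """Exposed coil residue outside any domain with a low predictor score
        is tagged benign-leaning."""
        rows, summary = build_feature_tracks(
            hairpin_model, 1, predictor_score=0.1, n_points=480)
        assert "benign-leaning" in summary

    def test_pathogenic_leaning_summary(self, tmp_path):
        p = tmp_path / "cl.pdb"
        generate_synthetic_structure("cluster", 26, seed=3, path=p)
        m = read_structure(p)
        rows, summary = build_feature_tracks(
            m, 1, domain_table=[(1, 5, "Core")], predictor_score=0.9,
            n_points=480)
        assert "pathogenic-leaning" in summary

    def test_track_length_mismatch_named(self, helix_model):
        with pytest.raises(FormatError, match="binding"):
            build_feature_tracks(helix_model, 10, binding_table={99: 0.5},
                                 n_points=480)
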