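"""The Shrake-Rupley accessibility engine against analytic and brute-force oracles."""

import math

import numpy as np
import pytest

from codp.structure import (
    AtomRecord,
    Burial,
    MissingResidueError,
    PDBParseError,
    StructureModel,
    UnknownElementError,
    classify_burial,
    golden_spiral_points,
    read_structure,
    residue_relative_accessibility,
    shrake_rupley_asa,
)


def carbon(x, y=0.0, z=0.0, name="C1", resnum=1, chain="A"):
    return AtomRecord(chain, resnum, "", "UNK", name, "C", (x, y, z), 1.70)


R = 1.70 + 1.4  # probe-expanded carbon radius


def two_sphere_cap_asa(d: float) -> float:
    """Analytic exposed area of one of two equal spheres at centre distance d."""
    h = R - d / 2.0
    return 4.0 * math.pi * R * R - 2.0 * math.pi * R * h


def monte_carlo_asa(center, other, n=200_000, seed=7) -> float:
    """Surface-point rejection oracle for the two-sphere case."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = np.asarray(center) + R * v
    exposed = np.linalg.norm(pts - np.asarray(other), axis=1) >= R
    return 4.0 * math.pi * R * R * exposed.mean()


class TestSpherePoints:
    def test_unit_norm_and_determinism(self):
        pts = golden_spiral_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert pts is golden_spiral_points(960)  # cached, fixed scheme

    def test_quasi_uniform_centroid_near_origin(self):
        assert np.linalg.norm(golden_spiral_points(960).mean(axis=0)) < 1e-2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            golden_spiral_points(5)


class TestShrakeRupley:
    def test_isolated_atom_full_sphere_area_exact(self):
        asa = shrake_rupley_asa(StructureModel((carbon(0.0),)), 1.4, 960)
        assert asa[0] == pytest.approx(4.0 * math.pi * R * R, rel=1e-12)

    def test_distant_atoms_unoccluded(self):
        s = StructureModel((carbon(0.0), carbon(2 * R + 0.5, name="C2")))
        asa = shrake_rupley_asa(s, 1.4, 960)
        full = 4.0 * math.pi * R * R
        assert asa[0] == pytest.approx(full, rel=1e-12)
        assert asa[1] == pytest.approx(full, rel=1e-12)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_sphere_matches_spherical_cap_formula(self, d):
        s = StructureModel((carbon(0.0), carbon(d, name="C2")))
        asa = shrake_rupley_asa(s, 1.4, 960)
        exact = two_sphere_cap_asa(d)
        for v in asa.values():
            assert v == pytest.approx(exact, rel=0.02)

    def test_two_sphere_matches_monte_carlo_oracle(self):
        d = 3.0
        s = StructureModel((carbon(0.0), carbon(d, name="C2")))
        asa = shrake_rupley_asa(s, 1.4, 960)
        mc = monte_carlo_asa((0.0, 0.0, 0.0), (d, 0.0, 0.0))
        assert asa[0] == pytest.approx(mc, rel=0.02)

    def test_point_count_convergence_to_analytic(self):
        d = 3.0
        s = StructureModel((carbon(0.0), carbon(d, name="C2")))
        exact = two_sphere_cap_asa(d)
        errs = [
            abs(shrake_rupley_asa(s, 1.4, n)[0] - exact) for n in (240, 960, 3840)
        ]
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] / exact < 0.01

    def test_monotone_under_added_occluder(self):
        base = StructureModel((carbon(0.0), carbon(3.0, name="C2")))
        more = StructureModel(base.atoms + (carbon(0.0, 3.0, name="C3"),))
        asa_base = shrake_rupley_asa(base, 1.4, 960)
        asa_more = shrake_rupley_asa(more, 1.4, 960)
        assert asa_more[0] <= asa_base[0]
        assert asa_more[1] <= asa_base[1]

    def test_translation_leaves_asa_unchanged(self):
        atoms = (carbon(0.0), carbon(2.0, 1.0, -0.5, name="C2"), carbon(-1.0, 2.5, name="C3"))
        shift = np.array([12.3, -45.6, 7.89])
        moved = tuple(
            AtomRecord(a.chain, a.residue_number, a.insertion_code, a.residue_name,
                       a.atom_name, a.element, tuple(np.array(a.coords) + shift), a.vdw_radius)
            for a in atoms
        )
        a1 = shrake_rupley_asa(StructureModel(atoms), 1.4, 960)
        a2 = shrake_rupley_asa(StructureModel(moved), 1.4, 960)
        for k in a1:
            assert a1[k] == pytest.approx(a2[k], rel=1e-9)

    def test_rotation_within_sampling_tolerance(self):
        # fixed global point scheme: rotation changes ASA only within tolerance
        atoms = (carbon(0.0), carbon(3.0, name="C2"))
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0], [math.sin(theta), math.cos(theta), 0], [0, 0, 1]]
        )
        rotated = tuple(
            AtomRecord(a.chain, a.residue_number, a.insertion_code, a.residue_name,
                       a.atom_name, a.element, tuple(rot @ np.array(a.coords)), a.vdw_radius)
            for a in atoms
        )
        a1 = shrake_rupley_asa(StructureModel(atoms), 1.4, 960)
        a2 = shrake_rupley_asa(StructureModel(rotated), 1.4, 960)
        for k in a1:
            assert a1[k] == pytest.approx(a2[k], rel=0.02)

    def test_neighbour_search_identical_to_all_pairs(self):
        rng = np.random.default_rng(3)
        atoms = tuple(
            carbon(*xyz, name=f"C{i}") for i, xyz in enumerate(rng.uniform(0, 8, size=(25, 3)))
        )
        s = StructureModel(atoms)
        asa = shrake_rupley_asa(s, 1.4, 240)
        # brute force: check every point against every other atom
        unit = golden_spiral_points(240)
        coords = np.array([a.coords for a in atoms])
        for i in range(len(atoms)):
            pts = coords[i] + R * unit
            exposed = np.ones(len(pts), dtype=bool)
            for j in range(len(atoms)):
                if j == i:
                    continue
                exposed &= np.linalg.norm(pts - coords[j], axis=1) >= R
            expected = 4 * math.pi * R * R * exposed.mean()
            assert asa[i] == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_biopython_engine_on_random_cluster(self):
        # independent implementation cross-check on the same radii
        from Bio.PDB.SASA import ShrakeRupley as BioSR
        from Bio.PDB.StructureBuilder import StructureBuilder

        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 6, size=(10, 3))
        sb = StructureBuilder()
        sb.init_structure("x")
        sb.init_model(0)
        sb.init_chain("A")
        sb.init_seg("    ")
        sb.init_residue("UNK", " ", 1, " ")
        for i, xyz in enumerate(coords):
            sb.init_atom(f"C{i}", xyz.astype(float), 0.0, 1.0, " ", f"C{i}", i + 1, "C")
        bio = sb.get_structure()
        BioSR(probe_radius=1.4, n_points=960).compute(bio, level="A")
        bio_asa = [a.sasa for a in bio.get_atoms()]
        atoms = tuple(carbon(*xyz, name=f"C{i}") for i, xyz in enumerate(coords))
        ours = shrake_rupley_asa(StructureModel(atoms), 1.4, 960)
        for i, ref in enumerate(bio_asa):
            assert ours[i] == pytest.approx(ref, rel=0.03, abs=1.0)


MINI_PDB = (
    "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
    "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
    "ATOM      3  C   ALA A   1       2.003   1.420   0.000  1.00  0.00           C\n"
    "END\n"
)


class TestReadStructure:
    def test_minimal_atom_records(self):
        s = read_structure(MINI_PDB)
        assert len(s.atoms) == 3
        assert s.atoms[1].atom_name == "CA"
        assert s.atoms[1].vdw_radius == 1.70

    def test_only_first_model_kept(self):
        text = (
            "MODEL        1\n" + MINI_PDB.replace("END\n", "") + "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      4  CB  ALA A   1       9.000   9.000   9.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        s = read_structure(text)
        assert len(s.atoms) == 3
        assert all(a.atom_name != "CB" for a in s.atoms)

    def test_altloc_resolved_to_highest_occupancy(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40  0.00           C\n"
            "END\n"
        )
        s = read_structure(text)
        assert len(s.atoms) == 1
        assert s.atoms[0].coords[0] == pytest.approx(0.0)

    def test_waters_flagged_and_excluded_from_asa(self):
        text = MINI_PDB.replace("END\n", "") + (
            "HETATM    4  O   HOH A 101       1.458   1.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        s = read_structure(text)
        assert any(a.is_water for a in s.atoms)
        asa = shrake_rupley_asa(s, 1.4, 240)
        water_idx = next(i for i, a in enumerate(s.atoms) if a.is_water)
        assert water_idx not in asa

    def test_heteroatoms_excluded_by_default_but_includable(self):
        text = MINI_PDB.replace("END\n", "") + (
            "HETATM    4  P1  LIG A 201       1.458   2.000   0.000  1.00  0.00           P\n"
            "END\n"
        )
        s = read_structure(text)
        default = shrake_rupley_asa(s, 1.4, 240)
        with_het = shrake_rupley_asa(s, 1.4, 240, include_hetero=True)
        assert len(with_het) == len(default) + 1
        # the ligand occludes nearby protein atoms when included
        assert sum(with_het[i] for i in default) < sum(default.values())
        assert with_het[2] < default[2]

    def test_no_atoms_is_a_parse_error(self):
        with pytest.raises(PDBParseError):
            read_structure("REMARK nothing here\nEND\n")

    def test_unknown_element_error_names_the_atom(self):
        text = "ATOM      1 FE   HEM A   1       0.000   0.000   0.000  1.00  0.00          FE\n"
        with pytest.raises(UnknownElementError, match="FE"):
            read_structure(text)


class TestRelativeAccessibility:
    def test_missing_residue_error_carries_position(self):
        s = read_structure(MINI_PDB)
        with pytest.raises(MissingResidueError) as exc:
            residue_relative_accessibility(s, "A", 551)
        assert exc.value.residue_number == 551
        assert exc.value.chain == "A"

    def test_relative_accessibility_can_exceed_one_for_extended_residue(self):
        # a lone backbone fragment has more exposed area than the compact
        # in-chain reference if normalized against a tighter reference value
        s = read_structure(MINI_PDB)
        rel = residue_relative_accessibility(s, "A", 1, max_asa_table={"ALA": 100.0})
        assert rel > 1.0


class TestClassifyBurial:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.05, Burial.BURIED), (0.10, Burial.SURFACE), (0.583, Burial.SURFACE), (0.0, Burial.BURIED)],
    )
    def test_threshold_convention(self, value, expected):
        assert classify_burial(value) is expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_burial(-0.01)
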