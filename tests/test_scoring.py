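"""Ambiguous restraints and the composite rigid-body score."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepdock import define_airs
from pepdock.scoring import (
    WEIGHTS,
    AirRestraintSet,
    NoInterfaceError,
    PoseScorer,
    ScoreComponents,
    ScoringConfig,
    air_energy,
    buried_surface_area,
    desolvation_energy,
    elec_energy,
    rigid_score,
    vdw_energy,
    write_airs_cns,
    write_airs_table,
)
from pepdock.structmodel import (
    Atom,
    Chain,
    Residue,
    Selection,
    Structure,
    chain_selection,
)


def single_atom_structure(chain_id, element="C", name="CA", coords=(0, 0, 0),
                          res_name="ALA"):
    atom = Atom(name, element, np.asarray(coords, float))
    return Structure([Chain(chain_id, [Residue(res_name, 1, "", [atom])])])


class TestScoreComponents:
    def test_printed_weight_arithmetic(self):
        s = ScoreComponents(e_rest=100, e_vdw=100, e_elec=10, e_desol=-5,
                            bsa=500)
        assert s.total == pytest.approx(2.0, abs=1e-12)

    def test_all_zero_components(self):
        assert ScoreComponents(0, 0, 0, 0, 0).total == 0.0

    def test_total_is_exact_linear_functional(self, rng):
        for _ in range(20):
            vals = rng.normal(size=5) * 100
            s = ScoreComponents(*vals)
            expected = (WEIGHTS["e_rest"] * vals[0] + WEIGHTS["e_vdw"] * vals[1]
                        + WEIGHTS["e_elec"] * vals[2]
                        + WEIGHTS["e_desol"] * vals[3]
                        + WEIGHTS["bsa"] * vals[4])
            assert s.total == pytest.approx(expected, abs=1e-12)


class TestDefineAirs:
    def test_active_set_matches_brute_force(self, groove_case):
        airs = groove_case["airs"]
        complex_ref = groove_case["complex"]
        expected = set()
        pep_atoms = [a.coords for r in complex_ref.chain("B").residues
                     for a in r.heavy_atoms()]
        for res in complex_ref.chain("A").residues:
            if any(np.linalg.norm(a.coords - p) <= 5.0
                   for a in res.heavy_atoms() for p in pep_atoms):
                expected.add(("A", res.seq_id, ""))
        assert set(airs.active.triples) == expected
        # every peptide residue is passive
        assert len(airs.passive) == len(complex_ref.chain("B").residues)

    def test_tiny_cutoff_raises_no_interface(self, groove_case):
        with pytest.raises(NoInterfaceError):
            define_airs(groove_case["complex"], "A", "B", cutoff=0.1)

    def test_broad_definition_exceeds_true_interface(self, groove_case):
        """The 5 A active surface is deliberately larger than the buried
        area it encloses."""
        from pepdock.structmodel import shrake_rupley_sasa

        airs = groove_case["airs"]
        receptor = groove_case["receptor"]
        areas = shrake_rupley_sasa(receptor, n_points=240)
        active = set(airs.active.triples)
        active_area = sum(
            a for (cid, res, _), a in zip(receptor.heavy_atoms(), areas)
            if (cid, res.seq_id, res.insertion_code) in active)
        pep = Structure([groove_case["complex"].chain("B")])
        bsa = buried_surface_area(receptor, pep)
        assert active_area > bsa / 2

    def test_empty_active_selection_rejected(self):
        with pytest.raises(NoInterfaceError):
            AirRestraintSet(active=Selection.of([]),
                            passive=Selection.of([("B", 1, "")]))


class TestAirEnergy:
    def test_single_pair_closed_form(self):
        rec = single_atom_structure("A", coords=(0, 0, 0))
        pep = single_atom_structure("B", coords=(12.0, 0, 0))
        airs = AirRestraintSet(active=Selection.of([("A", 1, "")]),
                               passive=Selection.of([("B", 1, "")]),
                               upper_bound=2.0, force_constant=1.0)
        # one atom pair: d_eff equals the distance, energy (12-2)^2
        assert air_energy(rec, pep, airs) == pytest.approx(100.0, abs=1e-9)

    def test_flat_bottom_is_zero_when_effective_distance_satisfied(self):
        rec = single_atom_structure("A", coords=(0, 0, 0))
        pep = single_atom_structure("B", coords=(1.5, 0, 0))
        airs = AirRestraintSet(active=Selection.of([("A", 1, "")]),
                               passive=Selection.of([("B", 1, "")]),
                               upper_bound=2.0, force_constant=1.0)
        assert air_energy(rec, pep, airs) == 0.0

    def test_reference_pose_much_lower_than_separated(self, groove_case):
        pep = Structure([groove_case["complex"].chain("B")])
        far = pep.transformed(np.eye(3), np.array([0.0, 0.0, 25.0]))
        in_groove = air_energy(groove_case["receptor"], pep,
                               groove_case["airs"])
        separated = air_energy(groove_case["receptor"], far,
                               groove_case["airs"])
        assert in_groove < separated / 10

    def test_matches_direct_summation_oracle(self, groove_case, rng):
        pep = Structure([groove_case["complex"].chain("B")])
        moved = pep.transformed(np.eye(3), np.array([0.0, 0.0, 20.0]))
        airs = groove_case["airs"]
        expected = 0.0
        pep_coords = [a.coords for _, _, a in moved.heavy_atoms()]
        for cid, seq_id, icode in airs.active.triples:
            res = groove_case["receptor"].chain(cid).residue(seq_id, icode)
            inv6 = 0.0
            for atom in res.heavy_atoms():
                for p in pep_coords:
                    inv6 += np.linalg.norm(atom.coords - p) ** -6
            d_eff = inv6 ** (-1 / 6)
            expected += airs.force_constant * max(0.0, d_eff - 2.0) ** 2
        value = air_energy(groove_case["receptor"], moved, airs)
        assert value == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_joint_rigid_motion(self, groove_case):
        rot = Rotation.from_euler("xyz", [12, 34, 56], degrees=True).as_matrix()
        t = np.array([3.0, -8.0, 2.0])
        rec = groove_case["receptor"].transformed(rot, t)
        pep = Structure([groove_case["complex"].chain("B")]).transformed(rot, t)
        moved_value = air_energy(rec, pep, groove_case["airs"])
        ref_value = air_energy(groove_case["receptor"],
                               Structure([groove_case["complex"].chain("B")]),
                               groove_case["airs"])
        assert moved_value == pytest.approx(ref_value, abs=1e-9)

    def test_monotone_decrease_on_approach(self, groove_case):
        pep = Structure([groove_case["complex"].chain("B")])
        airs = groove_case["airs"]
        values = []
        for dz in (30.0, 20.0, 12.0, 6.0):
            moved = pep.transformed(np.eye(3), np.array([0.0, 0.0, dz]))
            values.append(air_energy(groove_case["receptor"], moved, airs))
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestNonbonded:
    def test_separated_molecules_have_zero_vdw_and_elec(self):
        rec = single_atom_structure("A")
        pep = single_atom_structure("B", coords=(50.0, 0, 0))
        assert vdw_energy(rec, pep) == 0.0
        assert elec_energy(rec, pep) == 0.0

    def test_lj_minimum_depth(self):
        cfg = ScoringConfig()
        sigma = cfg.lj_sigma["C"]
        rec = single_atom_structure("A")
        pep = single_atom_structure("B", coords=(sigma * 2 ** (1 / 6), 0, 0))
        value = vdw_energy(rec, pep, cfg)
        # truncation shift moves the minimum slightly off -epsilon
        assert value == pytest.approx(-cfg.lj_epsilon["C"], rel=0.02)

    def test_opposite_charges_attract(self):
        cfg = ScoringConfig()
        rec = single_atom_structure("A", name="CB", res_name="LYS")
        pep = single_atom_structure("B", name="CB", res_name="ASP",
                                    coords=(4.0, 0, 0))
        assert elec_energy(rec, pep, cfg) < 0

    def test_untyped_element_raises(self):
        rec = single_atom_structure("A", element="FE")
        pep = single_atom_structure("B", coords=(4.0, 0, 0))
        from pepdock.structmodel import PepdockError

        with pytest.raises(PepdockError):
            vdw_energy(rec, pep)


class TestBuriedSurface:
    def test_zero_for_separated_and_nonnegative_in_contact(self, groove_case):
        pep = Structure([groove_case["complex"].chain("B")])
        far = pep.transformed(np.eye(3), np.array([500.0, 0.0, 0.0]))
        assert buried_surface_area(groove_case["receptor"], far) == 0.0
        assert desolvation_energy(groove_case["receptor"], far) == 0.0
        assert buried_surface_area(groove_case["receptor"], pep) > 0.0

    def test_pose_scorer_matches_module_functions(self, groove_case):
        pep = Structure([groove_case["complex"].chain("B")])
        components = rigid_score(groove_case["receptor"], pep,
                                 groove_case["airs"])
        assert components.bsa == pytest.approx(
            buried_surface_area(groove_case["receptor"], pep), abs=1e-9)
        assert components.e_desol == pytest.approx(
            desolvation_energy(groove_case["receptor"], pep), abs=1e-9)
        assert components.e_vdw == pytest.approx(
            vdw_energy(groove_case["receptor"], pep), abs=1e-9)

    def test_rotated_pose_bsa_consistent_and_nonnegative(self, groove_case):
        """With the co-rotated dot sphere, the incremental BSA of a rotated
        pose stays non-negative and tracks the from-scratch computation on
        the transformed structure (two discretizations of the same area)."""
        pep = Structure([groove_case["complex"].chain("B")])
        scorer = PoseScorer(groove_case["receptor"], pep,
                            groove_case["airs"])
        for angle in (40, 110, 220):
            rot = Rotation.from_euler("y", angle, degrees=True).as_matrix()
            centroid = scorer.pep.coords.mean(axis=0)
            world = (scorer.pep.coords - centroid) @ rot.T + centroid
            moved = pep.transformed(rot, centroid - rot @ centroid)
            fast = scorer.components(world, rot)
            slow = rigid_score(groove_case["receptor"], moved,
                               groove_case["airs"])
            assert fast.bsa >= 0.0
            if slow.bsa > 100.0:
                assert fast.bsa == pytest.approx(slow.bsa, rel=0.05)


class TestConfigAndSerialization:
    def test_config_roundtrip(self, tmp_path):
        cfg = ScoringConfig(dielectric=4.0, air_force_constant=25.0)
        path = tmp_path / "scoring.cfg"
        cfg.to_file(path)
        reread = ScoringConfig.from_file(path)
        assert reread.dielectric == 4.0
        assert reread.air_force_constant == 25.0
        assert reread.lj_sigma == cfg.lj_sigma

    def test_airs_serialization(self, tmp_path, groove_case):
        airs = groove_case["airs"]
        table = tmp_path / "airs.tsv"
        cns = tmp_path / "airs.cns"
        write_airs_table(airs, table)
        write_airs_cns(airs, cns)
        lines = table.read_text().splitlines()
        assert len(lines) == 1 + len(airs.active) + len(airs.passive)
        assert cns.read_text().count("assign") == len(airs.active)
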