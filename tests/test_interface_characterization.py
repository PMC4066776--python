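import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dockconsensus.geometry import RigidTransform, sasa, transformed
from dockconsensus.interface_characterization import (
    build_interface_report,
    buried_area_per_residue,
    detect_apolar_contacts,
    detect_salt_bridges,
    find_anchors,
    interface_residues,
    second_site_clash_check,
)
from dockconsensus.structure_io import concatenate


def far_ligand(toy, shift=200.0):
    return toy.ligand.with_coords(toy.ligand.coords
                                  + np.array([0.0, shift, 0.0]))


class TestInterfaceResidues:
    def test_separated_partners_empty(self, toy):
        r, l = interface_residues(toy.receptor, far_ligand(toy), 5.0)
        assert r == [] and l == []

    def test_bound_pose_contains_planted_residues(self, toy):
        r, l = interface_residues(toy.receptor, toy.ligand, 5.0)
        for key in toy.acidic_keys + [toy.anchor_receptor_key]:
            assert key in r
        for key in toy.basic_keys + [toy.anchor_ligand_key]:
            assert key in l

    def test_nested_in_larger_zone(self, toy):
        r5, l5 = interface_residues(toy.receptor, toy.ligand, 5.0)
        r10, l10 = interface_residues(toy.receptor, toy.ligand, 10.0)
        assert set(r5) <= set(r10)
        assert set(l5) <= set(l10)

    def test_single_partner_rejected(self, toy):
        empty = toy.ligand.select(np.zeros(toy.ligand.n_atoms, bool))
        with pytest.raises(ValueError):
            interface_residues(toy.receptor, empty)


class TestBuriedArea:
    def test_separated_all_zero(self, toy):
        buried = buried_area_per_residue(toy.receptor, far_ligand(toy))
        assert all(v == pytest.approx(0.0, abs=0.5) for v in buried.values())

    def test_additivity(self, toy):
        buried = buried_area_per_residue(toy.receptor, toy.ligand)
        total = sum(buried.values())
        gap = (sasa(toy.receptor).total() + sasa(toy.ligand).total()
               - sasa(concatenate([toy.receptor, toy.ligand])).total())
        assert total == pytest.approx(gap, rel=0.02)

    def test_touching_residue_buries_most(self, toy):
        buried = buried_area_per_residue(toy.receptor, toy.ligand)
        interface_keys = set(sum(interface_residues(toy.receptor,
                                                    toy.ligand, 5.0), []))
        top = max(buried, key=buried.get)
        assert top in interface_keys


class TestAnchors:
    def test_all_zero_burial_empty(self, toy):
        buried = buried_area_per_residue(toy.receptor, far_ligand(toy))
        buried = {k: 0.0 for k in buried}
        anchors = find_anchors(buried, {"A", "B"}, k=2)
        assert anchors["receptor"] == [] and anchors["ligand"] == []

    def test_planted_anchor_ranks_first(self, toy):
        buried = buried_area_per_residue(toy.receptor, toy.ligand)
        anchors = find_anchors(buried, {"A", "B"}, k=1)
        assert anchors["receptor"][0][0] == toy.anchor_receptor_key
        assert anchors["ligand"][0][0] == toy.anchor_ligand_key
        assert len(anchors["receptor"]) == 1

    def test_k_validated(self, toy):
        with pytest.raises(ValueError):
            find_anchors({}, {"A"}, k=0)


class TestContactTyping:
    def test_planted_salt_bridges_found(self, toy):
        bridges = detect_salt_bridges(toy.receptor, toy.ligand)
        assert len(bridges) >= 3
        pairs = {(c.res_a, c.res_b) for c in bridges}
        assert pairs == set(zip(toy.acidic_keys, toy.basic_keys))
        # hand distance check
        for c in bridges:
            assert c.distance <= 4.0

    def test_distance_cutoff_respected(self, toy):
        assert detect_salt_bridges(toy.receptor, toy.ligand,
                                   cutoff=1.0) == []

    def test_no_planted_features_no_bridges(self):
        from dockconsensus.synthetic_data import (ToyComplexSpec,
                                                  make_toy_complex)
        import dataclasses
        plain_spec = ToyComplexSpec()
        plain = make_toy_complex(plain_spec)
        # strip the planted side chains: backbone + CB only
        def backbone_only(s):
            return s.select(np.isin(s.atom_names, ("N", "CA", "C", "O",
                                                   "CB")))
        rec = backbone_only(plain.receptor)
        lig = backbone_only(plain.ligand)
        assert detect_salt_bridges(rec, lig) == []
        assert interface_residues(rec, lig, 5.0)[0] != []

    def test_anchor_apolar_contact(self, toy):
        contacts = detect_apolar_contacts(toy.receptor, toy.ligand)
        anchor_pairs = [c for c in contacts
                        if c.res_a == toy.anchor_receptor_key
                        and c.res_b == toy.anchor_ligand_key]
        assert len(anchor_pairs) >= 1
        assert all(c.distance <= 4.5 for c in contacts)

    def test_contacts_invariant_under_rigid_motion(self, toy, rng):
        quat = rng.standard_normal(4)
        quat /= np.linalg.norm(quat)
        t = RigidTransform(Rotation.from_quat(quat).as_matrix(),
                           rng.normal(scale=30, size=3))
        before = detect_apolar_contacts(toy.receptor, toy.ligand)
        after = detect_apolar_contacts(transformed(toy.receptor, t),
                                       transformed(toy.ligand, t))
        assert [(c.res_a, c.res_b, c.atom_a, c.atom_b) for c in before] == \
            [(c.res_a, c.res_b, c.atom_a, c.atom_b) for c in after]

    def test_contacts_within_interface_lists(self, toy):
        contacts = (detect_salt_bridges(toy.receptor, toy.ligand)
                    + detect_apolar_contacts(toy.receptor, toy.ligand))
        cutoff = 4.5  # >= every contact cutoff used above
        r, l = interface_residues(toy.receptor, toy.ligand, cutoff)
        for c in contacts:
            assert c.res_a in r
            assert c.res_b in l


class TestSecondSiteClash:
    def test_open_second_site_no_clash(self, toy):
        res = second_site_clash_check(toy.receptor, toy.ligand)
        assert res.clash_count == 0
        assert res.verdict == "no_clash"
        assert res.monomer_superposition_rmsd < 1e-6

    def test_ligand_on_twofold_axis_self_image(self, toy):
        # centre the ligand's atoms on the dimer's 2-fold axis: its
        # symmetry image superposes onto itself, every heavy atom clashes
        # with its own image
        sep = toy.spec.helix_separation
        axis_y = -(sep * 0.6)
        lig = toy.ligand.copy()
        coords = lig.coords.copy()
        coords[:, 1] = axis_y
        coords[:, 2] = 0.0
        lig = lig.with_coords(coords)
        res = second_site_clash_check(toy.receptor, lig,
                                      report_threshold=10)
        n_heavy = int(lig.heavy_mask().sum())
        assert res.clash_count >= n_heavy
        assert res.verdict == "clash"

    def test_matches_brute_force_recount(self, toy, rng):
        # asymmetric pose straddling the dimer interface
        lig = toy.ligand.with_coords(
            toy.ligand.coords + np.array([0.0, -14.0, 3.0]))
        res = second_site_clash_check(toy.receptor, lig, clash_cutoff=2.5)
        # brute force: apply the A->B transform manually
        from dockconsensus.geometry import kabsch_superpose
        a = toy.receptor.select(toy.receptor.chain_mask("A"))
        b = toy.receptor.select(toy.receptor.chain_mask("B"))
        tr, _ = kabsch_superpose(a.coords, b.coords)
        second = tr.apply(lig.coords[lig.heavy_mask()])
        obstacles = np.concatenate([
            toy.receptor.coords[toy.receptor.heavy_mask()],
            lig.coords[lig.heavy_mask()]])
        d = np.linalg.norm(second[:, None] - obstacles[None], axis=2)
        assert res.clash_count == int((d < 2.5).sum())

    def test_invariant_under_rigid_motion(self, toy, rng):
        quat = rng.standard_normal(4)
        quat /= np.linalg.norm(quat)
        t = RigidTransform(Rotation.from_quat(quat).as_matrix(),
                           rng.normal(scale=15, size=3))
        before = second_site_clash_check(toy.receptor, toy.ligand)
        after = second_site_clash_check(transformed(toy.receptor, t),
                                        transformed(toy.ligand, t))
        assert before.clash_count == after.clash_count

    def test_non_dimer_rejected(self, toy_monomer):
        with pytest.raises(ValueError, match="two chains"):
            second_site_clash_check(toy_monomer.receptor,
                                    toy_monomer.ligand)


class TestReport:
    def test_full_report_consistent(self, toy):
        report = build_interface_report(toy.receptor, toy.ligand,
                                        run_clash_check=True)
        d = report.to_dict()
        assert d["clash_check"]["verdict"] == "no_clash"
        assert d["anchors"]["receptor"][0][0] == str(toy.anchor_receptor_key)
        types = {c["type"] for c in d["contacts"]}
        assert "salt_bridge" in types and "apolar" in types
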