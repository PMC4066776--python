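import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dockconsensus.geometry import RigidTransform, transformed
from dockconsensus.restraints import (
    DPRA_ACTIVE,
    RestraintSet,
    TriadConstraint,
    build_passive_set,
    discard_restraints,
    effective_distance,
    restraint_satisfaction,
    resolve_labels,
    triad_filter,
)


class TestEffectiveDistance:
    def test_single_pair(self):
        assert effective_distance([[0, 0, 0]], [[5, 0, 0]]) == \
            pytest.approx(5.0)

    def test_two_pairs_closed_form(self):
        # one atom against two partner atoms at 4 and 6 A
        val = effective_distance([[0, 0, 0]], [[4, 0, 0], [0, 6, 0]])
        expected = (4.0 ** -6 + 6.0 ** -6) ** (-1.0 / 6.0)
        assert val == pytest.approx(expected)
        assert expected == pytest.approx(3.94, abs=0.01)

    def test_monotone_in_pair_set(self, rng):
        a = rng.uniform(-3, 3, size=(4, 3))
        b = rng.uniform(5, 9, size=(6, 3))
        full = effective_distance(a, b)
        for k in range(1, 6):
            assert effective_distance(a, b[:k]) >= full - 1e-12
        mins = np.linalg.norm(a[:, None] - b[None], axis=2).min()
        assert full <= mins

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            effective_distance(np.empty((0, 3)), [[1, 2, 3]])


def restraint_set_for(toy):
    rec_active = toy.acidic_keys + [toy.anchor_receptor_key]
    lig_active = toy.basic_keys + [toy.anchor_ligand_key]
    return RestraintSet(receptor_active=rec_active,
                        ligand_active=lig_active,
                        receptor_passive=[], ligand_passive=[],
                        effective_cutoff=4.5)


class TestSatisfaction:
    def test_bound_complex_fully_satisfied(self, toy):
        frac, details = restraint_satisfaction(toy.receptor, toy.ligand,
                                               restraint_set_for(toy))
        assert frac == 1.0
        assert all(d["satisfied"] for d in details)

    def test_separated_partners_zero(self, toy):
        far = toy.ligand.with_coords(toy.ligand.coords
                                     + np.array([0.0, 100.0, 0.0]))
        frac, _ = restraint_satisfaction(toy.receptor, far,
                                         restraint_set_for(toy))
        assert frac == 0.0

    def test_nonincreasing_along_separation(self, toy):
        rset = restraint_set_for(toy)
        fractions = []
        for step in (0.0, 2.0, 4.0, 8.0, 16.0, 50.0):
            lig = toy.ligand.with_coords(toy.ligand.coords
                                         + np.array([0.0, step, 0.0]))
            fractions.append(restraint_satisfaction(toy.receptor, lig,
                                                    rset)[0])
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_rigid_transform_invariance(self, toy, rng):
        rset = restraint_set_for(toy)
        quat = rng.standard_normal(4)
        quat /= np.linalg.norm(quat)
        t = RigidTransform(Rotation.from_quat(quat).as_matrix(),
                           rng.normal(scale=20, size=3))
        f0, _ = restraint_satisfaction(toy.receptor, toy.ligand, rset)
        f1, _ = restraint_satisfaction(transformed(toy.receptor, t),
                                       transformed(toy.ligand, t), rset)
        assert f0 == f1

    def test_unresolvable_residue(self, toy):
        from dockconsensus.structure_io import ResidueKey
        bad = RestraintSet(
            receptor_active=[ResidueKey("A", 999, "", "GLU")],
            ligand_active=[], ligand_passive=toy.basic_keys)
        with pytest.raises(KeyError):
            restraint_satisfaction(toy.receptor, toy.ligand, bad)


class TestDiscard:
    def _set_of_eight(self, toy):
        # eight active restraints on the receptor, like the DprA list
        keys = toy.receptor.residue_keys()[:8]
        return RestraintSet(receptor_active=list(keys),
                            discard_fraction=0.5)

    def test_fraction_zero_identity(self, toy):
        rset = self._set_of_eight(toy)
        rset.discard_fraction = 0.0
        out = discard_restraints(rset, seed=3)
        assert out.receptor_active == rset.receptor_active

    def test_half_of_eight_leaves_four(self, toy):
        out = discard_restraints(self._set_of_eight(toy), seed=3)
        assert len(out.receptor_active) == 4

    def test_deterministic_per_seed(self, toy):
        rset = self._set_of_eight(toy)
        a = discard_restraints(rset, seed=5)
        b = discard_restraints(rset, seed=5)
        assert a.receptor_active == b.receptor_active
        others = [discard_restraints(rset, seed=s).receptor_active
                  for s in range(10)]
        assert any(o != a.receptor_active for o in others)

    def test_mean_satisfaction_converges(self, toy):
        # equal-status case: every receptor-side restraint is satisfied
        # against the fixed ligand target set, so the satisfied count
        # after discarding averages (1 - fraction) times the full count
        rset = RestraintSet(
            receptor_active=toy.acidic_keys + [toy.anchor_receptor_key],
            ligand_passive=list(toy.ligand.residue_keys()),
            effective_cutoff=4.5, discard_fraction=0.5)
        full, _ = restraint_satisfaction(toy.receptor, toy.ligand, rset)
        assert full == 1.0
        totals = []
        for seed in range(20):
            sub = discard_restraints(rset, seed)
            _, details = restraint_satisfaction(toy.receptor, toy.ligand,
                                                sub)
            totals.append(sum(d["satisfied"] for d in details))
        expected = (1 - rset.discard_fraction) * rset.n_active * full
        assert np.mean(totals) == pytest.approx(expected, rel=0.01)


class TestPassiveSet:
    def test_accessible_neighbors_only(self, toy_monomer):
        s = toy_monomer.receptor
        active = [toy_monomer.anchor_receptor_key]
        passive = build_passive_set(s, active, rel_sasa_min=0.2,
                                    neighbor_cutoff=6.5)
        assert active[0] not in passive
        # oracle: direct all-pairs distance scan + accessibility check
        from dockconsensus.geometry import sasa
        from scipy.spatial import cKDTree
        heavy = s.select(s.heavy_mask())
        act = heavy.select(heavy.residue_mask(active))
        rel = sasa(s).relative
        expected = []
        for key in s.residue_keys():
            if key == active[0]:
                continue
            res = heavy.select(heavy.residue_mask([key]))
            d = cKDTree(act.coords).query(res.coords)[0].min()
            if d <= 6.5 and rel[key] >= 0.2:
                expected.append(key)
        assert passive == expected
        assert len(passive) > 0

    def test_absent_active_errors(self, toy_monomer):
        from dockconsensus.structure_io import ResidueKey
        with pytest.raises(KeyError):
            build_passive_set(toy_monomer.receptor,
                              [ResidueKey("A", 999, "", "GLU")])


class TestTriadFilter:
    def test_separated_false(self, toy):
        far = toy.ligand.with_coords(toy.ligand.coords
                                     + np.array([0.0, 80.0, 0.0]))
        ok, membership = triad_filter(
            toy.receptor, far,
            TriadConstraint(residues=toy.triad_labels, min_required=1,
                            chain_id="A"))
        assert not ok
        assert not any(membership.values())

    def test_bound_pose_all_three_in_interface(self, toy):
        ok, membership = triad_filter(
            toy.receptor, toy.ligand,
            TriadConstraint(residues=toy.triad_labels, min_required=3,
                            chain_id="A"))
        assert ok
        assert all(membership.values())

    def test_label_type_checked(self, toy):
        with pytest.raises(ValueError, match="label says"):
            resolve_labels(toy.ligand, ["E5"], chain_id="C")  # C5 is ARG


class TestPublishedDefaults:
    def test_active_passive_disjoint_enforced(self):
        from dockconsensus.structure_io import ResidueKey
        k = ResidueKey("A", 1, "", "ALA")
        with pytest.raises(ValueError, match="overlap"):
            RestraintSet(receptor_active=[k], receptor_passive=[k])

    def test_dpra_list_has_eight_active(self):
        assert len(DPRA_ACTIVE) == 8
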