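import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dockconsensus.geometry import (
    RigidTransform,
    interface_rmsd,
    kabsch_superpose,
    ligand_rmsd,
    pairwise_contacts,
    sasa,
    selection_mask,
    transformed,
)
from dockconsensus.structure_io import Structure


def random_transform(rng) -> RigidTransform:
    quat = rng.standard_normal(4)
    quat /= np.linalg.norm(quat)
    return RigidTransform(Rotation.from_quat(quat).as_matrix(),
                          rng.normal(scale=10.0, size=3))


def single_atom(element="C", xyz=(0.0, 0.0, 0.0)):
    return Structure(
        chain_ids=np.array(["A"]), seq_nums=np.array([1]),
        icodes=np.array([""]), res_names=np.array(["ALA"]),
        atom_names=np.array(["CA"]), elements=np.array([element]),
        coords=np.array([xyz]),
    )


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        tr, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_transform(self, rng):
        x = rng.normal(size=(25, 3)) * 5.0
        for _ in range(5):
            t = random_transform(rng)
            moved = t.apply(x)
            tr, rmsd = kabsch_superpose(moved, x)
            assert rmsd < 1e-6
            np.testing.assert_allclose(tr.apply(moved), x, atol=1e-6)

    def test_mirror_gives_proper_rotation_with_residual(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        mirror = x * np.array([1.0, 1.0, -1.0])
        tr, rmsd = kabsch_superpose(mirror, x)
        assert rmsd > 0.1
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_input_rejected(self):
        line = np.stack([np.arange(5.0)] * 3, axis=1)  # collinear
        target = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, target)
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(target[:4], target)


class TestRmsdMetrics:
    def test_identity_zero(self, toy):
        assert ligand_rmsd(toy.receptor, toy.ligand, toy.receptor,
                           toy.ligand) == pytest.approx(0.0, abs=1e-9)
        assert interface_rmsd(toy.receptor, toy.ligand, toy.receptor,
                              toy.ligand) == pytest.approx(0.0, abs=1e-6)

    def test_pure_translation_is_exact(self, toy):
        shifted = toy.ligand.with_coords(toy.ligand.coords
                                         + np.array([0.0, 3.0, 0.0]))
        v = ligand_rmsd(toy.receptor, toy.ligand, toy.receptor, shifted)
        assert v == pytest.approx(3.0, abs=1e-9)

    @pytest.mark.parametrize("magnitude", [0.5, 2.0, 8.0])
    def test_global_rigid_motion_invariance(self, toy, rng, magnitude):
        t = random_transform(rng)
        rec = transformed(toy.receptor, t)
        lig_moved = toy.ligand.with_coords(
            toy.ligand.coords + rng.normal(scale=magnitude, size=3))
        lig = transformed(lig_moved, t)
        direct = ligand_rmsd(toy.receptor, toy.ligand, toy.receptor,
                             lig_moved)
        moved = ligand_rmsd(toy.receptor, toy.ligand, rec, lig)
        assert moved == pytest.approx(direct, abs=1e-6)
        d_i = interface_rmsd(toy.receptor, toy.ligand, toy.receptor,
                             lig_moved)
        m_i = interface_rmsd(toy.receptor, toy.ligand, rec, lig)
        assert m_i == pytest.approx(d_i, abs=1e-6)

    def test_interface_rmsd_below_unfitted_rmsd_on_zone(self, toy, rng):
        # the fit minimises over the evaluated atoms, so any other
        # superposition (e.g. none) can only be worse
        lig = toy.ligand.with_coords(
            toy.ligand.coords + rng.normal(scale=1.5, size=(1, 3)))
        fitted = interface_rmsd(toy.receptor, toy.ligand, toy.receptor, lig)
        from dockconsensus.geometry import interface_zone_residues
        zr, zl = interface_zone_residues(toy.receptor, toy.ligand, 10.0)
        rmask = toy.receptor.residue_mask(zr) & \
            selection_mask(toy.receptor, "backbone")
        lmask = toy.ligand.residue_mask(zl) & \
            selection_mask(toy.ligand, "backbone")
        ref = np.concatenate([toy.receptor.coords[rmask],
                              toy.ligand.coords[lmask]])
        dec = np.concatenate([toy.receptor.coords[rmask], lig.coords[lmask]])
        unfitted = float(np.sqrt(((ref - dec) ** 2).sum(axis=1).mean()))
        assert fitted <= unfitted + 1e-9

    def test_ladder_displacement_monotone(self, toy):
        meds = []
        for step in (0.5, 1.5, 4.0, 9.0):
            vals = []
            for k in range(5):
                rng = np.random.default_rng(100 + k)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                lig = toy.ligand.with_coords(toy.ligand.coords
                                             + direction * step)
                vals.append(interface_rmsd(toy.receptor, toy.ligand,
                                           toy.receptor, lig))
            meds.append(np.median(vals))
        assert all(a <= b + 1e-9 for a, b in zip(meds, meds[1:]))

    def test_empty_interface_errors(self, toy):
        # the zone is defined on the reference: a reference with its
        # partners far apart has no interface anywhere
        far = toy.ligand.with_coords(toy.ligand.coords + 500.0)
        with pytest.raises(ValueError, match="empty interface"):
            interface_rmsd(toy.receptor, far, toy.receptor, far)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        res = sasa(single_atom("C"), probe_radius=1.4, n_points=960)
        analytic = 4.0 * math.pi * (1.70 + 1.4) ** 2
        assert res.total() == pytest.approx(analytic, rel=0.02)

    def test_enclosed_atom_zero(self):
        # central atom caged by a dense shell of overlapping atoms
        import itertools
        shell = []
        n = 0
        golden = math.pi * (3 - math.sqrt(5))
        for i in range(60):
            z = 1 - 2 * (i + 0.5) / 60
            r = math.sqrt(1 - z * z)
            shell.append((3.0 * r * math.cos(golden * i),
                          3.0 * r * math.sin(golden * i), 3.0 * z))
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        s = Structure(
            chain_ids=np.array(["A"] * len(coords)),
            seq_nums=np.arange(1, len(coords) + 1),
            icodes=np.array([""] * len(coords)),
            res_names=np.array(["ALA"] * len(coords)),
            atom_names=np.array(["CA"] * len(coords)),
            elements=np.array(["C"] * len(coords)),
            coords=coords,
        )
        res = sasa(s)
        assert res.per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_contact_occlusion_inequality(self, toy):
        from dockconsensus.structure_io import concatenate
        total = sasa(concatenate([toy.receptor, toy.ligand])).total()
        isolated = sasa(toy.receptor).total() + sasa(toy.ligand).total()
        assert total < isolated

    def test_rotation_invariance(self, toy, rng):
        t = random_transform(rng)
        a = sasa(toy.ligand).total()
        b = sasa(transformed(toy.ligand, t)).total()
        assert b == pytest.approx(a, rel=0.01)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            sasa(single_atom("XX"))


class TestContacts:
    def test_far_apart_empty(self, toy):
        far = toy.ligand.with_coords(toy.ligand.coords + 100.0)
        assert pairwise_contacts(toy.receptor, far, 5.0) == []

    def test_boundary_inclusive(self):
        a = single_atom("C", (0.0, 0.0, 0.0))
        b = single_atom("N", (4.99, 0.0, 0.0))
        assert len(pairwise_contacts(a, b, 5.0)) == 1
        b2 = single_atom("N", (5.01, 0.0, 0.0))
        assert pairwise_contacts(a, b2, 5.0) == []

    def test_grid_matches_brute_force(self, rng):
        def blob(chain, n):
            coords = rng.normal(scale=8.0, size=(n, 3))
            return Structure(
                chain_ids=np.array([chain] * n),
                seq_nums=np.arange(1, n + 1), icodes=np.array([""] * n),
                res_names=np.array(["ALA"] * n),
                atom_names=np.array(["CA"] * n),
                elements=np.array(["C"] * n), coords=coords,
            )

        a, b = blob("A", 500), blob("B", 500)
        got = pairwise_contacts(a, b, 4.0)
        d = np.linalg.norm(a.coords[:, None] - b.coords[None], axis=2)
        expected = int((d <= 4.0).sum())
        assert len(got) == expected

    def test_symmetry(self, toy):
        ab = pairwise_contacts(toy.receptor, toy.ligand, 4.5)
        ba = pairwise_contacts(toy.ligand, toy.receptor, 4.5)
        assert {(x, y, round(d, 6)) for x, y, d in ab} == \
            {(y, x, round(d, 6)) for x, y, d in ba}
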