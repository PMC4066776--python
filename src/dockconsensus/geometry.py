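"""Superposition, RMSD metrics, solvent accessibility and contacts.

These are the primitives every later stage consumes: Kabsch superposition
(proper rotations only), ligand RMSD (pose difference after receptor fit),
interface RMSD (CAPRI-style model similarity over the reference interface
zone), Shrake-Rupley solvent-accessible surface areas, and cutoff-based
heavy-atom contact detection.

Atom conventions follow common docking practice: ligand RMSD is computed
over ligand CA atoms after a receptor CA fit; interface RMSD over backbone
(N, CA, C, O) atoms of the 10 A reference interface zone.  Both presets are
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_io import ResidueKey, Structure, concatenate

__all__ = [
    "RigidTransform",
    "selection_mask",
    "kabsch_superpose",
    "superpose_coords",
    "ligand_rmsd",
    "interface_rmsd",
    "interface_zone_residues",
    "sasa",
    "SasaResult",
    "pairwise_contacts",
    "MAX_RESIDUE_SASA",
]

SelectionPreset = Literal["ca", "backbone", "heavy"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Residue-type maximum accessible areas (A^2) in a Gly-X-Gly extended
#: tripeptide context, used to normalise per-residue SASA to relative
#: accessibility (Tien et al. theoretical values).
MAX_RESIDUE_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body motion ``x -> R x + t`` in Angstroms."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def selection_mask(s: Structure, preset: SelectionPreset) -> np.ndarray:
    """Boolean atom mask for a named selection preset."""
    if preset == "ca":
        return (s.atom_names == "CA") & s.heavy_mask()
    if preset == "backbone":
        return np.isin(s.atom_names, BACKBONE_ATOMS) & s.heavy_mask()
    if preset == "heavy":
        return s.heavy_mask()
    raise ValueError(f"unknown selection preset {preset!r}")


# -- superposition -----------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray,
                     target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns the proper rotation + translation taking ``mobile`` onto
    ``target`` and the post-fit RMSD.  Reflections are never returned: for
    mirror-image inputs the best proper rotation is used and the residual
    RMSD stays positive.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape:
        raise ValueError(
            f"length mismatch: {len(mobile)} mobile vs {len(target)} target"
        )
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    m0 = mobile - mc
    t0 = target - tc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or \
       np.linalg.matrix_rank(t0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    rot, rssd = Rotation.align_vectors(t0, m0)
    R = rot.as_matrix()
    transform = RigidTransform(R, tc - R @ mc)
    return transform, float(rssd) / math.sqrt(n)


def superpose_coords(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Convenience: mobile coordinates after the Kabsch fit onto target."""
    tr, _ = kabsch_superpose(mobile, target)
    return tr.apply(mobile)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def _check_matched(ref: Structure, decoy: Structure, what: str) -> None:
    if ref.n_atoms != decoy.n_atoms or \
       not (np.array_equal(ref.atom_names, decoy.atom_names)
            and np.array_equal(ref.chain_ids, decoy.chain_ids)
            and np.array_equal(ref.seq_nums, decoy.seq_nums)):
        raise ValueError(f"unmatched {what} atoms between reference and decoy")


# -- RMSD metrics ------------------------------------------------------------

def ligand_rmsd(ref_receptor: Structure, ref_ligand: Structure,
                decoy_receptor: Structure, decoy_ligand: Structure,
                receptor_sel: SelectionPreset = "ca",
                ligand_sel: SelectionPreset = "ca") -> float:
    """Pose difference: RMSD over the ligand after a receptor-only fit.

    The decoy complex is superposed onto the reference using receptor
    atoms; the RMSD is then evaluated over the ligand selection with no
    further fitting, so a pure ligand translation by ``t`` scores exactly
    ``t``.
    """
    _check_matched(ref_receptor, decoy_receptor, "receptor")
    _check_matched(ref_ligand, decoy_ligand, "ligand")
    rmask = selection_mask(ref_receptor, receptor_sel)
    lmask = selection_mask(ref_ligand, ligand_sel)
    if not lmask.any():
        raise ValueError("empty ligand selection")
    tr, _ = kabsch_superpose(decoy_receptor.coords[rmask],
                             ref_receptor.coords[rmask])
    return _rmsd(tr.apply(decoy_ligand.coords[lmask]),
                 ref_ligand.coords[lmask])


def interface_zone_residues(receptor: Structure, ligand: Structure,
                            zone_cutoff: float = 10.0
                            ) -> tuple[list[ResidueKey], list[ResidueKey]]:
    """Residues of either partner with any heavy atom within ``zone_cutoff``
    of the other partner."""
    ra = receptor.select(receptor.heavy_mask())
    la = ligand.select(ligand.heavy_mask())
    if ra.n_atoms == 0 or la.n_atoms == 0:
        return [], []
    tree = cKDTree(la.coords)
    near_r = np.array(
        [len(v) > 0 for v in tree.query_ball_point(ra.coords, zone_cutoff)]
    )
    tree_r = cKDTree(ra.coords)
    near_l = np.array(
        [len(v) > 0 for v in tree_r.query_ball_point(la.coords, zone_cutoff)]
    )

    def _keys(struct: Structure, near: np.ndarray) -> list[ResidueKey]:
        keys = struct.residue_keys()
        idx = struct.residue_index()
        hit = np.zeros(len(keys), dtype=bool)
        hit[idx[near]] = True
        return [k for k, h in zip(keys, hit) if h]

    return _keys(ra, near_r), _keys(la, near_l)


def interface_rmsd(ref_receptor: Structure, ref_ligand: Structure,
                   decoy_receptor: Structure, decoy_ligand: Structure,
                   zone_cutoff: float = 10.0,
                   atom_sel: SelectionPreset = "backbone") -> float:
    """Model similarity over the reference interface zone.

    The zone is defined on the REFERENCE complex (heavy-atom distance
    ``zone_cutoff``); the decoy's matching zone atoms are fitted onto the
    reference zone and the RMSD over those same atoms is returned.
    """
    _check_matched(ref_receptor, decoy_receptor, "receptor")
    _check_matched(ref_ligand, decoy_ligand, "ligand")
    zr, zl = interface_zone_residues(ref_receptor, ref_ligand, zone_cutoff)
    if not zr and not zl:
        raise ValueError(
            f"empty interface zone (partners beyond {zone_cutoff} A everywhere)"
        )
    rmask = ref_receptor.residue_mask(zr) & selection_mask(ref_receptor, atom_sel)
    lmask = ref_ligand.residue_mask(zl) & selection_mask(ref_ligand, atom_sel)
    ref_zone = np.concatenate([ref_receptor.coords[rmask],
                               ref_ligand.coords[lmask]])
    decoy_zone = np.concatenate([decoy_receptor.coords[rmask],
                                 decoy_ligand.coords[lmask]])
    tr, rmsd = kabsch_superpose(decoy_zone, ref_zone)
    return rmsd


# -- solvent accessibility ---------------------------------------------------

@dataclass
class SasaResult:
    """Per-atom and per-residue Shrake-Rupley areas (A^2)."""

    per_atom: np.ndarray
    per_residue: dict[ResidueKey, float]
    relative: dict[ResidueKey, float]

    def total(self) -> float:
        return float(self.per_atom.sum())


def _to_atom_array(s: Structure):
    import biotite.structure as struc

    arr = struc.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coords, dtype=np.float32)
    arr.chain_id = s.chain_ids.astype("U4")
    arr.res_id = s.seq_nums.astype(int)
    arr.ins_code = s.icodes.astype("U1")
    arr.res_name = s.res_names.astype("U5")
    arr.atom_name = s.atom_names.astype("U6")
    arr.element = s.elements.astype("U2")
    return arr


def sasa(s: Structure, probe_radius: float = 1.4,
         n_points: int = 960) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area on heavy atoms.

    Element-based van der Waals radii; per-residue areas are sums over the
    residue's atoms, and relative accessibility divides by Gly-X-Gly
    reference areas (nonstandard residues get NaN relative values).
    """
    import biotite.structure as struc

    heavy = s.select(s.heavy_mask())
    if heavy.n_atoms == 0:
        raise ValueError("no heavy atoms")
    from biotite.structure.info import vdw_radius_single

    for elem in sorted(set(heavy.elements)):
        if vdw_radius_single(str(elem)) is None:
            raise ValueError(f"no van der Waals radius for element {elem!r}")
    arr = _to_atom_array(heavy)
    areas = struc.sasa(arr, probe_radius=probe_radius, point_number=n_points,
                       vdw_radii="Single", ignore_ions=False)
    keys = heavy.residue_keys()
    idx = heavy.residue_index()
    per_res_arr = np.zeros(len(keys))
    np.add.at(per_res_arr, idx, areas)
    per_res = {k: float(v) for k, v in zip(keys, per_res_arr)}
    rel = {
        k: (float(v) / MAX_RESIDUE_SASA[k.res_name]
            if k.res_name in MAX_RESIDUE_SASA else float("nan"))
        for k, v in per_res.items()
    }
    return SasaResult(per_atom=areas, per_residue=per_res, relative=rel)


# -- contacts ----------------------------------------------------------------

def pairwise_contacts(a: Structure, b: Structure, cutoff: float
                      ) -> list[tuple[tuple[ResidueKey, str],
                                      tuple[ResidueKey, str], float]]:
    """All heavy-atom cross-pairs within ``cutoff`` (inclusive).

    Returns ``((res_key_a, atom_name_a), (res_key_b, atom_name_b), d)``
    records, grid-accelerated but identical to the all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ha = a.select(a.heavy_mask())
    hb = b.select(b.heavy_mask())
    if ha.n_atoms == 0 or hb.n_atoms == 0:
        return []
    keys_a, idx_a = ha.residue_keys(), ha.residue_index()
    keys_b, idx_b = hb.residue_keys(), hb.residue_index()
    tree_a = cKDTree(ha.coords)
    tree_b = cKDTree(hb.coords)
    pairs = tree_a.sparse_distance_matrix(tree_b, cutoff, output_type="coo_matrix")
    out = []
    for i, j, d in zip(pairs.row, pairs.col, pairs.data):
        out.append((
            (keys_a[idx_a[i]], str(ha.atom_names[i])),
            (keys_b[idx_b[j]], str(hb.atom_names[j])),
            float(d),
        ))
    out.sort(key=lambda r: (r[0][0], r[1][0], r[0][1], r[1][1]))
    return out


def transformed(s: Structure, tr: RigidTransform) -> Structure:
    """Copy of ``s`` with the rigid transform applied to its coordinates."""
    return s.with_coords(tr.apply(s.coords))
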