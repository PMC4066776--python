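"""Interface composition, anchors, contact typing and the second-site test.

Given a two-partner complex this module identifies interface residues,
computes per-residue buried surface (isolated-partner SASA minus
in-complex SASA), ranks anchor residues by buried area, types contacts
(salt bridges between D/E carboxylates and K/R guanidinium/amino groups,
apolar carbon-carbon/carbon-sulfur contacts, donor/acceptor heavy-atom
hydrogen-bond candidates), and runs the steric-clash test for a
hypothetical second ligand bound at the symmetry-related site of a
homodimeric receptor - the computation behind a 2:1 stoichiometry argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import kabsch_superpose, pairwise_contacts, sasa
from .structure_io import ResidueKey, Structure, concatenate

__all__ = [
    "Contact",
    "InterfaceReport",
    "interface_residues",
    "buried_area_per_residue",
    "find_anchors",
    "detect_salt_bridges",
    "detect_hbond_candidates",
    "detect_apolar_contacts",
    "second_site_clash_check",
    "ClashCheckResult",
    "build_interface_report",
]

ContactType = Literal["salt_bridge", "hbond_candidate", "apolar"]

# charged side-chain group atoms (heavy-atom convention, His neutral)
ACIDIC_GROUP_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_GROUP_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}

DEFAULT_INTERFACE_CUTOFF = 5.0
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0
DEFAULT_APOLAR_CUTOFF = 4.5
DEFAULT_HBOND_CUTOFF = 3.5
DEFAULT_CLASH_CUTOFF = 2.5
DEFAULT_CLASH_REPORT_THRESHOLD = 50


@dataclass(frozen=True)
class Contact:
    res_a: ResidueKey
    res_b: ResidueKey
    atom_a: str
    atom_b: str
    distance: float
    type: ContactType

    def to_dict(self) -> dict:
        return {
            "res_a": str(self.res_a), "res_b": str(self.res_b),
            "atom_a": self.atom_a, "atom_b": self.atom_b,
            "distance": round(self.distance, 3), "type": self.type,
        }


def interface_residues(receptor: Structure, ligand: Structure,
                       cutoff: float = DEFAULT_INTERFACE_CUTOFF
                       ) -> tuple[list[ResidueKey], list[ResidueKey]]:
    """Residues of each partner with any heavy atom within ``cutoff`` of
    the other partner."""
    if receptor.n_atoms == 0 or ligand.n_atoms == 0:
        raise ValueError("both partners must be nonempty")
    from .geometry import interface_zone_residues

    return interface_zone_residues(receptor, ligand, cutoff)


def buried_area_per_residue(receptor: Structure, ligand: Structure,
                            probe_radius: float = 1.4,
                            n_points: int = 960
                            ) -> dict[ResidueKey, float]:
    """Per-residue surface buried upon binding (A^2), both partners.

    SASA of each isolated partner minus SASA in the complex, clipped at
    zero to absorb quadrature noise.  Partner chain identifiers must be
    disjoint so residues stay attributable.
    """
    complex_ = concatenate([receptor, ligand])
    s_complex = sasa(complex_, probe_radius, n_points).per_residue
    out: dict[ResidueKey, float] = {}
    for part in (receptor, ligand):
        iso = sasa(part, probe_radius, n_points).per_residue
        for k, a in iso.items():
            out[k] = max(0.0, a - s_complex.get(k, 0.0))
    return out


def find_anchors(buried: dict[ResidueKey, float], receptor_chains: set[str],
                 k: int = 1) -> dict[str, list[tuple[ResidueKey, float]]]:
    """Top-``k`` residues by buried area on each partner.

    Residues with zero burial never qualify; ties keep residue order as
    listed in ``buried``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = {key: i for i, key in enumerate(buried)}
    out: dict[str, list[tuple[ResidueKey, float]]] = {}
    for side, pred in (
        ("receptor", lambda key: key.chain_id in receptor_chains),
        ("ligand", lambda key: key.chain_id not in receptor_chains),
    ):
        cand = [(key, a) for key, a in buried.items() if pred(key) and a > 0.0]
        cand.sort(key=lambda ka: (-ka[1], order[ka[0]]))
        out[side] = cand[:k]
    return out


def _group_contacts(receptor: Structure, ligand: Structure, cutoff: float,
                    atoms_a: dict[str, tuple[str, ...]],
                    atoms_b: dict[str, tuple[str, ...]],
                    ctype: ContactType) -> list[Contact]:
    def mask(s: Structure, table: dict[str, tuple[str, ...]]) -> np.ndarray:
        m = np.zeros(s.n_atoms, dtype=bool)
        for res, names in table.items():
            m |= (s.res_names == res) & np.isin(s.atom_names, names)
        return m

    out: list[Contact] = []
    for sa, sb, flip in ((receptor, ligand, False), (receptor, ligand, True)):
        a = sa.select(mask(sa, atoms_b if flip else atoms_a))
        b = sb.select(mask(sb, atoms_a if flip else atoms_b))
        for (ka, na), (kb, nb), d in pairwise_contacts(a, b, cutoff):
            out.append(Contact(ka, kb, na, nb, d, ctype))
    uniq = {(c.res_a, c.res_b, c.atom_a, c.atom_b): c for c in out}
    return sorted(uniq.values(), key=lambda c: (c.res_a, c.res_b, c.atom_a,
                                                c.atom_b))


def detect_salt_bridges(receptor: Structure, ligand: Structure,
                        cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF
                        ) -> list[Contact]:
    """Oppositely charged side-chain group atoms across the interface.

    Asp OD1/OD2 and Glu OE1/OE2 versus Lys NZ and Arg NH1/NH2/NE within
    ``cutoff``; histidine is treated as neutral.
    """
    return _group_contacts(receptor, ligand, cutoff,
                           ACIDIC_GROUP_ATOMS, BASIC_GROUP_ATOMS,
                           "salt_bridge")


def detect_hbond_candidates(receptor: Structure, ligand: Structure,
                            cutoff: float = DEFAULT_HBOND_CUTOFF
                            ) -> list[Contact]:
    """N/O-N/O heavy-atom pairs within ``cutoff``.

    With no hydrogens there is no angular term, so these are candidates
    only, flagged as such.
    """
    def polar(s: Structure) -> Structure:
        return s.select(np.isin(s.elements, ("N", "O")))

    out = [Contact(ka, kb, na, nb, d, "hbond_candidate")
           for (ka, na), (kb, nb), d
           in pairwise_contacts(polar(receptor), polar(ligand), cutoff)]
    return out


def detect_apolar_contacts(receptor: Structure, ligand: Structure,
                           cutoff: float = DEFAULT_APOLAR_CUTOFF
                           ) -> list[Contact]:
    """Carbon-carbon and carbon-sulfur cross-pairs within ``cutoff``.

    Returned atom-pair contacts are aggregated per residue pair by
    :func:`aggregate_by_residue_pair` when counts are needed.
    """
    def apolar(s: Structure) -> Structure:
        return s.select(np.isin(s.elements, ("C", "S")))

    out = []
    for (ka, na), (kb, nb), d in pairwise_contacts(apolar(receptor),
                                                   apolar(ligand), cutoff):
        ea = "S" if na.startswith("S") else "C"
        eb = "S" if nb.startswith("S") else "C"
        if ea == "S" and eb == "S":
            continue  # C-C and C-S only
        out.append(Contact(ka, kb, na, nb, d, "apolar"))
    return out


def aggregate_by_residue_pair(contacts: Sequence[Contact]
                              ) -> dict[tuple[ResidueKey, ResidueKey], dict]:
    agg: dict[tuple[ResidueKey, ResidueKey], dict] = {}
    for c in contacts:
        rec = agg.setdefault((c.res_a, c.res_b),
                             {"n_atom_pairs": 0, "min_distance": np.inf,
                              "type": c.type})
        rec["n_atom_pairs"] += 1
        rec["min_distance"] = min(rec["min_distance"], c.distance)
    return agg


@dataclass
class ClashCheckResult:
    clash_count: int
    verdict: str  # "clash" | "no_clash"
    monomer_superposition_rmsd: float

    def to_dict(self) -> dict:
        return {"clash_count": self.clash_count, "verdict": self.verdict,
                "monomer_superposition_rmsd":
                    round(self.monomer_superposition_rmsd, 4)}


def second_site_clash_check(dimer_receptor: Structure, ligand_pose: Structure,
                            clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
                            report_threshold: int = DEFAULT_CLASH_REPORT_THRESHOLD,
                            max_symmetry_rmsd: float = 2.0
                            ) -> ClashCheckResult:
    """Would a second ligand bound at the symmetry-related site clash?

    The transform superposing receptor monomer A onto monomer B is applied
    to the ligand pose to place the hypothetical second ligand; heavy-atom
    pairs closer than ``clash_cutoff`` to the receptor or the first ligand
    are counted.  Verdict is "clash" when the count exceeds
    ``report_threshold`` - the situation that rules out simultaneous
    binding at both sites and supports a 2:1 receptor:ligand stoichiometry.
    """
    chains = dimer_receptor.chains()
    if len(chains) != 2:
        raise ValueError("receptor must have exactly two chains (homodimer)")
    mono_a = dimer_receptor.select(dimer_receptor.chain_mask(chains[0]))
    mono_b = dimer_receptor.select(dimer_receptor.chain_mask(chains[1]))
    # pair atoms between monomers on (residue number, insertion, atom name)
    key_a = {(int(n), str(i), str(an)): idx for idx, (n, i, an) in
             enumerate(zip(mono_a.seq_nums, mono_a.icodes, mono_a.atom_names))}
    sel_a, sel_b = [], []
    for idx, (n, i, an) in enumerate(zip(mono_b.seq_nums, mono_b.icodes,
                                         mono_b.atom_names)):
        j = key_a.get((int(n), str(i), str(an)))
        if j is not None:
            sel_a.append(j)
            sel_b.append(idx)
    if len(sel_a) < 3:
        raise ValueError("monomers share too few matching atoms")
    tr, rmsd = kabsch_superpose(mono_a.coords[sel_a], mono_b.coords[sel_b])
    if rmsd > max_symmetry_rmsd:
        raise ValueError(
            f"monomer superposition RMSD {rmsd:.2f} A exceeds "
            f"{max_symmetry_rmsd} A: receptor is not a symmetric dimer"
        )
    second = tr.apply(ligand_pose.coords[ligand_pose.heavy_mask()])
    obstacles = np.concatenate([
        dimer_receptor.coords[dimer_receptor.heavy_mask()],
        ligand_pose.coords[ligand_pose.heavy_mask()],
    ])
    tree = cKDTree(obstacles)
    # strict inequality: pairs closer than the clash cutoff
    counts = tree.query_ball_point(second, clash_cutoff * (1 - 1e-12),
                                   return_length=True)
    n_clash = int(counts.sum())
    verdict = "clash" if n_clash > report_threshold else "no_clash"
    return ClashCheckResult(clash_count=n_clash, verdict=verdict,
                            monomer_superposition_rmsd=rmsd)


@dataclass
class InterfaceReport:
    """Full characterization of one two-partner complex."""

    receptor_residues: list[ResidueKey]
    ligand_residues: list[ResidueKey]
    buried_area: dict[ResidueKey, float]
    anchors: dict[str, list[tuple[ResidueKey, float]]]
    contacts: list[Contact]
    clash_check: ClashCheckResult | None = None

    def to_dict(self) -> dict:
        return {
            "receptor_residues": [str(k) for k in self.receptor_residues],
            "ligand_residues": [str(k) for k in self.ligand_residues],
            "buried_area": {str(k): round(v, 2)
                            for k, v in self.buried_area.items() if v > 0.0},
            "anchors": {side: [[str(k), round(a, 2)] for k, a in lst]
                        for side, lst in self.anchors.items()},
            "contacts": [c.to_dict() for c in self.contacts],
            "clash_check": (self.clash_check.to_dict()
                            if self.clash_check else None),
        }


def build_interface_report(receptor: Structure, ligand: Structure,
                           interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                           anchor_k: int = 3,
                           run_clash_check: bool = False,
                           **clash_kwargs) -> InterfaceReport:
    """One-call interface characterization of a complex."""
    res_r, res_l = interface_residues(receptor, ligand, interface_cutoff)
    buried = buried_area_per_residue(receptor, ligand)
    anchors = find_anchors(buried, set(receptor.chains()), k=anchor_k)
    contacts = (detect_salt_bridges(receptor, ligand)
                + detect_hbond_candidates(receptor, ligand)
                + detect_apolar_contacts(receptor, ligand))
    clash = None
    if run_clash_check:
        clash = second_site_clash_check(receptor, ligand, **clash_kwargs)
    return InterfaceReport(
        receptor_residues=res_r, ligand_residues=res_l, buried_area=buried,
        anchors=anchors, contacts=contacts, clash_check=clash,
    )
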