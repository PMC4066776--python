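"""Ambiguous interaction restraints and the acidic-triad constraint filter.

Active residues are those required at the interface; passive residues are
their solvent-accessible neighbors, allowed as interaction targets.  Each
active residue defines one ambiguous restraint, satisfied when its
r^-6-summed effective distance to the union of active and passive residues
of the partner falls below a cutoff.  Following common guided-docking
practice, a configurable fraction of the active restraints (default 50%)
can be discarded at random to absorb errors in the interface definition.

The published DprA/RecA restraint definitions are provided as module
constants; the triad filter implements the requirement that the DprA
acidic triad (E235/D243/E265) belongs to the modelled interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import sasa
from .structure_io import ResidueKey, Structure

__all__ = [
    "RestraintSet",
    "TriadConstraint",
    "build_passive_set",
    "effective_distance",
    "restraint_satisfaction",
    "discard_restraints",
    "triad_filter",
    "parse_residue_label",
    "resolve_labels",
    "DPRA_ACTIVE",
    "DPRA_PASSIVE",
    "RECA_MAIN_ACTIVE",
    "RECA_MAIN_PASSIVE",
    "RECA_SMALL_ACTIVE",
    "RECA_SMALL_PASSIVE",
    "EDE_TRIAD",
    "RRK_TRIAD",
    "DEFAULT_DISCARD_FRACTION",
    "DEFAULT_EFFECTIVE_CUTOFF",
]

# Published restraint definitions for the DprA-RecA system (author
# numbering; one-letter type + residue number).
DPRA_ACTIVE = ("E235", "M238", "D243", "V244", "E265", "G266", "A267", "E281")
DPRA_PASSIVE = ("R217", "L231", "I232", "R236", "E239", "G241", "R242",
                "F245", "H261", "L262", "I263", "Q264", "K268", "E279",
                "F280", "F282")
RECA_MAIN_ACTIVE = ("R182", "M183", "S185", "R189", "K229", "F230", "Y231",
                    "R235", "K265", "K267")
RECA_MAIN_PASSIVE = ("R73", "I74", "Q186", "M188", "K190", "G192", "A193",
                     "G225", "R226", "S233", "V264", "V268", "A269", "P270",
                     "P271")
RECA_SMALL_ACTIVE = ("E335", "I336", "D337", "K338", "Q339", "D348", "G349",
                     "E350")
RECA_SMALL_PASSIVE = ("E328", "F333", "D334", "V340", "R341", "L346", "I347",
                      "E351", "V352", "S353")

#: DprA acidic triad at the core of the RecA-binding patch.
EDE_TRIAD = ("E235", "D243", "E265")
#: RecA basic triad contacting the acidic triad in the consensus model.
RRK_TRIAD = ("R189", "R226", "K267")

DEFAULT_DISCARD_FRACTION = 0.5
# Heavy-atom effective-distance cutoff (hydrogens are never used, so the
# hydrogen-based 2 A convention does not apply).
DEFAULT_EFFECTIVE_CUTOFF = 3.0
DEFAULT_REL_SASA_MIN = 0.40
DEFAULT_NEIGHBOR_CUTOFF = 6.5
DEFAULT_INTERFACE_CUTOFF = 5.0


def parse_residue_label(label: str) -> tuple[str, int]:
    """Split a ``'E235'``-style label into (one-letter type, number)."""
    aa = label[0].upper()
    try:
        num = int(label[1:])
    except ValueError as exc:
        raise ValueError(f"bad residue label {label!r}") from exc
    return aa, num


def resolve_labels(s: Structure, labels: Sequence[str],
                   chain_id: str | None = None) -> list[ResidueKey]:
    """Resolve ``'E235'``-style labels to residue keys on one chain.

    The residue type letter is checked against the structure; a mismatch
    or an absent residue raises.
    """
    from .structure_io import ONE_TO_THREE

    if chain_id is None:
        chains = s.chains()
        if len(chains) != 1:
            raise ValueError("chain_id required for multi-chain structures")
        chain_id = chains[0]
    by_num = {(k.seq_num, k.icode): k for k in s.residue_keys()
              if k.chain_id == chain_id}
    out = []
    for label in labels:
        aa, num = parse_residue_label(label)
        key = by_num.get((num, ""))
        if key is None:
            raise KeyError(f"residue {label} absent from chain {chain_id}")
        expected = ONE_TO_THREE.get(aa)
        if expected is not None and key.res_name != expected:
            raise ValueError(
                f"residue {num} on chain {chain_id} is {key.res_name}, "
                f"label says {expected}"
            )
        out.append(key)
    return out


@dataclass
class RestraintSet:
    """Active/passive residue selections on both partners.

    ``receptor_active`` etc. are residue keys on the respective partner
    structures.  ``effective_cutoff`` is the satisfaction threshold in
    Angstroms; ``discard_fraction`` the fraction of active restraints
    removed at random by :func:`discard_restraints`.
    """

    receptor_active: list[ResidueKey] = field(default_factory=list)
    receptor_passive: list[ResidueKey] = field(default_factory=list)
    ligand_active: list[ResidueKey] = field(default_factory=list)
    ligand_passive: list[ResidueKey] = field(default_factory=list)
    effective_cutoff: float = DEFAULT_EFFECTIVE_CUTOFF
    discard_fraction: float = DEFAULT_DISCARD_FRACTION

    def __post_init__(self) -> None:
        if not 0.0 <= self.discard_fraction <= 1.0:
            raise ValueError("discard_fraction must be within [0, 1]")
        for act, pas, side in (
            (self.receptor_active, self.receptor_passive, "receptor"),
            (self.ligand_active, self.ligand_passive, "ligand"),
        ):
            overlap = set(act) & set(pas)
            if overlap:
                raise ValueError(
                    f"{side} active/passive overlap: {sorted(map(str, overlap))}"
                )

    @property
    def n_active(self) -> int:
        return len(self.receptor_active) + len(self.ligand_active)


@dataclass
class TriadConstraint:
    """Require >= ``min_required`` triad residues in the interface."""

    residues: tuple[str, ...] = EDE_TRIAD
    min_required: int = 2
    interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF
    chain_id: str | None = None  # chain holding the triad (receptor side)

    def __post_init__(self) -> None:
        if not 1 <= self.min_required <= len(self.residues):
            raise ValueError("min_required out of range")


# -- operations --------------------------------------------------------------

def build_passive_set(s: Structure, active: Sequence[ResidueKey],
                      rel_sasa_min: float = DEFAULT_REL_SASA_MIN,
                      neighbor_cutoff: float = DEFAULT_NEIGHBOR_CUTOFF
                      ) -> list[ResidueKey]:
    """Solvent-accessible neighbors of the active residues.

    A residue qualifies when it is not active itself, its relative
    accessibility is >= ``rel_sasa_min``, and any of its heavy atoms lies
    within ``neighbor_cutoff`` of any active residue's heavy atom.
    """
    keys = s.residue_keys()
    active_set = set(active)
    missing = active_set - set(keys)
    if missing:
        raise KeyError(f"active residues absent: {sorted(map(str, missing))}")
    heavy = s.select(s.heavy_mask())
    act_mask = heavy.residue_mask(active)
    if not act_mask.any():
        raise KeyError("active residues have no heavy atoms")
    tree = cKDTree(heavy.coords[act_mask])
    near = tree.query_ball_point(heavy.coords, neighbor_cutoff,
                                 return_length=True) > 0
    res_idx = heavy.residue_index()
    hkeys = heavy.residue_keys()
    near_res = {hkeys[i] for i in np.unique(res_idx[near])}
    rel = sasa(s).relative
    out = []
    for k in keys:  # preserve structure residue order
        if k in active_set or k not in near_res:
            continue
        r = rel.get(k, float("nan"))
        if np.isnan(r) or r < rel_sasa_min:
            continue
        out.append(k)
    return out


def effective_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Ambiguous-restraint effective distance ``(sum d^-6)^(-1/6)``.

    Monotone in the pair set: adding a pair can only lower it, so it is
    always <= the minimum pairwise distance.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty atom set")
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    if (d2 <= 0).any():
        return 0.0
    return float(np.power(np.power(d2, -3.0).sum(), -1.0 / 6.0))


def restraint_satisfaction(receptor: Structure, ligand: Structure,
                           r: RestraintSet
                           ) -> tuple[float, list[dict]]:
    """Fraction of ambiguous restraints satisfied in a complex.

    One restraint per active residue; the restraint's target is the union
    of active and passive residues of the partner, and it is satisfied when
    the effective distance to that union is <= ``r.effective_cutoff``.
    Returns the fraction plus per-restraint detail records.
    """
    details: list[dict] = []

    def side(src: Structure, active: list[ResidueKey], dst: Structure,
             targets: list[ResidueKey], partner: str) -> None:
        if not active:
            return
        src_h = src.select(src.heavy_mask())
        dst_h = dst.select(dst.heavy_mask())
        tmask = dst_h.residue_mask(targets) if targets else \
            np.ones(dst_h.n_atoms, dtype=bool)
        tcoords = dst_h.coords[tmask]
        if len(tcoords) == 0:
            raise KeyError(f"no target atoms on {partner} partner")
        for key in active:
            amask = src_h.residue_mask([key])
            if not amask.any():
                raise KeyError(f"restraint residue {key} unresolvable")
            eff = effective_distance(src_h.coords[amask], tcoords)
            details.append({
                "residue": str(key), "partner": partner,
                "effective_distance": eff,
                "satisfied": bool(eff <= r.effective_cutoff),
            })

    side(receptor, r.receptor_active, ligand,
         r.ligand_active + r.ligand_passive, "ligand")
    side(ligand, r.ligand_active, receptor,
         r.receptor_active + r.receptor_passive, "receptor")
    if not details:
        raise ValueError("restraint set has no active residues")
    frac = sum(d["satisfied"] for d in details) / len(details)
    return float(frac), details


def discard_restraints(r: RestraintSet, seed: int) -> RestraintSet:
    """Randomly drop ``floor(discard_fraction * n_active)`` active restraints.

    Sampling is uniform over the combined active lists and fully
    deterministic for a given seed.  Passive residues define targets, not
    restraints, and are never discarded.
    """
    rng = np.random.default_rng(seed)
    pool = [("receptor", k) for k in r.receptor_active] + \
           [("ligand", k) for k in r.ligand_active]
    n_drop = int(np.floor(r.discard_fraction * len(pool)))
    if n_drop == 0:
        return replace(r)
    drop_idx = set(rng.choice(len(pool), size=n_drop, replace=False).tolist())
    keep_r = [k for i, (side, k) in enumerate(pool)
              if side == "receptor" and i not in drop_idx]
    keep_l = [k for i, (side, k) in enumerate(pool)
              if side == "ligand" and i not in drop_idx]
    return replace(r, receptor_active=keep_r, ligand_active=keep_l)


def triad_filter(receptor: Structure, ligand: Structure,
                 t: TriadConstraint) -> tuple[bool, dict[str, bool]]:
    """Does the pose put the required triad residues at the interface?

    A triad residue is an interface member when any of its heavy atoms is
    within ``t.interface_cutoff`` of any partner heavy atom.  Returns the
    verdict plus per-residue membership.
    """
    keys = resolve_labels(receptor, list(t.residues), t.chain_id)
    rec_h = receptor.select(receptor.heavy_mask())
    lig_h = ligand.select(ligand.heavy_mask())
    tree = cKDTree(lig_h.coords)
    membership: dict[str, bool] = {}
    for label, key in zip(t.residues, keys):
        mask = rec_h.residue_mask([key])
        if not mask.any():
            raise KeyError(f"triad residue {label} has no heavy atoms")
        hits = tree.query_ball_point(rec_h.coords[mask], t.interface_cutoff,
                                     return_length=True)
        membership[label] = bool((hits > 0).any())
    ok = sum(membership.values()) >= t.min_required
    return ok, membership
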