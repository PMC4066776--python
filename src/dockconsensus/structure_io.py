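"""Macromolecular coordinate I/O and residue-level editing.

Coordinates are held in a flat, numpy-backed :class:`Structure` keyed by
author (PDB) numbering.  Author numbering is authoritative throughout the
package: residue identities such as E235 or F230 always refer to the
numbers present in the input file, and no implicit renumbering ever occurs.

Reading goes through :mod:`gemmi`; writing emits fixed-column PDB v3
coordinate records directly so that the output contract (sequential serial
numbers from 1, TER after each chain, END) is guaranteed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ResidueKey",
    "ResidueRange",
    "Structure",
    "read_pdb",
    "read_models",
    "write_pdb",
    "excise_residue_ranges",
    "STANDARD_AMINO_ACIDS",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class ResidueKey(NamedTuple):
    """Identity of one residue under author numbering.

    ``(chain_id, seq_num, icode)`` is unique within a structure; ``res_name``
    is carried along for convenience and readable reports.
    """

    chain_id: str
    seq_num: int
    icode: str
    res_name: str

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AMINO_ACIDS

    def __str__(self) -> str:  # e.g. "A:GLU235"
        return f"{self.chain_id}:{self.res_name}{self.seq_num}{self.icode.strip()}"


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbered residue range on one chain."""

    chain_id: str
    start_seq_num: int
    end_seq_num: int

    def __post_init__(self) -> None:
        if self.start_seq_num > self.end_seq_num:
            raise ValueError(
                f"range start {self.start_seq_num} > end {self.end_seq_num}"
            )


@dataclass
class Structure:
    """Flat array-of-atoms coordinate model (chains -> residues -> atoms).

    All per-atom annotation arrays have length ``n_atoms``; ``coords`` is
    an ``(n_atoms, 3)`` float array in Angstroms.
    """

    chain_ids: np.ndarray
    seq_nums: np.ndarray
    icodes: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    occupancies: np.ndarray = field(default=None)  # type: ignore[assignment]
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.seq_nums = np.asarray(self.seq_nums, dtype=int)
        self.icodes = np.asarray(self.icodes, dtype="U1")
        self.res_names = np.asarray(self.res_names, dtype="U3")
        self.atom_names = np.asarray(self.atom_names, dtype="U4")
        self.elements = np.char.upper(np.asarray(self.elements, dtype="U2"))
        if self.occupancies is None:
            self.occupancies = np.ones(n)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        for arr in (self.chain_ids, self.seq_nums, self.icodes, self.res_names,
                    self.atom_names, self.elements, self.occupancies):
            if len(arr) != n:
                raise ValueError("annotation arrays and coords disagree in length")
        if n and not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    # -- basic introspection -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def residue_keys(self) -> list[ResidueKey]:
        """Unique residues in order of first appearance."""
        keys: dict[tuple, ResidueKey] = {}
        for c, s, i, r in zip(self.chain_ids, self.seq_nums, self.icodes,
                              self.res_names):
            k = (str(c), int(s), str(i))
            if k not in keys:
                keys[k] = ResidueKey(str(c), int(s), str(i), str(r))
        return list(keys.values())

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def residue_index(self) -> np.ndarray:
        """Per-atom index into :meth:`residue_keys` order."""
        order: dict[tuple, int] = {}
        idx = np.empty(self.n_atoms, dtype=int)
        for a, (c, s, i) in enumerate(zip(self.chain_ids, self.seq_nums,
                                          self.icodes)):
            k = (str(c), int(s), str(i))
            idx[a] = order.setdefault(k, len(order))
        return idx

    # -- selection -----------------------------------------------------------

    def select(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        return Structure(
            chain_ids=self.chain_ids[mask],
            seq_nums=self.seq_nums[mask],
            icodes=self.icodes[mask],
            res_names=self.res_names[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            coords=self.coords[mask],
            occupancies=self.occupancies[mask],
            title=self.title,
        )

    def chain_mask(self, chain_ids: str | Iterable[str]) -> np.ndarray:
        if isinstance(chain_ids, str):
            chain_ids = list(chain_ids)
        wanted = set(chain_ids)
        return np.isin(self.chain_ids, list(wanted))

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def residue_mask(self, keys: Iterable[ResidueKey | tuple]) -> np.ndarray:
        wanted = set()
        for k in keys:
            if isinstance(k, ResidueKey):
                wanted.add((k.chain_id, k.seq_num, k.icode))
            else:
                wanted.add(tuple(k[:3]))
        out = np.zeros(self.n_atoms, dtype=bool)
        for a, (c, s, i) in enumerate(zip(self.chain_ids, self.seq_nums,
                                          self.icodes)):
            if (str(c), int(s), str(i)) in wanted:
                out[a] = True
        return out

    def residue_atoms(self, key: ResidueKey | tuple) -> "Structure":
        return self.select(self.residue_mask([key]))

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def copy(self) -> "Structure":
        return Structure(
            chain_ids=self.chain_ids.copy(), seq_nums=self.seq_nums.copy(),
            icodes=self.icodes.copy(), res_names=self.res_names.copy(),
            atom_names=self.atom_names.copy(), elements=self.elements.copy(),
            coords=self.coords.copy(), occupancies=self.occupancies.copy(),
            title=self.title,
        )

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain in residue order ('X' nonstandard)."""
        return "".join(
            THREE_TO_ONE.get(k.res_name, "X")
            for k in self.residue_keys() if k.chain_id == chain_id
        )


def concatenate(parts: Sequence[Structure], title: str = "") -> Structure:
    """Merge structures into one; chain identifiers must not collide."""
    seen: set[str] = set()
    for p in parts:
        cs = set(p.chains())
        if cs & seen:
            raise ValueError(f"chain id collision: {sorted(cs & seen)}")
        seen |= cs
    return Structure(
        chain_ids=np.concatenate([p.chain_ids for p in parts]),
        seq_nums=np.concatenate([p.seq_nums for p in parts]),
        icodes=np.concatenate([p.icodes for p in parts]),
        res_names=np.concatenate([p.res_names for p in parts]),
        atom_names=np.concatenate([p.atom_names for p in parts]),
        elements=np.concatenate([p.elements for p in parts]),
        coords=np.concatenate([p.coords for p in parts]),
        occupancies=np.concatenate([p.occupancies for p in parts]),
        title=title,
    )


# -- reading -----------------------------------------------------------------

def _model_to_structure(model, include_hetatm: bool, title: str) -> Structure:
    chain_ids, seq_nums, icodes, res_names = [], [], [], []
    atom_names, elements, coords, occs = [], [], [], []
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and not include_hetatm:
                continue
            # alt-loc resolution: highest occupancy, ties -> lowest altloc char
            best: dict[str, tuple] = {}
            for atom in res:
                alt = atom.altloc or ""
                cur = best.get(atom.name)
                if cur is None or (atom.occ, _neg_ord(alt)) > (cur[0].occ,
                                                               _neg_ord(cur[1])):
                    best[atom.name] = (atom, alt)
            for name, (atom, _alt) in best.items():
                chain_ids.append(chain.name)
                seq_nums.append(res.seqid.num)
                icodes.append(res.seqid.icode.strip())
                res_names.append(res.name)
                atom_names.append(name)
                elements.append(atom.element.name.upper())
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occs.append(atom.occ)
    if not coords:
        raise ValueError("no coordinate records found")
    return Structure(
        chain_ids=np.array(chain_ids), seq_nums=np.array(seq_nums),
        icodes=np.array(icodes), res_names=np.array(res_names),
        atom_names=np.array(atom_names), elements=np.array(elements),
        coords=np.array(coords), occupancies=np.array(occs), title=title,
    )


def _neg_ord(alt: str) -> int:
    # sort key so that among equal occupancies the alphabetically first
    # alt-loc wins when compared with ">"
    return -ord(alt) if alt else 1


def _read_gemmi(path: str | os.PathLike):
    import gemmi

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)


def read_pdb(path: str | os.PathLike, model_index: int = 1,
             include_hetatm: bool = False) -> Structure:
    """Read one model of a PDB file.

    Parameters
    ----------
    path:
        PDB v3 coordinate file.
    model_index:
        1-based MODEL number position (default: first model).
    include_hetatm:
        Keep HETATM records (skipped by default).
    """
    st = _read_gemmi(path)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    if not 1 <= model_index <= len(st):
        raise ValueError(
            f"{path}: model {model_index} absent ({len(st)} model(s) present)"
        )
    return _model_to_structure(st[model_index - 1], include_hetatm,
                               title=st.name or "")


def read_models(path: str | os.PathLike,
                include_hetatm: bool = False) -> list[Structure]:
    """Read every MODEL block of a multi-model PDB file (decoy ensembles)."""
    st = _read_gemmi(path)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    return [_model_to_structure(m, include_hetatm, title=st.name or "")
            for m in st]


# -- writing -----------------------------------------------------------------

_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}{seq:>4d}"
    "{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {elem:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB column convention: element right-aligned in cols 13-14 for
    # one-letter elements with short names
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: Structure, path: str | os.PathLike) -> None:
    """Write fixed-column PDB records: serials from 1, TER per chain, END."""
    if s.n_atoms == 0:
        raise ValueError("refusing to write an empty Structure")
    for c in s.chains():
        if len(c) > 1:
            raise ValueError(f"chain id {c!r} longer than one character")
    if int(s.seq_nums.max()) > 9999 or int(s.seq_nums.min()) < -999:
        raise ValueError("residue number outside the PDB fixed-column range")
    lines: list[str] = []
    serial = 0
    prev = None
    for i in range(s.n_atoms):
        chain = str(s.chain_ids[i])
        if prev is not None and chain != prev:
            serial += 1
            lines.append(f"TER   {serial:>5d}\n")
        serial += 1
        if serial > 99999:
            raise ValueError("atom serial overflow")
        x, y, z = s.coords[i]
        lines.append(_PDB_ATOM.format(
            serial=serial,
            name=_format_atom_name(str(s.atom_names[i]), str(s.elements[i])),
            alt=" ", res=str(s.res_names[i]), chain=chain,
            seq=int(s.seq_nums[i]), icode=str(s.icodes[i]) or " ",
            x=x, y=y, z=z, occ=float(s.occupancies[i]), b=0.0,
            elem=str(s.elements[i]),
        ))
        prev = chain
    serial += 1
    lines.append(f"TER   {serial:>5d}\n")
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


# -- editing -----------------------------------------------------------------

def excise_residue_ranges(s: Structure,
                          ranges: Sequence[ResidueRange]) -> Structure:
    """Remove every residue inside any of the author-numbered ranges.

    The remaining residues keep their numbering and coordinates untouched.
    Flexible-region excision (e.g. a DNA-binding loop, or a mobile
    N-terminal helix) before rigid-body docking is the intended use.
    """
    present = set(s.chains())
    for r in ranges:
        if r.chain_id not in present:
            raise ValueError(f"range on absent chain {r.chain_id!r}")
    if not ranges:
        return s.copy()
    drop = np.zeros(s.n_atoms, dtype=bool)
    for r in ranges:
        drop |= (
            (s.chain_ids == r.chain_id)
            & (s.seq_nums >= r.start_seq_num)
            & (s.seq_nums <= r.end_seq_num)
        )
    return s.select(~drop)
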