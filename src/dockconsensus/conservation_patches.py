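"""MSA conservation scoring and surface patch detection.

Per-column conservation is the Jensen-Shannon divergence between the
column's amino-acid frequency distribution (gaps excluded) and a fixed
background, normalised so that an invariant column scores 1 and a column
indistinguishable from the background scores 0.  Scores mapped onto a
structure feed spatial patch detection: solvent-exposed residues passing a
conservation or charge criterion are single-linkage clustered on
side-chain-tip distances, recovering features such as a conserved acidic
triad or a basic DNA-binding face.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .geometry import sasa
from .structure_io import ResidueKey, Structure, THREE_TO_ONE

__all__ = [
    "AlignmentSet",
    "ConservationProfile",
    "SurfacePatch",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "conservation_scores",
    "map_profile_to_structure",
    "detect_surface_patches",
    "AMINO_ACIDS",
    "BACKGROUND_FREQUENCIES",
    "CHARGE_LABELS",
    "SIDE_CHAIN_TIP_ATOMS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Named background distributions over the 20 amino acids.  "uniform" is
#: the default (it makes the conservation scale exactly [0, 1] with
#: invariant columns at 1); "robinson" gives the Robinson-Robinson natural
#: abundance frequencies.
BACKGROUND_FREQUENCIES: dict[str, np.ndarray] = {
    "uniform": np.full(20, 1.0 / 20.0),
    "robinson": np.array([
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]),
}

CHARGE_LABELS = {"D": "acidic", "E": "acidic", "K": "basic", "R": "basic"}

#: Representative side-chain tip atom per residue type (CB fallback;
#: Gly uses CA), used for patch linkage distances.
SIDE_CHAIN_TIP_ATOMS = {
    "ALA": "CB", "ARG": "CZ", "ASN": "CG", "ASP": "CG", "CYS": "SG",
    "GLN": "CD", "GLU": "CD", "GLY": "CA", "HIS": "NE2", "ILE": "CD1",
    "LEU": "CG", "LYS": "NZ", "MET": "SD", "PHE": "CZ", "PRO": "CG",
    "SER": "OG", "THR": "OG1", "TRP": "CZ2", "TYR": "OH", "VAL": "CB",
}


@dataclass
class AlignmentSet:
    """A gapped multiple sequence alignment with a designated query."""

    identifiers: list[str]
    sequences: list[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if len(self.identifiers) != len(self.sequences):
            raise ValueError("identifiers and sequences length mismatch")
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least two sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        q = self.query
        bad = set(q) - set(AMINO_ACIDS) - {"-"}
        if bad:
            raise ValueError(f"query contains ambiguous letters {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]

    def query_columns(self) -> np.ndarray:
        """Alignment column index of each ungapped query position."""
        return np.array([i for i, c in enumerate(self.query) if c != "-"],
                        dtype=int)

    def pairwise_identity(self, i: int, j: int) -> float:
        """Fraction of columns identical between two sequences, over
        columns where neither is gapped."""
        a, b = self.sequences[i], self.sequences[j]
        both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        if not both:
            return 0.0
        return sum(x == y for x, y in both) / len(both)


@dataclass
class ConservationProfile:
    """Conservation scores on ungapped query positions.

    ``scores`` in [0, 1] (1 = invariant); NaN where the column was masked
    for excessive gapping.  ``coverage`` is the non-gap fraction of each
    column; ``positions`` are 1-based query residue positions.
    """

    scores: np.ndarray
    coverage: np.ndarray
    positions: np.ndarray


def read_fasta_alignment(path) -> AlignmentSet:
    """Read an aligned FASTA file (first record becomes the query)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    return AlignmentSet(
        identifiers=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
    )


def write_fasta_alignment(a: AlignmentSet, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(a.identifiers, a.sequences)]
    seqio_write(records, str(path), "fasta")


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, base-2 logs (range [0, 1])."""

    def h(x: np.ndarray) -> float:
        nz = x[x > 0]
        return float(-(nz * np.log2(nz)).sum())

    m = 0.5 * (p + q)
    return h(m) - 0.5 * (h(p) + h(q))


def conservation_scores(a: AlignmentSet, background: str | np.ndarray = "uniform",
                        max_gap_fraction: float = 0.5) -> ConservationProfile:
    """Normalised Jensen-Shannon conservation on query positions.

    Each column's amino-acid frequency distribution (gaps and ambiguous
    letters excluded) is compared against the background; scores divide by
    the largest divergence any single-letter (invariant) column can attain
    against that background, so values live in [0, 1].  Columns with gap
    fraction above ``max_gap_fraction`` are masked to NaN.  An all-gap
    column at a query position raises.
    """
    bg = BACKGROUND_FREQUENCIES[background] if isinstance(background, str) \
        else np.asarray(background, dtype=float)
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a 20-way distribution")
    norm = max(_jsd(np.eye(20)[i], bg) for i in range(20))
    cols = a.query_columns()
    scores = np.empty(len(cols))
    coverage = np.empty(len(cols))
    for out_i, col in enumerate(cols):
        letters = [s[col] for s in a.sequences]
        counts = np.zeros(20)
        for c in letters:
            idx = _AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
        coverage[out_i] = sum(c != "-" for c in letters) / a.n_sequences
        if counts.sum() == 0:
            raise ValueError(f"all-gap column at query position {out_i + 1}")
        if 1.0 - coverage[out_i] > max_gap_fraction:
            scores[out_i] = np.nan
            continue
        p = counts / counts.sum()
        scores[out_i] = _jsd(p, bg) / norm
    return ConservationProfile(scores=scores, coverage=coverage,
                               positions=np.arange(1, len(cols) + 1))


def map_profile_to_structure(p: ConservationProfile, s: Structure,
                             chain: str, query: str | None = None
                             ) -> dict[ResidueKey, float]:
    """Attach query-position scores to the residues of one chain.

    The ungapped query sequence must equal the chain's residue sequence
    exactly; the first mismatch is reported by position.  When ``query``
    is omitted only the lengths are checked.
    """
    if chain not in s.chains():
        raise KeyError(f"chain {chain!r} absent")
    keys = [k for k in s.residue_keys() if k.chain_id == chain]
    if len(keys) != len(p.scores):
        raise ValueError(
            f"profile has {len(p.scores)} positions but chain {chain!r} "
            f"has {len(keys)} residues"
        )
    if query is not None:
        ungapped = query.replace("-", "")
        for i, (k, q) in enumerate(zip(keys, ungapped), start=1):
            chain_letter = THREE_TO_ONE.get(k.res_name, "X")
            if chain_letter != q:
                raise ValueError(
                    f"sequence/structure mismatch at position {i}: "
                    f"alignment {q} vs chain {chain_letter} ({k})"
                )
    return {k: float(v) for k, v in zip(keys, p.scores)}


@dataclass
class SurfacePatch:
    """A spatially connected set of exposed residues sharing a property."""

    label: str
    members: list[ResidueKey]
    diameter: float
    mean_value: float
    is_singleton: bool = False

    def to_dict(self) -> dict:
        return {"label": self.label,
                "members": [str(k) for k in self.members],
                "diameter": round(self.diameter, 2),
                "mean_value": round(self.mean_value, 4),
                "is_singleton": self.is_singleton}


def _tip_coord(s: Structure, key: ResidueKey) -> np.ndarray | None:
    res = s.residue_atoms(key)
    wanted = SIDE_CHAIN_TIP_ATOMS.get(key.res_name, "CB")
    for name in (wanted, "CB", "CA"):
        hit = res.atom_names == name
        if hit.any():
            return res.coords[hit][0]
    return None


def detect_surface_patches(s: Structure,
                           annotation: dict[ResidueKey, float] | None = None,
                           mode: Literal["value", "charge"] = "value",
                           label: str = "conserved",
                           value_threshold: float = 0.8,
                           charge: Literal["acidic", "basic"] = "acidic",
                           rel_sasa_min: float = 0.25,
                           linkage_cutoff: float = 8.0,
                           chain: str | None = None
                           ) -> list[SurfacePatch]:
    """Spatial patches of exposed residues selected by value or charge.

    Exposed residues (relative accessibility >= ``rel_sasa_min``) passing
    the criterion - ``annotation[residue] >= value_threshold`` in value
    mode, residue type D/E (acidic) or K/R (basic) in charge mode - are
    single-linkage clustered on side-chain tip distances at
    ``linkage_cutoff``.  Patches with two or more members come first, in
    decreasing size; singletons are appended flagged as such.
    """
    rel = sasa(s).relative
    keys = s.residue_keys()
    if chain is not None:
        keys = [k for k in keys if k.chain_id == chain]
    selected: list[ResidueKey] = []
    values: list[float] = []
    for k in keys:
        r = rel.get(k, float("nan"))
        if np.isnan(r) or r < rel_sasa_min:
            continue
        if mode == "value":
            if annotation is None:
                raise ValueError("value mode needs an annotation")
            v = annotation.get(k, float("nan"))
            if np.isnan(v) or v < value_threshold:
                continue
        elif mode == "charge":
            one = THREE_TO_ONE.get(k.res_name, "X")
            if CHARGE_LABELS.get(one) != charge:
                continue
            v = 1.0 if one in "KR" else -1.0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        tip = _tip_coord(s, k)
        if tip is None:
            continue
        selected.append(k)
        values.append(float(v))
    if not selected:
        return []
    tips = np.stack([_tip_coord(s, k) for k in selected])
    if len(selected) == 1:
        dist = np.zeros((1, 1))
    else:
        dist = squareform(pdist(tips))
    adj = csr_matrix(dist <= linkage_cutoff)
    n_comp, comp = connected_components(adj, directed=False)
    patch_label = label if mode == "value" else charge
    patches: list[SurfacePatch] = []
    for ci in range(n_comp):
        idx = np.where(comp == ci)[0]
        members = [selected[i] for i in idx]
        diam = float(dist[np.ix_(idx, idx)].max()) if len(idx) > 1 else 0.0
        patches.append(SurfacePatch(
            label=patch_label, members=members, diameter=diam,
            mean_value=float(np.mean([values[i] for i in idx])),
            is_singleton=len(idx) == 1,
        ))
    patches.sort(key=lambda p: (p.is_singleton, -len(p.members),
                                p.members[0]))
    return patches


def profile_to_bfactor_pdb(s: Structure, annotation: dict[ResidueKey, float],
                           path) -> None:
    """Write a copy of the structure with per-residue scores in the
    B-factor column (0 where unannotated), for external visualisation."""
    lines = []
    serial = 0
    prev = None
    key_of = {(str(c), int(n), str(i)): ResidueKey(str(c), int(n), str(i), str(r))
              for c, n, i, r in zip(s.chain_ids, s.seq_nums, s.icodes,
                                    s.res_names)}
    from .structure_io import _PDB_ATOM, _format_atom_name

    for i in range(s.n_atoms):
        chain = str(s.chain_ids[i])
        if prev is not None and chain != prev:
            serial += 1
            lines.append(f"TER   {serial:>5d}\n")
        serial += 1
        key = key_of[(chain, int(s.seq_nums[i]), str(s.icodes[i]))]
        b = annotation.get(key, 0.0)
        x, y, z = s.coords[i]
        lines.append(_PDB_ATOM.format(
            serial=serial,
            name=_format_atom_name(str(s.atom_names[i]), str(s.elements[i])),
            alt=" ", res=str(s.res_names[i]), chain=chain,
            seq=int(s.seq_nums[i]), icode=str(s.icodes[i]) or " ",
            x=x, y=y, z=z, occ=float(s.occupancies[i]),
            b=float(0.0 if np.isnan(b) else b), elem=str(s.elements[i]),
        ))
        prev = chain
    serial += 1
    lines.append(f"TER   {serial:>5d}\nEND\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
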