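"""Synthetic inputs for every pipeline stage.

The generators produce, at desk scale, the same *kinds* of data a docking
study consumes: a bound two-partner reference complex whose interface
carries a planted acidic-triad/basic-triad pairing plus an apolar anchor
pair (the architecture of the DprA-RecA consensus interface), rigid-body
decoy ensembles with a controlled ladder of pose errors, pseudo-method
score columns whose correlation with true pose error is tunable, and MSAs
with designated conserved columns inside a target identity band.

Geometry is idealised: partners are rigid alpha-helical poly-alanine
scaffolds and planted side chains are placed explicitly so that the
specified contact distances are realised by construction.  Only the
geometric and combinatorial structure matters for the pipeline's
contracts, not physical realism.

Every generator is a pure function of its spec and seed, and each returns
its planted ground truth separately so oracle-based tests never leak truth
into pipeline inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conservation_patches import AMINO_ACIDS, AlignmentSet
from .decoy_clustering import DecoySet
from .geometry import RigidTransform, selection_mask
from .structure_io import ONE_TO_THREE, Structure

__all__ = [
    "ToyComplexSpec",
    "DecoyLadderSpec",
    "ScoreModelSpec",
    "ToyComplex",
    "make_toy_complex",
    "generate_decoy_ladder",
    "assign_scores",
    "generate_msa",
]


# -- specs -------------------------------------------------------------------

@dataclass(frozen=True)
class ToyComplexSpec:
    """Layout of the planted-interface toy complex.

    Partner A (receptor) is one helix - doubled into an exact two-fold
    homodimer when ``homodimer`` is set - carrying an acidic triad (Glu,
    Asp, Glu) and a Met apolar anchor; partner B (ligand) is a parallel
    helix carrying a basic triad (Arg, Arg, Lys) and a Phe anchor facing
    them.  Planted salt bridges are realised at 3.2 A and the anchor C-C
    contact at 4.0 A (within 0.3 A by construction).
    """

    receptor_size: int = 30
    ligand_size: int = 30
    # default planted positions sit on the helix face turned towards the
    # partner (helical phase within ~40 degrees of the interface normal)
    acidic_positions: tuple[int, ...] = (8, 15, 19)   # residue numbers on A
    anchor_position: int = 12
    basic_positions: tuple[int, ...] = (8, 15, 19)    # residue numbers on B
    ligand_anchor_position: int = 12
    homodimer: bool = True
    salt_bridge_distance: float = 3.2
    anchor_distance: float = 4.0
    helix_separation: float = 12.0
    end_bow: float = 4.0     # terminal curvature away from the partner
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.acidic_positions + (self.anchor_position,):
            if not 1 <= p <= self.receptor_size:
                raise ValueError(f"planted position {p} outside receptor")
        for p in self.basic_positions + (self.ligand_anchor_position,):
            if not 1 <= p <= self.ligand_size:
                raise ValueError(f"planted position {p} outside ligand")
        if len(self.acidic_positions) != len(self.basic_positions):
            raise ValueError("acidic and basic triads must pair one-to-one")


@dataclass(frozen=True)
class DecoyLadderSpec:
    """Controlled ladder of pose errors plus a random-pose background."""

    rungs: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0)
    decoys_per_rung: int = 300
    rotation_fraction: float = 0.5   # share of pose error from rotation
    n_random: int = 500
    random_shell_radius: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rungs):
            raise ValueError("rung values must be >= 0")
        if self.decoys_per_rung < 1:
            raise ValueError("decoys_per_rung must be >= 1")
        if not 0.0 <= self.rotation_fraction <= 1.0:
            raise ValueError("rotation_fraction must be within [0, 1]")


@dataclass(frozen=True)
class ScoreModelSpec:
    """Pseudo-method scoring: correlated with true pose error plus noise."""

    name: str = "method"
    correlation: float = 0.8
    noise_scale: float = 1.0
    lower_is_better: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be within [0, 1]")


# -- toy complex -------------------------------------------------------------

# local backbone offsets (A) applied in the helix frame around each CA
_BB_OFFSETS = {"N": (-1.20, 0.60, -0.50), "C": (1.10, 0.60, 0.50),
               "O": (1.30, 1.75, 0.55)}

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TURN = math.radians(100.0)


def _helix_backbone(n_res: int) -> dict[str, np.ndarray]:
    """Ideal alpha-helix backbone along +x, CA radius 2.3 A."""
    i = np.arange(n_res)
    angles = i * _HELIX_TURN
    ca = np.stack([
        i * _HELIX_RISE,
        _HELIX_RADIUS * np.cos(angles),
        _HELIX_RADIUS * np.sin(angles),
    ], axis=1)
    out = {"CA": ca}
    for name, (dx, dy, dz) in _BB_OFFSETS.items():
        # rotate the lateral offset with the helical phase so geometry
        # is identical at every position
        off = np.stack([
            np.full(n_res, dx),
            dy * np.cos(angles) - dz * np.sin(angles),
            dy * np.sin(angles) + dz * np.cos(angles),
        ], axis=1)
        out[name] = ca + off
    return out


# planted side-chain atom sequences, placed along the inter-partner axis
# from CB outward; element inferred from the atom name
_SIDE_CHAINS = {
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "MET": ("CB", "CG", "SD", "CE"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
}

# which atom of the planted side chain must sit at the specified contact
# distance from its partner's tip atom
_TIP_ATOM = {"GLU": "OE1", "ASP": "OD1", "MET": "CE", "ARG": "NH1",
             "LYS": "NZ", "PHE": "CZ"}


def _element_of(atom_name: str) -> str:
    return atom_name[0]


class _Builder:
    def __init__(self) -> None:
        self.chain, self.num, self.res, self.name, self.coord = [], [], [], [], []

    def add(self, chain: str, num: int, res: str, name: str,
            xyz: np.ndarray) -> None:
        self.chain.append(chain)
        self.num.append(num)
        self.res.append(res)
        self.name.append(name)
        self.coord.append(np.asarray(xyz, dtype=float))

    def build(self, title: str) -> Structure:
        return Structure(
            chain_ids=np.array(self.chain), seq_nums=np.array(self.num),
            icodes=np.array([""] * len(self.num)),
            res_names=np.array(self.res), atom_names=np.array(self.name),
            elements=np.array([_element_of(n) for n in self.name]),
            coords=np.stack(self.coord), title=title,
        )


def _ortho(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


def _place_side_chain(b: _Builder, chain: str, num: int, res: str,
                      start: np.ndarray, tip: np.ndarray) -> None:
    """Lay side-chain atoms from CB (at ``start``) towards ``tip``.

    The designated tip atom lands exactly on ``tip``.  Intermediate atoms
    interpolate along the axis with a small alternating lateral zig-zag
    (bond geometry is deliberately idealised, not chemical); terminal
    sibling atoms sit laterally offset just behind the tip, and the Phe
    ring is built as an explicit flat hexagon pointing at the partner.
    """
    names = _SIDE_CHAINS[res]
    tip_name = _TIP_ATOM[res]
    axis = tip - start
    length = np.linalg.norm(axis)
    u = axis / length
    v = _ortho(u)
    w = np.cross(u, v)
    if res == "PHE":
        # flat hexagon facing the partner, centred on the contact axis and
        # leaning into the contact: every ring atom engages the anchor on
        # the other side, which is what makes the pair bury the most area
        center = tip + u * 0.89
        ring = {"CB": start}
        for k, name in enumerate(("CZ", "CE1", "CD1", "CG", "CD2", "CE2")):
            ang = k * math.pi / 3.0
            ring[name] = center + 2.0 * (math.cos(ang) * v
                                         + math.sin(ang) * np.cross(u, v))
        for name in names:
            b.add(chain, num, res, name, ring[name])
        return
    if res == "MET":
        # thioether arm pointing straight at the partner ring so both
        # anchor atoms (SD, CE) engage the contact
        coords = {"CB": start, "CG": tip - u * 2.2 - v * 0.3,
                  "SD": tip - u * 1.1 + v * 0.3, "CE": tip}
        for name in names:
            b.add(chain, num, res, name, coords[name])
        return
    tip_rank = names.index(tip_name)
    for rank, name in enumerate(names):
        if rank < tip_rank:
            frac = rank / tip_rank
            zig = v * (0.55 * (-1.0) ** rank) if 0 < rank else np.zeros(3)
            pos = start + u * (length * frac) + zig
        elif rank == tip_rank:
            pos = tip
        else:
            k = rank - tip_rank
            if res in ("GLU", "ASP"):
                # bidentate carboxylate: both oxygens at contact depth,
                # so each planted pair carries two short salt bridges
                # that survive near-native pose jitter
                pos = tip + v * (1.3 * k)
            else:
                # basic termini stay thin (siblings pulled back from the
                # contact) so the apolar anchor dominates buried area
                pos = tip + v * (1.3 * k) - u * 1.2 + w * (0.3 * k)
        b.add(chain, num, res, name, pos)


@dataclass
class ToyComplex:
    """Bound reference complex plus its planted ground truth."""

    receptor: Structure          # chains A (+ B when homodimeric)
    ligand: Structure            # chain C, bound pose
    spec: ToyComplexSpec
    acidic_keys: list = field(default_factory=list)
    basic_keys: list = field(default_factory=list)
    anchor_receptor_key: object = None
    anchor_ligand_key: object = None

    @property
    def triad_labels(self) -> tuple[str, ...]:
        return tuple(_one_letter_label(k) for k in self.acidic_keys)


def _one_letter_label(key) -> str:
    from .structure_io import THREE_TO_ONE

    return f"{THREE_TO_ONE[key.res_name]}{key.seq_num}"


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> ToyComplex:
    """Build the bound reference complex with planted interface features."""
    sep = spec.helix_separation
    bbA = _helix_backbone(spec.receptor_size)
    bbB = _helix_backbone(spec.ligand_size)

    planted_A = {}
    for pos, res in zip(spec.acidic_positions, ("GLU", "ASP", "GLU")):
        planted_A[pos] = res
    planted_A[spec.anchor_position] = "MET"
    if len(planted_A) != len(spec.acidic_positions) + 1:
        raise ValueError("planted receptor positions overlap")
    planted_B = {}
    for pos, res in zip(spec.basic_positions, ("ARG", "ARG", "LYS")):
        planted_B[pos] = res
    planted_B[spec.ligand_anchor_position] = "PHE"
    if len(planted_B) != len(spec.basic_positions) + 1:
        raise ValueError("planted ligand positions overlap")

    # the ligand helix is flipped about its own axis so that the same
    # helical face (phase ~0) looks back at the receptor
    bbB = {name: xyz * np.array([1.0, -1.0, -1.0]) for name, xyz in bbB.items()}

    # bow both partners away from each other towards the chain termini so
    # that small near-native rotations cannot plunge a terminal residue
    # into the partner and bury it more than the planted anchor
    def bow(n: int) -> np.ndarray:
        t = (np.arange(n) - (n - 1) / 2.0) / max(1.0, (n - 1) / 2.0)
        return spec.end_bow * t * t

    bow_a = bow(spec.receptor_size)
    bow_b = bow(spec.ligand_size)
    bbA = {name: xyz - np.outer(bow_a, [0.0, 1.0, 0.0])
           for name, xyz in bbA.items()}
    bbB = {name: xyz + np.outer(bow_b, [0.0, 1.0, 0.0])
           for name, xyz in bbB.items()}

    rec = _Builder()
    lig = _Builder()

    def backbone(b: _Builder, chain: str, bb: dict, n: int,
                 planted: dict[int, str], y_shift: float) -> None:
        for i in range(n):
            num = i + 1
            res = planted.get(num, "ALA")
            for name in ("N", "CA", "C", "O"):
                xyz = bb[name][i] + np.array([0.0, y_shift, 0.0])
                b.add(chain, num, res, name, xyz)

    backbone(rec, "A", bbA, spec.receptor_size, planted_A, 0.0)
    backbone(lig, "C", bbB, spec.ligand_size, planted_B, sep)

    def ca(b_dict: dict, num: int, y_shift: float) -> np.ndarray:
        return b_dict["CA"][num - 1] + np.array([0.0, y_shift, 0.0])

    # paired planted side chains reach towards each other along the
    # CB-to-CB axis; tips land at the requested contact distance
    pairs = list(zip(spec.acidic_positions, spec.basic_positions,
                     ("GLU", "ASP", "GLU"), ("ARG", "ARG", "LYS"),
                     [spec.salt_bridge_distance] * 3))
    pairs.append((spec.anchor_position, spec.ligand_anchor_position,
                  "MET", "PHE", spec.anchor_distance))
    for pa, pb, res_a, res_b, d in pairs:
        ca_a = ca(bbA, pa, 0.0)
        ca_b = ca(bbB, pb, sep)
        axis = ca_b - ca_a
        dist = np.linalg.norm(axis)
        u = axis / dist
        start_a = ca_a + u * 1.1
        start_b = ca_b - u * 1.1
        if np.linalg.norm(start_b - start_a) <= d + 0.5:
            raise ValueError(
                f"infeasible geometry: planted pair {res_a}{pa}/{res_b}{pb} "
                f"has no room for a {d:.1f} A contact"
            )
        mid = 0.5 * (start_a + start_b)
        tip_a = mid - u * (d / 2.0)
        tip_b = mid + u * (d / 2.0)
        _place_side_chain(rec, "A", pa, res_a, start_a, tip_a)
        _place_side_chain(lig, "C", pb, res_b, start_b, tip_b)

    # plain CB for the unplanted residues so relative SASA is sensible
    for b, bb, n, planted, y_shift, chain in (
        (rec, bbA, spec.receptor_size, planted_A, 0.0, "A"),
        (lig, bbB, spec.ligand_size, planted_B, sep, "C"),
    ):
        for i in range(n):
            num = i + 1
            if num in planted:
                continue
            c = ca(bb, num, y_shift)
            away = c - np.array([c[0], y_shift, 0.0])
            nrm = np.linalg.norm(away)
            direction = away / nrm if nrm > 1e-9 else np.array([0.0, 1.0, 0.0])
            b.add(chain, num, "ALA", "CB", c + direction * 1.5)

    receptor = rec.build("toy receptor")
    ligand = lig.build("toy ligand")

    # audit: no spurious near-overlap across the interface; the closest
    # cross-partner approach must be the planted contacts themselves
    from scipy.spatial import cKDTree

    dmin = cKDTree(receptor.coords).query(ligand.coords, k=1)[0].min()
    floor = min(spec.salt_bridge_distance, spec.anchor_distance) - 0.5
    if dmin < floor:
        raise ValueError(
            f"infeasible geometry: cross-partner atoms at {dmin:.2f} A"
        )

    if spec.homodimer:
        # exact two-fold copy: rotate monomer A by pi about an x-parallel
        # axis placed clear of both the monomer and the ligand
        axis_y = -(sep * 0.6)
        flip = np.diag([1.0, -1.0, -1.0])
        shift = np.array([0.0, 2 * axis_y, 0.0])
        coords_b = receptor.coords @ flip.T + shift
        second = receptor.with_coords(coords_b)
        second = Structure(
            chain_ids=np.full(second.n_atoms, "B"),
            seq_nums=second.seq_nums, icodes=second.icodes,
            res_names=second.res_names, atom_names=second.atom_names,
            elements=second.elements, coords=second.coords,
            occupancies=second.occupancies, title=second.title,
        )
        from .structure_io import concatenate

        receptor = concatenate([receptor, second], title="toy receptor dimer")

    keys = {(k.chain_id, k.seq_num): k for k in receptor.residue_keys()}
    lkeys = {(k.chain_id, k.seq_num): k for k in ligand.residue_keys()}
    return ToyComplex(
        receptor=receptor, ligand=ligand, spec=spec,
        acidic_keys=[keys[("A", p)] for p in spec.acidic_positions],
        basic_keys=[lkeys[("C", p)] for p in spec.basic_positions],
        anchor_receptor_key=keys[("A", spec.anchor_position)],
        anchor_ligand_key=lkeys[("C", spec.ligand_anchor_position)],
    )


# -- decoy ladder ------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    quat = rng.standard_normal(4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix()


def _rotation_rmsd(coords_c: np.ndarray, axis: np.ndarray,
                   angle: float) -> float:
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(axis * angle).as_matrix()
    d = coords_c @ R.T - coords_c
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def _solve_rotation_angle(coords_c: np.ndarray, axis: np.ndarray,
                          target: float) -> float:
    """Bisection for the rotation angle whose CA displacement RMSD is
    ``target`` (rotation about the centroid)."""
    lo, hi = 0.0, math.pi
    if _rotation_rmsd(coords_c, axis, hi) < target:
        raise ValueError(
            f"rotation alone cannot reach {target:.1f} A on this ligand"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _rotation_rmsd(coords_c, axis, mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_decoy_ladder(toy: ToyComplex,
                          spec: DecoyLadderSpec = DecoyLadderSpec()
                          ) -> tuple[DecoySet, dict]:
    """Rigid decoy ensemble with controlled pose errors.

    Per rung, poses mix a rotation about the ligand centroid with a
    translation so that the realised ligand-CA RMSD matches the rung value
    (rotation and translation contributions add in quadrature because the
    rotation is centroid-centred).  Random background poses combine a
    uniform rotation with a translation onto a shell around the bound
    position.  Returns the decoy set and a separate ground-truth dict with
    each pose's true ligand RMSD and provenance.
    """
    rng = np.random.default_rng(spec.seed)
    ligand = toy.ligand
    ca_mask = selection_mask(ligand, "ca")
    ca = ligand.coords[ca_mask]
    centroid = ca.mean(axis=0)
    ca_c = ca - centroid

    transforms: list[RigidTransform] = []
    true_rmsd: list[float] = []
    provenance: list[str] = []

    def add_pose(R: np.ndarray, t: np.ndarray, origin: str) -> None:
        # pose applies R about the CA centroid then translates by t
        rot_t = centroid - R @ centroid + t
        tr = RigidTransform(R, rot_t)
        transforms.append(tr)
        moved = tr.apply(ca)
        true_rmsd.append(float(np.sqrt(((moved - ca) ** 2)
                                       .sum(axis=1).mean())))
        provenance.append(origin)

    for rung in spec.rungs:
        for _ in range(spec.decoys_per_rung):
            if rung == 0.0:
                add_pose(np.eye(3), np.zeros(3), "rung_0.0")
                continue
            rot_target = math.sqrt(spec.rotation_fraction) * rung
            trans_target = math.sqrt(1.0 - spec.rotation_fraction) * rung
            if rot_target > 0:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                try:
                    angle = _solve_rotation_angle(ca_c, axis, rot_target)
                except ValueError:
                    # unreachable by rotation: shift the budget to translation
                    angle = 0.0
                    trans_target = rung
                from scipy.spatial.transform import Rotation

                R = Rotation.from_rotvec(axis * angle).as_matrix()
            else:
                R = np.eye(3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            add_pose(R, direction * trans_target, f"rung_{rung}")

    for _ in range(spec.n_random):
        R = _random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        add_pose(R, direction * spec.random_shell_radius, "random")

    decoys = DecoySet(receptor=toy.receptor, ligand=ligand,
                      transforms=transforms)
    truth = {
        "true_ligand_rmsd": np.array(true_rmsd),
        "provenance": provenance,
        "rungs": list(spec.rungs),
        "n_random": spec.n_random,
    }
    return decoys, truth


# -- pseudo-method scores ----------------------------------------------------

def assign_scores(d: DecoySet, spec: ScoreModelSpec,
                  true_error: np.ndarray) -> None:
    """Attach one pseudo-method score column to a decoy set.

    ``score = c * z(true_error) + (1 - c) * noise`` with ``c`` the
    correlation strength; the direction flag marks the column lower-better
    (the default) or higher-better.  Deterministic per spec seed.
    """
    true_error = np.asarray(true_error, dtype=float)
    if len(true_error) != d.n_poses:
        raise ValueError("true_error length mismatch")
    rng = np.random.default_rng(spec.seed)
    z = (true_error - true_error.mean()) / (true_error.std() or 1.0)
    noise = rng.standard_normal(d.n_poses) * spec.noise_scale
    raw = spec.correlation * z + (1.0 - spec.correlation) * noise
    if not spec.lower_is_better:
        raw = -raw
    d.add_score(spec.name, raw, lower_is_better=spec.lower_is_better)


# -- synthetic MSA -----------------------------------------------------------

def generate_msa(n_seq: int = 99, length: int = 150,
                 conserved_positions: tuple[int, ...] = (),
                 identity_band: tuple[float, float] = (0.35, 0.90),
                 seed: int = 0) -> tuple[AlignmentSet, dict]:
    """Ungapped synthetic MSA with invariant planted columns.

    A random query is copied ``n_seq - 1`` times; each copy substitutes an
    exact count of non-conserved positions, with per-sequence divergence
    levels spread so realised pairwise identities stay inside
    ``identity_band``.  Returns the alignment and the planted truth
    (conserved positions, per-sequence divergence).
    """
    lo, hi = identity_band
    if not 0.0 < lo < hi <= 1.0:
        raise ValueError("infeasible identity band")
    conserved = sorted(set(conserved_positions))
    if conserved and (conserved[0] < 1 or conserved[-1] > length):
        raise ValueError("conserved positions outside sequence")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    query = rng.choice(aas, size=length)
    mutable = np.array([i for i in range(length)
                        if (i + 1) not in set(conserved)])
    if len(mutable) == 0 and n_seq > 1:
        seqs = ["".join(query)] * n_seq
        ids = [f"seq{i:03d}" for i in range(n_seq)]
        return AlignmentSet(ids, seqs), {"conserved_positions": conserved,
                                         "divergence": np.zeros(n_seq)}
    # per-sequence divergence chosen so that query-vs-copy and
    # copy-vs-copy identities both stay inside the band (quadratic decay
    # of identity between two independently mutated copies)
    u_min = max(0.02, 1.0 - hi + 0.02)
    u_max = 1.0 - math.sqrt(max(lo + 0.05, 1e-9))
    if u_max <= u_min:
        raise ValueError("identity band too narrow for this generator")
    divergence = np.concatenate([
        [0.0], rng.uniform(u_min, u_max, size=n_seq - 1)
    ])
    seqs = ["".join(query)]
    for s in range(1, n_seq):
        n_mut = int(round(divergence[s] * length))
        n_mut = min(n_mut, len(mutable))
        sites = rng.choice(mutable, size=n_mut, replace=False)
        copy = query.copy()
        for site in sites:
            choices = aas[aas != copy[site]]
            copy[site] = rng.choice(choices)
        seqs.append("".join(copy))
    ids = [f"seq{i:03d}" for i in range(n_seq)]
    truth = {"conserved_positions": conserved, "divergence": divergence}
    return AlignmentSet(ids, seqs), truth
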