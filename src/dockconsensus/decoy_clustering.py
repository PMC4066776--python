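"""Decoy ranking, mutual-RMSD matrices and greedy clustering.

The clustering step mirrors standard docking post-processing: the best-N
decoys by a scoring column are clustered on mutual ligand RMSD (rigid-body
track, 7.5 A cutoff) or mutual interface RMSD (restraint-guided track,
3.0 A cutoff) with the greedy largest-neighborhood algorithm: repeatedly
take out the remaining structure with the most remaining neighbors,
together with those neighbors, as the next cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import geometry
from .structure_io import Structure

__all__ = [
    "DecoySet",
    "Cluster",
    "ClusterSet",
    "top_n_by_score",
    "rmsd_matrix",
    "greedy_cluster",
    "cluster_representative",
    "DEFAULT_TOP_N",
    "DEFAULT_LIGAND_CUTOFF",
    "DEFAULT_INTERFACE_CUTOFF",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 1000
DEFAULT_LIGAND_CUTOFF = 7.5
DEFAULT_INTERFACE_CUTOFF = 3.0

Metric = Literal["ligand_rmsd", "interface_rmsd"]


@dataclass
class DecoySet:
    """A docking ensemble: fixed receptor, reference ligand, rigid poses.

    Pose ``i`` places the ligand at ``transforms[i]`` applied to the
    reference ligand coordinates.  ``scores`` holds one column per scoring
    method; ``lower_is_better`` records each column's direction.
    """

    receptor: Structure
    ligand: Structure
    transforms: list[geometry.RigidTransform]
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    lower_is_better: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.transforms) < 1:
            raise ValueError("a DecoySet needs at least one pose")
        for name, col in self.scores.items():
            col = np.asarray(col, dtype=float)
            if len(col) != self.n_poses:
                raise ValueError(f"score column {name!r} length mismatch")
            self.scores[name] = col
            self.lower_is_better.setdefault(name, True)

    @property
    def n_poses(self) -> int:
        return len(self.transforms)

    def ligand_coords(self, i: int) -> np.ndarray:
        return self.transforms[i].apply(self.ligand.coords)

    def ligand_pose(self, i: int) -> Structure:
        return self.ligand.with_coords(self.ligand_coords(i))

    def add_score(self, name: str, values: np.ndarray,
                  lower_is_better: bool = True) -> None:
        values = np.asarray(values, dtype=float)
        if len(values) != self.n_poses:
            raise ValueError(f"score column {name!r} length mismatch")
        self.scores[name] = values
        self.lower_is_better[name] = lower_is_better

    @classmethod
    def from_structures(cls, receptor: Structure, ligand: Structure,
                        decoy_ligands: Sequence[Structure],
                        **kwargs) -> "DecoySet":
        """Build from explicit per-decoy ligand coordinates.

        Each decoy ligand must be a rigid copy of the reference ligand;
        its pose transform is recovered by superposition.
        """
        transforms = []
        for d in decoy_ligands:
            tr, rmsd = geometry.kabsch_superpose(ligand.coords, d.coords)
            if rmsd > 0.1:
                raise ValueError(
                    f"decoy ligand is not a rigid copy of the reference "
                    f"(internal RMSD {rmsd:.2f} A)"
                )
            transforms.append(tr)
        return cls(receptor=receptor, ligand=ligand, transforms=transforms,
                   **kwargs)


@dataclass(frozen=True)
class Cluster:
    members: tuple[int, ...]
    seed: int
    representative: int


@dataclass
class ClusterSet:
    """Ordered greedy clusters over a decoy subset.

    Order is extraction order; sizes are typically but not necessarily
    nonincreasing (late extractions can tie).  Every member lies within
    ``cutoff`` of its cluster seed.
    """

    metric: str
    cutoff: float
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def all_members(self) -> list[int]:
        return [m for c in self.clusters for m in c.members]

    def sizes(self) -> list[int]:
        return [len(c.members) for c in self.clusters]

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "cutoff": self.cutoff,
            "clusters": [
                {"members": list(c.members), "seed": c.seed,
                 "representative": c.representative}
                for c in self.clusters
            ],
        }


def top_n_by_score(d: DecoySet, method: str,
                   n: int = DEFAULT_TOP_N) -> list[int]:
    """Indices of the ``n`` best decoys under a score column.

    Ties keep original decoy order (stable sort); ``n`` larger than the
    pose count returns every pose.
    """
    if method not in d.scores:
        raise KeyError(f"unknown score column {method!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    col = d.scores[method]
    key = col if d.lower_is_better.get(method, True) else -col
    order = np.argsort(key, kind="stable")
    return [int(i) for i in order[:n]]


def _mutual_ligand_rmsd(d: DecoySet, subset: Sequence[int],
                        sel: str = "ca") -> np.ndarray:
    mask = geometry.selection_mask(d.ligand, sel)
    if not mask.any():
        raise ValueError("empty ligand selection")
    coords = np.stack([d.ligand_coords(i)[mask] for i in subset])
    n = len(subset)
    out = np.zeros((n, n))
    # receptor is shared by all poses, so the receptor fit is the identity
    # and mutual ligand RMSD reduces to direct coordinate RMSD
    chunk = max(1, int(2e7 // max(1, coords[0].size)))
    for start in range(0, n, chunk):
        block = coords[start:start + chunk]
        diff = block[:, None, :, :] - coords[None, :, :, :]
        out[start:start + chunk] = np.sqrt(
            (diff * diff).sum(axis=3).mean(axis=2)
        )
    return (out + out.T) / 2.0


def _mutual_interface_rmsd(d: DecoySet, subset: Sequence[int],
                           zone_cutoff: float = 10.0,
                           sel: str = "backbone") -> np.ndarray:
    n = len(subset)
    rec = d.receptor
    rec_heavy = rec.heavy_mask()
    lig_heavy = d.ligand.heavy_mask()
    rec_sel = geometry.selection_mask(rec, sel)
    lig_sel = geometry.selection_mask(d.ligand, sel)
    rec_res = rec.residue_index()
    lig_res = d.ligand.residue_index()

    from scipy.spatial import cKDTree

    rec_tree = cKDTree(rec.coords[rec_heavy])

    # per-decoy interface-zone atom masks (zone defined on that decoy)
    zone_masks_r: list[np.ndarray] = []
    zone_masks_l: list[np.ndarray] = []
    lig_coords = [d.ligand_coords(i) for i in subset]
    for lc in lig_coords:
        lig_tree = cKDTree(lc[lig_heavy])
        near_r = np.zeros(rec.n_atoms, dtype=bool)
        near_r[rec_heavy] = [
            bool(v) for v in lig_tree.query_ball_point(
                rec.coords[rec_heavy], zone_cutoff, return_length=True)
        ]
        near_l = np.zeros(d.ligand.n_atoms, dtype=bool)
        near_l[lig_heavy] = [
            bool(v) for v in rec_tree.query_ball_point(
                lc[lig_heavy], zone_cutoff, return_length=True)
        ]
        res_r = np.unique(rec_res[near_r])
        res_l = np.unique(lig_res[near_l])
        zone_masks_r.append(np.isin(rec_res, res_r) & rec_sel)
        zone_masks_l.append(np.isin(lig_res, res_l) & lig_sel)

    def directed(i: int, j: int) -> float:
        zr, zl = zone_masks_r[i], zone_masks_l[i]
        if not zr.any() and not zl.any():
            return np.inf
        ref = np.concatenate([rec.coords[zr], lig_coords[i][zl]])
        dec = np.concatenate([rec.coords[zr], lig_coords[j][zl]])
        _, rmsd = geometry.kabsch_superpose(dec, ref)
        return rmsd

    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = directed(i, j)
            dji = directed(j, i)
            if np.isinf(dij) and np.isinf(dji):
                logger.warning(
                    "empty interface zone for decoy pair (%d, %d); "
                    "entry set to inf", subset[i], subset[j])
                val = np.inf
            elif np.isinf(dij) or np.isinf(dji):
                val = min(dij, dji)
            else:
                val = 0.5 * (dij + dji)
            out[i, j] = out[j, i] = val
    return out


def rmsd_matrix(d: DecoySet, subset: Sequence[int],
                metric: Metric = "ligand_rmsd", **kwargs) -> np.ndarray:
    """Symmetric mutual-RMSD matrix over a decoy subset.

    For the interface metric each decoy in turn defines the zone and the
    two directed values are averaged; pairs with no interface anywhere get
    an infinite sentinel entry.
    """
    if len(subset) == 0:
        raise ValueError("empty subset")
    if metric == "ligand_rmsd":
        return _mutual_ligand_rmsd(d, subset, **kwargs)
    if metric == "interface_rmsd":
        return _mutual_interface_rmsd(d, subset, **kwargs)
    raise ValueError(f"unknown metric {metric!r}")


def greedy_cluster(m: np.ndarray, cutoff: float,
                   metric: str = "ligand_rmsd") -> ClusterSet:
    """Greedy largest-neighborhood clustering of a mutual-distance matrix.

    A neighbor is a decoy at distance <= cutoff (self excluded).  The
    remaining decoy with the most remaining neighbors (ties: lowest index)
    is extracted together with its neighbors as the next cluster, until
    nothing remains.  Singletons come out as size-1 clusters.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    finite = np.isfinite(m)
    if not np.allclose(m[finite & finite.T], m.T[finite & finite.T],
                       atol=1e-8) or (finite != finite.T).any():
        raise ValueError("matrix must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = m.shape[0]
    adj = (m <= cutoff)
    np.fill_diagonal(adj, False)
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # argmax ties -> lowest index
        members = np.where(remaining & (adj[seed] | (np.arange(n) == seed)))[0]
        clusters.append(Cluster(members=tuple(int(i) for i in members),
                                seed=seed, representative=seed))
        remaining[members] = False
    return ClusterSet(metric=metric, cutoff=float(cutoff), clusters=clusters)


def cluster_representative(c: ClusterSet, d: DecoySet, method: str,
                           subset: Sequence[int] | None = None) -> ClusterSet:
    """Replace seed representatives with each cluster's best-scoring member.

    ``subset`` maps matrix-local member indices back to decoy indices when
    the cluster set was built on a subset matrix; scores are always looked
    up on the decoy set.  Ties keep the earliest member.
    """
    if method not in d.scores:
        raise KeyError(f"unknown score column {method!r}")
    col = d.scores[method]
    sign = 1.0 if d.lower_is_better.get(method, True) else -1.0

    def decoy_index(local: int) -> int:
        return int(subset[local]) if subset is not None else int(local)

    new = []
    for cl in c.clusters:
        best = min(cl.members, key=lambda i: (sign * col[decoy_index(i)], i))
        new.append(Cluster(members=cl.members, seed=cl.seed,
                           representative=int(best)))
    return ClusterSet(metric=c.metric, cutoff=c.cutoff, clusters=new)
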