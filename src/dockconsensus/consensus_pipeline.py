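"""Cross-method consensus detection and the end-to-end docking workflow.

Independent docking/scoring methods that converge on mutually consistent
models are a strong reliability indicator.  This module compares cluster
representatives across methods by interface RMSD, reports pairs within a
threshold ranked by combined cluster size, and drives the full workflow:
per rigid-body method, best-N selection, mutual ligand-RMSD clustering at
7.5 A and the acidic-triad constraint filter on representatives; per
guided method, interface-RMSD clustering of the refined subset at 3.0 A;
then cross-method consensus and interface characterization of the top
consensus model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import decoy_clustering as dc
from . import interface_characterization as ic
from . import restraints as rst
from .decoy_clustering import ClusterSet, DecoySet
from .geometry import interface_rmsd
from .structure_io import Structure

__all__ = [
    "MethodConfig",
    "PipelineConfig",
    "ConsensusPair",
    "ConsensusReport",
    "cross_method_consensus",
    "run_consensus_workflow",
    "DEFAULT_CONSENSUS_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_CONSENSUS_THRESHOLD = 3.0
DEFAULT_REFINE_N = 200


@dataclass(frozen=True)
class MethodConfig:
    """One scoring method: the score column to rank by and its track.

    Rigid-body methods rank all decoys, keep the best ``top_n`` and
    cluster on mutual ligand RMSD; guided methods keep the best
    ``refine_n`` (emulating a refined subset) and cluster on mutual
    interface RMSD.
    """

    name: str
    track: Literal["rigid", "guided"] = "rigid"
    decoyset: str = "main"


@dataclass
class PipelineConfig:
    """Every tunable of the workflow, with the study defaults.

    Defaults: the 1000 best-scored decoys enter rigid-track clustering at
    a 7.5 A ligand-RMSD cutoff; guided-track clustering uses a 3.0 A
    interface-RMSD threshold; consensus pairs must agree within 3.0 A
    interface RMSD; half of the active restraints are discarded at random;
    the triad constraint defaults to the DprA acidic triad E235/D243/E265.
    """

    methods: list[MethodConfig] = field(default_factory=list)
    top_n: int = dc.DEFAULT_TOP_N
    ligand_rmsd_cutoff: float = dc.DEFAULT_LIGAND_CUTOFF
    interface_rmsd_cutoff: float = dc.DEFAULT_INTERFACE_CUTOFF
    consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD
    refine_n: int = DEFAULT_REFINE_N
    triad_residues: tuple[str, ...] = rst.EDE_TRIAD
    triad_min_required: int = 2
    triad_chain: str | None = None
    triad_interface_cutoff: float = rst.DEFAULT_INTERFACE_CUTOFF
    discard_fraction: float = rst.DEFAULT_DISCARD_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        for value, what in (
            (self.top_n, "top_n"), (self.ligand_rmsd_cutoff, "ligand cutoff"),
            (self.interface_rmsd_cutoff, "interface cutoff"),
            (self.consensus_threshold, "consensus threshold"),
            (self.refine_n, "refine_n"),
        ):
            if value <= 0:
                raise ValueError(f"{what} must be positive")

    def to_dict(self) -> dict:
        return {
            "methods": [
                {"name": m.name, "track": m.track, "decoyset": m.decoyset}
                for m in self.methods
            ],
            "top_n": self.top_n,
            "ligand_rmsd_cutoff": self.ligand_rmsd_cutoff,
            "interface_rmsd_cutoff": self.interface_rmsd_cutoff,
            "consensus_threshold": self.consensus_threshold,
            "refine_n": self.refine_n,
            "triad_residues": list(self.triad_residues),
            "triad_min_required": self.triad_min_required,
            "triad_chain": self.triad_chain,
            "triad_interface_cutoff": self.triad_interface_cutoff,
            "discard_fraction": self.discard_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        methods = [MethodConfig(**m) for m in data.pop("methods", [])]
        if "triad_residues" in data:
            data["triad_residues"] = tuple(data["triad_residues"])
        return cls(methods=methods, **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class ConsensusPair:
    method_a: str
    method_b: str
    cluster_a: int
    cluster_b: int
    representative_a: int
    representative_b: int
    interface_rmsd: float
    combined_size: int
    mean_rank: float

    def to_dict(self) -> dict:
        return {
            "method_a": self.method_a, "method_b": self.method_b,
            "cluster_a": self.cluster_a, "cluster_b": self.cluster_b,
            "representative_a": self.representative_a,
            "representative_b": self.representative_b,
            "interface_rmsd": round(self.interface_rmsd, 3),
            "combined_size": self.combined_size,
            "mean_rank": round(self.mean_rank, 2),
        }


@dataclass
class ConsensusReport:
    methods: tuple[str, str]
    threshold: float
    pairs: list[ConsensusPair]
    all_pair_rmsds: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def top(self) -> ConsensusPair | None:
        return self.pairs[0] if self.pairs else None

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "threshold": self.threshold,
            "pairs": [p.to_dict() for p in self.pairs],
        }


def _sym_interface_rmsd(receptor: Structure, ligand: Structure,
                        coords_a: np.ndarray, coords_b: np.ndarray,
                        zone_cutoff: float = 10.0) -> float:
    """Direction-averaged interface RMSD between two poses of the same
    ligand against a shared receptor."""
    la = ligand.with_coords(coords_a)
    lb = ligand.with_coords(coords_b)
    vals = []
    for ref_l, dec_l in ((la, lb), (lb, la)):
        try:
            vals.append(interface_rmsd(receptor, ref_l, receptor, dec_l,
                                       zone_cutoff=zone_cutoff))
        except ValueError:
            vals.append(np.inf)
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("inf")


def cross_method_consensus(
    entries: Sequence[tuple[str, ClusterSet, DecoySet, Sequence[int] | None]],
    threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
) -> list[ConsensusReport]:
    """Compare cluster representatives across methods by interface RMSD.

    ``entries`` are ``(method name, cluster set, decoy set, subset)``
    where ``subset`` maps matrix-local cluster indices back to decoy
    indices (None when clusters already use decoy indices).  For every
    method pair, representative-versus-representative interface RMSDs are
    computed and pairs within ``threshold`` reported, ranked by combined
    cluster size then by mean cluster rank.
    """
    if len(entries) < 2:
        raise ValueError("need at least two cluster sets")
    ref = entries[0][2]
    for _, _, d, _ in entries[1:]:
        if d.ligand.n_atoms != ref.ligand.n_atoms or \
                not np.array_equal(d.ligand.atom_names, ref.ligand.atom_names):
            raise ValueError("incompatible partner definitions across methods")
    reports: list[ConsensusReport] = []
    for ai in range(len(entries)):
        for bi in range(ai + 1, len(entries)):
            name_a, ca, da, sub_a = entries[ai]
            name_b, cb, db, sub_b = entries[bi]

            def decoy_idx(local: int, sub) -> int:
                return int(sub[local]) if sub is not None else int(local)

            pairs: list[ConsensusPair] = []
            all_rmsds: dict[tuple[int, int], float] = {}
            for ia, cl_a in enumerate(ca.clusters):
                rep_a = decoy_idx(cl_a.representative, sub_a)
                coords_a = da.ligand_coords(rep_a)
                for ib, cl_b in enumerate(cb.clusters):
                    rep_b = decoy_idx(cl_b.representative, sub_b)
                    coords_b = db.ligand_coords(rep_b)
                    r = _sym_interface_rmsd(da.receptor, da.ligand,
                                            coords_a, coords_b)
                    all_rmsds[(ia, ib)] = r
                    if r <= threshold:
                        pairs.append(ConsensusPair(
                            method_a=name_a, method_b=name_b,
                            cluster_a=ia, cluster_b=ib,
                            representative_a=rep_a, representative_b=rep_b,
                            interface_rmsd=r,
                            combined_size=(len(cl_a.members)
                                           + len(cl_b.members)),
                            mean_rank=0.5 * (ia + ib),
                        ))
            pairs.sort(key=lambda p: (-p.combined_size, p.mean_rank,
                                      p.interface_rmsd))
            reports.append(ConsensusReport(
                methods=(name_a, name_b), threshold=float(threshold),
                pairs=pairs, all_pair_rmsds=all_rmsds,
            ))
    return reports


def run_consensus_workflow(decoysets: dict[str, DecoySet] | DecoySet,
                       cfg: PipelineConfig,
                       outdir: str | Path | None = None) -> dict:
    """Execute the complete consensus-docking analysis.

    Stages: (1) per rigid method - best-N selection, mutual ligand-RMSD
    matrix, greedy clustering, best-score representatives, triad filter on
    each representative (reported at both 2-of-3 and 3-of-3 strictness);
    (2) per guided method - best-``refine_n`` selection, mutual
    interface-RMSD matrix, greedy clustering, representatives; (3)
    cross-method consensus over representatives; (4) interface
    characterization of the top consensus representative, including the
    second-site clash check when the receptor is a two-chain dimer.
    Deterministic for a fixed config; returns the report bundle and
    optionally writes JSON artifacts.
    """
    if isinstance(decoysets, DecoySet):
        decoysets = {"main": decoysets}
    if not cfg.methods:
        raise ValueError("config lists no methods")
    for m in cfg.methods:
        if m.decoyset not in decoysets:
            raise ValueError(f"method {m.name!r}: unknown decoy set")
        if decoysets[m.decoyset].n_poses == 0:
            raise ValueError("empty decoy set")

    stages: list[dict] = []
    cluster_payload: dict[str, dict] = {}
    triad_payload: dict[str, dict] = {}
    entries: list[tuple[str, ClusterSet, DecoySet, list[int]]] = []

    triad = rst.TriadConstraint(
        residues=cfg.triad_residues, min_required=cfg.triad_min_required,
        interface_cutoff=cfg.triad_interface_cutoff, chain_id=cfg.triad_chain,
    )

    for m in cfg.methods:
        d = decoysets[m.decoyset]
        if m.track == "rigid":
            n_sel, metric, cutoff = cfg.top_n, "ligand_rmsd", \
                cfg.ligand_rmsd_cutoff
        else:
            n_sel, metric, cutoff = cfg.refine_n, "interface_rmsd", \
                cfg.interface_rmsd_cutoff
        subset = dc.top_n_by_score(d, m.name, n_sel)
        stages.append({"stage": "top_n", "method": m.name,
                       "n_in": d.n_poses, "n_out": len(subset)})
        matrix = dc.rmsd_matrix(d, subset, metric)
        clusters = dc.greedy_cluster(matrix, cutoff, metric=metric)
        clusters = dc.cluster_representative(clusters, d, m.name,
                                             subset=subset)
        stages.append({"stage": "cluster", "method": m.name,
                       "n_in": len(subset), "n_out": len(clusters)})
        cluster_payload[m.name] = {
            "metric": metric, "cutoff": cutoff,
            "clusters": [
                {"members": [int(subset[i]) for i in c.members],
                 "seed": int(subset[c.seed]),
                 "representative": int(subset[c.representative])}
                for c in clusters.clusters
            ],
        }
        # triad filter on every cluster representative
        verdicts = {}
        for ci, c in enumerate(clusters.clusters):
            rep = int(subset[c.representative])
            pose = d.ligand_pose(rep)
            ok2, membership = rst.triad_filter(
                d.receptor, pose,
                rst.TriadConstraint(residues=triad.residues, min_required=2,
                                    interface_cutoff=triad.interface_cutoff,
                                    chain_id=triad.chain_id))
            ok3, _ = rst.triad_filter(
                d.receptor, pose,
                rst.TriadConstraint(residues=triad.residues,
                                    min_required=len(triad.residues),
                                    interface_cutoff=triad.interface_cutoff,
                                    chain_id=triad.chain_id))
            verdicts[str(ci)] = {
                "representative": rep,
                "pass_2_of_3": bool(ok2), "pass_3_of_3": bool(ok3),
                "membership": membership,
            }
        triad_payload[m.name] = verdicts
        n_pass = sum(v["pass_2_of_3"] for v in verdicts.values())
        stages.append({"stage": "triad_filter", "method": m.name,
                       "n_in": len(clusters), "n_out": n_pass})
        entries.append((m.name, clusters, d, subset))

    if all(
        not v["pass_2_of_3"]
        for verdicts in triad_payload.values() for v in verdicts.values()
    ):
        outcome = "all_clusters_eliminated_by_triad_filter"
    else:
        outcome = "ok"

    reports = cross_method_consensus(entries, cfg.consensus_threshold)
    consensus_payload = [r.to_dict() for r in reports]
    n_pairs = sum(len(r.pairs) for r in reports)
    stages.append({"stage": "consensus",
                   "method": "+".join(m.name for m in cfg.methods),
                   "n_in": sum(len(e[1].clusters) for e in entries),
                   "n_out": n_pairs})

    interface_payload = None
    top_pair = None
    for r in reports:
        if r.top is not None and (top_pair is None
                                  or r.top.combined_size > top_pair.combined_size):
            top_pair = r.top
    if top_pair is not None:
        d = decoysets[cfg.methods[0].decoyset]
        pose = d.ligand_pose(top_pair.representative_a)
        run_clash = len(d.receptor.chains()) == 2
        report = ic.build_interface_report(d.receptor, pose,
                                           run_clash_check=run_clash)
        interface_payload = report.to_dict()
        interface_payload["representative"] = top_pair.representative_a
        stages.append({"stage": "interface_report", "method": "consensus",
                       "n_in": 1, "n_out": 1})

    bundle = {
        "config": cfg.to_dict(),
        "outcome": outcome,
        "stages": stages,
        "clusters": cluster_payload,
        "triad_filter": triad_payload,
        "consensus": consensus_payload,
        "interface_report": interface_payload,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("clusters", "triad_filter", "consensus",
                     "interface_report"):
            with open(outdir / f"{name}.json", "w") as fh:
                json.dump(bundle[name], fh, indent=2, sort_keys=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle


def summary_json(bundle: dict) -> str:
    """Canonical JSON serialisation of a workflow bundle (byte-stable
    across reruns with identical inputs)."""
    return json.dumps(bundle, indent=2, sort_keys=True)
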