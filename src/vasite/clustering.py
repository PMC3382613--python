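"""Trajectory clustering into dominant conformations.

Frames are clustered by single linkage on pairwise RMSD with a similarity
cutoff (default 1 Å); each cluster's simulation fraction is the percentage
of snapshots it holds, and clusters receive a dense rank by descending
fraction.  A representative structure (coordinate mean after superposition,
or medoid) stands in for every member frame downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .structure_io import Conformation, Ensemble


@dataclass
class ConformationCluster:
    cluster_id: int
    member_frames: frozenset[int]
    n_members: int
    simulation_fraction: float = 0.0  # percent, rounded to 2 decimals
    rank: int = 0
    representative: Conformation | None = None

    @classmethod
    def from_members(cls, cluster_id: int, members) -> "ConformationCluster":
        members = frozenset(int(m) for m in members)
        return cls(cluster_id=cluster_id, member_frames=members, n_members=len(members))


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (Kabsch)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def pairwise_rmsd(a: Conformation, b: Conformation,
                  selection: np.ndarray | None = None,
                  superpose_first: bool = True) -> float:
    """RMSD between two frames over ``selection`` (default: all atoms).

    With ``superpose_first`` the mobile frame is first optimally fitted onto
    the other, matching the usual trajectory-clustering convention.
    """
    xa, xb = a.coord, b.coord
    if selection is not None:
        if not np.any(selection):
            raise ValueError("empty atom selection")
        xa, xb = xa[selection], xb[selection]
    if xa.shape != xb.shape:
        raise ValueError("conformations differ in selected atom count")
    if superpose_first:
        xb = superpose(xb, xa)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def rmsd_matrix(ensemble: Ensemble, selection: np.ndarray | None = None,
                superpose_first: bool = True) -> np.ndarray:
    n = len(ensemble)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_rmsd(
                ensemble[i], ensemble[j], selection, superpose_first
            )
    return mat


def single_linkage_cluster(ensemble: Ensemble, cutoff: float = 1.0,
                           selection: np.ndarray | None = None,
                           superpose_first: bool = True,
                           representative_mode: str = "mean") -> list[ConformationCluster]:
    """Cluster frames by single linkage at an RMSD ``cutoff``.

    The resulting partition equals the connected components of the graph
    with an edge wherever RMSD ≤ cutoff.  Clusters come back sorted by
    descending size with fractions, dense ranks and representatives filled.
    """
    n = len(ensemble)
    if n == 1:
        clusters = [ConformationCluster.from_members(0, {ensemble[0].frame_index})]
    else:
        mat = rmsd_matrix(ensemble, selection, superpose_first)
        labels = fcluster(linkage(squareform(mat, checks=False), method="single"),
                          t=cutoff, criterion="distance")
        groups: dict[int, set[int]] = {}
        for conf, lab in zip(ensemble, labels):
            groups.setdefault(int(lab), set()).add(conf.frame_index)
        members = sorted(groups.values(), key=lambda m: (-len(m), min(m)))
        clusters = [ConformationCluster.from_members(i, m) for i, m in enumerate(members)]
    clusters = cluster_fraction_and_rank(clusters, ensemble.total_frames)
    by_frame = {conf.frame_index: conf for conf in ensemble}
    for cl in clusters:
        cl.representative = representative_structure(
            [by_frame[f] for f in sorted(cl.member_frames)], mode=representative_mode
        )
    return clusters


def cluster_fraction_and_rank(clusters: list[ConformationCluster],
                              n_total: int) -> list[ConformationCluster]:
    """Fill simulation fractions (percent, 2 decimals) and dense ranks.

    The fraction is 100·n_members/N; tied fractions share a dense rank and
    the next distinct fraction takes the next integer rank."""
    if sum(c.n_members for c in clusters) != n_total:
        raise ValueError("cluster sizes do not sum to the total frame count")
    for c in clusters:
        c.simulation_fraction = round(100.0 * c.n_members / n_total, 2)
    distinct = sorted({c.simulation_fraction for c in clusters}, reverse=True)
    rank_of = {f: r for r, f in enumerate(distinct, start=1)}
    for c in clusters:
        c.rank = rank_of[c.simulation_fraction]
    return clusters


def representative_structure(members: list[Conformation], mode: str = "mean") -> Conformation:
    """Mean (after superposing onto the lowest-index member) or medoid.

    Averaged structures can carry distorted stereochemistry; they reproduce
    the cluster's occupancy-weighted geometry, not a physical snapshot.
    """
    if not members:
        raise ValueError("cluster has no members")
    if mode not in ("mean", "medoid"):
        raise ValueError(f"unknown representative mode {mode!r}")
    members = sorted(members, key=lambda c: c.frame_index)
    if len(members) == 1:
        return members[0]
    if mode == "mean":
        ref = members[0].coord
        acc = np.zeros_like(ref)
        for conf in members:
            acc += superpose(conf.coord, ref)
        out = members[0].with_coords(acc / len(members))
        out.label = f"mean_of_{len(members)}"
        return out
    if mode == "medoid":
        total = np.zeros(len(members))
        for i in range(len(members)):
            for j in range(len(members)):
                if i != j:
                    total[i] += pairwise_rmsd(members[i], members[j])
        return members[int(np.argmin(total))]
    raise ValueError(f"unknown representative mode {mode!r}")


def cluster_table(clusters: list[ConformationCluster]):
    """Cluster summary as a DataFrame (id, members, simulation %, rank)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "n_members": [c.n_members for c in clusters],
            "simulation_pct": [c.simulation_fraction for c in clusters],
            "rank": [c.rank for c in clusters],
        }
    )
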