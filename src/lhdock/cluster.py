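"""Clustering and ranking of recorded encounter complexes.

The recorded set is clustered on all-pairs pose RMSD (closed form for
rigid bodies, no re-superposition) with average-linkage hierarchical
clustering cut to a fixed number of groups (10 by default).  Clusters are
ranked by occurrence-weighted size — each record contributes its
occurrence count — with ties broken by the representative's energy; the
representative of a cluster is its lowest-energy member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .bd import RecordedSet
from .structures import LHModel

__all__ = ["Cluster", "pose_rmsd_matrix", "cluster_recorded_set", "top_clusters"]


@dataclass
class Cluster:
    """One ranked cluster of recorded poses (ids index into the set)."""

    member_record_ids: list[int]
    weighted_size: int
    rank: int
    representative: int
    representative_energy: float
    population_fraction: float


def _canonical_order(rs: RecordedSet) -> np.ndarray:
    """Input-order-independent record ordering (energy, trajectory, step)."""
    n = rs.n
    return np.lexsort((rs.r_step[:n], rs.r_traj[:n], rs.r_energy[:n]))


def pose_rmsd_matrix(rs: RecordedSet, lh: LHModel | None = None,
                     order: np.ndarray | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise pose RMSDs (Å) over the recorded set.

    Uses the rigid-body closed form
    RMSD²(i,j) = |Δc|² + (2 tr S − 2 tr(RᵢᵀRⱼS))/N with the second-moment
    matrix S of the LH reference coordinates carried by the recorded set.
    """
    n = rs.n
    if n < 2:
        raise ValueError("need at least two records for an RMSD matrix")
    idx = np.arange(n) if order is None else order
    pos = rs.r_pos[idx]
    rot = rs.r_rot[idx]
    rotS = rs.r_rotS[idx]
    from scipy.spatial.distance import cdist

    r2 = cdist(pos, pos, metric="sqeuclidean")
    cross = rot @ rotS.T  # tr(Ri^T Rj S); symmetric because S is
    r2 += (2.0 * rs.trS - 2.0 * cross) / rs.natoms
    np.fill_diagonal(r2, 0.0)
    return np.sqrt(np.maximum(r2, 0.0))


def cluster_recorded_set(
    rs: RecordedSet,
    k: int = 10,
    lh: LHModel | None = None,
) -> list[Cluster]:
    """Average-linkage clustering of the recorded set into k ranked groups.

    Records are put in a canonical order first, so the result is invariant
    to the insertion order of the set.  With fewer than k records every
    record becomes a singleton cluster (with a warning).
    """
    n = rs.n
    if n == 0:
        return []
    order = _canonical_order(rs)
    counts = rs.r_count[:n][order]
    energies = rs.r_energy[:n][order]
    total = float(counts.sum())
    if n < k:
        warnings.warn(f"only {n} records for k={k}; returning singleton clusters")
        labels = np.arange(n)
    elif n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        mat = pose_rmsd_matrix(rs, lh, order=order)
        Z = average(squareform(mat, checks=False))
        labels = fcluster(Z, t=min(k, n), criterion="maxclust")
    clusters = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        wsize = int(counts[members].sum())
        best = members[np.argmin(energies[members])]
        clusters.append(
            Cluster(
                member_record_ids=[int(order[m]) for m in members],
                weighted_size=wsize,
                rank=0,
                representative=int(order[best]),
                representative_energy=float(energies[best]),
                population_fraction=wsize / total if total else 0.0,
            )
        )
    clusters.sort(key=lambda c: (-c.weighted_size, c.representative_energy))
    for i, c in enumerate(clusters):
        c.rank = i + 1
    return clusters


def top_clusters(clusters: list[Cluster], n: int = 2) -> list[Cluster]:
    """The first n clusters by rank (all of them when n exceeds the count)."""
    return sorted(clusters, key=lambda c: c.rank)[:n]
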