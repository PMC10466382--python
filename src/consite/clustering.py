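"""Pool heteroatoms in the query frame and find conserved sites by
3D density clustering.

Heteroatoms of every superposed chain are grouped by species type
(``RESNAME-ATOMNAME``) and clustered per species with DBSCAN on their 3D
coordinates (default eps 0.9 A). The minimum-neighbor parameter ``n`` is
swept from 1 to ``N_sp`` (the number of superimposed chains, query
included); every distinct member set the sweep produces becomes one
candidate cluster. A cluster's *conservation* is its member count divided
by ``N_sp``: values near 1 flag species present at the same position in
nearly every homolog, the signature of a functional site.

This DBSCAN is implemented here rather than delegated to scikit-learn
because border-point assignment in textbook DBSCAN depends on the point
ordering; the variant below resolves border ties canonically (lowest
coordinate-sorted core neighbor) so that the output is invariant to input
order, a property the reports rely on. The scikit-learn implementation
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._util import round_half_up
from .homologs import ChainRef
from .structure_io import StructureModel, extract_heteroatoms
from .superposition import AlignmentResult, RigidTransform


@dataclass(frozen=True)
class PooledPoint:
    """One heteroatom, transformed into the query frame, with provenance."""

    species: str
    coord: np.ndarray
    source: ChainRef

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("pooled point coordinates must be finite")


@dataclass
class ClusteringParams:
    """DBSCAN radius, sweep ceiling and reporting floor.

    ``n_sweep_max`` doubles as ``N_sp``, the conservation denominator.
    """

    eps: float = 0.9  # Angstroms
    n_sweep_max: int = 1
    min_conservation_report: float = 0.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.n_sweep_max < 1:
            raise ValueError("n_sweep_max must be >= 1")


@dataclass
class SpeciesCluster:
    """A DBSCAN cluster of pooled heteroatoms of one species."""

    species: str
    members: list[PooledPoint]
    centroid: np.ndarray
    conservation: float
    internal_rmsd: float
    max_min_neighbors: int
    distinct_sources: int

    @property
    def n_members(self) -> int:
        return len(self.members)


def conservation(member_count: int, n_sp: int) -> Fraction:
    """Cluster conservation: member count over superimposed-chain count.

    Returned as an exact ratio; display rounding (2 decimals, half-up) is
    applied by :func:`reported_conservation`.
    """
    if n_sp < 1:
        raise ValueError("n_sp must be >= 1")
    if member_count < 0:
        raise ValueError("member_count must be >= 0")
    return Fraction(member_count, n_sp)


def reported_conservation(member_count: int, n_sp: int) -> float:
    """Conservation as reported: rounded to 2 decimals, half-up."""
    frac = conservation(member_count, n_sp)
    return round_half_up(frac.numerator / frac.denominator, 2)


def pool_heteroatoms(
    query: StructureModel,
    query_chain: str,
    aligned: Sequence[tuple[StructureModel, str, AlignmentResult, ChainRef]],
    include_waters: bool = True,
) -> dict[str, list[PooledPoint]]:
    """Collect heteroatoms of the query and all superposed homologs.

    Query heteroatoms enter untransformed; each homolog's heteroatoms are
    mapped into the query frame through its alignment transform. The
    grouping key is the species label; a species absent from the query but
    present in homologs is still pooled.
    """
    pooled: dict[str, list[PooledPoint]] = {}
    query_ref = ChainRef(query.pdb_id, query_chain)

    def _add(model, chain_id, transform: RigidTransform | None, ref):
        for label, atom in extract_heteroatoms(model, include_waters):
            if atom.chain_id != chain_id:
                continue
            coord = atom.coord if transform is None \
                else transform.apply(atom.coord)
            pooled.setdefault(label, []).append(
                PooledPoint(species=label, coord=coord, source=ref))

    _add(query, query_chain, None, query_ref)
    for model, chain_id, result, ref in aligned:
        _add(model, chain_id, result.transform, ref)
    return pooled


def _canonical_order(points: np.ndarray) -> np.ndarray:
    """Indices sorting points by (x, y, z); the canonical DBSCAN ordering."""
    return np.lexsort((points[:, 2], points[:, 1], points[:, 0]))


def dbscan3(points: np.ndarray, eps: float, min_n: int) -> np.ndarray:
    """Density-based clustering of 3D points; returns labels (-1 = noise).

    A point is a *core point* when it has at least ``min_n`` neighbors
    within ``eps`` (itself included); clusters are the maximal
    density-connected sets of core points plus their border points. Border
    points reachable from several clusters join the cluster of their
    lowest core neighbor under the canonical coordinate ordering, which
    makes the labeling invariant to input order.
    """
    points = np.asarray(points, dtype=float)
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    if eps <= 0:
        raise ValueError("eps must be positive")
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    order = _canonical_order(points)
    P = points[order]
    tree = cKDTree(P)
    neighbors = tree.query_ball_point(P, eps)
    core = np.array([len(nb) >= min_n for nb in neighbors])

    sorted_labels = np.full(n, -1, dtype=int)
    cluster_id = 0
    for start in range(n):
        if not core[start] or sorted_labels[start] != -1:
            continue
        queue = deque([start])
        sorted_labels[start] = cluster_id
        while queue:
            i = queue.popleft()
            for j in neighbors[i]:
                if core[j] and sorted_labels[j] == -1:
                    sorted_labels[j] = cluster_id
                    queue.append(j)
        cluster_id += 1
    for i in range(n):
        if core[i] or sorted_labels[i] != -1:
            continue
        core_neigh = [j for j in neighbors[i] if core[j]]
        if core_neigh:
            sorted_labels[i] = sorted_labels[min(core_neigh)]
    labels[order] = sorted_labels
    return labels


def _build_cluster(
    species: str,
    members: list[PooledPoint],
    n_sp: int,
    max_min_neighbors: int,
) -> SpeciesCluster:
    coords = np.array([p.coord for p in members])
    centroid = coords.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))
    sources = {(p.source.pdb_id, p.source.chain_id) for p in members}
    return SpeciesCluster(
        species=species,
        members=members,
        centroid=centroid,
        conservation=len(members) / n_sp,
        internal_rmsd=rmsd,
        max_min_neighbors=max_min_neighbors,
        distinct_sources=len(sources),
    )


def sweep_clusters(
    pooled: Mapping[str, Sequence[PooledPoint]],
    params: ClusteringParams,
) -> list[SpeciesCluster]:
    """Run the min-neighbor sweep per species and collect distinct clusters.

    For each species, DBSCAN runs at every ``min_n`` in 1..``n_sweep_max``;
    each distinct member set produced anywhere in the sweep becomes one
    :class:`SpeciesCluster` whose ``max_min_neighbors`` is the largest
    ``min_n`` still returning it. Clusters below the reporting floor are
    dropped; the list is sorted by conservation (descending), ties broken
    by species label then centroid.
    """
    n_sp = params.n_sweep_max
    clusters: list[SpeciesCluster] = []
    for species in sorted(pooled):
        points = list(pooled[species])
        if not points:
            continue
        coords = np.array([p.coord for p in points])
        canon = _canonical_order(coords)
        rank = {int(orig): r for r, orig in enumerate(canon)}
        seen: dict[frozenset[int], int] = {}
        for min_n in range(1, n_sp + 1):
            labels = dbscan3(coords, params.eps, min_n)
            for label in np.unique(labels):
                if label < 0:
                    continue
                member_set = frozenset(
                    rank[int(i)] for i in np.flatnonzero(labels == label))
                seen[member_set] = min_n  # sweep goes upward: last is max
        inv = {r: orig for orig, r in rank.items()}
        for member_set, max_n in seen.items():
            members = [points[inv[r]] for r in sorted(member_set)]
            cluster = _build_cluster(species, members, n_sp, max_n)
            if cluster.conservation < params.min_conservation_report:
                continue
            clusters.append(cluster)
    clusters.sort(key=lambda c: (-c.conservation, c.species,
                                 tuple(np.round(c.centroid, 6))))
    return clusters
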