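"""Characterize a predicted cluster's environment and score it against a
reference.

Covers the post-clustering questions a user asks of a predicted site:
which query residues coordinate it (contact list), how tight the cluster
is (within-cluster RMSD), how far the prediction lies from a native
reference atom (d_c), and what region was searched (bounding box).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .clustering import SpeciesCluster
from .structure_io import AtomRecord, StructureModel


@dataclass(frozen=True)
class ContactRecord:
    """Closest-atom contact between a cluster centroid and a query residue."""

    chain_id: str
    res_name: str
    res_seq: int
    atom_name: str
    distance: float  # Angstroms


@dataclass(frozen=True)
class ValidationMetrics:
    """Cluster tightness and distance to a native reference atom."""

    internal_rmsd: float
    d_c: float


def nearest_residues(
    query: StructureModel,
    centroid: np.ndarray,
    cutoff: float = 3.5,
    max_hits: int = 8,
) -> list[ContactRecord]:
    """Closest polymer residues to a point, one contact per residue.

    For every polymer residue only its closest atom is considered; hits
    beyond ``cutoff`` are dropped and the list is sorted by distance
    (ascending) and truncated to ``max_hits``. The defaults (3.5 A, 8
    hits) cover a typical metal coordination sphere.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    centroid = np.asarray(centroid, dtype=float)
    hits: list[ContactRecord] = []
    for chain_id in query.chains:
        for (cid, res_seq, _icode), res_name, atoms in \
                query.polymer_residues(chain_id):
            coords = np.array([a.coord for a in atoms])
            d = np.linalg.norm(coords - centroid, axis=1)
            k = int(np.argmin(d))
            if d[k] <= cutoff:
                hits.append(ContactRecord(
                    chain_id=cid, res_name=res_name, res_seq=res_seq,
                    atom_name=atoms[k].atom_name, distance=float(d[k])))
    hits.sort(key=lambda h: (h.distance, h.chain_id, h.res_seq, h.atom_name))
    return hits[:max_hits]


def distance_to_native(
    cluster: SpeciesCluster, native_atom: AtomRecord
) -> float:
    """d_c: Euclidean distance from a native reference atom to the centroid."""
    return float(np.linalg.norm(cluster.centroid - native_atom.coord))


def cluster_rmsd(cluster: SpeciesCluster) -> float:
    """Within-cluster RMSD: root-mean-square member-to-centroid distance."""
    coords = np.array([p.coord for p in cluster.members])
    centroid = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))


def validation_metrics(
    cluster: SpeciesCluster, native_atom: AtomRecord
) -> ValidationMetrics:
    return ValidationMetrics(
        internal_rmsd=cluster_rmsd(cluster),
        d_c=distance_to_native(cluster, native_atom),
    )


def analyzed_area(
    points: np.ndarray | Iterable[Sequence[float]] | StructureModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Tight axis-aligned bounding box of the searched coordinates.

    Accepts an (n, 3) array or a structure fragment; returns the
    (min corner, max corner) pair in Angstroms.
    """
    if isinstance(points, StructureModel):
        coords = np.array([a.coord for a in points.atoms()])
    else:
        coords = np.asarray(list(points) if not isinstance(points, np.ndarray)
                            else points, dtype=float)
    if coords.size == 0:
        raise ValueError("analyzed_area requires at least one point")
    coords = coords.reshape(-1, 3)
    return coords.min(axis=0), coords.max(axis=0)


def write_contacts(
    contacts_by_cluster: Sequence[tuple[int, Sequence[ContactRecord]]],
    path: str | Path,
) -> Path:
    """Write the per-cluster contact table as TSV (full precision)."""
    path = Path(path)
    lines = ["# consite cluster contacts",
             "# cluster_id\tchain\tres_name\tres_seq\tatom\tdistance"]
    for cluster_id, contacts in contacts_by_cluster:
        for c in contacts:
            lines.append("\t".join([
                str(cluster_id), c.chain_id, c.res_name, str(c.res_seq),
                c.atom_name, repr(c.distance)]))
    path.write_text("\n".join(lines) + "\n")
    return path
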