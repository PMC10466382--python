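"""Synthetic homolog families with known ground truth.

Real inputs to the pipeline are families of experimentally solved
homologous chains. This module emulates them procedurally so every stage
— transform recovery, heteroatom pooling, cluster membership, centroid
error — can be scored against an exact ground truth without any
downloaded data.

A family is built from one ideal alpha-helical C-alpha trace (rise 1.5 A,
100 degrees per residue, 2.3 A radius, i.e. ~3.8 A consecutive C-alpha
spacing). Each member is that chain with residues substituted at a given
rate, Gaussian coordinate noise, optionally a coherent distortion of the
region distal to the first planted site (emulating homologs that match
the query only near the binding site), planted heteroatoms, random decoy
heteroatoms, and finally a random proper rigid transform carrying it into
its own frame. The query is the unperturbed base chain and, by default,
carries no planted heteroatoms (an apo structure).

``n_members`` counts the whole family including the query, so it equals
``N_sp`` when every member superposes; a site with presence fraction p is
planted in ``round(p * n_members)`` members and its ideal conservation is
exactly p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AA1TO3, AtomRecord, StructureModel, write_structure
from .superposition import RigidTransform

_AA_LETTERS = sorted(AA1TO3)

QUERY_ID = "QRY"


@dataclass(frozen=True)
class PlantedSite:
    """A conserved heteroatom planted at a known position.

    ``jitter`` is the per-coordinate Gaussian sigma of the planted
    positions around ``position``; ``presence`` is the fraction of the
    family carrying the site.
    """

    species: str = "ZN-ZN"
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jitter: float = 0.2  # Angstroms
    presence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence <= 1.0:
            raise ValueError("presence must be in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for one synthetic family.

    ``n_members`` is the family size including the query. ``ca_noise`` is
    the per-coordinate Gaussian sigma applied to every homolog atom.
    ``distal_distortion`` (when positive) coherently displaces residues
    farther than ``distal_radius`` from the first planted site, ramping
    linearly up to the given amplitude at the far end of the chain.
    With ``apo_query`` the query never carries planted sites.
    """

    n_members: int = 20
    base_length: int = 60
    ca_noise: float = 0.3  # Angstroms
    mutation_rate: float = 0.1
    planted_sites: tuple[PlantedSite, ...] = (PlantedSite(),)
    decoys_per_member: int = 3
    seed: int = 0
    apo_query: bool = True
    distal_distortion: float = 0.0  # Angstroms
    distal_radius: float = 12.0  # Angstroms

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if self.base_length < 10:
            raise ValueError("base_length must be >= 10")
        for sigma in (self.ca_noise, self.distal_distortion):
            if sigma < 0:
                raise ValueError("noise amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline on a synthetic family."""

    transforms: dict[str, RigidTransform]  # member frame <- base frame
    carriers: dict[int, list[str]]  # site index -> member pdb_ids
    site_positions: dict[int, np.ndarray]  # base/query frame
    planted_counts: dict[str, int]  # species -> planted atoms (sites only)
    decoy_counts: dict[str, int]  # species -> decoy atoms


@dataclass
class Family:
    query: StructureModel
    homologs: list[StructureModel]
    ground_truth: GroundTruth

    @property
    def n_members(self) -> int:
        return len(self.homologs) + 1


def member_id(i: int) -> str:
    return QUERY_ID if i == 0 else f"HM{i:02d}"


def _helix_ca(length: int) -> np.ndarray:
    i = np.arange(length)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([
        2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def make_base_chain(spec: FamilySpec) -> StructureModel:
    """Deterministic ideal-helix C-alpha chain with a random sequence."""
    rng = np.random.default_rng([spec.seed, 0])
    letters = rng.choice(_AA_LETTERS, size=spec.base_length)
    coords = _helix_ca(spec.base_length)
    atoms = [
        AtomRecord(
            serial=k + 1, atom_name="CA", alt_loc="",
            res_name=AA1TO3[letters[k]], chain_id="A", res_seq=k + 1,
            insertion_code="", coord=coords[k], occupancy=1.0,
            element="C", is_het=False)
        for k in range(spec.base_length)
    ]
    return StructureModel(pdb_id=QUERY_ID, chains={"A": atoms})


def _carrier_ids(spec: FamilySpec) -> dict[int, list[str]]:
    """Choose which members carry each planted site.

    An apo query never carries; a holo query (``apo_query=False``) always
    does, with the remaining carriers drawn from the homologs.
    """
    carriers: dict[int, list[str]] = {}
    candidates = list(range(1, spec.n_members))
    for s, site in enumerate(spec.planted_sites):
        k = int(np.floor(site.presence * spec.n_members + 0.5))
        if k < 1:
            warnings.warn(
                f"site {s} ({site.species}): presence {site.presence} "
                f"rounds to no carriers; site omitted")
            carriers[s] = []
            continue
        fixed = [] if spec.apo_query else [0]
        # an apo query cannot carry: full presence means every homolog does
        k_random = min(k - len(fixed), len(candidates))
        rng = np.random.default_rng([spec.seed, 7, s])
        chosen = sorted(
            fixed + list(rng.choice(candidates, size=k_random,
                                    replace=False)))
        carriers[s] = [member_id(int(i)) for i in chosen]
    return carriers


def _het_atom(serial: int, species: str, coord: np.ndarray,
              res_seq: int) -> AtomRecord:
    res_name, atom_name = species.split("-", maxsplit=1)
    return AtomRecord(
        serial=serial, atom_name=atom_name, alt_loc="", res_name=res_name,
        chain_id="A", res_seq=res_seq, insertion_code="", coord=coord,
        occupancy=1.0, element=atom_name[:2], is_het=True)


def make_family(spec: FamilySpec) -> Family:
    """Generate one synthetic family plus its ground truth.

    Random streams are split per member (and separately for geometry,
    transform and heteroatoms) so that, e.g., changing
    ``decoys_per_member`` leaves every member's transform unchanged.
    """
    base = make_base_chain(spec)
    base_atoms = base.chains["A"]
    base_coords = np.array([a.coord for a in base_atoms])
    carriers = _carrier_ids(spec)
    site_positions = {
        s: np.asarray(site.position, dtype=float)
        for s, site in enumerate(spec.planted_sites)
    }
    bbox_lo = base_coords.min(axis=0) - 5.0
    bbox_hi = base_coords.max(axis=0) + 5.0

    # Precompute the distal ramp in the base frame (identical per member).
    ramp = np.zeros(len(base_atoms))
    if spec.distal_distortion > 0 and spec.planted_sites:
        d = np.linalg.norm(base_coords - site_positions[0], axis=1)
        over = np.clip(d - spec.distal_radius, 0.0, None)
        if over.max() > 0:
            ramp = spec.distal_distortion * over / over.max()

    transforms: dict[str, RigidTransform] = {}
    planted_counts: dict[str, int] = {}
    decoy_counts: dict[str, int] = {}
    decoy_species = (spec.planted_sites[0].species
                     if spec.planted_sites else "ZN-ZN")
    members: list[StructureModel] = []

    for i in range(spec.n_members):
        mid = member_id(i)
        rng_geom = np.random.default_rng([spec.seed, 1, i])
        rng_xform = np.random.default_rng([spec.seed, 2, i])
        rng_het = np.random.default_rng([spec.seed, 3, i])
        atoms: list[AtomRecord] = []
        if i == 0:
            atoms.extend(base_atoms)
        else:
            direction = rng_geom.normal(size=3)
            direction /= np.linalg.norm(direction)
            for k, atom in enumerate(base_atoms):
                res_name = atom.res_name
                if rng_geom.random() < spec.mutation_rate:
                    choices = [x for x in _AA_LETTERS
                               if AA1TO3[x] != res_name]
                    res_name = AA1TO3[rng_geom.choice(choices)]
                coord = (atom.coord
                         + rng_geom.normal(0.0, spec.ca_noise, size=3)
                         + ramp[k] * direction)
                atoms.append(replace(atom, res_name=res_name, coord=coord))
        serial = len(atoms)
        for s, site in enumerate(spec.planted_sites):
            if mid not in carriers[s]:
                continue
            pos = site_positions[s] + rng_het.normal(0.0, site.jitter, size=3)
            serial += 1
            atoms.append(_het_atom(serial, site.species, pos, 1001 + s))
            planted_counts[site.species] = \
                planted_counts.get(site.species, 0) + 1
        if i > 0:
            for k in range(spec.decoys_per_member):
                pos = rng_het.uniform(bbox_lo, bbox_hi)
                serial += 1
                atoms.append(_het_atom(serial, decoy_species, pos, 2001 + k))
                decoy_counts[decoy_species] = \
                    decoy_counts.get(decoy_species, 0) + 1

        if i == 0:
            transform = RigidTransform.identity()
        else:
            rotation = Rotation.random(rng=rng_xform).as_matrix()
            translation = rng_xform.uniform(-20.0, 20.0, size=3)
            transform = RigidTransform(rotation, translation)
            atoms = [replace(a, coord=transform.apply(a.coord))
                     for a in atoms]
        transforms[mid] = transform
        members.append(StructureModel(pdb_id=mid, chains={"A": atoms}))

    ground_truth = GroundTruth(
        transforms=transforms, carriers=carriers,
        site_positions=site_positions, planted_counts=planted_counts,
        decoy_counts=decoy_counts)
    return Family(query=members[0], homologs=members[1:],
                  ground_truth=ground_truth)


@dataclass
class FamilyFiles:
    directory: Path
    query_path: Path
    member_paths: dict[str, Path]
    clusters_path: Path
    ground_truth_path: Path


def write_family(family: Family, directory: str | Path) -> FamilyFiles:
    """Write a family as PDB files, a cluster file and a ground-truth TSV.

    The cluster file has the one-line, one-token-per-entity shape of the
    sequence-identity cluster files the pipeline consumes; output is
    byte-deterministic for a fixed spec.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    member_paths: dict[str, Path] = {}
    for model in [family.query, *family.homologs]:
        path = directory / f"{model.pdb_id}.pdb"
        write_structure(model, path)
        member_paths[model.pdb_id] = path
    tokens = [f"{family.query.pdb_id}_1"] + \
        [f"{m.pdb_id}_1" for m in family.homologs]
    clusters_path = directory / "clusters.txt"
    clusters_path.write_text(" ".join(tokens) + "\n")

    gt = family.ground_truth
    lines = ["# record\tid\tvalues"]
    for s, pos in gt.site_positions.items():
        vals = "\t".join(f"{v:.6f}" for v in pos)
        lines.append(f"site_position\t{s}\t{vals}")
    for s, ids in gt.carriers.items():
        lines.append(f"site_carriers\t{s}\t" + ",".join(ids))
    for mid, t in gt.transforms.items():
        vals = "\t".join(
            f"{v:.9f}" for v in
            np.concatenate([t.rotation.ravel(), t.translation]))
        lines.append(f"transform\t{mid}\t{vals}")
    ground_truth_path = directory / "ground_truth.tsv"
    ground_truth_path.write_text("\n".join(lines) + "\n")
    return FamilyFiles(
        directory=directory,
        query_path=member_paths[family.query.pdb_id],
        member_paths=member_paths,
        clusters_path=clusters_path,
        ground_truth_path=ground_truth_path)
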