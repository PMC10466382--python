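"""Read and write PDB-format structures and consite cluster reports.

Parsing is delegated to :mod:`gemmi`; on top of it this module performs a
strict column-validation pass (gemmi silently coerces malformed coordinate
fields to zero, which would corrupt a superposition without warning),
resolves alternate locations to a single conformer, and derives one-letter
sequences for the aligner.

Coordinates are Angstroms everywhere; no unit conversion happens anywhere
in the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np
import pandas as pd

from .errors import PDBParseError
from ._util import round_half_up

#: Residue names treated as water for the ``include_waters`` switch.
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})

#: Standard 20 amino acids; anything else in a polymer maps to 'X'.
AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}


@dataclass(frozen=True, eq=False)
class AtomRecord:
    """One ATOM/HETATM record after alternate-location resolution."""

    serial: int
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    coord: np.ndarray  # shape (3,), Angstroms
    occupancy: float
    element: str
    is_het: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinates must be finite")
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")
        if self.occupancy < 0:
            raise ValueError("occupancy must be >= 0")

    @property
    def species_label(self) -> str:
        """RESNAME-ATOMNAME label typing a heteroatom, e.g. ``HOH-O``."""
        return species_label(self.res_name, self.atom_name)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)


def species_label(res_name: str, atom_name: str) -> str:
    res_name = res_name.strip().upper()
    atom_name = atom_name.strip().upper()
    if not res_name or not atom_name:
        raise ValueError("species label components must be nonempty")
    return f"{res_name}-{atom_name}"


@dataclass
class StructureModel:
    """A parsed structure: per-chain atom lists plus header metadata.

    ``chains`` maps chain id to the atoms of that chain in file order.
    Only the first MODEL of a multi-model file is represented.
    """

    pdb_id: str
    chains: dict[str, list[AtomRecord]]
    metadata: list[str] = field(default_factory=list)  # HETNAM/FORMUL lines

    def atoms(self) -> Iterator[AtomRecord]:
        for atoms in self.chains.values():
            yield from atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(a) for a in self.chains.values())

    def polymer_residues(
        self, chain_id: str
    ) -> list[tuple[tuple[str, int, str], str, list[AtomRecord]]]:
        """Polymer residues of a chain, in file order.

        Returns ``(residue_key, res_name, atoms)`` triples; heteroatom
        residues are excluded.
        """
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in {self.pdb_id}")
        out: list[tuple[tuple[str, int, str], str, list[AtomRecord]]] = []
        index: dict[tuple[str, int, str], int] = {}
        for atom in self.chains[chain_id]:
            if atom.is_het:
                continue
            key = atom.residue_key
            if key not in index:
                index[key] = len(out)
                out.append((key, atom.res_name, []))
            out[index[key]][2].append(atom)
        return out

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of the polymer residues of a chain."""
        return "".join(
            AA3TO1.get(res_name, "X")
            for _, res_name, _ in self.polymer_residues(chain_id)
        )


def _validate_atom_lines(text: str) -> tuple[int, list[str]]:
    """Check fixed-column numeric fields and harvest header metadata.

    Returns (number of ATOM/HETATM lines seen, HETNAM/FORMUL lines).
    Raises :class:`PDBParseError` naming the offending line on malformed
    coordinate fields — gemmi alone would silently read them as 0.0.
    """
    n_atoms = 0
    meta: list[str] = []
    in_first_model = True
    seen_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            in_first_model = not seen_model
            seen_model = True
        elif rec.startswith("ENDMDL"):
            in_first_model = False
        elif rec in ("ATOM  ", "HETATM") or rec.rstrip() in ("ATOM", "HETATM"):
            n_atoms += 1
            if not in_first_model:
                continue
            if len(line) < 54:
                raise PDBParseError(
                    f"line {lineno}: truncated {rec.strip()} record"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed coordinate field "
                        f"{what!r}: {line[lo:hi]!r}"
                    ) from None
        elif rec in ("HETNAM", "FORMUL"):
            meta.append(line.rstrip())
    return n_atoms, meta


def _resolve_altlocs(records: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom: highest occupancy, ties by file order."""
    best: dict[tuple, int] = {}
    for i, rec in enumerate(records):
        key = (rec.chain_id, rec.res_seq, rec.insertion_code,
               rec.res_name, rec.atom_name)
        if key not in best or rec.occupancy > records[best[key]].occupancy:
            best[key] = i
    keep = sorted(best.values())
    return [records[i] for i in keep]


def parse_pdb(
    text: str, model_policy: str = "first", pdb_id: str = ""
) -> StructureModel:
    """Parse fixed-column PDB text into a :class:`StructureModel`.

    Parameters
    ----------
    text:
        PDB-format content with at least one ATOM/HETATM record.
    model_policy:
        ``"first"`` (the only supported policy): keep MODEL 1 of a
        multi-model (e.g. NMR) entry, matching the single-conformer
        assumption of rigid superposition.
    pdb_id:
        Identifier stored on the model; defaults to the HEADER id when
        present.
    """
    if model_policy != "first":
        raise ValueError(f"unknown model_policy {model_policy!r}")
    n_atoms, meta = _validate_atom_lines(text)
    if n_atoms == 0:
        raise PDBParseError("no atoms")
    st = gemmi.read_pdb_string(text)
    if not pdb_id:
        pdb_id = st.name.strip() or "UNKN"
    model = st[0]
    records: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            for atom in res:
                alt = atom.altloc if atom.altloc not in ("\x00",) else ""
                records.append(AtomRecord(
                    serial=atom.serial,
                    atom_name=atom.name.strip().upper(),
                    alt_loc=alt.strip(),
                    res_name=res.name.strip().upper(),
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    element=atom.element.name.upper(),
                    is_het=(res.het_flag == "H"),
                ))
    records = _resolve_altlocs(records)
    chains: dict[str, list[AtomRecord]] = {}
    for rec in records:
        chains.setdefault(rec.chain_id, []).append(rec)
    return StructureModel(pdb_id=pdb_id, chains=chains, metadata=meta)


def read_structure(path: str | Path, pdb_id: str = "") -> StructureModel:
    path = Path(path)
    return parse_pdb(path.read_text(), pdb_id=pdb_id or path.stem.upper())


def extract_heteroatoms(
    model: StructureModel, include_waters: bool = True
) -> list[tuple[str, AtomRecord]]:
    """Type every HETATM as ``RESNAME-ATOMNAME`` (waters optionally dropped).

    Each heteroatom yields exactly one ``(species_label, atom)`` entry;
    polymer atoms are never returned.
    """
    out = []
    for atom in model.atoms():
        if not atom.is_het:
            continue
        if not include_waters and atom.res_name in WATER_RESNAMES:
            continue
        out.append((atom.species_label, atom))
    return out


def _format_atom_line(rec: AtomRecord, serial: int) -> str:
    name = rec.atom_name
    # Standard name justification: element symbols of one letter start in
    # column 14, two-letter elements (and 4-char names) in column 13.
    if len(name) < 4 and len(rec.element) < 2:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    record = "HETATM" if rec.is_het else "ATOM  "
    alt = rec.alt_loc or " "
    icode = rec.insertion_code or " "
    x, y, z = rec.coord
    return (
        f"{record}{min(serial, 99999):5d} {name_field}{alt:1s}"
        f"{rec.res_name:>3s} {rec.chain_id:1s}{rec.res_seq:4d}{icode:1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{rec.occupancy:6.2f}{0.0:6.2f}"
        f"          {rec.element:>2s}"
    )


def write_structure(model: StructureModel, path: str | Path | None = None) -> str:
    """Serialize a model as fixed-column PDB text (and optionally a file).

    Round-trip contract: re-parsing preserves names, flags and integer
    fields exactly, and coordinates to 3 decimals.
    """
    if model.n_atoms == 0:
        raise PDBParseError("no atoms")
    buf = io.StringIO()
    for line in model.metadata:
        buf.write(line + "\n")
    serial = 0
    for chain_atoms in model.chains.values():
        for rec in chain_atoms:
            serial += 1
            buf.write(_format_atom_line(rec, rec.serial or serial) + "\n")
    buf.write("END\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Cluster report


REPORT_COLUMNS = [
    "cluster_id", "species", "conservation", "distinct_sources", "n_members",
    "max_min_neighbors", "centroid_x", "centroid_y", "centroid_z",
    "member_x", "member_y", "member_z", "source_pdb", "source_chain",
]


def _cluster_sort_key(cluster) -> tuple:
    return (
        -cluster.conservation,
        cluster.species,
        tuple(np.round(cluster.centroid, 6)),
    )


def write_cluster_report(
    clusters: Iterable, run_meta: Mapping[str, object], path: str | Path
) -> Path:
    """Write the tab-separated cluster report.

    Header lines are ``#``-prefixed ``key<TAB>value`` pairs (query id, mode,
    eps, N_sp, radius, ...); each subsequent row describes one cluster
    member with its cluster's id, species, conservation and centroid plus
    the member position and source chain. Clusters are ordered by
    conservation (descending), ties broken by species label then centroid;
    the ordering is a pure function of cluster contents so identical runs
    produce byte-identical reports.
    """
    path = Path(path)
    ordered = sorted(clusters, key=_cluster_sort_key)
    lines = ["# consite cluster report"]
    for key, value in run_meta.items():
        lines.append(f"# {key}\t{value}")
    lines.append("# " + "\t".join(REPORT_COLUMNS))
    for cid, cluster in enumerate(ordered, start=1):
        cons = f"{round_half_up(cluster.conservation, 2):.2f}"
        cx, cy, cz = (f"{v:.3f}" for v in cluster.centroid)
        members = sorted(
            cluster.members,
            key=lambda p: (p.source.pdb_id, p.source.chain_id,
                           tuple(p.coord)),
        )
        for point in members:
            mx, my, mz = (f"{v:.3f}" for v in point.coord)
            lines.append("\t".join([
                str(cid), cluster.species, cons,
                str(cluster.distinct_sources), str(len(cluster.members)),
                str(cluster.max_min_neighbors),
                cx, cy, cz, mx, my, mz,
                point.source.pdb_id, point.source.chain_id,
            ]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_cluster_report(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read back a cluster report as (header metadata, member-row table)."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if "\t" in body and not body.startswith("cluster_id"):
                key, _, value = body.partition("\t")
                meta[key] = value
        elif line.strip():
            rows.append(line)
    if rows:
        df = pd.read_csv(
            io.StringIO("\n".join(rows)), sep="\t", names=REPORT_COLUMNS
        )
    else:
        df = pd.DataFrame(columns=REPORT_COLUMNS)
    return meta, df
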