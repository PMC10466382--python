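"""Select the homologous chains to superpose from a sequence-identity
cluster file.

The cluster file follows the RCSB sequence-identity-cluster dialect: one
whitespace-separated cluster of identifiers per line, grouped at a chosen
identity cutoff (30, 40, 50, 70, 90, 95 or 100 percent), or a hand-written
custom file of the same shape. Two token forms are understood:

* ``PDBID_n`` — a polymer entity; it expands to chains through a caller
  supplied ``chain_map`` built from local files (no web access).
* ``PDBID.C`` — an explicit chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ClusterFileError

VALID_CUTOFFS = (30, 40, 50, 70, 90, 95, 100)


@dataclass(frozen=True)
class ChainRef:
    """One chain of one PDB entry, backed by a local file."""

    pdb_id: str
    chain_id: str
    source_path: Path | None = None

    def __post_init__(self) -> None:
        if not self.pdb_id:
            raise ValueError("pdb_id must be nonempty")

    @property
    def label(self) -> str:
        return f"{self.pdb_id}.{self.chain_id}"


@dataclass
class HomologSet:
    """The chains that will be superposed onto the query.

    ``n_sp`` — the total number of superimposed chains, query included —
    is the conservation denominator and the ceiling of the DBSCAN
    min-neighbor sweep.
    """

    query: ChainRef
    members: list[ChainRef] = field(default_factory=list)
    identity_cutoff: int | str = "custom"
    one_chain_per_entry: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for ref in self.members:
            key = (ref.pdb_id, ref.chain_id)
            if key in seen:
                raise ValueError(f"duplicate member {ref.label}")
            seen.add(key)
        qkey = (self.query.pdb_id, self.query.chain_id)
        if qkey in seen:
            raise ValueError("query must not appear among members")

    @property
    def n_sp(self) -> int:
        return len(self.members) + 1


def parse_cluster_file(text: str, query_token: str) -> list[str]:
    """Return the tokens of the first cluster line containing the query.

    Token matching is exact; the query token itself is included in the
    returned list.
    """
    for line in text.splitlines():
        tokens = line.split()
        if query_token in tokens:
            return tokens
    raise ClusterFileError(
        f"query {query_token!r} not in cluster file"
    )


def find_query_token(text: str, pdb_id: str) -> str:
    """Locate the token of an entry in a cluster file by its PDB id.

    Matches ``PDBID``, ``PDBID_n`` and ``PDBID.C`` tokens
    case-insensitively; the first match wins.
    """
    want = pdb_id.upper()
    for line in text.splitlines():
        for token in line.split():
            head = token.split("_")[0].split(".")[0].upper()
            if head == want:
                return token
    raise ClusterFileError(f"query {pdb_id!r} not in cluster file")


def resolve_members(
    tokens: Sequence[str],
    chain_map: Mapping[str, Sequence[ChainRef]],
    one_chain_per_entry: bool,
    query_token: str,
    identity_cutoff: int | str = "custom",
) -> HomologSet:
    """Expand cluster-file tokens into a :class:`HomologSet`.

    Every token must be resolvable through ``chain_map`` (built by the
    caller from local files). Duplicate ``(pdb_id, chain_id)`` expansions
    are dropped, first occurrence wins, so the member order is the token
    order and then the chain order within each token. With
    ``one_chain_per_entry`` only the alphabetically first chain of each PDB
    entry survives (the query's own entry counts as taken by the query).
    """
    if query_token not in tokens:
        raise ClusterFileError(f"query {query_token!r} not among tokens")
    missing = [t for t in tokens if t not in chain_map]
    if missing:
        raise ClusterFileError(
            "unresolvable cluster tokens: " + ", ".join(missing)
        )
    query_chains = sorted(
        chain_map[query_token], key=lambda r: (r.pdb_id, r.chain_id)
    )
    if not query_chains:
        raise ClusterFileError(f"query token {query_token!r} maps to no chain")
    query = query_chains[0]

    expanded: list[ChainRef] = []
    seen: set[tuple[str, str]] = {(query.pdb_id, query.chain_id)}
    taken_entries: set[str] = {query.pdb_id}
    for token in tokens:
        refs = chain_map[token]
        if one_chain_per_entry:
            by_entry: dict[str, ChainRef] = {}
            for ref in sorted(refs, key=lambda r: (r.pdb_id, r.chain_id)):
                by_entry.setdefault(ref.pdb_id, ref)
            refs = list(by_entry.values())
        for ref in refs:
            key = (ref.pdb_id, ref.chain_id)
            if key in seen:
                continue
            if one_chain_per_entry and ref.pdb_id in taken_entries:
                continue
            seen.add(key)
            taken_entries.add(ref.pdb_id)
            expanded.append(ref)
    return HomologSet(
        query=query,
        members=expanded,
        identity_cutoff=identity_cutoff,
        one_chain_per_entry=one_chain_per_entry,
    )
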