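"""End-to-end orchestration: homolog resolution, superposition, pooling,
clustering, site analysis and report writing.

Outputs are deterministic functions of the inputs and configuration (no
timestamps), so identical runs produce byte-identical report files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import site_analysis
from .clustering import ClusteringParams, SpeciesCluster, pool_heteroatoms, \
    sweep_clusters
from .errors import ConsiteError, MissingInputError, SuperpositionError
from .homologs import ChainRef, HomologSet, find_query_token, \
    parse_cluster_file, resolve_members
from .structure_io import StructureModel, read_structure, \
    write_cluster_report, _cluster_sort_key
from .superposition import AlignmentResult, SiteSpec, SuperpositionParams, \
    superpose_local, superpose_whole


class NoHomologsSuperposedError(ConsiteError):
    """Every member failed to superpose; there is nothing to cluster."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    query_path: Path
    homolog_list_path: Path
    structures_dir: Path
    output_dir: Path
    query_chain: str | None = None  # default: first polymer chain
    mode: str = "whole"  # "whole" | "local"
    site: SiteSpec | None = None
    superposition: SuperpositionParams = field(
        default_factory=SuperpositionParams)
    eps: float = 0.9
    min_conservation: float = 0.0
    include_waters: bool = True
    one_chain_per_entry: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("query_path", "homolog_list_path", "structures_dir",
                     "output_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.mode not in ("whole", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "local" and self.site is None:
            raise ValueError("local mode requires a binding site")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class PipelineResult:
    homolog_set: HomologSet
    aligned: list[tuple[StructureModel, str, AlignmentResult, ChainRef]]
    skipped: list[tuple[ChainRef, str]]
    n_sp: int
    clusters: list[SpeciesCluster]
    report_path: Path
    contacts_path: Path
    log_path: Path


def _build_chain_map(
    tokens: list[str],
    query_token: str,
    query_path: Path,
    structures_dir: Path,
    cache: dict[Path, StructureModel],
) -> dict[str, list[ChainRef]]:
    """Resolve cluster-file tokens to chains of local PDB files.

    Entity tokens (``PDBID_n``) expand to every polymer chain of
    ``structures_dir/PDBID.pdb`` (without web access the entity-to-chain
    mapping is unknown, so the whole file stands in for the entity);
    explicit ``PDBID.C`` tokens name one chain. The query token always
    resolves through the query file itself.
    """

    def _load(path: Path) -> StructureModel:
        if path not in cache:
            if not path.is_file():
                raise MissingInputError(f"structure file not found: {path}")
            cache[path] = read_structure(path)
        return cache[path]

    chain_map: dict[str, list[ChainRef]] = {}
    for token in tokens:
        head = token.split("_")[0].split(".")[0]
        if token == query_token:
            path = query_path
        else:
            candidates = [structures_dir / f"{case(head)}.pdb"
                          for case in (str, str.upper, str.lower)]
            path = next((p for p in candidates if p.is_file()),
                        candidates[0])
        model = _load(path)
        if "." in token:
            chain_id = token.split(".", maxsplit=1)[1]
            if chain_id not in model.chains:
                raise MissingInputError(
                    f"chain {chain_id!r} of token {token!r} not in {path}")
            refs = [ChainRef(model.pdb_id, chain_id, path)]
        else:
            refs = [ChainRef(model.pdb_id, cid, path)
                    for cid in sorted(model.chains)
                    if model.polymer_residues(cid)]
        chain_map[token] = refs
    return chain_map


def _default_chain(model: StructureModel) -> str:
    for cid in model.chains:
        if model.polymer_residues(cid):
            return cid
    raise ConsiteError(f"{model.pdb_id} has no polymer chain")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full conserved-site detection pipeline.

    Per-homolog superposition failures are logged and skipped (reducing
    ``N_sp`` accordingly); the run only aborts when no member superposes
    at all.
    """
    for path in (config.query_path, config.homolog_list_path):
        if not Path(path).is_file():
            raise MissingInputError(f"input file not found: {path}")
    if not config.structures_dir.is_dir():
        raise MissingInputError(
            f"structures directory not found: {config.structures_dir}")

    cache: dict[Path, StructureModel] = {}
    query = read_structure(config.query_path)
    cache[config.query_path] = query
    query_chain = config.query_chain or _default_chain(query)

    cluster_text = config.homolog_list_path.read_text()
    query_token = find_query_token(cluster_text, query.pdb_id)
    tokens = parse_cluster_file(cluster_text, query_token)
    chain_map = _build_chain_map(tokens, query_token, config.query_path,
                                 config.structures_dir, cache)
    homolog_set = resolve_members(
        tokens, chain_map, config.one_chain_per_entry, query_token)

    aligned: list[tuple[StructureModel, str, AlignmentResult, ChainRef]] = []
    skipped: list[tuple[ChainRef, str]] = []
    for ref in homolog_set.members:
        model = cache[ref.source_path]
        try:
            if config.mode == "local":
                result = superpose_local(
                    query, query_chain, config.site, model, ref.chain_id,
                    config.superposition)
            else:
                result = superpose_whole(
                    query, query_chain, model, ref.chain_id,
                    config.superposition)
        except SuperpositionError as exc:
            skipped.append((ref, str(exc)))
            continue
        aligned.append((model, ref.chain_id, result, ref))
    if not aligned:
        raise NoHomologsSuperposedError("no homologs superposed")

    n_sp = len(aligned) + 1
    pooled = pool_heteroatoms(query, query_chain, aligned,
                              config.include_waters)
    clusters = sweep_clusters(pooled, ClusteringParams(
        eps=config.eps, n_sweep_max=n_sp,
        min_conservation_report=config.min_conservation))
    clusters = sorted(clusters, key=_cluster_sort_key)

    config.output_dir.mkdir(parents=True, exist_ok=True)
    radius = (config.superposition.local_radius
              if config.mode == "local" else "-")
    run_meta = {
        "query_id": query.pdb_id,
        "query_chain": query_chain,
        "mode": config.mode,
        "site": str(config.site) if config.site else "-",
        "eps": config.eps,
        "n_sp": n_sp,
        "radius": radius,
        "include_waters": config.include_waters,
        "one_chain_per_entry": config.one_chain_per_entry,
        "min_conservation": config.min_conservation,
        "seed": config.seed,
    }
    report_path = write_cluster_report(
        clusters, run_meta, config.output_dir / "clusters.tsv")
    contacts = [
        (cid, site_analysis.nearest_residues(query, cluster.centroid))
        for cid, cluster in enumerate(clusters, start=1)
    ]
    contacts_path = site_analysis.write_contacts(
        contacts, config.output_dir / "contacts.tsv")

    log_lines = ["# consite run log"]
    for key, value in run_meta.items():
        log_lines.append(f"param\t{key}\t{value}")
    for param, value in vars(config.superposition).items():
        log_lines.append(f"param\tsuperposition.{param}\t{value}")
    for _, chain_id, result, ref in aligned:
        log_lines.append(
            f"superposed\t{ref.label}\trmsd={result.rmsd:.4f}"
            f"\tpairs={result.n_pairs_final}/{result.n_pairs_initial}"
            f"\tcycles={result.cycles_run}")
    for ref, reason in skipped:
        log_lines.append(f"skipped\t{ref.label}\t{reason}")
    log_lines.append(f"n_clusters\t{len(clusters)}")
    log_path = config.output_dir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        homolog_set=homolog_set, aligned=aligned, skipped=skipped,
        n_sp=n_sp, clusters=clusters, report_path=report_path,
        contacts_path=contacts_path, log_path=log_path)
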