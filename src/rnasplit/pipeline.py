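"""End-to-end orchestration: parse → filter → cluster → search → split.

A single :class:`PipelineConfig` drives all five stages; every stage writes
its output under the run directory so later stages are resumable from
intermediate files, and a run manifest records parameters and the per-stage
counts (chains parsed, removals per filter, clusters, edges, components,
split sizes).

Homology hits are cached per representative sequence (keyed by a SHA-256 of
the sequence plus a database tag) so that routine updates — a handful of new
structures against an unchanged family database — re-search only the new
representatives.  Changing the database tag invalidates the whole cache.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from . import __version__
from .clustering import (
    SequenceCluster,
    cluster_sequences,
    write_membership_json,
    write_representatives_fasta,
)
from .filtering import FilterConfig, filter_chains
from .graph_split import (
    DEFAULT_E_THRESHOLD,
    STRICT_E_THRESHOLD,
    build_graph,
    emit_hierarchy,
    find_components,
    split_components,
    write_edge_list,
    write_hierarchy,
    write_split_lists,
)
from .homology import (
    HitTable,
    HomologyHit,
    read_hits_tsv,
    two_pass_search,
    write_hits_tsv,
)
from .mmcif_io import (
    load_component_dictionary,
    parse_directory,
    write_chain_json,
    write_fasta,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mmcif_dir: str
    dictionary: str
    out_dir: str
    tblout: str | None = None          # precomputed hit table (tblout or TSV)
    cm_database: str | None = None     # else: run the search engine
    engine_path: str = "cmscan"
    nmr_resolution_zero: bool = False
    filter: FilterConfig = field(default_factory=FilterConfig)
    identity: float = 0.99
    cluster_engine: str = "internal"
    e_threshold: float = DEFAULT_E_THRESHOLD
    strict_e_threshold: float = STRICT_E_THRESHOLD
    train_fraction: float = 0.70
    zero_policy: str = "test"
    cache_dir: str | None = None

    def __post_init__(self) -> None:
        if self.tblout is None and self.cm_database is None:
            raise ValueError("supply either a precomputed hit table or a cm database")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a JSON config file; the ``filter`` key nests FilterConfig fields."""
        with open(path) as fh:
            raw = json.load(fh)
        filt = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=filt, **raw)


def _sequence_key(sequence: str, db_tag: str) -> str:
    return hashlib.sha256(f"{db_tag}\n{sequence}".encode()).hexdigest()


def cached_two_pass_search(
    clusters: Sequence[SequenceCluster],
    cm_database: str | Path,
    cache_dir: str | Path,
    engine_path: str = "cmscan",
    runner: Callable[[list[str]], None] | None = None,
    work_dir: str | Path | None = None,
    db_tag: str | None = None,
) -> HitTable:
    """Two-pass search that skips representatives already in the cache.

    The cache holds one JSON file per (sequence, database-tag) pair with the
    hits found for that sequence; cached hits are re-labelled with the current
    cluster id on reuse, so renamed clusters do not trigger re-searches.
    """
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    db_tag = db_tag or Path(cm_database).name
    cached_hits: list[HomologyHit] = []
    cached_ids: set[str] = set()
    to_search: list[SequenceCluster] = []
    for cl in clusters:
        entry = cache / f"{_sequence_key(cl.representative.sequence, db_tag)}.json"
        if entry.exists():
            cached_ids.add(cl.cluster_id)
            for h in json.loads(entry.read_text()):
                cached_hits.append(HomologyHit(cluster_id=cl.cluster_id, **h))
        else:
            to_search.append(cl)

    table = HitTable(hits=cached_hits)
    table.searched |= cached_ids
    if to_search:
        work = Path(work_dir) if work_dir else cache / "work"
        work.mkdir(parents=True, exist_ok=True)
        fasta = work / "new_representatives.fasta"
        write_representatives_fasta(to_search, fasta)
        fresh = two_pass_search(
            fasta, cm_database, engine_path=engine_path, runner=runner, work_dir=work
        )
        by_cluster: dict[str, list[dict]] = {cl.cluster_id: [] for cl in to_search}
        for h in fresh.hits:
            by_cluster[h.cluster_id].append(
                {"family_accession": h.family_accession, "family_name": h.family_name,
                 "e_value": h.e_value, "bit_score": h.bit_score, "pass_index": h.pass_index}
            )
        for cl in to_search:
            entry = cache / f"{_sequence_key(cl.representative.sequence, db_tag)}.json"
            entry.write_text(json.dumps(by_cluster[cl.cluster_id]))
        table = table.merged_with(fresh)
    return table


def run_pipeline(
    config: PipelineConfig,
    runner: Callable[[list[str]], None] | None = None,
) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/5: parsing %s", config.mmcif_dir)
    try:
        mod_map = load_component_dictionary(config.dictionary)
        chains = parse_directory(
            config.mmcif_dir, mod_map, nmr_resolution_zero=config.nmr_resolution_zero
        )
    except Exception as exc:
        raise RuntimeError(f"parsing stage failed: {exc}") from exc
    write_fasta(chains, out / "chains.fasta")
    write_chain_json(chains, out / "chains.json")

    logger.info("stage 2/5: filtering %d chains", len(chains))
    kept, report = filter_chains(chains, config.filter)
    report.write_json(out / "filter_report.json")
    write_fasta(kept, out / "kept.fasta")

    logger.info("stage 3/5: clustering %d chains", len(kept))
    clusters = cluster_sequences(kept, identity=config.identity, engine=config.cluster_engine)
    write_membership_json(clusters, out / "clusters.json")
    write_representatives_fasta(clusters, out / "representatives.fasta")

    logger.info("stage 4/5: homology hits")
    try:
        if config.tblout is not None:
            from .homology import parse_tblout

            source = Path(config.tblout)
            if source.suffix == ".tsv":
                hit_table = read_hits_tsv(source)
            else:
                hit_table = parse_tblout(source)
            hit_table.searched |= {cl.cluster_id for cl in clusters}
        elif config.cache_dir is not None:
            hit_table = cached_two_pass_search(
                clusters, config.cm_database, config.cache_dir,
                engine_path=config.engine_path, runner=runner, work_dir=out / "search",
            )
        else:
            fasta = out / "representatives.fasta"
            hit_table = two_pass_search(
                fasta, config.cm_database, engine_path=config.engine_path,
                runner=runner, work_dir=out / "search",
            )
    except Exception as exc:
        raise RuntimeError(f"homology stage failed: {exc}") from exc
    write_hits_tsv(hit_table, out / "hits.tsv")

    logger.info("stage 5/5: graph, components, split")
    bipartite = build_graph(clusters, hit_table, e_threshold=config.e_threshold)
    sizes = {cl.cluster_id: cl.n_chains for cl in clusters}
    components = find_components(bipartite, cluster_sizes=sizes)
    split = split_components(
        components, train_fraction=config.train_fraction, zero_policy=config.zero_policy
    )
    write_edge_list(bipartite, out / "graph_edges.tsv")
    hierarchy = emit_hierarchy(
        components, split, clusters, hit_table, strict_e=config.strict_e_threshold
    )
    write_hierarchy(hierarchy, out / "hierarchy.json")
    write_split_lists(components, split, clusters, out)

    comp0 = next((c for c in components if c.index == 0), None)
    manifest = {
        "tool_version": __version__,
        "parameters": {
            "identity": config.identity,
            "e_threshold": config.e_threshold,
            "strict_e_threshold": config.strict_e_threshold,
            "train_fraction": config.train_fraction,
            "zero_policy": config.zero_policy,
            "nmr_resolution_zero": config.nmr_resolution_zero,
            "filter": asdict(config.filter),
        },
        "counts": {
            "chains_parsed": len(chains),
            "chains_kept": len(kept),
            "chains_rejected": report.n_rejected,
            "rejections_per_reason": report.counts,
            "clusters": len(clusters),
            "families": len(bipartite.family_nodes),
            "edges": bipartite.n_edges,
            "components": sum(1 for c in components if c.index > 0),
            "component0_clusters": comp0.n_sequences if comp0 else 0,
            "train_components": len(split.train),
            "test_components": len(split.test),
            "train_fraction_achieved": split.train_fraction_achieved,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
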