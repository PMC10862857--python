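"""Bipartite homology graph, Components, and leakage-free splitting.

The central construction: every sequence cluster and every RNA family with a
qualifying homology hit becomes a node in an undirected, unweighted bipartite
graph; an edge joins a cluster to a family when any hit between them has
E-value at or below the threshold (a deliberately generous default of 1.0, so
that missing a potential homology is traded against false-positive edges).

Maximally connected subgraphs of this graph — Components — share no family
with any other Component, so any assignment of whole Components to training,
validation or testing sets is free of structural-homology leakage.
Components are ranked by the number of clusters they contain; Component #0 is
special and collects every cluster with no family hit at the threshold
(synthetic constructs, mRNA fragments, unclassifiable short chains).

The splitter greedily assigns the largest Components to the training bin
until the requested fraction of clusters is reached; everything else — always
including Component #0 unless it is ignored outright — goes to the test bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .clustering import SequenceCluster
from .homology import FAMILY_ACCESSION_RE, HitTable

DEFAULT_E_THRESHOLD = 1.0
STRICT_E_THRESHOLD = 1e-3


@dataclass
class BipartiteGraph:
    """Cluster–family graph at a fixed E-value threshold."""

    graph: nx.Graph
    e_threshold: float

    @property
    def cluster_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "cluster"}

    @property
    def family_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "family"}

    @property
    def edges(self) -> set[tuple[str, str]]:
        out = set()
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["kind"] == "cluster":
                out.add((u, v))
            else:
                out.add((v, u))
        return out

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class Component:
    """A maximally connected subgraph: the unit of train/test assignment.

    ``index`` 0 is reserved for the edgeless clusters; indices 1..K are
    assigned by cluster count descending.
    """

    index: int
    cluster_ids: frozenset[str]
    family_accessions: frozenset[str] = frozenset()
    n_chains: int = 0

    @property
    def n_sequences(self) -> int:
        return len(self.cluster_ids)


@dataclass
class SplitResult:
    train: list[int]
    test: list[int]
    train_fraction_achieved: float
    target_fraction: float
    zero_policy: str
    exhausted: bool = False

    def to_dict(self) -> dict:
        return {
            "train": self.train,
            "test": self.test,
            "train_fraction_achieved": self.train_fraction_achieved,
            "target_fraction": self.target_fraction,
            "zero_policy": self.zero_policy,
            "exhausted": self.exhausted,
        }


def build_graph(
    clusters: Sequence[SequenceCluster] | Sequence[str],
    hit_table: HitTable,
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> BipartiteGraph:
    """Construct the bipartite graph from clusters and a hit table.

    An edge (cluster, family) exists iff some hit between them has
    ``e_value <= e_threshold`` (inclusive boundary); multiple qualifying hits
    collapse to a single edge.  Clusters without qualifying hits remain as
    isolated nodes.  A hit naming a cluster not in ``clusters`` is a pipeline
    wiring bug and raises.
    """
    cluster_ids = [
        c.cluster_id if isinstance(c, SequenceCluster) else str(c) for c in clusters
    ]
    if len(set(cluster_ids)) != len(cluster_ids):
        raise ValueError("duplicate cluster ids")
    known = set(cluster_ids)
    g = nx.Graph()
    g.add_nodes_from(cluster_ids, kind="cluster")
    for hit in hit_table.hits:
        if hit.cluster_id not in known:
            raise ValueError(f"hit references unknown cluster {hit.cluster_id!r}")
        if hit.e_value <= e_threshold:
            if hit.family_accession not in g:
                g.add_node(hit.family_accession, kind="family")
            g.add_edge(hit.cluster_id, hit.family_accession)
    return BipartiteGraph(graph=g, e_threshold=e_threshold)


def find_components(
    bipartite: BipartiteGraph,
    cluster_sizes: Mapping[str, int] | None = None,
) -> list[Component]:
    """Extract ranked Components from the bipartite graph.

    Component #0 gathers all isolated cluster nodes (emitted even when empty,
    provided the graph has any cluster nodes); connected subgraphs with edges
    are indexed 1..K by cluster count descending, ties broken by smallest
    member cluster id.  Family-only components cannot occur by construction
    (family nodes are only added with an edge) and are dropped defensively.
    ``cluster_sizes`` (cluster id → member chain count) fills ``n_chains``.
    """
    g = bipartite.graph
    sizes = cluster_sizes or {}

    def chains_in(ids) -> int:
        return sum(sizes.get(c, 1) for c in ids)

    isolated = {
        n for n, d in g.nodes(data=True) if d["kind"] == "cluster" and g.degree[n] == 0
    }
    connected: list[tuple[frozenset[str], frozenset[str]]] = []
    for nodes in nx.connected_components(g):
        clus = frozenset(n for n in nodes if g.nodes[n]["kind"] == "cluster")
        fams = frozenset(n for n in nodes if g.nodes[n]["kind"] == "family")
        if not clus:  # family-only: excluded
            continue
        if clus <= isolated:
            continue
        connected.append((clus, fams))
    connected.sort(key=lambda cf: (-len(cf[0]), min(cf[0])))

    components: list[Component] = []
    if g.number_of_nodes() > 0:
        components.append(
            Component(index=0, cluster_ids=frozenset(isolated), n_chains=chains_in(isolated))
        )
    for i, (clus, fams) in enumerate(connected, start=1):
        components.append(
            Component(index=i, cluster_ids=clus, family_accessions=fams,
                      n_chains=chains_in(clus))
        )
    assert_no_leakage(components)
    return components


def assert_no_leakage(components: Sequence[Component]) -> None:
    """Raise if any family accession occurs in more than one Component."""
    seen: dict[str, int] = {}
    for comp in components:
        for fam in comp.family_accessions:
            if fam in seen and seen[fam] != comp.index:
                raise AssertionError(
                    f"family {fam} leaks across components {seen[fam]} and {comp.index}"
                )
            seen[fam] = comp.index


def split_components(
    components: Sequence[Component],
    train_fraction: float = 0.70,
    zero_policy: str = "test",
) -> SplitResult:
    """Greedy train/test assignment of Components.

    Components are taken in rank order 1, 2, 3, … into the training set until
    the cumulative cluster count reaches ``train_fraction`` of the total
    (which includes Component #0's clusters when ``zero_policy="test"``);
    the remainder, and always Component #0, goes to the test set.  With
    ``zero_policy="ignore"`` Component #0 is omitted from both sets and from
    the denominator.  If the target is unreachable even using every non-zero
    Component, all are assigned with a warning flag and the achieved fraction
    reported.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in (0, 1]")
    if zero_policy not in ("test", "ignore"):
        raise ValueError("zero_policy must be 'test' or 'ignore'")

    nonzero = sorted((c for c in components if c.index != 0), key=lambda c: c.index)
    zero = next((c for c in components if c.index == 0), None)
    total = sum(c.n_sequences for c in nonzero)
    if zero_policy == "test" and zero is not None:
        total += zero.n_sequences

    train: list[int] = []
    cum = 0
    for comp in nonzero:
        if total > 0 and cum / total >= train_fraction:
            break
        train.append(comp.index)
        cum += comp.n_sequences
    achieved = cum / total if total else 0.0
    exhausted = achieved < train_fraction

    test = [c.index for c in nonzero if c.index not in set(train)]
    if zero is not None and zero_policy == "test":
        test = [0] + test
    return SplitResult(
        train=train,
        test=test,
        train_fraction_achieved=achieved,
        target_fraction=train_fraction,
        zero_policy=zero_policy,
        exhausted=exhausted,
    )


def split_multiway(
    components: Sequence[Component],
    fractions: Sequence[float],
    zero_policy: str = "test",
) -> list[list[int]]:
    """Generalized greedy split into len(fractions) bins (e.g. 0.7/0.15/0.15).

    Bins fill in order; each takes Components in rank order until its
    fraction of the total cluster count is met; the final bin receives the
    remainder plus Component #0 (``zero_policy="test"``).  Fractions must sum
    to 1 (within rounding).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    nonzero = sorted((c for c in components if c.index != 0), key=lambda c: c.index)
    zero = next((c for c in components if c.index == 0), None)
    total = sum(c.n_sequences for c in nonzero)
    if zero_policy == "test" and zero is not None:
        total += zero.n_sequences

    bins: list[list[int]] = [[] for _ in fractions]
    remaining = list(nonzero)
    for b, frac in enumerate(fractions[:-1]):
        cum = 0
        while remaining and (total == 0 or cum / total < frac):
            comp = remaining.pop(0)
            bins[b].append(comp.index)
            cum += comp.n_sequences
    bins[-1].extend(c.index for c in remaining)
    if zero is not None and zero_policy == "test":
        bins[-1].insert(0, 0)
    return bins


def emit_hierarchy(
    components: Sequence[Component],
    split: SplitResult,
    clusters: Sequence[SequenceCluster],
    hit_table: HitTable | None = None,
    strict_e: float = STRICT_E_THRESHOLD,
) -> dict:
    """Nested split → component → cluster → chain description.

    Per component, family lists are reported at two E-value tiers: the strict
    tier (default 1e-3, significant homology) and the lenient graph tier
    (every family edge used to build the component).
    """
    by_id = {cl.cluster_id: cl for cl in clusters}
    strict_fams: dict[str, set[str]] = {}
    if hit_table is not None:
        for h in hit_table.hits:
            if h.e_value <= strict_e:
                strict_fams.setdefault(h.cluster_id, set()).add(h.family_accession)

    def component_entry(comp: Component) -> dict:
        clus_entries = {}
        strict = set()
        for cid in sorted(comp.cluster_ids):
            cl = by_id.get(cid)
            strict |= strict_fams.get(cid, set())
            clus_entries[cid] = {
                "representative": cl.representative.full_id if cl else cid,
                "chains": {m.full_id: m.to_dict() for m in cl.members} if cl else {},
            }
        return {
            "index": comp.index,
            "n_sequences": comp.n_sequences,
            "n_chains": comp.n_chains,
            "families_strict": sorted(strict & set(comp.family_accessions)),
            "families_graph": sorted(comp.family_accessions),
            "clusters": clus_entries,
        }

    by_index = {c.index: c for c in components}
    return {
        "config": {
            "target_fraction": split.target_fraction,
            "zero_policy": split.zero_policy,
            "strict_e_threshold": strict_e,
        },
        "train_fraction_achieved": split.train_fraction_achieved,
        "train": {str(i): component_entry(by_index[i]) for i in split.train},
        "test": {str(i): component_entry(by_index[i]) for i in split.test},
    }


def write_hierarchy(hierarchy: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(hierarchy, fh, indent=1)


def load_split(hierarchy: dict | str | Path) -> SplitResult:
    """Reconstruct the :class:`SplitResult` recorded in an emitted hierarchy."""
    if not isinstance(hierarchy, dict):
        with open(hierarchy) as fh:
            hierarchy = json.load(fh)
    return SplitResult(
        train=sorted(int(i) for i in hierarchy["train"]),
        test=sorted(int(i) for i in hierarchy["test"]),
        train_fraction_achieved=hierarchy["train_fraction_achieved"],
        target_fraction=hierarchy["config"]["target_fraction"],
        zero_policy=hierarchy["config"]["zero_policy"],
    )


def write_edge_list(bipartite: BipartiteGraph, path: str | Path) -> None:
    """Tab-separated cluster→family edge export."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tfamily_accession\n")
        for c, f in sorted(bipartite.edges):
            fh.write(f"{c}\t{f}\n")


def write_split_lists(
    components: Sequence[Component], split: SplitResult,
    clusters: Sequence[SequenceCluster], out_dir: str | Path,
) -> None:
    """Per-split chain-id lists (one ``pdbid_chain`` per line) and FASTA."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_index = {c.index: c for c in components}
    by_id = {cl.cluster_id: cl for cl in clusters}
    for name, indices in (("train", split.train), ("test", split.test)):
        chains = []
        for i in indices:
            for cid in sorted(by_index[i].cluster_ids):
                cl = by_id.get(cid)
                if cl:
                    chains.extend(sorted(cl.members, key=lambda m: m.full_id))
        with open(out / f"{name}_chains.txt", "w") as fh:
            fh.writelines(c.full_id + "\n" for c in chains)
        with open(out / f"{name}.fasta", "w") as fh:
            for c in chains:
                fh.write(f">{c.full_id}\n{c.sequence}\n")
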