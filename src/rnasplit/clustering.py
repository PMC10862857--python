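"""Sequence clustering of filtered chains at high identity.

Chains are grouped at 99 % sequence identity so that near-identical deposits
of the same molecule — and fragments identical to a region of a longer chain —
fall into one cluster.  Identity is defined as aligned matches divided by the
length of the *shorter* sequence, so an exact substring scores 1.0 and joins
the cluster of its containing chain.  Each cluster is represented by its
longest member (ties broken by lexicographically smallest chain id) and named
``cluster_<representative id>``.

Two engines are available: an external clustering program invoked through a
subprocess wrapper, and a built-in greedy representative-linkage clusterer
(edlib infix alignments) so that small-scale runs and the test suite need no
external binary.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import edlib

from .mmcif_io import RnaChain, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class SequenceCluster:
    """A group of chains at >= ``identity`` pairwise to the representative."""

    representative: RnaChain
    members: list[RnaChain] = field(default_factory=list)

    @property
    def cluster_id(self) -> str:
        return f"cluster_{self.representative.full_id}"

    @property
    def n_chains(self) -> int:
        return len(self.members)

    def member_ids(self) -> list[str]:
        return sorted(m.full_id for m in self.members)


def sequence_identity(a: str, b: str) -> float:
    """Identity of two sequences: matches over the shorter length.

    Computed from an infix (glocal) alignment of the shorter sequence within
    the longer: ``(len_shorter - edit_distance) / len_shorter``.  Exact
    substrings therefore score 1.0.
    """
    if not a or not b:
        return 0.0
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    d = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
    return max(0.0, (len(query) - d) / len(query))


def _sorted_for_clustering(chains: Sequence[RnaChain]) -> list[RnaChain]:
    return sorted(chains, key=lambda c: (-c.length, c.full_id))


def internal_greedy_cluster(
    chains: Sequence[RnaChain], identity: float = 0.99
) -> list[SequenceCluster]:
    """Greedy representative-linkage clustering, longest chain first.

    Chains are visited by length descending (ties: id ascending); each joins
    the first existing cluster whose representative it matches at or above the
    identity threshold, else founds a new cluster.  Deterministic under input
    permutation.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must lie in (0, 1]")
    clusters: list[SequenceCluster] = []
    for chain in _sorted_for_clustering(chains):
        for cluster in clusters:
            if sequence_identity(chain.sequence, cluster.representative.sequence) >= identity:
                cluster.members.append(chain)
                break
        else:
            clusters.append(SequenceCluster(representative=chain, members=[chain]))
    return clusters


def external_cluster(
    chains: Sequence[RnaChain],
    identity: float = 0.99,
    engine_path: str = "mmseqs",
    extra_args: Sequence[str] = (),
    runner: Callable[[list[str]], None] | None = None,
) -> list[SequenceCluster]:
    """Cluster via an external engine's easy-cluster workflow.

    Writes the chains as FASTA, runs the engine with the identity threshold
    and coverage of the shorter sequence (matching the identity definition
    used internally), and reads back the representative↔member TSV.  A
    ``runner`` callable may replace the subprocess invocation in tests.
    """
    if runner is None and shutil.which(engine_path) is None:
        raise FileNotFoundError(
            f"external clustering engine {engine_path!r} not found on PATH"
        )
    by_id = {c.full_id: c for c in chains}
    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp)
        fasta = tmp_path / "chains.fasta"
        write_fasta(_sorted_for_clustering(chains), fasta)
        prefix = tmp_path / "clu"
        cmd = [
            engine_path, "easy-cluster", str(fasta), str(prefix), str(tmp_path / "tmp"),
            "--min-seq-id", str(identity), "-c", "1.0", "--cov-mode", "5",
            *extra_args,
        ]
        logger.info("external clustering: %s", " ".join(cmd))
        if runner is not None:
            runner(cmd)
        else:
            subprocess.run(cmd, check=True, capture_output=True)
        tsv = Path(str(prefix) + "_cluster.tsv")
        groups: dict[str, list[str]] = {}
        for line in tsv.read_text().splitlines():
            if not line.strip():
                continue
            rep, member = line.split("\t")[:2]
            groups.setdefault(rep, []).append(member)
    clusters = []
    for members in groups.values():
        chains_in = [by_id[m] for m in members]
        rep = min(chains_in, key=lambda c: (-c.length, c.full_id))
        clusters.append(SequenceCluster(representative=rep, members=chains_in))
    return clusters


def cluster_sequences(
    chains: Sequence[RnaChain],
    identity: float = 0.99,
    engine: str = "internal",
    strict: bool = False,
    **engine_kwargs,
) -> list[SequenceCluster]:
    """Partition chains into identity clusters with longest representatives.

    ``engine`` is ``"internal"`` (built-in greedy) or ``"external"``; when the
    external engine is unavailable the internal path is used with a warning
    unless ``strict`` is set.  Output order: cluster size descending, then
    representative length descending, then cluster id — deterministic.
    """
    if engine == "external":
        try:
            clusters = external_cluster(chains, identity=identity, **engine_kwargs)
        except FileNotFoundError:
            if strict:
                raise
            warnings.warn("external clustering engine unavailable; using internal clusterer")
            clusters = internal_greedy_cluster(chains, identity=identity)
    elif engine == "internal":
        clusters = internal_greedy_cluster(chains, identity=identity)
    else:
        raise ValueError(f"unknown clustering engine {engine!r}")
    clusters.sort(key=lambda cl: (-cl.n_chains, -cl.representative.length, cl.cluster_id))
    return clusters


def write_membership_json(clusters: Sequence[SequenceCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({cl.cluster_id: cl.member_ids() for cl in clusters}, fh, indent=1)


def write_representatives_fasta(clusters: Sequence[SequenceCluster], path: str | Path) -> None:
    """FASTA of cluster representatives, headers = cluster ids."""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(f">{cl.cluster_id}\n{cl.representative.sequence}\n")
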