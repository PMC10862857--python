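"""Covariance-model homology hits of cluster representatives vs RNA families.

The actual search is done by an external covariance-model engine (cmscan
against an Rfam-style family database); this module owns the wrapper contract
— a two-pass strategy that first searches every representative with default
settings and then re-searches only the zero-hit queries with all heuristic
filters disabled for maximum sensitivity — and the parser for the engine's
whitespace-delimited tabular (tblout) output.

The resulting :class:`HitTable` keeps every hit (multiple hits of one query to
one family included) so that E-value threshold sweeps are possible without
re-searching; graph building collapses them to edges.  The ``searched`` set
records which queries were run, so "no hit" is distinguishable from "never
searched".
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

logger = logging.getLogger(__name__)

FAMILY_ACCESSION_RE = re.compile(r"^RF\d{5}$")

#: cmscan tblout column layout (fmt 1): 0 target name, 1 target accession,
#: 2 query name, 3 query accession, ... 14 bit score, 15 E-value.
_COL_TARGET_NAME = 0
_COL_TARGET_ACC = 1
_COL_QUERY_NAME = 2
_COL_SCORE = 14
_COL_EVALUE = 15
_MIN_COLS = 16


@dataclass(frozen=True)
class HomologyHit:
    cluster_id: str
    family_accession: str
    family_name: str = ""
    e_value: float = 1.0
    bit_score: float = 0.0
    pass_index: int = 1

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if self.pass_index not in (1, 2):
            raise ValueError("pass_index must be 1 or 2")


@dataclass
class HitTable:
    hits: list[HomologyHit] = field(default_factory=list)
    searched: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.searched |= {h.cluster_id for h in self.hits}

    def queries_with_hits(self) -> set[str]:
        return {h.cluster_id for h in self.hits}

    def queries_without_hits(self) -> set[str]:
        return self.searched - self.queries_with_hits()

    def merged_with(self, other: "HitTable") -> "HitTable":
        return HitTable(hits=self.hits + other.hits, searched=self.searched | other.searched)


def parse_tblout(
    source: str | Path,
    pass_index: int = 1,
    searched: Iterable[str] | None = None,
) -> HitTable:
    """Parse an engine tblout file (or raw text) into a :class:`HitTable`.

    Comment lines start with ``#``; data rows are whitespace-delimited with a
    free-text description tail.  Malformed rows are skipped with a warning;
    a file with zero data rows yields a valid empty table.
    """
    if isinstance(source, Path) or ("\n" not in str(source) and Path(str(source)).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)

    hits: list[HomologyHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split(None, _MIN_COLS + 1)
        if len(fields) < _MIN_COLS:
            warnings.warn(f"tblout line {lineno}: expected >= {_MIN_COLS} columns; skipped")
            continue
        try:
            hits.append(
                HomologyHit(
                    cluster_id=fields[_COL_QUERY_NAME],
                    family_accession=fields[_COL_TARGET_ACC],
                    family_name=fields[_COL_TARGET_NAME],
                    e_value=float(fields[_COL_EVALUE]),
                    bit_score=float(fields[_COL_SCORE]),
                    pass_index=pass_index,
                )
            )
        except ValueError as exc:
            warnings.warn(f"tblout line {lineno}: {exc}; skipped")
    table = HitTable(hits=hits)
    if searched is not None:
        table.searched |= set(searched)
    return table


def write_tblout(table: HitTable, path: str | Path) -> None:
    """Serialize a hit table back to the engine's tblout column layout.

    Round-trips with :func:`parse_tblout` up to pass tags (recorded as a
    trailing comment-style description column).
    """
    with open(path, "w") as fh:
        fh.write("#target name\taccession\tquery name\taccession\tmdl\tmdl from\t"
                 "mdl to\tseq from\tseq to\tstrand\ttrunc\tpass\tgc\tbias\t"
                 "score\tE-value\tinc\tdescription of target\n")
        for h in table.hits:
            fh.write(
                f"{h.family_name or '-'} {h.family_accession} {h.cluster_id} - "
                f"cm 1 1 1 1 + no 1 0.50 0.0 {h.bit_score!r} {h.e_value!r} ! -\n"
            )


def write_hits_tsv(table: HitTable, path: str | Path) -> None:
    """Normalized hit table: cluster_id, accession, name, e_value, score, pass."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tfamily_accession\tfamily_name\te_value\tbit_score\tpass\n")
        for h in table.hits:
            fh.write(
                f"{h.cluster_id}\t{h.family_accession}\t{h.family_name}\t"
                f"{h.e_value!r}\t{h.bit_score!r}\t{h.pass_index}\n"
            )
        for q in sorted(table.queries_without_hits()):
            fh.write(f"{q}\t-\t-\t-\t-\t-\n")


def read_hits_tsv(path: str | Path) -> HitTable:
    hits: list[HomologyHit] = []
    searched: set[str] = set()
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        q, acc, name, ev, score, pidx = line.split("\t")
        searched.add(q)
        if acc == "-":
            continue
        hits.append(
            HomologyHit(
                cluster_id=q, family_accession=acc, family_name=name,
                e_value=float(ev), bit_score=float(score), pass_index=int(pidx),
            )
        )
    table = HitTable(hits=hits)
    table.searched |= searched
    return table


def _default_runner(cmd: list[str]) -> None:
    result = subprocess.run(cmd, capture_output=True, text=True)
    if result.returncode != 0:
        raise RuntimeError(
            f"search engine failed ({result.returncode}): {result.stderr.strip()}"
        )


def _query_names(fasta: str | Path) -> list[str]:
    names = []
    for line in Path(fasta).read_text().splitlines():
        if line.startswith(">"):
            names.append(line[1:].split()[0])
    return names


def _subset_fasta(fasta: str | Path, names: set[str], out: Path) -> None:
    keep = False
    with open(out, "w") as fh:
        for line in Path(fasta).read_text().splitlines():
            if line.startswith(">"):
                keep = line[1:].split()[0] in names
            if keep:
                fh.write(line + "\n")


def two_pass_search(
    representatives_fasta: str | Path,
    cm_database: str | Path,
    engine_path: str = "cmscan",
    extra_args: Sequence[str] = (),
    runner: Callable[[list[str]], None] | None = None,
    work_dir: str | Path | None = None,
    skip_pass2: bool = False,
) -> HitTable:
    """Run the two-pass homology search over cluster representatives.

    Pass 1 searches every representative with default engine settings.  Pass 2
    re-runs *only* the representatives with zero pass-1 hits, with all
    heuristic filters off (``--max``) for maximum sensitivity.  Hits are
    tagged with their pass; the ``searched`` set equals the full
    representative set regardless of hit outcomes.

    ``runner`` replaces the subprocess call (tests inject one that writes
    fixture tblout files); the default runner requires the engine on PATH.
    """
    if runner is None:
        if shutil.which(engine_path) is None:
            raise FileNotFoundError(
                f"covariance-model search engine {engine_path!r} not found on PATH; "
                "install it or supply a precomputed hit table"
            )
        runner = _default_runner
    work = Path(work_dir) if work_dir else Path(representatives_fasta).parent
    work.mkdir(parents=True, exist_ok=True)
    all_queries = _query_names(representatives_fasta)

    tbl1 = work / "pass1.tblout"
    cmd1 = [engine_path, "--tblout", str(tbl1), *extra_args,
            str(cm_database), str(representatives_fasta)]
    logger.info("pass 1: %s", " ".join(cmd1))
    runner(cmd1)
    table = parse_tblout(tbl1, pass_index=1, searched=all_queries)

    missing = set(all_queries) - table.queries_with_hits()
    if missing and not skip_pass2:
        fasta2 = work / "pass2.fasta"
        _subset_fasta(representatives_fasta, missing, fasta2)
        tbl2 = work / "pass2.tblout"
        cmd2 = [engine_path, "--max", "--tblout", str(tbl2), *extra_args,
                str(cm_database), str(fasta2)]
        logger.info("pass 2 (%d zero-hit queries): %s", len(missing), " ".join(cmd2))
        runner(cmd2)
        pass2 = parse_tblout(tbl2, pass_index=2, searched=missing)
        extraneous = pass2.queries_with_hits() - missing
        if extraneous:
            raise RuntimeError(f"pass-2 output contains unsolicited queries: {extraneous}")
        table = table.merged_with(pass2)
    table.searched |= set(all_queries)
    return table
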