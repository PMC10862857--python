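"""Reading PDBx/mmCIF structures and the Chemical Component Dictionary.

This module identifies RNA chains in mmCIF files and renders each one as a
normalized one-letter sequence.  A chain qualifies as RNA when at least one of
its residues has a chemical-component type containing the substring ``"RNA"``
(so author labelling of the entity is never trusted).  Modified nucleotides —
pseudouridine, 1-methyladenosine and hundreds of others — are converted to
their closest canonical symbol by recursive ascent through the Chemical
Component Dictionary's parent-component links; anything that cannot be
resolved (stray amino acids, ligands, waters) becomes the unknown symbol
``N``.

The sequence of a chain is taken from the deposited polymer sequence scheme
(``_pdbx_poly_seq_scheme``), i.e. the full entity sequence, not only the
residues with resolved coordinates; an option restricts to modeled residues.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi

logger = logging.getLogger(__name__)

#: Canonical ribonucleotide one-letter symbols.
CANONICAL = ("A", "C", "G", "U")

#: Symbol used for residues that cannot be mapped to a canonical nucleotide.
UNKNOWN = "N"

#: Maximum depth of parent-component ascent in the dictionary.  CCD parent
#: chains are shallow in practice; the limit only guards against pathology.
MAX_PARENT_DEPTH = 16


@dataclass
class ComponentDictEntry:
    """One chemical component from the dictionary.

    ``parent_codes`` holds the identifiers listed in
    ``_chem_comp.mon_nstd_parent_comp_id``; more than one parent means the
    component is a hybrid and is mapped to unknown rather than guessed at.
    """

    code: str
    comp_type: str = ""
    parent_codes: list[str] = field(default_factory=list)
    one_letter: str | None = None


@dataclass
class ModificationMap:
    """Mapping from three-letter component codes to one-letter nucleotides.

    Every value is one of ``A``, ``C``, ``G``, ``U`` or ``N`` (unknown).
    """

    entries: dict[str, str] = field(default_factory=dict)
    source_version: str = ""

    def __post_init__(self) -> None:
        for code in CANONICAL:
            self.entries.setdefault(code, code)

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, code: str) -> str:
        return self.entries.get(code, UNKNOWN)


@dataclass
class RnaChain:
    """One polymer chain with a normalized one-letter sequence.

    ``chain_id`` is the author chain identifier; ``full_id`` composes
    ``structure_id`` and ``chain_id`` as ``pdbid_chain``, the key used
    everywhere downstream.  ``n_modified`` counts residues whose deposited
    code was non-canonical but resolved to A/C/G/U through the dictionary.
    """

    structure_id: str
    chain_id: str
    sequence: str
    resolution: float | None = None
    method: str = ""
    release_date: str | None = None
    n_modified: int = 0

    @property
    def full_id(self) -> str:
        return f"{self.structure_id}_{self.chain_id}"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_unknown(self) -> int:
        return self.sequence.count(UNKNOWN)

    @property
    def is_nmr(self) -> bool:
        return "NMR" in self.method.upper()

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "chain_id": self.chain_id,
            "sequence": self.sequence,
            "length": self.length,
            "resolution": self.resolution,
            "method": self.method,
            "release_date": self.release_date,
            "n_unknown": self.n_unknown,
            "n_modified": self.n_modified,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RnaChain":
        return cls(
            structure_id=d["structure_id"],
            chain_id=d["chain_id"],
            sequence=d["sequence"],
            resolution=d.get("resolution"),
            method=d.get("method", ""),
            release_date=d.get("release_date"),
            n_modified=d.get("n_modified", 0),
        )


def _read_cif(path_or_text: str | Path) -> gemmi.cif.Document:
    """Read a CIF document from a path (gzip-transparent) or raw text."""
    if isinstance(path_or_text, Path) or (
        "\n" not in str(path_or_text) and Path(str(path_or_text)).exists()
    ):
        p = Path(path_or_text)
        if p.suffix == ".gz":
            with gzip.open(p, "rt") as fh:
                return gemmi.cif.read_string(fh.read())
        return gemmi.cif.read(str(p))
    return gemmi.cif.read_string(str(path_or_text))


def _is_nucleic_type(comp_type: str) -> bool:
    t = comp_type.upper()
    return "RNA" in t or "DNA" in t or "NUCLEIC" in t


def load_component_dictionary(
    dictionary_file: str | Path,
    max_depth: int = MAX_PARENT_DEPTH,
) -> ModificationMap:
    """Build a :class:`ModificationMap` from a Chemical Component Dictionary.

    Every nucleic-acid-typed component resolves by (a) canonical identity,
    else (b) recursive ascent through parent components until a canonical
    ribonucleotide is reached, else to unknown.  Components listing multiple
    parents resolve to unknown.  Cycles in the parent relation terminate the
    ascent.  Malformed blocks are skipped with a warning.
    """
    try:
        doc = _read_cif(dictionary_file)
    except (OSError, ValueError, RuntimeError) as exc:
        raise ValueError(f"cannot parse component dictionary: {exc}") from exc

    entries: dict[str, ComponentDictEntry] = {}
    for block in doc:
        try:
            code = block.find_value("_chem_comp.id")
            if code is None:
                continue
            code = gemmi.cif.as_string(code).strip()
            if not code:
                continue
            comp_type = block.find_value("_chem_comp.type") or ""
            comp_type = gemmi.cif.as_string(comp_type)
            parent_raw = block.find_value("_chem_comp.mon_nstd_parent_comp_id")
            parents: list[str] = []
            if parent_raw is not None:
                parent_str = gemmi.cif.as_string(parent_raw).strip()
                if parent_str not in ("", "?", "."):
                    parents = [p.strip().upper() for p in parent_str.split(",") if p.strip()]
            entries[code.upper()] = ComponentDictEntry(
                code=code.upper(), comp_type=comp_type, parent_codes=parents
            )
        except (ValueError, RuntimeError) as exc:  # malformed block
            warnings.warn(f"skipping malformed dictionary block {block.name!r}: {exc}")
            continue

    mapping: dict[str, str] = {}

    def resolve(code: str, seen: set[str], depth: int) -> str:
        if code in CANONICAL:
            return code
        if depth > max_depth or code in seen:
            return UNKNOWN
        seen.add(code)
        entry = entries.get(code)
        if entry is None:
            return UNKNOWN
        if len(entry.parent_codes) != 1:
            # no parent, or a multi-parent hybrid: "closest symbol" undefined
            return UNKNOWN
        return resolve(entry.parent_codes[0], seen, depth + 1)

    for code, entry in entries.items():
        if not _is_nucleic_type(entry.comp_type) and code not in CANONICAL:
            continue
        mapping[code] = resolve(code, set(), 0)

    return ModificationMap(entries=mapping, source_version=str(dictionary_file))


def residue_to_one_letter(code: str, mod_map: ModificationMap) -> str:
    """Map a three-letter component code to one of ``A C G U N``.

    Total: never raises; codes absent from the map (amino acids, ligands,
    water, arbitrary junk) return the unknown symbol.
    """
    if not isinstance(code, str):
        return UNKNOWN
    return mod_map.get(code.strip().upper())


def extract_resolution(
    block: gemmi.cif.Block,
    nmr_resolution_zero: bool = False,
) -> float | None:
    """Best available resolution in Å for one data block, or ``None``.

    Takes the minimum over the resolution-bearing categories present:
    refinement high-resolution limit, EM reconstruction resolution, and the
    reflections high-resolution limit.  NMR entries have no well-defined
    resolution and return ``None`` unless ``nmr_resolution_zero`` is set,
    in which case they return ``0.0``.
    """
    method = _extract_method(block)
    candidates = []
    for tag in (
        "_refine.ls_d_res_high",
        "_em_3d_reconstruction.resolution",
        "_reflns.d_resolution_high",
    ):
        for val in block.find_values(tag):
            s = gemmi.cif.as_string(val).strip()
            if s in ("", "?", "."):
                continue
            try:
                candidates.append(float(s))
            except ValueError:
                warnings.warn(f"non-numeric resolution value {s!r} in {tag}; ignored")
    if candidates:
        return min(candidates)
    if nmr_resolution_zero and "NMR" in method.upper():
        return 0.0
    return None


def _extract_method(block: gemmi.cif.Block) -> str:
    methods = [gemmi.cif.as_string(v) for v in block.find_values("_exptl.method")]
    return "; ".join(m for m in methods if m) if methods else ""


def _extract_release_date(block: gemmi.cif.Block) -> str | None:
    dates = [
        gemmi.cif.as_string(v).strip()
        for v in block.find_values("_pdbx_audit_revision_history.revision_date")
    ]
    dates = [d for d in dates if d and d not in ("?", ".")]
    if dates:
        return min(dates)
    d = block.find_value("_pdbx_database_status.recvd_initial_deposition_date")
    if d is not None:
        s = gemmi.cif.as_string(d).strip()
        if s and s not in ("?", "."):
            return s
    return None


def parse_structure(
    mmcif_file: str | Path,
    mod_map: ModificationMap,
    nmr_resolution_zero: bool = False,
    case_insensitive_rna: bool = False,
    modeled_only: bool = False,
) -> list[RnaChain]:
    """Extract all RNA chains from a PDBx/mmCIF file.

    A chain is admitted when at least one of its residues has ``"RNA"`` in its
    chemical-component type string (case-sensitive by default).  Each admitted
    chain's full deposited sequence is converted residue-by-residue via
    :func:`residue_to_one_letter`.  With ``modeled_only`` set, residues whose
    ``pdb_mon_id`` is absent (unmodeled) are dropped from the sequence.
    """
    try:
        doc = _read_cif(mmcif_file)
    except (OSError, ValueError, RuntimeError) as exc:
        raise ValueError(f"cannot parse mmCIF file {mmcif_file!r}: {exc}") from exc

    chains: list[RnaChain] = []
    for block in doc:
        chains.extend(
            _parse_block(
                block,
                mod_map,
                nmr_resolution_zero=nmr_resolution_zero,
                case_insensitive_rna=case_insensitive_rna,
                modeled_only=modeled_only,
            )
        )
    return chains


def _parse_block(
    block: gemmi.cif.Block,
    mod_map: ModificationMap,
    nmr_resolution_zero: bool,
    case_insensitive_rna: bool,
    modeled_only: bool,
) -> list[RnaChain]:
    entry_id = block.find_value("_entry.id")
    structure_id = (
        gemmi.cif.as_string(entry_id).strip().lower() if entry_id else block.name.lower()
    )

    comp_table = block.find("_chem_comp.", ["id", "type"])
    if len(comp_table) == 0:
        warnings.warn(f"{structure_id}: no _chem_comp loop; no chains parsed")
        return []
    rna_codes: set[str] = set()
    for row in comp_table:
        code = row[0].strip().upper()
        ctype = gemmi.cif.as_string(row[1])
        hay, needle = (ctype.upper(), "RNA") if case_insensitive_rna else (ctype, "RNA")
        if needle in hay:
            rna_codes.add(code)

    cols = ["mon_id", "pdb_strand_id"]
    if modeled_only:
        cols.append("pdb_mon_id")
    seq_table = block.find("_pdbx_poly_seq_scheme.", cols)
    per_chain: dict[str, list[str]] = {}
    for row in seq_table:
        if modeled_only:
            pdb_mon = row[2].strip()
            if pdb_mon in ("", "?", "."):
                continue
        per_chain.setdefault(row[1].strip(), []).append(row[0].strip().upper())

    resolution = extract_resolution(block, nmr_resolution_zero=nmr_resolution_zero)
    method = _extract_method(block)
    release_date = _extract_release_date(block)

    chains: list[RnaChain] = []
    for chain_id, residues in per_chain.items():
        if not any(code in rna_codes for code in residues):
            continue
        if not residues:
            warnings.warn(f"{structure_id}_{chain_id}: empty polymer sequence; skipped")
            continue
        seq_chars = []
        n_modified = 0
        for code in residues:
            sym = residue_to_one_letter(code, mod_map)
            seq_chars.append(sym)
            if sym != UNKNOWN and code not in CANONICAL:
                n_modified += 1
        chains.append(
            RnaChain(
                structure_id=structure_id,
                chain_id=chain_id,
                sequence="".join(seq_chars),
                resolution=resolution,
                method=method,
                release_date=release_date,
                n_modified=n_modified,
            )
        )
    chains.sort(key=lambda c: c.full_id)
    return chains


def parse_directory(
    mmcif_dir: str | Path,
    mod_map: ModificationMap,
    **kwargs,
) -> list[RnaChain]:
    """Parse every ``*.cif``/``*.cif.gz`` file in a directory, sorted by name."""
    chains: list[RnaChain] = []
    paths = sorted(Path(mmcif_dir).glob("*.cif")) + sorted(Path(mmcif_dir).glob("*.cif.gz"))
    for path in paths:
        chains.extend(parse_structure(path, mod_map, **kwargs))
    return chains


def write_fasta(chains: Iterable[RnaChain], path: str | Path) -> None:
    """Write chains as FASTA with ``pdbid_chain`` headers."""
    with open(path, "w") as fh:
        for chain in chains:
            fh.write(f">{chain.full_id}\n{chain.sequence}\n")


def write_chain_json(chains: Iterable[RnaChain], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in chains], fh, indent=1)


def read_chain_json(path: str | Path) -> list[RnaChain]:
    with open(path) as fh:
        return [RnaChain.from_dict(d) for d in json.load(fh)]
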