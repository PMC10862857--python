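"""Synthetic inputs with known ground truth.

Generates miniature PDBx/mmCIF structure files, a toy chemical-component
dictionary, and homology hit tables with planted component structure, so that
every stage of the pipeline — parsing, filtering, clustering, graph building
and splitting — can be exercised end-to-end with no downloads and its output
compared against an exactly known answer.

A :class:`ScenarioSpec` plants: a set of sequence clusters (each realized as
copies and exact substrings of a random representative), a bipartite edge
plan wiring clusters to RNA families inside disjoint planted components,
edgeless clusters destined for Component #0, chains violating each filter,
and modified-residue insertions that the dictionary must normalize away.
E-values for planted edges are drawn log-uniform in [1e-12, threshold];
decoy rows (never edges) in (threshold, 1e3].

Fixtures deliberately include only the mmCIF categories the parser contracts
on; they do not emulate realistic covariance-model score distributions — only
the tabular contract matters.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

DEFAULT_E_THRESHOLD = 1.0

#: Modified-residue codes in the toy dictionary, keyed by canonical letter.
MODIFIED_CODES = {
    "A": ["1MA", "6MA"],
    "C": ["OMC", "5MC"],
    "G": ["M2G", "OMG"],
    "U": ["PSU", "5MU"],
}

TOY_DICTIONARY = """\
data_A
_chem_comp.id A
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id ?
data_C
_chem_comp.id C
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id ?
data_G
_chem_comp.id G
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id ?
data_U
_chem_comp.id U
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id ?
data_PSU
_chem_comp.id PSU
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id U
data_5MU
_chem_comp.id 5MU
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id U
data_1MA
_chem_comp.id 1MA
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id A
data_6MA
_chem_comp.id 6MA
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id A
data_OMC
_chem_comp.id OMC
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id C
data_5MC
_chem_comp.id 5MC
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id C
data_M2G
_chem_comp.id M2G
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id G
data_OMG
_chem_comp.id OMG
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id G
data_2MA
_chem_comp.id 2MA
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id 1MA
data_HYB
_chem_comp.id HYB
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id 'A, C'
data_CY1
_chem_comp.id CY1
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id CY2
data_CY2
_chem_comp.id CY2
_chem_comp.type 'RNA linking'
_chem_comp.mon_nstd_parent_comp_id CY1
data_GLY
_chem_comp.id GLY
_chem_comp.type 'peptide linking'
_chem_comp.mon_nstd_parent_comp_id ?
data_DA
_chem_comp.id DA
_chem_comp.type 'DNA linking'
_chem_comp.mon_nstd_parent_comp_id ?
"""

#: Filter violation kinds a scenario can plant on a standalone chain.
VIOLATION_KINDS = ("length", "resolution", "composition", "unknown", "nmr")


@dataclass
class PlantedComponent:
    """One planted connected component: cluster indices, family indices, edges."""

    clusters: list[int]
    families: list[int]
    edges: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class ScenarioSpec:
    seed: int = 0
    n_clusters: int = 4
    n_families: int = 2
    planted_components: list[PlantedComponent] = field(default_factory=list)
    multiplicities: dict[int, int] = field(default_factory=dict)
    violations: list[tuple[str, ...]] = field(default_factory=list)
    modified_per_chain: int = 2
    e_threshold: float = DEFAULT_E_THRESHOLD

    def validate(self) -> None:
        used_clusters: list[int] = []
        used_families: list[int] = []
        for comp in self.planted_components:
            if not comp.clusters:
                raise ValueError("planted component without clusters")
            used_clusters.extend(comp.clusters)
            used_families.extend(comp.families)
            nodes = {("c", c) for c in comp.clusters} | {("f", f) for f in comp.families}
            for c, f in comp.edges:
                if c not in comp.clusters or f not in comp.families:
                    raise ValueError("edge plan leaves its planted component")
            if comp.families and not _is_connected(comp):
                raise ValueError("planted component's edge plan is not connected")
        if len(set(used_clusters)) != len(used_clusters):
            raise ValueError("cluster planted in more than one component")
        if len(set(used_families)) != len(used_families):
            raise ValueError("family planted in more than one component")
        if used_clusters and max(used_clusters) >= self.n_clusters:
            raise ValueError("cluster index out of range")
        if used_families and max(used_families) >= self.n_families:
            raise ValueError("family index out of range")
        for m in self.multiplicities.values():
            if m < 1:
                raise ValueError("chain multiplicity must be >= 1")
        for reasons in self.violations:
            for r in reasons:
                if r not in VIOLATION_KINDS:
                    raise ValueError(f"unknown violation kind {r!r}")
            if not reasons:
                raise ValueError("empty violation tuple")
            # combinations whose realizations interfere are rejected outright:
            # planting unknowns dilutes the dominant nucleotide, and NMR
            # entries carry no resolution value to violate
            if {"composition", "unknown"} <= set(reasons):
                raise ValueError("composition and unknown violations interfere")
            if "nmr" in reasons and "resolution" in reasons:
                raise ValueError("NMR chains have no resolution to violate")


def _is_connected(comp: PlantedComponent) -> bool:
    # union-find over the small planted node set
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in comp.clusters:
        find(("c", c))
    for f in comp.families:
        find(("f", f))
    for c, f in comp.edges:
        parent[find(("c", c))] = find(("f", f))
    roots = {find(("c", c)) for c in comp.clusters} | {find(("f", f)) for f in comp.families}
    return len(roots) == 1


def family_accession(index: int) -> str:
    return f"RF{index + 1:05d}"


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(length))


@dataclass
class GroundTruth:
    """Expected pipeline outcomes for a generated scenario."""

    chains: dict[str, dict]               # full_id -> metadata incl. sequence
    filter_reasons: dict[str, list[str]]  # full_id -> planted rejection reasons
    clusters: dict[str, list[str]]        # cluster_id -> sorted member full_ids
    component_zero: set[str]              # cluster_ids with no edges
    components: list[tuple[frozenset, frozenset]]  # ranked (cluster_ids, accessions)


@dataclass
class ScenarioData:
    spec: ScenarioSpec
    mmcif_dir: Path
    dictionary_path: Path
    tblout_path: Path
    ground_truth: GroundTruth


def _render_mmcif(
    structure_id: str,
    chain_residues: dict[str, list[str]],
    comp_types: dict[str, str],
    resolution: float | None,
    method: str,
) -> str:
    lines = [f"data_{structure_id}", f"_entry.id {structure_id.upper()}",
             f"_exptl.method '{method}'"]
    if resolution is not None:
        lines.append(f"_refine.ls_d_res_high {resolution:.2f}")
    lines.append("_pdbx_database_status.recvd_initial_deposition_date 2020-01-01")
    lines += ["loop_", "_chem_comp.id", "_chem_comp.type"]
    codes = sorted({c for residues in chain_residues.values() for c in residues})
    for code in codes:
        lines.append(f"{code} '{comp_types[code]}'")
    lines += ["loop_", "_pdbx_poly_seq_scheme.asym_id", "_pdbx_poly_seq_scheme.entity_id",
              "_pdbx_poly_seq_scheme.seq_id", "_pdbx_poly_seq_scheme.mon_id",
              "_pdbx_poly_seq_scheme.pdb_strand_id"]
    for n, (chain_id, residues) in enumerate(sorted(chain_residues.items()), start=1):
        for i, code in enumerate(residues, start=1):
            lines.append(f"{chr(64 + n)} {n} {i} {code} {chain_id}")
    return "\n".join(lines) + "\n"


def _residue_codes(rng: random.Random, sequence: str, n_modified: int) -> tuple[list[str], int]:
    """Replace up to ``n_modified`` residues with modified codes of the same base."""
    codes = list(sequence)
    n_actual = 0
    if n_modified > 0 and len(sequence) > 0:
        for i in rng.sample(range(len(sequence)), min(n_modified, len(sequence))):
            codes[i] = rng.choice(MODIFIED_CODES[sequence[i]])
            n_actual += 1
    return codes, n_actual


def generate_scenario(spec: ScenarioSpec, out_dir: str | Path) -> ScenarioData:
    """Realize a scenario on disk; deterministic under ``spec.seed``.

    Writes one mmCIF file per structure under ``out_dir/mmcif``, the toy
    dictionary, and a tblout hit table; returns paths plus the exact expected
    outcome of every pipeline stage.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    mmcif_dir = out / "mmcif"
    mmcif_dir.mkdir(parents=True, exist_ok=True)
    dictionary_path = out / "components.cif"
    dictionary_path.write_text(TOY_DICTIONARY)

    comp_types = {c: "RNA linking" for base in MODIFIED_CODES.values() for c in base}
    comp_types.update({b: "RNA linking" for b in "ACGU"})
    comp_types["GLY"] = "peptide linking"

    chains: dict[str, dict] = {}
    filter_reasons: dict[str, list[str]] = {}
    clusters: dict[str, list[str]] = {}
    struct_counter = 0

    def next_structure_id() -> str:
        nonlocal struct_counter
        sid = f"s{struct_counter:03d}"
        struct_counter += 1
        return sid

    def emit_chain(sequence: str, resolution: float | None, method: str,
                   n_unknown_residues: int = 0) -> str:
        sid = next_structure_id()
        codes, n_mod = _residue_codes(rng, sequence, spec.modified_per_chain)
        recorded = list(sequence)
        if n_unknown_residues:
            for i in rng.sample(range(len(sequence)), n_unknown_residues):
                codes[i] = "GLY"
                recorded[i] = "N"
        full_id = f"{sid}_A"
        (mmcif_dir / f"{sid}.cif").write_text(
            _render_mmcif(sid, {"A": codes}, comp_types, resolution, method)
        )
        chains[full_id] = {
            "sequence": "".join(recorded),
            "resolution": resolution,
            "method": method,
            "n_modified": sum(
                1 for c, s in zip(codes, recorded) if s != "N" and c not in "ACGU"
            ),
        }
        return full_id

    # --- clustered chains -------------------------------------------------
    rep_of_cluster: dict[int, str] = {}
    for ci in range(spec.n_clusters):
        rep_len = rng.randint(48, 120)
        rep_seq = _random_sequence(rng, rep_len)
        multiplicity = spec.multiplicities.get(ci, 1)
        member_ids = []
        rep_res = round(rng.uniform(1.5, 4.0), 2)
        rep_id = emit_chain(rep_seq, rep_res, "X-RAY DIFFRACTION")
        member_ids.append(rep_id)
        for _ in range(multiplicity - 1):
            if rng.random() < 0.5:
                seq = rep_seq  # exact copy
            else:
                sub_len = rng.randint(32, rep_len)
                start = rng.randint(0, rep_len - sub_len)
                seq = rep_seq[start:start + sub_len]
            member_ids.append(
                emit_chain(seq, round(rng.uniform(1.5, 4.0), 2), "X-RAY DIFFRACTION")
            )
        rep_of_cluster[ci] = rep_id
        clusters[f"cluster_{rep_id}"] = sorted(member_ids)
        filter_reasons.update({m: [] for m in member_ids})

    # --- filter-violating standalone chains --------------------------------
    for reasons in spec.violations:
        length = rng.randint(10, 31) if "length" in reasons else rng.randint(40, 90)
        resolution: float | None = round(rng.uniform(1.5, 4.0), 2)
        method = "X-RAY DIFFRACTION"
        if "resolution" in reasons:
            resolution = round(rng.uniform(9.01, 20.0), 2)
        if "nmr" in reasons:
            method, resolution = "SOLUTION NMR", None
        if "composition" in reasons:
            nt = rng.choice("ACGU")
            others = [b for b in "ACGU" if b != nt]
            n_dominant = math.floor(0.8 * length) + 1
            seq = [nt] * n_dominant + [rng.choice(others) for _ in range(length - n_dominant)]
            rng.shuffle(seq)
            sequence = "".join(seq)
        else:
            sequence = _random_sequence(rng, length)
        n_unknown = 0
        if "unknown" in reasons:
            n_unknown = math.floor(0.3 * length) + 1
        fid = emit_chain(sequence, resolution, method, n_unknown_residues=n_unknown)
        filter_reasons[fid] = sorted(reasons)

    # --- hit table ---------------------------------------------------------
    tblout_lines = ["# synthetic hit table"]
    planted_cluster_ids: set[int] = set()
    for comp in spec.planted_components:
        planted_cluster_ids.update(comp.clusters)
        for c, f in comp.edges:
            e_val = 10 ** rng.uniform(-12, math.log10(spec.e_threshold))
            score = round(rng.uniform(20, 200), 1)
            qname = f"cluster_{rep_of_cluster[c]}"
            tblout_lines.append(
                f"fam{f} {family_accession(f)} {qname} - cm 1 50 1 50 + no 1 "
                f"0.50 0.0 {score} {e_val:.6e} ! -"
            )
    # decoy rows: above-threshold E-values that must never become edges
    for _ in range(rng.randint(0, 3)):
        c = rng.randrange(spec.n_clusters)
        f = rng.randrange(spec.n_families) if spec.n_families else None
        if f is None:
            break
        e_val = 10 ** rng.uniform(math.log10(spec.e_threshold) + 0.05, 3)
        qname = f"cluster_{rep_of_cluster[c]}"
        tblout_lines.append(
            f"fam{f} {family_accession(f)} {qname} - cm 1 50 1 50 + no 1 "
            f"0.50 0.0 10.0 {e_val:.6e} ? -"
        )
    tblout_path = out / "hits.tblout"
    tblout_path.write_text("\n".join(tblout_lines) + "\n")

    # --- expected components, ranked ---------------------------------------
    component_zero = {
        f"cluster_{rep_of_cluster[ci]}"
        for ci in range(spec.n_clusters)
        if ci not in planted_cluster_ids
    }
    ranked = sorted(
        (
            (
                frozenset(f"cluster_{rep_of_cluster[c]}" for c in comp.clusters),
                frozenset(family_accession(f) for f in comp.families if
                          any(e[1] == f for e in comp.edges)),
            )
            for comp in spec.planted_components
        ),
        key=lambda cf: (-len(cf[0]), min(cf[0])),
    )

    truth = GroundTruth(
        chains=chains,
        filter_reasons=filter_reasons,
        clusters=clusters,
        component_zero=component_zero,
        components=ranked,
    )
    return ScenarioData(
        spec=spec,
        mmcif_dir=mmcif_dir,
        dictionary_path=dictionary_path,
        tblout_path=tblout_path,
        ground_truth=truth,
    )


def random_scenario(seed: int) -> ScenarioSpec:
    """Draw a small random scenario: 1–3 planted components plus extras.

    Each component gets 1–3 clusters and 1–2 families wired by a spanning
    edge plan plus optional extra edges; 0–3 edgeless clusters feed
    Component #0; chain multiplicities 1–3; a random subset of filter
    violations is planted.
    """
    rng = random.Random(seed)
    n_components = rng.randint(1, 3)
    planted: list[PlantedComponent] = []
    next_cluster = 0
    next_family = 0
    for _ in range(n_components):
        clus = list(range(next_cluster, next_cluster + rng.randint(1, 3)))
        fams = list(range(next_family, next_family + rng.randint(1, 2)))
        next_cluster, next_family = clus[-1] + 1, fams[-1] + 1
        # star through (clus[0], fams[0]) guarantees connectivity
        edges = [(c, fams[0]) for c in clus] + [(clus[0], f) for f in fams[1:]]
        for _ in range(rng.randint(0, 2)):  # redundant extra edges
            edge = (rng.choice(clus), rng.choice(fams))
            if edge not in edges:
                edges.append(edge)
        planted.append(PlantedComponent(clusters=clus, families=fams, edges=edges))
    n_edgeless = rng.randint(0, 3)
    n_clusters = next_cluster + n_edgeless
    multiplicities = {c: rng.randint(1, 3) for c in range(n_clusters)}
    violations = [
        (kind,) for kind in VIOLATION_KINDS if rng.random() < 0.4
    ]
    if rng.random() < 0.3:
        violations.append(("length", "resolution"))
    return ScenarioSpec(
        seed=rng.randrange(2**31),
        n_clusters=n_clusters,
        n_families=next_family,
        planted_components=planted,
        multiplicities=multiplicities,
        violations=violations,
    )
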