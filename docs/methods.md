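# Methods

## The problem and the model

Experimentally determined RNA 3D structures are scarce, highly redundant
(hundreds of deposits of the same ribosome), and structurally correlated far
below any practical sequence-identity threshold: homologous RNAs conserve
base-paired architecture while their sequences drift. A benchmark split of
PDB RNA chains is therefore only trustworthy if it separates *structural
families*, not sequences.

`rnasplit` formalizes this as a bipartite graph. Nodes are sequence clusters
of chains on one side and RNA family covariance models on the other; an
undirected, unweighted edge joins cluster *c* to family *f* whenever any
homology hit between them reaches the E-value threshold. Two chains can leak
structural information across a split only through some family both are
homologous to — i.e. through a path in this graph. Hence every maximally
connected subgraph (**Component**) is structurally independent of every
other Component by construction, and any assignment of whole Components to
training/validation/testing bins is leakage-free *with respect to the family
database used*. That conditionality is the method's main assumption: a
homology undetectable by the family models (or an RNA absent from the
database) is invisible to the graph. The generous default threshold exists
precisely to push this failure mode toward false-positive edges (harmless:
over-merging Components) rather than false negatives.

## Parameters that matter

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `min_length` | 32 | nt | shorter fragments are hard to distinguish from random sequence and from fragments of longer RNAs, risking hidden overlap between sides |
| `max_resolution` | 9.0 | Å | beyond this, atom positions carry too little signal to supervise on |
| `max_single_nt_fraction` | 0.80 | — | removes low-complexity/repetitive sequences |
| `max_unknown_fraction` | 0.30 | — | removes uninformative chains and non-RNA polymers that slip past the component-type test |
| `include_nmr` | false | — | NMR has no defined resolution; when included, resolution is read as 0.0 Å |
| clustering `identity` | 0.99 | — | matches over the shorter sequence, so substrings score 1.0 and co-cluster with their containing chain |
| graph `e_threshold` | 1.0 | — | deliberately lenient edge criterion (inclusive: E ≤ 1.0) |
| `strict_e_threshold` | 1e-3 | — | reporting tier for confidently assigned families in the hierarchy output |
| `train_fraction` | 0.70 | — | greedy target; Component #0 always tests (or is ignored) |

All four filter removals are strict inequalities; equality is kept. This is
stated explicitly because an off-by-one here shifts every downstream count.

Boundary and tie-break decisions, fixed for reproducibility where the
procedure itself is indifferent:

- **E-value boundary** is inclusive (an edge at exactly the threshold).
- **Component ranking**: cluster count descending, ties by the
  lexicographically smallest member cluster id. Component #0 is always the
  edgeless set, even when empty.
- **Representatives**: longest member, ties by smallest chain id; clusters
  are named `cluster_<representative>`.
- **Families with no edge** at the threshold are dropped rather than made
  singleton components: Components are defined by the chains they contain.
- **"Data" in the split fraction** counts sequence clusters, and the
  denominator includes Component #0 when it is routed to the test set — so
  "70 % training" describes the whole dataset, not just the classified part.
- **Multi-parent dictionary components** (hybrids) map to unknown rather
  than guessing a closest base; parent ascent is depth-limited (16) with
  cycle detection.
- **Chain sequences** come from the deposited polymer sequence scheme (the
  full entity sequence), not only residues with resolved coordinates — the
  deposition sequence is the stable object and the filters act on sequence
  composition. `modeled_only=True` restricts to resolved residues when the
  modeled subsequence is wanted instead.
- **Resolution** is the minimum over the categories present (refinement,
  EM reconstruction, reflections) — conservative and method-agnostic.

## External engines

Sequence clustering at scale and covariance-model searching are done by
external programs; both sit behind a single subprocess boundary with the
command line logged. The two-pass search contract: pass 1 with default
engine settings over all representatives; pass 2 with all heuristic filters
off (`--max`) over exactly the zero-hit queries; hits are tagged with their
pass. Hits are recorded per (query, family) pair and kept in full, so the
graph can be rebuilt at any threshold without re-searching; per-sequence
hit caching (SHA-256 of sequence + database tag) makes incremental updates
cheap — only new representatives are searched; changing the database tag
invalidates the cache. When the external clusterer is missing, a built-in
greedy representative-linkage clusterer is used (and is the default): chains
sorted by length descending join the first cluster whose representative they
match at the identity threshold. Its identity is computed from an edlib
infix alignment as (shorter length − edit distance)/shorter length — a lower
bound on matches over the shorter length, exact for the identical-or-
substring relations the 99 % threshold is meant to capture.

## What the synthetic generator emulates — and what it does not

The generator plants: miniature mmCIF files (only the categories the parser
contracts on: `chem_comp`, `pdbx_poly_seq_scheme`, resolution and method
fields), a toy component dictionary (canonical bases, one- and two-step
modified residues, a multi-parent hybrid, a parent cycle, an amino acid, a
DNA component), sequence clusters realized as exact copies and substrings of
random representatives, filter violations one predicate at a time, and a hit
table whose planted edges draw E-values log-uniform in [1e-12, threshold]
and whose decoy rows draw from (threshold, 1e3]. Every planted outcome is
recorded as ground truth, so end-to-end recovery is checked exactly.

It does **not** emulate: realistic covariance-model score distributions,
near-identical-but-mutated cluster members (planted members are exact
copies/substrings), multi-model NMR ensembles, or chains whose family
membership is ambiguous. Passing tests therefore demonstrate the logic of
parsing, filtering, clustering, graph construction and splitting — not the
biological fidelity of any particular family database, which enters only
through the external search engine on real data.

Scale: scenarios use 1–3 planted components, up to ~10 clusters and ~30
chains each; the acceptance checks run 1,000 random graphs (≤ 200 nodes) and
100 scenarios, sized so the whole suite completes in seconds while still
exercising every code path.

## Degenerate inputs and numerical notes

- `residue_to_one_letter` is total: any string maps into {A, C, G, U, N}.
- Empty chain lists, empty hit tables and empty graphs yield empty outputs,
  never errors; a hit naming an unknown cluster is a wiring bug and raises.
- An unachievable training fraction assigns all non-zero Components,
  flags `exhausted`, and reports the achieved fraction.
- Malformed dictionary blocks and malformed tblout rows are skipped with
  warnings; unreadable files are fatal.
- E-values round-trip losslessly through the TSV/tblout writers (`repr`
  formatting).

## Known limitations

- The leakage guarantee is relative to the family database: structural
  similarity invisible to the covariance models is invisible to the split.
- The internal clusterer is correctness-first and quadratic; large corpora
  should use the external engine (whose k-mer prefiltering is out of scope).
- Component #0 concentrates unclassifiable chains (synthetic constructs,
  mRNA fragments); routing it to the test set is conservative but means the
  test set contains sequences with no family annotation at all.
- Replicating published full-PDB dataset counts requires the exact PDB
  snapshot, family database release and engine versions; chain-level parsing
  of any single entry can be spot-checked cheaply, but full-scale homology
  searching is a multi-day compute job and is wrapped, not reimplemented,
  here.
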