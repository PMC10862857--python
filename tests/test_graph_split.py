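"""Bipartite graph construction, Components, ranking, and the greedy split."""

import random

import pytest

from rnasplit.graph_split import (
    Component,
    assert_no_leakage,
    build_graph,
    emit_hierarchy,
    find_components,
    load_split,
    split_components,
    split_multiway,
    write_hierarchy,
)
from rnasplit.homology import HitTable, HomologyHit

from conftest import make_chain
from rnasplit.clustering import SequenceCluster


def hit(cluster, family, e_value, pass_index=1):
    return HomologyHit(cluster_id=cluster, family_accession=family,
                       e_value=e_value, pass_index=pass_index)


def union_find_components(cluster_ids, edges):
    """Independent oracle: union-find over the bipartite node set.

    Returns (set of isolated cluster ids, set of frozenset({clusters},{families}))
    for the edge-bearing components.
    """
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in cluster_ids:
        find(("c", c))
    for c, f in edges:
        parent[find(("c", c))] = find(("f", f))
    groups = {}
    for node in list(parent):
        groups.setdefault(find(node), []).append(node)
    isolated, comps = set(), set()
    for members in groups.values():
        clus = frozenset(n for kind, n in members if kind == "c")
        fams = frozenset(n for kind, n in members if kind == "f")
        if not fams:
            isolated |= clus
        else:
            comps.add((clus, fams))
    return isolated, comps


def random_bipartite(rng):
    """Random cluster/family sets with E-values straddling the threshold."""
    n_c = rng.randint(1, 120)
    n_f = rng.randint(0, 80)
    clusters = [f"c{i}" for i in range(n_c)]
    hits = []
    for _ in range(rng.randint(0, 300)):
        if n_f == 0:
            break
        e = 10 ** rng.uniform(-12, 3)
        hits.append(hit(rng.choice(clusters), f"RF{rng.randrange(n_f):05d}", e))
    return clusters, HitTable(hits=hits)


class TestBuildGraph:
    def test_collapse_and_inclusive_boundary(self):
        table = HitTable(hits=[
            hit("c1", "RF00001", 0.5), hit("c1", "RF00001", 2.0),
            hit("c2", "RF00002", 1.0),
        ])
        g = build_graph(["c1", "c2"], table, e_threshold=1.0)
        assert g.edges == {("c1", "RF00001"), ("c2", "RF00002")}
        assert g.n_edges == 2

    def test_empty_hit_table_leaves_isolated_clusters(self):
        g = build_graph([f"c{i}" for i in range(5)], HitTable())
        assert len(g.cluster_nodes) == 5
        assert g.n_edges == 0 and g.family_nodes == set()

    def test_unknown_cluster_in_hit_is_wiring_error(self):
        with pytest.raises(ValueError, match="unknown cluster"):
            build_graph(["c1"], HitTable(hits=[hit("cX", "RF00001", 0.1)]))

    def test_multidomain_chain_bridges_family_groups(self):
        # a mitoribosome-like cluster hitting rRNA and tRNA families at once
        table = HitTable(hits=[
            hit("mito", "RF02541", 1e-9), hit("mito", "RF01960", 1e-9),
            hit("mito", "RF00005", 1e-4),
            hit("trna_only", "RF00005", 1e-20),
            hit("lsu_only", "RF02541", 1e-30),
        ])
        g = build_graph(["mito", "trna_only", "lsu_only"], table)
        comps = find_components(g)
        nonzero = [c for c in comps if c.index > 0]
        assert len(nonzero) == 1
        assert nonzero[0].cluster_ids == {"mito", "trna_only", "lsu_only"}


class TestFindComponents:
    def test_spec_example_with_isolated_cluster(self):
        table = HitTable(hits=[
            hit("c1", "RF00001", 0.1), hit("c2", "RF00001", 0.2),
            hit("c3", "RF00002", 0.3),
        ])
        g = build_graph(["c1", "c2", "c3", "c4"], table)
        comps = find_components(g)
        assert comps[0].index == 0 and comps[0].cluster_ids == {"c4"}
        assert comps[1].cluster_ids == {"c1", "c2"}
        assert comps[1].family_accessions == {"RF00001"}
        assert comps[2].cluster_ids == {"c3"}

    def test_shared_cluster_merges_families(self):
        table = HitTable(hits=[
            hit("c1", "RF00001", 0.1), hit("c2", "RF00001", 0.1),
            hit("c2", "RF00002", 0.1), hit("c3", "RF00002", 0.1),
        ])
        comps = find_components(build_graph(["c1", "c2", "c3"], table))
        nonzero = [c for c in comps if c.index > 0]
        assert len(nonzero) == 1
        assert nonzero[0].cluster_ids == {"c1", "c2", "c3"}
        assert nonzero[0].family_accessions == {"RF00001", "RF00002"}

    def test_empty_graph(self):
        assert find_components(build_graph([], HitTable())) == []

    def test_ranking_by_size_then_smallest_id(self):
        table = HitTable(hits=[
            hit("a1", "RF00001", 0.1),
            hit("b1", "RF00002", 0.1), hit("b2", "RF00002", 0.1),
            hit("a2", "RF00003", 0.1),
        ])
        comps = find_components(build_graph(["a1", "a2", "b1", "b2"], table))
        assert [c.cluster_ids for c in comps if c.index > 0] == [
            {"b1", "b2"}, {"a1"}, {"a2"},
        ]

    def test_n_chains_uses_cluster_sizes(self):
        table = HitTable(hits=[hit("c1", "RF00001", 0.1)])
        g = build_graph(["c1", "c2"], table)
        comps = find_components(g, cluster_sizes={"c1": 7, "c2": 3})
        assert {c.index: c.n_chains for c in comps} == {0: 3, 1: 7}

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_union_find_oracle(self, seed):
        rng = random.Random(seed)
        clusters, table = random_bipartite(rng)
        g = build_graph(clusters, table, e_threshold=1.0)
        comps = find_components(g)
        edges = [(h.cluster_id, h.family_accession)
                 for h in table.hits if h.e_value <= 1.0]
        iso, expected = union_find_components(clusters, edges)
        got_zero = next(c.cluster_ids for c in comps if c.index == 0)
        assert set(got_zero) == iso
        got = {(c.cluster_ids, c.family_accessions) for c in comps if c.index > 0}
        assert got == expected

    def test_threshold_monotonicity(self):
        rng = random.Random(77)
        clusters, table = random_bipartite(rng)
        comps_tight = find_components(build_graph(clusters, table, e_threshold=1e-3))
        comps_loose = find_components(build_graph(clusters, table, e_threshold=10.0))
        n_tight = sum(1 for c in comps_tight if c.index > 0)
        n_loose = sum(1 for c in comps_loose if c.index > 0)
        assert n_loose <= n_tight
        # raising the threshold only merges: every tight component's cluster
        # set is contained in exactly one loose component
        for t in comps_tight:
            if t.index == 0:
                continue
            containers = [
                l for l in comps_loose if l.index > 0 and t.cluster_ids <= l.cluster_ids
            ]
            assert len(containers) == 1

    def test_conservation_of_clusters_and_chains(self):
        rng = random.Random(5)
        clusters, table = random_bipartite(rng)
        sizes = {c: rng.randint(1, 9) for c in clusters}
        comps = find_components(build_graph(clusters, table), cluster_sizes=sizes)
        assert sum(c.n_sequences for c in comps) == len(clusters)
        assert sum(c.n_chains for c in comps) == sum(sizes.values())

    def test_leakage_assertion_fires_on_shared_family(self):
        bad = [
            Component(index=1, cluster_ids=frozenset({"c1"}),
                      family_accessions=frozenset({"RF00001"})),
            Component(index=2, cluster_ids=frozenset({"c2"}),
                      family_accessions=frozenset({"RF00001"})),
        ]
        with pytest.raises(AssertionError, match="RF00001"):
            assert_no_leakage(bad)


def components_of_sizes(sizes):
    """Component list from {index: n_sequences}; index 0 = edgeless."""
    comps = []
    for idx, n in sizes.items():
        comps.append(Component(
            index=idx,
            cluster_ids=frozenset(f"k{idx}_{j}" for j in range(n)),
            family_accessions=frozenset() if idx == 0 else frozenset({f"RF{idx:05d}"}),
            n_chains=n,
        ))
    return comps


class TestSplitComponents:
    def test_hand_example(self):
        comps = components_of_sizes({0: 4, 1: 50, 2: 30, 3: 10, 4: 6})
        result = split_components(comps, train_fraction=0.70)
        assert result.train == [1, 2]
        assert result.test == [0, 3, 4]
        assert result.train_fraction_achieved == pytest.approx(0.80)
        assert not result.exhausted

    def test_greedy_minimality(self):
        comps = components_of_sizes({0: 4, 1: 50, 2: 30, 3: 10, 4: 6})
        result = split_components(comps, train_fraction=0.70)
        total = 100
        without_last = sum(
            c.n_sequences for c in comps if c.index in result.train[:-1]
        )
        assert without_last / total < 0.70

    def test_full_fraction_with_ignore_policy_exhausts(self):
        comps = components_of_sizes({0: 4, 1: 50, 2: 30})
        result = split_components(comps, train_fraction=1.0, zero_policy="ignore")
        assert result.train == [1, 2] and result.test == []
        assert result.train_fraction_achieved == pytest.approx(1.0)

    def test_zero_policy_ignore_excludes_component_zero(self):
        comps = components_of_sizes({0: 40, 1: 50, 2: 30})
        kept = split_components(comps, train_fraction=0.5, zero_policy="ignore")
        assert 0 not in kept.train and 0 not in kept.test
        # denominator excludes component 0: 50/80 >= 0.5 after one component
        assert kept.train == [1]
        assert kept.train_fraction_achieved == pytest.approx(50 / 80)

    def test_unachievable_fraction_reports_exhaustion(self):
        comps = components_of_sizes({0: 90, 1: 5, 2: 5})
        result = split_components(comps, train_fraction=0.70)
        assert result.exhausted
        assert result.train == [1, 2]
        assert result.train_fraction_achieved == pytest.approx(0.10)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_components([], train_fraction=0.0)
        with pytest.raises(ValueError):
            split_components([], zero_policy="train")

    def test_multiway_three_bins(self):
        comps = components_of_sizes({0: 4, 1: 50, 2: 30, 3: 10, 4: 6})
        bins = split_multiway(comps, [0.5, 0.3, 0.2])
        assert bins[0] == [1]
        assert bins[1] == [2]
        assert bins[2] == [0, 3, 4]

    @pytest.mark.parametrize("seed", range(20))
    def test_achieved_fraction_meets_target_on_random_components(self, seed):
        rng = random.Random(seed)
        sizes = {0: rng.randint(0, 20)}
        for i in range(1, rng.randint(2, 12)):
            sizes[i] = rng.randint(1, 40)
        ordered = {0: sizes[0]}
        ranked = sorted((s for i, s in sizes.items() if i > 0), reverse=True)
        ordered.update({i + 1: s for i, s in enumerate(ranked)})
        comps = components_of_sizes(ordered)
        frac = rng.choice([0.3, 0.5, 0.7, 0.9])
        result = split_components(comps, train_fraction=frac)
        if not result.exhausted:
            assert result.train_fraction_achieved >= frac
        assert set(result.train) | set(result.test) == set(ordered)
        assert not set(result.train) & set(result.test)


class TestHierarchy:
    def build_toy(self):
        rng = random.Random(9)
        seqs = {f"s{i:03d}_A": "".join(rng.choice("ACGU") for _ in range(40 + i))
                for i in range(6)}
        chains = {fid: make_chain(fid, sequence=seq) for fid, seq in seqs.items()}
        clusters = [
            SequenceCluster(representative=chains["s000_A"],
                            members=[chains["s000_A"], chains["s001_A"]]),
            SequenceCluster(representative=chains["s002_A"],
                            members=[chains["s002_A"], chains["s003_A"], chains["s004_A"]]),
            SequenceCluster(representative=chains["s005_A"], members=[chains["s005_A"]]),
        ]
        table = HitTable(hits=[
            hit(clusters[0].cluster_id, "RF00001", 0.5),
            hit(clusters[1].cluster_id, "RF00002", 1e-6),
        ])
        g = build_graph(clusters, table)
        comps = find_components(g, cluster_sizes={c.cluster_id: c.n_chains for c in clusters})
        split = split_components(comps, train_fraction=0.6)
        return comps, split, clusters, table

    def test_leaf_chain_count_conserved(self):
        comps, split, clusters, table = self.build_toy()
        h = emit_hierarchy(comps, split, clusters, table)
        leaf_count = sum(
            len(cl["chains"])
            for side in ("train", "test")
            for comp in h[side].values()
            for cl in comp["clusters"].values()
        )
        assert leaf_count == 6
        per_level = sum(c["n_chains"] for side in ("train", "test")
                        for c in h[side].values())
        assert per_level == 6

    def test_strict_vs_lenient_family_tiers(self):
        comps, split, clusters, table = self.build_toy()
        h = emit_hierarchy(comps, split, clusters, table, strict_e=1e-3)
        all_comps = {**h["train"], **h["test"]}
        by_fams = {tuple(c["families_graph"]): c for c in all_comps.values()}
        # the E=0.5 hit is lenient-only; the 1e-6 hit is in both tiers
        assert by_fams[("RF00001",)]["families_strict"] == []
        assert by_fams[("RF00002",)]["families_strict"] == ["RF00002"]

    def test_split_round_trips_through_json(self, tmp_path):
        comps, split, clusters, table = self.build_toy()
        h = emit_hierarchy(comps, split, clusters, table)
        write_hierarchy(h, tmp_path / "hierarchy.json")
        again = load_split(tmp_path / "hierarchy.json")
        assert again.train == sorted(split.train)
        assert again.test == sorted(split.test)
        assert again.target_fraction == split.target_fraction
        assert again.zero_policy == split.zero_policy
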