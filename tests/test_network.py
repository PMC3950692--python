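"""Chromatin network construction, community partition and summaries."""

import numpy as np
import networkx as nx
import pytest

from mirchromnet.config import PipelineConfig
from mirchromnet.network import (
    GeneNetwork,
    TssIndex,
    build_network,
    filter_sv_blacklist,
    find_communities,
    link_genes_to_interaction,
    tad_overlap_report,
    topology_summary,
)
from mirchromnet.pipeline import (
    analyze_bundle,
    recovered_partition,
    restrict_partition,
)
from mirchromnet.types import GenomicInterval, make_duplex


def duplex(a, b, cell="K562", rep="r1"):
    return make_duplex(
        GenomicInterval(*a), GenomicInterval(*b), 2, cell, rep
    )


@pytest.fixture(scope="module")
def config():
    return PipelineConfig()


class TestBlacklist:
    def test_empty_blacklist_is_identity(self):
        ds = [duplex(("chr1", 0, 100), ("chr1", 500, 600))]
        assert filter_sv_blacklist(ds, []) == ds

    def test_abutting_interval_kept(self):
        ds = [duplex(("chr1", 0, 100), ("chr1", 500, 600))]
        kept = filter_sv_blacklist(ds, [GenomicInterval("chr1", 100, 200)])
        assert kept == ds
        gone = filter_sv_blacklist(ds, [GenomicInterval("chr1", 99, 200)])
        assert gone == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        ds = []
        for _ in range(300):
            chrom = f"chr{rng.integers(1, 4)}"
            s1, s2 = rng.integers(0, 100_000, size=2)
            ds.append(
                duplex((chrom, int(s1), int(s1) + 500), (chrom, int(s2), int(s2) + 500))
            )
        blacklist = [
            GenomicInterval(f"chr{rng.integers(1, 4)}", int(s), int(s) + 800)
            for s in rng.integers(0, 100_000, size=40)
        ]
        got = filter_sv_blacklist(ds, blacklist)
        expected = [
            d
            for d in ds
            if not any(
                d.anchor_a.overlaps(b) or d.anchor_b.overlaps(b) for b in blacklist
            )
        ]
        assert got == expected


class TestLinking:
    def test_window_overlap_forces_assignment(self, config):
        index = TssIndex({"g": ("chr1", 1_000)}, frozenset())
        assert index.entities_on_anchor(GenomicInterval("chr1", 2_500, 3_000), 2_000) == {"g"}
        assert index.entities_on_anchor(GenomicInterval("chr1", 3_001, 3_500), 2_000) == set()

    def test_cross_product_minus_self_pairs(self, config):
        index = TssIndex(
            {"g1": ("chr1", 1_000), "m1": ("chr1", 50_000), "g2": ("chr1", 51_000)},
            frozenset({"m1"}),
        )
        d = duplex(("chr1", 500, 1_500), ("chr1", 49_500, 50_500))
        pairs = link_genes_to_interaction(d, index, config)
        assert pairs == {frozenset(("g1", "m1")), frozenset(("g1", "g2"))}

    def test_colocated_entities_on_one_anchor_make_no_pair(self, config):
        index = TssIndex(
            {"a": ("chr1", 1_000), "b": ("chr1", 1_200)}, frozenset()
        )
        d = duplex(("chr1", 500, 1_500), ("chr2", 0, 100))
        assert link_genes_to_interaction(d, index, config) == set()


class TestBuildNetwork:
    INDEX = TssIndex(
        {"a": ("chr1", 1_000), "b": ("chr1", 100_000)}, frozenset()
    )

    def pair(self, cell, rep):
        return duplex(("chr1", 500, 1_500), ("chr1", 99_500, 100_500), cell, rep)

    def test_single_replicate_pair_absent(self, config):
        net = build_network([self.pair("K562", "r1")], self.INDEX, config)
        assert net.graph.number_of_edges() == 0

    def test_two_replicates_one_cell_retained(self, config):
        net = build_network(
            [self.pair("K562", "r1"), self.pair("K562", "r2")], self.INDEX, config
        )
        assert net.graph.has_edge("a", "b")
        assert net.graph.edges["a", "b"]["cell_status"] == ("K562",)

    def test_one_replicate_in_each_cell_not_enough(self, config):
        net = build_network(
            [self.pair("K562", "r1"), self.pair("MCF7", "r1")], self.INDEX, config
        )
        assert net.graph.number_of_edges() == 0

    def test_raising_replicate_threshold_is_monotone(self, bundle):
        base = PipelineConfig()
        res2 = analyze_bundle(bundle, base)
        res3 = analyze_bundle(bundle, base.replace(min_edge_replicates=3))
        e2 = set(map(frozenset, res2.network.graph.edges()))
        e3 = set(map(frozenset, res3.network.graph.edges()))
        assert e3 <= e2 and len(e3) < len(e2)

    def test_interaction_order_and_orientation_invariance(self, bundle, config, result):
        rng = np.random.default_rng(0)
        shuffled = list(bundle.interactions)
        rng.shuffle(shuffled)
        res_b = build_network(shuffled, result.tss_index, config)
        assert set(map(frozenset, res_b.graph.edges())) == set(
            map(frozenset, result.network.graph.edges())
        )


class TestCommunities:
    def net(self, edges):
        g = nx.Graph()
        for u, v in edges:
            g.add_edge(u, v, support={}, cell_status=("K562",))
        return GeneNetwork(g, frozenset())

    def test_two_components_giant_first(self):
        comms = find_communities(self.net([("a", "b"), ("b", "c"), ("d", "e")]))
        assert [set(c.members) for c in comms] == [{"a", "b", "c"}, {"d", "e"}]
        assert comms[0].is_giant and not comms[1].is_giant

    def test_empty_network_zero_communities(self):
        assert find_communities(self.net([])) == []

    def test_size_tie_breaks_to_smallest_member_id(self):
        comms = find_communities(self.net([("x", "y"), ("a", "b")]))
        assert comms[0].members == ("a", "b") and comms[0].is_giant

    def test_matches_dfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 80))
            g = nx.gnp_random_graph(n, 2.0 / n, seed=int(rng.integers(2**31)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            net = self.net([(str(u), str(v)) for u, v in g.edges()])
            got = {frozenset(c.members) for c in find_communities(net)}
            expected = {
                frozenset(map(str, comp))
                for comp in _dfs_components(
                    {str(u) for u in g.nodes},
                    {(str(u), str(v)) for u, v in g.edges()},
                )
            }
            assert got == expected

    def test_planted_partition_recovered_exactly(self, clean_bundle, clean_result):
        planted = restrict_partition(
            clean_bundle.truth.partition(), clean_bundle.truth.planted_entities
        )
        recovered = restrict_partition(
            recovered_partition(clean_result), clean_bundle.truth.planted_entities
        )
        assert planted == recovered


def _dfs_components(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.add(u)
            stack.extend(adj[u] - seen)
        comps.append(comp)
    return comps


class TestTopology:
    def test_star_graph_degrees(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = GeneNetwork(g, frozenset({"n1"}))
        comms = find_communities(net)
        summary = topology_summary(net, comms)
        degs = summary["node_degrees"]
        assert degs["n0"] == 5 and all(degs[f"n{i}"] == 1 for i in range(1, 6))

    def test_histogram_conserves_community_count(self, result):
        summary = topology_summary(result.network, result.communities)
        assert sum(summary["community_size_histogram"].values()) == len(
            result.communities
        )

    def test_single_group_comparison_not_applicable(self):
        g = nx.path_graph(4)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        net = GeneNetwork(g, frozenset())  # no MIR nodes at all
        summary = topology_summary(net, find_communities(net))
        assert summary["mir_vs_gene_degree"]["p"] is None


class TestTadOverlap:
    def test_all_members_inside_one_tad(self):
        index = TssIndex({"a": ("chr1", 100), "b": ("chr1", 200)}, frozenset())
        net = GeneNetwork(nx.Graph([("a", "b")]), frozenset())
        comms = find_communities(net)
        report = tad_overlap_report(comms, [GenomicInterval("chr1", 0, 1_000)], index)
        row = report.iloc[0]
        assert row.n_tads == 1 and row.fraction_in_tads == 1.0

    def test_no_tads_supplied(self, result):
        report = tad_overlap_report(result.communities, [], result.tss_index)
        assert (report.n_tads == 0).all() and (report.fraction_in_tads == 0).all()

    def test_matches_naive_containment_oracle(self, result):
        rng = np.random.default_rng(5)
        tads = [
            GenomicInterval(f"chr{c}", int(s), int(s) + 400_000)
            for c in range(1, 5)
            for s in rng.integers(0, 11_000_000, size=8)
        ]
        report = tad_overlap_report(result.communities, tads, result.tss_index)
        for c, row in zip(result.communities, report.itertuples()):
            hit_tads = set()
            inside = 0
            for m in c.members:
                chrom, pos = result.tss_index.tss[m]
                hits = [
                    i for i, t in enumerate(tads) if t.contains(chrom, pos)
                ]
                if hits:
                    inside += 1
                    hit_tads.update(hits)
            assert row.n_tads == len(hit_tads)
            assert row.fraction_in_tads == pytest.approx(inside / c.size)
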