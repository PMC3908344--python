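import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtfnet.fixtures import reference_gene_groups, reference_networks
from mirtfnet.markers import (
    PANEL_GROUPS,
    call_markers,
    classify_genes,
    compute_strategy_scores,
    containment_check,
    enrichment_rank_genes,
    key_nodes,
    select_panel_genes,
    shortest_path_members,
)
from mirtfnet.model import ConfigError, RegulatoryNetwork


def edgeless(cohort, genes):
    return RegulatoryNetwork.from_parts(cohort, genes=genes)


class TestClassifyGenes:
    def test_reference_fixture_groups(self):
        a, b, c = reference_networks()
        cls = classify_genes(a, b, c)
        assert cls.NSCLC_specific == {"E2F6", "TFDP1", "SUV39H1", "HNRPD"}
        assert cls.general_specific == {"RBL1", "IRF1", "HMGA1"}
        assert len(cls.common_SCLC_NSCLC) == 9
        assert cls.unique_SCLC == cls.common_SCLC_NSCLC == cls.common_all
        assert len(cls.common_NSCLC_general) == 14

    def test_identical_networks_collapse_to_common_all(self):
        genes = ["X", "Y", "Z"]
        cls = classify_genes(
            edgeless("NSCLC", genes), edgeless("SCLC", genes), edgeless("common", genes)
        )
        assert cls.common_all == set(genes)
        assert cls.NSCLC_specific == frozenset()
        assert cls.general_specific == frozenset()
        assert cls.unique_SCLC == cls.common_all

    def test_disjoint_networks_populate_unique_groups_only(self):
        cls = classify_genes(
            edgeless("NSCLC", ["A1"]), edgeless("SCLC", ["B1"]), edgeless("common", ["C1"])
        )
        assert cls.NSCLC_specific == {"A1"}
        assert cls.unique_SCLC == {"B1"}
        assert cls.general_specific == {"C1"}
        assert cls.common_all == cls.common_SCLC_NSCLC == frozenset()
        assert cls.common_NSCLC_general == frozenset()

    def test_mirna_nodes_excluded(self):
        a = edgeless("NSCLC", ["G"])
        a.add_node("miR-1", "mirna")
        cls = classify_genes(a, edgeless("SCLC", []), edgeless("common", []))
        assert cls.NSCLC_specific == {"G"}

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_partition_property_under_containment(self, data):
        # the six-group schema presumes the SCLC set is inside the NSCLC set
        pool = [f"g{i}" for i in range(12)]
        a = set(data.draw(st.sets(st.sampled_from(pool))))
        b = set(data.draw(st.sets(st.sampled_from(sorted(a) or pool), max_size=len(a) or 1))) & a
        c = set(data.draw(st.sets(st.sampled_from(pool))))
        cls = classify_genes(
            edgeless("NSCLC", a), edgeless("SCLC", b), edgeless("common", c)
        )
        groups = cls.as_dict()
        # each network's gene set reassembles exactly from its groups
        assert (
            groups["common_SCLC_NSCLC"] | groups["common_all"]
            | groups["common_NSCLC_general"] | groups["NSCLC_specific"]
        ) == a
        assert groups["unique_SCLC"] == b
        assert (
            groups["common_all"] | groups["common_NSCLC_general"]
            | groups["general_specific"] | (b & c)
        ) == c
        # groups 4-6 are pairwise disjoint and disjoint from groups 2-3
        for x, y in itertools.combinations(
            ["common_NSCLC_general", "NSCLC_specific", "general_specific"], 2
        ):
            assert not groups[x] & groups[y]
        for x in ("common_NSCLC_general", "NSCLC_specific", "general_specific"):
            assert not groups[x] & groups["common_all"]
        if b <= c:
            assert groups["unique_SCLC"] == groups["common_SCLC_NSCLC"] == groups["common_all"]


class TestContainment:
    def test_reference_sclc_inside_nsclc(self):
        a, b, _ = reference_networks()
        holds, witness = containment_check(b, a)
        assert holds and witness == frozenset()

    def test_single_foreign_gene_witnessed(self):
        a, b, _ = reference_networks()
        b = b.copy()
        b.add_node("FAKE1")
        holds, witness = containment_check(b, a)
        assert not holds
        assert witness == {"FAKE1"}

    def test_empty_subnetwork_contained(self):
        holds, witness = containment_check(
            RegulatoryNetwork("SCLC"), edgeless("NSCLC", ["G"])
        )
        assert holds and witness == frozenset()


class TestKeyNodes:
    def test_star_hub(self):
        net = RegulatoryNetwork.from_parts(
            "common", genes=["H", "A", "B", "C"],
            edges=[("H", "A", "ppi"), ("H", "B", "ppi"), ("H", "C", "ppi")],
        )
        assert key_nodes(net, 1) == {"H"}

    def test_degree_ties_all_returned(self):
        net = RegulatoryNetwork.from_parts(
            "common", genes=["A", "B", "C"],
            edges=[("A", "B", "ppi"), ("B", "C", "ppi"), ("A", "C", "ppi")],
        )
        assert key_nodes(net, 1) == {"A", "B", "C"}

    def test_nonpositive_k_rejected(self):
        net = edgeless("common", ["A"])
        with pytest.raises(ConfigError):
            key_nodes(net, 0)

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_degree_sort(self, data):
        genes = [f"g{i}" for i in range(data.draw(st.integers(3, 20)))]
        net = RegulatoryNetwork.from_parts("common", genes=genes)
        for a, b in itertools.combinations(genes, 2):
            if data.draw(st.booleans()):
                net.add_edge(a, b, "ppi")
        k = data.draw(st.integers(1, len(genes)))
        selected = key_nodes(net, k)
        degrees = {g: net.degree(g) for g in genes}
        ranked = sorted(genes, key=lambda g: -degrees[g])
        cutoff = degrees[ranked[min(k, len(genes)) - 1]]
        expected = {g for g in genes if degrees[g] >= cutoff}
        assert selected == expected
        assert len(selected) >= min(k, len(genes))


class TestShortestPathMembers:
    def test_path_graph(self):
        net = RegulatoryNetwork.from_parts(
            "common", genes=["A", "B", "C"],
            edges=[("A", "B", "ppi"), ("B", "C", "ppi")],
        )
        assert shortest_path_members(net, {"A", "C"}) == {"A", "B", "C"}

    def test_disconnected_endpoints_only(self):
        net = edgeless("common", ["A", "B"])
        assert shortest_path_members(net, {"A", "B"}) == {"A", "B"}

    def test_single_endpoint(self):
        net = edgeless("common", ["A", "B"])
        assert shortest_path_members(net, {"A"}) == {"A"}

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_matches_all_shortest_paths_enumeration(self, data):
        genes = [f"g{i}" for i in range(data.draw(st.integers(3, 15)))]
        net = RegulatoryNetwork.from_parts("common", genes=genes)
        for a, b in itertools.combinations(genes, 2):
            if data.draw(st.integers(0, 3)) == 0:
                net.add_edge(a, b, "ppi")
        endpoints = set(data.draw(
            st.sets(st.sampled_from(genes), min_size=2)
        ))
        graph = net.to_undirected()
        expected = set(endpoints)
        for s, t in itertools.combinations(sorted(endpoints), 2):
            if nx.has_path(graph, s, t):
                for path in nx.all_shortest_paths(graph, s, t):
                    expected.update(path)
        assert shortest_path_members(net, endpoints) == expected


class TestEnrichmentRank:
    def test_gene_in_no_set_excluded(self):
        net = edgeless("common", ["A", "B"])
        universe = {"A", "B", "C", "D"}
        selected, ranks = enrichment_rank_genes(
            net, {"s": {"A"}}, universe, top_n=5
        )
        assert "B" not in selected and "B" not in ranks
        assert selected == {"A"}

    def test_single_set_covering_network_all_tie(self):
        net = edgeless("common", ["A", "B"])
        universe = {"A", "B", "C"}
        selected, ranks = enrichment_rank_genes(
            net, {"s": {"A", "B"}}, universe, top_n=1
        )
        assert selected == {"A", "B"}
        assert ranks == {"A": 1, "B": 1}

    def test_planted_disease_sets_rank_markers_first(self, default_bundle, default_run):
        net = default_run.networks["NSCLC"]
        universe = default_bundle.gene_universe()
        selected, ranks = enrichment_rank_genes(
            net, default_bundle.disease_sets, universe, top_n=10
        )
        planted = set(default_bundle.truth["planted_A"])
        assert planted <= selected
        # all planted cohort-A markers share one rank (same disease set)
        assert len({ranks[g] for g in planted}) == 1
        decoys = set(default_bundle.truth["decoys"]) & net.gene_nodes()
        assert not decoys & selected


class TestCallMarkers:
    def _trivial_scores(self, nets):
        a, b, c = nets
        cls = classify_genes(a, b, c)
        universe = a.gene_nodes() | b.gene_nodes() | c.gene_nodes()
        panels = []
        for cohort, net in (("NSCLC", a), ("common", c)):
            scores = compute_strategy_scores(
                net,
                {"everything": universe},
                universe,
                key_top=len(net.gene_nodes()),
                top_n=len(universe),
            )
            panels.append(call_markers(scores, cls, "intersection", cohort))
        return cls, panels

    def test_reference_panel_has_seven_genes(self):
        nets = reference_networks()
        _, panels = self._trivial_scores(nets)
        panel = select_panel_genes(panels)
        groups = reference_gene_groups()
        assert panel == groups["NSCLC_specific"] | groups["general_specific"]
        assert len(panel) == 7

    def test_panel_records_carry_all_strategies(self):
        nets = reference_networks()
        _, panels = self._trivial_scores(nets)
        for p in panels:
            for record in p.records:
                assert record.strategies == {
                    "key_node", "shortest_path", "enrichment_rank",
                }
                assert record.expected_direction == "unknown"

    def test_one_empty_strategy_empties_intersection_panel(self):
        a, b, c = reference_networks()
        cls = classify_genes(a, b, c)
        universe = a.gene_nodes()
        scores = compute_strategy_scores(
            # disease sets disjoint from the network: enrichment selects nobody
            a, {"unrelated": {"ZZZ9"}}, universe | {"ZZZ9"},
            key_top=len(universe), top_n=5,
        )
        panel = call_markers(scores, cls, "intersection", "NSCLC")
        assert len(panel) == 0

    def test_majority_policy_superset_of_intersection(self):
        from mirtfnet.synth import SyntheticConfig, generate_bundle
        from tests.conftest import run_bundle

        for seed in range(6):
            bundle = generate_bundle(SyntheticConfig(seed=seed))
            res = run_bundle(bundle)
            for cohort in ("NSCLC", "common"):
                net = res.networks[cohort]
                if not net.gene_nodes():
                    continue
                scores = compute_strategy_scores(
                    net, bundle.disease_sets, bundle.gene_universe()
                )
                inter = call_markers(scores, res.classification, "intersection", cohort)
                major = call_markers(scores, res.classification, "majority", cohort)
                assert inter.genes <= major.genes

    def test_unknown_policy_rejected(self):
        a, b, c = reference_networks()
        cls = classify_genes(a, b, c)
        with pytest.raises(ConfigError):
            call_markers({}, cls, "unanimity")

    def test_panel_groups_are_the_specific_ones(self):
        assert PANEL_GROUPS == ("NSCLC_specific", "general_specific")
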