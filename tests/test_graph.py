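"""Graph model: sides, construction from variants, DAG orientation."""

import pytest

from gpbwt import (
    BidirectedGraph,
    GraphError,
    VariantSpec,
    build_from_variants,
    dag_orientation,
    node_of,
    opposite,
)
from gpbwt.threads import orientation_sequence

from conftest import make_worked_graph


class TestSides:
    @pytest.mark.parametrize("s, expected", [(5, 6), (6, 5), (1, 2), (2, 1)])
    def test_opposite_pairs_left_and_right(self, s, expected):
        assert opposite(s) == expected

    def test_opposite_is_fixed_point_free_involution(self):
        for s in range(1, 201):
            assert opposite(s) != s
            assert opposite(opposite(s)) == s

    def test_null_side_has_no_opposite_and_no_node(self):
        with pytest.raises(GraphError):
            opposite(0)
        with pytest.raises(GraphError):
            node_of(0)

    @pytest.mark.parametrize("s, nid", [(9, 5), (10, 5), (1, 1)])
    def test_node_of(self, s, nid):
        assert node_of(s) == nid


class TestGraphInvariants:
    def test_duplicate_edges_rejected(self):
        g = make_worked_graph()
        with pytest.raises(GraphError):
            g.add_edge(2, 5)
        with pytest.raises(GraphError):
            g.add_edge(5, 2)

    def test_edges_must_reference_real_sides(self):
        g = BidirectedGraph()
        g.add_node(1, "A")
        with pytest.raises(GraphError):
            g.add_edge(1, 3)

    def test_adjacent_sides_sorted_ascending(self):
        g = make_worked_graph()
        assert g.adjacent_sides(5) == [2, 4]
        assert g.adjacent_sides(9) == [6, 10]
        assert g.adjacent_sides(8) == [8]  # self-loop appears once
        assert g.adjacent_sides(1) == []

    def test_frozen_graph_rejects_mutation(self):
        g = make_worked_graph().freeze()
        with pytest.raises(GraphError):
            g.add_node(6, "C")
        with pytest.raises(GraphError):
            g.add_edge(1, 3)


class TestBuildFromVariants:
    def test_single_snp_splits_reference_into_four_nodes(self):
        g, amap = build_from_variants("GATTACA", [VariantSpec(3, "T", "C")])
        assert sorted(g.nodes.values()) == ["ACA", "C", "GAT", "T"]
        assert len(g.edges) == 4
        # alt node sides attach to everything the ref-allele node attaches to
        ref_node, alt_node = amap.variant_nodes[0]
        assert g.nodes[ref_node] == "T" and g.nodes[alt_node] == "C"
        assert g.adjacent_sides(2 * alt_node - 1) == g.adjacent_sides(2 * ref_node - 1)
        assert g.adjacent_sides(2 * alt_node) == g.adjacent_sides(2 * ref_node)

    def test_no_variants_yields_single_node(self):
        g, amap = build_from_variants("ACGT", [])
        assert list(g.nodes.values()) == ["ACGT"]
        assert g.edges == []
        assert amap.chain == (1,)

    def test_insertion_allele(self):
        g, _ = build_from_variants("ACGT", [VariantSpec(1, "C", "CTT")])
        assert sorted(g.nodes.values()) == ["A", "C", "CTT", "GT"]
        assert len(g.edges) == 4

    def test_overlapping_variants_rejected(self):
        with pytest.raises(GraphError):
            build_from_variants(
                "GATTACA",
                [VariantSpec(2, "TTA", "G"), VariantSpec(3, "TA", "C")],
            )

    def test_ref_allele_mismatch_rejected(self):
        with pytest.raises(GraphError):
            build_from_variants("GATTACA", [VariantSpec(3, "A", "C")])

    def test_identical_intervals_share_ref_node(self):
        # split multiallelic: two alts over the same reference base
        g, amap = build_from_variants(
            "GATTACA", [VariantSpec(3, "T", "C"), VariantSpec(3, "T", "G")]
        )
        assert amap.variant_nodes[0][0] == amap.variant_nodes[1][0]
        assert len(g.nodes) == 5

    def test_reference_walk_spells_reference(self):
        ref = "GATTACATTAGGA"
        variants = [VariantSpec(2, "T", "A"), VariantSpec(7, "TTA", "T")]
        g, amap = build_from_variants(ref, variants)
        walk = []
        for node in amap.chain:
            walk.append(2 * node - 1)
            walk.append(2 * node)
        assert orientation_sequence(walk, g) == ref

    def test_interior_snp_count_formula(self):
        # n well-separated interior SNPs: n alt + n ref-allele + (n+1) flanks
        ref = "ACGTACGTACGTACGTACGT"
        positions = [2, 7, 12, 17]
        variants = [VariantSpec(p, ref[p], "A" if ref[p] != "A" else "C") for p in positions]
        g, _ = build_from_variants(ref, variants)
        n = len(positions)
        assert len(g.nodes) == 2 * n + (n + 1)

    def test_adjacent_snps_create_no_empty_nodes(self):
        g, amap = build_from_variants(
            "GATTACA", [VariantSpec(3, "T", "C"), VariantSpec(4, "A", "G")]
        )
        assert all(len(seq) >= 1 for seq in g.nodes.values())
        # alt of first site connects straight to both alleles of second site
        alt1 = amap.variant_nodes[0][1]
        ref2, alt2 = amap.variant_nodes[1]
        assert g.has_edge(2 * alt1, 2 * ref2 - 1)
        assert g.has_edge(2 * alt1, 2 * alt2 - 1)


class TestDagOrientation:
    def test_snp_graph_is_dag_orientable(self):
        g, amap = build_from_variants("GATTACA", [VariantSpec(3, "T", "C")])
        order = dag_orientation(g)
        assert order
        pos = {nid: i for i, nid in enumerate(order)}
        ref_node, alt_node = amap.variant_nodes[0]
        assert pos[amap.chain[0]] < pos[ref_node] < pos[amap.chain[-1]]
        assert pos[amap.chain[0]] < pos[alt_node] < pos[amap.chain[-1]]

    def test_worked_graph_is_not_dag_orientable(self):
        failure = dag_orientation(make_worked_graph())
        assert not failure
        assert failure.offending_edge in {(8, 8), (9, 10)}

    def test_empty_graph_succeeds_with_empty_order(self):
        assert dag_orientation(BidirectedGraph()) == []

    def test_failure_names_cycle(self):
        g = BidirectedGraph()
        g.add_node(1, "A")
        g.add_node(2, "C")
        g.add_edge(2, 3)  # right of 1 -> left of 2
        g.add_edge(4, 1)  # right of 2 -> left of 1: cycle
        failure = dag_orientation(g)
        assert not failure
        assert failure.cycle == (1, 2)

    def test_topological_order_respects_edges(self):
        ref = "ACGTACGTACGT"
        variants = [VariantSpec(3, "T", "G"), VariantSpec(8, "A", "T")]
        g, _ = build_from_variants(ref, variants)
        order = dag_orientation(g)
        assert order
        pos = {nid: i for i, nid in enumerate(order)}
        for a, b in g.edges:
            right, left = (a, b) if a % 2 == 0 else (b, a)
            assert pos[node_of(right)] < pos[node_of(left)]
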