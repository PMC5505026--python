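"""gPBWT core: B[]/c() construction, navigation, extraction, counting."""

from collections import Counter

import pytest

from gpbwt import GPBWTIndex, SearchRange, Thread, random_graph, reverse_orientation
from gpbwt.index import IndexError_
from gpbwt.threads import visits

from conftest import (
    EXPECTED_B,
    EXPECTED_C,
    THREAD_A,
    THREAD_B,
    make_worked_graph,
    random_threads,
)


def brute_force_count(orientations, query) -> int:
    """Occurrences of query as a contiguous side subsequence of orientations."""
    q = tuple(query)
    n = 0
    for t in orientations:
        for i in range(0, len(t) - len(q) + 1, 2):
            if t[i : i + len(q)] == q:
                n += 1
    return n


class TestWorkedExample:
    def test_b_arrays_match_published_state(self, worked_index):
        for side, expected in EXPECTED_B.items():
            assert worked_index.b_array(side) == expected, f"B[{side}]"

    def test_c_values_match_published_state(self, worked_index):
        for (x, s), expected in EXPECTED_C.items():
            assert worked_index.c_value(x, s) == expected, f"c({x},{s})"

    def test_starts_at(self, worked_index):
        assert worked_index.starts_at(1) == 1  # isolated side, one entry
        assert worked_index.starts_at(5) == 0
        assert worked_index.starts_at(7) == 1
        empty = GPBWTIndex(make_worked_graph())
        assert all(empty.starts_at(s) == 0 for s in empty.graph.sides())

    @pytest.mark.parametrize(
        "side, i, next_side, expected",
        [(5, 0, 9, 0), (9, 0, 9, 1), (5, 2, 7, 2)],
    )
    def test_where_to(self, worked_index, side, i, next_side, expected):
        assert worked_index.where_to(side, i, next_side) == expected

    def test_where_to_null_side_errors(self, worked_index):
        with pytest.raises(IndexError_):
            worked_index.where_to(5, 0, 0)

    def test_extraction_recovers_all_four_orientations(self, worked_index):
        expected = {
            THREAD_A,
            reverse_orientation(THREAD_A),
            THREAD_B,
            reverse_orientation(THREAD_B),
        }
        assert set(worked_index.extract_orientations()) == expected

    def test_extract_threads_halves_multiplicity(self, worked_index):
        threads = worked_index.extract_threads()
        assert threads == Counter(
            {Thread.from_orientation(THREAD_A): 1, Thread.from_orientation(THREAD_B): 1}
        )

    @pytest.mark.parametrize(
        "query, expected",
        [
            ((5, 6), 2),
            ((5, 6, 9, 10), 1),
            ((1, 2, 7, 8), 0),
            ((7, 8, 8, 7), 2),  # self-loop traversal, both orientations
            ((9, 10, 9, 10), 1),
        ],
    )
    def test_count_subthread(self, worked_index, query, expected):
        assert worked_index.count_subthread(query) == expected
        assert worked_index.count_subthread(reverse_orientation(query)) == expected

    def test_extend_search_steps(self, worked_index):
        r = worked_index.search_start(5)
        assert (r.f, r.g) == (0, 2)
        r2 = worked_index.extend_search(r, 9)
        assert (r2.side, r2.f, r2.g) == (9, 0, 1)
        r3 = worked_index.extend_search(SearchRange(5, 0, 0), 9)
        assert r3.is_empty

    def test_self_loop_c_value_regression(self, worked_index):
        # the oriented self-loop occupies its slot in adjacency order like
        # any other far endpoint
        assert worked_index.c_value(8, 8) == 0
        assert worked_index.graph.adjacent_sides(8) == [8]


class TestEmbedding:
    def test_single_node_thread_into_empty_index(self):
        idx = GPBWTIndex(make_worked_graph())
        idx.embed_orientation((1, 2))
        assert idx.b_array(1) == [0]
        assert all(idx.b_length(s) == 0 for s in idx.graph.sides() if s != 1)

    def test_invalid_thread_leaves_index_unchanged(self, worked_index):
        before = worked_index.serialize()
        with pytest.raises(IndexError_):
            worked_index.embed_orientation((1, 2, 7, 8))
        assert worked_index.serialize() == before

    def test_embed_thread_adds_two_orientations(self, worked_index):
        assert worked_index.n_orientations == 4
        worked_index.embed_thread(THREAD_A)
        assert worked_index.n_orientations == 6

    def test_reembedding_doubles_run_lengths_not_run_count(self):
        g = make_worked_graph()
        once = GPBWTIndex(g)
        once.embed_thread(THREAD_A)
        once.embed_thread(THREAD_B)
        twice = GPBWTIndex(g)
        for _ in range(2):
            twice.embed_thread(THREAD_A)
            twice.embed_thread(THREAD_B)
        for s in g.sides():
            assert twice.b_length(s) == 2 * once.b_length(s)
            if once.b_length(s):
                assert twice.B[s].run_count == once.B[s].run_count

    def test_conservation_invariant_maintained_during_embedding(self):
        g = random_graph(20, rng=3)
        idx = GPBWTIndex(g)
        for t in random_threads(g, 15, seed=4):
            idx.embed_thread(t)
            idx.check_conservation()

    def test_c_monotone_in_far_endpoint(self):
        g = random_graph(25, rng=9)
        idx = GPBWTIndex(g)
        for t in random_threads(g, 20, seed=10):
            idx.embed_thread(t)
        for s in g.sides():
            adj = g.adjacent_sides(s)
            values = [idx.c_value(x, s) for x in adj]
            assert values == sorted(values)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_embed_extract_inverts_on_random_graphs(self, seed):
        g = random_graph(30, rng=seed, n_prob=0.02)
        threads = random_threads(g, 25, seed=seed + 100)
        idx = GPBWTIndex(g)
        for t in threads:
            idx.embed_thread(t)
        assert idx.extract_threads() == Counter(
            Thread.from_orientation(t) for t in threads
        )

    def test_duplicate_thread_multiplicity(self):
        g = make_worked_graph()
        idx = GPBWTIndex(g)
        idx.embed_thread(THREAD_A)
        idx.embed_thread(THREAD_A)
        assert idx.extract_threads() == Counter({Thread.from_orientation(THREAD_A): 2})

    def test_empty_index_extracts_nothing(self):
        idx = GPBWTIndex(make_worked_graph())
        assert idx.extract_orientations() == []
        assert idx.extract_threads() == Counter()


class TestCountingOracle:
    @pytest.mark.parametrize("seed", range(4))
    def test_counts_agree_with_brute_force(self, seed):
        import random

        g = random_graph(25, rng=seed * 7 + 1)
        threads = random_threads(g, 20, seed=seed + 50)
        idx = GPBWTIndex(g)
        for t in threads:
            idx.embed_thread(t)
        orientations = idx.extract_orientations()
        rng = random.Random(seed)
        for _ in range(100):
            base = rng.choice(orientations)
            i = rng.randrange(0, len(base), 2)
            j = rng.randrange(i + 2, len(base) + 1, 2)
            query = base[i:j]
            if rng.random() < 0.5:
                query = reverse_orientation(query)
            assert idx.count_subthread(query) == brute_force_count(
                orientations, query
            )

    def test_monotone_narrowing(self, worked_index):
        t = THREAD_A
        counts = [
            worked_index.count_subthread(t[: 2 * k]) for k in range(1, len(t) // 2 + 1)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_graph_invalid_queries_count_zero(self, worked_index):
        assert worked_index.count_subthread((1, 2, 7, 8)) == 0  # no edge
        assert worked_index.count_subthread((1, 3)) == 0  # not opposites
        assert worked_index.count_subthread((99, 100)) == 0  # absent side
        assert worked_index.count_subthread(()) == 0

    def test_single_node_query_counts_all_visits(self, worked_index):
        assert worked_index.count_subthread((5, 6)) == worked_index.b_length(5)
        assert worked_index.count_subthread((6, 5)) == worked_index.b_length(6)


class TestSerialization:
    def test_round_trip_preserves_everything(self, worked_index):
        g = worked_index.graph
        data = worked_index.serialize()
        back = GPBWTIndex.deserialize(data, g)
        assert back.serialize() == data
        assert back.extract_threads() == worked_index.extract_threads()
        for s in g.sides():
            assert back.b_array(s) == worked_index.b_array(s)

    def test_wrong_graph_rejected(self, worked_index):
        other = random_graph(4, rng=0)
        with pytest.raises(IndexError_):
            GPBWTIndex.deserialize(worked_index.serialize(), other)

    def test_malformed_data_rejected(self, worked_index):
        data = worked_index.serialize()
        with pytest.raises(IndexError_):
            GPBWTIndex.deserialize(data[:40], worked_index.graph)
        with pytest.raises(IndexError_):
            GPBWTIndex.deserialize(b"junk" + data, worked_index.graph)
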