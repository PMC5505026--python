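import random

import pytest

from gpbwt import BidirectedGraph, GPBWTIndex, random_walk


FIG_EDGES = [(2, 5), (4, 5), (6, 7), (6, 9), (8, 8), (10, 9)]
THREAD_A = (1, 2, 5, 6, 9, 10, 9, 10)
THREAD_B = (3, 4, 5, 6, 7, 8, 8, 7)

# Published worked-example state for the two-thread five-node graph.
EXPECTED_B = {
    1: [5],
    2: [0],
    3: [5],
    4: [0],
    5: [9, 7],
    6: [4, 2],
    7: [8, 8],
    8: [6, 0],
    9: [9, 0],
    10: [10, 6],
}
EXPECTED_C = {
    (2, 5): 0,
    (4, 5): 1,
    (6, 7): 1,
    (6, 9): 0,
    (8, 8): 0,
    (10, 9): 1,
    (5, 2): 0,
    (5, 4): 0,
    (7, 6): 0,
    (9, 6): 1,
}


def make_worked_graph() -> BidirectedGraph:
    g = BidirectedGraph()
    for nid in range(1, 6):
        g.add_node(nid, "A")
    for a, b in FIG_EDGES:
        g.add_edge(a, b)
    return g


@pytest.fixture
def worked_graph() -> BidirectedGraph:
    return make_worked_graph()


@pytest.fixture
def worked_index(worked_graph) -> GPBWTIndex:
    idx = GPBWTIndex(worked_graph)
    idx.embed_thread(THREAD_A)
    idx.embed_thread(THREAD_B)
    return idx


def random_threads(g, n_threads: int, seed: int, max_bp: int = 12) -> list[tuple[int, ...]]:
    """Random valid threads for a graph, via resampled random walks."""
    rng = random.Random(seed)
    threads = []
    attempts = 0
    while len(threads) < n_threads and attempts < n_threads * 50:
        attempts += 1
        w = random_walk(g, rng.randint(1, max_bp), rng)
        if w:
            threads.append(w)
    return threads
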