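import itertools
from functools import lru_cache

import numpy as np
import pytest

from mcnet import covnet, synth
from mcnet.graphlets import GRAPHLET_EDGES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    spec = synth.CohortSpec(n_subjects=60, n_vertices=40, n_components=2, seed=11)
    return synth.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_network(small_cohort):
    return covnet.covariance_network(covnet.residualize(small_cohort))


# ---------------------------------------------------------------------------
# independent brute-force graphlet oracle (subset enumeration, own
# canonicalization; shares no counting code with the package)


@lru_cache(maxsize=None)
def _oracle_pairs(k):
    return tuple(itertools.combinations(range(k), 2))


@lru_cache(maxsize=None)
def _oracle_canon(k, mask):
    pairs = _oracle_pairs(k)
    index = {p: i for i, p in enumerate(pairs)}
    best = mask
    for perm in itertools.permutations(range(k)):
        out = 0
        for i, (a, b) in enumerate(pairs):
            if mask >> i & 1:
                pa, pb = perm[a], perm[b]
                out |= 1 << index[(min(pa, pb), max(pa, pb))]
        best = min(best, out)
    return best


@lru_cache(maxsize=None)
def _oracle_class_table():
    table = {}
    for gid, edges in enumerate(GRAPHLET_EDGES):
        k = max(max(e) for e in edges) + 1
        pairs = _oracle_pairs(k)
        index = {p: i for i, p in enumerate(pairs)}
        mask = 0
        for a, b in edges:
            mask |= 1 << index[(min(a, b), max(a, b))]
        table[(k, _oracle_canon(k, mask))] = gid
    return table


def _oracle_connected(k, mask):
    pairs = _oracle_pairs(k)
    adj = {i: set() for i in range(k)}
    for i, (a, b) in enumerate(pairs):
        if mask >> i & 1:
            adj[a].add(b)
            adj[b].add(a)
    seen = {0}
    frontier = [0]
    while frontier:
        v = frontier.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                frontier.append(u)
    return len(seen) == k


def brute_force_census(n_nodes, edges):
    """Count connected induced subgraphs on 2-5 nodes by subset enumeration."""
    adj = [set() for _ in range(n_nodes)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    counts = np.zeros(30, dtype=np.int64)
    table = _oracle_class_table()
    for k in (2, 3, 4, 5):
        pairs = _oracle_pairs(k)
        for sub in itertools.combinations(range(n_nodes), k):
            mask = 0
            for i, (a, b) in enumerate(pairs):
                if sub[b] in adj[sub[a]]:
                    mask |= 1 << i
            if not _oracle_connected(k, mask):
                continue
            counts[table[(k, _oracle_canon(k, mask))]] += 1
    return counts
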