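"""Graphlet census of thresholded covariance networks.

Thresholds the correlation matrix at a signed cutoff (edges with rho <= t
for t < 0, rho >= t for t > 0), counts connected induced subgraphs on 2-5
nodes over the 30 isomorphism classes G0-G29 in the conventional graphlet
order, and normalizes counts with

    fstar_i = log10(1 + (f_i + 1) / sum_j (f_j + 1))

Counting is exact (enumeration of connected induced subgraphs with
canonical-form classification) or sampled (a lift-and-reweight
Horvitz-Thompson estimator with exactly computed inclusion probabilities,
unbiased against the exact census, with per-class standard errors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from pathlib import Path
from typing import Optional

import numpy as np

from mcnet.covnet import CovarianceNetwork

__all__ = [
    "GraphletCatalog",
    "ThresholdedGraph",
    "GraphletCensus",
    "NormalizedCensus",
    "build_catalog",
    "threshold_graph",
    "census_exact",
    "census_sampled",
    "normalize_census",
    "classify_edges",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "GRAPHLET_EDGES",
]

N_CLASSES = 30

# Canonical edge lists for G0-G29 in the conventional graphlet ordering:
# G0 the single edge; G1 the 3-path and G2 the triangle; G3-G8 the six
# connected 4-node classes; G9-G29 the twenty-one connected 5-node classes,
# grouped by edge count (trees first, K5 last).
GRAPHLET_EDGES: tuple[tuple[tuple[int, int], ...], ...] = (
    # 2 nodes
    ((0, 1),),  # G0 edge
    # 3 nodes
    ((0, 1), (1, 2)),  # G1 path
    ((0, 1), (1, 2), (0, 2)),  # G2 triangle
    # 4 nodes
    ((0, 1), (1, 2), (2, 3)),  # G3 path
    ((0, 1), (0, 2), (0, 3)),  # G4 star (claw)
    ((0, 1), (1, 2), (2, 3), (3, 0)),  # G5 4-cycle
    ((0, 1), (1, 2), (0, 2), (2, 3)),  # G6 triangle + pendant (paw)
    ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3)),  # G7 diamond
    ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)),  # G8 K4
    # 5 nodes, 4 edges (trees)
    ((0, 1), (1, 2), (2, 3), (3, 4)),  # G9 path
    ((0, 1), (1, 2), (2, 3), (2, 4)),  # G10 fork
    ((0, 1), (0, 2), (0, 3), (0, 4)),  # G11 star
    # 5 nodes, 5 edges
    ((0, 1), (1, 2), (0, 2), (0, 3), (0, 4)),  # G12 triangle + 2 pendants (cricket)
    ((0, 1), (1, 2), (0, 2), (2, 3), (3, 4)),  # G13 triangle + 2-path tail
    ((0, 1), (1, 2), (0, 2), (0, 3), (1, 4)),  # G14 bull
    ((0, 1), (1, 2), (2, 3), (3, 4), (4, 0)),  # G15 5-cycle
    ((0, 1), (1, 2), (2, 3), (3, 0), (0, 4)),  # G16 4-cycle + pendant
    # 5 nodes, 6 edges
    ((0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (0, 4)),  # G17 diamond + pendant (deg-2)
    ((0, 1), (1, 2), (0, 2), (0, 3), (3, 4), (0, 4)),  # G18 bowtie
    ((0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (1, 4)),  # G19 diamond + pendant (deg-3)
    ((0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4)),  # G20 K2,3
    ((0, 1), (1, 2), (2, 3), (3, 0), (0, 4), (1, 4)),  # G21 house
    # 5 nodes, 7 edges
    ((0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4)),  # G22 K2,3 + edge
    ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3), (0, 4)),  # G23 K4 + pendant
    ((0, 1), (1, 2), (2, 3), (0, 4), (1, 4), (2, 4), (3, 4)),  # G24 gem (fan)
    ((0, 1), (1, 2), (2, 3), (3, 0), (0, 4), (1, 4), (2, 4)),  # G25 wheel - spoke
    # 5 nodes, 8 edges
    (
        (0, 2), (0, 3), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4),
    ),  # G26 K5 - 2-path
    (
        (0, 1), (1, 2), (2, 3), (3, 0), (0, 4), (1, 4), (2, 4), (3, 4),
    ),  # G27 wheel
    # 5 nodes, 9 edges
    (
        (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4),
    ),  # G28 K5 - edge
    tuple(combinations(range(5), 2)),  # G29 K5
)

_PAIRS = {k: tuple(combinations(range(k), 2)) for k in (2, 3, 4, 5)}


def _mask_from_edges(k: int, edges) -> int:
    index = {pair: i for i, pair in enumerate(_PAIRS[k])}
    mask = 0
    for a, b in edges:
        mask |= 1 << index[(min(a, b), max(a, b))]
    return mask


def _mask_connected(k: int, mask: int) -> bool:
    adj = [0] * k
    for i, (a, b) in enumerate(_PAIRS[k]):
        if mask >> i & 1:
            adj[a] |= 1 << b
            adj[b] |= 1 << a
    seen = 1
    frontier = adj[0]
    while frontier & ~seen:
        new = frontier & ~seen
        seen |= new
        frontier = 0
        v = new
        while v:
            b = v & -v
            frontier |= adj[b.bit_length() - 1]
            v ^= b
    return seen == (1 << k) - 1


@lru_cache(maxsize=None)
def _perm_bit_maps(k: int) -> tuple[tuple[int, ...], ...]:
    """For each permutation of k nodes, the induced permutation of pair bits."""
    index = {pair: i for i, pair in enumerate(_PAIRS[k])}
    maps = []
    for perm in permutations(range(k)):
        maps.append(
            tuple(
                index[(min(perm[a], perm[b]), max(perm[a], perm[b]))]
                for a, b in _PAIRS[k]
            )
        )
    return tuple(maps)


def _canonical_mask(k: int, mask: int) -> int:
    best = mask
    n_bits = len(_PAIRS[k])
    for bit_map in _perm_bit_maps(k):
        permuted = 0
        for i in range(n_bits):
            if mask >> i & 1:
                permuted |= 1 << bit_map[i]
        if permuted < best:
            best = permuted
    return best


@dataclass(frozen=True)
class GraphletCatalog:
    """The 30 connected isomorphism classes on 2-5 nodes.

    ``edges[i]`` is the canonical edge list of class i, ``sizes[i]`` its
    node count, and ``class_of[k]`` maps every connected pair-bitmask on k
    labeled nodes to its class index.
    """

    edges: tuple[tuple[tuple[int, int], ...], ...]
    sizes: tuple[int, ...]
    class_of: dict[int, dict[int, int]] = field(repr=False, hash=False, compare=False)

    @property
    def n_classes(self) -> int:
        return len(self.edges)

    def classes_by_size(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.sizes:
            out[s] = out.get(s, 0) + 1
        return out


@lru_cache(maxsize=1)
def build_catalog() -> GraphletCatalog:
    """Brute-force enumeration of all connected classes on 2-5 nodes.

    Enumerates every labeled simple graph on 2-5 nodes, keeps the connected
    ones, collapses them by canonical form (minimum bitmask over all node
    permutations), and cross-checks the result against the shipped G0-G29
    table: exactly 30 classes with per-size counts (1, 2, 6, 21), in
    bijection with the table.  Classification never relies on degree
    sequences alone (5-node graphs with equal degree sequences and
    different structure exist).
    """
    class_of: dict[int, dict[int, int]] = {}
    canon_to_class: dict[tuple[int, int], int] = {}
    for gid, edges in enumerate(GRAPHLET_EDGES):
        k = max(max(e) for e in edges) + 1
        canon = _canonical_mask(k, _mask_from_edges(k, edges))
        key = (k, canon)
        if key in canon_to_class:
            raise AssertionError(f"catalog classes {canon_to_class[key]} and {gid} are isomorphic")
        canon_to_class[key] = gid

    per_size_found: dict[int, set[int]] = {}
    for k in (2, 3, 4, 5):
        lookup: dict[int, int] = {}
        canon_cache: dict[int, int] = {}
        for mask in range(1 << len(_PAIRS[k])):
            if not _mask_connected(k, mask):
                continue
            canon = canon_cache.get(mask)
            if canon is None:
                canon = _canonical_mask(k, mask)
            gid = canon_to_class.get((k, canon))
            if gid is None:
                raise AssertionError(
                    f"connected {k}-node graph (mask {mask:b}) missing from catalog"
                )
            lookup[mask] = gid
            per_size_found.setdefault(k, set()).add(gid)
        class_of[k] = lookup

    counts = {k: len(v) for k, v in per_size_found.items()}
    if counts != {2: 1, 3: 2, 4: 6, 5: 21}:
        raise AssertionError(f"unexpected per-size class counts: {counts}")
    sizes = tuple(max(max(e) for e in edges) + 1 for edges in GRAPHLET_EDGES)
    return GraphletCatalog(edges=GRAPHLET_EDGES, sizes=sizes, class_of=class_of)


# ---------------------------------------------------------------------------
# thresholded graphs


@dataclass
class ThresholdedGraph:
    """Simple undirected graph from a signed correlation cutoff.

    ``rule`` records the retention rule actually applied ("rho <= t" for
    t < 0, "rho >= t" for t > 0).  Isolated nodes are retained in
    ``n_nodes``.
    """

    n_nodes: int
    edges: np.ndarray  # (m, 2) int array, each row i < j
    threshold: Optional[float] = None
    rule: str = ""

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def neighbor_masks(self) -> list[int]:
        nbr = [0] * self.n_nodes
        for a, b in self.edges:
            a, b = int(a), int(b)
            if a == b:
                raise ValueError(f"self-loop at node {a}")
            if nbr[a] >> b & 1:
                raise ValueError(f"duplicate edge ({a}, {b})")
            nbr[a] |= 1 << b
            nbr[b] |= 1 << a
        return nbr


def threshold_graph(network: CovarianceNetwork, t: float) -> ThresholdedGraph:
    """Binary graph at a signed cutoff.

    Edge (i, j), i < j, is included iff rho_ij <= t for t < 0, or
    rho_ij >= t for t > 0.  t = 0 is rejected (the retention rule is
    undefined there).
    """
    if t == 0:
        raise ValueError("threshold t = 0 is undefined; use a signed cutoff")
    if abs(t) > 1:
        raise ValueError(f"|t| must be <= 1, got {t}")
    network.validate()
    rho = network.rho
    n = rho.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = rho[iu]
    keep = vals <= t if t < 0 else vals >= t
    edges = np.column_stack([iu[0][keep], iu[1][keep]]).astype(np.int64)
    rule = "rho <= t" if t < 0 else "rho >= t"
    return ThresholdedGraph(n_nodes=n, edges=edges, threshold=float(t), rule=rule)


def graph_from_edges(n_nodes: int, edges) -> ThresholdedGraph:
    """Build a ThresholdedGraph directly from an edge list (testing/IO)."""
    arr = np.asarray(
        [(min(a, b), max(a, b)) for a, b in edges], dtype=np.int64
    ).reshape(-1, 2)
    graph = ThresholdedGraph(n_nodes=n_nodes, edges=arr)
    graph.neighbor_masks()  # validates
    return graph


# ---------------------------------------------------------------------------
# exact census


@dataclass
class GraphletCensus:
    """Counts (exact, integer) or estimates (sampled) for G0-G29."""

    counts: np.ndarray
    method: str
    standard_errors: Optional[np.ndarray] = None
    n_samples: Optional[int] = None
    seed: Optional[int] = None


def _induced_mask(verts: tuple[int, ...], nbr: list[int]) -> int:
    sv = sorted(verts)
    mask = 0
    bit = 0
    k = len(sv)
    for i in range(k - 1):
        ni = nbr[sv[i]]
        for j in range(i + 1, k):
            if ni >> sv[j] & 1:
                mask |= 1 << bit
            bit += 1
    return mask


def census_exact(
    graph: ThresholdedGraph,
    catalog: Optional[GraphletCatalog] = None,
    max_subgraphs: Optional[int] = None,
) -> GraphletCensus:
    """Exact induced-subgraph census over the 30 classes.

    Enumerates every connected induced subgraph on 2-5 nodes exactly once
    (each connected vertex set is visited once in the enumeration tree,
    growing from its minimum vertex through exclusive neighborhoods) and
    classifies it by full canonical form via the precomputed lookup.

    ``max_subgraphs`` bounds the enumeration as a guardrail for graphs too
    dense for exact counting; exceeding it raises with a suggestion to use
    :func:`census_sampled`.
    """
    if catalog is None:
        catalog = build_catalog()
    nbr = graph.neighbor_masks()
    lookups = catalog.class_of
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    visited = 0
    n = graph.n_nodes
    for v in range(n):
        gt_v = ~((1 << (v + 1)) - 1)
        stack = [((v,), 1 << v, nbr[v], nbr[v] & gt_v)]
        while stack:
            verts, sub_mask, nbh, ext = stack.pop()
            size = len(verts)
            if size >= 2:
                counts[lookups[size][_induced_mask(verts, nbr)]] += 1
                visited += 1
                if max_subgraphs is not None and visited > max_subgraphs:
                    raise ValueError(
                        f"exact census exceeded max_subgraphs={max_subgraphs}; "
                        "use census_sampled for graphs this dense"
                    )
            if size == 5:
                continue
            while ext:
                wbit = ext & -ext
                ext ^= wbit
                w = wbit.bit_length() - 1
                excl = nbr[w] & gt_v & ~(nbh | sub_mask)
                stack.append(
                    (verts + (w,), sub_mask | wbit, nbh | nbr[w], ext | excl)
                )
    return GraphletCensus(counts=counts, method="exact")


# ---------------------------------------------------------------------------
# sampled census (lift-and-reweight Horvitz-Thompson estimator)


def _bits(x: int):
    while x:
        b = x & -x
        yield b.bit_length() - 1
        x ^= b


def _set_probability(verts: list[int], m: int, nbr: list[int]) -> float:
    """Exact probability that the growth sampler returns this vertex set.

    The sampler picks a uniform edge, then repeatedly a uniform vertex from
    the neighborhood boundary of the current set (in the full graph).  The
    probability of ending at set S sums (1/m) * prod 1/|boundary| over all
    edge-rooted growth orderings of S that are feasible in the full graph.
    """
    total = 0.0
    k = len(verts)
    for a, b in combinations(verts, 2):
        if not nbr[a] >> b & 1:
            continue
        rest = [u for u in verts if u not in (a, b)]
        for order in permutations(rest):
            cur = (1 << a) | (1 << b)
            nbh = nbr[a] | nbr[b]
            p = 1.0 / m
            ok = True
            for w in order:
                boundary = nbh & ~cur
                if not boundary >> w & 1:
                    ok = False
                    break
                p /= boundary.bit_count()
                cur |= 1 << w
                nbh |= nbr[w]
            if ok:
                total += p
    return total


def census_sampled(
    graph: ThresholdedGraph,
    catalog: Optional[GraphletCatalog] = None,
    n_samples: int = 10000,
    seed: int = 0,
) -> GraphletCensus:
    """Unbiased sampled census with per-class standard errors.

    For each subgraph size k in {3, 4, 5}, draws ``n_samples`` growth
    samples (uniform random edge, then uniform boundary vertices until the
    set has k nodes), reweights each drawn set by the reciprocal of its
    exactly computed inclusion probability (Horvitz-Thompson), and averages.
    Draws that die in a too-small connected component contribute zero.  The
    2-node count (G0) is the edge count, reported exactly with zero
    standard error.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if catalog is None:
        catalog = build_catalog()
    m = graph.n_edges
    counts = np.zeros(N_CLASSES)
    ses = np.zeros(N_CLASSES)
    if m == 0:
        warnings.warn("edgeless graph: all graphlet estimates are 0", stacklevel=2)
        return GraphletCensus(
            counts=counts, method="sampled", standard_errors=ses,
            n_samples=n_samples, seed=seed,
        )
    nbr = graph.neighbor_masks()
    edges = graph.edges
    rng = np.random.default_rng(seed)
    counts[0] = m  # exact by construction
    lookups = catalog.class_of
    for k in (3, 4, 5):
        sums = np.zeros(N_CLASSES)
        sumsq = np.zeros(N_CLASSES)
        edge_idx = rng.integers(0, m, size=n_samples)
        for s in range(n_samples):
            a, b = edges[edge_idx[s]]
            cur = (1 << int(a)) | (1 << int(b))
            nbh = nbr[int(a)] | nbr[int(b)]
            verts = [int(a), int(b)]
            alive = True
            while len(verts) < k:
                boundary = nbh & ~cur
                if boundary == 0:
                    alive = False
                    break
                members = list(_bits(boundary))
                w = members[rng.integers(0, len(members))]
                verts.append(w)
                cur |= 1 << w
                nbh |= nbr[w]
            if not alive:
                continue
            prob = _set_probability(verts, m, nbr)
            weight = 1.0 / prob
            cls = lookups[k][_induced_mask(tuple(verts), nbr)]
            sums[cls] += weight
            sumsq[cls] += weight * weight
        mean = sums / n_samples
        if n_samples > 1:
            var = (sumsq - n_samples * mean**2) / (n_samples - 1)
            var = np.clip(var, 0.0, None)
            se = np.sqrt(var / n_samples)
        else:
            se = np.zeros(N_CLASSES)
        size_mask = np.array([sz == k for sz in catalog.sizes])
        counts[size_mask] = mean[size_mask]
        ses[size_mask] = se[size_mask]
    return GraphletCensus(
        counts=counts, method="sampled", standard_errors=ses,
        n_samples=n_samples, seed=seed,
    )


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizedCensus:
    """Log-normalized graphlet frequencies fstar_0 .. fstar_29."""

    fstar: np.ndarray
    variant: str = "displayed"


def normalize_census(
    census: GraphletCensus, variant: str = "displayed"
) -> NormalizedCensus:
    """Normalize a 30-class census.

    variant="displayed" (default): fstar_i = log10(1 + (f_i+1)/sum(f_j+1)),
    which is strictly positive and strictly increasing in f_i at a fixed
    denominator.  variant="prose": log10((f_i+1)/sum(f_j+1)), the literal
    proportion-then-log reading, which is negative for every class.
    """
    f = np.asarray(census.counts, dtype=float)
    if f.shape != (N_CLASSES,):
        raise ValueError(f"census must have {N_CLASSES} counts, got {f.shape}")
    if np.any(f < 0):
        raise ValueError("negative graphlet counts")
    share = (f + 1.0) / (f + 1.0).sum()
    if variant == "displayed":
        fstar = np.log10(1.0 + share)
    elif variant == "prose":
        fstar = np.log10(share)
    else:
        raise ValueError(f"unknown normalization variant {variant!r}")
    return NormalizedCensus(fstar=fstar, variant=variant)


def classify_edges(edges, n_nodes: Optional[int] = None) -> int:
    """Class index of a single small connected graph (2-5 nodes)."""
    edges = [(min(a, b), max(a, b)) for a, b in edges]
    nodes = sorted({v for e in edges for v in e})
    if n_nodes is None:
        n_nodes = len(nodes)
    if not 2 <= n_nodes <= 5:
        raise ValueError("classify_edges handles 2-5 node graphs")
    relabel = {v: i for i, v in enumerate(nodes)}
    mask = _mask_from_edges(n_nodes, [(relabel[a], relabel[b]) for a, b in edges])
    catalog = build_catalog()
    try:
        return catalog.class_of[n_nodes][mask]
    except KeyError:
        raise ValueError("graph is not connected on its node set") from None


# ---------------------------------------------------------------------------
# graph IO


def write_edgelist(graph: ThresholdedGraph, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_nodes={graph.n_nodes}\n")
        fh.write("source\ttarget\n")
        for a, b in graph.edges:
            fh.write(f"{int(a)}\t{int(b)}\n")


def read_edgelist(path: str | Path) -> ThresholdedGraph:
    path = Path(path)
    n_nodes = None
    edges = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_nodes=" in line:
                    n_nodes = int(line.split("n_nodes=")[1])
                continue
            if line.startswith("source"):
                continue
            a, b = line.split("\t")
            edges.append((int(a), int(b)))
    if n_nodes is None:
        n_nodes = max((max(e) for e in edges), default=-1) + 1
    return graph_from_edges(n_nodes, edges)


def write_graphml(graph: ThresholdedGraph, path: str | Path) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from((int(a), int(b)) for a, b in graph.edges)
    nx.write_graphml(g, str(path))
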