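"""Distance and enrichment statistics on the protein interaction network.

The graph is undirected and unweighted, so all-pairs shortest paths are
computed by repeated breadth-first search; a dense min-plus Floyd-Warshall
engine is kept as an independent verification route for small graphs.
Unreachable pairs are reported distinctly and excluded from means.
"""
from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .variants import TestResult, compare_gene_classes

UNREACHABLE = "unreachable"


def all_pairs_distances(network: nx.Graph, engine: str = "bfs") -> pd.DataFrame:
    """Symmetric matrix of shortest-path lengths between all node pairs.

    ``engine='bfs'`` runs one breadth-first search per node (memory-safe on
    large sparse graphs); ``engine='floyd-warshall'`` is a dense dynamic-
    programming route intended for verification on small graphs.
    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    nodes = sorted(network.nodes)
    if engine == "bfs":
        dist = np.full((len(nodes), len(nodes)), np.inf)
        index = {v: i for i, v in enumerate(nodes)}
        for v in nodes:
            for u, d in nx.single_source_shortest_path_length(network, v).items():
                dist[index[v], index[u]] = d
    elif engine == "floyd-warshall":
        dist = _floyd_warshall(network, nodes)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return pd.DataFrame(dist, index=nodes, columns=nodes)


def _floyd_warshall(network: nx.Graph, nodes: list) -> np.ndarray:
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in network.edges:
        i, j = index[a], index[b]
        dist[i, j] = dist[j, i] = 1.0
    for k in range(n):
        # min-plus relaxation through intermediate k, row-vectorized
        via_k = dist[:, k][:, None] + dist[k, :][None, :]
        np.minimum(dist, via_k, out=dist)
    return dist


def multi_source_bfs(network: nx.Graph, sources: set) -> dict:
    """Distance from every reachable node to the nearest source node."""
    seeds = [s for s in sources if s in network]
    dist = {s: 0 for s in seeds}
    queue = deque(seeds)
    while queue:
        v = queue.popleft()
        for u in network[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


@dataclass
class DistanceProfile:
    """Per-query shortest distance to the nearest member of a reference set."""

    description: str
    distances: pd.Series            # finite distances, indexed by query gene
    unreachable: list               # query genes with no path to the reference set
    dropped_queries: int            # query genes absent from the network
    histogram: Counter

    @property
    def mean_distance(self) -> float:
        return float(self.distances.mean()) if len(self.distances) else float("nan")


def distance_to_set(
    network: nx.Graph, query_genes: set, reference_set: set, description: str = ""
) -> DistanceProfile:
    """Shortest distance from each query gene to its nearest reference gene.

    Distance 0 iff the query gene is itself in the reference set.  Queries
    not mapped to the network are dropped (counted); queries with no path
    are listed separately and never enter the mean or histogram bins other
    than 'unreachable'.
    """
    mapped_ref = {g for g in reference_set if g in network}
    if not mapped_ref:
        raise ValueError("reference set has no genes mapped to the network")
    near = multi_source_bfs(network, mapped_ref)
    mapped_q = sorted(g for g in query_genes if g in network)
    dropped = len(query_genes) - len(mapped_q)
    finite = {g: near[g] for g in mapped_q if g in near}
    unreachable = [g for g in mapped_q if g not in near]
    hist = Counter(finite.values())
    if unreachable:
        hist[UNREACHABLE] = len(unreachable)
    return DistanceProfile(
        description=description,
        distances=pd.Series(finite, dtype=float).sort_index(),
        unreachable=unreachable,
        dropped_queries=dropped,
        histogram=hist,
    )


@dataclass
class EnrichmentResult:
    order: int
    neighborhood_size: int
    neighborhood_fraction: float
    background_fraction: float
    fold_enrichment: float
    undefined: bool = False


def neighborhood_of_order(network: nx.Graph, seed_set: set, order: int) -> set:
    """Genes at shortest distance exactly ``order`` from the seed set
    (seed genes themselves excluded)."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    dist = multi_source_bfs(network, seed_set)
    return {g for g, d in dist.items() if d == order}


def neighbor_enrichment(
    network: nx.Graph, seed_set: set, class_set: set, order: int = 1
) -> EnrichmentResult:
    """Fold enrichment of a gene class in the order-1 (direct neighbors) or
    order-2 (distance exactly 2) neighborhood of a seed set, relative to the
    network-wide class fraction."""
    seeds = {g for g in seed_set if g in network}
    members = {g for g in class_set if g in network}
    hood = neighborhood_of_order(network, seeds, order)
    background = len(members) / network.number_of_nodes()
    if not hood or background == 0:
        return EnrichmentResult(order, len(hood), float("nan"), background,
                                float("nan"), undefined=True)
    frac = len(hood & members) / len(hood)
    return EnrichmentResult(order, len(hood), frac, background, frac / background)


def enrichment_permutation_null(
    network: nx.Graph, seed_set: set, class_size: int, order: int,
    n_permutations: int, seed: int,
) -> np.ndarray:
    """Fold enrichments for uniformly random gene classes of the given size
    (null distribution; mean tends to 1 as permutations grow)."""
    rng = np.random.default_rng(seed)
    nodes = np.array(sorted(network.nodes), dtype=object)
    folds = []
    for _ in range(n_permutations):
        random_class = set(rng.choice(nodes, size=class_size, replace=False))
        res = neighbor_enrichment(network, seed_set, random_class, order)
        if not res.undefined:
            folds.append(res.fold_enrichment)
    return np.array(folds)


@dataclass
class DegreeContrast:
    class_degrees: pd.Series
    all_degrees: pd.Series
    test: TestResult


def degree_contrast(network: nx.Graph, class_set: set) -> DegreeContrast:
    """Degree distribution of a gene class against all network nodes."""
    degrees = pd.Series(dict(network.degree)).sort_index()
    cls = degrees[degrees.index.isin(class_set)]
    if cls.empty:
        raise ValueError("class has no genes mapped to the network")
    return DegreeContrast(cls, degrees, compare_gene_classes(cls.values, degrees.values))


def extract_linker_subnetwork(
    network: nx.Graph, set_a: set, set_b: set, max_intermediates: int = 1
) -> nx.Graph:
    """Subgraph of set_a, set_b and the linker genes lying on a path of
    length <= max_intermediates+1 between two distinct kept genes.

    Node attribute ``klass`` is 'a', 'b', 'both' or 'linker'; the induced
    edges among the kept nodes are returned.
    """
    kept = {g for g in (set_a | set_b) if g in network}
    linkers: set = set()
    cutoff = max_intermediates + 1
    for u in kept:
        for path in nx.all_simple_paths(network, u, kept - {u}, cutoff=cutoff):
            linkers.update(path[1:-1])
    linkers -= kept
    sub = network.subgraph(kept | linkers).copy()
    for g in sub.nodes:
        if g in set_a and g in set_b:
            sub.nodes[g]["klass"] = "both"
        elif g in set_a:
            sub.nodes[g]["klass"] = "a"
        elif g in set_b:
            sub.nodes[g]["klass"] = "b"
        else:
            sub.nodes[g]["klass"] = "linker"
    return sub


def write_subnetwork(sub: nx.Graph, edge_path, node_path) -> None:
    """Edge-list TSV plus a node-attribute TSV (gene, class) for viewers."""
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in sub.edges):
            fh.write(f"{a}\t{b}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tclass\n")
        for g in sorted(sub.nodes):
            fh.write(f"{g}\t{sub.nodes[g]['klass']}\n")
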