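"""Query-time network algorithms and the propagation benchmark.

Group/independent expansion and MaxLink hypergeometric candidate ranking
operate on a calibrated network; EASE provides conservative overlap-based
pathway enrichment; random walk with restart (RWR) plus degree-preserving
rewiring null models quantify how well a network recovers held-out members
of a gene set (performance gain).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .containers import Link, Network, OrthologMap, Pair, canonical_pair


def _subnetwork(net: Network, nodes: Set[str], cutoff: float) -> Network:
    sub = Network()
    for (a, b), link in net.links.items():
        if a in nodes and b in nodes and link.ppv >= cutoff:
            sub.add(link)
    return sub


@dataclass
class RankedNode:
    """One candidate added by a network search, with its statistics."""

    node: str
    links_to_query: int
    summed_ppv: float
    p_value: Optional[float] = None


@dataclass
class QueryResult:
    subnetwork: Network
    added_nodes: List[RankedNode] = field(default_factory=list)


def group_search(
    net: Network,
    query: Iterable[str],
    n_add: int,
    prioritize_common: bool = False,
    cutoff: float = 0.85,
) -> QueryResult:
    """Expand a query set with the genes most connected to it as a group.

    Candidates are ranked by summed PPV of their links (>= cutoff) to the
    query; with ``prioritize_common`` the count of distinct query genes
    linked comes first, favouring genes that tie the query together.
    """
    query_set = {q for q in query}
    adj = net.neighbors()
    mapped = sorted(query_set & set(adj))
    if not mapped:
        warnings.warn("no query gene found in the network")
        return QueryResult(subnetwork=Network())
    stats_: Dict[str, RankedNode] = {}
    for q in mapped:
        for nb, link in adj[q].items():
            if nb in query_set or link.ppv < cutoff:
                continue
            entry = stats_.setdefault(nb, RankedNode(nb, 0, 0.0))
            entry.links_to_query += 1
            entry.summed_ppv += link.ppv
    if prioritize_common:
        key = lambda e: (-e.links_to_query, -e.summed_ppv, e.node)
    else:
        key = lambda e: (-e.summed_ppv, e.node)
    ranked = sorted(stats_.values(), key=key)[: max(n_add, 0)]
    nodes = set(mapped) | {e.node for e in ranked}
    return QueryResult(subnetwork=_subnetwork(net, nodes, cutoff), added_nodes=ranked)


def independent_search(
    net: Network,
    query: Iterable[str],
    n_add_per_gene: int,
    cutoff: float = 0.85,
) -> QueryResult:
    """Expand each query gene separately with its strongest neighbors."""
    query_set = {q for q in query}
    adj = net.neighbors()
    mapped = sorted(query_set & set(adj))
    if not mapped:
        warnings.warn("no query gene found in the network")
        return QueryResult(subnetwork=Network())
    added: Dict[str, RankedNode] = {}
    for q in mapped:
        neighbors = [
            (nb, link)
            for nb, link in adj[q].items()
            if nb not in query_set and link.ppv >= cutoff
        ]
        neighbors.sort(key=lambda t: (-t[1].ppv, t[0]))
        for nb, link in neighbors[: max(n_add_per_gene, 0)]:
            entry = added.setdefault(nb, RankedNode(nb, 0, 0.0))
            entry.links_to_query += 1
            entry.summed_ppv += link.ppv
    ranked = sorted(added.values(), key=lambda e: (-e.summed_ppv, e.node))
    nodes = set(mapped) | set(added)
    return QueryResult(subnetwork=_subnetwork(net, nodes, cutoff), added_nodes=ranked)


def maxlink_rank(
    net: Network,
    query: Iterable[str],
    cutoff: float = 0.85,
) -> List[RankedNode]:
    """Rank non-query candidates by their links into the query, with a
    hypergeometric enrichment p-value.

    For a candidate of degree d with x links into a query of size q in a
    network of N nodes, p = P(X >= x) with X hypergeometric drawing d from
    a population of N - 1 containing q successes.  Ranking is by link
    count, then p-value, then gene id.
    """
    query_set = {q for q in query}
    if not query_set:
        raise ValueError("query must be non-empty")
    adj = {
        node: {nb: l for nb, l in nbrs.items() if l.ppv >= cutoff}
        for node, nbrs in net.neighbors().items()
    }
    nodes = {n for n, nbrs in adj.items() if nbrs}
    q_in_net = query_set & nodes
    n_pop = len(nodes)
    out: List[RankedNode] = []
    for cand in sorted(nodes - query_set):
        nbrs = adj[cand]
        d = len(nbrs)
        x = sum(1 for nb in nbrs if nb in q_in_net)
        p = float(stats.hypergeom.sf(x - 1, n_pop - 1, len(q_in_net), d))
        summed = sum(l.ppv for nb, l in nbrs.items() if nb in q_in_net)
        out.append(RankedNode(cand, x, summed, p_value=p))
    out.sort(key=lambda e: (-e.links_to_query, e.p_value, e.node))
    return out


def ease_enrichment(
    query: Set[str], pathway: Set[str], universe: int
) -> float:
    """EASE score: one-sided Fisher/hypergeometric p with the overlap
    reduced by one (a conservative variant of Fisher's exact test)."""
    k = len(query & pathway)
    if k == 0:
        return 1.0
    if len(query) > universe or len(pathway) > universe:
        raise ValueError("query and pathway must fit in the universe")
    # P(X >= k - 1) drawing |query| from a universe with |pathway| successes
    return float(stats.hypergeom.sf(k - 2, universe, len(pathway), len(query)))


@dataclass(frozen=True)
class Rectangle:
    """A conserved link pattern: two intra-species links joined by two
    cross-species ortholog links."""

    a1: str
    b1: str
    a2: str
    b2: str


def align_orthologs(
    net_a: Network, net_b: Network, ortho: OrthologMap
) -> List[Rectangle]:
    """All rectangle constellations between two species' networks.

    A rectangle is a link (a1, b1) in network A and a link (a2, b2) in
    network B with a1-a2 and b1-b2 orthologous.
    """
    mapping = ortho.a_to_b()
    out: Set[Rectangle] = set()
    b_pairs = net_b.pairs()
    for a1, b1 in net_a.pairs():
        for a2 in mapping.get(a1, ()):
            for b2 in mapping.get(b1, ()):
                if a2 != b2 and canonical_pair(a2, b2) in b_pairs:
                    out.add(Rectangle(a1, b1, *canonical_pair(a2, b2)))
    return sorted(out, key=lambda r: (r.a1, r.b1, r.a2, r.b2))


# ---------------------------------------------------------------------------
# RWR and the performance-gain benchmark
# ---------------------------------------------------------------------------


def _adjacency(net: Network, weighted: bool) -> Tuple[List[str], np.ndarray]:
    nodes = sorted(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for (a, b), link in net.links.items():
        val = link.ppv if weighted else 1.0
        w[index[a], index[b]] = val
        w[index[b], index[a]] = val
    return nodes, w


def rwr(
    net: Network,
    seeds: Iterable[str],
    restart: float = 0.75,
    tol: float = 1e-10,
    weighted: bool = False,
    max_iter: int = 10_000,
) -> Dict[str, float]:
    """Random walk with restart on the (by default unweighted) network.

    Iterates p = restart * e + (1 - restart) * W p to convergence, with W
    the column-normalized adjacency and e uniform over the mapped seeds.
    The stationary probabilities sum to 1.
    """
    nodes, w = _adjacency(net, weighted)
    index = {n: i for i, n in enumerate(nodes)}
    mapped = sorted({s for s in seeds} & set(nodes))
    if not mapped:
        raise ValueError("no seed maps to the network")
    col_sums = w.sum(axis=0)
    w = w / col_sums  # every network node has degree >= 1
    e = np.zeros(len(nodes))
    for s in mapped:
        e[index[s]] = 1.0 / len(mapped)
    p = e.copy()
    for _ in range(max_iter):
        p_new = restart * e + (1.0 - restart) * (w @ p)
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return {n: float(p[i]) for n, i in index.items()}


def rewire_preserve_degree(
    net: Network,
    n_swaps: Optional[int] = None,
    seed: int = 0,
) -> Network:
    """Degree-preserving randomization by double-edge swaps.

    Performs ``n_swaps`` swap trials (default: the number of links).  A
    trial picks two distinct links (a, b) and (c, d), proposes (a, d) and
    (c, b), and applies the swap only if it creates neither self-loops nor
    multi-edges.  The degree sequence is preserved exactly.
    """
    edges = sorted(net.pairs())
    if len(edges) < 2:
        return Network(
            Link(a=a, b=b, ppv=l.ppv, gold_standard=l.gold_standard)
            for (a, b), l in net.links.items()
        )
    if n_swaps is None:
        n_swaps = len(edges)
    rng = random.Random(seed)
    edge_set = set(edges)
    for _ in range(n_swaps):
        i, j = rng.randrange(len(edges)), rng.randrange(len(edges))
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose a-d and c-b
        if len({a, b, c, d}) < 4:
            continue
        new1 = canonical_pair(a, d)
        new2 = canonical_pair(c, b)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i], edges[j] = new1, new2
    ppv = 0.85
    return Network(Link(a=a, b=b, ppv=ppv) for a, b in sorted(edge_set))


@dataclass
class BenchmarkResult:
    geneset_size: int
    real_aurocs: List[float]
    null_aurocs: List[float]
    median_real: float
    median_null: float
    pg: float


def _auroc_from_scores(
    scores: Mapping[str, float],
    positives: Set[str],
    excluded: Set[str],
) -> float:
    labels, values = [], []
    for node, score in scores.items():
        if node in excluded:
            continue
        labels.append(1 if node in positives else 0)
        values.append(score)
    return float(roc_auc_score(labels, values))


def performance_gain(
    geneset: Iterable[str],
    net: Network,
    n_splits: int = 30,
    n_randomizations: int = 30,
    restart: float = 0.75,
    seed: int = 0,
    weighted: bool = False,
) -> Optional[BenchmarkResult]:
    """Performance gain of a network at recovering a gene set by RWR.

    For each split, half the mapped genes seed the walk and the held-out
    half are positives against all other network genes.  The null
    distribution repeats the same splits on degree-preserving rewired
    networks; PG = (median real - median null) / median null.
    """
    nodes = net.nodes()
    mapped = sorted({g for g in geneset} & nodes)
    if len(mapped) < 2:
        warnings.warn("gene set maps fewer than 2 genes to the network; skipped")
        return None
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        order = list(mapped)
        rng.shuffle(order)
        half = len(order) // 2
        splits.append((set(order[:half] or order[:1]), set(order[half:])))

    def run(network: Network) -> List[float]:
        out = []
        net_nodes = network.nodes()
        for seeds_half, holdout in splits:
            mapped_seeds = seeds_half & net_nodes
            if not mapped_seeds:
                continue
            scores = rwr(network, mapped_seeds, restart=restart, weighted=weighted)
            out.append(
                _auroc_from_scores(scores, holdout & net_nodes, mapped_seeds)
            )
        return out

    real = run(net)
    null: List[float] = []
    for r in range(n_randomizations):
        rewired = rewire_preserve_degree(net, seed=seed * 1_000_003 + r)
        null.extend(run(rewired))
    median_real = float(np.median(real))
    median_null = float(np.median(null))
    pg = (median_real - median_null) / median_null
    return BenchmarkResult(
        geneset_size=len(mapped),
        real_aurocs=real,
        null_aurocs=null,
        median_real=median_real,
        median_null=median_null,
        pg=pg,
    )


def neighbor_gain(net: Network, query: Iterable[str]) -> float:
    """Ratio of distinct non-query first-order neighbors to mapped query
    genes; small values mean the query expands conservatively."""
    adj = net.neighbors()
    query_set = {q for q in query}
    mapped = query_set & set(adj)
    if not mapped:
        raise ValueError("query does not map to the network")
    outside: Set[str] = set()
    for q in mapped:
        outside |= set(adj[q]) - query_set
    return len(outside) / len(mapped)
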