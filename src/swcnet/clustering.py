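"""Complex discovery on the weighted composite network.

Two clusterers are implemented natively — the Markov Cluster algorithm
(MCL) and clustering by maximal cliques (CMC) — and any externally produced
clustering enters through :func:`swcnet.io.read_clusters`.  Every cluster C
is scored by its weighted density

    dens_C = sum_{u in C, v in C} w(u,v) / (|C| (|C| - 1))

(the sum runs over ordered pairs, so each unordered pair counts twice;
missing edges contribute 0).  The COMBINED strategy pools clusters from
several algorithms, groups mutually similar ones (Jaccard >= 0.75), keeps
the densest member of each group, and multiplies its score by the number of
distinct algorithms that voted for the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .types import Cluster, ClusterSet, CompositeNetwork

logger = logging.getLogger("swcnet")


def jaccard(a: FrozenSet[str], b: FrozenSet[str]) -> float:
    """Jaccard similarity |a ∩ b| / |a ∪ b| of two non-empty protein sets."""
    if not a or not b:
        raise ValueError("Jaccard of an empty set is undefined")
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def weighted_density(members: Iterable[str], network: CompositeNetwork) -> float:
    """Weighted density of a member set against the network's edge weights."""
    members = sorted(set(members))
    n = len(members)
    if n < 2:
        raise ValueError("weighted density needs at least 2 members")
    total = 0.0
    for i, u in enumerate(members):
        for v in members[i + 1 :]:
            total += network.weight(u, v, default=0.0)
    return 2.0 * total / (n * (n - 1))


def _score_members(
    member_sets: Iterable[FrozenSet[str]],
    network: CompositeNetwork,
    provenance: FrozenSet[str],
) -> ClusterSet:
    clusters = []
    for members in member_sets:
        dens = weighted_density(members, network)
        clusters.append(
            Cluster(members=members, density=dens, score=dens, provenance=provenance)
        )
    return ClusterSet(sorted(clusters, key=lambda c: (-c.score, c.sorted_members())))


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------

@dataclass
class MCLParams:
    """Markov-clustering parameters; the standard inflation grid is 2/3/4."""

    inflation: float = 2.0
    expansion: int = 2
    max_iterations: int = 200
    tolerance: float = 1e-6
    prune_threshold: float = 1e-5

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def _column_normalize(m: sp.csr_matrix) -> sp.csr_matrix:
    col_sums = np.asarray(m.sum(axis=0)).ravel()
    col_sums[col_sums == 0] = 1.0
    d = sp.diags(1.0 / col_sums)
    return (m @ d).tocsr()


def mcl(network: CompositeNetwork, params: MCLParams = MCLParams()) -> ClusterSet:
    """Markov clustering: alternating expansion and inflation to convergence.

    The transition matrix is column-normalized from edge weights with unit
    self-loops.  Expansion raises the matrix to the ``expansion`` power;
    inflation raises entries element-wise to the ``inflation`` power and
    renormalizes, with entries below ``prune_threshold`` zeroed for
    tractability.  Clusters are the weakly connected components of the
    attractor's non-zero structure (size >= 2; singletons are discarded).
    Non-convergence within ``max_iterations`` returns the current state with
    a warning.  Deterministic given identical inputs.
    """
    if network.n_vertices == 0:
        raise ValueError("empty network")
    nodes = sorted(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for (u, v), data in network.edges():
        w = data.get("weight")
        w = 1.0 if w is None else float(w)
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    m = m + sp.identity(n, format="csr")
    m = _column_normalize(m)

    converged = False
    for _ in range(params.max_iterations):
        prev = m.copy()
        expanded = m
        for _ in range(params.expansion - 1):
            expanded = (expanded @ m).tocsr()
        m = expanded
        m.data = np.power(m.data, params.inflation)
        m.data[m.data < params.prune_threshold] = 0.0
        m.eliminate_zeros()
        m = _column_normalize(m)
        diff = (m - prev)
        change = np.abs(diff.data).max() if diff.nnz else 0.0
        if change < params.tolerance:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", params.max_iterations)

    structure = ((m + m.T) > 0).astype(np.int8)
    n_comp, assignment = connected_components(structure, directed=False)
    groups: Dict[int, Set[str]] = {}
    for node, comp in zip(nodes, assignment):
        groups.setdefault(comp, set()).add(node)
    member_sets = [frozenset(g) for g in groups.values() if len(g) >= 2]
    return _score_members(member_sets, network, frozenset(["mcl"]))


# ---------------------------------------------------------------------------
# CMC
# ---------------------------------------------------------------------------

@dataclass
class CMCParams:
    """Maximal-clique merging parameters (reference grid: merge 0.25/0.5/0.75)."""

    min_deg_ratio: float = 1.0
    min_size: int = 4
    overlap_thres: float = 0.5
    merge_thres: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_thres <= 1.0 and 0.0 <= self.merge_thres <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")


def enumerate_maximal_cliques(network: CompositeNetwork) -> List[FrozenSet[str]]:
    """All maximal cliques (pivoting Bron–Kerbosch), deterministically ordered."""
    cliques = [frozenset(c) for c in nx.find_cliques(network.graph)]
    return sorted(cliques, key=lambda c: (len(c), tuple(sorted(c))))


def _interconnectivity(
    a: FrozenSet[str], b: FrozenSet[str], network: CompositeNetwork
) -> float:
    """Mean edge weight over pairs between b \\ a and a (absent edges count 0)."""
    outside = sorted(b - a)
    inside = sorted(a)
    if not outside:
        return 1.0  # b is contained in a: maximally interconnected
    total = 0.0
    for u in outside:
        for v in inside:
            total += network.weight(u, v, default=0.0)
    return total / (len(outside) * len(inside))


def _passes_degree_filter(
    members: FrozenSet[str], network: CompositeNetwork, min_deg_ratio: float
) -> bool:
    """Require every member to touch >= min_deg_ratio * (|C|-1) others.

    The ratio is on presence degree (count of intra-cluster edges).  Applied
    to candidate cliques, where it holds by construction at the default
    ratio of 1; merged clusters are exempt because their quality is already
    gated by the interconnectivity threshold.
    """
    n = len(members)
    for u in members:
        deg = sum(1 for v in members if v != u and network.has_edge(u, v))
        if deg < min_deg_ratio * (n - 1):
            return False
    return True


def cmc(network: CompositeNetwork, params: CMCParams = CMCParams()) -> ClusterSet:
    """Clustering by maximal cliques with overlap-driven merge/removal.

    Maximal cliques at least ``min_size`` large are ranked by weighted
    density.  For each ordered pair with overlap |A∩B|/min(|A|,|B|) strictly
    above ``overlap_thres``, the pair is merged when the interconnectivity
    between the lower-density cluster's non-shared part and the other
    cluster reaches ``merge_thres``; otherwise the lower-density cluster is
    removed.  Passes repeat until stable; surviving clusters below
    ``min_size`` are dropped.  ``min_deg_ratio`` screens the candidate
    cliques up front (inert at the default ratio of 1).
    """
    if network.n_vertices == 0:
        raise ValueError("empty network")
    cliques = [
        c
        for c in enumerate_maximal_cliques(network)
        if len(c) >= params.min_size
        and _passes_degree_filter(c, network, params.min_deg_ratio)
    ]
    entries: List[Tuple[FrozenSet[str], float]] = [
        (c, weighted_density(c, network)) for c in cliques
    ]

    def ranked(items):
        return sorted(items, key=lambda e: (-e[1], tuple(sorted(e[0]))))

    entries = ranked(entries)
    for _pass in range(100):
        changed = False
        i = 0
        while i < len(entries):
            a, dens_a = entries[i]
            j = i + 1
            while j < len(entries):
                b, dens_b = entries[j]
                overlap = len(a & b) / min(len(a), len(b))
                if overlap > params.overlap_thres:
                    if _interconnectivity(a, b, network) >= params.merge_thres:
                        a = a | b
                        dens_a = weighted_density(a, network)
                        entries[i] = (a, dens_a)
                    del entries[j]
                    changed = True
                else:
                    j += 1
            i += 1
        if not changed:
            break
        entries = ranked(entries)

    survivors = []
    seen = set()
    for members, _ in entries:
        if members in seen or len(members) < params.min_size:
            continue
        seen.add(members)
        survivors.append(members)
    return _score_members(survivors, network, frozenset(["cmc"]))


# ---------------------------------------------------------------------------
# COMBINED aggregation
# ---------------------------------------------------------------------------

@dataclass
class CombineParams:
    """Vote-aggregation parameters: similarity grouping and minimum size."""

    similarity_thres: float = 0.75
    min_cluster_size: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity_thres <= 1.0):
            raise ValueError("similarity_thres must be in (0, 1]")


def combine(
    cluster_sets: Sequence[ClusterSet],
    network: CompositeNetwork,
    params: CombineParams = CombineParams(),
) -> ClusterSet:
    """Aggregate clusterings by similarity grouping and algorithm voting.

    Clusters from all inputs are pooled (rescored against ``network``;
    members below ``min_cluster_size`` dropped), a similarity graph links
    clusters with Jaccard >= ``similarity_thres``, and each connected
    component keeps only its densest member (ties: lexicographically
    smallest member set).  That representative's score is its density times
    the number of distinct algorithms contributing to the group; its
    provenance is their union.  The output never contains two clusters with
    Jaccard >= ``similarity_thres``.
    """
    if not cluster_sets:
        raise ValueError("at least one cluster set required")
    pool: List[Cluster] = []
    vertices = set(network.graph.nodes)
    for cs in cluster_sets:
        for c in cs:
            if len(c.members) < params.min_cluster_size:
                continue
            if not c.members <= vertices:
                logger.warning(
                    "cluster references vertices absent from network; "
                    "missing edges scored 0"
                )
            dens = weighted_density(c.members, network)
            pool.append(
                Cluster(
                    members=c.members,
                    density=dens,
                    score=dens,
                    provenance=c.provenance,
                )
            )
    if not pool:
        return ClusterSet([])

    n = len(pool)
    sim = nx.Graph()
    sim.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if jaccard(pool[i].members, pool[j].members) >= params.similarity_thres:
                sim.add_edge(i, j)

    out: List[Cluster] = []
    for component in nx.connected_components(sim):
        group = [pool[i] for i in component]
        best = min(group, key=lambda c: (-c.density, c.sorted_members()))
        algorithms = frozenset().union(*(c.provenance for c in group))
        out.append(
            Cluster(
                members=best.members,
                density=best.density,
                score=best.density * len(algorithms),
                provenance=algorithms,
            )
        )
    return ClusterSet(sorted(out, key=lambda c: (-c.score, c.sorted_members())))
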