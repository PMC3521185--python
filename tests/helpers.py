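"""Shared test utilities: network builders and independent oracles.

The oracles deliberately re-derive results from first principles (exhaustive
search, brute-force enumeration, direct formula evaluation) so they stay
independent of the implementation paths they check.
"""

import itertools
import math

import networkx as nx

import swcnet as s
from swcnet.clustering import CMCParams, MCLParams, cmc, combine, mcl
from swcnet.evaluation import CVConfig, MatchCriterion, cluster_pr_curve, cv_split
from swcnet.types import CompositeNetwork


def make_weighted_network(weights):
    """Single-feature network with explicit edge weights ((u, v) -> w)."""
    net = CompositeNetwork(["w"])
    for (u, v), w in weights.items():
        net.add_edge(u, v, {"w": w if w > 0 else 1.0})
        net.edge_data(u, v)["weight"] = float(w)
    return net


# ---------------------------------------------------------------------------
# MDL discretization oracle: exhaustive search over boundary midpoints
# ---------------------------------------------------------------------------

def _ent(labels):
    n = len(labels)
    pos = sum(labels)
    if n == 0 or pos == 0 or pos == n:
        return 0.0
    p = pos / n
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def _k(labels):
    return len({bool(l) for l in labels})


def mdl_oracle(values, labels):
    """Accepted cuts by exhaustive recursive search with the MDL stop rule."""
    pairs = sorted(zip(values, labels))
    cuts = []

    def recurse(seg):
        n = len(seg)
        if n < 2 or _ent([l for _, l in seg]) == 0.0:
            return
        candidates = []
        for i in range(1, n):
            if seg[i - 1][0] != seg[i][0]:
                left = [l for _, l in seg[:i]]
                right = [l for _, l in seg[i:]]
                went = (len(left) * _ent(left) + len(right) * _ent(right)) / n
                cut = (seg[i - 1][0] + seg[i][0]) / 2.0
                candidates.append((went, cut, i, left, right))
        if not candidates:
            return
        went, cut, i, left, right = min(candidates, key=lambda c: (c[0], c[1]))
        labs = [l for _, l in seg]
        gain = _ent(labs) - went
        delta = (
            math.log2(3 ** _k(labs) - 2)
            - _k(labs) * _ent(labs)
            + _k(left) * _ent(left)
            + _k(right) * _ent(right)
        )
        if gain > (math.log2(n - 1) + delta) / n:
            cuts.append(cut)
            recurse(seg[:i])
            recurse(seg[i:])

    recurse(pairs)
    return sorted(cuts)


# ---------------------------------------------------------------------------
# Maximal-clique oracle: subset enumeration
# ---------------------------------------------------------------------------

def bruteforce_maximal_cliques(graph: nx.Graph):
    nodes = sorted(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                cliques.append(frozenset(subset))
    return sorted(
        (c for c in cliques if not any(c < d for d in cliques)),
        key=lambda c: (len(c), tuple(sorted(c))),
    )


# ---------------------------------------------------------------------------
# One-iteration AdjustCD oracle: direct formula evaluation over all pairs
# ---------------------------------------------------------------------------

def adjustcd_oracle_one_iteration(graph: nx.Graph):
    """(pair -> score) for every pair with a shared neighbor, w0 = 1."""
    deg = dict(graph.degree())
    lam = sum(deg.values()) / graph.number_of_nodes()
    scores = {}
    for u, v in itertools.combinations(sorted(graph.nodes), 2):
        shared = set(graph.neighbors(u)) & set(graph.neighbors(v))
        if not shared:
            continue
        num = 2.0 * len(shared)  # both previous weights are 1
        den = max(deg[u], lam) + max(deg[v], lam)
        scores[(u, v)] = num / den
    return scores


# ---------------------------------------------------------------------------
# End-to-end synthetic pipeline (weight -> top-k -> mcl+cmc -> combine)
# ---------------------------------------------------------------------------

def synthetic_pipeline_auc(seed, k=10000, weighted=True, match_thres=0.5):
    """Cluster-level PR AUC of the pipeline on the default benchmark.

    With ``weighted=False`` every edge gets weight 1 and all edges are used,
    the unweighted baseline.
    """
    params = s.SynthParams(seed=seed)
    reference, tables, _ = s.generate_benchmark(params)
    network = s.assemble_composite(tables)
    config = CVConfig(seed=seed, rounds=1, k_grid=(k,))
    train, test = cv_split(reference, config, 0)
    if weighted:
        s.label_edges(network, train)
        model = s.fit_naive_bayes(network, s.discretize_network(network))
        s.weight_edges(network, model)
        top = s.top_k_edges(network, k)
    else:
        for _, data in network.edges():
            data["weight"] = 1.0
        top = network
    produced = [mcl(top, MCLParams()), cmc(top, CMCParams())]
    combined = combine(produced, top)
    curve = cluster_pr_curve(combined, test, train, MatchCriterion(match_thres))
    return curve.auc
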