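"""Built-in data-source scoring and composite-network assembly.

Three kinds of per-source scores feed the composite network:

* **PPI** — observed physical interactions rescored by iterative AdjustCD, a
  shared-neighbor reliability measure.  Interactions whose endpoints share no
  neighbor are discarded as unreliable.
* **L2-PPI** — non-interacting pairs that share interaction partners, emitted
  as a separate source when their AdjustCD score exceeds a threshold
  (default 0.1).
* **PubMed** — literature co-occurrence, scored by the Jaccard similarity of
  the sets of documents each protein appears in.

Functional-association scores (STRING-style) are consumed as given through
:func:`swcnet.io.read_scored_pairs` with ``min_score=0.5``; no internal
evidence combination is re-implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import networkx as nx

from .types import CompositeNetwork, Pair, ScoredPairTable, pair_key

logger = logging.getLogger("swcnet")


@dataclass
class AdjustCDParams:
    """Parameters of iterative AdjustCD.

    ``iterations`` (default 2) is the number of reweighting rounds;
    ``l2_threshold`` (default 0.1) is the score above which a non-interacting
    shared-neighbor pair is emitted as an L2-PPI.
    """

    iterations: int = 2
    l2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 <= self.l2_threshold < 1.0):
            raise ValueError("l2_threshold must be in [0, 1)")


def read_interactions(path: str) -> nx.Graph:
    """Read an interaction edge list (two tab-separated columns per line).

    A third column, if present, is ignored with a warning: AdjustCD starts
    from unit weights.  Self-loops are dropped.
    """
    g = nx.Graph()
    warned = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            if len(cols) > 2 and not warned:
                logger.warning("%s: extra columns ignored (weights start at 1)", path)
                warned = True
            u, v = cols[0], cols[1]
            if u == v:
                logger.warning("%s:%d: self-interaction %r dropped", path, lineno, u)
                continue
            g.add_edge(u, v)
    return g


def _adjustcd_score(
    u: str,
    v: str,
    neighbors: Mapping[str, Set[str]],
    wdeg: Mapping[str, float],
    weights: Mapping[Pair, float],
    lam: float,
) -> float:
    shared = neighbors[u] & neighbors[v]
    if not shared:
        return 0.0
    num = 0.0
    for x in shared:
        num += weights[pair_key(u, x)] + weights[pair_key(v, x)]
    den = max(wdeg[u], lam) + max(wdeg[v], lam)
    return num / den


def iterative_adjustcd(
    graph: nx.Graph, params: AdjustCDParams = AdjustCDParams()
) -> Tuple[ScoredPairTable, ScoredPairTable]:
    """Score interactions and impute L2 pairs by iterative AdjustCD.

    At iteration k the weight of a pair (u, v) is

        w_k(u,v) = sum_{x in N_u ∩ N_v} [w_{k-1}(u,x) + w_{k-1}(v,x)]
                   / [max(deg_w(u), λ) + max(deg_w(v), λ)]

    with deg_w the weighted degree under w_{k-1} and λ the mean weighted
    degree over all vertices — a penalty that damps scores of sparsely
    connected proteins.  Neighbor sets are the *observed* interaction
    neighborhoods throughout; initial weights are 1 and updates are
    simultaneous (Jacobi-style).  Returns two tables:

    * ``ppi`` — observed interactions with their final score; interactions
      whose endpoints share no neighbor are discarded as unreliable.
    * ``l2`` — non-interacting pairs with at least one shared neighbor whose
      final score exceeds ``params.l2_threshold``.

    A pair never appears in both tables, and all scores lie in [0, 1].
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty interaction graph")
    neighbors: Dict[str, Set[str]] = {n: set(graph.neighbors(n)) for n in graph}
    weights: Dict[Pair, float] = {pair_key(u, v): 1.0 for u, v in graph.edges()}

    # candidate non-edges: pairs at distance exactly 2
    l2_candidates: Set[Pair] = set()
    for x in graph:
        nbrs = sorted(neighbors[x])
        for i, u in enumerate(nbrs):
            for v in nbrs[i + 1 :]:
                key = pair_key(u, v)
                if key not in weights:
                    l2_candidates.add(key)

    l2_scores: Dict[Pair, float] = {}
    for k in range(params.iterations):
        wdeg = {
            n: sum(weights[pair_key(n, x)] for x in neighbors[n]) for n in graph
        }
        lam = sum(wdeg.values()) / graph.number_of_nodes()
        new_weights = {
            (u, v): _adjustcd_score(u, v, neighbors, wdeg, weights, lam)
            for (u, v) in weights
        }
        if k == params.iterations - 1:
            l2_scores = {
                (u, v): _adjustcd_score(u, v, neighbors, wdeg, weights, lam)
                for (u, v) in l2_candidates
            }
        weights = new_weights

    ppi = ScoredPairTable("ppi")
    for (u, v), w in weights.items():
        if neighbors[u] & neighbors[v]:
            ppi.add(u, v, w)
    l2 = ScoredPairTable("l2")
    for (u, v), w in l2_scores.items():
        if w > params.l2_threshold:
            l2.add(u, v, w)
    return ppi, l2


def read_literature_incidence(path: str) -> Dict[str, Set[str]]:
    """Read a protein→document incidence table (protein<TAB>document-ID)."""
    incidence: Dict[str, Set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            incidence.setdefault(cols[0], set()).add(cols[1])
    return incidence


def literature_jaccard(
    incidence: Mapping[str, Set[str]], min_docs: int = 1
) -> ScoredPairTable:
    """Score protein pairs by Jaccard similarity of their document sets.

    s(u, v) = |A_u ∩ A_v| / |A_u ∪ A_v| for every pair sharing at least
    ``max(1, min_docs)`` documents; pairs with an empty intersection are
    omitted.  ``min_docs`` (default 1, the reference behavior) bounds memory
    on dense incidences.
    """
    if not incidence:
        raise ValueError("empty literature incidence")
    threshold = max(1, min_docs)
    # inverted index: document -> proteins mentioning it
    by_doc: Dict[str, list] = {}
    for protein, docs in incidence.items():
        for d in docs:
            by_doc.setdefault(d, []).append(protein)
    counts: Dict[Pair, int] = {}
    for proteins in by_doc.values():
        proteins = sorted(set(proteins))
        for i, u in enumerate(proteins):
            for v in proteins[i + 1 :]:
                key = (u, v)
                counts[key] = counts.get(key, 0) + 1
    table = ScoredPairTable("pubmed")
    for (u, v), inter in counts.items():
        if inter < threshold:
            continue
        union = len(incidence[u] | incidence[v])
        table.add(u, v, inter / union)
    return table


def assemble_composite(tables: Sequence[ScoredPairTable]) -> CompositeNetwork:
    """Union the per-source tables into a composite network.

    The edge set is the union of all tables' pairs; each edge's feature
    vector has one entry per source, zero where the source does not relate
    the pair.  Source names must be distinct.  The result is independent of
    the order of ``tables`` up to feature naming.
    """
    names = [t.source_name for t in tables]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate source names: {names}")
    network = CompositeNetwork(names)
    merged: Dict[Pair, Dict[str, float]] = {}
    for t in tables:
        for key, score in t.scores.items():
            merged.setdefault(key, {})[t.source_name] = score
    for (u, v), features in merged.items():
        network.add_edge(u, v, features)
    return network
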