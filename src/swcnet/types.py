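"""Core domain types shared across the pipeline.

The pipeline moves data through a small number of containers: per-source
scored protein-pair tables, reference complex sets used for supervision and
evaluation, a composite network whose edges carry one feature value per data
source, and sets of predicted clusters.  Protein identifiers are opaque,
case-sensitive strings; unordered protein pairs are canonicalized by
lexicographic ordering so that (u, v) and (v, u) always map to the same key.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

import networkx as nx

logger = logging.getLogger("swcnet")

Pair = Tuple[str, str]


def pair_key(u: str, v: str) -> Pair:
    """Canonical unordered-pair key: lexicographically ordered tuple."""
    if u == v:
        raise ValueError(f"self-pair not allowed: {u!r}")
    return (u, v) if u < v else (v, u)


@dataclass
class ScoredPairTable:
    """Scored protein pairs from a single data source.

    ``scores`` maps canonical pair keys to the source's score ``s`` for the
    pair.  Duplicate unordered pairs are collapsed keeping the maximum score
    (union semantics of repository merges); self-pairs are rejected.
    """

    source_name: str
    scores: Dict[Pair, float] = field(default_factory=dict)

    def add(self, u: str, v: str, score: float) -> None:
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for pair ({u}, {v}): {score}")
        key = pair_key(u, v)
        prev = self.scores.get(key)
        if prev is None or score > prev:
            self.scores[key] = score

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self) -> Iterator[Tuple[Pair, float]]:
        return iter(sorted(self.scores.items()))

    def proteins(self) -> FrozenSet[str]:
        out = set()
        for u, v in self.scores:
            out.add(u)
            out.add(v)
        return frozenset(out)


@dataclass(frozen=True)
class ReferenceComplex:
    identifier: str
    members: FrozenSet[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(
                f"complex {self.identifier!r} has fewer than 2 members"
            )
        if any(not m for m in self.members):
            raise ValueError(f"complex {self.identifier!r} has an empty member ID")


@dataclass
class ReferenceComplexSet:
    """A set of reference complexes, used for training or testing.

    Ordering is stable (insertion order); identifiers are unique.
    """

    complexes: List[ReferenceComplex] = field(default_factory=list)
    role: Optional[str] = None  # "training" | "test" | None

    def __post_init__(self) -> None:
        ids = [c.identifier for c in self.complexes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate complex identifiers")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[ReferenceComplex]:
        return iter(self.complexes)

    def member_sets(self) -> List[FrozenSet[str]]:
        return [c.members for c in self.complexes]

    def co_complex_pairs(self) -> FrozenSet[Pair]:
        """All unordered pairs co-resident in at least one complex."""
        pairs = set()
        for c in self.complexes:
            members = sorted(c.members)
            for i, u in enumerate(members):
                for v in members[i + 1 :]:
                    pairs.add((u, v))
        return frozenset(pairs)

    def proteins(self) -> FrozenSet[str]:
        out: set = set()
        for c in self.complexes:
            out |= c.members
        return frozenset(out)


class CompositeNetwork:
    """Undirected network whose edges carry one feature value per data source.

    An edge exists iff at least one source relates the pair (at least one
    feature value is non-zero).  After supervision, each edge additionally
    carries a boolean co-complex ``label``; after weighting, a posterior
    ``weight`` in (0, 1).
    """

    def __init__(self, feature_names: Sequence[str]) -> None:
        if len(set(feature_names)) != len(feature_names):
            raise ValueError("duplicate feature names")
        self.feature_names: Tuple[str, ...] = tuple(feature_names)
        self.graph = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_edge(self, u: str, v: str, features: Dict[str, float]) -> None:
        key = pair_key(u, v)
        vec = {name: float(features.get(name, 0.0)) for name in self.feature_names}
        if not any(vec.values()):
            raise ValueError(f"edge {key} has all-zero features")
        unknown = set(features) - set(self.feature_names)
        if unknown:
            raise ValueError(f"unknown feature names {sorted(unknown)} on edge {key}")
        self.graph.add_edge(key[0], key[1], features=vec, label=None, weight=None)

    # -- access -----------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    def edges(self) -> Iterator[Tuple[Pair, Dict]]:
        """Iterate (canonical pair, edge-data dict) in deterministic order."""
        for u, v, data in sorted(
            ((min(a, b), max(a, b), d) for a, b, d in self.graph.edges(data=True))
        ):
            yield (u, v), data

    def edge_data(self, u: str, v: str) -> Dict:
        return self.graph.edges[u, v]

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def weight(self, u: str, v: str, default: float = 0.0) -> float:
        if not self.graph.has_edge(u, v):
            return default
        w = self.graph.edges[u, v].get("weight")
        return default if w is None else w

    def is_labeled(self) -> bool:
        return all(d["label"] is not None for _, _, d in self.graph.edges(data=True))

    def is_weighted(self) -> bool:
        return all(d["weight"] is not None for _, _, d in self.graph.edges(data=True))

    def copy(self) -> "CompositeNetwork":
        out = CompositeNetwork(self.feature_names)
        out.graph = self.graph.copy()
        return out


@dataclass(frozen=True)
class Cluster:
    """A predicted cluster with its weighted density and (voted) score.

    ``score`` equals ``density`` for a single-algorithm cluster and
    ``density * votes`` after aggregation, so ``score >= density`` always.
    """

    members: FrozenSet[str]
    density: float = 0.0
    score: float = 0.0
    provenance: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty cluster")
        if self.score < self.density - 1e-12:
            raise ValueError("cluster score below its density")

    def sorted_members(self) -> Tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass
class ClusterSet:
    """Sequence of predicted clusters; member sets may overlap."""

    clusters: List[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[Cluster]:
        return iter(self.clusters)

    def sorted_by_score(self) -> List[Cluster]:
        return sorted(
            self.clusters, key=lambda c: (-c.score, c.sorted_members())
        )

    def member_sets(self) -> List[FrozenSet[str]]:
        return [c.members for c in self.clusters]
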