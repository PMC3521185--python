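"""GO-based semantic coherence of predicted complexes.

Semantic similarity between two proteins is the information content (IC) of
the most informative common ancestor over their annotated terms, per
namespace (biological process, cellular component, molecular function).
The IC of a term is -log2 of the fraction of annotated proteins covered by
the term or any of its descendants, computed against the user-supplied
annotation corpus itself.  The coherence of a complex is the average
pair similarity over its members; pairs involving unannotated proteins are
skipped (not scored 0) and reported through a coverage fraction, so missing
annotation is not conflated with dissimilarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

logger = logging.getLogger("swcnet")

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")
_RELATIONS = ("is_a", "part_of")


class OntologyDag:
    """Ontology terms with is-a / part-of parent edges and namespaces."""

    def __init__(
        self,
        namespace_of: Mapping[str, str],
        parents: Mapping[str, Set[str]],
    ) -> None:
        self.namespace_of: Dict[str, str] = dict(namespace_of)
        self.parents: Dict[str, Set[str]] = {
            t: set(parents.get(t, set())) for t in self.namespace_of
        }
        for t, ps in self.parents.items():
            missing = ps - set(self.namespace_of)
            if missing:
                raise ValueError(f"term {t} has unknown parents {sorted(missing)}")
        g = nx.DiGraph()
        g.add_nodes_from(self.namespace_of)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        self._ancestors: Dict[str, FrozenSet[str]] = {}

    @classmethod
    def from_obo(cls, path: str) -> "OntologyDag":
        """Load an OBO file; is_a and part_of are honored, others ignored."""
        import obonet

        g = obonet.read_obo(path)
        namespace_of = {}
        parents: Dict[str, Set[str]] = {}
        ignored: Set[str] = set()
        for term, data in g.nodes(data=True):
            namespace_of[term] = data.get("namespace", "biological_process")
            parents[term] = set()
        for child, parent, key in g.edges(keys=True):
            if key in _RELATIONS:
                parents[child].add(parent)
            else:
                ignored.add(key)
        if ignored:
            logger.warning("ignored ontology relations: %s", sorted(ignored))
        return cls(namespace_of, parents)

    def ancestors(self, term: str) -> FrozenSet[str]:
        """Ancestor closure of a term, including the term itself."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        out: Set[str] = {term}
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestors[term] = result
        return result


class AnnotationMap:
    """Protein -> directly annotated terms, per namespace."""

    def __init__(self, dag: OntologyDag) -> None:
        self.dag = dag
        self.by_namespace: Dict[str, Dict[str, Set[str]]] = {}

    def add(self, protein: str, term: str, namespace: Optional[str] = None) -> None:
        if term not in self.dag.namespace_of:
            raise KeyError(f"term {term!r} not in ontology")
        ns = namespace or self.dag.namespace_of[term]
        if ns != self.dag.namespace_of[term]:
            raise ValueError(
                f"term {term!r} belongs to {self.dag.namespace_of[term]!r}, not {ns!r}"
            )
        self.by_namespace.setdefault(ns, {}).setdefault(protein, set()).add(term)

    @classmethod
    def from_tsv(cls, path: str, dag: OntologyDag) -> "AnnotationMap":
        """Read a GAF-like TSV of (protein, term[, namespace]) rows."""
        out = cls(dag)
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
                out.add(cols[0], cols[1], cols[2] if len(cols) > 2 else None)
        return out

    def terms(self, protein: str, namespace: str) -> Set[str]:
        return self.by_namespace.get(namespace, {}).get(protein, set())

    def annotated_proteins(self, namespace: str) -> List[str]:
        return sorted(self.by_namespace.get(namespace, {}))


@dataclass
class CoherenceResult:
    """Mean pair similarity over computable pairs, plus their fraction."""

    coherence: Optional[float]
    coverage: float


class CoherenceScorer:
    """Most-informative-common-ancestor similarity over one annotation corpus.

    Precomputes, per namespace, each protein's ancestor closure and each
    term's cover (number of annotated proteins annotated to the term or a
    descendant); IC(term) = -log2(cover / #annotated proteins).
    """

    def __init__(self, dag: OntologyDag, annotations: AnnotationMap) -> None:
        self.dag = dag
        self.annotations = annotations
        self._closure: Dict[str, Dict[str, FrozenSet[str]]] = {}
        self._cover: Dict[str, Dict[str, int]] = {}
        self._n_annotated: Dict[str, int] = {}

    def _prepare(self, namespace: str) -> None:
        if namespace in self._closure:
            return
        closure: Dict[str, FrozenSet[str]] = {}
        cover: Dict[str, int] = {}
        proteins = self.annotations.annotated_proteins(namespace)
        for protein in proteins:
            anc: Set[str] = set()
            for term in self.annotations.terms(protein, namespace):
                anc |= self.dag.ancestors(term)
            closure[protein] = frozenset(anc)
            for t in anc:
                cover[t] = cover.get(t, 0) + 1
        self._closure[namespace] = closure
        self._cover[namespace] = cover
        self._n_annotated[namespace] = len(proteins)

    def term_ic(self, term: str, namespace: Optional[str] = None) -> float:
        ns = namespace or self.dag.namespace_of[term]
        self._prepare(ns)
        cover = self._cover[ns].get(term, 0)
        total = self._n_annotated[ns]
        if cover == 0 or total == 0:
            raise ValueError(f"term {term!r} annotates no protein; IC undefined")
        return -math.log2(cover / total)

    def pair_similarity(self, u: str, v: str, namespace: str) -> float:
        """Max IC over common ancestors of the two proteins' term sets."""
        self._prepare(namespace)
        closure = self._closure[namespace]
        if u not in closure or v not in closure:
            raise KeyError(f"protein pair ({u}, {v}) not annotated in {namespace}")
        common = closure[u] & closure[v]
        if not common:
            return 0.0
        return max(self.term_ic(t, namespace) for t in common)

    def complex_coherence(
        self, members: Iterable[str], namespace: str
    ) -> CoherenceResult:
        """Average pair similarity over computable unordered member pairs."""
        members = sorted(set(members))
        total_pairs = len(members) * (len(members) - 1) // 2
        if total_pairs == 0:
            raise ValueError("coherence needs at least 2 members")
        self._prepare(namespace)
        closure = self._closure[namespace]
        annotated = [m for m in members if m in closure]
        sims: List[float] = []
        for i, u in enumerate(annotated):
            for v in annotated[i + 1 :]:
                sims.append(self.pair_similarity(u, v, namespace))
        coverage = len(sims) / total_pairs
        if not sims:
            return CoherenceResult(None, 0.0)
        return CoherenceResult(sum(sims) / len(sims), coverage)

    def annotate_high_level(
        self, members: Iterable[str], candidate_terms: Sequence[str]
    ) -> Set[str]:
        """High-level terms covering the most members, if a strict majority.

        A member counts toward a candidate term when annotated to it or any
        descendant.  All candidates tied at the maximum count are returned,
        provided that count exceeds half the members; otherwise the empty
        set (a complex may legitimately carry several high-level terms).
        """
        members = sorted(set(members))
        counts: Dict[str, int] = {}
        for term in candidate_terms:
            ns = self.dag.namespace_of[term]
            self._prepare(ns)
            closure = self._closure[ns]
            counts[term] = sum(
                1 for m in members if term in closure.get(m, frozenset())
            )
        if not counts:
            return set()
        best = max(counts.values())
        if best * 2 <= len(members):
            return set()
        return {t for t, c in counts.items() if c == best}


def coherence_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided rank-sum p-value comparing two coherence distributions."""
    from scipy.stats import mannwhitneyu

    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
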