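"""Synthetic benchmark generator with the statistical structure the
weighting method assumes.

The generator plants protein complexes, then emits one scored pair table
per data source in which co-complex pairs and background pairs draw scores
from different Beta distributions (stochastically ordered, so likelihood
ratios increase with score).  It also emulates the two structured noise
regimes of real interaction data:

* **missing co-complex edges** — a co-complex pair is present in a source
  only with probability ``co_presence``, and a ``dropout`` fraction of
  co-complex pairs is removed from every source at once;
* **transient-interaction hubs** — promiscuous proteins outside every
  complex whose many interactions score like co-complex pairs in a single
  source (the interaction source) with no support from the others; exactly
  the failure mode supervised integration should suppress.

Everything is reproducible from the seed, and
:func:`true_likelihood_ratios` integrates the generative distributions over
a discretization scheme to give the exact ratios a learner should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np
from scipy.stats import beta as beta_dist

from .types import (
    Pair,
    ReferenceComplex,
    ReferenceComplexSet,
    ScoredPairTable,
    pair_key,
)
from .weighting import DiscretizationScheme, LikelihoodTable


@dataclass(frozen=True)
class SourceSpec:
    """Generative spec for one data source.

    ``co_presence``/``co_score`` govern co-complex pairs, ``bg_edges`` is the
    target background pair count with ``bg_score`` their Beta parameters,
    and ``hub_presence`` is the probability a transient-hub pair appears in
    this source (with co-complex-like scores).
    """

    name: str
    co_presence: float = 0.7
    co_score: Tuple[float, float] = (5.0, 2.0)
    bg_edges: int = 15000
    bg_score: Tuple[float, float] = (2.0, 5.0)
    hub_presence: float = 0.0


DEFAULT_SOURCES: Tuple[SourceSpec, ...] = (
    SourceSpec("ppi", hub_presence=1.0),
    SourceSpec("string"),
    SourceSpec("pubmed"),
)


@dataclass
class SynthParams:
    """Study conditions for the synthetic benchmark.

    Defaults plant 200 complexes of 4-12 proteins on 2000 proteins with
    three sources at 15000 background pairs each (about 50000 composite
    edges in total), 10% whole-pair dropout, and 20 transient hubs of
    degree 20-50.
    """

    seed: int
    n_proteins: int = 2000
    n_complexes: int = 200
    size_min: int = 4
    size_max: int = 12
    sources: Tuple[SourceSpec, ...] = DEFAULT_SOURCES
    dropout: float = 0.1
    n_transient_hubs: int = 20
    hub_degree_min: int = 20
    hub_degree_max: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be in [0, 1]")
        if self.size_min < 2 or self.size_max < self.size_min:
            raise ValueError("invalid complex size range")
        if self.size_max > self.n_proteins:
            raise ValueError("complexes need more proteins than exist")
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("duplicate source names")
        for s in self.sources:
            for p in (s.co_presence, s.hub_presence):
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"presence probability out of range in {s.name}")


def _protein_names(n: int) -> List[str]:
    width = len(str(n - 1))
    return [f"P{i:0{width}d}" for i in range(n)]


def _sample_background_pairs(
    rng: np.random.Generator,
    proteins: List[str],
    n_pairs: int,
    forbidden: Set[Pair],
) -> List[Pair]:
    """Distinct uniform random pairs avoiding ``forbidden``."""
    n = len(proteins)
    chosen: Set[Pair] = set()
    out: List[Pair] = []
    while len(out) < n_pairs:
        need = n_pairs - len(out)
        us = rng.integers(0, n, size=2 * need + 16)
        vs = rng.integers(0, n, size=2 * need + 16)
        for ui, vi in zip(us, vs):
            if ui == vi:
                continue
            key = pair_key(proteins[ui], proteins[vi])
            if key in forbidden or key in chosen:
                continue
            chosen.add(key)
            out.append(key)
            if len(out) == n_pairs:
                break
    return out


def generate_benchmark(
    params: SynthParams,
) -> Tuple[ReferenceComplexSet, List[ScoredPairTable], Dict[Pair, bool]]:
    """Plant complexes and emit per-source scored pair tables.

    Returns the planted reference complexes, one table per source, and the
    ground-truth co-complex label for every pair emitted by any source
    (True iff the pair co-occurs in some planted complex).
    """
    rng = np.random.default_rng(params.seed)
    proteins = _protein_names(params.n_proteins)

    # --- plant complexes (independent member draws; overlaps allowed) ----
    complexes: List[ReferenceComplex] = []
    for i in range(params.n_complexes):
        size = int(rng.integers(params.size_min, params.size_max + 1))
        members = rng.choice(params.n_proteins, size=size, replace=False)
        complexes.append(
            ReferenceComplex(f"S{i + 1}", frozenset(proteins[j] for j in members))
        )
    reference = ReferenceComplexSet(complexes, role="reference")
    co_pairs = sorted(reference.co_complex_pairs())

    # --- whole-pair dropout: missing from every source at once -----------
    keep_mask = rng.random(len(co_pairs)) >= params.dropout
    surviving_co = [p for p, keep in zip(co_pairs, keep_mask) if keep]

    # --- transient hubs outside every complex ----------------------------
    in_complex = reference.proteins()
    free = [p for p in proteins if p not in in_complex]
    if len(free) < params.n_transient_hubs:
        raise ValueError("not enough complex-free proteins for transient hubs")
    hub_idx = rng.choice(len(free), size=params.n_transient_hubs, replace=False)
    hubs = [free[i] for i in sorted(hub_idx)]
    co_pair_set = set(co_pairs)
    hub_pairs: List[Pair] = []
    hub_pair_set: Set[Pair] = set()
    for hub in hubs:
        degree = int(rng.integers(params.hub_degree_min, params.hub_degree_max + 1))
        partners = rng.choice(params.n_proteins, size=degree, replace=False)
        for j in partners:
            partner = proteins[j]
            if partner == hub:
                continue
            key = pair_key(hub, partner)
            if key in co_pair_set or key in hub_pair_set:
                continue
            hub_pair_set.add(key)
            hub_pairs.append(key)

    # --- per-source tables ------------------------------------------------
    forbidden = co_pair_set | hub_pair_set
    tables: List[ScoredPairTable] = []
    for spec in params.sources:
        table = ScoredPairTable(spec.name)
        present = rng.random(len(surviving_co)) < spec.co_presence
        scores = rng.beta(*spec.co_score, size=len(surviving_co))
        for (u, v), ok, s in zip(surviving_co, present, scores):
            if ok:
                table.add(u, v, float(s))
        if spec.hub_presence > 0 and hub_pairs:
            present = rng.random(len(hub_pairs)) < spec.hub_presence
            scores = rng.beta(*spec.co_score, size=len(hub_pairs))
            for (u, v), ok, s in zip(hub_pairs, present, scores):
                if ok:
                    table.add(u, v, float(s))
        bg = _sample_background_pairs(rng, proteins, spec.bg_edges, forbidden)
        scores = rng.beta(*spec.bg_score, size=len(bg))
        for (u, v), s in zip(bg, scores):
            table.add(u, v, float(s))
        tables.append(table)

    labels: Dict[Pair, bool] = {}
    for table in tables:
        for key in table.scores:
            labels[key] = key in co_pair_set
    return reference, tables, labels


def write_labels(labels: Dict[Pair, bool], path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for (u, v) in sorted(labels):
            fh.write(f"{u}\t{v}\t{int(labels[(u, v)])}\n")


# ---------------------------------------------------------------------------
# Exact likelihood-ratio oracle
# ---------------------------------------------------------------------------

def _expected_counts(params: SynthParams) -> Tuple[float, float, float]:
    """Expected (#co pairs after dropout, #non-co non-hub pairs, #hub pairs).

    Overlap between planted complexes is ignored (it is negligible at the
    default density); these counts only set the mixture weights of the
    non-co-complex class.
    """
    sizes = np.arange(params.size_min, params.size_max + 1)
    mean_pairs = float(np.mean(sizes * (sizes - 1) / 2))
    n_co = params.n_complexes * mean_pairs * (1.0 - params.dropout)
    mean_deg = (params.hub_degree_min + params.hub_degree_max) / 2.0
    n_hub = params.n_transient_hubs * mean_deg
    n_all = params.n_proteins * (params.n_proteins - 1) / 2.0
    n_bg = n_all - params.n_complexes * mean_pairs - n_hub
    return n_co, n_bg, n_hub


def true_likelihood_ratios(
    params: SynthParams, scheme: DiscretizationScheme
) -> LikelihoodTable:
    """Integrate the generative distributions over a scheme's bins.

    For each source and bin, returns the exact ratio
    P(bin | co-complex, edge) / P(bin | non-co-complex, edge) implied by the
    generative process, conditioning on the pair being an edge of the
    composite network (at least one source present).  This is the quantity
    the learner's empirical likelihood ratios should recover.
    """
    _, n_bg, n_hub = _expected_counts(params)
    pi = {s.name: s.co_presence for s in params.sources}
    hub = {s.name: s.hub_presence for s in params.sources}
    q = {
        s.name: min(1.0, s.bg_edges / n_bg) for s in params.sources
    }

    def p_any(probs: Dict[str, float], skip: str = "") -> float:
        out = 1.0
        for name, p in probs.items():
            if name != skip:
                out *= 1.0 - p
        return 1.0 - out

    rows: Dict[str, List[Tuple[float, float, float]]] = {}
    for spec in params.sources:
        name = spec.name
        disc = scheme.features.get(name)
        if disc is None or disc.dropped:
            continue
        co_rv = beta_dist(*spec.co_score)
        bg_rv = beta_dist(*spec.bg_score)
        p_edge_co = p_any(pi)
        p_edge_bg = p_any(q)
        p_edge_hub = p_any(hub)
        row: List[Tuple[float, float, float]] = []
        for b in range(disc.n_bins):
            lo, hi = disc.bin_range(b)
            lo_c = max(lo, 0.0) if math.isfinite(lo) else 0.0
            hi_c = min(hi, 1.0) if math.isfinite(hi) else 1.0
            zero_in_bin = lo < 0.0 or b == 0
            d_co = co_rv.cdf(hi_c) - co_rv.cdf(lo_c)
            d_bg = bg_rv.cdf(hi_c) - bg_rv.cdf(lo_c)

            num = pi[name] * d_co
            if zero_in_bin:
                num += (1.0 - pi[name]) * p_any(pi, skip=name)
            num /= p_edge_co

            bg_mass = q[name] * d_bg
            if zero_in_bin:
                bg_mass += (1.0 - q[name]) * p_any(q, skip=name)
            hub_mass = hub[name] * d_co
            if zero_in_bin:
                hub_mass += (1.0 - hub[name]) * p_any(hub, skip=name)
            den_mass = n_bg * bg_mass + n_hub * hub_mass
            den_norm = n_bg * p_edge_bg + n_hub * p_edge_hub
            den = den_mass / den_norm if den_norm > 0 else 0.0
            # degenerate support: the bin (or class) has no background mass,
            # so the finite empirical ratio is bounded only by smoothing
            ratio = math.inf if den == 0.0 else num / den
            row.append((lo, hi, ratio))
        rows[name] = row
    return LikelihoodTable(rows)
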