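"""Supervised edge weighting by posterior co-complex probability.

Each edge of the composite network is a data instance whose features are the
per-source scores (0 where a source does not relate the pair).  Training
complexes label each edge *co-complex* (both endpoints in one training
complex) or *non-co-complex*.  Learning proceeds in two steps:

1. minimum-description-length (MDL) supervised discretization of each
   feature; features with no accepted cut carry no class information and are
   dropped (simple feature selection);
2. maximum-likelihood estimation of the class-conditional bin probabilities
   P(F=f | co-comp) = n_{c,F=f} / n_c and the class priors.

The weight of an edge is then its two-class naive-Bayes posterior

    w(e) = Π_i P(F_i=f_i | c) P(c) / [Π_i P(F_i=f_i | c) P(c)
                                      + Π_i P(F_i=f_i | ¬c) P(¬c)]

computed in log space.  A pseudocount ``alpha`` (default 1) smooths the
conditionals only, so likelihood ratios stay finite on empty bins; priors
remain raw frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import yaml

from .types import CompositeNetwork, Cluster, ReferenceComplexSet

logger = logging.getLogger("swcnet")


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def label_edges(
    network: CompositeNetwork, training: ReferenceComplexSet
) -> CompositeNetwork:
    """Label every edge co-complex (True) / non-co-complex (False) in place.

    An edge is co-complex iff some single training complex contains both
    endpoints; one witnessing complex suffices.
    """
    if len(training) == 0:
        raise ValueError("empty training complex set: supervision impossible")
    positive = training.co_complex_pairs()
    for (u, v), data in network.edges():
        data["label"] = (u, v) in positive
    return network


# ---------------------------------------------------------------------------
# MDL supervised discretization (recursive entropy minimization)
# ---------------------------------------------------------------------------

def _entropy(n_pos: int, n_total: int) -> float:
    """Binary class entropy in bits."""
    if n_total == 0 or n_pos == 0 or n_pos == n_total:
        return 0.0
    p = n_pos / n_total
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def _n_classes(n_pos: int, n_total: int) -> int:
    k = 0
    if n_pos > 0:
        k += 1
    if n_total - n_pos > 0:
        k += 1
    return k


def _mdl_split(
    values: np.ndarray, pos_prefix: np.ndarray, lo: int, hi: int, cuts: List[float]
) -> None:
    """Recursively split sorted segment [lo, hi); append accepted cut values.

    A cut between positions i-1 and i is a candidate where the value
    changes.  The best candidate (minimum weighted class entropy, smallest
    cut value on ties) is accepted iff its information gain exceeds the MDL
    cost term; accepted cuts recurse into both halves.
    """
    n = hi - lo
    if n < 2:
        return
    pos = int(pos_prefix[hi] - pos_prefix[lo])
    ent_s = _entropy(pos, n)
    if ent_s == 0.0:
        return  # pure segment: no gain possible

    seg = values[lo:hi]
    # candidate split positions: value changes between i-1 and i
    change = np.nonzero(seg[1:] != seg[:-1])[0] + 1  # local indices into seg
    if change.size == 0:
        return
    idx = change + lo
    n1 = idx - lo
    n2 = hi - idx
    p1 = (pos_prefix[idx] - pos_prefix[lo]).astype(np.int64)
    p2 = pos - p1

    def vent(np_, nt):
        out = np.zeros(len(nt), dtype=float)
        mask = (np_ > 0) & (np_ < nt)
        p = np_[mask] / nt[mask]
        out[mask] = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        return out

    ent1 = vent(p1, n1)
    ent2 = vent(p2, n2)
    weighted = (n1 * ent1 + n2 * ent2) / n
    best = int(np.argmin(weighted))  # ties: smallest cut value (first index)
    gain = ent_s - weighted[best]

    k = _n_classes(pos, n)
    k1 = _n_classes(int(p1[best]), int(n1[best]))
    k2 = _n_classes(int(p2[best]), int(n2[best]))
    delta = (
        math.log2(3**k - 2) - k * ent_s + k1 * ent1[best] + k2 * ent2[best]
    )
    threshold = (math.log2(n - 1) + delta) / n
    if gain <= threshold:
        return

    split = int(idx[best])
    cut = (values[split - 1] + values[split]) / 2.0
    cuts.append(float(cut))
    _mdl_split(values, pos_prefix, lo, split, cuts)
    _mdl_split(values, pos_prefix, split, hi, cuts)


@dataclass(frozen=True)
class FeatureDiscretization:
    """Accepted cut points for one feature; ``dropped`` when none accepted."""

    cut_points: Tuple[float, ...]
    dropped: bool

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1

    def bin_index(self, value: float) -> int:
        return int(np.searchsorted(self.cut_points, value, side="right"))

    def bin_range(self, index: int) -> Tuple[float, float]:
        lo = -math.inf if index == 0 else self.cut_points[index - 1]
        hi = math.inf if index == len(self.cut_points) else self.cut_points[index]
        return lo, hi


def mdl_discretize(
    values: Sequence[float], labels: Sequence[bool]
) -> FeatureDiscretization:
    """Discretize one feature by recursive MDL entropy minimization.

    ``values`` and ``labels`` are parallel; labels are booleans
    (co-complex = True).  Returns the accepted cut points, sorted; the
    feature is flagged dropped when the top-level split is rejected.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels, dtype=bool)
    if vals.shape != labs.shape or vals.ndim != 1 or len(vals) < 2:
        raise ValueError("values and labels must be parallel sequences of length >= 2")
    bad = np.nonzero(~np.isfinite(vals))[0]
    if bad.size:
        raise ValueError(f"non-finite feature value at index {int(bad[0])}")
    order = np.argsort(vals, kind="stable")
    vals = vals[order]
    labs = labs[order]
    pos_prefix = np.concatenate([[0], np.cumsum(labs)])
    cuts: List[float] = []
    _mdl_split(vals, pos_prefix, 0, len(vals), cuts)
    return FeatureDiscretization(tuple(sorted(cuts)), dropped=not cuts)


@dataclass
class DiscretizationScheme:
    """Per-feature discretizations for the composite network's sources."""

    features: Dict[str, FeatureDiscretization] = field(default_factory=dict)

    def retained(self) -> List[str]:
        return [f for f, d in self.features.items() if not d.dropped]


def discretize_network(
    network: CompositeNetwork, min_instances: int = 2
) -> DiscretizationScheme:
    """Run MDL discretization on every feature of a labeled network."""
    if network.n_edges < min_instances:
        raise ValueError("too few edges to discretize")
    pairs = [(key, data) for key, data in network.edges()]
    labels = [data["label"] for _, data in pairs]
    if any(l is None for l in labels):
        raise ValueError("network must be labeled before discretization")
    scheme = DiscretizationScheme()
    for name in network.feature_names:
        values = [data["features"][name] for _, data in pairs]
        disc = mdl_discretize(values, labels)
        if disc.dropped:
            logger.warning("feature %r carries no class information; dropped", name)
        scheme.features[name] = disc
    return scheme


# ---------------------------------------------------------------------------
# Naive-Bayes model
# ---------------------------------------------------------------------------

@dataclass
class NaiveBayesModel:
    """Two-class naive-Bayes model over discretized source features.

    ``counts[feature]`` holds per-bin counts for each class;
    ``cond[feature]`` the alpha-smoothed conditional probabilities.  Priors
    are unsmoothed class frequencies over the composite network's edges.
    """

    scheme: DiscretizationScheme
    alpha: float
    n_co: int
    n_non: int
    counts_co: Dict[str, np.ndarray]
    counts_non: Dict[str, np.ndarray]
    cond_co: Dict[str, np.ndarray]
    cond_non: Dict[str, np.ndarray]

    @property
    def feature_names(self) -> List[str]:
        return self.scheme.retained()

    @property
    def prior_co(self) -> float:
        return self.n_co / (self.n_co + self.n_non)

    @property
    def prior_non(self) -> float:
        return self.n_non / (self.n_co + self.n_non)

    def known_feature(self, name: str) -> bool:
        return name in self.scheme.features


def fit_naive_bayes(
    network: CompositeNetwork,
    scheme: DiscretizationScheme,
    alpha: float = 1.0,
) -> NaiveBayesModel:
    """Learn maximum-likelihood class-conditional bin probabilities.

    Conditionals are (count + alpha) / (class total + alpha * #bins); priors
    are raw class frequencies.  Raises when every feature was dropped.
    """
    retained = scheme.retained()
    if not retained:
        raise ValueError("no informative features: all were dropped by discretization")
    edges = [(key, data) for key, data in network.edges()]
    labels = np.array([bool(data["label"]) for _, data in edges])
    n_co = int(labels.sum())
    n_non = len(labels) - n_co
    counts_co: Dict[str, np.ndarray] = {}
    counts_non: Dict[str, np.ndarray] = {}
    cond_co: Dict[str, np.ndarray] = {}
    cond_non: Dict[str, np.ndarray] = {}
    for name in retained:
        disc = scheme.features[name]
        values = np.array([data["features"][name] for _, data in edges])
        bins = np.searchsorted(disc.cut_points, values, side="right")
        n_bins = disc.n_bins
        c_co = np.bincount(bins[labels], minlength=n_bins).astype(float)
        c_non = np.bincount(bins[~labels], minlength=n_bins).astype(float)
        counts_co[name] = c_co
        counts_non[name] = c_non
        cond_co[name] = (c_co + alpha) / (n_co + alpha * n_bins)
        cond_non[name] = (c_non + alpha) / (n_non + alpha * n_bins)
    return NaiveBayesModel(
        scheme=scheme,
        alpha=alpha,
        n_co=n_co,
        n_non=n_non,
        counts_co=counts_co,
        counts_non=counts_non,
        cond_co=cond_co,
        cond_non=cond_non,
    )


def posterior_weight(model: NaiveBayesModel, features: Mapping[str, float]) -> float:
    """Posterior co-complex probability of one feature vector, in (0, 1).

    Accumulates log conditionals for both classes and normalizes once, so
    the posterior of the complement is exactly ``1 - weight``.
    """
    for name in features:
        if not model.known_feature(name):
            raise KeyError(f"feature {name!r} unknown to the model")
    log_co = math.log(model.prior_co)
    log_non = math.log(model.prior_non)
    for name in model.feature_names:
        b = model.scheme.features[name].bin_index(features.get(name, 0.0))
        log_co += math.log(model.cond_co[name][b])
        log_non += math.log(model.cond_non[name][b])
    # weight = exp(log_co) / (exp(log_co) + exp(log_non)), stably:
    return 1.0 / (1.0 + math.exp(log_non - log_co))


def weight_edges(network: CompositeNetwork, model: NaiveBayesModel) -> CompositeNetwork:
    """Assign the posterior weight to every edge of the network, in place."""
    edges = [(key, data) for key, data in network.edges()]
    log_co = np.full(len(edges), math.log(model.prior_co))
    log_non = np.full(len(edges), math.log(model.prior_non))
    for name in model.feature_names:
        disc = model.scheme.features[name]
        values = np.array([data["features"][name] for _, data in edges])
        bins = np.searchsorted(disc.cut_points, values, side="right")
        log_co += np.log(model.cond_co[name][bins])
        log_non += np.log(model.cond_non[name][bins])
    weights = 1.0 / (1.0 + np.exp(log_non - log_co))
    for ((_, data), w) in zip(edges, weights):
        data["weight"] = float(w)
    return network


# ---------------------------------------------------------------------------
# Likelihood ratios and exports
# ---------------------------------------------------------------------------

@dataclass
class LikelihoodTable:
    """Per-feature, per-bin likelihood ratios P(f|c)/P(f|¬c).

    Ratios are finite and positive thanks to smoothing; the ratio of a bin
    is the "co-complexness strength" of observing a source score in it.
    """

    rows: Dict[str, List[Tuple[float, float, float]]]  # feature -> [(lo, hi, ratio)]

    def ratio(self, feature: str, bin_index: int) -> float:
        return self.rows[feature][bin_index][2]


def likelihood_ratio_table(model: NaiveBayesModel) -> LikelihoodTable:
    rows: Dict[str, List[Tuple[float, float, float]]] = {}
    for name in model.feature_names:
        disc = model.scheme.features[name]
        ratios = model.cond_co[name] / model.cond_non[name]
        rows[name] = [
            (*disc.bin_range(i), float(ratios[i])) for i in range(disc.n_bins)
        ]
    return LikelihoodTable(rows)


def write_likelihood_table(table: LikelihoodTable, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("feature\tbin_lo\tbin_hi\tlikelihood_ratio\n")
        for feature in sorted(table.rows):
            for lo, hi, ratio in table.rows[feature]:
                fh.write(f"{feature}\t{lo:.17g}\t{hi:.17g}\t{ratio:.17g}\n")


def top_k_edges(network: CompositeNetwork, k: int) -> CompositeNetwork:
    """Keep the k highest-weight edges; isolated vertices are dropped.

    Ties at the boundary break by canonical edge key (lexicographic) so the
    output has exactly min(k, |E|) edges, deterministically.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    ranked = sorted(
        network.edges(), key=lambda item: (-item[1]["weight"], item[0])
    )
    out = CompositeNetwork(network.feature_names)
    for (u, v), data in ranked[:k]:
        out.graph.add_edge(u, v, **{key: val for key, val in data.items()})
    return out


def export_likelihood_network(
    network: CompositeNetwork,
    model: NaiveBayesModel,
    cluster: Cluster,
    path: str,
) -> None:
    """Export a cluster's evidence as a GraphML multi-edge graph.

    One edge per (protein pair, source with non-zero value), carrying the
    source name, raw value, bin index, and likelihood ratio, plus the pair's
    posterior weight — the data behind per-source edge-thickness renderings
    of predicted complexes.
    """
    missing = cluster.members - set(network.graph.nodes)
    if missing:
        raise ValueError(f"cluster members absent from network: {sorted(missing)}")
    table = likelihood_ratio_table(model)
    g = nx.MultiGraph()
    g.add_nodes_from(cluster.sorted_members())
    members = cluster.sorted_members()
    for i, u in enumerate(members):
        for v in members[i + 1 :]:
            if not network.has_edge(u, v):
                continue
            data = network.edge_data(u, v)
            w = posterior_weight(model, data["features"])
            for name in model.feature_names:
                value = data["features"].get(name, 0.0)
                if value == 0.0:
                    continue
                b = model.scheme.features[name].bin_index(value)
                g.add_edge(
                    u,
                    v,
                    source=name,
                    value=float(value),
                    bin=int(b),
                    likelihood_ratio=float(table.ratio(name, b)),
                    posterior_weight=float(w),
                )
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Model persistence (structured text)
# ---------------------------------------------------------------------------

def save_model(model: NaiveBayesModel, path: str) -> None:
    doc = {
        "alpha": model.alpha,
        "n_co": model.n_co,
        "n_non": model.n_non,
        "features": {
            name: {
                "cut_points": list(disc.cut_points),
                "dropped": disc.dropped,
            }
            for name, disc in model.scheme.features.items()
        },
        "counts_co": {k: v.tolist() for k, v in model.counts_co.items()},
        "counts_non": {k: v.tolist() for k, v in model.counts_non.items()},
    }
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_model(path: str) -> NaiveBayesModel:
    with open(path, "rt", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    scheme = DiscretizationScheme(
        {
            name: FeatureDiscretization(tuple(spec["cut_points"]), spec["dropped"])
            for name, spec in doc["features"].items()
        }
    )
    alpha = float(doc["alpha"])
    n_co, n_non = int(doc["n_co"]), int(doc["n_non"])
    counts_co = {k: np.array(v, dtype=float) for k, v in doc["counts_co"].items()}
    counts_non = {k: np.array(v, dtype=float) for k, v in doc["counts_non"].items()}
    cond_co = {}
    cond_non = {}
    for name in scheme.retained():
        n_bins = scheme.features[name].n_bins
        cond_co[name] = (counts_co[name] + alpha) / (n_co + alpha * n_bins)
        cond_non[name] = (counts_non[name] + alpha) / (n_non + alpha * n_bins)
    return NaiveBayesModel(
        scheme=scheme,
        alpha=alpha,
        n_co=n_co,
        n_non=n_non,
        counts_co=counts_co,
        counts_non=counts_non,
        cond_co=cond_co,
        cond_non=cond_non,
    )
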