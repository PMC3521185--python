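"""Evaluation of predicted clusters and edge weights.

A predicted cluster P *matches* a reference complex C when
Jaccard(P, C) >= match_thres (0.5 by default, 0.75 for the strict setting).
Cluster-level precision/recall curves sweep decreasing score thresholds d:

    Recall(d)    = |{C_i : some P_j with score >= d matches C_i}| / |C|
    Precision(d) = |{P_j : score >= d and P_j matches some test complex}|
                   / |{P_k : score >= d and (P_k matches no training complex
                                             or P_k matches a test complex)}|

Clusters that match only training complexes are excluded from the precision
denominator, which removes the supervised methods' bias toward re-predicting
their training complexes.  The area under the precision-recall curve (AUC,
trapezoidal) summarizes a curve.

Edge-level evaluation classifies edges as co-complex by thresholding their
weights, with training-complex edges excluded, and tracks the fraction of
test complexes covered by at least one retained edge.

The cross-validation driver repeats the full pipeline (split, label,
discretize, fit, weight, top-k, cluster, combine, evaluate) over several
random sub-sampling rounds and pools cluster scores into a monotone
score-to-precision calibration table used to filter novel predictions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .clustering import CombineParams, combine, jaccard
from .types import Cluster, ClusterSet, CompositeNetwork, ReferenceComplexSet
from .weighting import (
    discretize_network,
    fit_naive_bayes,
    label_edges,
    top_k_edges,
    weight_edges,
)

logger = logging.getLogger("swcnet")


@dataclass(frozen=True)
class MatchCriterion:
    match_thres: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.match_thres <= 1.0):
            raise ValueError("match_thres must be in (0, 1]")


def matches(p: FrozenSet[str], c: FrozenSet[str], criterion: MatchCriterion) -> bool:
    return jaccard(p, c) >= criterion.match_thres


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    recall: float
    precision: float
    retained: int
    coverage: Optional[float] = None


@dataclass
class PRCurve:
    """Score-thresholded precision/recall points (thresholds decreasing)."""

    points: List[PRPoint]
    auc: float

    def write_tsv(self, path: str) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            has_cov = any(p.coverage is not None for p in self.points)
            header = "threshold\trecall\tprecision\tretained"
            fh.write(header + ("\tcoverage\n" if has_cov else "\n"))
            for p in self.points:
                row = f"{p.threshold:.17g}\t{p.recall:.17g}\t{p.precision:.17g}\t{p.retained}"
                if has_cov:
                    row += f"\t{p.coverage:.17g}"
                fh.write(row + "\n")


def _trapezoid_auc(points: Sequence[PRPoint]) -> float:
    """Trapezoidal area over (recall, precision), anchored at recall 0.

    The curve starts at (0, precision of the first point) and ends at the
    last point; 0/0 precision corners carry zero weight because their
    recall span is zero.
    """
    if not points:
        return 0.0
    area = 0.0
    prev_r, prev_p = 0.0, points[0].precision
    for p in points:
        area += (p.recall - prev_r) * (p.precision + prev_p) / 2.0
        prev_r, prev_p = p.recall, p.precision
    return area


def cluster_pr_curve(
    predicted: ClusterSet,
    test: ReferenceComplexSet,
    train: ReferenceComplexSet,
    criterion: MatchCriterion = MatchCriterion(),
) -> PRCurve:
    """Precision/recall of predicted clusters against the test complexes.

    Thresholds are the distinct cluster scores in descending order.  At a
    threshold where every retained cluster matches only training complexes
    the precision denominator is empty; such points record precision 1 and
    carry no area (their recall is 0).
    """
    if len(test) == 0:
        raise ValueError("empty test complex set")
    clusters = predicted.sorted_by_score()
    test_sets = test.member_sets()
    train_sets = train.member_sets()

    match_test: List[List[int]] = []
    match_train: List[bool] = []
    for c in clusters:
        match_test.append(
            [i for i, t in enumerate(test_sets) if matches(c.members, t, criterion)]
        )
        match_train.append(
            any(matches(c.members, t, criterion) for t in train_sets)
        )

    points: List[PRPoint] = []
    covered: set = set()
    n_num = 0
    n_den = 0
    i = 0
    thresholds = sorted({c.score for c in clusters}, reverse=True)
    for d in thresholds:
        while i < len(clusters) and clusters[i].score >= d:
            hits = match_test[i]
            covered.update(hits)
            if hits:
                n_num += 1
                n_den += 1
            elif not match_train[i]:
                n_den += 1
            i += 1
        recall = len(covered) / len(test_sets)
        precision = (n_num / n_den) if n_den > 0 else 1.0
        points.append(PRPoint(d, recall, precision, retained=i))
    return PRCurve(points, _trapezoid_auc(points))


def edge_classification_curve(
    network: CompositeNetwork,
    test: ReferenceComplexSet,
    train: ReferenceComplexSet,
) -> PRCurve:
    """Edge-weight thresholding as a co-complex classifier.

    Positives are network edges co-resident in some test complex; edges
    co-resident in a training complex are excluded from both numerator and
    denominator.  Each point also reports complex coverage: the fraction of
    test complexes with at least one retained edge between its members.
    """
    test_pairs = test.co_complex_pairs()
    train_pairs = train.co_complex_pairs()

    weights: List[float] = []
    positive: List[bool] = []
    kept_pairs: List[Tuple[str, str]] = []
    for (u, v), data in network.edges():
        if (u, v) in train_pairs:
            continue
        w = data.get("weight")
        if w is None:
            raise ValueError("network must be weighted")
        weights.append(w)
        positive.append((u, v) in test_pairs)
        kept_pairs.append((u, v))

    w_arr = np.asarray(weights)
    p_arr = np.asarray(positive)
    order = np.argsort(-w_arr, kind="stable")
    w_sorted = w_arr[order]
    p_sorted = p_arr[order]
    total_pos = int(p_arr.sum())

    # best (max) retained-edge weight inside each test complex
    complex_best: List[float] = []
    pair_weight = {pair: w for pair, w in zip(kept_pairs, weights)}
    for c in test.member_sets():
        members = sorted(c)
        best = -math.inf
        for a_i, u in enumerate(members):
            for v in members[a_i + 1 :]:
                w = pair_weight.get((u, v))
                if w is not None and w > best:
                    best = w
        complex_best.append(best)
    complex_best_arr = np.asarray(complex_best)

    points: List[PRPoint] = []
    cum_pos = np.cumsum(p_sorted)
    thresholds = np.unique(w_sorted)[::-1]
    for d in thresholds:
        n_ret = int(np.searchsorted(-w_sorted, -d, side="right"))
        tp = int(cum_pos[n_ret - 1]) if n_ret else 0
        precision = tp / n_ret if n_ret else 1.0
        recall = tp / total_pos if total_pos else 0.0
        coverage = float((complex_best_arr >= d).mean()) if len(complex_best_arr) else 0.0
        points.append(PRPoint(float(d), recall, precision, n_ret, coverage))
    return PRCurve(points, _trapezoid_auc(points))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Random sub-sampling cross-validation configuration.

    ``t`` is the fraction of large complexes (size > ``size_floor``) held
    out for testing each round; everything else — including all small
    complexes — trains the model.  ``k_grid`` lists the top-k edge counts
    passed to the clusterers.
    """

    seed: int
    rounds: int = 10
    t: float = 0.9
    size_floor: int = 3
    k_grid: Tuple[int, ...] = (10000, 20000)
    match_thres: float = 0.5
    alpha: float = 1.0
    calibration_bins: int = 10
    combine_params: CombineParams = field(default_factory=CombineParams)

    def __post_init__(self) -> None:
        if not (0.0 < self.t < 1.0):
            raise ValueError("t must be in (0, 1)")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cv_split(
    reference: ReferenceComplexSet, config: CVConfig, round_index: int
) -> Tuple[ReferenceComplexSet, ReferenceComplexSet]:
    """Split reference complexes into (train, test) for one round.

    Test complexes are a uniform sample without replacement of
    round(t * #candidates) of the complexes larger than ``size_floor``
    (round half away from zero: 0.9 x 149 -> 134, 0.9 x 714 -> 643); the
    training set keeps everything else, small complexes included.
    """
    if len(reference) == 0:
        raise ValueError("empty reference complex set")
    candidates = [
        i for i, c in enumerate(reference) if len(c.members) > config.size_floor
    ]
    if not candidates:
        raise ValueError("no complexes above the size floor")
    n_test = _round_half_away(config.t * len(candidates))
    rng = np.random.default_rng([config.seed, round_index])
    chosen = set(rng.choice(len(candidates), size=n_test, replace=False).tolist())
    test_idx = {candidates[i] for i in chosen}
    train = ReferenceComplexSet(
        [c for i, c in enumerate(reference) if i not in test_idx], role="training"
    )
    test = ReferenceComplexSet(
        [c for i, c in enumerate(reference) if i in test_idx], role="test"
    )
    return train, test


@dataclass
class CalibrationTable:
    """Monotone mapping from cluster score to estimated precision.

    Built from pooled cross-validation outcomes: scores are binned, the
    empirical precision per bin is flattened with pool-adjacent-violators
    so the estimate never increases as the score decreases.
    """

    bin_edges: np.ndarray  # ascending, len = n_bins + 1
    precisions: np.ndarray  # len = n_bins, non-decreasing with score

    def estimate(self, score: float) -> float:
        idx = int(np.searchsorted(self.bin_edges[1:-1], score, side="right"))
        return float(self.precisions[idx])

    def write_tsv(self, path: str) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("score_lo\tscore_hi\testimated_precision\n")
            for i, p in enumerate(self.precisions):
                fh.write(
                    f"{self.bin_edges[i]:.17g}\t{self.bin_edges[i + 1]:.17g}\t{p:.17g}\n"
                )

    @classmethod
    def from_tsv(cls, path: str) -> "CalibrationTable":
        los, his, precs = [], [], []
        with open(path, "rt", encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                if not line.strip():
                    continue
                lo, hi, p = line.rstrip("\n").split("\t")
                los.append(float(lo))
                his.append(float(hi))
                precs.append(float(p))
        edges = np.asarray(los + [his[-1]])
        return cls(bin_edges=edges, precisions=np.asarray(precs))


def _pava_non_decreasing(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators for a non-decreasing fit."""
    blocks = [[v, w] for v, w in zip(values.tolist(), weights.tolist())]
    sizes = [1] * len(blocks)
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            v1, w1 = blocks[i]
            v2, w2 = blocks[i + 1]
            w = w1 + w2
            blocks[i] = [(v1 * w1 + v2 * w2) / w if w else 0.0, w]
            sizes[i] += sizes[i + 1]
            del blocks[i + 1], sizes[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = []
    for (v, _), s in zip(blocks, sizes):
        out.extend([v] * s)
    return np.asarray(out)


def build_calibration(
    samples: Sequence[Tuple[float, bool]], n_bins: int = 10
) -> CalibrationTable:
    """Bin (score, matched-a-test-complex) samples into a monotone table."""
    if not samples:
        raise ValueError("no calibration samples")
    scores = np.asarray([s for s, _ in samples], dtype=float)
    correct = np.asarray([c for _, c in samples], dtype=float)
    # quantile bin edges over observed scores, deduplicated
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(scores, qs))
    if len(edges) < 2:
        edges = np.array([scores.min(), scores.max() + 1e-9])
    idx = np.clip(np.searchsorted(edges[1:-1], scores, side="right"), 0, len(edges) - 2)
    n = len(edges) - 1
    prec = np.zeros(n)
    counts = np.zeros(n)
    for b in range(n):
        mask = idx == b
        counts[b] = mask.sum()
        prec[b] = correct[mask].mean() if counts[b] else 0.0
    prec = _pava_non_decreasing(prec, np.maximum(counts, 1e-9))
    return CalibrationTable(bin_edges=edges, precisions=np.clip(prec, 0.0, 1.0))


Clusterer = Callable[[CompositeNetwork], ClusterSet]


@dataclass
class RoundResult:
    round_index: int
    train: ReferenceComplexSet
    test: ReferenceComplexSet
    cluster_curves: Dict[Tuple[int, str], PRCurve]  # (k, algorithm) -> curve
    edge_curve: PRCurve


@dataclass
class CVResult:
    rounds: List[RoundResult]
    calibration_samples: Dict[int, List[Tuple[float, bool]]]  # k -> samples

    def calibration(self, k: int, n_bins: int = 10) -> CalibrationTable:
        return build_calibration(self.calibration_samples[k], n_bins)

    def mean_auc(self, k: int, algorithm: str = "combined") -> float:
        aucs = [r.cluster_curves[(k, algorithm)].auc for r in self.rounds]
        return float(np.mean(aucs))


def run_crossvalidation(
    network: CompositeNetwork,
    reference: ReferenceComplexSet,
    config: CVConfig,
    clusterers: Sequence[Tuple[str, Clusterer]],
) -> CVResult:
    """Full cross-validated pipeline over ``config.rounds`` rounds.

    Each round: split the reference complexes, label the composite network
    from the training complexes, discretize and fit the naive-Bayes model,
    weight every edge, then for each k keep the top-k edges, run every
    clusterer plus the COMBINED aggregation, and score the resulting cluster
    sets against the held-out test complexes.  A failing clusterer is
    skipped with a warning and COMBINED proceeds with the survivors.
    Calibration samples (combined-cluster score, matched a test complex)
    are pooled across rounds per k, excluding train-matching clusters.
    """
    criterion = MatchCriterion(config.match_thres)
    rounds: List[RoundResult] = []
    calib: Dict[int, List[Tuple[float, bool]]] = {k: [] for k in config.k_grid}
    for r in range(config.rounds):
        train, test = cv_split(reference, config, r)
        net = network.copy()
        label_edges(net, train)
        scheme = discretize_network(net)
        model = fit_naive_bayes(net, scheme, alpha=config.alpha)
        weight_edges(net, model)
        edge_curve = edge_classification_curve(net, test, train)

        curves: Dict[Tuple[int, str], PRCurve] = {}
        for k in config.k_grid:
            top = top_k_edges(net, k)
            produced: List[ClusterSet] = []
            for name, fn in clusterers:
                try:
                    cs = fn(top)
                except Exception:  # a failing clusterer must not sink the round
                    logger.warning("clusterer %r failed; skipped", name, exc_info=True)
                    continue
                # minimum reported cluster size applies to every clusterer
                cs = ClusterSet(
                    [
                        c
                        for c in cs
                        if len(c.members) >= config.combine_params.min_cluster_size
                    ]
                )
                produced.append(cs)
                curves[(k, name)] = cluster_pr_curve(cs, test, train, criterion)
            combined = combine(produced, top, config.combine_params)
            curves[(k, "combined")] = cluster_pr_curve(combined, test, train, criterion)
            for c in combined:
                hit_train = any(
                    matches(c.members, t, criterion) for t in train.member_sets()
                )
                hit_test = any(
                    matches(c.members, t, criterion) for t in test.member_sets()
                )
                if hit_train and not hit_test:
                    continue
                calib[k].append((c.score, hit_test))
        rounds.append(RoundResult(r, train, test, curves, edge_curve))
    return CVResult(rounds, calib)


# ---------------------------------------------------------------------------
# Novel-complex filtering
# ---------------------------------------------------------------------------

def filter_novel(
    predicted: ClusterSet,
    reference: ReferenceComplexSet,
    calibration: CalibrationTable,
    confidence_thres: float = 0.5,
    match_thres: float = 0.5,
) -> ClusterSet:
    """Keep unique, novel, high-confidence predictions.

    Three passes, in order: (1) deduplicate — among pairs matching at
    ``match_thres`` the lower-scoring cluster is removed (greedy over
    descending score); (2) novelty — clusters matching any reference complex
    are removed; (3) confidence — clusters whose calibrated precision is
    strictly below ``confidence_thres`` are removed.  The output contains no
    pair with Jaccard >= ``match_thres`` and no cluster matching a
    reference complex.
    """
    criterion = MatchCriterion(match_thres)
    kept: List[Cluster] = []
    for c in predicted.sorted_by_score():
        if any(jaccard(c.members, k.members) >= match_thres for k in kept):
            continue
        kept.append(c)
    ref_sets = reference.member_sets()
    novel = [
        c for c in kept
        if not any(matches(c.members, t, criterion) for t in ref_sets)
    ]
    confident = [
        c for c in novel if calibration.estimate(c.score) >= confidence_thres
    ]
    return ClusterSet(confident)
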