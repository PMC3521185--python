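import itertools

import numpy as np
import pytest

import swcnet as s
from helpers import make_weighted_network
from swcnet.clustering import MCLParams, mcl
from swcnet.evaluation import (
    CalibrationTable,
    CVConfig,
    MatchCriterion,
    build_calibration,
    cluster_pr_curve,
    cv_split,
    edge_classification_curve,
    filter_novel,
    matches,
    run_crossvalidation,
)
from swcnet.types import Cluster, ClusterSet, ReferenceComplex, ReferenceComplexSet


def refset(role, *member_sets):
    return ReferenceComplexSet(
        [ReferenceComplex(f"{role[0]}{i}", frozenset(m)) for i, m in enumerate(member_sets)],
        role=role,
    )


def cluster(members, score, density=None):
    density = score if density is None else density
    return Cluster(frozenset(members), density, score, frozenset({"mcl"}))


class TestClusterPRCurve:
    def test_perfect_predictions_auc_one(self):
        test = refset("test", "abcd", "efgh", "ijkl")
        train = refset("training", "mnop")
        predicted = ClusterSet(
            [cluster(c.members, 0.5 + 0.1 * i) for i, c in enumerate(test)]
        )
        curve = cluster_pr_curve(predicted, test, train)
        assert curve.auc == pytest.approx(1.0)
        assert all(p.precision == 1.0 for p in curve.points)
        assert curve.points[-1].recall == 1.0

    def test_hand_derived_two_cluster_curve(self):
        # scores 0.9 / 0.4; only the first matches one of 4 test complexes
        test = refset("test", "abcd", "efgh", "ijkl", "mnop")
        train = refset("training", "qrst")
        predicted = ClusterSet(
            [cluster("abcd", 0.9), cluster("wxyz", 0.4)]
        )
        curve = cluster_pr_curve(predicted, test, train)
        got = [(p.recall, p.precision) for p in curve.points]
        assert got == [(0.25, 1.0), (0.25, 0.5)]

    def test_train_only_match_excluded_from_denominator(self):
        test = refset("test", "abcd", "efgh")
        train = refset("training", "wxyz")
        predicted = ClusterSet([cluster("abcd", 0.9), cluster("wxyz", 0.8)])
        curve = cluster_pr_curve(predicted, test, train)
        # at the lower threshold the train-matching cluster is not counted
        assert curve.points[-1].precision == 1.0

    def test_only_train_matches_gives_unit_precision_zero_recall(self):
        test = refset("test", "abcd")
        train = refset("training", "wxyz")
        predicted = ClusterSet([cluster("wxyz", 0.9)])
        curve = cluster_pr_curve(predicted, test, train)
        assert curve.points[0].precision == 1.0
        assert curve.points[0].recall == 0.0
        assert curve.auc == 0.0

    def test_recall_monotone_and_auc_bounded(self, rng):
        proteins = [f"p{i}" for i in range(40)]
        test = refset(
            "test",
            *[rng.choice(proteins, size=5, replace=False) for _ in range(6)],
        )
        train = refset("training", rng.choice(proteins, size=5, replace=False))
        predicted = ClusterSet(
            [
                cluster(rng.choice(proteins, size=int(rng.integers(4, 7)), replace=False),
                        float(rng.uniform(0, 1)))
                for _ in range(15)
            ]
        )
        curve = cluster_pr_curve(predicted, test, train)
        recalls = [p.recall for p in curve.points]
        retained = [p.retained for p in curve.points]
        assert recalls == sorted(recalls)
        assert retained == sorted(retained)
        assert 0.0 <= curve.auc <= 1.0

    def test_empty_test_set_fatal(self):
        with pytest.raises(ValueError):
            cluster_pr_curve(
                ClusterSet([cluster("abcd", 1.0)]),
                ReferenceComplexSet([], role="test"),
                refset("training", "wxyz"),
            )


class TestEdgeClassification:
    def test_perfect_separation(self):
        net = make_weighted_network(
            {("a", "b"): 0.9, ("c", "d"): 0.8, ("x", "y"): 0.2, ("x", "z"): 0.1}
        )
        test = refset("test", "ab", "cd")
        train = refset("training", "mn")
        curve = edge_classification_curve(net, test, train)
        # weights separate positives from negatives: precision 1 up to full recall
        full = next(p for p in curve.points if p.recall == 1.0)
        assert full.precision == 1.0
        assert curve.points[0].precision == 1.0

    def test_hand_counted_recall_and_coverage(self):
        # 4 positive edges; threshold 0.5 retains 2, both inside complex ab/cd
        weights = {
            ("a", "b"): 0.9,
            ("c", "d"): 0.6,
            ("e", "f"): 0.3,
            ("g", "h"): 0.2,
        }
        net = make_weighted_network(weights)
        test = refset("test", "abcd", "efgh")
        train = refset("training", "xy")
        curve = edge_classification_curve(net, test, train)
        point = next(p for p in curve.points if p.threshold == 0.6)
        assert point.recall == pytest.approx(0.5)
        assert point.coverage == pytest.approx(0.5)

    def test_training_edges_excluded(self):
        net = make_weighted_network({("a", "b"): 0.9, ("c", "d"): 0.4})
        test = refset("test", "cdzz")
        train = refset("training", "ab")
        curve = edge_classification_curve(net, test, train)
        # the (a, b) edge is invisible: only one threshold from (c, d)
        assert [p.threshold for p in curve.points] == [0.4]


class TestCVSplit:
    def reference(self, n_large, n_small):
        members = []
        for i in range(n_large):
            members.append({f"L{i}_{j}" for j in range(4)})
        for i in range(n_small):
            members.append({f"S{i}_{j}" for j in range(2)})
        return refset("reference", *members)

    def test_yeast_scale_counts(self):
        # 408 complexes, 149 of size > 3, t = 0.9 -> 134 test / 274 train
        ref = self.reference(149, 259)
        train, test = cv_split(ref, CVConfig(seed=3), 0)
        assert len(test) == 134
        assert len(train) == 274

    def test_human_scale_counts(self):
        # 1829 complexes, 714 of size > 3, t = 0.9 -> 643 test / 1186 train
        ref = self.reference(714, 1115)
        train, test = cv_split(ref, CVConfig(seed=3), 0)
        assert len(test) == 643
        assert len(train) == 1186

    def test_small_complexes_always_train(self):
        ref = self.reference(10, 5)
        train, test = cv_split(ref, CVConfig(seed=1, t=0.999), 0)
        assert all(len(c.members) > 3 for c in test)
        assert sum(1 for c in train if len(c.members) <= 3) == 5

    def test_reproducible_and_round_dependent(self):
        ref = self.reference(30, 10)
        cfg = CVConfig(seed=9)
        t1a, _ = cv_split(ref, cfg, 0)
        t1b, _ = cv_split(ref, cfg, 0)
        t2, _ = cv_split(ref, cfg, 1)
        ids = lambda r: [c.identifier for c in r]
        assert ids(t1a) == ids(t1b)
        assert ids(t1a) != ids(t2)

    def test_no_candidates_fatal(self):
        ref = self.reference(0, 5)
        with pytest.raises(ValueError):
            cv_split(ref, CVConfig(seed=1), 0)


class TestCalibration:
    def test_monotone_and_estimate(self):
        rng = np.random.default_rng(0)
        samples = [(float(x), bool(x > rng.uniform(0, 1.2))) for x in rng.uniform(0, 1, 400)]
        table = build_calibration(samples, n_bins=8)
        precs = list(table.precisions)
        assert precs == sorted(precs)  # non-decreasing with score
        assert 0.0 <= table.estimate(-1.0) <= table.estimate(2.0) <= 1.0

    def test_roundtrip(self, tmp_path):
        table = build_calibration([(0.1, False), (0.5, True), (0.9, True)], n_bins=2)
        path = tmp_path / "cal.tsv"
        table.write_tsv(str(path))
        again = CalibrationTable.from_tsv(str(path))
        for x in (0.0, 0.4, 0.95):
            assert again.estimate(x) == pytest.approx(table.estimate(x))


class TestFilterNovel:
    def calibration(self):
        return CalibrationTable(
            bin_edges=np.array([0.0, 0.5, 1.0]), precisions=np.array([0.3, 0.9])
        )

    def test_reference_matching_cluster_removed(self):
        ref = refset("reference", "abcd")
        predicted = ClusterSet([cluster("abcd", 0.9)])
        out = filter_novel(predicted, ref, self.calibration())
        assert len(out) == 0

    def test_dedup_keeps_higher_score(self):
        ref = refset("reference", "stuv")
        a = cluster("abcde", 0.9)
        b = cluster("abcdx", 0.6)  # Jaccard 4/6 = 0.67 >= 0.5
        out = filter_novel(ClusterSet([b, a]), ref, self.calibration())
        assert [c.members for c in out] == [a.members]

    def test_confidence_strictly_less_removed(self):
        ref = refset("reference", "stuv")
        low = cluster("abcd", 0.2)  # calibrated to 0.3 < 0.4
        high = cluster("efgh", 0.8)  # calibrated to 0.9
        out = filter_novel(
            ClusterSet([low, high]), ref, self.calibration(), confidence_thres=0.4
        )
        assert [c.members for c in out] == [high.members]

    def test_postconditions_on_random_inputs(self, rng):
        proteins = [f"p{i}" for i in range(40)]
        ref = refset(
            "reference",
            *[rng.choice(proteins, size=5, replace=False) for _ in range(5)],
        )
        predicted = ClusterSet(
            [
                cluster(
                    rng.choice(proteins, size=int(rng.integers(4, 8)), replace=False),
                    float(rng.uniform(0, 1)),
                )
                for _ in range(25)
            ]
        )
        out = filter_novel(predicted, ref, self.calibration(), confidence_thres=0.0)
        criterion = MatchCriterion(0.5)
        for c1, c2 in itertools.combinations(out, 2):
            assert not matches(c1.members, c2.members, criterion)
        for c in out:
            assert not any(matches(c.members, r, criterion) for r in ref.member_sets())


class TestRunCrossValidation:
    def small_benchmark(self):
        from swcnet.synthgen import DEFAULT_SOURCES, SourceSpec, SynthParams

        params = SynthParams(
            seed=42,
            n_proteins=250,
            n_complexes=18,
            sources=tuple(
                SourceSpec(x.name, bg_edges=400, hub_presence=x.hub_presence)
                for x in DEFAULT_SOURCES
            ),
            n_transient_hubs=4,
        )
        reference, tables, _ = s.generate_benchmark(params)
        return s.assemble_composite(tables), reference

    def test_deterministic_across_reruns(self):
        network, reference = self.small_benchmark()
        cfg = CVConfig(seed=5, rounds=2, k_grid=(600,))
        clusterers = [("mcl", lambda net: mcl(net, MCLParams()))]
        r1 = run_crossvalidation(network, reference, cfg, clusterers)
        r2 = run_crossvalidation(network, reference, cfg, clusterers)
        for a, b in zip(r1.rounds, r2.rounds):
            for key in a.cluster_curves:
                assert a.cluster_curves[key].auc == b.cluster_curves[key].auc

    def test_single_clusterer_combine_matches_it(self):
        network, reference = self.small_benchmark()
        cfg = CVConfig(seed=5, rounds=1, k_grid=(600,))
        clusterers = [("mcl", lambda net: mcl(net, MCLParams()))]
        result = run_crossvalidation(network, reference, cfg, clusterers)
        curves = result.rounds[0].cluster_curves
        # with one voter the combined grouping keeps each cluster at
        # multiplier 1, so the PR curves coincide
        assert curves[(600, "combined")].auc == pytest.approx(curves[(600, "mcl")].auc)

    def test_failing_clusterer_skipped(self):
        network, reference = self.small_benchmark()
        cfg = CVConfig(seed=5, rounds=1, k_grid=(600,))

        def broken(net):
            raise RuntimeError("boom")

        clusterers = [("mcl", lambda net: mcl(net, MCLParams())), ("bad", broken)]
        result = run_crossvalidation(network, reference, cfg, clusterers)
        assert (600, "combined") in result.rounds[0].cluster_curves
        assert (600, "bad") not in result.rounds[0].cluster_curves
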