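import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_weighted_network, mdl_oracle
from swcnet.types import Cluster, CompositeNetwork, ReferenceComplex, ReferenceComplexSet
from swcnet.weighting import (
    DiscretizationScheme,
    FeatureDiscretization,
    NaiveBayesModel,
    discretize_network,
    export_likelihood_network,
    fit_naive_bayes,
    label_edges,
    likelihood_ratio_table,
    load_model,
    mdl_discretize,
    posterior_weight,
    save_model,
    top_k_edges,
    weight_edges,
)


def complexes(*member_sets):
    return ReferenceComplexSet(
        [ReferenceComplex(f"T{i}", frozenset(m)) for i, m in enumerate(member_sets)],
        role="training",
    )


def build_model(prior_co, cond_co, cond_non, cuts):
    """Hand-assembled two-class model for posterior arithmetic tests."""
    scheme = DiscretizationScheme(
        {f: FeatureDiscretization(tuple(cuts[f]), dropped=False) for f in cond_co}
    )
    n_co = int(round(prior_co * 1000))
    return NaiveBayesModel(
        scheme=scheme,
        alpha=0.0,
        n_co=n_co,
        n_non=1000 - n_co,
        counts_co={f: np.asarray(v) * n_co for f, v in cond_co.items()},
        counts_non={f: np.asarray(v) * (1000 - n_co) for f, v in cond_non.items()},
        cond_co={f: np.asarray(v, dtype=float) for f, v in cond_co.items()},
        cond_non={f: np.asarray(v, dtype=float) for f, v in cond_non.items()},
    )


class TestLabelEdges:
    def net(self):
        net = CompositeNetwork(["f"])
        for u, v in [("a", "b"), ("a", "c"), ("c", "d"), ("a", "e")]:
            net.add_edge(u, v, {"f": 0.5})
        return net

    def test_membership_rules(self):
        net = self.net()
        label_edges(net, complexes({"a", "b", "e"}, {"c", "d"}, {"a", "x"}))
        assert net.edge_data("a", "b")["label"] is True
        assert net.edge_data("c", "d")["label"] is True
        assert net.edge_data("a", "c")["label"] is False  # across complexes
        # a is in two complexes; one witnessing complex suffices for (a, e)
        assert net.edge_data("a", "e")["label"] is True

    def test_empty_training_set_fatal(self):
        with pytest.raises(ValueError, match="supervision"):
            label_edges(self.net(), ReferenceComplexSet([], role="training"))


class TestMDLDiscretize:
    def test_clean_split_accepted(self):
        # Gain = 1 > (log2 3 + log2 7 - 2)/4 ~ 0.598
        d = mdl_discretize([0, 0, 1, 1], [False, False, True, True])
        assert d.cut_points == (0.5,)
        assert not d.dropped

    def test_pure_labels_drop_feature(self):
        d = mdl_discretize([0, 1, 2, 3], [True, True, True, True])
        assert d.dropped

    def test_interleaved_labels_drop_feature(self):
        d = mdl_discretize([0, 1, 2, 3], [True, False, True, False])
        assert d.dropped

    def test_non_finite_value_fatal(self):
        with pytest.raises(ValueError, match="index 1"):
            mdl_discretize([0.0, float("nan"), 1.0], [True, False, True])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 5), st.booleans()), min_size=2, max_size=12
        )
    )
    def test_matches_exhaustive_search(self, data):
        values = [float(v) for v, _ in data]
        labels = [l for _, l in data]
        d = mdl_discretize(values, labels)
        assert list(d.cut_points) == mdl_oracle(values, labels)

    def test_bin_index_half_open(self):
        d = FeatureDiscretization((0.25, 0.75), dropped=False)
        assert [d.bin_index(x) for x in (0.0, 0.25, 0.5, 0.75, 1.0)] == [0, 1, 1, 2, 2]


class TestFitNaiveBayes:
    def labeled_net(self, labels_by_value):
        net = CompositeNetwork(["f"])
        for i, (value, label) in enumerate(labels_by_value):
            net.add_edge(f"u{i}", f"v{i}", {"f": value})
            net.edge_data(f"u{i}", f"v{i}")["label"] = label
        return net

    def test_prior_is_unsmoothed_frequency(self):
        rows = [(0.1, True)] * 4 + [(0.9, False)] * 6
        net = self.labeled_net(rows)
        scheme = DiscretizationScheme({"f": FeatureDiscretization((0.5,), False)})
        model = fit_naive_bayes(net, scheme, alpha=1.0)
        assert model.prior_co == pytest.approx(0.4)

    def test_conditional_counts_alpha_zero(self):
        # co-complex counts (1, 3) in bins (low, high): P(high|c) = 0.75
        rows = [(0.1, True), (0.9, True), (0.9, True), (0.9, True), (0.1, False)]
        net = self.labeled_net(rows)
        scheme = DiscretizationScheme({"f": FeatureDiscretization((0.5,), False)})
        model = fit_naive_bayes(net, scheme, alpha=0.0)
        assert model.cond_co["f"][1] == pytest.approx(0.75)

    def test_laplace_smoothing_on_empty_bin(self):
        # n_c = 4, 2 bins, bin never seen in class c, alpha = 1 -> 1/6
        rows = [(0.1, True)] * 4 + [(0.9, False)] * 3
        net = self.labeled_net(rows)
        scheme = DiscretizationScheme({"f": FeatureDiscretization((0.5,), False)})
        model = fit_naive_bayes(net, scheme, alpha=1.0)
        assert model.cond_co["f"][1] == pytest.approx(1.0 / 6.0)

    def test_all_features_dropped_fatal(self):
        net = self.labeled_net([(0.1, True), (0.9, False)])
        scheme = DiscretizationScheme({"f": FeatureDiscretization((), True)})
        with pytest.raises(ValueError, match="no informative features"):
            fit_naive_bayes(net, scheme)


class TestPosteriorWeight:
    def test_uninformative_features_return_prior(self):
        model = build_model(
            0.3, {"f": [0.5, 0.5]}, {"f": [0.5, 0.5]}, {"f": (0.5,)}
        )
        assert posterior_weight(model, {"f": 0.9}) == pytest.approx(0.3)

    def test_equal_priors_single_likelihood_ratio(self):
        model = build_model(
            0.5, {"f": [0.2, 0.8]}, {"f": [0.8, 0.2]}, {"f": (0.5,)}
        )
        # likelihood ratio 4 in the high bin -> LR/(LR+1) = 0.8
        assert posterior_weight(model, {"f": 0.9}) == pytest.approx(0.8)

    def test_product_formula_with_uneven_priors(self):
        # priors (0.25, 0.75), ratios 2 and 3 -> (6*0.25)/(6*0.25 + 0.75) = 2/3
        model = build_model(
            0.25,
            {"f": [0.4, 0.6], "g": [0.6, 0.4]},
            {"f": [0.2, 0.8], "g": [0.2, 0.8]},
            {"f": (0.5,), "g": (0.5,)},
        )
        assert posterior_weight(model, {"f": 0.1, "g": 0.1}) == pytest.approx(2.0 / 3.0)

    def test_unknown_feature_fatal(self):
        model = build_model(0.5, {"f": [0.5, 0.5]}, {"f": [0.5, 0.5]}, {"f": (0.5,)})
        with pytest.raises(KeyError):
            posterior_weight(model, {"mystery": 0.5})

    def test_complement_normalization_is_exact(self):
        model = build_model(
            0.3, {"f": [0.1, 0.9]}, {"f": [0.7, 0.3]}, {"f": (0.5,)}
        )
        flipped = build_model(
            0.7, {"f": [0.7, 0.3]}, {"f": [0.1, 0.9]}, {"f": (0.5,)}
        )
        for value in (0.1, 0.9):
            w = posterior_weight(model, {"f": value})
            w_complement = posterior_weight(flipped, {"f": value})
            assert w + w_complement == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        probs=st.lists(
            st.floats(0.05, 0.95), min_size=4, max_size=4
        ),
        prior=st.floats(0.1, 0.9),
        other=st.floats(0.0, 1.0),
    )
    def test_monotone_in_likelihood_ratio(self, probs, prior, other):
        """Moving one feature to a bin with a larger likelihood ratio never
        lowers the posterior, all else fixed."""
        p1, p2, q1, q2 = probs
        model = build_model(
            prior,
            {"f": [p1, 1 - p1], "g": [p2, 1 - p2]},
            {"f": [q1, 1 - q1], "g": [q2, 1 - q2]},
            {"f": (0.5,), "g": (0.5,)},
        )
        lr_low = p1 / q1
        lr_high = (1 - p1) / (1 - q1)
        w_low = posterior_weight(model, {"f": 0.0, "g": other})
        w_high = posterior_weight(model, {"f": 1.0, "g": other})
        if lr_high >= lr_low:
            assert w_high >= w_low - 1e-12
        else:
            assert w_high <= w_low + 1e-12


class TestTopK:
    def test_k_at_least_edge_count_keeps_all(self):
        net = make_weighted_network({("a", "b"): 0.9, ("c", "d"): 0.2})
        out = top_k_edges(net, 10)
        assert out.n_edges == 2

    def test_keeps_largest(self):
        weights = {(f"u{i}", f"v{i}"): 0.1 * (i + 1) for i in range(5)}
        out = top_k_edges(make_weighted_network(weights), 2)
        kept = {pair for pair, _ in out.edges()}
        assert kept == {("u4", "v4"), ("u3", "v3")}

    def test_boundary_ties_break_lexicographically(self):
        net = make_weighted_network({("x", "y"): 0.5, ("a", "b"): 0.5, ("m", "n"): 0.5})
        out = top_k_edges(net, 1)
        assert [pair for pair, _ in out.edges()] == [("a", "b")]

    def test_nonpositive_k_fatal(self):
        with pytest.raises(ValueError):
            top_k_edges(make_weighted_network({("a", "b"): 1.0}), 0)


class TestLikelihoodTable:
    def test_ratio_values_and_shape(self):
        model = build_model(
            0.5,
            {"f": [0.4, 0.35, 0.25]},
            {"f": [0.1, 0.35, 0.55]},
            {"f": (0.3, 0.6)},
        )
        table = likelihood_ratio_table(model)
        ratios = [r for _, _, r in table.rows["f"]]
        assert ratios[0] == pytest.approx(4.0)
        assert ratios[1] == pytest.approx(1.0)
        assert len(ratios) == 3

    def test_symmetric_conditionals_give_unit_ratios(self):
        model = build_model(0.5, {"f": [0.5, 0.5]}, {"f": [0.5, 0.5]}, {"f": (0.5,)})
        assert all(r == pytest.approx(1.0) for _, _, r in likelihood_ratio_table(model).rows["f"])


class TestExportLikelihoodNetwork:
    def fitted(self):
        net = CompositeNetwork(["s1", "s2", "s3"])
        members = ["a", "b", "c", "d"]
        rng = np.random.default_rng(5)
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                net.add_edge(u, v, {"s1": 0.8, "s2": 0.7, "s3": 0.6})
        for i in range(12):
            net.add_edge(f"x{i}", f"y{i}", {"s1": 0.2, "s2": 0.1, "s3": 0.3})
        label_edges(net, ReferenceComplexSet([ReferenceComplex("T", frozenset(members))], role="training"))
        scheme = discretize_network(net)
        model = fit_naive_bayes(net, scheme)
        return net, model, members

    def test_edge_count_contract(self, tmp_path):
        net, model, members = self.fitted()
        cluster = Cluster(frozenset(members), 0.5, 0.5, frozenset({"mcl"}))
        path = tmp_path / "lik.graphml"
        export_likelihood_network(net, model, cluster, str(path))
        g = nx.read_graphml(str(path))
        # 4 members -> 6 pairs x 3 non-zero sources = 18 multi-edges
        assert g.number_of_edges() == 18

    def test_zero_valued_source_skipped(self, tmp_path):
        net, model, members = self.fitted()
        net.edge_data("a", "b")["features"]["s3"] = 0.0
        cluster = Cluster(frozenset(members), 0.5, 0.5, frozenset({"mcl"}))
        path = tmp_path / "lik.graphml"
        export_likelihood_network(net, model, cluster, str(path))
        g = nx.read_graphml(str(path))
        assert g.number_of_edges() == 17

    def test_exported_ratio_consistent_with_table(self, tmp_path):
        net, model, members = self.fitted()
        table = likelihood_ratio_table(model)
        cluster = Cluster(frozenset(members), 0.5, 0.5, frozenset({"mcl"}))
        path = tmp_path / "lik.graphml"
        export_likelihood_network(net, model, cluster, str(path))
        g = nx.read_graphml(str(path))
        for _, _, data in g.edges(data=True):
            assert data["likelihood_ratio"] == pytest.approx(
                table.ratio(data["source"], data["bin"])
            )


def test_model_persistence_roundtrip(tmp_path):
    net = CompositeNetwork(["f"])
    for i in range(6):
        net.add_edge(f"u{i}", f"v{i}", {"f": 0.1 + 0.15 * i})
        net.edge_data(f"u{i}", f"v{i}")["label"] = i >= 3
    scheme = DiscretizationScheme({"f": FeatureDiscretization((0.5,), False)})
    model = fit_naive_bayes(net, scheme, alpha=1.0)
    path = tmp_path / "model.yaml"
    save_model(model, str(path))
    again = load_model(str(path))
    assert again.prior_co == model.prior_co
    np.testing.assert_allclose(again.cond_co["f"], model.cond_co["f"])
    f = {"f": 0.9}
    assert posterior_weight(again, f) == pytest.approx(posterior_weight(model, f))


def test_weight_edges_matches_single_posterior():
    net = CompositeNetwork(["f"])
    for i in range(8):
        net.add_edge(f"u{i}", f"v{i}", {"f": (i + 1) / 9})
        net.edge_data(f"u{i}", f"v{i}")["label"] = i >= 4
    scheme = DiscretizationScheme({"f": FeatureDiscretization((0.5,), False)})
    model = fit_naive_bayes(net, scheme)
    weight_edges(net, model)
    for _, data in net.edges():
        assert data["weight"] == pytest.approx(
            posterior_weight(model, data["features"])
        )
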