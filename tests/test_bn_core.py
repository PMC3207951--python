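"""CLG Bayesian network core: fitting, likelihood, BIC, prediction."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from dandelion.bn_core import (
    DAGStructure,
    Family,
    FamilyScorer,
    FittedNetwork,
    bic_score,
    fit_parameters,
    log_likelihood,
    network_from_dict,
    network_to_dict,
    predict_class,
    predict_expression,
)
from dandelion.data_model import CLASS_NODE

from .conftest import enumerate_dags, make_dataset


def _standardized(rng, n, d):
    v = rng.standard_normal((n, d))
    return (v - v.mean(0)) / v.std(0, ddof=1)


class TestStructure:
    def test_class_node_cannot_have_parents(self):
        with pytest.raises(ValueError, match="class node"):
            DAGStructure(("a",), [("a", CLASS_NODE)])

    def test_cycles_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DAGStructure(("a", "b", "c"), [("a", "b"), ("b", "c"), ("c", "a")])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            DAGStructure(("a",), [("a", "a")])

    def test_edge_edits(self):
        s = DAGStructure(("a", "b"), [("a", "b")])
        assert s.with_reversed_edge("a", "b").has_edge("b", "a")
        assert not s.without_edge("a", "b").edges


class TestFitParameters:
    def test_parentless_node_on_standardized_data(self, rng):
        ds = make_dataset(_standardized(rng, 100, 2), [0, 1] * 50)
        net = fit_parameters(DAGStructure(("f0", "f1"), ()), ds)
        fam = net.families["f0"]
        assert fam.intercept[0] == pytest.approx(0.0, abs=1e-9)
        assert fam.variance[0] == pytest.approx(1.0, rel=0.05)

    def test_single_parent_weight_recovery(self, rng):
        n = 500
        a = rng.standard_normal(n)
        b = 0.8 * a + rng.standard_normal(n)
        ds = make_dataset(np.column_stack([a, b]), [0, 1] * 250, feature_ids=["a", "b"])
        net = fit_parameters(DAGStructure(("a", "b"), [("a", "b")]), ds)
        assert net.families["b"].weights[0, 0] == pytest.approx(0.8, abs=0.1)

    def test_class_prior_is_empirical_frequency(self, rng):
        labels = [1] * 4 + [0] * 18
        ds = make_dataset(rng.standard_normal((22, 2)), labels)
        net = fit_parameters(DAGStructure(("f0", "f1"), ()), ds)
        assert net.class_prior == pytest.approx([18 / 22, 4 / 22])

    def test_small_stratum_falls_back_to_pooled_fit(self, rng):
        # 3 disease samples cannot support a per-class 2-parent regression
        labels = [1] * 3 + [0] * 17
        ds = make_dataset(_standardized(rng, 20, 3), labels)
        s = DAGStructure(("f0", "f1", "f2"), [(CLASS_NODE, "f2"), ("f0", "f2"), ("f1", "f2")])
        with pytest.warns(RuntimeWarning, match="pooling"):
            net = fit_parameters(s, ds)
        assert net.families["f2"].pooled
        assert net.families["f2"].n_configs == 1


class TestLogLikelihood:
    def test_mle_identity_single_node(self, rng):
        ds = make_dataset(rng.standard_normal((40, 1)), [0, 1] * 20)
        s = DAGStructure(("f0",), ())
        net = fit_parameters(s, ds)
        y = ds.values[:, 0]
        var = y.var()  # MLE against fitted mean
        var = float(((y - y.mean()) ** 2).mean())
        expected_gene = -(40 / 2) * (np.log(2 * np.pi * var) + 1)
        expected_class = 40 * np.log(0.5)
        assert log_likelihood(net, ds) == pytest.approx(expected_gene + expected_class)

    def test_additivity_under_row_duplication(self, rng):
        ds = make_dataset(_standardized(rng, 30, 3), [0, 1] * 15)
        s = DAGStructure(("f0", "f1", "f2"), [("f0", "f1")])
        doubled = make_dataset(
            np.vstack([ds.values, ds.values]), list(ds.class_labels) * 2
        )
        assert log_likelihood(fit_parameters(s, doubled), doubled) == pytest.approx(
            2 * log_likelihood(fit_parameters(s, ds), ds), rel=1e-9
        )

    def test_matches_per_sample_density_oracle(self, rng):
        ds = make_dataset(_standardized(rng, 25, 3), [0, 1] * 12 + [0])
        s = DAGStructure(
            ("f0", "f1", "f2"), [("f0", "f1"), (CLASS_NODE, "f2")]
        )
        net = fit_parameters(s, ds)
        # brute force: per-sample sum of class prior and conditional densities
        total = 0.0
        for i in range(25):
            c = ds.class_labels[i]
            total += np.log(net.class_prior[c])
            for node in ("f0", "f1", "f2"):
                fam = net.families[node]
                cfg = fam.config_for_class(c)
                mean = fam.intercept[cfg] + sum(
                    fam.weights[cfg, j] * ds.column(p)[i]
                    for j, p in enumerate(fam.cont_parents)
                )
                total += norm.logpdf(
                    ds.column(node)[i], mean, np.sqrt(fam.variance[cfg])
                )
        assert log_likelihood(net, ds) == pytest.approx(total, abs=1e-9)


class TestBicScore:
    def test_decomposability_and_locality_of_edge_change(self, rng):
        ds = make_dataset(_standardized(rng, 40, 4), [0, 1] * 20)
        base = DAGStructure(tuple(ds.feature_ids), [("f0", "f1")])
        plus = base.with_edge("f2", "f3")
        r0, r1 = bic_score(base, ds), bic_score(plus, ds)
        assert r0.total_bic == pytest.approx(sum(r0.family_scores.values()))
        for node in ("f0", "f1", CLASS_NODE):
            assert r0.family_scores[node] == r1.family_scores[node]
        assert r0.family_scores["f3"] != r1.family_scores["f3"]

    def test_argmax_over_all_three_node_dags_matches_oracle(self, chain_dataset):
        ds = chain_dataset
        scores = {}
        for edges in enumerate_dags(("a", "b", "c")):
            scores[edges] = bic_score(
                DAGStructure(("a", "b", "c"), edges), ds
            ).total_bic
        assert len(scores) == 25
        best = max(scores, key=scores.get)
        # the generative chain's skeleton must be the BIC winner
        assert {frozenset(e) for e in best} == {
            frozenset(("a", "b")),
            frozenset(("b", "c")),
        }

    def test_penalty_rejects_edges_on_independent_noise(self):
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            ds = make_dataset(_standardized(r, 100, 2), [0, 1] * 50)
            empty = bic_score(DAGStructure(("f0", "f1"), ()), ds).total_bic
            edge = bic_score(DAGStructure(("f0", "f1"), [("f0", "f1")]), ds).total_bic
            wins += empty > edge
        assert wins >= 95


def _two_node_network(w=0.7, shift=0.0):
    """CLASS -> a (per-class means +-shift), a -> b deterministic-ish."""
    s = DAGStructure(("a", "b"), [(CLASS_NODE, "a"), ("a", "b")])
    families = {
        "a": Family(
            "a", (), True,
            intercept=np.array([-shift, shift]),
            weights=np.zeros((2, 0)),
            variance=np.ones(2),
        ),
        "b": Family(
            "b", ("a",), False,
            intercept=np.array([0.1]),
            weights=np.array([[w]]),
            variance=np.array([0.5]),
        ),
    }
    return FittedNetwork(s, np.array([0.5, 0.5]), families)


class TestPredictExpression:
    def test_isolated_node_predicts_mixture_of_intercepts(self, rng):
        ds = make_dataset(_standardized(rng, 30, 2), [0, 1] * 15)
        net = fit_parameters(DAGStructure(("f0", "f1"), ()), ds)
        pred, _ = predict_expression(net, ds, "f0")
        assert np.allclose(pred, 0.0, atol=1e-9)

    def test_single_parent_prediction_is_linear_in_parent(self, rng):
        net = _two_node_network(w=0.7)
        ds = make_dataset(
            np.column_stack([np.linspace(-2, 2, 10), np.zeros(10)]),
            [0, 1] * 5,
            feature_ids=["a", "b"],
        )
        pred, _ = predict_expression(net, ds, "b")
        assert np.allclose(pred, 0.1 + 0.7 * ds.column("a"), atol=1e-9)

    def test_matches_joint_covariance_conditioning_oracle(self, rng):
        ds = make_dataset(_standardized(rng, 30, 4), [0, 1] * 15)
        s = DAGStructure(
            tuple(ds.feature_ids),
            [("f0", "f1"), ("f1", "f2"), ("f0", "f2"), (CLASS_NODE, "f3")],
        )
        net = fit_parameters(s, ds)
        order = list(s.gene_nodes)
        d = len(order)
        target = "f2"
        t = order.index(target)
        obs = [i for i in range(d) if i != t]
        # oracle: recursive moment propagation in topological order
        means, covs = [], []
        for c in (0, 1):
            mu = np.zeros(d)
            cov = np.zeros((d, d))
            for node in s.topological_gene_order():
                i = order.index(node)
                fam = net.families[node]
                cfg = fam.config_for_class(c)
                pidx = [order.index(p) for p in fam.cont_parents]
                w = fam.weights[cfg]
                mu[i] = fam.intercept[cfg] + sum(
                    wj * mu[j] for wj, j in zip(w, pidx)
                )
                for j in range(d):
                    if j == i:
                        continue
                    cov[i, j] = cov[j, i] = sum(
                        wk * cov[k, j] for wk, k in zip(w, pidx)
                    )
                cov[i, i] = fam.variance[cfg] + sum(
                    w[a] * w[b] * cov[pidx[a], pidx[b]]
                    for a in range(len(pidx))
                    for b in range(len(pidx))
                )
            means.append(mu)
            covs.append(cov)
        X = ds.values
        expected = np.zeros(30)
        for i in range(30):
            x_o = X[i, obs]
            posts, conds = [], []
            for c in (0, 1):
                mvn = multivariate_normal(means[c][obs], covs[c][np.ix_(obs, obs)])
                posts.append(net.class_prior[c] * mvn.pdf(x_o))
                sub = np.linalg.solve(
                    covs[c][np.ix_(obs, obs)], covs[c][obs, t]
                )
                conds.append(means[c][t] + (x_o - means[c][obs]) @ sub)
            posts = np.array(posts) / sum(posts)
            expected[i] = posts @ conds
        pred, sse = predict_expression(net, ds, target)
        assert np.allclose(pred, expected, atol=1e-9)
        assert sse == pytest.approx(float(((pred - X[:, t]) ** 2).sum()))

    def test_class_node_target_rejected(self, rng):
        ds = make_dataset(_standardized(rng, 10, 2), [0, 1] * 5)
        net = fit_parameters(DAGStructure(("f0", "f1"), ()), ds)
        with pytest.raises(ValueError, match="predict_class"):
            predict_expression(net, ds, CLASS_NODE)

    def test_saturated_chain_beats_empty_network_in_sample(self, chain_dataset):
        ds = chain_dataset
        chain = DAGStructure(("a", "b", "c"), [("a", "b"), ("b", "c")])
        empty = DAGStructure(("a", "b", "c"), ())
        sse_chain = predict_expression(fit_parameters(chain, ds), ds, "b")[1]
        sse_empty = predict_expression(fit_parameters(empty, ds), ds, "b")[1]
        assert sse_chain <= sse_empty


class TestPredictClass:
    def test_no_children_returns_prior(self):
        s = DAGStructure(("a",), ())
        net = FittedNetwork(
            s,
            np.array([0.7, 0.3]),
            {"a": Family("a", (), False, np.zeros(1), np.zeros((1, 0)), np.ones(1))},
        )
        assert predict_class(net, {"a": 1.3}) == pytest.approx([0.7, 0.3])

    def _class_child_network(self):
        s = DAGStructure(("x",), [(CLASS_NODE, "x")])
        fam = Family(
            "x", (), True, np.array([-1.0, 1.0]), np.zeros((2, 0)), np.ones(2)
        )
        return FittedNetwork(s, np.array([0.5, 0.5]), {"x": fam})

    def test_symmetric_evidence_is_uninformative(self):
        post = predict_class(self._class_child_network(), {"x": 0.0})
        assert post == pytest.approx([0.5, 0.5])

    def test_closed_form_gaussian_ratio(self):
        post = predict_class(self._class_child_network(), {"x": 1.0})
        expected1 = 1.0 / (1.0 + np.exp(-2.0))  # exp(0)/(exp(0)+exp(-2))
        assert post[1] == pytest.approx(expected1, abs=1e-4)
        assert post == pytest.approx([0.1192, 0.8808], abs=1e-4)

    def test_posterior_sums_to_one(self, rng):
        ds = make_dataset(_standardized(rng, 30, 3), [0, 1] * 15)
        s = DAGStructure(tuple(ds.feature_ids), [(CLASS_NODE, "f0"), ("f0", "f1")])
        net = fit_parameters(s, ds)
        for i in range(5):
            post = predict_class(net, dict(zip(ds.feature_ids, ds.values[i])))
            assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_class_independent_parameters_return_prior(self, rng):
        ds = make_dataset(_standardized(rng, 30, 3), [0, 1] * 15)
        s = DAGStructure(tuple(ds.feature_ids), [("f0", "f1")])
        net = fit_parameters(s, ds)  # no class edges at all
        for i in range(5):
            post = predict_class(net, dict(zip(ds.feature_ids, ds.values[i])))
            assert post == pytest.approx(net.class_prior, abs=1e-12)

    def test_missing_evidence_marginalized(self):
        # evidence on an unrelated gene leaves the posterior at the prior
        s = DAGStructure(("x", "y"), [(CLASS_NODE, "x")])
        families = {
            "x": Family("x", (), True, np.array([-1.0, 1.0]), np.zeros((2, 0)), np.ones(2)),
            "y": Family("y", (), False, np.zeros(1), np.zeros((1, 0)), np.ones(1)),
        }
        net = FittedNetwork(s, np.array([0.6, 0.4]), families)
        assert predict_class(net, {"y": 2.0}) == pytest.approx([0.6, 0.4])


def test_serialization_round_trip_exact(rng):
    ds = make_dataset(_standardized(rng, 30, 3), [0, 1] * 15)
    s = DAGStructure(tuple(ds.feature_ids), [("f0", "f1"), (CLASS_NODE, "f2")])
    net = fit_parameters(s, ds)
    back = network_from_dict(network_to_dict(net))
    assert back.structure == net.structure
    assert np.array_equal(back.class_prior, net.class_prior)
    for node, fam in net.families.items():
        other = back.families[node]
        assert np.array_equal(fam.intercept, other.intercept)
        assert np.array_equal(fam.weights, other.weights)
        assert np.array_equal(fam.variance, other.variance)
        assert fam.cont_parents == other.cont_parents
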