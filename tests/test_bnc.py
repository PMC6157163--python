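"""Pareto ordering, CLG fitting, classification, metrics and the CV sweep."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from miregnet import (EnsembleGraph, ScoredEdge, build_bnc_structure, classify,
                      cv_assess, evaluate_metrics, fit_clg, pareto_order,
                      select_optimal, trapezoidal_auc)
from miregnet.bnc import CLASS_NODE, BNClassifier, ModelAssessment

from conftest import make_matrix, make_phenotype
from miregnet import FeatureRole


def edge(m, g, b, d):
    return ScoredEdge(m, g, b, d)


class TestParetoOrder:
    def test_three_edge_front_example(self):
        edges = [edge("m1", "g1", 1.0, 0.01), edge("m2", "g2", 0.5, 0.02),
                 edge("m3", "g3", 0.4, 0.005)]
        g = pareto_order(edges)
        assert g.front_index == [1, 1, 2]
        assert [(e.b, e.d) for e in g.ordered_edges] == [
            (1.0, 0.01), (0.5, 0.02), (0.4, 0.005)]

    def test_identical_scores_single_front_lexicographic(self):
        edges = [edge("m2", "g9", 0.5, 0.01), edge("m1", "g3", 0.5, 0.01),
                 edge("m1", "g1", 0.5, 0.01)]
        g = pareto_order(edges)
        assert set(g.front_index) == {1}
        assert [(e.mirna_id, e.gene_id) for e in g.ordered_edges] == [
            ("m1", "g1"), ("m1", "g3"), ("m2", "g9")]

    def test_dominating_edge_comes_first(self):
        edges = [edge("m1", "g1", 0.3, 0.001), edge("m2", "g2", 0.9, 0.04),
                 edge("m3", "g3", 0.5, 0.02)]
        g = pareto_order(edges)
        assert g.ordered_edges[0].mirna_id == "m2"
        assert g.front_index[0] == 1

    @given(st.integers(0, 2**31 - 1))
    def test_fronts_match_brute_force_dominance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        edges = [edge(f"m{i}", f"g{i}",
                      float(rng.choice([0.2, 0.5, 0.8, 1.0])),
                      float(rng.choice([0.0, 0.01, 0.02])))
                 for i in range(n)]
        g = pareto_order(edges)

        def dominates(a, b):
            return (a.b >= b.b and a.d >= b.d) and (a.b > b.b or a.d > b.d)

        # brute-force front assignment by iterative peeling
        remaining = list(edges)
        expected: dict[ScoredEdge, int] = {}
        front = 0
        while remaining:
            front += 1
            nondom = [a for a in remaining
                      if not any(dominates(b, a) for b in remaining)]
            for a in nondom:
                expected[a] = front
            remaining = [a for a in remaining if a not in nondom]
        got = dict(zip(g.ordered_edges, g.front_index))
        assert got == expected
        # ordering is deterministic and sorted by front
        assert g.front_index == sorted(g.front_index)


class TestStructure:
    def test_single_edge_gives_three_nodes_three_arcs(self):
        g = EnsembleGraph(ordered_edges=[edge("m1", "g1", 1.0, 0.01)])
        model = build_bnc_structure(g, t=1, classes=["a", "b"])
        assert model.dag.number_of_nodes() == 3
        assert model.dag.number_of_edges() == 3
        assert set(model.dag.predecessors("g1")) == {CLASS_NODE, "m1"}

    def test_thirteen_edges_seven_mirnas_gives_21_nodes(self):
        pairs = [(0, 0), (0, 1), (1, 2), (1, 3), (2, 4), (2, 5), (3, 6),
                 (3, 7), (4, 8), (4, 9), (5, 10), (5, 11), (6, 12)]
        edges = [edge(f"m{i}", f"g{j}", 1.0 - 0.01 * k, 0.01)
                 for k, (i, j) in enumerate(pairs)]
        g = EnsembleGraph(ordered_edges=edges)
        model = build_bnc_structure(g, t=13, classes=["a", "b"])
        assert model.dag.number_of_nodes() == 21  # 7 miRNA + 13 genes + class

    @pytest.mark.parametrize("t", [1, 3, 5])
    def test_structure_is_acyclic(self, t, rng):
        edges = [edge(f"m{i % 3}", f"g{i}", 1.0 - 0.1 * i, 0.01) for i in range(5)]
        g = EnsembleGraph(ordered_edges=edges)
        model = build_bnc_structure(g, t=t, classes=["a", "b"])
        assert nx.is_directed_acyclic_graph(model.dag)

    def test_t_out_of_range_rejected(self):
        g = EnsembleGraph(ordered_edges=[edge("m1", "g1", 1.0, 0.01)])
        with pytest.raises(ValueError, match="out of range"):
            build_bnc_structure(g, t=2, classes=["a", "b"])


def _fit_fixture(rng, n_per_class=200, beta=1.5, sigma=0.5):
    labels = ["a"] * n_per_class + ["b"] * n_per_class
    n = len(labels)
    x = rng.standard_normal(n) + np.r_[np.zeros(n_per_class),
                                       np.full(n_per_class, 1.0)]
    y = beta * x + sigma * rng.standard_normal(n)
    m_mirna = make_matrix([x], role=FeatureRole.MIRNA, features=["m1"],
                          samples=[f"s{i}" for i in range(n)])
    m_gene = make_matrix([y], role=FeatureRole.GENE, features=["g1"],
                         samples=[f"s{i}" for i in range(n)])
    phen = make_phenotype(labels, samples=m_mirna.sample_ids)
    return m_mirna, m_gene, phen


class TestFit:
    def test_orphan_node_gets_class_mean_and_variance(self, rng):
        m_mirna, m_gene, phen = _fit_fixture(rng)
        g = EnsembleGraph(ordered_edges=[edge("m1", "g1", 1.0, 0.01)])
        model = fit_clg(build_bnc_structure(g, 1, phen.classes),
                        m_mirna, m_gene, phen)
        mask = phen.label_array(m_mirna.sample_ids) == "a"
        x_a = m_mirna.values[0][mask]
        p = model.params["m1"]
        assert p.beta0["a"] == pytest.approx(x_a.mean())
        assert p.sigma2["a"] == pytest.approx(x_a.var())
        assert p.beta["a"].size == 0

    def test_single_parent_coefficient_is_cov_ratio(self, rng):
        m_mirna, m_gene, phen = _fit_fixture(rng)
        g = EnsembleGraph(ordered_edges=[edge("m1", "g1", 1.0, 0.01)])
        model = fit_clg(build_bnc_structure(g, 1, phen.classes),
                        m_mirna, m_gene, phen)
        mask = phen.label_array(m_mirna.sample_ids) == "b"
        x = m_mirna.values[0][mask]
        y = m_gene.values[0][mask]
        s = np.cov(x, y, ddof=0)
        assert model.params["g1"].beta["b"][0] == pytest.approx(s[0, 1] / s[0, 0])

    def test_parameter_recovery_at_large_n(self):
        rng = np.random.default_rng(11)
        m_mirna, m_gene, phen = _fit_fixture(rng, n_per_class=5000,
                                             beta=1.5, sigma=0.5)
        g = EnsembleGraph(ordered_edges=[edge("m1", "g1", 1.0, 0.01)])
        model = fit_clg(build_bnc_structure(g, 1, phen.classes),
                        m_mirna, m_gene, phen)
        for c in ("a", "b"):
            assert model.params["g1"].beta[c][0] == pytest.approx(1.5, abs=0.05)
            assert model.params["g1"].sigma2[c] == pytest.approx(0.25, abs=0.05)

    def test_class_below_minimum_rejected(self, rng):
        m_mirna, m_gene, phen = _fit_fixture(rng, n_per_class=2)
        g = EnsembleGraph(ordered_edges=[edge("m1", "g1", 1.0, 0.01)])
        with pytest.raises(ValueError, match="needs at least"):
            fit_clg(build_bnc_structure(g, 1, phen.classes), m_mirna, m_gene, phen)


def _naive_bayes_model(rng, n_features=3, n_per_class=40, delta=1.0):
    labels = ["a"] * n_per_class + ["b"] * n_per_class
    n = len(labels)
    values = rng.standard_normal((n_features, n))
    values[:, n_per_class:] += delta
    samples = [f"s{i}" for i in range(n)]
    features = [f"g{i}" for i in range(n_features)]
    m = make_matrix(values, role=FeatureRole.GENE, features=features,
                    samples=samples)
    phen = make_phenotype(labels, samples=samples)
    dag = nx.DiGraph()
    dag.add_node(CLASS_NODE, type="class")
    for f in features:
        dag.add_node(f, type="gene")
        dag.add_edge(CLASS_NODE, f)
    model = BNClassifier(dag=dag, classes=phen.classes)
    m_empty = make_matrix(np.empty((0, n)), role=FeatureRole.MIRNA,
                          features=[], samples=samples)
    fit_clg(model, m_empty, m, phen)
    return model, m, phen, values


class TestClassify:
    def test_matches_gaussian_naive_bayes_oracle(self, rng):
        model, m, phen, values = _naive_bayes_model(rng)
        labels = phen.label_array(m.sample_ids)
        x_new = rng.standard_normal(3) + 0.5
        sample = {f"g{i}": float(x_new[i]) for i in range(3)}
        post, _ = classify(model, sample)

        # independent oracle: per-class product of Gaussian densities
        log_like = {}
        for c in ("a", "b"):
            block = values[:, labels == c]
            mu = block.mean(axis=1)
            var = block.var(axis=1)
            log_like[c] = (np.log(0.5)
                           + np.sum(-0.5 * (np.log(2 * np.pi * var)
                                            + (x_new - mu) ** 2 / var)))
        z = np.logaddexp(log_like["a"], log_like["b"])
        assert post["a"] == pytest.approx(math.exp(log_like["a"] - z), abs=1e-10)
        assert post["b"] == pytest.approx(math.exp(log_like["b"] - z), abs=1e-10)

    def test_symmetric_point_gives_half_half(self):
        dag = nx.DiGraph()
        dag.add_node(CLASS_NODE)
        dag.add_node("g0", type="gene")
        dag.add_edge(CLASS_NODE, "g0")
        model = BNClassifier(dag=dag, classes=["a", "b"],
                             priors={"a": 0.5, "b": 0.5})
        from miregnet.bnc import ClgNodeParams
        model.params["g0"] = ClgNodeParams(
            node_id="g0", beta0={"a": -1.0, "b": 1.0},
            beta={"a": np.empty(0), "b": np.empty(0)},
            sigma2={"a": 1.0, "b": 1.0})
        post, predicted = classify(model, {"g0": 0.0})
        assert post["a"] == pytest.approx(0.5, abs=1e-12)
        assert predicted == "a"  # tie breaks to first class label

    def test_well_separated_classes_confident(self, rng):
        model, m, phen, values = _naive_bayes_model(rng, delta=6.0)
        sample = {f"g{i}": 0.0 for i in range(3)}  # at class-a mean
        post, predicted = classify(model, sample)
        assert predicted == "a"
        assert post["a"] > 0.99

    def test_posterior_sums_to_one(self, rng):
        model, m, phen, _ = _naive_bayes_model(rng)
        for _ in range(10):
            sample = {f"g{i}": float(v)
                      for i, v in enumerate(rng.standard_normal(3) * 3)}
            post, _ = classify(model, sample)
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_feature_value_rejected(self, rng):
        model, *_ = _naive_bayes_model(rng)
        with pytest.raises(ValueError, match="g2"):
            classify(model, {"g0": 0.0, "g1": 0.0})


class TestAuc:
    def test_hand_examples(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        assert trapezoidal_auc(scores, np.array([1, 1, 0, 0], bool)) == 1.0
        # cross-checked against U/(n1*n0): three of the four
        # positive/negative score pairs are correctly ordered
        assert trapezoidal_auc(scores, np.array([1, 0, 1, 0], bool)) == 0.75

    def test_ties_counted_half(self):
        scores = np.array([0.5, 0.5, 0.5, 0.5])
        assert trapezoidal_auc(scores, np.array([1, 1, 0, 0], bool)) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            trapezoidal_auc(np.array([0.1, 0.2]), np.array([1, 1], bool))

    @given(st.integers(0, 2**31 - 1))
    def test_equals_mann_whitney_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = int(rng.integers(2, 15)), int(rng.integers(2, 15))
        scores = np.round(rng.random(n1 + n0), 2)  # force some ties
        positive = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
        auc = trapezoidal_auc(scores, positive)
        u = mannwhitneyu(scores[positive], scores[~positive],
                         alternative="two-sided").statistic
        assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)


class TestMetricsAndSweep:
    def test_perfect_separation_metrics(self, rng):
        model, m, phen, _ = _naive_bayes_model(rng, delta=8.0)
        samples = m.sample_ids
        m_empty = make_matrix(np.empty((0, len(samples))),
                              role=FeatureRole.MIRNA, features=[],
                              samples=samples)
        res = evaluate_metrics(model, m_empty, m, phen)
        assert res["auc"] == 1.0
        assert res["accuracy"] == 1.0

    def test_bic_penalizes_each_parameter_by_half_log_n(self, rng):
        m_mirna, m_gene, phen = _fit_fixture(rng, n_per_class=30)
        g = EnsembleGraph(ordered_edges=[edge("m1", "g1", 1.0, 0.01)])
        model = fit_clg(build_bnc_structure(g, 1, phen.classes),
                        m_mirna, m_gene, phen)
        # 2 classes: priors contribute 1; the orphan miRNA 2*(2+0); the
        # single-parent gene 2*(2+1): 11 free parameters in total
        assert model.dim == 11
        res = evaluate_metrics(model, m_mirna, m_gene, phen)
        n = len(phen.sample_ids)
        assert res["bic"] == pytest.approx(
            res["loglik"] - (math.log(n) / 2) * 11, abs=1e-9)

    def test_train_loglik_weakly_improves_with_added_arc(self, rng):
        # t=2 -> t=3 adds the arc m1 -> g2 between nodes already present,
        # so the MLE fit on the same data cannot get worse
        n = 40
        samples = [f"s{i}" for i in range(n)]
        labels = ["a"] * 20 + ["b"] * 20
        x = rng.standard_normal((2, n))
        y = np.vstack([x[0] + 0.3 * rng.standard_normal(n),
                       x[0] - x[1] + 0.3 * rng.standard_normal(n)])
        m_mirna = make_matrix(x, role=FeatureRole.MIRNA,
                              features=["m1", "m2"], samples=samples)
        m_gene = make_matrix(y, role=FeatureRole.GENE,
                             features=["g1", "g2"], samples=samples)
        phen = make_phenotype(labels, samples=samples)
        edges = [edge("m1", "g1", 0.9, 0.03), edge("m2", "g2", 0.8, 0.02),
                 edge("m1", "g2", 0.7, 0.01)]
        g = EnsembleGraph(ordered_edges=edges)
        lls = []
        for t in (2, 3):
            model = fit_clg(build_bnc_structure(g, t, phen.classes),
                            m_mirna, m_gene, phen)
            lls.append(evaluate_metrics(model, m_mirna, m_gene, phen)["loglik"])
        assert lls[1] >= lls[0] - 1e-9

    def test_cv_assess_is_deterministic(self, rng):
        from miregnet import model_selection_fixture

        g, mm, mg, phen, _ = model_selection_fixture(seed=3, n_noise=3,
                                                     n_per_class=15)
        a1 = cv_assess(g, mm, mg, phen, T=5, seed=9)
        a2 = cv_assess(g, mm, mg, phen, T=5, seed=9)
        for metric in ("auc", "accuracy", "bic", "loglik"):
            assert np.array_equal(a1.mean[metric], a2.mean[metric])
        assert a1.t_optimal == a2.t_optimal

    def test_select_optimal_unique_peak_and_tie_break(self):
        def assessment(auc):
            n = len(auc)
            flat = np.zeros(n)
            return ModelAssessment(
                t_values=list(range(1, n + 1)),
                mean={"auc": np.array(auc), "accuracy": flat,
                      "bic": flat, "loglik": flat},
                sd={m: np.zeros(n) for m in ("auc", "accuracy", "bic", "loglik")},
            )

        peaked = select_optimal(assessment([0.6, 0.8, 0.9, 0.7, 0.5]))
        assert peaked.t_optimal == 3
        flat = select_optimal(assessment([0.7, 0.7, 0.7, 0.7]))
        assert flat.t_optimal == 1  # parsimony tie-break

    def test_concordance_indicator_flags_shared_peak(self):
        curve = np.array([0.1, 0.9, 0.3])
        other = np.array([0.2, 0.8, 0.1])
        a = ModelAssessment(
            t_values=[1, 2, 3],
            mean={"auc": curve, "accuracy": other, "bic": other,
                  "loglik": other},
            sd={m: np.zeros(3) for m in ("auc", "accuracy", "bic", "loglik")},
        )
        assert select_optimal(a).concordant is True
        a.mean["bic"] = np.array([0.9, 0.1, 0.0])
        assert select_optimal(a).concordant is False
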