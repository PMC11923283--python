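"""The inference algorithm: per-target regression, monomial-to-hyperedge
mapping, correlation pre-filtering, and multi-DOF aggregation."""

from itertools import combinations

import numpy as np
import pytest

import thi
from thi.dynamics import KuramotoModel, SamplingConfig, TimeSeries, \
    sample_random_states
from thi.hypergraphs import DirectedHyperedge, Hypergraph
from thi.inference import (DirectedScores, InferenceConfig, aggregate_multidof,
                           correlation_filter, infer_all, infer_node,
                           score_from_fit, threshold_scores)
from thi.sindy import SparseFit, build_library


def edge(t, *srcs):
    return DirectedHyperedge(t, frozenset(srcs))


def fit_from_dense(lib, coeffs):
    """Wrap a dense coefficient vector as a SparseFit (identity scaling)."""
    coeffs = np.asarray(coeffs, dtype=float)
    return SparseFit(coefficients=coeffs, support=np.nonzero(coeffs)[0],
                     residual=0.0, n_iterations=1,
                     scaled_coefficients=coeffs.copy())


class TestScoreFromFit:
    def setup_method(self):
        self.lib = build_library(3, 3)
        self.names = self.lib.names()
        self.cfg = InferenceConfig(max_order=3, library_degree=3)

    def coeffs_for(self, mapping):
        v = np.zeros(len(self.lib))
        for name, value in mapping.items():
            v[self.names.index(name)] = value
        return v

    def test_cross_monomial_gives_triad(self):
        v = self.coeffs_for({"x1*x2": 0.7})
        scores = score_from_fit(fit_from_dense(self.lib, v), self.lib, 0, self.cfg)
        assert scores.scores == {edge(0, 1, 2): pytest.approx(0.7)}

    def test_intrinsic_terms_give_no_edges(self):
        v = self.coeffs_for({"1": 1.0, "x0": -2.0, "x0^2": 0.3})
        scores = score_from_fit(fit_from_dense(self.lib, v), self.lib, 0, self.cfg)
        assert len(scores) == 0

    def test_max_over_contributing_monomials(self):
        v = self.coeffs_for({"x1": 0.5, "x0*x1": 0.2})
        scores = score_from_fit(fit_from_dense(self.lib, v), self.lib, 0, self.cfg)
        assert scores.scores == {edge(0, 1): pytest.approx(0.5)}

    def test_sum_reduction_option(self):
        cfg = InferenceConfig(max_order=3, library_degree=3, score_reduce="sum")
        v = self.coeffs_for({"x1": 0.5, "x0*x1": 0.2})
        scores = score_from_fit(fit_from_dense(self.lib, v), self.lib, 0, cfg)
        assert scores.scores == {edge(0, 1): pytest.approx(0.7)}

    def test_cubic_monomial_with_two_distinct_sources_is_a_triad(self):
        """A degree-3 monomial witnesses the triad given by its distinct
        non-target variables, regardless of exponents."""
        v = self.coeffs_for({"x1^2*x2": 0.4, "x0*x1*x2": 0.9})
        scores = score_from_fit(fit_from_dense(self.lib, v), self.lib, 0, self.cfg)
        assert scores.scores == {edge(0, 1, 2): pytest.approx(0.9)}

    def test_sets_beyond_max_order_dropped(self):
        cfg = InferenceConfig(max_order=2, library_degree=3)
        v = self.coeffs_for({"x1*x2": 1.0, "x1": 0.3})
        scores = score_from_fit(fit_from_dense(self.lib, v), self.lib, 0, cfg)
        assert scores.scores == {edge(0, 1): pytest.approx(0.3)}


class TestThresholdScores:
    def test_examples_and_monotonicity(self):
        s = DirectedScores()
        s.add(edge(0, 1), 0.5)
        s.add(edge(1, 0), 0.1)
        assert threshold_scores(s, np.inf) == set()
        assert threshold_scores(s, 0.0) == {edge(0, 1), edge(1, 0)}
        assert threshold_scores(s, 0.3) == {edge(0, 1)}
        # monotone: larger epsilon -> subset
        eps = sorted(np.random.default_rng(0).uniform(0, 1, 20))
        sets = [threshold_scores(s, e) for e in eps]
        for a, b in zip(sets, sets[1:]):
            assert b <= a


class TestInferNode:
    def test_linear_system_single_pairwise_score(self, rng):
        """x0' = x1 exactly: one pairwise candidate, no triads."""
        X = rng.uniform(-1, 1, (60, 3))
        ts = TimeSeries(X=X, Xdot=np.column_stack(
            [X[:, 1], np.zeros(60), np.zeros(60)]), base_point=np.zeros(3))
        cfg = InferenceConfig(max_order=3, library_degree=2, lam=1e-6)
        fit, scores = infer_node(ts, 0, cfg)
        assert set(scores.scores) == {edge(0, 1)}

    def test_constant_series_empty(self):
        ts = TimeSeries(X=np.ones((30, 3)), Xdot=np.zeros((30, 3)),
                        base_point=np.zeros(3))
        cfg = InferenceConfig(max_order=3, lam=1e-6)
        fit, scores = infer_node(ts, 1, cfg)
        assert len(scores) == 0

    def test_target_validation_and_min_samples(self):
        ts = TimeSeries(X=np.zeros((5, 2)), Xdot=np.zeros((5, 2)),
                        base_point=np.zeros(2))
        with pytest.raises(IndexError):
            infer_node(ts, 5, InferenceConfig())
        tiny = TimeSeries(X=np.zeros((1, 2)), Xdot=np.zeros((1, 2)),
                          base_point=np.zeros(2))
        with pytest.raises(ValueError):
            infer_node(tiny, 0, InferenceConfig())

    def test_independent_of_other_targets_and_column_order(self, rng):
        """Inference for one target is unaffected by relabeling the order in
        which targets are processed (per-node independence)."""
        X = rng.uniform(-0.5, 0.5, (80, 4))
        Xdot = np.column_stack([X[:, 1] * X[:, 2], X[:, 0], X[:, 3], X[:, 0]])
        ts = TimeSeries(X=X, Xdot=Xdot, base_point=np.zeros(4))
        cfg = InferenceConfig(max_order=3, library_degree=2, lam=1e-6)
        _, s_alone = infer_node(ts, 0, cfg)
        all_scores, _ = infer_all(ts, cfg)
        assert {c: v for c, v in all_scores.items() if c.target == 0} == \
            pytest.approx(s_alone.scores)

    def test_exact_recovery_noiseless_polynomial_field(self, rng):
        """Abundant noiseless random-state data from a polynomial field whose
        monomials lie in the library: at some epsilon the inferred directed
        set equals the truth exactly (linear-consensus + cubic coupling)."""
        n = 4
        X = rng.uniform(-1, 1, (400, n))
        # x0' = (x1-x0) ; x1' = (x0-x1) + x2*x3^2 ; x2' = -x2 ; x3' = x0*x1
        Xdot = np.column_stack([
            X[:, 1] - X[:, 0],
            X[:, 0] - X[:, 1] + X[:, 2] * X[:, 3] ** 2,
            -X[:, 2],
            X[:, 0] * X[:, 1],
        ])
        ts = TimeSeries(X=X, Xdot=Xdot, base_point=np.zeros(n))
        cfg = InferenceConfig(max_order=3, library_degree=3, lam=1e-8)
        scores, _ = infer_all(ts, cfg)
        truth = {edge(0, 1), edge(1, 0), edge(1, 2, 3), edge(3, 0, 1)}
        # the truth candidates outscore everything else at some epsilon
        truth_scores = [scores.scores[c] for c in truth]
        others = [v for c, v in scores.items() if c not in truth]
        assert min(truth_scores) > (max(others) if others else 0.0)
        eps = (min(truth_scores) + max(others, default=0.0)) / 2
        assert threshold_scores(scores, eps) == truth

    def test_indistinguishability_negative_control(self, rng):
        """A linearly decomposable 'triadic' coupling h(xi,xj,xk) =
        h'(xi,xj) + h''(xi,xk) + h'''(xj,xk) is reproducible by pairwise
        terms, so no cross-term monomial x_j*x_k (j,k != i) should receive a
        coefficient above the noise floor: only pairwise structure is
        inferred."""
        n = 3
        X = rng.uniform(-1, 1, (500, n))
        # decomposable: x0' = (x1-x0) + (x2-x0) + (x1+x2)  -- all pairwise
        Xdot = np.column_stack([
            (X[:, 1] - X[:, 0]) + (X[:, 2] - X[:, 0]) + (X[:, 1] + X[:, 2]),
            np.zeros(500), np.zeros(500)])
        ts = TimeSeries(X=X, Xdot=Xdot, base_point=np.zeros(n))
        cfg = InferenceConfig(max_order=3, library_degree=3, lam=1e-8)
        _, scores = infer_node(ts, 0, cfg)
        triads = {c: v for c, v in scores.items() if c.order == 3}
        pair_floor = min(v for c, v in scores.items() if c.order == 2)
        assert all(v < 1e-8 * pair_floor for v in triads.values())


class TestCorrelationFilter:
    def test_identical_signals_beat_noise(self, rng):
        x0 = rng.normal(size=300)
        X = np.column_stack([x0, x0, rng.normal(size=300)])
        kept = correlation_filter(TimeSeries(X=X), l_keep=1)
        assert kept == {frozenset({0, 1})}

    def test_full_budget_is_noop(self, rng, demo_complex):
        m = KuramotoModel.with_random_frequencies(demo_complex, seed=2)
        ts = sample_random_states(
            m.field, SamplingConfig(n_samples=200, seed=3), 7)
        cfg_f = InferenceConfig(max_order=3, library_degree=3, lam=0.0, l_keep=21)
        cfg_u = InferenceConfig(max_order=3, library_degree=3, lam=0.0)
        s_f, _ = infer_all(ts, cfg_f)
        s_u, _ = infer_all(ts, cfg_u)
        assert set(s_f.scores) == set(s_u.scores)
        for c in s_u.scores:
            assert s_f.scores[c] == pytest.approx(s_u.scores[c], rel=1e-6)

    def test_top_k_matches_brute_force(self, rng):
        X = rng.normal(size=(150, 6))
        X[:, 3] += 0.8 * X[:, 1]
        X[:, 5] -= 0.5 * X[:, 2]
        C = np.corrcoef(X, rowvar=False)
        ranked = sorted(((abs(C[i, j]), (i, j))
                         for i, j in combinations(range(6), 2)),
                        key=lambda p: (-p[0], p[1]))
        for k in (1, 3, 7, 15):
            expected = {frozenset(p) for _, p in ranked[:k]}
            assert correlation_filter(TimeSeries(X=X), k) == expected

    def test_zero_variance_column_logged_not_fatal(self, rng, caplog):
        X = np.column_stack([np.ones(50), rng.normal(size=50),
                             rng.normal(size=50)])
        with caplog.at_level("WARNING"):
            kept = correlation_filter(TimeSeries(X=X), l_keep=1)
        assert kept == {frozenset({1, 2})} or len(kept) == 1

    def test_derivative_signal_preferred_when_present(self, rng):
        """With i.i.d. states, structure lives in the derivatives: a shared
        coupling term makes coupled nodes' derivatives correlate."""
        h = Hypergraph(4, edges2={frozenset({0, 1}), frozenset({2, 3})})
        m = KuramotoModel(h, np.zeros(4))
        ts = sample_random_states(
            m.field, SamplingConfig(n_samples=2000, box_side=0.5, seed=9), 4)
        kept = correlation_filter(ts, l_keep=2)
        assert kept == {frozenset({0, 1}), frozenset({2, 3})}


class TestAggregateMultiDof:
    def test_largest_coefficient_between_dofs(self):
        s = DirectedScores()
        s.add(edge(0, 3), 0.4)   # x-var of node 1 -> x-var of node 0
        s.add(edge(0, 4), 0.9)   # y-var of node 1 -> same node pair
        agg = aggregate_multidof(s, dof_per_node=3)
        assert agg.scores == {edge(0, 1): pytest.approx(0.9)}

    def test_within_node_dropped(self):
        s = DirectedScores()
        s.add(edge(0, 1, 2), 0.8)  # y,z of node 0 -> x of node 0
        agg = aggregate_multidof(s, dof_per_node=3)
        assert len(agg) == 0

    def test_matches_exhaustive_grouping_oracle(self, rng):
        dof, n_nodes = 3, 4
        nv = dof * n_nodes
        s = DirectedScores()
        cands = []
        for t in range(nv):
            for pair in combinations([v for v in range(nv) if v != t], 2):
                cands.append(DirectedHyperedge(t, frozenset(pair)))
            for v in range(nv):
                if v != t:
                    cands.append(DirectedHyperedge(t, frozenset({v})))
        picks = rng.choice(len(cands), size=60, replace=False)
        for i in picks:
            s.add(cands[i], float(rng.uniform(0, 1)))
        agg = aggregate_multidof(s, dof)
        oracle = {}
        for c, v in s.items():
            tn = c.target // dof
            sn = frozenset(x // dof for x in c.sources) - {tn}
            if not sn:
                continue
            key = DirectedHyperedge(tn, sn)
            oracle[key] = max(oracle.get(key, 0.0), v)
        assert agg.scores == pytest.approx(oracle)

    def test_indivisible_dimension_rejected(self):
        ts = TimeSeries(X=np.zeros((10, 4)), Xdot=np.zeros((10, 4)),
                        base_point=np.zeros(4))
        cfg = InferenceConfig(max_order=2, dof_per_node=3, lam=0.0)
        with pytest.raises(ValueError):
            infer_all(ts, cfg)


class TestConfigValidation:
    def test_degree_must_cover_max_order(self):
        with pytest.raises(ValueError):
            InferenceConfig(max_order=4, library_degree=2)

    def test_unknown_rules_rejected(self):
        with pytest.raises(ValueError):
            InferenceConfig(base_point_rule="nope")
        with pytest.raises(ValueError):
            InferenceConfig(score_scale="nope")
        with pytest.raises(ValueError):
            InferenceConfig(max_order=5)
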