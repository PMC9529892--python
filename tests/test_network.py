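"""MI estimator, permutation threshold, DPI pruning and regulon assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from regcycle.containers import GeneExpressionMatrix
from regcycle.network import (
    RegulonInference,
    apply_dpi,
    build_regulons,
    estimate_mi,
    mi_null_threshold,
)
from regcycle.simulate import SimulationConfig, simulate_cohort

from conftest import brute_force_dpi


class TestEstimateMi:
    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(123)
        for rho in (0.0, 0.5, 0.9):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 5000)
            expected = -0.5 * np.log1p(-rho ** 2)
            assert estimate_mi(z[:, 0], z[:, 1]) == pytest.approx(expected,
                                                                  abs=0.1)

    def test_independent_pairs_fall_below_null_quantile(self):
        rng = np.random.default_rng(5)
        hits = 0
        n = 2000
        for _ in range(100):
            x = rng.standard_normal(n)
            y = rng.permutation(rng.standard_normal(n))
            null = [estimate_mi(x, rng.permutation(y)) for _ in range(60)]
            if estimate_mi(x, y) <= np.quantile(null, 0.95):
                hits += 1
        assert hits >= 90

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        assert estimate_mi(x, y) == estimate_mi(y, x)

    def test_constant_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_mi(np.ones(50), np.arange(50.0)) == 0.0

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            estimate_mi(np.arange(5.0), np.arange(5.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, 40,
                      elements=st.floats(-50, 50, allow_nan=False)),
           hnp.arrays(np.float64, 40,
                      elements=st.floats(-50, 50, allow_nan=False)))
    def test_symmetric_and_nonnegative_property(self, x, y):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mi_xy = estimate_mi(x, y)
            mi_yx = estimate_mi(y, x)
        assert mi_xy == mi_yx
        assert mi_xy >= 0.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(300), rng.standard_normal(300)
        assert estimate_mi(x, y) == estimate_mi(np.exp(x), y ** 3)


@pytest.fixture(scope="module")
def matrix():
    rng = np.random.default_rng(0)
    return GeneExpressionMatrix(pd.DataFrame(
        rng.standard_normal((30, 100)),
        index=[f"G{i}" for i in range(30)],
        columns=[f"S{i}" for i in range(100)]))


class TestNullThreshold:

    def test_alpha_one_gives_null_minimum(self, matrix):
        thr = mi_null_threshold(matrix, n_permutations=200, alpha=1.0, seed=1)
        thr_small = mi_null_threshold(matrix, n_permutations=200, alpha=0.05,
                                      seed=1)
        assert thr <= thr_small

    def test_threshold_stable_in_permutation_count(self, matrix):
        t1 = mi_null_threshold(matrix, n_permutations=500, alpha=0.05, seed=3)
        t2 = mi_null_threshold(matrix, n_permutations=1000, alpha=0.05, seed=3)
        assert abs(t2 - t1) / t1 < 0.10

    def test_alpha_monotone(self, matrix):
        thrs = [mi_null_threshold(matrix, n_permutations=300, alpha=a, seed=5)
                for a in (0.01, 0.05, 0.2, 1.0)]
        assert thrs == sorted(thrs, reverse=True)

    def test_invalid_alpha_rejected(self, matrix):
        with pytest.raises(ValueError, match="alpha"):
            mi_null_threshold(matrix, n_permutations=200, alpha=0.0)

    def test_planted_edges_exceed_threshold(self, strong_cohort):
        expr, _, truth = strong_cohort
        thr = mi_null_threshold(expr, n_permutations=500, alpha=0.05, seed=9)
        above = []
        rng = np.random.default_rng(4)
        edges = sorted(truth.planted_edges())
        for tf, t in [edges[i] for i in rng.choice(len(edges), 100,
                                                   replace=False)]:
            mi = estimate_mi(expr.data.loc[tf], expr.data.loc[t])
            above.append(mi > thr)
        assert np.mean(above) >= 0.95


class TestDpi:
    def test_chain_triangle_removes_weakest(self):
        edges = {("X", "Y"): 0.8, ("Y", "Z"): 0.7, ("X", "Z"): 0.3}
        pruned = apply_dpi(edges, tolerance=0.0)
        assert set(pruned) == {("X", "Y"), ("Y", "Z")}

    def test_tolerance_one_removes_nothing(self):
        rng = np.random.default_rng(0)
        edges = {("A", "B"): 0.5, ("B", "C"): 0.4, ("A", "C"): 0.1,
                 ("C", "D"): 0.9}
        assert apply_dpi(edges, tolerance=1.0) == {
            tuple(sorted(k)): v for k, v in edges.items()}

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            nodes = [f"N{i:02d}" for i in range(20)]
            edges = {}
            for i in range(20):
                for j in range(i + 1, 20):
                    if rng.random() < 0.3:
                        edges[(nodes[i], nodes[j])] = float(rng.random())
            tol = float(rng.choice([0.0, 0.1, 0.3]))
            assert apply_dpi(edges, tol) == brute_force_dpi(edges, tol)

    def test_idempotent(self):
        rng = np.random.default_rng(23)
        nodes = [f"N{i}" for i in range(15)]
        edges = {(a, b): float(rng.random())
                 for i, a in enumerate(nodes) for b in nodes[i + 1:]
                 if rng.random() < 0.4}
        once = apply_dpi(edges, 0.1)
        assert apply_dpi(once, 0.1) == once


class TestBuildRegulons:
    def test_recovery_on_strong_simulation(self, strong_cohort):
        expr, _, truth = strong_cohort
        net = build_regulons(expr, list(truth.tf_programs),
                             n_permutations=1000, seed=7)
        tf_set = set(net.tfs)
        recovered = {(r.tf, r.target) for r in net.edges.itertuples()
                     if r.target not in tf_set}
        planted = truth.planted_edges()
        tp = len(recovered & planted)
        assert tp / len(recovered) >= 0.8
        assert tp / len(planted) >= 0.8

    def test_negative_modes_recovered(self, strong_cohort):
        expr, _, truth = strong_cohort
        net = build_regulons(expr, list(truth.tf_programs),
                             n_permutations=1000, seed=7)
        modes = truth.edge_modes()
        neg_hits = [r.mode == -1 for r in net.edges.itertuples()
                    if modes.get((r.tf, r.target)) == -1]
        assert len(neg_hits) > 50
        assert np.mean(neg_hits) >= 0.95

    def test_null_matrix_regulon_size_calibrated(self):
        rng = np.random.default_rng(31)
        genes = [f"G{i:03d}" for i in range(300)]
        expr = GeneExpressionMatrix(pd.DataFrame(
            rng.standard_normal((300, 200)), index=genes,
            columns=[f"S{i}" for i in range(200)]))
        net = build_regulons(expr, genes[:10], alpha=0.001,
                             n_permutations=2000, seed=1)
        mean_size = net.n_edges() / 10
        assert mean_size <= 300 * 0.001 * 2

    def test_absent_tfs_rejected(self, small_expression):
        with pytest.raises(ValueError, match="no TF"):
            build_regulons(GeneExpressionMatrix(small_expression), ["ZZZ"])

    def test_estimator_wrapper_fits(self, small_expression):
        est = RegulonInference(tfs=["G00", "G01"], n_permutations=100,
                               alpha=0.5, random_state=0)
        est.fit(small_expression)
        assert est.network_.tfs == ["G00", "G01"]
        assert est.threshold_ == est.network_.parameters["mi_threshold"]
        params = est.get_params()
        assert params["alpha"] == 0.5
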