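"""Signature construction and running-sum enrichment scores."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regcycle.activity import (
    RegulonActivity,
    enrichment_score,
    enrichment_score_difference,
    regulon_activity,
    sample_signature,
    signature_activity,
    signature_matrix,
)
from regcycle.containers import TranscriptionalNetwork

from conftest import brute_force_es, make_truth_network


class TestSampleSignature:
    def test_cohort_mean_sample_is_zero(self):
        df = pd.DataFrame({"S1": [1.0, 5.0], "S2": [2.0, 6.0],
                           "S3": [3.0, 7.0]}, index=["A", "B"])
        sig = sample_signature(df, "S2")
        assert sig.tolist() == [0.0, 0.0]

    def test_identical_samples_give_zero_signatures(self):
        df = pd.DataFrame(np.ones((4, 5)), index=list("ABCD"),
                          columns=[f"S{i}" for i in range(5)])
        assert (signature_matrix(df).to_numpy() == 0).all()

    def test_unknown_sample_rejected(self):
        df = pd.DataFrame(np.eye(3), index=list("ABC"), columns=list("XYZ"))
        with pytest.raises(KeyError):
            sample_signature(df, "W")


def _ranked_signature(n=100):
    genes = [f"G{i:03d}" for i in range(n)]
    return pd.Series(np.linspace(3, -3, n), index=genes)


class TestEnrichmentScore:
    def test_top_ranked_set_scores_one(self):
        sig = _ranked_signature()
        assert enrichment_score(sig, sig.index[:10], weight_exponent=0) == 1.0

    def test_bottom_ranked_set_scores_minus_one(self):
        sig = _ranked_signature()
        assert enrichment_score(sig, sig.index[-10:], weight_exponent=0) == -1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i:02d}" for i in range(50)]
        for case in range(1000):
            sig = pd.Series(rng.standard_normal(50), index=genes)
            members = rng.choice(genes, size=8, replace=False)
            exponent = float(rng.choice([0.0, 1.0]))
            got = enrichment_score(sig, members, weight_exponent=exponent)
            want = brute_force_es(sig, members, exponent)
            assert got == pytest.approx(want, abs=1e-12)

    def test_empty_intersection_rejected(self):
        sig = _ranked_signature(20)
        with pytest.raises(ValueError, match="intersection"):
            enrichment_score(sig, ["ZZZ"])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 20),
           st.sampled_from([0.0, 0.5, 1.0]))
    def test_single_set_score_bounded(self, seed, set_size, exponent):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:02d}" for i in range(40)]
        sig = pd.Series(rng.standard_normal(40), index=genes)
        members = rng.choice(genes, size=set_size, replace=False)
        es = enrichment_score(sig, members, weight_exponent=exponent)
        assert -1.0 <= es <= 1.0

    def test_invariant_under_monotone_transform_unweighted(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i:02d}" for i in range(30)]
        sig = pd.Series(rng.standard_normal(30), index=genes)
        members = genes[3:9]
        a = enrichment_score(sig, members, weight_exponent=0)
        b = enrichment_score(np.exp(sig) * 2 + 1, members, weight_exponent=0)
        assert a == pytest.approx(b, abs=1e-12)


def _two_sided_network(universe, pos, neg):
    edges = pd.DataFrame(
        [("TF", t, 1, 1.0) for t in pos] + [("TF", t, -1, 1.0) for t in neg],
        columns=["tf", "target", "mode", "weight"])
    return TranscriptionalNetwork(universe=list(universe) + ["TF"],
                                  edges=edges, tfs=["TF"], parameters={})


class TestRegulonActivity:
    def test_extreme_sample_scores_two(self):
        # positive targets occupy the top ranks, negative the bottom ranks of
        # sample A's signature; the {A, -A, 1, -1} design keeps gene means at
        # exactly zero so cohort z-scoring preserves A's ranking
        genes = [f"G{i:03d}" for i in range(100)]
        a = np.linspace(3, -3, 100)
        df = pd.DataFrame({"A": a, "negA": -a, "B": np.ones(100),
                           "negB": -np.ones(100)}, index=genes)
        net = _two_sided_network(genes, genes[:10], genes[-10:])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            act = regulon_activity(net, df, weight_exponent=0)
        assert act.data.loc["TF", "A"] == pytest.approx(2.0)
        assert act.data.loc["TF", "negA"] == pytest.approx(-2.0)

    def test_mode_negation_negates_score(self, strong_cohort):
        expr, _, truth = strong_cohort
        net = make_truth_network(truth, expr.gene_ids)
        flipped_edges = net.edges.assign(mode=-net.edges["mode"])
        flipped = TranscriptionalNetwork(universe=net.universe,
                                         edges=flipped_edges, tfs=net.tfs,
                                         parameters={})
        a = regulon_activity(net, expr, weight_exponent=1).data
        b = regulon_activity(flipped, expr, weight_exponent=1).data
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)

    def test_planted_high_cc_regulons_track_latent(self, strong_cohort):
        expr, _, truth = strong_cohort
        net = make_truth_network(truth, expr.gene_ids)
        act = regulon_activity(net, expr).data
        late = truth.groups == "late"
        hits = []
        for tf, prog in truth.tf_programs.items():
            if prog == "high":
                row = act.loc[tf]
                hits.append(row[late.to_numpy()].mean()
                            > row[(~late).to_numpy()].mean())
        assert np.mean(hits) >= 0.95

    def test_empty_regulon_row_is_nan_with_warning(self, small_expression):
        edges = pd.DataFrame([("G00", "ZZ", 1, 1.0)],
                             columns=["tf", "target", "mode", "weight"])
        net = TranscriptionalNetwork(
            universe=list(small_expression.index) + ["ZZ"], edges=edges,
            tfs=["G00"], parameters={})
        with pytest.warns(UserWarning):
            act = regulon_activity(net, small_expression)
        assert act.data.loc["G00"].isna().all()

    def test_two_tailed_scores_bounded(self, strong_cohort):
        expr, _, truth = strong_cohort
        net = make_truth_network(truth, expr.gene_ids)
        values = regulon_activity(net, expr).data.to_numpy()
        assert np.nanmax(np.abs(values)) <= 2.0

    def test_transformer_wrapper_matches_function(self, strong_cohort):
        expr, _, truth = strong_cohort
        net = make_truth_network(truth, expr.gene_ids)
        est = RegulonActivity(network=net).fit()
        direct = regulon_activity(net, expr).data
        pd.testing.assert_frame_equal(est.transform(expr), direct)


class TestSignatureActivity:
    def test_top_set_scores_one_for_that_sample(self):
        genes = [f"G{i:02d}" for i in range(50)]
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((50, 5)), index=genes,
                          columns=[f"S{i}" for i in range(5)])
        sig = signature_matrix(df)["S0"]
        top = sig.sort_values(ascending=False).index[:5]
        act = signature_activity(df, {"top": top}, weight_exponent=0)
        assert act.data.loc["top", "S0"] == pytest.approx(1.0)

    def test_constant_matrix_scores_zero(self):
        df = pd.DataFrame(np.full((10, 4), 7.0),
                          index=[f"G{i}" for i in range(10)],
                          columns=[f"S{i}" for i in range(4)])
        act = signature_activity(df, {"s": [f"G{i}" for i in range(3)]})
        assert (act.data.to_numpy() == 0).all()

    def test_planted_signature_separates_groups(self, strong_cohort):
        from scipy.stats import mannwhitneyu
        expr, _, truth = strong_cohort
        act = signature_activity(expr, {"late": truth.late_genes}).data
        late = (truth.groups == "late").to_numpy()
        p = mannwhitneyu(act.loc["late"].to_numpy()[late],
                         act.loc["late"].to_numpy()[~late]).pvalue
        assert p < 0.01


class TestEnrichmentScoreDifference:
    def test_arithmetic_example(self):
        row = pd.Series([0.5, 0.7, 0.9, -0.2, 0.0, 0.1],
                        index=[f"S{i}" for i in range(6)])
        groups = pd.Series(["late"] * 3 + ["early"] * 3, index=row.index)
        assert enrichment_score_difference(row, groups) == pytest.approx(0.7)

    def test_swapping_labels_negates(self):
        rng = np.random.default_rng(0)
        row = pd.Series(rng.standard_normal(10),
                        index=[f"S{i}" for i in range(10)])
        groups = pd.Series(["late"] * 5 + ["early"] * 5, index=row.index)
        swapped = groups.map({"late": "early", "early": "late"})
        assert enrichment_score_difference(row, groups) == pytest.approx(
            -enrichment_score_difference(row, swapped))

    def test_empty_group_rejected(self):
        row = pd.Series([1.0, 2.0], index=["S1", "S2"])
        groups = pd.Series(["late", "late"], index=row.index)
        with pytest.raises(ValueError, match="non-empty"):
            enrichment_score_difference(row, groups)
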