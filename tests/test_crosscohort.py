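"""Cross-cohort normalization chain and stage-group comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from regcycle.crosscohort import (
    RUVNormalizer,
    UpperQuartileNormalizer,
    compare_stage_groups,
    counts_to_tpm,
    project_regulon_activity,
    remove_unwanted_variation,
    upper_quartile_normalize,
)
from regcycle.activity import regulon_activity
from regcycle.simulate import (
    SimulationConfig,
    simulate_batch_counts,
    simulate_cohort,
    simulate_stage_cohort,
)

from conftest import make_truth_network


def _random_counts(seed=0, n_genes=60, n_samples=15):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(50, size=(n_genes, n_samples)).astype(float)
    return pd.DataFrame(counts, index=[f"G{i:03d}" for i in range(n_genes)],
                        columns=[f"S{i}" for i in range(n_samples)])


class TestUpperQuartile:
    def test_scaled_sample_becomes_equal(self):
        df = _random_counts(1, n_samples=1)
        df["S1"] = df["S0"] * 2.0
        norm = upper_quartile_normalize(df)
        np.testing.assert_allclose(norm["S0"], norm["S1"], atol=1e-9)

    def test_idempotent_to_machine_precision(self):
        df = _random_counts(2)
        once = upper_quartile_normalize(df)
        twice = upper_quartile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(),
                                   atol=1e-12)

    def test_postcondition_equal_upper_quartiles(self):
        for seed in range(5):
            norm = upper_quartile_normalize(_random_counts(seed))
            uq = [np.quantile(norm[c][norm[c] > 0], 0.75) for c in norm]
            np.testing.assert_allclose(uq, uq[0], atol=1e-9)

    def test_all_zero_sample_rejected(self):
        df = _random_counts(3)
        df["S0"] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            upper_quartile_normalize(df)

    def test_transformer_matches_function(self):
        df = _random_counts(4)
        pd.testing.assert_frame_equal(
            UpperQuartileNormalizer().fit_transform(df),
            upper_quartile_normalize(df))


class TestRemoveUnwantedVariation:
    def test_planted_batch_removed_from_housekeeping(self):
        counts, batch, hk = simulate_batch_counts(n_samples=200,
                                                  batch_effect=1.0, seed=12)
        corrected = remove_unwanted_variation(counts, hk, k=1)
        for g in hk:
            r = np.corrcoef(np.log(corrected.loc[g].to_numpy() + 1),
                            batch.to_numpy())[0, 1]
            assert abs(r) < 0.1

    def test_no_batch_structure_barely_changes_matrix(self):
        counts, _, hk = simulate_batch_counts(n_samples=200, batch_effect=0.0,
                                              seed=13)
        corrected = remove_unwanted_variation(counts, hk, k=1)
        lfc = np.abs(np.log(corrected.to_numpy() + 1)
                     - np.log(counts.data.to_numpy() + 1))
        assert np.median(lfc) < 0.05

    def test_k_zero_is_identity(self):
        counts, _, hk = simulate_batch_counts(n_samples=30, seed=14)
        out = remove_unwanted_variation(counts, hk, k=0)
        pd.testing.assert_frame_equal(out, counts.data)

    def test_too_few_housekeeping_rejected(self):
        counts, _, hk = simulate_batch_counts(n_samples=30, seed=15)
        with pytest.raises(ValueError, match="housekeeping"):
            remove_unwanted_variation(counts, hk[:2], k=1)

    def test_transformer_form(self):
        counts, _, hk = simulate_batch_counts(n_samples=40, seed=16)
        a = RUVNormalizer(housekeeping_genes=hk, k=1).fit_transform(counts)
        b = remove_unwanted_variation(counts, hk, k=1)
        pd.testing.assert_frame_equal(a, b)


class TestCountsToTpm:
    def test_equal_rates_split_evenly(self):
        counts = pd.DataFrame({"S1": [10.0, 20.0]}, index=["A", "B"])
        lengths = pd.Series([1000.0, 2000.0], index=["A", "B"])
        tpm = counts_to_tpm(counts, lengths)
        np.testing.assert_allclose(tpm["S1"], [500000.0, 500000.0])

    def test_single_gene_is_one_million(self):
        counts = pd.DataFrame({"S1": [7.0]}, index=["A"])
        tpm = counts_to_tpm(counts, pd.Series([500.0], index=["A"]))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self):
        df = _random_counts(5)
        lengths = pd.Series(np.random.default_rng(1).integers(200, 5000,
                                                              len(df)),
                            index=df.index, dtype=float)
        tpm = counts_to_tpm(df, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, atol=1e-6)

    def test_missing_length_names_gene(self):
        counts = pd.DataFrame({"S1": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="'B'"):
            counts_to_tpm(counts, pd.Series([100.0], index=["A"]))


class TestProjection:
    def test_projection_onto_itself_reproduces_activity(self, strong_cohort):
        expr, _, truth = strong_cohort
        net = make_truth_network(truth, expr.gene_ids)
        direct = regulon_activity(net, expr).data
        projected, coverage = project_regulon_activity(net, expr)
        pd.testing.assert_frame_equal(projected.data, direct)
        assert all(c == 1.0 for c in coverage.values())

    def test_missing_regulon_flagged_others_unaffected(self, strong_cohort):
        expr, _, truth = strong_cohort
        net = make_truth_network(truth, expr.gene_ids)
        victim = net.tfs[0]
        dropped = expr.data.drop(index=net.regulon(victim)["target"].tolist())
        with pytest.warns(UserWarning, match="coverage"):
            projected, coverage = project_regulon_activity(net, dropped)
        assert coverage[victim] < 0.8
        assert projected.data.loc[victim].isna().all()
        other = net.tfs[1]
        assert projected.data.loc[other].notna().all()

    def test_sign_agreement_across_replicate_cohorts(self):
        cfg_a = SimulationConfig(n_samples=250, seed=81)
        cfg_b = SimulationConfig(n_samples=250, seed=82)
        expr_a, _, truth_a = simulate_cohort(cfg_a)
        expr_b, _, truth_b = simulate_cohort(cfg_b)
        net = make_truth_network(truth_a, expr_a.gene_ids)
        act_a = regulon_activity(net, expr_a).data
        act_b = project_regulon_activity(net, expr_b)[0].data
        agree = []
        for tf in net.tfs:
            da = (act_a.loc[tf][(truth_a.groups == "late").to_numpy()].median()
                  - act_a.loc[tf][(truth_a.groups == "early").to_numpy()].median())
            db = (act_b.loc[tf][(truth_b.groups == "late").to_numpy()].median()
                  - act_b.loc[tf][(truth_b.groups == "early").to_numpy()].median())
            agree.append(np.sign(da) == np.sign(db))
        assert np.mean(agree) >= 0.9


@pytest.fixture(scope="module")
def stage_setup():
    cfg = SimulationConfig(n_samples=100, seed=91)
    counts, pheno, truth = simulate_stage_cohort(cfg, n_nipuc=150,
                                                 n_invasive=150,
                                                 stage_shift=2.0)
    log_expr = np.log2(counts.data + 1.0)
    net = make_truth_network(truth, list(log_expr.index))
    act = regulon_activity(net, log_expr)
    directions = pd.Series(
        {tf: "high-CC" if p == "high" else "low-CC"
         for tf, p in truth.tf_programs.items() if p != "null"})
    return act, pheno, directions, truth


class TestCompareStageGroups:
    def test_high_cc_regulons_gain_activity_in_invasive(self, stage_setup):
        act, pheno, directions, truth = stage_setup
        result = compare_stage_groups(act, pheno.data["stage_class"],
                                      directions=directions)
        high = [tf for tf, p in truth.tf_programs.items() if p == "high"]
        sub = result.loc[high]
        assert (sub["significant"] & (sub["median_difference"] > 0)).mean() >= 0.9
        assert sub["consistent"].mean() >= 0.9

    def test_label_permutation_yields_no_significance(self, stage_setup):
        act, pheno, directions, _ = stage_setup
        rng = np.random.default_rng(0)
        fractions = []
        for rep in range(20):
            permuted = pd.Series(
                rng.permutation(pheno.data["stage_class"].to_numpy()),
                index=pheno.data.index)
            res = compare_stage_groups(act, permuted)
            fractions.append(res["significant"].mean())
        assert np.mean(fractions) <= 0.05

    def test_swapping_groups_flips_sign_keeps_p(self, stage_setup):
        act, pheno, _, _ = stage_setup
        labels = pheno.data["stage_class"]
        swapped = labels.map({"NIPUC": "MIBC", "MIBC": "NIPUC"})
        a = compare_stage_groups(act, labels)
        b = compare_stage_groups(act, swapped)
        np.testing.assert_allclose(a["median_difference"],
                                   -b["median_difference"], atol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_single_group_rejected(self, stage_setup):
        act, pheno, _, _ = stage_setup
        labels = pd.Series("NIPUC", index=pheno.data.index)
        with pytest.raises(ValueError, match="non-empty"):
            compare_stage_groups(act, labels)
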