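"""Spectral-count quantification: G-test, indices, fold changes, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from evpanel.quant import (
    PsmExperiment,
    accumulate_psm,
    differential_analysis,
    filter_significant,
    g_test,
    normalize_psm_index,
)


def g_oracle(c_a, c_b, t_a, t_b):
    """Likelihood-ratio oracle: twice the Poisson log-likelihood ratio between
    the saturated model and the common-rate model, via scipy logpmf."""
    rate = (c_a + c_b) / (t_a + t_b)
    ll_sat = stats.poisson.logpmf(c_a, max(c_a, 1e-300)) + stats.poisson.logpmf(
        c_b, max(c_b, 1e-300)
    )
    ll_null = stats.poisson.logpmf(c_a, rate * t_a) + stats.poisson.logpmf(
        c_b, rate * t_b
    )
    return 2.0 * (ll_sat - ll_null)


class TestGTest:
    def test_balanced_split_gives_zero(self):
        g, p = g_test(5, 5, 1000, 1000)
        assert g == 0.0 and p == 1.0

    def test_closed_form_unbalanced(self):
        # 20 vs 5 at equal totals: expected counts 12.5 each
        g, p = g_test(20, 5, 1000, 1000)
        expected = 2 * (20 * np.log(20 / 12.5) + 5 * np.log(5 / 12.5))
        assert g == pytest.approx(expected, abs=1e-12)
        assert g == pytest.approx(9.637, abs=5e-4)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)
        assert p == pytest.approx(0.0019, abs=1e-4)

    def test_zero_cell_convention(self):
        # 0*ln(0) = 0: all counts in one group
        g, _ = g_test(0, 10, 1000, 1000)
        assert g == pytest.approx(2 * 10 * np.log(2), abs=1e-12)
        assert g == pytest.approx(g_oracle(0, 10, 1000, 1000), abs=1e-10)

    @given(
        c_a=st.integers(0, 50), c_b=st.integers(0, 50),
        t_a=st.integers(1, 500), t_b=st.integers(1, 500),
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_likelihood_ratio_oracle(self, c_a, c_b, t_a, t_b):
        if c_a + c_b == 0 or c_a > t_a or c_b > t_b:
            return
        g, _ = g_test(c_a, c_b, t_a, t_b)
        assert g == pytest.approx(g_oracle(c_a, c_b, t_a, t_b), abs=1e-10)

    @given(
        c_a=st.integers(0, 40), c_b=st.integers(0, 40),
        t_a=st.integers(50, 500), t_b=st.integers(50, 500),
    )
    @settings(max_examples=200, derandomize=True)
    def test_group_swap_symmetry(self, c_a, c_b, t_a, t_b):
        if c_a + c_b == 0:
            return
        g1, p1 = g_test(c_a, c_b, t_a, t_b)
        g2, p2 = g_test(c_b, c_a, t_b, t_a)
        assert g1 == pytest.approx(g2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_monotone_in_imbalance_at_fixed_sum(self):
        total = 30
        gs = [g_test(c, total - c, 1000, 1000)[0] for c in range(15, 31)]
        assert all(b >= a - 1e-12 for a, b in zip(gs, gs[1:]))

    def test_rejects_count_exceeding_total(self):
        with pytest.raises(ValueError):
            g_test(20, 5, 10, 1000)

    def test_rejects_double_zero(self):
        with pytest.raises(ValueError):
            g_test(0, 0, 10, 10)


class TestAccumulateNormalize:
    def test_accumulate_sums_replicates(self, small_experiment):
        c, total = accumulate_psm(small_experiment, genotype="WT")
        assert c.tolist() == [10, 40, 0, 0]
        assert total == 50

    def test_single_replicate_identity(self, small_experiment):
        c, _ = accumulate_psm(small_experiment, genotype="WT", replicate_id=1)
        assert c.tolist() == [3, 20, 0, 0]

    def test_empty_selector_is_an_error(self, small_experiment):
        with pytest.raises(ValueError, match="cerebellum"):
            accumulate_psm(small_experiment, tissue="cerebellum")

    def test_normalized_index_arithmetic(self):
        assert normalize_psm_index(10, 1000, scale=1e4) == pytest.approx(100.0)
        assert normalize_psm_index(0, 1000) == 0.0
        with pytest.raises(ValueError):
            normalize_psm_index(5, 0)


class TestDifferentialAnalysis:
    def test_fold_and_g_closed_form(self):
        # one protein 40 vs 10 on equal totals 1e4 => lfc ~ -2, G ~ 19.274
        from conftest import make_experiment

        filler = 10000 - 40, 10000 - 10
        meta = [
            {"sample_id": s, "tissue": "plasma_EV", "age_months": 3,
             "genotype": g, "replicate_id": 1}
            for s, g in [("a", "WT"), ("b", "5xFAD")]
        ]
        exp = make_experiment({"a": [40, filler[0]], "b": [10, filler[1]]}, meta)
        table = differential_analysis(exp, "plasma_EV", 3, pseudocount=1e-9)
        row = table.set_index("protein_id").loc["prot0"]
        assert row["log2_fold"] == pytest.approx(-2.0, abs=1e-6)
        expected_g = 2 * (40 * np.log(40 / 25) + 10 * np.log(10 / 25))
        assert row["G"] == pytest.approx(expected_g, abs=1e-9)
        assert row["p_value"] == pytest.approx(stats.chi2.sf(expected_g, 1), rel=1e-9)

    def test_pseudocount_gives_finite_fold_for_one_sided_detection(self):
        from conftest import make_experiment

        meta = [
            {"sample_id": s, "tissue": "plasma_EV", "age_months": 3,
             "genotype": g, "replicate_id": 1}
            for s, g in [("a", "WT"), ("b", "5xFAD")]
        ]
        # totals equal to the scale so indices equal raw counts
        exp = make_experiment({"a": [0, 10000], "b": [12, 10000 - 12]}, meta)
        table = differential_analysis(exp, "plasma_EV", 3, pseudocount=0.5)
        row = table.set_index("protein_id").loc["prot0"]
        assert row["log2_fold"] == pytest.approx(np.log2(12.5 / 0.5), abs=1e-6)

    def test_nd_convention(self, small_experiment):
        table = differential_analysis(small_experiment, "hippocampus", 3)
        row = table.set_index("protein_id").loc["prot3"]
        assert row["status"] == "ND"
        assert np.isnan(row["p_value"]) and np.isnan(row["G"])
        assert "prot3" not in set(
            filter_significant(table, p_max=1.1)["protein_id"]
        )

    def test_missing_genotype_is_an_error(self, small_experiment):
        with pytest.raises(ValueError):
            differential_analysis(small_experiment, "hippocampus", 3,
                                  group_b="KO")

    def test_label_swap_negates_folds(self, sim_experiment):
        _, exp, _ = sim_experiment
        fwd = differential_analysis(exp, "hippocampus", 3).set_index("protein_id")
        rev = differential_analysis(
            exp, "hippocampus", 3, group_a="5xFAD", group_b="WT"
        ).set_index("protein_id")
        q = fwd.index[fwd["status"] == "quantified"]
        assert np.allclose(fwd.loc[q, "log2_fold"], -rev.loc[q, "log2_fold"])
        assert np.allclose(fwd.loc[q, "G"], rev.loc[q, "G"])
        assert np.allclose(fwd.loc[q, "p_value"], rev.loc[q, "p_value"])

    def test_output_sorted_by_p_then_abs_fold(self, sim_experiment):
        _, exp, _ = sim_experiment
        table = differential_analysis(exp, "hippocampus", 3)
        p = table["p_value"].dropna()
        assert p.is_monotonic_increasing


class TestFilterSignificant:
    @pytest.fixture()
    def records(self):
        return pd.DataFrame(
            {
                "protein_id": list("abcde"),
                "log2_fold": [7.1, 4.6, -6.0, 5.5, 6.2],
                "p_value": [0.001, 0.001, 0.002, 0.049, 0.05],
                "status": ["quantified"] * 5,
            }
        )

    def test_threshold_and_direction(self, records):
        kept = filter_significant(records, p_max=0.05, lfc_min=5.0)
        assert kept["protein_id"].tolist() == ["a", "c", "d"]
        up = filter_significant(records, p_max=0.05, lfc_min=5.0, direction="up")
        assert up["protein_id"].tolist() == ["a", "d"]
        down = filter_significant(records, p_max=0.05, lfc_min=5.0, direction="down")
        assert down["protein_id"].tolist() == ["c"]

    def test_strict_p_inclusive_lfc_boundaries(self, records):
        kept = filter_significant(records, p_max=0.05, lfc_min=6.0)
        # |lfc| == 6.0 included (inclusive); p == 0.05 excluded (strict)
        assert kept["protein_id"].tolist() == ["a", "c"]


def test_experiment_validation_rejects_bad_input():
    counts = pd.DataFrame({"s1": [1, 2]}, index=["p1", "p1"])
    meta = pd.DataFrame(
        {"tissue": ["cortex"], "age_months": [3], "genotype": ["WT"],
         "replicate_id": [1]}, index=pd.Index(["s1"], name="sample_id"))
    with pytest.raises(ValueError, match="unique"):
        PsmExperiment(counts=counts, meta=meta)
    counts = pd.DataFrame({"s1": [-1, 2]}, index=["p1", "p2"])
    with pytest.raises(ValueError, match="non-negative"):
        PsmExperiment(counts=counts, meta=meta)
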