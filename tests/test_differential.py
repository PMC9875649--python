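import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from spatialpgx.core import filter_genes, normalize_per_spot
from spatialpgx.differential import (
    FLAG_BOTH_ZERO,
    FLAG_DEGENERATE,
    de_table,
    log2_fold_change,
    summarize_global,
    welch_t,
)
from spatialpgx.errors import ValidationError

from test_core import make_annotation, make_matrix


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_textbook_closed_form(self):
        x, y = [1, 2, 3, 4], [2, 3, 4, 5]
        t, df, p = welch_t(x, y)
        # hand computation: means 2.5, 3.5; variances 5/3 each; se^2 = 5/6
        se = math.sqrt(5 / 6)
        assert t == pytest.approx(-1.0 / se, abs=1e-10)
        assert df == pytest.approx(6.0, abs=1e-10)  # equal n, equal var -> nx+ny-2
        assert p == pytest.approx(2 * scipy.stats.t.sf(1.0 / se, 6.0), abs=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=9), rng.normal(1, 2, size=14)
        t1, df1, p1 = welch_t(x, y)
        t2, df2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert df1 == pytest.approx(df2) and p1 == pytest.approx(p2, abs=1e-12)

    def test_agrees_with_scipy_oracle(self):
        """Independent oracle: scipy.stats.ttest_ind(equal_var=False)."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            nx, ny = rng.integers(2, 40, size=2)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nx)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), ny)
            t, df, p = welch_t(x, y)
            ref = scipy.stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_degenerate_variance_unequal_means_undefined(self):
        t, df, p = welch_t([1, 1, 1], [2, 2, 2])
        assert math.isnan(t) and math.isnan(p)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1], [1, 2])


class TestLog2FoldChange:
    def test_infinity_rules(self):
        assert log2_fold_change(0.5, 0.0) == math.inf
        assert log2_fold_change(0.0, 0.5) == -math.inf
        assert math.isnan(log2_fold_change(0.0, 0.0))
        assert log2_fold_change(2.0, 1.0) == 1.0

    def test_sign_matches_mean_difference_when_finite(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = rng.uniform(0.01, 5, size=2)
            assert np.sign(log2_fold_change(a, b)) == np.sign(a - b)


def _two_sample_setup(tumor_counts, nontumor_counts, genes):
    """Build matrices/annotations: s1 holds tumor spots, s2 non-tumor."""
    m1 = make_matrix(tumor_counts, "s1", genes=genes)
    m2 = make_matrix(nontumor_counts, "s2", genes=genes)
    anns = {
        "s1": make_annotation(["tumor"] * len(tumor_counts), "s1"),
        "s2": make_annotation(["stroma"] * len(nontumor_counts), "s2"),
    }
    norm = {sid: normalize_per_spot(m) for sid, m in (("s1", m1), ("s2", m2))}
    return norm, anns


class TestDeTable:
    def test_zero_tumor_gene_gives_negative_infinity_retained(self):
        # gene A all-zero in tumor but expressed in non-tumor; gene B keeps both nonzero
        norm, anns = _two_sample_setup(
            [[0, 5], [0, 7], [0, 6]], [[3, 5], [2, 6], [4, 7]], genes=["A", "B"]
        )
        de = de_table(norm, anns)
        rec = de[(de.gene == "A") & (de["sample"] == "s1")].iloc[0]
        assert rec["log2fc"] == -math.inf
        assert "neg_inf" in rec["flags"]
        # the Welch test still ran (non-tumor variance is nonzero)
        assert not math.isnan(rec["p_raw"])

    def test_both_zero_flagged_and_untested(self):
        norm, anns = _two_sample_setup(
            [[0, 5], [0, 7]], [[0, 5], [0, 6]], genes=["A", "B"]
        )
        de = de_table(norm, anns)
        rec = de[de.gene == "A"].iloc[0]
        assert math.isnan(rec["log2fc"]) and FLAG_BOTH_ZERO in rec["flags"]
        assert math.isnan(rec["p_raw"])
        # M counts only performed tests
        assert de.attrs["n_tests"] == 1

    def test_bonferroni_multiplies_by_tests_performed_and_caps(self):
        rng = np.random.default_rng(3)
        tumor = rng.integers(1, 30, size=(30, 5))
        nont = rng.integers(1, 30, size=(30, 5))
        norm, anns = _two_sample_setup(tumor, nont, genes=list("ABCDE"))
        de = de_table(norm, anns)
        M = de.attrs["n_tests"]
        assert M == 5
        expected = np.minimum(1.0, de["p_raw"] * M)
        np.testing.assert_allclose(de["p_bonferroni"], expected)
        assert (de["p_bonferroni"] >= de["p_raw"] - 1e-15).all()

    def test_degenerate_variance_record_excluded_from_m(self):
        # gene A's expression fraction is constant in both groups but differs
        # between them -> degenerate variance, p NA, not in M; B and C vary
        # in the non-tumor group and are tested
        norm, anns = _two_sample_setup(
            [[1, 1, 1], [2, 2, 2], [1, 1, 1]],
            [[1, 1, 2], [2, 5, 1]],
            genes=["A", "B", "C"],
        )
        de = de_table(norm, anns)
        rec = de[de.gene == "A"].iloc[0]
        assert FLAG_DEGENERATE in rec["flags"]
        assert math.isnan(rec["p_raw"])
        assert de.attrs["n_tests"] == 2

    def test_sample_without_tumor_spots_omitted(self):
        m1 = make_matrix([[1, 2], [2, 3], [1, 1]], "s1")
        m2 = make_matrix([[2, 2], [3, 1], [2, 4]], "s2")
        anns = {
            "s1": make_annotation(["tumor", "tumor", "stroma"], "s1"),
            "s2": make_annotation(["stroma", "stroma", "stroma"], "s2"),
        }
        norm = {"s1": normalize_per_spot(m1), "s2": normalize_per_spot(m2)}
        de = de_table(norm, anns)
        assert set(de["sample"]) == {"s1"}

    def test_infinity_count_equals_single_zero_mean_pairs(self, default_dataset, default_panel):
        """Bookkeeping invariant on the simulated dataset."""
        ds = default_dataset
        norm = {
            sid: filter_genes(normalize_per_spot(m), default_panel)[0]
            for sid, m in ds.matrices.items()
        }
        de = de_table(norm, ds.annotations)
        n_inf = int(np.isinf(de["log2fc"]).sum())
        single_zero = (
            ((de["mean_tumor"] == 0) & (de["mean_nontumor"] > 0))
            | ((de["mean_tumor"] > 0) & (de["mean_nontumor"] == 0))
        )
        assert n_inf == int(single_zero.sum())


class TestPlantedDeRecovery:
    def test_planted_genes_significant_and_negative(self, de_dataset, default_panel):
        ds = de_dataset
        norm = {
            sid: filter_genes(normalize_per_spot(m), default_panel)[0]
            for sid, m in ds.matrices.items()
        }
        de = de_table(norm, ds.annotations)
        D = set(ds.truth.de_genes)
        sub = de[de["gene"].isin(D)]
        frac = ((sub["p_bonferroni"] < 0.05) & (sub["log2fc"] < 0)).mean()
        assert frac >= 0.9

        summary = summarize_global(de)
        flagged = summary.set_index("gene").loc[sorted(D), "down_in_all"]
        assert flagged.mean() >= 0.8


class TestSummarize:
    def test_all_infinite_gene_reported_na_mean(self):
        de = pd.DataFrame(
            {
                "gene": ["A", "A"],
                "sample": ["s1", "s2"],
                "log2fc": [math.inf, math.inf],
                "p_raw": [0.001, 0.002],
                "p_bonferroni": [0.002, 0.004],
            }
        )
        s = summarize_global(de)
        assert math.isnan(s.loc[0, "mean_log2fc"])
        assert s.loc[0, "n_inf"] == 2

    def test_single_sample_summary_mirrors_records(self):
        de = pd.DataFrame(
            {
                "gene": ["A", "B"],
                "sample": ["s1", "s1"],
                "log2fc": [-1.0, 2.0],
                "p_raw": [0.001, 0.5],
                "p_bonferroni": [0.002, 1.0],
            }
        )
        s = summarize_global(de).set_index("gene")
        assert s.loc["A", "mean_log2fc"] == -1.0
        assert bool(s.loc["A", "down_in_all"])
        assert not bool(s.loc["B", "down_in_all"])
        # ascending order by mean fold change
        assert list(summarize_global(de)["gene"]) == ["A", "B"]
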