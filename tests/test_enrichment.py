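import numpy as np
import pandas as pd
import pytest

from conftest import make_contrast_table
from sgcap.io_core import DesignError, FormatError, NormalizationError, RunConfig
from sgcap.enrichment import (
    bh_adjust,
    classify_transcriptome,
    estimate_dispersions,
    estimate_size_factors,
    significant_sets,
    test_contrast as nb_contrast,
)
from sgcap.synthetic_data import two_group_design, simulate_counts


def _cm(counts: np.ndarray, design: pd.DataFrame):
    from sgcap.io_core import CountMatrix
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(pd.DataFrame(counts, index=genes,
                                    columns=list(design.index)), design)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        np.testing.assert_allclose(estimate_size_factors(df), [1.0, 1.0])

    def test_doubled_sample_gives_sqrt2_split(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        np.testing.assert_allclose(
            estimate_size_factors(df), [1 / np.sqrt(2), np.sqrt(2)])

    def test_all_zero_gene_ignored(self):
        df = pd.DataFrame({"a": [10, 20, 0], "b": [10, 20, 0]})
        np.testing.assert_allclose(estimate_size_factors(df), [1.0, 1.0])

    def test_no_common_nonzero_gene_is_an_error(self):
        df = pd.DataFrame({"a": [10, 0], "b": [0, 5]})
        with pytest.raises(NormalizationError):
            estimate_size_factors(df)


class TestDispersions:
    def test_moment_formula_on_known_variance(self):
        # one gene, mean 100, sample variance 722 -> (722-100)/100^2 = 0.0622
        df = pd.DataFrame({"a": [81.0], "b": [119.0]}).astype(float)
        d = estimate_dispersions(df, pd.Series([1.0, 1.0], index=["a", "b"]))
        assert d.iloc[0] == pytest.approx((722 - 100) / 100**2, rel=1e-6)

    def test_sub_poisson_gene_falls_back_to_trend(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(100, size=(50, 6)).astype(float) * \
            rng.uniform(1.0, 1.5, size=(50, 1))
        arr[0] = 100.0  # constant row: zero variance, no dispersion signal
        df = pd.DataFrame(arr, columns=list("abcdef"))
        d = estimate_dispersions(df, pd.Series(1.0, index=list("abcdef")))
        # no spuriously tiny dispersion: the constant row sits at trend scale
        assert d.iloc[0] >= 1e-8
        assert d.iloc[0] > 0.1 * d.iloc[1:].min()

    def test_identical_genes_make_shrinkage_a_noop(self):
        row = [80.0, 120.0, 95.0, 105.0]
        df = pd.DataFrame([row] * 20, columns=list("abcd"))
        d = estimate_dispersions(df, pd.Series(1.0, index=list("abcd")))
        m = np.mean(row)
        s2 = np.var(row, ddof=1)
        raw = (s2 - m) / m**2
        np.testing.assert_allclose(d, raw, rtol=1e-6)


class TestContrast:
    def test_identical_groups_give_null_result(self):
        design = two_group_design(2, 2)
        counts = np.tile([[100], [50]], (1, 4))
        cm = _cm(counts, design)
        tab = nb_contrast(cm, ({"bait": "targeted"}, {"bait": "untargeted"}))
        np.testing.assert_allclose(tab.log2fc, 0.0)
        np.testing.assert_allclose(tab.pvalue, 1.0)

    def test_swapping_groups_negates_log2fc(self):
        design = two_group_design(3, 3)
        cm, _ = simulate_counts(50, design, seed=3, dispersion=0.05)
        a = ({"bait": "targeted"}, {"bait": "untargeted"})
        t1 = nb_contrast(cm, a)
        t2 = nb_contrast(cm, (a[1], a[0]))
        np.testing.assert_allclose(t1.log2fc, -t2.log2fc, atol=1e-10)
        np.testing.assert_allclose(t1.pvalue, t2.pvalue, atol=1e-10)

    def test_empty_group_is_design_error(self):
        design = two_group_design(3, 3)
        cm, _ = simulate_counts(10, design, seed=3)
        with pytest.raises(DesignError):
            nb_contrast(cm, ({"bait": "targeted"}, {"stress": "sorbitol"}))

    def test_all_zero_gene_marked_untested(self):
        design = two_group_design(2, 2)
        counts = np.array([[100, 90, 110, 95], [0, 0, 0, 0]])
        cm = _cm(counts, design)
        tab = nb_contrast(cm, ({"bait": "targeted"}, {"bait": "untargeted"}))
        assert not tab.loc["g1", "tested"]
        assert np.isnan(tab.loc["g1", "pvalue"])
        assert np.isnan(tab.loc["g1", "padj"])

    def test_unknown_named_contrast_rejected(self):
        design = two_group_design(2, 2)
        cm, _ = simulate_counts(5, design, seed=1)
        with pytest.raises(DesignError, match="unknown contrast"):
            nb_contrast(cm, "nope")


class TestBHAdjust:
    def test_hand_computed_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_nan_excluded_from_family(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            bh_adjust([0.5, 1.2])


class TestClassification:
    def test_proximal_is_triple_intersection(self):
        c1 = make_contrast_table(enriched=["a", "b", "c"], other=["d"])
        c2 = make_contrast_table(enriched=["b", "c", "d"], other=["a"])
        c3 = make_contrast_table(enriched=["c", "d", "a"], other=["b"])
        res = classify_transcriptome(c1, c2, c3)
        assert res.proximal == {"c"}

    def test_two_contrasts_only_is_not_proximal(self):
        c1 = make_contrast_table(enriched=["x"])
        c2 = make_contrast_table(other=["x"])
        c3 = make_contrast_table(enriched=["x"])
        res = classify_transcriptome(c1, c2, c3)
        assert res.proximal == frozenset()

    def test_excluded_from_contrasts_1_and_3(self):
        c1 = make_contrast_table(depleted=["y"], fc=0.5, padj=0.01)
        c2 = make_contrast_table(other=["y"])
        c3 = make_contrast_table(depleted=["y"], fc=0.5, padj=0.01)
        res = classify_transcriptome(c1, c2, c3)
        assert res.excluded == {"y"}

    def test_missing_padj_never_passes(self):
        df = pd.DataFrame({"log2fc": [5.0], "padj": [np.nan]},
                          index=["g"])
        enr, dep = significant_sets(df, 0.3, 0.05)
        assert enr == frozenset() and dep == frozenset()

    def test_strict_threshold_inequalities(self):
        df = pd.DataFrame({"log2fc": [0.3, 0.31], "padj": [0.01, 0.05]},
                          index=["at_fc", "at_alpha"])
        enr, _ = significant_sets(df, 0.3, 0.05)
        assert enr == frozenset()  # 0.3 fails fc >, 0.05 fails padj <

    def test_two_table_mode_requires_explicit_flag(self):
        c1 = make_contrast_table(enriched=["a"])
        c3 = make_contrast_table(enriched=["a"])
        with pytest.raises(DesignError):
            classify_transcriptome(c1, None, c3)
        res = classify_transcriptome(c1, None, c3, allow_two_contrasts=True)
        assert res.proximal == {"a"}

    def test_proximal_and_excluded_disjoint_on_random_tables(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(200)]
        for _ in range(10):
            tabs = []
            for _ in range(3):
                tabs.append(pd.DataFrame({
                    "log2fc": rng.normal(0, 1, 200),
                    "padj": rng.uniform(0, 1, 200)}, index=genes))
            res = classify_transcriptome(*tabs)
            assert not (res.proximal & res.excluded)

    def test_monotone_under_threshold_tightening(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(150)]
        tabs = [pd.DataFrame({"log2fc": rng.normal(0, 1, 150),
                              "padj": rng.uniform(0, 1, 150)}, index=genes)
                for _ in range(3)]
        loose = classify_transcriptome(
            *tabs, config=RunConfig(fc_threshold=0.2, alpha=0.2))
        tight = classify_transcriptome(
            *tabs, config=RunConfig(fc_threshold=0.5, alpha=0.05))
        assert tight.proximal <= loose.proximal
        assert tight.excluded <= loose.excluded
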