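from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sgcap.io_core import AnnotationError, GeneSetTable, TranscriptModel, \
    load_annotation, load_feature_resources
from sgcap.features import (
    EmptyGroupError,
    attach_te,
    au_fraction,
    compare_feature,
    compute_feature_table,
    m6a_metrics,
    m6a_proportion_table,
    region_metrics,
    select_longest_isoform,
)


def mk_model(gene, tid, utr5="", cds="", utr3=""):
    total = len(utr5) + len(cds) + len(utr3)
    return TranscriptModel(gene_id=gene, transcript_id=tid, strand="+",
                           exons=[(1, max(total, 1))], cds=[],
                           seq_full=utr5 + cds + utr3,
                           seq_utr5=utr5, seq_cds=cds, seq_utr3=utr3)


class TestLongestIsoform:
    def test_longest_wins(self):
        models = {"t1": mk_model("g", "t1", cds="A" * 500),
                  "t2": mk_model("g", "t2", cds="A" * 800)}
        assert select_longest_isoform(models)["g"].transcript_id == "t2"

    def test_tie_breaks_to_smallest_id(self):
        models = {"t2": mk_model("g", "t2", cds="A" * 600),
                  "t1": mk_model("g", "t1", cds="G" * 600)}
        assert select_longest_isoform(models)["g"].transcript_id == "t1"

    def test_single_isoform_is_itself(self):
        models = {"t1": mk_model("g", "t1", cds="AU")}
        assert select_longest_isoform(models)["g"].transcript_id == "t1"


class TestRegionMetrics:
    @pytest.mark.parametrize("seq,expected", [
        ("AUAUAU", 1.0), ("AUGC", 0.5), ("AUGCN", 0.5), ("GGCC", 0.0)])
    def test_au_fraction(self, seq, expected):
        assert au_fraction(seq) == pytest.approx(expected)

    def test_dna_t_mapped_to_u(self):
        assert au_fraction("ATAT") == 1.0

    def test_empty_region_gives_nan_au_and_zero_length(self):
        m = region_metrics(mk_model("g", "t", cds="AUGC"))
        assert m["len_utr3"] == 0
        assert np.isnan(m["au_utr3"])
        assert m["au_cds"] == 0.5

    def test_au_plus_gc_sums_to_one(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), 50))
            gc = (seq.count("G") + seq.count("C")) / 50
            assert au_fraction(seq) + gc == pytest.approx(1.0)


class TestM6aMetrics:
    @pytest.mark.parametrize("n_sites,length,density", [
        (3, 2000, 1.5), (0, 1000, 0.0), (2, 1000, 2.0)])
    def test_density_per_kilobase(self, n_sites, length, density):
        sites = {"g": list(range(n_sites))} if n_sites else {}
        m = m6a_metrics("g", sites, length)
        assert m["m6a_count"] == n_sites
        assert m["m6a_density"] == pytest.approx(density)

    def test_sites_on_zero_length_transcript_rejected(self):
        with pytest.raises(AnnotationError):
            m6a_metrics("g", {"g": [5]}, 0)


class TestAttachTe:
    def test_present_and_absent(self):
        feats = pd.DataFrame(index=["g1", "g2"])
        out = attach_te(feats, {"g1": 0.7})
        assert out.loc["g1", "te"] == 0.7
        assert np.isnan(out.loc["g2", "te"])

    def test_all_missing_te_raises_on_comparison(self):
        with pytest.raises(EmptyGroupError):
            compare_feature([np.nan, np.nan], [1.0])


def exact_two_sided_p(a, b):
    """Enumerate all group-A assignments of the pooled values."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum((x > y) + 0.5 * (x == y) for x in ga for y in gb))
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_worked_example(self):
        r = compare_feature([1, 2], [3, 4])
        assert r.u_statistic == 0
        assert r.pvalue == pytest.approx(1 / 3)
        assert r.method == "exact"

    def test_identical_groups_give_p_one(self):
        r = compare_feature([1, 2, 3], [1, 2, 3])
        assert r.pvalue == pytest.approx(1.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=6)
        b = rng.normal(1, 1, size=7)
        r1 = compare_feature(a, b)
        r2 = compare_feature(b, a)
        assert r1.u_statistic + r2.u_statistic == pytest.approx(6 * 7)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(17)
        for n1 in (2, 3, 4, 5):
            for n2 in (2, 3, 5):
                if n1 + n2 > 10:
                    continue
                a = rng.normal(size=n1)
                b = rng.normal(size=n2)
                r = compare_feature(a, b)
                assert r.method == "exact"
                assert r.pvalue == pytest.approx(exact_two_sided_p(a, b),
                                                 rel=1e-9)

    def test_stars_mapping(self):
        from sgcap.features import ComparisonResult
        mk = lambda p: ComparisonResult("a", "b", 5, 5, 0, 0, 10, p, "exact")
        assert mk(0.2).stars == "ns"
        assert mk(0.03).stars == "*"
        assert mk(0.005).stars == "**"
        assert mk(5e-4).stars == "***"
        assert mk(5e-5).stars == "****"


class TestM6aProportions:
    def test_worked_bins(self):
        feats = pd.DataFrame({"m6a_count": [0, 0, 1, 3]},
                             index=["a", "b", "c", "d"])
        sets = {"s": GeneSetTable("s", frozenset("abcd"))}
        tab = m6a_proportion_table(sets, feats,
                                   bins=((0, 0), (1, 2), (3, np.inf)))
        row = tab.loc["s"]
        assert row["0"] == pytest.approx(0.5)
        assert row["1-2"] == pytest.approx(0.25)
        assert row[">=3"] == pytest.approx(0.25)
        assert row["mean_sites_per_rna"] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(17)
        feats = pd.DataFrame({"m6a_count": rng.poisson(2, 100)},
                             index=[f"g{i}" for i in range(100)])
        sets = {"s": GeneSetTable("s", frozenset(feats.index))}
        tab = m6a_proportion_table(sets, feats)
        bins = [c for c in tab.columns if c not in ("n", "mean_sites_per_rna")]
        assert tab.loc["s", bins].sum() == pytest.approx(1.0)

    def test_members_absent_from_features_logged(self, caplog):
        feats = pd.DataFrame({"m6a_count": [1]}, index=["a"])
        sets = {"s": GeneSetTable("s", frozenset(["a", "zz"]))}
        with caplog.at_level("WARNING", logger="sgcap"):
            tab = m6a_proportion_table(sets, feats)
        assert tab.loc["s", "n"] == 1
        assert any("absent" in r.message for r in caplog.records)


class TestFeatureRecovery:
    def test_lengths_m6a_exact_and_au_near_target(self, annotation_fixture):
        paths, truth = annotation_fixture
        models = load_annotation(paths["gtf"], paths["fasta"])
        sites, te = load_feature_resources(paths["m6a"], paths["te"])
        table = compute_feature_table(models, sites, te)
        joined = table.join(truth.table, rsuffix="_true")
        for col in ("len_utr5", "len_cds", "len_utr3", "len_total",
                    "m6a_count"):
            assert (joined[col] == joined[f"{col}_true"]).all(), col
        # realized AU equals the truth record exactly (same sequence)
        for col in ("au_utr5", "au_cds", "au_utr3", "au_total"):
            np.testing.assert_allclose(joined[col], joined[f"{col}_true"])
        # long regions concentrate near their AU target
        long_cds = joined[joined.len_cds >= 500]
        assert ((long_cds.au_cds - 0.45).abs() < 0.05).all()

    def test_te_missingness_propagates(self, annotation_fixture):
        paths, truth = annotation_fixture
        models = load_annotation(paths["gtf"], paths["fasta"])
        sites, te = load_feature_resources(paths["m6a"], paths["te"])
        table = compute_feature_table(models, sites, te)
        truth_missing = truth.table.te.isna()
        assert (table.te.isna() == truth_missing.loc[table.index]).all()
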