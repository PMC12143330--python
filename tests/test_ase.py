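"""SNV- and gene-level ASE testing, classification, and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from hapase.ase import (
    TestConfig as Cfg,
    aggregate_gene_haplotypes,
    allele_fold_change,
    classify_expression,
    expression_class_tpm,
    filter_informative,
    gene_ase_test,
    reference_bias,
    snv_ase_test,
    subsample_robustness,
    tissue_dependence,
    tissue_enrichment,
)
from hapase.betabinom import bb_rvs


def _records(rows):
    df = pd.DataFrame(
        rows,
        columns=["animal", "tissue", "snv_id", "gene_id", "ref_count", "alt_count"],
    )
    df["total_count"] = df["ref_count"] + df["alt_count"]
    df["chrom"] = "chr1"
    df["pos"] = np.arange(1, len(df) + 1) * 100
    df["alt_on_hap1"] = pd.Series([False] * len(df), dtype=object)
    df["block_id"] = "1"
    return df


class TestInformativeFilter:
    def test_threshold_semantics(self):
        totals = [3, 9, 10, 11, 50]
        df = _records(
            [("a", "t", f"s{i}", "g", tot, 0) for i, tot in enumerate(totals)]
        )
        kept, dropped = filter_informative(df, Cfg())
        assert sorted(kept["total_count"]) == [10, 11, 50]
        assert dropped == 2

    def test_min_reads_one_is_identity(self):
        df = _records([("a", "t", "s1", "g", 1, 0), ("a", "t", "s2", "g", 0, 2)])
        kept, dropped = filter_informative(df, Cfg(min_reads=1))
        assert len(kept) == 2 and dropped == 0

    def test_matches_brute_force_on_simulated_depths(self, small_cohort):
        kept, dropped = filter_informative(small_cohort.records, Cfg())
        brute = (small_cohort.records["total_count"] >= 10).sum()
        assert len(kept) == brute
        assert dropped == len(small_cohort.records) - brute


class TestSnvTest:
    def test_balanced_site_not_significant(self):
        df = _records([("a", "t", f"s{i}", "g", 25, 25) for i in range(5)])
        res = snv_ase_test(df)
        assert (res["p_value"] > 0.5).all()
        assert not res["is_ase"].any()

    def test_monoallelic_site_extreme(self):
        rows = [("a", "t", f"s{i}", "g", 25, 25) for i in range(20)]
        rows.append(("a", "t", "mono", "g", 50, 0))
        res = snv_ase_test(_records(rows)).set_index("snv_id")
        assert res.loc["mono", "p_value"] < 1e-12
        assert res.loc["mono", "is_ase"]
        assert res.loc["mono", "expression_class"] == "monoallelic"
        assert res.loc["mono", "higher_allele"] == "ref"

    def test_bh_monotone_and_qvalue_dominates(self):
        rng = np.random.default_rng(4)
        n = np.full(300, 50)
        x = bb_rvs(n, 0.5, 0.001, rng)
        x[:20] = 48  # plant some imbalance
        df = _records(
            [("a", "t", f"s{i}", "g", xi, ni - xi) for i, (xi, ni) in enumerate(zip(x, n))]
        )
        res = snv_ase_test(df)
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()
        srt = res.sort_values("p_value")
        assert (np.diff(srt["q_value"]) >= -1e-12).all()
        assert set(res.loc[res["is_ase"], "snv_id"]) <= set(
            res.loc[res["p_value"] < 0.05, "snv_id"]
        )

    def test_ref_alt_choice_immaterial_under_symmetric_null(self):
        df = _records([("a", "t", "s1", "g", 30, 10), ("a", "t", "s2", "g", 10, 30)])
        res = snv_ase_test(df)
        assert res.loc[0, "p_value"] == pytest.approx(res.loc[1, "p_value"], abs=1e-12)

    def test_null_sample_mostly_clean_under_fdr(self):
        rng = np.random.default_rng(7)
        clean = 0
        for rep in range(20):
            n = np.full(1000, 50)
            x = bb_rvs(n, 0.5, 0.001, rng)
            df = _records(
                [
                    ("a", "t", f"s{i}", "g", xi, ni - xi)
                    for i, (xi, ni) in enumerate(zip(x, n))
                ]
            )
            res = snv_ase_test(df)
            clean += not res["is_ase"].any()
        assert clean >= 17  # BH on an all-null family rarely rejects at all


class TestGeneAggregation:
    def test_arithmetic_per_phase_rule(self):
        df = _records(
            [("a", "t", "s1", "g", 30, 10), ("a", "t", "s2", "g", 12, 28)]
        )
        df.loc[1, "alt_on_hap1"] = True  # hap1 carries alt at SNV2
        agg, excluded = aggregate_gene_haplotypes(df)
        assert excluded == 0
        assert agg.loc[0, "x"] == 30 + 28
        assert agg.loc[0, "y"] == 80
        assert agg.loc[0, "n_snvs"] == 2
        assert agg.loc[0, "single_block"]

    def test_single_snv_gene_identity_and_test_equivalence(self):
        df = _records([("a", "t", "s1", "g", 33, 11)])
        agg, _ = aggregate_gene_haplotypes(df)
        assert agg.loc[0, "x"] == 33 and agg.loc[0, "y"] == 44
        snv_p = snv_ase_test(df).loc[0, "p_value"]
        gene_p = gene_ase_test(agg).loc[0, "p_value"]
        assert gene_p == pytest.approx(snv_p, abs=1e-12)

    def test_unphased_records_excluded_with_tally(self):
        df = _records([("a", "t", "s1", "g", 30, 10), ("a", "t", "s2", "g", 12, 28)])
        df.loc[1, "alt_on_hap1"] = None
        agg, excluded = aggregate_gene_haplotypes(df)
        assert excluded == 1
        assert agg.loc[0, "y"] == 40

    def test_multi_block_flagged(self):
        df = _records([("a", "t", "s1", "g", 30, 10), ("a", "t", "s2", "g", 12, 28)])
        df.loc[1, "block_id"] = "2"
        agg, _ = aggregate_gene_haplotypes(df)
        assert not agg.loc[0, "single_block"]

    def test_planted_haplotype_fraction_recovered(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(6):
            n = 50
            x = int(bb_rvs(n, 0.8, 0.001, rng))
            rows.append(("a", "t", f"s{i}", "g", x, n - x))
        df = _records(rows)  # hap1 carries ref everywhere
        agg, _ = aggregate_gene_haplotypes(df)
        assert 0.7 <= agg.loc[0, "x"] / agg.loc[0, "y"] <= 0.9


class TestGeneTest:
    def test_exact_balance_never_significant(self):
        df = pd.DataFrame(
            {
                "animal": "a",
                "tissue": "t",
                "gene_id": [f"g{i}" for i in range(3)],
                "x": [20, 200, 2000],
                "y": [40, 400, 4000],
                "n_snvs": 1,
                "single_block": True,
            }
        )
        res = gene_ase_test(df)
        assert (res["p_value"] > 0.9).all()

    def test_planted_monoallelic_gene(self):
        df = pd.DataFrame(
            {
                "animal": "a",
                "tissue": "t",
                "gene_id": ["mono", "bal"],
                "x": [400, 200],
                "y": [400, 400],
                "n_snvs": 4,
                "single_block": True,
            }
        )
        res = gene_ase_test(df).set_index("gene_id")
        assert res.loc["mono", "q_value"] < 1e-6
        assert res.loc["mono", "expression_class"] == "monoallelic"
        assert res.loc["mono", "major_hap"] == 1
        assert res.loc["bal", "expression_class"] == "biallelic"

    def test_false_positive_rate_on_balanced_genes(self):
        rng = np.random.default_rng(21)
        reps, n_genes = 20, 500
        rates = []
        for _ in range(reps):
            y = np.full(n_genes, 300)
            x = bb_rvs(y, 0.5, 0.001, rng)
            df = pd.DataFrame(
                {
                    "animal": "a",
                    "tissue": "t",
                    "gene_id": [f"g{i}" for i in range(n_genes)],
                    "x": x,
                    "y": y,
                    "n_snvs": 1,
                    "single_block": True,
                }
            )
            res = gene_ase_test(df)
            rates.append((res["p_value"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / (reps * n_genes))
        assert np.mean(rates) <= 0.05 + 2 * se


def test_classify_expression_boundary():
    assert classify_expression(np.array([0]), np.array([37]))[0] == "monoallelic"
    assert classify_expression(np.array([1]), np.array([37]))[0] == "biallelic"


class TestReferenceBias:
    def test_exact_half(self):
        df = _records([("a", "t", f"s{i}", "g", 30, 30) for i in range(4)])
        assert reference_bias(df)["median"] == 0.5

    def test_unbiased_and_biased_simulations(self):
        rng = np.random.default_rng(3)
        for alpha, lo, hi in [(0.5, 0.48, 0.52), (0.55, 0.53, 0.57)]:
            n = np.full(10_000, 60)
            x = bb_rvs(n, alpha, 0.001, rng)
            df = _records(
                [
                    ("a", "t", f"s{i}", "g", xi, ni - xi)
                    for i, (xi, ni) in enumerate(zip(x, n))
                ]
            )
            assert lo <= reference_bias(df)["median"] <= hi

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reference_bias(_records([]).iloc[0:0])


class TestFoldChange:
    def test_arithmetic(self):
        np.testing.assert_allclose(
            allele_fold_change(np.array([40, 10]), np.array([10, 10])), [4.0, 1.0]
        )

    def test_monoallelic_infinite_and_empty_undefined(self):
        out = allele_fold_change(np.array([37, 0]), np.array([0, 0]))
        assert np.isinf(out[0]) and np.isnan(out[1])

    def test_planted_effect_mean_fold(self):
        rng = np.random.default_rng(5)
        n = np.full(4000, 100)
        x = bb_rvs(n, 0.75, 0.001, rng)
        fold = allele_fold_change(x, n - x)
        assert 2.6 <= np.nanmean(fold) <= 3.4  # 0.75/0.25 = 3


class TestSubsampling:
    def test_full_fraction_is_noop(self):
        out = subsample_robustness(90, 100, [1.0], iterations=50, seed=0)
        assert out.loc[0, "proportion_significant"] == 1.0
        out_null = subsample_robustness(50, 100, [1.0], iterations=50, seed=0)
        assert out_null.loc[0, "proportion_significant"] == 0.0

    def test_strong_effect_survives_deep_subsampling(self):
        out = subsample_robustness(900, 1000, [0.05], iterations=2000, seed=1)
        assert out.loc[0, "proportion_significant"] >= 0.95

    def test_null_type_i_preserved(self):
        out = subsample_robustness(500, 1000, [0.5, 0.1], iterations=2000, seed=2)
        assert (out["proportion_significant"] <= 0.07).all()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            subsample_robustness(10, 20, [0.0], iterations=10)


class TestTpmSummaries:
    def test_expression_classes(self):
        assert expression_class_tpm(5) == "low"
        assert expression_class_tpm(1500) == "high"
        assert expression_class_tpm(0.4) == "not-expressed"
        assert expression_class_tpm(0.5) == "not-expressed"  # detected means > 0.5
        assert expression_class_tpm(10) == "low"
        assert expression_class_tpm(1000) == "medium"
        with pytest.raises(ValueError):
            expression_class_tpm(-1)

    def test_enrichment_strict_four_fold(self):
        tissues = [f"t{i}" for i in range(10)]
        cols = [f"a1:{t}" for t in tissues]
        tpm = pd.DataFrame(
            [[100.0] + [10.0] * 9, [40.0] + [10.0] * 9, [5.0] * 10],
            index=["enriched", "boundary", "flat"],
            columns=cols,
        )
        out = tissue_enrichment(tpm)
        assert list(out["gene_id"]) == ["enriched"]
        assert list(out["tissue"]) == ["t0"]

    def test_single_tissue_rejected(self):
        tpm = pd.DataFrame({"a1:liver": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            tissue_enrichment(tpm)


class TestTissueDependence:
    def test_identical_counts_give_null(self):
        df = _records(
            [("a", t, f"s{t}{i}", "g", 10, 10) for t in ("x", "y", "z") for i in range(4)]
        )
        out = tissue_dependence(df)
        assert out.loc[0, "H"] == 0.0 and out.loc[0, "p_value"] == 1.0

    def test_planted_depth_shift_detected(self):
        rng = np.random.default_rng(8)
        rows = []
        for t in ("a", "b", "c"):
            depth = 500 if t == "a" else 50
            for i in range(12):
                n = rng.poisson(depth)
                rows.append(("an%d" % i, t, f"s{t}{i}", "g", n // 2, n - n // 2))
        out = tissue_dependence(_records(rows))
        assert out.loc[0, "p_value"] < 0.01

    def test_two_groups_reduce_to_rank_sum(self):
        rng = np.random.default_rng(12)
        ga = rng.poisson(40, 15)
        gb = rng.poisson(60, 15)
        rows = [("a", "t1", f"sa{i}", "g", v, 0) for i, v in enumerate(ga)]
        rows += [("a", "t2", f"sb{i}", "g", v, 0) for i, v in enumerate(gb)]
        df = _records(rows)
        df["total_count"] = df["ref_count"]  # totals are the grouped variable
        kw_p = tissue_dependence(df).loc[0, "p_value"]
        mw_p = mannwhitneyu(ga, gb, method="asymptotic", use_continuity=False).pvalue
        assert kw_p == pytest.approx(mw_p, rel=1e-6)
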