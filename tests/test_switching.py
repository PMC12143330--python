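"""Mixture model, canonicalization, switching calls, imprinting screen."""

import numpy as np
import pandas as pd
import pytest

from hapase.betabinom import bb_rvs
from hapase.switching import (
    call_cross_animal_switching,
    call_tissue_switching,
    canonicalize_haplotypes,
    fit_bb_mixture,
    imprinting_screen,
)


class TestMixtureFit:
    def test_null_recovers_single_component(self):
        rng = np.random.default_rng(1)
        y = np.full(8, 200)
        x = bb_rvs(y, 0.5, 0.001, rng)
        fit = fit_bb_mixture(x, y, seed=1)
        assert fit.k == 1
        assert 0.45 <= fit.alphas[0] <= 0.55
        assert fit.weights[0] == pytest.approx(1.0)

    def test_planted_two_components_recovered(self):
        rng = np.random.default_rng(2)
        y = np.full(11, 200)
        comp = np.array([0, 1] * 5 + [0])
        x = np.array(
            [int(bb_rvs(200, 0.8 if c else 0.2, 0.001, rng, size=None)) for c in comp]
        )
        fit = fit_bb_mixture(x, y, seed=2)
        assert fit.k >= 2
        assert abs(fit.alphas[0] - 0.2) <= 0.05
        assert abs(fit.alphas[-1] - 0.8) <= 0.05
        # components come out sorted by allelic ratio
        assert list(fit.alphas) == sorted(fit.alphas)
        # posterior assigns tissues to the right side
        assert (fit.posterior[comp == 1] > fit.posterior[comp == 0].max() - 1).all()

    def test_loglik_nesting_and_trail(self):
        rng = np.random.default_rng(3)
        y = np.full(9, 150)
        x = bb_rvs(y, 0.7, 0.001, rng)
        fit = fit_bb_mixture(x, y, k_max=3, seed=3)
        lls = [fit.loglik_by_k[k] for k in sorted(fit.loglik_by_k)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))
        assert all(t[3] == 2 for t in fit.lrt_trail)  # df = 2 per added component

    def test_pooled_ratio_matches_k1_alpha_at_depth(self):
        rng = np.random.default_rng(4)
        y = np.full(10, 500)
        x = bb_rvs(y, 0.65, 0.001, rng)
        fit = fit_bb_mixture(x, y, k_max=1, seed=4)
        assert fit.alphas[0] == pytest.approx(x.sum() / y.sum(), abs=0.01)

    def test_weights_sum_to_one_and_bounds(self):
        rng = np.random.default_rng(5)
        y = np.full(11, 100)
        x = bb_rvs(y, 0.8, 0.01, rng)
        fit = fit_bb_mixture(x, y, seed=5)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-8)
        assert ((fit.alphas > 0) & (fit.alphas < 1)).all()
        assert (fit.weights > 0).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_bb_mixture([10], [20])
        with pytest.raises(ValueError):
            fit_bb_mixture([10, 30], [20, 20])


class TestCanonicalization:
    @staticmethod
    def _phase(rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "animal", "snv_id", "pos", "alt_on_hap1"]
        )

    def test_anchor_orientation_rule(self):
        ph = self._phase(
            [
                ("g", "a1", "s1", 100, False),  # 0|1 at anchor -> keep
                ("g", "a2", "s1", 100, True),  # 1|0 at anchor -> flip
            ]
        )
        out = canonicalize_haplotypes(ph).set_index("animal")
        assert not out.loc["a1", "flip"]
        assert out.loc["a2", "flip"]
        assert out["comparable"].all()

    def test_transitive_fallback_through_shared_site(self):
        # a3 is not het at the anchor but shares s2 with a1
        ph = self._phase(
            [
                ("g", "a1", "s1", 100, False),
                ("g", "a2", "s1", 100, False),
                ("g", "a1", "s2", 200, True),
                ("g", "a3", "s2", 200, False),
            ]
        )
        out = canonicalize_haplotypes(ph).set_index("animal")
        # a1 unflipped: canonical hap1 carries alt at s2; a3's local hap1
        # carries ref there, so a3 must flip
        assert out.loc["a3", "flip"]
        assert out.loc["a3", "comparable"]

    def test_no_shared_site_flagged_non_comparable(self):
        ph = self._phase(
            [("g", "a1", "s1", 100, False), ("g", "a2", "s2", 200, False)]
        )
        out = canonicalize_haplotypes(ph)
        assert not out["comparable"].any()

    def test_generator_truth_recovered(self, small_cohort):
        recs = small_cohort.records
        ph = recs.dropna(subset=["alt_on_hap1"])[
            ["gene_id", "animal", "snv_id", "pos", "alt_on_hap1"]
        ].drop_duplicates(["gene_id", "animal", "snv_id"])
        out = canonicalize_haplotypes(ph)
        truth = small_cohort.truth.animal_gene.set_index(["gene_id", "animal"])
        ok = total = 0
        for row in out[out["comparable"]].itertuples(index=False):
            a_on_hap1 = truth.loc[(row.gene_id, row.animal), "a_on_hap1"]
            # founder B carries ref everywhere; canonical hap1 = ref at anchor
            # = founder B, so flip must equal "founder A on local hap1"
            ok += row.flip == bool(a_on_hap1)
            total += 1
        assert total > 0 and ok == total


class TestSwitchCalls:
    @staticmethod
    def _fits(rows):
        return pd.DataFrame(
            rows, columns=["animal", "gene_id", "k", "alphas", "weights", "n_tissues"]
        )

    def test_same_side_components_consistent(self):
        out = call_tissue_switching(
            self._fits([("a", "g", 2, [0.7, 0.9], [0.5, 0.5], 11)])
        )
        assert out.loc[0, "consistent"] and not out.loc[0, "switching"]

    def test_opposite_sides_switching(self):
        out = call_tissue_switching(
            self._fits([("a", "g", 2, [0.2, 0.8], [0.27, 0.73], 11)])
        )
        assert out.loc[0, "switching"] and not out.loc[0, "consistent"]

    def test_tiny_weight_component_ignored(self):
        out = call_tissue_switching(
            self._fits([("a", "g", 2, [0.2, 0.8], [0.02, 0.98], 11)])
        )
        assert not out.loc[0, "switching"]  # weight below 1/(2N)

    def test_band_component_neither(self):
        out = call_tissue_switching(
            self._fits([("a", "g", 2, [0.45, 0.8], [0.5, 0.5], 11)])
        )
        assert not out.loc[0, "switching"]
        assert not out.loc[0, "consistent"]  # sides of 0.5 differ


class TestCrossAnimal:
    @staticmethod
    def _gene_results(major_by_animal, tissue="liver", gene="g"):
        return pd.DataFrame(
            {
                "animal": list(major_by_animal),
                "tissue": tissue,
                "gene_id": gene,
                "is_ase": True,
                "major_hap": list(major_by_animal.values()),
            }
        )

    @staticmethod
    def _canonical(animals, gene="g"):
        return pd.DataFrame(
            {"gene_id": gene, "animal": animals, "flip": False, "comparable": True}
        )

    def test_balanced_split_flagged(self):
        majors = {f"a{i}": (1 if i < 4 else 2) for i in range(8)}
        out = call_cross_animal_switching(
            self._gene_results(majors), self._canonical(list(majors))
        )
        assert out.loc[0, "switching"]
        assert out.loc[0, "n_hap1_major"] == 4 and out.loc[0, "n_hap2_major"] == 4

    def test_unanimous_not_flagged(self):
        majors = {f"a{i}": 1 for i in range(6)}
        out = call_cross_animal_switching(
            self._gene_results(majors), self._canonical(list(majors))
        )
        assert not out.loc[0, "switching"]

    def test_one_vs_five_below_threshold(self):
        majors = {f"a{i}": (2 if i == 0 else 1) for i in range(6)}
        out = call_cross_animal_switching(
            self._gene_results(majors), self._canonical(list(majors))
        )
        assert not out.loc[0, "switching"]

    def test_flip_applied_before_counting(self):
        majors = {"a0": 1, "a1": 1, "a2": 2, "a3": 2}
        canon = self._canonical(list(majors))
        canon.loc[canon["animal"].isin(["a2", "a3"]), "flip"] = True
        out = call_cross_animal_switching(self._gene_results(majors), canon)
        # after flipping a2/a3 their major becomes hap1 too: unanimous
        assert not out.loc[0, "switching"]


class TestImprintingScreen:
    @staticmethod
    def _snv_results(gene, n_ase):
        return pd.DataFrame(
            {
                "animal": "a1",
                "tissue": "t1",
                "gene_id": gene,
                "snv_id": [f"{gene}:s{i}" for i in range(n_ase)],
                "is_ase": True,
            }
        )

    @staticmethod
    def _gene_results(rows):
        return pd.DataFrame(
            rows,
            columns=["animal", "tissue", "gene_id", "x", "y", "is_ase", "single_block"],
        )

    @staticmethod
    def _canonical(animals, gene):
        return pd.DataFrame(
            {"gene_id": gene, "animal": animals, "flip": False, "comparable": True}
        )

    def test_fully_monoallelic_gene_is_tier2(self):
        gr = self._gene_results(
            [
                ("a1", t, "g", 100, 100, True, True)
                for t in ("t1", "t2", "t3")
            ]
            + [("a2", t, "g", 120, 120, True, True) for t in ("t1", "t2")]
        )
        out = imprinting_screen(
            self._snv_results("g", 4), gr, self._canonical(["a1", "a2"], "g"), {"g"}
        )
        assert len(out) == 1
        assert out.loc[0, "tier"] == "all-sample-consistent"
        assert out.loc[0, "known_imprinted"]

    def test_one_biallelic_ase_sample_excludes(self):
        gr = self._gene_results(
            [("a1", "t1", "g", 100, 100, True, True), ("a1", "t2", "g", 90, 100, True, True)]
        )
        out = imprinting_screen(
            self._snv_results("g", 4), gr, self._canonical(["a1"], "g")
        )
        assert out.empty

    def test_snrpn_like_split_is_tier1_only(self):
        # two animals express opposite canonical haplotypes, each consistent
        gr = self._gene_results(
            [("a1", t, "g", 100, 100, True, True) for t in ("t1", "t2")]
            + [("a2", t, "g", 0, 110, True, True) for t in ("t1", "t2")]
        )
        out = imprinting_screen(
            self._snv_results("g", 5), gr, self._canonical(["a1", "a2"], "g")
        )
        assert len(out) == 1
        assert out.loc[0, "tier"] == "within-animal-consistent"

    def test_too_few_ase_snvs_excluded(self):
        gr = self._gene_results([("a1", "t1", "g", 100, 100, True, True)])
        out = imprinting_screen(
            self._snv_results("g", 3), gr, self._canonical(["a1"], "g")
        )
        assert out.empty

    def test_multi_block_gene_excluded(self):
        gr = self._gene_results([("a1", "t1", "g", 100, 100, True, False)])
        out = imprinting_screen(
            self._snv_results("g", 6), gr, self._canonical(["a1"], "g")
        )
        assert out.empty
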