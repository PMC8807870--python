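"""Exact tests, BH control, SNP enrichment, rank tests, logistic fit,
ICC variance components, and heritability-annotation preparation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from crhnet.intervals import GenomicInterval
from crhnet.stats import (
    bh_adjust,
    bh_select,
    fisher_exact_2x2,
    icc_fit,
    logistic_fit,
    prepare_ldsc_annotation,
    rank_tests,
    relative_fold,
    snp_fold_enrichment,
    snp_threshold_enrichment,
    snps_in_intervals,
    spearman,
    stratify_crhs,
)


def fisher_p_oracle(a, b, c, d, slack=1e-7):
    """Independent full hypergeometric enumeration (log-gamma arithmetic)."""
    N, r, k = a + b + c + d, a + b, a + c
    lo, hi = max(0, r + k - N), min(r, k)
    xs = np.arange(lo, hi + 1)

    def lchoose(n, x):
        return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)

    p = np.exp(lchoose(r, xs) + lchoose(N - r, k - xs) - lchoose(N, k))
    return float(p[p <= p[a - lo] * (1 + slack)].sum())


class TestFisher:
    def test_worked_example_2112(self):
        res = fisher_exact_2x2(2, 1, 1, 2)
        assert res.odds_ratio == pytest.approx(4.0)
        assert res.p_two_sided == pytest.approx(1.0)
        assert not res.corrected

    def test_worked_example_5005(self):
        res = fisher_exact_2x2(5, 0, 0, 5)
        assert res.p_two_sided == pytest.approx(2 / 252)
        assert res.corrected
        assert res.odds_ratio == pytest.approx(121.0)  # (5.5*5.5)/(0.5*0.5)

    def test_symmetric_table(self):
        res = fisher_exact_2x2(3, 3, 3, 3)
        assert res.odds_ratio == 1.0 and res.p_two_sided == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(0, 0, 3, 4)

    def test_ci_brackets_estimate(self):
        res = fisher_exact_2x2(12, 5, 7, 20)
        assert res.ci95[0] <= res.odds_ratio <= res.ci95[1]

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        res = fisher_exact_2x2(a, b, c, d)
        assert res.p_two_sided == pytest.approx(fisher_p_oracle(a, b, c, d), abs=1e-10)


class TestBH:
    def test_stepup_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.5], [-0.2]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, size=200)
        adj = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        # naive O(m^2): adj_(i) = min over j >= i of p_(j) * m / (j+1)
        naive = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            naive[i] = min(
                min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
            )
        expect = np.empty(m)
        expect[order] = naive
        assert np.allclose(adj, expect)
        assert np.all(adj >= p - 1e-15)

    def test_select_threshold(self):
        mask = bh_select([1e-6, 0.5, 1e-5], threshold=0.05)
        assert list(mask) == [True, False, True]


def snp_frame(chroms, positions, pvalues):
    return pd.DataFrame(
        {
            "snp_id": [f"rs{k}" for k in range(len(positions))],
            "chrom": chroms,
            "pos": positions,
            "pvalue": pvalues,
        }
    )


class TestSnpEnrichment:
    def test_boundary_base_half_open(self):
        ivs = [GenomicInterval("chr1", 100, 200)]
        snps = snp_frame(["chr1"] * 3, [100, 199, 200], [0.5] * 3)
        assert list(snps_in_intervals(snps, ivs)) == [True, True, False]

    def test_identical_fractions_or_near_one(self):
        a = [GenomicInterval("chr1", 0, 1000)]
        b = [GenomicInterval("chr1", 10_000, 11_000)]
        pos = list(range(0, 1000, 10)) + list(range(10_000, 11_000, 10))
        pv = ([0.01] * 50 + [0.5] * 50) * 2
        snps = snp_frame(["chr1"] * 200, pos, pv)
        res = snp_threshold_enrichment(snps, a, b, 0.05)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_no_snp_in_annotations_rejected(self):
        a = [GenomicInterval("chr1", 0, 10)]
        b = [GenomicInterval("chr1", 50, 60)]
        snps = snp_frame(["chr1"], [1000], [0.5])
        with pytest.raises(ValueError, match="no SNP"):
            snp_threshold_enrichment(snps, a, b, 0.05)

    def test_planted_enrichment_detected(self):
        # 3x significant fraction inside A; detected in >= 90% of 50 seeds
        a = [GenomicInterval("chr1", 0, 1000)]
        b = [GenomicInterval("chr1", 10_000, 11_000)]
        detected = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pos = list(rng.integers(0, 1000, 400)) + list(
                rng.integers(10_000, 11_000, 400)
            )
            pv = np.concatenate(
                [
                    np.where(rng.uniform(size=400) < 0.30, rng.uniform(0, 0.05, 400),
                             rng.uniform(0.05, 1, 400)),
                    np.where(rng.uniform(size=400) < 0.10, rng.uniform(0, 0.05, 400),
                             rng.uniform(0.05, 1, 400)),
                ]
            )
            snps = snp_frame(["chr1"] * 800, pos, pv)
            res = snp_threshold_enrichment(snps, a, b, 0.05)
            if res.odds_ratio > 1 and res.p_two_sided < 0.05:
                detected += 1
        assert detected >= 45

    def test_genome_comparator(self):
        a = [GenomicInterval("chr1", 0, 1000)]
        snps = snp_frame(
            ["chr1"] * 100, list(range(0, 2000, 20)), [0.01] * 50 + [0.9] * 50
        )
        res = snp_threshold_enrichment(snps, a, None, 0.05, comparator="genome")
        assert res.table[0] + res.table[1] == 50  # SNPs inside A


class TestFoldEnrichment:
    def test_arithmetic(self):
        # 10/50 significant SNPs inside; 100/1000 SNPs inside -> fold 2.0
        ivs = [GenomicInterval("chr1", 0, 1000)]
        n_in, n_out = 100, 900
        pos = list(range(0, 1000, 10)) + list(range(5000, 14_000, 10))
        sig = [0.01] * 10 + [0.9] * 90 + [0.01] * 40 + [0.9] * 860
        snps = snp_frame(["chr1"] * (n_in + n_out), pos, sig)
        fold = snp_fold_enrichment(snps, ivs, 0.05)
        assert fold == pytest.approx((10 / 50) / (100 / 1000))

    def test_whole_genome_identity(self):
        ivs = [GenomicInterval("chr1", 0, 10_000)]
        snps = snp_frame(["chr1"] * 100, list(range(0, 1000, 10)),
                         list(np.linspace(0.001, 0.999, 100)))
        assert snp_fold_enrichment(snps, ivs, 0.05) == pytest.approx(1.0)

    def test_duplication_invariance(self):
        ivs = [GenomicInterval("chr1", 0, 500)]
        snps = snp_frame(["chr1"] * 40, list(range(0, 2000, 50)),
                         [0.01] * 10 + [0.5] * 30)
        doubled = pd.concat([snps, snps], ignore_index=True)
        assert snp_fold_enrichment(snps, ivs, 0.05) == pytest.approx(
            snp_fold_enrichment(doubled, ivs, 0.05)
        )

    def test_null_annotation_unbiased(self):
        # random annotation: mean fold over 100 seeds within 3 SE of 1.0
        folds = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ivs = [GenomicInterval("chr1", int(s), int(s) + 500)
                   for s in rng.integers(0, 99_000, 20)]
            snps = snp_frame(
                ["chr1"] * 2000, rng.integers(0, 100_000, 2000), rng.uniform(size=2000)
            )
            try:
                folds.append(snp_fold_enrichment(snps, ivs, 0.05))
            except ValueError:
                continue
        folds = np.array(folds)
        se = folds.std(ddof=1) / math.sqrt(len(folds))
        assert abs(folds.mean() - 1.0) <= 3 * se


class TestRankTests:
    def test_spearman_monotone(self):
        x = [1, 5, 9, 12, 30]
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_rank_sum_identical_samples(self):
        _, p = rank_tests([1, 2, 3, 4], [1, 2, 3, 4], mode="rank_sum")
        assert p == pytest.approx(1.0)

    def test_exact_matches_permutation_oracle(self):
        from itertools import combinations

        x = [1.2, 3.4, 0.5, 7.7, 2.2]
        y = [4.1, 5.5, 6.0, 0.1, 9.9]
        stat, p = rank_tests(x, y, mode="rank_sum")
        pooled = np.array(x + y)
        ranks = pooled.argsort().argsort() + 1
        obs = ranks[:5].sum()
        null = [sum(c) for c in combinations(ranks, 5)]
        mean_null = np.mean(null)
        extreme = np.mean(
            [abs(v - mean_null) >= abs(obs - mean_null) - 1e-9 for v in null]
        )
        assert p == pytest.approx(extreme, abs=1e-9)

    def test_signed_rank_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rank_tests([1, 2, 3], [1, 2, 3], mode="signed_rank")

    def test_signed_rank_paired_lengths(self):
        with pytest.raises(ValueError, match="paired"):
            rank_tests([1, 2, 3], [1, 2], mode="signed_rank")


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = [1] * 25 + [0] * 75
        genes = pd.DataFrame({"scz_associated": y})
        out = logistic_fit(genes, covariates=[])
        const = out.loc[out["term"] == "const", "coef"].iloc[0]
        assert const == pytest.approx(math.log(1 / 3), abs=1e-6)

    def test_duplication_same_estimates_smaller_ci(self, rng):
        n = 400
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        y = rng.uniform(size=n) < p
        genes = pd.DataFrame({"scz_associated": y, "x": x})
        one = logistic_fit(genes, covariates=["x"])
        two = logistic_fit(pd.concat([genes, genes], ignore_index=True),
                           covariates=["x"])
        assert np.allclose(one["coef"], two["coef"], atol=1e-6)
        w1 = one["ci_high"] - one["ci_low"]
        w2 = two["ci_high"] - two["ci_low"]
        assert (w2 < w1).all()

    def test_constant_covariate_rejected(self):
        genes = pd.DataFrame({"scz_associated": [0, 1, 0, 1], "x": [2, 2, 2, 2]})
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(genes, covariates=["x"])

    def test_perfect_separation_rejected(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        genes = pd.DataFrame({"scz_associated": x.astype(int), "x": x})
        with pytest.raises(ValueError, match="separation|penaliz"):
            logistic_fit(genes, covariates=["x"])

    def test_p90_indicator_derived_when_missing(self, rng):
        n = 600
        prop = rng.uniform(size=n)
        y = rng.uniform(size=n) < 0.3
        genes = pd.DataFrame(
            {
                "scz_associated": y,
                "rna_level": rng.normal(size=n),
                "n_connections": rng.integers(0, 6, n),
                "prop_active_distal": prop,
                "monogamous": rng.uniform(size=n) < 0.2,
            }
        )
        out = logistic_fit(genes)
        assert "prop_active_distal_p90_indicator" in set(out["term"])


class TestICC:
    def test_equal_group_means_zero_icc(self):
        values = [1.0, -1.0, 2.0, -2.0, 0.5, -0.5]
        groups = ["a", "a", "b", "b", "c", "c"]  # all means 0
        res = icc_fit(values, groups)
        assert res.icc == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            icc_fit([1, 2, 3], ["a", "a", "a"])

    def test_recovers_planted_icc(self):
        rng = np.random.default_rng(42)
        k, n = 200, 10
        sb, sw = 1.0, 3.0  # icc = 0.25
        y, g = [], []
        for j in range(k):
            b = rng.normal(0, math.sqrt(sb))
            y.extend(b + rng.normal(0, math.sqrt(sw), n))
            g.extend([j] * n)
        res = icc_fit(y, g)
        assert res.icc == pytest.approx(0.25, abs=0.05)

    def test_unbalanced_groups_still_recover(self):
        rng = np.random.default_rng(7)
        y, g = [], []
        for j in range(150):
            n = int(rng.integers(2, 15))
            b = rng.normal(0, 1.0)
            y.extend(b + rng.normal(0, math.sqrt(3.0), n))
            g.extend([j] * n)
        res = icc_fit(y, g)
        assert res.icc == pytest.approx(0.25, abs=0.07)


class TestStrata:
    def test_boundaries_as_printed(self):
        class FakeCRH:
            def __init__(self, n):
                self.n_promoters = n

        strata = stratify_crhs([FakeCRH(n) for n in [1, 3, 4, 25, 26, 100]])
        assert [c.n_promoters for c in strata["small"]] == [1, 3]
        assert [c.n_promoters for c in strata["medium"]] == [4, 25]
        assert [c.n_promoters for c in strata["large"]] == [26, 100]


class TestLdscAnnotation:
    def test_extension_window(self):
        ivs = [GenomicInterval("chr1", 10_000, 10_500)]
        snps = snp_frame(["chr1"] * 3, [9600, 9499, 10_999], [0.5] * 3)
        annot, merged = prepare_ldsc_annotation(ivs, snps, extend=500)
        # 400 bp upstream -> inside; 501 bp upstream -> outside; end+499 inside
        assert list(annot["ANNOT"]) == [1, 0, 1]

    def test_merged_covers_at_least_raw(self):
        ivs = [GenomicInterval("chr1", 1000, 1400),
               GenomicInterval("chr1", 1600, 2000)]
        snps = snp_frame(["chr1"], [0], [0.5])
        _, merged = prepare_ldsc_annotation(ivs, snps, extend=500)
        assert sum(iv.width for iv in merged) >= sum(iv.width for iv in ivs)
        assert len(merged) == 1  # the extension bridges the 200 bp gap
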