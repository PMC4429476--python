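"""QC thresholds, HWE exact test, tiers, association tests, reporting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import gammaln

from fpescan.assoc import (
    QcThresholds,
    TierSpec,
    additive_test,
    apply_qc,
    bonferroni_correct,
    dominant_test,
    genomic_inflation,
    hwe_exact_test,
    redefine_status_by_srs,
    run_association,
    select_tier,
    top_k_report,
)
from fpescan.genotypes import (
    GenotypeMatrix,
    SnpPanelSpec,
    simulate_cohort,
    simulate_null_genotypes,
)


def hwe_oracle(n_hom1, n_het, n_hom2):
    """Log-factorial enumeration of the conditional heterozygote law."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0
    hs = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hs) // 2
    common_hom = n - hs - rare_hom
    logp = (
        hs * math.log(2.0)
        - gammaln(rare_hom + 1)
        - gammaln(hs + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.flatnonzero(hs == n_het)[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


class TestHweExactTest:
    def test_equals_enumeration_oracle_for_all_tables_up_to_200(self):
        """Exhaustive sweep: every table with n <= 200 via its (n, rare, het) key.

        A table is determined by total n, rare-allele count and heterozygote
        count; for each (n, rare) the oracle law is computed once and the
        p-values of all admissible heterozygote counts are compared in one
        vectorised pass, with the public function spot-called per key.
        """
        from fpescan.assoc import _hwe_het_distribution

        def pvals(probs):
            order = np.argsort(probs, kind="stable")
            cum = np.cumsum(probs[order])
            idx = np.searchsorted(
                probs[order], probs * (1 + 1e-12), side="right"
            )
            return np.minimum(1.0, cum[idx - 1])

        spot = 0
        for n in range(1, 201):
            for n_rare in range(1, n + 1):
                hs = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
                mine = _hwe_het_distribution(n, n_rare)
                rare_hom = (n_rare - hs) // 2
                common_hom = n - hs - rare_hom
                logp = (
                    hs * math.log(2.0)
                    - gammaln(rare_hom + 1)
                    - gammaln(hs + 1)
                    - gammaln(common_hom + 1)
                )
                ref = np.exp(logp - logp.max())
                ref /= ref.sum()
                assert np.allclose(mine, ref, atol=1e-12), (n, n_rare)
                assert np.allclose(pvals(mine), pvals(ref), atol=1e-9)
                # exercise the public entry point on a rotating het choice
                h = int(hs[(n + n_rare) % len(hs)])
                rh, ch = (n_rare - h) // 2, n - h - (n_rare - h) // 2
                assert hwe_exact_test(ch, h, rh) == pytest.approx(
                    hwe_oracle(ch, h, rh), abs=1e-9
                )
                spot += 1
        assert spot > 20_000  # the sweep really covered the space

    def test_balanced_table_is_modal(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(hwe_oracle(25, 50, 25))
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_maximal_het_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-4

    def test_monomorphic(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            hwe_exact_test(0, 0, 0)


class TestApplyQc:
    def test_clean_matrix_is_identity(self, discovery_cohort):
        panel = SnpPanelSpec(n_tier1=0, n_chrx_other=0, n_autosomal=300,
                             maf_range=(0.2, 0.5), seed=21)
        g = simulate_null_genotypes(panel, discovery_cohort)
        clean, report = apply_qc(g)
        assert clean.n_snps == g.n_snps - report.snps_removed_hwe
        assert report.snps_removed_maf == 0
        assert report.snps_removed_missingness == 0

    def test_rare_snp_removed_by_maf(self, discovery_cohort):
        panel = SnpPanelSpec(n_tier1=0, n_chrx_other=0, n_autosomal=5,
                             maf_range=(0.3, 0.4), seed=22)
        g = simulate_null_genotypes(panel, discovery_cohort)
        g.dosage[:, 2] = 2
        g.dosage[0, 2] = 1  # MAF ~ 0.0014
        clean, report = apply_qc(g)
        assert report.snps_removed_maf == 1
        assert "rs70002" not in clean.snps["snp_id"].tolist()

    def test_high_missingness_removes_all(self, discovery_cohort):
        panel = SnpPanelSpec(n_tier1=0, n_chrx_other=0, n_autosomal=200,
                             missing_rate=0.35, seed=23)
        g = simulate_null_genotypes(panel, discovery_cohort)
        # at 35% missingness every SNP fails the 10% cap; samples fail first
        clean, report = apply_qc(g)
        assert clean.n_snps == 0
        assert report.n_snps_out == 0

    def test_moderate_missingness_tail(self, discovery_cohort):
        """Removal count matches the binomial tail P(miss > 0.1) within 3 SE."""
        thresholds = QcThresholds(sample_call_rate_min=0.0)
        panel = SnpPanelSpec(n_tier1=0, n_chrx_other=0, n_autosomal=2000,
                             missing_rate=0.08, seed=24)
        g = simulate_null_genotypes(panel, discovery_cohort)
        clean, report = apply_qc(g, thresholds)
        n = g.n_individuals
        tail = stats.binom.sf(int(0.1 * n), n, 0.08)
        se = math.sqrt(2000 * tail * (1 - tail))
        assert abs(report.snps_removed_missingness - 2000 * tail) <= 3 * se + 2

    def test_sample_call_rate_filter(self, discovery_cohort):
        panel = SnpPanelSpec(n_tier1=0, n_chrx_other=0, n_autosomal=100, seed=25)
        g = simulate_null_genotypes(panel, discovery_cohort)
        g.dosage[3, :20] = -1  # 20% missing for one sample
        clean, report = apply_qc(g)
        assert report.samples_removed_call_rate == 1
        assert clean.n_individuals == g.n_individuals - 1


class TestSelectTier:
    ESC = (("X", 50, 150),)
    YHOM = (("X", 90, 110),)

    def _snps(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])

    def test_escape_snp_in_tier1(self):
        snps = self._snps([("a", "X", 101)])  # 0-based 100, inside [50,150)
        spec = TierSpec(1, self.ESC, ())
        assert select_tier(snps, spec).tolist() == [True]

    def test_y_homology_excluded_from_tier1_kept_in_tier2(self):
        snps = self._snps([("a", "X", 101)])  # falls in Y-homology [90,110)
        assert select_tier(snps, TierSpec(1, self.ESC, self.YHOM)).tolist() == [False]
        assert select_tier(snps, TierSpec(2)).tolist() == [True]

    def test_brute_force_interval_scan(self):
        rng = np.random.default_rng(31)
        pos = np.sort(rng.choice(1000, size=20, replace=False)) + 1
        snps = self._snps([(f"s{i}", "X", int(p)) for i, p in enumerate(pos)])
        esc = (("X", 100, 300), ("X", 500, 520), ("X", 900, 980))
        spec = TierSpec(1, esc, ())
        mask = select_tier(snps, spec)
        brute = [
            any(s <= p - 1 < e for _, s, e in esc) for p in pos
        ]
        assert mask.tolist() == brute

    def test_tier_nesting(self):
        rng = np.random.default_rng(32)
        rows = []
        for i in range(50):
            chrom = "X" if i % 2 else "7"
            rows.append((f"s{i}", chrom, int(rng.integers(1, 10_000))))
        snps = self._snps(rows).sort_values(["chrom", "pos"]).drop_duplicates(
            ["chrom", "pos"]
        )
        esc = (("X", 0, 5_000),)
        t1 = select_tier(snps, TierSpec(1, esc, ()))
        t2 = select_tier(snps, TierSpec(2))
        t3 = select_tier(snps, TierSpec(3))
        assert (t1 <= t2).all() and (t2 <= t3).all()

    def test_unknown_chromosome_only_in_tier3(self):
        snps = self._snps([("a", "scaffold_17", 5)])
        assert not select_tier(snps, TierSpec(2)).any()
        assert select_tier(snps, TierSpec(3)).all()


class TestDominant:
    def test_odds_ratio_arithmetic(self):
        # 10 carriers / 10 non among affected; 5 / 20 among unaffected
        dosage = np.array([1] * 10 + [0] * 10 + [1] * 5 + [0] * 20, dtype=np.int8)
        affected = np.array([True] * 20 + [False] * 25)
        res = dominant_test(dosage, affected)
        assert res["OR"] == pytest.approx(4.0)

    def test_equal_proportions_null(self):
        dosage = np.array([2, 0] * 20, dtype=np.int8)
        affected = np.array([True, True, False, False] * 10)
        res = dominant_test(dosage, affected)
        assert res["OR"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_haldane_correction_on_empty_cell(self):
        dosage = np.array([1] * 10 + [0] * 10, dtype=np.int8)
        affected = np.array([True] * 10 + [False] * 10)
        res = dominant_test(dosage, affected)
        assert np.isfinite(res["OR"]) and res["OR"] > 100

    def test_group_without_data_rejected(self):
        dosage = np.array([1, 1, -1], dtype=np.int8)
        affected = np.array([True, True, False])
        with pytest.raises(ValueError, match="no observed"):
            dominant_test(dosage, affected)


class TestAdditive:
    def test_all_heterozygous_is_null(self):
        dosage = np.ones(40, dtype=np.int8)
        affected = np.array([True, False] * 20)
        res = additive_test(dosage, affected)
        assert res["p"] == pytest.approx(1.0)

    def test_perfect_separation(self):
        dosage = np.array([2] * 30 + [0] * 30, dtype=np.int8)
        affected = np.array([True] * 30 + [False] * 30)
        assert additive_test(dosage, affected)["p"] < 1e-10

    def test_power_matches_analytic_trend_power(self):
        """Empirical rejection rate vs the analytic normal approximation."""
        rng = np.random.default_rng(33)
        n, alpha = 200, 0.05
        p_case, p_ctrl = 0.6, 0.4
        hits = 0
        reps = 400
        for _ in range(reps):
            d_case = rng.binomial(2, p_case, size=n).astype(np.int8)
            d_ctrl = rng.binomial(2, p_ctrl, size=n).astype(np.int8)
            dosage = np.concatenate([d_case, d_ctrl])
            affected = np.array([True] * n + [False] * n)
            hits += additive_test(dosage, affected)["p"] <= alpha
        # analytic: z-test on allele frequencies (HWE dosages)
        pbar = (p_case + p_ctrl) / 2
        se0 = math.sqrt(2 * pbar * (1 - pbar) * 2 / (2 * n))
        se1 = math.sqrt(
            2 * p_case * (1 - p_case) / (2 * n) + 2 * p_ctrl * (1 - p_ctrl) / (2 * n)
        )
        z_crit = stats.norm.isf(alpha / 2)
        analytic = stats.norm.sf((z_crit * se0 - (p_case - p_ctrl)) / se1)
        se_mc = math.sqrt(analytic * (1 - analytic) / reps)
        assert abs(hits / reps - analytic) <= 3 * se_mc + 0.01


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected", [(0.005, 451, 1.0), (1e-10, 451, 4.51e-8), (0.123, 1, 0.123)]
    )
    def test_values(self, p, m, expected):
        assert bonferroni_correct(p, m) == pytest.approx(expected)

    @given(p=st.floats(0, 1), m=st.integers(1, 10**6))
    def test_capped_and_monotone(self, p, m):
        out = bonferroni_correct(p, m)
        assert 0.0 <= out <= 1.0
        assert out >= p


class TestRedefineStatus:
    def test_threshold_below_minimum_marks_all_affected(self):
        cohort = simulate_cohort(20, 30, seed=41)
        out = redefine_status_by_srs(cohort, "threshold", cutoff=-1e9)
        assert out.affected.all()

    def test_extremes_keep_half_each_group(self):
        cohort = simulate_cohort(40, 40, seed=42)
        out = redefine_status_by_srs(cohort, "extremes", quantile=0.5)
        assert int(out.affected.sum()) == 20
        assert int((~out.affected).sum()) == 20

    def test_threshold_at_antimode_recovers_components(self):
        """A 4.5-SD mixture split at the antimode relabels at the rate set
        by the component tails: each side misclassifies with probability
        Phi(-2.25), so expected agreement is 98.78%."""
        cohort = simulate_cohort(2000, 2000, seed=43)
        out = redefine_status_by_srs(cohort, "threshold", cutoff=60.0)
        orig = cohort.table.set_index("id")["affected"]
        relabelled = out.table.set_index("id")["affected"]
        agreement = (orig.loc[relabelled.index] == relabelled).mean()
        expected = 1.0 - stats.norm.cdf(-2.25)
        se = math.sqrt(expected * (1 - expected) / 4000)
        assert abs(agreement - expected) <= 3 * se

    def test_missing_srs_dropped_and_counted(self):
        cohort = simulate_cohort(10, 10, seed=44)
        cohort.table.loc[0, "srs"] = np.nan
        out = redefine_status_by_srs(cohort, "threshold", cutoff=50.0)
        assert len(out) == 19
        assert out.table.attrs["n_dropped_missing_srs"] == 1


class TestGenomicInflation:
    def test_uniform_null(self):
        rng = np.random.default_rng(51)
        lam = genomic_inflation(rng.random(100_000))
        assert lam == pytest.approx(1.0, abs=0.01)

    def test_point_mass_at_half_is_unity(self):
        assert genomic_inflation(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_doubled_statistics_double_lambda(self):
        rng = np.random.default_rng(52)
        chi = stats.chi2.rvs(1, size=5000, random_state=rng)
        lam = genomic_inflation(stats.chi2.sf(2 * chi, 1))
        assert lam == pytest.approx(2.0, rel=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.full(200, 0.0))
        with pytest.raises(ValueError):
            genomic_inflation([0.5] * 50)


class TestTopK:
    def _results(self, ps):
        return pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(len(ps))],
                "p": ps,
                "p_corrected": np.minimum(1.0, np.asarray(ps) * len(ps)),
            }
        )

    def test_ordering(self):
        out = top_k_report(self._results([0.2, 0.005, 0.05]), k=2)
        assert out["p"].tolist() == [0.005, 0.05]

    def test_k_larger_than_table(self):
        out = top_k_report(self._results([0.4, 0.1]), k=10)
        assert len(out) == 2

    def test_tie_break_by_snp_id(self):
        out = top_k_report(self._results([0.05, 0.05, 0.05]), k=3)
        assert out["snp"].tolist() == ["rs0", "rs1", "rs2"]


def test_run_association_dominant_uniformity(discovery_cohort):
    """End-to-end null scan: corrected p never significant, lambda sane."""
    panel = SnpPanelSpec(n_tier1=0, n_chrx_other=0, n_autosomal=500, seed=61)
    g = simulate_null_genotypes(panel, discovery_cohort)
    res = run_association(g, discovery_cohort, TierSpec(3), method="chi2")
    assert res.attrs["n_tests"] == 500
    lam = genomic_inflation(res["p"].clip(lower=1e-12))
    assert 0.7 < lam < 1.3
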