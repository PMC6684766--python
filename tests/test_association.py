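"""Odds ratios, exact tests, multiple-testing control, usage comparisons."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from tcrpair.association import (
    AssociationResult,
    FeatureCount,
    aa_usage_ratio_test,
    association_scan,
    enumerate_features,
    exact_two_sided_p,
    odds_ratio,
    scan_to_frame,
    storey_qvalues,
    strength_comparison,
)
from tcrpair.core import Lineage, Scope, deduplicate

from conftest import make_cell


def brute_force_p(a, b, c, d):
    """Exact two-sided Fisher p as a Fraction, by direct enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [Fraction(math.comb(r1, k) * math.comb(r2, c1 - k),
                      math.comb(n, c1)) for k in range(lo, hi + 1)]
    obs = probs[a - lo]
    return sum(p for p in probs if p <= obs)


class TestExactTwoSidedP:
    def test_small_table_oracle(self):
        # table (3,1,1,3): p = 2 * [C(4,3)C(4,1) + C(4,4)C(4,0)] / C(8,4)
        assert exact_two_sided_p(3, 1, 1, 3) == pytest.approx(34 / 70)

    def test_balanced_table_is_one(self):
        assert exact_two_sided_p(5, 5, 5, 5) == 1.0

    @pytest.mark.parametrize("table", [
        (0, 10, 10, 0), (1, 9, 9, 1), (7, 3, 2, 8), (12, 0, 3, 9),
        (2, 2, 2, 2), (20, 5, 5, 20), (1, 0, 0, 1),
    ])
    def test_matches_brute_force_oracle(self, table):
        assert exact_two_sided_p(*table) == pytest.approx(
            float(brute_force_p(*table)), abs=1e-12)

    def test_large_table_float_path_agrees_with_scipy(self):
        from scipy.stats import fisher_exact

        table = (150, 350, 120, 380)  # N > 400 -> float enumeration
        assert exact_two_sided_p(*table) == pytest.approx(
            fisher_exact([[150, 350], [120, 380]]).pvalue, rel=1e-9)

    def test_row_swap_invariance(self):
        assert exact_two_sided_p(7, 3, 2, 8) == pytest.approx(
            exact_two_sided_p(2, 8, 7, 3), abs=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            exact_two_sided_p(0, 0, 3, 4)


class TestOddsRatio:
    def test_worked_example(self):
        res = odds_ratio(FeatureCount("TRAV1", 20, 80, 10, 90))
        assert res.odds_ratio == pytest.approx(2.25)
        assert res.ci_low < 2.25 < res.ci_high
        assert 0 < res.p <= 1

    def test_null_table(self):
        res = odds_ratio(FeatureCount("x", 50, 50, 50, 50))
        assert res.odds_ratio == 1.0 and res.p == 1.0

    def test_zero_cell_gives_infinite_or_finite_ci(self):
        res = odds_ratio(FeatureCount("x", 5, 10, 0, 15))
        assert res.odds_ratio == math.inf
        assert np.isfinite(res.ci_low) and np.isfinite(res.ci_high)
        assert res.log_or == math.inf

    def test_antisymmetry_under_lineage_swap(self):
        r = odds_ratio(FeatureCount("x", 20, 80, 10, 90))
        s = odds_ratio(FeatureCount("x", 10, 90, 20, 80))
        assert r.odds_ratio == pytest.approx(1 / s.odds_ratio)
        assert r.p == pytest.approx(s.p, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            FeatureCount("x", -1, 2, 3, 4)


class TestEnumerateFeatures:
    def build(self, scope, feature):
        cells = [
            make_cell("c1", lineage=Lineage.CD4, v_a="TRAV1", cdr3_a="CAAF"),
            make_cell("c2", lineage=Lineage.CD4, v_a="TRAV2", cdr3_a="CAGF"),
            make_cell("c3", lineage=Lineage.CD8, v_a="TRAV1", cdr3_a="CADF"),
        ]
        reps = deduplicate(cells, scope)
        return enumerate_features(reps[Lineage.CD4], reps[Lineage.CD8], feature)

    def test_margins_equal_repertoire_sizes(self):
        counts = self.build(Scope.ALPHA, "v_gene")
        for fc in counts:
            assert fc.a + fc.b == 2 and fc.c + fc.d == 1

    def test_v_gene_counts(self):
        by_feat = {fc.feature: fc for fc in self.build(Scope.ALPHA, "v_gene")}
        assert (by_feat["TRAV1"].a, by_feat["TRAV1"].c) == (1, 1)
        assert (by_feat["TRAV2"].a, by_feat["TRAV2"].c) == (1, 0)

    def test_scope_feature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            self.build(Scope.PAIRED, "v_gene")
        with pytest.raises(ValueError):
            self.build(Scope.ALPHA, "v_pair")

    def test_length_tail_pooling(self, reference_run):
        reps = reference_run["reps"][Scope.ALPHA]
        counts = enumerate_features(reps[Lineage.CD4], reps[Lineage.CD8],
                                    "length", pool_min_count=10)
        pooled = [fc for fc in counts
                  if isinstance(fc.feature, str) and fc.feature[0] in "<>"]
        assert pooled, "expected tail bins for sparse extreme lengths"
        for fc in pooled:
            assert fc.a + fc.c >= 10
        # pooling preserves the margins
        n4, n8 = len(reps[Lineage.CD4]), len(reps[Lineage.CD8])
        assert sum(fc.a for fc in counts) == n4
        assert sum(fc.c for fc in counts) == n8


class TestMultipleTesting:
    def test_bonferroni_on_single_chain_scan(self, reference_run):
        reps = reference_run["reps"][Scope.ALPHA]
        res = association_scan(reps[Lineage.CD4], reps[Lineage.CD8], "v_gene")
        m = len(res)
        for r in res:
            assert r.adjust_method == "bonferroni"
            assert r.adjusted == pytest.approx(min(1.0, r.p * m))

    def test_qvalues_on_paired_scan(self, reference_run):
        reps = reference_run["reps"][Scope.PAIRED]
        res = association_scan(reps[Lineage.CD4], reps[Lineage.CD8], "v_pair")
        assert all(r.adjust_method == "qvalue" for r in res)
        for r in res:
            assert r.p <= r.adjusted <= 1.0

    def test_qvalue_small_family_is_bh(self):
        p = [0.001, 0.01, 0.02, 0.8]
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(storey_qvalues(p),
                                   multipletests(p, method="fdr_bh")[1])

    def test_qvalue_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(size=180), rng.uniform(0, 1e-3, 20)])
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_qvalue_no_smaller_than_bh_under_null_pi0(self):
        # uniform p-values: pi0 estimate near 1 -> q approx BH
        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(p, method="fdr_bh")[1]
        q = storey_qvalues(p)
        assert np.all(q <= bh + 1e-9)

    def test_scan_recovers_planted_v_effects(self, reference_run):
        reps = reference_run["reps"][Scope.ALPHA]
        res = association_scan(reps[Lineage.CD4], reps[Lineage.CD8], "v_gene")
        by_feat = {r.feature: r for r in res}
        # strongest planted effects point the right way
        assert by_feat["TRAV1"].odds_ratio > 1
        assert by_feat["TRAV2"].odds_ratio < 1

    def test_scan_to_frame_round_trip(self, reference_run):
        reps = reference_run["reps"][Scope.ALPHA]
        res = association_scan(reps[Lineage.CD4], reps[Lineage.CD8], "v_gene")
        df = scan_to_frame(res)
        assert len(df) == len(res)
        assert {"feature", "odds_ratio", "p", "adjusted", "significant"} <= \
            set(df.columns)


class TestAAUsage:
    def make_freqs(self, values):
        return pd.DataFrame(values, index=[f"S{i}" for i in range(len(values))],
                            columns=["A", "G"])

    def test_planted_enrichment_detected(self):
        cd4 = self.make_freqs([[0.6, 0.4]] * 4 + [[0.62, 0.38]] * 3)
        cd8 = self.make_freqs([[0.4, 0.6]] * 4 + [[0.41, 0.59]] * 3)
        res = {r.amino_acid: r for r in aa_usage_ratio_test(cd4, cd8)}
        assert res["A"].mean_ratio > 1 and res["A"].p < 0.05
        assert res["G"].mean_ratio < 1

    def test_zero_frequency_subject_excluded_with_warning(self):
        cd4 = self.make_freqs([[0.5, 0.5], [0.6, 0.4], [0.55, 0.45]])
        cd8 = self.make_freqs([[0.0, 1.0], [0.5, 0.5], [0.52, 0.48]])
        with pytest.warns(UserWarning, match="excluded"):
            res = {r.amino_acid: r for r in aa_usage_ratio_test(cd4, cd8)}
        assert res["A"].n_subjects == 2

    def test_zero_variance_flagged(self):
        cd4 = self.make_freqs([[0.5, 0.5]] * 3)
        cd8 = self.make_freqs([[0.5, 0.5]] * 3)
        res = aa_usage_ratio_test(cd4, cd8)
        assert all(r.zero_variance and r.p == 1.0 for r in res)

    def test_single_subject_rejected(self):
        f = self.make_freqs([[0.5, 0.5]])
        with pytest.raises(ValueError):
            aa_usage_ratio_test(f, f)


class TestStrengthComparison:
    def mk(self, or_values, significant=True):
        return [AssociationResult(f"f{i}", 1, 1, 1, 1, v, v / 2, v * 2,
                                  0.01, 0.01, significant, "bonferroni")
                for i, v in enumerate(or_values)]

    def test_paired_stronger_than_single(self):
        single = self.mk([1.5, 1.6, 1.4, 1.7, 1.5])
        paired = self.mk([4.0, 5.0, 6.0, 4.5, 5.5])
        res = strength_comparison(single, paired, "CD4")
        assert res.applicable and res.median_paired > res.median_single
        assert res.p_value < 0.05

    def test_direction_filter(self):
        mixed = self.mk([2.0, 0.5, 3.0, 0.2])
        res = strength_comparison(mixed, self.mk([4.0, 5.0]), "CD4")
        assert res.n_single == 2  # only OR > 1 kept

    def test_infinite_or_excluded(self):
        res = strength_comparison(self.mk([math.inf, 2.0]),
                                  self.mk([3.0, 4.0]), "CD4")
        assert res.n_single == 1

    def test_not_applicable_when_one_side_empty(self):
        res = strength_comparison(self.mk([2.0], significant=False),
                                  self.mk([3.0]), "CD4")
        assert not res.applicable and math.isnan(res.p_value)
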