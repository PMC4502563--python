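"""Outlier rule, ANOVA/Tukey, Bonferroni, pseudo-count strata and CMH."""

import numpy as np
import pytest
from scipy import stats as sps

from clutraffic.exceptions import (
    ParameterError,
    StratificationError,
    UndefinedORError,
)
from clutraffic.secretion import PerExperiment, SecretionEstimate
from clutraffic.stats import (
    StratifiedTable,
    _largest_remainder,
    anova_tukey,
    apply_bonferroni,
    bonferroni_threshold,
    build_strata,
    cmh_test,
    remove_outliers,
)


class TestOutliers:
    def test_constant_list_removes_nothing(self):
        kept, removed = remove_outliers([3.0] * 10)
        assert kept.tolist() == [3.0] * 10 and removed.size == 0

    def test_single_extreme_value_removed(self):
        values = [0.0] * 50 + [10.0]
        x = np.asarray(values)
        m, s = x.mean(), x.std(ddof=1)
        assert abs(10.0 - m) > 3 * s  # oracle: the rule fires on this list
        kept, removed = remove_outliers(values)
        assert removed.tolist() == [50]
        assert kept.size == 50

    def test_symmetric_pair_with_padding_kept(self):
        kept, removed = remove_outliers([-1.0, 1.0, 0.0])
        assert removed.size == 0

    def test_single_pass_is_idempotent_wrt_original_moments(self, rng):
        x = rng.normal(size=200)
        x[5] = 12.0
        kept, removed = remove_outliers(x)
        m, s = x.mean(), x.std(ddof=1)
        assert not np.any(np.abs(kept - m) > 3 * s)

    def test_too_few_values_rejected(self):
        with pytest.raises(ParameterError):
            remove_outliers([1.0, 2.0])


class TestAnovaTukey:
    def test_all_identical_groups_flagged_nonsignificant(self):
        res = anova_tukey({"a": [2.0, 2.0], "b": [2.0, 2.0], "c": [2.0, 2.0]}, "a")
        assert np.isnan(res.anova_f)
        assert len(res.contrasts) == 2
        assert not any(c.significant for c in res.contrasts)

    def test_two_groups_equal_pooled_t_test(self, rng):
        """For k = 2 the Tukey p reduces to the two-sample pooled-variance
        t-test p (q = sqrt(2)|t|)."""
        a, b = rng.normal(0, 1, 14), rng.normal(0.7, 1, 11)
        res = anova_tukey({"a": a, "b": b}, reference="a")
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.contrasts[0].p_raw == pytest.approx(t.pvalue, abs=1e-9)

    def test_reference_contrasts_only_and_labels(self, rng):
        groups = {g: rng.normal(size=10) for g in ("wt", "m1", "m2", "m3")}
        res = anova_tukey(groups, reference="wt")
        assert sorted(c.genotype for c in res.contrasts) == ["m1", "m2", "m3"]

    def test_separated_groups_detected(self, rng):
        groups = {"wt": rng.normal(10, 1, 20), "mut": rng.normal(2, 1, 20)}
        res = anova_tukey(groups, reference="wt")
        assert res.contrasts[0].p_raw < 1e-6 and res.anova_p < 1e-6

    def test_undersized_group_rejected(self):
        with pytest.raises(ParameterError):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]}, "a")
        with pytest.raises(ParameterError):
            anova_tukey({"a": [1.0, 2.0]}, "missing")


class TestBonferroni:
    def test_paper_design_threshold(self):
        assert bonferroni_threshold(0.05, 11) == pytest.approx(0.0045, abs=5e-5)

    def test_identity_and_arithmetic(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 4) == 0.0025

    def test_apply_adjusts_and_calls(self):
        from clutraffic.stats import ComparisonResult

        res = [ComparisonResult("g", "m", 0.0, p, p, False) for p in (0.0001, 0.02)]
        out = apply_bonferroni(res, 0.05, 11)
        assert out[0].significant and not out[1].significant
        assert out[1].p_adjusted == pytest.approx(0.22)

    def test_domain_checks(self):
        with pytest.raises(ParameterError):
            bonferroni_threshold(0.0, 5)
        with pytest.raises(ParameterError):
            bonferroni_threshold(0.05, 0)


def est(name, rows):
    return SecretionEstimate(name, [PerExperiment(e, cm, cl) for e, cm, cl in rows])


class TestBuildStrata:
    def test_printed_proportions_rescale_directly(self):
        wt = est("wt", [(1, 0.91, 0.09)])
        mut = est("mut", [(1, 0.15, 0.85)])
        table = build_strata(wt, mut, pseudo_n=100)
        np.testing.assert_array_equal(table.strata[0], [[91, 9], [15, 85]])

    def test_identical_genotypes_give_equal_rows(self):
        a = est("a", [(1, 3.0, 7.0), (2, 4.0, 6.0)])
        b = est("b", [(1, 3.0, 7.0), (2, 4.0, 6.0)])
        for stratum in build_strata(a, b, 1000).strata:
            np.testing.assert_array_equal(stratum[0], stratum[1])

    def test_largest_remainder_rounding_sums_exactly(self):
        row = _largest_remainder(np.array([2 / 3, 1 / 3]), 100)
        assert row.tolist() == [67, 33]
        wt = est("wt", [(1, 2.0, 1.0)])
        mut = est("mut", [(1, 1.0, 2.0)])
        table = build_strata(wt, mut, pseudo_n=100)
        assert (table.strata[0].sum(axis=1) == 100).all()
        np.testing.assert_array_equal(table.strata[0], [[67, 33], [33, 67]])

    def test_mismatched_experiments_raise(self):
        with pytest.raises(StratificationError):
            build_strata(est("a", [(1, 1, 1)]), est("b", [(2, 1, 1)]))


class TestCMH:
    def test_null_table(self):
        r = cmh_test(StratifiedTable([np.array([[10, 10], [10, 10]])], [1]))
        assert r.or_mh == pytest.approx(1.0)
        assert r.p_raw == pytest.approx(1.0, abs=1e-6)

    def test_duplicated_stratum_leaves_or_unchanged(self):
        t = np.array([[30, 10], [12, 28]])
        single = cmh_test(StratifiedTable([t], [1]))
        double = cmh_test(StratifiedTable([t, t.copy()], [1, 2]))
        assert double.or_mh == pytest.approx(single.or_mh, rel=1e-12)

    def test_single_stratum_equals_cross_product_ratio(self):
        """For one stratum the MH pooled OR reduces to ad/bc of the
        test-vs-reference table; checked against direct arithmetic on the
        91/9 vs 68/32 split."""
        r = cmh_test(StratifiedTable([np.array([[91, 9], [68, 32]])], [1]))
        assert r.or_mh == pytest.approx((68 * 9) / (32 * 91), rel=1e-12)

    def test_row_transposition_inverts_or(self):
        t = np.array([[40, 20], [15, 45]])
        fwd = cmh_test(StratifiedTable([t], [1]))
        rev = cmh_test(StratifiedTable([t[::-1].copy()], [1]))
        assert fwd.or_mh == pytest.approx(1.0 / rev.or_mh, rel=1e-12)

    def test_pooled_or_matches_hand_formula_over_strata(self):
        strata = [np.array([[30, 10], [12, 28]]), np.array([[25, 15], [9, 31]])]
        r = cmh_test(StratifiedTable(strata, [1, 2]))
        num = sum(t[1, 0] * t[0, 1] / t.sum() for t in strata)
        den = sum(t[1, 1] * t[0, 0] / t.sum() for t in strata)
        assert r.or_mh == pytest.approx(num / den, rel=1e-12)

    def test_rbg_ci_matches_hand_computation(self):
        """The 95% CI follows the Robins–Breslow–Greenland variance of
        log OR_MH, recomputed here from its closed form."""
        strata = [np.array([[30, 10], [12, 28]]), np.array([[25, 15], [9, 31]])]
        r = cmh_test(StratifiedTable(strata, [1, 2]))
        # test-vs-reference orientation: a=test CM, b=test CL, c=ref CM, d=ref CL
        tabs = [t[::-1] for t in strata]
        R = sum(t[0, 0] * t[1, 1] / t.sum() for t in tabs)
        S = sum(t[0, 1] * t[1, 0] / t.sum() for t in tabs)
        num1 = sum(
            (t[0, 0] + t[1, 1]) / t.sum() * t[0, 0] * t[1, 1] / t.sum() for t in tabs
        )
        num2 = sum(
            ((t[0, 0] + t[1, 1]) / t.sum() * t[0, 1] * t[1, 0] / t.sum()
             + (t[0, 1] + t[1, 0]) / t.sum() * t[0, 0] * t[1, 1] / t.sum())
            for t in tabs
        )
        num3 = sum(
            (t[0, 1] + t[1, 0]) / t.sum() * t[0, 1] * t[1, 0] / t.sum() for t in tabs
        )
        var = num1 / (2 * R**2) + num2 / (2 * R * S) + num3 / (2 * S**2)
        z = sps.norm.ppf(0.975)
        lo = np.exp(np.log(R / S) - z * np.sqrt(var))
        hi = np.exp(np.log(R / S) + z * np.sqrt(var))
        assert r.ci95[0] == pytest.approx(lo, rel=1e-6)
        assert r.ci95[1] == pytest.approx(hi, rel=1e-6)
        assert r.ci95[0] <= r.or_mh <= r.ci95[1]

    def test_all_degenerate_strata_raise(self):
        with pytest.raises(UndefinedORError):
            cmh_test(StratifiedTable([np.array([[10, 0], [10, 0]])], [1]))
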