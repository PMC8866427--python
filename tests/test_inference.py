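"""Friedman test, Wilcoxon post-hocs, FDR adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ethosample.inference import (
    DegenerateInputError,
    bh_fdr_adjust,
    compare_methods,
    friedman_blocked,
    paired_wilcoxon,
)


class TestFriedmanBlocked:
    def test_unanimous_two_treatment_ordering(self):
        """9 blocks, treatment A strictly lower everywhere: the reference result."""
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 0.1, size=9)
        values = np.column_stack([a, a + rng.uniform(0.1, 1.0, size=9)])
        res = friedman_blocked(values)
        assert res.chi_square == pytest.approx(9.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.0027, abs=1e-4)
        assert res.kendalls_w == pytest.approx(1.0)

    def test_fully_tied_blocks(self):
        res = friedman_blocked(np.ones((5, 3)))
        assert res.chi_square == 0.0
        assert res.p_value == 1.0
        assert res.kendalls_w == 0.0

    def test_hand_computed_three_by_three(self):
        # ranks per block: (1,2,3),(2,1,3),(1,3,2) -> rank sums (4,6,8)
        # chi2 = 12/(3*3*4) * (16+36+64) - 3*3*4 = 8/3
        values = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [1.0, 3.0, 2.0]])
        res = friedman_blocked(values)
        assert res.chi_square == pytest.approx(8 / 3)
        assert res.kendalls_w == pytest.approx((8 / 3) / (3 * 2))

    @pytest.mark.parametrize("n,k", [(6, 3), (10, 4)])
    def test_matches_scipy_without_ties(self, n, k):
        """Cross-check against the library routine (untied, k >= 3)."""
        rng = np.random.default_rng(42)
        values = rng.normal(size=(n, k))
        res = friedman_blocked(values)
        ref = stats.friedmanchisquare(*values.T)
        assert res.chi_square == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_reduces_to_sign_test_for_two_treatments(self):
        """Untied k=2: chi2 = (n_plus - n_minus)^2 / n."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.normal(size=(9, 2))
            diff = values[:, 1] - values[:, 0]
            n_plus, n_minus = int((diff > 0).sum()), int((diff < 0).sum())
            res = friedman_blocked(values)
            assert res.chi_square == pytest.approx((n_plus - n_minus) ** 2 / 9)

    def test_block_permutation_invariance(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(12, 3))
        res = friedman_blocked(values)
        shuffled = friedman_blocked(values[rng.permutation(12)])
        assert shuffled == res

    def test_null_rejection_rate_calibrated(self):
        """Exchangeable null data rejects at about the nominal 5% level."""
        rng = np.random.default_rng(2026)
        n_reps, rejections = 2000, 0
        for _ in range(n_reps):
            if friedman_blocked(rng.normal(size=(40, 4))).p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_reps - 0.05) < 0.02

    @pytest.mark.parametrize(
        "values",
        [np.ones(5), np.ones((1, 3)), np.ones((3, 1)), np.array([[1.0, np.nan], [2.0, 3.0]])],
    )
    def test_invalid_input_rejected(self, values):
        with pytest.raises(ValueError):
            friedman_blocked(values)


class TestPairedWilcoxon:
    def test_five_positive_differences_exact(self):
        # exact two-sided p: 2 / 2^5 sign assignments
        assert paired_wilcoxon([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(2 / 32)

    def test_symmetric_pairs_give_p_one(self):
        assert paired_wilcoxon([1.0, -1.0, 2.0, -2.0]) == pytest.approx(1.0)

    def test_hundred_positive_differences_highly_significant(self):
        rng = np.random.default_rng(1)
        assert paired_wilcoxon(rng.uniform(0.1, 1.0, size=100)) < 1e-3

    def test_zeros_dropped_by_default(self):
        d = [0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        assert paired_wilcoxon(d) == pytest.approx(2 / 32)

    def test_pratt_zero_handling_available(self):
        # in the large-sample regime keeping zeros in the ranking shifts p
        d = np.concatenate([np.zeros(5), np.arange(1.0, 31.0)])
        assert paired_wilcoxon(d, zero_method="pratt") != paired_wilcoxon(d)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_wilcoxon([0.0, 0.0, 0.0])
        with pytest.raises(DegenerateInputError):
            paired_wilcoxon([])


class TestBhFdrAdjust:
    def test_single_p_unchanged(self):
        assert bh_fdr_adjust([0.04]) == pytest.approx([0.04])

    def test_step_up_examples(self):
        assert bh_fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr_adjust([0.001, 0.04]) == pytest.approx([0.002, 0.04])

    def test_q_dominates_p_and_caps_at_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1.0, size=50)
        q = bh_fdr_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        # step-up monotonicity: sorting by p sorts q
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.1], []])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr_adjust(bad)


class TestCompareMethods:
    def make_tidy(self, rng, n_reps=30):
        rows = []
        for condition in (3, 30):
            for interval in (5, 50):
                for rep in range(n_reps):
                    pp = rng.normal(0, 0.01)
                    oz = abs(pp) + rng.uniform(0.05, 0.2)
                    for method, err in (("pinpoint", pp), ("one_zero", oz)):
                        rows.append(
                            {
                                "family": "frequency",
                                "condition": condition,
                                "interval": interval,
                                "method": method,
                                "replicate": rep,
                                "estimate": 0.5 + err,
                                "truth": 0.5,
                                "error": err,
                            }
                        )
        return pd.DataFrame(rows)

    def test_unanimous_cells_give_w_one(self):
        tidy = self.make_tidy(np.random.default_rng(0))
        result = compare_methods(tidy)
        fr = result["friedman"]
        assert fr.n_blocks == 4 and fr.k_treatments == 2
        assert fr.kendalls_w == pytest.approx(1.0)
        assert (result["posthoc"]["p_raw"] < 1e-3).all()
        assert (result["posthoc"]["q_fdr"] >= result["posthoc"]["p_raw"]).all()

    def test_mixed_family_rejected(self):
        tidy = self.make_tidy(np.random.default_rng(0))
        tidy.loc[0, "family"] = "duration"
        with pytest.raises(ValueError):
            compare_methods(tidy)

    def test_absolute_error_scale_option(self):
        tidy = self.make_tidy(np.random.default_rng(0))
        res = compare_methods(tidy, error_scale="absolute")
        assert res["friedman"].kendalls_w == pytest.approx(1.0)
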