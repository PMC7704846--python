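import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dutchpt.stats import (
    StatResult,
    compare_paired_conditions,
    correlate,
    ecdf,
    jzs_bf_ttest,
    split_by_start_price,
    two_sample_t,
)


class TestCorrelate:
    def test_perfect(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1)
        assert res.estimate == pytest.approx(1.0)

    def test_orthogonal_by_construction(self):
        # balanced design: y pattern repeats identically at every x level
        x = np.repeat([1.0, 2.0, 3.0], 2)
        y = np.tile([-1.0, 1.0], 3)
        assert correlate(x, y).estimate == pytest.approx(0.0, abs=1e-12)

    def test_hand_oracle(self):
        # frozen from the covariance-sum formula on (1,2,3,4) vs (2,4,5,9)
        res = correlate([1, 2, 3, 4], [2, 4, 5, 9])
        assert res.estimate == pytest.approx(0.9647638212377322, rel=1e-12)
        assert res.extra["r2"] == pytest.approx(res.estimate**2)
        assert res.df == 2

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [3.0, 4.0])

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        flip=st.sampled_from([1.0, -1.0]),
    )
    @settings(max_examples=50)
    def test_affine_invariance(self, a, b, flip):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        r0 = correlate(x, y).estimate
        r1 = correlate(flip * a * x + b, y).estimate
        assert r1 == pytest.approx(flip * r0, abs=1e-9)


class TestSplitByStartPrice:
    def test_low_bin(self):
        low, high = split_by_start_price([60.0, 99.9], [1.0, 2.0], 100.0)
        assert list(low) == [1.0, 2.0] and len(high) == 0

    def test_boundary_goes_high(self):
        low, high = split_by_start_price([100.0, 140.0], [1.0, 2.0], 100.0)
        assert len(low) == 0 and list(high) == [1.0, 2.0]

    def test_partition_exhaustive_and_balanced(self, rng):
        sp = rng.uniform(50, 150, size=10_000)
        low, high = split_by_start_price(sp, sp, 100.0)
        assert len(low) + len(high) == len(sp)
        se = math.sqrt(0.25 / len(sp))
        assert abs(len(low) / len(sp) - 0.5) < 3 * se

    def test_empty_bin_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            split_by_start_price([60.0, 70.0], [1.0, 2.0], 100.0)


class TestTwoSampleT:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(a, a, compute_bf=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 6

    def test_shift_sign(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = two_sample_t(a, a + 2.0, compute_bf=False)
        assert res.statistic < 0

    def test_hand_pooled_oracle(self):
        # frozen from the textbook pooled-variance formula
        res = two_sample_t([1, 2, 3, 4, 5], [2, 4, 4, 5, 7, 8], compute_bf=False)
        assert res.statistic == pytest.approx(-1.6993235521110623, rel=1e-12)
        assert res.df == 9

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_sample_t([2.0, 2.0], [2.0, 2.0])

    def test_pooled_df_not_welch(self):
        # unequal variances: pooled df stays n1+n2-2 regardless
        rng = np.random.default_rng(4)
        res = two_sample_t(rng.normal(size=20), rng.normal(scale=9, size=10),
                           compute_bf=False)
        assert res.df == 28


class TestJzsBayesFactor:
    def test_null_t_favours_null(self):
        bf, lnbf = jzs_bf_ttest(0.0, 330, 330)
        assert bf < 1
        assert lnbf == pytest.approx(math.log(bf), abs=1e-12)

    def test_sign_invariant(self):
        assert jzs_bf_ttest(4.85, 330, 330)[1] == pytest.approx(
            jzs_bf_ttest(-4.85, 330, 330)[1], abs=1e-10
        )

    @pytest.mark.parametrize("t,n", [(2.0, 50), (4.85, 330), (11.47, 500)])
    def test_matches_independent_implementation(self, t, n):
        """Dual-route check against pingouin's JZS integrator."""
        pingouin = pytest.importorskip("pingouin")
        ours, _ = jzs_bf_ttest(t, n, n)
        theirs = float(
            pingouin.bayesfactor_ttest(t, n, n, paired=False, r=math.sqrt(2) / 2)
        )
        assert ours == pytest.approx(theirs, rel=1e-4)

    def test_one_sample_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        ours, _ = jzs_bf_ttest(3.1, 25)
        theirs = float(
            pingouin.bayesfactor_ttest(3.1, 25, paired=True, r=math.sqrt(2) / 2)
        )
        assert ours == pytest.approx(theirs, rel=1e-4)

    def test_monotone_in_t(self):
        lnbfs = [jzs_bf_ttest(t, 100, 100)[1] for t in (0.0, 1.0, 2.0, 4.0, 8.0)]
        assert all(b > a for a, b in zip(lnbfs, lnbfs[1:]))

    def test_bic_sanity_corridor(self):
        # loose large-|t| corridor: ln BF ~ (n/2) ln(1 + t^2/df) - 0.5 ln n
        n1 = n2 = 500
        df = n1 + n2 - 2
        n = n1 + n2
        for t in (12.0, 15.0, 20.0):
            _, lnbf = jzs_bf_ttest(t, n1, n2)
            bic = (n / 2) * math.log1p(t * t / df) - 0.5 * math.log(n)
            assert lnbf == pytest.approx(bic, rel=0.02)

    def test_extreme_t_no_overflow(self):
        bf, lnbf = jzs_bf_ttest(30.0, 500, 500)
        assert math.isinf(bf) or bf > 1e100
        assert 300 < lnbf < 500

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            jzs_bf_ttest(2.0, 1, 10)
        with pytest.raises(ValueError):
            jzs_bf_ttest(2.0, 10, 10, scale=-1.0)


def wilcoxon_exact_p(diff: np.ndarray) -> float:
    """Brute-force two-sided signed-rank p by enumerating all sign patterns."""
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    w_obs = ranks[diff > 0].sum()
    mean_w = ranks.sum() / 2
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(diff)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


class TestPairedComparisons:
    def test_identical_degenerate(self):
        with pytest.raises(ValueError, match="zero"):
            compare_paired_conditions([1.0, 2.0], [1.0, 2.0])

    def test_constant_shift_maximal_w(self):
        a = np.arange(1.0, 9.0)
        res = compare_paired_conditions(a, a + 3.0, method="wilcoxon")
        # all differences negative: W (smaller-sum statistic) is 0
        assert res.statistic == 0.0
        assert res.p_value < 0.01

    def test_wilcoxon_matches_exhaustive_enumeration(self, rng):
        a = rng.normal(size=9)
        b = a + rng.normal(0.8, 1.0, size=9)
        res = compare_paired_conditions(a, b, method="wilcoxon")
        assert res.p_value == pytest.approx(wilcoxon_exact_p(a - b), abs=0.02)

    def test_paired_t_route(self, rng):
        a = rng.normal(size=30)
        res = compare_paired_conditions(a, a + rng.normal(1.0, 0.5, size=30),
                                        method="t")
        assert res.method == "paired_t"
        assert res.bf10 is not None and res.bf10 > 0

    def test_auto_selects_and_reports_shapiro(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(0.3, 0.2, size=40)
        res = compare_paired_conditions(a, b, method="auto")
        assert res.method in ("paired_t", "wilcoxon_signed_rank")
        assert "shapiro_p" in res.extra


class TestEcdf:
    def test_single_point(self):
        f = ecdf([5.0])
        assert f(4.999) == 0.0
        assert f(5.0) == 1.0  # right-continuous

    def test_quartiles(self):
        f = ecdf([1.0, 2.0, 3.0, 4.0])
        assert f(2.5) == 0.5
        assert f(4.0) == 1.0

    def test_against_sorted_rank_construction(self, rng):
        vals = rng.normal(size=500)
        f = ecdf(vals)
        xs = np.sort(vals)
        independent = np.arange(1, len(xs) + 1) / len(xs)
        assert np.max(np.abs(f(xs) - independent)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])


class TestStatResult:
    def test_bf_positive_enforced(self):
        with pytest.raises(ValueError):
            StatResult(0.0, 0.0, 1, 0.5, bf10=-2.0)

    def test_p_range_enforced(self):
        with pytest.raises(ValueError):
            StatResult(0.0, 0.0, 1, 1.5)

    def test_log_consistency(self):
        bf, lnbf = jzs_bf_ttest(3.0, 40, 40)
        assert lnbf == pytest.approx(math.log(bf), abs=1e-12)


def test_repeated_measures_anova_wrapper():
    pytest.importorskip("pingouin")
    import pandas as pd

    from dutchpt.stats import repeated_measures_anova

    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 3),
            "cond": np.tile(["a", "b", "c"], 12),
            "y": rng.normal(size=36) + np.tile([0.0, 0.5, 1.0], 12),
        }
    )
    table = repeated_measures_anova(df, dv="y", within="cond", subject="subject")
    assert "F" in table.columns
    assert table["F"].iloc[0] > 0
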