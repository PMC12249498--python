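import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from ambitus.stats import (
    _gg_epsilon,
    exclude_outliers,
    fisher_lsd,
    mixed_anova_gg,
    one_way_anova,
    unpaired_t,
)


def _long(Y, groups, subjects=None):
    """subjects x phases matrix -> long dataframe."""
    n, k = Y.shape
    subjects = subjects or [f"S{i}" for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append({"animal_id": subjects[i], "group": groups[i],
                         "phase": f"P{j}", "z": Y[i, j]})
    return pd.DataFrame(rows)


class TestOneWayAnova:
    def test_hand_fixture(self):
        r = one_way_anova({"a": [2, 4], "b": [6, 8]})
        assert r.f == pytest.approx(8.0, abs=1e-10)
        assert (r.df1, r.df2) == (1, 2)
        assert r.ms_effect == pytest.approx(16.0)
        assert r.ms_error == pytest.approx(2.0)

    def test_identical_groups_f_zero(self):
        r = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert r.f == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_zero_variance_degenerate(self):
        r = one_way_anova({"a": [0, 0], "b": [1, 1]})
        assert r.degenerate and math.isinf(r.f)

    def test_matches_scipy(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1, size=9) for i in range(4)}
        r = one_way_anova(groups)
        f_ref, p_ref = sps.f_oneway(*groups.values())
        assert r.f == pytest.approx(f_ref, rel=1e-12)
        assert r.p == pytest.approx(p_ref, rel=1e-10)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        r = one_way_anova({"a": a, "b": b})
        t = unpaired_t(a, b)
        assert r.f == pytest.approx(t.t ** 2, abs=1e-10)
        assert r.p == pytest.approx(t.p, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0], "b": [1, 2]})


class TestMixedAnova:
    def test_interaction_equals_squared_t_on_differences(self, rng):
        """2 groups x 2 phases: interaction F == t^2 of the between-group
        test on within-subject phase differences."""
        Y = rng.normal(0, 1, size=(12, 2))
        groups = ["A"] * 6 + ["B"] * 6
        res = {r.effect: r for r in mixed_anova_gg(_long(Y, groups), gg="never")}
        d = Y[:, 1] - Y[:, 0]
        t = unpaired_t(d[:6], d[6:])
        assert res["group * phase"].f == pytest.approx(t.t ** 2, rel=1e-10)

    def test_compound_symmetry_epsilon_one(self):
        """Equal-variance, equal-covariance (spherical) data: epsilon = 1."""
        cov = 0.4 * np.ones((4, 4)) + 0.6 * np.eye(4)
        assert _gg_epsilon(cov) == pytest.approx(1.0, abs=1e-6)

    def test_epsilon_bounds(self, rng):
        for _ in range(20):
            A = rng.normal(size=(5, 5))
            eps = _gg_epsilon(A @ A.T)
            assert 1.0 / 4 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_matches_pingouin(self, rng):
        """Cross-check all three effects against an independent implementation."""
        Y = rng.normal(0, 1, size=(16, 4)) + rng.normal(0, 1, size=(16, 1))
        Y[8:] += 0.8
        groups = ["A"] * 8 + ["B"] * 8
        df = _long(Y, groups)
        res = {r.effect: r for r in mixed_anova_gg(df, gg="never")}
        ref = pg.mixed_anova(df, dv="z", within="phase", subject="animal_id",
                             between="group", correction=False)
        ref = ref.set_index("Source")
        assert res["group"].f == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert res["phase"].f == pytest.approx(ref.loc["phase", "F"], rel=1e-8)
        assert res["group * phase"].f == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8)
        assert res["group"].p == pytest.approx(ref.loc["group", "p_unc"],
                                               rel=1e-8)

    def test_gg_adjustment_raises_p(self, rng):
        # monotonicity p_GG >= p_unadjusted holds in the F > 1 regime
        Y = rng.normal(0, 1, size=(10, 4))
        Y[:, 0] *= 4.0  # break sphericity
        Y += np.array([0.0, 0.5, 1.0, 1.5])  # real phase effect, F > 1
        groups = ["A"] * 5 + ["B"] * 5
        df = _long(Y, groups)
        raw = {r.effect: r for r in mixed_anova_gg(df, gg="never")}
        adj = {r.effect: r for r in mixed_anova_gg(df, gg="always")}
        assert adj["phase"].p >= raw["phase"].p - 1e-15
        assert adj["phase"].gg_applied and not raw["phase"].gg_applied
        assert adj["phase"].df1 == pytest.approx(3 * adj["phase"].epsilon)

    def test_listwise_deletion_on_incomplete_subject(self, rng):
        Y = rng.normal(size=(8, 3))
        df = _long(Y, ["A"] * 4 + ["B"] * 4)
        df.loc[(df.animal_id == "S0") & (df.phase == "P2"), "z"] = np.nan
        res = mixed_anova_gg(df)
        assert "1 subject(s) dropped" in res[0].note

    def test_fewer_than_two_phases_rejected(self, rng):
        df = _long(rng.normal(size=(6, 1)), ["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValueError):
            mixed_anova_gg(df)


class TestFisherLSD:
    def test_three_group_hand_fixture(self):
        groups = {"g1": [1, 2], "g2": [3, 4], "g3": [5, 6]}
        res = fisher_lsd(groups)
        assert len(res) == 3
        pair = next(r for r in res if (r.group_a, r.group_b) == ("g1", "g3"))
        assert pair.t == pytest.approx(-4 / math.sqrt(0.5), abs=1e-9)
        assert pair.df == 3
        assert pair.mean_diff == pytest.approx(-4.0)

    def test_two_groups_equals_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        (lsd,) = fisher_lsd({"a": a, "b": b})
        t = unpaired_t(a, b)
        assert lsd.t == pytest.approx(t.t, rel=1e-12)
        assert lsd.p == pytest.approx(t.p, rel=1e-12)

    def test_identical_means_p_one(self):
        res = fisher_lsd({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        assert res[0].t == pytest.approx(0.0) and res[0].p == pytest.approx(1.0)


class TestUnpairedT:
    def test_hand_fixture(self):
        r = unpaired_t([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), abs=1e-9)
        assert r.t == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4

    def test_identical_samples(self):
        r = unpaired_t([1, 2, 3], [1, 2, 3])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_zero_variance_degenerate(self):
        assert unpaired_t([0, 0], [1, 1]).degenerate

    def test_matches_scipy_student_and_welch(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.4, 2, 14)
        r = unpaired_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert r.t == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-10)
        w = unpaired_t(a, b, welch=True)
        refw = sps.ttest_ind(a, b, equal_var=False)
        assert w.t == pytest.approx(refw.statistic, rel=1e-12)
        assert w.p == pytest.approx(refw.pvalue, rel=1e-10)


class TestExcludeOutliers:
    def test_extreme_value_excluded(self):
        # mean 16.67, sample SD 40.82, band ends at 98.3 < 100
        retained, excluded = exclude_outliers([0, 0, 0, 0, 0, 100])
        assert list(excluded) == [100]
        assert len(retained) == 5

    def test_small_symmetric_sample_untouched(self):
        retained, excluded = exclude_outliers([1, 2, 3])
        assert excluded.size == 0 and len(retained) == 3

    def test_constant_vector_untouched(self):
        retained, excluded = exclude_outliers([5.0, 5.0, 5.0, 5.0])
        assert excluded.size == 0

    def test_single_pass_not_iterated(self):
        # after removing 200 the remaining spread would flag more values if
        # iterated; the rule must not re-apply
        vals = [0, 0, 0, 0, 0, 9, 200]
        retained, excluded = exclude_outliers(vals)
        assert list(excluded) == [200]
        assert 9 in retained


class TestNullCalibration:
    def test_pvalues_uniform_under_null(self, rng):
        """One-way ANOVA p-values are U(0,1) under the null (KS check)."""
        pvals = []
        for _ in range(500):
            groups = {f"g{i}": rng.normal(0, 1, 8) for i in range(3)}
            pvals.append(one_way_anova(groups).p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_group_relabel_invariance(self, rng):
        groups = {"a": rng.normal(size=6), "b": rng.normal(size=7),
                  "c": rng.normal(size=5)}
        r1 = one_way_anova(groups)
        shuffled = {k: groups[k] for k in ["c", "a", "b"]}
        r2 = one_way_anova(shuffled)
        assert r1.f == pytest.approx(r2.f, rel=1e-12)
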