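"""Statistics oracles: worked sums-of-squares ANOVA, LSD t/p values,
F = t² at k = 2, Pearson hand computation, Fisher-Z closed form, aggregation
order, SEM convention, and the behavior metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plaquemetrics import behavior, stats
from plaquemetrics.errors import MeasurementError, UsageError

THREE_GROUPS = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])]


class TestAnova:
    def test_worked_three_group_example(self):
        # SSB = 6, SSW = 6 -> F = 3.0 on df (2, 6)
        res = stats.one_way_anova(THREE_GROUPS)
        assert res.f == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.mse == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(i, 1.0, size=8) for i in range(3)]
        res = stats.one_way_anova(groups)
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.f == pytest.approx(float(f_ref), rel=1e-12)
        assert res.p_omnibus == pytest.approx(float(p_ref), rel=1e-9)

    def test_identical_groups_f_zero(self):
        g = np.array([1.0, 2, 3])
        res = stats.one_way_anova([g, g.copy(), g.copy()])
        assert res.f == 0.0

    def test_relabel_invariance(self):
        res1 = stats.one_way_anova(THREE_GROUPS)
        res2 = stats.one_way_anova(THREE_GROUPS[::-1])
        assert res1.f == pytest.approx(res2.f)

    def test_k2_equals_pooled_t_squared(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 9)
        res = stats.one_way_anova([a, b])
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert res.f == pytest.approx(float(t) ** 2, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(UsageError):
            stats.one_way_anova([np.array([1.0, 2.0])])


class TestFisherLsd:
    def test_worked_pair(self):
        res = stats.one_way_anova(THREE_GROUPS)
        table = stats.fisher_lsd(THREE_GROUPS, res)
        pair = table[(table["group_1"] == "group1") & (table["group_2"] == "group3")].iloc[0]
        assert abs(pair["t"]) == pytest.approx(2.449, abs=0.001)
        assert pair["df"] == 6
        assert pair["p"] == pytest.approx(0.0499, abs=0.0005)
        assert pair["significance"] == "*"

    def test_identical_means_t_zero(self):
        g = [np.array([1.0, 2, 3]), np.array([1.0, 2, 3]), np.array([0.0, 2, 4])]
        res = stats.one_way_anova(g)
        table = stats.fisher_lsd(g, res)
        row = table.iloc[0]
        assert row["t"] == 0.0 and row["p"] == pytest.approx(1.0)

    def test_zero_difference_unbalanced(self):
        g = [np.array([1.0, 2, 3]), np.array([0.0, 1, 2, 3, 4, 2])]
        res = stats.one_way_anova(g)
        table = stats.fisher_lsd(g, res)
        assert table.iloc[0]["t"] == pytest.approx(0.0)

    def test_degenerate_variance(self):
        g = [np.array([1.0, 1.0]), np.array([2.0, 2.0])]
        res = stats.one_way_anova(g)
        with pytest.raises(MeasurementError):
            stats.fisher_lsd(g, res)

    def test_no_multiplicity_adjustment(self):
        """LSD pairwise p equals the plain pooled-error t-test p."""
        res = stats.one_way_anova(THREE_GROUPS)
        table = stats.fisher_lsd(THREE_GROUPS, res)
        row = table.iloc[0]
        se = np.sqrt(res.mse * (1 / 3 + 1 / 3))
        t = (res.group_means[0] - res.group_means[1]) / se
        assert row["t"] == pytest.approx(t)
        assert row["p"] == pytest.approx(2 * sps.t.sf(abs(t), 6), rel=1e-12)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.2, "ns"), (0.05, "ns")],
    )
    def test_convention(self, p, expected):
        assert stats.stars(p) == expected


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        assert stats.pearson(x, x)[0] == pytest.approx(1.0)
        assert stats.pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_example(self):
        r, p = stats.pearson([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = x * 0.3 + rng.normal(size=40)
        r, p = stats.pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(float(ref.statistic), rel=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_constant_input_undefined(self):
        with pytest.raises(MeasurementError):
            stats.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherZ:
    def test_equal_correlations(self):
        res = stats.fisher_z_independent(0.4, 50, 0.4, 50)
        assert res.z == 0.0 and res.p == pytest.approx(0.5)

    def test_closed_form_example(self):
        res = stats.fisher_z_independent(0.5, 103, 0.3, 103)
        z_expected = (np.arctanh(0.5) - np.arctanh(0.3)) / np.sqrt(2 / 100)
        assert res.z == pytest.approx(z_expected, rel=1e-12)
        assert res.z == pytest.approx(1.696, abs=0.001)
        assert res.p == pytest.approx(0.045, abs=0.001)

    def test_antisymmetry(self):
        a = stats.fisher_z_independent(0.5, 60, 0.2, 80, tail="greater")
        b = stats.fisher_z_independent(0.2, 80, 0.5, 60, tail="less")
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_one_tailed_is_half_two_tailed_in_observed_direction(self):
        one = stats.fisher_z_independent(0.5, 60, 0.2, 80, tail="greater")
        two = stats.fisher_z_independent(0.5, 60, 0.2, 80, tail="two-sided")
        assert one.p == pytest.approx(two.p / 2)

    def test_input_contracts(self):
        with pytest.raises(UsageError):
            stats.fisher_z_independent(1.0, 50, 0.3, 50)
        with pytest.raises(UsageError):
            stats.fisher_z_independent(0.5, 3, 0.3, 50)


class TestAggregate:
    def _records(self):
        return pd.DataFrame(
            {
                "group": ["g1"] * 4,
                "animal": ["a1", "a1", "a2", "a3"],
                "region": ["cortex"] * 4,
                "diameter": [1.0, 3.0, 4.0, 6.0],
                "iod": [10.0, 20.0, 5.0, 7.0],
            }
        )

    def test_mean_then_group_mean(self):
        per_animal, summaries = stats.aggregate(
            self._records(), {"diameter": "mean", "iod": "sum"}
        )
        # animal means: a1 = 2, a2 = 4, a3 = 6 -> group mean 4, SEM = 2/sqrt(3)
        s = {x.metric: x for x in summaries}
        assert s["diameter"].mean == pytest.approx(4.0)
        assert s["diameter"].sem == pytest.approx(2 / np.sqrt(3))
        assert s["diameter"].n_animals == 3

    def test_iod_cumulated_not_averaged(self):
        per_animal, _ = stats.aggregate(self._records(), {"iod": "sum"})
        a1 = per_animal[per_animal["animal"] == "a1"].iloc[0]
        assert a1["iod"] == pytest.approx(30.0)

    def test_single_animal_sem_flagged_nan(self):
        df = self._records()
        df = df[df["animal"] == "a1"]
        _, summaries = stats.aggregate(df, {"diameter": "mean"})
        assert summaries[0].mean == pytest.approx(2.0)
        assert np.isnan(summaries[0].sem)

    def test_missing_key_schema_error(self):
        with pytest.raises(UsageError, match="missing"):
            stats.aggregate(pd.DataFrame({"x": [1]}), {"x": "mean"})

    def test_sem_uses_n_minus_one(self):
        assert stats.sem([2.0, 4.0, 6.0]) == pytest.approx(2 / np.sqrt(3))
        assert np.isnan(stats.sem([5.0]))


class TestBehavior:
    @pytest.mark.parametrize(
        "tn,tf,frac,signed",
        [(30, 30, 0.5, 0.0), (45, 15, 0.75, 0.5), (0, 20, 0.0, -1.0)],
    )
    def test_discrimination_index(self, tn, tf, frac, signed):
        di = behavior.discrimination_index(tn, tf)
        assert di.fraction == pytest.approx(frac)
        assert di.signed == pytest.approx(signed)

    def test_zero_exploration_undefined(self):
        with pytest.raises(MeasurementError):
            behavior.discrimination_index(0.0, 0.0)

    def test_time_in_center_full_occupancy(self):
        pos = np.full((600, 2), 25.0)
        assert behavior.time_in_center(pos, (20, 20, 30, 30), 1.0) == 600.0

    def test_time_in_center_none(self):
        pos = np.zeros((100, 2))
        assert behavior.time_in_center(pos, (20, 20, 30, 30), 1.0) == 0.0

    def test_time_in_center_half(self):
        pos = np.zeros((6000, 2))
        pos[:3000] = 25.0
        assert behavior.time_in_center(pos, (20, 20, 30, 30), 0.1) == pytest.approx(300.0)

    def test_empty_track_warns_zero(self):
        with pytest.warns(UserWarning):
            assert behavior.time_in_center(np.zeros((0, 2)), (0, 0, 1, 1), 1.0) == 0.0
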