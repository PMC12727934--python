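"""ANOVA arithmetic, eta-squared identities, stars and assumption checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sst

from strokeeg.group_stats import (
    InsufficientDataError,
    ZeroVarianceError,
    assumption_checks,
    compare_groups,
    comparisons_to_frame,
    one_way_anova,
    stars_for_p,
    welch_anova,
)
from strokeeg.records import MetricTable


class TestOneWayANOVA:
    def test_textbook_sum_of_squares(self):
        # SSB = 6, SSW = 6, df = (2, 6) -> F = 3, eta2 = 0.5
        f, p, eta2 = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0, abs=1e-12)
        assert eta2 == pytest.approx(0.5, abs=1e-12)
        assert 0 < p < 1

    def test_agrees_with_scipy(self, rng):
        groups = [rng.normal(loc, 1.0, 12) for loc in (0.0, 0.3, 0.1, 0.5)]
        f, p, _ = one_way_anova(groups)
        ref = sst.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_group_copies_give_zero_f(self, rng):
        g = rng.standard_normal(8)
        f, p, eta2 = one_way_anova([g, g, g, g])
        assert f == 0.0
        assert eta2 == 0.0
        assert p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 14)
        f, p, _ = one_way_anova([a, b])
        t = sst.ttest_ind(a, b)
        assert f == pytest.approx(t.statistic**2, rel=1e-10)
        assert p == pytest.approx(t.pvalue, rel=1e-9)

    def test_eta_squared_identities(self, rng):
        """eta2 = 1 - SSW/SST and equals R2 of group-indicator regression."""
        groups = [rng.normal(mu, 1, 9) for mu in (0, 1, 2, 0.5)]
        _, _, eta2 = one_way_anova(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssw = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
        sst_ = ((allv - grand) ** 2).sum()
        assert eta2 == pytest.approx(1 - ssw / sst_, abs=1e-12)
        # R^2 from one-hot least squares
        import statsmodels.api as sm

        labels = np.repeat(np.arange(4), 9)
        X = sm.add_constant(pd.get_dummies(labels, drop_first=True).astype(float))
        r2 = sm.OLS(allv, X).fit().rsquared
        assert eta2 == pytest.approx(r2, abs=1e-10)

    def test_affine_invariance(self, rng):
        groups = [rng.normal(mu, 1, 7) for mu in (0, 1, 2)]
        f1, p1, e1 = one_way_anova(groups)
        f2, p2, e2 = one_way_anova([5.0 * g - 3.0 for g in groups])
        assert (f1, e1) == pytest.approx((f2, e2), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            one_way_anova([[1.0, 2.0]])

    def test_type_i_error_calibrated(self):
        """Under the null, rejection rate at alpha=0.05 is ~5% (800 sims)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 800
        for _ in range(n_sim):
            groups = [rng.standard_normal(10) for _ in range(4)]
            _, p, _ = one_way_anova(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestWelchANOVA:
    def test_matches_classical_under_equal_variance_roughly(self, rng):
        groups = [rng.normal(mu, 1, 30) for mu in (0, 0.5, 1.0)]
        f_c, p_c, _ = one_way_anova(groups)
        f_w, p_w = welch_anova(groups)
        assert f_w == pytest.approx(f_c, rel=0.2)

    def test_constant_group_rejected(self):
        with pytest.raises(ZeroVarianceError):
            welch_anova([np.ones(5), np.arange(5.0)])


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, "ns"), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.05, "ns")],
    )
    def test_thresholds(self, p, expected):
        assert stars_for_p(p) == expected


class TestAssumptionChecks:
    def test_null_gaussian_groups_pass(self):
        """Both checks pass at 0.05 for most draws from one normal (40 trials)."""
        rng = np.random.default_rng(7)
        passes = 0
        for _ in range(40):
            groups = [rng.standard_normal(10) for _ in range(4)]
            rep = assumption_checks(groups)
            ok = all(p > 0.05 for p in rep.shapiro_p.values()) and rep.levene_p > 0.05
            passes += ok
        assert passes >= 32  # >= 80% here; expected ~ 77-90% jointly

    def test_constant_group_flagged_not_fatal(self):
        rep = assumption_checks([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        assert np.isnan(rep.shapiro_p["group0"])
        assert any("constant" in f for f in rep.flags)

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            assumption_checks([np.arange(5.0)])

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            assumption_checks([np.arange(5.0), np.array([1.0, 2.0])])


def _toy_table(values_by_group, bands=("delta", "theta")):
    rows = []
    for band in bands:
        for g, vals in values_by_group.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"subject_id": f"{g}_{i}", "group": g, "band": band, "value": v}
                )
    return MetricTable("RP", pd.DataFrame(rows))


class TestCompareGroups:
    ORDER = ["Control", "MCAO", "MCAO_tDCS", "MCAO_Sham"]

    def _table(self, rng, shift=0.0):
        return _toy_table(
            {
                "Control": rng.normal(0.3, 0.02, 8),
                "MCAO": rng.normal(0.5 + shift, 0.02, 8),
                "MCAO_tDCS": rng.normal(0.4, 0.02, 8),
                "MCAO_Sham": rng.normal(0.5, 0.02, 8),
            }
        )

    def test_bands_in_canonical_order_with_summaries(self, rng):
        comps = compare_groups(self._table(rng), self.ORDER)
        assert [c.band for c in comps] == ["delta", "theta"]
        for c in comps:
            assert set(c.group_summaries) == set(self.ORDER)
            assert c.group_summaries["Control"]["n"] == 8
            assert 0 <= c.eta_squared <= 1
            assert c.stars in {"ns", "*", "**", "***"}

    def test_row_order_invariance(self, rng):
        table = self._table(rng)
        shuffled = MetricTable(
            "RP", table.data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        a = comparisons_to_frame(compare_groups(table, self.ORDER))
        b = comparisons_to_frame(compare_groups(shuffled, self.ORDER))
        pd.testing.assert_frame_equal(a, b)

    def test_identical_values_rejected(self):
        table = _toy_table({g: [0.5] * 4 for g in self.ORDER})
        with pytest.raises(ZeroVarianceError):
            compare_groups(table, self.ORDER)

    def test_missing_group_named_in_error(self, rng):
        table = self._table(rng)
        with pytest.raises(ValueError, match="Patients"):
            compare_groups(table, self.ORDER + ["Patients"])

    def test_holm_adjusts_p_upward(self, rng):
        table = self._table(rng)
        raw = compare_groups(table, self.ORDER, holm=False)
        adj = compare_groups(table, self.ORDER, holm=True)
        assert all(a.p >= r.p for a, r in zip(adj, raw))

    def test_welch_flag_changes_f(self, rng):
        table = self._table(rng)
        classical = compare_groups(table, self.ORDER, welch=False)
        welch = compare_groups(table, self.ORDER, welch=True)
        assert all(np.isfinite(c.F) for c in welch)
        assert any(c.F != w.F for c, w in zip(classical, welch))


@given(st.floats(1e-10, 0.9999))
def test_stars_monotone_in_p(p):
    order = {"***": 3, "**": 2, "*": 1, "ns": 0}
    assert order[stars_for_p(p)] >= order[stars_for_p(min(p * 2, 1.0))]
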