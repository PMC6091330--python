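"""Survival machinery against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mmstage.survival import (
    NOT_REACHED,
    cox_fit,
    km_estimate,
    logrank_test,
    univariate_os_table,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        """Three deaths at 2, 4, 6 months: S drops 2/3, 1/3, 0; median 4."""
        km = km_estimate([2, 4, 6], [True, True, True])
        assert km.event_times.tolist() == [2, 4, 6]
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km.median == 4
        assert km.survival_at(0) == 1.0
        assert km.survival_at(5) == pytest.approx(1 / 3)

    def test_all_censored_median_not_reached(self):
        km = km_estimate([5, 10, 15], [False, False, False])
        assert km.median is NOT_REACHED
        assert km.median_display == "NR"
        assert km.survival_at(20) == 1.0

    def test_no_censoring_equals_empirical_survivor(self, rng):
        times = rng.exponential(10, size=60).round(2)
        km = km_estimate(times, np.ones_like(times, dtype=bool))
        for t in km.event_times:
            assert km.survival_at(t) == pytest.approx((times > t).mean())

    def test_censoring_between_events_handled(self):
        # classic worked example: deaths at 1 and 3, censored at 2
        km = km_estimate([1, 2, 3], [True, False, True])
        assert km.survival == pytest.approx([2 / 3, 0.0])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [True, True])
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_survival_non_increasing(self, rng):
        t = rng.exponential(5, 100)
        e = rng.random(100) < 0.7
        km = km_estimate(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()


def hand_logrank_two_groups(t1, e1, t2, e2):
    """Observed/expected tally at every pooled event time, from first
    principles (hypergeometric variance)."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2]).astype(bool)
    group = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        dying = events & (times == t)
        d = dying.sum()
        d1 = (dying & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_null(self):
        g = (np.array([1.0, 2, 3]), np.array([True, True, False]))
        res = logrank_test([g, g])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.degrees_of_freedom == 1

    def test_matches_hand_tally_small_fixture(self):
        t1 = np.array([3.0, 5, 8])
        e1 = np.array([True, True, False])
        t2 = np.array([1.0, 4, 6])
        e2 = np.array([True, True, True])
        res = logrank_test([(t1, e1), (t2, e2)])
        assert res.chi_square == pytest.approx(hand_logrank_two_groups(t1, e1, t2, e2))

    def test_matches_hand_tally_with_ties(self, rng):
        for _ in range(5):
            t1 = rng.integers(1, 6, 8).astype(float)
            t2 = rng.integers(1, 6, 7).astype(float)
            e1 = rng.random(8) < 0.8
            e2 = rng.random(7) < 0.8
            if e1.sum() + e2.sum() == 0:
                continue
            res = logrank_test([(t1, e1), (t2, e2)])
            assert res.chi_square == pytest.approx(
                hand_logrank_two_groups(t1, e1, t2, e2)
            )

    def test_power_under_strongly_separated_hazards(self):
        rng = np.random.default_rng(7)
        groups = []
        for hr in (1.0, 3.0, 10.0):
            t = rng.exponential(1 / (0.01 * hr), size=100)
            groups.append((t, np.ones(100, dtype=bool)))
        res = logrank_test(groups)
        assert res.degrees_of_freedom == 2
        assert res.p_value < 0.001

    def test_requires_two_nonempty_groups(self):
        g = (np.array([1.0]), np.array([True]))
        with pytest.raises(ValueError):
            logrank_test([g])
        with pytest.raises(ValueError):
            logrank_test([g, (np.array([]), np.array([]))])


def grid_partial_likelihood(beta, times, events, x):
    """Written-out Cox partial likelihood for one covariate, Breslow ties."""
    ll = 0.0
    for t in np.unique(times[events]):
        dying = events & (times == t)
        risk = times >= t
        ll += beta * x[dying].sum() - dying.sum() * np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestCox:
    def test_micro_example_matches_grid_search(self):
        """n=4, one binary covariate, no ties: Newton solution equals the
        maximizer of the explicitly written-out partial likelihood."""
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([True, True, True, True])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = cox_fit(times, events, pd.DataFrame({"x": x}))
        res = minimize_scalar(
            lambda b: -grid_partial_likelihood(b, times, events, x),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-6)

    def test_breslow_matches_grid_with_ties(self):
        times = np.array([2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        events = np.array([True, True, False, True, True, True])
        x = np.array([1.0, 0, 1, 0, 1, 0])
        fit = cox_fit(times, events, pd.DataFrame({"x": x}), ties="breslow")
        res = minimize_scalar(
            lambda b: -grid_partial_likelihood(b, times, events, x),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-6)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        """Efron and Breslow coincide without ties; lifelines (Efron) is the
        independent implementation."""
        lifelines = pytest.importorskip("lifelines")
        n = 150
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * x1 - 0.3 * x2)))
        c = rng.uniform(5, 60, n)
        e = t <= c
        t = np.minimum(t, c)
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        for ties in ("breslow", "efron"):
            fit = cox_fit(t, e, df[["x1", "x2"]], ties=ties)
            cph = lifelines.CoxPHFitter().fit(df, "t", "e")
            # lifelines stops at a looser gradient tolerance than our Newton
            assert fit.coef == pytest.approx(cph.params_.to_numpy(), abs=1e-4)
            assert fit.se == pytest.approx(cph.standard_errors_.to_numpy(), abs=1e-4)

    def test_constant_covariate_dropped_with_warning(self):
        times = np.array([1.0, 2, 3, 4])
        events = np.array([True, True, True, False])
        X = pd.DataFrame({"const": [1.0] * 4, "x": [0.0, 1, 0, 1]})
        with pytest.warns(UserWarning, match="constant"):
            fit = cox_fit(times, events, X)
        assert fit.dropped == ("const",)
        assert fit.names == ("x",)
        with pytest.raises(ValueError, match="non-constant"):
            cox_fit(times, events, pd.DataFrame({"const": [1.0] * 4}))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit([1, 2], [False, False], pd.DataFrame({"x": [0.0, 1.0]}))

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(11)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.02 * 3.5**x))
        c = rng.uniform(0, 120, n)
        obs = np.minimum(t, c)
        e = t <= c
        fit = cox_fit(obs, e, pd.DataFrame({"x": x}))
        assert fit.ci_low[0] < 3.5 < fit.ci_high[0]
        assert fit.summary().loc["x", "HR"] == pytest.approx(3.5, rel=0.3)


class TestUnivariateTable:
    @pytest.fixture()
    def df(self):
        rng = np.random.default_rng(3)
        n = 80
        group = np.where(rng.random(n) < 0.5, "hot", "cold")
        rate = np.where(group == "hot", 0.08, 0.004)
        t = rng.exponential(1 / rate)
        c = rng.uniform(10, 60, n)
        return pd.DataFrame(
            {
                "os_months": np.minimum(t, c),
                "os_event": t <= c,
                "marrow": group,
                "all_same": "x",
            }
        )

    def test_shape_and_nr_formatting(self, df):
        table = univariate_os_table(df, {"Marrow uptake": "marrow"})
        assert set(table["level"]) == {"hot", "cold"}
        assert table["n"].sum() == len(df)
        # the indolent group never crosses S = 0.5 inside the window
        assert "NR" in set(table[table["level"] == "cold"]["median_os"])
        assert (table["logrank_p"] < 0.05).all()

    def test_single_level_grouping_rejected(self, df):
        with pytest.raises(ValueError, match="fewer than two"):
            univariate_os_table(df, {"Constant": "all_same"})

    def test_unknown_column_rejected(self, df):
        with pytest.raises(ValueError, match="nope"):
            univariate_os_table(df, {"Missing": "nope"})
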