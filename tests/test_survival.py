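"""Survival module vs hand oracles: KM, log-rank, maxstat, Cox."""

import warnings

import numpy as np
import pytest

from clearmark.cohort import (CohortConfig, HazardConfig, simulate_cohort,
                              simulate_outcomes, survival_to_frame)
from clearmark.survival import (cox_univariate, km_estimate, logrank_scores,
                                logrank_test, maxstat_cutpoint,
                                subgroup_compare)

# ---------------------------------------------------------------------------
# hand oracles (independent, naive implementations)


def km_oracle(times, events):
    """Direct product-limit computation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in np.unique(times):
        at_risk = np.sum(times >= t)
        d = np.sum(events[times == t])
        s *= 1.0 - d / at_risk
        out[t] = s
    return out


def logrank_oracle(times, events, groups):
    """Observed-minus-expected table computation at every event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g = np.asarray(groups)
    lab = np.unique(g)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (g == lab[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (g == lab[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def maxstat_oracle(times, events, marker, q1, q2):
    """Exhaustive standardized-statistic evaluation at every candidate."""
    a = logrank_scores(times, events)
    x = np.asarray(marker, float)
    n = x.size
    best = (None, -1.0)
    for c in np.unique(x)[1:]:
        m = int((x < c).sum())
        if not q1 <= m / n <= q2:
            continue
        z = abs(a[x < c].sum()) / np.sqrt(
            m * (n - m) / (n * (n - 1.0)) * np.sum(a ** 2))
        if z > best[1] + 1e-12:
            best = (float(c), float(z))
    return best


def efron_loglik(beta, times, events, x):
    """Efron-tie-corrected Cox log partial likelihood.

    ``beta`` may be a scalar or a grid (vectorized over beta, naive over
    risk sets).
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = np.zeros_like(beta)
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        risk = times >= t
        d = int(dead.sum())
        sum_dead = np.exp(np.outer(beta, x[dead])).sum(axis=1)
        sum_risk = np.exp(np.outer(beta, x[risk])).sum(axis=1)
        ll += beta * x[dead].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - ell / d * sum_dead)
    return ll if ll.size > 1 else float(ll[0])


# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(km["survival"] == 1.0)

    def test_textbook_three_events(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        got = dict(zip(km["time"], km["survival"]))
        assert got[1.0] == pytest.approx(2 / 3)
        assert got[2.0] == pytest.approx(1 / 3)
        assert got[3.0] == pytest.approx(0.0)

    def test_matches_product_limit_oracle(self, rng):
        times = rng.exponential(10.0, 20).round(1) + 0.1
        events = (rng.random(20) < 0.7).astype(int)
        km = km_estimate(times, events)
        oracle = km_oracle(times, events)
        for t, s in oracle.items():
            assert km.loc[km["time"] == t, "survival"].iloc[0] == \
                pytest.approx(s, abs=1e-10)
        assert np.all(np.diff(km["survival"]) <= 1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_ten_record_fixture_matches_hand_tables(self):
        times = [1, 2, 3, 4, 5, 2, 4, 6, 8, 10]
        events = [1, 1, 0, 1, 1, 1, 1, 1, 0, 1]
        groups = ["a"] * 5 + ["b"] * 5
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(
            logrank_oracle(times, events, groups), abs=1e-10)
        assert 0 < p <= 1

    def test_no_events_gives_zero_statistic(self):
        stat, p = logrank_test([1, 2, 3, 4], [0, 0, 0, 0],
                               ["a", "a", "b", "b"])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_permutation_type_one_error(self, rng):
        """Under label exchangeability the nominal 5% level holds."""
        n = 60
        times = rng.exponential(12.0, n) + 0.1
        events = (rng.random(n) < 0.8).astype(int)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            labels = np.where(rng.permutation(n) < n // 2, "a", "b")
            _, p = logrank_test(times, events, labels)
            hits += p < 0.05
        assert 0.03 <= hits / n_perm <= 0.07


class TestMaxstat:
    def _fixture(self, rng, n=50):
        marker = rng.normal(0.3, 0.1, n)
        times = rng.exponential(10.0 * np.exp(-1.5 * (marker - 0.3)), n) + 0.05
        events = (rng.random(n) < 0.8).astype(int)
        return times, events, marker

    def test_matches_brute_force_on_fixtures(self, rng):
        """Optimized statistic identical to exhaustive evaluation."""
        for _ in range(5):
            times, events, marker = self._fixture(rng)
            res = maxstat_cutpoint(times, events, marker)
            cut, stat = maxstat_oracle(times, events, marker, 0.10, 0.90)
            assert res.cutpoint == pytest.approx(cut, abs=0)
            assert res.statistic == pytest.approx(stat, rel=1e-12)
            assert res.quantile_range[0] <= np.mean(marker < res.cutpoint) \
                <= res.quantile_range[1]

    def test_perfect_separation(self, rng):
        """Marker perfectly ordered with uncensored survival: huge
        standardized statistic, adjusted p < 0.001."""
        times = np.sort(rng.exponential(10.0, 60)) + 0.1
        res = maxstat_cutpoint(times, np.ones(60, int), times.copy())
        assert res.p_adjusted < 1e-3
        assert res.statistic > 4.0

    def test_constant_marker_rejected(self, rng):
        with pytest.raises(ValueError, match="candidate"):
            maxstat_cutpoint(np.arange(1.0, 13.0), np.ones(12, int),
                             np.full(12, 1.0))

    def test_null_adjusted_p_not_inflated(self, rng):
        """Marker independent of survival: the adjusted p rejects at most
        7% of 500 replicates at alpha = 0.05 (the naive unadjusted maximum
        would reject far more often)."""
        n, hits, naive_hits = 100, 0, 0
        from scipy.stats import norm
        for _ in range(500):
            times = rng.exponential(10.0, n) + 0.1
            events = (rng.random(n) < 0.7).astype(int)
            marker = rng.normal(size=n)
            res = maxstat_cutpoint(times, events, marker)
            hits += res.p_adjusted < 0.05
            naive_hits += 2 * norm.sf(res.statistic) < 0.05
        assert hits / 500 <= 0.07
        assert naive_hits / 500 > 0.30  # anti-inflation contrast


class TestCox:
    def test_grid_oracle_with_ties(self):
        """Efron log partial likelihood at the lifelines optimum is within
        grid resolution of the exhaustive maximum over logHR."""
        times = [2, 2, 3, 3, 3, 5, 6, 6, 8, 9, 11, 12]
        events = [1, 1, 1, 0, 1, 1, 1, 1, 0, 1, 1, 0]
        x = [1, 0, 1, 1, 0, 1, 0, 1, 0, 0, 1, 0]
        fit = cox_univariate(times, events, x)
        grid = np.arange(-3.0, 3.0 + 1e-9, 1e-4)
        ll = efron_loglik(grid, times, events, x)
        best = grid[np.argmax(ll)]
        assert fit.log_hr == pytest.approx(best, abs=2e-4)
        assert efron_loglik(fit.log_hr, times, events, x) >= ll.max() - 1e-8

    def test_ci_convention(self):
        times = [2, 2, 3, 3, 3, 5, 6, 6, 8, 9, 11, 12]
        events = [1, 1, 1, 0, 1, 1, 1, 1, 0, 1, 1, 0]
        x = [1, 0, 1, 1, 0, 1, 0, 1, 0, 0, 1, 0]
        fit = cox_univariate(times, events, x)
        assert fit.ci_lower == pytest.approx(
            np.exp(fit.log_hr - 1.96 * fit.se_log_hr))
        assert fit.ci_upper == pytest.approx(
            np.exp(fit.log_hr + 1.96 * fit.se_log_hr))
        assert fit.ci_lower < fit.hr < fit.ci_upper

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1, 2, 3], [0, 0, 0], [0, 1, 0])

    def test_null_coverage(self, rng):
        """Independent covariate: the 95% Wald CI covers HR=1 in >=93%
        of 200 replicates (n=300)."""
        n, covered = 300, 0
        for _ in range(200):
            times = rng.exponential(10.0, n) + 0.01
            events = (rng.random(n) < 0.7).astype(int)
            x = (rng.random(n) < 0.5).astype(int)
            fit = cox_univariate(times, events, x)
            covered += fit.ci_lower <= 1.0 <= fit.ci_upper
        assert covered / 200 >= 0.93

    def test_recovers_generator_hazard_ratio(self, pop):
        """True-group Cox on cohorts from the calibrated generator: the
        group hazard ratio at the 0.232 L/day cut is about 2, estimated
        within [1.5, 2.7] in >=90% of 200 replicates at n=303."""
        cfg = CohortConfig(n=303, samples_median=1.0, samples_sdlog=0.0)
        hz = HazardConfig()
        ok = 0
        for rep in range(200):
            cohort = simulate_cohort(cfg, seed=1000 + rep, pop=pop)
            rec = survival_to_frame(simulate_outcomes(cohort, hz, 5000 + rep))
            high = np.array([p.true_cl_first_norm() >= 0.232 for p in cohort])
            fit = cox_univariate(rec["pfs_time"], rec["pfs_event"],
                                 high.astype(int))
            ok += 1.5 <= fit.hr <= 2.7
        assert ok / 200 >= 0.90

    def test_null_simulation_ci_covers_one(self, pop):
        """beta = 0 generator: marker groups carry no hazard signal and the
        CI covers 1 in >=93% of 200 replicates."""
        cfg = CohortConfig(n=303, samples_median=1.0, samples_sdlog=0.0)
        null = HazardConfig()
        null.pfs.beta_cl = null.pfs.beta_delta = 0.0
        null.os.beta_cl = null.os.beta_delta = 0.0
        covered = 0
        for rep in range(200):
            cohort = simulate_cohort(cfg, seed=3000 + rep, pop=pop)
            rec = survival_to_frame(simulate_outcomes(cohort, null, 7000 + rep))
            high = np.array([p.true_cl_first_norm() >= 0.232 for p in cohort])
            fit = cox_univariate(rec["pfs_time"], rec["pfs_event"],
                                 high.astype(int))
            covered += fit.ci_lower <= 1.0 <= fit.ci_upper
        assert covered / 200 >= 0.93


class TestSubgroup:
    def _records(self, pop, seed):
        cfg = CohortConfig(n=303, samples_median=1.0, samples_sdlog=0.0)
        cohort = simulate_cohort(cfg, seed=seed, pop=pop)
        df = survival_to_frame(simulate_outcomes(cohort, HazardConfig(),
                                                 seed + 1))
        df["chemo_added"] = (df["regimen"] != "monotherapy").astype(int)
        return df

    def test_null_chemo_effect_in_pdl1_high(self, pop):
        """Treatment regimen is independent of outcome in the generator:
        within the PD-L1 >= 50% stratum each endpoint's log-rank p exceeds
        0.05 in >= 90% of replicates."""
        above = {"pfs": 0, "os": 0}
        n_rep = 100
        for rep in range(n_rep):
            sub = subgroup_compare(self._records(pop, 400 + rep),
                                   {"pd_l1_stratum": ">=50%"}, "chemo_added")
            for row in sub.itertuples():
                above[row.endpoint] += row.p > 0.05
        assert above["pfs"] / n_rep >= 0.90
        assert above["os"] / n_rep >= 0.90

    def test_empty_stratum_warns_and_returns_empty(self, pop):
        df = self._records(pop, 99)
        with pytest.warns(UserWarning, match="matched no records"):
            out = subgroup_compare(df, {"pd_l1_stratum": "no-such"},
                                   "chemo_added")
        assert out.empty
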