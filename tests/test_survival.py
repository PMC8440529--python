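"""Dichotomization, log-rank, Cox fits and the cohort descriptive table."""

import importlib.resources

import numpy as np
import pandas as pd
import pytest

from mrith.core_io import read_clinical
from mrith.survival import (
    best_cutoff_dichotomize,
    cohort_summary,
    cox_fit,
    logrank_test,
    spearman,
    upper_quantile_dichotomize,
)


def _two_group_data(rng, n=120, hr=3.0):
    group = rng.integers(0, 2, size=n)
    lam = 0.02 * np.where(group == 1, hr, 1.0)
    t = rng.exponential(1.0 / lam)
    c = rng.uniform(10, 120, size=n)
    return group, np.minimum(t, c), t <= c


class TestLogrank:
    def test_identical_groups_null(self):
        times = np.array([5, 8, 12, 20, 5, 8, 12, 20], dtype=float)
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1], dtype=bool)
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        chi2, p = logrank_test(groups, times, events)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines_reference(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(50):
            group, times, events = _two_group_data(rng)
            chi2, p = logrank_test(group, times, events)
            ref = ll_logrank(
                times[group == 0], times[group == 1],
                event_observed_A=events[group == 0],
                event_observed_B=events[group == 1],
            )
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_label_swap_invariance(self, rng):
        group, times, events = _two_group_data(rng, n=60)
        chi_a, _ = logrank_test(group, times, events)
        chi_b, _ = logrank_test(1 - group, times, events)
        assert chi_a == pytest.approx(chi_b, abs=1e-12)

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([0, 0, 0], [1.0, 2.0, 3.0], [True, True, False])


class TestBestCutoff:
    def test_well_separated_groups_recovered(self, rng):
        values = np.concatenate([np.arange(1, 11), np.arange(91, 101)]).astype(float)
        lam = np.where(values > 50, 0.2, 0.01)
        times = rng.exponential(1.0 / lam)
        events = np.ones(20, dtype=bool)
        cutoff, labels = best_cutoff_dichotomize(values, times, events)
        assert 10 <= cutoff < 91
        assert np.array_equal(labels, values > 50)

    def test_matches_bruteforce_scan(self, rng):
        values = rng.uniform(0, 1, size=60)
        times = rng.exponential(20, size=60)
        events = rng.random(60) < 0.7
        cutoff, _ = best_cutoff_dichotomize(values, times, events)
        lo, hi = np.quantile(values, [0.2, 0.8])
        best = None
        for c in sorted(values[(values >= lo) & (values <= hi)]):
            if not (values > c).any() or not (values <= c).any():
                continue
            chi, _ = logrank_test(values > c, times, events)
            if best is None or chi > best[0] + 1e-12:
                best = (chi, c)
        assert cutoff == pytest.approx(best[1])

    def test_flat_survival_ties_to_smallest_candidate(self):
        values = np.arange(20, dtype=float)
        times = np.full(20, 10.0)
        events = np.ones(20, dtype=bool)
        cutoff, _ = best_cutoff_dichotomize(values, times, events)
        assert cutoff == np.quantile(values, 0.2).round() or cutoff <= np.quantile(values, 0.25)

    def test_degenerate_config_rejected(self):
        values = np.arange(20, dtype=float)
        with pytest.raises(ValueError):
            best_cutoff_dichotomize(
                values, np.ones(20), np.ones(20, bool), min_group_frac=0.5
            )

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="no valid cutoff"):
            best_cutoff_dichotomize(
                np.ones(20), np.arange(20.0), np.ones(20, bool)
            )


class TestUpperQuantile:
    def test_type7_quantile_count(self):
        values = np.arange(1, 41, dtype=float)
        high = upper_quantile_dichotomize(values, q=0.75)
        # type-7 0.75-quantile of 1..40 is 30.25 -> 10 values >= cutoff
        assert high.sum() == 10

    def test_all_equal_all_high(self):
        assert upper_quantile_dichotomize(np.full(8, 3.0)).all()

    def test_q_zero_all_high(self):
        assert upper_quantile_dichotomize(np.arange(5.0), q=0.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            upper_quantile_dichotomize(np.array([]))


class TestCox:
    def test_binary_covariate_hr_recovery(self, rng):
        n = 500
        x = rng.integers(0, 2, size=n)
        lam = 0.02 * np.exp(np.log(2.0) * x)
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(10, 150, size=n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "event": t <= c, "x": x.astype(float)}
        )
        res = cox_fit(df, "time", "event", "x")
        assert res.converged
        assert 1.7 <= res.hazard_ratio <= 2.3

    def test_null_covariate_ci_coverage(self, rng):
        covered = 0
        n_reps = 100
        for _ in range(n_reps):
            n = 80
            x = rng.normal(size=n)
            t = rng.exponential(50, size=n)
            c = rng.uniform(10, 120, size=n)
            df = pd.DataFrame(
                {"time": np.minimum(t, c), "event": t <= c, "x": x}
            )
            res = cox_fit(df, "time", "event", "x")
            if res.converged and res.hr_ci[0] <= 1.0 <= res.hr_ci[1]:
                covered += 1
        assert covered >= 90

    def test_zero_events_flagged(self):
        df = pd.DataFrame(
            {"time": [5.0, 8.0, 10.0, 3.0], "event": [False] * 4,
             "x": [0.0, 1.0, 0.0, 1.0]}
        )
        res = cox_fit(df, "time", "event", "x")
        assert not res.converged
        assert "non-estimable" in res.note

    def test_adjusted_fit_reports_covariate_hr(self, rng):
        n = 300
        x = rng.integers(0, 2, size=n).astype(float)
        age = rng.normal(60, 8, size=n)
        lam = 0.02 * np.exp(0.7 * x + 0.01 * (age - 60))
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(5, 150, size=n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "event": t <= c, "x": x, "age": age}
        )
        res = cox_fit(df, "time", "event", "x", adjusters=("age",))
        assert res.adjusted and res.converged
        assert res.hazard_ratio > 1.2


class TestCohortSummary:
    @pytest.fixture()
    def table1(self):
        src = importlib.resources.files("mrith.data").joinpath(
            "synthetic_table1_cohort.tsv"
        )
        with importlib.resources.as_file(src) as p:
            return cohort_summary(read_clinical(p))

    @staticmethod
    def pct(summary, char, cat, col="Total_pct"):
        row = summary[(summary.characteristic == char) & (summary.category == cat)]
        return float(row[col].iloc[0])

    def test_fixture_percentages(self, table1):
        assert self.pct(table1, "Sex", "male") == 87.5
        assert self.pct(table1, "Smoking", "smoker") == 77.5
        assert round(self.pct(table1, "Status", "True")) == 38
        assert round(self.pct(table1, "Classic EGFR mutation", "True", "P-SCLC_pct"), 1) == 5.9

    def test_percentages_normalize(self, table1):
        for char in ("Sex", "Smoking", "Stage", "Status"):
            sub = table1[table1.characteristic == char]
            assert sub["Total_pct"].sum() == pytest.approx(100.0)

    def test_empty_stratum_zero_counts(self):
        recs = read_clinical(
            importlib.resources.files("mrith.data").joinpath(
                "synthetic_table1_cohort.tsv"
            )
        )
        pure_only = [r for r in recs if r.histology == "P-SCLC"]
        s = cohort_summary(pure_only)
        assert self.pct(s, "Sex", "male", "C-SCLC_pct") == 0.0
        row = s[(s.characteristic == "Sex") & (s.category == "male")]
        assert int(row["C-SCLC_n"].iloc[0]) == 0


def test_univariate_os_analysis_flags_ith():
    """Cohorts simulated with a positive OS hazard on SNV ITH show HR > 1."""
    from mrith.simulate import SimConfig, simulate_patient

    flagged = 0
    n_cohorts = 5
    for s in range(n_cohorts):
        cfg = SimConfig(seed=200 + s, n_patients=200)
        rows = []
        for i in range(cfg.n_patients):
            _, _, _, clin, truth = simulate_patient(cfg, i)
            rows.append(
                {"time": clin.os_time, "event": clin.os_event,
                 "ith": truth.true_snv_ith}
            )
        res = cox_fit(pd.DataFrame(rows), "time", "event", "ith")
        if res.converged and res.hazard_ratio > 1.0:
            flagged += 1
    assert flagged >= 0.8 * n_cohorts


def test_spearman_wrapper(rng):
    x = rng.normal(size=50)
    y = x + rng.normal(scale=0.5, size=50)
    r, p = spearman(x, y)
    assert r > 0.5 and p < 0.01
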