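"""C-index, time-dependent AUC, KM/log-rank, risk strata, baseline table."""

import numpy as np
import pandas as pd
import pytest

import oracles
from radrep.evaluation import (
    baseline_table,
    censoring_survival,
    compare_cindex,
    concordance_index,
    delong_test,
    km_logrank,
    risk_stratify,
    time_dependent_auc,
)


class TestConcordance:
    def test_perfectly_concordant(self):
        r = concordance_index([1, 2, 3], [1, 1, 1], [3, 2, 1], n_bootstrap=0)
        assert r["c_index"] == 1.0

    def test_hand_enumerated_third(self):
        """Risks (2,1,3) on times (1,2,3): 1 of 3 comparable pairs concordant."""
        r = concordance_index([1, 2, 3], [1, 1, 1], [2, 1, 3], n_bootstrap=0)
        assert r["c_index"] == pytest.approx(1 / 3)

    def test_null_calibration(self, rng):
        n = 1000
        t = rng.exponential(size=n)
        s = rng.normal(size=n)
        r = concordance_index(t, np.ones(n, dtype=int), s, n_bootstrap=0)
        assert r["c_index"] == pytest.approx(0.5, abs=0.03)

    def test_matches_pair_enumeration_with_censoring(self, rng):
        n = 60
        t = rng.exponential(size=n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        s = rng.normal(size=n)
        r = concordance_index(t, e, s, n_bootstrap=0)
        assert r["c_index"] == pytest.approx(oracles.naive_concordance(t, e, s), abs=1e-12)

    def test_negation_symmetry(self, rng):
        t = rng.exponential(size=50)
        s = rng.normal(size=50)
        e = np.ones(50, dtype=int)
        a = concordance_index(t, e, s, n_bootstrap=0)["c_index"]
        b = concordance_index(t, e, -s, n_bootstrap=0)["c_index"]
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_bootstrap_ci_contains_point(self, rng):
        t = rng.exponential(size=80)
        e = np.ones(80, dtype=int)
        s = -t + rng.normal(0, 0.5, 80)
        r = concordance_index(t, e, s, n_bootstrap=200, seed=1)
        lo, hi = r["ci"]
        assert lo <= r["c_index"] <= hi


class TestCompareCindex:
    def test_identical_models_p_one(self, rng):
        t = rng.exponential(size=40)
        e = np.ones(40, dtype=int)
        s = rng.normal(size=40)
        r = compare_cindex(s, s.copy(), t, e)
        assert r["p"] == 1.0 and r["diff"] == 0.0

    def test_signal_vs_noise_significant(self):
        wins = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            n = 300
            eta = g.normal(size=n)
            t = np.exp(-eta) * g.exponential(size=n)
            e = np.ones(n, dtype=int)
            r = compare_cindex(eta, g.normal(size=n), t, e, seed=seed, n_bootstrap=300)
            if r["p"] < 0.01:
                wins += 1
        assert wins >= 9

    def test_two_sided_symmetry(self, rng):
        t = rng.exponential(size=60)
        e = np.ones(60, dtype=int)
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        ra = compare_cindex(a, b, t, e, seed=4)
        rb = compare_cindex(b, a, t, e, seed=4)
        assert ra["p"] == pytest.approx(rb["p"], abs=1e-12)
        assert ra["diff"] == pytest.approx(-rb["diff"], abs=1e-12)

    def test_t_boot_variant_reported(self, rng):
        t = rng.exponential(size=60)
        e = np.ones(60, dtype=int)
        r = compare_cindex(rng.normal(size=60), rng.normal(size=60), t, e, method="t_boot")
        assert r["method"] == "t_boot" and 0 <= r["p"] <= 1


class TestTimeDependentAUC:
    def test_perfect_marker(self, rng):
        t = rng.uniform(1, 100, 200)
        e = np.ones(200, dtype=int)
        auc = time_dependent_auc(t, e, -t, horizon=50.0)
        assert auc == 1.0

    def test_uncensored_equals_rank_auc_oracle(self, rng):
        for _ in range(10):
            n = 80
            t = rng.uniform(0, 10, n)
            e = np.ones(n, dtype=int)
            s = rng.normal(size=n)
            h = 5.0
            auc = time_dependent_auc(t, e, s, horizon=h)
            want = oracles.naive_rank_auc(t <= h, s)
            assert auc == pytest.approx(want, abs=1e-10)

    def test_null_marker_near_half(self, rng):
        n = 500
        t = rng.exponential(10, n)
        c = rng.uniform(0, 30, n)
        time_obs = np.minimum(t, c)
        e = (t <= c).astype(int)
        auc = time_dependent_auc(time_obs, e, rng.normal(size=n), horizon=8.0)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_sksurv_ipcw_estimator(self, rng):
        """Cross-check against scikit-survival's cumulative/dynamic AUC."""
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 200
        t = rng.exponential(10, n)
        c = rng.uniform(2, 25, n)
        time_obs = np.minimum(t, c)
        e = (t <= c).astype(int)
        s = -t + rng.normal(0, 2, n)
        y = Surv.from_arrays(event=e.astype(bool), time=time_obs)
        for h in (5.0, 8.0):
            want, _ = cumulative_dynamic_auc(y, y, s, [h])
            got = time_dependent_auc(time_obs, e, s, horizon=h)
            assert got == pytest.approx(float(want[0]), abs=2e-2)

    def test_invariance_under_monotone_transform(self, rng):
        t = rng.uniform(0, 10, 100)
        e = np.ones(100, dtype=int)
        s = rng.normal(size=100)
        a = time_dependent_auc(t, e, s, horizon=5.0)
        b = time_dependent_auc(t, e, np.exp(2 * s) + 3, horizon=5.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_horizon_outside_followup_rejected(self, rng):
        with pytest.raises(ValueError):
            time_dependent_auc([1, 2, 3], [1, 1, 1], [1, 2, 3], horizon=10.0)


class TestDeLong:
    def test_equal_markers(self, rng):
        t = rng.uniform(0, 10, 100)
        e = np.ones(100, dtype=int)
        s = rng.normal(size=100)
        r = delong_test(s, s, t, e, horizon=5.0)
        assert r["diff"] == 0.0 and r["p"] == 1.0

    def test_better_marker_detected(self, rng):
        n = 400
        t = rng.uniform(0, 10, n)
        e = np.ones(n, dtype=int)
        good = -t + rng.normal(0, 1.0, n)
        noise = rng.normal(size=n)
        r = delong_test(good, noise, t, e, horizon=5.0)
        assert r["auc_a"] > r["auc_b"] and r["p"] < 0.01


class TestKMLogrank:
    def test_duplicated_group_is_null(self, rng):
        t = rng.exponential(size=40)
        e = rng.integers(0, 2, 40)
        e[:2] = 1
        labels = np.array(["a"] * 40 + ["b"] * 40)
        r = km_logrank(labels, np.tile(t, 2), np.tile(e, 2))
        assert r["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert r["p"] == pytest.approx(1.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        r = km_logrank(np.array(["x", "x", "y", "y"]), t, e)
        kmf = r["curves"]["x"]
        assert kmf.predict(1.0) == pytest.approx(0.5)
        assert kmf.predict(2.0) == pytest.approx(0.0)

    def test_hand_computed_logrank_on_toy(self):
        """6-patient toy cross-checked against the classic O-E calculation."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, dtype=int)
        g = np.array(["a", "b", "a", "b", "a", "b"])
        r = km_logrank(g, t, e)
        # observed minus expected for group a: events at t=1,3,5
        # risk sets: t1 a3/b3, t2 a2/b3, t3 a2/b2, t4 a1/b2, t5 a1/b1, t6 b1
        expected_a = 3 / 6 + 2 / 5 + 2 / 4 + 1 / 3 + 1 / 2 + 0
        ns = [(3, 3), (2, 3), (2, 2), (1, 2), (1, 1), (0, 1)]
        # single event per time: hypergeometric variance term = na*nb/n^2
        var = sum(na * nb / (na + nb) ** 2 for na, nb in ns if na + nb > 1)
        chi2 = (3 - expected_a) ** 2 / var
        assert r["statistic"] == pytest.approx(chi2, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank(np.array(["a", "a"]), [1.0, 2.0], [1, 1])


class TestRiskStratify:
    def test_training_median_splits_evenly(self, rng):
        scores = pd.Series(rng.normal(size=50))
        cutoff = float(scores.median())
        strata = risk_stratify(scores, cutoff, rng.exponential(size=50), np.ones(50))
        counts = strata.labels.value_counts()
        assert abs(counts["high"] - counts["low"]) <= 1

    def test_shift_invariance_of_labels(self, rng):
        scores = pd.Series(rng.normal(size=30))
        cutoff = 0.1
        t = rng.exponential(size=30)
        e = np.ones(30)
        a = risk_stratify(scores, cutoff, t, e)
        b = risk_stratify(scores + 5.0, cutoff + 5.0, t, e)
        assert (a.labels == b.labels).all()

    def test_strong_signal_hr_excludes_one(self):
        hits = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            n = 200
            eta = g.normal(size=n)
            t = np.exp(-1.2 * eta) * g.exponential(size=n)
            scores = pd.Series(eta)
            strata = risk_stratify(scores, float(scores.median()), t, np.ones(n))
            if strata.hazard_ratio > 1 and strata.hr_ci[0] > 1:
                hits += 1
        assert hits >= 8

    def test_degenerate_one_sided_flagged(self, rng):
        scores = pd.Series(np.ones(10))
        strata = risk_stratify(scores, 5.0, rng.exponential(size=10), np.ones(10))
        assert strata.degenerate and strata.hazard_ratio is None


def test_km_plot_returns_axes(rng):
    import matplotlib

    matplotlib.use("Agg")
    from radrep.evaluation import plot_km_curves

    t = rng.exponential(size=40)
    e = np.ones(40, dtype=int)
    g = np.array(["high"] * 20 + ["low"] * 20)
    ax = plot_km_curves(g, t, e)
    assert ax.get_ylabel() == "survival probability"
    assert len(ax.lines) >= 2


class TestBaselineTable:
    def make_cohorts(self, counts):
        """counts: {var: ([train per cat], [val per cat])}."""
        tr = {}
        va = {}
        for var, (a, b) in counts.items():
            tr[var] = np.repeat([f"c{i}" for i in range(len(a))], a)
            va[var] = np.repeat([f"c{i}" for i in range(len(b))], b)
        return pd.DataFrame(tr), pd.DataFrame(va)

    def test_published_two_by_two_tables(self):
        """Gender 587/205 vs 91/29 -> p 0.77; length 470/322 vs 80/40 -> 0.15;
        T stage 554/238 vs 73/47 -> 0.06 (Yates-corrected chi-square)."""
        tr, va = self.make_cohorts({
            "gender": ([587, 205], [91, 29]),
            "tumor_length": ([470, 322], [80, 40]),
            "t_stage": ([554, 238], [73, 47]),
        })
        res = baseline_table(tr, va)
        p = res.statistics["p"]
        assert round(p["gender"], 2) == 0.77
        assert round(p["tumor_length"], 2) == 0.15
        assert round(p["t_stage"], 2) == 0.06

    def test_equal_proportions_give_p_one(self):
        tr, va = self.make_cohorts({"v": ([50, 50], [20, 20])})
        res = baseline_table(tr, va)
        assert res.statistics.loc["v", "chi2"] == pytest.approx(0.0)
        assert res.statistics.loc["v", "p"] == pytest.approx(1.0)

    def test_counts_sum_to_cohort_sizes(self):
        tr, va = self.make_cohorts({"v": ([30, 20, 10], [5, 10, 15])})
        res = baseline_table(tr, va)
        assert res.table["train"].sum() == 60
        assert res.table["validation"].sum() == 30
        assert res.statistics.loc["v", "dof"] == 2
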