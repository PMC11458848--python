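"""Selection cascade: volume filter, univariate Cox screen, redundancy
clustering, LASSO-Cox, and nesting of the stages."""

import numpy as np
import pandas as pd
import pytest

from radrep.selection import (
    SelectionConfig,
    cox_partial_loglik,
    lasso_cox_select,
    redundancy_filter,
    run_selection_cascade,
    survival_relevance_filter,
    univariate_cox,
    volume_dependency_filter,
)


def simulate_survival(rng, eta, scale=40.0, shape=1.2, censor_max=120.0):
    t = scale * (rng.exponential(size=eta.size) / np.exp(eta)) ** (1 / shape)
    c = rng.uniform(0, censor_max, size=eta.size)
    return np.minimum(t, c), (t <= c).astype(int)


@pytest.fixture(scope="module")
def survival_data():
    rng = np.random.default_rng(42)
    n = 300
    X = rng.normal(size=(n, 20))
    eta = 0.8 * X[:, 0] + 0.6 * X[:, 1]
    time, event = simulate_survival(rng, eta)
    feats = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(20)])
    return feats, time, event


class TestVolumeFilter:
    def test_affine_function_of_volume_removed(self, rng):
        vol = pd.Series(rng.uniform(500, 5000, 50), index=range(50))
        feats = pd.DataFrame({
            "affine": 2.0 * vol.to_numpy() + 7.0,
            "noise": rng.normal(size=50),
        }, index=vol.index)
        removed, retained, r2 = volume_dependency_filter(feats, vol)
        assert "affine" in removed and r2["affine"] == pytest.approx(1.0)
        assert "noise" in retained

    def test_independent_feature_retained(self, rng):
        n = 200
        vol = pd.Series(rng.uniform(500, 5000, n), index=range(n))
        feats = pd.DataFrame({"indep": rng.normal(size=n)}, index=vol.index)
        _, retained, r2 = volume_dependency_filter(feats, vol)
        assert "indep" in retained and r2["indep"] < 0.1

    def test_boundary_r2_is_removed(self, rng):
        """A feature constructed with r^2 = 0.6 exactly falls on the
        'greater than or equal' side of the criterion."""
        n = 500
        v = rng.normal(size=n)
        noise = rng.normal(size=n)
        # orthogonalize then mix so that corr^2 is exactly 0.6
        v_c = (v - v.mean()) / v.std()
        e = noise - np.polyval(np.polyfit(v_c, noise, 1), v_c)
        e /= e.std()
        rho = np.sqrt(0.6)
        feat = rho * v_c + np.sqrt(1 - rho**2) * e
        feats = pd.DataFrame({"boundary": feat})
        vols = pd.Series(v_c, index=feats.index)
        removed, _, r2 = volume_dependency_filter(feats, vols)
        assert r2["boundary"] == pytest.approx(0.6, abs=1e-9)
        assert "boundary" in removed

    def test_zero_variance_feature_retained_with_zero_r2(self, rng):
        vol = pd.Series(rng.uniform(1, 2, 10), index=range(10))
        feats = pd.DataFrame({"const": np.ones(10)}, index=vol.index)
        _, retained, r2 = volume_dependency_filter(feats, vol)
        assert r2["const"] == 0.0 and "const" in retained


class TestUnivariateCox:
    def test_matches_lifelines(self, survival_data):
        from lifelines import CoxPHFitter

        feats, time, event = survival_data
        mine = univariate_cox(feats[["f00", "f05"]], time, event)
        for col in ("f00", "f05"):
            df = pd.DataFrame({"x": feats[col], "T": time, "E": event})
            ll = CoxPHFitter().fit(df, "T", "E")
            assert mine.loc[col, "beta"] == pytest.approx(ll.params_.iloc[0], abs=1e-5)
            assert mine.loc[col, "p"] == pytest.approx(ll.summary["p"].iloc[0], abs=1e-4)

    def test_no_events_rejected(self, survival_data):
        feats, time, _ = survival_data
        with pytest.raises(ValueError):
            univariate_cox(feats, time, np.zeros_like(time))


class TestRedundancy:
    def test_duplicate_feature_collapses(self, survival_data):
        feats, time, event = survival_data
        dup = feats[["f00"]].copy()
        dup["copy"] = feats["f00"]
        reps, clusters, _ = redundancy_filter(dup, time, event)
        assert len(reps) == 1

    def test_uncorrelated_features_all_survive(self, survival_data):
        feats, time, event = survival_data
        reps, _, _ = redundancy_filter(feats, time, event)
        assert set(reps) == set(feats.columns)

    def test_order_invariance(self, survival_data):
        feats, time, event = survival_data
        wide = feats.copy()
        wide["f00_dup"] = feats["f00"] + 1e-9
        a, _, _ = redundancy_filter(wide, time, event)
        shuffled = wide[list(reversed(wide.columns))]
        b, _, _ = redundancy_filter(shuffled, time, event)
        assert a == b


class TestRelevance:
    def test_true_signal_retained(self, survival_data):
        feats, time, event = survival_data
        keep, p = survival_relevance_filter(feats, time, event)
        assert "f00" in keep and "f01" in keep

    def test_type_one_error_calibrated(self, rng):
        """Pure-noise features pass the alpha=0.05 screen at ~5% rate."""
        n = 300
        noise = pd.DataFrame(rng.normal(size=(n, 200)),
                             columns=[f"n{i}" for i in range(200)])
        eta = np.zeros(n)
        time, event = simulate_survival(rng, eta)
        keep, _ = survival_relevance_filter(noise, time, event)
        assert len(keep) / 200 == pytest.approx(0.05, abs=0.03)

    def test_zero_event_data_rejected(self, rng):
        feats = pd.DataFrame(rng.normal(size=(20, 2)))
        with pytest.raises(ValueError):
            survival_relevance_filter(feats, np.arange(1, 21.0), np.zeros(20))


class TestLassoCox:
    def test_near_zero_penalty_matches_mle(self, rng):
        """The coefficient path at vanishing penalty equals the unpenalized fit."""
        from lifelines import CoxPHFitter

        n = 500
        X = rng.normal(size=(n, 2))
        eta = 0.7 * X[:, 0] - 0.4 * X[:, 1]
        time, event = simulate_survival(rng, eta, censor_max=1e9)
        feats = pd.DataFrame(X, columns=["a", "b"])
        from radrep.selection import _coxnet_path

        alphas, coefs = _coxnet_path(X, time, event, alphas=[1e-9])
        df = feats.copy()
        df["T"] = time
        df["E"] = event
        mle = CoxPHFitter().fit(df, "T", "E").params_
        assert coefs[:, 0] == pytest.approx(mle.to_numpy(), abs=1e-3)

    def test_huge_penalty_selects_nothing(self, survival_data):
        feats, time, event = survival_data
        from radrep.selection import _coxnet_path

        _, coefs = _coxnet_path(feats.to_numpy(), time, event, alphas=[1e9])
        assert np.all(coefs == 0.0)

    def test_signal_recovery(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 400
            X = r.normal(size=(n, 53))
            beta = np.zeros(53)
            beta[:3] = 0.8
            time, event = simulate_survival(r, X @ beta)
            feats = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(53)])
            sel = lasso_cox_select(feats, time, event, n_folds=10, seed=seed)
            if {"f00", "f01", "f02"} <= set(sel.selected):
                hits += 1
        assert hits >= 8

    def test_path_sparsity_monotone_in_penalty(self, survival_data):
        feats, time, event = survival_data
        from radrep.selection import _coxnet_path

        alphas, coefs = _coxnet_path(feats.to_numpy(), time, event)
        nnz = (coefs != 0).sum(axis=0)
        order = np.argsort(alphas)  # increasing penalty
        assert all(a >= b for a, b in zip(nnz[order], nnz[order][1:]))

    def test_deterministic_given_seed(self, survival_data):
        feats, time, event = survival_data
        a = lasso_cox_select(feats, time, event, seed=5)
        b = lasso_cox_select(feats, time, event, seed=5)
        assert a.selected == b.selected and a.best_lambda == b.best_lambda


class TestCascade:
    def test_stages_nested_and_reproducible(self, survival_data):
        feats, time, event = survival_data
        res = run_selection_cascade(feats, time, event, seed=3)
        res.assert_nested()
        res2 = run_selection_cascade(feats, time, event, seed=3)
        assert res.stages == res2.stages

    def test_partial_loglik_matches_lifelines(self, survival_data):
        from lifelines import CoxPHFitter

        feats, time, event = survival_data
        df = feats[["f00", "f01"]].copy()
        df["T"] = time
        df["E"] = event
        cf = CoxPHFitter().fit(df, "T", "E")
        ll = cox_partial_loglik(
            feats[["f00", "f01"]].to_numpy(), time, event, cf.params_.to_numpy()
        )
        assert ll == pytest.approx(cf.log_likelihood_, rel=1e-10)
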