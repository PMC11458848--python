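"""Model/Results layer: multivariate Cox, radiomic signature pipeline,
clinical screen, fusion model, and the ICC-threshold sweep."""

import numpy as np
import pandas as pd
import pytest

from radrep.modeling import (
    ClinicalCoxModel,
    FusionCoxModel,
    RadiomicsCoxModel,
    fit_cox,
    icc_threshold_sweep,
    standardize_features,
)
from radrep.selection import SelectionConfig


def simulate(rng, eta, scale=40.0, shape=1.2, censor_max=120.0):
    t = scale * (rng.exponential(size=eta.size) / np.exp(eta)) ** (1 / shape)
    c = rng.uniform(0, censor_max, size=eta.size)
    return np.minimum(t, c), (t <= c).astype(int)


@pytest.fixture(scope="module")
def radiomic_like_data():
    rng = np.random.default_rng(99)
    n = 240
    X = rng.normal(size=(n, 25))
    eta = 0.8 * X[:, 0] + 0.6 * X[:, 1]
    time, event = simulate(rng, eta)
    feats = pd.DataFrame(
        X, columns=[f"f{i:02d}" for i in range(25)],
        index=[f"P{i:03d}" for i in range(n)],
    )
    return feats, time, event


class TestFitCox:
    def test_hr2_recovery(self):
        """A binary covariate with true HR 2 is recovered at n = 500."""
        hrs = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            x = g.integers(0, 2, 500).astype(float)
            t = g.exponential(size=500) / np.exp(np.log(2.0) * x)
            res = fit_cox(pd.DataFrame({"x": x}), t, np.ones(500))
            hrs.append(float(np.exp(res.params.iloc[0])))
        assert 1.7 <= np.median(hrs) <= 2.3

    def test_null_covariate_near_zero(self):
        g = np.random.default_rng(0)
        x = g.normal(size=500)
        t = g.exponential(size=500)
        res = fit_cox(pd.DataFrame({"x": x}), t, np.ones(500))
        assert abs(res.params.iloc[0]) < 0.15

    def test_efron_tied_fit_maximizes_hand_written_likelihood(self):
        """Four patients with two tied event times: the fitted coefficient
        maximizes the hand-written Efron partial likelihood, and the fitted
        log-likelihood equals its hand evaluation."""
        from scipy.optimize import minimize_scalar

        x = np.array([1.0, 0.0, 1.0, 0.0])
        # T = [2, 2, 3, 4], E = [1, 1, 1, 0]: ties at t=2 (patients 0, 1)

        def efron_ll(beta):
            w = np.exp(beta * x)
            # tied pair in the full risk set {0,1,2,3}
            s0 = w.sum()
            st = w[0] + w[1]
            term1 = beta * (x[0] + x[1]) - np.log(s0) - np.log(s0 - 0.5 * st)
            # single event at t=3, risk set {2, 3}
            term2 = beta * x[2] - np.log(w[2] + w[3])
            return term1 + term2

        res = fit_cox(
            pd.DataFrame({"x": x}), [2.0, 2.0, 3.0, 4.0], [1, 1, 1, 0]
        )
        opt = minimize_scalar(lambda b: -efron_ll(b), bounds=(-5, 5), method="bounded")
        assert res.params.iloc[0] == pytest.approx(opt.x, abs=1e-3)
        assert res.fitter.log_likelihood_ == pytest.approx(efron_ll(res.params.iloc[0]), abs=1e-8)

    def test_collinear_columns_rejected(self):
        g = np.random.default_rng(1)
        x = g.normal(size=50)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            fit_cox(design, g.exponential(size=50), np.ones(50))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(pd.DataFrame({"x": [1.0, 2.0]}), [1.0, 2.0], [0, 0])


class TestRadiomicsModel:
    def test_fit_selects_signal_and_predicts(self, radiomic_like_data):
        feats, time, event = radiomic_like_data
        res = RadiomicsCoxModel(feats, time, event).fit(seed=1)
        assert {"f00", "f01"} <= set(res.selected_features)
        scores = res.predict(feats)
        assert scores.index.equals(feats.index)
        assert res.train_scores.median() == pytest.approx(res.cutoff)

    def test_cutoff_is_training_median(self, radiomic_like_data):
        feats, time, event = radiomic_like_data
        res = RadiomicsCoxModel(feats, time, event).fit(seed=1)
        assert float(res.predict(feats).median()) == pytest.approx(res.cutoff)

    def test_summary_has_selected_rows(self, radiomic_like_data):
        feats, time, event = radiomic_like_data
        res = RadiomicsCoxModel(feats, time, event).fit(seed=1)
        assert set(res.summary().index) == set(res.selected_features)

    def test_signature_monotone_in_positive_coefficient(self, radiomic_like_data):
        feats, time, event = radiomic_like_data
        res = RadiomicsCoxModel(feats, time, event).fit(seed=1)
        name = res.params.index[0]
        beta = res.params.iloc[0]
        bumped = feats.copy()
        bumped[name] = bumped[name] + 1.0
        delta = res.predict(bumped) - res.predict(feats)
        assert np.all(np.sign(delta.round(12)) == np.sign(beta))


class TestClinicalModel:
    def test_only_hazard_factor_screened(self):
        hits = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            n = 400
            factors = pd.DataFrame({
                "t4": g.integers(0, 2, n).astype(float),
                "age": g.integers(0, 2, n).astype(float),
                "chemo": g.integers(0, 2, n).astype(float),
            })
            time, event = simulate(g, 0.9 * factors["t4"].to_numpy())
            res = ClinicalCoxModel(factors, time, event).fit()
            if res.screened == ("t4",):
                hits += 1
        assert hits >= 8

    def test_alpha_one_passes_everything(self, rng):
        n = 100
        factors = pd.DataFrame({
            "a": rng.integers(0, 2, n).astype(float),
            "b": rng.integers(0, 2, n).astype(float),
        })
        time, event = simulate(rng, np.zeros(n))
        model = ClinicalCoxModel(factors, time, event, alpha=1.0)
        kept, _ = model.screen()
        assert set(kept) == {"a", "b"}

    def test_no_screened_factor_gives_flagged_null_model(self, rng):
        n = 80
        factors = pd.DataFrame({"a": rng.integers(0, 2, n).astype(float)})
        time, event = simulate(rng, np.zeros(n))
        res = ClinicalCoxModel(factors, time, event, alpha=1e-6).fit()
        assert res.screened == ()
        assert res.cox is None
        assert (res.predict(factors) == 0).all()


class TestFusionModel:
    def test_null_signature_reduces_to_clinical(self, rng):
        n = 300
        factors = pd.DataFrame({"t4": rng.integers(0, 2, n).astype(float)})
        time, event = simulate(rng, 0.8 * factors["t4"].to_numpy())
        clinical = fit_cox(factors, time, event)
        # an all-zero-coefficient signature scores every patient 0: it is
        # degenerate and the fusion reduces exactly to the clinical model
        sig = pd.Series(np.zeros(n), index=factors.index)
        fusion = FusionCoxModel(factors, sig, time, event)
        assert fusion.signature_degenerate
        fused = fusion.fit()
        assert "signature" not in fused.params.index
        assert fused.params["t4"] == pytest.approx(clinical.params["t4"], abs=1e-6)

    def test_fusion_never_worse_than_clinical_in_train(self):
        from lifelines.utils import concordance_index

        wins = 0
        for seed in range(5):
            g = np.random.default_rng(seed)
            n = 300
            factors = pd.DataFrame({"t4": g.integers(0, 2, n).astype(float)})
            image_trait = g.normal(size=n)
            time, event = simulate(g, 0.6 * factors["t4"].to_numpy() + 0.6 * image_trait)
            clinical = ClinicalCoxModel(factors, time, event, alpha=1.0).fit()
            sig = pd.Series(image_trait, index=factors.index)
            fused = FusionCoxModel(factors, sig, time, event).fit()
            c_clin = concordance_index(time, -clinical.train_scores, event)
            c_fus = concordance_index(time, -fused.train_scores, event)
            if c_fus >= c_clin:
                wins += 1
        assert wins == 5

    def test_single_factor_plus_signature_has_two_params(self, rng):
        n = 100
        factors = pd.DataFrame({"t4": rng.integers(0, 2, n).astype(float)})
        time, event = simulate(rng, 0.5 * factors["t4"].to_numpy())
        sig = pd.Series(rng.normal(size=n), index=factors.index)
        fused = FusionCoxModel(factors, sig, time, event).fit()
        assert len(fused.params) == 2


class TestSweep:
    def test_threshold_zero_equals_unfiltered_and_counts_monotone(self, radiomic_like_data):
        feats, time, event = radiomic_like_data
        icc = pd.Series(
            np.linspace(0.05, 0.95, feats.shape[1]), index=feats.columns
        )
        half = feats.index[:120]
        other = feats.index[120:]
        cfg = SelectionConfig(n_folds=5)
        sweep = icc_threshold_sweep(
            feats.loc[half], feats.loc[other],
            time[:120], event[:120], time[120:], event[120:],
            icc, thresholds=np.array([0.0, 0.3, 0.6, 0.9, 1.0]), config=cfg, seed=2,
        )
        assert sweep.loc[0.0, "n_eligible"] == feats.shape[1]
        assert sweep["n_eligible"].is_monotonic_decreasing
        # threshold 0 reproduces the unfiltered pipeline
        res = RadiomicsCoxModel(feats.loc[half], time[:120], event[:120], config=cfg).fit(seed=2)
        assert sweep.loc[0.0, "n_selected"] == len(res.selected_features)
        assert np.isnan(sweep.loc[1.0, "c_train"])


def test_standardize_features_train_statistics(rng):
    df = pd.DataFrame(rng.normal(5, 3, size=(40, 3)), columns=list("abc"))
    scaled, scaler = standardize_features(df)
    assert np.allclose(scaled.mean(), 0.0, atol=1e-12)
    assert np.allclose(scaled.std(ddof=1), 1.0, atol=1e-12)
    other = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
    out = scaler.transform(other)
    assert np.allclose(out.to_numpy(), (other - df.mean()) / df.std(ddof=1))
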