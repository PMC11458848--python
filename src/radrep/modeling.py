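"""Prognostic Cox modeling, statsmodels-style: Model objects built from data
whose ``fit()`` returns a Results object with coefficients, uncertainties,
a ``summary()`` table, prediction and evaluation methods.

Three model families mirror the study design:

* :class:`RadiomicsCoxModel` — the full selection cascade (redundancy,
  survival relevancy, LASSO-Cox) over one feature group, then a multivariate
  Cox model on the surviving features; its linear predictor is the radiomic
  *signature*, dichotomized at the training-set median for risk
  stratification.
* :class:`ClinicalCoxModel` — univariate screening of clinical factors
  (Wald p < alpha), then a multivariate Cox model on the screened set.
* :class:`FusionCoxModel` — screened clinical factors plus the radiomic
  signature as one covariate.

Multivariate fits go through lifelines' Cox implementation (Newton-Raphson
on the Efron-corrected partial likelihood); the selection cascade lives in
:mod:`radrep.selection`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .evaluation import EvaluationReport, evaluate_signature
from .selection import (
    SelectionConfig,
    SelectionResult,
    run_selection_cascade,
    univariate_cox,
)

__all__ = [
    "FeatureScaler",
    "standardize_features",
    "fit_cox",
    "CoxResults",
    "RadiomicsCoxModel",
    "RadiomicsCoxResults",
    "ClinicalCoxModel",
    "FusionCoxModel",
    "icc_threshold_sweep",
]


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature training mean/SD; zero-variance features scale to 0."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        sd = self.sd.replace(0.0, 1.0)
        return (df[self.mean.index] - self.mean) / sd


def standardize_features(train: pd.DataFrame) -> tuple[pd.DataFrame, FeatureScaler]:
    """Standardize features with training-set mean/SD (penalized and
    screened fits require a common scale)."""
    scaler = FeatureScaler(mean=train.mean(), sd=train.std(ddof=1))
    return scaler.transform(train), scaler


def fit_cox(design: pd.DataFrame, times, events, tol: float = 1e-7) -> "CoxResults":
    """Multivariate Cox proportional-hazards fit (Efron tie correction).

    Raises on duplicate/collinear columns or a dataset without events;
    non-convergence and separation surface as explicit errors.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() < 1:
        raise ValueError("need at least one event")
    X = design.to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise ValueError("design matrix has no covariates")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("design matrix contains collinear or constant columns")
    df = design.copy()
    df["__T"] = t
    df["__E"] = e
    cf = CoxPHFitter()
    try:
        cf.fit(df, duration_col="__T", event_col="__E",
               fit_options={"precision": tol})
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    return CoxResults(fitter=cf, covariates=tuple(design.columns))


@dataclass
class CoxResults:
    """Fitted multivariate Cox model: coefficients in log-hazard units."""

    fitter: CoxPHFitter
    covariates: tuple[str, ...]

    @property
    def params(self) -> pd.Series:
        return self.fitter.params_

    @property
    def bse(self) -> pd.Series:
        return self.fitter.standard_errors_

    @property
    def pvalues(self) -> pd.Series:
        return self.fitter.summary["p"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.fitter.params_)

    def conf_int(self) -> pd.DataFrame:
        return self.fitter.confidence_intervals_

    @property
    def converged(self) -> bool:
        return bool(np.all(np.isfinite(self.params)))

    def predict(self, design: pd.DataFrame) -> pd.Series:
        """Linear predictor sum(beta * x) (no baseline hazard involved)."""
        missing = [c for c in self.covariates if c not in design.columns]
        if missing:
            raise KeyError(f"design is missing covariates {missing}")
        scores = design[list(self.covariates)].to_numpy(dtype=float) @ self.params.to_numpy()
        return pd.Series(scores, index=design.index, name="linear_predictor")

    def summary(self) -> pd.DataFrame:
        s = self.fitter.summary
        return s[["coef", "exp(coef)", "se(coef)", "p",
                  "exp(coef) lower 95%", "exp(coef) upper 95%"]]


class RadiomicsCoxModel:
    """Radiomic prognostic model over one (already grouped) feature set.

    Parameters
    ----------
    features : DataFrame
        Training-set feature table (patients x features), raw scale; the
        columns define the candidate set (e.g. the volume-independent
        high-repeatable group).
    times, events : array-like
        Endpoint follow-up (months) and event indicators for the same rows.
    config : SelectionConfig
        Cascade thresholds; standardization uses training mean/SD.
    """

    def __init__(self, features: pd.DataFrame, times, events,
                 config: SelectionConfig | None = None):
        self.features = features
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)
        self.config = config or SelectionConfig()

    def fit(self, seed: int = 0) -> "RadiomicsCoxResults":
        scaled, scaler = standardize_features(self.features)
        selection = run_selection_cascade(
            scaled, self.times, self.events, config=self.config, seed=seed
        )
        selected = list(selection.selected)
        if selected:
            cox = fit_cox(scaled[selected], self.times, self.events)
            scores = cox.predict(scaled)
        else:
            cox = None
            scores = pd.Series(0.0, index=self.features.index)
        return RadiomicsCoxResults(
            model=self,
            scaler=scaler,
            selection=selection,
            cox=cox,
            cutoff=float(scores.median()),
            train_scores=scores,
        )


@dataclass
class RadiomicsCoxResults:
    """Fitted radiomic signature: selection trace + Cox fit + risk cutoff."""

    model: RadiomicsCoxModel
    scaler: FeatureScaler
    selection: SelectionResult
    cox: CoxResults | None
    cutoff: float  # training-set median of the signature
    train_scores: pd.Series

    @property
    def selected_features(self) -> tuple[str, ...]:
        return self.selection.selected

    @property
    def params(self) -> pd.Series:
        if self.cox is None:
            return pd.Series(dtype=float)
        return self.cox.params

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Signature scores for new patients (training scaler applied)."""
        if self.cox is None:
            return pd.Series(0.0, index=features.index)
        return self.cox.predict(self.scaler.transform(features))

    def evaluate(self, features: pd.DataFrame, times, events,
                 n_bootstrap: int = 200, seed: int = 0) -> EvaluationReport:
        return evaluate_signature(
            self.predict(features), times, events, cutoff=self.cutoff,
            n_bootstrap=n_bootstrap, seed=seed,
        )

    def summary(self) -> pd.DataFrame:
        if self.cox is None:
            return pd.DataFrame(columns=["coef", "exp(coef)", "se(coef)", "p"])
        return self.cox.summary()


class ClinicalCoxModel:
    """Clinical prognostic model: univariate screen then multivariate Cox."""

    def __init__(self, factors: pd.DataFrame, times, events, alpha: float = 0.05):
        self.factors = factors.astype(float)
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)
        self.alpha = alpha

    def screen(self) -> tuple[tuple[str, ...], pd.Series]:
        res = univariate_cox(self.factors, self.times, self.events)
        keep = tuple(res.index[(res["p"] < self.alpha).fillna(False)])
        return keep, res["p"]

    def fit(self) -> "ClinicalCoxResults":
        kept, pvals = self.screen()
        cox = fit_cox(self.factors[list(kept)], self.times, self.events) if kept else None
        scores = (
            cox.predict(self.factors) if cox is not None
            else pd.Series(0.0, index=self.factors.index)
        )
        return ClinicalCoxResults(
            model=self, screened=kept, screen_p=pvals, cox=cox,
            cutoff=float(scores.median()), train_scores=scores,
        )


@dataclass
class ClinicalCoxResults:
    model: ClinicalCoxModel
    screened: tuple[str, ...]
    screen_p: pd.Series
    cox: CoxResults | None
    cutoff: float
    train_scores: pd.Series

    @property
    def params(self) -> pd.Series:
        return self.cox.params if self.cox is not None else pd.Series(dtype=float)

    def predict(self, factors: pd.DataFrame) -> pd.Series:
        if self.cox is None:
            return pd.Series(0.0, index=factors.index)
        return self.cox.predict(factors.astype(float))

    def evaluate(self, factors: pd.DataFrame, times, events,
                 n_bootstrap: int = 200, seed: int = 0) -> EvaluationReport:
        return evaluate_signature(
            self.predict(factors), times, events, cutoff=self.cutoff,
            n_bootstrap=n_bootstrap, seed=seed,
        )

    def summary(self) -> pd.DataFrame:
        if self.cox is None:
            return pd.DataFrame(columns=["coef", "exp(coef)", "se(coef)", "p"])
        return self.cox.summary()


class FusionCoxModel:
    """Fusion model: screened clinical factors + the radiomic signature.

    The signature must come from a model fitted on training data only; it
    enters the multivariate Cox fit as one covariate.
    """

    def __init__(self, factors: pd.DataFrame, signature: pd.Series, times, events):
        if not factors.index.equals(signature.index):
            raise ValueError("clinical factors and signature must share patients")
        self.design = factors.astype(float).copy()
        # a degenerate (constant) signature carries no information and would
        # break the fit; the fusion then reduces to the clinical model
        self.signature_degenerate = bool(signature.std(ddof=0) == 0.0)
        if not self.signature_degenerate:
            self.design["signature"] = signature.to_numpy(dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)

    def fit(self) -> "FusionCoxResults":
        cox = fit_cox(self.design, self.times, self.events)
        scores = cox.predict(self.design)
        return FusionCoxResults(
            model=self, cox=cox, cutoff=float(scores.median()), train_scores=scores
        )


@dataclass
class FusionCoxResults:
    model: FusionCoxModel
    cox: CoxResults
    cutoff: float
    train_scores: pd.Series

    @property
    def params(self) -> pd.Series:
        return self.cox.params

    def predict(self, factors: pd.DataFrame, signature: pd.Series) -> pd.Series:
        design = factors.astype(float).copy()
        if not self.model.signature_degenerate:
            design["signature"] = signature.to_numpy(dtype=float)
        return self.cox.predict(design)

    def summary(self) -> pd.DataFrame:
        return self.cox.summary()


def icc_threshold_sweep(
    train_features: pd.DataFrame,
    val_features: pd.DataFrame,
    train_times,
    train_events,
    val_times,
    val_events,
    icc: pd.Series,
    thresholds: np.ndarray | None = None,
    config: SelectionConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit the full selection+Cox pipeline keeping only features with
    ICC >= threshold, for thresholds 0, 0.05, ..., 1.

    Returns one row per threshold: number of eligible and selected features
    and the training/validation C-indices (NaN where fewer than 2 features
    remain eligible or nothing is selected).
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    rows = []
    for thr in thresholds:
        eligible = [c for c in train_features.columns if icc[c] >= thr]
        row = {"threshold": float(thr), "n_eligible": len(eligible),
               "n_selected": 0, "c_train": np.nan, "c_validation": np.nan}
        if len(eligible) >= 2:
            model = RadiomicsCoxModel(
                train_features[eligible], train_times, train_events, config=config
            )
            res = model.fit(seed=seed)
            if res.selected_features:
                row["n_selected"] = len(res.selected_features)
                row["c_train"] = res.evaluate(
                    train_features[eligible], train_times, train_events, n_bootstrap=0
                ).c_index
                row["c_validation"] = res.evaluate(
                    val_features[eligible], val_times, val_events, n_bootstrap=0
                ).c_index
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")
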