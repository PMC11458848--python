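"""Feature-selection cascade: volume-dependency filter, redundancy filter,
survival-relevancy filter, and cross-validated LASSO-Cox selection.

The cascade is strictly nested: each stage only ever removes features.  The
redundancy test is concretized as single-linkage clustering of |Spearman|
correlation at a threshold (connected components of the thresholded
correlation graph), keeping from each cluster the feature with the smallest
univariate Cox p-value — an interpretation documented in the methods note.

Univariate screening uses an in-package vectorized single-covariate Cox
(Newton iterations on the partial likelihood, Breslow tie handling — exact
for the tie-free continuous times used throughout); fitting thousands of
features through a general-purpose Cox fitter would dominate the pipeline's
runtime.  It is cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "volume_dependency_filter",
    "univariate_cox",
    "redundancy_filter",
    "survival_relevance_filter",
    "lasso_cox_select",
    "cox_partial_loglik",
    "run_selection_cascade",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the selection cascade."""

    r2_threshold: float = 0.6
    corr_threshold: float = 0.8
    alpha: float = 0.05
    n_folds: int = 10
    lambda_rule: str = "min"  # or "1se"
    standardize: bool = True
    #: events-per-variable guard: the final model keeps at most
    #: ``n_events / epv`` covariates (largest |penalized coefficient| first).
    #: None disables the cap.
    epv: float | None = 10.0

    def __post_init__(self) -> None:
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.epv is not None and self.epv <= 0:
            raise ValueError("epv must be positive or None")


@dataclass
class SelectionResult:
    """Surviving feature sets per stage (nested) plus diagnostics."""

    stages: dict[str, tuple[str, ...]]
    volume_r2: pd.Series | None = None
    univariate_p: pd.Series | None = None
    clusters: list[tuple[str, ...]] | None = None
    lasso_coef: pd.Series | None = None
    lambda_path: np.ndarray | None = None
    cv_deviance: np.ndarray | None = None
    best_lambda: float | None = None

    @property
    def selected(self) -> tuple[str, ...]:
        return self.stages[list(self.stages)[-1]]

    def assert_nested(self) -> None:
        names = list(self.stages)
        for a, b in zip(names, names[1:]):
            if not set(self.stages[b]) <= set(self.stages[a]):
                raise AssertionError(f"stage {b} is not nested in {a}")


def volume_dependency_filter(
    features: pd.DataFrame, volumes: pd.Series, r2_threshold: float = 0.6
) -> tuple[tuple[str, ...], tuple[str, ...], pd.Series]:
    """Remove features whose squared Pearson correlation with tumor mesh
    volume reaches the threshold.

    Returns ``(removed, retained, r2)``.  A zero-variance feature has r^2
    defined as 0 and is retained.
    """
    if features.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    v = volumes.loc[features.index].to_numpy(dtype=float)
    x = features.to_numpy(dtype=float)
    vc = v - v.mean()
    xc = x - x.mean(axis=0)
    num = vc @ xc
    den = np.sqrt((vc**2).sum() * (xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(den > 0, (num / np.where(den > 0, den, 1.0)) ** 2, 0.0)
    r2 = pd.Series(r2, index=features.columns, name="r2_volume")
    removed = tuple(features.columns[r2 >= r2_threshold])
    retained = tuple(features.columns[r2 < r2_threshold])
    return removed, retained, r2


def cox_partial_loglik(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> float:
    """Breslow partial log-likelihood of a Cox model at coefficients beta."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o, ev_o = eta[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    return float(np.sum((eta_o - log_cum)[ev_o.astype(bool)]))


def univariate_cox(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Single-covariate Cox fits for every column, vectorized across columns.

    Returns a DataFrame with ``beta``, ``se``, ``z``, ``p`` per feature.
    Non-convergent fits (separation) come back with ``p = NaN``.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if e.sum() < 1:
        raise ValueError("need at least one event")
    order = np.argsort(-t, kind="stable")
    X = features.to_numpy(dtype=float)[order]
    ev = e[order].astype(bool)
    n, f = X.shape

    beta = np.zeros(f)
    info = np.full(f, np.nan)
    for _ in range(max_iter):
        w = np.exp(np.clip(X * beta, -500, 500))
        s0 = np.cumsum(w, axis=0)
        s1 = np.cumsum(w * X, axis=0)
        s2 = np.cumsum(w * X * X, axis=0)
        r = s1 / s0
        grad = (X[ev] - r[ev]).sum(axis=0)
        info = (s2[ev] / s0[ev] - r[ev] ** 2).sum(axis=0)
        step = np.where(info > 0, grad / np.where(info > 0, info, 1.0), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.clip(beta + step, -50, 50)
        if np.max(np.abs(step)) < tol:
            break

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.where(info > 0, info, 1.0)), np.nan)
        z = beta / se
    diverged = np.abs(beta) >= 50
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[diverged | ~np.isfinite(z)] = np.nan
    return pd.DataFrame({"beta": beta, "se": se, "z": z, "p": p}, index=features.columns)


def redundancy_filter(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    corr_threshold: float = 0.8,
) -> tuple[tuple[str, ...], list[tuple[str, ...]], pd.Series]:
    """Cluster features by |Spearman| >= threshold (single linkage) and keep
    one prognosis-based representative per cluster.

    Returns ``(representatives, clusters, univariate_p)``.  The output is
    independent of the input column order: ties in p break on the feature id.
    """
    if features.shape[1] < 2:
        cols = tuple(features.columns)
        pvals = univariate_cox(features, time, event)["p"]
        return cols, [cols], pvals

    rho = features.corr(method="spearman").abs().to_numpy()
    np.fill_diagonal(rho, 1.0)
    adj = csr_matrix(rho >= corr_threshold)
    n_comp, labels = connected_components(adj, directed=False)

    pvals = univariate_cox(features, time, event)["p"]
    reps: list[str] = []
    clusters: list[tuple[str, ...]] = []
    cols = np.asarray(features.columns)
    for comp in range(n_comp):
        members = sorted(cols[labels == comp])
        clusters.append(tuple(members))
        member_p = pvals.loc[members].fillna(np.inf)
        reps.append(min(members, key=lambda m: (member_p[m], m)))
    return tuple(sorted(reps)), clusters, pvals


def survival_relevance_filter(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float = 0.05,
) -> tuple[tuple[str, ...], pd.Series]:
    """Keep features with univariate Cox Wald p < alpha (no multiplicity
    correction: a per-feature screen)."""
    if features.shape[0] < 10:
        raise ValueError("need at least 10 patients")
    res = univariate_cox(features, time, event)
    dropped = res["p"].isna()
    if dropped.any():
        warnings.warn(
            f"{int(dropped.sum())} features dropped from the relevancy screen "
            "(non-convergent univariate fit)",
            stacklevel=2,
        )
    keep = tuple(res.index[(res["p"] < alpha).fillna(False)])
    return keep, res["p"]


def _coxnet_path(X, time, event, alphas=None):
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=alphas, n_alphas=50, alpha_min_ratio=0.01, fit_baseline_model=False
    )
    model.fit(X, y)
    return model.alphas_, model.coef_


def lasso_cox_select(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
) -> SelectionResult:
    """L1-penalized Cox selection with the penalty chosen by K-fold
    cross-validated partial-likelihood deviance.

    The held-out deviance of a fold is the glmnet-style difference
    ``-2 [ll_full(beta) - ll_train(beta)]``.  ``lambda_rule`` picks the
    deviance minimum or the 1-SE lambda.  Returns a
    :class:`SelectionResult` carrying the selected ids, the penalized
    coefficients at the chosen lambda, and the full path.
    """
    from sklearn.model_selection import KFold

    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if n_folds < 2:
        raise ValueError("need at least 2 folds")

    alphas, coef_full = _coxnet_path(X, t, e)
    k = min(n_folds, int(e.sum()))
    folds = KFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    dev = np.zeros((k, alphas.size))
    for f_idx, (tr, _) in enumerate(folds.split(X)):
        try:
            alphas_tr, coef_tr = _coxnet_path(X[tr], t[tr], e[tr], alphas=list(alphas))
        except (ArithmeticError, ValueError):
            dev[f_idx] = np.nan
            continue
        dev[f_idx] = np.nan
        for a_idx, alpha in enumerate(alphas):
            # the solver may truncate the requested path; skip missing alphas
            match = np.nonzero(np.isclose(alphas_tr, alpha, rtol=1e-10))[0]
            if match.size == 0:
                continue
            b = coef_tr[:, match[0]]
            ll_full = cox_partial_loglik(X, t, e, b)
            ll_train = cox_partial_loglik(X[tr], t[tr], e[tr], b)
            dev[f_idx, a_idx] = -2.0 * (ll_full - ll_train)

    valid = (~np.isnan(dev)).sum(axis=0) > 0
    mean_dev = np.full(alphas.size, np.inf)
    mean_dev[valid] = np.nanmean(dev[:, valid], axis=0)
    best_idx = int(np.argmin(mean_dev))
    if lambda_rule == "1se":
        se_dev = np.full(alphas.size, np.inf)
        se_dev[valid] = np.nanstd(dev[:, valid], axis=0, ddof=1) / np.sqrt(k)
        bound = mean_dev[best_idx] + se_dev[best_idx]
        # largest penalty whose deviance is within one SE of the minimum
        candidates = np.nonzero(mean_dev <= bound)[0]
        best_idx = int(candidates[np.argmax(alphas[candidates])])
    best_lambda = float(alphas[best_idx])

    coef = pd.Series(coef_full[:, best_idx], index=features.columns, name="coef")
    selected = tuple(coef.index[coef != 0.0])
    if not selected:
        warnings.warn("LASSO selected no features at the chosen penalty", stacklevel=2)
    return SelectionResult(
        stages={"input": tuple(features.columns), "lasso": selected},
        lasso_coef=coef,
        lambda_path=np.asarray(alphas),
        cv_deviance=mean_dev,
        best_lambda=best_lambda,
    )


def run_selection_cascade(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    config: SelectionConfig | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Redundancy -> survival relevancy -> LASSO, on one feature group.

    ``features`` should already be restricted to the candidate group (e.g.
    the volume-independent high-repeatable features) and standardized if the
    config requires it (see :func:`radrep.modeling.standardize_features`).
    """
    config = config or SelectionConfig()
    stages: dict[str, tuple[str, ...]] = {"input": tuple(features.columns)}

    reps, clusters, univ_p = redundancy_filter(
        features, time, event, corr_threshold=config.corr_threshold
    )
    stages["redundancy"] = reps

    relevant, pvals = survival_relevance_filter(
        features[list(reps)], time, event, alpha=config.alpha
    )
    stages["relevancy"] = relevant

    if len(relevant) == 0:
        stages["lasso"] = ()
        return SelectionResult(
            stages=stages, univariate_p=univ_p, clusters=clusters, lasso_coef=None
        )
    lasso = lasso_cox_select(
        features[list(relevant)],
        time,
        event,
        n_folds=config.n_folds,
        seed=seed,
        lambda_rule=config.lambda_rule,
    )
    stages["lasso"] = lasso.selected

    # events-per-variable guard: cap the final model size so that the
    # multivariate fit keeps roughly `epv` events per coefficient
    if config.epv is not None and lasso.selected:
        cap = max(1, int(np.asarray(event).sum() // config.epv))
        if len(lasso.selected) > cap:
            ranked = lasso.lasso_coef.loc[list(lasso.selected)].abs().sort_values(
                ascending=False
            )
            stages["epv_cap"] = tuple(sorted(ranked.index[:cap]))
        else:
            stages["epv_cap"] = lasso.selected

    result = SelectionResult(
        stages=stages,
        univariate_p=univ_p,
        clusters=clusters,
        lasso_coef=lasso.lasso_coef,
        lambda_path=lasso.lambda_path,
        cv_deviance=lasso.cv_deviance,
        best_lambda=lasso.best_lambda,
    )
    result.assert_nested()
    return result
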