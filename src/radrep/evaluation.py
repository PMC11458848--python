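"""Discrimination and stratification metrics for survival models.

Harrell's C-index with bootstrap confidence intervals and paired model
comparison, IPCW time-dependent AUC (cumulative cases / dynamic controls)
with a DeLong comparison at a horizon, Kaplan-Meier curves with the log-rank
test, training-median risk stratification with its hazard ratio, and the
baseline chi-square comparison of categorical cohort characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _harrell_c
from scipy import stats

__all__ = [
    "concordance_index",
    "compare_cindex",
    "censoring_survival",
    "time_dependent_auc",
    "delong_test",
    "km_logrank",
    "RiskStrata",
    "risk_stratify",
    "BaselineComparison",
    "baseline_table",
    "EvaluationReport",
    "evaluate_signature",
]

#: Evaluation horizons in months (1, 2, 3 and 5 years).
DEFAULT_HORIZONS = (12.0, 24.0, 36.0, 60.0)


def concordance_index(
    times,
    events,
    risk_scores,
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Harrell's C with a seeded patient-bootstrap percentile CI.

    Comparable pairs are (i, j) with ``event_i`` and ``time_i < time_j``;
    a pair is concordant when the earlier failure has the higher risk score,
    ties in risk count one half.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = np.asarray(risk_scores, dtype=float)
    c = float(_harrell_c(t, -s, e))
    out = {"c_index": c, "n": t.size}
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, t.size, t.size)
            if e[idx].sum() == 0:
                reps[b] = np.nan
                continue
            reps[b] = _harrell_c(t[idx], -s[idx], e[idx])
        lo, hi = np.nanpercentile(reps, [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100])
        out["ci"] = (float(lo), float(hi))
    return out


def compare_cindex(
    scores_a,
    scores_b,
    times,
    events,
    method: str = "bootstrap_z",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict:
    """Two-sided comparison of two models' C-indices on the same patients.

    ``bootstrap_z``: paired patient bootstrap of the C difference, p from the
    normal deviate of the observed difference against the bootstrap SE.
    ``t_boot``: one-sample t-test of the bootstrap replicate differences
    (kept for fidelity to reporting conventions that quote a Student t-test).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != t.shape:
        raise ValueError("score vectors must align with times/events")
    c_a = float(_harrell_c(t, -a, e))
    c_b = float(_harrell_c(t, -b, e))
    diff = c_a - c_b
    if np.array_equal(a, b):
        return {"c_a": c_a, "c_b": c_b, "diff": 0.0, "p": 1.0, "method": method}
    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = rng.integers(0, t.size, t.size)
        if e[idx].sum() == 0:
            reps[i] = np.nan
            continue
        reps[i] = _harrell_c(t[idx], -a[idx], e[idx]) - _harrell_c(t[idx], -b[idx], e[idx])
    reps = reps[np.isfinite(reps)]
    se = reps.std(ddof=1)
    if se == 0:
        p = 1.0
    elif method == "bootstrap_z":
        p = float(2 * stats.norm.sf(abs(diff) / se))
    elif method == "t_boot":
        p = float(stats.ttest_1samp(reps, 0.0).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"c_a": c_a, "c_b": c_b, "diff": diff, "p": p, "method": method}


def censoring_survival(times, events) -> KaplanMeierFitter:
    """Kaplan-Meier estimate G(t) of the censoring distribution."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), 1 - np.asarray(events, dtype=int))
    return kmf


def time_dependent_auc(
    times,
    events,
    risk_scores,
    horizon: float,
    censoring_km: KaplanMeierFitter | None = None,
) -> float:
    """IPCW time-dependent AUC with cumulative cases / dynamic controls.

    Cases are subjects with an observed event by the horizon, controls those
    still at risk beyond it; cases are weighted by the inverse censoring
    survival 1/G(T_i-).  Without censoring this reduces exactly to the rank
    AUC of the event indicator against the score.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = np.asarray(risk_scores, dtype=float)
    if horizon >= t.max():
        raise ValueError("horizon must lie within follow-up")
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if not cases.any() or not controls.any():
        raise ValueError("no cases or no controls at the requested horizon")
    if censoring_km is None:
        censoring_km = censoring_survival(t, e)
    # left-continuous G at the case's event time (predict returns a scalar
    # for a single query point)
    g = np.atleast_1d(
        np.asarray(censoring_km.predict((t[cases] - 1e-9).clip(min=0.0)), dtype=float)
    )
    w = 1.0 / np.clip(g, 1e-12, None)

    sc, sn = s[cases], s[controls]
    greater = (sc[:, None] > sn[None, :]).astype(float)
    ties = (sc[:, None] == sn[None, :]) * 0.5
    num = float(np.sum(w[:, None] * (greater + ties)))
    den = float(w.sum() * sn.size)
    return num / den


def delong_test(scores_a, scores_b, times, events, horizon: float) -> dict:
    """DeLong comparison of two markers' AUCs at one horizon.

    Cases/controls are the subjects whose status at the horizon is known
    (events by the horizon vs at-risk beyond it); censored-before-horizon
    subjects are excluded, as in the classic binary-outcome DeLong test.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() < 2 or controls.sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls at the horizon")

    def placements(s):
        x, y = s[cases], s[controls]
        v_x = np.array([np.mean((xi > y) + 0.5 * (xi == y)) for xi in x])
        v_y = np.array([np.mean((x > yj) + 0.5 * (x == yj)) for yj in y])
        return float(v_x.mean()), v_x, v_y

    auc_a, vxa, vya = placements(np.asarray(scores_a, dtype=float))
    auc_b, vxb, vyb = placements(np.asarray(scores_b, dtype=float))
    m, n = vxa.size, vya.size
    s10 = np.cov(np.vstack([vxa, vxb]))
    s01 = np.cov(np.vstack([vya, vyb]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(diff) / np.sqrt(var)))
    return {"auc_a": auc_a, "auc_b": auc_b, "diff": diff, "p": p}


def km_logrank(group_labels, times, events) -> dict:
    """Kaplan-Meier curves per group plus the log-rank test."""
    g = np.asarray(group_labels)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    curves = {}
    for label in np.unique(g):
        sel = g == label
        if sel.sum() == 0:
            raise ValueError(f"group {label!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(label))
        curves[str(label)] = kmf
    if len(curves) < 2:
        raise ValueError("need at least 2 non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return {
        "curves": curves,
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
    }


@dataclass(frozen=True)
class RiskStrata:
    """High/low risk labels from a training-median signature cutoff."""

    cutoff: float
    labels: pd.Series  # "high" / "low" per patient
    hazard_ratio: float | None
    hr_ci: tuple[float, float] | None
    degenerate: bool = False


def risk_stratify(scores: pd.Series, cutoff: float, times, events) -> RiskStrata:
    """Label patients by ``score > cutoff`` and estimate the high-vs-low HR
    from a single-covariate Cox model.

    The cutoff must come from training data; validation patients are
    labelled with the unchanged cutoff.  If every patient falls on one side
    the HR is undefined and the result is flagged degenerate.
    """
    labels = pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index)
    high = (labels == "high").astype(int)
    if high.nunique() < 2:
        return RiskStrata(cutoff=cutoff, labels=labels, hazard_ratio=None, hr_ci=None,
                          degenerate=True)
    df = pd.DataFrame({
        "high": high.to_numpy(),
        "T": np.asarray(times, dtype=float),
        "E": np.asarray(events, dtype=int),
    })
    cf = CoxPHFitter()
    cf.fit(df, duration_col="T", event_col="E")
    hr = float(np.exp(cf.params_.iloc[0]))
    lo, hi = np.exp(cf.confidence_intervals_.to_numpy()[0])
    return RiskStrata(cutoff=cutoff, labels=labels, hazard_ratio=hr, hr_ci=(float(lo), float(hi)))


@dataclass(frozen=True)
class BaselineComparison:
    """Per-variable contingency counts and chi-square p (train vs validation)."""

    table: pd.DataFrame  # variable, category, train, validation
    statistics: pd.DataFrame  # variable, chi2, p, dof


def baseline_table(train: pd.DataFrame, validation: pd.DataFrame,
                   variables: list[str] | None = None) -> BaselineComparison:
    """Chi-square comparison of categorical variables between two cohorts.

    2x2 tables use the Yates continuity correction; larger tables the plain
    chi-square.  Categories absent from both cohorts are dropped.
    """
    if variables is None:
        variables = [c for c in train.columns if c in validation.columns]
    rows, stat_rows = [], []
    for var in variables:
        cats = sorted(set(train[var].unique()) | set(validation[var].unique()))
        counts = np.array(
            [[(train[var] == c).sum(), (validation[var] == c).sum()] for c in cats]
        )
        keep = counts.sum(axis=1) > 0
        counts = counts[keep]
        cats = [c for c, k in zip(cats, keep) if k]
        chi2, p, dof, _ = stats.chi2_contingency(counts, correction=True)
        for c, (a, b) in zip(cats, counts):
            rows.append({"variable": var, "category": c, "train": int(a), "validation": int(b)})
        stat_rows.append({"variable": var, "chi2": float(chi2), "p": float(p), "dof": int(dof)})
    return BaselineComparison(
        table=pd.DataFrame(rows), statistics=pd.DataFrame(stat_rows).set_index("variable")
    )


def plot_km_curves(group_labels, times, events, ax=None):
    """Kaplan-Meier curves per risk group with the log-rank p in the title.

    Returns the matplotlib axes (figure creation is left to the caller when
    embedding).
    """
    import matplotlib.pyplot as plt

    res = km_logrank(group_labels, times, events)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, kmf in res["curves"].items():
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"log-rank p = {res['p']:.3g}")
    return ax


@dataclass
class EvaluationReport:
    """Collected discrimination/stratification metrics for one model+cohort."""

    c_index: float
    c_index_ci: tuple[float, float]
    auc: dict[float, float]
    km_logrank_p: float | None
    risk_strata: RiskStrata | None
    n: int


def evaluate_signature(
    scores: pd.Series,
    times,
    events,
    cutoff: float | None = None,
    horizons=DEFAULT_HORIZONS,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> EvaluationReport:
    """One-stop evaluation of a prognostic signature on one cohort."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    ci = concordance_index(t, e, scores.to_numpy(), n_bootstrap=n_bootstrap, seed=seed)
    aucs = {}
    for h in horizons:
        try:
            aucs[h] = time_dependent_auc(t, e, scores.to_numpy(), h)
        except ValueError:
            aucs[h] = float("nan")
    strata = None
    km_p = None
    if cutoff is not None:
        strata = risk_stratify(scores, cutoff, t, e)
        if not strata.degenerate:
            km_p = km_logrank(strata.labels.to_numpy(), t, e)["p"]
    return EvaluationReport(
        c_index=ci["c_index"],
        c_index_ci=ci.get("ci", (float("nan"), float("nan"))),
        auc=aucs,
        km_logrank_p=km_p,
        risk_strata=strata,
        n=t.size,
    )
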