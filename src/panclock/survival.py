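"""Survival analysis: Kaplan-Meier, log-rank, Cox regression, horizon ROC.

Kaplan-Meier curves and the k-group log-rank test come from lifelines, as does
the Cox proportional-hazards fit (Efron tie handling). The fixed-horizon ROC
treats death on or before the horizon as a case and survival beyond it as a
control; samples censored before the horizon are excluded (their count is
logged) and the AUC is the Mann-Whitney concordance of the score between cases
and controls with ties counted one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # per group: columns time, survival
    logrank_chi2: float | None
    logrank_p: float | None
    df: int | None = None


@dataclass
class ROCResult:
    auc: float
    points: pd.DataFrame  # columns fpr, tpr, threshold
    n_cases: int
    n_controls: int
    n_excluded: int


def km_logrank(times, events, group_labels) -> KMResult:
    """Product-limit curves per group plus the k-group log-rank test.

    With a single group the curves are returned and the test is omitted with a
    warning; the test requires at least one event overall.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = pd.Series(group_labels).reset_index(drop=True)
    curves = {}
    for g in groups.dropna().unique():
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        })
    if len(curves) < 2:
        logger.warning("single group supplied; log-rank test omitted")
        return KMResult(curves, None, None)
    res = multivariate_logrank_test(times, groups, events)
    return KMResult(curves, float(res.test_statistic), float(res.p_value),
                    df=len(curves) - 1)


def _check_design(covariates: pd.DataFrame) -> None:
    for col in covariates.columns:
        if covariates[col].nunique() <= 1:
            raise ValueError(f"degenerate design: covariate {col!r} is constant")


def quartile_dummies(labels: pd.Series, reference: str = "Q1") -> pd.DataFrame:
    """Indicator columns for each quartile label except the reference."""
    levels = [l for l in ("Q1", "Q2", "Q3", "Q4") if l != reference]
    return pd.DataFrame({f"{l}_vs_{reference}": (labels == l).astype(float)
                         for l in levels}, index=labels.index)


def cox_regression(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Returns one row per covariate: ``hazard_ratio``, Wald ``ci95_low``,
    ``ci95_high``, ``p`` and the log-hazard ``coef``. Constant covariates raise
    a degenerate-design error; non-convergence propagates with lifelines'
    diagnostics attached.
    """
    covariates = pd.DataFrame(covariates)
    _check_design(covariates)
    n_events = int(np.sum(np.asarray(events, dtype=int)))
    if n_events < covariates.shape[1]:
        raise ValueError(f"{n_events} events cannot identify "
                         f"{covariates.shape[1]} parameters")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    summary = cph.summary
    return pd.DataFrame({
        "coef": summary["coef"],
        "hazard_ratio": summary["exp(coef)"],
        "ci95_low": summary["exp(coef) lower 95%"],
        "ci95_high": summary["exp(coef) upper 95%"],
        "p": summary["p"],
    })


def roc_auc_at_horizon(scores, times, events, horizon_days: float) -> ROCResult:
    """Fixed-horizon survival ROC.

    Cases died on or before ``horizon_days``; controls were followed beyond it
    (alive at the horizon); samples censored before the horizon are excluded.
    The AUC equals the Mann-Whitney concordance of scores for cases versus
    controls (ties count one half).
    """
    if horizon_days <= 0:
        raise ValueError("horizon must be positive")
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    case = (events == 1) & (times <= horizon_days)
    control = times > horizon_days
    excluded = int((~case & ~control).sum())
    if excluded:
        logger.info("horizon ROC: excluded %d sample(s) censored before the "
                    "horizon", excluded)
    n1, n0 = int(case.sum()), int(control.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(f"need at least one case and one control at the "
                         f"horizon (got {n1} cases, {n0} controls)")
    used = case | control
    s = scores[used]
    y = case[used]
    ranks = rankdata(s)  # average ranks handle ties -> half credit
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-s, kind="stable")
    tp = np.cumsum(y[order])
    fp = np.cumsum(~y[order])
    thresholds = s[order]
    keep = np.r_[np.diff(thresholds) != 0, True]  # one point per threshold
    points = pd.DataFrame({
        "fpr": np.r_[0.0, fp[keep] / n0],
        "tpr": np.r_[0.0, tp[keep] / n1],
        "threshold": np.r_[np.inf, thresholds[keep]],
    })
    return ROCResult(float(auc), points, n1, n0, excluded)


def combined_predictor(score, tnm_stage, times, events) -> pd.Series:
    """Linear predictor of a bivariate Cox model on score and TNM stage.

    Fits ``h(t) = h0(t) exp(b1 * score + b2 * stage)`` and returns
    ``b1 * score + b2 * stage`` per sample, suitable for
    :func:`roc_auc_at_horizon`. If one covariate is constant it is dropped and
    the model reduces to the other alone.
    """
    score = pd.Series(np.asarray(score, dtype=float), name="score")
    stage = pd.Series(np.asarray(tnm_stage, dtype=float), name="tnm_stage")
    cov = pd.concat([score, stage], axis=1)
    varying = [c for c in cov.columns if cov[c].nunique() > 1]
    if not varying:
        raise ValueError("degenerate design: both covariates constant")
    if len(varying) < 2:
        logger.warning("constant covariate dropped from combined model: %s",
                       [c for c in cov.columns if c not in varying])
    fit = cox_regression(times, events, cov[varying])
    lp = np.zeros(len(cov))
    for c in varying:
        lp += fit.loc[c, "coef"] * cov[c].to_numpy()
    return pd.Series(lp, name="linear_predictor")
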