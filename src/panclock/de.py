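"""Two-group differential expression with an empirical-Bayes moderated t.

The statistic is the limma-style moderated t for a two-group contrast on
log2-scale expression: per gene the pooled residual variance ``s2`` with ``d``
degrees of freedom is shrunk towards a prior variance ``s0^2`` estimated,
together with its prior degrees of freedom ``d0``, by matching the first two
moments of ``log(s2)`` against the scaled-F sampling model,

    s2_tilde = (d0 * s0^2 + d * s2) / (d0 + d),
    t_mod    = log2fc / (sqrt(s2_tilde) * sqrt(1/n1 + 1/n2)),

with p-values from a t distribution on ``d0 + d`` degrees of freedom and
Benjamini-Hochberg adjustment across genes. When the moment estimate of ``d0``
is non-finite (the observed variances are underdispersed relative to chi-square
sampling noise), ``d0`` falls back to infinity, i.e. complete shrinkage to the
common variance; the fallback is logged.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExprMatrix

logger = logging.getLogger(__name__)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled F prior for gene-wise variances.

    Returns ``(d0, s0_sq)``: prior degrees of freedom (possibly ``inf``) and
    prior variance, estimated from the mean and spread of ``log(s2)``.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.all():
        # zero sample variances carry no spread information; offset them by the
        # smallest positive variance so the log moments stay finite
        floor = s2[ok].min() if ok.any() else 1.0
        s2 = np.maximum(s2, floor * 1e-8)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.sum((e - emean) ** 2) / (n - 1))
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        logger.info("variance moments underdispersed; using complete shrinkage "
                    "(d0 = inf)")
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_values(group) -> pd.DataFrame:
    if isinstance(group, ExprMatrix):
        return group.values
    return group


def moderated_t_de(group1, group2, prior_df: float | None = None,
                   prior_var: float | None = None) -> pd.DataFrame:
    """Moderated-t differential expression, group1 versus group2.

    Both arguments are :class:`~panclock.io.ExprMatrix` or genes x samples
    DataFrames sharing a gene index. Returns a DataFrame indexed by gene with
    columns ``log2fc`` (mean1 - mean2), ``t``, ``p``, ``q`` and ``df_total``.

    ``prior_df``/``prior_var`` override the moment estimates of ``(d0, s0^2)``;
    ``prior_df=0`` recovers the classical pooled two-sample t exactly.
    """
    x1 = _as_values(group1)
    x2 = _as_values(group2)
    if not x1.index.equals(x2.index):
        common = x1.index.intersection(x2.index)
        if len(common) == 0:
            raise ValueError("groups share no gene ids")
        logger.warning("gene universes differ; intersecting to %d genes",
                       len(common))
        x1, x2 = x1.loc[common], x2.loc[common]
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples "
                         f"(got {n1} and {n2})")
    a1, a2 = x1.to_numpy(float), x2.to_numpy(float)
    m1, m2 = a1.mean(axis=1), a2.mean(axis=1)
    log2fc = m1 - m2
    df_resid = n1 + n2 - 2
    ss = ((a1 - m1[:, None]) ** 2).sum(axis=1) + ((a2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    d0, s0_sq = fit_f_dist(s2, df_resid)
    if prior_df is not None:
        d0 = float(prior_df)
    if prior_var is not None:
        s0_sq = float(prior_var)
    if d0 == 0:
        s2_tilde = s2.copy()
        df_total = float(df_resid)
    elif np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "q": q,
         "df_total": np.full(len(s2), df_total), "s2": s2,
         "s2_tilde": s2_tilde},
        index=x1.index.rename("gene"))


def classical_t_de(group1, group2) -> pd.DataFrame:
    """Unmoderated pooled two-sample t on the same contract (the d0 -> 0 limit)."""
    x1, x2 = _as_values(group1), _as_values(group2)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    a1, a2 = x1.to_numpy(float), x2.to_numpy(float)
    m1, m2 = a1.mean(axis=1), a2.mean(axis=1)
    log2fc = m1 - m2
    df = n1 + n2 - 2
    s2 = (((a1 - m1[:, None]) ** 2).sum(axis=1)
          + ((a2 - m2[:, None]) ** 2).sum(axis=1)) / df
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"log2fc": log2fc, "t": t, "p": p, "q": bh_adjust(p),
                         "df_total": float(df), "s2": s2},
                        index=x1.index.rename("gene"))


def cross_cancer_concordance(de_results: Mapping[str, pd.DataFrame],
                             fc_linear: float = 1.5,
                             p_threshold: float = 0.05,
                             use_adjusted: bool = True) -> pd.DataFrame:
    """Count, per gene, the cancer types significantly down/up in tumours.

    A cancer counts as "down" when ``log2fc <= -log2(fc_linear)`` and the
    (adjusted, by default) p-value is below ``p_threshold``; symmetric for
    "up". Gene universes are intersected across cancers with a warning when
    they differ. Returns columns ``n_cancers_down`` and ``n_cancers_up``.
    """
    if not de_results:
        raise ValueError("no DE results supplied")
    tables = list(de_results.values())
    universe = tables[0].index
    for t in tables[1:]:
        universe = universe.intersection(t.index)
    if any(len(t.index) != len(universe) for t in tables):
        logger.warning("inconsistent gene universes across cancers; "
                       "intersecting to %d genes", len(universe))
    if len(universe) == 0:
        raise ValueError("gene universes across cancers do not overlap")
    cut = np.log2(fc_linear)
    col = "q" if use_adjusted else "p"
    down = np.zeros(len(universe), dtype=int)
    up = np.zeros(len(universe), dtype=int)
    for t in tables:
        t = t.loc[universe]
        sig = t[col].to_numpy() < p_threshold
        down += ((t["log2fc"].to_numpy() <= -cut) & sig).astype(int)
        up += ((t["log2fc"].to_numpy() >= cut) & sig).astype(int)
    return pd.DataFrame({"n_cancers_down": down, "n_cancers_up": up},
                        index=universe.rename("gene"))


def deg_between_strata(expr, labels: pd.Series,
                       group1: str = "Q4", group2: str = "Q1",
                       log2fc_threshold: float = 1.5,
                       p_threshold: float = 0.01,
                       use_adjusted: bool = True):
    """DEG calling between two patient strata (default 4th vs 1st quartile).

    The threshold is applied literally on the log2 scale: a gene is a DEG when
    ``|log2fc| > log2fc_threshold`` and its (adjusted by default) p-value is
    below ``p_threshold``. Returns ``(up_set, down_set, table)``.
    """
    values = _as_values(expr)
    labels = labels.reindex(values.columns)
    ids1 = labels.index[labels == group1]
    ids2 = labels.index[labels == group2]
    if len(ids1) == 0 or len(ids2) == 0:
        raise ValueError(f"empty stratum: {group1} has {len(ids1)}, "
                         f"{group2} has {len(ids2)} samples")
    if set(ids1) & set(ids2):
        raise ValueError("strata overlap")
    table = moderated_t_de(values[ids1], values[ids2])
    col = "q" if use_adjusted else "p"
    sig = table[col] < p_threshold
    up = set(table.index[(table["log2fc"] > log2fc_threshold) & sig])
    down = set(table.index[(table["log2fc"] < -log2fc_threshold) & sig])
    return up, down, table


def overlap_and_fisher(deg_sets_a: Mapping[str, Iterable[str]],
                       deg_sets_b: Mapping[str, Iterable[str]],
                       universe: Iterable[str]) -> dict:
    """Compare two families of DEG sets over a common gene universe.

    Returns per-family union counts, per-set sizes, shared-between-family
    overlap, and a two-sided Fisher exact test on the 2x2 table
    [DEG, non-DEG] x [family A, family B] built from the distinct DEG counts.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    union_a = set().union(*[set(s) for s in deg_sets_a.values()]) & universe \
        if deg_sets_a else set()
    union_b = set().union(*[set(s) for s in deg_sets_b.values()]) & universe \
        if deg_sets_b else set()
    m = len(universe)
    table = np.array([[len(union_a), m - len(union_a)],
                      [len(union_b), m - len(union_b)]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "sizes_a": {k: len(set(v) & universe) for k, v in deg_sets_a.items()},
        "sizes_b": {k: len(set(v) & universe) for k, v in deg_sets_b.items()},
        "union_a": len(union_a),
        "union_b": len(union_b),
        "shared": len(union_a & union_b),
        "table": table,
        "odds_ratio": odds,
        "fisher_p": p,
    }
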