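"""Hypoxia-clock crosstalk statistics.

Spearman rank correlation between signature scores (exact permutation p for
small n, t-approximation otherwise), Mann-Whitney tumour-vs-normal comparison,
principal-coordinates ordination with a PERMANOVA permutation test on Euclidean
distances, per-gene score correlation exports (circular-heatmap data), and
hypergeometric over-representation of query gene sets against a GMT collection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .de import bh_adjust
from .io import ExprMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    rho: float
    p: float
    n: int


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    permanova_F: float
    permanova_p: float
    n_permutations: int


EXACT_SPEARMAN_N = 10  # exhaustive n! permutation null up to this size


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho on average ranks."""
    n = len(rx)
    mx, my = rx.mean(), ry.mean()
    sx = rx.std()
    sy = ry.std()
    count = 0
    total = 0
    chunk = 100_000
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        perm = np.asarray(block)
        s = ry[perm] @ rx  # sum of rx[i] * ry[perm[i]] per permutation
        rho_perm = (s / n - mx * my) / (sx * sy)
        count += int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))
        total += len(block)
    return count / total


def spearman_assoc(x_scores, y_scores) -> AssociationResult:
    """Spearman rank-order correlation on average ranks (ties averaged).

    The p-value is exact (full permutation enumeration) for n <= 10 and uses
    the t-approximation above that; a constant vector leaves rho undefined and
    raises.
    """
    x = np.asarray(x_scores, dtype=float)
    y = np.asarray(y_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho is undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return AssociationResult(rho, p, n)


def mannwhitney_test(a_values, b_values) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U counts (a > b) pairs, so fully separated samples
    with every a below every b give U = 0. The null distribution is exact for
    min(n) <= 8 without ties, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _permanova_f(dsq: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from a squared distance matrix and integer group codes."""
    n = dsq.shape[0]
    ss_total = dsq[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 1:
            continue
        sub = dsq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def pcoa_permanova(expr_subset, labels, n_permutations: int = 9999,
                   seed: int = 0) -> OrdinationResult:
    """Metric ordination plus a PERMANOVA test on Euclidean sample distances.

    ``expr_subset`` is a genes x samples matrix restricted to a gene set;
    ``labels`` assigns each sample to a group (e.g. tumour / normal), each
    group needing at least 2 samples. Coordinates come from classical metric
    scaling (principal coordinates); the PERMANOVA pseudo-F is
    ``(SS_between/(g-1)) / (SS_within/(n-g))`` on squared distances with
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` over seeded free
    label permutations.
    """
    values = expr_subset.values if isinstance(expr_subset, ExprMatrix) else expr_subset
    labels = pd.Series(labels)
    if set(values.columns).issubset(set(labels.index)):
        labels = labels.reindex(values.columns)
    elif len(labels) == values.shape[1]:
        labels = pd.Series(labels.to_numpy(), index=values.columns)
    else:
        raise ValueError("labels do not align with the sample columns")
    codes, uniques = pd.factorize(labels)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 samples")
    X = values.to_numpy(float).T  # samples x genes
    from scipy.spatial.distance import pdist, squareform
    dm = squareform(pdist(X, metric="euclidean"))
    dsq = dm ** 2

    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                module="skbio.*")
        ord_res = _skbio_pcoa(
            DistanceMatrix(dm, ids=[str(s) for s in values.columns]),
            warn_neg_eigval=False)
    coords = ord_res.samples.copy()
    coords.index = values.columns

    f_obs = _permanova_f(dsq, codes, n_groups)
    rng = np.random.default_rng(seed)
    n = len(codes)
    ss_total = dsq[np.triu_indices(n, k=1)].sum() / n
    count = 0
    chunk = 512
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = np.empty((m, n), dtype=codes.dtype)
        for i in range(m):
            perms[i] = rng.permutation(codes)
        ss_within = np.zeros(m)
        for g in range(n_groups):
            z = (perms == g).astype(float)  # m x n one-hot for group g
            n_g = counts[g]
            ss_within += np.einsum("pi,ij,pj->p", z, dsq, z) / (2.0 * n_g)
        f_perm = ((ss_total - ss_within) / (n_groups - 1)) \
            / (ss_within / (n - n_groups))
        count += int(np.sum(f_perm >= f_obs - 1e-12))
        done += m
    p = (1 + count) / (1 + n_permutations)
    return OrdinationResult(coords, np.asarray(ord_res.eigvals, dtype=float),
                            float(f_obs), float(p), n_permutations)


def score_gene_correlation(scores: pd.Series, expr, target_genes: Iterable[str]
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate a signature score with individual target genes.

    Returns ``(associations, export)``: per present target gene the Spearman
    rho/p against the score, and the circular-heatmap export table with samples
    sorted by descending score and one expression column per target. Missing
    targets are listed in a warning and skipped.
    """
    values = expr.values if isinstance(expr, ExprMatrix) else expr
    scores = scores.loc[scores.index.intersection(values.columns)]
    present = [g for g in target_genes if g in values.index]
    missing = [g for g in target_genes if g not in values.index]
    if missing:
        logger.warning("target gene(s) absent from the matrix, skipped: %s",
                       missing)
    rows = []
    for g in present:
        res = spearman_assoc(scores.to_numpy(),
                             values.loc[g, scores.index].to_numpy())
        rows.append({"gene": g, "rho": res.rho, "p": res.p, "n": res.n})
    assoc = pd.DataFrame(rows).set_index("gene") if rows else \
        pd.DataFrame(columns=["rho", "p", "n"])
    export = pd.DataFrame({"score": scores})
    for g in present:
        export[g] = values.loc[g, scores.index].to_numpy()
    export = export.sort_values("score", ascending=False, kind="stable")
    return assoc, export


def ora_hypergeometric(query_set: Iterable[str], universe: Iterable[str],
                       gene_set_collection: Mapping[str, Iterable[str]]
                       ) -> pd.DataFrame:
    """Over-representation of a query gene set against a collection.

    Per term the upper-tail hypergeometric p-value of the observed overlap
    (drawing ``len(query)`` genes from the universe), BH-adjusted across terms.
    Query genes outside the universe are dropped with a warning; term members
    are intersected with the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_set_collection:
        raise ValueError("empty gene-set collection")
    query = set(query_set)
    outside = query - universe
    if outside:
        logger.warning("query gene(s) outside the universe dropped: %s",
                       sorted(outside)[:5])
        query &= universe
    m = len(universe)
    n_q = len(query)
    rows = []
    for term, members in gene_set_collection.items():
        members = set(members) & universe
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_q))
        rows.append({"term": term, "overlap": k, "term_size": len(members),
                     "query_size": n_q, "universe_size": m, "p": p})
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable")
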