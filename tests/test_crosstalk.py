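import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from panclock import (mannwhitney_test, ora_hypergeometric, pcoa_permanova,
                      score_gene_correlation, spearman_assoc)


def test_spearman_trivial_cases():
    x = np.arange(20, dtype=float)
    assert spearman_assoc(x, x ** 3).rho == pytest.approx(1.0)
    assert spearman_assoc(x, -x).rho == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="constant"):
        spearman_assoc(x, np.ones(20))


def test_spearman_invariant_under_monotone_transform(rng):
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    r1 = spearman_assoc(x, y)
    r2 = spearman_assoc(np.exp(x), 5 * y - 2)
    assert r1.rho == pytest.approx(r2.rho)
    assert r1.p == pytest.approx(r2.p)


def test_spearman_exact_p_matches_scipy_permutation_oracle(rng):
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])  # includes a tie
    y = np.array([2.0, 1.0, 4.0, 3.0, 3.0, 6.0])
    res = spearman_assoc(x, y)
    assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def statistic(yy):
        return stats.spearmanr(x, yy).statistic

    oracle = stats.permutation_test(
        (y,), lambda yy: np.abs(statistic(yy)),
        permutation_type="pairings", n_resamples=np.inf,
        alternative="greater")
    assert res.p == pytest.approx(oracle.pvalue, rel=1e-9)


def test_spearman_large_n_t_approximation(rng):
    x = rng.normal(size=200)
    y = x + rng.normal(size=200)
    res = spearman_assoc(x, y)
    ref = stats.spearmanr(x, y)
    assert res.rho == pytest.approx(ref.statistic)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


def test_mannwhitney_extremes_and_symmetry():
    u, p = mannwhitney_test([1, 2, 3], [10, 11, 12, 13])
    # the most extreme arrangement: exact two-sided p is 2 / C(7, 3)
    assert u == 0.0 and p == pytest.approx(2 / 35)
    a = np.arange(10, dtype=float)
    u, p = mannwhitney_test(a, a + 0.0)
    assert p >= 0.99


def test_mannwhitney_exact_matches_enumeration_oracle(rng):
    a = np.array([1.3, 4.2, 2.7, 9.9])
    b = np.array([3.1, 5.5, 0.4, 7.2, 8.8])
    u_obs, p_obs = mannwhitney_test(a, b)
    combined = np.r_[a, b]
    na, nb = len(a), len(b)
    centre = na * nb / 2.0
    count = total = 0
    for idx in itertools.combinations(range(na + nb), na):
        aa = combined[list(idx)]
        bb = np.delete(combined, list(idx))
        u = sum(1.0 if x > y else (0.5 if x == y else 0.0)
                for x in aa for y in bb)
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            count += 1
        total += 1
    assert p_obs == pytest.approx(min(1.0, count / total), rel=1e-9)


def test_pcoa_preserves_euclidean_distances(rng):
    genes = [f"G{i}" for i in range(4)]
    samples = [f"S{i}" for i in range(12)]
    expr = pd.DataFrame(rng.normal(size=(4, 12)), index=genes, columns=samples)
    labels = ["a"] * 6 + ["b"] * 6
    res = pcoa_permanova(expr, labels, n_permutations=49, seed=0)
    coords = res.coordinates.to_numpy()
    d_orig = squareform(pdist(expr.to_numpy().T))
    d_coords = squareform(pdist(coords))
    np.testing.assert_allclose(d_coords, d_orig, atol=1e-8)
    eig = res.eigenvalues
    assert (np.diff(eig[eig > 1e-9]) <= 1e-9).all()  # non-increasing


def test_permanova_floor_for_perfectly_separated_clusters(rng):
    expr = pd.DataFrame(
        np.c_[rng.normal(0, 0.01, (3, 8)), rng.normal(50, 0.01, (3, 8))],
        index=["G1", "G2", "G3"], columns=[f"S{i}" for i in range(16)])
    labels = ["t"] * 8 + ["n"] * 8
    res = pcoa_permanova(expr, labels, n_permutations=199, seed=1)
    assert res.permanova_p == pytest.approx(1 / 200)
    assert res.permanova_F > 100


def test_permanova_matches_skbio_reference(rng):
    from skbio import DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova
    expr = pd.DataFrame(rng.normal(size=(5, 20)),
                        index=[f"G{i}" for i in range(5)],
                        columns=[f"S{i}" for i in range(20)])
    labels = ["a"] * 10 + ["b"] * 10
    res = pcoa_permanova(expr, labels, n_permutations=999, seed=2)
    dm = DistanceMatrix(squareform(pdist(expr.to_numpy().T)),
                        ids=list(expr.columns))
    ref = skbio_permanova(dm, list(labels), permutations=999, seed=7)
    assert res.permanova_F == pytest.approx(ref["test statistic"], rel=1e-9)
    assert abs(res.permanova_p - ref["p-value"]) < 0.05  # Monte-Carlo error


def test_permanova_p_stable_under_joint_reordering(rng):
    expr = pd.DataFrame(rng.normal(size=(4, 18)),
                        index=[f"G{i}" for i in range(4)],
                        columns=[f"S{i}" for i in range(18)])
    labels = np.array(["a"] * 9 + ["b"] * 9)
    res1 = pcoa_permanova(expr, labels, n_permutations=999, seed=3)
    perm = rng.permutation(18)
    res2 = pcoa_permanova(expr.iloc[:, perm], labels[perm],
                          n_permutations=999, seed=3)
    assert res2.permanova_F == pytest.approx(res1.permanova_F, rel=1e-9)
    assert abs(res2.permanova_p - res1.permanova_p) < 0.05


def test_permanova_requires_two_groups(rng):
    expr = pd.DataFrame(rng.normal(size=(3, 6)))
    with pytest.raises(ValueError, match="2 groups"):
        pcoa_permanova(expr, ["a"] * 6, n_permutations=9, seed=0)


def test_score_gene_correlation_contract(rng, caplog):
    samples = [f"S{i}" for i in range(30)]
    score = pd.Series(rng.normal(size=30), index=samples)
    expr = pd.DataFrame(rng.normal(size=(2, 30)), index=["CA9", "VEGFA"],
                        columns=samples)
    expr.loc["CA9"] = score.to_numpy()  # target equal to the score itself
    with caplog.at_level(logging.WARNING):
        assoc, export = score_gene_correlation(score, expr,
                                               ["CA9", "VEGFA", "LDHA"])
    assert assoc.loc["CA9", "rho"] == pytest.approx(1.0)
    assert "LDHA" not in assoc.index
    assert any("LDHA" in rec.message for rec in caplog.records)
    assert (np.diff(export["score"].to_numpy()) <= 0).all()
    assert list(export.columns) == ["score", "CA9", "VEGFA"]


def test_ora_closed_form_and_null():
    universe = [f"g{i}" for i in range(20)]
    collection = {"term": universe[:5], "other": universe[10:13]}
    res = ora_hypergeometric(universe[:5], universe, collection)
    assert res.loc["term", "p"] == pytest.approx(1 / 15504, rel=1e-12)
    res0 = ora_hypergeometric(universe[5:10], universe,
                              {"term": universe[:3]})
    assert res0.loc["term", "overlap"] == 0
    assert res0.loc["term", "p"] >= 0.5


def test_ora_matches_tail_sum_oracle(rng):
    universe = [f"g{i}" for i in range(40)]
    query = list(rng.choice(universe, size=12, replace=False))
    term = list(rng.choice(universe, size=9, replace=False))
    res = ora_hypergeometric(query, universe, {"t": term})
    k = len(set(query) & set(term))
    oracle = sum(stats.hypergeom.pmf(j, 40, 9, 12)
                 for j in range(k, min(9, 12) + 1))
    assert res.loc["t", "p"] == pytest.approx(oracle, rel=1e-9)


def test_ora_query_outside_universe_warned(caplog):
    universe = ["a", "b", "c", "d"]
    with caplog.at_level(logging.WARNING):
        res = ora_hypergeometric(["a", "zzz"], universe, {"t": ["a", "b"]})
    assert res.loc["t", "query_size"] == 1
    assert any("zzz" in rec.message for rec in caplog.records)
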