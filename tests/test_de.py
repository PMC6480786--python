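import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panclock import (bh_adjust, cross_cancer_concordance, deg_between_strata,
                      moderated_t_de, overlap_and_fisher)


def test_identical_groups_give_zero_fc_unit_p(rng):
    x = pd.DataFrame(rng.normal(size=(20, 6)), index=[f"G{i}" for i in range(20)])
    res = moderated_t_de(x, x.copy())
    assert np.allclose(res["log2fc"], 0)
    assert np.allclose(res["p"], 1)


def test_zero_prior_df_recovers_classical_pooled_t(rng):
    g1 = pd.DataFrame(rng.normal(size=(40, 8)), index=[f"G{i}" for i in range(40)])
    g2 = pd.DataFrame(rng.normal(size=(40, 10)), index=g1.index)
    res = moderated_t_de(g1, g2, prior_df=0)
    t_ref, p_ref = stats.ttest_ind(g1, g2, axis=1, equal_var=True)
    np.testing.assert_allclose(res["t"], t_ref, rtol=1e-10)
    np.testing.assert_allclose(res["p"], p_ref, rtol=1e-10)


def test_planted_shift_recovered(rng):
    genes = [f"G{i}" for i in range(100)]
    g1 = pd.DataFrame(rng.normal(8.0, 0.1, (100, 50)), index=genes)
    g2 = pd.DataFrame(rng.normal(8.0, 0.1, (100, 50)), index=genes)
    g1.iloc[0] -= 1.0
    res = moderated_t_de(g1, g2)
    assert res.iloc[0]["q"] < 0.05
    assert abs(res.iloc[0]["log2fc"] + 1.0) < 0.1
    assert res.iloc[1:]["log2fc"].abs().max() < 0.2


def test_variance_shrinkage_envelope(rng):
    from panclock.de import fit_f_dist
    g1 = pd.DataFrame(rng.normal(size=(60, 5)))
    g2 = pd.DataFrame(rng.normal(size=(60, 5)))
    res = moderated_t_de(g1, g2)
    s2 = res["s2"].to_numpy()
    s2t = res["s2_tilde"].to_numpy()
    d0, s0_sq = fit_f_dist(s2, 8)
    # posterior variance is a convex combination of the gene and prior variances
    lo = np.minimum(s2, s0_sq) - 1e-12
    hi = np.maximum(s2, s0_sq) + 1e-12
    assert ((s2t >= lo) & (s2t <= hi)).all()


def test_bh_hand_example_and_single_value():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.5])[0] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def _bh_oracle(p):
    """Naive O(m^2) step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q[idx] = min(min(p[order[j - 1]] * m / j
                         for j in range(rank, m + 1)), 1.0)
    return q


def test_bh_matches_min_over_tail_oracle_and_permutation(rng):
    p = rng.random(37)
    np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), rtol=1e-12)
    perm = rng.permutation(37)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), rtol=1e-12)


def _de_frame(log2fc, q):
    idx = pd.Index([f"G{i}" for i in range(len(log2fc))], name="gene")
    return pd.DataFrame({"log2fc": log2fc, "p": q, "q": q}, index=idx)


def test_concordance_counts_and_linear_fc_boundary():
    down = _de_frame([-1.0, -0.5, -1.0], [0.001, 0.001, 1.0])
    results = {f"C{i}": down for i in range(9)}
    conc = cross_cancer_concordance(results, fc_linear=1.5, p_threshold=0.05)
    assert conc.loc["G0", "n_cancers_down"] == 9
    # |log2fc| = 0.5 is below the log2(1.5) = 0.585 cut
    assert conc.loc["G1", "n_cancers_down"] == 0
    # significant filter fails for G2 (p = 1) despite the fold change
    assert conc.loc["G2", "n_cancers_down"] == 0
    assert (conc["n_cancers_up"] == 0).all()


def test_deg_between_strata_threshold_is_log2_scale(rng):
    genes = [f"G{i}" for i in range(50)]
    samples = [f"S{i}" for i in range(80)]
    expr = pd.DataFrame(rng.normal(8, 0.2, (50, 80)), index=genes,
                        columns=samples)
    labels = pd.Series(["Q1"] * 40 + ["Q4"] * 40, index=samples)
    expr.loc["G0", labels == "Q4"] += 2.0   # clear DEG
    expr.loc["G1", labels == "Q4"] += 1.4   # below the log2 threshold of 1.5
    up, down, table = deg_between_strata(expr, labels)
    assert "G0" in up and "G1" not in up and not down

    same = pd.DataFrame(np.tile(rng.normal(8, 0.2, (50, 1)), (1, 80)),
                        index=genes, columns=samples)
    same += rng.normal(0, 1e-6, same.shape)
    up2, down2, _ = deg_between_strata(same, labels)
    assert not up2 and not down2

    with pytest.raises(ValueError, match="empty stratum"):
        deg_between_strata(expr, pd.Series("Q2", index=samples))


def _fisher_two_sided_oracle(table):
    """Exact two-sided p by summing hypergeometric outcomes as or less likely."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    support = range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = {k: stats.hypergeom.pmf(k, n, row1, col1) for k in support}
    p_obs = pmf[a]
    return sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-9))


def test_fisher_matches_exact_tail_sum_oracle():
    table = [[10, 90], [50, 50]]
    res = overlap_and_fisher({"c": [f"g{i}" for i in range(10)]},
                             {"c": [f"g{i}" for i in range(50)]},
                             universe=[f"g{i}" for i in range(100)])
    # the helper builds the same 2x2 table from the union counts
    assert res["table"].tolist() == table
    assert res["fisher_p"] == pytest.approx(_fisher_two_sided_oracle(table),
                                            rel=1e-9)


def test_fisher_symmetry_and_disjoint_overlap():
    fam = {"x": ["g1", "g2", "g3"]}
    res = overlap_and_fisher(fam, fam, universe=[f"g{i}" for i in range(20)])
    assert res["odds_ratio"] == pytest.approx(1.0)
    assert res["fisher_p"] == pytest.approx(1.0)
    res2 = overlap_and_fisher({"x": ["g1", "g2", "g3"]},
                              {"y": ["g4", "g5", "g6", "g7"]},
                              universe=[f"g{i}" for i in range(20)])
    assert res2["shared"] == 0
    with pytest.raises(ValueError, match="universe"):
        overlap_and_fisher(fam, fam, universe=[])


def test_small_group_errors(rng):
    g = pd.DataFrame(rng.normal(size=(5, 1)))
    with pytest.raises(ValueError, match="at least 2 samples"):
        moderated_t_de(g, pd.DataFrame(rng.normal(size=(5, 4))))
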