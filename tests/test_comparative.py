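"""Phylogenetic comparative statistics against independent oracles."""
import math

import numpy as np
import pandas as pd
import pytest

from ormine import (
    PhyloTree,
    ancestral_states,
    balanced_tree,
    fit_bm,
    fit_multivariate,
    fit_ou,
    pagel_lambda,
    pca_families,
    phylo_tukey,
    qc_correlation,
    random_coalescent_tree,
    simulate,
    star_tree,
)
from ormine.comparative import _lambda_cov, _profiled_loglik


@pytest.fixture(scope="module")
def tree64():
    return balanced_tree(64)


def _grid_lambda(tree, y, npoints=1001):
    _, C = tree.vcv()
    X = np.ones((len(y), 1))
    grid = np.linspace(0.0, 1.0, npoints)
    lls = [_profiled_loglik(_lambda_cov(C, l), X, np.asarray(y))[2] for l in grid]
    return grid[int(np.argmax(lls))]


def test_lambda_zero_equals_iid_loglik(tree64):
    """On an ultrametric tree, lambda=0 collapses the model to iid normals."""
    y = simulate.simulate_traits(tree64, "BM", seed=1)["rep0"].to_numpy()
    _, C = tree64.vcv()
    ll0 = _profiled_loglik(_lambda_cov(C, 0.0), np.ones((64, 1)), y)[2]
    mu, s2 = y.mean(), y.var()
    iid = -0.5 * 64 * (math.log(2 * math.pi * s2) + 1)
    assert ll0 == pytest.approx(iid, abs=1e-9)


def test_lambda_bm_simulation_matches_grid_oracle(tree64):
    y = simulate.simulate_traits(tree64, "BM", sigma2=1.0, seed=11)["rep0"]
    res = pagel_lambda(tree64, y)
    assert res.lambda_ >= 0.9
    assert res.p_value < 0.05
    assert abs(res.lambda_ - _grid_lambda(tree64, y)) <= 1e-3


def test_lambda_vanishes_on_permuted_tips(tree64):
    y = simulate.simulate_traits(tree64, "BM", sigma2=1.0, seed=11)["rep0"]
    rng = np.random.default_rng(12)
    perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
    res = pagel_lambda(tree64, perm)
    assert res.lambda_ <= 0.1
    assert abs(res.lambda_ - _grid_lambda(tree64, perm)) <= 1e-3


def test_lambda_one_equals_bm_loglik(tree64):
    y = simulate.simulate_traits(tree64, "BM", seed=2)["rep0"]
    _, C = tree64.vcv()
    ll1 = _profiled_loglik(_lambda_cov(C, 1.0), np.ones((64, 1)), y.to_numpy())[2]
    assert fit_bm(tree64, y).loglik == pytest.approx(ll1, abs=1e-9)


@pytest.mark.parametrize("a,b", [(1.0, 0.0), (3.5, -2.0), (-0.25, 10.0)])
def test_lambda_invariant_to_affine_transform(tree64, a, b):
    y = simulate.simulate_traits(tree64, "BM", seed=3)["rep0"]
    lam0 = pagel_lambda(tree64, y).lambda_
    lam1 = pagel_lambda(tree64, a * y + b).lambda_
    assert lam1 == pytest.approx(lam0, abs=1e-4)


def test_lambda_input_validation(tree64):
    const = pd.Series(1.0, index=tree64.tips)
    with pytest.raises(ValueError):
        pagel_lambda(tree64, const)
    with pytest.raises(ValueError):
        pagel_lambda(tree64, {t: 0.0 for t in tree64.tips[:10]})


# ----------------------------------------------------------------------
# BM / OU


def test_bm_two_tip_closed_form():
    t1, t2 = 2.0, 0.5
    x1, x2 = 1.3, -0.4
    tree = PhyloTree.from_newick(f"(a:{t1},b:{t2});")
    fit = fit_bm(tree, {"a": x1, "b": x2})
    mu = (x1 / t1 + x2 / t2) / (1 / t1 + 1 / t2)
    s2 = (x1 - x2) ** 2 / (2 * (t1 + t2))
    assert fit.params["z0"] == pytest.approx(mu, abs=1e-9)
    assert fit.params["sigma2"] == pytest.approx(s2, abs=1e-9)
    assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)


def test_bm_constant_trait_flags_boundary(tree64):
    fit = fit_bm(tree64, pd.Series(2.5, index=tree64.tips))
    assert fit.boundary
    assert fit.params["sigma2"] == 0.0


def test_bm_sigma2_recovery_bias(tree64):
    """ML rate estimates over 200 replicates: relative bias below 5%."""
    reps = simulate.simulate_traits(tree64, "BM", sigma2=2.0, replicates=200, seed=21)
    est = [fit_bm(tree64, reps[c]).params["sigma2"] for c in reps.columns]
    assert abs(np.mean(est) / 2.0 - 1.0) < 0.05


def test_ou_two_regime_recovery(tree64):
    """alpha=5, optima {0, 3}: mean optimum error < 0.3 and OU beats BM
    on AIC in at least 90 of 100 replicates."""
    reg = {t: ("A" if i % 2 == 0 else "B") for i, t in enumerate(tree64.tips)}
    errs, ou_wins = [], 0
    for rep in range(100):
        y = simulate.simulate_traits(
            tree64, "OU", sigma2=10.0, alpha=5.0,
            optima={"A": 0.0, "B": 3.0}, regimes=reg, seed=1300 + rep,
        )["rep0"]
        fo = fit_ou(tree64, y, regimes=reg)
        fb = fit_bm(tree64, y)
        errs.append(0.5 * (abs(fo.params["theta[A]"]) + abs(fo.params["theta[B]"] - 3)))
        ou_wins += fo.aic < fb.aic
    assert np.mean(errs) < 0.3
    assert ou_wins >= 90


def test_ou_rejects_non_ultrametric():
    tree = PhyloTree.from_newick("(a:1.0,(b:0.5,c:2.0):1.0);")
    with pytest.raises(ValueError, match="ultrametric"):
        fit_ou(tree, {"a": 0.0, "b": 1.0, "c": 2.0})


# ----------------------------------------------------------------------
# phylogenetic Tukey


def _ols_tukey_oracle(tips, y, groups, n_draws, seed):
    levels = sorted(set(groups.values()))
    X = np.zeros((len(tips), len(levels)))
    for i, t in enumerate(tips):
        X[i, levels.index(groups[t])] = 1.0
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ b
    s2 = r @ r / (len(y) - len(levels))
    covb = s2 * np.linalg.inv(X.T @ X)
    pairs = [(a, c) for i, a in enumerate(levels) for c in levels[i + 1 :]]
    K = np.zeros((len(pairs), len(levels)))
    for row, (a, c) in enumerate(pairs):
        K[row, levels.index(c)] = 1.0
        K[row, levels.index(a)] = -1.0
    est = K @ b
    covc = K @ covb @ K.T
    se = np.sqrt(np.diag(covc))
    return est, se, est / se


def test_tukey_star_tree_equals_ols_oracle():
    tree = star_tree([f"s{i}" for i in range(30)])
    groups = {f"s{i}": f"g{i % 3}" for i in range(30)}
    y = pd.Series(np.random.default_rng(1).normal(size=30), index=tree.tips)
    res = phylo_tukey(tree, y, groups, n_draws=5000, seed=99)
    est, se, z = _ols_tukey_oracle(tree.tips, y.to_numpy(), groups, 5000, 99)
    assert np.allclose(res.table["estimate"], est, atol=1e-9)
    assert np.allclose(res.table["se"], se, atol=1e-9)
    assert np.allclose(res.table["z"], z, atol=1e-9)


def test_tukey_null_familywise_error(tree64):
    """BM null, 3 groups, 500 replicates: FWE at nominal 0.05 stays <= 0.07."""
    groups = {t: f"g{i % 3}" for i, t in enumerate(tree64.tips)}
    rejections = 0
    for rep in range(500):
        y = simulate.simulate_traits(tree64, "BM", seed=1400 + rep)["rep0"]
        res = phylo_tukey(tree64, y, groups, n_draws=2000, seed=rep)
        rejections += bool((res.table["p_adj"] < 0.05).any())
    assert rejections / 500 <= 0.07


def test_tukey_power_finds_planted_shift(tree64):
    """A 2-phylogenetic-SD group shift: the top contrast involves the
    shifted group in at least 80 of 100 replicates."""
    groups = {t: f"g{i % 3}" for i, t in enumerate(tree64.tips)}
    psd = math.sqrt(tree64.depth())
    hits = 0
    for rep in range(100):
        y = simulate.simulate_traits(tree64, "BM", seed=1500 + rep)["rep0"]
        shift = pd.Series(
            [2 * psd if groups[t] == "g2" else 0.0 for t in tree64.tips],
            index=tree64.tips,
        )
        res = phylo_tukey(tree64, y + shift, groups, n_draws=2000, seed=rep)
        top = res.table.sort_values("p_adj").iloc[0]
        hits += "g2" in (top["group_a"], top["group_b"])
    assert hits >= 80


def test_tukey_adjusted_never_below_raw(tree64):
    groups = {t: f"g{i % 2}" for i, t in enumerate(tree64.tips)}
    y = simulate.simulate_traits(tree64, "BM", seed=77)["rep0"]
    for method in ("single-step", "holm"):
        res = phylo_tukey(tree64, y, groups, method=method, n_draws=2000, seed=1)
        assert (res.table["p_adj"] >= res.table["p_raw"] - 1e-12).all()
        assert res.table["p_adj"].between(0, 1).all()


def test_tukey_group_validation(tree64):
    with pytest.raises(ValueError):
        phylo_tukey(tree64, simulate.simulate_traits(tree64, seed=1)["rep0"],
                    {t: "g0" for t in tree64.tips})


# ----------------------------------------------------------------------
# multivariate fits


def test_multivariate_single_trait_consistency(tree64):
    y = simulate.simulate_traits(tree64, "BM", seed=31)["rep0"]
    eco = simulate.make_ecology(tree64.tips, seed=3)
    fits, _ = fit_multivariate(
        tree64, y.to_frame("trait"), eco, models=("BM", "OU:lifestyle")
    )
    by_model = {f.model: f for f in fits}
    bm_uni = fit_bm(tree64, y)
    assert by_model["BM"].loglik == pytest.approx(bm_uni.loglik, abs=1e-6)
    assert by_model["BM"].aic == pytest.approx(bm_uni.aic, abs=1e-6)
    ou_uni = fit_ou(
        tree64, y, regimes={t: eco.loc[t, "lifestyle"] for t in tree64.tips}
    )
    assert by_model["OU:lifestyle"].loglik == pytest.approx(ou_uni.loglik, abs=1e-4)
    assert by_model["OU:lifestyle"].k == ou_uni.k


def test_multivariate_rejects_p_ge_n():
    tree = balanced_tree(8)
    Y = pd.DataFrame(np.eye(8), index=tree.tips)
    with pytest.raises(ValueError, match="traits"):
        fit_multivariate(tree, Y)


def test_multivariate_model_recovery(tree64):
    """BM data ranks BM first; OU-with-lifestyle data ranks OU:lifestyle
    first, in at least 80 of 100 replicates each."""
    species = tree64.tips
    eco = simulate.make_ecology(species, seed=3)
    models = ("BM", "OU:lifestyle", "OU:diet", "OU:activity", "OU:all")
    _, C = tree64.vcv()
    _, D = tree64.patristic_distances()
    p = 13
    L = np.linalg.cholesky(C + 1e-12 * np.eye(64))
    bm_first = 0
    for rep in range(100):
        rng = np.random.default_rng(1600 + rep)
        Y = pd.DataFrame(L @ rng.standard_normal((64, p)), index=species)
        fits, _ = fit_multivariate(tree64, Y, eco, models)
        bm_first += fits[0].model == "BM"
    assert bm_first >= 80

    alpha = 5.0
    Lou = np.linalg.cholesky(np.exp(-alpha * D) + 1e-12 * np.eye(64))
    lv = sorted(set(eco["lifestyle"]))
    mean = np.array([3.0 * lv.index(eco.loc[s, "lifestyle"]) for s in species])
    ou_first = 0
    for rep in range(100):
        rng = np.random.default_rng(1700 + rep)
        Y = pd.DataFrame(
            mean[:, None] + Lou @ rng.standard_normal((64, p)), index=species
        )
        fits, anova = fit_multivariate(tree64, Y, eco, models)
        ou_first += fits[0].model == "OU:lifestyle"
    assert ou_first >= 80


# ----------------------------------------------------------------------
# PCA


def test_pca_two_variable_closed_form():
    rng = np.random.default_rng(5)
    r = 0.6
    Z = rng.standard_normal((200, 2)) @ np.linalg.cholesky(
        np.array([[1, r], [r, 1]])
    ).T
    df = pd.DataFrame(Z, columns=["a", "b"], index=[f"s{i}" for i in range(200)])
    res = pca_families(df)
    emp_r = np.corrcoef(Z.T)[0, 1]
    assert res.explained[0] == pytest.approx(100 * (1 + emp_r) / 2, abs=1e-8)
    assert res.explained.sum() == pytest.approx(100.0, abs=1e-9)


def test_pca_reconstruction_and_orthonormal_loadings():
    rng = np.random.default_rng(6)
    df = pd.DataFrame(
        rng.standard_normal((20, 5)) + rng.standard_normal((20, 1)),
        index=[f"s{i}" for i in range(20)],
        columns=list("abcde"),
    )
    res = pca_families(df)
    W = res.loadings.to_numpy()
    assert np.allclose(W.T @ W, np.eye(5), atol=1e-9)
    Z = (df - df.mean()) / df.std(ddof=1)
    assert np.allclose(res.scores.to_numpy() @ W.T, Z.to_numpy(), atol=1e-9)
    # sign convention: the largest-magnitude loading per column is positive
    for j in range(W.shape[1]):
        assert W[np.argmax(np.abs(W[:, j])), j] > 0


def test_pca_zero_variance_column_named():
    df = pd.DataFrame(
        {"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]}, index=["x", "y", "z"]
    )
    with pytest.raises(ValueError, match="b"):
        pca_families(df)


# ----------------------------------------------------------------------
# ancestral states


def test_ancestral_two_tip_root_closed_form():
    t1, t2 = 2.0, 0.5
    x1, x2 = 1.3, -0.4
    tree = PhyloTree.from_newick(f"(a:{t1},b:{t2});")
    anc = ancestral_states(tree, {"a": x1, "b": x2})
    mu = (x1 / t1 + x2 / t2) / (1 / t1 + 1 / t2)
    assert anc.loc["root", "estimate"] == pytest.approx(mu, abs=1e-9)


def test_ancestral_constant_trait():
    tree = random_coalescent_tree(6, seed=4)
    anc = ancestral_states(tree, {t: 3.14 for t in tree.tips})
    assert np.allclose(anc["estimate"], 3.14)
    assert np.allclose(anc["variance"], 0.0, atol=1e-12)


@pytest.mark.parametrize("n_tips,seed", [(5, 18), (8, 18), (10, 19)])
def test_ancestral_matches_brute_force_gls_oracle(n_tips, seed):
    tree = random_coalescent_tree(n_tips, seed=seed)
    y = simulate.simulate_traits(tree, "BM", seed=seed)["rep0"]
    est = ancestral_states(tree, y)
    _, C = tree.vcv()
    _, Cnt, _ = tree.node_tip_cov()
    Vi = np.linalg.inv(C)
    ones = np.ones(n_tips)
    z0 = (ones @ Vi @ y.to_numpy()) / (ones @ Vi @ ones)
    oracle = z0 + Cnt @ Vi @ (y.to_numpy() - z0)
    assert np.allclose(est["estimate"].to_numpy(), oracle, atol=1e-8)


# ----------------------------------------------------------------------
# assembly-QC correlations


def test_qc_correlation_exact_linear():
    x = np.arange(10.0)
    r, t, p = qc_correlation(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(0.0, abs=1e-12)


def test_qc_correlation_orthogonal_pair():
    x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    y = np.array([1.0, -1.0, 0.0, 1.0, -1.0])
    y = y - (x @ y) / (x @ x) * x
    r, _, _ = qc_correlation(x, y)
    assert abs(r) < 1e-12


def test_qc_correlation_textbook_formula():
    rng = np.random.default_rng(9)
    x = rng.normal(size=10)
    y = 0.5 * x + rng.normal(size=10)
    r, t, p = qc_correlation(x, y)
    oracle = ((x - x.mean()) @ (y - y.mean())) / math.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert r == pytest.approx(oracle, abs=1e-12)
    assert t == pytest.approx(r * math.sqrt(8 / (1 - r * r)), abs=1e-10)


def test_qc_correlation_validation():
    with pytest.raises(ValueError):
        qc_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        qc_correlation([1.0, 2.0], [1.0, 2.0])
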