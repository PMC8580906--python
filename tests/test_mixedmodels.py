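"""Kernel BLUP engines, BayesB, and the multi-trait model."""

import numpy as np
import pandas as pd
import pytest

from omicpred.kernels import RelationshipKernel, compute_grm, stabilize_kernel
from omicpred.mixedmodels import (
    fit_bayesb,
    fit_multi_kernel,
    fit_multitrait,
    fit_single_kernel,
    predict_new_lines,
    two_kernel_fit,
)
from omicpred.simdata import EnvCovariance, TraitArchitecture, simulate_line_values


def _chol_draw(rng, K, scale=1.0):
    w, V = np.linalg.eigh(K)
    L = V @ np.diag(np.sqrt(np.maximum(w, 0)))
    return scale * (L @ rng.normal(size=K.shape[0]))


# ---------------------------------------------------------------------------
# single kernel
# ---------------------------------------------------------------------------


def test_identity_kernel_shrinkage_closed_form():
    """K=I: BLUPs are centered values shrunk by s_g/(s_g+s_e)."""
    rng = np.random.default_rng(0)
    n = 120
    y = pd.Series(rng.normal(size=n), index=[f"l{i}" for i in range(n)])
    K = RelationshipKernel(np.eye(n), list(y.index))
    fit = fit_single_kernel(y, K)
    sg, se = fit.varcomps["G"], fit.varcomps["residual"]
    shrink = sg / (sg + se)
    np.testing.assert_allclose(
        fit.blups["G"], shrink * (y.to_numpy() - fit.beta[0]), atol=1e-8
    )


def test_reml_beats_random_variance_points(grm):
    """REML log-likelihood exceeds the restricted likelihood at 50 random
    variance pairs (grid oracle computed from the V-matrix definition)."""
    rng = np.random.default_rng(1)
    ids = grm.line_ids[:80]
    K = grm.align(ids)
    g = _chol_draw(rng, K.matrix)
    y = pd.Series(g + rng.normal(size=80), index=ids)
    fit = fit_single_kernel(y, K)

    def restricted_ll(sg, se):
        V = sg * K.matrix + se * np.eye(80)
        X = np.ones((80, 1))
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        b = np.linalg.solve(XtViX, X.T @ Vi @ y.to_numpy())
        r = y.to_numpy() - (X @ b).ravel()
        _, ld = np.linalg.slogdet(V)
        _, ldx = np.linalg.slogdet(XtViX)
        _, ldxx = np.linalg.slogdet(X.T @ X)
        return -0.5 * (ld + ldx - ldxx + r @ Vi @ r + 79 * np.log(2 * np.pi))

    ll_hat = restricted_ll(fit.varcomps["G"], fit.varcomps["residual"])
    for _ in range(50):
        sg, se = rng.uniform(0.01, 5, size=2)
        assert restricted_ll(sg, se) <= ll_hat + 1e-6


def test_single_kernel_h2_recovery(grm):
    """h2=0.5 traits: mean estimated h2 within the Monte-Carlo band."""
    rng = np.random.default_rng(2)
    K = grm
    diag = float(np.mean(np.diag(K.matrix)))
    h2s = []
    for _ in range(15):
        g = _chol_draw(rng, K.matrix)
        g = g / g.std()
        y = pd.Series(g + rng.normal(size=K.n), index=K.line_ids)
        fit = fit_single_kernel(y, K)
        sg, se = fit.varcomps["G"], fit.varcomps["residual"]
        h2s.append(sg * diag / (sg * diag + se))
    assert 0.42 < np.mean(h2s) < 0.58


def test_non_psd_rejected():
    M = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])  # eigenvalue -1
    K = RelationshipKernel(M, ["a", "b", "c"])
    y = pd.Series([0.1, -0.2, 0.3], index=["a", "b", "c"])
    with pytest.raises(ValueError, match="PSD"):
        fit_single_kernel(y, K)


# ---------------------------------------------------------------------------
# multi-kernel
# ---------------------------------------------------------------------------


def test_duplicate_kernel_aliasing(grm):
    """Same kernel twice: component split is unidentifiable but the SUM of
    components and the total genetic variance match the single-kernel fit."""
    rng = np.random.default_rng(3)
    ids = grm.line_ids[:100]
    K = grm.align(ids)
    y = pd.Series(_chol_draw(rng, K.matrix) + 0.8 * rng.normal(size=100), index=ids)
    single = fit_single_kernel(y, K)
    double = fit_multi_kernel(y, [K, K], tol=1e-10, max_iter=2000)
    tot_single = single.varcomps["G"]
    tot_double = double.varcomps["G"] + double.varcomps["G2"]
    assert tot_double == pytest.approx(tot_single, rel=0.02)
    np.testing.assert_allclose(
        double.blups["G"] + double.blups["G2"], single.blups["G"], atol=1e-3
    )


def test_multi_kernel_single_reduces_to_single(grm):
    rng = np.random.default_rng(4)
    ids = grm.line_ids[:90]
    K = grm.align(ids)
    y = pd.Series(_chol_draw(rng, K.matrix) + rng.normal(size=90), index=ids)
    f1 = fit_single_kernel(y, K)
    fm = fit_multi_kernel(y, [K], tol=1e-11, max_iter=3000)
    assert fm.varcomps["G"] == pytest.approx(f1.varcomps["G"], rel=5e-3)
    assert fm.varcomps["residual"] == pytest.approx(f1.varcomps["residual"], rel=5e-3)


def test_multi_kernel_em_loglik_monotone(grm):
    rng = np.random.default_rng(5)
    ids = grm.line_ids[:80]
    K = grm.align(ids)
    K2 = RelationshipKernel(np.eye(80), ids)
    y = pd.Series(_chol_draw(rng, K.matrix) + rng.normal(size=80), index=ids)
    fit = fit_multi_kernel(y, [K, K2])
    diffs = np.diff(fit.trace)
    assert (diffs > -1e-7).all()


def test_disjoint_markers_weighted_sum_equivalence(geno):
    """Two kernels with variances (s1, s2) predict identically to the single
    kernel s1 K1 + s2 K2 at those weights (algebraic oracle, small n)."""
    rng = np.random.default_rng(6)
    sub = geno.subset(lines=np.arange(40))
    g1 = sub.subset(markers=np.arange(0, 150))
    g2 = sub.subset(markers=np.arange(150, 360))
    K1 = stabilize_kernel(compute_grm(g1))
    K2 = stabilize_kernel(compute_grm(g2))
    ids = K1.line_ids
    y = pd.Series(
        _chol_draw(rng, K1.matrix, 1.0) + _chol_draw(rng, K2.matrix, 0.7)
        + 0.5 * rng.normal(size=40),
        index=ids,
    )
    fit = fit_multi_kernel(y, [K1, K2], tol=1e-10, max_iter=2000)
    s1, s2 = fit.varcomps["G"], fit.varcomps["G2"]
    Kw = RelationshipKernel(s1 * K1.matrix + s2 * K2.matrix, ids)
    # with the combined kernel at weight 1, the same V is reproduced
    fitw = fit_multi_kernel(y, [Kw], tol=1e-10, max_iter=2000)
    np.testing.assert_allclose(
        fit.blups["G"] + fit.blups["G2"], fitw.blups["G"],
        atol=5e-3,
    )


def test_multi_kernel_variance_recovery(grm):
    """True variances (1.0, 0.5, 1.0) for (G, I, residual) recovered on average."""
    rng = np.random.default_rng(7)
    ids = grm.line_ids[:150]
    K1 = grm.align(ids)
    # normalize so the genetic variance is on the sample scale
    K1 = RelationshipKernel(K1.matrix / np.mean(np.diag(K1.matrix)), ids)
    K2 = RelationshipKernel(np.eye(150), ids)
    est = []
    for _ in range(10):
        y = pd.Series(
            _chol_draw(rng, K1.matrix) + _chol_draw(rng, K2.matrix, np.sqrt(0.5))
            + rng.normal(size=150),
            index=ids,
        )
        f = fit_multi_kernel(y, [K1, K2])
        est.append([f.varcomps["G"], f.varcomps["G2"], f.varcomps["residual"]])
    m = np.mean(est, axis=0)
    assert abs(m[0] - 1.0) < 0.35
    assert abs(m[1] - 0.5) < 0.35
    assert abs(m[2] - 1.0) < 0.35


def test_gibbs_backend_agrees_with_em(grm):
    rng = np.random.default_rng(8)
    ids = grm.line_ids[:100]
    K = grm.align(ids)
    y = pd.Series(_chol_draw(rng, K.matrix) + 0.7 * rng.normal(size=100), index=ids)
    em = fit_multi_kernel(y, [K])
    gb = fit_multi_kernel(y, [K], backend="gibbs", gibbs_iterations=4000,
                          gibbs_burnin=800, seed=1)
    # posterior-mean BLUPs track the REML BLUPs
    r = np.corrcoef(em.blups["G"], gb.blups["G"])[0, 1]
    assert r > 0.95


# ---------------------------------------------------------------------------
# prediction of new lines
# ---------------------------------------------------------------------------


def test_predict_full_mme_oracle(grm):
    """Agreement with a direct mixed-model-equation solve on n=20."""
    rng = np.random.default_rng(9)
    ids = grm.line_ids[:20]
    K = stabilize_kernel(RelationshipKernel(grm.align(ids).matrix + 1e-6 * np.eye(20), ids))
    y_all = pd.Series(_chol_draw(rng, K.matrix) + 0.6 * rng.normal(size=20), index=ids)
    train, test = ids[:14], ids[14:]
    fit = fit_single_kernel(y_all.loc[train], K.align(train))
    pred = predict_new_lines(fit, K, list(train), list(test))

    sg, se = fit.varcomps["G"], fit.varcomps["residual"]
    # oracle: Henderson MME over all 20 lines with train records only
    Z = np.zeros((14, 20))
    for i, l in enumerate(train):
        Z[i, ids.index(l)] = 1.0
    X = np.ones((14, 1))
    Kinv = np.linalg.inv(K.matrix)
    lhs = np.block(
        [
            [X.T @ X / se, X.T @ Z / se],
            [Z.T @ X / se, Z.T @ Z / se + Kinv / sg],
        ]
    )
    rhs = np.concatenate([X.T @ y_all.loc[train] / se, Z.T @ y_all.loc[train] / se])
    sol = np.linalg.solve(lhs, rhs)
    mme_pred = sol[0] + sol[1:][np.array([ids.index(l) for l in test])]
    np.testing.assert_allclose(pred.to_numpy(), mme_pred, atol=1e-6)


def test_predict_trivial_cases(grm):
    rng = np.random.default_rng(10)
    ids = grm.line_ids[:30]
    K = grm.align(ids)
    y = pd.Series(_chol_draw(rng, K.matrix) + 0.5 * rng.normal(size=30), index=ids)
    fit = fit_single_kernel(y, K)
    # a "test" line identical to a train line gets its fitted genetic value
    pred = predict_new_lines(fit, K, list(ids), [ids[3]])
    assert pred.iloc[0] == pytest.approx(fit.beta[0] + fit.blups["G"][3], abs=1e-8)
    # zero genetic variance: all predictions collapse to the intercept
    fit0 = fit_single_kernel(pd.Series(rng.normal(size=30) * 0 + 5.0, index=ids), K)
    pred0 = predict_new_lines(fit0, K, list(ids), list(ids[:5]))
    np.testing.assert_allclose(pred0.to_numpy(), 5.0, atol=1e-6)


# ---------------------------------------------------------------------------
# BayesB
# ---------------------------------------------------------------------------


def test_bayesb_seed_determinism(geno):
    rng = np.random.default_rng(11)
    sub = geno.subset(lines=np.arange(60), markers=np.arange(100))
    y = pd.Series(rng.normal(size=60), index=sub.line_ids)
    f1 = fit_bayesb(y, sub, iterations=400, burnin=100, seed=5)
    f2 = fit_bayesb(y, sub, iterations=400, burnin=100, seed=5)
    np.testing.assert_array_equal(f1.marker_effects, f2.marker_effects)
    np.testing.assert_array_equal(f1.inclusion_probs, f2.inclusion_probs)


def test_bayesb_finds_large_qtl(geno):
    """5 large QTL among the markers rank in the top 20 inclusion probs
    (allowing an LD partner to stand in for the causal marker)."""
    rng = np.random.default_rng(12)
    sub = geno.subset(lines=np.arange(200))
    qtl = [20, 100, 180, 250, 320]
    g = sub.dosages[:, qtl] @ np.ones(5)
    g = (g - g.mean()) / g.std()
    y = pd.Series(g + np.sqrt(3 / 7) * rng.normal(size=200), index=sub.line_ids)  # h2 = 0.7
    fit = fit_bayesb(y, sub, iterations=3000, burnin=600, seed=6)
    top = set(np.argsort(-fit.inclusion_probs)[:20])
    Z = sub.dosages - sub.dosages.mean(0)
    Zs = Z / np.maximum(Z.std(0), 1e-9)
    hits = 0
    for q in qtl:
        partners = set(np.where((Zs.T @ Zs[:, q] / 200) ** 2 > 0.3)[0])
        if top & (partners | {q}):
            hits += 1
    assert hits >= 4


def test_bayesb_validation(geno):
    y = pd.Series(np.zeros(10), index=geno.line_ids[:10])
    with pytest.raises(ValueError, match="iterations"):
        fit_bayesb(y, geno, iterations=100, burnin=100)


# ---------------------------------------------------------------------------
# multi-trait
# ---------------------------------------------------------------------------


def test_dd_equals_independent_single_fits(geno, grm):
    arch = TraitArchitecture(h2_target=0.5, polygenic_var=1.0)
    env = EnvCovariance(np.eye(3), np.eye(3))
    Y, _ = simulate_line_values(geno, arch, env, seed=13)
    dd = fit_multitrait(Y, grm, "D", "D", max_iter=5000, tol=1e-12)
    for i, c in enumerate(Y.columns):
        fs = fit_single_kernel(Y[c], grm)
        assert dd.G0[i, i] == pytest.approx(fs.varcomps["G"], abs=1e-4)
        assert dd.R0[i, i] == pytest.approx(fs.varcomps["residual"], abs=1e-4)
    assert np.all(dd.G0[~np.eye(3, dtype=bool)] == 0)


def test_multitrait_e1_consistency(geno, grm):
    arch = TraitArchitecture(h2_target=0.5, polygenic_var=1.0)
    Y, _ = simulate_line_values(geno, arch, EnvCovariance(np.eye(1), np.eye(1)), seed=14)
    mt = fit_multitrait(Y, grm, "UN", "UN", max_iter=5000, tol=1e-12)
    fs = fit_single_kernel(Y[Y.columns[0]], grm)
    assert mt.G0[0, 0] == pytest.approx(fs.varcomps["G"], rel=1e-3)
    assert mt.R0[0, 0] == pytest.approx(fs.varcomps["residual"], rel=1e-3)


def test_multitrait_un_recovers_zero_correlation(geno, grm):
    arch = TraitArchitecture(h2_target=0.6, polygenic_var=1.0)
    env = EnvCovariance(np.eye(3), np.eye(3))
    offs = []
    for seed in range(8):
        Y, _ = simulate_line_values(geno, arch, env, seed=seed)
        fit = fit_multitrait(Y, grm, "UN", "UN")
        C = fit.G0 / np.sqrt(np.outer(np.diag(fit.G0), np.diag(fit.G0)))
        offs.extend(C[np.triu_indices(3, 1)])
    assert abs(np.mean(offs)) < 0.15


def test_multitrait_un_recovers_high_correlation(geno, grm):
    arch = TraitArchitecture(h2_target=0.6, polygenic_var=1.0)
    env = EnvCovariance.exchangeable(3, g_cor=0.8)
    offs = []
    for seed in range(8):
        Y, _ = simulate_line_values(geno, arch, env, seed=seed)
        fit = fit_multitrait(Y, grm, "UN", "UN")
        C = fit.G0 / np.sqrt(np.outer(np.diag(fit.G0), np.diag(fit.G0)))
        offs.extend(C[np.triu_indices(3, 1)])
    assert abs(np.mean(offs) - 0.8) < 0.15


def test_fa1_structure_constraint(geno, grm):
    arch = TraitArchitecture(h2_target=0.6, polygenic_var=1.0)
    env = EnvCovariance.exchangeable(3, g_cor=0.7)
    Y, _ = simulate_line_values(geno, arch, env, seed=21)
    fit = fit_multitrait(Y, grm, "FA1", "D")
    G = fit.G0
    assert np.allclose(G, G.T)
    assert np.linalg.eigvalsh(G).min() > -1e-8
    assert np.all(np.diag(fit.R0) >= 0)
    assert np.count_nonzero(fit.R0 - np.diag(np.diag(fit.R0))) == 0


def test_multitrait_rejects_bad_structures(geno, grm):
    Y, _ = simulate_line_values(
        geno, TraitArchitecture(polygenic_var=1.0), EnvCovariance(np.eye(2), np.eye(2)), seed=1
    )
    with pytest.raises(ValueError, match="structure_r"):
        fit_multitrait(Y, grm, "UN", "FA1")
    with pytest.raises(ValueError, match="structure_g"):
        fit_multitrait(Y, grm, "XX", "UN")


def test_masked_cells_predicted(geno, grm):
    arch = TraitArchitecture(h2_target=0.6, polygenic_var=1.0)
    env = EnvCovariance.exchangeable(3, g_cor=0.8)
    Y, bv = simulate_line_values(geno, arch, env, seed=15)
    Ym = Y.copy()
    masked = Y.index[:40]
    Ym.loc[masked, "env1"] = np.nan
    fit = fit_multitrait(Ym, grm, "UN", "UN")
    r = np.corrcoef(fit.fitted.loc[masked, "env1"], bv.loc[masked, "env1"])[0, 1]
    assert r > 0.3


# ---------------------------------------------------------------------------
# two-kernel wrapper
# ---------------------------------------------------------------------------


def test_two_kernel_rejects_empty(grm):
    y = pd.Series(np.zeros(grm.n), index=grm.line_ids)
    empty = RelationshipKernel(np.zeros((grm.n, grm.n)), grm.line_ids)
    with pytest.raises(ValueError, match="empty"):
        two_kernel_fit(y, grm, empty)
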