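"""Prediction engines: kernel BLUP models, BayesB, and multi-trait fits.

The module provides every mixed-model backend used by the pipeline:

* :func:`fit_single_kernel` — GBLUP-style model ``y = Xb + g + e`` with
  ``g ~ N(0, s_g K)``, fitted by restricted maximum likelihood via the
  eigendecomposition trick (one-dimensional profile over the variance
  ratio).
* :func:`fit_multi_kernel` — several additive kernel effects
  (``y = Xb + g_1 + ... + g_k + e``) fitted by EM-REML (deterministic,
  monotone) or an optional Gibbs sampler backend.
* :func:`fit_bayesb` — Gibbs sampler for per-marker effects with a point
  mass at zero and scaled-inverse-chi-square effect variances.
* :func:`fit_multitrait` — environments-as-traits model
  ``Cov(g) = G0 (x) K``, ``Cov(e) = I (x) R0`` with diagonal (D),
  unstructured (UN), or first-order factor-analytic (FA1) G0 and D/UN R0,
  fitted by expectation-maximization with EM imputation of masked cells.
* :func:`two_kernel_fit` — the two-genomic-kernel model used after marker
  prioritization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .kernels import RelationshipKernel, GenotypeMatrix
from .stageone import TraitValues

__all__ = [
    "KernelModelFit",
    "BayesBFit",
    "MultiTraitFit",
    "fit_single_kernel",
    "fit_multi_kernel",
    "predict_new_lines",
    "fit_bayesb",
    "fit_multitrait",
    "two_kernel_fit",
]


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------


@dataclass
class KernelModelFit:
    """Variance components, fixed effects and BLUPs of a kernel model."""

    varcomps: dict[str, float]  # per-kernel genetic variances + "residual"
    beta: np.ndarray
    blups: dict[str, np.ndarray]  # per-kernel per-line genetic components
    loglik: float
    line_ids: list[str]
    kernel_kinds: list[str]
    Py: np.ndarray  # V^{-1}(y - Xb) on the training lines, for projection
    converged: bool = True
    trace: list[float] = field(default_factory=list)

    @property
    def total_genetic(self) -> np.ndarray:
        return np.sum(list(self.blups.values()), axis=0)

    @property
    def fitted(self) -> np.ndarray:
        return self.beta[0] + self.total_genetic

    def to_json(self) -> str:
        return json.dumps(
            {
                "varcomps": self.varcomps,
                "beta": list(map(float, np.atleast_1d(self.beta))),
                "loglik": self.loglik,
                "kernel_kinds": self.kernel_kinds,
                "converged": self.converged,
            }
        )


@dataclass
class BayesBFit:
    """Posterior summaries of the BayesB marker-effect model."""

    marker_effects: np.ndarray  # posterior means
    inclusion_probs: np.ndarray
    mu: float
    pi: float
    settings: dict
    marker_ids: list[str]

    def __post_init__(self) -> None:
        if np.any((self.inclusion_probs < 0) | (self.inclusion_probs > 1)):
            raise ValueError("inclusion probabilities must lie in [0, 1]")

    def predict(self, geno: GenotypeMatrix) -> pd.Series:
        idx = geno.marker_index(self.marker_ids)
        yhat = self.mu + geno.dosages[:, idx] @ self.marker_effects
        return pd.Series(yhat, index=geno.line_ids)


@dataclass
class MultiTraitFit:
    """Across-environment covariance estimates and per-cell BLUPs."""

    G0: np.ndarray
    R0: np.ndarray
    structure_g: str
    structure_r: str
    beta: np.ndarray  # per-environment intercepts
    blups: pd.DataFrame  # lines x environments genetic values
    fitted: pd.DataFrame  # beta + blups (the masked-cell predictions)
    loglik: float
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# alignment helpers
# ---------------------------------------------------------------------------


def _as_series(y) -> pd.Series:
    if isinstance(y, TraitValues):
        return y.values
    if isinstance(y, pd.Series):
        return y
    raise TypeError("y must be a TraitValues or a pandas Series indexed by line")


def _align(y, kernels: list[RelationshipKernel]) -> tuple[np.ndarray, list[str], list[np.ndarray]]:
    s = _as_series(y).dropna()
    ids = [l for l in s.index if all(l in set(K.line_ids) for K in kernels)]
    if len(ids) < len(s):
        missing = len(s) - len(ids)
        warnings.warn(f"{missing} phenotyped line(s) absent from a kernel; dropped", stacklevel=3)
    if len(ids) < 3:
        raise ValueError("fewer than 3 lines shared between phenotypes and kernels")
    mats = [K.align(ids).matrix for K in kernels]
    return s.loc[ids].to_numpy(float), list(ids), mats


# ---------------------------------------------------------------------------
# single kernel: eigendecomposition REML
# ---------------------------------------------------------------------------


def _reml_profile(y: np.ndarray, X: np.ndarray, s: np.ndarray, U: np.ndarray):
    """Profile REML over delta = s_e/s_g after rotating by eigenvectors."""
    n, p = X.shape
    yt = U.T @ y
    Xt = U.T @ X
    _, logdet_xx = np.linalg.slogdet(X.T @ X)

    def neg_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = s + delta
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return 1e12
        b = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ b
        R = np.sum(r * r / w)
        if R <= 0:
            return 1e12
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi * R / (n - p)) + 1.0)
            + np.sum(np.log(w))
            + logdet_xwx
            - logdet_xx
        )
        return -ll

    grid = np.linspace(-12.0, 12.0, 61)
    vals = np.array([neg_ll(g) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded")
    log_delta = float(res.x)
    delta = np.exp(log_delta)
    w = s + delta
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    b = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ b
    sg = float(np.sum(r * r / w) / (n - p))
    se = sg * delta
    ll = -float(neg_ll(log_delta))
    return sg, se, b, ll, yt, Xt, w, r


def fit_single_kernel(
    y, K: RelationshipKernel, X: np.ndarray | None = None
) -> KernelModelFit:
    """REML fit of ``y = Xb + g + e`` with ``g ~ N(0, s_g K)``.

    ``y`` is a :class:`~omicpred.stageone.TraitValues` or a Series indexed
    by line id; lines missing from the kernel are dropped.  ``X`` defaults
    to an intercept.  Negative kernel eigenvalues beyond round-off are
    rejected (stabilize the kernel first).
    """
    yv, ids, (Km,) = _align(y, [K])
    n = len(ids)
    Xm = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, float))
    s, U = np.linalg.eigh(Km)
    if s[0] < -1e-6:
        raise ValueError("kernel is not PSD; apply stabilize_kernel first")
    s = np.maximum(s, 0.0)
    sg, se, b, ll, yt, Xt, w, r = _reml_profile(yv, Xm, s, U)
    # BLUP in the rotated basis: shrink each eigen-component by s_i/(s_i+delta)
    g = U @ ((s / w) * r)
    Py = U @ (r / w) / sg  # V^{-1}(y - Xb)
    return KernelModelFit(
        varcomps={f"{K.kind}": sg, "residual": se},
        beta=b,
        blups={K.kind: g},
        loglik=ll,
        line_ids=ids,
        kernel_kinds=[K.kind],
        Py=Py,
    )


# ---------------------------------------------------------------------------
# multi-kernel EM-REML (+ optional Gibbs backend)
# ---------------------------------------------------------------------------


def _reml_loglik(yv, Xm, V) -> float:
    n, p = Xm.shape
    L = np.linalg.cholesky(V)
    Vi_y = np.linalg.solve(V, yv)
    Vi_X = np.linalg.solve(V, Xm)
    XtViX = Xm.T @ Vi_X
    b = np.linalg.solve(XtViX, Xm.T @ Vi_y)
    Py = Vi_y - Vi_X @ b
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    _, logdet_xvx = np.linalg.slogdet(XtViX)
    return -0.5 * (logdetV + logdet_xvx + yv @ Py + (n - p) * np.log(2 * np.pi))


def _kernel_names(kernels: list[RelationshipKernel]) -> list[str]:
    names, seen = [], {}
    for K in kernels:
        base = K.kind
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base}{seen[base]}")
    return names


def fit_multi_kernel(
    y,
    kernels: list[RelationshipKernel],
    X: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    backend: str = "em",
    gibbs_iterations: int = 6000,
    gibbs_burnin: int = 1000,
    seed: int = 0,
) -> KernelModelFit:
    """Joint variance components for several additive kernel effects.

    The primary backend is EM-REML: the classic expectation-maximization
    updates keep every component non-negative and increase the restricted
    likelihood monotonically.  ``backend="gibbs"`` runs a Gibbs sampler in
    each kernel's eigenbasis instead (posterior means reported); the two
    agree within sampling error.
    """
    if len(kernels) < 1:
        raise ValueError("at least one kernel required")
    for K in kernels:
        if K.n == 0:
            raise ValueError("empty kernel")
    yv, ids, mats = _align(y, kernels)
    n = len(ids)
    Xm = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, float))
    names = _kernel_names(kernels)

    if backend == "gibbs":
        return _multi_kernel_gibbs(
            yv, ids, mats, names, Xm, gibbs_iterations, gibbs_burnin, seed
        )
    if backend != "em":
        raise ValueError("backend must be 'em' or 'gibbs'")

    k = len(mats)
    vary = max(yv.var(), 1e-12)
    sig = np.full(k + 1, vary / (k + 1))  # kernels..., residual
    trace: list[float] = []
    converged = False
    p = Xm.shape[1]
    for it in range(max_iter):
        V = sig[-1] * np.eye(n)
        for i in range(k):
            V += sig[i] * mats[i]
        Vi = np.linalg.inv(V)
        Vi_X = Vi @ Xm
        XtViX = Xm.T @ Vi_X
        b = np.linalg.solve(XtViX, Vi_X.T @ yv)
        P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
        Py = P @ yv
        ll = _reml_loglik(yv, Xm, V)
        trace.append(ll)
        new = sig.copy()
        for i in range(k):
            quad = Py @ mats[i] @ Py
            tr = np.einsum("ij,ji->", P, mats[i])
            new[i] = (sig[i] ** 2 * quad + sig[i] * (n - sig[i] * tr)) / n
        quad_e = Py @ Py
        tr_e = np.trace(P)
        new[-1] = (sig[-1] ** 2 * quad_e + sig[-1] * (n - sig[-1] * tr_e)) / n
        new = np.maximum(new, vary * 1e-10)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-1])):
            sig = new
            converged = True
            break
        sig = new
    if not converged and max_iter > 50:
        warnings.warn("EM-REML reached max_iter without full convergence", stacklevel=2)

    V = sig[-1] * np.eye(n)
    for i in range(k):
        V += sig[i] * mats[i]
    Vi = np.linalg.inv(V)
    Vi_X = Vi @ Xm
    XtViX = Xm.T @ Vi_X
    b = np.linalg.solve(XtViX, Vi_X.T @ yv)
    Py = Vi @ (yv - Xm @ b)
    blups = {names[i]: sig[i] * (mats[i] @ Py) for i in range(k)}
    return KernelModelFit(
        varcomps={**{names[i]: float(sig[i]) for i in range(k)}, "residual": float(sig[-1])},
        beta=b,
        blups=blups,
        loglik=float(_reml_loglik(yv, Xm, V)),
        line_ids=ids,
        kernel_kinds=[K.kind for K in kernels],
        Py=Py,
        converged=converged,
        trace=trace,
    )


def _multi_kernel_gibbs(yv, ids, mats, names, Xm, iterations, burnin, seed):
    """Gibbs sampler in each kernel's eigenbasis (diagonal full conditionals)."""
    rng = np.random.default_rng(seed)
    n = len(yv)
    k = len(mats)
    eigs = []
    for M in mats:
        d, U = np.linalg.eigh(M)
        keep = d > max(d.max(), 1.0) * 1e-10
        eigs.append((d[keep], U[:, keep]))
    vary = max(yv.var(), 1e-12)
    sig = np.full(k + 1, vary / (k + 1))
    mu = float(yv.mean())
    a = [np.zeros(d.size) for d, _ in eigs]  # eigen-coordinates of each g_i
    u = [np.zeros(n) for _ in range(k)]
    nu0, S0 = 4.0, vary / (k + 1) / 2.0

    acc_sig = np.zeros(k + 1)
    acc_u = [np.zeros(n) for _ in range(k)]
    acc_mu = 0.0
    kept = 0
    for it in range(iterations):
        resid = yv - mu - np.sum(u, axis=0)
        # intercept
        mu_mean = float(np.mean(resid + mu))
        mu = rng.normal(mu_mean, np.sqrt(sig[-1] / n))
        resid = yv - mu - np.sum(u, axis=0)
        for i in range(k):
            d, U = eigs[i]
            r = resid + u[i]
            rt = U.T @ r
            prec = 1.0 / sig[-1] + 1.0 / (sig[i] * d)
            mean = (rt / sig[-1]) / prec
            a[i] = mean + rng.normal(size=d.size) / np.sqrt(prec)
            new_u = U @ a[i]
            resid += u[i] - new_u
            u[i] = new_u
            ss = np.sum(a[i] ** 2 / d)
            sig[i] = (ss + nu0 * S0) / rng.chisquare(d.size + nu0)
        ss_e = np.sum(resid**2)
        sig[-1] = (ss_e + nu0 * S0) / rng.chisquare(n + nu0)
        if it >= burnin:
            kept += 1
            acc_sig += sig
            acc_mu += mu
            for i in range(k):
                acc_u[i] += u[i]
    sig_hat = acc_sig / kept
    u_hat = [x / kept for x in acc_u]
    b = np.array([acc_mu / kept])
    V = sig_hat[-1] * np.eye(n)
    for i in range(k):
        V += sig_hat[i] * mats[i]
    Py = np.linalg.solve(V, yv - b[0])
    return KernelModelFit(
        varcomps={**{names[i]: float(sig_hat[i]) for i in range(k)}, "residual": float(sig_hat[-1])},
        beta=b,
        blups={names[i]: u_hat[i] for i in range(k)},
        loglik=float(_reml_loglik(yv, Xm, V)),
        line_ids=ids,
        kernel_kinds=names,
        Py=Py,
    )


def predict_new_lines(
    fit: KernelModelFit,
    K_full,
    train_ids: list[str],
    test_ids: list[str],
) -> pd.Series:
    """BLUP projection of fitted genetic values onto unphenotyped lines.

    ``ghat_test = sum_i s_i K_i[test, train] V^{-1} (y - Xb)`` plus the
    intercept.  ``K_full`` is the kernel (or list of kernels, ordered as in
    the fit) over the union of train and test lines.
    """
    kernels = K_full if isinstance(K_full, (list, tuple)) else [K_full]
    names = [k for k in fit.varcomps if k != "residual"]
    if len(kernels) != len(names):
        raise ValueError("number of kernels does not match the fit")
    if list(train_ids) != list(fit.line_ids):
        # re-align: projection needs Py in the fit's own order
        raise ValueError("train_ids must equal fit.line_ids (same order)")
    pred = np.full(len(test_ids), float(fit.beta[0]))
    for name, K in zip(names, kernels):
        idx = {l: i for i, l in enumerate(K.line_ids)}
        rows = np.array([idx[l] for l in test_ids])
        cols = np.array([idx[l] for l in train_ids])
        Kxt = K.matrix[np.ix_(rows, cols)]
        pred += fit.varcomps[name] * (Kxt @ fit.Py)
    return pd.Series(pred, index=list(test_ids))


# ---------------------------------------------------------------------------
# BayesB
# ---------------------------------------------------------------------------


def _bayesb_gibbs_py(y, Z, pi, nu, S, iterations, burnin, thin, seed):
    """Single-site Gibbs for the point-mass + scaled-inv-chi2 mixture."""
    rng = np.random.default_rng(seed)
    n, p = Z.shape
    zz = np.einsum("ij,ij->j", Z, Z)
    mu = float(y.mean())
    beta = np.zeros(p)
    delta = np.zeros(p, dtype=bool)
    sig_j = np.full(p, S * nu / max(nu - 2.0, 0.5))
    vare = float(y.var()) / 2.0 + 1e-12
    nu_e, S_e = 5.0, float(y.var()) / 2.0
    e = y - mu  # current residual (beta all zero)

    acc_beta = np.zeros(p)
    acc_delta = np.zeros(p)
    acc_mu = 0.0
    kept = 0
    log_pi = np.log(pi) if pi > 0 else -np.inf
    log_1mpi = np.log(1.0 - pi) if pi < 1 else -np.inf

    for it in range(iterations):
        # intercept
        e += mu
        mu = rng.normal(e.mean(), np.sqrt(vare / n))
        e -= mu
        for j in range(p):
            zj = Z[:, j]
            if delta[j]:
                e += zj * beta[j]
            rhs = zj @ e / vare
            C = zz[j] / vare + 1.0 / sig_j[j]
            log_like1 = 0.5 * (rhs * rhs / C) - 0.5 * np.log(sig_j[j] * C)
            log_odds = log_1mpi + log_like1 - log_pi
            p_in = 1.0 / (1.0 + np.exp(-log_odds)) if np.isfinite(log_odds) else (0.0 if log_odds < 0 else 1.0)
            if rng.random() < p_in:
                delta[j] = True
                beta[j] = rng.normal(rhs / C, 1.0 / np.sqrt(C))
                e -= zj * beta[j]
            else:
                delta[j] = False
                beta[j] = 0.0
            # per-marker variance: posterior update when in, prior draw when out
            if delta[j]:
                sig_j[j] = (nu * S + beta[j] ** 2) / rng.chisquare(nu + 1.0)
            else:
                sig_j[j] = nu * S / rng.chisquare(nu)
        vare = (e @ e + nu_e * S_e) / rng.chisquare(n + nu_e)
        if not np.isfinite(vare) or vare <= 0:
            raise FloatingPointError("BayesB chain diverged (non-finite residual variance)")
        if it >= burnin and (it - burnin) % thin == 0:
            kept += 1
            acc_beta += beta
            acc_delta += delta
            acc_mu += mu
    return acc_beta / kept, acc_delta / kept, acc_mu / kept


def fit_bayesb(
    y,
    geno: GenotypeMatrix,
    pi: float = 0.95,
    nu: float = 4.2,
    scale: float | None = None,
    iterations: int = 12000,
    burnin: int = 2000,
    thin: int = 5,
    seed: int = 0,
) -> BayesBFit:
    """BayesB: marker effects with a point mass at zero.

    Each marker effect is zero with prior probability ``pi``; otherwise it
    is normal with its own scaled-inverse-chi-square variance (``nu``,
    ``scale``).  When ``scale`` is None it is solved from a prior trait
    heritability of 0.5 following the usual rule
    ``S = vary * h2 * (nu - 2) / (nu * (1 - pi) * sum(2 p q))``.
    Returns posterior-mean effects and per-marker inclusion probabilities.
    """
    if iterations <= burnin:
        raise ValueError("iterations must exceed burnin")
    s = _as_series(y).dropna()
    ids = [l for l in s.index if l in set(geno.line_ids)]
    sub = geno.subset(lines=np.array([geno.line_ids.index(l) for l in ids]))
    Z = sub.dosages
    if np.isnan(Z).any():
        raise ValueError("BayesB requires complete dosages")
    yv = s.loc[ids].to_numpy(float)
    if scale is None:
        p_frq = Z.mean(axis=0) / 2.0
        sum2pq = float(np.sum(2.0 * p_frq * (1.0 - p_frq)))
        vary = float(yv.var())
        scale = vary * 0.5 * (nu - 2.0) / (nu * max(1.0 - pi, 1e-6) * max(sum2pq, 1e-12))

    runner = _bayesb_numba if _HAVE_NUMBA else _bayesb_gibbs_py
    beta, probs, mu = runner(
        yv.astype(np.float64),
        np.ascontiguousarray(Z, dtype=np.float64),
        float(pi),
        float(nu),
        float(scale),
        int(iterations),
        int(burnin),
        int(thin),
        int(seed),
    )
    return BayesBFit(
        marker_effects=np.asarray(beta),
        inclusion_probs=np.asarray(probs),
        mu=float(mu),
        pi=pi,
        settings={
            "nu": nu,
            "scale": float(scale),
            "iterations": iterations,
            "burnin": burnin,
            "thin": thin,
            "seed": seed,
        },
        marker_ids=list(geno.marker_ids),
    )


# numba version of the sampler (numpy RandomState API inside nopython mode)
_HAVE_NUMBA = False
try:
    from numba import njit as _njit

    @_njit(cache=False)
    def _bayesb_numba(y, Z, pi, nu, S, iterations, burnin, thin, seed):  # pragma: no cover - exercised via fit_bayesb
        np.random.seed(seed)
        n, p = Z.shape
        zz = np.empty(p)
        for j in range(p):
            acc = 0.0
            for i in range(n):
                acc += Z[i, j] * Z[i, j]
            zz[j] = acc
        mu = y.mean()
        beta = np.zeros(p)
        delta = np.zeros(p, dtype=np.bool_)
        sig_j = np.full(p, S * nu / max(nu - 2.0, 0.5))
        vary = y.var()
        vare = vary / 2.0 + 1e-12
        nu_e = 5.0
        S_e = vary / 2.0
        e = y - mu
        acc_beta = np.zeros(p)
        acc_delta = np.zeros(p)
        acc_mu = 0.0
        kept = 0
        log_pi = np.log(pi) if pi > 0 else -1e300
        log_1mpi = np.log(1.0 - pi) if pi < 1 else -1e300
        for it in range(iterations):
            e += mu
            mu = np.random.normal(e.mean(), np.sqrt(vare / n))
            e -= mu
            for j in range(p):
                bj = beta[j]
                if delta[j]:
                    for i in range(n):
                        e[i] += Z[i, j] * bj
                rhs = 0.0
                for i in range(n):
                    rhs += Z[i, j] * e[i]
                rhs /= vare
                C = zz[j] / vare + 1.0 / sig_j[j]
                log_like1 = 0.5 * (rhs * rhs / C) - 0.5 * np.log(sig_j[j] * C)
                log_odds = log_1mpi + log_like1 - log_pi
                if log_odds > 35.0:
                    p_in = 1.0
                elif log_odds < -35.0:
                    p_in = 0.0
                else:
                    p_in = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p_in:
                    delta[j] = True
                    bj = np.random.normal(rhs / C, 1.0 / np.sqrt(C))
                    beta[j] = bj
                    for i in range(n):
                        e[i] -= Z[i, j] * bj
                    sig_j[j] = (nu * S + bj * bj) / np.random.chisquare(nu + 1.0)
                else:
                    delta[j] = False
                    beta[j] = 0.0
                    sig_j[j] = nu * S / np.random.chisquare(nu)
            ss = 0.0
            for i in range(n):
                ss += e[i] * e[i]
            vare = (ss + nu_e * S_e) / np.random.chisquare(n + nu_e)
            if not np.isfinite(vare) or vare <= 0.0:
                raise FloatingPointError("BayesB chain diverged")
            if it >= burnin and (it - burnin) % thin == 0:
                kept += 1
                acc_mu += mu
                for j in range(p):
                    acc_beta[j] += beta[j]
                    if delta[j]:
                        acc_delta[j] += 1.0
        return acc_beta / kept, acc_delta / kept, acc_mu / kept

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    pass


# ---------------------------------------------------------------------------
# multi-trait (environments as traits)
# ---------------------------------------------------------------------------


def _fa1_project(S: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Nearest (in the alternating sense) FA1 matrix lam lam' + Psi to S."""
    e = S.shape[0]
    w, V = np.linalg.eigh(S)
    lam = V[:, -1] * np.sqrt(max(w[-1], 1e-12))
    psi = np.maximum(np.diag(S) - lam**2, 1e-8)
    for _ in range(n_iter):
        # alternating least squares: rank-1 fit to S - Psi, then refresh Psi
        M = S - np.diag(psi)
        w2, V2 = np.linalg.eigh(0.5 * (M + M.T))
        lam_new = V2[:, -1] * np.sqrt(max(w2[-1], 0.0))
        psi_new = np.maximum(np.diag(S) - lam_new**2, 1e-8)
        if np.allclose(lam_new, lam, atol=1e-10) and np.allclose(psi_new, psi, atol=1e-10):
            lam, psi = lam_new, psi_new
            break
        lam, psi = lam_new, psi_new
    return np.outer(lam, lam) + np.diag(psi)


def _project_structure(S: np.ndarray, structure: str) -> np.ndarray:
    if structure == "UN":
        return 0.5 * (S + S.T)
    if structure == "D":
        return np.diag(np.diag(S))
    if structure == "FA1":
        return _fa1_project(0.5 * (S + S.T))
    raise ValueError(f"unknown covariance structure: {structure}")


def fit_multitrait(
    Y: pd.DataFrame,
    K: RelationshipKernel,
    structure_g: str = "UN",
    structure_r: str = "UN",
    max_iter: int = 500,
    tol: float = 1e-8,
    n_impute_rounds: int = 8,
) -> MultiTraitFit:
    """Environments-as-traits mixed model with structured G0 and R0.

    ``Y`` is lines x environments and may contain NaN cells (the CV2
    masking); masked cells are EM-imputed with the current model's fitted
    values between covariance updates, and the returned ``fitted`` frame
    carries their predictions.  ``structure_g`` in {D, UN, FA1},
    ``structure_r`` in {D, UN} (a factor-analytic residual is rejected).
    """
    if structure_r not in ("D", "UN"):
        raise ValueError("structure_r must be 'D' or 'UN'")
    if structure_g not in ("D", "UN", "FA1"):
        raise ValueError("structure_g must be 'D', 'UN' or 'FA1'")
    e = Y.shape[1]
    if not 1 <= e <= 5:
        raise ValueError("between 1 and 5 environments supported")
    ids = [l for l in Y.index if l in set(K.line_ids)]
    Yv = Y.loc[ids].to_numpy(float)
    n = len(ids)
    Km = K.align(ids).matrix
    d, U = np.linalg.eigh(Km)
    d = np.maximum(d, 0.0)
    ones_t = U.T @ np.ones(n)

    mask = np.isnan(Yv)
    Yc = Yv.copy()
    col_means = np.nanmean(Yv, axis=0)
    for j in range(e):
        Yc[mask[:, j], j] = col_means[j]

    vary = np.nanvar(Yv, axis=0)
    G0 = np.diag(vary / 2.0 + 1e-12)
    R0 = np.diag(vary / 2.0 + 1e-12)
    beta = col_means.copy()
    ll_old = -np.inf
    converged = False
    it_total = 0
    outer = n_impute_rounds if mask.any() else 1

    pos = d > 1e-10
    ng = max(int(pos.sum()), 1)
    for _outer in range(outer):
        Yt = U.T @ Yc
        for _it in range(max_iter // outer + 1):
            it_total += 1
            # batched per-eigencomponent algebra: Sig_i = d_i G0 + R0
            Sig = d[:, None, None] * G0[None] + R0[None]  # (n, e, e)
            Sig_inv = np.linalg.inv(Sig)
            sign, logdet = np.linalg.slogdet(Sig)
            A = np.einsum("i,ijk->jk", ones_t**2, Sig_inv)
            rhs = np.einsum("i,ijk,ik->j", ones_t, Sig_inv, Yt)
            beta = np.linalg.solve(A, rhs)
            R = Yt - np.outer(ones_t, beta)  # residuals from fixed part
            SiR = np.einsum("ijk,ik->ij", Sig_inv, R)
            _, logdetA = np.linalg.slogdet(A)
            ll = -0.5 * float(
                np.sum(logdet)
                + logdetA
                + np.einsum("ij,ij->", R, SiR)
                + (n - 1) * e * np.log(2 * np.pi)
            )
            # REML E-step: conditional covariances use the projection
            # P_ii = Sig_inv - u_i^2 Sig_inv A^{-1} Sig_inv (beta integrated out)
            Ainv = np.linalg.inv(A)
            Pii = Sig_inv - (ones_t**2)[:, None, None] * np.einsum(
                "ijk,kl,ilm->ijm", Sig_inv, Ainv, Sig_inv
            )
            GSi = d[:, None, None] * np.einsum("jk,ikl->ijl", G0, Sig_inv)
            Ghat = np.einsum("ijk,ik->ij", GSi, R)
            GP = d[:, None, None] * np.einsum("jk,ikl->ijl", G0, Pii)
            Cg = d[:, None, None] * G0[None] - d[:, None, None] * np.einsum(
                "ijk,kl->ijl", GP, G0
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                inv_d = np.where(pos, 1.0 / np.maximum(d, 1e-300), 0.0)
                Sg_acc = np.einsum("i,ij,ik->jk", inv_d, Ghat, Ghat) + np.einsum(
                    "i,ijk->jk", inv_d, Cg
                )
            E = R - Ghat
            Ce = R0[None] - np.einsum("jk,ikl,lm->ijm", R0, Pii, R0)
            Sr_acc = E.T @ E + Ce.sum(axis=0)
            G0_new = _project_structure(Sg_acc / ng, structure_g)
            R0_new = _project_structure(Sr_acc / n, structure_r)
            G0_new += 1e-12 * np.eye(e)
            R0_new += 1e-12 * np.eye(e)
            done = abs(ll - ll_old) < tol * (1 + abs(ll))
            G0, R0 = G0_new, R0_new
            ll_old = ll
            if done:
                converged = True
                break
        # EM imputation of masked cells with current fitted values
        if mask.any():
            G_lines = U @ Ghat
            fitted_now = beta[None, :] + G_lines
            Yc = np.where(mask, fitted_now, Yv)
        else:
            break

    G_lines = U @ Ghat
    fitted = pd.DataFrame(beta[None, :] + G_lines, index=ids, columns=Y.columns)
    blups = pd.DataFrame(G_lines, index=ids, columns=Y.columns)
    return MultiTraitFit(
        G0=G0,
        R0=R0,
        structure_g=structure_g,
        structure_r=structure_r,
        beta=beta,
        blups=blups,
        fitted=fitted,
        loglik=float(ll_old),
        converged=converged,
        n_iter=it_total,
    )


def two_kernel_fit(
    y, K_prioritized: RelationshipKernel, K_rest: RelationshipKernel, **kwargs
) -> KernelModelFit:
    """Two-genomic-kernel BLUP: prioritized markers vs. the remaining genome."""
    for K in (K_prioritized, K_rest):
        if K.n == 0:
            raise ValueError("empty kernel passed to two_kernel_fit")
        if not np.any(np.abs(K.matrix) > 0):
            raise ValueError("kernel built from an empty marker set")
    return fit_multi_kernel(y, [K_prioritized, K_rest], **kwargs)
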