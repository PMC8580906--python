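"""Cross-validation schemes, accuracy estimators and paired comparisons.

Three schemes mirror the study design:

* 50:50 half splits repeated many times for single-environment prediction,
  scored by the genetic-correlation accuracy ``cor_g * sqrt(h2_uhat)``
  (a bivariate mixed model on observed and predicted values over the test
  lines, robust to micro-environmental covariance between omics and
  phenotypes);
* five-fold CV for the distantly-related-population experiment, scored by
  ``r(yhat, y) / sqrt(h2)``;
* the CV2 multi-environment scheme: the same 20% of lines is masked in
  each target environment in turn, the metabolite kernel is built from the
  other environments only, and a multi-trait model predicts the masked
  cells.

Model objects expose ``fit_predict(y, train_ids, test_ids)`` so that every
model sees the identical partition in every repeat (pairing integrity for
the signed-rank comparisons).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import FeatureMatrix, GenotypeMatrix, RelationshipKernel, compute_feature_kernel
from .mixedmodels import (
    fit_bayesb,
    fit_multi_kernel,
    fit_multitrait,
    fit_single_kernel,
    predict_new_lines,
)

__all__ = [
    "CVResult",
    "KernelModel",
    "BayesBModel",
    "half_split_cv",
    "fivefold_cv",
    "cv2_multienv",
    "accuracy_corg",
    "accuracy_scaled",
    "wilcoxon_paired",
    "summarize_percent_change",
]


# ---------------------------------------------------------------------------
# model adapters
# ---------------------------------------------------------------------------


class KernelModel:
    """One or more relationship kernels fitted jointly by REML."""

    def __init__(self, kernels: list[RelationshipKernel] | RelationshipKernel, **fit_kwargs):
        self.kernels = kernels if isinstance(kernels, list) else [kernels]
        self.fit_kwargs = fit_kwargs

    def fit_predict(self, y: pd.Series, train_ids: list[str], test_ids: list[str]) -> pd.Series:
        y_train = y.loc[train_ids]
        if len(self.kernels) == 1:
            Ktr = self.kernels[0].align(train_ids)
            fit = fit_single_kernel(y_train, Ktr)
        else:
            fit = fit_multi_kernel(y_train, [K.align(train_ids) for K in self.kernels], **self.fit_kwargs)
        return predict_new_lines(fit, self.kernels, fit.line_ids, test_ids)


class BayesBModel:
    """Marker-effect BayesB adapter; refit per training partition."""

    def __init__(self, geno: GenotypeMatrix, **settings):
        self.geno = geno
        self.settings = settings

    def fit_predict(self, y: pd.Series, train_ids: list[str], test_ids: list[str]) -> pd.Series:
        fit = fit_bayesb(y.loc[train_ids], _subset_lines(self.geno, train_ids), **self.settings)
        test = _subset_lines(self.geno, test_ids)
        return fit.predict(test)


class OracleModel:
    """Returns stored values regardless of training data (test upper bound)."""

    def __init__(self, values: pd.Series):
        self.values = values

    def fit_predict(self, y, train_ids, test_ids) -> pd.Series:
        return self.values.reindex(test_ids)


def _subset_lines(geno: GenotypeMatrix, ids: list[str]) -> GenotypeMatrix:
    lookup = {l: i for i, l in enumerate(geno.line_ids)}
    return geno.subset(lines=np.array([lookup[l] for l in ids]))


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-repeat, per-model accuracies plus the partitions that produced them."""

    accuracies: pd.DataFrame  # columns: repeat, model, env, accuracy
    scheme: str
    n_repeats: int
    seed: int
    partition_hashes: list[str] = field(default_factory=list)

    def per_model(self, model: str, env: str | None = None) -> np.ndarray:
        df = self.accuracies[self.accuracies["model"] == model]
        if env is not None:
            df = df[df["env"] == env]
        return df.sort_values("repeat")["accuracy"].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.accuracies.to_csv(path, sep="\t", index=False)


def _hash_partition(ids: tuple) -> str:
    return hashlib.sha1(repr(ids).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# accuracy estimators
# ---------------------------------------------------------------------------


def accuracy_scaled(y: np.ndarray, yhat: np.ndarray, h2: float) -> float:
    """``r(yhat, y) / sqrt(h2)``; not clamped, may exceed 1 by chance."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    ok = np.isfinite(y) & np.isfinite(yhat)
    y, yhat = y[ok], yhat[ok]
    if y.size < 3 or np.std(yhat) == 0 or np.std(y) == 0:
        warnings.warn("accuracy undefined (constant predictions or too few points)", stacklevel=2)
        return np.nan
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    r = float(np.corrcoef(y, yhat)[0, 1])
    return r / float(np.sqrt(h2))


def accuracy_corg(
    y_test: pd.Series,
    yhat_test: pd.Series,
    K_test: RelationshipKernel,
    h2_fallback: float = 1.0,
) -> float:
    """Genetic-correlation accuracy ``cor_g(y, yhat) * sqrt(h2_yhat)``.

    Fits a bivariate (observed, predicted) mixed model with kernel
    ``K_test`` over the test lines, estimating a 2x2 genetic covariance;
    the accuracy is the genetic correlation scaled by the square root of
    the prediction's genetic signal fraction, clamped to [-1, 1].  On a
    degenerate fit it falls back to :func:`accuracy_scaled` with
    ``h2_fallback`` (logged as a warning).
    """
    ids = [l for l in y_test.index if l in set(K_test.line_ids) and l in set(yhat_test.index)]
    Y = pd.DataFrame({"y": y_test.reindex(ids), "yhat": yhat_test.reindex(ids)})
    try:
        fit = fit_multitrait(Y, K_test.align(ids), structure_g="UN", structure_r="UN", max_iter=200)
        G = fit.G0
        R = fit.R0
        denom = np.sqrt(G[0, 0] * G[1, 1])
        if denom <= 1e-10 or (G[1, 1] + R[1, 1]) <= 1e-12:
            raise FloatingPointError("degenerate genetic covariance")
        cor_g = G[0, 1] / denom
        h2_uhat = G[1, 1] / (G[1, 1] + R[1, 1])
        return float(np.clip(cor_g * np.sqrt(h2_uhat), -1.0, 1.0))
    except Exception as exc:  # pragma: no cover - exercised via degenerate inputs
        warnings.warn(f"bivariate accuracy failed ({exc}); using scaled correlation", stacklevel=2)
        return accuracy_scaled(Y["y"].to_numpy(), Y["yhat"].to_numpy(), h2_fallback)


# ---------------------------------------------------------------------------
# paired signed-rank test (exact by DP for n <= 25 non-zero differences)
# ---------------------------------------------------------------------------


def wilcoxon_paired(acc_a: np.ndarray, acc_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired accuracies.

    Zero differences are dropped.  For up to 25 non-zero differences the
    null distribution of the positive-rank sum is computed exactly by
    dynamic programming over (doubled) midranks, which remains exact under
    ties; beyond that a normal approximation with continuity and tie
    correction is used.  Returns ``(W_plus, p)``.
    """
    a = np.asarray(acc_a, float)
    b = np.asarray(acc_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    ranks = _midranks(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    if n <= 25:
        R = np.rint(2 * ranks).astype(int)  # doubled midranks are integers
        total = int(R.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in R:
            # RHS is materialized before assignment, so the in-place-looking
            # update stays a 0/1 (subset-sum) convolution
            counts[r:] = counts[r:] + counts[:-r]
        counts /= counts.sum()
        s_obs = int(round(2 * w_plus))
        mu = total / 2.0
        dev = abs(s_obs - mu)
        support = np.arange(total + 1)
        p = float(counts[np.abs(support - mu) >= dev - 1e-9].sum())
        return w_plus, min(p, 1.0)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_corr = np.sum(tie_counts**3 - tie_counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    from scipy.stats import norm

    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    return w_plus, float(2 * norm.sf(abs(z)))


def _midranks(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


# ---------------------------------------------------------------------------
# CV schemes
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def half_split_cv(
    y,
    models: dict[str, object],
    K_acc: RelationshipKernel,
    n_repeats: int = 50,
    seed: int = 0,
    h2: float = 1.0,
) -> CVResult:
    """Repeated 50:50 split CV scored by the genetic-correlation accuracy.

    Every model sees the same partition in each repeat.  ``K_acc`` is the
    genomic kernel used inside the bivariate accuracy model; ``h2`` is the
    fallback denominator when that model degenerates.
    """
    ys = _series_of(y)
    ids = list(ys.index)
    seeds = _spawn_seeds(seed, n_repeats)
    rows, hashes = [], []
    for rep, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        train = [ids[i] for i in perm[:half]]
        test = [ids[i] for i in perm[half:]]
        hashes.append(_hash_partition((tuple(train), tuple(test))))
        for name, model in models.items():
            yhat = model.fit_predict(ys, train, test)
            acc = accuracy_corg(ys.loc[test], yhat, K_acc, h2_fallback=h2)
            rows.append({"repeat": rep, "model": name, "env": "single", "accuracy": acc})
    return CVResult(pd.DataFrame(rows), "half_split", n_repeats, seed, hashes)


def fivefold_cv(
    y,
    models: dict[str, object],
    n_repeats: int = 50,
    seed: int = 0,
    h2: float = 1.0,
) -> CVResult:
    """Repeated five-fold CV; per-repeat accuracy on pooled predictions."""
    ys = _series_of(y)
    ids = np.array(list(ys.index))
    seeds = _spawn_seeds(seed, n_repeats)
    rows, hashes = [], []
    for rep, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        perm = rng.permutation(len(ids))
        folds = np.array_split(perm, 5)
        hashes.append(_hash_partition(tuple(tuple(f) for f in folds)))
        preds = {name: pd.Series(index=ys.index, dtype=float) for name in models}
        for f in folds:
            test = list(ids[f])
            train = list(ids[np.setdiff1d(perm, f, assume_unique=True)])
            for name, model in models.items():
                preds[name].loc[test] = model.fit_predict(ys, train, test).to_numpy()
        for name in models:
            acc = accuracy_scaled(ys.to_numpy(float), preds[name].to_numpy(float), h2)
            rows.append({"repeat": rep, "model": name, "env": "single", "accuracy": acc})
    return CVResult(pd.DataFrame(rows), "fivefold", n_repeats, seed, hashes)


def cv2_multienv(
    Y: pd.DataFrame,
    K_g: RelationshipKernel,
    metabolites: dict[str, FeatureMatrix],
    model_specs: dict[str, dict],
    mask_fraction: float = 0.2,
    n_repeats: int = 50,
    seed: int = 0,
    h2: dict[str, float] | float = 1.0,
    mrm_mode: str = "average",
) -> CVResult:
    """CV2 multi-environment scheme with out-of-environment metabolite kernels.

    For each repeat the same ``mask_fraction`` of lines is masked in each
    target environment in turn; the metabolite kernel for a target
    environment is built only from the other environments' features
    (``mrm_mode="average"`` averages each line's feature vector across the
    source environments before the kernel product; ``"concat"``
    concatenates them).  Each model spec is a dict with keys ``kernel`` in
    {"G", "M", "G+M"}, ``structure_g`` and ``structure_r``; "G+M" uses the
    unweighted mean of the two kernels.  Per-repeat accuracy is the
    average over target environments of ``r(yhat, y)/sqrt(h2_env)`` on the
    masked cells.
    """
    envs = list(Y.columns)
    ids = list(Y.index)
    n_mask = int(round(mask_fraction * len(ids)))
    if n_mask < 2:
        raise ValueError("mask_fraction leaves fewer than 2 masked lines")
    h2_map = {e: (h2[e] if isinstance(h2, dict) else float(h2)) for e in envs}
    seeds = _spawn_seeds(seed, n_repeats)
    rows, hashes = [], []
    mrm_cache: dict[str, RelationshipKernel] = {}

    def mrm_for(target: str) -> RelationshipKernel:
        if target not in mrm_cache:
            sources = [metabolites[e] for e in envs if e != target]
            mats = [f.values for f in sources]
            if mrm_mode == "average":
                W = np.mean(mats, axis=0)
            elif mrm_mode == "concat":
                W = np.concatenate(mats, axis=1)
            else:
                raise ValueError("mrm_mode must be 'average' or 'concat'")
            fm = FeatureMatrix(
                W,
                list(sources[0].line_ids),
                [f"oof_{target}_{j}" for j in range(W.shape[1])],
                omics_kind="metabolite",
            )
            mrm_cache[target] = compute_feature_kernel(fm)
        return mrm_cache[target]

    for rep, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        masked = [ids[i] for i in rng.choice(len(ids), size=n_mask, replace=False)]
        hashes.append(_hash_partition(tuple(masked)))
        accs: dict[str, list[float]] = {m: [] for m in model_specs}
        for target in envs:
            Ymask = Y.copy()
            Ymask.loc[masked, target] = np.nan
            for name, spec in model_specs.items():
                K = _combine_kernel(spec.get("kernel", "G"), K_g, mrm_for(target), ids)
                fit = fit_multitrait(
                    Ymask,
                    K,
                    structure_g=spec.get("structure_g", "UN"),
                    structure_r=spec.get("structure_r", "UN"),
                    max_iter=spec.get("max_iter", 200),
                )
                yhat = fit.fitted.loc[masked, target].to_numpy(float)
                yobs = Y.loc[masked, target].to_numpy(float)
                accs[name].append(accuracy_scaled(yobs, yhat, h2_map[target]))
        for name in model_specs:
            rows.append(
                {"repeat": rep, "model": name, "env": "mean", "accuracy": float(np.nanmean(accs[name]))}
            )
    return CVResult(pd.DataFrame(rows), "cv2_multienv", n_repeats, seed, hashes)


def _combine_kernel(which: str, K_g: RelationshipKernel, K_m: RelationshipKernel, ids) -> RelationshipKernel:
    if which == "G":
        return K_g.align(ids)
    if which == "M":
        return K_m.align(ids)
    if which == "G+M":
        A = K_g.align(ids).matrix
        B = K_m.align(ids).matrix
        return RelationshipKernel(0.5 * (A + B), list(ids), kind="G")
    raise ValueError("kernel must be 'G', 'M' or 'G+M'")


def _series_of(y) -> pd.Series:
    from .stageone import TraitValues

    if isinstance(y, TraitValues):
        return y.values.dropna()
    if isinstance(y, pd.Series):
        return y.dropna()
    raise TypeError("y must be a TraitValues or Series")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_percent_change(results: CVResult, baseline_model: str) -> pd.DataFrame:
    """Median/mean percent change in accuracy relative to a baseline model.

    Per repeat: ``100 (acc_model - acc_base) / acc_base``; repeats with a
    zero baseline accuracy are excluded with a warning.  Significance stars
    come from the paired signed-rank test across repeats
    (*, **, *** at 0.05 / 0.01 / 0.001).
    """
    base = results.per_model(baseline_model)
    rows = []
    for model in results.accuracies["model"].unique():
        if model == baseline_model:
            continue
        acc = results.per_model(model)
        ok = base != 0
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} repeat(s) with zero baseline accuracy excluded", stacklevel=2
            )
        pct = 100.0 * (acc[ok] - base[ok]) / base[ok]
        _, p = wilcoxon_paired(acc, base)
        stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "NS"
        rows.append(
            {
                "model": model,
                "baseline": baseline_model,
                "median_pct_change": float(np.median(pct)) if pct.size else np.nan,
                "mean_pct_change": float(np.mean(pct)) if pct.size else np.nan,
                "wilcoxon_p": p,
                "stars": stars,
            }
        )
    return pd.DataFrame(rows)
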