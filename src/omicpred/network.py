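"""Weighted-correlation network analysis of omics features.

Implements the co-abundance module workflow on metabolite (or transcript)
features: soft-threshold selection by scale-free fit, power adjacency,
topological overlap (TOM) and its dissimilarity, average-linkage
clustering with a Dynamic-Hybrid tree cut, module eigenvectors, chemical
superclass enrichment by Fisher's exact test, and hierarchical clustering
of module summaries against an external trait composite.

The Dynamic-Hybrid cut is implemented from its published description:
stage 1 recursively accepts dendrogram branches as module cores when they
are large enough, internally tight (core scatter) and separated from their
surroundings (gap); stage 2 assigns leftover features to the nearest
module medoid, ignoring the dendrogram. The deepSplit level maps to the
documented preset pairs (maxCoreScatter, minGap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .kernels import FeatureMatrix

__all__ = [
    "ModulePartition",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "cluster_modules",
    "module_eigenvector",
    "enrichment_fisher",
    "cluster_summaries",
]

# deepSplit presets: (maxCoreScatter, minGap), minGap = 3/4 (1 - maxCoreScatter)
DEEPSPLIT_PRESETS = {
    0: (0.64, 0.27),
    1: (0.73, 0.2025),
    2: (0.82, 0.135),
    3: (0.91, 0.0675),
    4: (0.95, 0.0375),
}


@dataclass
class ModulePartition:
    """Feature -> module labels (0 = unassigned) plus per-module eigenvectors."""

    labels: pd.Series  # feature_id -> int label
    eigenvectors: pd.DataFrame = field(default_factory=pd.DataFrame)  # line x module
    linkage: np.ndarray | None = None

    @property
    def modules(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def to_tsv(self, path) -> None:
        self.labels.rename("module").rename_axis("feature").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# adjacency / TOM
# ---------------------------------------------------------------------------


def adjacency(
    features: FeatureMatrix | np.ndarray, power: float = 4, mode: str = "unsigned"
) -> np.ndarray:
    """Soft-threshold power adjacency ``A_ij = |cor(x_i, x_j)|^power``.

    ``mode="signed"`` uses ``((1 + cor)/2)^power`` instead.  Diagonal is 1.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.shape[0] < 3:
        raise ValueError("at least 3 lines required for correlations")
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    if mode == "unsigned":
        A = np.abs(C) ** power
    elif mode == "signed":
        A = ((1.0 + C) / 2.0) ** power
    else:
        raise ValueError("mode must be 'unsigned' or 'signed'")
    np.fill_diagonal(A, 1.0)
    return np.clip(A, 0.0, 1.0)


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbour-weighted similarity in [0, 1].

    ``TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)`` with
    connectivity ``k_i = sum_{u != i} A_iu`` and the sum excluding u in
    {i, j}; the diagonal is 1.
    """
    A = np.asarray(A, float)
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    shared = A0 @ A0  # sum_u A_iu A_uj over u != i, j (diagonal of A0 is 0)
    num = shared + A0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(T, 1.0)
    return np.clip(0.5 * (T + T.T), 0.0, 1.0)


def pick_soft_threshold(
    features: FeatureMatrix | np.ndarray,
    powers: np.ndarray | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free-fit summary for a range of soft-threshold powers.

    For each power the whole-network connectivity distribution is binned
    and ``log10 p(k)`` regressed on ``log10 k``; the signed fit index is
    ``-sign(slope) * R^2`` so that the biologically expected negative slope
    yields a positive value.  Power 0 gives an all-ones adjacency whose
    fit is reported as missing.
    """
    powers = np.arange(1, 21) if powers is None else np.asarray(powers)
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    with np.errstate(invalid="ignore"):
        C = np.nan_to_num(np.corrcoef(X, rowvar=False), nan=0.0)
    absC = np.abs(C)
    rows = []
    for b in powers:
        if b == 0:
            rows.append({"power": 0, "sft_r2": np.nan, "slope": np.nan, "mean_k": float(absC.shape[0] - 1)})
            continue
        A = absC**b
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        rows.append({"power": int(b), **_scale_free_fit(k, n_bins), "mean_k": float(k.mean())})
    return pd.DataFrame(rows)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> dict:
    k = k[k > 0]
    if k.size < n_bins:
        return {"sft_r2": np.nan, "slope": np.nan}
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean() + 1e-12))
    if len(xs) < 3:
        return {"sft_r2": np.nan, "slope": np.nan}
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = np.sum((ys - ys.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    return {"sft_r2": float(-np.sign(slope) * r2), "slope": float(slope)}


# ---------------------------------------------------------------------------
# Dynamic Hybrid tree cut
# ---------------------------------------------------------------------------


def _branch_leaves(Z: np.ndarray, node: int, n: int) -> list[int]:
    """Leaves under an internal node of a scipy linkage matrix."""
    stack, out = [node], []
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.append(int(Z[v - n, 0]))
            stack.append(int(Z[v - n, 1]))
    return out


def _internal_heights(Z: np.ndarray, node: int, n: int) -> list[float]:
    stack, out = [node], []
    while stack:
        v = stack.pop()
        if v >= n:
            out.append(Z[v - n, 2])
            stack.append(int(Z[v - n, 0]))
            stack.append(int(Z[v - n, 1]))
    return out


def cluster_modules(
    dissTOM: np.ndarray,
    linkage_method: str = "average",
    deep_split: int = 2,
    min_cluster_size: int = 20,
    cut_height: float | None = None,
    pam_stage: bool = True,
    feature_ids: list[str] | None = None,
) -> ModulePartition:
    """Average-linkage clustering + Dynamic-Hybrid cut of a TOM dissimilarity.

    Stage 1 walks the dendrogram from the cut height downwards and accepts
    a branch as a module core when (a) it holds at least
    ``min_cluster_size`` leaves, (b) its normalized core scatter (mean
    internal merge height of its tightest ``min_cluster_size`` leaves) is
    below the deepSplit preset's ``maxCoreScatter``, and (c) it is
    separated from its merge partner by at least ``minGap``.  A branch that
    fails but whose children can be split recursively is descended into.
    Stage 2 (PAM-like, enabled by default) assigns every unlabelled
    feature to the module with the nearest medoid provided that distance
    does not exceed the cut height; remaining features keep label 0.
    """
    D = np.asarray(dissTOM, float)
    n = D.shape[0]
    if min_cluster_size > n:
        raise ValueError("min_cluster_size exceeds the number of features")
    if deep_split not in DEEPSPLIT_PRESETS:
        raise ValueError("deep_split must be in 0..4")
    max_core_scatter, min_gap = DEEPSPLIT_PRESETS[deep_split]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n)]

    Z = average(squareform(D, checks=False))
    heights = Z[:, 2]
    hmax = heights.max()
    h5 = np.quantile(heights, 0.05)
    if cut_height is None:
        cut_height = h5 + 0.99 * (hmax - h5)
    span = max(cut_height - h5, 1e-12)

    def norm(h: float) -> float:
        return (h - h5) / span

    # parent height of every internal node (root attaches above the top)
    parent_h = np.full(n - 1, hmax + span * 0.05)
    for k in range(n - 1):
        for child in (int(Z[k, 0]), int(Z[k, 1])):
            if child >= n:
                parent_h[child - n] = Z[k, 2]

    def core_scatter(node: int) -> float:
        """Mean normalized height of the lowest merges forming the core."""
        hs = sorted(_internal_heights(Z, node, n))
        m = max(min_cluster_size - 1, 1)
        core = hs[: min(m, len(hs))]
        return float(np.mean([norm(x) for x in core]))

    # bottom-up scan for MINIMAL qualified branches: large enough, internally
    # tight (core scatter), and separated from their surroundings (the gap to
    # the merge where the branch attaches to the rest of the tree)
    labels = np.zeros(n, dtype=int)
    next_label = 1
    leaf_count = np.ones(2 * n - 1, dtype=int)
    has_selected = np.zeros(2 * n - 1, dtype=bool)
    selected: list[int] = []
    for k in range(n - 1):  # scipy merge order is height-sorted
        node = n + k
        left, right = int(Z[k, 0]), int(Z[k, 1])
        leaf_count[node] = leaf_count[left] + leaf_count[right]
        has_selected[node] = has_selected[left] or has_selected[right]
        if has_selected[node] or heights[k] > cut_height:
            continue
        if leaf_count[node] < min_cluster_size:
            continue
        gap = norm(parent_h[k]) - norm(heights[k])
        if gap >= min_gap and core_scatter(node) <= max_core_scatter:
            selected.append(node)
            has_selected[node] = True
    for node in selected:
        labels[_branch_leaves(Z, node, n)] = next_label
        next_label += 1

    # stage 2: PAM-like medoid assignment, ignoring the dendrogram
    if pam_stage and labels.any():
        medoids = {}
        radius = {}
        for m in np.unique(labels[labels > 0]):
            idx = np.where(labels == m)[0]
            within = D[np.ix_(idx, idx)].mean(axis=1)
            med = idx[int(np.argmin(within))]
            medoids[m] = med
            radius[m] = D[idx, med].max()
        for i in np.where(labels == 0)[0]:
            dists = {m: D[i, med] for m, med in medoids.items()}
            m_best = min(dists, key=dists.get)
            if dists[m_best] <= radius[m_best]:
                labels[i] = m_best

    # relabel by decreasing size (1 = largest), 0 stays unassigned
    sizes = pd.Series(labels[labels > 0]).value_counts()
    remap = {old: i + 1 for i, old in enumerate(sizes.index)}
    labels = np.array([remap.get(l, 0) for l in labels])
    return ModulePartition(
        labels=pd.Series(labels, index=feature_ids), linkage=Z
    )


# ---------------------------------------------------------------------------
# module summaries
# ---------------------------------------------------------------------------


def module_eigenvector(
    features: FeatureMatrix, partition: ModulePartition, module: int
) -> pd.Series:
    """First principal component of a module's standardized features.

    The sign is aligned so that the average correlation with the member
    features is positive, making the score a consensus abundance.
    """
    members = partition.members(module)
    if not members:
        raise ValueError(f"module {module} has no members")
    idx = [features.feature_ids.index(f) for f in members]
    X = features.values[:, idx]
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    pc1 = U[:, 0]  # unit-norm over lines
    mean_cor = float(np.mean(Xs.T @ pc1))
    if mean_cor < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=features.line_ids)


def all_eigenvectors(features: FeatureMatrix, partition: ModulePartition) -> pd.DataFrame:
    cols = {m: module_eigenvector(features, partition, m) for m in partition.modules}
    return pd.DataFrame(cols, index=features.line_ids)


def enrichment_fisher(
    partition: ModulePartition,
    annotations: dict[str, str],
    target_class: str,
) -> pd.DataFrame:
    """Per-module one-sided Fisher enrichment for a chemical superclass.

    Builds the 2x2 table (in module x in class) over all partitioned
    features, reports the odds ratio and one-sided hypergeometric p-value,
    and BH-adjusts across modules.  A module containing all features has
    an undefined odds ratio (reported missing, p = 1).
    """
    feats = list(partition.labels.index)
    in_class = np.array([annotations.get(f) == target_class for f in feats])
    rows = []
    for m in partition.modules:
        in_mod = (partition.labels == m).to_numpy()
        a = int(np.sum(in_mod & in_class))
        b = int(np.sum(in_mod & ~in_class))
        c = int(np.sum(~in_mod & in_class))
        d = int(np.sum(~in_mod & ~in_class))
        if (c + d) == 0 or in_class.sum() == 0:
            rows.append({"module": m, "odds_ratio": np.nan, "p": 1.0, "n_in_class": a, "n_module": a + b})
            continue
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"module": m, "odds_ratio": float(odds), "p": float(p), "n_in_class": a, "n_module": a + b})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def cluster_summaries(
    eigenvectors: pd.DataFrame, external: pd.Series | None = None, external_name: str = "trait_pc1"
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of module summaries by correlation distance.

    Optionally appends an external trait composite (e.g. PC1 of a trait
    family).  Returns the scipy linkage matrix and the column labels, in
    linkage leaf order of the input columns.
    """
    M = eigenvectors.copy()
    if external is not None:
        M[external_name] = external.reindex(M.index)
    labels = [str(c) for c in M.columns]
    C = np.corrcoef(M.to_numpy(float), rowvar=False)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(0.5 * (D + D.T), checks=False))
    return Z, labels


def nearest_summary(Z: np.ndarray, labels: list[str], query: str) -> set[str]:
    """Labels that ``query`` first merges with in the summary dendrogram."""
    n = len(labels)
    qi = labels.index(query)
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    for k, row in enumerate(Z):
        a, b = int(row[0]), int(row[1])
        if qi in clusters[a]:
            return {labels[i] for i in clusters[b]}
        if qi in clusters[b]:
            return {labels[i] for i in clusters[a]}
        clusters[n + k] = clusters[a] | clusters[b]
    raise ValueError("query never merges")  # pragma: no cover
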