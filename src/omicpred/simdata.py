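"""Synthetic genotypes, omics features, and phenotypes with the statistical
structure the downstream analysis assumes.

The generator emulates the structure of a two-panel small-grain breeding
study: a large diverse training panel and a smaller elite panel with
divergent allele frequencies and a handful of shared lines; marker LD along
chromosomes; a major-effect pleiotropic QTL that drives both a target trait
and a correlated module of omics features; multi-environment phenotypes
with a specified across-environment genetic covariance; and augmented
incomplete block field designs with replicated checks and batch effects.

Model summary
-------------
* Population divergence follows the Balding-Nichols model: each marker has
  an ancestral allele frequency drawn uniformly from ``maf_range`` and
  population-specific frequencies drawn from
  ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` with ``F = fst``.
* LD is first-order Markov haplotype copying: along a chromosome each
  haplotype copies its previous allele with probability ``ld_rho`` and
  otherwise draws a fresh Bernoulli from the marker's frequency.
* Lines are partially inbred: with probability ``inbreeding`` a line's two
  haplotypes are identical (selfing-crop default 0.95).
* Omics features are linear in QTL dosages plus Gaussian noise; planted
  co-abundance modules share a latent factor partially driven by the QTL
  named in the architecture's pleiotropy map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import FeatureMatrix, GenotypeMatrix
from .stageone import PhenotypeTable

__all__ = [
    "SimConfig",
    "TraitArchitecture",
    "EnvCovariance",
    "simulate_genotypes",
    "simulate_features",
    "simulate_phenotypes",
    "simulate_line_values",
    "module_annotations",
    "write_truth",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Two-panel genotype simulation settings.

    Defaults mirror the study conditions being emulated: a diversity-like
    panel of 368 lines, an elite-like panel of 232 lines, 32 lines in
    common, and a hexaploid-oat-like genome scaled to 7 chromosomes.
    """

    n_lines_pop1: int = 368
    n_lines_pop2: int = 232
    n_shared: int = 32
    n_chrom: int = 7
    markers_per_chrom: int = 300
    ld_rho: float = 0.6
    fst: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    inbreeding: float = 0.95
    miss_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_lines_pop1", "n_lines_pop2", "n_chrom", "markers_per_chrom"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_shared <= min(self.n_lines_pop1, self.n_lines_pop2):
            raise ValueError("n_shared must be <= both panel sizes")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must lie in [0, 1)")


@dataclass
class TraitArchitecture:
    """Additive genetic architecture of the simulated target trait.

    ``qtl_effects`` are per-dosage additive effects for the markers listed
    in ``qtl_ids``; ``polygenic_var`` is the variance of an additional
    genome-wide polygenic component on the same scale, so the ratio of the
    QTL variance to ``polygenic_var`` sets how oligogenic the trait is.
    ``pleiotropy_map`` names, per QTL marker index, the planted omics
    modules (0-based) whose latent factor that QTL drives.
    """

    qtl_ids: list[int] = field(default_factory=list)
    qtl_effects: list[float] = field(default_factory=list)
    major_qtl_id: int | None = None
    h2_target: float = 0.5
    pleiotropy_map: dict[int, list[int]] = field(default_factory=dict)
    polygenic_var: float = 0.5

    def __post_init__(self) -> None:
        if len(self.qtl_ids) != len(self.qtl_effects):
            raise ValueError("qtl_ids and qtl_effects must have equal length")
        if len(set(self.qtl_ids)) != len(self.qtl_ids):
            raise ValueError("qtl_ids must be distinct")
        if not 0.0 < self.h2_target <= 1.0:
            raise ValueError("h2_target must lie in (0, 1]")
        if self.polygenic_var < 0:
            raise ValueError("polygenic_var must be >= 0")
        if self.major_qtl_id is not None and self.major_qtl_id not in self.qtl_ids:
            raise ValueError("major_qtl_id must be one of qtl_ids")


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(M).min() < -1e-10:
        raise ValueError(f"{name} must be positive semi-definite")
    return M


@dataclass
class EnvCovariance:
    """Across-environment genetic (G0) and residual (R0) covariance."""

    G0: np.ndarray
    R0: np.ndarray

    def __post_init__(self) -> None:
        self.G0 = _check_psd(self.G0, "G0")
        self.R0 = _check_psd(self.R0, "R0")
        if self.G0.shape != self.R0.shape:
            raise ValueError("G0 and R0 must have equal dimension")

    @property
    def n_env(self) -> int:
        return self.G0.shape[0]

    @classmethod
    def exchangeable(
        cls, n_env: int = 3, g_var: float = 1.0, g_cor: float = 0.6, r_var: float = 1.0
    ) -> "EnvCovariance":
        """Equal-variance, equal-correlation G0 with independent residuals.

        The default across-environment genetic correlation of 0.6 is a
        placeholder for moderately consistent multi-location trials, not an
        estimate from any real data set.
        """
        G0 = g_var * ((1 - g_cor) * np.eye(n_env) + g_cor * np.ones((n_env, n_env)))
        R0 = r_var * np.eye(n_env)
        return cls(G0, R0)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _sim_haplotypes(
    rng: np.random.Generator,
    freqs: np.ndarray,
    chrom_sizes: list[int],
    n_hap: int,
    ld_rho: float,
) -> np.ndarray:
    """Markov-copying haplotypes: P(copy previous allele) = ld_rho."""
    p = freqs
    H = np.empty((n_hap, p.size), dtype=np.int8)
    j0 = 0
    for size in chrom_sizes:
        for j in range(j0, j0 + size):
            fresh = rng.random(n_hap) < p[j]
            if j == j0 or ld_rho == 0.0:
                H[:, j] = fresh
            else:
                copy = rng.random(n_hap) < ld_rho
                H[:, j] = np.where(copy, H[:, j - 1], fresh)
        j0 += size
    return H


def _lines_from_haps(
    rng: np.random.Generator,
    freqs: np.ndarray,
    chrom_sizes: list[int],
    n_lines: int,
    ld_rho: float,
    inbreeding: float,
) -> np.ndarray:
    h1 = _sim_haplotypes(rng, freqs, chrom_sizes, n_lines, ld_rho)
    h2 = _sim_haplotypes(rng, freqs, chrom_sizes, n_lines, ld_rho)
    selfed = rng.random(n_lines) < inbreeding
    h2[selfed] = h1[selfed]
    return (h1 + h2).astype(float)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Simulate the two partially overlapping panels.

    Returns ``(pop1, pop2)``; the first ``cfg.n_shared`` lines of each panel
    are the same lines (identical ids and genotype rows).  Population
    frequencies diverge by Balding-Nichols drift at level ``cfg.fst``;
    shared lines are drawn from population 1.
    """
    rng = np.random.default_rng(cfg.seed)
    n_mark = cfg.n_chrom * cfg.markers_per_chrom
    chrom_sizes = [cfg.markers_per_chrom] * cfg.n_chrom
    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=n_mark)

    if cfg.fst > 0:
        F = cfg.fst
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    else:
        p1 = p_anc.copy()
        p2 = p_anc.copy()

    d1 = _lines_from_haps(rng, p1, chrom_sizes, cfg.n_lines_pop1, cfg.ld_rho, cfg.inbreeding)
    d2 = _lines_from_haps(rng, p2, chrom_sizes, cfg.n_lines_pop2, cfg.ld_rho, cfg.inbreeding)
    if cfg.n_shared:
        d2[: cfg.n_shared] = d1[: cfg.n_shared]

    if cfg.miss_rate > 0:
        for d in (d1, d2):
            mask = rng.random(d.shape) < cfg.miss_rate
            d[mask] = np.nan
        if cfg.n_shared:  # keep shared rows identical after masking
            d2[: cfg.n_shared] = d1[: cfg.n_shared]

    marker_ids = [f"m{j:05d}" for j in range(n_mark)]
    chroms = np.repeat([f"chr{c + 1}" for c in range(cfg.n_chrom)], cfg.markers_per_chrom)
    pos = np.tile(np.arange(cfg.markers_per_chrom) * 100_000 + 1, cfg.n_chrom)
    mmap = pd.DataFrame({"chrom": chroms, "pos": pos}, index=marker_ids)

    shared_ids = [f"S{i:04d}" for i in range(cfg.n_shared)]
    ids1 = shared_ids + [f"D{i:04d}" for i in range(cfg.n_lines_pop1 - cfg.n_shared)]
    ids2 = shared_ids + [f"E{i:04d}" for i in range(cfg.n_lines_pop2 - cfg.n_shared)]
    return (
        GenotypeMatrix(d1, ids1, marker_ids, mmap),
        GenotypeMatrix(d2, ids2, marker_ids, mmap.copy()),
    )


# ---------------------------------------------------------------------------
# omics features with planted modules
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else x - x.mean()


def simulate_features(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    n_features: int = 500,
    n_modules: int = 4,
    module_size: int = 30,
    noise_sd: float = 0.5,
    seed: int = 0,
    qtl_loading: float = 0.7,
    module_drivers: dict[int, np.ndarray] | None = None,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Omics feature matrix with planted co-abundance modules.

    Each planted module m has a latent per-line factor; if the architecture's
    ``pleiotropy_map`` names module m for some QTL, the factor loads on that
    QTL's standardized dosage with coefficient ``qtl_loading`` (remaining
    variance independent noise).  ``module_drivers`` optionally supplies an
    arbitrary per-line driver signal for chosen modules (0-based), e.g. a
    trait's total genetic value, replacing the QTL dosage as the factor's
    genetic component — this emulates omics features that are themselves
    heritable and genetically correlated with a trait.  Module features
    equal the factor plus ``noise_sd`` Gaussian noise; all other features
    are pure standard normal noise.  Returns the matrix plus true labels
    (0 = background, 1..n_modules = planted module).
    """
    if n_modules * module_size > n_features:
        raise ValueError("n_modules * module_size exceeds n_features")
    if np.isnan(geno.dosages).any():
        raise ValueError("feature simulation requires complete dosages")
    rng = np.random.default_rng(seed)
    n = geno.n_lines
    X = rng.normal(size=(n, n_features))
    labels = np.zeros(n_features, dtype=int)

    drivers: dict[int, list[int]] = {m: [] for m in range(n_modules)}
    for qtl, modules in arch.pleiotropy_map.items():
        for m in modules:
            if 0 <= m < n_modules:
                drivers[m].append(qtl)

    for m in range(n_modules):
        cols = slice(m * module_size, (m + 1) * module_size)
        labels[cols] = m + 1
        factor = rng.normal(size=n)
        if module_drivers is not None and m in module_drivers:
            z = _standardize(np.asarray(module_drivers[m], float))
            factor = qtl_loading * z + np.sqrt(max(0.0, 1 - qtl_loading**2)) * _standardize(factor)
        elif drivers[m]:
            z = _standardize(geno.dosages[:, drivers[m]].mean(axis=1))
            factor = qtl_loading * z + np.sqrt(max(0.0, 1 - qtl_loading**2)) * _standardize(factor)
        else:
            factor = _standardize(factor)
        X[:, cols] = factor[:, None] + noise_sd * rng.normal(size=(n, module_size))

    fm = FeatureMatrix(
        X,
        list(geno.line_ids),
        [f"feat{j:04d}" for j in range(n_features)],
        omics_kind="metabolite",
    )
    return fm, labels


def module_annotations(
    labels: np.ndarray,
    feature_ids: list[str],
    target_modules: list[int],
    target_class: str = "Lipids and lipid-like molecules",
    background_rate: float = 0.1,
    seed: int = 0,
) -> dict[str, str]:
    """Chemical-superclass annotations enriching chosen planted modules.

    Features of the modules in ``target_modules`` (1-based labels) are
    annotated with ``target_class``; other features receive it at
    ``background_rate`` and are otherwise labelled 'Other'.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for fid, lab in zip(feature_ids, labels):
        if lab in target_modules:
            out[fid] = target_class
        else:
            out[fid] = target_class if rng.random() < background_rate else "Other"
    return out


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _genetic_values(
    rng: np.random.Generator,
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    G0: np.ndarray,
) -> np.ndarray:
    """Per-line genetic values for each environment, Cov ~ G0 (x) A.

    With one environment the architecture's fixed QTL effects are used
    directly (deterministic oligogenic signal).  With several environments
    the e genetic vectors are built from e independent realizations of the
    architecture (fresh effect draws with per-marker sd equal to the stated
    |effect|) mixed through chol(G0), which gives the exact Kronecker
    genetic covariance at the cost of randomizing effect signs per
    realization.
    """
    n = geno.n_lines
    e = G0.shape[0]
    Z = geno.dosages - geno.dosages.mean(axis=0)
    qtl = np.asarray(arch.qtl_ids, dtype=int)
    eff = np.asarray(arch.qtl_effects, dtype=float)

    def one_copy(effects: np.ndarray) -> np.ndarray:
        g = Z[:, qtl] @ effects if qtl.size else np.zeros(n)
        if arch.polygenic_var > 0:
            u = rng.normal(size=geno.n_markers)
            poly = Z @ u
            poly = _standardize(poly) * np.sqrt(arch.polygenic_var)
            g = g + poly
        return g

    if e == 1:
        g = one_copy(eff)
        sd = g.std()
        g = (g - g.mean()) / (sd if sd > 0 else 1.0) * np.sqrt(G0[0, 0])
        return g[:, None]

    T = np.empty((n, e))
    for k in range(e):
        a_k = rng.normal(size=eff.size) * np.abs(eff) if eff.size else eff
        t = one_copy(a_k)
        sd = t.std()
        T[:, k] = (t - t.mean()) / (sd if sd > 0 else 1.0)
    # mix through the Cholesky factor of G0 so Cov over envs equals G0
    w, V = np.linalg.eigh(G0)
    B = V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T
    return T @ B.T


def _residual_cov(envcov: EnvCovariance, arch: TraitArchitecture) -> np.ndarray:
    """R0, with its diagonal rescaled so line-level h2 equals h2_target."""
    R0 = envcov.R0.copy()
    G0 = envcov.G0
    h2 = arch.h2_target
    target_diag = np.diag(G0) * (1.0 - h2) / h2
    d_old = np.sqrt(np.maximum(np.diag(R0), 1e-300))
    d_new = np.sqrt(target_diag)
    scale = np.outer(d_new / d_old, d_new / d_old)
    return R0 * scale


def simulate_line_values(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    envcov: EnvCovariance,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Line-level phenotypes per environment, skipping the field design.

    Returns ``(Y, true_bv)`` DataFrames (lines x environments) where
    ``Y = true_bv + residual`` with residuals MVN(0, R0) across
    environments (R0 diagonal rescaled to meet ``arch.h2_target``).
    """
    rng = np.random.default_rng(seed)
    G = _genetic_values(rng, geno, arch, envcov.G0)
    R0 = _residual_cov(envcov, arch)
    w, V = np.linalg.eigh(R0)
    L = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    E = rng.normal(size=G.shape) @ L.T
    envs = [f"env{k + 1}" for k in range(envcov.n_env)]
    Y = pd.DataFrame(G + E, index=geno.line_ids, columns=envs)
    bv = pd.DataFrame(G, index=geno.line_ids, columns=envs)
    return Y, bv


def simulate_phenotypes(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    envcov: EnvCovariance,
    design: dict | None = None,
    seed: int = 0,
    trait: str = "trait",
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Plot-level phenotypes under an augmented incomplete block design.

    ``design`` keys (with defaults): ``n_blocks`` (18), ``plots_per_block``
    (capacity check only), ``n_checks`` (3), ``block_sd`` (0.5),
    ``batch_sd`` (0.0).  One common check appears in every block; secondary
    checks are each replicated in a third of the blocks.  Test lines are
    unreplicated.  Returns the plot table plus true breeding values
    (lines x environments).
    """
    design = dict(design or {})
    n_blocks = int(design.get("n_blocks", 18))
    n_checks = int(design.get("n_checks", 3))
    block_sd = float(design.get("block_sd", 0.5))
    batch_sd = float(design.get("batch_sd", 0.0))

    rng = np.random.default_rng(seed)
    e = envcov.n_env
    envs = [f"env{k + 1}" for k in range(e)]
    G = _genetic_values(rng, geno, arch, envcov.G0)
    R0 = _residual_cov(envcov, arch)

    g_sd = float(np.sqrt(np.diag(envcov.G0).mean()))
    check_ids = [f"check_{c + 1}" for c in range(n_checks)]
    check_vals = rng.normal(scale=g_sd, size=(n_checks, e))

    # plot layout: every test line once, round-robin over blocks
    order = rng.permutation(geno.n_lines)
    entries: list[tuple[str, int, bool, int]] = []  # (line, block, is_check, line_row)
    for i, row in enumerate(order):
        entries.append((geno.line_ids[row], i % n_blocks + 1, False, row))
    for b in range(1, n_blocks + 1):
        entries.append((check_ids[0], b, True, -1))
    for c in range(1, n_checks):
        reps = max(1, n_blocks // 3)
        for b in rng.choice(n_blocks, size=reps, replace=False):
            entries.append((check_ids[c], int(b) + 1, True, -(c + 1)))

    ppb = design.get("plots_per_block")
    if ppb is not None:
        counts = pd.Series([b for _, b, _, _ in entries]).value_counts()
        if counts.max() > int(ppb):
            raise ValueError("design capacity exceeded: too many plots per block")

    n_batches = max(2, n_blocks // 3)
    w, V = np.linalg.eigh(R0)
    Lr = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))

    records = []
    for env_i, env in enumerate(envs):
        block_eff = rng.normal(scale=block_sd, size=n_blocks)
        batch_eff = rng.normal(scale=batch_sd, size=n_batches)
        batch_of = rng.integers(0, n_batches, size=len(entries))
        resid = (rng.normal(size=(len(entries), e)) @ Lr.T)[:, env_i]
        for k, (line, block, is_check, row) in enumerate(entries):
            g = check_vals[-row - 1, env_i] if is_check else G[row, env_i]
            val = g + block_eff[block - 1] + batch_eff[batch_of[k]] + resid[k]
            records.append(
                {
                    "line_id": line,
                    "trait": trait,
                    "environment": env,
                    "block": block,
                    "is_check": is_check,
                    "batch": int(batch_of[k] + 1),
                    "value": float(val),
                }
            )
    table = PhenotypeTable(pd.DataFrame.from_records(records))
    bv = pd.DataFrame(G, index=geno.line_ids, columns=envs)
    return table, bv


# ---------------------------------------------------------------------------
# truth-file output (TSV, for external inspection and tests)
# ---------------------------------------------------------------------------


def write_truth(
    path_prefix: str,
    arch: TraitArchitecture,
    labels: np.ndarray | None = None,
    feature_ids: list[str] | None = None,
    true_bv: pd.DataFrame | None = None,
) -> None:
    """Write QTL, module-label, and breeding-value truth tables as TSV."""
    pd.DataFrame(
        {"marker_index": arch.qtl_ids, "effect": arch.qtl_effects}
    ).to_csv(f"{path_prefix}.qtl.tsv", sep="\t", index=False)
    if labels is not None and feature_ids is not None:
        pd.DataFrame({"feature": feature_ids, "module": labels}).to_csv(
            f"{path_prefix}.modules.tsv", sep="\t", index=False
        )
    if true_bv is not None:
        true_bv.rename_axis("line").to_csv(f"{path_prefix}.bv.tsv", sep="\t")
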