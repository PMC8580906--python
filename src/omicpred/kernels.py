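"""Genotype/omics containers, QC filters, and relationship-kernel construction.

This module holds the data containers shared across the package and every
operation that turns raw marker or omics data into line x line relationship
kernels: marker and line quality filters, missing-genotype imputation, the
VanRaden genomic relationship matrix (GRM), transcript/metabolite
relationship matrices (TRM/MRM), Rogers' genetic distance, neighbor-joining
trees, and genotype principal components.

Conventions
-----------
* Dosages are stored as floats in {0, 1, 2} with ``nan`` marking missing
  calls; 2 counts copies of the non-reference (arbitrary "alternate")
  allele.
* Every kernel is a symmetric ``n x n`` matrix indexed by ``line_ids``;
  positive semi-definiteness is enforced (up to round-off) via
  :func:`stabilize_kernel`.
* Heterozygosity of a marker or line is the fraction of dosage-1 calls
  among its non-missing calls.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh

__all__ = [
    "GenotypeMatrix",
    "FeatureMatrix",
    "RelationshipKernel",
    "filter_markers",
    "filter_lines",
    "impute_missing",
    "compute_grm",
    "compute_feature_kernel",
    "stabilize_kernel",
    "rogers_distance",
    "neighbor_joining",
    "genotype_pca",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Lines x biallelic markers dosage matrix with a marker map.

    Parameters
    ----------
    dosages
        ``(n_lines, n_markers)`` float array with entries in {0, 1, 2} or
        ``nan`` for missing calls.
    line_ids, marker_ids
        Unique string identifiers for rows and columns.
    marker_map
        DataFrame indexed by marker with columns ``chrom`` and ``pos``.
    """

    dosages: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    marker_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        n, p = self.dosages.shape
        if n != len(self.line_ids) or p != len(self.marker_ids):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            # imputed matrices may carry real values; only warn when a
            # value falls outside the feasible dosage range
            if np.any((obs < 0) | (obs > 2)):
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset(self, lines: np.ndarray | None = None, markers: np.ndarray | None = None) -> "GenotypeMatrix":
        """Boolean/index subsetting preserving order."""
        d = self.dosages
        lid, mid = self.line_ids, self.marker_ids
        if lines is not None:
            lines = np.asarray(lines)
            d = d[lines]
            lid = [lid[i] for i in np.arange(len(lid))[lines]] if lines.dtype == bool else [lid[i] for i in lines]
        if markers is not None:
            markers = np.asarray(markers)
            d = d[:, markers]
            mid = [mid[i] for i in np.arange(len(mid))[markers]] if markers.dtype == bool else [mid[i] for i in markers]
        mmap = self.marker_map.loc[mid] if self.marker_map is not None else None
        return GenotypeMatrix(d, lid, mid, mmap)

    def marker_index(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        return np.array([lookup[m] for m in marker_ids], dtype=int)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)
        df.index.name = "line"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, marker_map: pd.DataFrame | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.index), list(df.columns), marker_map)

    def to_vcf(self, path) -> None:
        """Write diploid unphased genotypes (missing dosages as ./.)."""
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            chroms = (
                self.marker_map["chrom"].astype(str).unique()
                if self.marker_map is not None
                else ["0"]
            )
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.line_ids) + "\n")
            for j, m in enumerate(self.marker_ids):
                if self.marker_map is not None:
                    chrom = str(self.marker_map.loc[m, "chrom"])
                    pos = int(self.marker_map.loc[m, "pos"])
                else:
                    chrom, pos = "0", j + 1
                col = self.dosages[:, j]
                gts = "\t".join(
                    "./." if np.isnan(x) else gt_of[round(float(x))] for x in col
                )
                fh.write(f"{chrom}\t{pos}\t{m}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read biallelic sites from an (uncompressed) VCF, GT field only."""
        rows, markers, chroms, poss = [], [], [], []
        samples: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    samples = parts[9:]
                    continue
                chrom, pos, mid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
                if "," in alt:  # multi-allelic sites are out of scope
                    continue
                fmt = parts[8].split(":")
                gt_idx = fmt.index("GT")
                dos = []
                for s in parts[9:]:
                    gt = s.split(":")[gt_idx].replace("|", "/")
                    if "." in gt:
                        dos.append(np.nan)
                    else:
                        dos.append(float(sum(int(a) for a in gt.split("/"))))
                rows.append(dos)
                markers.append(mid)
                chroms.append(chrom)
                poss.append(int(pos))
        mmap = pd.DataFrame({"chrom": chroms, "pos": poss}, index=markers)
        return cls(np.asarray(rows, dtype=float).T, samples, markers, mmap)


@dataclass
class FeatureMatrix:
    """Lines x omics features (transcripts or metabolites).

    ``annotations`` optionally maps feature id -> chemical superclass (used
    by the enrichment stage of the network analysis).
    """

    values: np.ndarray
    line_ids: list[str]
    feature_ids: list[str]
    omics_kind: str = "metabolite"
    annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.values.shape != (len(self.line_ids), len(self.feature_ids)):
            raise ValueError("value shape does not match id lists")
        if len(set(self.line_ids)) != len(self.line_ids) or len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate ids")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.line_ids, columns=self.feature_ids)
        df.index.name = "line"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, omics_kind: str = "metabolite") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.index), list(df.columns), omics_kind)


@dataclass
class RelationshipKernel:
    """Symmetric PSD similarity among lines; the unit of every BLUP model."""

    matrix: np.ndarray
    line_ids: list[str]
    kind: str = "G"  # one of G, T, M, G_prioritized, G_rest
    stabilized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("kernel must be square over line_ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("kernel must be symmetric within 1e-8")

    @property
    def n(self) -> int:
        return len(self.line_ids)

    def align(self, ids: list[str]) -> "RelationshipKernel":
        """Reorder/subset to ``ids`` (all must be present)."""
        idx = {l: i for i, l in enumerate(self.line_ids)}
        sel = np.array([idx[i] for i in ids], dtype=int)
        return RelationshipKernel(self.matrix[np.ix_(sel, sel)], list(ids), self.kind, self.stabilized)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, index=self.line_ids, columns=self.line_ids)
        df.index.name = "line"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str = "G") -> "RelationshipKernel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.index), kind)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def _marker_stats(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (MAF, missing fraction, het fraction)."""
    miss = np.isnan(dos)
    n_obs = (~miss).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * np.where(n_obs > 0, n_obs, np.nan))
        maf = np.minimum(p, 1.0 - p)
        het = np.nansum(dos == 1.0, axis=0) / np.where(n_obs > 0, n_obs, np.nan)
    miss_frac = miss.mean(axis=0)
    return maf, miss_frac, het


def filter_markers(
    geno: GenotypeMatrix,
    maf_min: float = 0.02,
    miss_max: float = 0.60,
    het_max: float = 0.10,
) -> GenotypeMatrix:
    """Keep markers with MAF > ``maf_min``, missingness < ``miss_max`` and
    heterozygosity < ``het_max`` (all strict), preserving order."""
    maf, miss, het = _marker_stats(geno.dosages)
    keep = (maf > maf_min) & (miss < miss_max) & (het < het_max)
    keep &= ~np.isnan(maf)
    if not keep.any():
        warnings.warn("no markers survive filtering", stacklevel=2)
    return geno.subset(markers=keep)


def filter_lines(
    geno: GenotypeMatrix,
    callrate_min: float = 0.80,
    het_max: float = 0.10,
) -> GenotypeMatrix:
    """Keep lines with call rate > ``callrate_min`` and heterozygosity
    < ``het_max`` (strict inequalities)."""
    miss = np.isnan(geno.dosages)
    callrate = 1.0 - miss.mean(axis=1)
    n_obs = (~miss).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        het = np.nansum(geno.dosages == 1.0, axis=1) / np.where(n_obs > 0, n_obs, np.nan)
    het = np.where(n_obs > 0, het, 1.0)
    keep = (callrate > callrate_min) & (het < het_max)
    if not keep.any():
        warnings.warn("no lines survive filtering", stacklevel=2)
    return geno.subset(lines=keep)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_missing(geno: GenotypeMatrix, method: str = "mean") -> GenotypeMatrix:
    """Fill missing dosages.

    ``mean`` fills each column with its observed mean (real-valued entries
    allowed afterwards).  ``within_chrom_regression`` regresses each marker
    on its nearest complete-enough neighbours on the same chromosome
    (exploiting local LD) and falls back to the mean where regression is
    impossible.
    """
    dos = geno.dosages.copy()
    miss = np.isnan(dos)
    if not miss.any():
        return geno
    if np.any(miss.all(axis=0)):
        raise ValueError("marker with no observed dosage cannot be imputed")
    col_mean = np.nanmean(dos, axis=0)

    if method == "mean":
        idx = np.where(miss)
        dos[idx] = col_mean[idx[1]]
        return replace(geno, dosages=dos)

    if method != "within_chrom_regression":
        raise ValueError(f"unknown imputation method: {method}")

    if geno.marker_map is None:
        raise ValueError("within_chrom_regression requires a marker map")
    chroms = geno.marker_map.loc[geno.marker_ids, "chrom"].to_numpy()
    filled = dos.copy()
    # initial mean fill used as predictor matrix
    idx = np.where(miss)
    filled[idx] = col_mean[idx[1]]
    out = filled.copy()
    for j in np.unique(idx[1]):
        same = np.where((chroms == chroms[j]) & (np.arange(len(chroms)) != j))[0]
        if same.size == 0:
            continue
        # up to 8 nearest same-chromosome neighbours by map position
        if geno.marker_map is not None:
            pos = geno.marker_map.loc[geno.marker_ids, "pos"].to_numpy(float)
            same = same[np.argsort(np.abs(pos[same] - pos[j]))][:8]
        obs_rows = ~miss[:, j]
        if obs_rows.sum() < same.size + 2:
            continue
        X = np.column_stack([np.ones(obs_rows.sum()), filled[obs_rows][:, same]])
        beta, *_ = np.linalg.lstsq(X, dos[obs_rows, j], rcond=None)
        mrows = np.where(miss[:, j])[0]
        Xm = np.column_stack([np.ones(mrows.size), filled[mrows][:, same]])
        out[mrows, j] = np.clip(Xm @ beta, 0.0, 2.0)
    return replace(geno, dosages=out)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def compute_grm(geno: GenotypeMatrix) -> RelationshipKernel:
    """VanRaden (method 1) additive genomic relationship matrix.

    Each marker is centered by twice its allele frequency; the cross
    product is scaled by ``2 * sum(p * (1 - p))`` so the mean diagonal is
    about ``1 + f`` for inbreeding level ``f``.
    """
    dos = geno.dosages
    if np.isnan(dos).any():
        raise ValueError("impute missing dosages before computing the GRM")
    p = dos.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    Z = dos - 2.0 * p
    K = (Z @ Z.T) / denom
    K = 0.5 * (K + K.T)
    return RelationshipKernel(K, list(geno.line_ids), kind="G")


def compute_feature_kernel(
    features: FeatureMatrix, scale: bool = True
) -> RelationshipKernel:
    """Omics relationship matrix ``W W' / N`` over ``N`` features.

    By default each feature is centered and scaled to unit variance first,
    making the kernel scale-free (diagonal mean ~ 1); ``scale=False`` uses
    the raw values (sensitivity mode).  Zero-variance features are dropped
    with a warning before scaling.
    """
    W = features.values.astype(float)
    sd = W.std(axis=0)  # population scaling: diagonal mean exactly 1
    if scale:
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {(~keep).sum()} zero-variance feature(s)", stacklevel=2
            )
            W = W[:, keep]
            sd = sd[keep]
        if W.shape[1] == 0:
            raise ValueError("no features with positive variance")
        W = (W - W.mean(axis=0)) / sd
    n_feat = W.shape[1]
    K = (W @ W.T) / n_feat
    K = 0.5 * (K + K.T)
    kind = "T" if features.omics_kind == "transcript" else "M"
    return RelationshipKernel(K, list(features.line_ids), kind=kind)


def stabilize_kernel(K: RelationshipKernel, epsilon: float = 1e-6) -> RelationshipKernel:
    """Add ``epsilon`` to the diagonal iff the smallest eigenvalue is < 0."""
    w0 = eigh(K.matrix, eigvals_only=True, subset_by_index=(0, 0))[0]
    if w0 >= 0:
        return K
    # round-off negatives clear with epsilon alone; genuinely indefinite
    # input needs a shift past its most negative eigenvalue
    shift = epsilon if w0 >= -epsilon else (-w0 + epsilon)
    M = K.matrix + shift * np.eye(K.n)
    return RelationshipKernel(M, list(K.line_ids), K.kind, stabilized=True)


# ---------------------------------------------------------------------------
# distances, trees, PCA
# ---------------------------------------------------------------------------


def rogers_distance(geno: GenotypeMatrix) -> pd.DataFrame:
    """Rogers' distance between every pair of lines.

    Each genotype is represented by its within-individual allele frequency
    p in {0, 0.5, 1}; the distance is the root mean square over markers of
    the allele-frequency difference, which lies in [0, 1] for biallelic
    loci.
    """
    dos = geno.dosages
    if np.isnan(dos).any():
        raise ValueError("impute missing dosages before computing distances")
    P = dos / 2.0
    # mean over markers of (p_i - p_j)^2, expanded for vectorization
    sq = P**2
    G = P @ P.T
    m = P.shape[1]
    d2 = (sq.sum(axis=1)[:, None] + sq.sum(axis=1)[None, :] - 2.0 * G) / m
    D = np.sqrt(np.maximum(d2, 0.0))
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=geno.line_ids, columns=geno.line_ids)


def neighbor_joining(dist: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining; returns Newick text.

    On an additive (tree-metric) input the reconstructed path lengths
    reproduce the input distances exactly.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    ids = [str(i) for i in dist.index]
    tree = nj(DistanceMatrix(D, ids))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def genotype_pca(geno: GenotypeMatrix, n_pc: int = 2) -> np.ndarray:
    """Principal-component scores of the centered dosage matrix.

    Deterministic up to sign; the convention fixes each component so that
    its largest-magnitude loading is positive.
    """
    dos = geno.dosages
    if np.isnan(dos).any():
        raise ValueError("impute missing dosages before PCA")
    if n_pc >= min(dos.shape):
        raise ValueError("n_pc must be smaller than both matrix dimensions")
    Z = dos - dos.mean(axis=0)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    for k in range(n_pc):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    return U[:, :n_pc] * s[:n_pc]


def pca_variance_explained(geno: GenotypeMatrix) -> np.ndarray:
    """Fraction of variance carried by each principal component."""
    Z = geno.dosages - geno.dosages.mean(axis=0)
    s = np.linalg.svd(Z, compute_uv=False)
    ev = s**2
    return ev / ev.sum()
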