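"""Stage-one adjustment of plot-level data from augmented field designs.

Unreplicated test lines are tied together by replicated check varieties:
the model removes check, block, and (optionally) batch effects and returns
one adjusted value per line together with REML variance components and a
line-mean heritability used downstream to scale prediction accuracies.

Model: ``value = intercept + check effects (fixed) + block (random)
+ batch (random, optional) + line (random or fixed) + residual``.
BLUP mode (default) models test-line effects as random and returns
shrunken line values; BLUE mode refits line effects as fixed via GLS at
the REML variance estimates, returning unshrunken line means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["PhenotypeTable", "TraitValues", "adjust_augmented", "reml_varcomp"]

_REQUIRED = ["line_id", "trait", "environment", "block", "is_check", "value"]


@dataclass
class PhenotypeTable:
    """Plot-level records of an augmented incomplete block trial."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if "batch" not in self.records.columns:
            self.records = self.records.assign(batch=1)
        if not np.all(np.isfinite(self.records["value"].to_numpy(float))):
            raise ValueError("phenotype values must be finite")

    def subset(self, trait: str, environment: str) -> pd.DataFrame:
        df = self.records
        out = df[(df["trait"] == trait) & (df["environment"] == environment)]
        if out.empty:
            raise ValueError(f"no records for trait={trait!r}, environment={environment!r}")
        blocks_without_check = (
            out.groupby("block")["is_check"].any().pipe(lambda s: s[~s]).index.tolist()
        )
        if blocks_without_check:
            warnings.warn(
                f"blocks without a check record: {blocks_without_check}", stacklevel=2
            )
        return out.reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class TraitValues:
    """Line-level adjusted values with heritability and variance components."""

    values: pd.Series  # line_id -> adjusted value
    h2: float
    varcomps: dict[str, float]
    trait: str = "trait"
    environment: str = "env1"
    mode: str = "blup"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")

    def aligned(self, line_ids: list[str]) -> np.ndarray:
        return self.values.reindex(line_ids).to_numpy(float)


# ---------------------------------------------------------------------------
# dense REML for a few iid random effects
# ---------------------------------------------------------------------------


def _dummies(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(labels))
    idx = {l: i for i, l in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [idx[l] for l in labels]] = 1.0
    return Z, levels


def reml_varcomp(
    y: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray],
    tol: float = 1e-9,
) -> dict:
    """REML for ``y = Xb + sum_i Z_i u_i + e`` with ``u_i ~ N(0, s_i I)``.

    Profile-likelihood optimization over log variance components (bounded
    below near zero); returns variances, fixed effects, BLUPs and the REML
    log-likelihood.  Sized for the small crossed models of stage one
    (hundreds of plots); V is handled densely.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = y.size
    names = list(Zs)
    ZZt = {k: Zs[k] @ Zs[k].T for k in names}
    vary = max(y.var(), 1e-12)

    def build_V(s: np.ndarray) -> np.ndarray:
        V = s[-1] * np.eye(n)
        for i, k in enumerate(names):
            V += s[i] * ZZt[k]
        return V

    def neg_restricted_ll(log_s: np.ndarray) -> float:
        s = np.exp(log_s)
        V = build_V(s)
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return 1e12
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_X = cho_solve((c, low), X)
        Vi_y = cho_solve((c, low), y)
        XtViX = X.T @ Vi_X
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        b = np.linalg.solve(XtViX, X.T @ Vi_y)
        Py = Vi_y - Vi_X @ b
        return 0.5 * (logdetV + logdetX + y @ Py)

    x0 = np.log(np.full(len(names) + 1, vary / (len(names) + 1)))
    res = optimize.minimize(
        neg_restricted_ll,
        x0,
        method="L-BFGS-B",
        bounds=[(np.log(vary) - 23.0, np.log(vary) + 7.0)] * (len(names) + 1),
        options={"ftol": tol, "maxiter": 500},
    )
    s = np.exp(res.x)
    # components at the lower bound are effectively zero
    s = np.where(s < vary * 1e-8, 0.0, s)

    V = build_V(np.maximum(s, vary * 1e-10))
    c, low = cho_factor(V, lower=True)
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    b = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ np.linalg.solve(XtViX, Vi_X.T @ y)
    blups = {k: s[i] * (Zs[k].T @ Py) for i, k in enumerate(names)}
    # prediction-error variance of each random level (for reliabilities)
    pev = {}
    for i, k in enumerate(names):
        Vi_Z = cho_solve((c, low), Zs[k])
        PZ = Vi_Z - Vi_X @ np.linalg.solve(XtViX, Vi_X.T @ Zs[k])
        ztpz = np.einsum("ij,ij->j", Zs[k], PZ)
        pev[k] = np.maximum(s[i] - s[i] ** 2 * ztpz, 0.0)
    return {
        "varcomps": {**{k: float(s[i]) for i, k in enumerate(names)}, "residual": float(s[-1])},
        "beta": b,
        "blups": blups,
        "pev": pev,
        "loglik": float(-res.fun),
        "converged": bool(res.success),
        "message": str(res.message),
    }


# ---------------------------------------------------------------------------
# the augmented-design adjustment
# ---------------------------------------------------------------------------


def adjust_augmented(
    table: PhenotypeTable,
    trait: str,
    environment: str,
    include_batch: bool = False,
    mode: str = "blup",
    deregress: bool = False,
) -> TraitValues:
    """Adjust one trait in one environment for design effects.

    Parameters
    ----------
    include_batch
        Add a random batch term (used for lab-processed features measured
        in batches).
    mode
        ``"blup"`` returns shrunken random-line predictions (plus the
        intercept); ``"blue"`` refits line effects as fixed via GLS at the
        REML variance estimates.
    deregress
        In BLUP mode, divide each line BLUP by its reliability
        ``1 - PEV / sigma_g^2`` to undo shrinkage.

    Returns line-level adjusted values for the (non-check) test lines and
    the line-mean heritability ``h2 = s_g / (s_g + s_e / r_bar)`` with
    ``r_bar`` the harmonic-mean replication of test lines.
    """
    df = table.subset(trait, environment)
    y = df["value"].to_numpy(float)
    is_check = df["is_check"].to_numpy(bool)

    # fixed: intercept + one effect per check variety
    X_cols = [np.ones(len(df))]
    for chk in pd.unique(df.loc[is_check, "line_id"]):
        X_cols.append((df["line_id"] == chk).to_numpy(float))
    X = np.column_stack(X_cols)

    Z_block, _ = _dummies(df["block"])
    Zs: dict[str, np.ndarray] = {"block": Z_block}
    if include_batch:
        Z_batch, _ = _dummies(df["batch"])
        Zs["batch"] = Z_batch

    test_mask = ~is_check
    test_lines = pd.unique(df.loc[test_mask, "line_id"])
    line_col = df["line_id"].where(test_mask, other="__check__")
    Z_line_full, line_levels = _dummies(line_col)
    keep = [i for i, l in enumerate(line_levels) if l != "__check__"]
    Z_line = Z_line_full[:, keep]
    line_levels = [line_levels[i] for i in keep]
    Zs["line"] = Z_line

    fit = reml_varcomp(y, X, Zs)
    vc = fit["varcomps"]
    if not fit["converged"]:
        warnings.warn(f"REML did not converge cleanly: {fit['message']}", stacklevel=2)

    reps = df.loc[test_mask].groupby("line_id").size().reindex(test_lines)
    r_bar = len(reps) / np.sum(1.0 / reps.to_numpy(float))
    s_g, s_e = vc["line"], vc["residual"]
    h2 = float(s_g / (s_g + s_e / r_bar)) if (s_g + s_e) > 0 else 0.0
    h2 = min(max(h2, 0.0), 1.0)

    mu = float(fit["beta"][0])
    if mode == "blup":
        u = pd.Series(fit["blups"]["line"], index=line_levels)
        if deregress:
            rel = 1.0 - pd.Series(fit["pev"]["line"], index=line_levels) / max(s_g, 1e-12)
            rel = rel.clip(lower=0.05)
            u = u / rel
        vals = (mu + u).reindex(test_lines)
    elif mode == "blue":
        vals = _blue_lines(y, df, is_check, Zs, vc, test_lines)
    else:
        raise ValueError("mode must be 'blup' or 'blue'")

    return TraitValues(
        values=vals,
        h2=h2,
        varcomps=vc,
        trait=trait,
        environment=environment,
        mode=mode,
        diagnostics={"loglik": fit["loglik"], "converged": fit["converged"], "r_bar": float(r_bar)},
    )


def _blue_lines(y, df, is_check, Zs, vc, test_lines) -> pd.Series:
    """Fixed-line GLS fit at the stage-one variance estimates."""
    n = len(df)
    V = max(vc["residual"], 1e-10) * np.eye(n)
    for k, Z in Zs.items():
        if k != "line":
            V += vc[k] * (Z @ Z.T)
    # design: one column per entry (test line or check variety), no intercept
    Xl, levels = _dummies(df["line_id"])
    c, low = cho_factor(V, lower=True)
    Vi_X = cho_solve((c, low), Xl)
    XtViX = Xl.T @ Vi_X
    beta = np.linalg.solve(XtViX + 1e-10 * np.eye(len(levels)), Xl.T @ cho_solve((c, low), y))
    return pd.Series(beta, index=levels).reindex(test_lines)
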