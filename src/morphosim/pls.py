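"""PLS regression of regional MS change on regional gene expression.

Partial least squares with a univariate response ranks genes by their
multivariate spatial alignment with a cortical map: PLS1 is the linear
combination of gene expression maps that covaries most with the target
map. Inference follows the permutation + bootstrap recipe standard in
imaging transcriptomics: component significance by permuting the response
(1000 permutations by default) and per-gene Z scores as the ratio of the
PLS1 weight to its standard error over region-resampling bootstraps, with
BH-FDR over genes and Z > 3 / Z < -3 defining the PLS1+ / PLS1- lists.

For a univariate response the first X-weight vector is proportional to
X'y (on standardized data, to the vector of gene-map covariances); the
sklearn PLS engine is cross-checked against this identity and against an
independent NIPALS implementation in the test suite.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests


def _zscore(a: np.ndarray, axis: int = 0) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - a.mean(axis=axis, keepdims=True)) / sd


@dataclasses.dataclass
class PLSFit:
    """Decomposition of (X, y): weights, region scores, variance profile."""

    x_weights: np.ndarray  # genes x components, unit columns
    region_scores: np.ndarray  # regions x components (x-scores)
    pct_var_explained: np.ndarray  # per-component increment, % of var(y)
    gene_ids: tuple[str, ...]

    @property
    def cum_pct_var(self) -> np.ndarray:
        return np.cumsum(self.pct_var_explained)


@dataclasses.dataclass
class PLSResult:
    """PLS1 gene ranking with bootstrap and permutation inference."""

    weights: pd.Series  # per-gene PLS1 weight
    z_scores: pd.Series  # weight / bootstrap SE
    p: pd.Series
    p_fdr: pd.Series
    region_scores: np.ndarray  # PLS1 region scores
    pct_var_explained: np.ndarray
    perm_p: np.ndarray
    pls1_plus: tuple[str, ...]
    pls1_minus: tuple[str, ...]
    threshold: float
    n_redrawn_bootstraps: int = 0


def pls_fit(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_components: int = 15,
    standardize: bool = True,
) -> PLSFit:
    """Fit PLS of a univariate regional response on a region x gene matrix.

    Columns of X (and y) are z-scored by default so weights are comparable
    across genes. ``pct_var_explained[c]`` is the extra share of var(y)
    explained by component c+1 on top of the previous ones (increments sum
    to the cumulative R^2, which is non-decreasing).
    """
    if isinstance(X, pd.DataFrame):
        gene_ids = tuple(map(str, X.columns))
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, dtype=float)
        gene_ids = tuple(f"g{j}" for j in range(Xv.shape[1]))
    y = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != y.size:
        raise ValueError("X rows and y must be aligned")
    if np.ptp(y) == 0:
        raise ValueError("constant response; PLS undefined")
    if standardize:
        Xv = _zscore(Xv)
        y = _zscore(y)
    n_components = int(min(n_components, Xv.shape[0] - 1, Xv.shape[1]))
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(Xv, y[:, None])
    T = model.x_scores_
    W = model.x_weights_.copy()
    # cumulative R^2 of y on the first c scores -> per-component increments
    cum = np.empty(n_components)
    tss = float(((y - y.mean()) ** 2).sum())
    for c in range(1, n_components + 1):
        coef, *_ = np.linalg.lstsq(T[:, :c], y, rcond=None)
        resid = y - T[:, :c] @ coef
        cum[c - 1] = 1.0 - (resid ** 2).sum() / tss
    increments = np.diff(np.concatenate([[0.0], cum])) * 100.0
    # sign convention: PLS1 region scores correlate positively with y
    if np.corrcoef(T[:, 0], y)[0, 1] < 0:
        W[:, 0] *= -1.0
        T = T.copy()
        T[:, 0] *= -1.0
    return PLSFit(
        x_weights=W,
        region_scores=T,
        pct_var_explained=increments,
        gene_ids=gene_ids,
    )


def permutation_test(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_components: int = 15,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Component significance by permuting the response.

    For each component count c, perm_p[c] = (1 + #{null cumulative
    variance explained by 1..c >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    fit = pls_fit(X, y, n_components=n_components)
    observed = fit.cum_pct_var
    exceed = np.zeros_like(observed)
    y = np.asarray(y, dtype=float).ravel()
    for _ in range(n_perm):
        null = pls_fit(X, rng.permutation(y),
                       n_components=len(observed)).cum_pct_var
        exceed += null >= observed
    return (1.0 + exceed) / (n_perm + 1.0)


def _pls1_weight(Xz: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit-norm first X-weight vector for a univariate response."""
    yz = _zscore(y)
    w = Xz.T @ yz
    norm = np.linalg.norm(w)
    if norm == 0:
        return w
    return w / norm


def bootstrap_z(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    threshold: float = 3.0,
    n_components: int = 15,
    n_perm: int | None = 1000,
) -> PLSResult:
    """Bootstrap the PLS1 gene weights by resampling regions.

    Regions are resampled with replacement; each refit weight vector is
    sign-aligned to the original (flipped when negatively correlated); the
    bootstrap SD is the weight's SE and Z = weight / SE with a two-sided
    normal p, BH-FDR over genes, and threshold lists PLS1+ (Z > threshold)
    and PLS1- (Z < -threshold). Bootstrap draws that leave the response
    constant are redrawn (counted, capped at 10 * n_boot attempts).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    fit = pls_fit(X, y, n_components=n_components)
    if isinstance(X, pd.DataFrame):
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    w0 = fit.x_weights[:, 0]
    n = y.size
    boots = np.empty((n_boot, w0.size))
    redrawn = 0
    attempts = 0
    b = 0
    while b < n_boot:
        attempts += 1
        if attempts > 10 * n_boot:
            raise RuntimeError("too many degenerate bootstrap draws")
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if np.ptp(yb) == 0:
            redrawn += 1
            continue
        wb = _pls1_weight(_zscore(Xv[idx]), yb)
        if float(wb @ w0) < 0:
            wb = -wb
        boots[b] = wb
        b += 1
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w0 / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_fdr = multipletests(p, method="fdr_bh")[1]
    genes = list(fit.gene_ids)
    weights = pd.Series(w0, index=genes, name="pls1_weight")
    zs = pd.Series(z, index=genes, name="pls1_z")
    perm_p = (
        permutation_test(X, y, n_components=n_components,
                         n_perm=n_perm, seed=rng)
        if n_perm else np.array([])
    )
    plus = tuple(zs.index[zs > threshold])
    minus = tuple(zs.index[zs < -threshold])
    return PLSResult(
        weights=weights,
        z_scores=zs,
        p=pd.Series(p, index=genes, name="p"),
        p_fdr=pd.Series(p_fdr, index=genes, name="p_fdr"),
        region_scores=fit.region_scores[:, 0],
        pct_var_explained=fit.pct_var_explained,
        perm_p=perm_p,
        pls1_plus=plus,
        pls1_minus=minus,
        threshold=threshold,
        n_redrawn_bootstraps=redrawn,
    )


def write_gene_table(result: PLSResult, path) -> None:
    df = pd.DataFrame(
        {
            "weight": result.weights,
            "z": result.z_scores,
            "p": result.p,
            "p_fdr": result.p_fdr,
        }
    )
    df["list"] = ""
    df.loc[list(result.pls1_plus), "list"] = "PLS1+"
    df.loc[list(result.pls1_minus), "list"] = "PLS1-"
    df.index.name = "gene"
    df.to_csv(path)
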