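"""Case-control inference on regional morphometric similarity.

Per-region ordinary least squares of regional MS on group with age, sex and
intracranial volume as covariates; Benjamini-Hochberg FDR over regions;
leave-one-feature-out sensitivity maps; cytoarchitectonic (von Economo
class) aggregation; hub-susceptibility quadrants; and the cross-condition
principal component that summarises shared remodelling across datasets.

Conventions (recorded in every output):
  * Cohen's d is derived from the covariate-adjusted group contrast as
    d = t * sqrt(1/n1 + 1/n2).
  * The regional "Z-score" is the inverse-normal transform of the
    two-sided p carrying the sign of t, a monotone function of t.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .msnet import (
    RegionalMSProfile,
    SubjectMorphometry,
    cohort_profiles,
)

COVARIATES = ("age", "sex", "icv")


class RankDeficientDesignError(ValueError):
    """The design matrix is rank deficient (collinear columns listed)."""


@dataclasses.dataclass
class CaseControlMap:
    """Per-region case-control statistics for one dataset."""

    dataset_id: str
    region_labels: Sequence[str]
    t_stat: np.ndarray
    z_stat: np.ndarray
    cohen_d: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    df_resid: float
    covariates_used: tuple[str, ...] = COVARIATES
    d_formula: str = "t*sqrt(1/n1+1/n2)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": list(self.region_labels),
                "t": self.t_stat,
                "z": self.z_stat,
                "d": self.cohen_d,
                "p": self.p,
                "p_fdr": self.p_fdr,
            }
        )


@dataclasses.dataclass
class CrossConditionPattern:
    """PCA of z-maps across conditions (correlation-matrix PCA)."""

    pc_scores: np.ndarray  # region scores of PC1
    explained_variance_pct: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray  # condition x component
    condition_ids: tuple[str, ...]
    region_labels: Sequence[str]


QUADRANT_NAMES = (
    "dedifferentiation",   # low control MS, MS increases
    "hypercoupling",       # high control MS, MS increases
    "hyperdifferentiation",  # low control MS, MS decreases
    "decoupling",          # high control MS, MS decreases
)


@dataclasses.dataclass
class QuadrantSummary:
    labels: pd.Series  # region -> quadrant name
    percentages: pd.Series  # quadrant name -> % of regions


def metadata_frame(subjects: Iterable[SubjectMorphometry]) -> pd.DataFrame:
    """Covariate table (subject_id, group, age, sex, icv) from subjects."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "icv": s.icv,
            }
            for s in subjects
        ]
    )


def _design(meta: pd.DataFrame,
            covariates: Sequence[str]) -> tuple[np.ndarray, list[str], int]:
    cols = ["intercept", "group"] + list(covariates)
    group = (meta["group"].to_numpy() == "case").astype(float)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    X = np.column_stack(
        [np.ones(len(meta)), group]
        + [meta[c].to_numpy(float) for c in covariates]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = [
            cols[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise RankDeficientDesignError(
            f"rank-deficient design; collinear columns: {collinear}"
        )
    return X, cols, 1  # group coefficient index


def _ols_group_stats(
    X: np.ndarray, Y: np.ndarray, g: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """t and two-sided p of the group coefficient for every column of Y."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[g, g])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[g] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return t, p, float(dof)


def _signed_z(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    # inverse-normal of the two-sided p, carrying the sign of t
    z = stats.norm.isf(np.clip(p / 2.0, 1e-300, 1.0))
    return np.sign(t) * z


def fit_region_models(
    profiles: Sequence[RegionalMSProfile],
    metadata: pd.DataFrame,
    dataset_id: str = "dataset",
    covariates: Sequence[str] = COVARIATES,
) -> CaseControlMap:
    """Region-wise OLS of regional MS on group + covariates.

    Regions with missing values for some subjects are refit on the subjects
    that have them (with a warning); nothing is imputed. p values over the
    regions are BH-FDR adjusted.
    """
    meta = metadata.set_index("subject_id").loc[
        [p.subject_id for p in profiles]].reset_index()
    X, _, g = _design(meta, covariates)
    Y = np.column_stack([p.regional_ms for p in profiles]).T  # subj x region
    labels = list(profiles[0].region_labels)
    n1 = int((meta["group"] == "case").sum())
    n2 = int((meta["group"] == "control").sum())

    nan_cols = np.flatnonzero(np.isnan(Y).any(axis=0))
    t = np.empty(Y.shape[1])
    p = np.empty(Y.shape[1])
    clean = np.setdiff1d(np.arange(Y.shape[1]), nan_cols)
    dof = np.nan
    if clean.size:
        t[clean], p[clean], dof = _ols_group_stats(X, Y[:, clean], g)
    for j in nan_cols:
        keep = ~np.isnan(Y[:, j])
        warnings.warn(
            f"region {labels[j]}: {int((~keep).sum())} subject(s) dropped "
            "for missing regional MS")
        tj, pj, _ = _ols_group_stats(X[keep], Y[keep, j][:, None], g)
        t[j], p[j] = tj[0], pj[0]
    p_fdr = multipletests(p, method="fdr_bh")[1]
    d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    return CaseControlMap(
        dataset_id=dataset_id,
        region_labels=labels,
        t_stat=t,
        z_stat=_signed_z(t, p),
        cohen_d=d,
        p=p,
        p_fdr=p_fdr,
        df_resid=dof,
        covariates_used=tuple(covariates),
    )


def global_comparison(
    profiles: Sequence[RegionalMSProfile],
    metadata: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
) -> tuple[float, float, float]:
    """Case-control test of global MS; returns (t, p, df_resid)."""
    meta = metadata.set_index("subject_id").loc[
        [p.subject_id for p in profiles]].reset_index()
    X, _, g = _design(meta, covariates)
    y = np.array([[p.global_ms] for p in profiles])
    t, p, dof = _ols_group_stats(X, y, g)
    return float(t[0]), float(p[0]), dof


def leave_one_feature_out(
    subjects: Sequence[SubjectMorphometry],
    metadata: pd.DataFrame | None = None,
    scope: str = "within_subject",
    dataset_id: str = "dataset",
) -> tuple[dict[str, CaseControlMap], pd.Series, str]:
    """Recompute the case-control map excluding each feature in turn.

    Returns the per-excluded-feature maps, the Spearman correlation of each
    leave-one-out t-map with the full map, and the name of the feature
    whose exclusion changes the topography the most (minimum correlation).
    """
    if subjects[0].n_features < 3:
        raise ValueError("leave-one-feature-out needs at least 3 features")
    meta = metadata if metadata is not None else metadata_frame(subjects)
    full = fit_region_models(
        cohort_profiles(subjects, scope=scope), meta, dataset_id=dataset_id)
    maps: dict[str, CaseControlMap] = {}
    rhos: dict[str, float] = {}
    for j, fname in enumerate(subjects[0].feature_names):
        reduced = [
            dataclasses.replace(
                s,
                features=np.delete(s.features, j, axis=1),
                feature_names=tuple(
                    f for i, f in enumerate(s.feature_names) if i != j),
            )
            for s in subjects
        ]
        m = fit_region_models(
            cohort_profiles(reduced, scope=scope), meta,
            dataset_id=f"{dataset_id}-minus-{fname}")
        maps[fname] = m
        rhos[fname] = correlate_maps(full.t_stat, m.t_stat)
    rho_series = pd.Series(rhos, name="spearman_vs_full")
    return maps, rho_series, str(rho_series.idxmin())


def aggregate_von_economo(
    profiles: Sequence[RegionalMSProfile],
    metadata: pd.DataFrame,
    class_map: Mapping[str, str] | pd.Series,
    dataset_id: str = "dataset",
) -> CaseControlMap:
    """Average regional MS within cytoarchitectonic classes, then refit.

    Every region must be mapped to a class; per-subject class values are
    the mean regional MS over member regions, and the same covariate-
    adjusted machinery as :func:`fit_region_models` runs per class.
    """
    class_map = pd.Series(dict(class_map))
    labels = list(profiles[0].region_labels)
    unmapped = [r for r in labels if r not in class_map.index]
    if unmapped:
        raise ValueError(f"regions not mapped to a class: {unmapped}")
    classes = sorted(class_map.loc[labels].unique())
    members = {
        c: [i for i, r in enumerate(labels) if class_map[r] == c]
        for c in classes
    }
    class_profiles = [
        RegionalMSProfile(
            subject_id=p.subject_id,
            regional_ms=np.array(
                [np.nanmean(p.regional_ms[members[c]]) for c in classes]),
            global_ms=p.global_ms,
            region_labels=classes,
        )
        for p in profiles
    ]
    return fit_region_models(
        class_profiles, metadata, dataset_id=f"{dataset_id}-von-economo")


def hub_susceptibility(
    delta: np.ndarray | CaseControlMap,
    control_ms: np.ndarray,
) -> tuple[float, QuadrantSummary]:
    """Hub-susceptibility correlation and sign-quadrant classification.

    ``delta`` is the case-control change axis (Cohen's d when a map is
    given; any monotone choice yields the same quadrants). Each region is
    labelled from the signs of (mean control regional MS, change):
    (-,+) dedifferentiation, (+,+) hypercoupling, (-,-) hyperdifferentiation,
    (+,-) decoupling. Significance of the correlation is delegated to the
    spatial null (spin test) module.
    """
    if isinstance(delta, CaseControlMap):
        labels = list(delta.region_labels)
        dvec = delta.cohen_d
    else:
        dvec = np.asarray(delta, dtype=float)
        labels = [f"region_{i + 1:03d}" for i in range(dvec.size)]
    control_ms = np.asarray(control_ms, dtype=float)
    if dvec.shape != control_ms.shape:
        raise ValueError("delta and control MS must have equal length")
    if np.ptp(dvec) == 0 or np.ptp(control_ms) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = correlate_maps(dvec, control_ms)
    pos_ms = control_ms >= 0
    pos_d = dvec >= 0
    quadrant = np.where(
        pos_d,
        np.where(pos_ms, "hypercoupling", "dedifferentiation"),
        np.where(pos_ms, "decoupling", "hyperdifferentiation"),
    )
    lab = pd.Series(quadrant, index=labels, name="quadrant")
    pct = (
        lab.value_counts().reindex(QUADRANT_NAMES, fill_value=0)
        / len(lab) * 100.0
    )
    return rho, QuadrantSummary(labels=lab, percentages=pct)


def cross_condition_pca(
    maps: Sequence[CaseControlMap],
) -> CrossConditionPattern:
    """Correlation-matrix PCA of the region x condition z-stat matrix.

    Columns (conditions) are standardized, so eigenvalues sum to the number
    of conditions and explained variance percentages to 100. PC1's sign is
    fixed so its region scores correlate positively with the mean of the
    input maps.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 condition maps")
    labels = list(maps[0].region_labels)
    for m in maps[1:]:
        if list(m.region_labels) != labels:
            raise ValueError("maps must share a common region order")
    Z = np.column_stack([m.z_stat for m in maps])
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant z-map column; PCA undefined")
    Zs = (Z - Z.mean(axis=0)) / sd
    n_regions, n_cond = Zs.shape
    corr = Zs.T @ Zs / (n_regions - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scores = Zs @ eigvec
    if np.corrcoef(scores[:, 0], Zs.mean(axis=1))[0, 1] < 0:
        eigvec[:, 0] *= -1.0
        scores[:, 0] *= -1.0
    return CrossConditionPattern(
        pc_scores=scores[:, 0],
        explained_variance_pct=eigval / n_cond * 100.0,
        eigenvalues=eigval,
        loadings=eigvec,
        condition_ids=tuple(m.dataset_id for m in maps),
        region_labels=labels,
    )


def correlate_maps(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Spearman rank correlation between two regional maps (ties mid-ranked)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant map")
    return float(stats.spearmanr(a, b).statistic)
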