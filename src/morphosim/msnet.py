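"""Per-subject morphometric similarity (MS) networks.

A subject's cortical anatomy is summarised as a region x feature table of
five structural measures (gray matter volume, surface area, cortical
thickness, mean curvature, Gaussian curvature). After z-scoring each
feature, the MS network is the region-by-region Pearson correlation of
feature vectors: an edge quantifies how anatomically similar two cortical
regions are. Regional MS (nodal similarity, or weighted degree) is the mean
of a region's edges to all other regions; global MS is the mean of the
regional values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

FEATURE_NAMES: tuple[str, ...] = (
    "gm_volume",
    "surface_area",
    "thickness",
    "mean_curvature",
    "gaussian_curvature",
)

NormScope = Literal["within_subject", "dataset_pooled"]


class ZeroVarianceError(ValueError):
    """A feature has zero variance within the chosen normalization scope."""


@dataclasses.dataclass
class SubjectMorphometry:
    """One subject's regional feature table plus model covariates.

    ``features`` is an (n_regions, n_features) array; ``region_labels``
    fixes the region order, which must be identical across the subjects of
    a dataset. ``group`` is "case" or "control"; ``sex`` is coded 0/1 and
    ``icv`` is total intracranial volume in mm^3.
    """

    subject_id: str
    group: str
    age: float
    sex: int
    icv: float
    features: np.ndarray
    region_labels: Sequence[str]
    feature_names: Sequence[str] = FEATURE_NAMES
    normalized: bool = False
    norm_scope: str | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a region x feature matrix")
        if self.features.shape[0] != len(self.region_labels):
            raise ValueError("features rows must match region_labels")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(
                f"subject {self.subject_id}: non-finite feature values"
            )
        if self.group not in ("case", "control"):
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def n_regions(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclasses.dataclass
class MSMatrix:
    """Symmetric region x region Pearson-correlation MS matrix.

    The diagonal is stored as 1 but excluded from every summary. Edges of
    degenerate regions (zero-variance feature vector) are NaN and the
    offending regions are listed in ``degenerate_regions``.
    """

    subject_id: str
    matrix: np.ndarray
    region_labels: Sequence[str]
    degenerate_regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("MS matrix must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("MS matrix must be symmetric")
        self.matrix = m


@dataclasses.dataclass
class RegionalMSProfile:
    """Row-averaged regional MS vector and its mean (global MS)."""

    subject_id: str
    regional_ms: np.ndarray
    global_ms: float
    region_labels: Sequence[str]


def _zscore_columns(values: np.ndarray, label: str) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ZeroVarianceError(
            f"zero-variance feature(s) in {label}: "
            + ", ".join(FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i)
                        for i in bad)
        )
    return (values - mean) / sd


def normalize_features(
    subjects: Iterable[SubjectMorphometry],
    scope: NormScope = "within_subject",
) -> list[SubjectMorphometry]:
    """Z-score each feature to mean 0, sample SD 1 (n-1 denominator).

    ``within_subject`` standardizes each feature over the subject's own
    regions; ``dataset_pooled`` standardizes over all regions of all
    subjects jointly. The scope used is recorded on each returned subject.
    Raises :class:`ZeroVarianceError`, naming the feature, if a feature is
    constant within the chosen scope.
    """
    subjects = list(subjects)
    if not subjects:
        return []
    for s in subjects:
        if s.n_regions < 2:
            raise ValueError("need at least 2 regions to normalize")
    if scope == "within_subject":
        out = []
        for s in subjects:
            z = _zscore_columns(s.features, f"subject {s.subject_id}")
            out.append(dataclasses.replace(
                s, features=z, normalized=True, norm_scope=scope))
        return out
    if scope == "dataset_pooled":
        stacked = np.vstack([s.features for s in subjects])
        z = _zscore_columns(stacked, "pooled dataset")
        out = []
        start = 0
        for s in subjects:
            stop = start + s.n_regions
            out.append(dataclasses.replace(
                s, features=z[start:stop], normalized=True, norm_scope=scope))
            start = stop
        return out
    raise ValueError(f"unknown scope {scope!r}")


def compute_ms_matrix(subject: SubjectMorphometry) -> MSMatrix:
    """Pearson-correlate normalized feature vectors of every region pair.

    Requires a normalized subject (see :func:`normalize_features`) with at
    least two features. A region whose feature vector is constant has no
    defined correlation; its edges are set to NaN and it is reported in the
    result's ``degenerate_regions``.
    """
    if not subject.normalized:
        raise ValueError("features must be normalized before MS computation")
    if subject.n_features < 2:
        raise ValueError("need at least 2 features for pairwise correlation")
    f = subject.features
    centered = f - f.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    # tolerance: a constant row's centered norm is rounding noise
    degenerate = norms < 1e-10 * max(1.0, float(np.abs(f).max()))
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    m = unit @ unit.T
    np.clip(m, -1.0, 1.0, out=m)
    m[degenerate, :] = np.nan
    m[:, degenerate] = np.nan
    np.fill_diagonal(m, 1.0)
    return MSMatrix(
        subject_id=subject.subject_id,
        matrix=m,
        region_labels=subject.region_labels,
        degenerate_regions=tuple(
            np.asarray(subject.region_labels)[degenerate]),
    )


def regional_profile(ms: MSMatrix) -> RegionalMSProfile:
    """Average each region's off-diagonal MS edges; global MS is their mean.

    Missing edges (NaN) are excluded from the row means, so a region's
    regional MS is the mean over its available edges.
    """
    m = ms.matrix.copy()
    np.fill_diagonal(m, np.nan)
    with np.errstate(invalid="ignore"):
        regional = np.nanmean(m, axis=1)
    return RegionalMSProfile(
        subject_id=ms.subject_id,
        regional_ms=regional,
        global_ms=float(np.nanmean(regional)),
        region_labels=ms.region_labels,
    )


def cohort_profiles(
    subjects: Iterable[SubjectMorphometry],
    scope: NormScope = "within_subject",
) -> list[RegionalMSProfile]:
    """Normalize, build MS matrices and profile every subject of a cohort."""
    normed = normalize_features(subjects, scope=scope)
    return [regional_profile(compute_ms_matrix(s)) for s in normed]


def batch_regional_ms(features: np.ndarray) -> np.ndarray:
    """Regional MS for a stack of already-normalized subjects.

    ``features`` is (n_subjects, n_regions, n_features); returns
    (n_subjects, n_regions). Fast path used by the simulator's calibration
    loop; equivalent to per-subject :func:`compute_ms_matrix` +
    :func:`regional_profile` for non-degenerate inputs.
    """
    f = np.asarray(features, dtype=float)
    centered = f - f.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2, keepdims=True)
    unit = centered / norms
    corr = unit @ unit.transpose(0, 2, 1)
    n_regions = f.shape[1]
    # row sums minus the diagonal 1, averaged over the other regions
    return (corr.sum(axis=2) - 1.0) / (n_regions - 1)


# ---------------------------------------------------------------------------
# I/O: FreeSurfer aparcstats2table-style tables and result writers
# ---------------------------------------------------------------------------

def read_feature_tables(
    features_dir: str | Path,
    metadata: str | Path | pd.DataFrame,
    feature_names: Sequence[str] = FEATURE_NAMES,
    expected_labels: Sequence[str] | None = None,
) -> list[SubjectMorphometry]:
    """Read per-subject TSV feature tables plus a metadata CSV.

    Each subject ``<id>.tsv`` has a ``region`` column and one column per
    feature (the layout `aparcstats2table` produces after merging the five
    per-feature tables). The metadata table needs columns
    ``subject_id, group, age, sex, icv``. If ``expected_labels`` is given
    (e.g. the DK68 manifest), any subject whose region column does not
    match it exactly — same names, same order — is rejected.
    """
    features_dir = Path(features_dir)
    meta = (metadata if isinstance(metadata, pd.DataFrame)
            else pd.read_csv(metadata))
    required = {"subject_id", "group", "age", "sex", "icv"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata missing columns {required - set(meta.columns)}")
    subjects: list[SubjectMorphometry] = []
    reference: list[str] | None = (
        list(expected_labels) if expected_labels is not None else None)
    for row in meta.itertuples(index=False):
        table = pd.read_csv(features_dir / f"{row.subject_id}.tsv", sep="\t")
        labels = list(table["region"])
        if reference is None:
            reference = labels
        if labels != reference:
            raise ValueError(
                f"subject {row.subject_id}: region labels/order do not match "
                "the dataset manifest; refusing to reorder silently")
        missing = [f for f in feature_names if f not in table.columns]
        if missing:
            raise ValueError(f"subject {row.subject_id}: missing {missing}")
        subjects.append(SubjectMorphometry(
            subject_id=str(row.subject_id),
            group=str(row.group),
            age=float(row.age),
            sex=int(row.sex),
            icv=float(row.icv),
            features=table[list(feature_names)].to_numpy(float),
            region_labels=labels,
            feature_names=tuple(feature_names),
        ))
    return subjects


def write_subject_table(subject: SubjectMorphometry, path: str | Path) -> None:
    df = pd.DataFrame(subject.features, columns=list(subject.feature_names))
    df.insert(0, "region", list(subject.region_labels))
    df.to_csv(path, sep="\t", index=False)


def write_ms_matrix(ms: MSMatrix, path: str | Path) -> None:
    pd.DataFrame(
        ms.matrix, index=list(ms.region_labels), columns=list(ms.region_labels)
    ).to_csv(path, sep="\t")


def write_profiles(
    profiles: Iterable[RegionalMSProfile], path: str | Path
) -> None:
    profiles = list(profiles)
    df = pd.DataFrame(
        {p.subject_id: p.regional_ms for p in profiles},
        index=list(profiles[0].region_labels),
    )
    df.index.name = "region"
    df.to_csv(path)
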