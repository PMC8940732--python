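"""Donor-level microarray processing to a region x gene expression matrix.

Mirrors the standard workflow for Allen-atlas-style data: intensity-based
probe filtering, one-probe-per-gene selection by differential stability,
constrained nearest-region sample assignment, per-donor robust-sigmoid
normalization across regions with unit-interval rescaling, and averaging
across donors. A precomputed region x gene table can be ingested directly,
bypassing all donor-level steps.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ASSIGNMENT_RADIUS_MM = 2.0


@dataclasses.dataclass
class DonorSampleTable:
    """One donor's samples: coordinates, division labels and intensities.

    ``samples`` needs columns x, y, z (mm), hemisphere (L/R) and division
    (cortex/subcortex). ``intensities`` and ``above_background`` are
    sample x probe; ``probe_to_gene`` maps every probe id to a gene symbol.
    """

    donor_id: str
    samples: pd.DataFrame
    intensities: np.ndarray
    above_background: np.ndarray
    probe_ids: Sequence[str]
    probe_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        n_s = len(self.samples)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.above_background = np.asarray(self.above_background, dtype=bool)
        if self.intensities.shape != (n_s, len(self.probe_ids)):
            raise ValueError("intensities must be sample x probe")
        if self.above_background.shape != self.intensities.shape:
            raise ValueError("above_background must match intensities")
        missing = [p for p in self.probe_ids if p not in self.probe_to_gene]
        if missing:
            raise ValueError(f"probes without gene annotation: {missing[:5]}")


@dataclasses.dataclass
class ExpressionMatrix:
    """Regions x genes matrix in [0, 1] with per-donor provenance counts."""

    values: pd.DataFrame  # index: region labels; columns: gene ids
    provenance: pd.DataFrame | None = None  # region x donor sample counts

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("expression values must lie in [0, 1]")
        if self.values.isna().all(axis=0).any():
            raise ValueError("all-missing gene column")


def filter_probes(
    tables: Sequence[DonorSampleTable], per_donor: bool = False
) -> list[str]:
    """Keep probes above background in more than half of the samples.

    A probe below background in >= 50% of samples (pooled over donors by
    default; every donor individually when ``per_donor``) is discarded.
    """
    probe_ids = list(tables[0].probe_ids)
    for t in tables[1:]:
        if list(t.probe_ids) != probe_ids:
            raise ValueError("donor tables must share the probe set")
    if per_donor:
        keep = np.ones(len(probe_ids), dtype=bool)
        for t in tables:
            frac_below = 1.0 - t.above_background.mean(axis=0)
            keep &= frac_below < 0.5
    else:
        below = np.vstack([~t.above_background for t in tables])
        keep = below.mean(axis=0) < 0.5
    return [p for p, k in zip(probe_ids, keep) if k]


def differential_stability(profiles: Sequence[np.ndarray]) -> float:
    """Mean pairwise Spearman correlation of donor regional profiles.

    ``profiles`` holds one probe's region-aggregated expression per donor
    (aligned region order; NaN = region missing for that donor). Donor
    pairs with fewer than 3 common regions are skipped with a warning; if
    every pair is skipped the result is NaN.
    """
    if len(profiles) < 2:
        raise ValueError("differential stability needs >= 2 donors")
    rhos = []
    for a, b in itertools.combinations(profiles, 2):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        common = ~np.isnan(a) & ~np.isnan(b)
        if common.sum() < 3:
            warnings.warn("donor pair skipped: <3 common regions")
            continue
        rhos.append(stats.spearmanr(a[common], b[common]).statistic)
    return float(np.mean(rhos)) if rhos else float("nan")


def _batch_differential_stability(
    profiles: Sequence[np.ndarray],
) -> np.ndarray:
    """Differential stability of every probe column at once.

    Vectorised equivalent of :func:`differential_stability` for complete
    (no-NaN) region x probe matrices; falls back to the per-probe routine
    for probes with missing regions.
    """
    stacked = np.stack(profiles)  # donors x regions x probes
    has_nan = np.isnan(stacked).any(axis=(0, 1))
    n_probes = stacked.shape[2]
    out = np.empty(n_probes)
    clean = ~has_nan
    if clean.any():
        ranks = np.stack([
            stats.rankdata(p[:, clean], axis=0) for p in profiles])
        z = ranks - ranks.mean(axis=1, keepdims=True)
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        n_donors = len(profiles)
        pair_sum = np.zeros(clean.sum())
        for i in range(n_donors - 1):
            for j in range(i + 1, n_donors):
                pair_sum += (z[i] * z[j]).sum(axis=0)
        out[clean] = pair_sum / (n_donors * (n_donors - 1) / 2)
    for idx in np.flatnonzero(has_nan):
        out[idx] = differential_stability([p[:, idx] for p in profiles])
    return out


def select_probes(
    donor_region_by_probe: Sequence[pd.DataFrame],
    probe_to_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Pick the probe with maximal differential stability per gene.

    Input: one region x probe frame per donor (aligned). Ties on the
    maximum are broken by lexicographically smallest probe id. Returns a
    frame indexed by gene with columns ``probe`` and ``ds``.
    """
    probes = list(donor_region_by_probe[0].columns)
    ds_values = _batch_differential_stability(
        [df.to_numpy(float) for df in donor_region_by_probe])
    ds = dict(zip(probes, ds_values))
    rows = []
    by_gene: dict[str, list[str]] = {}
    for p in probes:
        by_gene.setdefault(probe_to_gene[p], []).append(p)
    for gene, plist in by_gene.items():
        # NaN-safe argmax; lexicographic tie-break for reproducibility
        best = max(
            sorted(plist),
            key=lambda p: (-np.inf if np.isnan(ds[p]) else ds[p], ),
        )
        candidates = [
            p for p in plist
            if not np.isnan(ds[p]) and ds[p] == ds[best]
        ] or [best]
        chosen = sorted(candidates)[0]
        rows.append({"gene": gene, "probe": chosen, "ds": ds[chosen]})
    return pd.DataFrame(rows).set_index("gene").sort_index()


@dataclasses.dataclass
class SampleAssignment:
    """sample index -> region per donor; -1 = unassigned in pass 1."""

    pass1: np.ndarray  # per-sample region index or -1
    pass2: dict[int, int]  # region index -> sample index (fallback fill)
    region_labels: Sequence[str]

    def samples_for_region(self, r: int) -> list[int]:
        idx = list(np.flatnonzero(self.pass1 == r))
        if not idx and r in self.pass2:
            idx = [self.pass2[r]]
        return idx


def assign_samples(
    table: DonorSampleTable, geometry: pd.DataFrame
) -> SampleAssignment:
    """Two-pass constrained nearest-region assignment.

    Pass 1: each sample goes to the nearest region representative point
    with matching hemisphere and division, if within 2 mm; otherwise it
    stays unassigned. Pass 2: a region that received no sample takes its
    nearest sample (matching hemisphere and division), which may therefore
    serve several regions. ``geometry`` needs columns region, x, y, z,
    hemisphere, division.
    """
    if geometry.empty:
        raise ValueError("empty parcel geometry")
    reg_xyz = geometry[["x", "y", "z"]].to_numpy(float)
    reg_hemi = geometry["hemisphere"].to_numpy()
    reg_div = geometry["division"].to_numpy()
    s_xyz = table.samples[["x", "y", "z"]].to_numpy(float)
    s_hemi = table.samples["hemisphere"].to_numpy()
    s_div = table.samples["division"].to_numpy()

    dist = np.linalg.norm(s_xyz[:, None, :] - reg_xyz[None, :, :], axis=2)
    compat = (s_hemi[:, None] == reg_hemi[None, :]) & (
        s_div[:, None] == reg_div[None, :])
    dist = np.where(compat, dist, np.inf)

    pass1 = np.full(len(s_xyz), -1, dtype=int)
    nearest = dist.argmin(axis=1)
    within = dist[np.arange(len(s_xyz)), nearest] <= ASSIGNMENT_RADIUS_MM
    pass1[within] = nearest[within]

    pass2: dict[int, int] = {}
    for r in range(len(reg_xyz)):
        if not np.any(pass1 == r):
            d_r = dist[:, r]
            if np.isfinite(d_r).any():
                pass2[r] = int(d_r.argmin())
    return SampleAssignment(
        pass1=pass1, pass2=pass2,
        region_labels=list(geometry["region"]))


def robust_sigmoid(x: np.ndarray) -> np.ndarray:
    """Median/IQR logistic squash of one gene's regional values.

    x' = 1 / (1 + exp(-(x - median) / (IQR / 1.35))); the 1.35 factor makes
    the scale consistent with an SD under normality. Zero IQR collapses the
    vector to 0.5 (with a warning from the caller).
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    iqr = np.percentile(x, 75) - np.percentile(x, 25)
    if iqr == 0:
        return np.full_like(x, 0.5)
    return 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))


def _unit_rescale(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def _sigmoid_rescale_columns(
    vals: np.ndarray, gene_ids, donor_index: int
) -> np.ndarray:
    """Column-wise robust sigmoid + unit rescale for complete matrices."""
    med = np.median(vals, axis=0)
    q75, q25 = np.percentile(vals, [75, 25], axis=0)
    iqr = q75 - q25
    zero = iqr == 0
    for j in np.flatnonzero(zero):
        warnings.warn(
            f"donor {donor_index}, gene {gene_ids[j]}: zero IQR, set to 0.5")
    safe = np.where(zero, 1.0, iqr)
    sig = 1.0 / (1.0 + np.exp(-(vals - med) / (safe / 1.35)))
    lo = sig.min(axis=0)
    hi = sig.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    out = (sig - lo) / span
    out[:, zero] = 0.5
    out[:, (hi == lo) & ~zero] = 0.5
    return out


def _donor_region_matrix(
    table: DonorSampleTable,
    assignment: SampleAssignment,
    probes: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Region x probe means over assigned samples; NaN where no sample."""
    index = {p: i for i, p in enumerate(table.probe_ids)}
    cols = [index[p] for p in probes]
    inten = table.intensities[:, cols]
    n_regions = len(assignment.region_labels)
    out = np.full((n_regions, len(probes)), np.nan)
    counts = np.zeros(n_regions, dtype=int)
    for r in range(n_regions):
        idx = assignment.samples_for_region(r)
        counts[r] = len(np.flatnonzero(assignment.pass1 == r))
        if idx:
            out[r] = inten[idx].mean(axis=0)
    return out, counts


def normalize_and_average(
    donor_matrices: Sequence[pd.DataFrame],
    donor_ids: Sequence[str] | None = None,
    counts: Sequence[np.ndarray] | None = None,
) -> ExpressionMatrix:
    """Robust-sigmoid + unit rescale per donor, then average across donors.

    Each input frame is one donor's region x gene matrix (aligned). For
    each donor and gene the values are squashed across regions with the
    robust sigmoid, rescaled to [0, 1], and finally averaged across donors
    ignoring regions a donor is missing. Zero-IQR genes collapse to 0.5
    with a warning.
    """
    ref = donor_matrices[0]
    scaled = []
    for d, df in enumerate(donor_matrices):
        if list(df.columns) != list(ref.columns) or list(df.index) != list(ref.index):
            raise ValueError("donor matrices must be aligned")
        vals = df.to_numpy(float)
        if not np.isnan(vals).any():
            out = _sigmoid_rescale_columns(vals, ref.columns, d)
        else:
            out = np.full_like(vals, np.nan)
            for j in range(vals.shape[1]):
                col = vals[:, j]
                ok = ~np.isnan(col)
                if ok.sum() == 0:
                    continue
                x = col[ok]
                if np.percentile(x, 75) - np.percentile(x, 25) == 0:
                    warnings.warn(
                        f"donor {d}, gene {ref.columns[j]}: zero IQR, "
                        "set to 0.5")
                    out[ok, j] = 0.5
                else:
                    out[ok, j] = _unit_rescale(robust_sigmoid(x))
        scaled.append(out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(np.stack(scaled), axis=0)
    provenance = None
    if counts is not None:
        provenance = pd.DataFrame(
            np.column_stack(counts),
            index=ref.index,
            columns=list(donor_ids) if donor_ids else None,
        )
    return ExpressionMatrix(
        values=pd.DataFrame(avg, index=ref.index, columns=ref.columns),
        provenance=provenance,
    )


def build_expression_matrix(
    tables: Sequence[DonorSampleTable],
    geometry: pd.DataFrame,
    per_donor_filter: bool = False,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Full donor-level pipeline to a single region x gene matrix.

    filter probes -> assign samples -> region-average per donor -> pick one
    probe per gene by differential stability -> robust sigmoid + [0,1]
    rescale per donor -> average donors. Returns the matrix and the probe
    selection table. Gene columns are ordered lexicographically and region
    rows follow the geometry manifest.
    """
    kept = filter_probes(tables, per_donor=per_donor_filter)
    if not kept:
        raise ValueError("no probe passed background filtering")
    assignments = [assign_samples(t, geometry) for t in tables]
    regions = list(geometry["region"])
    per_donor, counts = [], []
    for t, a in zip(tables, assignments):
        m, c = _donor_region_matrix(t, a, kept)
        per_donor.append(pd.DataFrame(m, index=regions, columns=kept))
        counts.append(c)
    selection = select_probes(per_donor, tables[0].probe_to_gene)
    gene_frames = [
        df[selection["probe"].to_list()].set_axis(selection.index, axis=1)
        for df in per_donor
    ]
    matrix = normalize_and_average(
        gene_frames, donor_ids=[t.donor_id for t in tables], counts=counts)
    return matrix, selection


def _first_pc_scores(values: pd.DataFrame) -> np.ndarray:
    v = values.to_numpy(float)
    v = v - v.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(v, full_matrices=False)
    return u[:, 0] * s[0]


def leave_one_donor_out(
    tables: Sequence[DonorSampleTable],
    geometry: pd.DataFrame,
) -> tuple[list[ExpressionMatrix], float]:
    """Donor-robustness check on the final matrix.

    Rebuilds the expression matrix N times leaving out each donor, then
    reports the mean pairwise Pearson correlation between the first
    principal-component region scores of the N matrices (signs aligned to
    the first one).
    """
    if len(tables) < 3:
        raise ValueError("leave-one-donor-out needs >= 3 donors")
    mats = []
    for i in range(len(tables)):
        subset = [t for j, t in enumerate(tables) if j != i]
        m, _ = build_expression_matrix(subset, geometry)
        mats.append(m)
    pcs = [_first_pc_scores(m.values) for m in mats]
    ref = pcs[0]
    pcs = [p if np.corrcoef(p, ref)[0, 1] >= 0 else -p for p in pcs]
    rs = [
        np.corrcoef(a, b)[0, 1]
        for a, b in itertools.combinations(pcs, 2)
    ]
    return mats, float(np.mean(rs))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Ingest a precomputed region x gene TSV (regions in rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path
) -> None:
    matrix.values.to_csv(path, sep="\t")


def read_donor_table(
    samples_path: str | Path,
    intensities_path: str | Path,
    probe_annotation_path: str | Path,
    donor_id: str,
) -> DonorSampleTable:
    """Read one donor from TSVs: sample metadata, intensities, annotation.

    ``intensities`` is sample x probe with probe ids as columns, paired
    with an ``above_background`` boolean block written as 0/1 columns
    suffixed ``__bg``; the annotation maps probe -> gene.
    """
    samples = pd.read_csv(samples_path, sep="\t")
    inten = pd.read_csv(intensities_path, sep="\t")
    probes = [c for c in inten.columns if not c.endswith("__bg")]
    above = inten[[f"{p}__bg" for p in probes]].to_numpy(bool)
    annot = pd.read_csv(probe_annotation_path, sep="\t")
    return DonorSampleTable(
        donor_id=donor_id,
        samples=samples,
        intensities=inten[probes].to_numpy(float),
        above_background=above,
        probe_ids=probes,
        probe_to_gene=dict(zip(annot["probe"], annot["gene"])),
    )
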