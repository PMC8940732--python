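"""Spherical spin-test nulls for correlations between cortical maps.

Parcel-level spatial permutation: parcel centroids on the spherical
cortical projection are randomly rotated (the mirrored rotation applied to
the right hemisphere preserves hemispheric symmetry) and each original
parcel is matched one-to-one to a rotated parcel, yielding a permutation
of regions that preserves the spatial autocorrelation structure of a map.
The empirical correlation between two maps is compared against the
distribution over many such rotations.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class ParcelGeometry:
    """Unit-sphere parcel centroids with hemisphere labels."""

    coords: np.ndarray  # regions x 3, unit norm
    hemisphere: np.ndarray  # 'L'/'R' per region
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("centroids must be unit-norm (spherical)")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParcelGeometry":
        """Build from a manifest with columns region, x, y, z, hemisphere."""
        return cls(
            coords=df[["x", "y", "z"]].to_numpy(float),
            hemisphere=df["hemisphere"].to_numpy(),
            region_labels=tuple(df["region"]),
        )


@dataclasses.dataclass
class SpinNull:
    """Cached table of rotation-induced region permutations."""

    permutations: np.ndarray  # n_rotations x n_regions, each row a bijection
    seed: int | None = None

    @property
    def n_rotations(self) -> int:
        return self.permutations.shape[0]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform 3x3 rotation: QR of a Gaussian matrix, det fixed to +1."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1.0
    return q


def _greedy_one_to_one(original: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """perm[i] = rotated parcel landing nearest to original slot i.

    Pairs are assigned greedily by ascending distance so each rotated
    parcel is used exactly once (value-preserving null maps).
    """
    n = original.shape[0]
    dist = np.linalg.norm(original[:, None, :] - rotated[None, :, :], axis=2)
    order = np.argsort(dist, axis=None, kind="stable")
    perm = np.full(n, -1, dtype=int)
    used = np.zeros(n, dtype=bool)
    filled = 0
    for flat in order:
        i, j = divmod(int(flat), n)
        if perm[i] == -1 and not used[j]:
            perm[i] = j
            used[j] = True
            filled += 1
            if filled == n:
                break
    return perm


def generate_spins(
    geometry: ParcelGeometry,
    n_rotations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> SpinNull:
    """Rotation-induced permutations of the parcellation.

    Each rotation draws a Haar-uniform rotation for the left hemisphere
    and applies its x-mirrored counterpart to the right, then matches
    original to rotated parcels one-to-one within hemisphere. A map ``v``
    spun by permutation ``p`` is ``v[p]``.
    """
    hemis = np.unique(geometry.hemisphere)
    idx_by_hemi = {
        h: np.flatnonzero(geometry.hemisphere == h) for h in hemis
    }
    for h, idx in idx_by_hemi.items():
        if idx.size < 2:
            raise ValueError(f"hemisphere {h}: fewer than 2 parcels")
    rng = np.random.default_rng(seed)
    mirror = np.diag([-1.0, 1.0, 1.0])
    n = geometry.coords.shape[0]
    perms = np.empty((n_rotations, n), dtype=int)
    for k in range(n_rotations):
        rot_l = random_rotation(rng)
        for h, idx in idx_by_hemi.items():
            rot = rot_l if h == "L" else mirror @ rot_l @ mirror
            pts = geometry.coords[idx]
            local = _greedy_one_to_one(pts, pts @ rot.T)
            perms[k, idx] = idx[local]
    return SpinNull(
        permutations=perms,
        seed=seed if isinstance(seed, int) else None,
    )


def spin_p(
    map_a: np.ndarray,
    map_b: np.ndarray,
    spins: SpinNull,
    statistic: Literal["spearman", "pearson"] = "spearman",
    two_tailed: bool = True,
) -> tuple[float, float]:
    """Spin-test p for the correlation between two aligned regional maps.

    ``map_a`` is permuted by each cached rotation; the p-value is
    (1 + #{|null| >= |empirical|}) / (n_rotations + 1) two-tailed (or the
    one-tailed count in the sign of the empirical statistic).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.size != spins.permutations.shape[1]:
        raise ValueError("maps must be aligned with the spin geometry")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant map")

    if statistic == "spearman":
        a_t = stats.rankdata(a)
        b_t = stats.rankdata(b)
    else:
        a_t, b_t = a, b

    def corr(x: np.ndarray) -> np.ndarray:
        xz = (x - x.mean(axis=-1, keepdims=True))
        bz = b_t - b_t.mean()
        num = xz @ bz
        den = np.linalg.norm(xz, axis=-1) * np.linalg.norm(bz)
        return num / den

    emp = float(corr(a_t))
    # ranks are value-preserving under permutation, so permute the ranks
    null = corr(a_t[spins.permutations])
    if two_tailed:
        count = int(np.sum(np.abs(null) >= abs(emp)))
    else:
        count = int(np.sum(null >= emp)) if emp >= 0 else int(
            np.sum(null <= emp))
    return emp, (1.0 + count) / (spins.n_rotations + 1.0)
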