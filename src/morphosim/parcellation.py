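"""Desikan-Killiany parcel manifests and synthetic parcel geometries.

The 68-region cortical parcellation (34 labels per hemisphere, left then
right) is the fixed region order for whole-cortex analyses; association
analyses with expression data use the 34 left-hemisphere regions only.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: The 34 Desikan-Killiany cortical labels of one hemisphere, fixed order.
DK_BASE_LABELS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: 68 whole-cortex labels, left hemisphere first.
DK68_LABELS: tuple[str, ...] = tuple(
    f"{hemi}_{lab}" for hemi in ("lh", "rh") for lab in DK_BASE_LABELS
)

#: 34 left-hemisphere labels used for expression association analyses.
DK34_LEFT_LABELS: tuple[str, ...] = DK68_LABELS[:34]


def generic_labels(n_regions: int) -> tuple[str, ...]:
    """Placeholder region labels for synthetic parcellations."""
    return tuple(f"region_{i + 1:03d}" for i in range(n_regions))


def load_von_economo_classes() -> pd.Series:
    """Region -> cytoarchitectonic class for the 68 DK regions.

    Shipped as an editable CSV; the default assignment is approximate and
    intended for aggregation machinery, not as an authoritative atlas.
    """
    path = resources.files("morphosim") / "data" / "dk68_von_economo.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    return pd.Series(df["von_economo_class"].values, index=df["region"].values)


def fibonacci_sphere(n: int, hemisphere: str = "L") -> np.ndarray:
    """`n` roughly equidistant unit vectors restricted to one x-hemisphere.

    Points are laid out on a Fibonacci lattice over the half sphere with
    x < 0 for the left hemisphere and its x-mirror for the right, so left
    and right layouts are symmetric as on a spherical cortical projection.
    """
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    # Half-sphere: polar coordinate restricted so x = cos(phi) < 0.
    u = (i + 0.5) / n  # in (0, 1)
    phi = np.arccos(-u)  # x in (-1, 0)
    theta = 2.0 * np.pi * i / golden
    x = np.cos(phi)
    y = np.sin(phi) * np.cos(theta)
    z = np.sin(phi) * np.sin(theta)
    pts = np.column_stack([x, y, z])
    if hemisphere == "R":
        pts[:, 0] *= -1.0
    return pts


def synthetic_dk_geometry(whole_cortex: bool = True) -> pd.DataFrame:
    """Synthetic spherical centroid manifest for the DK parcellation.

    Not measured from any real surface: a deterministic Fibonacci layout
    carrying DK labels, sufficient for hemisphere-symmetric spin testing.
    Columns: region, x, y, z, hemisphere.
    """
    left = fibonacci_sphere(34, "L")
    rows = [
        (lab, *left[i], "L") for i, lab in enumerate(DK34_LEFT_LABELS)
    ]
    if whole_cortex:
        right = fibonacci_sphere(34, "R")
        rows += [
            (lab, *right[i], "R")
            for i, lab in enumerate(DK68_LABELS[34:])
        ]
    return pd.DataFrame(rows, columns=["region", "x", "y", "z", "hemisphere"])
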