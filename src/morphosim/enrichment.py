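"""Gene-set overlap enrichment by Fisher's exact test.

Tests whether a target gene list (e.g. PLS1+ or PLS1-) overlaps a named
gene set (cell-type markers, pain genes, disorder genes) more than chance
given a background universe — the genes that survived expression
preprocessing. The one-sided (greater) Fisher p equals the hypergeometric
upper tail; the odds ratio is the conditional maximum-likelihood estimate,
with the sample OR (Haldane-corrected on zero cells) also reported.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio
from statsmodels.stats.multitest import multipletests


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets filtered to a common background universe."""

    sets: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.background = frozenset(self.background)
        filtered = {}
        for name, genes in self.sets.items():
            filtered[name] = frozenset(genes) & self.background
        self.sets = filtered


def build_omnibus_celltype_sets(
    study_sets: Mapping[str, Mapping[str, Sequence[str]]],
    background: Sequence[str],
    exclude: Sequence[str] = (),
) -> GeneSetCollection:
    """Merge per-study marker lists into one omnibus set per cell type.

    ``study_sets`` maps study -> {cell type -> genes}; per cell type the
    union over studies is intersected with the background. Cell types in
    ``exclude`` (e.g. classes annotated by too few studies) are dropped.
    Empty post-filter sets are kept with a warning.
    """
    merged: dict[str, set[str]] = {}
    for per_type in study_sets.values():
        for cell_type, genes in per_type.items():
            if cell_type in exclude:
                continue
            merged.setdefault(cell_type, set()).update(genes)
    collection = GeneSetCollection(
        sets={k: frozenset(v) for k, v in merged.items()},
        background=frozenset(background),
    )
    for name, genes in collection.sets.items():
        if not genes:
            warnings.warn(f"cell type {name!r}: empty after background filter")
    return collection


def fisher_enrichment(
    target: Sequence[str],
    gene_sets: GeneSetCollection | Mapping[str, Sequence[str]],
    background: Sequence[str] | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher exact overlap test of one target list against each set.

    Rows: one per set with overlap count, conditional-MLE odds ratio,
    sample odds ratio (Haldane 0.5 correction on zero cells), p and BH-FDR
    adjusted p across the sets tested in this call. The null hypothesis of
    the default one-sided test is that the odds ratio is no larger than 1.
    An empty set or empty overlap-defining margin yields OR = NaN, flagged
    in the ``degenerate`` column.
    """
    if isinstance(gene_sets, GeneSetCollection):
        bg = gene_sets.background
        sets = gene_sets.sets
    else:
        if background is None:
            raise ValueError("background required with a plain mapping")
        bg = frozenset(background)
        sets = {k: frozenset(v) & bg for k, v in gene_sets.items()}
    target_set = frozenset(target)
    strays = sorted(target_set - bg)
    if strays:
        raise ValueError(
            f"target genes outside the background universe: {strays[:10]}")
    rows = []
    for name, genes in sets.items():
        a = len(target_set & genes)
        b = len(target_set) - a
        c = len(genes) - a
        d = len(bg) - a - b - c
        table = np.array([[a, b], [c, d]])
        degenerate = len(genes) == 0 or len(target_set) == 0
        if degenerate:
            p = 1.0
            or_cmle = float("nan")
        else:
            p = float(stats.fisher_exact(table,
                                         alternative=alternative)[1])
            or_cmle = float(_cmle_odds_ratio(table,
                                             kind="conditional").statistic)
        if a * d == 0 or b * c == 0:
            or_sample = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            or_sample = (a * d) / (b * c)
        rows.append(
            {
                "set": name,
                "overlap": a,
                "target_size": len(target_set),
                "set_size": len(genes),
                "background_size": len(bg),
                "odds_ratio": or_cmle,
                "sample_odds_ratio": or_sample,
                "p": p,
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows).set_index("set")
    df["p_fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def run_panels(
    pls1_plus: Sequence[str],
    pls1_minus: Sequence[str],
    collections: Mapping[str, GeneSetCollection],
) -> dict[str, pd.DataFrame]:
    """Enrichment of both PLS1 lists against each panel of gene sets.

    FDR correction is applied within each (list, panel) combination — for
    the cell-type panel that is correction for the number of cell types
    tested. Returns a frame per ``"<list>:<panel>"`` key.
    """
    out = {}
    for panel, coll in collections.items():
        for list_name, target in (("PLS1+", pls1_plus),
                                  ("PLS1-", pls1_minus)):
            if len(target) == 0:
                raise ValueError(f"{list_name} is empty")
            out[f"{list_name}:{panel}"] = fisher_enrichment(target, coll)
    return out


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a tab-delimited GMT gene-set file (name, description, genes)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]], path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
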