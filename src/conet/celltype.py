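"""Cell-type identity of modules from marker gene lists.

Brain coexpression modules often track cell types (neurons, endothelial
cells, microglia, oligodendrocyte lineages, astrocytes). The identity
statistic is a *marker proportion score*: 100 times the fraction of a cell
type's dataset-mapped markers that fall inside a module. Normalizing by the
mapped marker count removes the bias from cell types with differently sized
marker lists; a module's dominant type is the argmax of its scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .netbuild import GREY


def map_markers(markers: dict, universe) -> dict:
    """Intersect marker lists with the analysis universe.

    Deduplicates each list, drops genes outside the universe, and excludes
    cell types left with zero mapped markers (with a warning). Returns a new
    ``{cell type: [genes]}`` dict.
    """
    uni = set(universe)
    mapped = {}
    for ct, genes in markers.items():
        kept = [g for g in dict.fromkeys(genes) if g in uni]
        if not kept:
            warnings.warn(f"cell type {ct!r} has no mapped markers; excluded")
            continue
        mapped[ct] = kept
    return mapped


def celltype_scores(partition: pd.Series, markers: dict) -> pd.DataFrame:
    """Module x cell-type marker proportion scores (percent scale).

    score(m, c) = 100 * |module_m ∩ markers_c| / |mapped markers_c|. The
    grey (unassigned) set is included as a row so the per-type scores sum to
    100 over all rows. The ``dominant`` column is the argmax cell type, or
    "ambiguous(...)" on ties, or "none" for all-zero rows.
    """
    markers = map_markers(markers, partition.index)
    modules = sorted(set(partition), key=lambda m: (m == GREY, str(m)))
    types = sorted(markers)
    scores = pd.DataFrame(0.0, index=modules, columns=types)
    for ct, genes in markers.items():
        total = len(genes)
        counts = partition.loc[[g for g in genes]].value_counts()
        for mod, n in counts.items():
            scores.loc[mod, ct] = 100.0 * n / total
    dominant = []
    for mod in modules:
        row = scores.loc[mod]
        if row.max() == 0:
            dominant.append("none")
            continue
        top = row[row == row.max()].index.tolist()
        dominant.append(top[0] if len(top) == 1
                        else "ambiguous(" + ",".join(top) + ")")
    scores["dominant"] = dominant
    return scores


def select_top_markers(reference: pd.DataFrame, n: int = 500) -> dict:
    """Top-``n`` most highly expressed genes per cell type from a reference
    expression table (genes x cell types; values = mean expression).

    Ties break lexicographically by gene id; if fewer than ``n`` genes are
    available the full list is returned with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    out = {}
    for ct in reference.columns:
        col = reference[ct]
        if n > len(col):
            warnings.warn(f"only {len(col)} genes available for {ct!r}")
        order = sorted(col.index, key=lambda g: (-col[g], g))
        out[str(ct)] = order[: min(n, len(order))]
    return out
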