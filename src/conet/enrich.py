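"""Local over-representation analysis of gene lists against gene-set
collections (e.g. GO biological process GMTs), using the one-sided Fisher
exact test with Benjamini-Hochberg correction."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(query, sets: dict, universe) -> pd.DataFrame:
    """Over-representation of ``query`` in each named gene set.

    For each set the 2x2 table (query/non-query x set/non-set over the
    universe) is tested with the one-sided (greater) Fisher exact test —
    equivalently the hypergeometric upper tail — with the sample odds ratio
    and BH-adjusted p across all tested sets. Query genes outside the
    universe are dropped with a warning. Sorted ascending by p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - uni
    if outside:
        warnings.warn(f"{len(outside)} query genes outside universe dropped")
        query &= uni
    if not query:
        raise ValueError("empty query after universe mapping")
    rows = []
    for name, genes in sets.items():
        gs = set(genes) & uni
        if not gs:
            continue
        a = len(query & gs)
        b = len(query - gs)
        c = len(gs - query)
        d = len(uni) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        odds = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan)
        rows.append({"set": name, "set_size": len(gs), "overlap": a,
                     "odds_ratio": odds, "p": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "set"]).reset_index(drop=True)
    return table
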