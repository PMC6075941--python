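"""Integration of externally computed differential-expression results.

DE testing itself (e.g. an upstream likelihood-ratio or shrinkage model)
is consumed as a file interface: a table of (gene, q-value, tissue, age)
rows. This module filters it at the inclusion threshold q <= 0.01, maps DE
burden onto coexpression modules per stratum, summarizes cross-strata
overlaps, and tests module eigengenes for group differences with Welch
t-tests.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .expr import AGES, TISSUES
from .netbuild import GREY, EigengeneSet

STRATA = [(t, a) for t in TISSUES for a in AGES]


def read_de_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    required = {"gene", "qval", "tissue", "age_months"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if ((tab["qval"] < 0) | (tab["qval"] > 1)).any():
        raise ValueError("q-values outside [0, 1]")
    if tab.duplicated(["gene", "tissue", "age_months"]).any():
        raise ValueError("duplicate (gene, stratum) rows in DE table")
    return tab


def significant_genes(de: pd.DataFrame, q_max: float = 0.01) -> dict:
    """Per-stratum sets of genes with q <= q_max (inclusive threshold)."""
    bad = set(de["tissue"]) - set(TISSUES)
    if bad or (set(de["age_months"].astype(int)) - set(AGES)):
        raise ValueError(f"unknown stratum labels: {sorted(bad)}")
    out = {}
    for (tissue, age), grp in de.groupby(["tissue", "age_months"]):
        out[(tissue, int(age))] = set(grp.loc[grp["qval"] <= q_max, "gene"])
    return out


def de_overlap(sets: dict) -> dict:
    """Pairwise overlaps, the full cross-strata intersection, and
    per-stratum exclusive counts."""
    if len(sets) < 2:
        raise ValueError("need at least two strata")
    keys = sorted(sets, key=str)
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(keys, 2)
    }
    full = set.intersection(*(set(sets[k]) for k in keys))
    exclusive = {
        k: len(set(sets[k]) - set.union(*(set(sets[j]) for j in keys if j != k)))
        for k in keys
    }
    return {"pairwise": pairwise, "intersection": sorted(full),
            "exclusive": exclusive}


def de_fold_ratio(n1: int, n2: int):
    """Fold ratio of two DE counts with its integer display value."""
    if n2 == 0:
        return float("inf"), "inf"
    fold = n1 / n2
    return fold, f"{round(fold)}-fold"


def de_per_module(partition: pd.Series, sets: dict) -> pd.DataFrame:
    """Percentage of each module's genes that are DE, per stratum.

    Rows = modules (grey included, flagged by the ``is_grey`` column),
    columns = strata; values = 100 * |module ∩ DE| / |module|.
    """
    universe = set(partition.index)
    modules = sorted(set(partition), key=lambda m: (m == GREY, str(m)))
    cols = {}
    for stratum in sorted(sets, key=str):
        de = set(sets[stratum]) & universe
        col = {}
        for mod in modules:
            members = set(partition.index[partition == mod])
            col[mod] = 100.0 * len(members & de) / len(members)
        cols[f"{stratum[0]}_{stratum[1]}m"] = col
    out = pd.DataFrame(cols).loc[modules]
    out["is_grey"] = [m == GREY for m in modules]
    return out


def welch_ttest(x, y):
    """Two-sided Welch two-sample t-test: (t, Welch-Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least 2 samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def eigengene_group_test(es: EigengeneSet, meta: pd.DataFrame,
                         grouping: str = "age_months") -> pd.DataFrame:
    """Per-module Welch t-test of eigengene values between the two levels of
    ``grouping`` (default: 4 vs 8 months) within one network's samples."""
    e = es.eigengenes
    groups = meta.loc[e.index, grouping]
    levels = sorted(groups.unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, "
                         f"got {levels}")
    ia = groups == levels[0]
    rows = []
    for mod in e.columns:
        x, y = e.loc[ia, mod], e.loc[~ia, mod]
        t, df, p = welch_ttest(x, y)
        unstable = (np.std(x) == 0 or np.std(y) == 0) and min(len(x), len(y)) <= 2
        rows.append({"module": mod, "group1": levels[0], "group2": levels[1],
                     "t": t, "df": df, "p": p, "unstable": unstable})
    return pd.DataFrame(rows).set_index("module")
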