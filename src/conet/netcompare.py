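"""Cross-condition module comparison: matching, preservation, membership.

Modules detected in a test network (KO) are matched to reference (WT)
modules by hypergeometric overlap and inherit the best-matching reference
color; test modules with no significant counterpart — or whose counterpart
was already claimed by a stronger match — keep a fresh color and are flagged
*emergent*, while reference modules never chosen are flagged *lost*.

Preservation of reference modules in the test data is quantified by the
permutation Z statistics of seven density/connectivity statistics and their
composites Zsummary (mean of the density and connectivity medians; > 10 =
strong evidence of preservation, < 2 = none) and medianRank (rank-based,
insensitive to module size; higher rank = less preserved).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .expr import ExpressionMatrix
from .netbuild import (GREY, STANDARD_COLORS, _row_transform, adjacency,
                       correlation_matrix)

DENSITY_STATS = ("meanAdj", "propVarExplained", "meanSignAwareKME",
                 "meanSignAwareCorDat")
CONNECTIVITY_STATS = ("cor_kIM", "cor_kME", "cor_cor")


def hypergeom_overlap(ref_genes, test_genes, universe_size: int):
    """Upper-tail hypergeometric probability of the observed overlap.

    Population = analysis universe, successes = reference module genes,
    draws = test module genes; returns ``(overlap, P(X >= overlap))``.
    """
    ref, test = set(ref_genes), set(test_genes)
    if universe_size < len(ref | test):
        raise ValueError("universe smaller than the union of the sets")
    overlap = len(ref & test)
    assert overlap <= min(len(ref), len(test))
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(ref),
                                 len(test)))
    return overlap, min(max(p, np.nextafter(0, 1)), 1.0)


class OverlapPercent(NamedTuple):
    """Overlap as a percentage of a module with its display values:
    ``rounded`` for plain reporting ("only 5%") and ``floored`` for
    lower-bound phrasing ("over 72%")."""

    percent: float
    rounded: int
    floored: int


def overlap_percent(overlap: int, module_size: int) -> OverlapPercent:
    """Percentage of a module covered by an overlap, with integer displays."""
    if module_size <= 0:
        raise ValueError("module_size must be positive")
    if not 0 <= overlap <= module_size:
        raise ValueError("overlap must be in [0, module_size]")
    pct = 100.0 * overlap / module_size
    return OverlapPercent(pct, int(round(pct)), int(np.floor(pct)))


@dataclass
class MatchTable:
    """Reference x test module overlap table and the induced relabeling."""

    counts: pd.DataFrame          # ref modules (rows, incl grey) x test modules
    pvalues: pd.DataFrame         # non-grey rows/cols only
    neglog10p: pd.DataFrame
    relabeling: dict              # original test label -> assigned color
    best_match: dict              # original test label -> ref color
    emergent: list
    lost: list
    alpha: float = 0.05


def match_modules(ref: pd.Series, test: pd.Series,
                  alpha: float = 0.05) -> MatchTable:
    """Match test-network modules to reference-network modules.

    Both partitions must cover the same gene universe. Each test module is
    assigned the color of the reference module with the smallest
    hypergeometric overlap p-value (ties: larger overlap, then smaller
    reference module); assignment is greedy in ascending p so each reference
    color is claimed at most once. A test module is *emergent* when its best
    p exceeds the Bonferroni-adjusted ``alpha`` or its best color was
    already claimed; reference modules never claimed are *lost*. Grey is
    excluded from matching but kept in the count table.
    """
    if set(ref.index) != set(test.index):
        raise ValueError("partitions cover different gene universes")
    test = test.loc[ref.index]
    universe = len(ref)
    ref_mods = [m for m in ref.unique() if m != GREY]
    test_mods = [m for m in test.unique() if m != GREY]
    counts = pd.crosstab(ref, test)
    counts = counts.reindex(
        index=sorted(ref.unique(), key=str),
        columns=sorted(test.unique(), key=str), fill_value=0)

    pvals = pd.DataFrame(np.ones((len(ref_mods), len(test_mods))),
                         index=ref_mods, columns=test_mods, dtype=float)
    for rm in ref_mods:
        rg = set(ref.index[ref == rm])
        for tm in test_mods:
            tg = set(test.index[test == tm])
            _, p = hypergeom_overlap(rg, tg, universe)
            pvals.loc[rm, tm] = p

    n_tests = max(pvals.size, 1)
    threshold = alpha / n_tests
    ref_sizes = ref.value_counts()

    # best reference match per test module
    best = {}
    for tm in test_mods:
        col = pvals[tm]
        order = sorted(
            ref_mods,
            key=lambda rm: (col[rm], -counts.loc[rm, tm], ref_sizes[rm], str(rm)),
        )
        best[tm] = (order[0], col[order[0]]) if order else (None, 1.0)

    # greedy color assignment in ascending best-p
    used_colors = set(ref_mods) | {GREY}
    fresh_pool = [c for c in STANDARD_COLORS if c not in used_colors]
    relabeling, emergent, claimed = {}, [], set()
    for tm in sorted(test_mods, key=lambda t: (best[t][1], str(t))):
        rm, p = best[tm]
        if rm is not None and p <= threshold and rm not in claimed:
            relabeling[tm] = rm
            claimed.add(rm)
        else:
            fresh = fresh_pool.pop(0) if fresh_pool else f"novel_{tm}"
            relabeling[tm] = fresh
            emergent.append(tm)
    lost = [rm for rm in ref_mods if rm not in claimed]
    neglog = -np.log10(pvals)
    return MatchTable(counts=counts, pvalues=pvals, neglog10p=neglog,
                      relabeling=relabeling,
                      best_match={tm: best[tm][0] for tm in test_mods},
                      emergent=emergent, lost=lost, alpha=alpha)


def apply_relabeling(test: pd.Series, table: MatchTable) -> pd.Series:
    """Rewrite a test partition with the matched reference colors."""
    return test.map(lambda m: table.relabeling.get(m, m))


# ---------------------------------------------------------------------------
# module preservation


@dataclass
class PreservationReport:
    observed: pd.DataFrame        # module x statistic
    z: pd.DataFrame               # module x statistic permutation Z
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    summary: pd.DataFrame         # Zsummary/Zdensity/Zconnectivity/medianRank
    n_permutations: int = 0
    seed: int = 0
    skipped: list = field(default_factory=list)


class _NetworkData:
    """Per-condition precomputations shared by observed and null statistics."""

    def __init__(self, expr: ExpressionMatrix, power: float,
                 corr_method: str = "bicor"):
        self.genes = list(expr.features)
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.corr = correlation_matrix(expr, method=corr_method).to_numpy()
        self.adj = ((1.0 + self.corr) / 2.0) ** power
        np.fill_diagonal(self.adj, 1.0)
        vals = expr.values.to_numpy(dtype=float)
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        self.z = (vals - mu) / np.where(sd == 0, 1.0, sd)
        self.t = _row_transform(vals, corr_method)  # for kME
        self.corr_method = corr_method

    def eigengene(self, idx: np.ndarray):
        """First right-singular direction of the standardized submatrix and
        its proportion of variance explained."""
        sub = self.z[idx]
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        if np.dot(e, sub.mean(axis=0)) < 0:
            e = -e
        return e, float(s[0] ** 2 / np.sum(s ** 2))

    def kme(self, idx: np.ndarray, eigengene: np.ndarray) -> np.ndarray:
        from .netbuild import _bicor_transform
        if self.corr_method == "bicor":
            et, _ = _bicor_transform(eigengene)
        else:
            et = eigengene - eigengene.mean()
        nrm = np.sqrt(np.sum(et ** 2))
        et = et / nrm if nrm > 0 else et
        return np.clip(self.t[idx] @ et, -1.0, 1.0)


def _module_stats(idx: np.ndarray, ref: _NetworkData,
                  test: _NetworkData) -> dict:
    """The seven preservation statistics of one gene set."""
    q = len(idx)
    iu = np.triu_indices(q, k=1)
    a_test = test.adj[np.ix_(idx, idx)]
    r_ref = ref.corr[np.ix_(idx, idx)]
    r_test = test.corr[np.ix_(idx, idx)]

    e_ref, _ = ref.eigengene(idx)
    e_test, pve_test = test.eigengene(idx)
    kme_ref = ref.kme(idx, e_ref)
    kme_test = test.kme(idx, e_test)

    a_ref = ref.adj[np.ix_(idx, idx)]
    kim_ref = a_ref.sum(axis=1) - 1.0
    kim_test = a_test.sum(axis=1) - 1.0

    def safe_cor(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    return {
        "meanAdj": float(a_test[iu].mean()),
        "propVarExplained": pve_test,
        "meanSignAwareKME": float(np.mean(np.sign(kme_ref) * kme_test)),
        "meanSignAwareCorDat": float(np.mean(np.sign(r_ref[iu]) * r_test[iu])),
        "cor_kIM": safe_cor(kim_ref, kim_test),
        "cor_kME": safe_cor(kme_ref, kme_test),
        "cor_cor": safe_cor(r_ref[iu], r_test[iu]),
    }


def module_preservation(ref_expr: ExpressionMatrix,
                        test_expr: ExpressionMatrix,
                        ref_partition: pd.Series,
                        power: float = 6.0,
                        n_perm: int = 200,
                        seed: int = 0,
                        corr_method: str = "bicor",
                        min_module_size: int = 4,
                        extra_sets: dict | None = None) -> PreservationReport:
    """Permutation preservation of reference modules in the test data.

    For each reference module the seven statistics are computed in the test
    (and, where the definition needs it, reference) data, then compared with
    ``n_perm`` same-size gene sets drawn uniformly from the shared universe:
    Z = (observed - null mean)/null sd. ``extra_sets`` allows scoring
    arbitrary gene sets (e.g. random controls) alongside the modules.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives unstable null standard deviations")
    shared = [g for g in ref_expr.features if g in set(test_expr.features)]
    ref_expr = ref_expr.subset_features(shared)
    test_expr = test_expr.subset_features(shared)
    ref_net = _NetworkData(ref_expr, power, corr_method)
    test_net = _NetworkData(test_expr, power, corr_method)
    rng = np.random.default_rng(seed)

    sets, skipped = {}, []
    for mod in sorted(set(ref_partition.loc[shared]) - {GREY}, key=str):
        genes = [g for g in shared if ref_partition.get(g) == mod]
        if len(genes) < min_module_size:
            skipped.append(mod)
            continue
        sets[str(mod)] = np.array([ref_net.index[g] for g in genes])
    for name, genes in (extra_sets or {}).items():
        sets[str(name)] = np.array([ref_net.index[g] for g in genes])

    observed = pd.DataFrame(
        {name: _module_stats(idx, ref_net, test_net)
         for name, idx in sets.items()}).T
    all_stats = list(DENSITY_STATS) + list(CONNECTIVITY_STATS)
    observed = observed[all_stats]

    n_genes = len(shared)
    null_mean, null_sd = {}, {}
    # share the null across sets of equal size
    by_size: dict[int, list[str]] = {}
    for name, idx in sets.items():
        by_size.setdefault(len(idx), []).append(name)
    for size, names in sorted(by_size.items()):
        draws = np.empty((n_perm, len(all_stats)))
        for p in range(n_perm):
            idx = rng.choice(n_genes, size=size, replace=False)
            s = _module_stats(idx, ref_net, test_net)
            draws[p] = [s[k] for k in all_stats]
        mu = draws.mean(axis=0)
        sd = draws.std(axis=0, ddof=1)
        for name in names:
            null_mean[name] = mu
            null_sd[name] = sd
    null_mean = pd.DataFrame(null_mean, index=all_stats).T
    null_sd = pd.DataFrame(null_sd, index=all_stats).T
    sd_safe = null_sd.where(null_sd > 0)
    z = (observed - null_mean) / sd_safe

    zdensity = z[list(DENSITY_STATS)].median(axis=1)
    zconn = z[list(CONNECTIVITY_STATS)].median(axis=1)
    zsummary = (zdensity + zconn) / 2.0

    # medianRank from observed statistics only (higher value = rank 1)
    ranks = observed.rank(ascending=False, method="average")
    mr_density = ranks[list(DENSITY_STATS)].median(axis=1)
    mr_conn = ranks[list(CONNECTIVITY_STATS)].median(axis=1)
    median_rank = (mr_density + mr_conn) / 2.0

    summary = pd.DataFrame({
        "moduleSize": pd.Series({n: len(i) for n, i in sets.items()}),
        "Zdensity": zdensity, "Zconnectivity": zconn, "Zsummary": zsummary,
        "medianRank_density": mr_density, "medianRank_connectivity": mr_conn,
        "medianRank": median_rank,
    })
    return PreservationReport(observed=observed, z=z, null_mean=null_mean,
                              null_sd=null_sd, summary=summary,
                              n_permutations=n_perm, seed=seed,
                              skipped=skipped)


# ---------------------------------------------------------------------------
# module membership comparison


def mm_correlation(ref_kme: pd.DataFrame, test_kme: pd.DataFrame,
                   ref_partition: pd.Series,
                   min_genes: int = 3) -> pd.DataFrame:
    """Correlation of kME vectors between two networks, per matched module.

    Variant (a) uses all shared genes (overall module conservation);
    variant (b) restricts to genes assigned to the module in the reference
    network (hub conservation). Correlations on fewer than ``min_genes``
    genes are reported as NaN.
    """
    shared_genes = [g for g in ref_kme.index if g in set(test_kme.index)]
    shared_mods = [m for m in ref_kme.columns if m in set(test_kme.columns)]
    rows = []
    for mod in shared_mods:
        x = ref_kme.loc[shared_genes, mod].to_numpy()
        y = test_kme.loc[shared_genes, mod].to_numpy()
        if len(x) >= min_genes and np.std(x) > 0 and np.std(y) > 0:
            r_all, p_all = stats.pearsonr(x, y)
        else:
            r_all, p_all = np.nan, np.nan
        members = [g for g in shared_genes
                   if str(ref_partition.get(g)) == str(mod)]
        if len(members) >= min_genes:
            xm = ref_kme.loc[members, mod].to_numpy()
            ym = test_kme.loc[members, mod].to_numpy()
            if np.std(xm) > 0 and np.std(ym) > 0:
                r_mod, p_mod = stats.pearsonr(xm, ym)
            else:
                r_mod, p_mod = np.nan, np.nan
        else:
            r_mod, p_mod = np.nan, np.nan
        rows.append({"module": str(mod), "cor_all": r_all, "p_all": p_all,
                     "cor_module": r_mod, "p_module": p_mod,
                     "n_module_genes": len(members)})
    absent = [m for m in ref_kme.columns if m not in set(test_kme.columns)]
    for mod in absent:
        rows.append({"module": str(mod), "cor_all": np.nan, "p_all": np.nan,
                     "cor_module": np.nan, "p_module": np.nan,
                     "n_module_genes": 0})
    return pd.DataFrame(rows).set_index("module")
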