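"""Signed weighted coexpression network construction and module summaries.

One network is built per condition: robust biweight midcorrelations for all
gene pairs, a signed soft-thresholded adjacency a_ij = ((1+r_ij)/2)^beta with
beta chosen by the scale-free topology criterion, optionally the topological
overlap measure, average-linkage clustering with a dynamic-hybrid tree cut
(see :mod:`conet.treecut`), module eigengenes via SVD, module membership
(kME) and per-module hub rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .expr import ExpressionMatrix
from .treecut import cut_tree_hybrid

GREY = "grey"

# Conventional module color palette, in size-rank order (largest module first).
STANDARD_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


@dataclass
class NetworkConfig:
    """Parameters of one condition's signed network."""

    power: float | None = None          # soft threshold; None -> pick by R^2
    candidate_powers: tuple = tuple(range(1, 21))
    r2_target: float = 0.8
    min_module_size: int = 30
    deep_split: int = 2
    merge_height: float | None = 0.25   # eigengene-dissimilarity merge cutoff
    tom: bool = True
    corr_method: str = "bicor"          # estimator for network and kME

    def __post_init__(self):
        if self.power is not None and self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")


# ---------------------------------------------------------------------------
# correlation


def _bicor_transform(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Median-centered, Tukey-biweight-weighted deviations of one vector.

    Returns (weighted deviations, used_pearson_fallback). Observations beyond
    9 MADs from the median get zero weight. If MAD is zero the biweight is
    undefined; we fall back to mean-centered (Pearson-style) deviations for
    that vector.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x - np.mean(x), True
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w, False


def bicor(x, y) -> float:
    """Biweight midcorrelation of two sample vectors.

    Robust alternative to Pearson correlation: deviations are taken from the
    median and down-weighted by Tukey's biweight, so observations beyond
    9 median absolute deviations are ignored. Constant vectors yield 0 with
    a warning (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector in bicor; returning 0")
        return 0.0
    xt, _ = _bicor_transform(x)
    yt, _ = _bicor_transform(y)
    denom = np.sqrt(np.sum(xt ** 2) * np.sum(yt ** 2))
    if denom == 0:
        warnings.warn("degenerate weighting in bicor; returning 0")
        return 0.0
    return float(np.clip(np.sum(xt * yt) / denom, -1.0, 1.0))


def _row_transform(values: np.ndarray, method: str) -> np.ndarray:
    """Per-row normalized deviations such that R = T @ T.T is the
    correlation matrix under ``method`` ('bicor' or 'pearson')."""
    n_genes, _ = values.shape
    out = np.empty_like(values, dtype=float)
    constant = np.ptp(values, axis=1) == 0
    for i in range(n_genes):
        if constant[i]:
            out[i] = 0.0
            continue
        if method == "bicor":
            t, _ = _bicor_transform(values[i])
        elif method == "pearson":
            t = values[i] - values[i].mean()
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        norm = np.sqrt(np.sum(t ** 2))
        out[i] = 0.0 if norm == 0 else t / norm
    return out


def correlation_matrix(m: ExpressionMatrix,
                       method: str = "bicor") -> pd.DataFrame:
    """All-pairs gene correlation matrix (default biweight midcorrelation).

    Symmetric with unit diagonal; genes with zero variance get correlation 0
    against everything (flagged by warning).
    """
    if m.n_samples < 4:
        raise ValueError("need at least 4 samples")
    vals = m.values.to_numpy(dtype=float)
    if (np.ptp(vals, axis=1) == 0).any():
        warnings.warn("zero-variance genes present; their correlations are 0")
    t = _row_transform(vals, method)
    r = np.clip(t @ t.T, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return pd.DataFrame(r, index=m.features, columns=m.features)


def corr_with_profiles(m: ExpressionMatrix, profiles: pd.DataFrame,
                       method: str = "bicor") -> pd.DataFrame:
    """Correlation of every gene with every column profile (e.g. eigengene).

    Rows = genes, columns = profile names; same estimator options as the
    network correlation.
    """
    gv = _row_transform(m.values.to_numpy(dtype=float), method)
    pv = _row_transform(profiles.to_numpy(dtype=float).T, method)
    r = np.clip(gv @ pv.T, -1.0, 1.0)
    return pd.DataFrame(r, index=m.features, columns=profiles.columns)


# ---------------------------------------------------------------------------
# adjacency / scale-free fit / TOM


def adjacency(corr: pd.DataFrame, power: float) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + r_ij)/2)^power, diagonal 1.

    r = -1 maps to 0 (strong negative correlation = unconnected) and r = 1
    maps to 1 for any power, preserving correlation sign information.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    a = ((1.0 + corr.to_numpy(dtype=float)) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins log10(k), regresses log10 of the discretized frequency p(k) on the
    per-bin mean log10(k) and returns (signed R^2, slope) where the sign of
    R^2 is flipped positive only when the slope is negative.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if np.ptp(k) == 0:
        raise ValueError("degenerate connectivity: all k identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    logk, logp = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        logk.append(np.log10(k[sel].mean()))
        logp.append(np.log10(sel.mean()))
    logk, logp = np.array(logk), np.array(logp)
    if len(logk) < 3 or np.ptp(logk) == 0:
        raise ValueError("too few occupied bins for scale-free fit")
    slope, intercept = np.polyfit(logk, logp, 1)
    fitted = slope * logk + intercept
    ss_res = np.sum((logp - fitted) ** 2)
    ss_tot = np.sum((logp - logp.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def _default_signed_power(n_samples: int) -> int:
    """Rule-of-thumb soft threshold for signed networks when the scale-free
    criterion is indecisive, stratified by sample size."""
    if n_samples > 40:
        return 12
    if n_samples > 30:
        return 14
    if n_samples > 20:
        return 16
    return 18


def pick_soft_threshold(corr: pd.DataFrame,
                        candidate_powers=tuple(range(1, 21)),
                        r2_target: float = 0.8,
                        n_samples: int | None = None):
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power the signed adjacency is formed and the fit of
    log p(k) ~ log k evaluated; the smallest power reaching ``r2_target``
    (with negative slope) wins. When no candidate reaches the target — data
    with a few strong, similarly sized modules is not scale-free — the
    fallback is the conventional sample-size-stratified default for signed
    networks if ``n_samples`` is given, else the best-fitting power; either
    way a warning is raised. Returns ``(power, fit table)``.
    """
    candidate_powers = list(candidate_powers)
    if not candidate_powers or sorted(candidate_powers) != candidate_powers:
        raise ValueError("candidate_powers must be nonempty and ascending")
    r = corr.to_numpy(dtype=float)
    base = (1.0 + r) / 2.0
    np.fill_diagonal(base, 0.0)  # exclude self from connectivity
    rows = []
    for beta in candidate_powers:
        a = base ** beta
        k = a.sum(axis=1)
        fit, slope = scale_free_fit(k)
        rows.append({"power": beta, "sft_r2": fit, "slope": slope,
                     "mean_k": k.mean(), "median_k": np.median(k),
                     "max_k": k.max()})
    table = pd.DataFrame(rows)
    ok = table[table["sft_r2"] >= r2_target]
    if len(ok):
        power = int(ok.iloc[0]["power"])
        if n_samples is not None and power > _default_signed_power(n_samples):
            # extreme powers over-sparsify the network: weak noise
            # correlations raised to a large exponent rival true module
            # signal, so the rule-of-thumb default acts as a cap
            power = _default_signed_power(n_samples)
            warnings.warn(
                f"scale-free target first reached above the signed-network "
                f"default; capping beta at {power}"
            )
    elif n_samples is not None:
        power = _default_signed_power(n_samples)
        power = int(np.clip(power, candidate_powers[0], candidate_powers[-1]))
        warnings.warn(
            f"no candidate power reached scale-free R^2 {r2_target}; "
            f"using the signed-network default beta={power} for "
            f"{n_samples} samples"
        )
    else:
        power = int(table.loc[table["sft_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached scale-free R^2 {r2_target}; "
            f"using best fit beta={power}"
        )
    return power, table


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbor-weighted similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    connectivity k excluding the diagonal; TOM_ii = 1. Downstream clustering
    uses the dissimilarity 1 - TOM.
    """
    a = adj.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# module detection


def _labels_to_colors(labels: pd.Series, min_module_size: int) -> pd.Series:
    """Size-rank integer module labels into the conventional color palette."""
    sizes = labels[labels != 0].value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], l))
    mapping = {0: GREY}
    for rank, lab in enumerate(order):
        mapping[lab] = (STANDARD_COLORS[rank] if rank < len(STANDARD_COLORS)
                        else f"module{rank + 1}")
    return labels.map(mapping)


def detect_modules(diss: pd.DataFrame, cfg: NetworkConfig,
                   expr: ExpressionMatrix | None = None):
    """Average-linkage clustering plus dynamic-hybrid tree cut.

    Returns ``(partition, linkage matrix)`` where partition maps gene ->
    color label ("grey" = unassigned). If ``expr`` is given and
    ``cfg.merge_height`` is set, modules whose eigengenes are closer than
    ``merge_height`` in correlation dissimilarity are merged before coloring.
    """
    genes = list(diss.index)
    if cfg.min_module_size > len(genes):
        raise ValueError("min_module_size exceeds gene count")
    d = diss.to_numpy(dtype=float)
    condensed = squareform((d + d.T) / 2.0, checks=False)
    link = sch.linkage(condensed, method="average")
    labels = cut_tree_hybrid(link, n_leaves=len(genes),
                             min_cluster_size=cfg.min_module_size,
                             deep_split=cfg.deep_split, diss=d)
    labels = pd.Series(labels, index=genes)
    if expr is not None and cfg.merge_height is not None:
        labels = _merge_close_modules(labels, expr, cfg)
    colors = _labels_to_colors(labels, cfg.min_module_size)
    return colors, link


def _merge_close_modules(labels: pd.Series, expr: ExpressionMatrix,
                         cfg: NetworkConfig) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity below
    ``cfg.merge_height`` (dissimilarity = 1 - correlation of eigengenes)."""
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            return labels
        es = eigengenes(expr, labels.map(lambda l: str(l) if l != 0 else GREY))
        e = es.eigengenes
        cols = [str(m) for m in mods if str(m) in e.columns]
        if len(cols) < 2:
            return labels
        c = np.corrcoef(e[cols].to_numpy().T)
        d = 1.0 - c
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= cfg.merge_height:
            return labels
        a, b = int(cols[i]), int(cols[j])
        labels[labels == max(a, b)] = min(a, b)


# ---------------------------------------------------------------------------
# eigengenes / module membership / hubs


@dataclass
class EigengeneSet:
    """Per-module first-principal-component sample profiles.

    ``eigengenes`` is a sample x module DataFrame; each column has unit
    Euclidean norm and its sign is aligned so that it correlates positively
    with the module's mean standardized expression. ``prop_var_explained``
    is sigma_1^2 / sum(sigma_k^2) for the module's standardized submatrix.
    """

    eigengenes: pd.DataFrame
    prop_var_explained: pd.Series
    sign_convention: str = "align_to_mean_expression"


def eigengenes(m: ExpressionMatrix, partition: pd.Series,
               include_grey: bool = False) -> EigengeneSet:
    """Module eigengenes via singular value decomposition.

    Gene rows are standardized (zero mean, unit variance over samples);
    the eigengene is the first right-singular vector of the standardized
    module submatrix — equivalently the first principal component over
    samples.
    """
    vals = m.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    if not ok.all():
        warnings.warn("dropping zero-variance genes from eigengene SVD")
    z = np.where(ok[:, None], (vals - mu) / np.where(sd == 0, 1, sd), 0.0)
    z = pd.DataFrame(z, index=m.features, columns=m.samples)
    cols, pve = {}, {}
    for mod in sorted(set(partition), key=str):
        if mod == GREY and not include_grey:
            continue
        genes = partition.index[partition == mod]
        genes = [g for g, keep in zip(m.features, ok) if keep and partition.get(g) == mod]
        if len(genes) < 2:
            continue
        sub = z.loc[genes].to_numpy()
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        cols[str(mod)] = e
        pve[str(mod)] = float(s[0] ** 2 / np.sum(s ** 2))
    eg = pd.DataFrame(cols, index=m.samples)
    return EigengeneSet(eg, pd.Series(pve, dtype=float))


def module_membership(m: ExpressionMatrix, es: EigengeneSet,
                      method: str = "bicor") -> pd.DataFrame:
    """kME: correlation of each gene's profile with each module eigengene."""
    return corr_with_profiles(m, es.eigengenes, method=method)


def top_hubs(kme: pd.DataFrame, partition: pd.Series, n: int = 10) -> dict:
    """Per-module member genes ranked by descending own-module kME.

    Ties break lexicographically by gene id; ``n`` larger than the module
    returns the full ranked membership.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = {}
    for mod in kme.columns:
        members = [g for g in kme.index if str(partition.get(g)) == str(mod)]
        ranked = sorted(members, key=lambda g: (-kme.loc[g, mod], g))
        out[str(mod)] = ranked[:n]
    return out


def export_edges(corr: pd.DataFrame, partition: pd.Series,
                 threshold: float = 0.5) -> pd.DataFrame:
    """Undirected edge list of gene pairs with correlation strictly above
    ``threshold`` (signed: raw r, not |r|), annotated with module labels."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    r = corr.to_numpy(dtype=float)
    genes = list(corr.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = r[iu, ju] > threshold
    rows = {
        "gene1": [genes[i] for i in iu[keep]],
        "gene2": [genes[j] for j in ju[keep]],
        "correlation": r[iu, ju][keep],
    }
    edges = pd.DataFrame(rows)
    edges["module1"] = [partition.get(g, GREY) for g in edges["gene1"]]
    edges["module2"] = [partition.get(g, GREY) for g in edges["gene2"]]
    return edges


def write_sif(edges: pd.DataFrame, path) -> None:
    """Cytoscape SIF dialect: gene1 <tab> coexp <tab> gene2."""
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['gene1']}\tcoexp\t{row['gene2']}\n")
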