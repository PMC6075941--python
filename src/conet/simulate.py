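"""Two-condition synthetic expression data with known planted structure.

The generator emulates a 64-sample, two-genotype (WT/KO), two-tissue
(hippocampus/cortex), two-age (4/8 months) brain RNA-seq design at a
desk-scale gene count. Signal is a Gaussian latent-factor model on the log
scale: each module m has a per-sample factor value (redrawn independently in
every stratum, so strata can be concatenated into one multi-tissue,
multi-age network per genotype), and gene g in module m observes
``loading(g) * factor(m) + noise``. Background genes are pure noise.

Planted perturbations in the KO condition give every downstream comparison a
ground truth: one module is split into two independent sub-factors (a module
disruption), one module swaps the identity of its top-loading hub gene, and
a block of genes receives an additive differential-expression shift in one
(tissue, age) stratum. Cell-type marker lists are seeded into designated
modules at a chosen purity. An optional negative-binomial count layer
(mean = library size * 2^(baseline + signal)) exercises read-count
filtering; all network mathematics runs on the continuous layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expr import ExpressionMatrix, TISSUES, AGES
from .io_utils import write_gmt

CONDITIONS = ("WT", "KO")
GREY = "grey"


class ConfigurationError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass
class DEPlan:
    """Additive expression shift for the first ``n_genes`` genes of a module
    in the KO samples of one (tissue, age) stratum."""

    module: int
    n_genes: int
    shift: float
    tissue: str
    age: int


@dataclass
class MarkerPlan:
    """Seed ``n_markers`` markers of one cell type: ``purity`` of them from
    the designated module, the rest from elsewhere in the genome."""

    module: int
    n_markers: int
    purity: float = 0.8


@dataclass
class SyntheticSpec:
    """Study-design parameters of the synthetic two-condition experiment.

    Defaults mirror the emulated design: 8 replicates per
    (genotype, tissue, age) cell = 64 samples, five planted modules, one
    KO-specific module split, one hub-identity shift, DE genes concentrated
    in the split module at 4 months cortex, and marker-seeded modules for
    four brain cell types.
    """

    n_genes: int = 500
    module_sizes: tuple = (100, 100, 100, 100, 100)
    n_samples_per_stratum: int = 8
    loading_range: tuple = (0.3, 0.5)
    hub_loading: float = 0.95
    noise_sd: float = 0.3
    split_module: int | None = 1
    split_fraction: float = 0.7
    hub_shift: tuple | None = (2, None, None)  # (module, old hub, new hub)
    de_config: tuple = (DEPlan(module=1, n_genes=40, shift=1.0,
                               tissue="cortex", age=4),)
    marker_config: dict = field(default_factory=lambda: {
        "neurons": MarkerPlan(module=0, n_markers=50),
        "endothelial": MarkerPlan(module=1, n_markers=50),
        "microglia": MarkerPlan(module=3, n_markers=50),
        "astrocytes": MarkerPlan(module=4, n_markers=50),
    })
    nb_dispersion: float | None = 0.1
    seed: int = 0

    def validate(self) -> None:
        k = len(self.module_sizes)
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError("module sizes exceed n_genes")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("loading_range must be within (0, 1]")
        if self.split_module is not None:
            if not 0 <= self.split_module < k:
                raise ConfigurationError("split_module out of range")
            if not 0 < self.split_fraction < 1:
                raise ConfigurationError("split_fraction must be in (0,1)")
        if self.hub_shift is not None and not 0 <= self.hub_shift[0] < k:
            raise ConfigurationError("hub_shift module out of range")
        for plan in self.de_config:
            if not 0 <= plan.module < k:
                raise ConfigurationError("de_config module out of range")
            if plan.tissue not in TISSUES or plan.age not in AGES:
                raise ConfigurationError("de_config stratum unknown")
            if plan.n_genes > self.module_sizes[plan.module]:
                raise ConfigurationError("de_config larger than module")
        for ct, plan in self.marker_config.items():
            if not 0 <= plan.module < k:
                raise ConfigurationError(f"marker module out of range: {ct}")
            if not 0 < plan.purity <= 1:
                raise ConfigurationError(f"marker purity out of range: {ct}")


def recovery_spec(seed: int = 0) -> SyntheticSpec:
    """The planted-structure recovery scenario used by the validation suite:
    500 genes in five 100-gene modules, 60 samples per condition."""
    return SyntheticSpec(n_samples_per_stratum=15, seed=seed)


@dataclass
class TruthBundle:
    """Ground truth written alongside the synthetic matrices."""

    module_labels: dict            # condition -> Series gene -> label
    split_assignment: pd.Series    # gene -> "a"/"b" within split module (KO)
    de_genes: dict                 # (tissue, age) -> list of genes
    markers: dict                  # cell type -> list of genes
    hub_genes: dict                # condition -> {module label -> gene}
    factors: dict                  # condition -> DataFrame factor x sample
    loadings: dict                 # condition -> Series gene -> loading


def _module_label(i: int) -> str:
    return f"M{i}"


def generate(spec: SyntheticSpec, out_dir=None):
    """Draw the synthetic experiment.

    Returns ``(matrices, truth)`` with ``matrices[condition]`` an
    :class:`ExpressionMatrix` of the continuous (log-scale) layer; when the
    spec requests a count layer it is attached as
    ``provenance["counts"]`` (DataFrame). With ``out_dir`` set, expression,
    metadata and truth files are also written as TSV/GMT.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k = len(spec.module_sizes)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]

    # gene -> planted module (condition A labelling)
    labels_a = np.full(spec.n_genes, GREY, dtype=object)
    bounds = np.cumsum((0,) + tuple(spec.module_sizes))
    module_genes = {}
    for m in range(k):
        idx = np.arange(bounds[m], bounds[m + 1])
        module_genes[m] = [genes[i] for i in idx]
        labels_a[idx] = _module_label(m)

    lo, hi = spec.loading_range
    loadings_a = rng.uniform(lo, hi, size=spec.n_genes)
    loadings_a[bounds[k]:] = 0.0  # background

    # hub designation: per module the max-loading gene; the hub-shift module
    # gets an explicit hub at hub_loading well above the bulk range
    hub_shift = None
    if spec.hub_shift is not None:
        hmod, old_hub, new_hub = spec.hub_shift
        if old_hub is None:
            old_hub = module_genes[hmod][0]
        if new_hub is None:
            new_hub = module_genes[hmod][1]
        loadings_a[genes.index(old_hub)] = spec.hub_loading
        hub_shift = (hmod, old_hub, new_hub)

    loadings_b = loadings_a.copy()
    if hub_shift is not None:
        i, j = genes.index(hub_shift[1]), genes.index(hub_shift[2])
        loadings_b[i], loadings_b[j] = loadings_b[j], loadings_b[i]

    # split assignment (condition B): first split_fraction of the module's
    # genes follow sub-factor "a", the rest "b"
    split_assignment = pd.Series(dtype=object)
    labels_b = labels_a.copy()
    if spec.split_module is not None:
        sm = spec.split_module
        mg = module_genes[sm]
        n_a = int(round(spec.split_fraction * len(mg)))
        sub = ["a"] * n_a + ["b"] * (len(mg) - n_a)
        split_assignment = pd.Series(sub, index=mg)
        for g, s in split_assignment.items():
            if s == "b":
                labels_b[genes.index(g)] = _module_label(sm) + "_split"

    de_truth = {(t, a): [] for t in TISSUES for a in AGES}
    for plan in spec.de_config:
        de_truth[(plan.tissue, plan.age)].extend(
            module_genes[plan.module][: plan.n_genes])

    markers = {}
    for ct, plan in spec.marker_config.items():
        own = module_genes[plan.module]
        n_in = int(round(plan.purity * plan.n_markers))
        n_in = min(n_in, len(own))
        n_out = plan.n_markers - n_in
        outside = [g for g in genes if g not in set(own)]
        chosen = list(rng.choice(own, size=n_in, replace=False))
        if n_out:
            chosen += list(rng.choice(outside, size=n_out, replace=False))
        markers[ct] = sorted(chosen)

    matrices, factors_out, hubs_out = {}, {}, {}
    loadings = {"WT": loadings_a, "KO": loadings_b}
    labels = {"WT": labels_a, "KO": labels_b}
    counts_layer = {}
    for cond in CONDITIONS:
        ld = loadings[cond]
        sample_ids, meta_rows, blocks = [], [], []
        factor_rows: dict[str, list] = {}
        # factor ids: one per module, plus the two sub-factors in KO
        for tissue in TISSUES:
            for age in AGES:
                n = spec.n_samples_per_stratum
                for r in range(n):
                    sid = f"{cond}_{tissue[:3]}_{age}m_r{r + 1}"
                    sample_ids.append(sid)
                    meta_rows.append((sid, cond, tissue, age, r + 1))
                fac = rng.standard_normal((k, n))
                sub_fac = rng.standard_normal((2, n))  # used only if split
                block = np.zeros((spec.n_genes, n))
                for m in range(k):
                    idx = np.arange(bounds[m], bounds[m + 1])
                    if (cond == "KO" and spec.split_module == m):
                        for jj, g in enumerate(module_genes[m]):
                            which = 0 if split_assignment[g] == "a" else 1
                            block[idx[jj]] = ld[idx[jj]] * sub_fac[which]
                    else:
                        block[idx] = ld[idx, None] * fac[m]
                block += rng.normal(0.0, spec.noise_sd,
                                    size=(spec.n_genes, n))
                if cond == "KO":
                    for plan in spec.de_config:
                        if plan.tissue == tissue and plan.age == age:
                            sel = np.arange(bounds[plan.module],
                                            bounds[plan.module] + plan.n_genes)
                            block[sel] += plan.shift
                blocks.append(block)
                for m in range(k):
                    factor_rows.setdefault(_module_label(m), []).append(fac[m])
                if cond == "KO" and spec.split_module is not None:
                    sm_lab = _module_label(spec.split_module)
                    factor_rows.setdefault(f"{sm_lab}_a", []).append(sub_fac[0])
                    factor_rows.setdefault(f"{sm_lab}_b", []).append(sub_fac[1])
        values = pd.DataFrame(np.concatenate(blocks, axis=1), index=genes,
                              columns=sample_ids)
        meta = pd.DataFrame(
            meta_rows,
            columns=["sample_id", "genotype", "tissue", "age_months",
                     "replicate_id"],
        ).set_index("sample_id")
        em = ExpressionMatrix(values, meta, unit="log-intensity")
        if spec.nb_dispersion is not None:
            base = rng.uniform(4.0, 9.0, size=spec.n_genes)
            mean = 2.0 ** (base[:, None] + values.to_numpy())
            r_nb = 1.0 / spec.nb_dispersion
            p_nb = r_nb / (r_nb + mean)
            counts = rng.negative_binomial(r_nb, p_nb)
            counts_layer[cond] = pd.DataFrame(counts, index=genes,
                                              columns=sample_ids)
            em.provenance["counts"] = counts_layer[cond]
        matrices[cond] = em
        factors_out[cond] = pd.DataFrame(
            {name: np.concatenate(parts) for name, parts in factor_rows.items()},
            index=sample_ids,
        ).T
        hubs = {}
        for m in range(k):
            idx = np.arange(bounds[m], bounds[m + 1])
            hubs[_module_label(m)] = genes[idx[np.argmax(ld[idx])]]
        hubs_out[cond] = hubs

    truth = TruthBundle(
        module_labels={c: pd.Series(labels[c], index=genes) for c in CONDITIONS},
        split_assignment=split_assignment,
        de_genes={s: sorted(v) for s, v in de_truth.items()},
        markers=markers,
        hub_genes=hubs_out,
        factors=factors_out,
        loadings={c: pd.Series(loadings[c], index=genes) for c in CONDITIONS},
    )

    if out_dir is not None:
        _write_outputs(spec, matrices, truth, counts_layer, Path(out_dir))
    return matrices, truth


def _write_outputs(spec, matrices, truth, counts_layer, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for cond, em in matrices.items():
        em.values.to_csv(out / f"expr_{cond}.tsv", sep="\t",
                         index_label="gene", float_format="%.6g")
        em.meta.to_csv(out / f"meta_{cond}.tsv", sep="\t",
                       index_label="sample_id")
        if cond in counts_layer:
            counts_layer[cond].to_csv(out / f"counts_{cond}.tsv", sep="\t",
                                      index_label="gene")
        truth.module_labels[cond].rename("module").to_csv(
            out / f"truth_modules_{cond}.tsv", sep="\t", index_label="gene")
    write_gmt(truth.markers, out / "truth_markers.gmt")
    rows = []
    genes = list(matrices["WT"].features)
    for (tissue, age), de in truth.de_genes.items():
        de = set(de)
        for g in genes:
            rows.append((g, 1e-6 if g in de else 1.0, tissue, age))
    pd.DataFrame(rows, columns=["gene", "qval", "tissue", "age_months"]).to_csv(
        out / "truth_de.tsv", sep="\t", index=False)
    hub_rows = [
        (cond, mod, gene)
        for cond, hubs in truth.hub_genes.items()
        for mod, gene in hubs.items()
    ]
    pd.DataFrame(hub_rows, columns=["condition", "module", "hub_gene"]).to_csv(
        out / "truth_hubs.tsv", sep="\t", index=False)
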