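"""End-to-end WT-vs-KO coexpression comparison from a single config.

Stages: ingest -> (collapse) -> (filter) -> per-condition network build ->
module matching + preservation + membership comparison -> cell-type scores
-> gene-set enrichment -> DE overlay. Every stage writes plain TSV
intermediates into the output directory; a stage is skipped on re-run when
its outputs already exist and the configuration hash is unchanged, so the
slow permutation step never forces network reconstruction. A fixed seed and
config yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import celltype as ct
from . import de as de_mod
from . import enrich as enrich_mod
from . import netbuild as nb
from . import netcompare as nc
from .expr import ExpressionMatrix, read_expression, read_transcript_map, \
    collapse_transcripts, filter_expressed
from .io_utils import read_gmt, read_partition, write_partition

log = logging.getLogger("conet")

DEFAULT_CONFIG = {
    "paths": {
        "expression": None,       # TSV gene x sample, both genotypes
        "metadata": None,
        "transcript_map": None,   # optional
        "markers": None,          # optional GMT
        "de_table": None,         # optional TSV gene/qval/tissue/age_months
        "gene_sets": None,        # optional GMT for enrichment
    },
    "unit": "counts",
    "filter": {"enabled": False, "min_reads": 10, "min_fraction": 0.9,
               "keep_if_any_stratum": True},
    "transform": "none",          # log2p1 | none
    "network": {"power": None, "r2_target": 0.8, "min_module_size": 30,
                "deep_split": 2, "merge_height": 0.25, "tom": True,
                "corr_method": "bicor"},
    "compare": {"n_perm": 200, "seed": 0, "alpha": 0.05,
                "edge_threshold": 0.5},
    "out_dir": None,
}


def _deep_update(base: dict, overrides: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    return _deep_update(DEFAULT_CONFIG, user)


def validate_config(cfg: dict) -> list[str]:
    """Exhaustive validation; returns the (possibly empty) list of errors."""
    errors = []
    paths = cfg.get("paths", {})
    for key in ("expression", "metadata"):
        if not paths.get(key):
            errors.append(f"paths.{key} is required")
        elif not Path(paths[key]).exists():
            errors.append(f"paths.{key} does not exist: {paths[key]}")
    for key in ("transcript_map", "markers", "de_table", "gene_sets"):
        p = paths.get(key)
        if p and not Path(p).exists():
            errors.append(f"paths.{key} does not exist: {p}")
    f = cfg["filter"]
    if not 0 <= f["min_fraction"] < 1:
        errors.append("filter.min_fraction must be in [0, 1)")
    n = cfg["network"]
    if n["power"] is not None and n["power"] < 1:
        errors.append("network.power must be >= 1")
    if n["min_module_size"] < 3:
        errors.append("network.min_module_size must be >= 3")
    if not 0 <= n["deep_split"] <= 4:
        errors.append("network.deep_split must be in 0..4")
    if n["corr_method"] not in ("bicor", "pearson"):
        errors.append("network.corr_method must be bicor or pearson")
    if cfg["transform"] not in ("log2p1", "none"):
        errors.append("transform must be log2p1 or none")
    c = cfg["compare"]
    if c["n_perm"] < 1:
        errors.append("compare.n_perm must be positive")
    if not 0 < c["edge_threshold"] < 1:
        errors.append("compare.edge_threshold must be in (0,1)")
    if not cfg.get("out_dir"):
        errors.append("out_dir is required")
    return errors


def _config_hash(cfg: dict) -> str:
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Stages:
    """Skip-if-done bookkeeping keyed by the config hash."""

    def __init__(self, out: Path, cfg: dict):
        self.out = out
        self.hash = _config_hash(cfg)
        self.hash_file = out / "config_hash.txt"
        previous = (self.hash_file.read_text().strip()
                    if self.hash_file.exists() else None)
        self.reuse = previous == self.hash
        self.hash_file.write_text(self.hash + "\n")

    def done(self, *outputs) -> bool:
        return self.reuse and all((self.out / o).exists() for o in outputs)


def build_network(expr: ExpressionMatrix, cfg_net: dict, out: Path | None,
                  tag: str, edge_threshold: float = 0.5) -> dict:
    """One condition's network: correlation, soft threshold, (TOM), modules,
    eigengenes, kME, hubs, thresholded edge export."""
    corr = nb.correlation_matrix(expr, method=cfg_net["corr_method"])
    power = cfg_net.get("power")
    fit_table = None
    if power is None:
        power, fit_table = nb.pick_soft_threshold(
            corr, r2_target=cfg_net.get("r2_target", 0.8),
            n_samples=expr.n_samples)
    adj = nb.adjacency(corr, power)
    sim = nb.tom_similarity(adj) if cfg_net.get("tom", True) else adj
    diss = 1.0 - sim
    ncfg = nb.NetworkConfig(
        power=power, min_module_size=cfg_net["min_module_size"],
        deep_split=cfg_net["deep_split"],
        merge_height=cfg_net.get("merge_height"),
        tom=cfg_net.get("tom", True), corr_method=cfg_net["corr_method"])
    partition, link = nb.detect_modules(diss, ncfg, expr=expr)
    es = nb.eigengenes(expr, partition)
    kme = nb.module_membership(expr, es, method=cfg_net["corr_method"])
    hubs = nb.top_hubs(kme, partition, n=10)
    edges = nb.export_edges(corr, partition, threshold=edge_threshold)
    result = {"corr": corr, "power": power, "fit_table": fit_table,
              "adjacency": adj, "diss": diss, "partition": partition,
              "eigengenes": es, "kme": kme, "hubs": hubs, "edges": edges,
              "linkage": link}
    if out is not None:
        write_partition(partition, out / f"modules_{tag}.tsv")
        es.eigengenes.to_csv(out / f"eigengenes_{tag}.tsv", sep="\t",
                             index_label="sample_id", float_format="%.6g")
        es.prop_var_explained.rename("prop_var_explained").to_csv(
            out / f"eigengene_varexpl_{tag}.tsv", sep="\t",
            index_label="module", float_format="%.6g")
        kme.to_csv(out / f"kme_{tag}.tsv", sep="\t", index_label="gene",
                   float_format="%.6g")
        if fit_table is not None:
            fit_table.to_csv(out / f"sft_fit_{tag}.tsv", sep="\t",
                             index=False, float_format="%.6g")
        edges.to_csv(out / f"edges_{tag}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        nb.write_sif(edges, out / f"edges_{tag}.sif")
        pd.DataFrame(
            [(m, i + 1, g) for m, gs in hubs.items()
             for i, g in enumerate(gs)],
            columns=["module", "rank", "gene"],
        ).to_csv(out / f"hubs_{tag}.tsv", sep="\t", index=False)
    return result


def run_pipeline(cfg) -> dict:
    """Execute the full two-condition workflow; returns a report dict and
    writes all tables under ``cfg['out_dir']``."""
    cfg = load_config(cfg)
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = _Stages(out, cfg)
    report: dict = {"config_hash": stages.hash, "out_dir": str(out)}

    log.info("stage=ingest expression=%s", cfg["paths"]["expression"])
    m = read_expression(cfg["paths"]["expression"], cfg["paths"]["metadata"],
                        unit=cfg["unit"])
    if cfg["paths"].get("transcript_map"):
        tx2gene = read_transcript_map(cfg["paths"]["transcript_map"])
        m = collapse_transcripts(m, tx2gene)
    if cfg["filter"]["enabled"]:
        m, filter_report = filter_expressed(
            m, min_reads=cfg["filter"]["min_reads"],
            min_fraction=cfg["filter"]["min_fraction"],
            keep_if_any_stratum=cfg["filter"]["keep_if_any_stratum"])
        filter_report.to_csv(out / "filter_report.tsv", sep="\t",
                             index_label="gene")
        report["n_genes_retained"] = int(m.n_features)
    if cfg["transform"] == "log2p1":
        m = m.log2p1()

    nets = {}
    for cond in ("WT", "KO"):
        build_outputs = [f"modules_{cond}.tsv", f"eigengenes_{cond}.tsv",
                         f"eigengene_varexpl_{cond}.tsv", f"kme_{cond}.tsv",
                         f"edges_{cond}.tsv", f"hubs_{cond}.tsv",
                         f"network_info_{cond}.json"]
        sub = m.subset_condition(cond)
        if stages.done(*build_outputs):
            log.info("stage=build condition=%s (resumed)", cond)
            nets[cond] = _load_network(out, cond)
        else:
            log.info("stage=build condition=%s", cond)
            nets[cond] = build_network(
                sub, cfg["network"], out, cond,
                edge_threshold=cfg["compare"]["edge_threshold"])
            with open(out / f"network_info_{cond}.json", "w") as fh:
                json.dump({"power": nets[cond]["power"]}, fh)
        report[f"power_{cond}"] = nets[cond]["power"]
        sizes = nets[cond]["partition"].value_counts()
        report[f"modules_{cond}"] = sizes.to_dict()

    log.info("stage=compare n_perm=%d", cfg["compare"]["n_perm"])
    match = nc.match_modules(nets["WT"]["partition"], nets["KO"]["partition"],
                             alpha=cfg["compare"]["alpha"])
    ko_relabeled = nc.apply_relabeling(nets["KO"]["partition"], match)
    write_partition(ko_relabeled, out / "modules_KO_matched.tsv")
    match.counts.to_csv(out / "match_counts.tsv", sep="\t",
                        index_label="WT_module")
    match.pvalues.to_csv(out / "match_pvalues.tsv", sep="\t",
                         index_label="WT_module", float_format="%.6g")
    report["emergent_modules"] = [match.relabeling[m_] for m_ in match.emergent]
    report["lost_modules"] = list(match.lost)

    wt_expr = m.subset_condition("WT")
    ko_expr = m.subset_condition("KO")
    if stages.done("preservation_WT_in_KO.tsv"):
        log.info("stage=preservation (resumed)")
        pres_summary = pd.read_csv(out / "preservation_WT_in_KO.tsv",
                                   sep="\t", index_col="module")
    else:
        preservation = nc.module_preservation(
            wt_expr, ko_expr, nets["WT"]["partition"],
            power=nets["KO"]["power"], n_perm=cfg["compare"]["n_perm"],
            seed=cfg["compare"]["seed"],
            corr_method=cfg["network"]["corr_method"])
        pres_summary = preservation.summary
        pres_summary.to_csv(out / "preservation_WT_in_KO.tsv", sep="\t",
                            index_label="module", float_format="%.6g")
    report["preservation"] = pres_summary["Zsummary"].to_dict()

    # kME comparison against matched colors in both networks
    ko_es = nb.eigengenes(ko_expr, ko_relabeled)
    ko_kme = nb.module_membership(ko_expr, ko_es,
                                  method=cfg["network"]["corr_method"])
    mm = nc.mm_correlation(nets["WT"]["kme"], ko_kme, nets["WT"]["partition"])
    mm.to_csv(out / "mm_correlation.tsv", sep="\t", float_format="%.6g")

    if cfg["paths"].get("markers"):
        markers = read_gmt(cfg["paths"]["markers"])
        for cond, part in (("WT", nets["WT"]["partition"]),
                           ("KO", ko_relabeled)):
            scores = ct.celltype_scores(part, markers)
            scores.to_csv(out / f"celltype_{cond}.tsv", sep="\t",
                          index_label="module", float_format="%.6g")
            report[f"dominant_celltype_{cond}"] = scores["dominant"].to_dict()

    if cfg["paths"].get("gene_sets"):
        gene_sets = read_gmt(cfg["paths"]["gene_sets"])
        universe = list(m.features)
        tables = []
        for mod in sorted(set(nets["WT"]["partition"]) - {nb.GREY}, key=str):
            query = nets["WT"]["partition"].index[
                nets["WT"]["partition"] == mod]
            tab = enrich_mod.fisher_enrichment(query, gene_sets, universe)
            tab.insert(0, "module", mod)
            tables.append(tab)
        if tables:
            pd.concat(tables).to_csv(out / "enrichment_WT.tsv", sep="\t",
                                     index=False, float_format="%.6g")

    if cfg["paths"].get("de_table"):
        de_tab = de_mod.read_de_table(cfg["paths"]["de_table"])
        sets = de_mod.significant_genes(de_tab)
        for cond, part in (("WT", nets["WT"]["partition"]),
                           ("KO", ko_relabeled)):
            pm = de_mod.de_per_module(part, sets)
            pm.to_csv(out / f"de_per_module_{cond}.tsv", sep="\t",
                      index_label="module", float_format="%.6g")
            report[f"de_per_module_{cond}"] = {
                c: pm[c].drop(nb.GREY, errors="ignore").idxmax()
                for c in pm.columns if c != "is_grey"}
        for cond in ("WT", "KO"):
            age_tests = de_mod.eigengene_group_test(
                nets[cond]["eigengenes"], m.subset_condition(cond).meta)
            age_tests.to_csv(out / f"eigengene_age_test_{cond}.tsv", sep="\t",
                             float_format="%.6g")

    with open(out / "summary.json", "w") as fh:
        json.dump({k: v for k, v in report.items() if k != "out_dir"},
                  fh, indent=2, sort_keys=True, default=str)
    log.info("pipeline complete: %s", out)
    return report


def _load_network(out: Path, tag: str) -> dict:
    """Reload a condition's build-stage outputs from intermediates."""
    partition = read_partition(out / f"modules_{tag}.tsv")
    eg = pd.read_csv(out / f"eigengenes_{tag}.tsv", sep="\t",
                     index_col="sample_id")
    pve = pd.read_csv(out / f"eigengene_varexpl_{tag}.tsv", sep="\t",
                      index_col="module")["prop_var_explained"]
    pve.index = pve.index.astype(str)
    kme = pd.read_csv(out / f"kme_{tag}.tsv", sep="\t", index_col="gene")
    edges = pd.read_csv(out / f"edges_{tag}.tsv", sep="\t")
    with open(out / f"network_info_{tag}.json") as fh:
        info = json.load(fh)
    hubs_tab = pd.read_csv(out / f"hubs_{tag}.tsv", sep="\t")
    hubs = {str(mod): grp.sort_values("rank")["gene"].tolist()
            for mod, grp in hubs_tab.groupby("module")}
    return {"partition": partition, "eigengenes": nb.EigengeneSet(eg, pve),
            "kme": kme, "edges": edges, "power": info["power"],
            "hubs": hubs, "corr": None, "fit_table": None,
            "adjacency": None, "diss": None, "linkage": None}
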