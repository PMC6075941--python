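"""Overlay differential-expression results on the coexpression modules.

Filters the DE table at q <= 0.01 per (tissue, age) stratum, reports
cross-strata overlaps and fold ratios of DE counts, maps the percentage of
DE genes into each module per stratum, and Welch-tests each module
eigengene for age differences within each genotype.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from conet import de as de_mod
from conet import netbuild as nb
from conet.expr import read_expression
from conet.io_utils import read_partition

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--networks", type=Path,
                    default=ROOT / "results" / "networks")
    ap.add_argument("--comparison", type=Path,
                    default=ROOT / "results" / "comparison")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "de")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    warnings.filterwarnings("ignore")

    de = de_mod.read_de_table(args.data / "truth_de.tsv")
    sets = de_mod.significant_genes(de)
    counts = {s: len(g) for s, g in sets.items()}
    print(f"significant genes per stratum (q <= 0.01): {counts}")
    nonzero = [s for s, n in counts.items() if n > 0]
    if len(nonzero) >= 2:
        rep = de_mod.de_overlap({s: sets[s] for s in nonzero})
        print(f"cross-strata intersection: {len(rep['intersection'])} genes")
    pairs = [(a, b) for a in counts for b in counts
             if counts[b] > 0 and counts[a] > counts[b]]
    for a, b in pairs[:3]:
        fold, shown = de_mod.de_fold_ratio(counts[a], counts[b])
        print(f"{a} vs {b}: {shown} ({fold:.1f})")

    parts = {
        "WT": read_partition(args.networks / "modules_WT.tsv"),
        "KO": read_partition(args.comparison / "modules_KO_matched.tsv"),
    }
    for cond, part in parts.items():
        burden = de_mod.de_per_module(part, sets)
        burden.to_csv(args.out / f"de_per_module_{cond}.tsv", sep="\t",
                      index_label="module", float_format="%.6g")
        col = burden["cortex_4m"].drop("grey", errors="ignore")
        print(f"{cond}: highest DE burden at 4mo cortex in module "
              f"{col.idxmax()} ({col.max():.1f}% of its genes)")

    m = read_expression(args.data / "expr_all.tsv",
                        args.data / "meta_all.tsv", unit="log-intensity")
    for cond, part in parts.items():
        sub = m.subset_condition(cond)
        es = nb.eigengenes(sub, part)
        tests = de_mod.eigengene_group_test(es, sub.meta,
                                            grouping="age_months")
        tests.to_csv(args.out / f"eigengene_age_test_{cond}.tsv", sep="\t",
                     float_format="%.6g")
        sig = tests[tests["p"] < 0.05]
        print(f"{cond}: {len(sig)} modules with age-associated eigengenes "
              f"(Welch p < 0.05)")


if __name__ == "__main__":
    main()
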