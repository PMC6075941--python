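"""Match KO modules to WT modules and quantify preservation.

Hypergeometric matching assigns each KO module the color of its best WT
counterpart (emergent modules keep a fresh color); permutation Zsummary and
medianRank statistics quantify how well each WT module's density and
connectivity survive in the KO data, with a random gene set as negative
control.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np

from conet import netbuild as nb
from conet import netcompare as nc
from conet.expr import read_expression
from conet.io_utils import read_partition, write_partition

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=200)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--networks", type=Path,
                    default=ROOT / "results" / "networks")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "comparison")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    warnings.filterwarnings("ignore")

    m = read_expression(args.data / "expr_all.tsv",
                        args.data / "meta_all.tsv", unit="log-intensity")
    wt_part = read_partition(args.networks / "modules_WT.tsv")
    ko_part = read_partition(args.networks / "modules_KO.tsv")

    table = nc.match_modules(wt_part, ko_part)
    table.counts.to_csv(args.out / "match_counts.tsv", sep="\t",
                        index_label="WT_module")
    table.pvalues.to_csv(args.out / "match_pvalues.tsv", sep="\t",
                         index_label="WT_module", float_format="%.6g")
    relabeled = nc.apply_relabeling(ko_part, table)
    write_partition(relabeled, args.out / "modules_KO_matched.tsv")
    print(f"matching: {table.relabeling}")
    for em in table.emergent:
        genes = set(ko_part.index[ko_part == em])
        parent = table.best_match[em]
        ov = len(genes & set(wt_part.index[wt_part == parent]))
        pct = nc.overlap_percent(ov, len(genes))
        print(f"emergent KO module {table.relabeling[em]} ({len(genes)} "
              f"genes): over {pct.floored}% ({ov} of {len(genes)}) overlap "
              f"the WT {parent} module")
    print(f"lost WT modules: {table.lost or 'none'}")

    rng = np.random.default_rng(args.seed + 1_000_003)
    wt = m.subset_condition("WT")
    ko = m.subset_condition("KO")
    random_set = list(rng.choice(wt.features, size=100, replace=False))
    corr = nb.correlation_matrix(ko)
    power, _ = nb.pick_soft_threshold(corr, n_samples=ko.n_samples)
    pres = nc.module_preservation(wt, ko, wt_part, power=power,
                                  n_perm=args.n_perm, seed=args.seed,
                                  extra_sets={"random_set": random_set})
    pres.summary.to_csv(args.out / "preservation_WT_in_KO.tsv", sep="\t",
                        index_label="module", float_format="%.6g")
    print(pres.summary[["moduleSize", "Zsummary", "medianRank"]]
          .round(2).to_string())
    worst = pres.summary["medianRank"].drop("random_set").idxmax()
    print(f"least preserved WT module by medianRank: {worst}")

    # kME agreement between networks, overall and over module genes
    wt_es = nb.eigengenes(wt, wt_part)
    ko_es = nb.eigengenes(ko, relabeled)
    mm = nc.mm_correlation(nb.module_membership(wt, wt_es),
                           nb.module_membership(ko, ko_es), wt_part)
    mm.to_csv(args.out / "mm_correlation.tsv", sep="\t",
              float_format="%.6g")
    print(mm[["cor_all", "cor_module"]].round(3).to_string())


if __name__ == "__main__":
    main()
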