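"""Annotate modules with cell-type identities and gene-set enrichment.

Scores every module against the marker lists (percentage of each cell
type's mapped markers falling in the module) and runs Fisher
over-representation of each WT module against the planted DE gene set.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from conet import celltype as ct
from conet.enrich import fisher_enrichment
from conet.io_utils import read_gmt, read_partition

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--networks", type=Path,
                    default=ROOT / "results" / "networks")
    ap.add_argument("--comparison", type=Path,
                    default=ROOT / "results" / "comparison")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "annotation")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    warnings.filterwarnings("ignore")

    markers = read_gmt(args.data / "truth_markers.gmt")
    parts = {
        "WT": read_partition(args.networks / "modules_WT.tsv"),
        "KO": read_partition(args.comparison / "modules_KO_matched.tsv"),
    }
    for cond, part in parts.items():
        scores = ct.celltype_scores(part, markers)
        scores.to_csv(args.out / f"celltype_{cond}.tsv", sep="\t",
                      index_label="module", float_format="%.6g")
        print(f"-- {cond} cell-type profiles (percent of mapped markers)")
        print(scores.round(1).to_string())

    # over-representation of the planted DE genes in each WT module
    de = pd.read_csv(args.data / "truth_de.tsv", sep="\t")
    de_set = set(de.loc[de["qval"] <= 0.01, "gene"])
    part = parts["WT"]
    universe = list(part.index)
    rows = []
    for mod in sorted(set(part) - {"grey"}):
        tab = fisher_enrichment(part.index[part == mod],
                                {"planted_de": sorted(de_set)}, universe)
        tab.insert(0, "module", mod)
        rows.append(tab)
    enr = pd.concat(rows).sort_values("p").reset_index(drop=True)
    enr.to_csv(args.out / "enrichment_WT.tsv", sep="\t", index=False,
               float_format="%.6g")
    print("-- WT module enrichment for the DE gene set")
    print(enr[["module", "overlap", "p", "p_adj"]].round(6).to_string())


if __name__ == "__main__":
    main()
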