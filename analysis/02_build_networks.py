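"""Build one signed coexpression network per genotype.

Reads the combined expression matrix from 01, selects the soft-threshold
power per condition by the scale-free criterion, and writes module
partitions, eigengenes, kME tables, hub rankings and thresholded edge
lists per condition.
"""

import argparse
import warnings
from pathlib import Path

from conet.expr import read_expression
from conet.pipeline import build_network

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "networks")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    warnings.filterwarnings("ignore")

    m = read_expression(args.data / "expr_all.tsv",
                        args.data / "meta_all.tsv", unit="log-intensity")
    cfg = {"power": None, "r2_target": 0.8, "min_module_size": 30,
           "deep_split": 2, "merge_height": 0.25, "tom": True,
           "corr_method": "bicor"}
    for cond in ("WT", "KO"):
        sub = m.subset_condition(cond)
        net = build_network(sub, cfg, args.out, cond)
        sizes = net["partition"].value_counts()
        print(f"{cond}: beta={net['power']}, "
              f"{len(sizes.drop('grey', errors='ignore'))} modules, "
              f"sizes {sizes.to_dict()}")
        for mod, hubs in sorted(net["hubs"].items()):
            print(f"  {cond} {mod}: top hubs {hubs[:3]}")


if __name__ == "__main__":
    main()
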