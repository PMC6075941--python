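"""Small plain-text format helpers: GMT gene sets, partition tables."""

from __future__ import annotations

import pandas as pd


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line, ``name <tab> description <tab> gene ...``.

    Duplicate genes within a set are removed (order preserved); duplicate
    set names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, genes = parts[0], parts[2:]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = list(dict.fromkeys(g for g in genes if g))
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_partition(path) -> pd.Series:
    """Two-column TSV (gene, module) -> Series gene -> module label."""
    tab = pd.read_csv(path, sep="\t")
    return tab.set_index(tab.columns[0])[tab.columns[1]].astype(str)


def write_partition(partition: pd.Series, path) -> None:
    partition.rename("module").to_csv(path, sep="\t", index_label="gene")
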