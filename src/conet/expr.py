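"""Expression matrices, sample metadata, transcript collapsing and expression filters.

The universal currency of the pipeline is :class:`ExpressionMatrix`: a
feature-by-sample numeric table joined with per-sample metadata describing a
two-genotype (WT vs KO), two-tissue (hippocampus/cortex), two-age (4/8 months)
design. Features may be transcripts (pre-collapse) or genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "KO")
TISSUES = ("hippocampus", "cortex")
AGES = (4, 8)

META_COLUMNS = ("genotype", "tissue", "age_months")


class ExpressionError(ValueError):
    """Raised on malformed expression input."""


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values plus aligned sample metadata.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by feature id (transcript or gene), columns by sample id.
    meta : DataFrame
        Indexed by sample id, with at least ``genotype``, ``tissue`` and
        ``age_months`` columns; row order matches ``values.columns``.
    unit : str
        What the numbers are ("counts", "tpm", "log2" ...) — recorded only.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: str = "counts"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate feature ids: {dups[:10]}")
        if list(self.values.columns) != list(self.meta.index):
            self.meta = self.meta.loc[self.values.columns]
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ExpressionError("non-finite values in expression matrix")
        if self.unit in ("counts", "tpm") and (arr < 0).any():
            raise ExpressionError(f"negative values with unit {self.unit!r}")
        bad_gt = set(self.meta["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ExpressionError(f"unknown genotype labels: {sorted(bad_gt)}")
        bad_ts = set(self.meta["tissue"]) - set(TISSUES)
        if bad_ts:
            raise ExpressionError(f"unknown tissue labels: {sorted(bad_ts)}")
        bad_age = set(self.meta["age_months"].astype(int)) - set(AGES)
        if bad_age:
            raise ExpressionError(f"unknown ages: {sorted(bad_age)}")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def strata(self) -> pd.Series:
        """Per-sample (genotype, tissue, age_months) stratum labels."""
        m = self.meta
        return pd.Series(
            list(zip(m["genotype"], m["tissue"], m["age_months"].astype(int))),
            index=m.index,
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[sample_ids], self.meta.loc[sample_ids], self.unit,
            dict(self.provenance),
        )

    def subset_condition(self, genotype: str) -> "ExpressionMatrix":
        keep = self.meta.index[self.meta["genotype"] == genotype]
        return self.subset_samples(keep)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)], self.meta, self.unit,
            dict(self.provenance),
        )

    def log2p1(self) -> "ExpressionMatrix":
        """log2(x + 1) transform, the default network-input transform."""
        out = ExpressionMatrix(
            np.log2(self.values + 1.0), self.meta, unit=f"log2p1({self.unit})",
            provenance=dict(self.provenance),
        )
        return out


def read_expression(path, metadata_path, unit: str = "counts") -> ExpressionMatrix:
    """Read a TSV expression matrix (row 1 = sample ids, column 1 = feature id)
    joined with a metadata TSV keyed by ``sample_id``.

    Samples present in both files only; column order of the matrix file is
    preserved. Missing metadata or non-numeric cells are hard errors.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        if coerced.isna().any() and not values[col].isna().any():
            bad = values.index[coerced.isna() & values[col].notna()][:5].tolist()
            raise ExpressionError(
                f"non-numeric cells in column {col!r} at features {bad}"
            )
        values[col] = coerced
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ExpressionError("metadata must have a sample_id column")
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ExpressionError(f"metadata missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("sample_id")
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise ExpressionError(f"samples missing from metadata: {absent}")
    extra = [s for s in meta.index if s not in values.columns]
    if extra:
        meta = meta.drop(index=extra)
    return ExpressionMatrix(values, meta.loc[values.columns], unit=unit)


def write_expression(m: ExpressionMatrix, path, metadata_path=None,
                     float_format: str = "%.6g") -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id",
                    float_format=float_format)
    if metadata_path is not None:
        m.meta.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_transcript_map(path) -> pd.Series:
    """Two-column TSV (transcript_id, gene_id) -> Series transcript -> gene."""
    tab = pd.read_csv(path, sep="\t")
    if tab.shape[1] < 2:
        raise ExpressionError("transcript map needs two columns")
    tab = tab.iloc[:, :2]
    tab.columns = ["transcript_id", "gene_id"]
    if tab["transcript_id"].duplicated().any():
        dups = tab.loc[tab["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise ExpressionError(f"transcripts mapped to multiple genes: {dups[:10]}")
    return tab.set_index("transcript_id")["gene_id"]


def collapse_transcripts(m: ExpressionMatrix, tx2gene: pd.Series,
                         on_unmapped: str = "drop") -> ExpressionMatrix:
    """Collapse transcript rows to one row per gene.

    The retained row for each gene is the transcript with the highest mean
    expression across all samples (ties broken by lexicographically smallest
    transcript id). The chosen transcript is recorded per gene in
    ``provenance["representative_transcript"]``.
    """
    if on_unmapped not in ("drop", "error"):
        raise ValueError("on_unmapped must be 'drop' or 'error'")
    unmapped = [t for t in m.features if t not in tx2gene.index]
    if unmapped:
        if on_unmapped == "error":
            raise ExpressionError(f"transcripts absent from map: {unmapped[:10]}")
        warnings.warn(f"dropping {len(unmapped)} unmapped transcripts")
    mapped = [t for t in m.features if t in tx2gene.index]
    vals = m.values.loc[mapped]
    genes = tx2gene.loc[mapped]
    means = vals.mean(axis=1)
    # sort by gene, then descending mean, then transcript id; keep the first
    # transcript per gene -> argmax with lexicographic tie-break
    order = pd.DataFrame({"gene": genes.values, "mean": means.values,
                          "tx": vals.index})
    order = order.sort_values(["gene", "mean", "tx"],
                              ascending=[True, False, True])
    chosen = order.drop_duplicates("gene")
    out = vals.loc[chosen["tx"]]
    out.index = chosen["gene"].values
    out = out.sort_index()
    prov = dict(m.provenance)
    prov["representative_transcript"] = dict(
        zip(chosen["gene"], chosen["tx"]))
    return ExpressionMatrix(out, m.meta, unit=m.unit, provenance=prov)


def filter_expressed(m: ExpressionMatrix, min_reads: float = 10,
                     min_fraction: float = 0.9,
                     keep_if_any_stratum: bool = True):
    """Keep genes expressed above ``min_reads`` in strictly more than
    ``min_fraction`` of samples, either globally or (by default) within at
    least one (genotype, tissue, age) stratum.

    The stratum escape hatch retains genes silenced in one genotype but well
    expressed in the other — e.g. a knocked-out gene that is only expressed
    in WT samples. Returns ``(filtered matrix, per-gene report DataFrame)``.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    vals = m.values.to_numpy()
    ok = vals >= min_reads
    global_pass = ok.mean(axis=1) > min_fraction
    stratum_pass = np.zeros(m.n_features, dtype=bool)
    if keep_if_any_stratum:
        strata = m.strata()
        for _, idx in strata.groupby(strata).groups.items():
            cols = [m.samples.index(s) for s in idx]
            stratum_pass |= ok[:, cols].mean(axis=1) > min_fraction
    keep = global_pass | stratum_pass
    report = pd.DataFrame(
        {
            "global_pass": global_pass,
            "stratum_pass": stratum_pass,
            "retained": keep,
        },
        index=m.values.index,
    )
    return m.subset_features(m.values.index[keep]), report
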