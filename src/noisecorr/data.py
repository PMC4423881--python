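"""Data model and descriptive statistics for multi-study expression matrices.

A merged gene-expression corpus is held as a genes x replicates matrix of
log-scale abundances with an explicit observation mask, plus a replicate
metadata table mapping every replicate (column) to its study (experiment),
measurement technology, and molecule type (mRNA or protein).  These strata
define the noise structure used by the structured covariance model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ReplicateMeta",
    "read_replicate_meta",
    "read_expression_table",
    "log_prepare",
    "merge_datasets",
    "pairwise_correlation_matrix",
    "correlation_summary",
]

MOLECULE_TYPES = ("protein", "mRNA")

#: minimum shared genes for a pairwise correlation to be defined
MIN_SHARED_GENES = 3


@dataclass(frozen=True)
class ReplicateMeta:
    """Replicate -> (experiment, technology, molecule type) mapping.

    Wraps a table with columns ``replicate_id``, ``experiment_id``,
    ``technology_id`` and ``molecule_type`` and exposes the integer index
    arrays k[j] (experiment), t[j] (technology) and l[j] (molecule type,
    0 = protein, 1 = mRNA) used by the hierarchical model.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"replicate_id", "experiment_id", "technology_id", "molecule_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata table missing columns: {sorted(missing)}")
        tab = self.table.reset_index(drop=True)
        if tab["replicate_id"].duplicated().any():
            dups = tab.loc[tab["replicate_id"].duplicated(), "replicate_id"].tolist()
            raise ValueError(f"duplicate replicate ids: {dups}")
        bad = set(tab["molecule_type"]) - set(MOLECULE_TYPES)
        if bad:
            raise ValueError(
                f"molecule_type must be one of {MOLECULE_TYPES}, got {sorted(bad)}"
            )
        # each experiment maps to exactly one technology and one molecule type
        for col in ("technology_id", "molecule_type"):
            per_exp = tab.groupby("experiment_id")[col].nunique()
            if (per_exp > 1).any():
                offenders = per_exp[per_exp > 1].index.tolist()
                raise ValueError(f"experiments with inconsistent {col}: {offenders}")
        object.__setattr__(self, "table", tab)

    @property
    def replicate_ids(self) -> np.ndarray:
        return self.table["replicate_id"].to_numpy()

    @property
    def n_replicates(self) -> int:
        return len(self.table)

    @property
    def experiment_ids(self) -> list:
        """Unique experiment ids in first-appearance order."""
        return list(dict.fromkeys(self.table["experiment_id"]))

    @property
    def technology_ids(self) -> list:
        return list(dict.fromkeys(self.table["technology_id"]))

    @property
    def experiment_index(self) -> np.ndarray:
        """k[j]: 0-based experiment index per replicate."""
        order = {e: i for i, e in enumerate(self.experiment_ids)}
        return np.array([order[e] for e in self.table["experiment_id"]])

    @property
    def technology_index(self) -> np.ndarray:
        """t[j]: 0-based technology index per replicate."""
        order = {t: i for i, t in enumerate(self.technology_ids)}
        return np.array([order[t] for t in self.table["technology_id"]])

    @property
    def molecule_index(self) -> np.ndarray:
        """l[j]: 0 for protein, 1 for mRNA."""
        return np.array(
            [MOLECULE_TYPES.index(m) for m in self.table["molecule_type"]]
        )

    def subset(self, replicate_ids: Sequence) -> "ReplicateMeta":
        keep = self.table["replicate_id"].isin(list(replicate_ids))
        return ReplicateMeta(self.table[keep].reset_index(drop=True))


@dataclass
class ExpressionMatrix:
    """Genes x replicates abundance matrix with an explicit missingness mask.

    ``values[i, j]`` is the measurement X_ij of gene i in replicate j;
    ``observed[i, j]`` is the detection indicator I_ij.  Cells flagged
    unobserved carry NaN.  ``log_scale`` records whether values are natural
    logs (the canonical analysis scale) or raw linear-scale intensities.
    """

    gene_ids: np.ndarray
    replicate_ids: np.ndarray
    values: np.ndarray
    observed: np.ndarray
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=object)
        self.values = np.array(self.values, dtype=float)
        self.observed = np.array(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed mask must have identical shape")
        if self.values.shape != (len(self.gene_ids), len(self.replicate_ids)):
            raise ValueError("matrix shape inconsistent with gene/replicate ids")
        if len(self.gene_ids) < 2 or len(self.replicate_ids) < 1:
            raise ValueError("need at least 2 genes and 1 replicate")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(set(self.replicate_ids)) != len(self.replicate_ids):
            raise ValueError("replicate ids must be unique")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise ValueError("observed cells must hold finite values")
        self.values[~self.observed] = np.nan

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def column(self, replicate_id) -> np.ndarray:
        """One replicate's values (NaN where unobserved)."""
        j = list(self.replicate_ids).index(replicate_id)
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.replicate_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.gene_ids.copy(),
            self.replicate_ids.copy(),
            self.values.copy(),
            self.observed.copy(),
            self.log_scale,
        )


def read_replicate_meta(path) -> ReplicateMeta:
    """Read a tab-separated replicate metadata table."""
    return ReplicateMeta(pd.read_csv(path, sep="\t"))


def read_expression_table(path, meta: ReplicateMeta, log_scale: bool = False) -> ExpressionMatrix:
    """Read a TSV expression table (first column gene id, one column per replicate).

    Empty cells and NA tokens are treated as missing.  ``log_scale`` declares
    whether the file already holds natural-log values; raw linear-scale tables
    should be passed through :func:`log_prepare` afterwards.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate gene ids in {path}")
    unknown = set(df.columns) - set(meta.replicate_ids)
    if unknown:
        raise ValueError(f"replicate columns not in metadata: {sorted(unknown)}")
    # order columns as in the metadata, restricted to those present
    cols = [r for r in meta.replicate_ids if r in set(df.columns)]
    df = df[cols]
    values = df.to_numpy(dtype=float)  # raises on non-numeric payload
    observed = np.isfinite(values)
    return ExpressionMatrix(
        df.index.to_numpy(dtype=object), np.array(cols, dtype=object),
        values, observed, log_scale=log_scale,
    )


def log_prepare(x: ExpressionMatrix) -> ExpressionMatrix:
    """Natural-log transform a linear-scale matrix.

    Zeros and negative entries cannot be log-transformed and become missing,
    following the convention of omitting zeros and missing values before
    correlating log-scale measurements.
    """
    if x.log_scale:
        raise ValueError("matrix is already on the log scale")
    positive = x.observed & (x.values > 0)
    values = np.full_like(x.values, np.nan)
    values[positive] = np.log(x.values[positive])
    return ExpressionMatrix(x.gene_ids, x.replicate_ids, values, positive, log_scale=True)


def merge_datasets(
    datasets: Iterable[tuple[ExpressionMatrix, ReplicateMeta]],
) -> tuple[ExpressionMatrix, ReplicateMeta]:
    """Merge per-study matrices into one corpus over the union of genes.

    Genes absent from a study are missing in that study's columns.  Replicate
    ids must be globally unique and molecule types consistent.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("nothing to merge")
    scales = {x.log_scale for x, _ in datasets}
    if len(scales) > 1:
        raise ValueError("cannot merge matrices on different scales")
    frames = []
    metas = []
    for x, m in datasets:
        extra = set(x.replicate_ids) - set(m.replicate_ids)
        if extra:
            raise ValueError(f"replicates without metadata: {sorted(extra)}")
        frames.append(x.to_frame())
        metas.append(m.table[m.table["replicate_id"].isin(set(x.replicate_ids))])
    meta_tab = pd.concat(metas, ignore_index=True)  # ReplicateMeta rejects duplicates
    meta = ReplicateMeta(meta_tab)
    merged = pd.concat(frames, axis=1)
    if merged.columns.duplicated().any():
        raise ValueError("duplicate replicate ids across datasets")
    merged = merged[list(meta.replicate_ids)]
    values = merged.to_numpy(dtype=float)
    return (
        ExpressionMatrix(
            merged.index.to_numpy(dtype=object),
            meta.replicate_ids.copy(),
            values,
            np.isfinite(values),
            log_scale=datasets[0][0].log_scale,
        ),
        meta,
    )


def _pairwise_complete_corr(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, int]:
    shared = np.isfinite(a) & np.isfinite(b)
    n = int(shared.sum())
    if n < MIN_SHARED_GENES:
        return np.nan, n
    aa, bb = a[shared], b[shared]
    if method == "spearman":
        aa = pd.Series(aa).rank().to_numpy()
        bb = pd.Series(bb).rank().to_numpy()
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if aa.std() == 0 or bb.std() == 0:
        return np.nan, n
    return float(np.corrcoef(aa, bb)[0, 1]), n


def pairwise_correlation_matrix(
    x: ExpressionMatrix,
    meta: ReplicateMeta,
    method: Literal["pearson", "spearman"] = "pearson",
) -> pd.DataFrame:
    """All replicate-pair correlations over genes observed in both replicates.

    Returns a long-form table with one row per unordered replicate pair,
    annotated by whether the pair is within- or between-study, shares a
    technology, and compares like or unlike molecule types.  Pairs with fewer
    than three shared genes get a missing correlation, not an error.
    """
    if not x.log_scale:
        raise ValueError("descriptive correlations expect log-scale values")
    ids = list(x.replicate_ids)
    tab = meta.table.set_index("replicate_id").loc[ids]
    rows = []
    for i in range(len(ids)):
        for j in range(i, len(ids)):
            r, n = _pairwise_complete_corr(x.values[:, i], x.values[:, j], method)
            rows.append({
                "replicate_1": ids[i],
                "replicate_2": ids[j],
                "correlation": 1.0 if i == j else r,
                "n_shared_genes": n,
                "within_study": tab["experiment_id"].iloc[i] == tab["experiment_id"].iloc[j],
                "same_technology": tab["technology_id"].iloc[i] == tab["technology_id"].iloc[j],
                "molecule_pair": "-".join(sorted([
                    tab["molecule_type"].iloc[i], tab["molecule_type"].iloc[j]
                ])),
            })
    return pd.DataFrame(rows)


def correlation_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Median correlations by molecule pair and within/between-study status.

    Self-pairs are excluded; this is the summary behind plots of within- vs
    between-study reliability.
    """
    sub = pairs[pairs["replicate_1"] != pairs["replicate_2"]]
    out = (
        sub.groupby(["molecule_pair", "within_study"])["correlation"]
        .agg(["median", "mean", "count"])
        .reset_index()
    )
    return out
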