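"""qPCR Ct preprocessing.

Raw qPCR output is a long table of wells (sample, gene, technical replicate,
Ct).  Preprocessing collapses technical replicates to a per-(gene, sample)
mean Ct, applies an abundance filter on the per-gene grand-mean Ct
(default: retain genes with grand mean below 28 cycles), converts Ct to
log2 relative quantities using per-gene amplification efficiency, and
produces an overview of each candidate's expression relative to the panel
geometric mean.

The central container is :class:`CtMatrix`: genes x biological samples of
mean Ct, a sample -> stage-group map, and per-gene efficiencies (default
2.0, i.e. perfect doubling per cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, InsufficientDataError

__all__ = [
    "CtMatrix",
    "read_ct_table",
    "read_wide_ct",
    "read_group_map",
    "collapse_replicates",
    "filter_by_mean_ct",
    "ct_to_log_quantity",
    "overview_relative_expression",
]

REQUIRED_COLUMNS = ("sample_id", "gene", "replicate", "ct")

#: replicate scatter above this many cycles earns a QC flag on the cell
REPLICATE_SD_FLAG = 0.5


@dataclass
class CtMatrix:
    """Mean Ct per gene (rows) and biological sample (columns).

    ``groups`` maps every sample column to its stage label; ``efficiency``
    holds the per-gene amplification factor in (1, 2.2].  ``qc`` carries
    replicate counts/SDs from :func:`collapse_replicates` when available.
    """

    data: pd.DataFrame
    groups: pd.Series
    efficiency: pd.Series = None
    qc: pd.DataFrame = None

    def __post_init__(self):
        original_index = self.data.index
        self.data = self.data.sort_index()
        if self.efficiency is None:
            self.efficiency = pd.Series(2.0, index=self.data.index)
        else:
            if isinstance(self.efficiency, (int, float)):
                self.efficiency = pd.Series(float(self.efficiency), index=self.data.index)
            elif isinstance(self.efficiency, (pd.Series, dict)):
                self.efficiency = pd.Series(self.efficiency, dtype=float).reindex(
                    self.data.index
                )
            else:  # sequence aligned with the rows as originally given
                self.efficiency = pd.Series(
                    np.asarray(self.efficiency, dtype=float), index=original_index
                ).reindex(self.data.index)
            if self.efficiency.isna().any():
                missing = self.efficiency.index[self.efficiency.isna()].tolist()
                raise ConfigError(f"efficiency missing for genes: {missing}")
        eff = self.efficiency.to_numpy()
        if np.any((eff <= 1.0) | (eff > 2.2)):
            raise ConfigError("efficiency must lie in (1, 2.2]")
        unmapped = [s for s in self.data.columns if s not in self.groups.index]
        if unmapped:
            raise DataError(f"samples without a group label: {unmapped}")
        self.groups = self.groups.reindex(self.data.columns)

    @property
    def genes(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def group_labels(self) -> list:
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def subset(self, genes=None, samples=None) -> "CtMatrix":
        d = self.data
        if genes is not None:
            missing = [g for g in genes if g not in d.index]
            if missing:
                raise DataError(f"genes not in matrix: {missing}")
            d = d.loc[list(genes)]
        if samples is not None:
            d = d[list(samples)]
        return CtMatrix(
            data=d.copy(),
            groups=self.groups.reindex(d.columns),
            efficiency=self.efficiency.reindex(d.index),
        )

    def subset_group(self, label: str) -> "CtMatrix":
        cols = [s for s in self.data.columns if self.groups[s] == label]
        if not cols:
            raise DataError(f"no samples in group {label!r}")
        return self.subset(samples=cols)

    def check_complete(self) -> None:
        if self.data.isna().any().any():
            bad = [
                (g, s)
                for g in self.data.index
                for s in self.data.columns
                if pd.isna(self.data.at[g, s])
            ]
            raise DataError(f"CtMatrix has missing cells: {bad[:10]}")


def read_group_map(path) -> pd.Series:
    """Read a two-column sample_id/group sidecar TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise DataError(f"group map {path} lacks column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"group map {path}: duplicate sample ids {dup}")
    return df.set_index("sample_id")["group"]


def read_ct_table(path, group_map=None) -> pd.DataFrame:
    """Read and validate a long-format Ct TSV.

    Expected columns: ``sample_id, gene, replicate, ct`` and either a
    ``group`` column or an external *group_map* (dict / Series / sidecar
    path) covering every sample.  Raises :class:`DataError` naming the
    offending row or key on malformed input.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"Ct table {path} lacks required columns: {missing}")

    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad = df.index[ct.isna()]
    if len(bad):
        raise DataError(f"Ct table {path}: non-numeric ct at row(s) {list(bad[:5])}")
    df = df.assign(ct=ct.astype(float))
    out_of_range = df.index[(df["ct"] <= 0) | (df["ct"] > 45)]
    if len(out_of_range):
        raise DataError(
            f"Ct table {path}: ct outside (0, 45] at row(s) {list(out_of_range[:5])}"
        )

    key = df[["sample_id", "gene", "replicate"]].astype(str).agg("|".join, axis=1)
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise DataError(f"Ct table {path}: duplicate (sample, gene, replicate) key {dup!r}")

    if group_map is not None:
        if isinstance(group_map, (str, Path)):
            group_map = read_group_map(group_map)
        gm = pd.Series(group_map)
        unmapped = sorted(set(df["sample_id"]) - set(gm.index))
        if unmapped:
            raise DataError(f"samples missing from group map: {unmapped}")
        df["group"] = df["sample_id"].map(gm)
    elif "group" not in df.columns:
        raise DataError(f"Ct table {path} has no 'group' column and no group map given")
    return df[["sample_id", "group", "gene", "replicate", "ct"]]


def read_wide_ct(path, group_map) -> pd.DataFrame:
    """Read a wide genes x samples mean-Ct TSV into long-format records.

    Wide input has already-collapsed replicates; each cell becomes a single
    replicate-1 record so the long/wide routes share downstream code.
    """
    wide = pd.read_csv(path, sep="\t", index_col=0)
    if isinstance(group_map, (str, Path)):
        group_map = read_group_map(group_map)
    gm = pd.Series(group_map)
    long = (
        wide.rename_axis("gene")
        .reset_index()
        .melt(id_vars="gene", var_name="sample_id", value_name="ct")
    )
    long["replicate"] = 1
    unmapped = sorted(set(long["sample_id"]) - set(gm.index))
    if unmapped:
        raise DataError(f"samples missing from group map: {unmapped}")
    long["group"] = long["sample_id"].map(gm)
    long["ct"] = pd.to_numeric(long["ct"], errors="raise").astype(float)
    return long[["sample_id", "group", "gene", "replicate", "ct"]]


def collapse_replicates(records: pd.DataFrame, efficiency=None) -> CtMatrix:
    """Average technical replicates into a :class:`CtMatrix`.

    Cell value = arithmetic mean Ct of the replicates; replicate count and
    SD are kept as QC metadata and cells whose replicate SD exceeds
    ``REPLICATE_SD_FLAG`` cycles (or with a single replicate) are flagged.
    """
    for col in ("sample_id", "group", "gene", "replicate", "ct"):
        if col not in records.columns:
            raise DataError(f"records lack column {col!r}")
    grouped = records.groupby(["gene", "sample_id"])["ct"]
    mean = grouped.mean().unstack("sample_id")
    n = grouped.size().unstack("sample_id")
    sd = grouped.std(ddof=1).unstack("sample_id")

    groups = (
        records[["sample_id", "group"]]
        .drop_duplicates()
        .set_index("sample_id")["group"]
    )
    qc = pd.DataFrame(
        {
            "gene": np.repeat(mean.index, mean.shape[1]),
            "sample_id": np.tile(mean.columns, mean.shape[0]),
            "n_replicates": n.to_numpy().reshape(-1),
            "replicate_sd": sd.to_numpy().reshape(-1),
        }
    )
    qc["flag"] = (qc["replicate_sd"] > REPLICATE_SD_FLAG) | (qc["n_replicates"] == 1)
    # preserve input sample order rather than the groupby's lexical order
    order = [s for s in records["sample_id"].unique() if s in mean.columns]
    return CtMatrix(data=mean[order], groups=groups, efficiency=efficiency, qc=qc)


def filter_by_mean_ct(
    matrix: CtMatrix, threshold: float = 28.0, boundary: str = "exclude_equal"
):
    """Abundance filter on the per-gene grand-mean Ct.

    A gene is retained when its mean Ct over *all* biological samples is
    below *threshold* (high Ct = low abundance = unreliable quantification).
    ``boundary`` decides the tie at exactly the threshold:
    ``"exclude_equal"`` (default, mirrors 'retain mean Ct lower than 28') or
    ``"retain_equal"``.

    Returns ``(retained CtMatrix, excluded frame)`` where the excluded frame
    lists each dropped gene with its grand mean.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    if boundary not in ("exclude_equal", "retain_equal"):
        raise ConfigError("boundary must be 'exclude_equal' or 'retain_equal'")
    matrix.check_complete()
    grand = matrix.data.mean(axis=1)
    if boundary == "exclude_equal":
        keep = grand < threshold
    else:
        keep = grand <= threshold
    excluded = (
        pd.DataFrame({"grand_mean_ct": grand[~keep]})
        .rename_axis("gene")
        .sort_values("grand_mean_ct", ascending=False)
    )
    retained = matrix.subset(genes=list(matrix.data.index[keep]))
    return retained, excluded


def ct_to_log_quantity(matrix: CtMatrix) -> pd.DataFrame:
    """Convert Ct to log2 relative quantities.

    ``q_ij = log2(E_i) * (max_j' Ct_ij' - Ct_ij)``: each gene is anchored at
    its least-abundant sample (q = 0 there) and one cycle corresponds to
    ``log2 E`` doublings.  With E = 2 differences of q are exactly negated
    Ct differences, which makes the geNorm M value on q coincide with the
    comparative delta-Ct statistic on Ct.
    """
    matrix.check_complete()
    log2e = np.log2(matrix.efficiency.to_numpy())[:, None]
    ct = matrix.data.to_numpy()
    q = log2e * (ct.max(axis=1, keepdims=True) - ct)
    return pd.DataFrame(q, index=matrix.data.index.copy(), columns=matrix.data.columns.copy())


def overview_relative_expression(matrix: CtMatrix) -> pd.Series:
    """Fold change of each gene relative to the panel geometric mean.

    Per sample the reference Ct is the arithmetic mean over all panel genes
    (at E = 2 this is the geometric mean on the quantity scale); each gene's
    per-sample fold change ``2^-(Ct_gene - Ct_ref)`` is averaged over samples.
    Sorted descending — the panel's span shows the dynamic range of the
    candidates' abundances.
    """
    if matrix.data.shape[0] < 2:
        raise InsufficientDataError("overview needs >= 2 genes")
    matrix.check_complete()
    ct = matrix.data.to_numpy()
    ref = ct.mean(axis=0, keepdims=True)
    fold = np.power(2.0, -(ct - ref)).mean(axis=1)
    return pd.Series(fold, index=matrix.data.index, name="fold_change").sort_values(
        ascending=False
    )
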