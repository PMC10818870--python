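"""Tabular and graph I/O with strict validation.

Canonical on-disk dialect is TSV (tab-delimited, UTF-8, "." decimal, header
row, first column = ids), matching QIIME2 feature-table exports. Missing
phenotype values are encoded as "NA". Networks are written as GraphML or a
plain edge-list TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates a table contract."""


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are taxa, columns are samples. Non-negative.
    kind : {"counts", "relative"}
        ``relative`` requires every sample column to sum to 1 (+- 1e-9);
        all-zero columns are rejected for relative tables.
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValidationError(f"unknown table kind {self.kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric values in abundance table")
        if np.isnan(values).any():
            t, s = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"NaN at taxon {self.data.index[t]!r}, sample {self.data.columns[s]!r}")
        if (values < 0).any():
            t, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value {values[t, s]} at taxon {self.data.index[t]!r}, "
                f"sample {self.data.columns[s]!r}")
        if self.kind == "relative" and self.data.shape[0] > 0:
            sums = values.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                raise ValidationError(
                    f"relative table columns must sum to 1; sample "
                    f"{self.data.columns[bad[0]]!r} sums to {sums[bad[0]]}")

    @property
    def taxon_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return AbundanceTable(self.data.loc[:, list(sample_ids)].copy(), self.kind)


def read_abundance_table(path, orientation: str = "taxa_rows",
                         kind: str = "counts") -> AbundanceTable:
    """Read a TSV abundance table; orientation is normalized to taxa x samples."""
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValidationError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}")
        df[col] = coerced
    if orientation == "samples_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df, kind=kind)


def write_abundance_table(table: AbundanceTable, path) -> None:
    out = table.data.copy()
    out.index.name = out.index.name or "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata: first column sample_id, 'group' column required.

    Numeric phenotype columns use "NA" for missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    if "group" not in df.columns:
        raise ValidationError("metadata must contain a 'group' column")
    for col in df.columns:
        if col == "group":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric, non-NA value in phenotype column {col!r} "
                f"at sample {df.index[bad.argmax()]!r}")
        if np.isinf(vals.dropna()).any():
            raise ValidationError(f"non-finite value in phenotype column {col!r}")
        df[col] = vals
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square TSV distance matrix; validates symmetry and zero diagonal."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix row and column ids differ")
    m = df.to_numpy(dtype=float)
    if (m < 0).any():
        i, j = np.argwhere(m < 0)[0]
        raise ValidationError(
            f"negative distance at ({df.index[i]!r}, {df.columns[j]!r})")
    asym = np.abs(m - m.T)
    if asym.max(initial=0.0) > 1e-12:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"asymmetry at ({df.index[i]!r}, {df.columns[j]!r}): "
            f"{m[i, j]} vs {m[j, i]}")
    diag = np.flatnonzero(np.diag(m) != 0)
    if diag.size:
        raise ValidationError(
            f"nonzero diagonal at {df.index[diag[0]]!r}: {m[diag[0], diag[0]]}")
    return DistanceMatrix((m + m.T) / 2.0, ids=list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write a co-occurrence network.

    ``graphml`` keeps all node attributes (abundance, module, Zi, Pi, role)
    and the signed edge correlation; ``edgelist_tsv`` writes columns
    source, target, correlation.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edgelist_tsv":
        rows = [{"source": u, "target": v,
                 "correlation": d.get("correlation", np.nan)}
                for u, v, d in net.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "correlation"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_results_json(analysis: str, params: dict, results, path) -> None:
    """Results envelope: {"analysis": ..., "params": ..., "results": ...}."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump({"analysis": analysis, "params": params, "results": results},
                  fh, indent=2, default=_default)
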