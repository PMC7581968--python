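"""Readers and writers for the plain-text interchange formats.

All inputs and outputs are TSV (or one-symbol-per-line gene lists and GMT
annotation sets); matrices are dense with a header row of region names, or
long-format (region_a, region_b, weight) edge tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import Parcellation

__all__ = [
    "read_parcellation",
    "read_matrix",
    "write_matrix",
    "read_expression",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "read_cell_by_gene",
]


def read_parcellation(lookup_path, centroids_path=None) -> Parcellation:
    """Parcellation from a lookup TSV (region_id, name, hemisphere, class)
    and an optional centroid TSV (region_id, x, y, z)."""
    lut = pd.read_csv(lookup_path, sep="\t")
    cen = pd.read_csv(centroids_path, sep="\t") if centroids_path else None
    return Parcellation.from_tables(lut, cen)


def read_matrix(path, parcellation: Parcellation) -> np.ndarray:
    """Dense or long-format connectivity/length matrix ordered like the
    parcellation.

    Dense: region-name header row, one row per region. Long: columns
    (region_a, region_b, weight) naming regions; missing pairs are zero.
    """
    df = pd.read_csv(path, sep="\t")
    names = parcellation.regions["name"]
    if set(df.columns[:3]) >= {"region_a", "region_b", "weight"}:
        idx = pd.Series(names.index.to_numpy(), index=names.to_numpy())
        n = parcellation.n_regions
        w = np.zeros((n, n))
        ia = idx.loc[df["region_a"]].to_numpy()
        ib = idx.loc[df["region_b"]].to_numpy()
        w[ia, ib] = df["weight"].to_numpy(float)
        w[ib, ia] = df["weight"].to_numpy(float)
        return w
    if list(df.columns) != list(names):
        raise ValueError("matrix header does not match parcellation names")
    return df.to_numpy(float)


def write_matrix(path, matrix: np.ndarray, parcellation: Parcellation) -> None:
    names = parcellation.regions["name"].tolist()
    pd.DataFrame(matrix, columns=names).to_csv(path, sep="\t", index=False)


def read_expression(path, parcellation: Parcellation | None = None) -> pd.DataFrame:
    """Regions x genes expression TSV (first column = region id).

    Accepts the published regions-by-genes layout (e.g. the 180 x 15745
    left-hemisphere matrix); if a parcellation is given, region ids are
    checked against its left cortical regions.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(int)
    if df.isna().any().any():
        raise ValueError("expression matrix contains NaN")
    if parcellation is not None:
        allowed = set(parcellation.cortical_ids)
        extra = set(df.index) - allowed
        if extra:
            raise ValueError(f"{len(extra)} expression rows are not cortical regions")
    return df


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line."""
    lines = Path(path).read_text().splitlines()
    return [s.strip() for s in lines if s.strip()]


def write_gene_list(path, genes) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT annotation sets: name <tab> description <tab> gene1 <tab> ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_cell_by_gene(path, labels_path) -> tuple[pd.DataFrame, pd.Series]:
    """Cells x genes expression TSV plus a (cell, cell_type) labels TSV."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    return expr, labels
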