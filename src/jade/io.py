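"""Reading and writing slices and alignment results.

A slice is a set of spatial capture units ("spots"), each with a 2-D
coordinate and a gene-expression vector. Two on-disk layouts are supported:

* ``h5ad`` — an AnnData container with expression in ``X``, coordinates in
  ``obsm["spatial"]`` and (optionally) a categorical domain annotation in
  ``obs``.
* ``csv_mtx`` — a directory holding ``coords.csv`` (spot_id,x,y),
  ``expression.mtx`` (spots × genes, Matrix Market), ``genes.tsv`` and
  ``barcodes.tsv``, plus an optional ``labels.tsv``.

Transport plans are written as sparse Matrix Market files with row/column
barcode TSVs and a per-row argmax pairs table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "SliceData",
    "read_slice",
    "write_slice",
    "write_alignment",
    "read_alignment",
]

DEFAULT_LABEL_KEY = "domain"


@dataclass
class SliceData:
    """One slice: coordinates, expression and identifiers.

    ``expr`` holds raw counts straight after reading and normalised values
    after preprocessing; both are dense float arrays over the same spot order
    as ``coords``.
    """

    coords: np.ndarray
    expr: np.ndarray
    gene_ids: list = field(default_factory=list)
    spot_ids: list = field(default_factory=list)
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if sparse.issparse(self.expr):
            self.expr = np.asarray(self.expr.todense())
        self.expr = np.asarray(self.expr, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an n×2 array")
        if self.expr.ndim != 2:
            raise ValueError("expr must be an n×p matrix")
        if self.coords.shape[0] != self.expr.shape[0]:
            raise ValueError(
                f"coordinate rows ({self.coords.shape[0]}) do not match "
                f"expression rows ({self.expr.shape[0]})"
            )
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(self.expr.shape[1])]
        if not self.spot_ids:
            self.spot_ids = [f"spot_{i}" for i in range(self.expr.shape[0])]
        self.gene_ids = list(map(str, self.gene_ids))
        self.spot_ids = list(map(str, self.spot_ids))
        if len(self.gene_ids) != self.expr.shape[1]:
            raise ValueError("gene_ids length does not match expression columns")
        if len(self.spot_ids) != self.expr.shape[0]:
            raise ValueError("spot_ids length does not match expression rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n:
                raise ValueError("labels length does not match spot count")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite values in coords")
        if not np.isfinite(self.expr).all():
            raise ValueError("non-finite values in expr")

    @property
    def n(self) -> int:
        return self.expr.shape[0]

    @property
    def p(self) -> int:
        return self.expr.shape[1]


def read_slice(path: str, format: str = "auto", label_key: str = DEFAULT_LABEL_KEY) -> SliceData:
    """Read one slice from ``h5ad`` or a ``csv_mtx`` directory.

    ``format='auto'`` dispatches on the path: ``.h5ad`` files go through
    anndata, directories are treated as csv_mtx bundles.
    """
    if format == "auto":
        format = "h5ad" if str(path).endswith(".h5ad") else "csv_mtx"
    if format == "h5ad":
        return _read_h5ad(path, label_key)
    if format == "csv_mtx":
        return _read_csv_mtx(path, label_key)
    raise ValueError(f"unknown slice format: {format!r}")


def _read_h5ad(path: str, label_key: str) -> SliceData:
    import anndata as ad

    adata = ad.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise ValueError(f"{path}: no spatial coordinate slot (obsm['spatial'])")
    coords = np.asarray(adata.obsm["spatial"], dtype=np.float64)
    x = adata.X
    if sparse.issparse(x):
        x = np.asarray(x.todense())
    labels = None
    if label_key in adata.obs:
        labels = adata.obs[label_key].to_numpy()
    return SliceData(
        coords=coords,
        expr=np.asarray(x, dtype=np.float64),
        gene_ids=list(adata.var_names),
        spot_ids=list(adata.obs_names),
        labels=labels,
    )


def _read_csv_mtx(path: str, label_key: str) -> SliceData:
    coords_df = pd.read_csv(os.path.join(path, "coords.csv"))
    expr = spio.mmread(os.path.join(path, "expression.mtx"))
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=None)[0].tolist()
    expr = np.asarray(sparse.coo_matrix(expr).todense(), dtype=np.float64)
    if coords_df.shape[0] != expr.shape[0] or len(barcodes) != expr.shape[0]:
        raise ValueError(
            f"{path}: coordinate rows ({coords_df.shape[0]}) / barcodes "
            f"({len(barcodes)}) do not match expression rows ({expr.shape[0]})"
        )
    labels = None
    labels_path = os.path.join(path, "labels.tsv")
    if os.path.exists(labels_path):
        labels = pd.read_csv(labels_path, sep="\t", header=None)[0].to_numpy()
    return SliceData(
        coords=coords_df[["x", "y"]].to_numpy(dtype=np.float64),
        expr=expr,
        gene_ids=genes,
        spot_ids=[str(b) for b in barcodes],
        labels=labels,
    )


def write_slice(sl: SliceData, path: str, format: str = "csv_mtx") -> None:
    """Write a slice in either supported layout."""
    if format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(X=sl.expr.copy())
        adata.obs_names = sl.spot_ids
        adata.var_names = sl.gene_ids
        adata.obsm["spatial"] = sl.coords.copy()
        if sl.labels is not None:
            adata.obs[DEFAULT_LABEL_KEY] = pd.Categorical(sl.labels.astype(str))
        adata.write_h5ad(path)
        return
    if format != "csv_mtx":
        raise ValueError(f"unknown slice format: {format!r}")
    os.makedirs(path, exist_ok=True)
    pd.DataFrame(
        {"spot_id": sl.spot_ids, "x": sl.coords[:, 0], "y": sl.coords[:, 1]}
    ).to_csv(os.path.join(path, "coords.csv"), index=False)
    spio.mmwrite(os.path.join(path, "expression.mtx"), sparse.coo_matrix(sl.expr))
    pd.Series(sl.gene_ids).to_csv(
        os.path.join(path, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(sl.spot_ids).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    if sl.labels is not None:
        pd.Series(sl.labels).to_csv(
            os.path.join(path, "labels.tsv"), sep="\t", index=False, header=False
        )


def write_alignment(plan, ids_a: Sequence[str], ids_b: Sequence[str], path: str,
                    floor: float = 0.0) -> None:
    """Write a transport plan Π plus barcode lists and an argmax pairs table.

    Entries with mass strictly below ``floor`` are dropped from the sparse
    file. The pairs table records, per slice-1 spot, its highest-mass slice-2
    partner and the transported mass.
    """
    pi = np.asarray(getattr(plan, "pi", plan), dtype=np.float64)
    if pi.shape != (len(ids_a), len(ids_b)):
        raise ValueError(
            f"plan shape {pi.shape} does not match identifier lists "
            f"({len(ids_a)}, {len(ids_b)})"
        )
    os.makedirs(path, exist_ok=True)
    kept = np.where(pi >= floor, pi, 0.0) if floor > 0 else pi
    spio.mmwrite(os.path.join(path, "plan.mtx"), sparse.coo_matrix(kept))
    pd.Series(list(ids_a)).to_csv(
        os.path.join(path, "rows.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(list(ids_b)).to_csv(
        os.path.join(path, "cols.tsv"), sep="\t", index=False, header=False
    )
    j_star = pi.argmax(axis=1)
    pd.DataFrame(
        {
            "spot_a": list(ids_a),
            "spot_b": [ids_b[j] for j in j_star],
            "mass": pi[np.arange(pi.shape[0]), j_star],
        }
    ).to_csv(os.path.join(path, "pairs.tsv"), sep="\t", index=False)


def read_alignment(path: str) -> np.ndarray:
    """Read back a plan written by :func:`write_alignment` as a dense array."""
    return np.asarray(
        sparse.coo_matrix(spio.mmread(os.path.join(path, "plan.mtx"))).todense(),
        dtype=np.float64,
    )
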