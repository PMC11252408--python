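"""Readers and writers for the formats the pipeline touches.

Single-cell data comes in as either an MTX triplet directory
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` + a ``cell_types.tsv``
label sidecar) or an HDF5 single-cell container (``.h5ad``); bulk samples
as a TSV/CSV table with a gene-ID first column and one numeric column per
sample.  The HDF5 dialect is the community AnnData layout (X, obs, var,
layers), so third-party viewers open the files directly.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import (AnnotatedExpressionMatrix, BulkProfile, RunConfig,
                        ValidationError)

__all__ = ["read_single_cell", "write_single_cell", "read_bulk_counts",
           "write_bulk_counts", "write_augmented", "to_anndata",
           "from_anndata", "match_genes"]

INTERPOLATED_KEY = "interpolated"


# ---------------------------------------------------------------------------
# AnnData bridging
# ---------------------------------------------------------------------------

def to_anndata(matrix: AnnotatedExpressionMatrix) -> ad.AnnData:
    """Convert to the community single-cell container."""
    obs = pd.DataFrame(index=pd.Index(matrix.cell_ids, name="cell_id"))
    obs["cell_type"] = pd.Categorical(matrix.cell_type.astype(str))
    interp = matrix.provenance.get(INTERPOLATED_KEY)
    obs[INTERPOLATED_KEY] = (np.zeros(matrix.n_cells, dtype=bool)
                             if interp is None else np.asarray(interp, dtype=bool))
    var = pd.DataFrame(index=pd.Index(matrix.gene_ids, name="gene_id"))
    adata = ad.AnnData(X=matrix.counts.copy(), obs=obs, var=var)
    for name, layer in matrix.layers.items():
        adata.layers[name] = layer.copy()
    if matrix.embedding is not None:
        adata.obsm["X_pca"] = np.asarray(matrix.embedding)
    if matrix.pseudotime is not None:
        adata.obs["pseudotime"] = np.asarray(matrix.pseudotime, dtype=float)
    uns_prov = {k: v for k, v in matrix.provenance.items()
                if k != INTERPOLATED_KEY and _h5_serializable(v)}
    adata.uns["provenance"] = uns_prov
    return adata


def _h5_serializable(v) -> bool:
    if isinstance(v, (str, int, float, bool, np.ndarray, type(None))):
        return v is not None
    if isinstance(v, (list, tuple)):
        return all(_h5_serializable(x) for x in v)
    if isinstance(v, dict):
        return all(isinstance(k, str) and _h5_serializable(x) for k, x in v.items())
    return False


def from_anndata(adata: ad.AnnData) -> AnnotatedExpressionMatrix:
    if "cell_type" not in adata.obs:
        raise ValidationError("labels required: obs column 'cell_type' missing")
    X = adata.X
    counts = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))
    prov = dict(adata.uns.get("provenance", {}))
    if INTERPOLATED_KEY in adata.obs:
        prov[INTERPOLATED_KEY] = adata.obs[INTERPOLATED_KEY].to_numpy(dtype=bool)
    if "cell_type_order" in adata.uns:
        prov["cell_type_order"] = list(adata.uns["cell_type_order"])
    return AnnotatedExpressionMatrix(
        counts=counts,
        gene_ids=list(adata.var_names),
        cell_ids=list(adata.obs_names),
        cell_type=adata.obs["cell_type"].astype(str).to_numpy(dtype=object),
        layers={k: (v.tocsr() if sp.issparse(v) else np.asarray(v))
                for k, v in adata.layers.items()},
        embedding=np.asarray(adata.obsm["X_pca"]) if "X_pca" in adata.obsm else None,
        pseudotime=(adata.obs["pseudotime"].to_numpy(dtype=float)
                    if "pseudotime" in adata.obs else None),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# single-cell I/O
# ---------------------------------------------------------------------------

def read_single_cell(path, format: str | None = None) -> AnnotatedExpressionMatrix:
    """Read a single-cell profile.

    ``format`` is ``"mtx_triplet"`` (a directory with matrix.mtx,
    genes.tsv, barcodes.tsv and a cell_types.tsv label sidecar, genes in
    MTX rows as in the common convention) or ``"h5_container"`` (an
    ``.h5ad`` file).  Inferred from the path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx_triplet" if path.is_dir() else "h5_container"
    if format == "h5_container":
        return from_anndata(ad.read_h5ad(path))
    if format != "mtx_triplet":
        raise ValueError(f"unknown format {format!r}")

    mtx = path / "matrix.mtx"
    genes_f = path / "genes.tsv"
    barcodes_f = path / "barcodes.tsv"
    labels_f = path / "cell_types.tsv"
    for f in (mtx, genes_f, barcodes_f):
        if not f.exists():
            raise ValidationError(f"MTX triplet incomplete: missing {f.name}")
    if not labels_f.exists():
        raise ValidationError("labels required: cell_types.tsv sidecar missing")

    mat = sp.csr_matrix(scipy.io.mmread(mtx)).T  # genes x cells on disk
    genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str).tolist()
    labels = pd.read_csv(labels_f, sep="\t", header=None)[0].astype(str).to_numpy(dtype=object)
    if mat.shape[0] != len(barcodes) or mat.shape[1] != len(genes):
        raise ValidationError(
            f"dimension mismatch: matrix is {mat.shape[1]} genes x "
            f"{mat.shape[0]} cells but sidecars list {len(genes)} genes / "
            f"{len(barcodes)} barcodes")
    if len(labels) != len(barcodes):
        raise ValidationError("cell_types.tsv row count != number of barcodes")
    return AnnotatedExpressionMatrix(
        counts=mat, gene_ids=genes, cell_ids=barcodes, cell_type=labels,
        provenance={"source": str(path)})


def write_single_cell(matrix: AnnotatedExpressionMatrix, path,
                      format: str | None = None) -> None:
    """Write a profile as an MTX triplet directory or an ``.h5ad`` file."""
    path = Path(path)
    if format is None:
        format = "h5_container" if path.suffix == ".h5ad" else "mtx_triplet"
    if format == "h5_container":
        _write_h5(matrix, path)
        return
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), matrix.counts.T.tocoo())
    pd.Series(matrix.gene_ids).to_csv(path / "genes.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(matrix.cell_type.astype(str)).to_csv(
        path / "cell_types.tsv", sep="\t", header=False, index=False)


def _write_h5(matrix: AnnotatedExpressionMatrix, path: Path,
              config: RunConfig | None = None) -> None:
    adata = to_anndata(matrix)
    # preserve the category order of the label column across round-trips
    adata.uns["cell_type_order"] = list(
        matrix.provenance.get("cell_type_order",
                              adata.obs["cell_type"].cat.categories))
    if config is not None:
        adata.uns["run_config"] = {k: ("" if v is None else v)
                                   for k, v in config.as_dict().items()}
    path.parent.mkdir(parents=True, exist_ok=True)
    adata.write_h5ad(path)


def write_augmented(matrix: AnnotatedExpressionMatrix, path,
                    config: RunConfig | None = None) -> None:
    """Write an augmented profile (with per-cell ``interpolated`` flags and
    the run configuration) as an HDF5 container re-readable by
    :func:`read_single_cell`."""
    if matrix.n_cells == 0:
        raise ValidationError("empty profile")
    _write_h5(matrix, Path(path), config=config)


# ---------------------------------------------------------------------------
# bulk I/O
# ---------------------------------------------------------------------------

def read_bulk_counts(path) -> list[BulkProfile]:
    """Read a bulk count table (gene-ID first column, one numeric column per
    sample) into one :class:`BulkProfile` per sample, state ``raw``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    genes = df.index.astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()][0]
        raise ValidationError(f"duplicate gene IDs in bulk table (e.g. {dup!r})")
    profiles = []
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df[col][vals.isna()].iloc[0]
            raise ValueError(f"non-numeric entry {bad!r} in sample {col!r}")
        if (vals < 0).any():
            raise ValueError(f"negative entry in sample {col!r}")
        profiles.append(BulkProfile(list(genes), vals.to_numpy(dtype=float),
                                    state="raw", sample_id=str(col)))
    return profiles


def write_bulk_counts(profiles: list[BulkProfile], path) -> None:
    path = Path(path)
    genes = profiles[0].gene_ids
    for p in profiles[1:]:
        if p.gene_ids != genes:
            raise ValidationError("bulk profiles must share a gene universe")
    df = pd.DataFrame({p.sample_id: p.values for p in profiles},
                      index=pd.Index(genes, name="gene_id"))
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# gene-universe reconciliation
# ---------------------------------------------------------------------------

def match_genes(matrix: AnnotatedExpressionMatrix, bulk: BulkProfile,
                ) -> tuple[AnnotatedExpressionMatrix, BulkProfile, int]:
    """Intersect the bulk and single-cell gene universes by exact gene-ID
    string match, order taken from the single-cell reference.  Returns the
    restricted matrix and profile plus the number of genes dropped from
    either side."""
    bulk_set = set(bulk.gene_ids)
    shared = [g for g in matrix.gene_ids if g in bulk_set]
    if not shared:
        raise ValidationError("no shared genes between bulk and single-cell data")
    dropped = (len(matrix.gene_ids) - len(shared)) + (len(bulk.gene_ids) - len(shared))
    if dropped == 0:
        return matrix, bulk.reindex(list(matrix.gene_ids)), 0
    gidx = {g: i for i, g in enumerate(matrix.gene_ids)}
    cols = [gidx[g] for g in shared]
    sub = AnnotatedExpressionMatrix(
        counts=matrix.counts[:, cols],
        gene_ids=shared,
        cell_ids=list(matrix.cell_ids),
        cell_type=matrix.cell_type.copy(),
        layers={k: v[:, cols] for k, v in matrix.layers.items()},
        embedding=matrix.embedding,
        pseudotime=matrix.pseudotime,
        provenance=dict(matrix.provenance),
    )
    return sub, bulk.reindex(shared), dropped
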