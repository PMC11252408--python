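"""Quality control, normalization and PCA embedding.

Single cells are filtered on total counts (< 1000 removed) and
mitochondrial fraction (> 0.2 removed), then normalized per cell to a
fixed target sum and log1p-transformed into a ``"lognorm"`` layer — raw
counts are kept alongside because the fraction autoencoder trains on raw
counts while the generative model trains on the normalized layer.  Bulk
samples are normalized with DESeq2-style median-of-ratios size factors and
log1p.  The PCA embedding (unit-scaled genes, 50 components by default)
feeds the neighbourhood-graph stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .datamodel import AnnotatedExpressionMatrix, BulkProfile, ValidationError

__all__ = ["QCReport", "qc_filter", "normalize_log1p", "normalize_bulk",
           "pca_embed"]


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_kept: int
    n_removed_low_counts: int
    n_removed_mito: int
    min_counts: int
    max_mito: float

    def __post_init__(self):
        if self.n_cells_kept + self.n_removed_low_counts + self.n_removed_mito \
                != self.n_cells_in:
            raise ValidationError("QC report does not conserve cells")


def qc_filter(matrix: AnnotatedExpressionMatrix, min_counts: int = 1000,
              max_mito: float = 0.2, mito_prefix: str = "MT-",
              ) -> tuple[AnnotatedExpressionMatrix, QCReport]:
    """Remove cells with total counts < ``min_counts`` or mitochondrial
    fraction > ``max_mito`` (both bounds strict; a cell at exactly the
    threshold is kept).  The mitochondrial fraction is the count share of
    genes whose ID starts with ``mito_prefix`` (case-insensitive)."""
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    mito_genes = np.array([g.upper().startswith(mito_prefix.upper())
                           for g in matrix.gene_ids])
    if mito_genes.any():
        mito_counts = np.asarray(matrix.counts[:, mito_genes].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    else:
        mito_frac = np.zeros(matrix.n_cells)

    low = totals < min_counts
    high_mito = (mito_frac > max_mito) & ~low  # count each removal once
    keep = ~low & ~high_mito
    if not keep.any():
        raise ValidationError("empty after QC")
    report = QCReport(
        n_cells_in=matrix.n_cells,
        n_cells_kept=int(keep.sum()),
        n_removed_low_counts=int(low.sum()),
        n_removed_mito=int(high_mito.sum()),
        min_counts=min_counts, max_mito=max_mito,
    )
    return matrix.subset_cells(keep), report


def normalize_log1p(matrix: AnnotatedExpressionMatrix,
                    target_sum: float = 1e4) -> AnnotatedExpressionMatrix:
    """Attach a ``"lognorm"`` layer: log(1 + target_sum * count / cell_total).

    Raw counts stay untouched in ``counts``.  Row totals satisfy
    ``expm1(lognorm_row).sum() == target_sum`` for every cell.
    """
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValidationError("zero-total cell encountered; run qc_filter first")
    scaled = sp.diags(target_sum / totals) @ matrix.counts.tocsr()
    lognorm = scaled.copy()
    lognorm.data = np.log1p(lognorm.data)
    out = matrix.copy()
    out.layers["lognorm"] = lognorm.tocsr()
    return out


def normalize_bulk(profiles: list[BulkProfile]) -> list[BulkProfile]:
    """Median-of-ratios size-factor normalization followed by log1p.

    The size factor of a sample is the median, over genes with a nonzero
    geometric mean across samples, of the ratio of the sample's value to
    that geometric mean.  A single sample gets factor 1.
    """
    if not profiles:
        return []
    genes = profiles[0].gene_ids
    for p in profiles:
        if p.state != "raw":
            raise ValidationError("bulk normalization expects raw profiles")
        if p.gene_ids != genes:
            raise ValidationError("bulk profiles must share a gene universe")
    vals = np.stack([p.values for p in profiles])  # samples x genes
    if len(profiles) == 1:
        factors = np.ones(1)
    else:
        positive = (vals > 0).all(axis=0)
        if not positive.any():
            raise ValidationError("size factors undefined: no gene nonzero in all samples")
        log_geo = np.log(vals[:, positive]).mean(axis=0)
        ratios = np.log(vals[:, positive]) - log_geo
        factors = np.exp(np.median(ratios, axis=1))
    return [BulkProfile(list(genes), np.log1p(p.values / f), state="log1p",
                        sample_id=p.sample_id)
            for p, f in zip(profiles, factors)]


def pca_embed(matrix: AnnotatedExpressionMatrix, n_components: int = 50,
              scale: bool = True, seed: int = 0) -> AnnotatedExpressionMatrix:
    """Set the embedding to the top principal-component scores of the
    (centered, optionally unit-scaled) lognorm layer.

    The sign of each component is fixed by forcing its largest-magnitude
    loading positive, so results are deterministic.  ``n_components`` is
    clipped to the data rank with a warning when too large.
    """
    if "lognorm" not in matrix.layers:
        raise ValidationError("lognorm layer required; run normalize_log1p first")
    X = matrix.layers["lognorm"]
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    max_rank = min(matrix.n_cells - 1, matrix.n_genes)
    if n_components > max_rank:
        warnings.warn(f"n_components={n_components} clipped to data rank {max_rank}")
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(pca.components_[np.arange(n_components),
                                   np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    out = matrix.copy()
    out.embedding = scores * flip
    out.provenance["pca_explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out
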