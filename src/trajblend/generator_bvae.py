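"""Fraction-constrained beta-VAE for candidate single-cell generation.

The model learns a generative latent space of the reference single cells
from their normalized (lognorm) expression.  The encoder outputs a
Gaussian posterior (mu, logvar); the first M latent coordinates double as
the fraction head V (a per-cell softmax trained toward the cell's one-hot
label by mean absolute error, so batch-averaged V tracks the dataset's
cell-type fractions), while the remaining coordinates form an
unconstrained subspace where the per-type generative factor W stays
entangled.  The objective is the beta-weighted evidence lower bound — a
Gaussian reconstruction term plus beta times the KL divergence of the
posterior from the isotropic unit-Gaussian prior (beta > 1 encourages
disentangling) — plus the fraction penalty.

After training, W for each cell type is the mean posterior mean over that
type's cells.  Generation decodes z = W_type with Gaussian perturbation on
the unconstrained subspace, allocating cells per type proportionally to
the bulk-derived fraction state, with the target type scaled to a multiple
of its reference abundance.  Generated profiles are denoised by Leiden
clustering: clusters below a size floor are discarded as generator noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scanpy as sc
import scipy.sparse as sp

from ._nn import Adam, Linear, relu, relu_grad, softmax, softmax_jvp_rows
from .datamodel import (AnnotatedExpressionMatrix, CellFractionVector,
                        RunConfig, ValidationError)
from .synthetic import _largest_remainder

__all__ = ["BetaVAEModel", "GenerativeFactorTable", "NoiseFilterReport",
           "kl_gaussian", "train_beta_vae", "extract_type_factors",
           "generate_cells", "filter_noise_clusters"]


def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL divergence of N(mu, diag(exp(logvar))) from the unit Gaussian:
    0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2).  Nonnegative."""
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    return float(0.5 * np.sum(mu ** 2 + np.exp(logvar) - 1.0 - logvar))


def _dense_lognorm(matrix: AnnotatedExpressionMatrix) -> np.ndarray:
    if "lognorm" not in matrix.layers:
        raise ValidationError("lognorm layer required; run normalize_log1p first")
    X = matrix.layers["lognorm"]
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


@dataclass
class GenerativeFactorTable:
    """Per-type generative factors: W row m is the mean posterior mean over
    cells of type m, ``sd`` the per-dimension spread of those posterior
    means (the within-type variation the generator resamples), and
    ``n_cells`` each type's reference abundance."""

    cell_types: list[str]
    W: np.ndarray  # M x latent_dim
    sd: np.ndarray | None = None  # M x latent_dim
    n_cells: dict = field(default_factory=dict)

    def row(self, cell_type: str) -> np.ndarray:
        try:
            return self.W[self.cell_types.index(cell_type)]
        except ValueError:
            raise KeyError(f"no generative factor for type {cell_type!r}") from None

    def sd_row(self, cell_type: str) -> np.ndarray | None:
        if self.sd is None:
            return None
        return self.sd[self.cell_types.index(cell_type)]


@dataclass
class NoiseFilterReport:
    n_clusters_total: int
    n_noise_clusters: int
    cells_removed: int
    resolution: float
    min_cells: int
    cluster_sizes: dict = field(default_factory=dict)


@dataclass
class BetaVAEModel:
    """Trained fraction-constrained beta-VAE."""

    gene_ids: list[str]
    cell_types: list[str]
    latent_dim: int
    beta: float
    layers: dict = field(repr=False, default_factory=dict)
    history: dict = field(default_factory=dict)
    config: RunConfig = field(default_factory=RunConfig)
    seed: int = 0
    # per-gene overdispersion of the reference on the depth-normalised
    # count scale (var = mu + phi * mu^2), used by the generator so that
    # emitted cells carry the same noise footprint as real ones
    gene_dispersion: np.ndarray | None = None

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def _params(self):
        return [p for lay in self.layers.values() for p in lay.params]

    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log-variance for each row of X."""
        L = self.layers
        h = relu(L["enc1"](X))
        return L["mu"](h), np.clip(L["logvar"](h), -10.0, 10.0)

    def fraction_head(self, mu: np.ndarray) -> np.ndarray:
        """Per-cell simplex V: softmax over the first M latent means."""
        return softmax(mu[:, :self.n_types])

    def decode(self, Z: np.ndarray) -> np.ndarray:
        L = self.layers
        return L["dec_out"](relu(L["dec1"](Z)))


def train_beta_vae(ref: AnnotatedExpressionMatrix,
                   config: RunConfig | None = None) -> BetaVAEModel:
    """Train the beta-VAE on the reference's lognorm layer.

    Per-cell loss = 0.5*||x - xhat||^2 + beta * KL(q(z|x) || N(0, I))
    + lambda_v * |V - onehot(label)|_1, averaged over the batch, optimised
    with Adam and the reparameterisation trick.  Set ``beta=0`` together
    with ``generation_noise=0`` to recover a plain autoencoder.
    Deterministic given ``config.seed``.
    """
    config = config or RunConfig()
    X = _dense_lognorm(ref)
    types = ref.cell_types
    m = len(types)
    d = config.resolved_latent_dim(m)
    n, g = X.shape
    onehot = np.zeros((n, m))
    onehot[np.arange(n), [types.index(t) for t in ref.cell_type]] = 1.0

    init = np.random.default_rng(config.seed + 2)
    h = config.hidden_units
    model = BetaVAEModel(
        gene_ids=list(ref.gene_ids), cell_types=types, latent_dim=d,
        beta=config.beta, config=config, seed=config.seed,
        layers={
            "enc1": Linear(init, g, h),
            "mu": Linear(init, h, d),
            "logvar": Linear(init, h, d),
            "dec1": Linear(init, d, h),
            "dec_out": Linear(init, h, g),
        },
        history={"reconstruction": [], "kl": [], "fraction_mae": []},
    )
    model.gene_dispersion = _estimate_gene_dispersion(X, ref.cell_type, types)
    L = model.layers
    opt = Adam(model._params(), lr=config.vae_learning_rate)
    rng = np.random.default_rng(config.seed + 3)
    bs = min(config.vae_batch_size, n)
    sample_latent = config.generation_noise > 0 or config.beta > 0

    for epoch in range(config.vae_epochs):
        order = rng.permutation(n)
        rec_e, kl_e, fr_e = [], [], []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            x, y = X[idx], onehot[idx]
            nb = len(idx)
            opt.zero_grad()

            z0 = L["enc1"](x); h1 = relu(z0)
            mu = L["mu"](h1)
            logvar = np.clip(L["logvar"](h1), -10.0, 10.0)
            std = np.exp(0.5 * logvar)
            eps = rng.standard_normal(mu.shape) if sample_latent else 0.0
            z = mu + eps * std

            zd = L["dec1"](z); hd = relu(zd)
            xhat = L["dec_out"](hd)

            V = softmax(mu[:, :m])
            recon = 0.5 * np.sum((xhat - x) ** 2) / nb
            kl = kl_gaussian(mu, logvar) / nb
            fmae = float(np.abs(V - y).sum() / nb)
            if not np.isfinite(recon + kl + fmae):
                raise ValidationError(f"NaN loss at epoch {epoch}")

            # backprop (all terms averaged over the batch)
            gx = (xhat - x) / nb
            gq = L["dec_out"].backward(gx)
            gz = L["dec1"].backward(relu_grad(gq, zd))

            gmu = gz + config.beta * mu / nb
            glogvar = (gz * (eps * 0.5 * std) if sample_latent else 0.0) \
                + config.beta * 0.5 * (np.exp(logvar) - 1.0) / nb
            # fraction-head gradient taken directly on the logits (the
            # softmax cross-entropy form, minimised exactly at V = y and
            # immune to the vanishing gradient of saturated softmax
            # coordinates); the tracked metric stays the MAE
            gmu[:, :m] += config.lambda_v * (V - y) / nb

            gh = L["mu"].backward(gmu) + L["logvar"].backward(np.asarray(glogvar))
            L["enc1"].backward(relu_grad(gh, z0))
            opt.step()

            rec_e.append(recon); kl_e.append(kl); fr_e.append(fmae)
        model.history["reconstruction"].append(float(np.mean(rec_e)))
        model.history["kl"].append(float(np.mean(kl_e)))
        model.history["fraction_mae"].append(float(np.mean(fr_e)))
    return model


def _estimate_gene_dispersion(lognorm: np.ndarray, labels: np.ndarray,
                              types: list[str]) -> np.ndarray:
    """Method-of-moments per-gene overdispersion on the depth-normalised
    count scale, pooled within cell types (so genuine between-type marker
    structure does not masquerade as noise): var = mu + phi * mu^2."""
    norm_counts = np.expm1(lognorm)
    num = np.zeros(lognorm.shape[1])
    den = np.zeros(lognorm.shape[1])
    for t in types:
        sub = norm_counts[labels == t]
        if len(sub) < 2:
            continue
        mu = sub.mean(axis=0)
        var = sub.var(axis=0)
        w = len(sub)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_t = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
        num += w * np.maximum(phi_t, 0.0)
        den += w
    return num / np.maximum(den, 1.0)


def extract_type_factors(model: BetaVAEModel, ref: AnnotatedExpressionMatrix,
                         ) -> GenerativeFactorTable:
    """Average the posterior means per cell type to get the generative
    factor table W (one row per type present in ``ref``)."""
    X = _dense_lognorm(ref)
    mu, _ = model.encode(X)
    rows, sds, kept, counts = [], [], [], {}
    for t in model.cell_types:
        idx = np.where(ref.cell_type == t)[0]
        if len(idx) == 0:
            warnings.warn(f"type {t!r} has no cells in the reference; excluded")
            continue
        rows.append(mu[idx].mean(axis=0))
        sds.append(mu[idx].std(axis=0) if len(idx) > 1
                   else np.zeros(mu.shape[1]))
        kept.append(t)
        counts[t] = int(len(idx))
    return GenerativeFactorTable(kept, np.vstack(rows), np.vstack(sds), counts)


def generate_cells(model: BetaVAEModel, factors: GenerativeFactorTable,
                   fractions: CellFractionVector, target_type: str | None = None,
                   scale: float = 2.0, n_cells: int | None = None,
                   seed: int = 0) -> AnnotatedExpressionMatrix:
    """Generate candidate cells under the bulk-derived fraction state.

    Cells are allocated to types proportionally to ``fractions`` (largest
    remainder, so the allocation sums exactly to ``n_cells``); when a
    ``target_type`` is given its allocation is overridden to
    ``round(scale * reference abundance)`` — the interpolation-scale rule.
    Each cell decodes z = W_type plus Gaussian noise scaled, per latent
    dimension, by the type's empirical posterior spread (falling back to a
    flat sd of ``config.generation_noise`` on the unconstrained subspace
    when the factor table carries no spread), so a transitional type whose
    latent code varies along a mixing continuum is regenerated as a
    continuum rather than a point mass.  Counts are sampled per gene from
    a Poisson whose mean is expm1 of the decoded lognorm value (floored at
    zero): emitting the decoded mean itself would place every generated
    cell at the noise-free centroid of its type, where it turns into a
    nearest-neighbour hub and distorts the downstream graph; Poisson
    sampling puts generated cells on the same sampling-noise manifold as
    real cells.  Deterministic given ``seed``.
    """
    shared = [t for t in fractions.cell_types if t in factors.cell_types]
    if target_type is not None and target_type not in shared:
        raise ValidationError(
            f"target absent from state space: {target_type!r} has no "
            "fraction mass or no generative factor row")
    if n_cells is None:
        n_cells = sum(factors.n_cells.values()) or 1000
    fr = np.array([fractions[t] for t in shared], dtype=float)
    if fr.sum() <= 0:
        raise ValidationError("fraction state is empty on the shared types")
    fr = fr / fr.sum()
    alloc = dict(zip(shared, _largest_remainder(fr * n_cells, int(n_cells))))
    if target_type is not None:
        ref_abund = factors.n_cells.get(target_type, 0)
        alloc[target_type] = int(round(scale * ref_abund))

    rng = np.random.default_rng(seed)
    m = model.n_types
    blocks, labels = [], []
    for t in shared:
        k = alloc[t]
        if k == 0:
            continue
        Z = np.tile(factors.row(t), (k, 1))
        sd = factors.sd_row(t)
        if sd is not None:
            Z += sd * rng.standard_normal((k, model.latent_dim))
        else:
            noise = rng.standard_normal((k, model.latent_dim - m))
            Z[:, m:] += model.config.generation_noise * noise
        lognorm = model.decode(Z)
        blocks.append(lognorm)
        labels += [t] * k
    if not blocks:
        raise ValidationError("no cells allocated for generation")
    decoded_mean = np.expm1(np.maximum(np.vstack(blocks), 0.0))
    if model.gene_dispersion is not None and np.any(model.gene_dispersion > 0):
        # gamma-Poisson emission reproducing the reference's per-gene
        # overdispersion (var = mu + phi mu^2)
        phi = np.maximum(model.gene_dispersion, 0.0)
        shape = np.where(phi > 0, 1.0 / np.maximum(phi, 1e-12), np.inf)
        lam = np.where(phi > 0,
                       rng.gamma(np.broadcast_to(shape, decoded_mean.shape),
                                 np.maximum(phi * decoded_mean, 1e-30)),
                       decoded_mean)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = rng.poisson(decoded_mean).astype(float)
    totals = np.maximum(counts.sum(axis=1, keepdims=True), 1.0)
    target_sum = model.config.target_sum
    lognorm = np.log1p(target_sum * counts / totals)
    return AnnotatedExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=list(model.gene_ids),
        cell_ids=[f"generated_{i}" for i in range(len(labels))],
        cell_type=np.array(labels, dtype=object),
        layers={"lognorm": lognorm},
        provenance={"source": "beta_vae", "seed": seed,
                    "target_type": "" if target_type is None else target_type,
                    "scale": float(scale)},
    )


def filter_noise_clusters(generated: AnnotatedExpressionMatrix,
                          resolution: float = 1.0, min_cells: int = 25,
                          labels: np.ndarray | None = None, seed: int = 0,
                          ) -> tuple[AnnotatedExpressionMatrix, NoiseFilterReport]:
    """Discard generator-noise clusters.

    Leiden-clusters the generated profile (PCA on lognorm, kNN graph) at
    the given resolution and removes every cluster with fewer than
    ``min_cells`` members (strict: a cluster of exactly ``min_cells`` is
    kept).  A precomputed per-cell ``labels`` array bypasses clustering.
    ``min_cells=0`` is the identity.
    """
    if labels is None:
        labels = _leiden_labels(generated, resolution, seed)
    labels = np.asarray(labels)
    if len(labels) != generated.n_cells:
        raise ValidationError("cluster labels length mismatch")
    uniq, counts = np.unique(labels, return_counts=True)
    sizes = dict(zip(uniq.tolist(), counts.tolist()))
    noise = {u for u, c in sizes.items() if c < min_cells}
    keep = ~np.isin(labels, list(noise)) if noise else np.ones(len(labels), bool)
    if not keep.any():
        raise ValidationError("all generated cells are noise")
    report = NoiseFilterReport(
        n_clusters_total=len(uniq), n_noise_clusters=len(noise),
        cells_removed=int((~keep).sum()), resolution=resolution,
        min_cells=min_cells, cluster_sizes={str(k): v for k, v in sizes.items()})
    return generated.subset_cells(keep), report


def _leiden_labels(matrix: AnnotatedExpressionMatrix, resolution: float,
                   seed: int) -> np.ndarray:
    X = _dense_lognorm(matrix)
    adata = ad.AnnData(X=X)
    n_comps = min(50, matrix.n_cells - 1, matrix.n_genes - 1)
    sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(15, matrix.n_cells - 1),
                    random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="leidenalg")
    return adata.obs["leiden"].to_numpy()
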