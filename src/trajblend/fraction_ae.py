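"""Cell-type fraction estimation from bulk RNA-seq with an autoencoder.

Training data are pseudo-bulk mixtures of the labelled single-cell
reference: the encoder maps a bulk expression vector to a simplex vector T
of cell-type proportions (trained toward the realized mixing fractions by
mean absolute error), and the decoder maps T back to the bulk vector G
(trained toward the input by mean absolute error).  After convergence the
real bulk sample is fed through the model; a short adaptation phase
fine-tunes on the reconstruction term alone so the pretrained decoder's
generation aligns with the real sample, and the encoder output is read off
as the bulk's cell-type fraction state.

Both encoder and decoder are two-hidden-layer perceptrons (64 units by
default).  Raw counts are used throughout this stage; internally each bulk
vector is library-size scaled and log1p-compressed purely as feature
conditioning, which leaves the estimated proportions invariant to
sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Linear, relu, relu_grad, softmax, softmax_jvp_rows
from .datamodel import (AnnotatedExpressionMatrix, BulkProfile,
                        CellFractionVector, RunConfig, ValidationError)
from .synthetic import make_pseudobulk

__all__ = ["FractionAEModel", "build_celltype_matrix", "train_fraction_ae",
           "estimate_real_fractions"]


def build_celltype_matrix(ref: AnnotatedExpressionMatrix,
                          ) -> tuple[np.ndarray, BulkProfile]:
    """Aggregate raw counts by cell type.

    Returns the N_genes x M cell-type signature matrix (column m = summed
    counts over cells of type m, types in sorted label order) and the
    simulated bulk profile formed by its row sums — exactly the per-gene
    total counts of the reference.  Integer arithmetic throughout.
    """
    types = ref.cell_types
    mat = np.zeros((ref.n_genes, len(types)))
    for j, t in enumerate(types):
        idx = np.where(ref.cell_type == t)[0]
        mat[:, j] = np.asarray(ref.counts[idx].sum(axis=0)).ravel()
    bulk = BulkProfile(list(ref.gene_ids), mat.sum(axis=1), state="raw",
                       sample_id="simulated_bulk")
    return mat, bulk


def _featurize(values: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Depth-invariant feature map for bulk vectors (rows = samples)."""
    v = np.atleast_2d(np.asarray(values, dtype=float))
    totals = v.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(target_sum * v / totals)


@dataclass
class FractionAEModel:
    """Trained fraction autoencoder with its optimisation history."""

    gene_ids: list[str]
    cell_types: list[str]
    layers: dict = field(repr=False, default_factory=dict)
    history: dict = field(default_factory=dict)
    config: RunConfig = field(default_factory=RunConfig)
    seed: int = 0

    # ---- forward passes ------------------------------------------------
    def encode(self, X: np.ndarray) -> np.ndarray:
        """Bulk features -> simplex fraction matrix T."""
        L = self.layers
        h1 = relu(L["enc1"](X))
        h2 = relu(L["enc2"](h1))
        return softmax(L["enc_out"](h2))

    def decode(self, T: np.ndarray) -> np.ndarray:
        """Fractions -> reconstructed bulk features G (nonnegative)."""
        L = self.layers
        h1 = relu(L["dec1"](T))
        h2 = relu(L["dec2"](h1))
        return relu(L["dec_out"](h2))

    def _params(self):
        return [p for lay in self.layers.values() for p in lay.params]

    # ---- training ------------------------------------------------------
    def _forward_backward(self, X: np.ndarray, F: np.ndarray | None,
                          recon_weight: float = 1.0,
                          fraction_weight: float = 1.0) -> tuple[float, float]:
        """One joint MAE loss evaluation with backprop.

        Returns (fraction MAE, reconstruction MAE), both per-element means.
        When ``F`` is None only the reconstruction term is used (the
        adaptation phase on a real bulk).
        """
        L = self.layers
        n = X.shape[0]

        z1 = L["enc1"](X); h1 = relu(z1)
        z2 = L["enc2"](h1); h2 = relu(z2)
        logits = L["enc_out"](h2)
        T = softmax(logits)

        z3 = L["dec1"](T); h3 = relu(z3)
        z4 = L["dec2"](h3); h4 = relu(z4)
        z5 = L["dec_out"](h4); G = relu(z5)

        recon_mae = float(np.abs(G - X).mean())
        frac_mae = float(np.abs(T - F).mean()) if F is not None else 0.0

        # MAE gradients (per-element mean)
        gG = recon_weight * np.sign(G - X) / G.size
        g = relu_grad(gG, z5)
        g = L["dec_out"].backward(g)
        g = L["dec2"].backward(relu_grad(g, z4))
        gT = L["dec1"].backward(relu_grad(g, z3))
        g = softmax_jvp_rows(T, gT)
        if F is not None:
            # fraction-matching gradient taken directly on the logits
            # (the softmax cross-entropy form, whose unique minimum is
            # T = F and whose gradient never saturates); the tracked
            # metric stays the mean absolute error
            g = g + fraction_weight * (T - F) / n
        g = L["enc_out"].backward(g)
        g = L["enc2"].backward(relu_grad(g, z2))
        L["enc1"].backward(relu_grad(g, z1))
        return frac_mae, recon_mae

    def adapt(self, bulk_features: np.ndarray, steps: int,
              learning_rate: float | None = None) -> None:
        """Adaptive stage: fine-tune encoder and decoder on the
        reconstruction MAE of one (or a few) real bulk vectors,
        early-stopping on a loss plateau.

        The learning rate is reduced fivefold relative to pretraining so
        the single real sample nudges the pretrained model toward its own
        state space without overfitting it.
        """
        if steps <= 0:
            return
        opt = Adam(self._params(),
                   lr=learning_rate or 0.2 * self.config.ae_learning_rate)
        best, patience = np.inf, 0
        for _ in range(steps):
            opt.zero_grad()
            _, recon = self._forward_backward(bulk_features, None)
            opt.step()
            if recon < best - 1e-6:
                best, patience = recon, 0
            else:
                patience += 1
                if patience >= 10:
                    break


def train_fraction_ae(ref: AnnotatedExpressionMatrix, n_train_bulks: int = 200,
                      config: RunConfig | None = None,
                      holdout_fraction: float = 0.2) -> FractionAEModel:
    """Train the fraction autoencoder on Dirichlet(1,...,1) pseudo-bulks of
    the reference.

    The joint loss is MAE(T, realized fractions) + MAE(G, bulk features)
    with unit weights.  A held-out slice of the pseudo-bulks is scored each
    epoch; history records per-epoch fraction and reconstruction MAE.
    Deterministic given ``config.seed``.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    types = ref.cell_types
    m, g = len(types), ref.n_genes

    bulks, fracs = make_pseudobulk(ref, n_train_bulks, np.ones(m),
                                   seed=int(rng.integers(2**31)))
    X = _featurize(np.stack([b.values for b in bulks]), config.target_sum)
    F = np.stack([f.fractions for f in fracs])

    n_hold = max(1, int(round(holdout_fraction * n_train_bulks))) \
        if n_train_bulks > 4 else 0
    perm = rng.permutation(n_train_bulks)
    hold, train = perm[:n_hold], perm[n_hold:]

    h = config.hidden_units
    init = np.random.default_rng(config.seed + 1)
    model = FractionAEModel(
        gene_ids=list(ref.gene_ids), cell_types=types,
        layers={
            "enc1": Linear(init, g, h), "enc2": Linear(init, h, h),
            "enc_out": Linear(init, h, m),
            "dec1": Linear(init, m, h), "dec2": Linear(init, h, h),
            "dec_out": Linear(init, h, g),
        },
        config=config, seed=config.seed,
        history={"fraction_mae": [], "reconstruction_mae": [],
                 "holdout_fraction_mae": []},
    )
    opt = Adam(model._params(), lr=config.ae_learning_rate)
    bs = min(config.ae_batch_size, max(1, len(train)))
    for epoch in range(config.ae_epochs):
        order = rng.permutation(train)
        fmaes, rmaes = [], []
        for start in range(0, len(order), bs):
            batch = order[start:start + bs]
            opt.zero_grad()
            fm, rm = model._forward_backward(X[batch], F[batch])
            if not (np.isfinite(fm) and np.isfinite(rm)):
                raise ValidationError(f"divergent loss (NaN) at epoch {epoch}")
            opt.step()
            fmaes.append(fm); rmaes.append(rm)
        model.history["fraction_mae"].append(float(np.mean(fmaes)))
        model.history["reconstruction_mae"].append(float(np.mean(rmaes)))
        if n_hold:
            T_hold = model.encode(X[hold])
            model.history["holdout_fraction_mae"].append(
                float(np.abs(T_hold - F[hold]).mean()))
    return model


def estimate_real_fractions(model: FractionAEModel, real_bulk: BulkProfile,
                            adapt_steps: int = 50) -> CellFractionVector:
    """Estimate the cell-type fraction state of a real bulk sample.

    The bulk is reindexed to the model's gene order (raising ``KeyError``
    on a mismatch), optionally adapted for ``adapt_steps`` gradient steps
    on the reconstruction term only, and the encoder output is returned.
    ``adapt_steps=0`` is a plain forward pass.
    """
    if real_bulk.state != "raw":
        raise ValidationError("fraction estimation expects a raw bulk profile")
    bulk = real_bulk.reindex(model.gene_ids)
    X = _featurize(bulk.values, model.config.target_sum)
    # adaptation is sample-local: restore the pretrained weights afterwards
    snapshot = [p.value.copy() for p in model._params()]
    try:
        model.adapt(X, adapt_steps)
        T = model.encode(X)[0]
    finally:
        for p, v in zip(model._params(), snapshot):
            p.value[...] = v
    T = np.maximum(T, 0.0)
    T = T / T.sum()
    return CellFractionVector(list(model.cell_types), T)
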