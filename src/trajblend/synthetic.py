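"""Synthetic single-cell references, pseudo-bulk mixtures, and simulated
"omission" profiles.

The generator emulates the statistical structure the pipeline assumes in
real data: M discrete cell types, each with a disjoint set of marker genes
elevated by a fold factor over a shared baseline; negative-binomial counts;
and, optionally, a "bridge" population whose expression program is linearly
interpolated between two parent types — the stand-in for a transitional
cell state that platform bias tends to omit.  Pseudo-bulk mixtures are
formed by sampling labelled cells with replacement under Dirichlet-drawn
proportions and summing their counts, so the returned ground-truth
fractions are the realized cell proportions of each mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .datamodel import (AnnotatedExpressionMatrix, BulkProfile,
                        CellFractionVector, ValidationError)

__all__ = ["SyntheticSpec", "make_reference", "make_pseudobulk",
           "apply_omission", "planted_overlapping_sbm", "BRIDGE_LABEL"]

BRIDGE_LABEL = "bridge"


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic reference generator.

    Defaults produce the standard test fixture: 5 well-separated types of
    370 cells each plus a 150-cell bridge population between the first two
    types (2000 cells total), 300 genes with 20 disjoint markers per type
    at 8-fold elevation, and moderately overdispersed negative-binomial
    counts whose per-cell totals comfortably clear the default QC floor.
    """

    n_types: int = 5
    n_cells_per_type: Sequence[int] = (370, 370, 370, 370, 370)
    n_genes: int = 300
    markers_per_type: int = 20
    marker_fold: float = 8.0
    nb_mean: float = 8.0
    nb_dispersion: float = 2.0  # NB shape theta; variance = mu + mu^2/theta
    bridge: Optional[tuple] = ("type_0", "type_1", 150, 11)
    seed: int = 0

    def __post_init__(self):
        self.n_cells_per_type = list(self.n_cells_per_type)
        if self.n_types < 2:
            raise ValidationError("need at least 2 cell types")
        if len(self.n_cells_per_type) == 1:
            self.n_cells_per_type = self.n_cells_per_type * self.n_types
        if len(self.n_cells_per_type) != self.n_types:
            raise ValidationError("n_cells_per_type length must equal n_types")
        if self.n_genes < self.n_types * self.markers_per_type:
            raise ValidationError(
                "marker capacity exceeded: need n_genes >= n_types * markers_per_type")
        for name in ("marker_fold", "nb_mean", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if min(self.n_cells_per_type) < 1:
            raise ValidationError("every type needs at least one cell")

    @property
    def type_names(self) -> list[str]:
        return [f"type_{i}" for i in range(self.n_types)]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               theta: float) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def make_reference(spec: SyntheticSpec) -> AnnotatedExpressionMatrix:
    """Generate a labelled synthetic single-cell reference.

    Each type's mean program is a shared gamma-distributed baseline with
    its own markers multiplied by ``marker_fold``; bridge cells (if
    requested) interpolate linearly between the two parent programs along
    an evenly spaced mixing grid and carry the label ``"bridge"``.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    g, m = spec.n_genes, spec.n_types

    # shared baseline, marker blocks disjoint by construction
    baseline = spec.nb_mean * rng.gamma(shape=2.0, scale=0.5, size=g)
    baseline = np.maximum(baseline, 0.1 * spec.nb_mean)
    type_means = np.tile(baseline, (m, 1))
    marker_sets = {}
    for t in range(m):
        lo = t * spec.markers_per_type
        hi = lo + spec.markers_per_type
        type_means[t, lo:hi] *= spec.marker_fold
        marker_sets[spec.type_names[t]] = list(range(lo, hi))

    blocks, labels = [], []
    for t, n_t in enumerate(spec.n_cells_per_type):
        blocks.append(_nb_sample(rng, np.tile(type_means[t], (n_t, 1)),
                                 spec.nb_dispersion))
        labels += [spec.type_names[t]] * n_t

    if spec.bridge is not None:
        type_a, type_b, n_bridge, grid = spec.bridge
        names = spec.type_names
        if type_a not in names or type_b not in names:
            raise ValidationError("bridge parent types must exist")
        mix = np.linspace(0.0, 1.0, grid) if np.isscalar(grid) else np.asarray(grid)
        ia, ib = names.index(type_a), names.index(type_b)
        t_per_cell = mix[np.arange(n_bridge) % len(mix)]
        means = ((1.0 - t_per_cell)[:, None] * type_means[ia]
                 + t_per_cell[:, None] * type_means[ib])
        blocks.append(_nb_sample(rng, means, spec.nb_dispersion))
        labels += [BRIDGE_LABEL] * n_bridge

    counts = np.vstack(blocks)
    n = counts.shape[0]
    return AnnotatedExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"gene_{i}" for i in range(g)],
        cell_ids=[f"cell_{i}" for i in range(n)],
        cell_type=np.array(labels, dtype=object),
        provenance={"source": "synthetic", "seed": spec.seed,
                    "marker_sets": marker_sets,
                    "bridge": None if spec.bridge is None else list(spec.bridge[:3])},
    )


def make_pseudobulk(ref: AnnotatedExpressionMatrix, n_samples: int,
                    dirichlet_alpha: Sequence[float], seed: int = 0,
                    n_cells_per_bulk: int = 500,
                    ) -> tuple[list[BulkProfile], list[CellFractionVector]]:
    """Simulate bulk RNA-seq samples by mixing labelled single cells.

    For each sample, proportions are drawn from a Dirichlet, cells are
    allocated to types by largest remainder, sampled with replacement
    within each type, and their counts summed per gene.  The returned
    fraction vectors are the *realized* proportions (allocated cells over
    total), not the Dirichlet draws.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    types = ref.cell_types
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if len(alpha) != len(types):
        raise ValueError(f"alpha length {len(alpha)} != number of types {len(types)}")
    rng = np.random.default_rng(seed)
    type_idx = {t: np.where(ref.cell_type == t)[0] for t in types}
    counts = ref.counts

    bulks, fracs = [], []
    for s in range(n_samples):
        p = rng.dirichlet(alpha)
        n_alloc = _largest_remainder(p * n_cells_per_bulk, n_cells_per_bulk)
        total = np.zeros(ref.n_genes)
        for t, n_t in zip(types, n_alloc):
            if n_t == 0:
                continue
            chosen = rng.choice(type_idx[t], size=n_t, replace=True)
            total += np.asarray(counts[chosen].sum(axis=0)).ravel()
        bulks.append(BulkProfile(list(ref.gene_ids), total, state="raw",
                                 sample_id=f"pseudobulk_{s}"))
        fracs.append(CellFractionVector(types, n_alloc / n_cells_per_bulk))
    return bulks, fracs


def _largest_remainder(target: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing exactly to ``total``: floor, then hand the
    leftover units to the largest fractional remainders."""
    floor = np.floor(target).astype(int)
    remainder = target - floor
    short = total - int(floor.sum())
    order = np.argsort(-remainder, kind="stable")
    floor[order[:short]] += 1
    return floor


def apply_omission(ref: AnnotatedExpressionMatrix, target_type: str,
                   keep_fraction: float, seed: int = 0,
                   ) -> AnnotatedExpressionMatrix:
    """Simulate platform omission of one cell type.

    Retains ``ceil(keep_fraction * n_target)`` uniformly chosen cells of
    the target type and every other cell untouched.  ``keep_fraction=0``
    removes the type entirely (the cluster-removal experiment);
    ``keep_fraction=0.2`` reproduces the random elimination of 80% of a
    population.
    """
    if target_type not in ref.cell_types:
        raise KeyError(f"unknown cell type {target_type!r}")
    if not (0.0 <= keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    target = np.where(ref.cell_type == target_type)[0]
    n_keep = math.ceil(keep_fraction * len(target))
    kept_target = rng.choice(target, size=n_keep, replace=False) if n_keep else []
    keep = np.ones(ref.n_cells, dtype=bool)
    keep[target] = False
    keep[np.asarray(kept_target, dtype=int)] = True
    out = ref.subset_cells(keep)
    out.provenance = dict(ref.provenance)
    out.provenance["omission"] = {"target_type": target_type,
                                  "keep_fraction": keep_fraction, "seed": seed}
    return out


def planted_overlapping_sbm(n_nodes: int = 300, n_communities: int = 3,
                            n_overlap: int = 10, p_in: float = 0.2,
                            p_out: float = 0.01, seed: int = 0,
                            ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Planted overlapping stochastic block model.

    Nodes are split evenly over communities; ``n_overlap`` of them receive
    a second membership in the next community (cyclically).  A pair of
    nodes sharing at least one community is connected with probability
    ``p_in``, otherwise ``p_out``.  Returns the symmetric 0/1 adjacency and
    the planted boolean membership matrix (n_nodes x n_communities).
    """
    rng = np.random.default_rng(seed)
    membership = np.zeros((n_nodes, n_communities), dtype=bool)
    base = np.arange(n_nodes) % n_communities
    membership[np.arange(n_nodes), base] = True
    dual = rng.choice(n_nodes, size=n_overlap, replace=False)
    membership[dual, (base[dual] + 1) % n_communities] = True

    shared = (membership @ membership.T) > 0
    prob = np.where(shared, p_in, p_out)
    upper = np.triu(rng.random((n_nodes, n_nodes)) < prob, k=1)
    adj = upper | upper.T
    return sp.csr_matrix(adj.astype(np.int8)), membership
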