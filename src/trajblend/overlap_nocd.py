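"""Overlapping community detection on the cell neighbourhood graph and
interpolation of overlap-state cells into the original profile.

A kNN graph over the PCA embedding of the generated cells is fed to a
two-layer graph convolutional network whose rectified output F is a
nonnegative cells x communities affinity matrix.  The fit between F and
the graph is measured by the negative log-likelihood of the
Bernoulli-Poisson model — an edge (u, v) exists with probability
1 - exp(-F_u . F_v) — estimated in balanced form with equal expected
weight on uniformly sampled edges and non-edges, which counters the
sparsity of neighbourhood graphs.  Cells whose thresholded affinity row
places them in two or more communities sit in transitional (bridge)
states; target-type cells among them are the candidates re-interpolated
into the original single-cell profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from ._nn import Adam, BatchNorm, Param
from .datamodel import AnnotatedExpressionMatrix, RunConfig, ValidationError

__all__ = ["NeighborGraph", "NocdModel", "AffinityMatrix",
           "CommunityAssignment", "build_knn_graph", "normalize_adjacency",
           "bernoulli_poisson_loss", "train_nocd",
           "extract_overlap_memberships", "interpolate_target_cells",
           "overlapping_f1"]

_EPS = 1e-10  # clamp for zero affinity inner products on existing edges


@dataclass
class NeighborGraph:
    """Symmetric 0/1 kNN adjacency with zero diagonal.

    ``coords`` optionally keeps the embedding the graph was built from, so
    downstream consumers (e.g. pseudotime) can weight edges by Euclidean
    length instead of unit hops.
    """

    adjacency: sp.csr_matrix
    k: int
    cell_ids: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None

    def __post_init__(self):
        A = self.adjacency.tocsr()
        A.setdiag(0)
        A.eliminate_zeros()
        if (A != A.T).nnz:
            raise ValidationError("adjacency must be symmetric")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def edge_list(self) -> np.ndarray:
        """Unordered edges as an (n_edges, 2) array with u < v."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])


def build_knn_graph(matrix: AnnotatedExpressionMatrix | np.ndarray,
                    k: int = 15) -> NeighborGraph:
    """Undirected kNN graph in the PCA embedding: edge (u, v) iff v is among
    u's k nearest Euclidean neighbours or vice versa; no self-loops."""
    if isinstance(matrix, AnnotatedExpressionMatrix):
        if matrix.embedding is None:
            raise ValidationError("embedding required; run pca_embed first")
        X = np.asarray(matrix.embedding)
        cell_ids = list(matrix.cell_ids)
    else:
        X = np.asarray(matrix)
        cell_ids = [str(i) for i in range(len(X))]
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    A = nn.kneighbors_graph(X, mode="connectivity")
    A.setdiag(0)
    A = A.maximum(A.T)  # mutual-or union symmetrisation
    A.data[:] = 1.0
    return NeighborGraph(adjacency=A.tocsr(), k=k, cell_ids=cell_ids, coords=X)


def normalize_adjacency(graph: NeighborGraph) -> sp.csr_matrix:
    """Symmetrically normalized adjacency with self-loops:
    A_hat = D^(-1/2) (A + I) D^(-1/2)."""
    A = graph.adjacency
    At = A + sp.identity(graph.n_nodes, format="csr")
    deg = np.asarray(At.sum(axis=1)).ravel()
    dinv = sp.diags(1.0 / np.sqrt(deg))
    return (dinv @ At @ dinv).tocsr()


@dataclass
class AffinityMatrix:
    """Nonnegative cells x communities affinity with a membership rule:
    rows are divided by their maximum and thresholded at rho."""

    F: np.ndarray
    membership_threshold: float = 0.5
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if np.any(self.F < 0):
            raise ValidationError("affinity matrix must be nonnegative")
        if not (0.0 < self.membership_threshold < 1.0):
            raise ValidationError("membership threshold must lie in (0, 1)")

    @property
    def n_communities(self) -> int:
        return self.F.shape[1]

    def memberships(self) -> np.ndarray:
        """Boolean cells x communities membership matrix."""
        rowmax = self.F.max(axis=1, keepdims=True)
        safe = np.where(rowmax > 0, rowmax, 1.0)
        return (self.F / safe >= self.membership_threshold) & (rowmax > 0)


def _pair_scores(F: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", F[pairs[:, 0]], F[pairs[:, 1]])


def bernoulli_poisson_loss(F: AffinityMatrix | np.ndarray,
                           graph: NeighborGraph, mode: str = "full",
                           n_samples: int = 10000, seed: int = 0) -> float:
    """Negative log-likelihood of the Bernoulli-Poisson graph model.

    ``full`` evaluates the exact sum over all unordered pairs:
    -sum_edges log(1 - exp(-F_u.F_v)) + sum_non_edges F_u.F_v.
    ``balanced`` averages the edge term over ``n_samples`` uniform edges
    and the non-edge term over ``n_samples`` uniform non-edges, giving the
    two expectations equal weight.  Edge inner products of zero are
    clamped at 1e-10 (an exact zero would make the edge term infinite).
    """
    Fm = F.F if isinstance(F, AffinityMatrix) else np.asarray(F, dtype=float)
    if Fm.shape[0] != graph.n_nodes:
        raise ValidationError("affinity matrix not aligned to graph")
    edges = graph.edge_list()
    n = graph.n_nodes
    if mode == "full":
        s_edges = np.maximum(_pair_scores(Fm, edges), _EPS)
        edge_term = -np.log1p(-np.exp(-s_edges)).sum()
        # sum over all unordered pairs minus edges, via the Gram identity
        total = 0.5 * (np.sum((Fm.sum(axis=0)) ** 2) - np.sum(Fm * Fm))
        nonedge_term = total - _pair_scores(Fm, edges).sum()
        return float(edge_term + nonedge_term)
    if mode != "balanced":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    e_idx = rng.integers(len(edges), size=n_samples)
    s_edges = np.maximum(_pair_scores(Fm, edges[e_idx]), _EPS)
    edge_term = float(-np.log1p(-np.exp(-s_edges)).mean())
    non_edges = _sample_non_edges(graph, n_samples, rng)
    nonedge_term = float(_pair_scores(Fm, non_edges).mean())
    return edge_term + nonedge_term


def _sample_non_edges(graph: NeighborGraph, n_samples: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniform unordered non-edge pairs via rejection sampling (the graphs
    here are sparse, so acceptance is near 1)."""
    A = graph.adjacency
    n = graph.n_nodes
    out = np.empty((0, 2), dtype=int)
    while len(out) < n_samples:
        m = int(1.5 * (n_samples - len(out))) + 8
        u = rng.integers(n, size=m)
        v = rng.integers(n, size=m)
        ok = u != v
        u, v = u[ok], v[ok]
        linked = np.asarray(A[u, v]).ravel() > 0
        cand = np.column_stack([u[~linked], v[~linked]])
        out = np.vstack([out, cand])
    return out[:n_samples]


@dataclass
class NocdModel:
    """Two-layer GCN for overlapping community detection:
    F = ReLU(A_hat ReLU(BN(A_hat X W1)) W2), batch-normalised after the
    first convolution, L2-regularised weights."""

    W1: Param
    W2: Param
    bn: BatchNorm
    n_communities: int
    config: RunConfig
    seed: int
    history: dict = field(default_factory=dict)

    def forward(self, A_hat: sp.csr_matrix, X, cache: dict | None = None,
                ) -> np.ndarray:
        XW = X @ self.W1.value
        P1 = A_hat @ XW
        B = self.bn(P1)
        H1 = np.maximum(B, 0.0)
        M2 = A_hat @ (H1 @ self.W2.value)
        F = np.maximum(M2, 0.0)
        if cache is not None:
            cache.update(X=X, B=B, H1=H1, M2=M2)
        return F

    def backward(self, A_hat: sp.csr_matrix, cache: dict, gF: np.ndarray):
        gM2 = gF * (cache["M2"] > 0)
        gHW = A_hat @ gM2  # A_hat symmetric
        self.W2.grad += cache["H1"].T @ gHW
        gH1 = gHW @ self.W2.value.T
        gB = gH1 * (cache["B"] > 0)
        gP1 = self.bn.backward(gB)
        gXW = A_hat @ gP1
        self.W1.grad += cache["X"].T @ gXW

    def params(self):
        return [self.W1, self.W2] + self.bn.params


def train_nocd(graph: NeighborGraph, features, config: RunConfig | None = None,
               n_communities: int | None = None, n_restarts: int = 5,
               ) -> tuple[NocdModel, AffinityMatrix]:
    """Fit the GCN by minimising the balanced Bernoulli-Poisson negative
    log-likelihood with Adam.

    ``features`` is a row-aligned node-feature matrix (typically the
    one-hot cell-type matrix; an identity matrix makes the model learn
    free per-node embeddings).  Each step draws a balanced batch of
    ``config.nocd_batch_edges`` edges and as many non-edges.  The
    objective is non-convex, so ``n_restarts`` independent initialisations
    are trained and the run with the lowest exact (full) likelihood loss
    is kept — model selection uses the training objective only.  Returns
    the trained model and the full affinity matrix.  Deterministic given
    ``config.seed``.
    """
    config = config or RunConfig()
    best = None
    for r in range(max(1, n_restarts)):
        model, affinity = _train_nocd_once(graph, features, config,
                                           n_communities, restart=r)
        score = bernoulli_poisson_loss(affinity, graph, mode="full")
        if best is None or score < best[0]:
            best = (score, model, affinity)
    return best[1], best[2]


def _train_nocd_once(graph: NeighborGraph, features, config: RunConfig,
                     n_communities: int | None, restart: int = 0,
                     ) -> tuple[NocdModel, AffinityMatrix]:
    X = features.toarray() if sp.issparse(features) else np.asarray(features, float)
    if X.shape[0] != graph.n_nodes:
        raise ValidationError("features not row-aligned to graph")
    C = n_communities or config.n_communities
    if C is None:
        raise ValueError("n_communities must be given")
    rng = np.random.default_rng(config.seed + 4 + 7919 * restart)
    init = np.random.default_rng(config.seed + 5 + 7919 * restart)
    h = config.nocd_hidden
    model = NocdModel(
        W1=Param(init.normal(0, np.sqrt(2.0 / X.shape[1]), (X.shape[1], h))),
        W2=Param(init.normal(0, np.sqrt(2.0 / h), (h, C))),
        bn=BatchNorm(h), n_communities=C, config=config, seed=config.seed,
        history={"balanced_loss": []},
    )
    A_hat = normalize_adjacency(graph)
    edges = graph.edge_list()
    n_batch = min(config.nocd_batch_edges, len(edges))
    opt = Adam(model.params(), lr=config.nocd_learning_rate,
               weight_decay=config.nocd_weight_decay,
               decay_params=[model.W1, model.W2])

    for epoch in range(config.nocd_epochs):
        cache: dict = {}
        F = model.forward(A_hat, X, cache)
        e_idx = rng.integers(len(edges), size=n_batch)
        e_pairs = edges[e_idx]
        ne_pairs = _sample_non_edges(graph, n_batch, rng)

        s_e = np.maximum(_pair_scores(F, e_pairs), _EPS)
        loss = float(-np.log1p(-np.exp(-s_e)).mean()
                     + _pair_scores(F, ne_pairs).mean())
        if not np.isfinite(loss):
            raise ValidationError(f"NaN loss at epoch {epoch}")
        model.history["balanced_loss"].append(loss)

        # gradient of the balanced loss wrt F
        gF = np.zeros_like(F)
        coef_e = (-np.exp(-s_e) / (1.0 - np.exp(-s_e))) / len(s_e)
        np.add.at(gF, e_pairs[:, 0], coef_e[:, None] * F[e_pairs[:, 1]])
        np.add.at(gF, e_pairs[:, 1], coef_e[:, None] * F[e_pairs[:, 0]])
        coef_n = 1.0 / len(ne_pairs)
        np.add.at(gF, ne_pairs[:, 0], coef_n * F[ne_pairs[:, 1]])
        np.add.at(gF, ne_pairs[:, 1], coef_n * F[ne_pairs[:, 0]])

        opt.zero_grad()
        model.backward(A_hat, cache, gF)
        opt.step()

    F = model.forward(A_hat, X)
    affinity = AffinityMatrix(F, config.membership_threshold,
                              cell_ids=list(graph.cell_ids))
    return model, affinity


@dataclass
class CommunityAssignment:
    """Binarised community structure with per-community majority labels."""

    memberships: np.ndarray              # bool cells x communities
    community_labels: list[str]          # majority provisional label
    overlap_cells: np.ndarray            # indices with >= 2 memberships
    selected_cells: np.ndarray           # overlap cells carrying the target label
    target_type: str


def extract_overlap_memberships(F: AffinityMatrix,
                                generated: AnnotatedExpressionMatrix,
                                target_type: str,
                                require_target_community: bool = True,
                                ) -> CommunityAssignment:
    """Select target-type cells sitting in overlapping community states.

    Memberships come from thresholding F; each community is labelled by the
    majority provisional label of its members (ties broken toward the
    lexicographically smallest label).  Selected cells are those labelled
    ``target_type`` that belong to two or more communities, i.e. bridge the
    target community and a neighbour.

    When no community carries the target majority this raises by default;
    with ``require_target_community=False`` the selection proceeds from
    the membership matrix alone — a transitional population can be fully
    absorbed as dual members of its parent communities, which is itself
    the overlap state of interest — as long as some target-labelled
    overlap cell exists.
    """
    if F.F.shape[0] != generated.n_cells:
        raise ValidationError("affinity matrix not aligned to generated cells")
    member = F.memberships()
    labels = generated.cell_type
    comm_labels = []
    for c in range(member.shape[1]):
        members = labels[member[:, c]]
        if len(members) == 0:
            comm_labels.append("")
            continue
        uniq, counts = np.unique(members.astype(str), return_counts=True)
        best = uniq[counts == counts.max()]
        comm_labels.append(sorted(best)[0])
    n_member = member.sum(axis=1)
    overlap = np.where(n_member >= 2)[0]
    selected = overlap[labels[overlap] == target_type]
    if target_type not in comm_labels:
        if require_target_community or len(selected) == 0:
            raise ValidationError(
                f"target community absent: no community has majority label "
                f"{target_type!r}")
        warnings.warn(
            f"no community has majority label {target_type!r}; selecting "
            f"{len(selected)} dual-membership target cells directly")
    return CommunityAssignment(member, comm_labels, overlap, selected,
                               target_type)


def interpolate_target_cells(original: AnnotatedExpressionMatrix,
                             selected: AnnotatedExpressionMatrix,
                             ) -> AnnotatedExpressionMatrix:
    """Row-concatenate the selected overlap cells into the original profile.

    Gene universes must match exactly.  Interpolated cells keep their
    generated expression and target label and carry a per-cell
    ``interpolated`` flag in the provenance.
    """
    if list(original.gene_ids) != list(selected.gene_ids):
        raise KeyError("gene universes differ between original and selected cells")
    if selected.n_cells == 0:
        warnings.warn("empty selection: nothing to interpolate")
        out = original.copy()
        out.provenance["interpolated"] = np.zeros(original.n_cells, dtype=bool)
        return out
    counts = sp.vstack([original.counts, selected.counts]).tocsr()
    cell_ids = list(original.cell_ids) + \
        [f"interp_{c}" for c in selected.cell_ids]
    cell_type = np.concatenate([original.cell_type, selected.cell_type])
    layers = {}
    for name in set(original.layers) & set(selected.layers):
        a, b = original.layers[name], selected.layers[name]
        if sp.issparse(a) or sp.issparse(b):
            layers[name] = sp.vstack([sp.csr_matrix(a), sp.csr_matrix(b)]).tocsr()
        else:
            layers[name] = np.vstack([a, b])
    flags = np.concatenate([
        np.asarray(original.provenance.get("interpolated",
                                           np.zeros(original.n_cells, bool))),
        np.ones(selected.n_cells, dtype=bool)])
    prov = dict(original.provenance)
    prov["interpolated"] = flags
    return AnnotatedExpressionMatrix(
        counts=counts, gene_ids=list(original.gene_ids), cell_ids=cell_ids,
        cell_type=cell_type, layers=layers, provenance=prov)


def overlapping_f1(predicted: np.ndarray, planted: np.ndarray) -> float:
    """Symmetric overlapping-community F1: communities of the two sides are
    matched one-to-one to maximise the mean per-pair set F1 (Hungarian
    assignment on the pairwise F1 matrix)."""
    from scipy.optimize import linear_sum_assignment

    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(planted, dtype=bool)
    n_p, n_t = pred.shape[1], true.shape[1]
    f1 = np.zeros((n_p, n_t))
    for i in range(n_p):
        for j in range(n_t):
            inter = np.sum(pred[:, i] & true[:, j])
            denom = pred[:, i].sum() + true[:, j].sum()
            f1[i, j] = 2.0 * inter / denom if denom else 0.0
    rows, cols = linear_sum_assignment(-f1)
    return float(f1[rows, cols].mean())
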