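"""Scoring suite for generated and interpolated single-cell profiles.

Six views on a run: (1) the count of interpolated cells; (2) Pearson
correlation of per-type mean expression over the reference's top marker
genes between reference and generated profiles; (3) cosine similarity of
the two profiles' top-marker-gene sets; (4) a transition-confidence matrix
between cell-type clusters on the neighbourhood graph, oriented by mean
pseudotime — the statistic that goes to zero when an omitted type breaks
a differentiation trajectory and recovers after interpolation; (5) the
number of sub-threshold noise clusters among generated cells; and (6) the
variance of pseudotime within the target population.

Pseudotime at desk scale is graph shortest-path distance from a root cell,
min-max scaled to [0, 1]; the evaluation report records which engine
produced it so accession-scale runs can substitute a full trajectory
method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path
from scipy.stats import pearsonr

from .datamodel import AnnotatedExpressionMatrix, RunConfig, ValidationError
from .generator_bvae import _dense_lognorm, filter_noise_clusters
from .overlap_nocd import NeighborGraph, build_knn_graph
from .preprocessing import normalize_log1p, pca_embed

__all__ = ["MarkerTable", "EvaluationReport", "rank_markers",
           "marker_correlation", "marker_cosine", "transition_confidence",
           "pseudotime_stats", "graph_pseudotime", "evaluate_run",
           "progenitor_target_confidence"]


@dataclass
class MarkerTable:
    """Per-type ranked marker genes with scores (descending)."""

    markers: dict  # type -> list[(gene_id, score)]
    top_n: int

    def genes(self, cell_type: str) -> list[str]:
        return [g for g, _ in self.markers[cell_type]]

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.markers)


def rank_markers(matrix: AnnotatedExpressionMatrix, groupby: str = "cell_type",
                 top_n: int = 200) -> MarkerTable:
    """One-vs-rest Wilcoxon rank-sum marker ranking on the lognorm layer
    (ties broken by gene ID); groups with fewer than 2 cells are excluded
    with a warning."""
    if groupby != "cell_type":
        raise ValueError("only grouping by cell_type is supported")
    X = _dense_lognorm(matrix)
    labels = matrix.cell_type.astype(str)
    uniq, counts = np.unique(labels, return_counts=True)
    keep_types = [t for t, c in zip(uniq, counts) if c >= 2]
    for t, c in zip(uniq, counts):
        if c < 2:
            warnings.warn(f"group {t!r} has {c} cell(s); excluded from ranking")
    if len(keep_types) < 2:
        raise ValidationError("marker ranking needs at least 2 groups")
    mask = np.isin(labels, keep_types)
    adata = ad.AnnData(X=X[mask],
                       obs=pd.DataFrame({"cell_type": pd.Categorical(labels[mask])}),
                       var=pd.DataFrame(index=pd.Index(matrix.gene_ids)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(adata, "cell_type", method="wilcoxon",
                                n_genes=matrix.n_genes, tie_correct=True)
    res = adata.uns["rank_genes_groups"]
    table = {}
    for t in keep_types:
        names = np.asarray(res["names"][t])
        scores = np.asarray(res["scores"][t], dtype=float)
        # stable ordering: score descending, then gene ID
        order = np.lexsort((names, -scores))
        ranked = [(str(names[i]), float(scores[i])) for i in order[:top_n]]
        table[t] = ranked
    return MarkerTable(table, top_n)


def _type_means(matrix: AnnotatedExpressionMatrix) -> dict:
    X = _dense_lognorm(matrix)
    return {t: X[matrix.cell_type == t].mean(axis=0)
            for t in matrix.cell_types}


def marker_correlation(ref: AnnotatedExpressionMatrix,
                       gen: AnnotatedExpressionMatrix,
                       markers: MarkerTable) -> dict:
    """Per-type Pearson r between reference and generated type-mean lognorm
    expression over the reference's top marker genes.  Types absent from
    the generated profile are reported as ``None``."""
    if list(ref.gene_ids) != list(gen.gene_ids):
        raise KeyError("gene universes differ between reference and generated")
    gidx = {g: i for i, g in enumerate(ref.gene_ids)}
    ref_means = _type_means(ref)
    gen_means = _type_means(gen)
    out = {}
    for t in markers.cell_types:
        if t not in ref_means:
            continue
        if t not in gen_means:
            out[t] = None
            continue
        cols = [gidx[g] for g in markers.genes(t)]
        a, b = ref_means[t][cols], gen_means[t][cols]
        if np.std(a) == 0 or np.std(b) == 0:
            out[t] = None
            continue
        out[t] = float(pearsonr(a, b).statistic)
    return out


def marker_cosine(ref_markers: MarkerTable, gen_markers: MarkerTable) -> dict:
    """Cosine similarity of the binary bag-of-genes vectors of two marker
    lists per type: |A ∩ B| / sqrt(|A| |B|).  Empty lists report ``None``."""
    out = {}
    for t in ref_markers.cell_types:
        if t not in gen_markers.markers:
            out[t] = None
            continue
        a, b = set(ref_markers.genes(t)), set(gen_markers.genes(t))
        out[t] = None if not a or not b else \
            float(len(a & b) / np.sqrt(len(a) * len(b)))
    return out


def transition_confidence(graph: NeighborGraph, labels, pseudotime,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-to-cluster transition confidence on the neighbourhood graph.

    For clusters i, j the (symmetric) confidence is the observed number of
    inter-cluster edges divided by its expectation under uniformly random
    edge placement given cluster sizes, clipped to [0, 1].  The directed
    matrix carries the value on i -> j when mean pseudotime(i) < mean
    pseudotime(j), zero on the reverse entry.  Returns
    ``(directed, symmetric)`` DataFrames indexed by cluster label.
    """
    labels = np.asarray(labels).astype(str)
    pt = np.asarray(pseudotime, dtype=float)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        return (pd.DataFrame(index=uniq, columns=uniq, dtype=float),) * 2
    n = graph.n_nodes
    m = graph.n_edges
    sizes = {t: int((labels == t).sum()) for t in uniq}
    mean_pt = {t: float(pt[labels == t].mean()) for t in uniq}
    edges = graph.edge_list()
    eu, ev = labels[edges[:, 0]], labels[edges[:, 1]]

    sym = pd.DataFrame(0.0, index=uniq, columns=uniq)
    total_pairs = n * (n - 1) / 2.0
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            observed = int(np.sum(((eu == a) & (ev == b))
                                  | ((eu == b) & (ev == a))))
            expected = m * sizes[a] * sizes[b] / total_pairs
            conf = min(1.0, observed / expected) if expected > 0 else 0.0
            sym.loc[a, b] = sym.loc[b, a] = conf
    directed = sym.copy()
    for a in uniq:
        for b in uniq:
            if a == b or mean_pt[a] >= mean_pt[b]:
                directed.loc[a, b] = 0.0
    return directed, sym


def graph_pseudotime(graph: NeighborGraph, root: int | str) -> np.ndarray:
    """Desk-scale pseudotime: shortest-path distance from the root cell,
    min-max scaled to [0, 1].

    When the graph carries the embedding it was built from, edges are
    weighted by their Euclidean length, giving a continuous ordering;
    otherwise unit hop counts are used.  Cells disconnected from the root
    get pseudotime 1 with a warning.
    """
    if isinstance(root, str):
        try:
            root = graph.cell_ids.index(root)
        except ValueError:
            raise KeyError(f"root cell {root!r} not in graph") from None
    if graph.coords is not None:
        A = graph.adjacency.tocoo()
        w = np.linalg.norm(graph.coords[A.row] - graph.coords[A.col], axis=1)
        W = sp.csr_matrix((np.maximum(w, 1e-12), (A.row, A.col)),
                          shape=A.shape)
        dist = shortest_path(W, method="D", indices=root)
    else:
        dist = shortest_path(graph.adjacency, method="D", unweighted=True,
                             indices=root)
    finite = np.isfinite(dist)
    if not finite.all():
        warnings.warn(f"{int((~finite).sum())} cells disconnected from the "
                      "root; assigned pseudotime 1")
    dmax = dist[finite].max()
    pt = np.where(finite, dist / dmax if dmax > 0 else 0.0, 1.0)
    return pt


def pseudotime_stats(matrix: AnnotatedExpressionMatrix, target_type: str,
                     ) -> tuple[float, dict]:
    """Population variance and quartile summary of pseudotime over the
    target-type cells (interpolated and original alike)."""
    if matrix.pseudotime is None:
        raise ValidationError("pseudotime missing; run graph_pseudotime first")
    sel = matrix.cell_type == target_type
    if not sel.any():
        raise ValidationError(f"no cells of type {target_type!r}")
    pt = np.asarray(matrix.pseudotime, dtype=float)[sel]
    q = np.percentile(pt, [0, 25, 50, 75, 100])
    summary = {"n": int(sel.sum()), "min": float(q[0]), "q25": float(q[1]),
               "median": float(q[2]), "q75": float(q[3]), "max": float(q[4])}
    return float(np.var(pt)), summary


@dataclass
class EvaluationReport:
    """The metric suite for one run, plus provenance."""

    n_interpolated: int
    marker_correlation: dict
    marker_cosine: dict
    transition_confidence: dict        # profile -> directed matrix (nested dict)
    n_noise_clusters: int
    pseudotime_variance: dict          # profile -> variance of the target type
    pseudotime_engine: str
    target_type: str
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {"schema_version": 1, **self.__dict__}
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _prepare(matrix: AnnotatedExpressionMatrix, config: RunConfig,
             ) -> tuple[AnnotatedExpressionMatrix, NeighborGraph]:
    """Lognorm + PCA + kNN graph + shortest-path pseudotime rooted at the
    tip of the progenitor cluster.

    The root is the cell of the root type (``provenance["root_type"]``,
    falling back to the lexicographically first label) farthest in the
    embedding from the centroid of all other types — the deep end of the
    progenitor population, so pseudotime increases outward through it
    toward transitional and derived states.
    """
    out = matrix if "lognorm" in matrix.layers else \
        normalize_log1p(matrix, config.target_sum)
    if out.embedding is None:
        out = pca_embed(out, min(config.n_pcs, out.n_cells - 1, out.n_genes),
                        seed=config.seed)
    graph = build_knn_graph(out, min(config.knn_k, out.n_cells - 1))
    root_type = matrix.provenance.get("root_type") or sorted(out.cell_types)[0]
    root_idx = np.where(out.cell_type == root_type)[0]
    others = out.embedding[out.cell_type != root_type]
    if len(others) and len(root_idx) > 1:
        centroid = others.mean(axis=0)
        dists = np.linalg.norm(out.embedding[root_idx] - centroid, axis=1)
        root = int(root_idx[np.argmax(dists)])
    else:
        root = int(root_idx[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out.pseudotime = graph_pseudotime(graph, root)
    return out, graph


def evaluate_run(original: AnnotatedExpressionMatrix,
                 omitted: AnnotatedExpressionMatrix,
                 augmented: AnnotatedExpressionMatrix,
                 target_type: str, config: RunConfig | None = None,
                 progenitor_type: str | None = None) -> EvaluationReport:
    """Score a full omission-rescue run.

    ``original`` is the intact reference, ``omitted`` the profile with the
    target type dropped, ``augmented`` the omitted profile after
    interpolation.  Reports marker fidelity of the augmented against the
    original, the progenitor -> target transition confidence on all three
    profiles (expected 0 on the omitted profile and positive again on the
    augmented one), noise-cluster count, and target pseudotime variance.
    """
    config = config or RunConfig()
    for other in (omitted, augmented):
        if list(other.gene_ids) != list(original.gene_ids):
            raise KeyError("profiles must share a gene universe")

    markers_ref = rank_markers(normalize_log1p(original, config.target_sum)
                               if "lognorm" not in original.layers else original)
    aug_prep, aug_graph = _prepare(augmented, config)
    orig_prep, orig_graph = _prepare(original, config)
    omit_prep, omit_graph = _prepare(omitted, config)

    corr = marker_correlation(orig_prep, aug_prep, markers_ref)
    markers_aug = rank_markers(aug_prep)
    cosine = marker_cosine(markers_ref, markers_aug)

    conf = {}
    for name, prep, graph in (("original", orig_prep, orig_graph),
                              ("omitted", omit_prep, omit_graph),
                              ("augmented", aug_prep, aug_graph)):
        directed, sym = transition_confidence(graph, prep.cell_type,
                                              prep.pseudotime)
        conf[name] = {"directed": directed.to_dict(),
                      "symmetric": sym.to_dict()}

    flags = np.asarray(augmented.provenance.get(
        "interpolated", np.zeros(augmented.n_cells, bool)), dtype=bool)
    n_interp = int(flags.sum())

    interp_cells = aug_prep.subset_cells(flags) if flags.any() else None
    if interp_cells is not None and interp_cells.n_cells > 2:
        # count sub-threshold clusters among interpolated cells without
        # discarding anything (min_cells=0 keeps the identity)
        _, noise_report = filter_noise_clusters(
            interp_cells, config.leiden_resolution, 0, seed=config.seed)
        n_noise = sum(1 for s in noise_report.cluster_sizes.values()
                      if s < config.noise_min_cells)
    else:
        n_noise = 0

    pt_var = {}
    for name, prep in (("original", orig_prep), ("omitted", omit_prep),
                       ("augmented", aug_prep)):
        if target_type in prep.cell_types:
            var, _ = pseudotime_stats(prep, target_type)
            pt_var[name] = var
        else:
            pt_var[name] = None

    return EvaluationReport(
        n_interpolated=n_interp,
        marker_correlation=corr,
        marker_cosine=cosine,
        transition_confidence=conf,
        n_noise_clusters=n_noise,
        pseudotime_variance=pt_var,
        pseudotime_engine="graph_shortest_path",
        target_type=target_type,
        config=config.as_dict(),
    )


def progenitor_target_confidence(report: EvaluationReport, profile: str,
                                 progenitor: str, target: str) -> float:
    """Directed progenitor -> target confidence from a report; 0 when the
    target cluster is absent from that profile."""
    directed = report.transition_confidence[profile]["directed"]
    # pandas to_dict is column-major: directed[col][row] = value row->col
    try:
        return float(directed[target][progenitor])
    except KeyError:
        return 0.0
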