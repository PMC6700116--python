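"""Dimension reduction, shared-nearest-neighbor clustering, marker genes.

PCA runs on the covariate-regressed z-scores restricted to a gene set
(typically the variable genes).  Clustering builds a k-nearest-neighbor
graph in PC space, reweights edges by the Jaccard overlap of neighbor sets
(shared nearest neighbors), and partitions it by seeded modularity
optimization.  Markers come from per-gene two-sided Wilcoxon rank-sum
tests on the log-normalized layer with both Bonferroni and
Benjamini-Hochberg adjustments reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._stats import EXACT_MAX_N, benjamini_hochberg, bonferroni, rank_sum_p_matrix
from .datatypes import ClusterLabels, NormalizedMatrix, ScaledMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Cell scores (cells x PCs), gene loadings (genes x PCs), variance shares."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratio: np.ndarray

    def loading(self, pc: int) -> pd.Series:
        return self.loadings.iloc[:, pc]


def run_pca(scaled: ScaledMatrix, genes: Iterable[str] | None = None,
            n_pcs: int = 7) -> PCAResult:
    """Principal components of cells over the chosen genes.

    Deterministic full SVD.  Sign convention: each loading vector is
    oriented so its largest-magnitude entry is positive, which fixes the
    top/bottom poles used for programme derivation downstream.
    """
    genes = list(genes) if genes is not None else list(scaled.gene_ids)
    missing = set(genes) - set(scaled.gene_ids)
    if missing:
        raise ValidationError(f"genes not in matrix: {sorted(missing)[:10]}")
    X = scaled.values.loc[genes].to_numpy(dtype=float).T  # cells x genes
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise ValidationError("PCA needs at least 2 cells")
    if n_pcs > min(n_genes, n_cells) - 1:
        raise ValidationError(
            f"n_pcs={n_pcs} exceeds min(n_genes, n_cells) - 1 = {min(n_genes, n_cells) - 1}"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = Vt[:n_pcs]  # n_pcs x genes, orthonormal rows
    # orient each component so its largest-|.| loading is positive
    flip = np.sign(comps[np.arange(n_pcs), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    scores = Xc @ comps.T
    var = (S**2) / max(n_cells - 1, 1)
    ratio = var[:n_pcs] / var.sum()
    pcs = [f"PC{i + 1}" for i in range(n_pcs)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=scaled.cell_ids, columns=pcs),
        loadings=pd.DataFrame(comps.T, index=pd.Index(genes, name="gene_id"), columns=pcs),
        variance_ratio=ratio,
    )


def _snn_graph(coords: np.ndarray, k: int) -> igraph.Graph:
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k, n)).fit(coords)
    _, idx = nn.kneighbors(coords)
    # neighbor sets include the cell itself (it is its own nearest neighbor)
    sets = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), idx.shape[1])
    sets[rows, idx.ravel()] = True
    sets[np.arange(n), np.arange(n)] = True
    inter = sets.astype(np.int32) @ sets.astype(np.int32).T
    sizes = sets.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    jaccard = inter / union
    # connect pairs that appear in each other's kNN lists (undirected union)
    adj = np.zeros((n, n), dtype=bool)
    adj[rows, idx.ravel()] = True
    adj = adj | adj.T
    np.fill_diagonal(adj, False)
    src, dst = np.where(np.triu(adj))
    weights = jaccard[src, dst]
    keep = weights > 0
    g = igraph.Graph(n=n, edges=list(zip(src[keep].tolist(), dst[keep].tolist())))
    g.es["weight"] = weights[keep].tolist()
    return g


def snn_cluster(pc_scores: pd.DataFrame, k: int = 150, resolution: float = 0.8,
                seed: int = 0) -> ClusterLabels:
    """Shared-nearest-neighbor modularity clustering of cells in PC space.

    Euclidean kNN graph, Jaccard-of-neighbor-sets edge weights, seeded
    Leiden modularity optimization at the given resolution.  Deterministic
    given the seed.  Cluster indices are renumbered by decreasing size.
    """
    n = pc_scores.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of cells ({n}); lower k")
    g = _snn_graph(pc_scores.to_numpy(dtype=float), k)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
    )
    raw = np.asarray(part.membership)
    order = pd.Series(raw).value_counts().index.tolist()
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[v] for v in raw], index=pc_scores.index, name="cluster")
    return ClusterLabels(labels, params={"k": k, "resolution": resolution, "seed": seed,
                                         "n_pcs": pc_scores.shape[1]})


def cluster_markers(
    norm: NormalizedMatrix,
    labels: ClusterLabels | None = None,
    cluster: int | None = None,
    groups: tuple | None = None,
) -> pd.DataFrame:
    """Differential expression by two-sided Wilcoxon rank-sum test.

    Contrast is either one-vs-rest (``labels`` + ``cluster``) or an explicit
    cell-set pair ``groups=(cells_in, cells_out)``.  Returns a DataFrame
    indexed by gene with mean_in, mean_out (mean log-normalized expression),
    log_fold_change (their difference, natural-log units), fold_change,
    p_value, p_bonferroni and q_bh.

    Group sizes <= 8 on both sides use exact enumeration of the rank-sum
    permutation distribution; larger groups use the tie-corrected normal
    approximation.  A group smaller than 3 cells triggers a warning (the
    exact test is still valid but nearly powerless).
    """
    if groups is not None:
        cells_in, cells_out = (pd.Index(list(g)) for g in groups)
    elif labels is not None and cluster is not None:
        cells_in = labels.cells_in(cluster)
        cells_out = labels.labels.index[labels.labels != cluster]
    else:
        raise ValueError("supply either labels+cluster or groups=(in, out)")
    if len(cells_in) == 0 or len(cells_out) == 0:
        raise ValidationError("both contrast groups must be nonempty")
    if min(len(cells_in), len(cells_out)) < 3:
        warnings.warn("a contrast group has fewer than 3 cells; exact test used, power is minimal")
    A = norm.values[cells_in].to_numpy(dtype=float)
    B = norm.values[cells_out].to_numpy(dtype=float)
    constant = (A.std(axis=1) == 0) & (B.std(axis=1) == 0) & (A[:, :1] == B[:, :1]).ravel()
    p = np.ones(A.shape[0])
    if (~constant).any():
        p[~constant] = rank_sum_p_matrix(A[~constant], B[~constant])
    mean_in = A.mean(axis=1)
    mean_out = B.mean(axis=1)
    lfc = mean_in - mean_out
    out = pd.DataFrame(
        {
            "mean_in": mean_in,
            "mean_out": mean_out,
            "log_fold_change": lfc,
            "fold_change": np.exp(lfc),
            "p_value": p,
            "p_bonferroni": bonferroni(p),
            "q_bh": benjamini_hochberg(p),
        },
        index=norm.gene_ids,
    )
    out.attrs["n_in"] = len(cells_in)
    out.attrs["n_out"] = len(cells_out)
    out.attrs["exact"] = max(len(cells_in), len(cells_out)) <= EXACT_MAX_N
    return out


def annotate_compartments(labels: ClusterLabels, scores: pd.DataFrame) -> dict:
    """Assign each cluster the compartment signature with the highest mean score.

    ``scores`` is a per-cell ScoreTable over compartment signatures.  Exact
    ties go to the lexicographically first compartment with a warning.
    """
    if scores.shape[1] == 0:
        raise ValidationError("no compartment signatures supplied")
    missing = labels.labels.index.difference(scores.index)
    if len(missing):
        raise ValidationError(f"scores missing for cells: {sorted(missing)[:10]}")
    assignment = {}
    cols = sorted(scores.columns)
    for c in range(labels.n_clusters):
        means = scores.loc[labels.cells_in(c), cols].mean(axis=0)
        best = means.max()
        winners = [name for name in cols if means[name] == best]
        if len(winners) > 1:
            warnings.warn(
                f"cluster {c}: tie between {winners}; picking {winners[0]} (lexicographic)"
            )
        assignment[c] = winners[0]
    return assignment
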