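"""Gene programme derivation and programme-level statistics.

Programmes are the top and bottom 50 genes of a principal-component loading
vector (signed loadings, not magnitudes): in pilocytic astrocytoma the two
poles of PC1 over cancer cells are the MAPK-signaling and astrocyte-like
programmes, and PC2 carries the small oligodendrocyte-like branch.
Programme scores are compared by tie-corrected Spearman correlation with
Bonferroni adjustment, and gene lists by one-sided Fisher/hypergeometric
overlap tests against a fixed genome-size universe (18,000 genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import GeneSignature, NormalizedMatrix
from .errors import ValidationError


def derive_programmes(loadings: pd.Series, n: int = 50,
                      names: tuple = ("top", "bottom")) -> tuple:
    """Split a PC loading vector into its top-n and bottom-n gene programmes.

    Genes are ranked by signed loading with ties broken by gene id
    (ascending), so the split is deterministic and the two programmes are
    always disjoint.  Negating the loadings swaps top and bottom.
    """
    if len(loadings) < 2 * n:
        raise ValidationError(f"need at least {2 * n} genes with loadings, got {len(loadings)}")
    order = sorted(loadings.index, key=lambda g: (loadings[g], g))
    bottom = order[:n]
    top = order[-n:]
    return (
        GeneSignature(names[0], top, provenance=f"top {n} PC loadings"),
        GeneSignature(names[1], bottom, provenance=f"bottom {n} PC loadings"),
    )


def correlate_programmes(scores: pd.DataFrame,
                         extra_columns: pd.DataFrame | None = None) -> pd.DataFrame:
    """All pairwise Spearman correlations between programme-score columns.

    ``extra_columns`` (e.g. single-gene log-normalized expression) is joined
    on the cell index before correlating.  Returns a long DataFrame
    (col_a, col_b, rho, p, q, n) with two-sided p and Bonferroni
    ``q = min(1, p * n_pairs)`` over the pairs tested in this call.
    Constant columns yield missing rho with a warning.
    """
    data = scores
    if extra_columns is not None:
        data = scores.join(extra_columns.loc[scores.index])
    if data.shape[1] < 2:
        raise ValidationError("need at least 2 columns to correlate")
    if data.shape[0] < 3:
        raise ValidationError("need at least 3 cells")
    cols = list(data.columns)
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    rows = []
    for a, b in pairs:
        x = data[a].to_numpy(dtype=float)
        y = data[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"constant column in pair ({a}, {b}); rho undefined")
            rows.append((a, b, np.nan, np.nan, np.nan, len(x)))
            continue
        rho, p = scipy.stats.spearmanr(x, y)
        rows.append((a, b, float(rho), float(p), min(1.0, float(p) * len(pairs)), len(x)))
    return pd.DataFrame(rows, columns=["col_a", "col_b", "rho", "p", "q", "n"])


@dataclass
class OverlapResult:
    overlap: int
    p: float
    q: float
    n_a: int
    n_b: int
    genome_size: int
    shared_genes: frozenset


def overlap_test(list_a: GeneSignature, list_b: GeneSignature,
                 genome_size: int = 18000, n_comparisons: int = 1) -> OverlapResult:
    """One-sided (enrichment) Fisher exact test for gene-list overlap.

    With k shared genes out of lists of size |A| and |B| drawn from a
    genome of N genes, the p-value is the hypergeometric upper tail
    P(X >= k); ``q`` is the Bonferroni adjustment over ``n_comparisons``
    pairs.  p is monotone decreasing in k at fixed margins.
    """
    na, nb = len(list_a), len(list_b)
    if na > genome_size or nb > genome_size:
        raise ValidationError("gene list larger than the genome universe")
    shared = list_a.genes & list_b.genes
    k = len(shared)
    if na + nb - k > genome_size:
        raise ValidationError(
            f"inconsistent universe: |A|+|B|-k = {na + nb - k} exceeds genome size {genome_size}"
        )
    p = float(scipy.stats.hypergeom.sf(k - 1, genome_size, na, nb))
    p = min(1.0, p)
    return OverlapResult(k, p, min(1.0, p * n_comparisons), na, nb, genome_size,
                         frozenset(shared))


def overlap_test_table(pairs: Iterable[tuple], genome_size: int = 18000) -> pd.DataFrame:
    """Run overlap_test over (GeneSignature, GeneSignature) pairs with a shared
    Bonferroni family; returns (list_a, list_b, overlap, p, q)."""
    pairs = list(pairs)
    rows = []
    for a, b in pairs:
        r = overlap_test(a, b, genome_size=genome_size, n_comparisons=len(pairs))
        rows.append((a.name, b.name, r.overlap, r.p, r.q))
    return pd.DataFrame(rows, columns=["list_a", "list_b", "overlap", "p", "q"])


def mean_expression_heatmap(norm: NormalizedMatrix, genes: Iterable[str],
                            groups: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Group-mean expression of programme genes, z-scored per gene across groups.

    Returns genes x groups.  Means are taken on the log-normalized layer;
    the z-score uses the sample SD across groups (ddof=1), so two groups
    that differ on a gene land at +-1/sqrt(2).  Genes constant across
    groups get z = 0.
    """
    genes = [g for g in genes if g in norm.gene_ids]
    if not genes:
        raise ValidationError("none of the requested genes are in the matrix")
    cols = {}
    for name, cells in groups.items():
        cells = pd.Index(list(cells))
        if len(cells) == 0:
            raise ValidationError(f"group {name!r} is empty")
        cols[name] = norm.values.loc[genes, cells].mean(axis=1)
    frame = pd.DataFrame(cols)
    mu = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=1)
    z = frame.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return z
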