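"""Fold-enrichment signature scoring.

The score of signature S in cell c is

    score(c, S) = mean_{g in S} expr(g, c) / mean_{g in universe} expr(g, c)

on the log-normalized (non-negative) layer: the mean increase in expression
of the signature's genes relative to the mean over all expressed genes.  A
score of 1 means "no enrichment"; subpopulations are defined by scores
strictly above a threshold (2.5 by default).  Cluster- and tumor-level
scores apply the same ratio to mean expression vectors.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ClusterLabels, GeneSignature, NormalizedMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)


def _score_frame(values: pd.DataFrame, signatures: Sequence[GeneSignature]) -> pd.DataFrame:
    """Score columns of a genes x units expression frame; units = cells or clusters."""
    universe = values.index
    denom = values.mean(axis=0).to_numpy(dtype=float)
    if (denom <= 0).any():
        bad = values.columns[denom <= 0]
        raise ValidationError(f"all-zero expression for: {list(bad[:10])}")
    cols = {}
    for sig in signatures:
        present = universe.intersection(sig.sorted_genes())
        if len(present) == 0:
            raise ValidationError(f"signature {sig.name!r} has no genes in the matrix")
        if len(present) < len(sig):
            log.info("signature %r: %d of %d genes absent from matrix, dropped",
                     sig.name, len(sig) - len(present), len(sig))
        cols[sig.name] = values.loc[present].mean(axis=0).to_numpy(dtype=float) / denom
    out = pd.DataFrame(cols, index=values.columns)
    return out


def score_cells(expr: NormalizedMatrix, signatures: Sequence[GeneSignature]) -> pd.DataFrame:
    """Per-cell fold-enrichment score table (cells x signatures).

    Signature genes missing from the gene universe are dropped and logged,
    never imputed as zero.  The score is scale-free in each cell: scaling a
    cell's expression vector leaves all its scores unchanged.
    """
    out = _score_frame(expr.values, signatures)
    out.attrs["layer"] = "lognorm"
    return out


def score_clusters(expr: NormalizedMatrix, labels: ClusterLabels,
                   signatures: Sequence[GeneSignature]) -> pd.DataFrame:
    """Fold-enrichment scores of per-cluster mean expression vectors."""
    means = {}
    for c in range(labels.n_clusters):
        cells = labels.cells_in(c)
        if len(cells) == 0:
            raise ValidationError(f"cluster {c} is empty")
        means[c] = expr.values[cells].mean(axis=1)
    frame = pd.DataFrame(means)
    out = _score_frame(frame, signatures)
    out.attrs["layer"] = "lognorm cluster means"
    return out


def assign_subpopulations(scores: pd.DataFrame, programmes: Sequence[str],
                          threshold: float = 2.5) -> pd.DataFrame:
    """Boolean cell x programme membership: score strictly above threshold.

    A cell may carry zero, one, or several programme labels; a score equal
    to the threshold does not qualify.
    """
    unknown = set(programmes) - set(scores.columns)
    if unknown:
        raise ValidationError(f"unknown programmes: {sorted(unknown)}")
    return scores[list(programmes)] > threshold


def derive_atlas_signatures(
    reference_de: Mapping[str, pd.DataFrame],
    fc_min: float = 1.5,
    q_max: float = 0.05,
    universe: Iterable[str] | None = None,
) -> list[GeneSignature]:
    """Upregulation signatures from per-subtype differential expression tables.

    For each subtype keeps genes with fold change strictly above ``fc_min``
    and Bonferroni-adjusted p below ``q_max``; subtypes yielding fewer than
    one usable gene (optionally after intersecting a gene universe) are
    skipped with a logged reason rather than raising.
    """
    universe_set = set(universe) if universe is not None else None
    out = []
    for name, de in reference_de.items():
        passing = de.index[(de["fold_change"] > fc_min) & (de["p_bonferroni"] < q_max)]
        genes = list(passing)
        if universe_set is not None:
            genes = [g for g in genes if g in universe_set]
        if not genes:
            log.warning("subtype %r skipped: no usable upregulated genes "
                        "(passing=%d, in-universe=%d)", name, len(passing), len(genes))
            continue
        out.append(GeneSignature(name, genes,
                                 provenance=f"atlas DE, fc>{fc_min}, Bonferroni q<{q_max}"))
    return out


def normalize_to_tumor(scores: pd.DataFrame, labels: ClusterLabels,
                       tumor_clusters: Iterable[int]) -> pd.DataFrame:
    """Divide each signature column by its mean over tumor-cluster cells.

    After normalization the tumor-cell mean of every signature is 1, so
    immune scores read directly as enrichment over the tumor baseline.
    """
    tumor_clusters = set(tumor_clusters)
    cells = labels.labels.index[labels.labels.isin(tumor_clusters)]
    if len(cells) == 0:
        raise ValidationError(f"no cells in tumor clusters {sorted(tumor_clusters)}")
    baseline = scores.loc[scores.index.intersection(cells)].mean(axis=0)
    zero = baseline[baseline == 0]
    if len(zero):
        raise ValidationError(f"zero tumor mean for signatures: {list(zero.index)}")
    return scores / baseline


def subsample_for_comparison(scores: pd.DataFrame, cell_types: pd.Series,
                             n: int = 500, seed: int = 0):
    """Seeded per-type subsample and mean enrichment per type.

    Samples up to ``n`` cells per type uniformly without replacement (all
    cells, with a warning, when a type has fewer); returns
    ``(subset cell index, type x signature mean-score DataFrame)``.
    """
    rng = np.random.default_rng(seed)
    chosen: list = []
    means = {}
    for t in sorted(cell_types.unique()):
        cells = cell_types.index[cell_types == t]
        cells = cells.intersection(scores.index)
        if len(cells) <= n:
            if len(cells) < n:
                warnings.warn(f"type {t!r} has only {len(cells)} cells (< {n}); using all")
            picked = cells
        else:
            picked = pd.Index(rng.choice(np.asarray(cells), size=n, replace=False))
        chosen.extend(picked)
        means[t] = scores.loc[picked].mean(axis=0)
    return pd.Index(chosen), pd.DataFrame(means).T
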