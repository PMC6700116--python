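"""Compartment-signature deconvolution of bulk expression profiles.

Compartment marker lists (tumor, microglia, macrophage, T cell) are derived
from the single-cell data by one-vs-rest Wilcoxon tests with Bonferroni
control; each bulk sample is then scored per compartment by the mean
z-scored expression of that compartment's markers (z per gene across
samples), negative scores are clipped at zero, and scores are normalized to
proportions summing to 1 -- the estimated contribution of each compartment
to the bulk profile.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bonferroni as _bonf
from .cluster import cluster_markers
from .datatypes import BulkProfile, FractionEstimate, GeneSignature, NormalizedMatrix
from .errors import ValidationError
from .scoring import score_cells

log = logging.getLogger(__name__)


def compartment_signatures(norm: NormalizedMatrix, compartments: pd.Series,
                           p_max: float = 0.05) -> list[GeneSignature]:
    """One-vs-rest marker signature per compartment.

    Keeps genes with Bonferroni-adjusted Wilcoxon p below ``p_max`` and a
    positive fold change.  A compartment with an empty signature is an
    error: it cannot be deconvolved.
    """
    out = []
    for comp in sorted(compartments.unique()):
        cells_in = compartments.index[compartments == comp]
        cells_out = compartments.index[compartments != comp]
        de = cluster_markers(norm, groups=(cells_in, cells_out))
        genes = de.index[(de["p_bonferroni"] < p_max) & (de["log_fold_change"] > 0)]
        if len(genes) == 0:
            raise ValidationError(f"compartment {comp!r} yields an empty marker signature")
        out.append(GeneSignature(str(comp), list(genes),
                                 provenance=f"one-vs-rest Wilcoxon, Bonferroni p<{p_max}"))
    return out


def estimate_fractions(bulk: BulkProfile, signatures: Sequence[GeneSignature],
                       log_transform: bool = False,
                       negative_scores: str = "shift") -> FractionEstimate:
    """Estimate per-sample compartment proportions from marker signatures.

    Steps: (i) intersect each signature with the bulk gene universe,
    counting discarded genes; (ii) z-score each gene across samples;
    (iii) compartment score = mean z over the signature's genes;
    (iv) handle negative scores -- the default ``"shift"`` translates each
    sample's scores so the smallest is zero, preserving the rank information
    that plain clipping destroys (z-scores are zero-mean across samples, so
    clipping would pin every below-average sample to fraction 0);
    ``"clip"`` truncates at zero instead; (v) normalize to sum 1.
    A sample with all-zero scores gets uniform fractions with a warning.

    Fractions are invariant to per-gene affine transforms of the bulk
    matrix (the z-score absorbs them) and equivariant under compartment
    relabeling.
    """
    if len(signatures) < 2:
        raise ValidationError("need at least 2 compartments to deconvolve")
    values = bulk.values
    if log_transform:
        values = np.log1p(values)
    universe = values.index
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zf = pd.DataFrame(z, index=universe, columns=values.columns)

    used = {}
    discarded = 0
    raw = {}
    for sig in signatures:
        present = universe.intersection(sig.sorted_genes())
        discarded += len(sig) - len(present)
        if len(present) == 0:
            raise ValidationError(
                f"signature {sig.name!r} has no genes on the bulk platform"
            )
        used[sig.name] = frozenset(present)
        raw[sig.name] = zf.loc[present].mean(axis=0)
    scores = pd.DataFrame(raw)  # samples x compartments
    if negative_scores == "clip":
        scores = scores.clip(lower=0.0)
    elif negative_scores == "shift":
        scores = scores.sub(scores.min(axis=1).clip(upper=0.0), axis=0)
    else:
        raise ValueError(f"unknown negative_scores policy {negative_scores!r}")
    totals = scores.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} samples with all-zero compartment scores; "
                      "assigning uniform fractions")
        scores.loc[zero, :] = 1.0
        totals = scores.sum(axis=1)
    fractions = scores.div(totals, axis=0)
    return FractionEstimate(fractions, used, genes_discarded=discarded)


def location_signature_enrichment(gene_set: GeneSignature, norm: NormalizedMatrix,
                                  compartments: pd.Series) -> pd.DataFrame:
    """Score a bulk-derived gene set in each single-cell compartment.

    Returns one row per compartment: mean fold-enrichment score of the gene
    set in that compartment's cells, the two-sided Wilcoxon rank-sum p for
    compartment-vs-rest score differences, and its Bonferroni adjustment
    over the compartments tested.
    """
    scores = score_cells(norm, [gene_set])[gene_set.name]
    from ._stats import rank_sum_p

    comps = sorted(compartments.unique())
    rows = []
    for comp in comps:
        cells_in = compartments.index[compartments == comp]
        cells_out = compartments.index[compartments != comp]
        p = rank_sum_p(scores.loc[cells_in].to_numpy(), scores.loc[cells_out].to_numpy())
        rows.append((comp, float(scores.loc[cells_in].mean()), p))
    out = pd.DataFrame(rows, columns=["compartment", "mean_score", "p_value"])
    out["p_bonferroni"] = _bonf(out["p_value"].to_numpy(), len(comps))
    return out.set_index("compartment")
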