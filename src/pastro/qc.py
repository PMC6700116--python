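"""Quality filtering, normalization, covariate regression, variable genes.

The QC rules are species-specific: human cells need >=1000 expressed genes
and <=4% mitochondrial counts, mouse cells >=3000 genes and <=3%.  Cells are
filtered first, then genes expressed in too few of the retained cells are
dropped.  "Expressed" means count > 0; the mitochondrial fraction is taken
on raw counts.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import CountMatrix, NormalizedMatrix, ScaledMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_MITO_PREFIXES = ("MT-", "mt-")


def mito_fraction(counts: CountMatrix, mito_prefixes=DEFAULT_MITO_PREFIXES,
                  mito_genes: Iterable[str] | None = None) -> pd.Series:
    """Per-cell fraction of counts attributed to mitochondrial genes."""
    if mito_genes is not None:
        mask = counts.gene_ids.isin(list(mito_genes))
    else:
        mask = counts.gene_ids.str.startswith(tuple(mito_prefixes))
    totals = counts.values.sum(axis=0)
    if (totals == 0).any():
        zero = counts.cell_ids[totals == 0]
        raise ValidationError(f"cells with zero total counts: {list(zero[:10])}")
    return counts.values.loc[mask].sum(axis=0) / totals


def qc_filter(
    counts: CountMatrix,
    config: PipelineConfig | None = None,
    mito_prefixes=DEFAULT_MITO_PREFIXES,
    mito_genes: Iterable[str] | None = None,
):
    """Apply cell-level then gene-level quality filters.

    Returns ``(filtered CountMatrix, report DataFrame)`` where the report
    records (step, n_removed, n_remaining) for each filter.  Raises if no
    cell or no gene survives, embedding the attrition table in the message.

    The filter is idempotent on its own output as long as removing rare
    genes does not push a cell below the expressed-gene threshold, which
    holds for any cell passing with a margin wider than the number of rare
    genes it expresses.
    """
    config = config or PipelineConfig()
    species = counts.cell_meta["species"]
    expressed = (counts.values > 0).sum(axis=0)
    min_genes = species.map(config.min_genes).astype(int)
    max_mito = species.map(config.max_mito).astype(float)
    mito = mito_fraction(counts, mito_prefixes, mito_genes)

    pass_genes = expressed >= min_genes
    pass_mito = mito <= max_mito
    keep_cells = pass_genes & pass_mito

    steps = [
        ("cells_low_expressed_genes", int((~pass_genes).sum())),
        ("cells_high_mito_fraction", int((pass_genes & ~pass_mito).sum())),
    ]
    retained = counts.values.loc[:, keep_cells]
    n_cells = retained.shape[1]

    gene_prevalence = (retained > 0).sum(axis=1)
    keep_genes = gene_prevalence >= config.min_cells_per_gene
    steps.append(("genes_in_few_cells", int((~keep_genes).sum())))
    retained = retained.loc[keep_genes]

    report = pd.DataFrame(steps, columns=["step", "n_removed"])
    report["n_remaining"] = [
        counts.n_cells - steps[0][1],
        n_cells,
        retained.shape[0],
    ]
    if n_cells == 0 or retained.shape[0] == 0:
        raise ValidationError(f"no cells or genes survive QC:\n{report.to_string(index=False)}")
    out = CountMatrix(retained, counts.cell_meta.loc[retained.columns], unit=counts.unit)
    return out, report


def log_normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """``value(g, c) = ln(1 + count(g, c) / total(c) * scale_factor)``.

    Conservation property: per cell, ``sum(exp(value) - 1) == scale_factor``.
    """
    totals = counts.values.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        zero = counts.cell_ids[totals == 0]
        raise ValidationError(f"zero-total cells cannot be normalized: {list(zero[:10])}")
    vals = np.log1p(counts.values.to_numpy(dtype=float) / totals * scale_factor)
    frame = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.cell_ids)
    return NormalizedMatrix(frame, scale_factor=scale_factor, source_unit=counts.unit)


def _design_matrix(cell_ids: pd.Index, covariates: pd.DataFrame | None):
    cols = ["intercept"]
    n = len(cell_ids)
    parts = [np.ones((n, 1))]
    if covariates is not None:
        cov = covariates.loc[cell_ids]
        if "n_detected_genes" in cov.columns:
            parts.append(cov["n_detected_genes"].to_numpy(dtype=float).reshape(-1, 1))
            cols.append("n_detected_genes")
        if "tumor_of_origin" in cov.columns:
            dummies = pd.get_dummies(cov["tumor_of_origin"], drop_first=True, dtype=float)
            if dummies.shape[1]:
                parts.append(dummies.to_numpy())
                cols.extend(f"tumor_of_origin[{c}]" for c in dummies.columns)
    X = np.hstack(parts)
    return X, cols


def scale_and_regress(
    norm: NormalizedMatrix, covariates: pd.DataFrame | None = None
) -> ScaledMatrix:
    """OLS residuals per gene against technical covariates, then z-scored.

    The design is [intercept, n_detected_genes, tumor-of-origin indicators],
    restricted to whichever covariate columns are supplied; with no
    covariates this reduces to a plain per-gene z-score.  Residuals are
    standardized to mean 0 / population SD 1; zero-variance genes map to
    all-zero rows.  A rank-deficient design (e.g. one cell per tumor level
    making indicators collinear) is an error.
    """
    X, cols = _design_matrix(norm.cell_ids, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            "singular covariate design matrix; drop a covariate "
            f"(rank {rank} < {X.shape[1]} columns: {cols})"
        )
    Y = norm.values.to_numpy(dtype=float)  # genes x cells
    # residual maker: R = Y (I - X (X'X)^-1 X')
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    sd = resid.std(axis=1, ddof=0)
    mean = resid.mean(axis=1)
    out = np.zeros_like(resid)
    nz = sd > 1e-12
    out[nz] = (resid[nz] - mean[nz, None]) / sd[nz, None]
    frame = pd.DataFrame(out, index=norm.gene_ids, columns=norm.cell_ids)
    return ScaledMatrix(frame, regressed_covariates=tuple(cols[1:]))


def select_variable_genes(
    norm: NormalizedMatrix, config: PipelineConfig | None = None
) -> set:
    """Genes with mean log-normalized expression in [0.25, 5] and SD > 1.

    Bounds on the mean are closed, the SD threshold is strict; both are on
    the log-normalized (not scaled) values.
    """
    config = config or PipelineConfig()
    lo, hi = config.var_gene_mean_range
    means = norm.values.mean(axis=1)
    sds = norm.values.std(axis=1, ddof=0)
    chosen = norm.gene_ids[(means >= lo) & (means <= hi) & (sds > config.var_gene_sd_min)]
    if len(chosen) == 0:
        raise ValidationError(
            "no variable genes under current thresholds; consider relaxing "
            f"var_gene_mean_range={config.var_gene_mean_range} or "
            f"var_gene_sd_min={config.var_gene_sd_min}"
        )
    return set(chosen)


def purge_immune_from_cancer(
    cells: Iterable[str],
    norm: NormalizedMatrix,
    config: PipelineConfig | None = None,
    gene: str = "GZMB",
):
    """Drop putative immune contaminants from a cancer cell set.

    Removes cells whose log-normalized expression of ``gene`` (GZMB, a
    cytotoxic-lymphocyte granzyme) exceeds the configured threshold
    (strict ``>``; a cell sitting exactly on the threshold is retained).
    Returns ``(retained cell ids, removed cell ids)``.
    """
    config = config or PipelineConfig()
    if gene not in norm.gene_ids:
        raise ValidationError(f"purge gene {gene!r} absent from the gene universe")
    cells = pd.Index(list(cells))
    missing = cells.difference(norm.cell_ids)
    if len(missing):
        raise ValidationError(f"cells not in matrix: {sorted(missing)[:10]}")
    expr = norm.values.loc[gene, cells]
    removed = cells[(expr > config.gzmb_filter).to_numpy()]
    kept = cells.difference(removed, sort=False)
    if len(removed):
        log.info("purged %d cells with %s > %g", len(removed), gene, config.gzmb_filter)
    return kept, removed
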