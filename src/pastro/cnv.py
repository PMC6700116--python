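"""Expression-based CNV inference by 100-gene windowed averaging.

Genes are ordered along the genome (by chromosome, then start coordinate);
per cell, log-normalized expression is averaged over sliding windows of 100
consecutive genes within each chromosome, and every window value is
centered by subtracting that window's mean over a reference cell set (all
cancer cells by default, the cell itself included).  Large chromosomal
gains or losses then appear as contiguous runs of windows shifted up or
down in carrier cells.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import CnvMatrix, GenePositions, NormalizedMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)


def infer_cnv(
    expr: NormalizedMatrix,
    positions: GenePositions,
    cells: Iterable[str] | None = None,
    window: int = 100,
    truncate_short: bool = True,
    leave_one_out: bool = False,
    min_position_coverage: float = 0.8,
) -> CnvMatrix:
    """Reference-relative moving-window expression along the genome.

    ``cells`` is both the cell set analyzed and the reference population
    (each window is centered on its mean over these cells; with
    ``leave_one_out`` each cell is excluded from its own reference, an
    O(1/n) refinement that is off by default).  Chromosomes with fewer than
    ``window`` genes contribute one truncated, flagged window when
    ``truncate_short`` is set and are skipped otherwise.  Genes without a
    genomic position are dropped (at most ``1 - min_position_coverage`` of
    the expressed genes, else an error).
    """
    cells = pd.Index(list(cells)) if cells is not None else expr.cell_ids
    missing_cells = cells.difference(expr.cell_ids)
    if len(missing_cells):
        raise ValidationError(f"cells not in matrix: {sorted(missing_cells)[:10]}")
    covered = expr.gene_ids.intersection(positions.gene_ids)
    coverage = len(covered) / max(len(expr.gene_ids), 1)
    if coverage < min_position_coverage:
        raise ValidationError(
            f"gene positions cover only {coverage:.0%} of expressed genes "
            f"(need >= {min_position_coverage:.0%})"
        )
    n_dropped = len(expr.gene_ids) - len(covered)
    if n_dropped:
        log.info("dropping %d genes without genomic positions", n_dropped)

    ordered = positions.ordered_genes(covered)
    X = expr.values.loc[ordered.index, cells].to_numpy(dtype=float)

    rows = []
    meta = []
    offset = 0
    for chrom in dict.fromkeys(ordered["chromosome"]):
        genes = ordered.index[ordered["chromosome"] == chrom]
        block = X[offset:offset + len(genes)]
        offset += len(genes)
        if len(genes) >= window:
            csum = np.cumsum(block, axis=0)
            csum = np.vstack([np.zeros((1, block.shape[1])), csum])
            win = (csum[window:] - csum[:-window]) / window  # sliding, step 1
            for i in range(win.shape[0]):
                meta.append((chrom, genes[i], genes[i + window - 1], i, i + window - 1, False))
            rows.append(win)
        elif truncate_short:
            log.info("chromosome %s has %d < %d genes; single truncated window",
                     chrom, len(genes), window)
            rows.append(block.mean(axis=0, keepdims=True))
            meta.append((chrom, genes[0], genes[-1], 0, len(genes) - 1, True))
        else:
            log.info("chromosome %s skipped (%d < %d genes)", chrom, len(genes), window)
    if not rows:
        raise ValidationError(
            f"no chromosome reaches the window size {window} and truncation is disabled"
        )
    W = np.vstack(rows)
    if leave_one_out:
        n = W.shape[1]
        if n < 2:
            raise ValidationError("leave-one-out reference needs at least 2 cells")
        totals = W.sum(axis=1, keepdims=True)
        W = W - (totals - W) / (n - 1)
    else:
        W = W - W.mean(axis=1, keepdims=True)
    window_meta = pd.DataFrame(
        meta, columns=["chromosome", "start_gene", "end_gene", "start_order",
                       "end_order", "truncated"],
    )
    window_meta.index = [f"{m[0]}:{i}" for i, m in zip(window_meta.groupby("chromosome").cumcount(), meta)]
    values = pd.DataFrame(W, index=window_meta.index, columns=cells)
    return CnvMatrix(values, window_meta)


def summarize_arm_calls(
    cnv: CnvMatrix,
    arm_of: Mapping[str, str] | None = None,
    cutoff: float = 0.2,
):
    """Per-cell per-arm mean window values with gain/loss flags.

    ``arm_of`` maps chromosome name to arm name; by default each chromosome
    is its own arm.  A cell is flagged ``gain`` on an arm if its mean
    window value exceeds ``cutoff`` and ``loss`` below ``-cutoff``; the
    cutoff is a display/report threshold, not part of the inference.
    Returns ``(arm x cell mean DataFrame, arm x cell call DataFrame)``.
    """
    chroms = cnv.window_meta["chromosome"]
    arms = chroms.map(arm_of) if arm_of is not None else chroms
    if arms.isna().any():
        skipped = sorted(chroms[arms.isna()].unique())
        log.warning("chromosomes without an arm mapping skipped: %s", skipped)
    means = {}
    for arm in dict.fromkeys(arms.dropna()):
        rows = cnv.values.loc[(arms == arm).to_numpy()]
        means[arm] = rows.mean(axis=0)
    arm_means = pd.DataFrame(means).T
    calls = pd.DataFrame("neutral", index=arm_means.index, columns=arm_means.columns)
    calls = calls.mask(arm_means > cutoff, "gain").mask(arm_means < -cutoff, "loss")
    return arm_means, calls
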