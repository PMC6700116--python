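"""Typed containers for the pilocytic-astrocytoma expression pipeline.

Matrices are stored gene-major (genes as rows, cells/samples as columns),
the dominant scRNA-seq interchange convention.  Gene and cell identifiers
are opaque, case-sensitive strings; human/mouse harmonisation happens only
through explicit ortholog tables (:func:`pastro.io.map_orthologs`).

Every container validates its invariants at construction so downstream code
can rely on them without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

CELL_META_COLUMNS = ("tumor_of_origin", "marker_status", "fusion_status", "species")

MARKER_STATUS_VALUES = {"positive", "negative", "unknown"}
FUSION_STATUS_VALUES = {"detected", "not_detected", "not_assayed"}
SPECIES_VALUES = {"human", "mouse"}


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = sorted(index[index.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


def default_cell_meta(cell_ids: Iterable[str], species: str = "human") -> pd.DataFrame:
    """Minimal per-cell annotation table for cells with no known metadata."""
    idx = pd.Index(list(cell_ids), name="cell_id")
    return pd.DataFrame(
        {
            "tumor_of_origin": "unknown",
            "marker_status": "unknown",
            "fusion_status": "not_assayed",
            "species": species,
        },
        index=idx,
    )


@dataclass
class CountMatrix:
    """Raw gene x cell expression with per-cell annotations.

    ``unit`` is ``"counts"`` for integer read/UMI counts (integrality is
    enforced) or ``"tpm_like"`` for continuous TPM-style input, which the
    pipeline treats identically downstream while recording what was supplied.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "cell ids")
        arr = self.values.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValidationError("negative expression values in count matrix")
        if self.unit == "counts":
            if arr.size and not np.allclose(arr, np.round(arr)):
                raise ValidationError("non-integer values in a matrix declared as counts")
        elif self.unit != "tpm_like":
            raise ValidationError(f"unknown unit {self.unit!r}")
        missing = self.values.columns.difference(self.cell_meta.index)
        if len(missing):
            raise ValidationError(f"cell_meta missing cells: {sorted(missing)[:10]}")
        self.cell_meta = self.cell_meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, genes=None, cells=None) -> "CountMatrix":
        vals = self.values
        if genes is not None:
            vals = vals.loc[list(genes)]
        if cells is not None:
            vals = vals[list(cells)]
        return CountMatrix(vals, self.cell_meta.loc[vals.columns], unit=self.unit)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ``ln(1 + count/total * scale_factor)``."""

    values: pd.DataFrame
    scale_factor: float = 10_000.0
    log_base: str = "natural"
    source_unit: str = "counts"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "cell ids")
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")
        arr = self.values.to_numpy()
        if arr.size and arr.min() < -1e-12:
            raise ValidationError("log-normalized values must be non-negative")
        if self.log_base != "natural":
            raise ValidationError("only natural-log normalization is supported")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ScaledMatrix:
    """Per-gene standardized residuals after covariate regression.

    For every gene with nonzero residual variance the row has mean ~0 and
    SD ~1 across cells (population SD); zero-variance genes are all-zero.
    """

    values: pd.DataFrame
    regressed_covariates: tuple = ()

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "cell ids")
        self.regressed_covariates = tuple(self.regressed_covariates)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneSignature:
    """A named, nonempty gene set with a free-text provenance note."""

    name: str
    genes: frozenset = field(default_factory=frozenset)
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def sorted_genes(self) -> list:
        return sorted(self.genes)

    def restrict(self, universe: Iterable[str]) -> "GeneSignature":
        """Intersect with a gene universe; raises if nothing survives."""
        kept = self.genes & set(universe)
        if not kept:
            raise ValidationError(
                f"signature {self.name!r} has no genes in the supplied universe"
            )
        dropped = len(self.genes) - len(kept)
        prov = self.provenance
        if dropped:
            prov = f"{prov}; {dropped} genes outside universe dropped".lstrip("; ")
        return GeneSignature(self.name, kept, prov)


class GenePositions:
    """Genomic placement of genes: chromosome, 0-based half-open start/end.

    ``order_index`` is the rank of the gene by start coordinate within its
    chromosome -- the total order the 100-gene CNV windows slide along.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chromosome", "start"}
        if not required.issubset(table.columns):
            raise ValidationError(f"gene position table needs columns {sorted(required)}")
        _check_unique(table.index, "gene ids")
        if (table["start"].to_numpy() < 0).any():
            raise ValidationError("negative start coordinate")
        tab = table.copy()
        tab["order_index"] = (
            tab.groupby("chromosome", sort=False)["start"]
            .rank(method="first")
            .astype(int)
            - 1
        )
        self.table = tab

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    def ordered_genes(self, genes: Iterable[str] | None = None) -> pd.DataFrame:
        """Rows sorted by (chromosome, start), optionally restricted."""
        tab = self.table
        if genes is not None:
            tab = tab.loc[tab.index.intersection(list(genes))]
        chrom_order = {c: i for i, c in enumerate(self.chromosomes())}
        key = tab["chromosome"].map(chrom_order)
        return tab.iloc[np.lexsort((tab["start"].to_numpy(), key.to_numpy()))]


@dataclass
class ClusterLabels:
    """Cell -> 0-based contiguous cluster assignment plus algorithm parameters."""

    labels: pd.Series
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "cell ids")
        vals = np.asarray(self.labels, dtype=int)
        uniq = np.unique(vals)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValidationError("cluster indices must be contiguous from 0")
        self.labels = pd.Series(vals, index=self.labels.index, name="cluster")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cells_in(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]


@dataclass
class BulkProfile:
    """Bulk expression (genes x samples) with optional sample metadata."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if self.values.to_numpy().size and self.values.to_numpy().min() < 0:
            raise ValidationError("bulk profile has negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class FractionEstimate:
    """Per-sample compartment proportions (rows sum to 1) and their provenance."""

    fractions: pd.DataFrame
    signatures: Mapping[str, frozenset]
    genes_discarded: int = 0

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy()
        if arr.size:
            if arr.min() < -1e-12:
                raise ValidationError("negative compartment fraction")
            if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValidationError("fractions do not sum to 1 per sample")


@dataclass
class CnvMatrix:
    """Window x cell reference-relative expression plus window metadata.

    ``window_meta`` columns: chromosome, start_gene, end_gene, start_order,
    end_order, truncated.
    """

    values: pd.DataFrame
    window_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.values) != len(self.window_meta):
            raise ValidationError("window metadata does not match value rows")
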