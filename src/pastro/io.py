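"""Readers and writers for the standard formats the pipeline touches.

Supported inputs: Matrix Market triplet matrices with gene/cell TSV
sidecars (10x convention: genes are rows, cells are columns), dense TSV
matrices (first column = gene id, header = cell ids), GMT gene-set files,
and BED-like TSV gene position tables.  All coordinates are held 0-based
half-open internally; a converter for 1-based inclusive input is provided.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import CountMatrix, GenePositions, GeneSignature, default_cell_meta
from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# count matrices


def _sidecar_paths(mtx_path: Path, genes_path, cells_path):
    genes = Path(genes_path) if genes_path else mtx_path.with_name("genes.tsv")
    if cells_path:
        cells = Path(cells_path)
    else:
        cells = mtx_path.with_name("cells.tsv")
        if not cells.exists():
            cells = mtx_path.with_name("barcodes.tsv")
    return genes, cells


def _read_id_column(path: Path, what: str) -> list:
    if not path.exists():
        raise FormatError(f"missing {what} sidecar: {path}")
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    if not ids:
        raise FormatError(f"{what} sidecar {path} is empty")
    return ids


def read_counts(
    path,
    format: str = "mtx",
    genes_path=None,
    cells_path=None,
    cell_meta: pd.DataFrame | None = None,
    unit: str = "counts",
) -> CountMatrix:
    """Read a gene x cell count matrix from MTX (+ sidecars) or dense TSV.

    Order of genes and cells is preserved from file.  Raises
    :class:`FormatError` for malformed files and :class:`ValidationError`
    for duplicate identifiers or negative / non-integer counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        genes_p, cells_p = _sidecar_paths(path, genes_path, cells_path)
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise FormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_ids = _read_id_column(genes_p, "gene")
        cell_ids = _read_id_column(cells_p, "cell")
        if arr.shape != (len(gene_ids), len(cell_ids)):
            raise FormatError(
                f"matrix shape {arr.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
        values = pd.DataFrame(arr, index=pd.Index(gene_ids, name="gene_id"),
                              columns=pd.Index(cell_ids, name="cell_id"))
    elif format == "tsv":
        try:
            values = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise FormatError(f"malformed TSV matrix {path}: {exc}") from exc
        values.index.name = "gene_id"
        values.columns.name = "cell_id"
        if values.isna().to_numpy().any():
            raise FormatError(f"ragged or missing entries in TSV matrix {path}")
    else:
        raise ValueError(f"unknown format {format!r}")
    if unit == "counts":
        arr = values.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"non-integer counts in {path}")
        values = values.round().astype(np.int64)
    meta = cell_meta if cell_meta is not None else default_cell_meta(values.columns)
    return CountMatrix(values, meta, unit=unit)


def write_counts(counts: CountMatrix, path, format: str = "mtx") -> None:
    """Write a CountMatrix as MTX + genes.tsv/cells.tsv sidecars, or dense TSV."""
    path = Path(path)
    if format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        sp = scipy.sparse.coo_matrix(counts.values.to_numpy())
        scipy.io.mmwrite(path, sp, field="integer" if counts.unit == "counts" else "real")
        path.with_name("genes.tsv").write_text("\n".join(counts.gene_ids) + "\n")
        path.with_name("cells.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    elif format == "tsv":
        counts.values.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# gene sets


def read_signatures(path) -> list[GeneSignature]:
    """Parse a GMT file: one signature per line (name, description, genes...).

    Duplicate genes within a line are collapsed with a logged warning; an
    empty gene list raises a :class:`ValidationError` naming the line.
    """
    path = Path(path)
    signatures = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
            raise ValidationError(f"{path}:{lineno}: gene set {parts[0]!r} has no genes")
        name, description = parts[0], parts[1]
        genes = [g.strip() for g in parts[2:] if g.strip()]
        unique = list(dict.fromkeys(genes))
        if len(unique) < len(genes):
            log.warning(
                "%s:%d: %d duplicate genes collapsed in %r",
                path, lineno, len(genes) - len(unique), name,
            )
        signatures.append(GeneSignature(name, unique, provenance=f"{path}:{lineno} {description}"))
    return signatures


def write_signatures(signatures: Iterable[GeneSignature], path) -> None:
    lines = [
        "\t".join([s.name, s.provenance or "."] + s.sorted_genes())
        for s in signatures
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def map_orthologs(signature: GeneSignature, table: Mapping[str, str]) -> GeneSignature:
    """Translate a signature through a one-to-one (or one-to-none) gene map.

    Genes without a mapping are dropped and counted in the provenance note;
    an empty result is an error.
    """
    mapped = {table[g] for g in signature.genes if g in table}
    dropped = len(signature.genes) - sum(g in table for g in signature.genes)
    if not mapped:
        raise ValidationError(f"signature {signature.name!r} empty after mapping")
    prov = signature.provenance
    note = f"ortholog-mapped, {dropped} of {len(signature)} genes dropped"
    prov = f"{prov}; {note}" if prov else note
    return GeneSignature(signature.name, mapped, prov)


def read_ortholog_table(path, from_col: int = 0, to_col: int = 1) -> dict:
    """Two-column TSV (source gene, target gene) -> dict, later rows win."""
    table = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) <= max(from_col, to_col):
            raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
        table[parts[from_col].strip()] = parts[to_col].strip()
    return table


# ---------------------------------------------------------------------------
# gene positions


def read_gene_positions(path, one_based: bool = False) -> GenePositions:
    """Read a BED-like TSV (chrom, start, end, gene_id) into GenePositions.

    With ``one_based=True`` the input is interpreted as 1-based inclusive
    and converted to the internal 0-based half-open convention.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns (chrom, start, end, gene)")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if one_based:
            start -= 1
        rows.append((parts[3].strip(), parts[0].strip(), start, end))
    frame = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    frame = frame.set_index("gene_id")
    return GenePositions(frame)


def write_gene_positions(positions: GenePositions, path) -> None:
    tab = positions.table
    with open(path, "w") as fh:
        for gene, row in tab.iterrows():
            end = row["end"] if "end" in tab.columns else row["start"] + 1
            fh.write(f"{row['chromosome']}\t{row['start']}\t{end}\t{gene}\n")
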