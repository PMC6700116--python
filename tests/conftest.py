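"""Shared fixtures: one default synthetic dataset run through the pipeline.

Session-scoped so the expensive simulation + QC + normalization happen once
and every test file reuses them read-only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pastro


@pytest.fixture(scope="session")
def sim():
    """Default synthetic tumor dataset: (CountMatrix, SyntheticTruth)."""
    return pastro.simulate_cells(pastro.GeneratorParams(seed=0))


@pytest.fixture(scope="session")
def pipeline(sim):
    """QC-filtered, normalized default dataset with truth aligned to cells."""
    counts, truth = sim
    filtered, report = pastro.qc_filter(counts)
    norm = pastro.log_normalize(filtered)
    t = truth.cells.loc[norm.cell_ids]
    cov = pd.DataFrame(
        {
            "n_detected_genes": (filtered.values > 0).sum(axis=0),
            "tumor_of_origin": filtered.cell_meta["tumor_of_origin"],
        }
    )
    return {
        "counts": filtered,
        "report": report,
        "norm": norm,
        "truth": truth,
        "t": t,
        "covariates": cov,
    }


@pytest.fixture(scope="session")
def cancer_norm(pipeline):
    """Log-normalized matrix restricted to cancer cells, plus aligned truth."""
    t = pipeline["t"]
    cancer = t.index[t["compartment"] == "cancer"]
    norm = pastro.NormalizedMatrix(pipeline["norm"].values[cancer])
    return norm, t.loc[cancer]


@pytest.fixture(scope="session")
def module_signatures(pipeline):
    truth = pipeline["truth"]
    return {m: pastro.GeneSignature(m, truth.modules[m]) for m in truth.modules}


@pytest.fixture(scope="session")
def cancer_scores(cancer_norm, module_signatures):
    norm, _ = cancer_norm
    sigs = [module_signatures[m] for m in ("mapk", "ac", "cycling", "senescence")]
    return pastro.score_cells(norm, sigs)


def tiny_counts(values: np.ndarray, genes=None, cells=None, **kw) -> pastro.CountMatrix:
    """Build a CountMatrix from a raw array with auto-generated identifiers."""
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                         columns=pd.Index(cells, name="cell_id"))
    return pastro.CountMatrix(frame, pastro.default_cell_meta(frame.columns), **kw)


def tiny_norm(values: np.ndarray, genes=None, cells=None) -> pastro.NormalizedMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                         columns=pd.Index(cells, name="cell_id"))
    return pastro.NormalizedMatrix(frame)
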