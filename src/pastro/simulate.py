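"""Synthetic single-cell and bulk data with full ground truth.

The generator emulates the population structure of a BRAF-fusion pilocytic
astrocytoma sequenced at single-cell resolution:

* four cell compartments -- cancer (~45%), microglia (~30%, the dominant
  immune population), macrophages and T cells -- each with a planted
  50-gene marker module;
* cancer cells occupying discrete programme states: a MAPK-high
  progenitor-like minority (~30%), an astrocyte-like (AC) majority (~60%),
  a small intermediate group, and a rare oligodendrocyte-like (OC) branch
  with moderate MAPK activity.  MAPK and AC activities are anti-correlated
  by construction;
* mutually exclusive cycling and senescent subsets confined to the
  MAPK-high cells;
* negative-binomial counts with log-normal library sizes, optional extra
  dropout, dedicated mitochondrial genes realising a target mito fraction,
  and optional planted QC-failing cells and GZMB+ immune contaminants;
* one chromosome-arm CNV block (log-shifted expression over a contiguous
  gene run in a subset of cancer cells);
* bulk samples as known convex (Dirichlet) mixtures of compartment mean
  profiles with multiplicative noise.

Every dataset is reproducible from its seed, and the returned truth object
is sufficient to recompute every planted quantity independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import BulkProfile, CountMatrix, GenePositions, NormalizedMatrix
from .errors import ValidationError

COMPARTMENTS = ("cancer", "microglia", "macrophage", "tcell")
MODULES = ("mapk", "ac", "oc", "cycling", "senescence",
           "microglia", "macrophage", "tcell")


@dataclass
class GeneratorParams:
    """Knobs of the human-tumor generator; defaults are the study conditions.

    Effect sizes are natural-log activations applied to a module's genes at
    activity 1: 3.5 ln-units lifts a ~6-count module gene to ~200 counts,
    which puts a fully activated 50-gene module at a fold-enrichment score
    above 3 while inactive cells stay near 1 and partially active states
    (intermediate, OC-branch MAPK) stay safely below the 2.5 subpopulation
    threshold.
    """

    n_genes: int = 2000
    n_cancer: int = 450
    n_microglia: int = 300
    n_macrophage: int = 100
    n_tcell: int = 150
    module_size: int = 50
    module_baseline_count: float = 6.0
    activation_effect: float = 3.5   # cancer programme modules
    marker_effect: float = 2.5       # immune compartment markers
    # cancer programme state frequencies
    mapk_frac: float = 0.30
    ac_frac: float = 0.60
    intermediate_frac: float = 0.05
    oc_frac: float = 0.05
    cycling_frac: float = 0.25       # of MAPK-high cells
    senescent_frac: float = 0.25     # of MAPK-high cells, disjoint from cycling
    # senescence activity = coupling * mapk + (1 - coupling) * flag: oncogene-
    # induced senescence rides on MAPK dosage, with strong activation confined
    # to a flagged subset of MAPK-high cells; cycling is flag-only
    senescence_mapk_coupling: float = 0.3
    # basal stochastic programme activity added to every cancer cell's
    # mapk/ac/cycling/senescence activities (uniform on [0, jitter])
    basal_activity_jitter: float = 0.15
    # noise model
    nb_phi: float = 0.1              # var = mu + phi * mu^2
    library_sigma: float = 0.35
    target_total: float = 20_000.0
    dropout: float = 0.1
    # mitochondrial genes
    n_mito_genes: int = 13
    mito_fraction_mean: float = 0.015
    mito_fraction_sd: float = 0.004
    mito_fail_fraction: float = 0.10
    # planted pathological cells
    n_qc_fail_low: int = 0
    n_qc_fail_mito: int = 0
    n_gzmb_contaminants: int = 0
    gzmb_contaminant_mean: float = 300.0
    # genome layout / CNV
    n_chromosomes: int = 10
    cnv_chromosome: str = "chr5"
    cnv_n_genes: int = 150
    cnv_shift: float = 0.4
    cnv_carrier_frac: float = 0.4
    # bulk mixtures
    n_bulk_samples: int = 50
    dirichlet_alpha: tuple = (5.7, 3.0, 0.8, 0.5)  # cancer, microglia, macrophage, tcell
    bulk_noise_sigma: float = 0.1
    n_tumors: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = [self.n_genes, self.n_cancer, self.n_microglia, self.n_macrophage,
                 self.n_tcell, self.module_size, self.n_mito_genes, self.n_chromosomes]
        if any(s <= 0 for s in sizes):
            raise ValidationError("all sizes must be positive")
        for eff in (self.activation_effect, self.marker_effect, self.cnv_shift):
            if not np.isfinite(eff):
                raise ValidationError("effect sizes must be finite")
        reserved = len(MODULES) * self.module_size + self.n_mito_genes + 1
        if reserved > self.n_genes:
            raise ValidationError(
                f"module layout needs {reserved} genes but n_genes={self.n_genes}"
            )
        frac_sum = self.mapk_frac + self.ac_frac + self.intermediate_frac + self.oc_frac
        if abs(frac_sum - 1.0) > 1e-9:
            raise ValidationError("cancer state fractions must sum to 1")
        if self.cycling_frac + self.senescent_frac > 1.0:
            raise ValidationError("cycling and senescent subsets must be disjoint")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset.

    ``cells`` has one row per cell: compartment, programme state, planted
    activities, cycling/senescent/CNV-carrier flags, QC-fail class and
    contaminant flag.  ``modules`` maps module name to its planted gene
    list; ``cnv_segments`` records (chromosome, gene span, shift, carriers).
    """

    cells: pd.DataFrame
    modules: dict
    cnv_segments: list
    positions: GenePositions
    seed: int
    params: GeneratorParams
    bulk_weights: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    @property
    def mapk_high_cells(self) -> pd.Index:
        return self.cells.index[self.cells["state"] == "mapk"]


def _gene_names(params: GeneratorParams) -> list:
    names = [f"G{i:04d}" for i in range(params.n_genes)]
    names[-params.n_mito_genes:] = [f"MT-{i + 1}" for i in range(params.n_mito_genes)]
    names[-(params.n_mito_genes + 1)] = "GZMB"
    return names


def _gene_layout(params: GeneratorParams):
    """Module gene index blocks and the genomic position table."""
    modules = {}
    for i, mod in enumerate(MODULES):
        lo = i * params.module_size
        modules[mod] = np.arange(lo, lo + params.module_size)
    chunk = int(np.ceil(params.n_genes / params.n_chromosomes))
    chroms = [f"chr{i // chunk + 1}" for i in range(params.n_genes)]
    starts = [(i % chunk) * 1000 for i in range(params.n_genes)]
    return modules, chroms, starts, chunk


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with var = mu + phi mu^2 (gamma-Poisson mixture)."""
    if phi <= 0:
        return rng.poisson(mu)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mu * phi)
    return rng.poisson(lam)


def simulate_cells(params: GeneratorParams | None = None):
    """Generate a (CountMatrix, SyntheticTruth) pair for the human tumor model."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)
    genes = _gene_names(params)
    module_idx, chroms, starts, chunk = _gene_layout(params)
    n_genes = params.n_genes
    gzmb_idx = n_genes - params.n_mito_genes - 1
    mito_idx = np.arange(n_genes - params.n_mito_genes, n_genes)

    # --- baselines -------------------------------------------------------
    baseline = rng.lognormal(0.0, 1.0, size=n_genes)
    all_module_idx = np.concatenate(list(module_idx.values()))
    baseline[all_module_idx] = params.module_baseline_count
    baseline[gzmb_idx] = 1e-3
    background = np.ones(n_genes, dtype=bool)
    background[all_module_idx] = False
    background[gzmb_idx] = False
    background[mito_idx] = False
    budget = params.target_total - baseline[all_module_idx].sum()
    baseline[background] *= budget / baseline[background].sum()
    f = params.mito_fraction_mean
    baseline[mito_idx] = (f / (1 - f)) * params.target_total / params.n_mito_genes

    # --- cells -----------------------------------------------------------
    comp = (["cancer"] * params.n_cancer + ["microglia"] * params.n_microglia
            + ["macrophage"] * params.n_macrophage + ["tcell"] * params.n_tcell)
    comp += ["cancer"] * (params.n_qc_fail_low + params.n_qc_fail_mito
                          + params.n_gzmb_contaminants)
    n_cells = len(comp)
    cell_ids = [f"C{i:04d}" for i in range(n_cells)]
    cells = pd.DataFrame({"compartment": comp}, index=pd.Index(cell_ids, name="cell_id"))
    n_main = params.n_cancer + params.n_microglia + params.n_macrophage + params.n_tcell
    qc_fail = np.array(["none"] * n_cells, dtype=object)
    qc_fail[n_main:n_main + params.n_qc_fail_low] = "low_genes"
    qc_fail[n_main + params.n_qc_fail_low:
            n_main + params.n_qc_fail_low + params.n_qc_fail_mito] = "high_mito"
    contaminant = np.zeros(n_cells, dtype=bool)
    contaminant[n_main + params.n_qc_fail_low + params.n_qc_fail_mito:] = True
    cells["qc_fail"] = qc_fail
    cells["contaminant"] = contaminant

    # --- cancer programme states ----------------------------------------
    is_cancer = cells["compartment"].to_numpy() == "cancer"
    state = np.array(["none"] * n_cells, dtype=object)
    probs = [params.mapk_frac, params.ac_frac, params.intermediate_frac, params.oc_frac]
    cancer_pos = np.where(is_cancer)[0]
    drawn = rng.choice(["mapk", "ac", "intermediate", "oc"], size=len(cancer_pos), p=probs)
    # planted pathological cells behave like AC-state cancer cells
    drawn[cancer_pos >= n_main] = "ac"
    state[cancer_pos] = drawn
    cells["state"] = state

    mapk_act = np.zeros(n_cells)
    ac_act = np.zeros(n_cells)
    oc_act = np.zeros(n_cells)
    for pos in cancer_pos:
        s = state[pos]
        if s == "mapk":
            mapk_act[pos] = rng.uniform(0.9, 1.0)
            ac_act[pos] = rng.uniform(0.0, 0.1)
        elif s == "ac":
            mapk_act[pos] = rng.uniform(0.0, 0.1)
            ac_act[pos] = rng.uniform(0.9, 1.0)
        elif s == "intermediate":
            mapk_act[pos] = rng.uniform(0.35, 0.5)
            ac_act[pos] = rng.uniform(0.35, 0.5)
        else:  # oc branch: high OC, moderate MAPK, little AC
            oc_act[pos] = rng.uniform(0.9, 1.0)
            mapk_act[pos] = rng.uniform(0.4, 0.6)
            ac_act[pos] = rng.uniform(0.0, 0.1)
    cells["oc_activity"] = oc_act

    mapk_high = np.where(state == "mapk")[0]
    perm = rng.permutation(mapk_high)
    n_cyc = int(round(params.cycling_frac * len(mapk_high)))
    n_sen = int(round(params.senescent_frac * len(mapk_high)))
    cycling = np.zeros(n_cells, dtype=bool)
    senescent = np.zeros(n_cells, dtype=bool)
    cycling[perm[:n_cyc]] = True
    senescent[perm[n_cyc:n_cyc + n_sen]] = True
    cells["cycling"] = cycling
    cells["senescent"] = senescent
    cpl = params.senescence_mapk_coupling
    cyc_act = cycling.astype(float)
    sen_act = cpl * mapk_act + (1 - cpl) * senescent.astype(float)
    j = params.basal_activity_jitter
    if j > 0:
        cancer_mask = is_cancer.astype(float)
        for act in (mapk_act, ac_act, cyc_act, sen_act):
            act += rng.uniform(0.0, j, size=n_cells) * cancer_mask
            np.clip(act, 0.0, 1.0, out=act)
    cells["mapk_activity"] = mapk_act
    cells["ac_activity"] = ac_act
    cells["cycling_activity"] = cyc_act
    cells["senescence_activity"] = sen_act

    # --- CNV carriers ----------------------------------------------------
    chrom_arr = np.asarray(chroms)
    cnv_gene_pos = np.where(chrom_arr == params.cnv_chromosome)[0][:params.cnv_n_genes]
    main_cancer = cancer_pos[cancer_pos < n_main]
    n_carriers = int(round(params.cnv_carrier_frac * len(main_cancer)))
    carrier_pos = rng.choice(main_cancer, size=n_carriers, replace=False)
    carrier = np.zeros(n_cells, dtype=bool)
    carrier[carrier_pos] = True
    cells["cnv_carrier"] = carrier

    # --- per-cell technical factors --------------------------------------
    lib = rng.lognormal(0.0, params.library_sigma, size=n_cells)
    lib[qc_fail == "low_genes"] *= 0.02
    f_cell = np.clip(rng.normal(params.mito_fraction_mean, params.mito_fraction_sd,
                                size=n_cells), 0.004, 0.03)
    f_cell[qc_fail == "high_mito"] = params.mito_fail_fraction
    mito_mult = (f_cell / (1 - f_cell)) / (f / (1 - f))

    # --- expected counts --------------------------------------------------
    log_act = np.zeros((n_genes, n_cells))
    act_of = {
        "mapk": mapk_act, "ac": ac_act, "oc": oc_act,
        "cycling": cyc_act, "senescence": sen_act,
    }
    for mod, act in act_of.items():
        log_act[np.ix_(module_idx[mod], np.arange(n_cells))] += (
            params.activation_effect * act[None, :]
        )
    for mod in ("microglia", "macrophage", "tcell"):
        on = (cells["compartment"].to_numpy() == mod).astype(float)
        log_act[np.ix_(module_idx[mod], np.arange(n_cells))] += (
            params.marker_effect * on[None, :]
        )
    log_act[np.ix_(cnv_gene_pos, np.arange(n_cells))] += params.cnv_shift * carrier[None, :]

    mu = baseline[:, None] * np.exp(log_act) * lib[None, :]
    mu[mito_idx, :] = baseline[mito_idx, None] * mito_mult[None, :] * lib[None, :]
    is_tcell = cells["compartment"].to_numpy() == "tcell"
    mu[gzmb_idx, is_tcell] = params.gzmb_contaminant_mean * lib[is_tcell]
    mu[gzmb_idx, contaminant] = params.gzmb_contaminant_mean * lib[contaminant]

    counts = _nb_sample(rng, mu, params.nb_phi)
    if params.dropout > 0:
        keep = rng.random(counts.shape) >= params.dropout
        # planted GZMB+ cells are defined by detected GZMB expression, so the
        # marker transcript itself is exempt from capture dropout there
        keep[gzmb_idx, contaminant | is_tcell] = True
        counts = counts * keep

    # --- containers -------------------------------------------------------
    values = pd.DataFrame(counts.astype(np.int64),
                          index=pd.Index(genes, name="gene_id"),
                          columns=pd.Index(cell_ids, name="cell_id"))
    meta = pd.DataFrame(
        {
            "tumor_of_origin": rng.choice(
                [f"BT{i + 1}" for i in range(params.n_tumors)], size=n_cells
            ),
            "marker_status": np.where(is_cancer, "positive", "negative"),
            "fusion_status": np.where(
                is_cancer & ~contaminant, "detected",
                np.where(contaminant, "not_assayed", "not_detected"),
            ),
            "species": "human",
        },
        index=values.columns,
    )
    positions = GenePositions(pd.DataFrame(
        {"chromosome": chroms, "start": starts,
         "end": [s + 500 for s in starts]},
        index=values.index,
    ))
    modules = {m: [genes[i] for i in idx] for m, idx in module_idx.items()}
    truth = SyntheticTruth(
        cells=cells,
        modules=modules,
        cnv_segments=[{
            "chromosome": params.cnv_chromosome,
            "genes": [genes[i] for i in cnv_gene_pos],
            "shift": params.cnv_shift,
            "carriers": list(values.columns[carrier]),
        }],
        positions=positions,
        seed=params.seed,
        params=params,
        extras={"library_factor": pd.Series(lib, index=values.columns),
                "mito_fraction_target": pd.Series(f_cell, index=values.columns)},
    )
    return CountMatrix(values, meta), truth


def compartment_means(norm: NormalizedMatrix, compartments: pd.Series) -> pd.DataFrame:
    """Mean log-normalized profile per compartment (genes x compartments)."""
    cols = {}
    for comp in sorted(compartments.unique()):
        cells = compartments.index[compartments == comp]
        cols[comp] = norm.values[cells].mean(axis=1)
    return pd.DataFrame(cols)


def simulate_bulk(cell_means: pd.DataFrame, params: GeneratorParams | None = None,
                  seed: int | None = None):
    """Bulk samples as Dirichlet mixtures of compartment mean profiles.

    ``sample_s = sum_c w_sc * mean_c * exp(noise)`` with the weight rows
    drawn from Dirichlet(alpha) and recorded in the returned truth frame.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    comps = list(cell_means.columns)
    if set(comps) <= set(COMPARTMENTS):
        # align alpha with the named compartments regardless of column order
        by_name = dict(zip(COMPARTMENTS, params.dirichlet_alpha))
        alpha = np.array([by_name[c] for c in comps], dtype=float)
    else:
        alpha = np.asarray(params.dirichlet_alpha, dtype=float)[:len(comps)]
    if len(alpha) != len(comps):
        raise ValidationError("dirichlet_alpha shorter than the compartment list")
    W = rng.dirichlet(alpha, size=params.n_bulk_samples)
    assert np.allclose(W.sum(axis=1), 1.0)
    M = cell_means.to_numpy(dtype=float)
    noise = rng.lognormal(0.0, params.bulk_noise_sigma,
                          size=(M.shape[0], params.n_bulk_samples))
    samples = (M @ W.T) * noise
    ids = [f"S{i:03d}" for i in range(params.n_bulk_samples)]
    bulk = BulkProfile(pd.DataFrame(samples, index=cell_means.index,
                                    columns=pd.Index(ids, name="sample_id")))
    weights = pd.DataFrame(W, index=bulk.sample_ids, columns=comps)
    return bulk, weights


@dataclass
class MouseNscParams:
    """Generator knobs for the engineered mouse neural stem cell model."""

    n_genes: int = 5000
    n_per_group: int = 150
    group_names: tuple = ("vector", "kiaa_braf", "v600e")
    module_size: int = 50
    marker_effect: float = 2.5
    module_baseline_count: float = 6.0
    ac_effect_vector: float = 1.8
    ac_effect_oncogene: float = 0.3
    nb_phi: float = 0.1
    library_sigma: float = 0.35
    target_total: float = 40_000.0
    dropout: float = 0.1
    n_mito_genes: int = 13
    mito_fraction_mean: float = 0.01
    mito_fraction_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        reserved = (len(self.group_names) + 1) * self.module_size + self.n_mito_genes
        if reserved > self.n_genes:
            raise ValidationError("module layout exceeds n_genes")


def simulate_mouse_nsc(params: MouseNscParams | None = None):
    """Mouse NSC dataset: three construct groups plus a shared AC-like module.

    Each group activates its own 50-gene marker module; the AC-like module
    is strongly active in vector-control cells and weakly in the two
    oncogenic-BRAF groups, mirroring the repression of mature-glia
    programmes by constitutive MAPK signaling.
    """
    params = params or MouseNscParams()
    rng = np.random.default_rng(params.seed)
    n_genes = params.n_genes
    genes = [f"mg{i:05d}" for i in range(n_genes)]
    genes[-params.n_mito_genes:] = [f"mt-{i + 1}" for i in range(params.n_mito_genes)]
    groups = list(params.group_names)
    module_idx = {g: np.arange(i * params.module_size, (i + 1) * params.module_size)
                  for i, g in enumerate(groups)}
    ac_lo = len(groups) * params.module_size
    module_idx["ac_like"] = np.arange(ac_lo, ac_lo + params.module_size)
    mito_idx = np.arange(n_genes - params.n_mito_genes, n_genes)

    baseline = rng.lognormal(0.0, 1.0, size=n_genes)
    all_mod = np.concatenate(list(module_idx.values()))
    baseline[all_mod] = params.module_baseline_count
    background = np.ones(n_genes, dtype=bool)
    background[all_mod] = False
    background[mito_idx] = False
    budget = params.target_total - baseline[all_mod].sum()
    baseline[background] *= budget / baseline[background].sum()
    f = params.mito_fraction_mean
    baseline[mito_idx] = (f / (1 - f)) * params.target_total / params.n_mito_genes

    n_cells = params.n_per_group * len(groups)
    cell_ids = [f"M{i:04d}" for i in range(n_cells)]
    group = np.repeat(groups, params.n_per_group)
    lib = rng.lognormal(0.0, params.library_sigma, size=n_cells)
    f_cell = np.clip(rng.normal(f, params.mito_fraction_sd, size=n_cells), 0.003, 0.025)
    mito_mult = (f_cell / (1 - f_cell)) / (f / (1 - f))

    log_act = np.zeros((n_genes, n_cells))
    for g in groups:
        on = (group == g).astype(float)
        log_act[np.ix_(module_idx[g], np.arange(n_cells))] += params.marker_effect * on[None, :]
    ac_act = np.where(group == "vector", params.ac_effect_vector, params.ac_effect_oncogene)
    log_act[np.ix_(module_idx["ac_like"], np.arange(n_cells))] += ac_act[None, :]

    mu = baseline[:, None] * np.exp(log_act) * lib[None, :]
    mu[mito_idx, :] = baseline[mito_idx, None] * mito_mult[None, :] * lib[None, :]
    counts = _nb_sample(rng, mu, params.nb_phi)
    if params.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= params.dropout)

    values = pd.DataFrame(counts.astype(np.int64),
                          index=pd.Index(genes, name="gene_id"),
                          columns=pd.Index(cell_ids, name="cell_id"))
    meta = pd.DataFrame(
        {"tumor_of_origin": group, "marker_status": "unknown",
         "fusion_status": np.where(group == "kiaa_braf", "detected", "not_detected"),
         "species": "mouse"},
        index=values.columns,
    )
    cells = pd.DataFrame({"group": group}, index=values.columns)
    chunk = int(np.ceil(n_genes / 10))
    positions = GenePositions(pd.DataFrame(
        {"chromosome": [f"chr{i // chunk + 1}" for i in range(n_genes)],
         "start": [(i % chunk) * 1000 for i in range(n_genes)],
         "end": [(i % chunk) * 1000 + 500 for i in range(n_genes)]},
        index=values.index,
    ))
    modules = {m: [genes[i] for i in idx] for m, idx in module_idx.items()}
    truth = SyntheticTruth(cells=cells, modules=modules, cnv_segments=[],
                           positions=positions, seed=params.seed, params=params)
    return CountMatrix(values, meta), truth


def null_params(seed: int = 0) -> GeneratorParams:
    """Conditions with all planted effects switched off (negative control)."""
    return replace(GeneratorParams(seed=seed), activation_effect=0.0,
                   marker_effect=0.0, cnv_shift=0.0)
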