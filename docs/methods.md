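# Methods

This note documents the models, formulas, parameter choices and numerical
conventions implemented in `pastro`, and what the synthetic benchmark does
and does not establish about real data.

## Quality control and normalization

Cells are filtered first, genes second. A cell is retained when its number
of expressed genes (count > 0) meets the species threshold and its
mitochondrial count fraction does not exceed the species ceiling: human
≥ 1000 genes and ≤ 4%, mouse ≥ 3000 genes and ≤ 3%. Thresholds quoted with
strict inequalities are implemented strictly ("< 1000 excluded" keeps a
cell at exactly 1000; "> 4% excluded" keeps a cell at exactly 4%). The
mitochondrial fraction is computed on raw counts, with mitochondrial genes
identified by prefix (`MT-`/`mt-`) or an explicit list. After cell
filtering, genes expressed in fewer than 10 of the retained cells are
dropped. The filter emits an attrition report (step, removed, remaining)
and errors out, embedding that report, if nothing survives.

Normalization is `value(g, c) = ln(1 + count(g, c) / total(c) × 10,000)` —
natural log of counts-per-10k with a pseudocount of 1. The conserved
quantity `Σ_g (e^value − 1) = 10,000` per cell is asserted in tests.
TPM-like continuous input is accepted through the same path; the container
records which unit was supplied.

Scaling regresses each gene's log-normalized profile on an intercept, the
number of detected genes, and tumor-of-origin indicator variables
(closed-form OLS residuals via a single least-squares solve), then
standardizes residuals to mean 0 / population SD 1. Zero-variance genes map
to all-zero rows; a rank-deficient design is an error rather than a silent
pseudo-inverse. Variable genes are those with mean log-normalized
expression in the closed interval [0.25, 5] and SD strictly above 1, both
computed on the log-normalized (not scaled) layer so the mean range and the
dispersion threshold live on the same scale.

The cancer-cell purge removes cells whose log-normalized *GZMB* (a
cytotoxic-lymphocyte granzyme) exceeds 1.5 — rare sorted cells that carry
an immune transcriptome despite a positive surface marker.

## Population structure

PCA runs on the scaled matrix restricted to a chosen gene set, by full SVD
(deterministic; no randomized solver). Each loading vector is oriented so
its largest-magnitude entry is positive, which fixes the identity of the
"top" and "bottom" programme poles across runs. 7 components are used for
the all-cells analysis and 5 for the cancer-cell subset.

Clustering builds a k-nearest-neighbor graph (Euclidean, k = 150 by
default, each cell counted in its own neighbor set), reweights edges by
the Jaccard overlap of neighbor sets, prunes zero-weight edges, and
partitions by seeded Leiden modularity optimization (RB-configuration
objective, resolution 0.8 by default). Cluster indices are renumbered by
decreasing size. The default resolution intentionally resolves
within-cancer substructure: on synthetic data the cancer compartment splits
into MAPK-high and AC-like clusters, exactly as PA tumors split into two
cancer clusters, so compartment-level agreement is evaluated after
signature-based annotation maps clusters to compartments.

Marker detection is a per-gene two-sided Wilcoxon rank-sum test on
log-normalized values, one-vs-rest or between explicit cell sets. When both
groups have ≤ 8 cells the p-value is computed by full enumeration of the
rank-sum permutation distribution with average-rank tie handling (scipy's
exact method declines ties); larger groups use the tie-corrected normal
approximation with continuity correction. Both Bonferroni and
Benjamini–Hochberg adjustments are reported; callers choose. Log fold
change is the difference of mean log-normalized expression (natural-log
units); `fold_change = exp(lfc)`.

## Fold-enrichment scoring

The signature score is the mean expression of the signature's genes divided
by the mean over all genes in the post-QC universe, per cell (or per
cluster mean-expression vector). It is computed on the log-normalized,
non-negative layer: a fold-enrichment is undefined on zero-mean z-scores,
so the scaled layer is not used even where a covariate-adjusted variant
might seem natural (both layers are accepted; log-normalized is the
default and the choice is recorded in the table metadata). Signature genes
absent from the universe are dropped and logged, never imputed as zero.
Useful identities, all asserted in tests: the whole-universe signature
scores exactly 1; scores are invariant to rescaling a cell's expression
vector; for any partition of the universe into signatures the
size-weighted mean of scores is 1.

Subpopulations are defined by score strictly above 2.5; a cell may carry
any number of programme labels. Atlas-derived immune signatures keep genes
with fold change strictly above 1.5 and Bonferroni-adjusted p < 0.05;
subtypes left without a usable gene (e.g. a single marker with no expressed
ortholog) are skipped with a logged reason. Microglia/macrophage signature
scores are reported normalized to their mean over the tumor clusters, so an
immune cell's value reads directly as enrichment over tumor baseline.
Cross-tumor comparisons subsample up to 500 cancer cells per tumor type,
seeded, without replacement.

## Gene programmes and overlap statistics

Programmes are the top and bottom 50 genes of a PC loading vector by signed
loading (not magnitude), ties broken by gene identifier; a single stable
sort guarantees the two programmes are disjoint and that negating the PC
swaps them. Programme score correlations are tie-corrected Spearman with
two-sided p and Bonferroni multiplier equal to the number of pairs in the
call. Gene-list overlaps use the one-sided (enrichment) Fisher exact test,
i.e. the hypergeometric upper tail P(X ≥ k) in a fixed universe of 18,000
genes; depletion is not tested.

## Bulk deconvolution

Compartment signatures are one-vs-rest Wilcoxon markers (Bonferroni
p < 0.05, positive fold change). For a bulk cohort: intersect each
signature with the platform's gene universe (discarded genes are counted),
z-score each gene across samples, and score each sample–compartment pair by
the mean z over the signature's genes. A plain ratio to "mean expression of
all genes" is numerically vacuous after z-scoring (the per-sample mean
z-score is ~0), so the compartment score is the mean marker z-score itself.
Negative scores are handled by a per-sample shift (subtract the minimum
score) before normalizing to fractions that sum to 1; plain clipping at
zero is available by flag, but because z-scores are zero-mean across
samples clipping pins every below-cohort-average sample to fraction 0 and
destroys rank information. A sample with all-zero scores receives uniform
fractions with a warning.

Properties and limitations, measured on synthetic mixtures: fractions are
invariant to per-gene affine transforms of the bulk matrix and equivariant
under compartment relabeling; per-compartment fractions rank-track the true
mixing weights (Spearman ρ ≈ 0.9 for the major compartments over 50
Dirichlet mixtures). The estimates are *relative enrichment shares*, not
calibrated proportions: absolute fractions are compressed toward
uniformity, the per-sample minimum compartment is floored at exactly 0, and
at extreme compositions the fraction response saturates because compartment
signatures share an immune-vs-cancer variance axis (raising the microglia
weight also raises macrophage and T-cell marker scores). Strict
monotonicity of the estimated fraction in a planted weight therefore holds
through the cohort-typical range but not at the extremes; the tests probe
it on a one-dimensional microglia-vs-cancer grid inside that range.

## CNV inference

Genes are ordered by (chromosome, start); per cell, log-normalized
expression is averaged over sliding windows of 100 consecutive genes within
each chromosome (step 1 — "contiguous stretches" with maximal positional
resolution). Chromosomes shorter than the window contribute one truncated,
flagged window (or are skipped if truncation is disabled; an error if
nothing remains). Each window is centered by its mean over the reference
cell set — all supplied cancer cells, the cell itself included; a
leave-one-out reference (an O(1/n) refinement) is available by flag, off by
default. No expression clamping or per-cell median re-centering is applied
by default. Genes without a genomic position are dropped; if they exceed
20% of the expressed genes the call errors out. Arm-level summaries average
window values per chromosome arm and flag |mean| beyond a user cutoff; the
cutoff is a reporting threshold, not part of the inference, and per-cell
arm means carry ~0.08 log-units of sampling noise at the default problem
size, so only strong events are callable per cell.

A known confound, shared with all expression-based CNV inference: planted
(or real) transcriptional programmes are indistinguishable from
copy-number blocks on the chromosomes that carry their genes. The
synthetic benchmark therefore judges CNV specificity on module-free
chromosomes.

## The synthetic generator

The generator is the package's study system: it plants the population
structure that the estimators are supposed to recover, with full ground
truth.

**Counts.** `count(g, c) ~ NB(mean = b_g · exp(Σ_m effect_m · activity_m(c))
· lib_c, var = mean + 0.1·mean²)` via a gamma–Poisson mixture, followed by
10% independent capture dropout. Library factors are log-normal
(σ = 0.35); baseline means are log-normal across genes, scaled so a typical
cell totals ~20,000 counts; 13 dedicated `MT-` genes realize a per-cell
mitochondrial fraction targeted at 1.5% (SD 0.4%, clipped at 3% so healthy
cells never cross the 4% QC ceiling). The full-length plate-based
chemistry this emulates captures transcripts deeply, hence the modest
dropout.

**Population.** 1,000 cells by default: 450 cancer, 300 microglia (30% of
cells — the dominant immune population), 100 macrophages, 150 T cells.
Each immune compartment activates a planted 50-gene marker module
(2.5 ln-units). Cancer cells occupy discrete programme states — 30%
MAPK-high, 60% AC-like, 5% intermediate, 5% OC-like (the OC branch with
moderate MAPK activity) — with jittered activities and an added basal
U(0, 0.15) activity term on every programme in every cancer cell, modelling
basal stochastic expression. MAPK and AC activities are anti-correlated by
construction (Pearson ≈ −0.96 among cancer cells). Programme modules are
50 genes at a baseline of ~6 counts with a 3.5 ln-unit activation, sized so
a fully active module scores ≈ 3 on the fold-enrichment scale (above the
2.5 subpopulation threshold) while intermediate states stay near 1.7 and
inactive cells near 1.

**Cycling and senescence.** Disjoint 25% subsets of the MAPK-high cells
are flagged cycling or senescent. Senescence activity is
`0.3·mapk + 0.7·flag` — oncogene-induced senescence rides on MAPK dosage —
while cycling is flag-only. This asymmetry is what reproduces the observed
correlation pattern: MAPK–senescence strongly positive, MAPK–cycling near
zero, cycling–senescence indistinguishable from zero despite the mutual
exclusivity of the flags.

**CNV and contaminants.** One chromosome block (150 genes on a module-free
chromosome, +0.4 ln-units, 40% of cancer cells as carriers) is the planted
copy-number event. Optional planted pathology: low-coverage cells (library
× 0.02), high-mito cells (10% fraction), and GZMB⁺ cancer-labelled
contaminants (mean 300 GZMB counts; the marker transcript is exempt from
dropout in cells planted as GZMB⁺, since a planted contaminant is defined
by detected expression).

**Bulk.** Samples are convex mixtures of compartment mean log-normalized
profiles with weights drawn from Dirichlet(5.7, 3.0, 0.8, 0.5) for
(cancer, microglia, macrophage, T cell) — median composition ≈ 57% cancer,
30% microglia — times per-entry log-normal noise (σ = 0.1); 50 samples by
default.

**Mouse NSCs.** A separate generator produces three construct groups
(vector control, fusion-type, V600E-type; 150 cells each over 5,000 genes,
~40,000 counts per cell so mouse QC thresholds are meaningful) with
group-specific marker modules and a shared AC-like module activated at
1.8 ln-units in vector cells versus 0.3 in the oncogene groups — oncogenic
BRAF repressing the mature-glia programme.

Everything derives from a single `numpy` generator seeded per dataset, so
identical parameters and seed give bitwise-identical counts, and the truth
object (states, activities, flags, modules, segments, weights) suffices to
recompute every planted quantity independently.

**What passing tests show — and don't.** The benchmark establishes that the
estimators recover clean modular structure at realistic depth and noise:
exact formula agreement with independent oracles, exact planted filter
counts, ≥ 80% programme recovery from PC1, ≥ 95% subpopulation sensitivity
at ≤ 5% FPR, ρ > 0.9 mixture-weight rank recovery, and AUC > 0.95 CNV
separation inside the planted segment. Real tumors add features the
generator omits — overlapping and correlated gene programmes, ambient RNA,
doublets, batch effects across plates, gene-length and GC biases,
platform-specific dropout — so these numbers bound what the pipeline can
do under ideal conditions rather than guarantee field performance.

## Problem sizes and runtime

Defaults were chosen so every analysis is interactive on one CPU: the full
test suite (several complete pipeline runs over a 5-seed panel plus ~100
small Monte-Carlo simulations) completes in about a minute, and
`scripts/acceptance.py` — three full pipeline re-runs plus the planted
filter fixtures — in well under a minute.
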