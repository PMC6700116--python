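"""Cluster cells in PC space and annotate clusters with compartment signatures.

Reproduces the core population-structure analysis: covariate-regressed
scaling, PCA (7 components), shared-nearest-neighbor clustering (k = 150),
Wilcoxon marker genes, and signature-score-based compartment annotation.
Like the real tumors, the cancer cells split into a MAPK-high and an
astrocyte-like cluster, so more clusters than compartments is expected.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

import pastro

counts, truth = pastro.simulate_cells(pastro.GeneratorParams(seed=7))
filtered, _ = pastro.qc_filter(counts)
norm = pastro.log_normalize(filtered)
covariates = pd.DataFrame({
    "n_detected_genes": (filtered.values > 0).sum(axis=0),
    "tumor_of_origin": filtered.cell_meta["tumor_of_origin"],
})
scaled = pastro.scale_and_regress(norm, covariates)
pca = pastro.run_pca(scaled, n_pcs=7)
labels = pastro.snn_cluster(pca.scores, k=150, seed=7)
print(f"{labels.n_clusters} clusters from {len(labels.labels)} cells; sizes:",
      labels.labels.value_counts().sort_index().to_dict())

sigs = [
    pastro.GeneSignature("cancer", truth.modules["mapk"] + truth.modules["ac"]),
    pastro.GeneSignature("microglia", truth.modules["microglia"]),
    pastro.GeneSignature("macrophage", truth.modules["macrophage"]),
    pastro.GeneSignature("tcell", truth.modules["tcell"]),
]
scores = pastro.score_cells(norm, sigs)
compartment_of = pastro.annotate_compartments(labels, scores)
print("cluster -> compartment:", compartment_of)

t = truth.cells.loc[labels.labels.index]
mapped = labels.labels.map(compartment_of)
ari = adjusted_rand_score(t["compartment"], mapped)
print(f"annotated compartments vs planted truth: ARI = {ari:.3f}")

de = pastro.cluster_markers(norm, labels, cluster=0)
top = de.sort_values("p_bonferroni").head(5)
print("\ntop cluster-0 markers (gene, lfc, Bonferroni p):")
for g, row in top.iterrows():
    print(f"  {g}  {row.log_fold_change:+.2f}  {row.p_bonferroni:.2e}")
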