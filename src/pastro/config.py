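"""Pipeline configuration: every tunable threshold in one place.

Defaults are the analysis constants of the study this pipeline reproduces:
QC cutoffs per species, the variable-gene window, SNN/PCA parameters, the
programme size and subpopulation threshold, the CNV window, and the gene
universe assumed by the overlap test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    # QC (strict "<"/">" readings: keep >= min_genes, keep <= max_mito)
    min_genes_human: int = 1000
    max_mito_human: float = 0.04
    min_genes_mouse: int = 3000
    max_mito_mouse: float = 0.03
    min_cells_per_gene: int = 10
    # variable genes: mean log-normalized expression in a closed range, SD strictly above
    var_gene_mean_range: tuple = (0.25, 5.0)
    var_gene_sd_min: float = 1.0
    # dimension reduction / clustering
    n_pcs_all: int = 7
    n_pcs_cancer: int = 5
    snn_k: int = 150
    snn_resolution: float = 0.8
    # programmes and scoring
    programme_size: int = 50
    subpop_threshold: float = 2.5
    cnv_window: int = 100
    overlap_genome_size: int = 18000
    gzmb_filter: float = 1.5
    atlas_fc_min: float = 1.5
    atlas_q_max: float = 0.05
    heatmap_subsample: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.var_gene_mean_range = tuple(self.var_gene_mean_range)
        positive = [
            self.min_genes_human, self.max_mito_human, self.min_genes_mouse,
            self.max_mito_mouse, self.min_cells_per_gene, self.var_gene_sd_min,
            self.n_pcs_all, self.n_pcs_cancer, self.snn_k, self.programme_size,
            self.subpop_threshold, self.cnv_window, self.overlap_genome_size,
            self.gzmb_filter, self.atlas_fc_min, self.atlas_q_max,
            self.heatmap_subsample,
        ]
        if any(v <= 0 for v in positive):
            raise ValidationError("all thresholds must be strictly positive")
        lo, hi = self.var_gene_mean_range
        if not lo < hi:
            raise ValidationError("var_gene_mean_range must be well-ordered")

    def min_genes(self, species: str) -> int:
        return self.min_genes_human if species == "human" else self.min_genes_mouse

    def max_mito(self, species: str) -> float:
        return self.max_mito_human if species == "human" else self.max_mito_mouse

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v
                 for k, v in dataclasses.asdict(self).items()},
                fh, sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
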