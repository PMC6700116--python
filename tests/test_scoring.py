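"""Fold-enrichment scoring, subpopulation calls, atlas signatures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pastro
from pastro.errors import ValidationError

from conftest import tiny_norm


def sig(name, genes):
    return pastro.GeneSignature(name, genes)


class TestScoreCells:
    def test_whole_universe_signature_scores_one(self):
        rng = np.random.default_rng(0)
        norm = tiny_norm(rng.gamma(2, 1, size=(10, 5)))
        scores = pastro.score_cells(norm, [sig("all", list(norm.gene_ids))])
        np.testing.assert_allclose(scores["all"], 1.0, atol=1e-12)

    def test_direct_formula_evaluation(self):
        norm = tiny_norm(np.array([[2.0], [1.0], [0.0]]), genes=["a", "b", "c"])
        scores = pastro.score_cells(norm, [sig("s", ["a"])])
        assert scores.loc["c0", "s"] == pytest.approx(2.0)

    def test_ratio_conservation_over_a_partition(self):
        """For signatures partitioning the universe, sum |S| * score = N."""
        rng = np.random.default_rng(1)
        norm = tiny_norm(rng.gamma(2, 1, size=(12, 7)))
        genes = list(norm.gene_ids)
        parts = [genes[:3], genes[3:8], genes[8:]]
        sigs = [sig(f"p{i}", g) for i, g in enumerate(parts)]
        scores = pastro.score_cells(norm, sigs)
        total = sum(scores[f"p{i}"] * len(parts[i]) for i in range(3))
        np.testing.assert_allclose(total, len(genes), atol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_free_in_each_cell(self, factor):
        """Multiplying a cell's expression vector rescales nothing in its scores."""
        rng = np.random.default_rng(3)
        base = rng.gamma(2, 1, size=(8, 3)) + 0.01
        scaled = base.copy()
        scaled[:, 1] *= factor
        s1 = pastro.score_cells(tiny_norm(base), [sig("s", ["g0", "g4"])])
        s2 = pastro.score_cells(tiny_norm(scaled), [sig("s", ["g0", "g4"])])
        np.testing.assert_allclose(s1["s"], s2["s"], rtol=1e-9)

    def test_missing_genes_dropped_not_imputed(self):
        norm = tiny_norm(np.array([[2.0], [4.0]]), genes=["a", "b"])
        scores = pastro.score_cells(norm, [sig("s", ["a", "NOT_THERE"])])
        assert scores.loc["c0", "s"] == pytest.approx(2.0 / 3.0)

    def test_zero_overlap_and_zero_cell_errors(self):
        norm = tiny_norm(np.array([[1.0, 2.0], [1.0, 2.0]]))
        with pytest.raises(ValidationError, match="ghost"):
            pastro.score_cells(norm, [sig("ghost", ["nope"])])
        norm0 = tiny_norm(np.array([[1.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError, match="c1"):
            pastro.score_cells(norm0, [sig("s", ["g0"])])

    def test_planted_module_scores_separate_carriers(self, cancer_scores, cancer_norm):
        """Planted module carriers score > 2; non-carriers sit near 1 (+-0.2)."""
        _, t = cancer_norm
        carriers = cancer_scores.loc[t.state == "mapk", "mapk"]
        bystanders = cancer_scores.loc[t.state == "ac", "mapk"]
        assert carriers.min() > 2.0
        assert abs(bystanders.mean() - 1.0) < 0.2


class TestScoreClusters:
    def test_singleton_cluster_equals_cell_score(self):
        rng = np.random.default_rng(4)
        norm = tiny_norm(rng.gamma(2, 1, size=(6, 3)))
        labels = pastro.ClusterLabels(pd.Series([0, 1, 2], index=norm.cell_ids))
        s_cluster = pastro.score_clusters(norm, labels, [sig("s", ["g1", "g2"])])
        s_cell = pastro.score_cells(norm, [sig("s", ["g1", "g2"])])
        np.testing.assert_allclose(s_cluster["s"].to_numpy(), s_cell["s"].to_numpy())

    def test_identical_mean_vectors_score_identically(self):
        vals = np.hstack([np.array([[1.0], [2.0]])] * 4)
        norm = tiny_norm(vals)
        labels = pastro.ClusterLabels(pd.Series([0, 0, 1, 1], index=norm.cell_ids))
        s = pastro.score_clusters(norm, labels, [sig("s", ["g0"])])
        assert s.loc[0, "s"] == pytest.approx(s.loc[1, "s"])

    def test_microglia_cluster_tops_its_own_signature(self, pipeline, module_signatures):
        t = pipeline["t"]
        comp_codes = {c: i for i, c in enumerate(sorted(t.compartment.unique()))}
        labels = pastro.ClusterLabels(t.compartment.map(comp_codes))
        sigs = [module_signatures[m] for m in ("microglia", "macrophage", "tcell")]
        scores = pastro.score_clusters(pipeline["norm"], labels, sigs)
        microglia_cluster = comp_codes["microglia"]
        assert scores.loc[microglia_cluster].idxmax() == "microglia"
        assert scores["microglia"].idxmax() == microglia_cluster


class TestAssignSubpopulations:
    def test_threshold_is_strict_and_monotone(self):
        scores = pd.DataFrame({"p": [2.5, 2.50001, 0.1]}, index=["c0", "c1", "c2"])
        out = pastro.assign_subpopulations(scores, ["p"])
        assert list(out["p"]) == [False, True, False]
        assert pastro.assign_subpopulations(scores, ["p"], threshold=-np.inf)["p"].all()
        assert not pastro.assign_subpopulations(scores, ["p"], threshold=np.inf)["p"].any()

    def test_unknown_programme_is_error(self):
        scores = pd.DataFrame({"p": [1.0]}, index=["c0"])
        with pytest.raises(ValidationError, match="unknown"):
            pastro.assign_subpopulations(scores, ["q"])

    def test_planted_mapk_subpopulation_detected(self, cancer_scores, cancer_norm):
        """Threshold 2.5 recovers planted MAPK-high cells at >= 95% sensitivity
        and <= 5% false positive rate."""
        _, t = cancer_norm
        called = pastro.assign_subpopulations(cancer_scores, ["mapk"])["mapk"]
        truth_high = t.state == "mapk"
        sens = (called & truth_high).sum() / truth_high.sum()
        fpr = (called & ~truth_high).sum() / (~truth_high).sum()
        assert sens >= 0.95
        assert fpr <= 0.05


class TestAtlasSignatures:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["fold_change", "p_bonferroni"]).rename(
            index=lambda i: f"g{i}"
        )

    def test_toy_table_yields_passing_genes(self):
        de = self._de([(2.0, 0.001), (3.0, 0.01), (1.6, 0.04), (5.0, 0.02),
                       (1.4, 0.001), (2.0, 0.2)])
        sigs = pastro.derive_atlas_signatures({"subtypeA": de})
        assert len(sigs) == 1
        assert sigs[0].genes == frozenset({"g0", "g1", "g2", "g3"})

    def test_fold_change_boundary_is_strict(self):
        de = self._de([(1.5, 0.001)])
        assert pastro.derive_atlas_signatures({"s": de}) == []

    def test_subtype_without_usable_gene_skipped(self, caplog):
        """A subtype whose single passing gene is absent from the universe is
        skipped with a logged reason, not an error."""
        de_ok = self._de([(2.0, 0.01), (2.5, 0.01)])
        de_orphan = pd.DataFrame([(2.0, 0.01)], columns=["fold_change", "p_bonferroni"],
                                 index=["mOrphanGene"])  # no expressed human ortholog
        with caplog.at_level("WARNING"):
            sigs = pastro.derive_atlas_signatures(
                {"cluster7a": de_orphan, "good": de_ok}, universe={"g0", "g1"}
            )
        assert [s.name for s in sigs] == ["good"]
        assert any("cluster7a" in r.message for r in caplog.records)


class TestNormalizeToTumor:
    def _setup(self):
        rng = np.random.default_rng(6)
        norm = tiny_norm(rng.gamma(2, 1, size=(10, 8)))
        labels = pastro.ClusterLabels(
            pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=norm.cell_ids)
        )
        scores = pastro.score_cells(norm, [sig("a", ["g0", "g1"]), sig("b", ["g2"])])
        return norm, labels, scores

    def test_tumor_mean_becomes_one(self):
        _, labels, scores = self._setup()
        out = pastro.normalize_to_tumor(scores, labels, {0})
        tumor_cells = labels.cells_in(0)
        np.testing.assert_allclose(out.loc[tumor_cells].mean(axis=0), 1.0, atol=1e-12)

    def test_all_cells_tumor_degenerate(self):
        _, labels, scores = self._setup()
        out = pastro.normalize_to_tumor(scores, labels, {0, 1})
        np.testing.assert_allclose(out.mean(axis=0), 1.0, atol=1e-12)

    def test_planted_immune_enrichment_ratio(self, pipeline, module_signatures):
        """Normalized microglia-signature scores in microglia cells reproduce the
        planted microglia-over-tumor enrichment ratio within 20%."""
        t = pipeline["t"]
        comp_codes = {c: i for i, c in enumerate(sorted(t.compartment.unique()))}
        labels = pastro.ClusterLabels(t.compartment.map(comp_codes))
        scores = pastro.score_cells(pipeline["norm"], [module_signatures["microglia"]])
        out = pastro.normalize_to_tumor(scores, labels, {comp_codes["cancer"]})
        in_microglia = out.loc[t.compartment == "microglia", "microglia"].mean()
        raw = scores["microglia"]
        planted_ratio = (raw[t.compartment == "microglia"].mean()
                         / raw[t.compartment == "cancer"].mean())
        assert in_microglia == pytest.approx(planted_ratio, rel=1e-9)
        assert in_microglia > 2.0  # microglia markers are planted well above tumor baseline


class TestSubsample:
    def _scores(self, n=700):
        rng = np.random.default_rng(8)
        return pd.DataFrame({"s": rng.normal(2, 0.5, n)},
                            index=[f"c{i}" for i in range(n)])

    def test_small_type_clamps_with_warning(self):
        scores = self._scores(300)
        types = pd.Series("pa", index=scores.index)
        with pytest.warns(UserWarning, match="only 300"):
            subset, means = pastro.subsample_for_comparison(scores, types, n=500, seed=0)
        assert len(subset) == 300

    def test_same_seed_same_subset(self):
        scores = self._scores()
        types = pd.Series("pa", index=scores.index)
        s1, _ = pastro.subsample_for_comparison(scores, types, n=500, seed=42)
        s2, _ = pastro.subsample_for_comparison(scores, types, n=500, seed=42)
        assert list(s1) == list(s2)

    def test_subsampled_mean_near_population_mean(self):
        scores = self._scores(2000)
        types = pd.Series(["a"] * 1000 + ["b"] * 1000, index=scores.index)
        _, means = pastro.subsample_for_comparison(scores, types, n=500, seed=1)
        for t in ("a", "b"):
            full = scores.loc[types == t, "s"]
            se = full.std() / np.sqrt(500)
            assert abs(means.loc[t, "s"] - full.mean()) < 2 * se
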