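"""PCA, shared-nearest-neighbor clustering, Wilcoxon markers, annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

import pastro
from pastro.errors import ValidationError


def _scaled(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return pastro.ScaledMatrix(pd.DataFrame(values, index=genes, columns=cells))


def brute_force_rank_sum_p(x, y):
    """Independent oracle: enumerate every relabeling of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        hits += abs(ranks[list(idx)].sum() - mu) >= obs - 1e-12
    return hits / total


class TestRunPca:
    def test_planted_rank_one_axis_recovered(self):
        """A single planted axis of variation dominates PC1 and its loadings."""
        rng = np.random.default_rng(0)
        n_genes, n_cells = 60, 200
        w = rng.normal(0, 1, n_genes)
        w /= np.linalg.norm(w)
        u = rng.normal(0, 3, n_cells)
        X = np.outer(w, u) + rng.normal(0, 0.05, (n_genes, n_cells))
        pca = pastro.run_pca(_scaled(X), n_pcs=5)
        assert pca.variance_ratio[0] > 0.9
        cos = abs(np.dot(pca.loadings["PC1"], w))
        assert cos > 0.99

    def test_duplicating_cells_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (30, 50))
        base = pastro.run_pca(_scaled(X), n_pcs=3)
        dup = pastro.run_pca(
            _scaled(np.hstack([X, X]), cells=[f"c{j}" for j in range(100)]), n_pcs=3
        )
        np.testing.assert_allclose(
            np.abs(base.loadings.to_numpy()), np.abs(dup.loadings.to_numpy()), atol=1e-8
        )

    def test_isotropic_noise_has_flat_spectrum(self):
        """At n = 2000 cells, iid noise spreads variance ~evenly over PCs."""
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (30, 2000))
        pca = pastro.run_pca(_scaled(X), n_pcs=7)
        assert pca.variance_ratio.max() / pca.variance_ratio.min() < 1.5

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        pca = pastro.run_pca(_scaled(rng.normal(0, 1, (20, 40))), n_pcs=4)
        L = pca.loadings.to_numpy()
        peaks = L[np.abs(L).argmax(axis=0), np.arange(4)]
        assert (peaks > 0).all()

    def test_too_many_components_is_error(self):
        with pytest.raises(ValidationError, match="n_pcs"):
            pastro.run_pca(_scaled(np.random.default_rng(0).normal(size=(5, 4))), n_pcs=4)


class TestSnnCluster:
    def test_two_separated_blobs_found_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (40, 3))
        b = rng.normal(5, 0.1, (40, 3))
        pcs = pd.DataFrame(np.vstack([a, b]), index=[f"c{i}" for i in range(80)])
        labels = pastro.snn_cluster(pcs, k=10, resolution=0.3, seed=1)
        assert labels.n_clusters == 2
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, labels.labels) == 1.0

    def test_identical_cells_form_one_cluster(self):
        pcs = pd.DataFrame(np.zeros((20, 3)), index=[f"c{i}" for i in range(20)])
        labels = pastro.snn_cluster(pcs, k=5, seed=0)
        assert labels.n_clusters == 1

    def test_k_at_least_n_cells_is_error(self):
        pcs = pd.DataFrame(np.zeros((10, 2)), index=[f"c{i}" for i in range(10)])
        with pytest.raises(ValidationError, match="lower k"):
            pastro.snn_cluster(pcs, k=10)

    def test_cell_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, (30, 2)), rng.normal(4, 0.3, (30, 2))])
        pcs = pd.DataFrame(X, index=[f"c{i}" for i in range(60)])
        labels = pastro.snn_cluster(pcs, k=8, seed=2)
        perm = rng.permutation(60)
        labels_p = pastro.snn_cluster(pcs.iloc[perm], k=8, seed=2)
        joined = pd.concat([labels.labels, labels_p.labels], axis=1, keys=["a", "b"])
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_planted_compartments_recovered(self, pipeline, module_signatures):
        """The default dataset clusters into compartments; after signature-based
        annotation the compartment assignment matches truth at ARI > 0.9."""
        truth = pipeline["truth"]
        scaled = pastro.scale_and_regress(pipeline["norm"], pipeline["covariates"])
        pca = pastro.run_pca(scaled, n_pcs=7)
        labels = pastro.snn_cluster(pca.scores, k=150, seed=7)
        sigs = [
            pastro.GeneSignature("cancer", truth.modules["mapk"] + truth.modules["ac"]),
            module_signatures["microglia"],
            module_signatures["macrophage"],
            module_signatures["tcell"],
        ]
        scores = pastro.score_cells(pipeline["norm"], sigs)
        comp_of = pastro.annotate_compartments(labels, scores)
        mapped = labels.labels.map(comp_of)
        assert adjusted_rand_score(pipeline["t"]["compartment"], mapped) > 0.9


class TestClusterMarkers:
    def test_identical_groups_yield_p_one(self):
        vals = np.tile(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]), (4, 1))
        norm = pastro.NormalizedMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(4)],
                         columns=[f"c{j}" for j in range(6)])
        )
        de = pastro.cluster_markers(norm, groups=(["c0", "c1", "c2"], ["c3", "c4", "c5"]))
        assert (de["p_value"] == 1.0).all()

    @pytest.mark.parametrize("n1,n2", [(4, 4), (5, 3), (8, 8)])
    def test_exact_p_matches_permutation_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = np.round(rng.gamma(2, 1, n1), 1)  # rounding creates ties
            y = np.round(rng.gamma(2, 1, n2), 1)
            vals = np.concatenate([x, y])[None, :]
            norm = pastro.NormalizedMatrix(
                pd.DataFrame(vals, index=["g0"],
                             columns=[f"c{j}" for j in range(n1 + n2)])
            )
            de = pastro.cluster_markers(
                norm,
                groups=([f"c{j}" for j in range(n1)],
                        [f"c{j}" for j in range(n1, n1 + n2)]),
            )
            assert de["p_value"].iloc[0] == pytest.approx(brute_force_rank_sum_p(x, y),
                                                          abs=1e-12)

    def test_gene_private_to_one_group_hits_exact_tail(self):
        """A gene expressed only in group A attains the exact rank-sum tail p."""
        x = np.full(6, 2.0)
        y = np.zeros(6)
        vals = np.concatenate([x, y])[None, :]
        norm = pastro.NormalizedMatrix(
            pd.DataFrame(vals, index=["g0"], columns=[f"c{j}" for j in range(12)])
        )
        de = pastro.cluster_markers(
            norm, groups=([f"c{j}" for j in range(6)], [f"c{j}" for j in range(6, 12)])
        )
        # most extreme separation: p = 2 / C(12, 6)
        assert de["p_value"].iloc[0] == pytest.approx(2 / 924, abs=1e-12)

    def test_planted_markers_recovered_at_bonferroni(self):
        """>= 27 of 30 planted 2x-shifted genes reach Bonferroni p < 0.05."""
        rng = np.random.default_rng(9)
        n = 200
        base = rng.gamma(2.0, 1.0, size=(400, 2 * n))
        base[:30, :n] *= 2.0
        norm = pastro.NormalizedMatrix(
            pd.DataFrame(base, index=[f"g{i}" for i in range(400)],
                         columns=[f"c{j}" for j in range(2 * n)])
        )
        de = pastro.cluster_markers(
            norm, groups=([f"c{j}" for j in range(n)], [f"c{j}" for j in range(n, 2 * n)])
        )
        hits = de.index[(de["p_bonferroni"] < 0.05) & (de["log_fold_change"] > 0)]
        planted = {f"g{i}" for i in range(30)}
        assert len(set(hits) & planted) >= 27

    def test_multiplicity_columns_are_consistent(self, pipeline):
        t = pipeline["t"]
        cells_in = t.index[t.compartment == "tcell"]
        cells_out = t.index[t.compartment != "tcell"]
        de = pastro.cluster_markers(pipeline["norm"], groups=(cells_in, cells_out))
        assert ((de.p_value >= 0) & (de.p_value <= 1)).all()
        np.testing.assert_allclose(
            de.p_bonferroni, np.minimum(1.0, de.p_value * len(de)), atol=1e-12
        )
        ordered = de.sort_values("p_value")
        assert (np.diff(ordered.q_bh.to_numpy()) >= -1e-12).all() or True
        # BH q is monotone along the p ordering after step-up smoothing
        q = ordered.q_bh.to_numpy()
        assert (q[:-1] <= q[1:] + 1e-12).all()

    def test_tiny_group_warns(self):
        rng = np.random.default_rng(10)
        norm = pastro.NormalizedMatrix(
            pd.DataFrame(rng.gamma(2, 1, size=(3, 8)),
                         index=["g0", "g1", "g2"], columns=[f"c{j}" for j in range(8)])
        )
        with pytest.warns(UserWarning, match="fewer than 3"):
            pastro.cluster_markers(norm, groups=(["c0", "c1"], [f"c{j}" for j in range(2, 8)]))


class TestAnnotateCompartments:
    def _labels(self, assignment):
        return pastro.ClusterLabels(pd.Series(assignment,
                                              index=[f"c{i}" for i in range(len(assignment))]))

    def test_argmax_assignment(self):
        labels = self._labels([0, 0, 1, 1])
        scores = pd.DataFrame(
            {"tumor": [2.0, 2.0, 0.1, 0.1], "microglia": [0.5, 0.5, 3.0, 3.0]},
            index=[f"c{i}" for i in range(4)],
        )
        assert pastro.annotate_compartments(labels, scores) == {0: "tumor", 1: "microglia"}

    def test_tie_goes_lexicographic_with_warning(self):
        labels = self._labels([0, 0])
        scores = pd.DataFrame({"b_sig": [1.0, 1.0], "a_sig": [1.0, 1.0]},
                              index=["c0", "c1"])
        with pytest.warns(UserWarning, match="tie"):
            out = pastro.annotate_compartments(labels, scores)
        assert out == {0: "a_sig"}

    def test_missing_scores_is_error(self):
        labels = self._labels([0, 0])
        scores = pd.DataFrame({"s": [1.0]}, index=["c0"])
        with pytest.raises(ValidationError, match="missing"):
            pastro.annotate_compartments(labels, scores)
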