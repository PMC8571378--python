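import numpy as np
import pandas as pd
import pytest
import scipy.special
from hypothesis import given, settings
from hypothesis import strategies as st

from tilseq import sc


class TestQCMetrics:
    def test_hand_computed_cell(self):
        X = np.array([[10, 90]])
        m = sc.compute_qc_metrics(X, ["mt-Nd1", "Actb"])
        assert m.loc[0, "total_umis"] == 100
        assert m.loc[0, "n_genes"] == 2
        assert m.loc[0, "mito_frac"] == pytest.approx(0.10)

    def test_all_zero_cell_has_zero_fractions(self):
        m = sc.compute_qc_metrics(np.zeros((1, 3)), ["mt-Nd1", "Rps1", "Actb"])
        assert m.loc[0, "total_umis"] == 0
        assert m.loc[0, "n_genes"] == 0
        assert m.loc[0, "mito_frac"] == 0.0
        assert m.loc[0, "ribo_frac"] == 0.0

    def test_metrics_match_generator_truth(self, toy_pooled):
        pooled, truth = toy_pooled
        m = sc.compute_qc_metrics(pooled.X, pooled.var_names, pooled.obs_names)
        assert (m["total_umis"] == np.asarray(pooled.X.sum(axis=1)).ravel()).all()
        assert ((m["mito_frac"] >= 0) & (m["mito_frac"] <= 1)).all()


class TestQCFilter:
    def _metrics(self, total, genes, mito, ribo):
        return pd.DataFrame(
            {"total_umis": [total], "n_genes": [genes], "mito_frac": [mito], "ribo_frac": [ribo]}
        )

    def test_cell_just_over_umi_limit_is_excluded(self):
        kept = sc.qc_filter(self._metrics(30001, 1000, 0.01, 0.20))
        assert len(kept) == 0

    def test_boundary_cell_is_kept_because_comparisons_are_strict(self):
        kept = sc.qc_filter(self._metrics(30000, 500, 0.10, 0.05))
        assert len(kept) == 1

    def test_low_ribosomal_cell_is_excluded(self):
        kept = sc.qc_filter(self._metrics(1000, 1000, 0.01, 0.04))
        assert len(kept) == 0

    def test_exactly_planted_clean_cells_survive(self, toy_pooled, toy_thresholds):
        pooled, truth = toy_pooled
        m = sc.compute_qc_metrics(pooled.X, pooled.var_names, pooled.obs_names)
        kept = sc.qc_filter(m, toy_thresholds)
        clean = truth.obs.index[truth.obs["qc_flag"] == "clean"]
        assert set(kept) == set(clean)

    def test_idempotent_and_order_independent(self, toy_pooled, toy_thresholds):
        pooled, truth = toy_pooled
        m = sc.compute_qc_metrics(pooled.X, pooled.var_names, pooled.obs_names)
        kept = sc.qc_filter(m, toy_thresholds)
        again = sc.qc_filter(m.loc[kept], toy_thresholds)
        assert list(again) == list(kept)
        shuffled = m.sample(frac=1.0, random_state=0)
        assert set(sc.qc_filter(shuffled, toy_thresholds)) == set(kept)


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [(0, 0.0), (1, 1.0), (3, 2.0)])
    def test_closed_form_values(self, value, expected):
        assert sc.log_transform(np.array([[value]]))[0, 0] == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sc.log_transform(np.array([[-1.0]]))


class TestTfidf:
    def test_everywhere_expressed_gene_scores_exactly_zero(self):
        X = np.array([[1, 5], [2, 1], [3, 2]])
        scores = sc.tfidf_gene_scores(X, ["a", "b"])
        assert scores["a"] == 0.0 and scores["b"] == 0.0

    def test_hand_computed_score(self):
        # 4 cells of total 2 each; gene X has count 1 in exactly one cell:
        # TF = 1/2, IDF = log2(4/1) = 2, averaged over 4 cells -> 0.25
        X = np.array([[1, 1], [0, 2], [0, 2], [0, 2]])
        scores = sc.tfidf_gene_scores(X, ["X", "other"])
        assert scores["X"] == pytest.approx(0.25)

    def test_cell_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(30, 8))
        scores = sc.tfidf_gene_scores(X)
        perm = rng.permutation(30)
        pd.testing.assert_series_equal(scores, sc.tfidf_gene_scores(X[perm]))

    def test_restricted_markers_outrank_flat_housekeeping_genes(self):
        # 40 cells: 3 housekeeping genes detected in every cell (IDF = 0) vs
        # 3 marker genes expressed strongly in a 10-cell subset only.
        rng = np.random.default_rng(7)
        housekeeping = rng.poisson(3.0, size=(40, 3)) + 1
        markers = np.zeros((40, 3), dtype=int)
        markers[:10] = rng.poisson(6.0, size=(10, 3)) + 1
        X = np.hstack([housekeeping, markers])
        names = ["hk1", "hk2", "hk3", "mk1", "mk2", "mk3"]
        scores = sc.tfidf_gene_scores(X, names)
        assert scores[["mk1", "mk2", "mk3"]].min() > scores[["hk1", "hk2", "hk3"]].max()
        np.testing.assert_allclose(scores[["hk1", "hk2", "hk3"]], 0.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            sc.tfidf_gene_scores(np.empty((0, 0)))


class TestGeneSelection:
    def test_top_k_by_score(self):
        scores = pd.Series({"a": 0.1, "b": 0.5, "c": 0.3, "d": 0.2, "e": 0.0})
        assert sc.select_informative_genes(scores, 3) == ["b", "c", "d"]

    def test_tie_broken_lexicographically(self):
        scores = pd.Series({"zz": 0.5, "aa": 0.5, "mm": 1.0})
        assert sc.select_informative_genes(scores, 2) == ["mm", "aa"]

    def test_k_equal_n_returns_all_ordered(self):
        scores = pd.Series({"b": 0.5, "a": 0.5})
        assert sc.select_informative_genes(scores, 2) == ["a", "b"]

    @pytest.mark.parametrize("k", [0, -1])
    def test_nonpositive_k_rejected(self, k):
        with pytest.raises(ValueError):
            sc.select_informative_genes(pd.Series({"a": 1.0}), k)

    def test_selector_estimator_matches_function(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(2.0, size=(40, 12)).astype(float)
        names = [f"g{i:02d}" for i in range(12)]
        sel = sc.TfidfGeneSelector(k=5, gene_names=names).fit(X)
        assert sel.selected_genes_ == sc.select_informative_genes(
            sc.tfidf_gene_scores(X, names), 5
        )
        assert sel.transform(X).shape == (40, 5)


def _ward_oracle_merges(X):
    """Brute-force greedy Ward: merge the pair minimizing the ESS increase."""
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a = np.array(sorted(clusters[i])), np.array(sorted(clusters[j]))
                xa, xb = X[a[0]], X[a[1]]
                na, nb = len(xa), len(xb)
                delta = (na * nb / (na + nb)) * np.sum(
                    (xa.mean(axis=0) - xb.mean(axis=0)) ** 2
                )
                if best is None or delta < best[0]:
                    best = (delta, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


class TestWardClustering:
    def test_single_cluster_is_trivial(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        labels = sc.ward_cluster(X, 1)
        assert set(labels) == {0}

    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, (20, 4)), rng.normal(5, 0.1, (20, 4))])
        labels = sc.ward_cluster(X, 2)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_merge_sequence_matches_brute_force_ward(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 2))
        expected = _ward_oracle_merges(X)
        model = sc.WardCluster(n_clusters=1).fit(X)
        # replay scipy linkage merges as leaf sets
        members = {i: frozenset([i]) for i in range(6)}
        got = []
        for step, (a, b, _, _) in enumerate(model.linkage_):
            merged = members[int(a)] | members[int(b)]
            members[6 + step] = merged
            got.append(merged)
        assert got == expected

    def test_determinism(self):
        X = np.random.default_rng(4).normal(size=(30, 5))
        assert (sc.ward_cluster(X, 4) == sc.ward_cluster(X, 4)).all()

    def test_invalid_n_clusters_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            sc.WardCluster(n_clusters=5).fit(X)


def _welch_oracle(a, b):
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * scipy.special.stdtr(df, -abs(t))
    return t, p


class TestDifferentialExpression:
    def test_identical_groups_have_zero_fold_change(self):
        X = np.vstack([np.arange(4.0)] * 6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        de = sc.differential_expression(X, labels, 0)
        assert (de["log2_fold_change"] == 0).all()
        assert not de["passed"].any()

    def test_matches_textbook_welch_formula(self):
        x_in = np.array([1.0, 2.0, 3.0])
        x_out = np.array([1.0, 2.0, 3.0, 10.0])
        X = np.concatenate([x_in, x_out])[:, None]
        labels = np.array([0] * 3 + [1] * 4)
        de = sc.differential_expression(X, labels, 0)
        t, p = _welch_oracle(x_in, x_out)
        assert de.iloc[0]["t"] == pytest.approx(t)
        assert de.iloc[0]["p_value"] == pytest.approx(p)

    def test_sign_flips_when_groups_swap_but_p_is_unchanged(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 6))
        labels = np.array([0] * 9 + [1] * 11)
        de0 = sc.differential_expression(X, labels, 0)
        de1 = sc.differential_expression(X, labels, 1)
        np.testing.assert_allclose(
            de0["log2_fold_change"], -de1["log2_fold_change"], atol=1e-12
        )
        np.testing.assert_allclose(de0["p_value"], de1["p_value"], atol=1e-12)

    def test_planted_marker_passes_with_expected_fold_change(self, toy_pooled, toy_thresholds):
        pooled, truth = toy_pooled
        m = sc.compute_qc_metrics(pooled.X, pooled.var_names, pooled.obs_names)
        kept = sc.qc_filter(m, toy_thresholds)
        sub = pooled[kept]
        types = truth.obs.loc[kept, "cell_type"].to_numpy()
        X_log = sc.log_transform(np.asarray(sub.X.todense()))
        target = "CD8 T"
        de = sc.differential_expression(X_log, types, target, sub.var_names)
        markers = truth.marker_genes[target]
        assert de.loc[markers, "passed"].all()
        assert (de.loc[markers, "log2_fold_change"] > 1).all()

    def test_tiny_cluster_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            sc.differential_expression(X, np.array([0, 1, 1]), 0)


def _de_with_up(genes_up):
    index = ["Cd3e", "Cd8a", "Cd8b1", "S100a8", "S100a9", "Itgam", "Actb"]
    de = pd.DataFrame(
        {
            "log2_fold_change": [2.0 if g in genes_up else 0.0 for g in index],
            "p_value": [1e-5 if g in genes_up else 0.5 for g in index],
        },
        index=index,
    )
    de["passed"] = (de["p_value"] < 0.01) & (de["log2_fold_change"].abs() > 1)
    return de


class TestAnnotation:
    def test_cd8_markers_give_cd8_label(self):
        assert sc.annotate_cluster(_de_with_up({"Cd3e", "Cd8a", "Cd8b1"})) == "CD8 T"

    def test_neutrophil_markers_give_neutrophil_label(self):
        assert sc.annotate_cluster(_de_with_up({"S100a8", "S100a9", "Itgam"})) == "neutrophil"

    def test_no_passing_markers_gives_unassigned(self):
        assert sc.annotate_cluster(_de_with_up(set())) == "unassigned"

    def test_tied_panels_give_ambiguous(self):
        assert sc.annotate_cluster(_de_with_up({"Cd8a", "S100a8"})) == "ambiguous"


class TestCellCycleFlagging:
    def test_all_zero_cc_genes_flag_nothing(self):
        X = np.zeros((6, 3))
        flags = sc.flag_cell_cycle(X, [0, 0, 1, 1, 2, 2], ["Mki67", "a", "b"], ["Mki67"])
        assert not any(flags.values())

    def test_planted_proliferating_cluster_is_flagged(self, toy_thresholds):
        from tilseq import simulate

        cfg = simulate.CountSimConfig(
            n_libraries=1, cells_per_library=150, n_genes=600, marker_genes_per_type=5,
            mito_mean=3.0, ribo_mean=3.0, thresholds=toy_thresholds,
            proliferating_type=0, cc_gene_boost=3.0, seed=6,
        )
        adatas, truth = simulate.simulate_counts(cfg)
        adata = adatas["lib1"]
        types = truth.obs.loc[adata.obs_names, "cell_type"].to_numpy()
        X_log = sc.log_transform(np.asarray(adata.X.todense()))
        flags = sc.flag_cell_cycle(X_log, types, adata.var_names, truth.cc_genes, ratio=1.5)
        proliferating = cfg.type_names[0]
        assert flags[proliferating]
        assert sum(flags.values()) == 1

    def test_infinite_ratio_flags_nothing(self):
        X = np.random.default_rng(0).poisson(2.0, (10, 3)).astype(float)
        flags = sc.flag_cell_cycle(X, [0] * 5 + [1] * 5, ["Mki67", "a", "b"], ["Mki67"], ratio=np.inf)
        assert not any(flags.values())

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            sc.flag_cell_cycle(np.zeros((2, 2)), [0, 1], ["a", "b"], [])

    def test_bundled_gene_list_loads(self):
        genes = sc.load_cell_cycle_genes()
        assert "Mki67" in genes and len(genes) >= 20


class TestComposition:
    def test_even_split_is_fifty_fifty(self):
        out = sc.composition_by_library(
            ["lymphoid", "lymphoid", "myeloid", "myeloid"], ["L1"] * 4
        )
        assert out.loc["L1", "lymphoid"] == pytest.approx(50.0)
        assert out.loc["L1", "myeloid"] == pytest.approx(50.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rows_always_sum_to_one_hundred(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        groups = rng.choice(["a", "b", "c"], size=n)
        libs = rng.choice(["L1", "L2"], size=n)
        out = sc.composition_by_library(groups, libs)
        np.testing.assert_allclose(out.sum(axis=1), 100.0, atol=1e-9)

    def test_planted_mixing_recovered_within_multinomial_error(self, toy_pooled):
        pooled, truth = toy_pooled
        clean = truth.obs[truth.obs["qc_flag"] == "clean"]
        out = sc.composition_by_library(clean["cell_type"], clean["library"])
        for lib in out.index:
            n = (clean["library"] == lib).sum()
            for cell_type in out.columns:
                p = truth.mixing.loc[lib, cell_type]
                se = np.sqrt(p * (1 - p) / n) * 100
                assert abs(out.loc[lib, cell_type] - 100 * p) < 4 * se + 1e-9


class TestClusterMeanSummary:
    def test_single_cluster_row_max_is_all_ones(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = sc.cluster_mean_summary(X, [0, 0], ["a", "b"], ["a", "b"], mode="row_max")
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_hand_computed_row_max(self):
        # cluster means ((2,4),(1,1)) -> rows (0.5,1.0) and (1.0,1.0)
        X = np.array([[2.0, 1.0], [4.0, 1.0]])
        out = sc.cluster_mean_summary(X, [0, 1], ["g1", "g2"], ["g1", "g2"], mode="row_max")
        np.testing.assert_allclose(out.loc["g1"], [0.5, 1.0])
        np.testing.assert_allclose(out.loc["g2"], [1.0, 1.0])

    def test_zscore_rows_standardized(self):
        rng = np.random.default_rng(1)
        X = rng.normal(2.0, 1.0, size=(30, 4))
        labels = rng.integers(0, 3, size=30)
        out = sc.cluster_mean_summary(X, labels, ["a", "b", "c", "d"], ["a", "b", "c", "d"], mode="zscore")
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_constant_zscore_rows_are_zero(self):
        X = np.ones((4, 1))
        out = sc.cluster_mean_summary(X, [0, 0, 1, 1], ["a"], ["a"], mode="zscore")
        np.testing.assert_allclose(out.to_numpy(), 0.0)

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            sc.cluster_mean_summary(np.ones((2, 1)), [0, 1], ["missing"], ["a"])
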