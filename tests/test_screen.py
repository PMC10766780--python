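"""Unit tests for the TF-interactome screen: universe selection, ranking,
interactor capping, fold changes, scores and permutation p-values."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from airscreen.errors import (EmptyUniverseError, UndefinedScoreError,
                              ValidationError)
from airscreen.screen import (GeneSetAnnotation, InteractionNetwork,
                              LabeledExpressionMatrix, ScreenParams,
                              aggregated_score, combined_score,
                              gene_fold_change, get_interactors,
                              permutation_pvalue, rank_top_expressed,
                              run_screen, select_tf_universe)

from conftest import random_small_matrix


class TestUniverse:
    def test_annotated_and_present(self, toy_matrix, toy_annotation):
        assert select_tf_universe(toy_annotation, toy_matrix, "TF") == ["g1", "g2"]

    def test_term_absent_everywhere_raises(self, toy_matrix, toy_annotation):
        with pytest.raises(EmptyUniverseError):
            select_tf_universe(toy_annotation, toy_matrix, "nonexistent")

    def test_toy_enumeration(self, toy_matrix):
        # 6 genes carry the term, only those also in the matrix survive
        ann = GeneSetAnnotation({g: {"T"} for g in
                                 ["g1", "g2", "g3", "g4", "g9", "g10"]})
        assert select_tf_universe(ann, toy_matrix, "T") == ["g1", "g2", "g3", "g4"]


class TestRankTopExpressed:
    def test_k_at_least_n_returns_all(self, toy_matrix):
        assert rank_top_expressed(toy_matrix, ["g2", "g1"], k=5) == ["g1", "g2"]

    def test_max_over_class_rule(self):
        # gene A: mean 5 in one class only; gene B: mean 4 in all classes
        values = np.array([[0.0, 4.0], [0.0, 4.0], [5.0, 4.0]])
        m = LabeledExpressionMatrix(
            values, ["A", "B"], ["c0", "c1", "c2"],
            np.array(["B0", "S", "M"], dtype=object), "B0",
        )
        assert rank_top_expressed(m, ["A", "B"], k=1) == ["A"]

    def test_matches_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(42)
        m = random_small_matrix(rng, max_cells=16, max_genes=8)
        k = 3
        got = rank_top_expressed(m, m.gene_ids, k)
        # independent recomputation with pandas groupby
        df = pd.DataFrame(m.values, columns=m.gene_ids)
        df["cls"] = m.cell_class
        maxima = df.groupby("cls").mean().max(axis=0)
        expected = sorted(m.gene_ids, key=lambda g: (-maxima[g], g))[:k]
        assert got == expected


class TestGetInteractors:
    def test_under_cap_returns_all(self, toy_network):
        assert get_interactors(toy_network, "g1", cap=250) == ["g2", "g3"]

    def test_cap_keeps_highest_confidence(self):
        edges = [("tf", f"n{i:03d}", i / 1000.0) for i in range(1, 301)]
        net = InteractionNetwork(edges)
        kept = get_interactors(net, "tf", cap=250)
        assert len(kept) == 250
        assert set(kept) == {f"n{i:03d}" for i in range(51, 301)}

    def test_tied_confidence_at_cap_breaks_lexicographically(self):
        edges = [("tf", n, 0.5) for n in ["b", "a", "d", "c"]] + [("tf", "z", 0.9)]
        net = InteractionNetwork(edges)
        # brute-force sort oracle: confidence desc, then gene id
        expected = [n for _, n in sorted(
            [(-0.9, "z")] + [(-0.5, n) for n in "abcd"])][:3]
        assert get_interactors(net, "tf", cap=3) == expected

    def test_absent_tf_warns_and_returns_empty(self, toy_network):
        with pytest.warns(UserWarning):
            assert get_interactors(toy_network, "missing") == []

    def test_matrix_restriction(self, toy_matrix):
        net = InteractionNetwork([("g1", "g2", 0.9), ("g1", "g99", 0.99)])
        assert get_interactors(net, "g1", matrix=toy_matrix) == ["g2"]


class TestFoldChange:
    def test_hand_computed_mean_mode(self, toy_matrix):
        eps = 0.01
        # g1: basal mean 2, non-basal mean 4
        assert gene_fold_change(toy_matrix, "g1", "mean", eps) == pytest.approx(
            (4 + eps) / (2 + eps), rel=1e-14
        )

    def test_identical_group_means_give_one(self, toy_matrix):
        assert gene_fold_change(toy_matrix, "g2", "mean") == pytest.approx(1.0)
        assert gene_fold_change(toy_matrix, "g2", "positive_fraction") == pytest.approx(1.0)

    def test_all_zero_gene_is_pseudocount_limit(self, toy_matrix):
        assert gene_fold_change(toy_matrix, "g4", "mean") == pytest.approx(1.0)
        assert gene_fold_change(toy_matrix, "g4", "positive_fraction") == pytest.approx(1.0)

    def test_positive_fraction_mode(self, toy_matrix):
        eps = 0.01
        # g3 positive in 0/3 basal and 2/3 non-basal cells
        expected = (2 / 3 + eps) / (0 + eps)
        assert gene_fold_change(toy_matrix, "g3", "positive_fraction", eps) == pytest.approx(
            expected, rel=1e-14
        )

    def test_absent_gene_raises_keyerror(self, toy_matrix):
        with pytest.raises(KeyError):
            gene_fold_change(toy_matrix, "nope")


class TestScores:
    def test_combined_is_mean_of_fold_changes(self, toy_matrix):
        fc = [gene_fold_change(toy_matrix, g, "mean") for g in ["g1", "g3"]]
        assert combined_score(toy_matrix, ["g1", "g3"]) == pytest.approx(np.mean(fc))

    def test_two_interactors_with_fc_2_and_4_average_to_3(self):
        values = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 4.0], [2.0, 4.0]])
        m = LabeledExpressionMatrix(
            values, ["a", "b"], list("wxyz"),
            np.array(["B", "B", "N", "N"], dtype=object), "B",
        )
        assert combined_score(m, ["a", "b"], pseudocount=1e-12) == pytest.approx(3.0)

    def test_empty_interactors_raise(self, toy_matrix):
        with pytest.raises(UndefinedScoreError):
            combined_score(toy_matrix, [])
        with pytest.raises(UndefinedScoreError):
            aggregated_score(toy_matrix, [])

    def test_aggregated_all_positive_mean_one_sum_n(self, toy_matrix):
        # g1 and g2 positive in every cell of both groups
        assert aggregated_score(toy_matrix, ["g1", "g2"], "mean") == pytest.approx(1.0)
        assert aggregated_score(toy_matrix, ["g1", "g2"], "sum") == pytest.approx(2.0)

    def test_oracle_recomputation_both_aggregations(self):
        rng = np.random.default_rng(7)
        m = random_small_matrix(rng)
        genes = list(rng.choice(m.gene_ids, size=min(5, m.n_genes), replace=False))
        eps = 0.01
        basal = m.cell_class == "B"
        naive = []
        for g in genes:
            col = m.values[:, m.gene_ids.index(g)]
            nb = (col[~basal] > 0).mean()
            b = (col[basal] > 0).mean()
            naive.append((nb + eps) / (b + eps))
        assert aggregated_score(m, genes, "mean", eps) == pytest.approx(
            np.mean(naive), rel=1e-12)
        assert aggregated_score(m, genes, "sum", eps) == pytest.approx(
            np.sum(naive), rel=1e-12)


class TestPermutationPvalue:
    def test_observed_equals_all_nulls_gives_one(self, toy_matrix):
        const_fn = lambda m, genes: 1.0
        p, null = permutation_pvalue(
            toy_matrix, 1.0, 2, toy_matrix.gene_ids, const_fn, n_perm=99, seed=0,
            alternative="greater",
        )
        assert p == 1.0
        p_less, _ = permutation_pvalue(
            toy_matrix, 1.0, 2, toy_matrix.gene_ids, const_fn, n_perm=99, seed=0,
            alternative="less",
        )
        assert p_less == 1.0

    def test_same_seed_reproduces_p_and_null(self, toy_matrix):
        fn = lambda m, genes: combined_score(m, genes)
        out1 = permutation_pvalue(toy_matrix, 1.5, 2, toy_matrix.gene_ids, fn,
                                  n_perm=200, seed=3)
        out2 = permutation_pvalue(toy_matrix, 1.5, 2, toy_matrix.gene_ids, fn,
                                  n_perm=200, seed=3)
        assert out1[0] == out2[0]
        assert np.array_equal(out1[1], out2[1])

    def test_montecarlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        m = random_small_matrix(rng, max_cells=12, max_genes=10)
        universe = sorted(m.gene_ids)[:5]
        size = 2
        fn = lambda mat, genes: combined_score(mat, genes)
        observed = fn(m, universe[:size])
        # exhaustive oracle over all C(5,2)=10 subsets, add-one convention
        null_exact = [fn(m, list(c)) for c in itertools.combinations(universe, size)]
        p_exact = (1 + sum(s >= observed for s in null_exact)) / (1 + len(null_exact))
        n_perm = 4000
        p_mc, _ = permutation_pvalue(m, observed, size, universe, fn,
                                     n_perm=n_perm, seed=11, alternative="greater")
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) <= 3 * se + 1 / n_perm

    def test_set_size_exceeding_universe_raises(self, toy_matrix):
        with pytest.raises(ValidationError):
            permutation_pvalue(toy_matrix, 1.0, 10, ["g1", "g2"],
                               lambda m, g: 1.0, n_perm=10)


class TestRunScreen:
    @pytest.fixture
    def planted(self):
        from airscreen.simulate import ScreenSimConfig, simulate_screen_inputs

        cfg = ScreenSimConfig(n_cells_per_class=60, n_genes=300, n_tfs=30,
                              planted_interactors=20, background_edges=500, seed=5)
        return simulate_screen_inputs(cfg)

    def test_planted_tf_ranks_first(self, planted):
        m, ann, net, gt = planted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_screen(m, ann, net,
                             ScreenParams(k=30, n_perm=199, seed=5,
                                          alternative="greater"))
        assert res.iloc[0]["tf_id"] == gt["planted_tf"]
        assert res.iloc[0]["p_combined"] == pytest.approx(1 / 200)

    def test_result_invariants(self, planted):
        m, ann, net, _ = planted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_screen(m, ann, net, ScreenParams(k=30, n_perm=99, seed=1))
        scored = res.dropna(subset=["p_combined"])
        assert ((scored["p_combined"] > 0) & (scored["p_combined"] <= 1)).all()
        assert (scored["q_combined"] >= scored["p_combined"] - 1e-12).all()
        assert (scored["combined_score"] > 0).all()
        assert (res["n_interactors"] <= 250).all()
        # TFs without interactors carried through with missing scores
        empty = res[res["n_interactors"] == 0]
        assert empty["combined_score"].isna().all()

    def test_label_invariance_under_cell_and_gene_permutation(self, planted):
        m, ann, net, gt = planted
        params = ScreenParams(k=30, n_perm=99, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res1 = run_screen(m, ann, net, params)
        rng = np.random.default_rng(0)
        cell_perm = rng.permutation(m.n_cells)
        gene_perm = rng.permutation(m.n_genes)
        m2 = LabeledExpressionMatrix(
            values=m.values[cell_perm][:, gene_perm],
            gene_ids=[m.gene_ids[i] for i in gene_perm],
            cell_ids=[m.cell_ids[i] for i in cell_perm],
            cell_class=m.cell_class[cell_perm],
            basal_label=m.basal_label,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = run_screen(m2, ann, net, params)
        pd.testing.assert_frame_equal(res1, res2)

    def test_empty_network_reports_all_tfs_unscored(self, toy_matrix, toy_annotation):
        net = InteractionNetwork([])
        with pytest.warns(UserWarning):
            res = run_screen(toy_matrix, toy_annotation, net,
                             ScreenParams(term="TF", k=5, n_perm=9))
        assert (res["n_interactors"] == 0).all()
        assert res["p_combined"].isna().all()

    def test_monotone_in_planted_effect(self):
        from airscreen.simulate import ScreenSimConfig, simulate_screen_inputs

        scores = []
        for lfc in (0.0, 1.0, 2.0):
            cfg = ScreenSimConfig(n_cells_per_class=80, n_genes=300, n_tfs=30,
                                  planted_interactors=25, background_edges=400,
                                  planted_log2fc=lfc, seed=21)
            m, ann, net, gt = simulate_screen_inputs(cfg)
            ints = get_interactors(net, gt["planted_tf"], matrix=m)
            scores.append(combined_score(m, ints))
        assert scores[0] <= scores[1] <= scores[2]
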