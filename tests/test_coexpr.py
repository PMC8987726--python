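"""Weighted co-expression network construction and candidate mining."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from camptomine import coexpr
from camptomine.coexpr import (ModuleAssignment, adjacency, detect_modules,
                               locate_baits, merge_modules, mine_candidates,
                               module_eigengenes, prefilter, tom_similarity)


def _expr_from_log2(rows, index=None, columns=None):
    df = pd.DataFrame(2.0 ** np.asarray(rows) - 1.0, index=index,
                      columns=columns)
    df[df < 0] = 0.0
    return df


def _planted(seed, sizes, n_noise, loading=0.8, within_cor=0.8,
             n_samples=12):
    rng = np.random.default_rng(seed)
    sd = np.sqrt(loading ** 2 * (1 / within_cor - 1))
    Q, _ = np.linalg.qr(rng.normal(size=(n_samples, len(sizes))))
    rows, labels = [], []
    for m, size in enumerate(sizes):
        z = Q[:, m] * np.sqrt(n_samples)
        for _ in range(size):
            rows.append(5 + loading * z + rng.normal(0, sd, n_samples))
            labels.append(m + 1)
    for _ in range(n_noise):
        rows.append(5 + rng.normal(0, 1, n_samples))
        labels.append(0)
    genes = [f"g{i:04d}" for i in range(len(rows))]
    expr = _expr_from_log2(rows, index=genes,
                           columns=[f"s{j}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=genes)


class TestPrefilter:
    def test_all_zero_gene_removed(self):
        expr = pd.DataFrame([[0, 0, 0, 0], [1, 2, 3, 4], [2, 1, 2, 3],
                             [5, 5, 4, 6]],
                            index=list("abcd"), columns=list("wxyz"))
        assert list(prefilter(expr).index) == ["b", "c", "d"]

    def test_informative_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.lognormal(2, 0.5, (10, 6)))
        pd.testing.assert_frame_equal(prefilter(expr), expr)

    def test_matches_filter_by_definition_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(1, 1, (50, 8))
        vals[rng.random((50, 8)) < 0.5] = 0.0
        expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(50)])
        got = set(prefilter(expr, min_nonzero_frac=0.5).index)
        want = {f"g{i}" for i in range(50)
                if (vals[i] > 0).mean() >= 0.5 and vals[i].std() > 0}
        assert got == want

    def test_too_few_survivors_raise(self):
        expr = pd.DataFrame(np.zeros((5, 4)), index=list("abcde"))
        with pytest.raises(ValueError, match="survive"):
            prefilter(expr)

    def test_duplicate_gene_ids_rejected(self):
        expr = pd.DataFrame(np.ones((2, 4)), index=["a", "a"])
        with pytest.raises(ValueError, match="unique"):
            prefilter(expr)


class TestAdjacency:
    def test_power_one_is_absolute_correlation(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.lognormal(2, 0.4, (6, 10)))
        A = adjacency(expr, power=1).values
        C = np.corrcoef(np.log2(expr.values + 1))
        assert np.allclose(A, np.abs(C) + np.diag(1 - np.abs(np.diag(C))))

    def test_perfectly_correlated_pair_is_one_at_any_power(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        expr = pd.DataFrame(2.0 ** np.vstack([base, 2 * base]) - 1)
        for power in (1, 4, 8):
            assert adjacency(expr, power=power).values[0, 1] == \
                pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.lognormal(2, 0.4, (10, 8)))
        A = adjacency(expr, power=8).values
        C = np.corrcoef(np.log2(expr.values + 1))
        want = np.abs(C) ** 8
        np.fill_diagonal(want, 1.0)
        assert np.allclose(A, want, atol=1e-12)

    def test_signed_mode_formula(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.lognormal(2, 0.4, (6, 8)))
        A = adjacency(expr, power=2, kind="signed").values
        C = np.corrcoef(np.log2(expr.values + 1))
        want = ((1 + C) / 2) ** 2
        np.fill_diagonal(want, 1.0)
        assert np.allclose(A, want, atol=1e-12)

    def test_constant_gene_rejected(self):
        expr = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4], [2, 4, 1, 3]])
        with pytest.raises(ValueError, match="constant"):
            adjacency(expr)


class TestTom:
    def test_identity_adjacency_gives_identity(self):
        A = pd.DataFrame(np.eye(5))
        assert np.allclose(tom_similarity(A).values, np.eye(5))

    def test_complete_graph_gives_all_ones(self):
        A = pd.DataFrame(np.ones((6, 6)))
        assert np.allclose(tom_similarity(A).values, 1.0)

    def test_matches_triple_sum_oracle(self):
        rng = np.random.default_rng(5)
        n = 8
        A = rng.uniform(0, 0.9, (n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        got = tom_similarity(pd.DataFrame(A)).values
        k = A.sum(1) - 1
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert got[i, j] == 1.0
                    continue
                num = sum(A[i, u] * A[u, j] for u in range(n)
                          if u not in (i, j)) + A[i, j]
                den = min(k[i], k[j]) + 1 - A[i, j]
                assert got[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_symmetric_bounded_unit_diagonal(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(0, 1, (12, 12))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        T = tom_similarity(pd.DataFrame(A)).values
        assert np.allclose(T, T.T)
        assert (T >= -1e-12).all() and (T <= 1 + 1e-12).all()
        assert np.allclose(np.diag(T), 1.0)

    def test_asymmetric_input_rejected(self):
        A = pd.DataFrame(np.triu(np.ones((4, 4))))
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(A)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        expr, truth = _planted(seed=0, sizes=(40, 40), n_noise=0,
                               within_cor=0.8)
        tom = tom_similarity(adjacency(expr, power=8))
        asg = detect_modules(tom, expr)
        ari = adjusted_rand_score(truth.values, asg.labels.values)
        assert ari >= 0.95
        assert len(asg.modules()) == 2

    def test_independent_genes_all_grey(self):
        expr, _ = _planted(seed=1, sizes=(), n_noise=100)
        tom = tom_similarity(adjacency(expr, power=8))
        asg = detect_modules(tom, expr)
        assert set(asg.labels) == {"grey"}
        assert asg.eigengenes.empty

    def test_single_block_is_one_module(self):
        expr, _ = _planted(seed=2, sizes=(60,), n_noise=0, within_cor=0.8)
        tom = tom_similarity(adjacency(expr, power=8))
        asg = detect_modules(tom, expr)
        assert set(asg.labels) == {"turquoise"}

    def test_labels_invariant_to_gene_order(self):
        expr, _ = _planted(seed=3, sizes=(40, 35), n_noise=30,
                           within_cor=0.8)
        tom = tom_similarity(adjacency(expr, power=8))
        base = detect_modules(tom, expr).labels
        perm = np.random.default_rng(9).permutation(len(expr))
        expr2 = expr.iloc[perm]
        tom2 = tom_similarity(adjacency(expr2, power=8))
        again = detect_modules(tom2, expr2).labels
        assert base.sort_index().equals(again.sort_index())


class TestEigengenesAndMerge:
    def test_eigengenes_unit_norm_and_positively_oriented(self):
        expr, truth = _planted(seed=4, sizes=(30, 30), n_noise=0,
                               within_cor=0.8)
        labels = truth.map({1: "blue", 2: "brown"})
        eig = module_eigengenes(expr, labels)
        assert np.allclose(np.linalg.norm(eig.values, axis=0), 1.0)
        Xs = np.log2(expr.values + 1)
        Xs = (Xs - Xs.mean(1, keepdims=True)) / Xs.std(1, keepdims=True)
        for module in ("blue", "brown"):
            members = Xs[(labels == module).values]
            assert (members @ eig[module].values).mean() > 0

    def test_identical_driver_modules_merge_to_one(self):
        rng = np.random.default_rng(10)
        z = rng.normal(0, 1, 12)
        rows = [5 + 0.9 * z + rng.normal(0, 0.3, 12) for _ in range(60)]
        expr = _expr_from_log2(rows, index=[f"g{i}" for i in range(60)])
        labels = pd.Series(["x"] * 30 + ["y"] * 30, index=expr.index)
        asg = ModuleAssignment(labels=labels,
                               eigengenes=module_eigengenes(expr, labels))
        merged = merge_modules(asg, expr)
        assert len(set(merged.labels)) == 1
        assert merged.merge_history

    def test_moderately_similar_modules_not_merged(self):
        # eigengene correlation 0.5 exactly -> dissimilarity 0.5 > 0.25
        rng = np.random.default_rng(11)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 2)))
        z1 = Q[:, 0] * np.sqrt(12)
        w = Q[:, 1] * np.sqrt(12)
        z2 = 0.5 * z1 + np.sqrt(0.75) * w
        rows = [5 + 0.9 * z1 + rng.normal(0, 0.2, 12) for _ in range(30)]
        rows += [5 + 0.9 * z2 + rng.normal(0, 0.2, 12) for _ in range(30)]
        expr = _expr_from_log2(rows, index=[f"g{i}" for i in range(60)])
        labels = pd.Series(["x"] * 30 + ["y"] * 30, index=expr.index)
        asg = ModuleAssignment(labels=labels,
                               eigengenes=module_eigengenes(expr, labels))
        merged = merge_modules(asg, expr)
        assert len(set(merged.labels)) == 2

    def test_only_the_shared_driver_pair_merges(self):
        rng = np.random.default_rng(12)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 2)))
        z1 = Q[:, 0] * np.sqrt(12)
        z3 = Q[:, 1] * np.sqrt(12)
        z2 = 0.9 * z1 + np.sqrt(1 - 0.81) * rng.normal(0, 1, 12)
        rows = []
        for z in (z1, z2, z3):
            rows += [5 + 0.9 * z + rng.normal(0, 0.25, 12)
                     for _ in range(30)]
        expr = _expr_from_log2(rows, index=[f"g{i}" for i in range(90)])
        labels = pd.Series(["a"] * 30 + ["b"] * 30 + ["c"] * 30,
                           index=expr.index)
        asg = ModuleAssignment(labels=labels,
                               eigengenes=module_eigengenes(expr, labels))
        merged = merge_modules(asg, expr)
        assert merged.merge_history == [("b", "a")]
        assert set(merged.labels) == {"a", "c"}


class TestBaitsAndMining:
    def _generated(self, seed=5):
        from camptomine.synth import ExpressionTruth, gen_expression

        truth = ExpressionTruth(
            n_genes=300,
            module_sizes=(("M1", 60), ("M2", 50), ("M3", 40)),
            baits=(("bait1", "M1"), ("bait2", "M1"), ("bait3", "M3")),
            cyp_genes=tuple((f"cyp{k}", "M1") for k in range(6))
            + (("cyp_out", "M2"),),
            module_effects=(("M1", (("MeJa", 1.5), ("AgNO3", 1.5))),),
        )
        gen = gen_expression(truth, seed=seed)
        expr = prefilter(gen.expr)
        tom = tom_similarity(adjacency(expr, power=8))
        asg = detect_modules(tom, expr)
        return gen, asg, expr

    def test_baits_located_in_their_planted_modules(self):
        gen, asg, expr = self._generated()
        located = locate_baits(asg, ["bait1", "bait2", "bait3", "ghost"])
        by = dict(zip(located.bait, located.module))
        assert by["bait1"] == by["bait2"] != "grey"
        assert by["ghost"] == "missing"
        assert by["bait3"] not in (by["bait1"], "missing")

    def test_planted_candidates_mined_with_full_precision_and_recall(self):
        gen, asg, expr = self._generated()
        table = mine_candidates(asg, expr, ["bait1", "bait2"],
                                gen.annotations)
        got = set(table.gene)
        assert got == {f"cyp{k}" for k in range(6)}  # recall and precision 1
        assert "cyp_out" not in got  # CYP in a non-bait module excluded

    def test_upregulation_dominates_ranking_and_ties_sorted_by_id(self):
        gen, asg, expr = self._generated()
        genes = [f"cyp{k}" for k in range(6)]
        deg = {}
        for treatment, up_genes in (("MeJa", genes[:2]), ("AgNO3",
                                                          genes[:1])):
            table = pd.DataFrame({"direction": "ns"}, index=expr.index)
            table.loc[up_genes, "direction"] = "up"
            deg[treatment] = table
        out = mine_candidates(asg, expr, ["bait1", "bait2"],
                              gen.annotations, deg_results=deg)
        assert out.gene.iloc[0] == "cyp0"        # up in two treatments
        assert out.n_up_treatments.iloc[0] == 2
        assert out.gene.iloc[1] == "cyp1"        # up in one
        rest = list(out.gene.iloc[2:])
        assert out.n_up_treatments.iloc[2:].eq(0).all()
        # zero-up candidates are ordered by correlation, ties by id
        assert sorted(rest) == ["cyp2", "cyp3", "cyp4", "cyp5"]

    def test_no_bait_module_returns_empty_with_warning(self):
        gen, asg, expr = self._generated()
        with pytest.warns(UserWarning, match="no bait-containing"):
            out = mine_candidates(asg, expr, ["ghost"], gen.annotations)
        assert out.empty
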