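import itertools
import warnings

import numpy as np
import pytest
from scipy import stats

import scxtalk as sx
from _oracles import exhaustive_crosstalk_pvalue
from conftest import make_annotation, make_matrix


class TestGroupMeanAndScore:
    def _simple(self):
        vals = np.array([[1, 3, 2, 2, 5], [4, 4, 2, 2, 5]], dtype=float)
        m = make_matrix(vals, gene_ids=["L", "R"])
        ann = make_annotation(
            ["A", "A", "B", "B", "B"],
            ["young", "young", "young", "young", "young"],
            cell_ids=m.cell_ids,
        )
        return m, ann

    def test_group_mean_arithmetic(self):
        m, ann = self._simple()
        assert sx.group_mean(m, ann, "A", "young", "L") == 2.0

    def test_group_mean_all_zero(self):
        m = make_matrix(np.zeros((1, 2)), gene_ids=["L"])
        ann = make_annotation(["A", "A"], ["young", "old"], cell_ids=m.cell_ids)
        assert sx.group_mean(m, ann, "A", "young", "L") == 0.0

    def test_group_mean_empty_group_raises(self):
        m, ann = self._simple()
        with pytest.raises(ValueError, match="no cells"):
            sx.group_mean(m, ann, "A", "old", "L")

    def test_group_mean_matches_masked_recomputation(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.integers(0, 50, size=(5, 50)))
        ann = make_annotation(
            rng.choice(["A", "B"], 50), rng.choice(list(sx.AGE_GROUPS), 50),
            cell_ids=m.cell_ids,
        )
        for s, age, g in itertools.product("AB", sx.AGE_GROUPS, m.gene_ids):
            mask = (ann.subset == s) & (ann.age_group == age)
            if mask.any():
                expected = float(np.mean([m.values[m.gene_row(g), i]
                                          for i in np.flatnonzero(mask)]))
                assert sx.group_mean(m, ann, s, age, g) == pytest.approx(expected)

    def test_score_is_product_of_means(self):
        m, ann = self._simple()
        # sender A mean(L) = 2, receiver B mean(R) = 3
        assert sx.interaction_score(m, ann, ("L", "R"), "A", "B", "young") == 6.0

    def test_zero_ligand_mean_annihilates(self):
        m, ann = self._simple()
        m.values[0, :2] = 0
        assert sx.interaction_score(m, ann, ("L", "R"), "A", "B", "young") == 0.0


class TestPermuteAgeLabels:
    def _ann(self):
        return make_annotation(
            ["A"] * 4 + ["B"] * 4,
            ["old", "old", "young", "young", "young", "old", "young", "old"],
        )

    def test_counts_preserved_within_each_subset(self):
        ann = self._ann()
        perm = sx.permute_age_labels(ann, seed=1)
        for s in "AB":
            mask = ann.subset == s
            assert sorted(perm.age_group[mask]) == sorted(ann.age_group[mask])
        assert np.array_equal(perm.subset, ann.subset)
        assert np.array_equal(perm.cell_ids, ann.cell_ids)

    def test_seed_determinism(self):
        ann = self._ann()
        p1 = sx.permute_age_labels(ann, seed=7)
        p2 = sx.permute_age_labels(ann, seed=7)
        assert np.array_equal(p1.age_group, p2.age_group)

    def test_arrangements_uniform(self):
        # subset of 4 cells with 2 old: 6 arrangements, each ~1/6 of draws
        ann = make_annotation(["A"] * 4, ["old", "old", "young", "young"])
        rng = np.random.default_rng(0)
        counts: dict[tuple, int] = {}
        for _ in range(6000):
            perm = sx.permute_age_labels(ann, rng)
            key = tuple(perm.age_group)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        chi2 = stats.chisquare(list(counts.values())).pvalue
        assert chi2 > 0.01

    def test_single_age_subset_unchanged_with_warning(self):
        ann = make_annotation(["A", "A", "B", "B"],
                              ["young", "young", "young", "old"])
        with pytest.warns(UserWarning, match="single age group"):
            perm = sx.permute_age_labels(ann, seed=0)
        assert list(perm.age_group[:2]) == ["young", "young"]


class TestPermutationPvalue:
    def test_constant_expression_gives_p_one(self):
        vals = np.full((2, 8), 3.0)
        m = make_matrix(vals.astype(int), gene_ids=["L", "R"])
        ann = make_annotation(["A"] * 4 + ["B"] * 4,
                              ["young", "young", "old", "old"] * 2,
                              cell_ids=m.cell_ids)
        S, n, N, p = sx.permutation_pvalue(m, ann, ("L", "R"), "A", "B", "old",
                                           n_permutations=200, seed=0)
        assert S == 9.0 and n == N == 200 and p == 1.0

    def test_monte_carlo_approaches_exhaustive(self, toy_two_subset):
        matrix, annotation = toy_two_subset
        gene_rows = {g: matrix.gene_row(g) for g in matrix.gene_ids}
        N = 2000
        for (lig, rec), age in [(("L1", "R1"), "old"), (("L2", "R2"), "young")]:
            p_exact = exhaustive_crosstalk_pvalue(
                matrix.values, annotation.subset, annotation.age_group,
                gene_rows, lig, rec, "A", "B", age,
            )
            _, _, _, p_mc = sx.permutation_pvalue(
                matrix, annotation, (lig, rec), "A", "B", age,
                n_permutations=N, seed=5,
            )
            bound = 3 * np.sqrt(max(p_exact * (1 - p_exact), 1e-4) / N)
            assert abs(p_mc - p_exact) <= bound

    def test_missing_gene_raises(self, toy_two_subset):
        matrix, annotation = toy_two_subset
        with pytest.raises(KeyError, match="could not be scored"):
            sx.permutation_pvalue(matrix, annotation, ("NOPE", "R1"), "A", "B", "old")

    def test_zero_permutations_rejected(self, toy_two_subset):
        matrix, annotation = toy_two_subset
        with pytest.raises(ValueError):
            sx.permutation_pvalue(matrix, annotation, ("L1", "R1"), "A", "B", "old",
                                  n_permutations=0)


class TestRunCrosstalk:
    def _null_run(self, seed=0, n_perm=300):
        cfg = sx.SimConfig(n_subsets=2, cells_per_subset_per_age=30, n_genes=100,
                           n_mito_genes=5, n_decoy_pairs=8, seed=seed)
        matrix, annotation, lr = sx.make_null_dataset(cfg)
        norm = sx.normalize(matrix, "cp10k")
        acfg = sx.AnalysisConfig(n_permutations=n_perm, seed=seed + 1)
        return sx.run_crosstalk(norm, annotation, lr, acfg), acfg

    def test_record_grid_is_complete(self):
        result, _ = self._null_run()
        # 8 pairs x 2 senders x 2 receivers x 2 age groups
        assert len(result.records) == 8 * 2 * 2 * 2
        keys = {(r.ligand, r.receptor, r.sender, r.receiver, r.age_group)
                for r in result.records}
        assert len(keys) == len(result.records)

    def test_p_arithmetic_is_exact(self):
        result, _ = self._null_run()
        for r in result.records:
            assert 0 <= r.n <= r.N
            assert r.p == r.n / r.N  # exact n/N, no pseudocount or correction
            assert round(r.p * r.N) == r.n
            assert r.significant == (r.p <= 0.01)

    def test_determinism(self):
        r1, _ = self._null_run(seed=9)
        r2, _ = self._null_run(seed=9)
        assert r1.records == r2.records

    def test_missing_gene_pairs_are_skipped_not_scored(self):
        cfg = sx.SimConfig(n_subsets=2, cells_per_subset_per_age=10, n_genes=50,
                           n_mito_genes=2, n_decoy_pairs=4, seed=3)
        matrix, annotation, lr = sx.make_null_dataset(cfg)
        import pandas as pd

        lr2 = sx.LRPairTable(
            pd.concat([lr.records,
                       pd.DataFrame({"ligand": ["ABSENT"], "receptor": ["G00001"],
                                     "source": ["user"]})], ignore_index=True)
        )
        result = sx.run_crosstalk(sx.normalize(matrix, "cp10k"), annotation, lr2,
                                  sx.AnalysisConfig(n_permutations=50))
        assert ("ABSENT", "G00001", "missing gene(s): ABSENT") in result.skipped_pairs
        scored = {(r.ligand, r.receptor) for r in result.records}
        assert ("ABSENT", "G00001") not in scored

    def test_scale_covariance(self, toy_two_subset):
        matrix, annotation = toy_two_subset
        table = sx.LRPairTable.from_pairs([("L1", "R1"), ("L2", "R2")])
        cfg = sx.AnalysisConfig(n_permutations=400, seed=2)
        base = sx.run_crosstalk(matrix, annotation, table, cfg)
        c = 3.7
        scaled_matrix = sx.ExpressionMatrix(matrix.values * c, matrix.gene_ids,
                                            matrix.cell_ids, "cp10k")
        scaled = sx.run_crosstalk(scaled_matrix, annotation, table, cfg)
        for r0, r1 in zip(base.records, scaled.records):
            assert r1.S == pytest.approx(c * c * r0.S, rel=1e-12)
            assert r1.p == r0.p and r1.n == r0.n

    def test_planted_effect_lifts_old_score(self):
        fold = 3.0
        effect = sx.PlantedEffect("G00001", "G00002", "subset1", "subset2", "old", fold)
        cfg = sx.SimConfig(n_subsets=2, cells_per_subset_per_age=200, n_genes=150,
                           n_mito_genes=5, n_decoy_pairs=5,
                           planted_effects=(effect,), seed=13)
        matrix, annotation, lr, _ = sx.generate_dataset(cfg)
        s_old = sx.interaction_score(matrix, annotation, ("G00001", "G00002"),
                                     "subset1", "subset2", "old")
        s_young = sx.interaction_score(matrix, annotation, ("G00001", "G00002"),
                                       "subset1", "subset2", "young")
        # ligand and receptor means are both scaled, so S scales ~ fold^2
        assert s_old / s_young == pytest.approx(fold**2, rel=0.35)

    def test_larger_planted_fold_does_not_raise_mean_p(self):
        # average over replicate datasets with shared seeds: a stronger
        # planted effect can only make the planted pair's p smaller
        def mean_p(fold):
            ps = []
            for rep in range(10):
                effect = sx.PlantedEffect("G00001", "G00002", "subset1",
                                          "subset1", "old", fold)
                cfg = sx.SimConfig(n_subsets=1, cells_per_subset_per_age=50,
                                   n_genes=80, n_mito_genes=4, n_decoy_pairs=2,
                                   planted_effects=(effect,), seed=100 + rep)
                matrix, annotation, _, _ = sx.generate_dataset(cfg)
                *_, p = sx.permutation_pvalue(
                    matrix, annotation, ("G00001", "G00002"),
                    "subset1", "subset1", "old", n_permutations=200, seed=rep,
                )
                ps.append(p)
            return np.mean(ps)

        assert mean_p(4.0) <= mean_p(1.5)

    def test_pseudo_pvalue_reported_when_requested(self, toy_two_subset):
        matrix, annotation = toy_two_subset
        table = sx.LRPairTable.from_pairs([("L1", "R1")])
        cfg = sx.AnalysisConfig(n_permutations=100, seed=0, crosstalk_pseudo=True)
        result = sx.run_crosstalk(matrix, annotation, table, cfg)
        for r in result.records:
            assert r.p_pseudo == pytest.approx((r.n + 1) / (r.N + 1))

    def test_subset_without_both_ages_excluded(self):
        m = make_matrix(np.ones((2, 6), dtype=int) * 2, gene_ids=["L", "R"])
        ann = make_annotation(["A"] * 4 + ["B"] * 2,
                              ["young", "young", "old", "old", "young", "young"],
                              cell_ids=m.cell_ids)
        table = sx.LRPairTable.from_pairs([("L", "R")])
        with pytest.warns(UserWarning, match="lack one age group"):
            result = sx.run_crosstalk(m, ann, table,
                                      sx.AnalysisConfig(n_permutations=20))
        senders = {r.sender for r in result.records}
        assert senders == {"A"}
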