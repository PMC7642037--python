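"""Soft threshold, TOM, clustering, eigengenes and module merging."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gelnet.coexpression import CorrelationMatrix
from gelnet.errors import ValidationError
from gelnet.io import ExpressionMatrix
from gelnet.modules import (
    GREY,
    DetectionConfig,
    ModuleDetector,
    adjacency,
    cluster_modules,
    merge_modules,
    module_eigengene,
    soft_threshold_scan,
    tom_similarity,
)
from gelnet.simulate import SimulationSpec, simulate_expression


def _cm(matrix, prefix="g"):
    n = matrix.shape[0]
    return CorrelationMatrix(tuple(f"{prefix}{i:03d}" for i in range(n)), matrix)


class TestAdjacency:
    def test_negative_half_to_the_seventh(self):
        m = np.array([[1.0, -0.5], [-0.5, 1.0]])
        a = adjacency(_cm(m), beta=7)
        assert a[0, 1] == pytest.approx(0.0078125)

    def test_perfect_correlation_stays_one(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0]])
        for beta in (1, 3, 12):
            assert adjacency(_cm(m), beta)[0, 1] == 1.0

    def test_beta_one_is_absolute_value(self, rng):
        x = rng.uniform(-1, 1, size=(6, 6))
        m = np.clip((x + x.T) / 2, -0.99, 0.99)
        np.fill_diagonal(m, 1.0)
        cm = _cm(m)
        np.testing.assert_allclose(adjacency(cm, 1), np.abs(cm.matrix))


class TestSoftThresholdScan:
    def test_mean_connectivity_decreases_with_power(self, block_sim):
        from gelnet.coexpression import correlation_matrix

        cm = correlation_matrix(block_sim.expression, 0, 0.0)
        table = soft_threshold_scan(cm, powers=(1, 7))
        k1 = table.loc[table["power"] == 1, "mean_connectivity"].iloc[0]
        k7 = table.loc[table["power"] == 7, "mean_connectivity"].iloc[0]
        assert k7 <= k1

    def test_identity_matrix_has_zero_connectivity(self):
        cm = _cm(np.eye(10))
        table = soft_threshold_scan(cm, powers=(1, 5))
        assert (table["mean_connectivity"] == 0).all()


class TestTOM:
    def test_complete_unit_adjacency_gives_unit_tom(self):
        a = np.ones((3, 3))
        np.testing.assert_allclose(tom_similarity(a), np.ones((3, 3)))

    def test_disconnected_pair_gives_zero(self):
        a = np.eye(4)
        t = tom_similarity(a)
        assert t[0, 1] == 0.0

    def test_three_node_chain_hand_values(self):
        a = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.5], [0.0, 0.5, 1.0]])
        t = tom_similarity(a)
        assert t[0, 1] == pytest.approx(0.5)
        assert t[0, 2] == pytest.approx(0.25 / 1.5)

    def test_matches_triple_loop_oracle(self, rng):
        n = 40
        x = rng.uniform(0, 1, size=(n, n))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 1.0)
        got = tom_similarity(a)
        # brute-force oracle straight from the definition
        expect = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                L = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                expect[i, j] = (L + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_symmetric_unit_diagonal_in_range(self, rng):
        x = rng.uniform(0, 1, size=(25, 25))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 1.0)
        t = tom_similarity(a)
        np.testing.assert_allclose(t, t.T)
        assert np.all((t >= 0) & (t <= 1))
        np.testing.assert_allclose(np.diag(t), 1.0)


class TestClusterModules:
    def _blocks_cm(self, sizes=(50, 50), within=0.9, between=0.0, seed=0):
        n = sum(sizes)
        m = np.full((n, n), between)
        pos = 0
        for s in sizes:
            m[pos : pos + s, pos : pos + s] = within
            pos += s
        np.fill_diagonal(m, 1.0)
        return _cm(m)

    def test_two_planted_blocks_fully_recovered(self):
        cm = self._blocks_cm()
        tom = tom_similarity(adjacency(cm, 7))
        labels = cluster_modules(tom, cm.gene_ids, DetectionConfig(min_module_size=30))
        assert set(labels) == {"M1", "M2"}
        assert (labels.iloc[:50].nunique(), labels.iloc[50:].nunique()) == (1, 1)

    def test_uncorrelated_genes_all_grey(self):
        cm = _cm(np.eye(10))
        tom = tom_similarity(adjacency(cm, 7))
        with pytest.warns(UserWarning):
            labels = cluster_modules(tom, cm.gene_ids, DetectionConfig(min_module_size=30))
        assert (labels == GREY).all()

    def test_gene_order_permutation_invariant_up_to_names(self, rng):
        cm = self._blocks_cm(sizes=(40, 40), within=0.85)
        tom = tom_similarity(adjacency(cm, 7))
        labels = cluster_modules(tom, cm.gene_ids, DetectionConfig(min_module_size=20))
        perm = rng.permutation(cm.n_genes)
        genes_p = tuple(np.array(cm.gene_ids)[perm])
        labels_p = cluster_modules(tom[np.ix_(perm, perm)], genes_p,
                                   DetectionConfig(min_module_size=20))
        aligned = labels_p.loc[list(cm.gene_ids)]
        assert adjusted_rand_score(labels, aligned) == pytest.approx(1.0)


class TestEigengene:
    def _em(self, X):
        return ExpressionMatrix(
            pd.DataFrame(
                X - X.min() if (X < 0).any() else X,
                index=[f"g{i}" for i in range(X.shape[0])],
                columns=[f"s{j}" for j in range(X.shape[1])],
            )
        )

    def test_identical_profiles_give_standardized_profile(self):
        profile = np.array([1.0, 4.0, 2.0, 6.0, 3.0])
        X = np.tile(profile, (5, 1))
        em = self._em(X)
        e = module_eigengene(em, em.gene_ids)
        std = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(e, std / np.linalg.norm(std), atol=1e-10)

    def test_single_gene_module(self):
        X = np.array([[2.0, 5.0, 3.0, 9.0]])
        em = self._em(X)
        e = module_eigengene(em, ["g0"])
        assert np.linalg.norm(e) == pytest.approx(1.0)
        assert np.corrcoef(e, X[0])[0, 1] == pytest.approx(1.0)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        X = rng.gamma(2, 2, size=(20, 15))
        em = self._em(X)
        e = module_eigengene(em, em.gene_ids)
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        _, _, vt = np.linalg.svd(Xs)
        oracle = vt[0] / np.linalg.norm(vt[0])
        assert min(np.abs(e - oracle).max(), np.abs(e + oracle).max()) < 1e-10

    def test_missing_member_named(self, block_sim):
        with pytest.raises(ValidationError, match="nope"):
            module_eigengene(block_sim.expression, ["nope"])


class TestMerge:
    def _em_two_identical_blocks(self, seed=0):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=30)
        X = np.vstack([
            latent + rng.normal(0, 0.05, size=(20, 30)),
            latent + rng.normal(0, 0.05, size=(20, 30)),
            -latent + rng.normal(0, 0.05, size=(20, 30)),
        ])
        X -= X.min()
        em = ExpressionMatrix(pd.DataFrame(
            X, index=[f"g{i:02d}" for i in range(60)], columns=[f"s{j}" for j in range(30)]
        ))
        labels = pd.Series(["A"] * 20 + ["B"] * 20 + ["C"] * 20, index=em.gene_ids)
        return em, labels

    def test_identical_eigengenes_merge(self):
        em, labels = self._em_two_identical_blocks()
        merged = merge_modules(labels, em, merge_cut_height=0.25)
        # A and B share the latent profile -> one module; C is anti-correlated
        assert merged.nunique() == 2
        assert merged.iloc[:40].nunique() == 1

    def test_uncorrelated_eigengenes_do_not_merge(self, rng):
        X = np.vstack([
            np.tile(rng.normal(size=30), (10, 1)) + rng.normal(0, 0.01, (10, 30)),
            np.tile(rng.normal(size=30), (10, 1)) + rng.normal(0, 0.01, (10, 30)),
        ])
        X -= X.min()
        em = ExpressionMatrix(pd.DataFrame(
            X, index=[f"g{i}" for i in range(20)], columns=[f"s{j}" for j in range(30)]
        ))
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=em.gene_ids)
        merged = merge_modules(labels, em, merge_cut_height=0.25)
        assert merged.nunique() == 2

    def test_three_mutually_similar_modules_collapse(self, rng):
        latent = rng.normal(size=40)
        X = np.vstack([
            latent + rng.normal(0, 0.3, size=(15, 40)) for _ in range(3)
        ])
        X -= X.min()
        em = ExpressionMatrix(pd.DataFrame(
            X, index=[f"g{i:02d}" for i in range(45)], columns=[f"s{j}" for j in range(40)]
        ))
        labels = pd.Series(["A"] * 15 + ["B"] * 15 + ["C"] * 15, index=em.gene_ids)
        merged = merge_modules(labels, em, merge_cut_height=0.25)
        assert merged.nunique() == 1

    def test_merging_never_increases_count_and_grey_untouched(self, rng):
        em, labels = self._em_two_identical_blocks(seed=5)
        labels.iloc[55:] = GREY
        merged = merge_modules(labels, em, merge_cut_height=0.25)
        assert merged.nunique() <= labels.nunique()
        assert (merged[labels == GREY] == GREY).all()


class TestModuleDetector:
    def test_recovers_planted_modules(self, block_sim):
        det = ModuleDetector(min_module_size=20).fit(block_sim.expression)
        labels = det.labels_
        non_grey = labels[labels != GREY]
        ari = adjusted_rand_score(block_sim.truth[non_grey.index], non_grey)
        assert ari >= 0.9
        assert det.partition_.n_modules == 3

    def test_eigengene_correlates_with_module_mean(self, block_sim):
        det = ModuleDetector(min_module_size=20).fit(block_sim.expression)
        em = block_sim.expression
        for module in det.partition_.module_names:
            members = det.partition_.members(module)
            mean_profile = em.data.loc[members].mean(axis=0)
            e = det.eigengenes_.loc[module]
            assert abs(np.corrcoef(e, mean_profile)[0, 1]) > 0.8
            assert np.corrcoef(e, mean_profile)[0, 1] >= 0  # sign convention

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        det = ModuleDetector(power=5, min_module_size=10)
        det2 = clone(det)
        assert det2.get_params()["power"] == 5

    def test_duplicate_blocks_reduce_module_count_via_merge(self):
        spec = SimulationSpec(n_genes=120, n_samples=30, module_sizes=(40, 40),
                              signal_sd=3.0, noise_sd=0.5, seed=21)
        rngd = np.random.default_rng(99)
        sim = simulate_expression(spec)
        # make the second block a noisy duplicate of the first block's latent
        df = sim.expression.data.copy()
        base = df.iloc[:40].to_numpy()
        df.iloc[40:80] = base + rngd.normal(0, 0.5, size=(40, df.shape[1]))
        em = ExpressionMatrix(df.clip(lower=0))
        no_merge = ModuleDetector(min_module_size=20, merge_cut_height=0.0).fit(em)
        merged = ModuleDetector(min_module_size=20, merge_cut_height=0.25).fit(em)
        assert merged.partition_.n_modules <= no_merge.partition_.n_modules
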