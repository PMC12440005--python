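"""Attribution constraints, Moran's I, SVG calls, covariation and niches."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import s3reg as s


class TestAttributionConstraints:
    def test_negative_shrunk_to_zero(self):
        values = np.array([[-0.3, 0.5]])
        props = np.array([[0.5, 0.5]])
        out = s.apply_attribution_constraints(values, props)
        assert out[0, 0] == 0.0 and out[0, 1] == 0.5

    def test_absent_celltype_contributes_nothing(self):
        values = np.array([[0.7, 0.5]])
        props = np.array([[0.0, 0.5]])
        out = s.apply_attribution_constraints(values, props)
        assert out[0, 0] == 0.0

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_no_violations_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(30, 4))
        props = rng.uniform(size=(30, 4)) * (rng.uniform(size=(30, 4)) > 0.3)
        out = s.apply_attribution_constraints(values, props)
        assert (out >= 0).all()
        assert not ((out > 0) & (props == 0)).any()

    def test_generative_recovery_of_celltype_levels(self):
        """Expression driven by one cell type is attributed to that type."""
        means, spurious = [], []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n, K = 200, 3
            # mixed abundances below a full simplex (deconvolution totals
            # need not reach one), with genuinely absent cell types per spot
            props = rng.dirichlet([1.0] * K, size=n) * rng.uniform(0.7, 1.0, (n, 1))
            props[props < 0.05] = 0.0
            level = np.array([2.0, 0.0, 0.0])
            expr = props @ level + rng.normal(scale=0.05, size=n)
            coords = rng.uniform(size=(n, 2))
            graph = s.build_knn_graph(coords, 7)
            att = s.attribute_celltypes(
                expr, props, coords, graph,
                spot_ids=[f"s{i}" for i in range(n)],
                celltype_names=["kera", "fibro", "imm"],
                opt=s.OptimizerConfig(max_iter=2500, seed=seed),
                seed=seed,
            )
            active1 = att.values[:, 0] > 0
            if active1.any():
                means.append(att.values[active1, 0].mean())
            spurious.append(max((att.values[:, 1] > 0).mean(),
                                (att.values[:, 2] > 0).mean()))
        assert 1.6 <= np.median(means) <= 2.4
        assert np.median(spurious) <= 0.10

    def test_too_many_celltypes_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(s.ValidationError):
            s.attribute_celltypes(
                rng.normal(size=5), rng.uniform(size=(5, 6)) / 6,
                rng.uniform(size=(5, 2)), s.build_knn_graph(rng.uniform(size=(5, 2)), 2),
                spot_ids=list("abcde"), celltype_names=[f"c{i}" for i in range(6)],
            )


class TestMoransI:
    def test_linear_gradient_on_path(self, path_graph4):
        res = s.morans_i(np.array([1.0, 2.0, 3.0, 4.0]), path_graph4, 99, seed=0)
        assert res.statistic == pytest.approx(0.4)

    def test_alternating_on_path(self, path_graph4):
        res = s.morans_i(np.array([1.0, -1.0, 1.0, -1.0]), path_graph4, 99, seed=0)
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_vector_rejected(self, path_graph4):
        with pytest.raises(s.ValidationError):
            s.morans_i(np.ones(4), path_graph4, 99)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        g = s.build_knn_graph(rng.uniform(size=(40, 2)), 4)
        v = rng.normal(size=40)
        base = s.morans_i(v, g, 99, seed=1).statistic
        shifted = s.morans_i(3.0 * v + 7.0, g, 99, seed=1).statistic
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_pvalue_floor(self, path_graph4):
        res = s.morans_i(np.array([1.0, 2.0, 3.0, 4.0]), path_graph4, 99, seed=0)
        assert res.perm_pvalue >= 1 / 100


class TestDetectSvgs:
    @staticmethod
    def _attribution(values, graph):
        n, K = values.shape
        return s.AttributionField(
            gene="g", values=np.maximum(values, 0.0),
            celltype_names=[f"ct{k}" for k in range(K)],
            spot_ids=[f"s{i}" for i in range(n)],
            proportions_ref=np.ones_like(values),
        )

    def test_gradient_flagged_noise_not(self):
        grad_hits, noise_hits = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            coords = rng.uniform(size=(100, 2))
            g = s.build_knn_graph(coords, 7)
            gradient = coords[:, 0] + rng.normal(scale=0.1, size=100)
            noise = np.abs(rng.normal(size=100))
            att = self._attribution(np.column_stack([gradient, noise]), g)
            table = s.detect_svgs([att], g, alpha=0.05, n_permutations=199, seed=seed)
            flags = dict(zip(table["celltype"], table["is_svg"]))
            grad_hits += int(flags["ct0"])
            noise_hits += int(flags["ct1"])
        assert grad_hits >= 9
        assert noise_hits <= 1

    def test_constant_and_zero_columns_skipped(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(size=(50, 2))
        g = s.build_knn_graph(coords, 5)
        values = np.column_stack([np.zeros(50), np.abs(rng.normal(size=50))])
        att = self._attribution(values, g)
        table = s.detect_svgs([att], g, n_permutations=99, seed=0)
        assert list(table["celltype"]) == ["ct1"]


class TestCovariation:
    def test_identical_vectors_perfect_rho(self):
        idx = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        v = rng.normal(size=10)
        A = pd.DataFrame({"g1": v}, index=idx)
        res = s.covariation_test(A, A.rename(columns={"g1": "g2"}),
                                 n_permutations=99, seed=0)
        assert res[0].rho == pytest.approx(1.0)

    def test_hand_spearman_example(self):
        idx = ["a", "b", "c"]
        A = pd.DataFrame({"g1": [1.0, 2.0, 3.0]}, index=idx)
        B = pd.DataFrame({"g2": [3.0, 1.0, 2.0]}, index=idx)
        res = s.covariation_test(A, B, n_permutations=99, min_nonzero_spots=3, seed=0)
        assert res[0].rho == pytest.approx(-0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(30)]
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        A = pd.DataFrame({"g1": a}, index=idx)
        r1 = s.covariation_test(A, pd.DataFrame({"g2": b}, index=idx),
                                n_permutations=99, seed=3)[0].rho
        r2 = s.covariation_test(A, pd.DataFrame({"g2": np.exp(b)}, index=idx),
                                n_permutations=99, seed=3)[0].rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_sparse_genes_skipped(self):
        idx = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        A = pd.DataFrame({"dense": rng.normal(size=10),
                          "sparse": np.r_[1.0, np.zeros(9)]}, index=idx)
        B = pd.DataFrame({"g": rng.normal(size=10)}, index=idx)
        res = s.covariation_test(A, B, n_permutations=99, seed=0)
        assert {r.gene_pair[0] for r in res} == {"dense"}

    def test_spot_axis_mismatch_rejected(self):
        A = pd.DataFrame({"g": [1.0, 2.0]}, index=["a", "b"])
        B = pd.DataFrame({"g": [1.0, 2.0]}, index=["a", "c"])
        with pytest.raises(s.ValidationError):
            s.covariation_test(A, B)


class TestTensorAggregation:
    def test_interaction_strength_is_mean_count(self):
        sec1 = {(f"g{i}", "h", "C1", "C2") for i in range(3)}
        sec2 = {(f"g{i}", "h", "C1", "C2") for i in range(5)}
        t = s.aggregate_tensors({"s1": sec1, "s2": sec2}, min_sections=2)
        assert t.interaction_strength[("C1", "C2")] == pytest.approx(4.0)

    def test_replication_rule(self):
        shared = ("a", "b", "C1", "C2")
        only1 = ("c", "d", "C1", "C2")
        t = s.aggregate_tensors({"s1": {shared, only1}, "s2": {shared}}, min_sections=2)
        assert shared in t.replicated
        assert only1 not in t.replicated

    def test_canonical_ordering_merges_symmetric_keys(self):
        k1 = s.canonical_association(("g1", "g2"), ("C1", "C2"))
        k2 = s.canonical_association(("g2", "g1"), ("C2", "C1"))
        assert k1 == k2


class TestContextFeatures:
    def test_uniform_type_gives_one_hot_rows(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(size=(50, 2))
        feats = s.build_context_features(coords, ["T"] * 50, k_neighbors=10,
                                         k_niches=2, seed=0)
        assert np.allclose(feats.local_composition, 1.0)

    def test_composition_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(size=(80, 2))
        labels = rng.choice(["A", "B", "C"], size=80)
        feats = s.build_context_features(coords, labels, k_neighbors=15,
                                         k_niches=3, seed=1)
        assert np.allclose(feats.local_composition.sum(axis=1), 1.0)
        assert np.allclose(feats.niche_indicators.sum(axis=1), 1.0)

    def test_disjoint_regions_recovered_as_niches(self):
        rng = np.random.default_rng(2)
        left = rng.uniform([0, 0], [1, 1], size=(60, 2))
        right = rng.uniform([10, 0], [11, 1], size=(60, 2))
        coords = np.vstack([left, right])
        labels = ["A"] * 60 + ["B"] * 60
        feats = s.build_context_features(coords, labels, k_neighbors=10,
                                         k_niches=2, seed=2)
        region = np.r_[np.zeros(60, dtype=int), np.ones(60, dtype=int)]
        assert s.adjusted_rand_index(region, feats.niche_labels) == pytest.approx(1.0)
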