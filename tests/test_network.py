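"""Network construction: adjacency, TOM, calibration, consensus, modules."""

import numpy as np
import pandas as pd
import pytest

import ocrnet as oc
from ocrnet.io import ExpressionDataset
from ocrnet.network import (
    GREY,
    AdjacencyMatrix,
    TomMatrix,
    _quantile_normalize_columns,
)


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(gene_ids=[f"g{i}" for i in range(n)], values=a, beta=1)


def brute_force_tom(a):
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return tom


class TestSignedAdjacency:
    def test_forced_correlation_values(self):
        s = np.arange(6.0)
        values = np.vstack([s, 2 * s + 1, -s])  # r(0,1)=1, r(0,2)=-1
        ds = ExpressionDataset(["a", "b", "c"], [f"S{j}" for j in range(6)], values)
        adj = oc.signed_adjacency(ds, beta=7)
        assert adj.values[0, 1] == pytest.approx(1.0)
        assert adj.values[0, 2] == pytest.approx(0.0)

    def test_zero_correlation_at_beta_12(self, rng):
        # two exactly orthogonal, centered profiles: r = 0 -> a = 2^-12
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        ds = ExpressionDataset(["a", "b"], [f"S{j}" for j in range(4)], np.vstack([x, y]))
        adj = oc.signed_adjacency(ds, beta=12)
        assert adj.values[0, 1] == pytest.approx(1.0 / 4096.0)

    def test_constant_gene_named(self, rng):
        values = rng.normal(size=(3, 8))
        values[1] = 2.0
        ds = ExpressionDataset(["a", "flat", "c"], [f"S{j}" for j in range(8)], values)
        with pytest.raises(ValueError, match="flat"):
            oc.signed_adjacency(ds)

    def test_symmetric_bounded(self, rng):
        ds = ExpressionDataset(
            [f"g{i}" for i in range(20)], [f"S{j}" for j in range(15)],
            rng.normal(size=(20, 15)),
        )
        adj = oc.signed_adjacency(ds, beta=6)
        np.testing.assert_allclose(adj.values, adj.values.T, atol=1e-12)
        assert adj.values.min() >= 0 and adj.values.max() <= 1


class TestTopologicalOverlap:
    def test_zero_offdiagonal(self):
        a = np.eye(5)
        tom = oc.topological_overlap(AdjacencyMatrix([f"g{i}" for i in range(5)], a, 1))
        np.testing.assert_array_equal(tom.values, np.eye(5))

    def test_complete_graph_is_all_ones(self):
        n = 6
        a = np.ones((n, n))
        tom = oc.topological_overlap(AdjacencyMatrix([f"g{i}" for i in range(n)], a, 1))
        np.testing.assert_allclose(tom.values, np.ones((n, n)), atol=1e-12)

    def test_matches_brute_force(self, rng):
        adj = random_adjacency(rng, 20)
        tom = oc.topological_overlap(adj)
        np.testing.assert_allclose(tom.values, brute_force_tom(adj.values), atol=1e-10)

    def test_symmetry_and_bounds_property(self, rng):
        for _ in range(5):
            adj = random_adjacency(rng, 12)
            tom = oc.topological_overlap(adj)
            np.testing.assert_allclose(tom.values, tom.values.T, atol=1e-12)
            assert tom.values.min() >= 0 and tom.values.max() <= 1


class TestCalibration:
    def toy_toms(self, rng, n=8, k=2):
        out = []
        for _ in range(k):
            adj = random_adjacency(rng, n)
            out.append(oc.topological_overlap(adj))
        return out

    def test_identical_inputs_are_fixed_points(self, rng):
        t = self.toy_toms(rng, k=1)[0]
        t2 = TomMatrix(gene_ids=list(t.gene_ids), values=t.values.copy())
        out = oc.calibrate_toms([t, t2])
        np.testing.assert_allclose(out[0].values, t.values, atol=1e-12)
        np.testing.assert_allclose(out[1].values, t.values, atol=1e-12)

    def test_sorted_upper_triangles_identical(self, rng):
        toms = self.toy_toms(rng, n=12, k=3)
        out = oc.calibrate_toms(toms)
        iu = np.triu_indices(12, 1)
        ref = np.sort(out[0].values[iu])
        for t in out[1:]:
            np.testing.assert_allclose(np.sort(t.values[iu]), ref, atol=1e-12)

    def test_rank_preservation_within_matrix(self, rng):
        toms = self.toy_toms(rng, n=10, k=2)
        out = oc.calibrate_toms(toms)
        iu = np.triu_indices(10, 1)
        for before, after in zip(toms, out):
            np.testing.assert_array_equal(
                np.argsort(before.values[iu], kind="stable"),
                np.argsort(after.values[iu], kind="stable"),
            )

    def test_three_gene_hand_oracle(self):
        # upper triangles (0.1, 0.4, 0.2) and (0.3, 0.5, 0.7):
        # sorted means: (0.1+0.3)/2=0.2, (0.2+0.5)/2=0.35, (0.4+0.7)/2=0.55
        g = ["a", "b", "c"]
        t1 = np.eye(3); t1[0, 1] = t1[1, 0] = 0.1; t1[0, 2] = t1[2, 0] = 0.4; t1[1, 2] = t1[2, 1] = 0.2
        t2 = np.eye(3); t2[0, 1] = t2[1, 0] = 0.3; t2[0, 2] = t2[2, 0] = 0.5; t2[1, 2] = t2[2, 1] = 0.7
        out = oc.calibrate_toms([TomMatrix(g, t1), TomMatrix(g, t2)])
        assert out[0].values[0, 1] == pytest.approx(0.2)
        assert out[0].values[1, 2] == pytest.approx(0.35)
        assert out[0].values[0, 2] == pytest.approx(0.55)
        assert out[1].values[0, 1] == pytest.approx(0.2)
        assert out[1].values[0, 2] == pytest.approx(0.35)
        assert out[1].values[1, 2] == pytest.approx(0.55)

    def test_tie_rule_averages_target_values(self):
        # first matrix has a tie; tied entries share the mean of their targets
        g = ["a", "b", "c"]
        t1 = np.eye(3); t1[0, 1] = t1[1, 0] = 0.2; t1[0, 2] = t1[2, 0] = 0.2; t1[1, 2] = t1[2, 1] = 0.8
        t2 = np.eye(3); t2[0, 1] = t2[1, 0] = 0.1; t2[0, 2] = t2[2, 0] = 0.5; t2[1, 2] = t2[2, 1] = 0.9
        out = oc.calibrate_toms([TomMatrix(g, t1), TomMatrix(g, t2)])
        # targets: (0.2+0.1)/2=0.15, (0.2+0.5)/2=0.35, (0.8+0.9)/2=0.85
        assert out[0].values[0, 1] == pytest.approx(0.25)  # (0.15+0.35)/2
        assert out[0].values[0, 2] == pytest.approx(0.25)
        assert out[0].values[1, 2] == pytest.approx(0.85)

    def test_mismatched_gene_sets_rejected(self, rng):
        t1 = self.toy_toms(rng, k=1)[0]
        t2 = TomMatrix(gene_ids=[g + "x" for g in t1.gene_ids], values=t1.values.copy())
        with pytest.raises(ValueError):
            oc.calibrate_toms([t1, t2])


class TestConsensus:
    def test_single_tom_is_itself(self, rng):
        t = oc.topological_overlap(random_adjacency(rng, 6))
        out = oc.consensus_tom([t])
        np.testing.assert_array_equal(out.values, t.values)

    def test_mean_of_entries(self):
        g = ["a", "b"]
        t1 = TomMatrix(g, np.array([[1.0, 0.2], [0.2, 1.0]]))
        t2 = TomMatrix(g, np.array([[1.0, 0.4], [0.4, 1.0]]))
        assert oc.consensus_tom([t1, t2]).values[0, 1] == pytest.approx(0.3)
        assert oc.consensus_tom([t1, t2], operator="min").values[0, 1] == pytest.approx(0.2)

    def test_permutation_equivariance(self, rng):
        toms = [oc.topological_overlap(random_adjacency(rng, 9)) for _ in range(2)]
        cons = oc.consensus_tom(toms)
        perm = rng.permutation(9)
        permuted = [
            TomMatrix([t.gene_ids[i] for i in perm], t.values[np.ix_(perm, perm)])
            for t in toms
        ]
        cons_p = oc.consensus_tom(permuted)
        np.testing.assert_allclose(cons_p.values, cons.values[np.ix_(perm, perm)], atol=1e-15)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            oc.consensus_tom([])


class TestDetectModules:
    def test_all_ones_single_module(self):
        n = 40
        t = TomMatrix([f"g{i}" for i in range(n)], np.ones((n, n)))
        assignment, _ = oc.detect_modules(t, min_size=30)
        assert assignment.modules == ["turquoise"]
        assert (assignment.labels == "turquoise").all()

    def test_small_cluster_goes_grey(self):
        # 10 tightly overlapping genes among 40 unconnected ones, min size 30
        n = 50
        v = np.eye(n)
        v[:10, :10] = 1.0
        t = TomMatrix([f"g{i}" for i in range(n)], v)
        assignment, _ = oc.detect_modules(t, min_size=30)
        assert (assignment.labels == GREY).all()

    def test_static_cut_rule(self):
        n = 50
        v = np.eye(n)
        v[:30, :30] = 1.0
        t = TomMatrix([f"g{i}" for i in range(n)], v)
        assignment, _ = oc.detect_modules(t, cut_height=0.999, min_size=30, method="static")
        assert assignment.sizes()["turquoise"] == 30
        assert assignment.sizes()[GREY] == 20

    def test_gene_order_invariance_up_to_relabeling(self, bundle):
        from sklearn.metrics import adjusted_rand_score

        net = oc.build_consensus_network(bundle.datasets)
        perm = np.random.default_rng(0).permutation(len(net.gene_ids))
        t = net.consensus
        tp = TomMatrix([t.gene_ids[i] for i in perm], t.values[np.ix_(perm, perm)])
        a1, _ = oc.detect_modules(t)
        a2, _ = oc.detect_modules(tp)
        joined = pd.concat([a1.labels.rename("a"), a2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) > 0.95


class TestEigengenes:
    def test_rank_one_module_recovers_profile(self, rng):
        profile = rng.normal(size=25)
        values = np.outer(rng.uniform(0.5, 1.5, size=8), profile)
        ds = ExpressionDataset([f"g{i}" for i in range(8)], [f"S{j}" for j in range(25)], values)
        labels = pd.Series("turquoise", index=ds.gene_ids)
        mes = oc.module_eigengene(ds, oc.ModuleAssignment(labels=labels))
        me = mes.values.loc["turquoise"].to_numpy()
        assert abs(np.corrcoef(me, profile)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert mes.var_explained["turquoise"] == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_sign_alignment_positive_mean_correlation(self, rng):
        ds = ExpressionDataset(
            [f"g{i}" for i in range(10)], [f"S{j}" for j in range(30)],
            rng.normal(size=(10, 30)),
        )
        labels = pd.Series("blue", index=ds.gene_ids)
        mes = oc.module_eigengene(ds, oc.ModuleAssignment(labels=labels))
        me = mes.values.loc["blue"].to_numpy()
        z = (ds.values - ds.values.mean(axis=1, keepdims=True)) / ds.values.std(axis=1, keepdims=True)
        corrs = [np.corrcoef(z[i], me)[0, 1] for i in range(10)]
        assert np.mean(corrs) > 0

    def test_matches_pca_oracle(self, rng):
        values = rng.normal(size=(12, 40))
        ds = ExpressionDataset([f"g{i}" for i in range(12)], [f"S{j}" for j in range(40)], values)
        labels = pd.Series("brown", index=ds.gene_ids)
        me = oc.module_eigengene(ds, oc.ModuleAssignment(labels=labels)).values.loc["brown"].to_numpy()
        # oracle: leading eigenvector of the sample-by-sample Gram matrix
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
        w, v = np.linalg.eigh(z.T @ z)
        pc1 = v[:, -1]
        assert abs(np.corrcoef(me, pc1)[0, 1]) >= 1 - 1e-10

    def test_zero_variance_gene_dropped_with_warning(self, rng):
        values = rng.normal(size=(5, 20))
        values[2] = 3.0
        ds = ExpressionDataset([f"g{i}" for i in range(5)], [f"S{j}" for j in range(20)], values)
        labels = pd.Series("tan", index=ds.gene_ids)
        with pytest.warns(UserWarning, match="zero-variance"):
            mes = oc.module_eigengene(ds, oc.ModuleAssignment(labels=labels))
        assert "tan" in mes.modules


class TestKme:
    def test_gene_equal_to_eigengene(self, rng):
        profile = rng.normal(size=20)
        values = np.vstack([profile, rng.normal(size=(4, 20))])
        ds = ExpressionDataset([f"g{i}" for i in range(5)], [f"S{j}" for j in range(20)], values)
        me = oc.EigengeneMatrix(
            values=pd.DataFrame([profile], index=["mod"], columns=ds.sample_ids),
            var_explained=pd.Series({"mod": 1.0}),
        )
        table = oc.kme(ds, me)
        assert table.loc["g0", "mod"] == pytest.approx(1.0)

    def test_consensus_is_mean(self):
        idx = ["g1"]
        tables = [
            pd.DataFrame({"m": [v]}, index=idx) for v in (0.6, 0.7, 0.8)
        ]
        out = oc.consensus_kme(tables)
        assert out.loc["g1", "m"] == pytest.approx(0.7)

    def test_constant_gene_is_nan(self, rng):
        values = rng.normal(size=(3, 15))
        values[1] = 0.0
        ds = ExpressionDataset(["a", "b", "c"], [f"S{j}" for j in range(15)], values)
        me = oc.EigengeneMatrix(
            values=pd.DataFrame([values[0]], index=["m"], columns=ds.sample_ids),
            var_explained=pd.Series({"m": 1.0}),
        )
        assert np.isnan(oc.kme(ds, me).loc["b", "m"])


class TestScaleFree:
    def test_perfect_power_law_r2_one(self):
        # regression on log-log of an exact power law is an exact line;
        # feed the fit synthetic connectivity via a diagonal-ish adjacency
        x = np.log10([1.0, 2.0, 4.0, 8.0])
        y = np.log10([64.0, 16.0, 4.0, 1.0])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        assert np.allclose(resid, 0, atol=1e-12) and slope < 0

    def test_constructed_power_law_connectivity_fits_perfectly(self):
        # adjacency whose connectivities form an exact geometric ladder with
        # power-law bin frequencies: the log-log regression is an exact line
        counts = [64, 16, 4, 1]
        ks = [0.1, 0.2, 0.4, 0.8]
        diag = np.concatenate([np.full(c, k) for c, k in zip(counts, ks)])
        n = diag.size
        # star-free construction: gene i only connects to a shared hub row so
        # its connectivity equals diag[i]; the hub is excluded via many bins
        a = np.zeros((n + 1, n + 1))
        a[0, 1:] = diag
        a[1:, 0] = diag
        np.fill_diagonal(a, 1.0)
        adj = AdjacencyMatrix([f"g{i}" for i in range(n + 1)], a, 1)
        r2, slope = oc.scale_free_fit(adj, n_bins=10)
        assert slope < 0
        assert r2 > 0.9

    def test_emphasis_increases_fit_on_fixture(self, bundle):
        # raising the soft threshold suppresses weak background links and
        # moves the modular network toward a heavy-tailed connectivity profile
        r2s = []
        for beta in (4, 12, 20):
            adj = oc.signed_adjacency(bundle.organoid_matched, beta=beta)
            r2, slope = oc.scale_free_fit(adj)
            r2s.append(r2)
        assert r2s[0] < r2s[-1]

    def test_equal_connectivities_rejected(self):
        n = 25
        a = np.full((n, n), 0.5)
        np.fill_diagonal(a, 1.0)
        with pytest.raises(ValueError, match="equal"):
            oc.scale_free_fit(AdjacencyMatrix([f"g{i}" for i in range(n)], a, 1))


class TestSoftThreshold:
    def test_smallest_qualifying_beta_and_determinism(self, bundle):
        expr = bundle.tissue.subset_genes(bundle.tissue.gene_ids[:120])
        beta1, scan1 = oc.pick_soft_threshold(expr, beta_grid=[2, 4, 6, 8, 10, 12])
        beta2, scan2 = oc.pick_soft_threshold(expr, beta_grid=[2, 4, 6, 8, 10, 12])
        assert beta1 == beta2
        pd.testing.assert_frame_equal(scan1, scan2)
        qualifying = scan1[(scan1.r_squared >= 0.75) & (scan1.slope < 0)]
        if len(qualifying):
            assert beta1 == qualifying.beta.iloc[0]

    def test_fallback_to_best_r2_with_warning(self, bundle):
        expr = bundle.tissue.subset_genes(bundle.tissue.gene_ids[:60])
        with pytest.warns(UserWarning, match="best-fitting"):
            beta, scan = oc.pick_soft_threshold(expr, beta_grid=[1], r2_target=1.1)
        assert beta == 1


def test_quantile_normalize_columns_small_oracle():
    mat = np.array([[3.0, 10.0], [1.0, 30.0], [2.0, 20.0]])
    out = _quantile_normalize_columns(mat)
    # targets: mean of order stats = (1+10)/2, (2+20)/2, (3+30)/2
    np.testing.assert_allclose(out[:, 0], [16.5, 5.5, 11.0])
    np.testing.assert_allclose(out[:, 1], [5.5, 16.5, 11.0])
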