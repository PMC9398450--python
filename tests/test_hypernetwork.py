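import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trophonet.containers import ExpressionMatrix, ValidationError
from trophonet import hypernetwork as hn


def _expr(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells))


def _ci(r, mean_r, sd_r, genes=None, cols=None):
    r = np.asarray(r, dtype=float)
    genes = genes or [f"i{k}" for k in range(r.shape[0])]
    cols = cols or [f"t{k}" for k in range(r.shape[1])]
    return hn.CorrelationIncidence(
        pd.DataFrame(r, index=genes, columns=cols), mean_r, sd_r, "pearson"
    )


class TestCorrelationIncidence:
    def test_self_correlation_is_one_and_excluded_from_stats(self):
        m = _expr([[1, 2, 3], [3, 2, 1], [1, 3, 2]], genes=["a", "b", "c"])
        ci = hn.correlation_incidence(["a"], m, log_transform=False)
        assert ci.r_matrix.loc["a", "a"] == pytest.approx(1.0)
        # mean/sd computed over the two non-self entries only
        vals = [ci.r_matrix.loc["a", "b"], ci.r_matrix.loc["a", "c"]]
        assert ci.mean_r == pytest.approx(np.mean(vals))
        assert ci.sd_r == pytest.approx(np.std(vals))

    def test_perfect_anticorrelation(self):
        m = _expr([[1, 2, 3], [3, 2, 1]], genes=["x", "y"])
        ci = hn.correlation_incidence(["x"], m, log_transform=False)
        assert ci.r_matrix.loc["x", "y"] == pytest.approx(-1.0)

    def test_matches_per_pair_formula(self, rng):
        m = _expr(rng.gamma(2.0, 2.0, size=(50, 30)))
        interface = [f"g{i}" for i in range(5)]
        ci = hn.correlation_incidence(interface, m, log_transform=True)
        logx = np.log1p(m.values.to_numpy())
        for i, gi in enumerate(interface):
            for j, gj in enumerate(m.gene_ids):
                expected = np.corrcoef(logx[i], logx[j])[0, 1]
                assert ci.r_matrix.iloc[i][gj] == pytest.approx(expected, abs=1e-10)

    def test_too_few_cells_rejected(self):
        m = _expr([[1, 2], [2, 1]])
        with pytest.raises(ValidationError):
            hn.correlation_incidence(["g0"], m)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        m = _expr(rng.gamma(2.0, 2.0, size=(10, 20)))
        ci = hn.correlation_incidence(["g0"], m, method="spearman")
        x = stats.rankdata(np.log1p(m.values.to_numpy()[0]))
        y = stats.rankdata(np.log1p(m.values.to_numpy()[5]))
        assert ci.r_matrix.loc["g0", "g5"] == pytest.approx(np.corrcoef(x, y)[0, 1])


class TestBinarize:
    def test_rule_arithmetic(self):
        ci = _ci([[0.6, 0.3, -0.6]], mean_r=0.0, sd_r=0.5)
        m = hn.binarize(ci).to_numpy()
        np.testing.assert_array_equal(m, [[1, 0, 1]])

    def test_degenerate_sd_gives_all_zero(self, caplog):
        ci = _ci([[0.5, 0.5]], mean_r=0.5, sd_r=0.0)
        assert hn.binarize(ci).to_numpy().sum() == 0

    def test_matches_elementwise_loop(self, rng):
        r = rng.uniform(-1, 1, size=(6, 40))
        mean_r, sd_r = float(r.mean()), float(r.std())
        ci = _ci(r, mean_r, sd_r)
        m = hn.binarize(ci, 1.5).to_numpy()
        for i in range(6):
            for j in range(40):
                assert m[i, j] == (1 if abs(r[i, j] - mean_r) > 1.5 * sd_r else 0)

    def test_self_pairs_forced_zero(self):
        ci = _ci([[0.99, 0.99]], 0.0, 0.1, genes=["t0"], cols=["t0", "t1"])
        m = hn.binarize(ci)
        assert m.loc["t0", "t0"] == 0
        assert m.loc["t0", "t1"] == 1


class TestHypernetworkMatrix:
    def test_hand_multiplication(self):
        M = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["a", "b"])
        H = hn.build_hypernetwork(M).H.to_numpy()
        np.testing.assert_array_equal(H, [[2, 1], [1, 2]])

    def test_all_zero_incidence(self):
        M = pd.DataFrame(np.zeros((3, 5), dtype=int))
        assert hn.build_hypernetwork(M).H.to_numpy().sum() == 0

    def test_counts_shared_columns(self, rng):
        M = pd.DataFrame(rng.integers(0, 2, size=(10, 50)))
        H = hn.build_hypernetwork(M).H.to_numpy()
        arr = M.to_numpy()
        for i in range(10):
            for j in range(10):
                assert H[i, j] == int(np.sum(arr[i] & arr[j]))

    def test_symmetry_and_bound_properties(self, rng):
        for _ in range(20):
            M = pd.DataFrame(rng.integers(0, 2, size=(8, 30)))
            H = hn.build_hypernetwork(M).H.to_numpy()
            assert (H == H.T).all()
            d = np.diag(H)
            assert (H <= np.minimum.outer(d, d)).all()


class TestCentralCluster:
    def _hn_from_H(self, H, genes):
        Hdf = pd.DataFrame(H, index=genes, columns=genes)
        M = pd.DataFrame(np.zeros((len(genes), 1), dtype=int), index=genes)
        return hn.Hypernetwork(M, Hdf)

    def test_dense_block_wins_and_matches_partition_search(self):
        genes = ["g1", "g2", "g3", "g4", "g5"]
        H = np.array(
            [
                [20, 10, 10, 0, 0],
                [10, 20, 10, 0, 0],
                [10, 10, 20, 0, 0],
                [0, 0, 0, 5, 1],
                [0, 0, 0, 1, 5],
            ]
        )
        cluster = hn.extract_central_cluster(self._hn_from_H(H, genes))
        assert set(cluster) == {"g1", "g2", "g3"}
        # brute force: the chosen set's mean within-group off-diagonal value
        # must equal the best achievable over all 2-partitions
        def mean_within(idx):
            if len(idx) < 2:
                return -np.inf
            block = H[np.ix_(idx, idx)]
            return block[~np.eye(len(idx), dtype=bool)].mean()

        best = max(
            mean_within(list(subset))
            for r in range(1, 5)
            for subset in itertools.combinations(range(5), r)
        )
        chosen = mean_within([genes.index(g) for g in cluster])
        assert chosen == pytest.approx(best)

    def test_uniform_h_returns_whole_set(self):
        H = np.full((4, 4), 3)
        np.fill_diagonal(H, 7)
        cluster = hn.extract_central_cluster(
            self._hn_from_H(H, ["a", "b", "c", "d"])
        )
        assert set(cluster) == {"a", "b", "c", "d"}

    def test_all_zero_h_gives_empty_cluster(self):
        cluster = hn.extract_central_cluster(
            self._hn_from_H(np.zeros((3, 3), dtype=int), ["a", "b", "c"])
        )
        assert cluster == []

    def test_planted_module_recovered(self):
        from trophonet import simulate as sim

        te, truth = sim.generate_te_single_cells(
            n_genes=800, n_polar=86, n_mural=20, seed=3
        )
        ifc = sim.default_interface_genes()
        sub = te.subset_obs(te.obs_in_group("polar"))
        hyper, _, _, _ = hn.analyze_subset(ifc, sub)
        planted = set(truth.planted_modules["polar"]["interface"])
        got = set(hyper.central_cluster)
        jaccard = len(got & planted) / len(got | planted)
        assert jaccard >= 0.8


class TestMetrics:
    def _hn_from_H(self, H, genes):
        Hdf = pd.DataFrame(H, index=genes, columns=genes)
        M = pd.DataFrame(np.zeros((len(genes), 1), dtype=int), index=genes)
        return hn.Hypernetwork(M, Hdf)

    def test_connectivity_two_genes(self):
        h = self._hn_from_H(np.array([[2, 1], [1, 2]]), ["a", "b"])
        vals, mean = hn.connectivity(h, ["a", "b"])
        assert list(vals) == [1.0]
        assert mean == 1.0

    def test_connectivity_mean_of_three(self):
        H = np.array([[9, 2, 4], [2, 9, 6], [4, 6, 9]])
        h = self._hn_from_H(H, ["a", "b", "c"])
        vals, mean = hn.connectivity(h, ["a", "b", "c"])
        assert sorted(vals) == [2, 4, 6]
        assert mean == pytest.approx(4.0)

    def test_connectivity_matches_double_loop(self, rng):
        H = rng.integers(0, 20, size=(7, 7))
        H = H + H.T
        genes = [f"g{i}" for i in range(7)]
        h = self._hn_from_H(H, genes)
        vals, _ = hn.connectivity(h, genes)
        expected = [H[i, j] for i in range(7) for j in range(i + 1, 7)]
        assert sorted(vals) == sorted(expected)

    def test_entropy_equal_weights(self):
        # 4 genes -> 6 pairs; make 4 pairs weight 1, two pairs weight 0:
        H = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (1, 2), (2, 3), (0, 3)]:
            H[i, j] = H[j, i] = 1
        h = self._hn_from_H(H, list("abcd"))
        assert hn.cluster_entropy(h, list("abcd")) == pytest.approx(2.0)

    def test_entropy_degenerate_single_pair(self):
        H = np.zeros((3, 3), dtype=int)
        H[0, 1] = H[1, 0] = 9
        h = self._hn_from_H(H, list("abc"))
        assert hn.cluster_entropy(h, list("abc")) == pytest.approx(0.0)

    def test_entropy_matches_direct_formula_and_bound(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            H = rng.integers(0, 15, size=(n, n))
            H = H + H.T
            genes = [f"g{i}" for i in range(n)]
            h = self._hn_from_H(H, genes)
            vals, _ = hn.connectivity(h, genes)
            total = vals.sum()
            if total == 0:
                continue
            p = vals[vals > 0] / total
            expected = -(p * np.log2(p)).sum()
            ent = hn.cluster_entropy(h, genes)
            assert ent == pytest.approx(expected)
            assert 0 <= ent <= np.log2(len(vals)) + 1e-12

    def test_zero_weight_entropy_is_nan(self):
        h = self._hn_from_H(np.diag([3, 3, 3]), list("abc"))
        assert np.isnan(hn.cluster_entropy(h, list("abc")))

    def test_connected_gene_set_examples_and_oracle(self, rng):
        M = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["a", "b"], columns=["x", "y", "z"])
        h = hn.build_hypernetwork(M)
        assert hn.connected_gene_set(h, ["a"]) == ["x", "y"]
        assert hn.connected_gene_set(h, []) == []
        Mr = pd.DataFrame(
            rng.integers(0, 2, size=(6, 25)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"t{j}" for j in range(25)],
        )
        hr = hn.build_hypernetwork(Mr)
        cluster = ["g0", "g2", "g5"]
        got = set(hn.connected_gene_set(hr, cluster))
        expected = {
            f"t{j}" for j in range(25) if any(Mr.loc[g, f"t{j}"] for g in cluster)
        }
        assert got == expected
        all_sem = set(hn.connected_gene_set(hr, cluster, require_all=True))
        expected_all = {
            f"t{j}" for j in range(25) if all(Mr.loc[g, f"t{j}"] for g in cluster)
        }
        assert all_sem == expected_all


class TestPermutationNull:
    def test_zero_permutations_yield_empty(self, small_expression):
        null = hn.permutation_null(small_expression, None, 5, 0, seed=1)
        assert null.connectivity_samples.size == 0

    def test_same_seed_is_bitwise_identical(self, small_expression):
        a = hn.permutation_null(small_expression, None, 5, 10, seed=42)
        b = hn.permutation_null(small_expression, None, 5, 10, seed=42)
        np.testing.assert_array_equal(a.connectivity_samples, b.connectivity_samples)
        np.testing.assert_array_equal(a.entropy_samples, b.entropy_samples)

    def test_planted_module_exceeds_null(self):
        from trophonet import simulate as sim

        # the module must be a small fraction of the transcriptome, else
        # random draws catch module genes and inflate the null's tail
        ifc = sim.default_interface_genes(15)
        te, _ = sim.generate_te_single_cells(
            n_genes=3000, n_polar=86, n_mural=10, interface_genes=ifc,
            module_size=15, polar_module_n=8, mural_module_n=8, module_overlap=8,
            rho_polar=0.9, seed=9,
        )
        sub = te.subset_obs(te.obs_in_group("polar"))
        _, _, mean_c, _ = hn.analyze_subset(ifc, sub)
        null = hn.permutation_null(sub, None, 15, 200, seed=10)
        assert mean_c > np.nanpercentile(null.connectivity_samples, 95)


class TestRankSum:
    def test_exact_small_case(self):
        p, direction = hn.rank_sum_compare([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)
        assert direction == "b_greater"

    def test_identical_samples_give_p_one(self):
        p, direction = hn.rank_sum_compare([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)
        assert direction == "equal"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            hn.rank_sum_compare([], [1.0])

    def test_exact_agrees_with_scipy(self, rng):
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            p, _ = hn.rank_sum_compare(a, b)
            p_sp = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(p_sp, abs=1e-12)

    def test_normal_approx_close_to_scipy_asymptotic(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(0.5, 1.0, size=30)
        p, _ = hn.rank_sum_compare(a, b)
        p_sp = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert p == pytest.approx(p_sp, abs=0.01)
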