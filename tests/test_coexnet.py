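import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wpcna import coexnet
from wpcna.coexnet import (
    GREY,
    NetworkParams,
    cluster_tree,
    dynamic_cut,
    merge_modules,
    module_eigengenes,
    module_membership,
    scale_free_fit,
    signed_adjacency,
    soft_threshold_report,
    tom_similarity,
)


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop topological overlap oracle."""
    n = a.shape[0]
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            omega[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return omega


def random_adjacency(n, rng):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def block_matrix(sizes, n_samples=40, noise=0.3, seed=0, anti=False):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(sizes):
        template = rng.standard_normal(n_samples)
        for k in range(size):
            sign = -1.0 if anti and k >= size // 2 else 1.0
            rows.append(10 + sign * template + noise * rng.standard_normal(n_samples))
            labels.append(b)
    idx = [f"P{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), labels


class TestAdjacency:
    def test_extreme_correlations(self):
        x = np.arange(10.0)
        m = pd.DataFrame([x, 2 * x + 1, -x], index=["a", "b", "c"])
        adj = signed_adjacency(m, beta=2.0)
        assert adj.loc["a", "b"] == pytest.approx(1.0)
        assert adj.loc["a", "c"] == pytest.approx(0.0)

    def test_zero_correlation_floor(self):
        # two orthogonal profiles: cor 0 -> ((1+0)/2)^2 = 0.25
        m = pd.DataFrame([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]], index=["a", "b"])
        adj = signed_adjacency(m, beta=2.0)
        assert adj.loc["a", "b"] == pytest.approx(0.25)

    def test_insufficient_shared_samples_get_half_power(self):
        m = pd.DataFrame(
            [[1.0, 2.0, np.nan, np.nan], [np.nan, np.nan, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]],
            index=["a", "b", "c"],
        )
        adj = signed_adjacency(m, beta=2.0)
        assert adj.loc["a", "b"] == pytest.approx(0.25)  # cor treated as 0

    def test_fewer_than_three_samples_rejected(self):
        m = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            signed_adjacency(m, beta=2.0)


class TestTom:
    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 21))
            a = random_adjacency(n, rng)
            omega = tom_similarity(a)
            assert np.abs(omega - brute_force_tom(a)).max() < 1e-12

    def test_two_node_overlap_equals_adjacency(self):
        a = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert tom_similarity(a)[0, 1] == pytest.approx(0.6)

    def test_complete_graph_has_unit_overlap(self):
        a = np.ones((5, 5))
        assert np.allclose(tom_similarity(a), 1.0)

    def test_nonsymmetric_rejected(self):
        a = np.array([[1.0, 0.2], [0.8, 1.0]])
        with pytest.raises(ValueError):
            tom_similarity(a)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 25))
    def test_values_in_unit_interval_and_symmetric(self, seed, n):
        rng = np.random.default_rng(seed)
        a = random_adjacency(n, rng)
        omega = np.asarray(tom_similarity(a))
        assert omega.min() >= 0 and omega.max() <= 1 + 1e-12
        assert np.allclose(omega, omega.T)
        assert np.allclose(np.diag(omega), 1.0)


class TestSoftThreshold:
    def test_power_law_connectivity_fits_well(self):
        # frequencies proportional to k^-2 are log-log linear
        ks = np.repeat(np.arange(1, 11, dtype=float), (1000 / np.arange(1, 11.0) ** 2).astype(int))
        r2, slope = scale_free_fit(ks)
        assert r2 >= 0.95
        assert slope < 0

    def test_degenerate_connectivity_reports_zero(self):
        with pytest.warns(UserWarning):
            r2, slope = scale_free_fit(np.full(10, 3.0))
        assert r2 == 0.0

    def test_mean_connectivity_decreases_with_power(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(40, 30)))
        reports = soft_threshold_report(m, [1, 2, 4, 8])
        means = [r.mean_connectivity for r in reports]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_empty_powers_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold_report(pd.DataFrame(np.eye(3)), [])


class TestClusterTree:
    def test_identical_profiles_merge_first_at_zero(self):
        d = np.array(
            [
                [0.0, 0.0, 0.9],
                [0.0, 0.0, 0.9],
                [0.9, 0.9, 0.0],
            ]
        )
        Z = cluster_tree(d)
        assert Z[0, 2] == pytest.approx(0.0)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(15, 15))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        Z = cluster_tree(d)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_five_point_hand_trace(self):
        # average linkage by hand: (1,2)@0.1, (3,4)@0.2, ({3,4},5)@0.45,
        # final merge @ (0.9+1.0+0.9+1.0+1.1+1.2)/6
        d = np.zeros((5, 5))
        pairs = {
            (0, 1): 0.1, (2, 3): 0.2, (0, 2): 0.9, (1, 2): 0.9,
            (0, 3): 1.0, (1, 3): 1.0, (2, 4): 0.4, (3, 4): 0.5,
            (0, 4): 1.1, (1, 4): 1.2,
        }
        for (i, j), v in pairs.items():
            d[i, j] = d[j, i] = v
        Z = cluster_tree(d)
        assert Z[:, 2] == pytest.approx([0.1, 0.2, 0.45, 6.1 / 6])
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert set(Z[1, :2].astype(int)) == {2, 3}

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            cluster_tree(d)


def cut_pipeline(matrix, params=None):
    params = params or NetworkParams()
    adj = signed_adjacency(matrix, params.power)
    diss = 1.0 - tom_similarity(adj)
    np.fill_diagonal(diss.values, 0.0)
    Z = cluster_tree(diss)
    return dynamic_cut(Z, diss, params)


class TestDynamicCut:
    def test_two_separated_blocks_recovered_pure(self):
        m, labels = block_matrix([40, 35], seed=1)
        part = cut_pipeline(m)
        assert set(part) == {"turquoise", "blue"}
        # block purity: each recovered module maps to one planted block
        df = pd.DataFrame({"module": part.to_numpy(), "block": labels})
        purity = df.groupby("module")["block"].nunique()
        assert (purity == 1).all()

    def test_small_block_dissolved(self):
        m, labels = block_matrix([40, 10], seed=2)
        part = cut_pipeline(m)
        small = part.iloc[40:]
        assert (small == GREY).all() or small.nunique() == 1

    def test_pure_noise_yields_at_most_one_module(self):
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(900 + seed)
            m = pd.DataFrame(10 + rng.standard_normal((40, 40)))
            part = cut_pipeline(m)
            counts.append(len(set(part) - {GREY}))
        assert all(c <= 1 for c in counts)

    def test_min_cluster_size_above_n_gives_all_grey(self):
        m, _ = block_matrix([20], seed=3)
        with pytest.warns(UserWarning):
            part = cut_pipeline(m, NetworkParams(min_cluster_size=50))
        assert (part == GREY).all()

    def test_color_order_matches_descending_size(self):
        m, _ = block_matrix([35, 45, 55], seed=4)
        part = cut_pipeline(m)
        sizes = part[part != GREY].value_counts()
        expected = coexnet.MODULE_COLORS[: len(sizes)]
        assert list(sizes.index) == expected
        assert sizes.is_monotonic_decreasing


class TestEigengenes:
    def test_identical_profiles_give_unit_variance_explained(self):
        m, _ = block_matrix([10], noise=0.0, seed=5)
        part = pd.Series("blue", index=m.index)
        egs = module_eigengenes(m, part)
        assert egs.variance_explained["blue"] == pytest.approx(1.0)
        me = egs.eigengenes["blue"]
        profile = (m.iloc[0] - m.iloc[0].mean()) / m.iloc[0].std()
        assert abs(np.corrcoef(me, profile)[0, 1]) == pytest.approx(1.0)

    def test_unit_norm_and_sign_orientation(self):
        m, _ = block_matrix([12], noise=0.2, seed=6)
        part = pd.Series("blue", index=m.index)
        egs = module_eigengenes(m, part)
        me = egs.eigengenes["blue"].to_numpy()
        assert np.linalg.norm(me) == pytest.approx(1.0)
        avg = coexnet._standardize_rows(m).mean(axis=0)
        assert np.dot(me, avg) >= 0

    def test_flipping_all_proteins_flips_eigengene(self):
        m, _ = block_matrix([8], noise=0.1, seed=7)
        part = pd.Series("blue", index=m.index)
        me = module_eigengenes(m, part).eigengenes["blue"]
        me_flipped = module_eigengenes(20 - m, part).eigengenes["blue"]
        assert np.allclose(me, -me_flipped, atol=1e-9)

    def test_anticorrelated_halves_high_variance_low_mean_kme(self):
        m, _ = block_matrix([20], noise=0.05, seed=8, anti=True)
        part = pd.Series("blue", index=m.index)
        egs = module_eigengenes(m, part)
        assert egs.variance_explained["blue"] > 0.9
        kme, _ = module_membership(m, egs, part)
        assert abs(kme["blue"].mean()) < 0.3


class TestMerge:
    def test_highly_correlated_modules_merge(self):
        # one planted block artificially split in two -> eigengene cor ~1
        m, _ = block_matrix([60], noise=0.3, seed=9)
        part = pd.Series(["turquoise"] * 30 + ["blue"] * 30, index=m.index)
        egs = module_eigengenes(m, part)
        merged, egs2 = merge_modules(m, part, egs, 0.25)
        assert merged.nunique() == 1

    def test_distinct_modules_not_merged(self):
        m, _ = block_matrix([30, 30], noise=0.2, seed=10)
        part = pd.Series(["turquoise"] * 30 + ["blue"] * 30, index=m.index)
        egs = module_eigengenes(m, part)
        merged, egs2 = merge_modules(m, part, egs, 0.25)
        assert merged.nunique() == 2
        corr = egs2.eigengenes.corr().iloc[0, 1]
        assert 1 - abs(corr) >= 0.25

    def test_module_count_non_increasing(self):
        m, _ = block_matrix([30, 25, 20], noise=0.4, seed=11)
        part = pd.Series(
            ["turquoise"] * 30 + ["blue"] * 25 + ["brown"] * 20, index=m.index
        )
        egs = module_eigengenes(m, part)
        merged, _ = merge_modules(m, part, egs, 0.25)
        assert merged.nunique() <= part.nunique()


class TestModuleMembership:
    def test_protein_equal_to_eigengene_is_weighted(self):
        m, _ = block_matrix([10], noise=0.0, seed=12)
        part = pd.Series("turquoise", index=m.index)
        egs = module_eigengenes(m, part)
        kme, weighted = module_membership(m, egs, part)
        assert np.allclose(kme["turquoise"].abs(), 1.0)
        assert weighted == set(m.index)

    def test_threshold_is_inclusive(self):
        rng = np.random.default_rng(13)
        m, _ = block_matrix([15], noise=0.5, seed=13)
        part = pd.Series("turquoise", index=m.index)
        egs = module_eigengenes(m, part)
        kme, weighted = module_membership(m, egs, part, kme_threshold=0.8)
        own = kme["turquoise"]
        assert weighted == set(own[own >= 0.8].index)

    def test_grey_proteins_never_weighted(self):
        m, _ = block_matrix([12, 12], noise=0.2, seed=14)
        part = pd.Series(["turquoise"] * 12 + [GREY] * 12, index=m.index)
        egs = module_eigengenes(m, part)
        _, weighted = module_membership(m, egs, part)
        assert weighted <= set(m.index[:12])

    def test_too_few_paired_observations_excluded(self):
        m, _ = block_matrix([10], noise=0.1, seed=15)
        sparse = m.copy()
        sparse.iloc[0, 2:] = np.nan  # only 2 present samples
        part = pd.Series("turquoise", index=m.index)
        egs = module_eigengenes(m, part)
        kme, weighted = module_membership(sparse, egs, part)
        assert np.isnan(kme.iloc[0]["turquoise"])
        assert sparse.index[0] not in weighted
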