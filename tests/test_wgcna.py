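"""Network core: robust Z, adjacency, scale-free fit, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from gutliver.config import AnalysisConfig
from gutliver.wgcna import (
    build_network,
    detect_modules,
    merge_modules,
    module_eigengene,
    robust_z,
    scale_free_fit,
    _scale_free_r2,
    spearman_adjacency,
    tom,
)
from tests.conftest import truth_labels, two_compartment_study


def frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


def factor_blocks(rng, block_sizes, n_samples=28, noise=0.5):
    """Features sharing one latent factor per block (plus background rows)."""
    rows = []
    truth = []
    for b, size in enumerate(block_sizes, start=1):
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(f + rng.normal(0, noise, n_samples))
            truth.append(b)
    return frame(np.array(rows)), np.array(truth)


class TestRobustZ:
    def test_hand_computed_outlier(self):
        """x = (1,2,3,4,100): median 3, MAD 1, z(100) = 97 / 1.4826."""
        z, excluded = robust_z(frame([[1, 2, 3, 4, 100]]))
        assert excluded == []
        assert np.isclose(z.iloc[0, 4], 97 / 1.4826)
        assert np.isclose(z.iloc[0, 2], 0.0)

    def test_constant_feature_excluded(self):
        z, excluded = robust_z(frame([[5, 5, 5, 5], [1, 2, 3, 4]]))
        assert excluded == ["f0"]
        assert list(z.index) == ["f1"]

    def test_zero_mad_falls_back_to_sd(self):
        """Majority-constant rows use the SD scale instead of MAD."""
        z, excluded = robust_z(frame([[1, 1, 1, 1, 9]]))
        assert excluded == []
        assert np.isfinite(z.to_numpy()).all()

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 10))
        z1, _ = robust_z(frame(x))
        z2, _ = robust_z(frame(3.0 * x + 7.0))
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


class TestAdjacency:
    def test_monotone_pairs_hit_one(self):
        x = np.arange(10.0)
        a = spearman_adjacency(frame([x, np.exp(x), -x]), beta=4)
        assert np.allclose(a.to_numpy(), 1.0)  # unsigned: anti-monotone too

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(1)
        z = frame(rng.normal(size=(5, 12)))
        a = spearman_adjacency(z, beta=4)
        rho = stats.spearmanr(z.to_numpy(), axis=1).statistic
        expected = np.abs(rho) ** 4
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(a.to_numpy(), expected, atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_adjacency(frame(np.ones((2, 2))), beta=2)


class TestScaleFreeFit:
    def test_power_law_degrees_fit_well(self):
        """Preferential-attachment degree sequences give R^2 >= 0.8."""
        import networkx as nx

        g = nx.barabasi_albert_graph(2000, 2, seed=0)
        k = np.array([d for _, d in g.degree()], dtype=float)
        assert _scale_free_r2(k) >= 0.8

    def test_equal_connectivity_degenerate(self):
        assert np.isnan(_scale_free_r2(np.full(50, 3.0)))

    def test_selection_on_correlated_blocks(self):
        rng = np.random.default_rng(2)
        z, _ = factor_blocks(rng, [30, 30, 30], noise=1.0)
        fit = scale_free_fit(z, beta_grid=range(1, 13))
        assert fit.selected_beta in list(range(1, 13))
        assert len(fit.r_squared) == 12

    def test_config_beta_bypasses_selection(self):
        """The network stage uses the configured power directly."""
        design_cfg = AnalysisConfig(beta=4)
        rng = np.random.default_rng(3)
        z, _ = factor_blocks(rng, [35, 35], noise=0.4)
        from gutliver.tables import FeatureTable

        table = FeatureTable(
            z - z.min().min() + 1.0, compartment="SI", layer="metabolite"
        )
        net = build_network([table], design_cfg)
        assert net.beta == 4


class TestTom:
    def test_isolated_pair_zero_overlap(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.0
        t = tom(frame(a, prefix="n").set_axis([f"n{i}" for i in range(4)], axis=1))
        assert t.iloc[0, 1] == 0.0

    def test_perfect_triangle(self):
        """All off-diagonal A = 1: TOM = (1+1)/(2+1-1) = 1."""
        a = np.ones((3, 3))
        t = tom(frame(a, prefix="n").set_axis([f"n{i}" for i in range(3)], axis=1))
        assert np.allclose(t.to_numpy(), 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 1, size=(6, 6))
        a = (m + m.T) / 2
        np.fill_diagonal(a, 1.0)
        af = frame(a, prefix="n").set_axis([f"n{i}" for i in range(6)], axis=1)
        t = tom(af).to_numpy()
        n = 6
        expected = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                expected[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
        np.testing.assert_allclose(t, expected, atol=1e-12)

    def test_bounds_on_random_adjacency(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0, 1, size=(20, 20))
        a = (m + m.T) / 2
        np.fill_diagonal(a, 1.0)
        af = frame(a, prefix="n").set_axis([f"n{i}" for i in range(20)], axis=1)
        t = tom(af).to_numpy()
        assert (t >= 0).all() and (t <= 1).all()

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        af = frame(a, prefix="n").set_axis([f"n{i}" for i in range(3)], axis=1)
        with pytest.raises(ValueError, match="symmetric"):
            tom(af)


class TestDetectModules:
    def _diss(self, z):
        return 1.0 - tom(spearman_adjacency(z, 4))

    def test_three_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(6)
        z, truth = factor_blocks(rng, [40, 40, 40], noise=0.65)  # within-rho ~ 0.7
        _, labels = detect_modules(self._diss(z), min_module_size=30)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_independent_features_all_background(self):
        rng = np.random.default_rng(7)
        z = frame(rng.standard_normal((150, 28)))
        _, labels = detect_modules(self._diss(z), min_module_size=30)
        assert (labels == 0).all()

    def test_small_blocks_fall_below_size_rule(self):
        rng = np.random.default_rng(8)
        blocks, _ = factor_blocks(rng, [10, 10], noise=0.3)
        background = frame(rng.standard_normal((60, 28)), prefix="bg")
        z = pd.concat([blocks, background.set_axis(blocks.columns, axis=1)])
        _, labels = detect_modules(self._diss(z), min_module_size=30)
        assert (labels == 0).all()

    def test_feature_order_permutation_consistency(self):
        rng = np.random.default_rng(9)
        z, _ = factor_blocks(rng, [35, 35], noise=0.5)
        _, labels = detect_modules(self._diss(z), min_module_size=30)
        perm = rng.permutation(len(z))
        zp = z.iloc[perm]
        _, labels_p = detect_modules(self._diss(zp), min_module_size=30)
        aligned = labels_p.reindex(labels.index)
        assert adjusted_rand_score(labels.to_numpy(), aligned.to_numpy()) == 1.0


class TestEigengene:
    def test_identical_features_share_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        z = frame(np.tile(profile, (4, 1)))
        labels = pd.Series([1, 1, 1, 1], index=z.index)
        me = module_eigengene(z, labels)[1].to_numpy()
        standardized = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(me, standardized, atol=1e-9)

    def test_recovers_latent_factor(self):
        rng = np.random.default_rng(10)
        f = rng.standard_normal(28)
        rows = [f + rng.normal(0, 0.3, 28) for _ in range(40)]
        z = frame(np.array(rows))
        labels = pd.Series([1] * 40, index=z.index)
        me = module_eigengene(z, labels)[1]
        assert abs(np.corrcoef(me, f)[0, 1]) >= 0.95

    def test_sign_orientation_restored_after_flip(self):
        rng = np.random.default_rng(11)
        f = rng.standard_normal(20)
        z = frame(np.array([f + rng.normal(0, 0.1, 20) for _ in range(5)]))
        labels = pd.Series([1] * 5, index=z.index)
        me1 = module_eigengene(z, labels)[1]
        me2 = module_eigengene(-z, labels)[1]
        # orientation rule keeps mean member-correlation positive in both
        assert np.corrcoef(me1, f)[0, 1] > 0.9
        assert np.corrcoef(me2, -f)[0, 1] > 0.9

    def test_unit_variance(self):
        rng = np.random.default_rng(12)
        z, truth = factor_blocks(rng, [30], noise=0.4)
        me = module_eigengene(z, pd.Series(truth, index=z.index))
        assert np.isclose(me[1].std(ddof=1), 1.0)


class TestMerge:
    def test_same_factor_modules_merge(self):
        rng = np.random.default_rng(13)
        f = rng.standard_normal(28)
        rows = np.array([f + rng.normal(0, 0.2, 28) for _ in range(60)])
        z = frame(rows)
        labels = pd.Series([1] * 30 + [2] * 30, index=z.index)
        merged, mes = merge_modules(z, labels, cut_height=0.2)
        assert merged.max() == 1
        assert mes.shape[1] == 1

    def test_orthogonal_modules_stay(self):
        rng = np.random.default_rng(14)
        z, truth = factor_blocks(rng, [30, 30], noise=0.3)
        labels = pd.Series(truth, index=z.index)
        merged, _ = merge_modules(z, labels, cut_height=0.2)
        assert merged.max() == 2

    def test_cut_height_zero_never_merges(self):
        rng = np.random.default_rng(15)
        f = rng.standard_normal(28)
        rows = np.array([f + rng.normal(0, 0.2, 28) for _ in range(40)])
        z = frame(rows)
        labels = pd.Series([1] * 20 + [2] * 20, index=z.index)
        merged, _ = merge_modules(z, labels, cut_height=0.0)
        assert merged.max() == 2


class TestEndToEnd:
    def test_cross_compartment_recovery_single_seed(self):
        design, study = two_compartment_study(seed=0)
        net = build_network(study.tables, AnalysisConfig())
        truth = truth_labels(design, net.labels.index)
        assert adjusted_rand_score(truth, net.labels) >= 0.9
        assert net.origin.loc[net.labels.index[0], "compartment"] in ("SI", "liver")
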