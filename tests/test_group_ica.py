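"""Order estimation, PCA reduction, infomax/ICASSO, dual regression, Dice."""

import warnings

import numpy as np
import pytest

from netstates import group_ica as gi
from netstates import synthcohort as sc


def laplace_mixture(n_sources, n_samples, seed, noise_sd=0.0):
    rng = np.random.default_rng(seed)
    S = rng.laplace(size=(n_sources, n_samples))
    A = rng.standard_normal((n_sources, n_sources))
    X = A @ S
    if noise_sd:
        X = X + noise_sd * rng.standard_normal(X.shape)
    return X, S, A


def match_abs_corr(est, truth):
    """Best |corr| match of each true source among the estimates."""
    C = np.abs(np.corrcoef(np.vstack([truth, est]))[: truth.shape[0], truth.shape[0]:])
    return C.max(axis=1)


def amari_index(P):
    """Amari permutation error of a product unmixing*mixing matrix."""
    P = np.abs(P)
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return (rows.sum() + cols.sum()) / (2 * n * (n - 1))


class TestMdlOrder:
    def test_white_noise_gives_near_zero_order(self):
        low = 0
        for seed in range(20):
            X = np.random.default_rng(seed).standard_normal((2000, 50))
            low += gi.estimate_order_mdl(X) <= 2
        assert low >= 18

    def test_planted_rank_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            tc = rng.standard_normal((60, 5))
            # 100 background voxels so no signal direction is absorbed by
            # the mean removal (network maps never tile a real volume)
            maps = np.zeros((5, 600))
            for m in range(5):
                maps[m, m * 100 : (m + 1) * 100] = 1.0
            X = sc.generate_voxel_data(maps, tc, noise_sd=0.01, seed=seed)
            hits += gi.estimate_order_mdl(X) == 5
        assert hits == 20

    def test_rank_one_input(self):
        col = np.arange(100.0)[:, None]
        X = np.tile(col, (1, 6))
        with pytest.warns(UserWarning, match="rank-deficient"):
            assert gi.estimate_order_mdl(X) == 1


class TestPcaReduce:
    def test_full_rank_reconstruction_exact(self, rng):
        X = rng.standard_normal((40, 8))
        red = gi.pca_reduce(X, 8)
        np.testing.assert_allclose(red.back_project(), X - X.mean(axis=0), atol=1e-10)

    def test_rank3_matrix_with_k3_is_lossless(self, rng):
        X = rng.standard_normal((50, 3)) @ rng.standard_normal((3, 10))
        red = gi.pca_reduce(X, 3)
        np.testing.assert_allclose(red.back_project(), X - X.mean(axis=0), atol=1e-8)

    def test_reconstruction_error_equals_discarded_eigenvalues(self, rng):
        # eigen-decomposition oracle
        X = rng.standard_normal((100, 50))
        red = gi.pca_reduce(X, 10)
        Xc = X - X.mean(axis=0)
        sse = np.sum((red.back_project() - Xc) ** 2)
        expected = red.eigenvalues[10:].sum() * (X.shape[0] - 1)
        assert sse == pytest.approx(expected, rel=1e-8)

    def test_out_of_range_k_rejected(self, rng):
        with pytest.raises(ValueError):
            gi.pca_reduce(rng.standard_normal((20, 5)), 6)


class TestInfomax:
    def test_laplace_sources_recovered(self):
        X, S, _ = laplace_mixture(3, 20_000, seed=0)
        res = gi.infomax_ica(X, seed=1)
        assert np.all(match_abs_corr(res.source_maps, S) > 0.95)

    def test_identity_mixture_gives_signed_permutation(self):
        rng = np.random.default_rng(2)
        S = rng.laplace(size=(4, 20_000))
        res = gi.infomax_ica(S, seed=3)
        # unmixing estimated from recovered sources: S_hat = W_eff S
        W_eff, *_ = np.linalg.lstsq(S.T, res.source_maps.T, rcond=None)
        assert amari_index(W_eff.T) < 0.1

    def test_gaussian_sources_do_not_crash(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((3, 5000))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gi.infomax_ica(X, seed=0)
        assert res.source_maps.shape == (3, 5000)

    def test_sources_decorrelated(self):
        X, _, _ = laplace_mixture(4, 10_000, seed=5)
        res = gi.infomax_ica(X, seed=6)
        C = np.corrcoef(res.source_maps)
        off = np.abs(C[~np.eye(4, dtype=bool)])
        assert off.max() < 0.05


class TestIcasso:
    def test_well_separated_sources_are_stable(self):
        X, _, _ = laplace_mixture(3, 8000, seed=7)
        stable = gi.icasso(X, k=3, n_runs=10, seed=0)
        assert np.all(stable.stability_index > 0.9)
        assert np.all(np.diff(stable.stability_index) <= 1e-12)

    def test_pure_noise_less_stable_than_planted(self):
        X, _, _ = laplace_mixture(4, 4000, seed=8)
        noise = np.random.default_rng(9).standard_normal(X.shape)
        iq_signal = gi.icasso(X, 4, n_runs=6, seed=1).stability_index.mean()
        iq_noise = gi.icasso(noise, 4, n_runs=6, seed=1).stability_index.mean()
        assert iq_signal > iq_noise

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            gi.icasso(np.zeros((3, 100)), 3, n_runs=1)


class TestBackReconstruct:
    def test_noiseless_mixture_inverted_exactly(self, rng):
        maps, _ = sc.default_spatial_maps(n_maps=5)
        tc = rng.standard_normal((80, 5))
        data = sc.generate_voxel_data(maps, tc, 0.0, 0)
        sub = gi.back_reconstruct(maps, data, "s1")
        for m in range(5):
            assert abs(np.corrcoef(sub.timecourses[:, m], tc[:, m])[0, 1]) > 0.999

    def test_noisy_mixture_recovered(self, rng):
        maps, _ = sc.default_spatial_maps(n_maps=5)
        tc = rng.standard_normal((80, 5))
        data = sc.generate_voxel_data(maps, tc, 0.1, 1)
        sub = gi.back_reconstruct(maps, data, "s1")
        for m in range(5):
            assert abs(np.corrcoef(sub.timecourses[:, m], tc[:, m])[0, 1]) > 0.95

    def test_zero_map_rejected(self, rng):
        maps, _ = sc.default_spatial_maps(n_maps=3)
        maps[1] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            gi.back_reconstruct(maps, rng.standard_normal((maps.shape[1], 10)))


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.array([0, 1, 1, 0, 1])
        assert gi.dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        assert gi.dice_coefficient(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_direct_formula(self):
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        b = np.array([0, 0, 1, 1, 1, 1, 0, 0])
        assert gi.dice_coefficient(a, b) == pytest.approx(0.5)

    def test_symmetry_and_identity_property(self, rng):
        for _ in range(20):
            a = rng.integers(0, 2, 30)
            b = rng.integers(0, 2, 30)
            assert gi.dice_coefficient(a, b) == gi.dice_coefficient(b, a)
            if a.any():
                assert (gi.dice_coefficient(a, a) == 1.0)

    def test_empty_masks_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert gi.dice_coefficient(np.zeros(5), np.zeros(5)) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gi.dice_coefficient(np.zeros(5), np.zeros(6))


class TestSelection:
    def test_template_match_selected_with_dice_one(self):
        maps, _ = sc.default_spatial_maps(n_maps=3)
        tc = np.sin(2 * np.pi * 0.01 * np.arange(200) / 1.25)[:, None] * np.ones((1, 3))
        templates = {f"net{m}": maps[m] for m in range(3)}
        sel = gi.select_components(maps, tc, templates, dice_min=0.5, lf_power_min=0.5)
        assert sel.indices == [0, 1, 2]
        assert sel.dice == [1.0, 1.0, 1.0]
        assert sel.labels == ["net0", "net1", "net2"]

    def test_disjoint_component_rejected(self):
        maps, _ = sc.default_spatial_maps(n_maps=2)
        stray = np.zeros((1, maps.shape[1]))
        stray[0, -5:] = 1.0
        tc = np.sin(2 * np.pi * 0.01 * np.arange(200) / 1.25)[:, None]
        with pytest.warns(UserWarning, match="no component"):
            sel = gi.select_components(stray, tc, {"a": maps[0]}, dice_min=0.2,
                                       lf_power_min=0.5)
        assert sel.indices == []

    def test_high_frequency_component_rejected(self):
        maps, _ = sc.default_spatial_maps(n_maps=1)
        t = np.arange(400) / 1.25
        tc = np.sin(2 * np.pi * 0.4 * t)[:, None]  # power well above 0.10 Hz
        with pytest.warns(UserWarning, match="no component"):
            sel = gi.select_components(maps, tc, {"a": maps[0]}, dice_min=0.5,
                                       lf_power_min=0.5)
        assert sel.indices == []


class TestEndToEnd:
    def test_planted_networks_recovered_through_full_chain(self):
        """pca -> icasso -> dual regression -> selection on toy voxel data
        with 11 planted networks recovers all 11 with matching labels and
        high subject time-course fidelity."""
        rng = np.random.default_rng(10)
        maps, grid = sc.default_spatial_maps(n_maps=11)
        n_sub, frames = 4, 120
        truths, datas = [], []
        for s in range(n_sub):
            model = sc.default_state_model(11)
            labels = sc.generate_state_sequence(model, frames, seed=200 + s)
            tc = sc.generate_timecourses(labels, model, seed=300 + s)
            truths.append(tc)
            datas.append(sc.generate_voxel_data(maps, tc, noise_sd=0.1, seed=400 + s))
        group = np.hstack(datas)  # voxels x (n_sub*frames), temporal concat
        red = gi.pca_reduce(group, 11)
        stable = gi.icasso(red.reduced, 11, n_runs=8, seed=0)
        # binarize centrotype maps at |z| > 2 for template matching
        Z = stable.centrotype_maps
        masks = (np.abs(Z) > 2.0).astype(int)
        templates = {f"net{m:02d}": maps[m] for m in range(11)}
        corrs = []
        labels_ok = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(n_sub):
                sub = gi.back_reconstruct(Z, datas[s], f"s{s}")
                sel = gi.select_components(masks, sub.timecourses, templates,
                                           dice_min=0.2, lf_power_min=0.0)
                assert len(sel.indices) == 11
                seen = set()
                for comp, lab in zip(sel.indices, sel.labels):
                    m = int(lab[3:])
                    seen.add(m)
                    corrs.append(abs(np.corrcoef(sub.timecourses[:, comp],
                                                 truths[s][:, m])[0, 1]))
                labels_ok += seen == set(range(11))
        assert labels_ok == n_sub
        assert np.median(corrs) > 0.9
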