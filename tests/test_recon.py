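import numpy as np
import pytest
from scipy import ndimage

from temac.io_core import VoxelImage
from temac.projsim import (
    ScannerGeometry,
    Sinogram,
    attenuation_factors,
    forward_project,
    simulate_acquisition,
)
from temac.recon import (
    ReconConfig,
    _bit_reversed,
    estimate_randoms,
    estimate_scatter,
    mlem_reconstruct,
    poisson_loglik,
)
from temac.synthdata import centered_affine, make_head_phantom


@pytest.fixture(scope="module")
def disc_setup():
    """Noiseless disc on a small grid with mu = 0."""
    shape, spacing = (64, 64, 8), (2.0, 2.0, 3.0)
    grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
    g = ScannerGeometry(n_angles=48, n_bins=64, bin_spacing=2.0,
                        n_slices=8, slice_spacing=3.0, fov_radius=64.0)
    w = grid.world_coords()
    data = np.zeros(shape)
    data[(w[0] ** 2 + w[1] ** 2) <= 35.0**2] = 2.0
    truth = grid.like(data)
    sino = forward_project(truth, g)
    return grid, g, truth, sino


@pytest.fixture(scope="module")
def noisy_scan():
    ph = make_head_phantom(seed=13, n_vois=8)
    g = ScannerGeometry()
    counts, gt = simulate_acquisition(ph, g, total_counts=2_000_000,
                                      scatter_fraction=0.2, randoms_fraction=0.1,
                                      seed=3)
    return ph, g, counts, gt


class TestMLEM:
    def test_zero_counts_give_zero_image(self, disc_setup):
        grid, g, _, _ = disc_setup
        zeros = Sinogram(np.zeros((g.n_slices, g.n_angles, g.n_bins)), g, kind="counts")
        rec = mlem_reconstruct(zeros, None, None, ReconConfig(grid=grid, n_iterations=3))
        assert np.all(rec.data == 0)

    def test_nrmse_decreases_over_early_iterations(self, disc_setup):
        grid, g, truth, sino = disc_setup
        norm = np.ptp(truth.data)
        errs = []
        for n in (1, 5, 10, 20):
            cfg = ReconConfig(grid=grid, n_iterations=n, n_subsets=1)
            rec = mlem_reconstruct(sino, None, None, cfg)
            errs.append(np.sqrt(np.mean((rec.data - truth.data) ** 2)) / norm)
        assert errs[0] > errs[1] > errs[2] > errs[3]

    def test_loglik_nondecreasing_one_subset(self, noisy_scan):
        _, g, counts, gt = noisy_scan
        shape, spacing = (64, 64, 40), (3.0, 3.0, 3.0)
        grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
        additive = Sinogram(gt["scatter"].data + gt["randoms"].data, g, kind="additive")
        a = gt["acf"].data
        r = additive.data
        lls = []
        for n in range(1, 31):
            cfg = ReconConfig(grid=grid, n_iterations=n, n_subsets=1)
            rec = mlem_reconstruct(counts, gt["acf"], additive, cfg)
            lam = a * forward_project(rec, g).data + r
            lls.append(poisson_loglik(counts, lam))
        lls = np.asarray(lls)
        assert np.all(np.diff(lls) >= -1e-9 * np.abs(lls[:-1]))

    def test_reconstruction_nonnegative_every_iteration(self, noisy_scan):
        _, g, counts, gt = noisy_scan
        shape, spacing = (64, 64, 40), (3.0, 3.0, 3.0)
        grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
        for n in (1, 3, 6):
            cfg = ReconConfig(grid=grid, n_iterations=n, n_subsets=6)
            rec = mlem_reconstruct(counts, gt["acf"], None, cfg)
            assert np.all(rec.data >= 0)

    def test_subsets_must_divide_angles(self, disc_setup):
        grid, g, _, sino = disc_setup
        cfg = ReconConfig(grid=grid, n_subsets=7)
        with pytest.raises(ValueError, match="divide"):
            mlem_reconstruct(sino, None, None, cfg)

    def test_bit_reversed_is_a_permutation(self):
        for n in (1, 2, 6, 8, 12):
            order = _bit_reversed(n)
            assert sorted(order) == list(range(n))

    def test_noiseless_per_region_recovery_within_3pct(self):
        ph = make_head_phantom(shape=(96, 96, 96), spacing=(2.0, 2.0, 2.0),
                               seed=21, n_vois=12)
        g = ScannerGeometry(n_angles=96, n_bins=96, bin_spacing=2.0,
                            n_slices=96, slice_spacing=2.0, fov_radius=96.0)
        _, gt = simulate_acquisition(ph, g, total_counts=5_000_000,
                                     scatter_fraction=0.2, randoms_fraction=0.1,
                                     seed=1)
        noiseless = Sinogram(gt["expectation"].data, g, kind="expectation")
        additive = Sinogram(gt["scatter"].data + gt["randoms"].data, g,
                            kind="additive")
        cfg = ReconConfig(grid=ph.activity, n_iterations=60, n_subsets=6)
        rec = mlem_reconstruct(noiseless, gt["acf"], additive, cfg)
        # undo the count-budget scaling applied to the simulated trues
        scale = gt["trues"].data.sum() / (
            forward_project(ph.activity, g).data * gt["acf"].data
        ).sum()
        labels, idx = ph.vois.data, np.arange(1, ph.vois.data.max() + 1)
        rec_means = ndimage.mean(rec.data, labels, idx) / scale
        true_means = ndimage.mean(ph.activity.data, labels, idx)
        assert np.all(np.abs(rec_means / true_means - 1) < 0.03)


class TestPoissonLoglik:
    def test_zero_expectation_with_counts_is_minus_inf(self):
        g = ScannerGeometry(n_angles=4, n_bins=4, n_slices=1)
        counts = Sinogram(np.ones((1, 4, 4)), g, kind="counts")
        assert poisson_loglik(counts, np.zeros((1, 4, 4))) == -np.inf

    def test_matches_hand_computation(self):
        g = ScannerGeometry(n_angles=4, n_bins=4, n_slices=1)
        y = np.zeros((1, 4, 4))
        y[0, 0, 0] = 3
        counts = Sinogram(y, g, kind="counts")
        lam = np.full((1, 4, 4), 2.0)
        expected = 3 * np.log(2.0) - 2.0 * 16
        assert poisson_loglik(counts, lam) == pytest.approx(expected, rel=1e-12)


class TestEstimateRandoms:
    def test_zero_rate_gives_zeros(self):
        g = ScannerGeometry(n_angles=8, n_bins=8, n_slices=2)
        assert np.all(estimate_randoms(0.0, g).data == 0)

    def test_sum_is_bins_times_rate(self):
        g = ScannerGeometry(n_angles=8, n_bins=8, n_slices=2)
        s = estimate_randoms(0.25, g)
        assert s.data.sum() == pytest.approx(2 * 8 * 8 * 0.25, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            estimate_randoms(-1.0, ScannerGeometry())


class TestEstimateScatter:
    def test_oracle_default_scale_restores_truth(self, noisy_scan):
        ph, g, counts, gt = noisy_scan
        shape, spacing = (64, 64, 40), (3.0, 3.0, 3.0)
        grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
        cfg = ReconConfig(grid=grid, scatter_mode="oracle", scatter_scale=1.1)
        est = estimate_scatter(counts, cfg=cfg, true_scatter=gt["scatter"])
        np.testing.assert_allclose(est.data, gt["scatter"].data, rtol=1e-12)

    def test_oracle_scale_is_linear(self, noisy_scan):
        _, g, counts, gt = noisy_scan
        shape, spacing = (64, 64, 40), (3.0, 3.0, 3.0)
        grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
        cfg = ReconConfig(grid=grid, scatter_mode="oracle", scatter_scale=2.2)
        est = estimate_scatter(counts, cfg=cfg, true_scatter=gt["scatter"])
        np.testing.assert_allclose(est.data, 2.0 * gt["scatter"].data, rtol=1e-12)

    def test_none_mode_gives_zeros(self, noisy_scan):
        _, g, counts, _ = noisy_scan
        est = estimate_scatter(counts, cfg=None)
        assert np.all(est.data == 0)

    def test_tail_fit_total_within_10pct_on_pure_scatter(self):
        # with no trues there is no object support, so every bin is tail
        ph = make_head_phantom(seed=14, n_vois=8)
        g = ScannerGeometry()
        _, gt = simulate_acquisition(ph, g, total_counts=5_000_000,
                                     scatter_fraction=0.89, randoms_fraction=0.0,
                                     seed=4)
        rng = np.random.default_rng(15)
        pure = Sinogram(rng.poisson(gt["scatter"].data).astype(np.int64), g,
                        kind="counts")
        empty = Sinogram(np.zeros_like(gt["scatter"].data), g, kind="additive")
        shape, spacing = (64, 64, 40), (3.0, 3.0, 3.0)
        grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
        cfg = ReconConfig(grid=grid, scatter_mode="tail_fit", scatter_scale=1.0)
        est = estimate_scatter(pure, object_mask=empty, cfg=cfg)
        true_total = gt["scatter"].data.sum()
        assert abs(est.data.sum() - true_total) / true_total < 0.10

    def test_tail_fit_under_object_mask_is_order_of_magnitude_correct(self):
        # with the object masked out the fit extrapolates inward from the
        # flanks, which biases the centre; totals stay within a small factor
        ph = make_head_phantom(seed=14, n_vois=8)
        g = ScannerGeometry()
        counts, gt = simulate_acquisition(ph, g, total_counts=5_000_000,
                                          scatter_fraction=0.89, randoms_fraction=0.0,
                                          seed=4)
        mask = Sinogram((gt["trues"].data > 1e-3 * gt["trues"].data.max()).astype(float),
                        g, kind="additive")
        shape, spacing = (64, 64, 40), (3.0, 3.0, 3.0)
        grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
        cfg = ReconConfig(grid=grid, scatter_mode="tail_fit", scatter_scale=1.0)
        est = estimate_scatter(counts, object_mask=mask, cfg=cfg)
        true_total = gt["scatter"].data.sum()
        assert np.all(est.data >= 0)
        assert true_total / 3 < est.data.sum() < true_total * 3

    def test_tail_fit_requires_mask(self, noisy_scan):
        _, g, counts, _ = noisy_scan
        shape, spacing = (64, 64, 40), (3.0, 3.0, 3.0)
        grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
        cfg = ReconConfig(grid=grid, scatter_mode="tail_fit")
        with pytest.raises(ValueError, match="mask"):
            estimate_scatter(counts, cfg=cfg)

    def test_tail_fit_full_mask_rejected(self, noisy_scan):
        _, g, counts, _ = noisy_scan
        shape, spacing = (64, 64, 40), (3.0, 3.0, 3.0)
        grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
        cfg = ReconConfig(grid=grid, scatter_mode="tail_fit")
        full = Sinogram(np.ones_like(counts.data, dtype=float), g, kind="additive")
        with pytest.raises(ValueError, match="tail"):
            estimate_scatter(counts, object_mask=full, cfg=cfg)

    def test_oracle_requires_truth(self, noisy_scan):
        _, g, counts, _ = noisy_scan
        shape, spacing = (64, 64, 40), (3.0, 3.0, 3.0)
        grid = VoxelImage(np.zeros(shape), centered_affine(shape, spacing))
        cfg = ReconConfig(grid=grid, scatter_mode="oracle")
        with pytest.raises(ValueError, match="oracle"):
            estimate_scatter(counts, cfg=cfg)


class TestOracleEstimateEquivalence:
    def test_pipeline_randoms_estimate_equals_truth_when_rates_match(self, noisy_scan):
        _, g, _, gt = noisy_scan
        rate = gt["randoms"].data.flat[0]
        est = estimate_randoms(rate, g)
        np.testing.assert_allclose(est.data, gt["randoms"].data, rtol=1e-12)
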