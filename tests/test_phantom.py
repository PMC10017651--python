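"""Phantom generator: analytic ground truth, invariants, cohort coupling."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.ndimage import binary_erosion, gaussian_filter

from lungshrink.core import DisplacementField, ImageVolume
from lungshrink.jacobian import jacobian_determinant
from lungshrink.phantom import (
    AffineWarp,
    AxialContractionWarp,
    FoldingWarpError,
    IdentityWarp,
    PhantomSpec,
    RadialWarp,
    analytic_logjac,
    coupling_for_spearman,
    generate_pft_cohort,
    generate_phantom,
    generate_vessel_tree,
)
from lungshrink.registration import warp_image


class TestAnalyticLogjac:
    def test_identity_is_zero(self):
        grid = ImageVolume(np.zeros((20, 20, 20)))
        m = analytic_logjac(IdentityWarp(), grid)
        assert np.all(m.data == 0.0)

    def test_affine_is_constant_log_det(self):
        A = np.diag([0.9, 1.1, 0.95])
        grid = ImageVolume(np.zeros((20, 20, 20)))
        m = analytic_logjac(AffineWarp(A, center=(10, 10, 10)), grid)
        assert np.allclose(m.data, np.log(np.linalg.det(A)), atol=1e-14)

    @pytest.mark.parametrize(
        "warp",
        [
            RadialWarp(center=(20, 20, 20), amplitude=0.06, sigma=12.0),
            AxialContractionWarp(
                center=(20, 20, 20), amplitude=0.07, gradient=2.0, z_top=52, z_base=0
            ),
        ],
        ids=["radial", "axial"],
    )
    def test_matches_central_difference_oracle(self, warp):
        """Closed-form determinant agrees with dense numerical differentiation."""
        grid = ImageVolume(np.zeros((40, 40, 40)))
        X, Y, Z = grid.grid_coords()
        u = np.stack(warp.displacement(X, Y, Z), axis=-1)
        numeric = jacobian_determinant(DisplacementField(u))
        analytic = warp.jacobian_det(X, Y, Z)
        interior = (slice(2, -2),) * 3
        assert np.abs(numeric[interior] - analytic[interior]).max() < 1e-3

    def test_non_invertible_rejected(self):
        grid = ImageVolume(np.zeros((20, 20, 20)))
        with pytest.raises((FoldingWarpError, ValueError)):
            analytic_logjac(AffineWarp(np.zeros((3, 3))), grid)


class TestGeneratePhantom:
    def test_stable_noiseless_pair_is_identical(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32), noise_sd=0.0, scenario="stable", seed=0
        )
        base, follow, mask, truth = generate_phantom(spec)
        assert np.array_equal(base.data, follow.data)
        assert np.all(truth.displacement.data == 0.0)
        assert np.all(truth.logjac_true.data == 0.0)

    def test_uniform_contraction_has_constant_logjac(self):
        s = 0.9
        spec = PhantomSpec(
            grid_shape=(48, 48, 48),
            shrink_amplitude=1 - s,
            basal_gradient=0.0,
            noise_sd=0.0,
            scenario="deteriorate",
        )
        _, _, mask, truth = generate_phantom(spec)
        assert np.allclose(truth.logjac_true.data[mask.data], 3 * np.log(s), atol=1e-12)
        assert truth.lung_volume_change_ml < 0

    def test_basal_gradient_orders_regional_means(self):
        spec = PhantomSpec(
            grid_shape=(48, 48, 48),
            shrink_amplitude=0.08,
            basal_gradient=1.5,
            noise_sd=0.0,
            scenario="deteriorate",
        )
        _, _, mask, truth = generate_phantom(spec)
        m = mask.data
        z = np.where(m.any(axis=(0, 1)))[0]
        lo, hi = z.min(), z.max() + 1
        third = (hi - lo) // 3
        basal = m.copy()
        basal[:, :, lo + third:] = False
        apical = m.copy()
        apical[:, :, : hi - third] = False
        assert (
            truth.logjac_true.data[basal].mean() < truth.logjac_true.data[apical].mean()
        )

    def test_improve_scenario_has_positive_mean(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32), shrink_amplitude=0.05, noise_sd=0.0,
            scenario="improve",
        )
        _, _, mask, truth = generate_phantom(spec)
        assert truth.logjac_true.data[mask.data].mean() > 0
        assert truth.lung_volume_change_ml > 0

    def test_folding_spec_rejected(self):
        # a steep basal gradient makes the axial term fold at the base
        spec = PhantomSpec(
            grid_shape=(32, 32, 32), shrink_amplitude=0.45, basal_gradient=6.0,
            noise_sd=0.0, scenario="deteriorate",
        )
        with pytest.raises(FoldingWarpError):
            generate_phantom(spec)

    @pytest.mark.parametrize("bad", [
        dict(grid_shape=(8, 32, 32)),
        dict(shrink_amplitude=0.6),
        dict(noise_sd=-1),
        dict(scenario="worse"),
        dict(spacing_mm=(0, 1, 1)),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomSpec(**bad)

    def test_roundtrip_warp_recovers_baseline(self, basal_phantom):
        """Warping the follow-up back through the true field reproduces the
        baseline within noise plus a local-gradient interpolation term."""
        spec, (base, follow, mask, truth) = basal_phantom
        back = warp_image(follow, truth.displacement)
        er = binary_erosion(mask.data, iterations=1)
        mae = np.abs(back.data - base.data)[er].mean()
        grad = np.linalg.norm(np.stack(np.gradient(base.data, *spec.spacing_mm)), axis=0)
        bound = 2 * spec.noise_sd + 0.5 * max(spec.spacing_mm) * grad[er].mean()
        assert mae < bound

    @pytest.mark.parametrize("seed", range(5))
    def test_volume_conservation(self, seed):
        """Integrating exp(log-Jacobian) over the lung equals the warped
        lung's rasterized volume within 1%."""
        rng = np.random.default_rng(seed)
        spec = PhantomSpec(
            grid_shape=(48, 48, 48),
            shrink_amplitude=float(rng.uniform(0.02, 0.1)),
            basal_gradient=float(rng.uniform(0, 2)),
            noise_sd=0.0,
            seed=seed,
            scenario="deteriorate" if seed % 2 else "improve",
        )
        _, _, mask, truth = generate_phantom(spec)
        voxvol = np.prod(spec.spacing_mm)
        integral = np.exp(truth.logjac_true.data[mask.data]).sum() * voxvol
        warped = truth.followup_lung_mask.sum() * voxvol
        assert integral == pytest.approx(warped, rel=0.01)

    def test_sign_law_links_mean_logjac_and_volume(self):
        for seed in range(8):
            scenario = "deteriorate" if seed % 2 else "improve"
            spec = PhantomSpec(
                grid_shape=(32, 32, 32), shrink_amplitude=0.05, noise_sd=0.0,
                seed=seed, scenario=scenario, vessel_depth=0,
            )
            _, _, mask, truth = generate_phantom(spec)
            mean = truth.logjac_true.data[mask.data].mean()
            assert (mean < 0) == (truth.lung_volume_change_ml < 0)


class TestVesselTree:
    def test_single_tube(self):
        mask, n, vol = generate_vessel_tree(seed=0, depth=1, segment_length_mm=30)
        assert n == 1
        assert mask.sum() > 0

    @pytest.mark.parametrize("depth", [1, 2, 3, 4])
    def test_symmetric_tree_segment_count(self, depth):
        _, n, _ = generate_vessel_tree(seed=1, depth=depth)
        assert n == 2**depth - 1

    def test_tube_volume_matches_cylinder(self):
        r, L = 2.5, 60.0
        mask, _, vol = generate_vessel_tree(
            seed=0, depth=1, segment_length_mm=L, radius_mm=r
        )
        assert vol == pytest.approx(np.pi * r**2 * L / 1000.0, rel=1e-9)
        measured = mask.sum() / 1000.0  # 1 mm voxels
        assert measured == pytest.approx(vol, rel=0.10)

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError):
            generate_vessel_tree(depth=0)


class TestPFTCohort:
    def test_perfect_coupling_gives_monotone_link(self):
        df = generate_pft_cohort(50, seed=0, coupling=1.0)
        d_fvc = df.fvc_pct_follow - df.fvc_pct_base
        r = sps.spearmanr(df.true_mean_logjac, d_fvc).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_coupling_gives_small_mean_abs_r(self):
        rs = []
        for seed in range(200):
            df = generate_pft_cohort(50, seed=seed, coupling=0.0)
            d_fvc = df.fvc_pct_follow - df.fvc_pct_base
            rs.append(abs(sps.spearmanr(df.true_mean_logjac, d_fvc).statistic))
        assert np.mean(rs) < 0.15

    def test_target_spearman_recovered(self):
        """Cohorts built for population rho = 0.5 at n = 69 recover it."""
        c = coupling_for_spearman(0.5)
        rs = []
        for seed in range(200):
            df = generate_pft_cohort(69, seed=seed, coupling=c)
            d_fvc = df.fvc_pct_follow - df.fvc_pct_base
            rs.append(sps.spearmanr(df.true_mean_logjac, d_fvc).statistic)
        lo, hi = np.quantile(rs, [0.025, 0.975])
        assert lo < 0.5 < hi
        assert np.mean(rs) == pytest.approx(0.5, abs=0.05)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_pft_cohort(4, seed=0, coupling=0.5)
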