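"""Level-set solver: initialization, region means, steps and full runs."""

import numpy as np
import pytest

from oecontour import (
    Image2D,
    LevelSet,
    ParameterMaps,
    PhantomSpec,
    SolverConfig,
    evolve_step,
    init_level_set,
    make_phantom,
    region_means,
    segment,
    tanimoto,
)
from oecontour.chanvese import MU_FINE, _delta, _heaviside


def unit_maps(shape) -> ParameterMaps:
    ones = np.ones(shape)
    return ParameterMaps(w_reg=ones.copy(), w_df=ones.copy(), tile_side=8)


class TestInitLevelSet:
    def test_center_value_equals_radius(self):
        img = Image2D(np.zeros((33, 33)))
        ls = init_level_set(img, (16, 16), 10.0)
        assert np.isclose(ls.phi[16, 16], 10.0)

    def test_zero_on_the_circle(self):
        img = Image2D(np.zeros((33, 33)))
        ls = init_level_set(img, (16, 16), 10.0)
        assert abs(ls.phi[16, 26]) < 1e-12
        assert abs(ls.phi[6, 16]) < 1e-12

    def test_unit_gradient_away_from_center(self):
        img = Image2D(np.zeros((64, 64)))
        ls = init_level_set(img, (32, 32), 20.0)
        gr, gc = np.gradient(ls.phi)
        norm = np.hypot(gr, gc)
        far = np.hypot(*np.mgrid[0:64, 0:64] - 32.0) > 8
        interior = np.zeros((64, 64), bool)
        interior[1:-1, 1:-1] = True
        assert np.allclose(norm[far & interior], 1.0, atol=1e-2)

    def test_degenerate_radius_rejected(self):
        img = Image2D(np.zeros((32, 32)))
        with pytest.raises(ValueError):
            init_level_set(img, (16, 16), 0.0)


class TestRegionMeans:
    def test_constant_image(self):
        img = Image2D(np.full((32, 32), 77.0))
        ls = init_level_set(img, (16, 16), 8.0)
        c1, c2 = region_means(img, ls, 1.0)
        assert np.isclose(c1, 77.0) and np.isclose(c2, 77.0)

    def test_sharp_heaviside_recovers_region_intensities(self):
        px = np.full((32, 32), 40.0)
        px[8:24, 8:24] = 200.0
        img = Image2D(px)
        phi = np.full((32, 32), -1.0)
        phi[8:24, 8:24] = 1.0
        c1, c2 = region_means(img, LevelSet(phi), heaviside_eps=1e-6)
        assert np.isclose(c1, 200.0, atol=1e-3)
        assert np.isclose(c2, 40.0, atol=1e-3)

    def test_matches_direct_summation_oracle(self):
        # a 4x4 two-scale toy pattern replicated up to the minimum size
        toy = np.arange(16, dtype=float).reshape(4, 4) * 10 + 10
        img = Image2D(np.pad(toy, ((0, 12), (0, 12)), mode="edge"))
        rng = np.random.default_rng(0)
        phi = rng.normal(scale=2.0, size=(16, 16))
        eps = 1.3
        c1, c2 = region_means(img, LevelSet(phi), eps)
        # independent transcription
        h = 0.5 * (1 + (2 / np.pi) * np.arctan(phi / eps))
        exp_c1 = (img.pixels * h).sum() / h.sum()
        exp_c2 = (img.pixels * (1 - h)).sum() / (1 - h).sum()
        assert np.isclose(c1, exp_c1, atol=1e-12)
        assert np.isclose(c2, exp_c2, atol=1e-12)


def semi_implicit_oracle(phi, img, mu, lam, c1, c2, dt, eps, eta2=1e-8):
    """Loop transcription of one semi-implicit update, written independently
    of the vectorized implementation."""
    n, m = phi.shape

    def P(i, j):
        return phi[min(max(i, 0), n - 1), min(max(j, 0), m - 1)]

    def coef_a(i, j):  # horizontal coefficient at (i, j)
        dxp = P(i, j + 1) - P(i, j)
        dyc = 0.5 * (P(i + 1, j) - P(i - 1, j))
        return mu[i, j] / np.sqrt(eta2 + dxp**2 + dyc**2)

    def coef_b(i, j):  # vertical coefficient at (i, j)
        dyp = P(i + 1, j) - P(i, j)
        dxc = 0.5 * (P(i, j + 1) - P(i, j - 1))
        return mu[i, j] / np.sqrt(eta2 + dyp**2 + dxc**2)

    out = np.empty_like(phi)
    for i in range(n):
        for j in range(m):
            a = coef_a(i, j)
            a_left = coef_a(i, max(j - 1, 0))
            b = coef_b(i, j)
            b_up = coef_b(max(i - 1, 0), j)
            force = lam[i, j] * ((img[i, j] - c1) ** 2 - (img[i, j] - c2) ** 2)
            d = dt * eps / (np.pi * (eps**2 + phi[i, j] ** 2))
            num = phi[i, j] + d * (
                a * P(i, j + 1)
                + a_left * P(i, j - 1)
                + b * P(i + 1, j)
                + b_up * P(i - 1, j)
                - force
            )
            den = 1.0 + d * (a + a_left + b + b_up)
            out[i, j] = num / den
    return out


class TestEvolveStep:
    def test_single_step_matches_loop_oracle(self):
        rng = np.random.default_rng(12)
        img = Image2D(rng.uniform(0, 255, (16, 16)))
        phi = rng.normal(scale=3.0, size=(16, 16))
        ls = LevelSet(phi)
        cfg = SolverConfig(mode="custom", mu_fixed=50.0, lambda_fixed=1.0)
        stepped = evolve_step(ls, img, None, cfg)
        c1, c2 = region_means(img, ls, cfg.heaviside_eps)
        expected = semi_implicit_oracle(
            phi,
            img.pixels,
            np.full(img.shape, 50.0),
            np.full(img.shape, 1.0),
            c1,
            c2,
            cfg.dt,
            cfg.heaviside_eps,
        )
        assert np.allclose(stepped.phi, expected, atol=1e-12)
        assert stepped.iteration == 1

    def test_zero_data_weight_decouples_from_image(self):
        rng = np.random.default_rng(13)
        phi = rng.normal(size=(16, 16))
        cfg = SolverConfig(mode="custom", mu_fixed=100.0, lambda_fixed=0.0)
        img_a = Image2D(rng.uniform(0, 255, (16, 16)))
        img_b = Image2D(rng.uniform(0, 255, (16, 16)))
        pa = evolve_step(LevelSet(phi), img_a, None, cfg).phi
        pb = evolve_step(LevelSet(phi), img_b, None, cfg).phi
        assert np.array_equal(pa, pb)

    def test_constant_image_reduces_to_shrinking_curvature_flow(self):
        img = Image2D(np.full((64, 64), 99.0))
        ls = init_level_set(img, (32, 32), 20.0)
        cfg = SolverConfig(mode="fine_tuned")
        areas = [int((ls.phi > 0).sum())]
        for _ in range(30):
            ls = evolve_step(ls, img, None, cfg)
            areas.append(int((ls.phi > 0).sum()))
        assert areas[-1] < areas[0]


class TestSegment:
    def test_max_iter_zero_returns_initial_mask(self):
        img = Image2D(np.full((32, 32), 10.0))
        init = init_level_set(img, (16, 16), 8.0)
        res = segment(img, SolverConfig(mode="fine_tuned", max_iter=0), init=init)
        assert res.mask == init.mask
        assert res.iterations_run == 0

    def test_unsupervised_with_unit_maps_is_step_identical_to_fine_tuned(self):
        img, _ = make_phantom(
            PhantomSpec(size=(64, 64), clutter_density=0.5, noise_sigma=5.0, seed=1)
        )
        init = init_level_set(img, (32, 32), 16.0)
        cfg_u = SolverConfig(mode="unsupervised", max_iter=40)
        cfg_f = SolverConfig(mode="fine_tuned", max_iter=40)
        res_u = segment(img, cfg_u, maps=unit_maps(img.shape), init=init)
        res_f = segment(img, cfg_f, init=init)
        assert np.array_equal(res_u.phi_final, res_f.phi_final)
        assert np.array_equal(res_u.energy_trace, res_f.energy_trace)
        assert res_u.mask == res_f.mask

    def test_determinism(self):
        img, _ = make_phantom(PhantomSpec(size=(64, 64), seed=2))
        init = init_level_set(img, (32, 32), 16.0)
        cfg = SolverConfig(mode="fine_tuned", max_iter=30)
        r1 = segment(img, cfg, init=init)
        r2 = segment(img, cfg, init=init)
        assert r1.mask == r2.mask
        assert np.array_equal(r1.phi_final, r2.phi_final)

    def test_degenerate_initialization_raises(self):
        img = Image2D(np.full((32, 32), 50.0))
        all_outside = LevelSet(np.full((32, 32), -5.0))
        with pytest.raises(ValueError, match="degenerate"):
            segment(img, SolverConfig(mode="fine_tuned", max_iter=10), init=all_outside)

    def test_unsupervised_requires_maps(self):
        img = Image2D(np.full((32, 32), 50.0))
        init = init_level_set(img, (16, 16), 8.0)
        with pytest.raises(ValueError, match="maps"):
            segment(img, SolverConfig(mode="unsupervised", max_iter=5), init=init)

    @pytest.mark.parametrize("mode", ["fine_tuned", "unsupervised"])
    def test_high_contrast_disk_is_recovered(self, mode):
        from oecontour import build_parameter_maps, default_grid_side

        img, truth = make_phantom(
            PhantomSpec(
                size=(128, 128),
                target_shape="disk",
                clutter_density=0.2,
                noise_sigma=2.0,
                seed=3,
            )
        )
        maps = None
        if mode == "unsupervised":
            maps = build_parameter_maps(img, default_grid_side(*img.shape))
        init = init_level_set(img, (64, 64), 32.0)
        res = segment(img, SolverConfig(mode=mode, max_iter=150), maps=maps, init=init)
        assert tanimoto(res.mask, truth) >= 0.95

    def test_energy_trace_is_monotone_after_warmup(self):
        img, _ = make_phantom(
            PhantomSpec(size=(128, 128), clutter_density=0.8, noise_sigma=5.0, seed=4)
        )
        from oecontour import build_parameter_maps, default_grid_side

        maps = build_parameter_maps(img, default_grid_side(*img.shape))
        init = init_level_set(img, (64, 64), 32.0)
        for mode, m in [("fine_tuned", None), ("unsupervised", maps)]:
            res = segment(img, SolverConfig(mode=mode, max_iter=120), maps=m, init=init)
            e = res.energy_trace
            running_min = np.minimum.accumulate(e)
            assert np.all(e[5:] <= running_min[4:-1] * (1 + 1e-6))

    def test_fine_tuned_mode_pins_classic_weights(self):
        cfg = SolverConfig(mode="fine_tuned", mu_fixed=1.0, lambda_fixed=9.0)
        assert cfg.mu_fixed == MU_FINE
        assert cfg.lambda_fixed == 1.0


class TestHeavisideHelpers:
    def test_heaviside_limits_and_midpoint(self):
        phi = np.array([-1e6, 0.0, 1e6])
        h = _heaviside(phi, 1.0)
        assert np.allclose(h, [0.0, 0.5, 1.0], atol=1e-5)

    def test_delta_integrates_to_one(self):
        x = np.linspace(-5000, 5000, 400001)
        d = _delta(x, 1.0)
        assert np.isclose(np.trapezoid(d, x), 1.0, atol=1e-3)
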