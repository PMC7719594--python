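"""Edge indicator, regional fits, and the combined evolution step."""

import numpy as np
import pytest

from conftest import loop_gaussian_smooth
from ventseg import (
    EvolutionParams,
    RegionalFits,
    combined_energy,
    data_terms,
    distance_regularizer_flow,
    edge_indicator,
    evolution_step,
    initialize_lsf,
    regional_fits,
)
from ventseg.core import gradient
from ventseg.segment import BoundingBox, rescale_intensity


def line_sdf(shape, col):
    """Signed distance to a vertical line (negative left of it)."""
    cols = np.tile(np.arange(shape[1], dtype=float), (shape[0], 1))
    return cols - col


def disk_sdf(shape, radius):
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    return np.hypot(rr - (h - 1) / 2, cc - (w - 1) / 2) - radius


class TestEvolutionParams:
    def test_tuned_defaults(self):
        p = EvolutionParams()
        assert (p.alpha, p.lam, p.eps, p.dt, p.sigma, p.ksize) == (2.0, 1.0, 2.0, 1.5, 2.5, 15)
        assert p.mu == pytest.approx(0.2 / 1.5)
        assert p.dt * p.mu < 0.25

    @pytest.mark.parametrize(
        "kw",
        [dict(ksize=14), dict(ksize=1), dict(dt=-1), dict(eps=0), dict(lam=0),
         dict(mu=0.2, dt=1.5), dict(edge_kernel="sobel"), dict(c0=0)],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            EvolutionParams(**kw)

    def test_replace_rederives_auto_mu_with_dt(self):
        p = EvolutionParams()
        q = p.replace(dt=1.0)
        assert q.mu == pytest.approx(0.2)
        r = EvolutionParams(mu=0.1).replace(dt=1.0)
        assert r.mu == 0.1  # explicit mu is preserved


class TestEdgeIndicator:
    def test_constant_image_gives_one(self):
        g = edge_indicator(np.full((20, 20), 80.0), 2.5, 15)
        np.testing.assert_allclose(g, 1.0, atol=1e-12)

    def test_stronger_step_gives_smaller_minimum(self):
        def min_g(h):
            I = np.zeros((32, 32))
            I[:, 16:] = h
            return edge_indicator(I, 2.5, 15).min()

        assert min_g(100.0) < min_g(30.0) < 1.0

    def test_matches_convolution_oracle(self, rng):
        I = rng.uniform(0, 255, size=(16, 16))
        smoothed = loop_gaussian_smooth(I, 2.5, 7)
        gx, gy = gradient(smoothed)
        expected = 1.0 / (1.0 + gx**2 + gy**2)
        np.testing.assert_allclose(edge_indicator(I, 2.5, 7), expected, atol=1e-10)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            edge_indicator(np.zeros((8, 8)), 2.5, 8)

    @pytest.mark.parametrize("kernel", ["average", "median"])
    def test_alternative_smoothers_flat_regions(self, kernel):
        g = edge_indicator(np.full((16, 16), 40.0), 2.5, 5, kernel=kernel)
        np.testing.assert_allclose(g, 1.0, atol=1e-12)

    def test_values_in_unit_interval(self, rng):
        g = edge_indicator(rng.uniform(0, 255, (24, 24)), 2.5, 15)
        assert np.all(g > 0) and np.all(g <= 1)


class TestRegionalFits:
    def test_constant_image_fits_equal_constant(self):
        I = np.full((16, 16), 55.0)
        phi = line_sdf(I.shape, 8)
        for kernel in ("gaussian", "global"):
            fits = regional_fits(I, phi, 2.0, 2.5, 7, kernel)
            np.testing.assert_allclose(fits.f1, 55.0, atol=1e-9)
            np.testing.assert_allclose(fits.f2, 55.0, atol=1e-9)

    def test_two_region_fits_recover_region_values(self):
        # disk of 40 inside radius 20, 120 outside; true signed distance
        phi = disk_sdf((64, 64), 20)
        I = np.where(phi < 0, 40.0, 120.0)
        fits = regional_fits(I, phi, 50.0, 2.5, 15, "gaussian")
        far_in = phi < -15
        far_out = phi > 15
        assert np.all(np.abs(fits.f1[far_in] - 40.0) < 1.0)
        assert np.all(np.abs(fits.f2[far_out] - 120.0) < 1.0)

    def test_global_kernel_gives_membership_weighted_means(self, rng):
        from ventseg.core import smoothed_heaviside

        I = rng.uniform(0, 255, (20, 20))
        phi = line_sdf(I.shape, 9)
        fits = regional_fits(I, phi, 2.0, 2.5, 7, "global")
        m1 = smoothed_heaviside(-phi, 2.0)
        np.testing.assert_allclose(fits.f1, (m1 * I).sum() / m1.sum(), atol=1e-9)
        np.testing.assert_allclose(
            fits.f2, ((1 - m1) * I).sum() / (1 - m1).sum(), atol=1e-9
        )

    def test_gaussian_fits_match_double_loop_oracle(self, rng):
        from ventseg.core import smoothed_heaviside

        I = rng.uniform(0, 255, (12, 12))
        phi = rng.normal(size=(12, 12))
        fits = regional_fits(I, phi, 2.0, 2.5, 7, "gaussian")
        m1 = smoothed_heaviside(-phi, 2.0)
        for m, f in ((m1, fits.f1), (1 - m1, fits.f2)):
            num = loop_gaussian_smooth(m * I, 2.5, 7)
            den = loop_gaussian_smooth(m, 2.5, 7)
            np.testing.assert_allclose(f, num / den, atol=1e-9)

    def test_roi_restricts_statistics(self):
        I = np.full((16, 16), 10.0)
        I[:, 12:] = 200.0  # intensities that must be excluded
        roi = np.ones((16, 16), dtype=np.uint8)
        roi[:, 12:] = 0
        phi = line_sdf(I.shape, 6)
        fits = regional_fits(I, phi, 2.0, 2.5, 7, "global", roi=roi)
        assert fits.f2[0, 0] == pytest.approx(10.0, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            regional_fits(np.zeros((8, 8)), np.zeros((8, 9)), 2.0, 2.5, 7)


class TestDataTerms:
    def test_residuals_are_squared_differences(self):
        I = np.full((8, 8), 100.0)
        fits = RegionalFits(np.full((8, 8), 40.0), np.full((8, 8), 120.0))
        e1, e2 = data_terms(I, fits)
        assert np.all(e1 == 3600.0) and np.all(e2 == 400.0)

    def test_zero_when_fit_is_exact(self, rng):
        I = rng.uniform(0, 255, (8, 8))
        e1, e2 = data_terms(I, RegionalFits(I.copy(), rng.uniform(0, 255, (8, 8))))
        assert np.all(e1 == 0.0) and np.all(e2 >= 0.0)


class TestFlows:
    def test_signed_distance_is_regularizer_fixed_point(self):
        phi = line_sdf((32, 32), 15.5)
        flow = distance_regularizer_flow(phi)
        assert np.abs(flow).max() < 1e-8

    def test_regularizer_drives_gradient_toward_wells(self):
        # double the slope of a signed distance: |grad phi| = 2, and one
        # explicit step must reduce the regularizer energy mu*sum p(|grad|)
        from ventseg.core import double_well_potential, neumann_extend

        def reg_energy(phi):
            gx, gy = gradient(neumann_extend(phi))
            return double_well_potential(np.hypot(gx, gy)).sum()

        phi = 2.0 * line_sdf((32, 32), 15.5)
        stepped = phi + 1.5 * 0.133 * distance_regularizer_flow(phi)
        assert reg_energy(stepped) < reg_energy(phi)

    def test_step_is_identity_at_joint_fixed_point(self):
        # constant image (f1 = f2, data flow cancels for any lam/alpha via
        # e1 = e2 = 0) and straight-line signed distance (regularizer 0)
        I = np.full((32, 32), 77.0)
        phi = line_sdf(I.shape, 15.5)
        p = EvolutionParams(curvature_weight=0.0)
        g = edge_indicator(I, p.sigma, p.ksize)
        out = evolution_step(phi, I, g, p)
        assert np.abs(out - phi).max() < 1e-6

    def test_data_flow_cancels_when_weights_and_fits_agree(self):
        # lam = alpha and f1 = f2 (constant image): the data terms cancel
        # exactly, so the step reduces to the pure regularizer flow
        I = np.full((32, 32), 150.0)
        phi = disk_sdf(I.shape, 10)
        p = EvolutionParams(lam=2.0, alpha=2.0, curvature_weight=0.0)
        g = edge_indicator(I, p.sigma, p.ksize)
        out = evolution_step(phi, I, g, p)
        expected = phi + p.dt * p.mu * distance_regularizer_flow(phi)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_outward_displaced_contour_is_pushed_back(self):
        # contour 4 px outside the true dark disk: bright pixels currently
        # "inside" resemble f2, so lam*e1 - alpha*e2 > 0 there and the step
        # raises phi (expels them)
        phi = disk_sdf((64, 64), 22)
        I = np.where(disk_sdf((64, 64), 18) < 0, 40.0, 120.0)
        p = EvolutionParams(curvature_weight=0.0)
        g = edge_indicator(I, p.sigma, p.ksize)
        fits = regional_fits(I, phi, p.eps, p.sigma, p.ksize, "global")
        e1, e2 = data_terms(I, fits)
        ring = (disk_sdf((64, 64), 18) > 0.5) & (phi < -0.5)  # bright, inside
        assert np.all(p.lam * e1[ring] - p.alpha * e2[ring] > 0)
        out = evolution_step(phi, I, g, p, "global")
        assert np.mean(out[ring] - phi[ring]) > 0

    def test_energy_non_increasing_over_ten_steps(self, disk):
        ph, box = disk
        I = rescale_intensity(ph.image)
        p = EvolutionParams()
        g = edge_indicator(I, p.sigma, p.ksize)
        phi = initialize_lsf(box, I.shape, p.c0)
        energies = [combined_energy(phi, I, g, p)]
        for _ in range(10):
            phi = evolution_step(phi, I, g, p)
            energies.append(combined_energy(phi, I, g, p))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9 * np.abs(energies[0]))

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_phi_stays_finite_and_blowup_is_reported(self):
        I = np.full((16, 16), 1e200)
        I[:, 8:] = 0.0
        phi = line_sdf(I.shape, 8)
        p = EvolutionParams(force_cap=np.inf)
        g = np.ones_like(I)
        with pytest.raises(FloatingPointError, match="iteration 7"):
            evolution_step(phi, I, g, p, "global", iteration=7)
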