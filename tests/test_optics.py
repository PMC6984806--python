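"""Unit and property tests for the excitation/fluorescence model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mpdepth import optics


def radial_power(field, z, params, quad=optics.DEFAULT_QUADRATURE):
    """2 pi Int field(z, rho) rho d rho on the model's radial grid."""
    rho, wq = optics._radial_rule(z, params, quad)
    vals = field(z, rho)
    return 2.0 * math.pi * float((vals * rho) @ wq)


class TestPropagationDistance:
    def test_on_axis_equals_depth(self):
        assert optics.propagation_distance(100.0, 0.0, 450.0, 0.6) == 100.0

    def test_oblique_ray_formula(self):
        s = optics.propagation_distance(300.0, 40.0, 450.0, 0.7)
        assert s == pytest.approx(300.0 * math.sqrt(1 + (40.0 / 150.0) ** 2))

    def test_slope_cap_at_focal_plane(self, params):
        theta = params.half_angle
        s = optics.propagation_distance(450.0, 10.0, 450.0, theta)
        assert s == pytest.approx(450.0 * math.sqrt(1 + math.tan(theta) ** 2))

    @pytest.mark.parametrize("z,rho", [(-1.0, 0.0), (10.0, -2.0)])
    def test_negative_arguments_rejected(self, z, rho):
        with pytest.raises(ValueError):
            optics.propagation_distance(z, rho, 450.0, 0.6)

    @given(
        z=st.floats(0.0, 1000.0),
        rho=st.floats(0.0, 500.0),
        z0=st.floats(50.0, 900.0),
    )
    def test_bounded_between_depth_and_capped_path(self, z, rho, z0):
        theta = 0.6453821359990306
        s = optics.propagation_distance(z, rho, z0, theta)
        assert s >= z - 1e-9
        assert s <= z * math.sqrt(1 + math.tan(theta) ** 2) + 1e-9


class TestBallisticIntensity:
    def test_surface_peak_value(self, params):
        w0sq = params.beam_width_sq(0.0)
        expected = 2.0 * params.surface_power / (math.pi * w0sq)
        assert optics.ballistic_intensity(0.0, 0.0, params) == pytest.approx(expected)

    def test_on_axis_attenuation_factor(self, params):
        # I_b(z, 0) * pi w^2 / (2 P0) = exp(-z / l) since s(z, 0) = z
        z = 150.0
        val = optics.ballistic_intensity(z, 0.0, params)
        ratio = val * math.pi * params.beam_width_sq(z) / (2.0 * params.surface_power)
        assert ratio == pytest.approx(math.exp(-z / params.scattering_length_um))

    def test_power_conserved_without_attenuation(self, scatter_free):
        for z in (0.0, 200.0, 430.0):
            p = radial_power(
                lambda zz, r: optics.ballistic_intensity(zz, r, scatter_free),
                z,
                scatter_free,
            )
            assert p == pytest.approx(scatter_free.surface_power, rel=1e-6)

    def test_radial_quadrature_matches_fine_grid(self, params):
        # independent oracle: trapezoid on a 10x-denser uniform grid
        z = 200.0
        p = radial_power(
            lambda zz, r: optics.ballistic_intensity(zz, r, params), z, params
        )
        rho = np.linspace(0.0, 8.0 * math.sqrt(params.beam_width_sq(z)), 20001)
        fine = np.trapezoid(
            optics.ballistic_intensity(z, rho, params) * 2 * math.pi * rho, rho
        )
        assert p == pytest.approx(fine, rel=5e-3)


class TestScatteredSpread:
    @pytest.mark.parametrize("z", [50.0, 200.0, 800.0])
    def test_normalized_over_plane(self, params, z):
        scale = params.attenuation * z**3 * params.mean_square_spread
        rho = np.linspace(0.0, 40.0 * math.sqrt(scale / (3 * 1.33)), 200001)
        total = np.trapezoid(
            optics.scattered_spread(z, rho, params) * 2 * math.pi * rho, rho
        )
        assert total == pytest.approx(1.0, rel=1e-6)

    def test_on_axis_value_is_prefactor(self, params):
        z = 100.0
        expected = (3 * params.refractive_index) / (
            math.pi
            * params.attenuation
            * z**3
            * params.mean_square_spread
        )
        assert optics.scattered_spread(z, 0.0, params) == pytest.approx(expected)

    def test_spreading_parameter_from_anisotropy(self, params):
        assert params.mean_square_spread == pytest.approx(2 * (1 - 0.9))

    def test_undefined_at_surface(self, params):
        with pytest.raises(ValueError):
            optics.scattered_spread(0.0, 10.0, params)


class TestScatteredIntensity:
    def test_vanishes_without_scattering(self, scatter_free):
        vals = optics.scattered_intensity(
            400.0, np.array([0.0, 50.0, 200.0]), scatter_free
        )
        assert np.all(np.abs(vals) < 1e-12)

    def test_monte_carlo_oracle_on_axis(self, params):
        # independent Monte-Carlo evaluation of the surface integral at
        # z=400, rho=0 (defaults, z0=450), compared within 3 standard errors
        z, z0 = 400.0, params.focal_depth_um
        a = params.attenuation
        w0sq = params.beam_width_sq(0.0)
        rng = np.random.default_rng(42)
        n = 10**6
        eta_max = math.sqrt(w0sq) * math.sqrt(math.log(1e8) / 2.0)
        eta = rng.uniform(0.0, eta_max, n)
        s0 = z * np.sqrt(1.0 + eta**2 / z0**2)
        beta = 3 * params.refractive_index / (a * s0**3 * params.mean_square_spread)
        c = (z0 - z) / z0
        # rho = 0: the phi integral contributes a plain 2 pi factor
        samples = (
            (2 * params.surface_power * beta / (math.pi**2 * w0sq))
            * np.exp(-2 * eta**2 / w0sq)
            * np.exp(-beta * (c * eta) ** 2)
            * (1.0 - np.exp(-a * s0))
            * eta
        ) * (2 * math.pi * eta_max)
        mc, se = samples.mean(), samples.std(ddof=1) / math.sqrt(n)
        quad_val = optics.scattered_intensity(z, 0.0, params)
        assert abs(quad_val - mc) < 3 * se

    def test_total_scattered_power_increases_with_depth(self, params):
        p200 = radial_power(
            lambda z, r: optics.scattered_intensity(z, r, params), 200.0, params
        )
        p400 = radial_power(
            lambda z, r: optics.scattered_intensity(z, r, params), 400.0, params
        )
        assert 0 < p200 < p400

    def test_energy_conservation(self, params):
        # ballistic + scattered power never exceeds the surface power
        for z in (100.0, 250.0, 420.0):
            pb = radial_power(
                lambda zz, r: optics.ballistic_intensity(zz, r, params), z, params
            )
            ps = radial_power(
                lambda zz, r: optics.scattered_intensity(zz, r, params), z, params
            )
            assert pb + ps <= params.surface_power * 1.005

    def test_matches_refined_grid(self, params):
        for z, rho in ((50.0, 10.0), (400.0, 50.0)):
            coarse = optics.scattered_intensity(z, rho, params)
            fine = optics.scattered_intensity(
                z, rho, params, optics.DEFAULT_QUADRATURE.refined(4)
            )
            assert coarse == pytest.approx(fine, rel=5e-3)

    def test_surface_rejected(self, params):
        with pytest.raises(ValueError):
            optics.scattered_intensity(0.0, 10.0, params)


class TestFocalPower:
    def test_no_attenuation_gives_surface_power(self, scatter_free):
        assert optics.focal_power(scatter_free) == pytest.approx(1.0, rel=1e-6)

    def test_decreasing_with_focal_depth(self, params):
        powers = [
            optics.focal_power(params.replace(focal_depth_um=z))
            for z in (300.0, 450.0, 650.0)
        ]
        assert powers[0] > powers[1] > powers[2] > 0

    def test_bounded_by_on_axis_attenuation(self, params):
        # every ray travels at least z0, at most z0 sec(theta-ish); the
        # Gaussian-weighted average lies strictly between those bounds
        z0 = 400.0
        p = optics.focal_power(params.replace(focal_depth_um=z0))
        a = params.attenuation
        assert p < math.exp(-a * z0)
        assert p > math.exp(-a * z0 / math.cos(params.half_angle))


class TestInFocusFluorescence:
    def test_two_photon_closed_form(self, scatter_free):
        # P_z0 = P0 = 1 without attenuation -> F_i = pi / lambda
        fi = optics.in_focus_fluorescence(scatter_free)
        assert fi == pytest.approx(math.pi / 0.9, rel=1e-6)

    @pytest.mark.parametrize("m", [2, 3])
    def test_matches_volume_quadrature(self, scatter_free, m):
        # oracle: numerical full-axis volume integral of the Gaussian
        # focus carrying power P_z0, raised to the m-th power
        p = scatter_free.replace(photon_order=m)
        power = optics.focal_power(p)
        z0, zr = p.focal_depth_um, p.rayleigh_length_um
        # tangent substitution z = z0 + zR tan(u) resolves the zR-scale core
        u = np.linspace(-math.atan(4000.0), math.atan(4000.0), 2001)
        zs = z0 + zr * np.tan(u)
        dz = zr / np.cos(u) ** 2
        dens = []
        for z in zs:
            w2 = float(p.beam_width_sq(z))
            rho = np.linspace(0.0, 6.0 * math.sqrt(w2), 2001)
            ib = (2 * power / (math.pi * w2)) * np.exp(-2 * rho**2 / w2)
            dens.append(np.trapezoid(ib**m * 2 * math.pi * rho, rho))
        axial = np.trapezoid(np.asarray(dens) * dz, u)
        assert optics.in_focus_fluorescence(p) == pytest.approx(axial, rel=0.01)

    def test_homogeneity_in_power(self, scatter_free):
        p3 = scatter_free.replace(photon_order=3)
        f1 = optics.in_focus_fluorescence(p3)
        f2 = optics.in_focus_fluorescence(p3.replace(surface_power=2.0))
        assert f2 == pytest.approx(8.0 * f1, rel=1e-9)

    def test_invalid_photon_order_rejected(self):
        with pytest.raises(ValueError):
            optics.OpticalParameters(photon_order=4)


class TestOutOfFocusFluorescence:
    def test_no_scattering_closed_form(self, scatter_free, draft):
        # exact Lorentzian axial integral of the squared Gaussian focus
        # over the out-of-focus volume (0, z0-d) u (z0+d, inf)
        budget = optics.out_of_focus_fluorescence(scatter_free, draft)
        zr = scatter_free.rayleigh_length_um
        z0, d = scatter_free.focal_depth_um, scatter_free.exclusion_depth
        share = (
            math.pi / 2 + math.atan(z0 / zr) - 2 * math.atan(d / zr)
        ) / math.pi
        assert budget.out_of_focus == pytest.approx(
            budget.in_focus * share, rel=2e-3
        )
        # the full-axis form quoted for this limit is close but not exact
        # (it includes the tissue-free half-space above the surface)
        simple = budget.in_focus * (1 - 2 / math.pi * math.atan(d / zr))
        assert budget.out_of_focus == pytest.approx(simple, rel=0.05)

    def test_terms_sum_to_total(self, params, draft):
        for m in (2, 3):
            budget = optics.out_of_focus_fluorescence(
                params.replace(photon_order=m), draft
            )
            assert sum(t.value for t in budget.terms) == pytest.approx(
                budget.out_of_focus, rel=1e-9
            )
            assert all(t.value >= 0 for t in budget.terms)

    def test_three_photon_has_four_terms(self, params, draft):
        budget = optics.out_of_focus_fluorescence(
            params.replace(photon_order=3, wavelength_um=1.3), draft
        )
        assert [(t.ballistic_power, t.scattered_power) for t in budget.terms] == [
            (3, 0), (2, 1), (1, 2), (0, 3),
        ]

    def test_scattered_term_dominates_at_depth(self, params, draft):
        budget = optics.out_of_focus_fluorescence(
            params.replace(focal_depth_um=650.0), draft
        )
        assert budget.term(0) > budget.term(2)  # F_s > F_b


class TestContrastRatio:
    def test_equal_fluorescence_gives_half(self):
        b = optics.FluorescenceBudget(
            in_focus=1.0, out_of_focus=1.0, terms=(), focal_ballistic_power=1.0,
            photon_order=2,
        )
        assert b.contrast == 0.5

    def test_background_free_is_one_not_error(self):
        b = optics.FluorescenceBudget(
            in_focus=2.0, out_of_focus=0.0, terms=(), focal_ballistic_power=1.0,
            photon_order=2,
        )
        assert b.contrast == 1.0
        assert math.isinf(b.sbr)

    def test_near_one_without_scattering(self, scatter_free, draft):
        budget = optics.contrast_ratio(scatter_free, draft)
        zr = scatter_free.rayleigh_length_um
        z0, d = scatter_free.focal_depth_um, scatter_free.exclusion_depth
        share = (
            math.pi / 2 + math.atan(z0 / zr) - 2 * math.atan(d / zr)
        ) / math.pi
        assert budget.contrast > 0.985
        assert budget.contrast == pytest.approx(1 / (1 + share), rel=1e-3)

    def test_invariant_to_surface_power(self, params, draft):
        c1 = optics.contrast_ratio(params.replace(focal_depth_um=600.0), draft)
        c2 = optics.contrast_ratio(
            params.replace(focal_depth_um=600.0, surface_power=7.25), draft
        )
        assert c1.contrast == pytest.approx(c2.contrast, abs=1e-12)

    def test_decreasing_with_depth_increasing_with_scattering_length(
        self, params, draft
    ):
        depths = [300.0, 450.0, 600.0, 750.0]
        crs = [
            optics.contrast_ratio(params.replace(focal_depth_um=z), draft).contrast
            for z in depths
        ]
        assert all(a > b for a, b in zip(crs, crs[1:]))
        by_l = [
            optics.contrast_ratio(
                params.replace(focal_depth_um=500.0, scattering_length_um=l), draft
            ).contrast
            for l in (150.0, 200.0, 300.0)
        ]
        assert by_l[0] < by_l[1] < by_l[2]


class TestBalanceDepth:
    def test_absent_without_scattering(self, scatter_free, draft):
        assert (
            optics.balance_depth(scatter_free, [300.0, 600.0, 900.0], draft) is None
        )

    def test_shallower_for_shorter_scattering_length(self, params, draft):
        b200 = optics.balance_depth(params, np.arange(450.0, 851.0, 100.0), draft)
        b150 = optics.balance_depth(
            params.replace(scattering_length_um=150.0),
            np.arange(300.0, 701.0, 100.0),
            draft,
        )
        assert b150 is not None and b200 is not None
        assert b150 < b200

    def test_depth_profile_reports_crossing(self, params, draft):
        prof = optics.depth_profile(params, np.arange(500.0, 801.0, 100.0), draft)
        assert prof.balance_depth_um is not None
        assert 500.0 < prof.balance_depth_um < 800.0
        assert np.all((prof.contrast >= 0) & (prof.contrast <= 1))


class TestOriginProfile:
    def test_unity_at_focal_plane(self, params, draft):
        vals = optics.fluorescence_origin_profile(
            params.replace(focal_depth_um=600.0), [100.0, 600.0], draft
        )
        assert vals[1] == pytest.approx(1.0, rel=1e-9)

    def test_three_photon_background_far_smaller(self, params, draft):
        p2 = params.replace(focal_depth_um=600.0)
        p3 = p2.replace(photon_order=3, wavelength_um=1.3)
        v2 = optics.fluorescence_origin_profile(p2, [100.0], draft)[0]
        v3 = optics.fluorescence_origin_profile(p3, [100.0], draft)[0]
        assert v3 < v2 / 100.0

    def test_consistent_with_out_of_focus_total(self, params, draft):
        # trapezoid over a fine depth grid of the (unnormalized) density
        # reproduces the out-of-focus integral
        p = params.replace(focal_depth_um=500.0)
        budget = optics.out_of_focus_fluorescence(p, draft)
        d = p.exclusion_depth
        zmax = p.focal_depth_um + 5 * p.scattering_length_um
        lo = np.linspace(1.0, p.focal_depth_um - d, 400)
        hi = np.linspace(p.focal_depth_um + d, zmax, 800)
        dens = [
            sum(optics.transverse_fluorescence_density(float(z), p, draft).values())
            for z in np.concatenate([lo, hi])
        ]
        total = np.trapezoid(dens[: len(lo)], lo) + np.trapezoid(dens[len(lo):], hi)
        assert total == pytest.approx(budget.out_of_focus, rel=0.05)
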