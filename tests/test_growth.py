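"""Anisotropic growth model: ellipsoid algebra, fitting, contour inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import dblquad

from oligogrowth.growth import (
    CCSMeasurement,
    CCSSeries,
    FitError,
    KNUD_THOMSEN_P,
    distortion_factor,
    eccentricity_from_sigma,
    ellipsoid_area_exact,
    fit_growth,
    knud_thomsen_area,
    mean_projected_area_mc,
    optimal_power_exponent,
    predict_ccs,
    read_ccs_series,
    solve_axis_ratios,
    write_ccs_series,
)
from oligogrowth.synth import synth_ccs_series


def quadrature_ellipsoid_area(a, b, c):
    """Independent oracle: direct surface integral over the parametric map."""

    def integrand(u, t):
        st_, ct = np.sin(t), np.cos(t)
        su, cu = np.sin(u), np.cos(u)
        rt = np.array([a * ct * cu, b * ct * su, -c * st_])
        ru = np.array([-a * st_ * su, b * st_ * cu, 0.0])
        return np.linalg.norm(np.cross(rt, ru))

    val, _ = dblquad(integrand, 0, np.pi, 0, 2 * np.pi, epsabs=1e-8, epsrel=1e-8)
    return val


class TestKnudThomsenArea:
    def test_sphere_exact(self):
        assert knud_thomsen_area(1, 1, 1) == pytest.approx(4 * np.pi, rel=1e-12)

    @pytest.mark.parametrize("axes", [(1, 1, 2), (1, 2, 3), (1, 1, 5)])
    def test_within_one_percent_of_quadrature(self, axes):
        exact = quadrature_ellipsoid_area(*axes)
        assert knud_thomsen_area(*axes) == pytest.approx(exact, rel=0.011)

    def test_permutation_invariance(self):
        vals = {knud_thomsen_area(*p) for p in [(1, 2, 3), (3, 1, 2), (2, 3, 1)]}
        assert max(vals) - min(vals) < 1e-12

    def test_exact_area_matches_quadrature(self):
        for axes in [(1, 1, 2), (1.3, 2.1, 4.7), (1, 3, 3)]:
            assert ellipsoid_area_exact(*axes) == pytest.approx(
                quadrature_ellipsoid_area(*axes), rel=1e-7
            )

    def test_nonpositive_axis_raises(self):
        with pytest.raises(ValueError):
            knud_thomsen_area(1, 0, 1)


class TestOptimalExponent:
    def test_converged_minimax_reproduces_canonical_constant(self):
        p, err = optimal_power_exponent()
        assert round(p, 4) == pytest.approx(1.6075, abs=1e-12)
        assert err == pytest.approx(0.0106, abs=5e-4)

    def test_restricted_domain_trades_exponent_for_error(self):
        p10, err10 = optimal_power_exponent(ratio_max=10.0, n_grid=40)
        assert p10 < 1.6075
        assert err10 < 0.0106


class TestDistortionFactor:
    def test_sphere_to_sphere_is_one(self):
        assert distortion_factor(1, 1) == pytest.approx(1.0, rel=1e-12)

    def test_prolate_doubling(self):
        # direct evaluation of the closed form for a (1,1,2) assembly
        assert distortion_factor(1, 2) == pytest.approx(1.0761, abs=2e-4)

    def test_symmetry_in_i_j(self):
        assert distortion_factor(1.3, 2.7) == pytest.approx(distortion_factor(2.7, 1.3), rel=1e-12)

    def test_cauchy_consistency_with_mc_shadow(self):
        """sigma from the closed form vs the Monte-Carlo shadow-area route
        (mean shadow = area/4 by Cauchy's theorem)."""
        i, j = 1.0, 2.0
        mc, se = mean_projected_area_mc(1, i, j, n_orientations=200_000, seed=11)
        mc_mono, _ = mean_projected_area_mc(1, 1, 1, n_orientations=1000, seed=1)
        # shadow ratio scaled to equal volume: sigma = (A/A0) * (V0/V)^(2/3)
        sigma_mc = (mc / np.pi) * (1.0 / (i * j)) ** (2.0 / 3.0)
        assert distortion_factor(i, j) == pytest.approx(sigma_mc, rel=0.012)

    def test_minimum_at_sphere_over_grid(self):
        grid = np.linspace(1, 5, 21)
        vals = np.array([[distortion_factor(i, j) for j in grid] for i in grid])
        assert np.all(vals >= 1.0 - 1e-12)
        assert vals[0, 0] == pytest.approx(1.0)
        assert np.sum(np.isclose(vals, 1.0, atol=1e-9)) == 1

    @settings(max_examples=30, deadline=None)
    @given(
        st.floats(min_value=1.0, max_value=4.0),
        st.floats(min_value=1.0, max_value=4.0),
        st.floats(min_value=0.2, max_value=5.0),
    )
    def test_scale_free_in_monomer_folds(self, i, j, s):
        """sigma depends only on shape ratios: scaling the assembly and the
        monomer description identically (same relative geometry via p) is a
        no-op; and i0=j0=1 equals explicitly passing the same folds."""
        assert distortion_factor(i, j, 1.0, 1.0) == pytest.approx(
            distortion_factor(i, j, i0=1.0, j0=1.0, p=KNUD_THOMSEN_P), rel=1e-12
        )
        # identical assembly and monomer shape always gives n^(2/3)-pure growth
        assert distortion_factor(i, j, i0=i, j0=j) == pytest.approx(1.0, rel=1e-12)


class TestMeanProjectedArea:
    def test_sphere_constant_shadow(self):
        m, se = mean_projected_area_mc(1, 1, 1, n_orientations=1000, seed=0)
        assert m == pytest.approx(np.pi, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_cauchy_quarter_area(self):
        m, se = mean_projected_area_mc(1, 1, 2, n_orientations=100_000, seed=42)
        assert m == pytest.approx(ellipsoid_area_exact(1, 1, 2) / 4, rel=0.005)

    def test_seed_determinism(self):
        a = mean_projected_area_mc(1, 2, 3, 1000, seed=7)
        b = mean_projected_area_mc(1, 2, 3, 1000, seed=7)
        assert a == b

    def test_cauchy_consistency_random_axes(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            axes = rng.uniform(0.5, 4.0, size=3)
            m, se = mean_projected_area_mc(*axes, n_orientations=100_000, seed=int(rng.integers(1e6)))
            kt4 = knud_thomsen_area(*axes) / 4
            tol = max(3 * se, 0.011 * kt4)
            assert abs(m - kt4) <= tol


class TestPredictCCS:
    def test_monomer_identity(self):
        assert predict_ccs(1, 1.0, 440.0) == 440.0

    def test_octamer_isotropic(self):
        assert predict_ccs(8, 1.0, 100.0) == pytest.approx(400.0, rel=1e-12)

    def test_tetradecamer_at_fitted_sigma(self):
        # sigma = 1.28 and the measured monomer CCS 439.7 A^2
        assert predict_ccs(14, 1.28, 439.7) == pytest.approx(3269, rel=2e-3)

    def test_anisotropic_sigma_one_bit_identical_to_isotropic(self):
        n = np.arange(1, 30)
        assert np.array_equal(predict_ccs(n, 1.0, 440.0), 1.0 * 440.0 * n ** (2.0 / 3.0))


class TestFitGrowth:
    def test_noiseless_round_trip(self):
        series, _ = synth_ccs_series(1.28, omega0=440.0, n_range=range(2, 17), seed=0)
        fit = fit_growth(series, model="anisotropic", omega0=440.0)
        assert fit.sigma == pytest.approx(1.280, abs=1e-4)
        assert fit.omega0 == pytest.approx(440.0, abs=0.05)

    def test_isotropic_on_isotropic_data_zero_rmse(self):
        series, _ = synth_ccs_series(1.0, omega0=500.0, n_range=range(2, 10), seed=0)
        fit = fit_growth(series, model="isotropic")
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)
        assert fit.sigma == 1.0

    def test_most_abundant_selection(self):
        ms = [
            CCSMeasurement(5, 3, 1500.0, intensity=10.0),
            CCSMeasurement(5, 3, 1800.0, intensity=1.0),
            CCSMeasurement(2, 2, 800.0, intensity=5.0),
        ]
        fit = fit_growth(CCSSeries(ms), model="linear", selection="most_abundant")
        # only the intensity-10 pentamer point and the dimer enter
        assert fit.n_points == 2
        assert fit.predict(5) == pytest.approx(1500.0)

    def test_linear_model(self):
        ms = [CCSMeasurement(n, 2, 100.0 * n + 50.0, 1.0) for n in range(1, 8)]
        fit = fit_growth(CCSSeries(ms), model="linear")
        assert fit.slope == pytest.approx(100.0)
        assert fit.intercept == pytest.approx(50.0)

    def test_parameter_recovery_under_noise(self):
        errs = []
        for rep in range(200):
            s, _ = synth_ccs_series(1.28, omega0=440.0, n_range=range(2, 17), noise_cv=0.01, seed=rep)
            f = fit_growth(s, model="anisotropic", omega0=440.0)
            errs.append(abs(f.sigma - 1.28) / 1.28)
        assert np.median(errs) <= 0.02

    def test_free_omega0_stays_in_bounds_and_recovers_product(self):
        sf = lambda n: 1.0 if n == 1 else 1.28
        s, _ = synth_ccs_series(sf, omega0=439.7, n_range=range(1, 17), seed=0)
        f = fit_growth(s, model="anisotropic", omega0="free", n_range=(2, 16))
        assert 439.7 * 0.8 <= f.omega0 <= 439.7 * 1.2
        assert f.sigma * f.omega0 == pytest.approx(1.28 * 439.7, rel=1e-6)

    def test_insufficient_points_raise(self):
        with pytest.raises(FitError):
            fit_growth(CCSSeries([CCSMeasurement(3, 2, 900.0)]), model="linear")
        with pytest.raises(FitError):
            fit_growth(CCSSeries([]), model="isotropic")

    def test_series_io_round_trip(self, tmp_path):
        series, _ = synth_ccs_series(1.2, omega0=450.0, n_range=range(2, 8), noise_cv=0.02, seed=5)
        path = tmp_path / "ccs.csv"
        write_ccs_series(series, path)
        back = read_ccs_series(path)
        assert back.to_frame().shape == series.to_frame().shape
        np.testing.assert_allclose(
            back.to_frame()["ccs_A2"], series.to_frame()["ccs_A2"], rtol=1e-12
        )


class TestSolveAxisRatios:
    def test_spherical_contour_degenerates_to_point(self):
        pairs = solve_axis_ratios(1.0, [1.0])
        assert len(pairs) == 1
        assert pairs[0][1] == pytest.approx(1.0, abs=1e-4)

    def test_contour_at_1p05_has_multiple_configurations(self):
        pairs = solve_axis_ratios(1.05, [1.0, 1.1, 1.2])
        assert len(pairs) >= 2
        for i, j in pairs:
            assert distortion_factor(i, j) == pytest.approx(1.05, abs=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=1.01, max_value=3.0), st.floats(min_value=1.01, max_value=3.0))
    def test_round_trip_forward_then_invert(self, i, j):
        target = distortion_factor(i, j)
        pairs = solve_axis_ratios(target, [i])
        assert any(abs(jj - j) < 1e-6 for _, jj in pairs)

    def test_unattainable_sigma_on_branch_gives_no_pair(self):
        # sigma below the minimum over j for i=1 (which is 1.0)
        assert solve_axis_ratios(0.99, [1.0]) == []


class TestEccentricity:
    def test_sphere_zero(self):
        assert eccentricity_from_sigma(1.0) == 0.0

    def test_prolate_matches_forward_evaluation(self):
        e = eccentricity_from_sigma(1.0761, family="prolate")
        # j = 2 gives sigma ~= 1.0761, and e = sqrt(1 - 1/4)
        assert e == pytest.approx(np.sqrt(0.75), abs=1e-3)
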