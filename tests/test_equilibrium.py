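"""K_D estimation: area-to-species conversion, linear and nonlinear fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from secdimer import (
    KdLinearEstimator,
    SimulationConfig,
    bootstrap_kd,
    fit_kd_linear,
    fit_kd_nonlinear,
    quantify_species_peaks,
    simulate_dilution_series,
    simulate_equilibrium_species,
    species_from_areas,
    subtract_baseline,
)


def pipeline_points(true_kd, c_totals, noise_cv, seed):
    cfg = SimulationConfig(true_kd=true_kd, c_totals=tuple(c_totals),
                           noise_cv=noise_cv, seed=seed)
    points = []
    for chrom in simulate_dilution_series(cfg):
        dimer, monomer = quantify_species_peaks(subtract_baseline(chrom))
        points.append(species_from_areas(monomer.area, dimer.area, chrom.c_total))
    return points


class TestSpeciesFromAreas:
    def test_all_monomer(self):
        sp = species_from_areas(3.0, 0.0, 50.0)
        assert (sp.M, sp.D) == (50.0, 0.0)

    def test_equal_areas_split_mass_equally(self):
        sp = species_from_areas(1.0, 1.0, 40.0)
        assert sp.M == pytest.approx(20.0)
        assert sp.D == pytest.approx(10.0)   # dimer-molar units

    def test_noiseless_generator_round_trip_is_exact(self):
        (p,) = pipeline_points(7.0, [30.0], 0.0, 0)
        truth = simulate_equilibrium_species(30.0, 7.0)
        assert p.M == pytest.approx(truth.M, rel=1e-3)
        assert p.D == pytest.approx(truth.D, rel=1e-3)

    def test_both_areas_zero_rejected(self):
        with pytest.raises(ValueError):
            species_from_areas(0.0, 0.0, 10.0)


class TestLinearFit:
    def test_single_point_slope(self):
        sp = species_from_areas(1.0, 1.0, 21.0)   # M=10.5, D=5.25 -> Kd=21
        fit = fit_kd_linear([sp])
        assert fit.kd == pytest.approx(sp.M**2 / sp.D)

    def test_noiseless_points_return_generating_kd_exactly(self):
        pts = [simulate_equilibrium_species(c, 7.0) for c in np.logspace(0, 2, 9)]
        fit = fit_kd_linear(pts)
        assert fit.kd == pytest.approx(7.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_free_intercept_mode_agrees_on_noiseless_data(self):
        pts = [simulate_equilibrium_species(c, 12.0) for c in np.logspace(0, 2, 9)]
        fit = fit_kd_linear(pts, through_origin=False)
        assert fit.kd == pytest.approx(12.0, rel=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-7)

    def test_noisy_recovery_within_ten_percent(self):
        pts = pipeline_points(7.0, np.logspace(0, 2, 12), 0.01, 42)
        fit = fit_kd_linear(pts)
        assert fit.kd == pytest.approx(7.0, rel=0.10)

    def test_all_zero_dimer_is_degenerate(self):
        pts = [species_from_areas(1.0, 0.0, c) for c in (1.0, 2.0)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_kd_linear(pts)

    def test_extreme_dimer_fractions_are_flagged(self):
        pts = [simulate_equilibrium_species(c, 7.0) for c in (1e-4, 10.0, 1e6)]
        with pytest.warns(UserWarning, match="leverage"):
            fit_kd_linear(pts)

    def test_sklearn_estimator_contract(self):
        pts = [simulate_equilibrium_species(c, 5.0) for c in (2.0, 10.0, 50.0)]
        X = np.array([[p.D] for p in pts])
        y = np.array([p.M for p in pts]) ** 2
        est = KdLinearEstimator().fit(X, y)
        assert est.kd_ == pytest.approx(5.0, rel=1e-12)
        assert est.predict(X) == pytest.approx(y, rel=1e-9)
        assert KdLinearEstimator().get_params() == {"through_origin": True}


class TestNonlinearFit:
    @pytest.mark.parametrize("true_kd", [7.0, 135.0])
    def test_noiseless_recovery_exact(self, true_kd):
        samples = [(c, simulate_equilibrium_species(c, true_kd).dimer_mass_fraction)
                   for c in np.logspace(0, 3, 10)]
        fit = fit_kd_nonlinear(samples)
        assert fit.kd == pytest.approx(true_kd, rel=1e-6)

    def test_agrees_with_linear_estimator_on_noisy_series(self):
        pts = pipeline_points(7.0, np.logspace(0, 2, 12), 0.05, 7)
        lin = fit_kd_linear(pts)
        nl = fit_kd_nonlinear([(p.c_total, p.dimer_mass_fraction) for p in pts])
        (lo, hi), _ = bootstrap_kd(pts, n_boot=1000, seed=7)
        assert lo <= nl.kd <= hi

    def test_needs_two_distinct_concentrations(self):
        with pytest.raises(ValueError):
            fit_kd_nonlinear([(10.0, 0.5), (10.0, 0.5)])


class TestBootstrap:
    def test_noiseless_interval_has_zero_width(self):
        pts = [simulate_equilibrium_species(c, 7.0) for c in (2.0, 10.0, 60.0)]
        (lo, hi), _ = bootstrap_kd(pts, n_boot=200, seed=0)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_fixed_seed_reproducible(self):
        pts = pipeline_points(7.0, np.logspace(0, 2, 8), 0.05, 11)
        assert bootstrap_kd(pts, seed=5) == bootstrap_kd(pts, seed=5)

    def test_interval_brackets_estimate(self):
        pts = pipeline_points(7.0, np.logspace(0, 2, 12), 0.05, 3)
        fit = fit_kd_linear(pts)
        (lo, hi), stderr = bootstrap_kd(pts, n_boot=500, seed=1)
        assert lo < fit.kd < hi
        assert stderr > 0

    def test_too_few_points_rejected(self):
        pts = [simulate_equilibrium_species(c, 7.0) for c in (2.0, 10.0)]
        with pytest.raises(ValueError):
            bootstrap_kd(pts)

    def test_percentile_interval_available(self):
        pts = pipeline_points(7.0, np.logspace(0, 2, 12), 0.05, 3)
        (lo, hi), _ = bootstrap_kd(pts, n_boot=500, seed=1, interval="percentile")
        assert lo < hi


class TestEstimatorProperties:
    @given(log_kd=st.floats(min_value=-1.0, max_value=4.0))
    def test_consistency_over_kd_range(self, log_kd):
        kd = 10.0 ** log_kd
        # concentrations spanning the transition region for this Kd
        cs = kd * np.logspace(-1.5, 1.5, 8)
        pts = [simulate_equilibrium_species(c, kd) for c in cs]
        assert fit_kd_linear(pts).kd == pytest.approx(kd, rel=1e-9)

    @given(scale=st.floats(min_value=1e-2, max_value=1e3),
           log_kd=st.floats(min_value=0.0, max_value=2.0))
    def test_scale_equivariance(self, scale, log_kd):
        kd = 10.0 ** log_kd
        from secdimer import SpeciesConcentrations
        pts = pipeline_points(kd, np.logspace(0, 2, 6), 0.03, 21)
        base = fit_kd_linear(pts).kd
        pts_s = [SpeciesConcentrations(M=p.M * scale, D=p.D * scale,
                                       c_total=p.c_total * scale) for p in pts]
        assert fit_kd_linear(pts_s).kd == pytest.approx(base * scale, rel=1e-9)

    @given(log_kd1=st.floats(min_value=0.0, max_value=2.0),
           delta=st.floats(min_value=0.2, max_value=2.0))
    def test_mean_dimer_fraction_decreases_with_kd(self, log_kd1, delta):
        cs = np.logspace(0, 2, 8)
        f1 = np.mean([simulate_equilibrium_species(c, 10**log_kd1).dimer_mass_fraction
                      for c in cs])
        f2 = np.mean([simulate_equilibrium_species(c, 10**(log_kd1 + delta)).dimer_mass_fraction
                      for c in cs])
        assert f2 < f1
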