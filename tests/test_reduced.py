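"""Reduced-model fitting, mode analysis and the bimodality phase diagram."""

import numpy as np
import pytest

from popmaxent import (
    FitDivergedError,
    ReducedConstraints,
    bimodality_region,
    bimodality_threshold_N,
    find_modes,
    fit_reduced,
    gbar_from_rhobar,
    reduced_distribution,
    stationary_points,
)


class TestFitReduced:
    def test_uniform_moments_give_zero_multipliers(self):
        h, J = fit_reduced(ReducedConstraints(N=20, mbar=0.5, gbar=0.25))
        assert h == pytest.approx(0.0, abs=1e-9)
        assert J == pytest.approx(0.0, abs=1e-9)

    def test_independent_constraints_give_zero_coupling(self):
        m = 0.1
        h, J = fit_reduced(ReducedConstraints(N=30, mbar=m, gbar=m * m))
        assert J == pytest.approx(0.0, abs=1e-9)
        assert h == pytest.approx(np.log(m / (1 - m)), abs=1e-9)

    def test_round_trip_recovers_multipliers(self):
        n, h0, J0 = 7, -1.3, 0.2
        model = reduced_distribution(n, h0, J0)
        constraints = ReducedConstraints(
            N=n, mbar=model.E_sbar, gbar=model.E_factorial / (n * (n - 1)))
        h, J = fit_reduced(constraints)
        assert h == pytest.approx(h0, abs=1e-8)
        assert J == pytest.approx(J0, abs=1e-8)

    @pytest.mark.parametrize("n,mbar,gbar", [
        (159, 0.0499, 0.00261),
        (300, 0.0499, 0.00261),
        (50, 0.2, 0.045),
    ])
    def test_refit_reproduces_constraints(self, n, mbar, gbar):
        """Moments recomputed from the fitted model match the constraints."""
        h, J = fit_reduced(ReducedConstraints(N=n, mbar=mbar, gbar=gbar))
        model = reduced_distribution(n, h, J)
        assert model.E_sbar == pytest.approx(mbar, rel=1e-8)
        assert model.E_factorial / (n * (n - 1)) == pytest.approx(gbar, rel=1e-8)

    def test_boundary_constraints_rejected(self):
        with pytest.raises((FitDivergedError, ValueError)):
            # gbar at the pair upper bound min(m, m) = m: diverges
            fit_reduced(ReducedConstraints(N=10, mbar=0.2, gbar=0.2))

    def test_constraint_validation(self):
        with pytest.raises(ValueError):
            ReducedConstraints(N=10, mbar=0.0, gbar=0.0)
        with pytest.raises(ValueError):
            ReducedConstraints(N=10, mbar=0.2, gbar=0.3)  # gbar > mbar

    def test_rho_conversion(self):
        c = ReducedConstraints.from_rho(N=10, mbar=0.1, rhobar=0.05)
        assert c.gbar == pytest.approx(0.01 + 0.05 * 0.09)


class TestStationaryPoints:
    def test_symmetric_binomial_single_maximum_at_half(self):
        analysis = stationary_points(40, 0.0, 0.0)
        assert not analysis.bimodal
        assert len(analysis.maxima) == 1
        assert analysis.maxima[0] == pytest.approx(0.5, abs=1e-9)

    def test_printed_multipliers_two_maxima_one_minimum(self):
        analysis = stationary_points(159, -3.259, 0.03859)
        assert analysis.bimodal
        assert len(analysis.maxima) == 2 and len(analysis.minima) == 1
        lo, hi = analysis.maxima
        assert analysis.minima[0] > lo and analysis.minima[0] < hi

    def test_maxima_minima_alternate(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            analysis = stationary_points(n, rng.normal(-1, 1),
                                         abs(rng.normal(0, 0.05)))
            kinds = [k for _, k in analysis.stationary]
            for a, b in zip(kinds, kinds[1:]):
                assert a != b

    def test_agrees_with_discrete_mode_count(self, rng):
        """Continuous classification matches the pmf scan when maxima are
        separated by more than two grid steps."""
        checked = 0
        for _ in range(30):
            n = int(rng.integers(20, 200))
            h = rng.normal(-2, 1)
            J = abs(rng.normal(0, 0.1))
            analysis = stationary_points(n, h, J)
            maxima = analysis.maxima
            if len(maxima) >= 2 and min(
                    b - a for a, b in zip(maxima, maxima[1:])) < 2.0 / n:
                continue  # merged on the grid; no meaningful comparison
            modes, _ = find_modes(reduced_distribution(n, h, J))
            if 0 in modes or n in modes:
                # boundary pmf modes have no interior stationary counterpart
                continue
            assert len(modes) == max(1, len(maxima))
            checked += 1
        assert checked >= 10


class TestFindModes:
    def test_binomial_single_mode_near_half(self):
        modes, ratio = find_modes(reduced_distribution(30, 0.0, 0.0))
        assert modes == [15]
        assert ratio is None

    def test_brute_force_scan_oracle(self):
        model = reduced_distribution(12, -2.2, 0.45)
        p = model.pmf
        oracle = [s for s in range(13)
                  if (s == 0 or p[s] > p[s - 1]) and (s == 12 or p[s] > p[s + 1])]
        modes, ratio = find_modes(model)
        assert modes == oracle
        if len(oracle) >= 2:
            assert ratio == pytest.approx(p[oracle[0]] / p[oracle[-1]])

    def test_plateau_collapses_to_leftmost(self):
        from popmaxent.reduced import _discrete_modes

        log_pmf = np.log(np.array([1, 3, 3, 1, 2, 1], dtype=float) / 11)
        modes, _ = _discrete_modes(log_pmf)
        assert modes == [1, 4]


class TestBimodalityRegion:
    def test_weak_correlation_point_is_unimodal(self):
        boundary = bimodality_region(100, n_points=400)
        assert boundary.classify(0.5, 1e-4) == "unimodal"

    def test_data_point_is_bimodal_at_159(self):
        boundary = bimodality_region(159, n_points=400)
        assert boundary.classify(0.0499, 0.00319) == "bimodal"

    def test_curve_symmetric_about_half(self):
        boundary = bimodality_region(60, n_points=400)
        order = np.argsort(boundary.E)
        E, rho = boundary.E[order], boundary.rho[order]
        # mirror each point through E=0.5 and compare to the interpolant
        mask = (E > 0.05) & (E < 0.45)
        mirrored = np.interp(1 - E[mask], E, rho)
        assert np.allclose(mirrored, rho[mask], rtol=1e-3, atol=1e-6)

    def test_classification_agrees_with_direct_fit(self, rng):
        n = 100
        boundary = bimodality_region(n, n_points=600)
        agreements = 0
        for _ in range(20):
            E = float(rng.uniform(0.02, 0.3))
            rho = float(10 ** rng.uniform(-3.5, -0.5))
            region = boundary.classify(E, rho)
            try:
                h, J = fit_reduced(
                    ReducedConstraints(N=n, mbar=E,
                                       gbar=gbar_from_rhobar(E, rho)))
            except (FitDivergedError, ValueError):
                continue
            direct = ("bimodal" if stationary_points(n, h, J).bimodal
                      else "unimodal")
            # skip points numerically on the boundary
            crit = boundary.rho_critical(E)
            if abs(rho - crit) / crit < 0.02:
                continue
            assert region == direct, (E, rho, crit)
            agreements += 1
        assert agreements >= 10


class TestThresholdN:
    def test_independent_units_never_bimodal(self):
        thr, analysis = bimodality_threshold_N(0.1, 0.01, range(50, 400, 25))
        assert thr is None and analysis is None

    def test_matches_brute_force_scan(self):
        mbar, rhobar = 0.1, 0.01
        gbar = gbar_from_rhobar(mbar, rhobar)
        grid = range(40, 400, 10)
        thr, analysis = bimodality_threshold_N(mbar, gbar, grid)
        oracle = None
        for n in grid:
            h, J = fit_reduced(ReducedConstraints(N=n, mbar=mbar, gbar=gbar))
            if stationary_points(n, h, J).bimodal:
                oracle = n
                break
        assert thr == oracle
        assert analysis is not None and analysis.bimodal

    def test_bimodal_region_grows_with_n(self):
        """Once bimodal, the fitted model stays bimodal at larger N."""
        mbar, gbar = 0.0499, 0.00261
        thr, _ = bimodality_threshold_N(mbar, gbar, range(100, 301, 5))
        assert thr is not None
        for n in range(thr, 301, 25):
            h, J = fit_reduced(ReducedConstraints(N=n, mbar=mbar, gbar=gbar))
            assert stationary_points(n, h, J).bimodal
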