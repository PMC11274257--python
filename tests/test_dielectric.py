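"""Conductivity, permittivity conversion, Clausius-Mossotti algebra,
Maxwell-Wagner mixture, and DEP crossover prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eisdep.circuit_models import ImpedanceSpectrum
from eisdep.dielectric import (
    EPSILON_0,
    CellGeometry,
    cm_factor_impedance,
    cm_factor_permittivity,
    complex_permittivity,
    conductivity_from_resistance,
    dep_response,
    invert_maxwell_wagner,
    maxwell_wagner_mixture,
    mixture_state,
    permittivity_from_impedance,
)


def analytic_crossover_hz(sigma_p, sigma_m, eps_p, eps_m):
    """Closed-form Re[f_CM] = 0 frequency for homogeneous lossy spheres.

    Derived from Re[N * conj(D)] = 0 with N = (eps_p - eps_m) -
    j(sigma_p - sigma_m)/(omega eps0) and D = (eps_p + 2 eps_m) -
    j(sigma_p + 2 sigma_m)/(omega eps0):

        omega^2 = (sigma_m - sigma_p)(sigma_p + 2 sigma_m)
                  / [eps0^2 (eps_p - eps_m)(eps_p + 2 eps_m)]

    Real only when the conductivity and permittivity contrasts have
    opposite signs.
    """
    num = (sigma_m - sigma_p) * (sigma_p + 2 * sigma_m)
    den = (eps_p - eps_m) * (eps_p + 2 * eps_m) * EPSILON_0**2
    ratio = num / den
    if ratio <= 0:
        return None
    return np.sqrt(ratio) / (2 * np.pi)


class TestConductivity:
    def test_published_series_values(self, cell_geometry):
        # polarization resistances of the concentration series reproduce
        # the published suspension conductivities to 3 significant figures
        expected = {23.69: 1.02, 3.785e3: 6.37e-3}
        for r, sigma in expected.items():
            assert conductivity_from_resistance(r, cell_geometry) == pytest.approx(
                sigma, rel=5e-3
            )

    def test_resistance_equal_to_cell_constant(self, cell_geometry):
        assert conductivity_from_resistance(
            cell_geometry.cell_constant, cell_geometry
        ) == pytest.approx(1.0, rel=1e-15)

    def test_rejects_nonpositive_resistance(self, cell_geometry):
        with pytest.raises(ValueError):
            conductivity_from_resistance(0.0, cell_geometry)

    def test_geometry_invariants(self):
        g = CellGeometry(thickness=4.75e-3, area=1.97e-4)
        assert g.cell_constant == 4.75e-3 / 1.97e-4
        with pytest.raises(ValueError):
            CellGeometry(thickness=0.0, area=1.0)


class TestPermittivityFromImpedance:
    def test_pure_capacitor_is_lossless(self, cell_geometry):
        c = 1e-9
        f = np.logspace(1, 5, 30)
        z = 1.0 / (1j * 2 * np.pi * f * c)
        ps = permittivity_from_impedance(ImpedanceSpectrum(f, z), cell_geometry)
        assert np.allclose(ps.sigma, 0.0, atol=1e-18)
        assert np.allclose(ps.eps_real, c * cell_geometry.cell_constant / EPSILON_0, rtol=1e-12)

    def test_pure_resistor_matches_conductivity_formula(self, cell_geometry):
        r = 1234.5
        f = np.logspace(0, 6, 20)
        ps = permittivity_from_impedance(
            ImpedanceSpectrum(f, np.full(f.size, complex(r))), cell_geometry
        )
        sigma = conductivity_from_resistance(r, cell_geometry)
        assert np.allclose(ps.sigma, sigma, rtol=1e-15)
        assert np.allclose(ps.eps_real, 0.0, atol=1e-18)

    def test_parallel_rc_against_closed_form_admittance(self, cell_geometry):
        r, c = 1e3, 1e-9
        f = np.array([500.0, 1e3, 5e3])
        omega = 2 * np.pi * f
        z = r / (1 + 1j * omega * r * c)
        ps = permittivity_from_impedance(ImpedanceSpectrum(f, z), cell_geometry)
        kappa = cell_geometry.cell_constant
        assert np.allclose(ps.sigma, kappa / r, rtol=1e-12)
        assert np.allclose(ps.eps_real, c * kappa / EPSILON_0, rtol=1e-12)

    def test_eps_imag_identity_holds(self, cell_geometry, default_grid):
        from eisdep.synthetic_data import TAU441_SERIES, generate_spectrum

        s = generate_spectrum(TAU441_SERIES[1][2], default_grid)
        ps = permittivity_from_impedance(s, cell_geometry)
        omega = 2 * np.pi * ps.frequencies
        assert np.allclose(ps.eps_imag, ps.sigma / (omega * EPSILON_0), rtol=1e-14)

    def test_literal_mode_flags_zero_reactance(self, cell_geometry):
        f = np.array([1.0, 10.0, 100.0])
        z = np.array([100.0 + 0j, 100.0 - 50j, 100.0 - 80j])
        ps = permittivity_from_impedance(
            ImpedanceSpectrum(f, z), cell_geometry, mode="literal"
        )
        assert ps.undefined.tolist() == [True, False, False]
        assert np.isnan(ps.eps_real[0]) and np.isfinite(ps.eps_real[1])
        kappa = cell_geometry.cell_constant
        assert ps.eps_real[1] == pytest.approx(kappa / (2 * np.pi * 10 * EPSILON_0 * 50.0))


class TestClausiusMossotti:
    def test_hand_computed_values(self):
        assert cm_factor_permittivity(1 - 0.5j, 1 - 0.5j) == 0j
        assert cm_factor_permittivity(2 - 1j, 1 - 0.5j) == pytest.approx(0.25 + 0j)
        assert cm_factor_impedance(1 + 0j, 4 + 0j) == pytest.approx(0.5 + 0j)
        assert cm_factor_impedance(1 + 2j, 1 + 2j) == 0j

    def test_bound_cases(self):
        # perfectly polarizable particle -> 1; void -> -0.5
        assert cm_factor_permittivity(1e12, 1.0).real == pytest.approx(1.0, abs=1e-9)
        assert cm_factor_permittivity(1e-12, 1.0).real == pytest.approx(-0.5, abs=1e-9)

    def test_impedance_and_permittivity_forms_agree(self):
        rng = np.random.default_rng(4)
        kappa = 24.11
        for _ in range(100):
            eps_p = complex(rng.uniform(1, 100), -(10.0 ** rng.uniform(-3, 4)))
            eps_m = complex(rng.uniform(1, 100), -(10.0 ** rng.uniform(-3, 4)))
            omega = 10.0 ** rng.uniform(1, 8)
            z_p = kappa / (1j * omega * EPSILON_0 * eps_p)
            z_m = kappa / (1j * omega * EPSILON_0 * eps_m)
            assert cm_factor_impedance(z_p, z_m) == pytest.approx(
                cm_factor_permittivity(eps_p, eps_m), rel=1e-13
            )

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(
        ep=st.floats(0.5, 1e4),
        em=st.floats(0.5, 1e4),
        sp=st.floats(0.0, 10.0),
        sm=st.floats(1e-6, 10.0),
        logf=st.floats(1.0, 9.0),
    )
    def test_real_part_bounded_for_admissible_phases(self, ep, em, sp, sm, logf):
        omega = 2 * np.pi * 10.0**logf
        eps_p = ep - 1j * sp / (omega * EPSILON_0)
        eps_m = em - 1j * sm / (omega * EPSILON_0)
        f_cm = cm_factor_permittivity(eps_p, eps_m)
        assert -0.5 - 1e-9 <= f_cm.real <= 1.0 + 1e-9

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            cm_factor_permittivity(-2.0 + 0j, 1.0 + 0j)
        with pytest.raises(ValueError):
            cm_factor_impedance(1.0 + 0j, -2.0 + 0j)


class TestMaxwellWagner:
    def test_no_particles_or_index_matched(self):
        assert maxwell_wagner_mixture(3 - 1j, 0.5 + 0.1j, 0.0) == 3 - 1j
        assert maxwell_wagner_mixture(3 - 1j, 0j, 0.2) == pytest.approx(3 - 1j)

    def test_hand_computed_value_and_inverse(self):
        mix = maxwell_wagner_mixture(1.0, 0.25, 0.1)
        assert mix == pytest.approx(1.05 / 0.975)
        assert invert_maxwell_wagner(mix, 1.0, 0.1) == pytest.approx(0.25, rel=1e-14)

    def test_round_trip_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            eps_m = complex(rng.uniform(1, 100), -rng.uniform(0, 100))
            f_cm = complex(rng.uniform(-0.5, 1.0), rng.uniform(-0.5, 0.5))
            delta = rng.uniform(1e-4, 0.5)
            mix = maxwell_wagner_mixture(eps_m, f_cm, delta)
            assert invert_maxwell_wagner(mix, eps_m, delta) == pytest.approx(f_cm, rel=1e-12)

    def test_delta_validation(self):
        with pytest.raises(ValueError):
            maxwell_wagner_mixture(1.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            invert_maxwell_wagner(1.1, 1.0, 0.0)

    def test_mixture_state_assembly(self):
        state = mixture_state(2 - 1j, 1 - 0.5j, 0.1)
        assert state.f_cm == pytest.approx(0.25 + 0j)
        assert state.eps_mix == pytest.approx(
            maxwell_wagner_mixture(1 - 0.5j, 0.25, 0.1)
        )


class TestDEPResponse:
    def test_all_positive_band_no_crossover(self):
        f = np.logspace(2, 8, 61)
        eps_p = complex_permittivity(100.0, 1.0, f)  # more polarizable, more conductive
        eps_m = complex_permittivity(80.0, 0.1, f)
        pred = dep_response(f, eps_p, eps_m)
        assert pred.crossover_frequencies == []
        assert pred.sign_bands == [(f[0], f[-1], "positive")]
        assert pred.recommended_band == (f[0], f[-1])

    def test_crossover_matches_closed_form(self):
        # conductivity-driven positive DEP giving way to permittivity-driven
        # negative DEP: the bisection result must match the analytic
        # crossover within 0.1%
        rng = np.random.default_rng(6)
        checked = 0
        while checked < 20:
            sigma_p, sigma_m = 10.0 ** rng.uniform(-2, 0), 10.0 ** rng.uniform(-5, -3)
            eps_p, eps_m = rng.uniform(2, 40), rng.uniform(50, 90)
            fc = analytic_crossover_hz(sigma_p, sigma_m, eps_p, eps_m)
            if fc is None or not 1e3 < fc < 1e9:
                continue
            # asymmetric window so the crossover falls strictly between
            # grid points and the bisection path is exercised
            f = np.logspace(np.log10(fc) - 3.07, np.log10(fc) + 2.93, 241)
            pred = dep_response(
                f,
                complex_permittivity(eps_p, sigma_p, f),
                complex_permittivity(eps_m, sigma_m, f),
            )
            assert len(pred.crossover_frequencies) == 1
            assert pred.crossover_frequencies[0] == pytest.approx(fc, rel=1e-3)
            checked += 1

    def test_limits_three_decades_beyond_relaxation(self):
        sigma_p, sigma_m, eps_p, eps_m = 0.5, 1e-4, 5.0, 78.0
        fc = analytic_crossover_hz(sigma_p, sigma_m, eps_p, eps_m)
        f = np.logspace(np.log10(fc) - 3.2, np.log10(fc) + 3.2, 100)
        pred = dep_response(
            f,
            complex_permittivity(eps_p, sigma_p, f),
            complex_permittivity(eps_m, sigma_m, f),
        )
        low_limit = (sigma_p - sigma_m) / (sigma_p + 2 * sigma_m)
        high_limit = (eps_p - eps_m) / (eps_p + 2 * eps_m)
        assert pred.re_fcm[0] == pytest.approx(low_limit, rel=5e-3)
        assert pred.re_fcm[-1] == pytest.approx(high_limit, rel=5e-3)

    def test_band_signs_separate_across_crossover(self):
        f = np.logspace(3, 9, 121)
        pred = dep_response(
            f,
            complex_permittivity(5.0, 0.5, f),
            complex_permittivity(78.0, 1e-4, f),
        )
        assert [b[2] for b in pred.sign_bands] == ["positive", "negative"]
        fc = pred.crossover_frequencies[0]
        assert f[0] < fc < f[-1]
        assert pred.sign_bands[0][1] == fc == pred.sign_bands[1][0]
        assert pred.recommended_band == pred.sign_bands[0][:2]

    def test_index_matched_perturbation_antisymmetry(self):
        # eps_p = eps_m (1+h) gives f_CM ~ h/3 to first order; swapping the
        # phases flips the sign
        f = np.logspace(3, 6, 31)
        eps_m = complex_permittivity(78.0, 1e-3, f)
        h = 1e-6
        eps_p = eps_m * (1 + h)
        forward = dep_response(f, eps_p, eps_m).re_fcm
        backward = dep_response(f, eps_m, eps_p).re_fcm
        assert np.allclose(forward, h / 3, rtol=1e-4)
        assert np.allclose(backward, -forward, rtol=1e-4)

    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            dep_response([1.0], [1 + 0j], [1 + 0j])
        with pytest.raises(ValueError):
            dep_response([2.0, 1.0], [1 + 0j, 1 + 0j], [1 + 0j, 1 + 0j])
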