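"""Oscillator thermodynamics, the F(T, V) surface and response properties."""

import numpy as np
import pandas as pd
import pytest

from cqha.constants import GPA_A3_TO_KJMOL, R_GAS, THZ_TO_K, THZ_TO_KJMOL
from cqha.eos import MurnaghanFit, murnaghan_energy, pressure_volume
from cqha.thermo import (
    build_surface,
    composite_thermo,
    equilibrium_state,
    linear_expansion,
    thermo_properties,
    vibrational_cv,
    vibrational_entropy,
    vibrational_helmholtz,
    zero_point_energy,
)

EOS = dict(e0=-100.0, v0=900.0, b0=10.0, b0_prime=5.0)


def e_static(v):
    return murnaghan_energy(np.asarray(v), **EOS)


def einstein_model(nu=2.0, n_modes=1):
    """Volume-independent single-frequency crystal (no thermal expansion)."""
    freqs = np.full(n_modes, nu)

    def freqs_of_v(_v):
        return ((1.0, freqs.copy()),)

    return freqs_of_v


class TestOscillatorSums:
    def test_zpe_of_1thz_mode(self):
        # N_A·h·ν/2 = 0.199511 kJ/mol for ν = 1 THz
        fs = ((1.0, np.array([1.0])),)
        assert vibrational_helmholtz(fs, 0.0) == pytest.approx(
            0.5 * THZ_TO_KJMOL, rel=1e-12)
        assert zero_point_energy(fs) == pytest.approx(0.1995, abs=1e-4)

    def test_classical_limit(self):
        # A → R·T·ln(hν/kT) + ZPE as T → ∞
        nu, t = 1.0, 1e5
        fs = ((1.0, np.array([nu])),)
        x = THZ_TO_K * nu / t
        expected = R_GAS * t * np.log(x) / 1000.0 + 0.5 * THZ_TO_KJMOL * nu
        assert vibrational_helmholtz(fs, t) == pytest.approx(expected, rel=1e-3)

    def test_weights_are_normalized_average(self):
        f = np.array([1.0, 5.0, 9.0])
        one = ((1.0, f),)
        two = ((0.25, f), (0.75, f))
        for t in (0.0, 100.0, 300.0):
            assert vibrational_helmholtz(two, t) == pytest.approx(
                vibrational_helmholtz(one, t), rel=1e-14)
            assert vibrational_entropy(two, t) == pytest.approx(
                vibrational_entropy(one, t), rel=1e-14)

    @pytest.mark.parametrize("t", [50.0, 300.0, 1000.0])
    def test_einstein_heat_capacity_closed_form(self, t):
        # independent oracle: C_v = R·x²·eˣ/(eˣ−1)²
        nu = 2.0
        x = THZ_TO_K * nu / t
        expected = R_GAS * x**2 * np.exp(x) / np.expm1(x) ** 2
        got = vibrational_cv(((1.0, np.array([nu])),), t)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_dulong_petit_limit(self):
        freqs = np.array([1.0, 2.5, 5.0])
        t = 20.0 * THZ_TO_K * freqs.max()
        cv = vibrational_cv(((1.0, freqs),), t)
        assert cv == pytest.approx(3 * R_GAS, rel=1e-3)

    def test_entropy_vanishes_at_zero(self):
        fs = ((1.0, np.array([0.5, 3.0])),)
        assert vibrational_entropy(fs, 0.0) == 0.0
        assert vibrational_cv(fs, 0.0) == 0.0


class TestSurface:
    volumes = EOS["v0"] * np.linspace(0.9, 1.1, 7)

    def test_zero_phonons_gives_static_surface(self):
        surf = build_surface(e_static, lambda v: (), self.volumes,
                             np.array([0.0, 150.0, 300.0]))
        for row in surf.f_values:
            assert np.allclose(row, e_static(self.volumes), rtol=1e-12)
        st = equilibrium_state(surf, 300.0, 0.0)
        assert st["v_eq"] == pytest.approx(EOS["v0"], rel=1e-8)

    def test_t0_row_is_static_plus_zpe(self):
        freqs_of_v = einstein_model(nu=3.0)
        surf = build_surface(e_static, freqs_of_v, self.volumes,
                             np.array([0.0]))
        zpe = 0.5 * THZ_TO_KJMOL * 3.0
        assert np.allclose(surf.f_values[0],
                           e_static(self.volumes) + zpe, rtol=1e-12)

    def test_einstein_solid_does_not_expand(self):
        surf = build_surface(e_static, einstein_model(), self.volumes,
                             np.array([0.0, 100.0, 300.0]))
        for t in (0.0, 100.0, 300.0):
            assert equilibrium_state(surf, t)["v_eq"] == pytest.approx(
                EOS["v0"], rel=1e-8)

    def test_pressure_state_matches_closed_form_inversion(self):
        surf = build_surface(e_static, lambda v: (), self.volumes,
                             np.array([0.0]))
        p = 0.4
        st = equilibrium_state(surf, 0.0, p)
        fit = MurnaghanFit(**EOS)
        assert st["v_eq"] == pytest.approx(pressure_volume(fit, p), rel=1e-8)

    def test_positive_gamma_expands_on_heating(self, m1_table):
        # dense-scan oracle is the table itself built on a fine grid
        dv = np.diff(m1_table.v_eq[m1_table.temperatures >= 10.0])
        assert np.all(dv > 0)

    def test_escaping_minimum_warns(self):
        v = EOS["v0"] * np.linspace(1.005, 1.1, 6)
        with pytest.warns(UserWarning, match="beyond grid"):
            build_surface(e_static, lambda v: (), v, np.array([0.0]))


class TestProperties:
    def test_entropy_consistent_with_gibbs_slope(self, m1_model, m1_table):
        surf = build_surface(m1_model.e_of_v, m1_model.freqs_of_v,
                             m1_model.default_volumes,
                             np.array([0.0]))
        z = m1_model.z_molecules
        for t in (100.0, 300.0):
            d = 1.0
            g = {s: equilibrium_state(surf, t + s)["g"] / z for s in (-d, 0, d)}
            s_fd = -(g[d] - g[-d]) / (2 * d) * 1000.0
            s_dir = np.interp(t, m1_table.temperatures, m1_table.s)
            assert s_fd == pytest.approx(s_dir, rel=1e-3)
            cp_fd = -t * (g[d] - 2 * g[0] + g[-d]) / d**2 * 1000.0
            cp_dir = np.interp(t, m1_table.temperatures, m1_table.cp)
            assert cp_fd == pytest.approx(cp_dir, rel=1e-3)

    def test_gibbs_concave_in_t_and_increasing_in_p(self, m1_model, m1_table):
        t = m1_table.temperatures
        assert np.all(np.diff(m1_table.g, 2) <= 1e-10)
        table_p = composite_thermo(m1_model, t[:21], p=0.2)
        assert np.all(table_p.g > m1_table.g[:21])

    def test_heat_capacity_ordering(self, m1_table):
        mask = m1_table.temperatures > 0
        assert np.all(m1_table.cp[mask] >= m1_table.cv[mask] - 1e-10)
        assert np.all(m1_table.cv >= 0)

    def test_cp_cv_thermodynamic_identity(self, m1_table):
        # C_p − C_v = T·V·α²/κ_T (per molecule, unit-consistent)
        t = m1_table.temperatures
        mask = t >= 50.0
        rhs = (t * m1_table.v_eq * m1_table.alpha_p**2 / m1_table.kappa_t
               * GPA_A3_TO_KJMOL * 1000.0 / m1_table.z_molecules)
        lhs = m1_table.cp - m1_table.cv
        assert np.max(np.abs(lhs[mask] - rhs[mask]) / rhs[mask]) < 0.01

    def test_entropy_zero_and_third_law_columns_at_t0(self, m1_table):
        assert m1_table.s[0] == 0.0
        assert m1_table.cp[0] == 0.0
        assert m1_table.alpha_p[0] == 0.0

    def test_avib_isotherms_convex_near_linear(self, m1_model):
        v = m1_model.default_volumes
        a = np.array([vibrational_helmholtz(m1_model.freqs_of_v(x), 300.0)
                      for x in v])
        assert np.all(np.diff(a, 2) > 0)          # convex
        lin = np.polyval(np.polyfit(v, a, 1), v)
        assert np.max(np.abs(a - lin)) < 0.02 * (a.max() - a.min())

    def test_coarse_grid_warns(self, m1_model):
        surf = build_surface(m1_model.e_of_v, m1_model.freqs_of_v,
                             m1_model.default_volumes, np.array([0.0]))
        with pytest.warns(UserWarning, match="spacing"):
            thermo_properties(surf, np.array([0.0, 50.0, 300.0]))


class TestLinearExpansion:
    def test_isotropic_cube(self):
        v = np.linspace(800, 1000, 9)
        table = pd.DataFrame({"volume": v, "a": v ** (1 / 3),
                              "b": v ** (1 / 3), "c": v ** (1 / 3)})
        v_of_t = {100.0: 850.0, 300.0: 950.0}
        out = linear_expansion(table, v_of_t, 100.0, 300.0)
        expected = (950.0 / 850.0) ** (1 / 3) - 1.0
        for ax in ("a", "b", "c"):
            assert out[ax] == pytest.approx(expected, rel=1e-4)

    def test_constant_axis_has_zero_expansion(self):
        v = np.linspace(800, 1000, 5)
        table = pd.DataFrame({"volume": v, "a": np.full(5, 10.0),
                              "b": v / 80.0, "c": np.full(5, 8.0)})
        out = linear_expansion(table, {10.0: 820.0, 20.0: 980.0}, 10.0, 20.0)
        assert out["a"] == 0.0
        assert out["min_axis"] == 0.0
        assert out["max_axis"] == pytest.approx(980.0 / 820.0 - 1.0, rel=1e-6)

    def test_equal_temperatures_give_zeros(self):
        v = np.linspace(800, 1000, 5)
        table = pd.DataFrame({"volume": v, "a": v / 80.0})
        out = linear_expansion(table, {50.0: 900.0}, 50.0, 50.0)
        assert out["a"] == 0.0
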