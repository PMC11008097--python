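"""Polymorph ΔG/ΔH ranking and the entropy / heat-capacity probes."""

import numpy as np
import pytest

from cqha.constants import R_GAS, THZ_TO_K, THZ_TO_KJMOL
from cqha.datamodel import EVCurve, PhononSet, QPoint, ThermoTable
from cqha.composite import Ingredients, assemble_composite
from cqha.eos import murnaghan_energy
from cqha.exceptions import InputError
from cqha.ranking import (
    rank_polymorphs,
    refine_ranking,
    sensitivity_cp_scale,
    sensitivity_entropy_offset,
)
from cqha.thermo import composite_thermo

EOS = dict(e0=-100.0, v0=900.0, b0=10.0, b0_prime=5.0)
TGRID = np.arange(0.0, 401.0, 5.0)


def einstein_table(nu, e0=EOS["e0"]):
    """Pipeline table of a volume-independent single-mode crystal (Z=1)."""
    v = EOS["v0"] * np.linspace(0.9, 1.1, 7)
    curve = EVCurve(v, murnaghan_energy(v, e0, EOS["v0"], EOS["b0"],
                                        EOS["b0_prime"]))
    phonons = PhononSet(
        v, tuple((QPoint(1.0, np.array([nu]), q=(0, 0, 0)),) for _ in v))
    model = assemble_composite(
        "M1", Ingredients(ev=curve, phonons=phonons), Ingredients())
    return composite_thermo(model, TGRID)


@pytest.fixture(scope="module")
def einstein_pair():
    return einstein_table(2.0), einstein_table(3.0)


class TestRanking:
    def test_identical_tables_are_indeterminate(self, einstein_pair):
        a, _ = einstein_pair
        res = rank_polymorphs(a, a)
        assert np.allclose(res.delta_g, 0.0)
        assert res.relationship == "indeterminate"
        assert res.crossing_temperatures == ()

    def test_gibbs_helmholtz_consistency(self, einstein_pair):
        a, b = einstein_pair
        res = rank_polymorphs(a, b)
        t = res.temperatures
        slope = np.diff(res.delta_g) / np.diff(t)
        ds_mid = (b.s - a.s)[:-1] / 2 + (b.s - a.s)[1:] / 2
        assert np.allclose(slope, -ds_mid / 1000.0, atol=2e-5)

    def test_delta_g_identity(self, einstein_pair):
        a, b = einstein_pair
        res = rank_polymorphs(a, b)
        assert np.allclose(res.delta_g, res.delta_h - res.t_delta_s,
                           atol=1e-9)

    def test_stiffer_partner_with_equal_e0_is_monotropic(self, einstein_pair):
        # equal static energies: the stiff crystal starts higher (larger
        # ZPE) and its deficit only grows, with the asymptotic ΔG slope
        # +R·ln(3/2); no stability crossover can exist
        a, b = einstein_pair
        res = rank_polymorphs(a, b)
        assert res.relationship == "monotropic"
        assert res.crossing_temperatures == ()
        # at 400 K the classical limit is approached to ~1%
        ds_inf = (b.s - a.s)[-1]
        assert ds_inf == pytest.approx(-R_GAS * np.log(3.0 / 2.0), rel=0.01)
        slope_tail = np.diff(res.delta_g)[-1] / 5.0 * 1000.0
        assert slope_tail == pytest.approx(R_GAS * np.log(3.0 / 2.0), rel=0.01)

    def test_einstein_crossing_matches_closed_form(self, einstein_pair):
        # a static offset on the softer crystal creates an enantiotropic
        # pair; oracle: harmonic-oscillator G(T) difference,
        # ΔE0 + ΔZPE + RT·[ln(1−e^-x2) − ln(1−e^-x3)] = 0
        a = einstein_table(3.0)
        de0 = 0.4
        b = einstein_table(2.0, e0=EOS["e0"] + de0)
        res = rank_polymorphs(a, b)
        assert res.relationship == "enantiotropic"
        assert len(res.crossing_temperatures) == 1

        def dg_exact(t):
            x2 = THZ_TO_K * 2.0 / t
            x3 = THZ_TO_K * 3.0 / t
            return (de0 + 0.5 * THZ_TO_KJMOL * (2.0 - 3.0)
                    + R_GAS * t / 1000.0
                    * (np.log1p(-np.exp(-x2)) - np.log1p(-np.exp(-x3))))

        tgrid = np.linspace(1.0, 400.0, 8000)
        vals = dg_exact(tgrid)
        i = int(np.argmax(vals < 0))
        t_cross = float(np.interp(0.0, [vals[i], vals[i - 1]],
                                  [tgrid[i], tgrid[i - 1]]))
        assert res.crossing_temperatures[0] == pytest.approx(t_cross, abs=1.0)

    def test_everywhere_positive_is_monotropic(self, einstein_pair):
        a, _ = einstein_pair
        b = einstein_table(2.0, e0=EOS["e0"] + 3.0)
        res = rank_polymorphs(a, b)
        assert np.all(res.delta_g > 0)
        assert res.relationship == "monotropic"

    def test_curvature_follows_heat_capacity_hierarchy(self, einstein_pair):
        a, b = einstein_pair
        res = rank_polymorphs(a, b)
        t = res.temperatures
        mask = (t >= 50) & (t <= 350)
        curv = np.diff(res.delta_g, 2)[mask[1:-1]]
        dcp = (b.cp - a.cp)[1:-1][mask[1:-1]]
        assert np.all(np.sign(curv) == np.sign(-dcp))

    def test_grid_mismatch_rejected(self, einstein_pair):
        a, _ = einstein_pair
        other = a.replace(temperatures=a.temperatures + 1.0)
        with pytest.raises(InputError, match="incompatible"):
            rank_polymorphs(a, other)


class TestEntropyOffset:
    def test_slope_changes_by_minus_delta_s(self, einstein_pair):
        a, b = einstein_pair
        base = rank_polymorphs(a, b)
        probed = rank_polymorphs(a, sensitivity_entropy_offset(b, 8.0))
        t = base.temperatures
        slope_change = np.diff(probed.delta_g - base.delta_g) / np.diff(t)
        assert np.allclose(slope_change * 1000.0, -8.0, atol=1e-9)

    def test_g_shift_at_300k(self, einstein_pair):
        a, _ = einstein_pair
        probed = sensitivity_entropy_offset(a, 8.0)
        i = int(np.where(a.temperatures == 300.0)[0][0])
        assert probed.g[i] - a.g[i] == pytest.approx(-2.4, rel=1e-12)
        assert np.allclose(probed.h, a.h)

    def test_zero_offset_is_identity(self, einstein_pair):
        a, _ = einstein_pair
        same = sensitivity_entropy_offset(a, 0.0)
        assert np.array_equal(same.g, a.g)
        assert np.array_equal(same.s, a.s)


class TestCpScale:
    def test_unit_factor_is_identity(self, einstein_pair):
        a, _ = einstein_pair
        same = sensitivity_cp_scale(a, 1.0)
        for col in ("g", "h", "s", "cp"):
            assert np.allclose(getattr(same, col), getattr(a, col),
                               atol=1e-12)

    def test_entropy_scales_when_s0_is_zero(self, einstein_pair):
        a, _ = einstein_pair
        scaled = sensitivity_cp_scale(a, 1.03)
        assert a.s[0] == 0.0
        assert np.allclose(scaled.s, 1.03 * a.s, rtol=1e-12)

    def test_scale_unscale_involution(self, einstein_pair):
        a, _ = einstein_pair
        back = sensitivity_cp_scale(sensitivity_cp_scale(a, 1.03), 1 / 1.03)
        for col in ("g", "h", "s", "cp"):
            assert np.allclose(getattr(back, col), getattr(a, col),
                               atol=1e-9)

    def test_table_must_start_at_zero(self, einstein_pair):
        a, _ = einstein_pair
        trimmed = ThermoTable(
            pressure=a.pressure, temperatures=a.temperatures[1:],
            v_eq=a.v_eq[1:], g=a.g[1:], h=a.h[1:], s=a.s[1:], cp=a.cp[1:],
            cv=a.cv[1:], alpha_p=a.alpha_p[1:], kappa_t=a.kappa_t[1:],
            zpe=a.zpe, z_molecules=a.z_molecules)
        with pytest.raises(InputError, match="re-integrate"):
            sensitivity_cp_scale(trimmed, 1.03)


class TestRefinement:
    def test_zero_correction_is_identity(self, einstein_pair):
        a, b = einstein_pair
        res = rank_polymorphs(a, b)
        same = refine_ranking(res, 0.0)
        assert np.array_equal(same.delta_g, res.delta_g)
        assert same.relationship == res.relationship

    def test_constant_shift_of_flat_curve(self, einstein_pair):
        a, _ = einstein_pair
        b = einstein_table(2.0, e0=EOS["e0"] + 2.0)
        res = rank_polymorphs(a, b)
        refined = refine_ranking(res, 1.5)
        assert np.allclose(refined.delta_g, res.delta_g + 1.5)
        assert np.allclose(refined.delta_h, res.delta_h + 1.5)
        assert refined.relationship == "monotropic"

    def test_correction_can_flip_to_enantiotropic(self, einstein_pair):
        a, b = einstein_pair
        res = rank_polymorphs(a, b)
        # push the curve so it crosses zero mid-range
        mid = res.delta_g[len(res.delta_g) // 2]
        refined = refine_ranking(res, -mid + 0.2)
        assert refined.relationship == "enantiotropic"

    def test_commutes_with_entropy_offset(self, einstein_pair):
        # offsetting the entropy before or after the energy refinement
        # yields the same ΔG curve (both are additive corrections)
        a, b = einstein_pair
        t = a.temperatures
        offset_then_refine = refine_ranking(
            rank_polymorphs(a, sensitivity_entropy_offset(b, 8.0)), 1.5)
        refine_then_offset = refine_ranking(rank_polymorphs(a, b), 1.5)
        expected = refine_then_offset.delta_g - t * 8.0 / 1000.0
        assert np.allclose(offset_then_refine.delta_g, expected, atol=1e-12)
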