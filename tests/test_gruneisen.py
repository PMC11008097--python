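"""Sorted-rank mode matching, γ fitting and frequency extrapolation."""

import numpy as np
import pytest

from cqha.datamodel import PhononSet, QPoint
from cqha.exceptions import InputError, NumericalError
from cqha.gruneisen import (
    extrapolate_frequencies,
    filter_ranks,
    fit_gruneisen,
    match_modes,
)
from cqha.synthetic import ModelCrystalSpec, default_mode_table, make_model_crystal


def phonon_set(volumes, freq_lists):
    return PhononSet(
        np.asarray(volumes, float),
        tuple((QPoint(1.0, np.asarray(f, float), q=(0, 0, 0)),)
              for f in freq_lists),
    )


class TestMatching:
    def test_sorted_rank_pairing(self):
        ps = phonon_set([900.0, 950.0], [[1.0, 3.0, 2.0], [1.1, 2.9, 2.2]])
        (block,) = match_modes(ps)
        assert np.allclose(block, [[1.0, 1.1], [2.0, 2.2], [3.0, 2.9]])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        freqs = [rng.uniform(0.5, 50, 20) for _ in range(3)]
        ps = phonon_set([900, 950, 1000], freqs)
        shuffled = phonon_set(
            [900, 950, 1000], [rng.permutation(f) for f in freqs])
        a = match_modes(ps)[0]
        b = match_modes(shuffled)[0]
        assert np.array_equal(a, b)

    def test_degenerate_frequencies_keep_stable_order(self):
        ps = phonon_set([900.0, 950.0, 1000.0], [[2.0, 2.0, 5.0]] * 3)
        (block,) = match_modes(ps)
        assert np.allclose(block[0], 2.0) and np.allclose(block[1], 2.0)

    def test_imaginary_sorts_below_real(self):
        ps = phonon_set([900.0, 950.0], [[1.0, -0.05, 2.0]] * 2)
        (block,) = match_modes(ps)
        assert block[0, 0] == -0.05


class TestFiltering:
    def test_gamma_acoustic_zeros_dropped(self):
        block = np.array([[0.0, 0.0], [0.0, 0.0], [0.01, -0.01], [2.0, 2.1]])
        kept = filter_ranks(block, is_gamma=True)
        assert kept.shape == (1, 2)

    def test_noise_level_imaginary_dropped_with_warning(self):
        block = np.array([[-0.05, 0.02], [2.0, 2.1]])
        with pytest.warns(UserWarning, match="dropping"):
            kept = filter_ranks(block, is_gamma=False)
        assert kept.shape == (1, 2)

    def test_large_imaginary_aborts(self):
        block = np.array([[-3.0, -3.1], [2.0, 2.1]])
        with pytest.raises(NumericalError, match="imaginary"):
            filter_ranks(block, is_gamma=False)

    def test_small_real_modes_survive_off_gamma(self):
        block = np.array([[0.2, 0.21], [2.0, 2.1]])
        assert filter_ranks(block, is_gamma=False).shape == (2, 2)


class TestFitting:
    def test_exact_power_law_recovered(self):
        v = np.array([900.0, 950.0, 1000.0, 1050.0])
        block = 2.0 * (v / 1000.0) ** (-1.5)
        table = fit_gruneisen([block[None, :]], v, 1000.0)
        assert table.modes[0][0].gamma == pytest.approx(1.5, abs=1e-10)
        assert table.modes[0][0].nu0 == pytest.approx(2.0, rel=1e-10)
        assert table.modes[0][0].fit_residual < 1e-12

    def test_volume_independent_mode_has_zero_gamma(self):
        v = np.array([900.0, 950.0, 1000.0])
        table = fit_gruneisen([np.full((1, 3), 4.0)], v, 950.0)
        assert table.modes[0][0].gamma == pytest.approx(0.0, abs=1e-12)
        assert table.modes[0][0].nu0 == pytest.approx(4.0, rel=1e-12)

    def test_two_point_slope_identity_on_exact_data(self):
        v = np.array([880.0, 930.0, 980.0, 1030.0, 1080.0])
        gamma = 2.2
        block = 5.0 * (v / 980.0) ** (-gamma)
        table = fit_gruneisen([block[None, :]], v, 980.0)
        slope = -(np.log(block[3]) - np.log(block[0])) / (
            np.log(v[3]) - np.log(v[0]))
        assert table.modes[0][0].gamma == pytest.approx(slope, rel=1e-12)

    def test_noisy_recovery_within_band(self):
        # oracle: per-mode log-log linear regression of the noisy data
        mt = default_mode_table(100)
        spec = ModelCrystalSpec(mode_table_high=mt, mode_table_low=mt,
                                noise_sd=1e-3, seed=42)
        c = make_model_crystal(spec)
        matched = [filter_ranks(b, True) for b in match_modes(c.phonons_low)]
        table = fit_gruneisen(matched, c.phonons_low.volumes, spec.v0_low)
        got = table.gammas(0)
        truth = np.sort(mt[:, 1])[::-1]  # freq-ascending rank order
        assert np.sqrt(np.mean((got - truth) ** 2)) < 0.02
        x = np.log(c.phonons_low.volumes / spec.v0_low)
        oracle = np.array([
            -np.polyfit(x, np.log(row), 1)[0] for row in matched[0]])
        assert np.allclose(got, oracle, atol=1e-10)

    def test_nonpositive_frequency_rejected(self):
        v = np.array([900.0, 950.0, 1000.0])
        with pytest.raises(NumericalError, match="imaginary mode"):
            fit_gruneisen([np.array([[1.0, -0.5, 1.0]])], v, 950.0)

    def test_neighboring_ranks_vary_smoothly(self, default_crystal):
        spec, c = default_crystal
        matched = [filter_ranks(b, True) for b in match_modes(c.phonons_low)]
        table = fit_gruneisen(matched, c.phonons_low.volumes, spec.v0_low)
        g = table.gammas(0)
        assert np.max(np.abs(np.diff(g))) < 0.5


class TestExtrapolation:
    def test_identity_at_reference_volume(self):
        v = np.array([900.0, 950.0, 1000.0])
        block = 3.0 * (v / 1000.0) ** (-2.0)
        table = fit_gruneisen([block[None, :]], v, 1000.0)
        ref = [np.array([3.3])]
        out = extrapolate_frequencies(ref, table, 1000.0)
        assert out[0][0] == pytest.approx(3.3, rel=1e-12)

    def test_zero_gamma_is_volume_independent(self):
        v = np.array([900.0, 950.0, 1000.0])
        table = fit_gruneisen([np.full((2, 3), 4.0)], v, 950.0)
        for vol in (850.0, 950.0, 1100.0):
            out = extrapolate_frequencies([np.array([3.0, 5.0])], table, vol)
            assert np.allclose(out[0], [3.0, 5.0])

    def test_unit_gamma_closed_form(self):
        v = np.array([900.0, 950.0, 1000.0])
        block = (2.0 * (v / 1000.0) ** (-1.0))[None, :]
        table = fit_gruneisen([block], v, 1000.0)
        out = extrapolate_frequencies([np.array([2.0])], table, 900.0)
        assert out[0][0] == pytest.approx(2.0 * 1000.0 / 900.0, rel=1e-10)

    def test_mode_count_mismatch_rejected(self):
        v = np.array([900.0, 950.0, 1000.0])
        table = fit_gruneisen([np.full((2, 3), 4.0)], v, 950.0)
        with pytest.raises(InputError, match="rank alignment"):
            extrapolate_frequencies([np.array([3.0])], table, 900.0)

    def test_matching_low_and_high_reproduces_low(self, default_crystal):
        # identical volume dependence at both levels: extrapolated
        # frequencies coincide with the source frequencies at every volume
        spec, c = default_crystal
        matched = [filter_ranks(b, True) for b in match_modes(c.phonons_low)]
        table = fit_gruneisen(matched, c.phonons_low.volumes, spec.v0_low)
        ref = [matched[0][:, 0]]  # low frequencies at the first volume
        for k, v in enumerate(c.phonons_low.volumes):
            out = extrapolate_frequencies(
                ref, table, float(v), v_ref_high=float(c.phonons_low.volumes[0]))
            assert np.allclose(out[0], matched[0][:, k], rtol=1e-9)
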