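"""Two-histogram chi-square, truncation, end-to-end report, gamma index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linacvsm import model as model_mod
from linacvsm import synthetic, validate
from linacvsm.validate import (chi2_two_histograms, fraction_retained,
                               gamma_index, shuffled_energy_model,
                               validate_model)


class TestChiSquare:
    def test_identical_histograms_give_zero(self):
        res = chi2_two_histograms([10, 20, 30], [10, 20, 30])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_proportional_histograms_give_zero(self):
        assert chi2_two_histograms([10, 20], [20, 40]).statistic == 0.0

    def test_hand_computed_three_bin_example(self):
        # N1 = N2 = 60; bins contribute 10 + 0 + 10
        res = chi2_two_histograms([10, 20, 30], [30, 20, 10])
        assert res.statistic == pytest.approx(20.0)
        assert res.dof == 2

    def test_swap_symmetry(self):
        a, b = [5, 9, 1, 7], [3, 3, 8, 2]
        assert (chi2_two_histograms(a, b).statistic
                == pytest.approx(chi2_two_histograms(b, a).statistic))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=3, max_size=20),
           st.randoms(use_true_random=False))
    def test_joint_bin_permutation_invariance(self, pairs, pyrandom):
        h1 = [a for a, _ in pairs]
        h2 = [b for _, b in pairs]
        if sum(h1) == 0 or sum(h2) == 0:
            h1[0] += 1
            h2[0] += 1
        order = list(range(len(h1)))
        pyrandom.shuffle(order)
        base = chi2_two_histograms(h1, h2)
        perm = chi2_two_histograms([h1[i] for i in order],
                                   [h2[i] for i in order])
        assert perm.statistic == pytest.approx(base.statistic)
        assert perm.dof == base.dof

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            chi2_two_histograms([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            chi2_two_histograms([1, 2], [1, 2], edges1=[0, 1, 2],
                                edges2=[0, 1, 3])


class TestFractionRetained:
    def test_full_support_is_unity(self):
        edges = np.linspace(0, 10, 11)
        assert fraction_retained(np.arange(10), edges, (0, 10)) == 1.0

    def test_half_support_of_symmetric_histogram(self):
        edges = np.linspace(-4, 4, 9)
        counts = [1, 2, 3, 4, 4, 3, 2, 1]
        assert fraction_retained(counts, edges, (-4, 0)) == pytest.approx(0.5)

    def test_gaussian_central_band_closed_form(self, rng):
        edges = np.linspace(-5, 5, 1001)
        counts, _ = np.histogram(rng.standard_normal(2_000_000), bins=edges)
        frac = fraction_retained(counts, edges, (-1.96, 1.96))
        assert frac == pytest.approx(0.950, abs=0.002)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            fraction_retained([0, 0], [0, 1, 2], (0, 2))


class TestModelValidation:
    def test_round_trip_report_passes_truncated(self, beam_model, beam_array):
        """A model validated against its own source phase space passes every
        truncated comparison, mirroring the published p-value pattern."""
        rep = validate_model(beam_model, beam_array, n_samples=500_000,
                             planes=(0, 70), seed=77)
        assert rep.all_truncated_pass()
        # positions at the scoring plane also pass without truncation
        assert rep.full["x@0cm"].p_value > 0.05
        assert rep.full["y@0cm"].p_value > 0.05
        # truncation retains most of the probability mass
        assert rep.truncated["x@70cm"].fraction_retained > 0.85
        assert rep.truncated["E"].fraction_retained > 0.9

    def test_shuffled_energy_tables_fail_energy_comparison(self, beam_model,
                                                           beam_array):
        corrupted = shuffled_energy_model(beam_model)
        rep = validate_model(corrupted, beam_array, n_samples=500_000,
                             planes=(0,), seed=78)
        assert rep.truncated["E"].p_value < 0.05
        # positions are untouched by the corruption
        assert rep.truncated["x@0cm"].p_value > 0.05


class TestGammaIndex:
    def _gauss_profile(self, shift=0.0):
        x = np.arange(-30, 30.0001, 0.1)  # mm
        return x, np.exp(-((x - shift) ** 2) / (2 * 25.0))

    def test_identical_grids_pass_everywhere(self):
        x, d = self._gauss_profile()
        res = gamma_index(d, d, coords=(x,))
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma_map) == 0.0

    def test_uniform_two_percent_scaling_within_three_percent(self):
        x, d = self._gauss_profile()
        res = gamma_index(d, 1.02 * d, coords=(x,))
        assert res.pass_rate == 100.0

    def test_three_mm_shift_gives_gamma_of_one_at_steepest_point(self):
        x, ref = self._gauss_profile()
        _, ev = self._gauss_profile(shift=3.0)
        res = gamma_index(ref, ev, coords=(x,))
        g = res.gamma_map[np.isfinite(res.gamma_map)]
        # a pure DTA-sized shift caps gamma at 1 (up to grid discretisation)
        assert np.max(g) == pytest.approx(1.0, abs=1e-6)
        steep = np.nanargmax(np.abs(np.gradient(ref)))
        assert res.gamma_map[steep] == pytest.approx(1.0, abs=0.05)

    def test_tightening_criteria_never_raises_pass_rate(self):
        x, ref = self._gauss_profile()
        _, ev = self._gauss_profile(shift=2.0)
        loose = gamma_index(ref, ev, coords=(x,), dd_percent=3, dta_mm=3)
        tight = gamma_index(ref, ev, coords=(x,), dd_percent=2, dta_mm=2)
        assert tight.pass_rate <= loose.pass_rate

    def test_two_dimensional_grids_supported(self):
        yy, xx = np.mgrid[0:40, 0:40]
        ref = np.exp(-((xx - 20) ** 2 + (yy - 20) ** 2) / (2 * 36.0))
        res = gamma_index(ref, ref * 1.01, spacing=1.0)
        assert res.pass_rate == 100.0

    def test_non_overlapping_grids_rejected(self):
        x1 = np.arange(0, 10.0)
        x2 = np.arange(100, 110.0)
        with pytest.raises(ValueError):
            gamma_index(np.ones(10), np.ones(10), coords=((x1,), (x2,)))

    def test_low_dose_voxels_excluded(self):
        x, ref = self._gauss_profile()
        ev = ref.copy()
        ev[ref < 0.05] = 0.0  # mangle only sub-threshold dose
        res = gamma_index(ref, ev, coords=(x,), threshold_percent=10.0)
        assert res.pass_rate == 100.0
        assert np.isnan(res.gamma_map[ref < 0.1]).all()
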