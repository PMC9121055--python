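"""Plane transport, jaw/MLC chord geometry, attenuation, and Compton."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from linacvsm import transport as T
from linacvsm.transport import (BeamModifier, DegenerateDirectionError,
                                constant_mu, path_length_through_modifier,
                                transport_to_plane)


class TestPlaneTransport:
    def test_zero_distance_is_identity(self):
        assert transport_to_plane(1.0, -2.0, 0.1, 0.05, 0.0) == (1.0, -2.0)

    def test_known_oblique_shift(self):
        x, y = transport_to_plane(0.0, 0.0, 0.1, 0.0, 26.7)
        assert x == pytest.approx(0.1 * 26.7 / np.sqrt(0.99), rel=1e-12)
        assert y == 0.0

    def test_forward_then_backward_is_identity(self, rng):
        x = rng.uniform(-5, 5, 100)
        y = rng.uniform(-5, 5, 100)
        u = rng.uniform(-0.3, 0.3, 100)
        v = rng.uniform(-0.3, 0.3, 100)
        xf, yf = transport_to_plane(x, y, u, v, 70.0)
        xb, yb = transport_to_plane(xf, yf, u, v, -70.0)
        assert np.allclose(xb, x, atol=1e-9)
        assert np.allclose(yb, y, atol=1e-9)

    def test_degenerate_direction_raises(self):
        with pytest.raises(DegenerateDirectionError):
            transport_to_plane(0, 0, 0.8, 0.7, 10.0)


class TestChordGeometry:
    def test_open_aperture_gives_zero(self):
        jaw = BeamModifier("jaw", "x", 0.0, 3.0, (-2.0, 2.0))
        assert path_length_through_modifier(0.5, 0.0, 0.0, 0.0, jaw) == 0.0

    def test_axial_ray_through_full_slab(self):
        jaw = BeamModifier("jaw", "x", 0.0, 3.0, (0.0, 0.0))  # closed
        assert path_length_through_modifier(1.0, 0, 0, 0, jaw) == pytest.approx(3.0)

    def test_oblique_slab_chord_scales_with_inverse_w(self):
        jaw = BeamModifier("jaw", "x", 0.0, 3.0, (0.0, 0.0))
        u = 0.25
        w = np.sqrt(1 - u * u)
        t = path_length_through_modifier(5.0, 0, u, 0, jaw)
        assert t == pytest.approx(3.0 / w)

    def test_ray_crossing_jaw_edge_gets_partial_chord(self):
        # ray starts inside the aperture and dives under the right jaw edge
        jaw = BeamModifier("jaw", "x", 0.0, 4.0, (-1.0, 1.0))
        u = 0.5
        w = np.sqrt(1 - u * u)
        # enters material when x(z) = 1: z* = (1 - 0) * w / u = 2 w / ... in
        # slope terms m = u / w, z* = 1 / m
        m = u / w
        z_star = 1.0 / m
        expect = (4.0 - z_star) / w
        t = path_length_through_modifier(0.0, 0.0, u, 0.0, jaw)
        assert t == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("offset", [7.5, 7.9, 7.99])
    def test_rounded_tip_chord_formula(self, offset):
        """Axial ray at distance d from the tip-circle centre sees the
        circle chord 2*sqrt(rho^2 - d^2) when the slab is thick enough."""
        rho = 8.0
        mlc = BeamModifier("mlc_leaf", "x", 0.0, 6.0, (0.0, np.inf),
                           tip_radius=rho)
        x = offset - rho  # tip circle centre sits at aperture edge - rho
        chord = 2 * np.sqrt(rho**2 - offset**2)
        if chord <= 6.0:
            t = path_length_through_modifier(x, 0.0, 0.0, 0.0, mlc)
            assert t == pytest.approx(chord, rel=1e-12)

    def test_rounded_tip_clips_to_slab_thickness(self):
        mlc = BeamModifier("mlc_leaf", "x", 0.0, 6.0, (0.0, np.inf),
                           tip_radius=8.0)
        # deep inside the leaf body the full slab is traversed
        assert path_length_through_modifier(-3.0, 0, 0, 0, mlc) == pytest.approx(6.0)

    def test_tip_shortens_edge_chord_relative_to_straight_face(self):
        straight = BeamModifier("jaw", "x", 0.0, 6.0, (0.0, np.inf))
        rounded = BeamModifier("mlc_leaf", "x", 0.0, 6.0, (0.0, np.inf),
                               tip_radius=8.0)
        x = -0.2  # just behind the apex
        assert (path_length_through_modifier(x, 0, 0, 0, rounded)
                < path_length_through_modifier(x, 0, 0, 0, straight))

    def test_transmission_monotone_in_path_and_mu(self):
        jaw = BeamModifier("jaw", "x", 0.0, 2.0, (0.0, np.inf))
        ts = [path_length_through_modifier(x, 0, 0, 0, jaw)
              for x in (-0.1, -1.0, -3.0)]
        assert ts == sorted(ts)


class TestTransmission:
    def _photons(self, n, group=1, energy=1.0, x=0.2):
        dt = np.dtype([("type", "i1"), ("energy", "<f4"), ("x", "<f4"),
                       ("y", "<f4"), ("u", "<f4"), ("v", "<f4"),
                       ("group", "i1")])
        p = np.zeros(n, dtype=dt)
        p["type"] = 1
        p["group"] = group
        p["energy"] = energy
        p["x"] = x
        return p

    def test_zero_path_passes_unchanged(self, rng):
        jaw = BeamModifier("jaw", "x", 0.0, 1.0, (-5.0, 5.0))
        p = self._photons(100)
        out, p2, w = T.first_order_transmit(p, [jaw], rng)
        assert np.all(out == T.OUTCOME_PASS)
        assert np.array_equal(p2, p)
        assert np.all(w == 1.0)

    def test_analog_survival_matches_exponential(self, rng):
        """Closed slab with mu*t = 1: survival frequency e^-1."""
        jaw = BeamModifier("jaw", "x", 0.0, 1.0, (0.0, 0.0),
                           mu=constant_mu(1.0))
        n = 100_000
        p = self._photons(n, group=1)  # scattered group: attenuation only
        out, _, _ = T.first_order_transmit(p, [jaw], rng)
        surv = (out == T.OUTCOME_PASS).mean()
        expect = np.exp(-1.0)
        assert abs(surv - expect) <= 4 * np.sqrt(expect * (1 - expect) / n)

    def test_weighted_mode_carries_attenuation_weight(self, rng):
        jaw = BeamModifier("jaw", "x", 0.0, 1.0, (0.0, 0.0),
                           mu=constant_mu(2.0))
        p = self._photons(1000)
        out, _, w = T.first_order_transmit(p, [jaw], rng, mode="weighted")
        assert np.all(out == T.OUTCOME_PASS)
        assert np.allclose(w, np.exp(-2.0))

    def test_primary_photons_compton_scatter_once(self, rng):
        jaw = BeamModifier("jaw", "x", 0.0, 1.0, (0.0, 0.0),
                           mu=constant_mu(3.0))
        p = self._photons(20_000, group=0)
        out, p2, _ = T.first_order_transmit(p, [jaw], rng)
        comp = out == T.OUTCOME_COMPTON
        assert comp.mean() == pytest.approx(1 - np.exp(-3.0), abs=0.01)
        # Compton always lowers the photon energy
        assert np.all(p2["energy"][comp] < 1.0)
        assert np.all(p2["energy"][comp]
                      >= T.compton_scattered_energy(1.0, -1.0) - 1e-6)

    def test_charged_particles_absorbed_on_strike(self, rng):
        jaw = BeamModifier("jaw", "x", 0.0, 1.0, (0.0, np.inf))
        p = self._photons(10, group=2)
        p["type"] = 2
        p["x"] = [-1, -1, -1, -1, -1, 1, 1, 1, 1, 1]
        out, _, _ = T.first_order_transmit(p, [jaw], rng)
        assert np.all(out[:5] == T.OUTCOME_ABSORBED)
        assert np.all(out[5:] == T.OUTCOME_PASS)


class TestCompton:
    def test_backscatter_energy_closed_form(self):
        # E' = E / (1 + 2E/mec2) at 180 degrees: 0.2037 MeV for 1 MeV
        assert T.compton_scattered_energy(1.0, -1.0) == pytest.approx(
            1.0 / (1 + 2 / 0.511), rel=1e-6)
        assert T.compton_scattered_energy(1.0, -1.0) == pytest.approx(0.2037,
                                                                      abs=5e-4)

    def test_forward_scatter_preserves_energy(self):
        assert T.compton_scattered_energy(2.5, 1.0) == 2.5

    def test_klein_nishina_angles_match_numerical_integration(self):
        """Empirical angular distribution vs quadrature of the differential
        cross-section (50 bins, 1e6 samples)."""
        e_mev = 1.0
        n = 1_000_000
        cos = T.sample_klein_nishina_cos(e_mev, n, np.random.default_rng(3))
        edges = np.linspace(-1, 1, 51)
        obs, _ = np.histogram(cos, bins=edges)
        norm = quad(lambda c: T.klein_nishina_pdf(e_mev, c), -1, 1)[0]
        expect = np.array([
            quad(lambda c: T.klein_nishina_pdf(e_mev, c), lo, hi)[0]
            for lo, hi in zip(edges[:-1], edges[1:])
        ]) / norm * n
        _, p = chisquare(obs, expect)
        assert p > 0.05

    def test_klein_nishina_forward_peaking_grows_with_energy(self):
        rng = np.random.default_rng(4)
        lo = T.sample_klein_nishina_cos(0.1, 200_000, rng).mean()
        hi = T.sample_klein_nishina_cos(6.0, 200_000, rng).mean()
        assert hi > lo
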