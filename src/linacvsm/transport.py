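"""Straight-line transport and first-order beam-modifier transmission.

Sampled particles are transported between parallel planes along their
direction cosines.  Jaws and MLC leaves are modelled to first order: the
geometric chord of the straight ray through the modifier body is computed,
and only attenuation (plus at most one Compton interaction for primary
photons, with the scattering angle drawn from the Klein-Nishina differential
cross-section) is applied.  MLC leaf tips are modelled as a single circular
arc tangent to the leaf faces, with no tip angle.

Coordinates: a particle lives at z = 0 of its current plane and travels
toward +z; a modifier occupies the slab ``z_near <= z <= z_far`` downstream.
Aperture edges are physical edge positions at the modifier (cm), defined at
the apex of the rounded tip for MLC leaves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

ELECTRON_REST_MEV = 0.511


class DegenerateDirectionError(ValueError):
    pass


def transport_to_plane(x, y, u, v, dz: float):
    """Shift positions to a plane ``dz`` cm downstream; directions unchanged.

    x += (u/w) dz, y += (v/w) dz with w = sqrt(1 - u^2 - v^2) > 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    s = u * u + v * v
    if np.any(s >= 1.0):
        raise DegenerateDirectionError("w <= 0: particle does not move forward")
    w = np.sqrt(1.0 - s)
    return x + (u / w) * dz, y + (v / w) * dz


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated linear attenuation coefficient mu(E), log-log interpolated."""

    energies_mev: np.ndarray
    mu_per_cm: np.ndarray

    def __call__(self, energy):
        e = np.clip(np.asarray(energy, dtype=np.float64),
                    self.energies_mev[0], self.energies_mev[-1])
        val = np.exp(np.interp(np.log(e), np.log(self.energies_mev),
                               np.log(self.mu_per_cm)))
        return float(val) if val.ndim == 0 else val


#: Approximate tungsten attenuation curve for tests and defaults (cm^-1).
TUNGSTEN_MU = AttenuationTable(
    energies_mev=np.array([0.1, 0.2, 0.5, 1.0, 2.0, 4.0, 6.0, 10.0]),
    mu_per_cm=np.array([85.6, 14.9, 2.41, 1.28, 0.85, 0.75, 0.76, 0.90]),
)


def constant_mu(mu: float) -> AttenuationTable:
    """Energy-independent attenuation (useful for closed-form checks)."""
    return AttenuationTable(np.array([1e-3, 1e3]), np.array([mu, mu]))


@dataclass(frozen=True)
class BeamModifier:
    """A jaw pair or an MLC leaf pair blocking one transverse axis.

    ``aperture = (lo, hi)`` leaves open the strip lo < s < hi of the axis
    coordinate; material extends to infinity on both sides (use -inf/inf for
    a one-sided or absent block, lo == hi for fully closed).  ``tip_radius``
    applies to ``mlc_leaf`` only: each leaf face is a circular arc of that
    radius tangent to the leaf top/bottom faces, apex at the aperture edge.
    """

    kind: str                      # "jaw" | "mlc_leaf"
    axis: str                      # "x" | "y"
    z_near: float                  # cm downstream of the particle plane
    z_far: float
    aperture: tuple[float, float]
    mu: Callable = TUNGSTEN_MU
    tip_radius: float = 8.0        # cm

    def __post_init__(self):
        if self.kind not in ("jaw", "mlc_leaf"):
            raise ValueError(f"unknown modifier kind {self.kind!r}")
        if self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")
        if not self.z_far > self.z_near:
            raise ValueError("slab z-extent must be positive")
        if self.kind == "mlc_leaf":
            if not self.tip_radius > 0:
                raise ValueError("tip radius must be positive")
            if 2 * self.tip_radius < self.z_far - self.z_near:
                raise ValueError("tip radius must be at least half the leaf "
                                 "thickness so the arc spans the slab")


def _interval_len(lo, hi):
    return np.maximum(hi - lo, 0.0)


def _halfplane_z_interval(s0, m, edge, side, z_near, z_far):
    """z-interval where s(z) = s0 + m z is on ``side`` ('le'/'ge') of edge."""
    lo = np.full_like(s0, -np.inf)
    hi = np.full_like(s0, np.inf)
    zc = np.where(m != 0, (edge - s0) / np.where(m == 0, 1.0, m), 0.0)
    if side == "le":
        inside_flat = s0 <= edge
        lo = np.where(m > 0, lo, np.where(m < 0, zc, lo))
        hi = np.where(m > 0, zc, hi)
    else:
        inside_flat = s0 >= edge
        lo = np.where(m < 0, lo, np.where(m > 0, zc, lo))
        hi = np.where(m < 0, zc, hi)
    flat = m == 0
    lo = np.where(flat, np.where(inside_flat, -np.inf, np.inf), lo)
    hi = np.where(flat, np.where(inside_flat, np.inf, -np.inf), hi)
    return np.maximum(lo, z_near), np.minimum(hi, z_far)


def _circle_z_interval(s0, m, center_s, center_z, radius, z_near, z_far):
    """z-interval where (s(z) - cs)^2 + (z - cz)^2 <= rho^2."""
    # (m^2+1) z^2 + 2(m d - cz) z + d^2 + cz^2 - rho^2 <= 0, d = s0 - cs
    d = s0 - center_s
    a = m * m + 1.0
    b = 2.0 * (m * d - center_z)
    c = d * d + center_z * center_z - radius * radius
    disc = b * b - 4.0 * a * c
    has = disc > 0
    sq = np.sqrt(np.where(has, disc, 0.0))
    z1 = (-b - sq) / (2.0 * a)
    z2 = (-b + sq) / (2.0 * a)
    lo = np.where(has, z1, np.inf)
    hi = np.where(has, z2, -np.inf)
    return np.maximum(lo, z_near), np.minimum(hi, z_far)


def _leaf_z_length(s0, m, edge, side, modifier: BeamModifier):
    """Blocked z-measure for one leaf/jaw on one side of the aperture."""
    zn, zf = modifier.z_near, modifier.z_far
    if modifier.kind == "jaw":
        lo, hi = _halfplane_z_interval(s0, m, edge, side, zn, zf)
        return _interval_len(lo, hi)
    rho = modifier.tip_radius
    zm = 0.5 * (zn + zf)
    # material = halfplane beyond the tip-circle centre, union the circle cap
    center = edge - rho if side == "le" else edge + rho
    hp_side = "le" if side == "le" else "ge"
    l1, h1 = _halfplane_z_interval(s0, m, center, hp_side, zn, zf)
    l2, h2 = _circle_z_interval(s0, m, center, zm, rho, zn, zf)
    len1 = _interval_len(l1, h1)
    len2 = _interval_len(l2, h2)
    overlap = _interval_len(np.maximum(l1, l2), np.minimum(h1, h2))
    return len1 + len2 - overlap


def path_length_through_modifier(x, y, u, v, modifier: BeamModifier):
    """Geometric chord length (cm) of the straight ray inside the modifier.

    Zero for rays fully inside the aperture.  Works on scalars or arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    s2 = u * u + v * v
    if np.any(s2 >= 1.0):
        raise DegenerateDirectionError("w <= 0")
    w = np.sqrt(1.0 - s2)
    s0 = x if modifier.axis == "x" else y
    comp = u if modifier.axis == "x" else v
    m = comp / w  # d(axis coordinate)/dz
    lo_edge, hi_edge = modifier.aperture
    dz = np.zeros_like(np.broadcast_arrays(s0, m)[0], dtype=np.float64)
    s0b, mb = np.broadcast_arrays(s0, m)
    s0b = s0b.astype(np.float64)
    mb = mb.astype(np.float64)
    if np.isfinite(lo_edge):
        dz = dz + _leaf_z_length(s0b, mb, lo_edge, "le", modifier)
    if np.isfinite(hi_edge):
        dz = dz + _leaf_z_length(s0b, mb, hi_edge, "ge", modifier)
    t = dz / w
    return float(t) if t.ndim == 0 else t


# -- Compton / Klein-Nishina ------------------------------------------------

def compton_scattered_energy(energy_mev, cos_theta):
    """Photon energy after Compton scattering through angle theta."""
    e = np.asarray(energy_mev, dtype=np.float64)
    k = e / ELECTRON_REST_MEV
    out = e / (1.0 + k * (1.0 - np.asarray(cos_theta, dtype=np.float64)))
    return float(out) if out.ndim == 0 else out


def klein_nishina_pdf(energy_mev: float, cos_theta) -> np.ndarray:
    """Unnormalised Klein-Nishina angular density in cos(theta)."""
    c = np.asarray(cos_theta, dtype=np.float64)
    k = energy_mev / ELECTRON_REST_MEV
    r = 1.0 / (1.0 + k * (1.0 - c))  # E'/E
    return r * r * (r + 1.0 / r - (1.0 - c * c))


def sample_klein_nishina_cos(energy_mev, n: int | None, rng) -> np.ndarray:
    """Sample cos(theta) from the Klein-Nishina distribution by rejection.

    ``energy_mev`` may be a scalar (with ``n`` samples) or an array of
    per-photon energies (``n`` ignored).
    """
    e = np.asarray(energy_mev, dtype=np.float64)
    if e.ndim == 0:
        e = np.full(n, float(e))
    m = len(e)
    out = np.empty(m)
    todo = np.arange(m)
    # the unnormalised density attains its global maximum 2 at cos(theta)=1
    # for every energy, so a flat envelope of height 2 is exact
    while len(todo):
        c = rng.uniform(-1.0, 1.0, len(todo))
        et = e[todo]
        k = et / ELECTRON_REST_MEV
        r = 1.0 / (1.0 + k * (1.0 - c))
        f = r * r * (r + 1.0 / r - (1.0 - c * c))
        accept = rng.random(len(todo)) * 2.0 <= f
        out[todo[accept]] = c[accept]
        todo = todo[~accept]
    return out


def _rotate_direction(u, v, w, cos_theta, phi, rng=None):
    """Rotate unit vectors (u, v, w) by polar angle theta, azimuth phi."""
    d = np.stack([np.asarray(u, float), np.asarray(v, float),
                  np.asarray(w, float)], axis=-1)
    # orthonormal frame transverse to d
    ref = np.zeros_like(d)
    small = np.abs(d[..., 2]) < 0.99
    ref[..., 2] = 1.0
    ref[~small] = [1.0, 0.0, 0.0]
    e1 = np.cross(ref, d)
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = np.cross(d, e1)
    st = np.sqrt(np.maximum(1.0 - np.asarray(cos_theta) ** 2, 0.0))
    newd = (np.asarray(cos_theta)[..., None] * d
            + (st * np.cos(phi))[..., None] * e1
            + (st * np.sin(phi))[..., None] * e2)
    newd /= np.linalg.norm(newd, axis=-1, keepdims=True)
    return newd[..., 0], newd[..., 1], newd[..., 2]


OUTCOME_PASS = 0
OUTCOME_COMPTON = 1
OUTCOME_ABSORBED = 2


def first_order_transmit(particles: np.ndarray, modifiers: Sequence[BeamModifier],
                         rng, mode: str = "analog"):
    """First-order transmission of a sampled batch through beam modifiers.

    Scattered-group photons and (in weighted mode) all photons undergo pure
    attenuation over the summed optical depth tau = sum_i mu_i(E) t_i.
    In analog mode primary-group photons that interact undergo exactly one
    Compton scatter: the new energy and polar angle follow Klein-Nishina
    kinematics with uniform azimuth.  Charged particles are absorbed if they
    geometrically strike any modifier.

    Returns ``(outcomes, particles, weights)``: an int array of
    OUTCOME_{PASS,COMPTON,ABSORBED} per particle, the (possibly updated)
    particle batch, and per-particle weights (1 except in weighted mode).
    """
    if mode not in ("analog", "weighted"):
        raise ValueError(f"unknown transmission mode {mode!r}")
    p = particles.copy()
    n = len(p)
    e = np.asarray(p["energy"], dtype=np.float64)
    u = np.asarray(p["u"], dtype=np.float64)
    v = np.asarray(p["v"], dtype=np.float64)
    tau = np.zeros(n)
    t_total = np.zeros(n)
    for mod in modifiers:
        t = path_length_through_modifier(p["x"], p["y"], u, v, mod)
        t_total += t
        tau += mod.mu(e) * t

    outcomes = np.full(n, OUTCOME_PASS, dtype=np.int8)
    weights = np.ones(n)
    is_photon = p["type"] == 1
    is_primary = is_photon & (p["group"] == 0) if "group" in (p.dtype.names or ()) \
        else is_photon
    surv = np.exp(-tau)

    if mode == "weighted":
        weights[is_photon] = surv[is_photon]
    else:
        xi = rng.random(n)
        interact = is_photon & (xi >= surv)
        # scattered-group photons: attenuation only -> absorbed
        outcomes[interact & ~is_primary] = OUTCOME_ABSORBED
        # primary photons: exactly one Compton interaction
        comp = interact & is_primary
        if comp.any():
            idx = np.flatnonzero(comp)
            cos_t = sample_klein_nishina_cos(e[idx], None, rng)
            e_new = compton_scattered_energy(e[idx], cos_t)
            w_old = np.sqrt(np.maximum(1.0 - u[idx] ** 2 - v[idx] ** 2, 1e-12))
            phi = rng.uniform(0.0, 2.0 * np.pi, len(idx))
            nu, nv, nw = _rotate_direction(u[idx], v[idx], w_old, cos_t, phi)
            p["energy"][idx] = e_new
            p["u"][idx] = nu
            p["v"][idx] = nv
            outcomes[idx] = OUTCOME_COMPTON
    # charged contaminants: absorbed on any geometric strike
    charged = ~is_photon
    outcomes[charged & (t_total > 0)] = OUTCOME_ABSORBED
    return outcomes, p, weights
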