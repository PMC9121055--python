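"""Synthetic linac phase spaces with a known parametric ground truth.

The generator emulates the statistical structure of a treatment-head phase
space scored 26.7 cm from the focal spot: a narrow Gaussian focal-spot primary
photon source at Z = 0, a spatially broad scattered-photon source at an
intermediate plane, sub-percent electron/positron contamination, radially
softening energy spectra, and forward-peaked direction cosines correlated
with position.  Because the truth parameters are known, downstream stages
(classification, model building, sampling, validation) can assert parameter
recovery instead of relying on vendor data.

Emission model per particle: an origin is drawn on the source plane
(focal spot for primaries, a broad Gaussian at ``scatter_origin_z`` for
scatter and charged particles), an endpoint is drawn inside the field window
at the scoring plane, the direction is the normalised origin-to-endpoint
vector plus a small Gaussian jitter on (u, v), and the kinetic energy is drawn
from a radially softening spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy.integrate import quad
from scipy.special import ndtr, erf

from . import phsp_io
from .phsp_io import Species


@dataclass
class SourceTruthConfig:
    """Ground-truth parameters of the synthetic treatment head.

    Defaults describe a 6 MV-class beam: a ~1 mm Gaussian focal spot, 84% of
    photons primary, 0.5% charged contamination, and a bremsstrahlung-like
    spectrum with mean energy decreasing with off-axis distance.
    """

    sigma_x: float = 0.10          # focal-spot Gaussian width, cm
    sigma_y: float = 0.10          # cm
    primary_photon_fraction: float = 0.84
    scatter_origin_sigma: float = 1.5   # cm, width of the scatter origin plane
    scatter_origin_z: float = 10.0      # cm from the focal spot
    e_max: float = 6.0                  # MeV, spectrum support (0, e_max]
    primary_e_scale: float = 1.2        # MeV, E*exp(-E/scale) characteristic energy
    scatter_e_scale: float = 0.5        # MeV, exponential scatter spectrum
    charged_e_scale: float = 0.8        # MeV, exponential charged spectrum
    radial_softening: float = 0.3       # fractional softening at the field edge
    charged_fraction: float = 0.005     # electrons+positrons among all particles
    positron_share: float = 0.1         # positrons among charged particles
    primary_jitter: float = 2e-4        # Gaussian sigma added to (u, v), primaries
    scatter_jitter: float = 0.05        # same, scatter and charged
    endpoint_xy_corr: float = 0.0       # Gaussian-copula correlation of (x, y)
    field_half_width: float = 5.5       # cm at the scoring plane
    scoring_plane_z: float = 26.7       # cm from the focal spot
    seed: int | None = None

    def __post_init__(self):
        for name in ("primary_photon_fraction", "charged_fraction",
                     "positron_share"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for name in ("sigma_x", "sigma_y", "scatter_origin_sigma", "e_max",
                     "field_half_width", "scoring_plane_z"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.scatter_origin_z < self.scoring_plane_z:
            raise ValueError("scatter_origin_z must lie between the focal spot "
                             "and the scoring plane")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SourceTruthConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for key, val in mapping.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = int(val) if key == "seed" else float(val)
        return cls(**kwargs)


def _softening(r: np.ndarray, cfg: SourceTruthConfig) -> np.ndarray:
    f = 1.0 - cfg.radial_softening * np.minimum(r, cfg.field_half_width) / cfg.field_half_width
    return np.clip(f, 0.3, None)


def generate_synthetic_phsp(
    config: SourceTruthConfig, n: int, seed: int | None = None
) -> np.ndarray:
    """Generate ``n`` particles as a structured array in the phsp layout.

    Reproducible: the same (config, seed) pair yields identical output.
    ``seed`` overrides ``config.seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    cfg = config
    F = cfg.field_half_width
    Z = cfg.scoring_plane_z

    u_species = rng.random(n)
    u_split = rng.random(n)
    is_charged = u_species < cfg.charged_fraction
    is_positron = is_charged & (u_split < cfg.positron_share)
    is_primary = ~is_charged & (u_split < cfg.primary_photon_fraction)

    # endpoints at the scoring plane, uniform over the field window,
    # optionally correlated through a Gaussian copula
    rho = cfg.endpoint_xy_corr
    if rho == 0.0:
        xe = rng.uniform(-F, F, n)
        ye = rng.uniform(-F, F, n)
    else:
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        xe = (2.0 * ndtr(z1) - 1.0) * F
        ye = (2.0 * ndtr(z2) - 1.0) * F

    # origins: focal spot for primaries, broad plane for scatter and charged
    x0 = np.where(is_primary, rng.normal(0.0, cfg.sigma_x, n),
                  rng.normal(0.0, cfg.scatter_origin_sigma, n))
    y0 = np.where(is_primary, rng.normal(0.0, cfg.sigma_y, n),
                  rng.normal(0.0, cfg.scatter_origin_sigma, n))
    z0 = np.where(is_primary, 0.0, cfg.scatter_origin_z)

    dx, dy, dz = xe - x0, ye - y0, Z - z0
    norm = np.sqrt(dx * dx + dy * dy + dz * dz)
    u = dx / norm
    v = dy / norm

    jitter = np.where(is_primary, cfg.primary_jitter, cfg.scatter_jitter)
    u = u + rng.standard_normal(n) * jitter
    v = v + rng.standard_normal(n) * jitter
    bad = u * u + v * v >= 1.0 - 1e-9
    while bad.any():  # redraw jitter for (vanishingly rare) degenerate rays
        k = int(bad.sum())
        u[bad] = (dx / norm)[bad] + rng.standard_normal(k) * jitter[bad]
        v[bad] = (dy / norm)[bad] + rng.standard_normal(k) * jitter[bad]
        bad = u * u + v * v >= 1.0 - 1e-9

    r = np.hypot(xe, ye)
    soft = _softening(r, cfg)
    energy = np.empty(n)
    for mask, draw in (
        (is_primary, lambda m, s: rng.gamma(2.0, s * cfg.primary_e_scale)),
        (~is_charged & ~is_primary, lambda m, s: rng.exponential(s * cfg.scatter_e_scale)),
        (is_charged, lambda m, s: rng.exponential(s * cfg.charged_e_scale)),
    ):
        if mask.any():
            s_m = soft[mask]
            # truncation by redraw, keeping each particle's radial softening
            e = draw(int(mask.sum()), s_m)
            out = (e > cfg.e_max) | (e <= 0)
            while out.any():
                e[out] = draw(int(out.sum()), s_m[out])
                out = (e > cfg.e_max) | (e <= 0)
            energy[mask] = e
    energy = np.maximum(energy, 1e-6)

    type_code = np.ones(n, dtype=np.int8)
    type_code[is_charged] = int(Species.ELECTRON)
    type_code[is_positron] = int(Species.POSITRON)

    out = np.empty(n, dtype=phsp_io.layout_dtype(phsp_io.LAYOUT_BASIC))
    out["type"] = type_code
    out["energy"] = energy
    out["x"] = xe
    out["y"] = ye
    out["u"] = u
    out["v"] = v
    return out


def write_synthetic_phsp(config: SourceTruthConfig, n: int, out_path,
                         seed: int | None = None,
                         chunk_size: int = 2_000_000) -> phsp_io.PhspHeader:
    """Generate and write a phase-space pair, chunked to bound memory."""
    if seed is None:
        seed = config.seed
    # one generator stream across chunks keeps the file identical for a seed
    rng_seed = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)

    def chunks():
        remaining = n
        sub = 0
        while remaining > 0:
            k = min(chunk_size, remaining)
            yield generate_synthetic_phsp(config, k, seed=int(rng_seed) + sub)
            remaining -= k
            sub += 1

    meta = {"GENERATOR": "linacvsm.synthetic", "SEED": str(seed)}
    return phsp_io.write_phsp(chunks(), out_path,
                              scoring_plane_z=config.scoring_plane_z,
                              extra_meta=meta)


@dataclass(frozen=True)
class TruthExpectations:
    """Analytic values the classifier should recover on synthetic data."""

    sigma_x: float
    sigma_y: float
    primary_in_window: float       # P(primary photon classified primary)
    scatter_in_window: float       # P(scatter photon classified primary)
    classified_primary_fraction: float


def _axis_window_prob_scatter(lo: float, hi: float, cfg: SourceTruthConfig) -> float:
    """P(reverse-transported scatter origin in [lo, hi]) on one axis.

    For an unjittered scatter ray the reverse-transported origin is exactly
    x0_rev = (1 - a) * xe + a * xs with a = Z / (Z - z_s), xe uniform over the
    field window and xs Gaussian.  Direction jitter adds ~Z*jitter of Gaussian
    blur (small-angle approximation).  Computed by quadrature over xe.
    """
    Z, zs, F = cfg.scoring_plane_z, cfg.scatter_origin_z, cfg.field_half_width
    a = Z / (Z - zs)
    b = 1.0 - a
    s_eff = float(np.hypot(a * cfg.scatter_origin_sigma, Z * cfg.scatter_jitter))

    def integrand(xe):
        return ndtr((hi - b * xe) / s_eff) - ndtr((lo - b * xe) / s_eff)

    val, _ = quad(integrand, -F, F, limit=200)
    return val / (2.0 * F)


def truth_expectations(config: SourceTruthConfig, fit=None) -> TruthExpectations:
    """Expected classifier outputs for a synthetic configuration.

    If ``fit`` (a GaussianFocalFit) is given, window probabilities are
    evaluated for that fitted window; otherwise the ideal n_sigma=3 window
    around the true (jitter-blurred) focal profile is assumed.
    """
    cfg = config
    Z = cfg.scoring_plane_z
    blur = Z * cfg.primary_jitter
    sig_x = float(np.hypot(cfg.sigma_x, blur))
    sig_y = float(np.hypot(cfg.sigma_y, blur))

    if fit is None:
        k = 3.0
        p_axis_x = float(erf(k / np.sqrt(2.0)))
        p_axis_y = p_axis_x
        win_x = (-k * sig_x, k * sig_x)
        win_y = (-k * sig_y, k * sig_y)
    else:
        win_x = (fit.mu_x - fit.n_sigma * fit.sigma_x,
                 fit.mu_x + fit.n_sigma * fit.sigma_x)
        win_y = (fit.mu_y - fit.n_sigma * fit.sigma_y,
                 fit.mu_y + fit.n_sigma * fit.sigma_y)
        p_axis_x = float(ndtr(win_x[1] / sig_x) - ndtr(win_x[0] / sig_x))
        p_axis_y = float(ndtr(win_y[1] / sig_y) - ndtr(win_y[0] / sig_y))

    p_primary_in = p_axis_x * p_axis_y
    p_scatter_in = (_axis_window_prob_scatter(*win_x, cfg)
                    * _axis_window_prob_scatter(*win_y, cfg))
    f_p = cfg.primary_photon_fraction
    classified = f_p * p_primary_in + (1.0 - f_p) * p_scatter_in
    return TruthExpectations(sig_x, sig_y, p_primary_in, p_scatter_in, classified)
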