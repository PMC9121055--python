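"""Dual-source photon classification.

Photons at the scoring plane are reverse-transported along their straight-line
direction to the focal-spot plane (Z = 0).  The focal-spot footprint of
bremsstrahlung ("primary") photons is a narrow Gaussian; photons scattered in
the flattening filter or collimators produce a broad pedestal.  Gaussian fits
to the central X and Y profiles define a classification window
mu +/- n_sigma * sigma (default 3 sigma) per axis: photons whose focal-plane
position falls inside the window on both axes are primary, all others
scattered.  Electrons and positrons never enter this classifier; they are
pooled as scatter upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .phsp_io import PhaseSpaceRecord, Species

DEFAULT_FIT_WINDOW = 0.5  # cm; isolates the focal peak from the scatter pedestal
DEFAULT_FIT_BIN = 0.02  # cm


class DegenerateDirectionError(ValueError):
    """u^2 + v^2 >= 1: the longitudinal direction cosine cannot be recovered."""


class FocalFitError(RuntimeError):
    """Gaussian fit failed; carries the axis histogram for inspection."""

    def __init__(self, axis: str, centers: np.ndarray, counts: np.ndarray):
        self.axis = axis
        self.centers = centers
        self.counts = counts
        super().__init__(f"Gaussian fit to the {axis} focal profile did not converge")


@dataclass(frozen=True)
class GaussianFocalFit:
    """Fitted focal-spot profile and the derived classification window."""

    mu_x: float
    sigma_x: float
    mu_y: float
    sigma_y: float
    n_sigma: float = 3.0
    primary_fraction: float | None = None

    def __post_init__(self):
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise ValueError("fitted sigmas must be positive")

    def with_primary_fraction(self, fraction: float) -> "GaussianFocalFit":
        return replace(self, primary_fraction=fraction)


def reverse_transport_to_focal(x, y, u, v, scoring_plane_z: float = 26.7):
    """Project scoring-plane positions back to the focal plane (Z = 0).

    x0 = x - (u / w) * z with w = sqrt(1 - u^2 - v^2).  Works on scalars or
    arrays; raises :class:`DegenerateDirectionError` if any ray has
    u^2 + v^2 >= 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    s = u * u + v * v
    if np.any(s >= 1.0):
        raise DegenerateDirectionError("u^2 + v^2 >= 1 for at least one photon")
    w = np.sqrt(1.0 - s)
    x0 = x - (u / w) * scoring_plane_z
    y0 = y - (v / w) * scoring_plane_z
    if x0.ndim == 0:
        return float(x0), float(y0)
    return x0, y0


def _gauss(t, amp, mu, sigma):
    return amp * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def _fit_axis_hist(centers: np.ndarray, counts: np.ndarray, axis: str,
                   bin_width: float, baseline: bool) -> tuple[float, float]:
    total = counts.sum()
    if total == 0:
        raise FocalFitError(axis, centers, counts)
    mu0 = float(np.average(centers, weights=counts))
    var0 = float(np.average((centers - mu0) ** 2, weights=counts))
    sigma0 = max(np.sqrt(var0), bin_width)
    amp0 = float(counts.max())
    try:
        if baseline:
            def model(t, amp, mu, sigma, c):
                return _gauss(t, amp, mu, sigma) + c

            popt, _ = curve_fit(model, centers, counts,
                                p0=(amp0, mu0, sigma0, 0.0), maxfev=20000)
        else:
            popt, _ = curve_fit(_gauss, centers, counts,
                                p0=(amp0, mu0, sigma0), maxfev=20000)
    except RuntimeError as exc:
        raise FocalFitError(axis, centers, counts) from exc
    mu, sigma = float(popt[1]), abs(float(popt[2]))
    # Sheppard correction: binned least squares inflates sigma^2 by h^2/12
    sigma = float(np.sqrt(max(sigma**2 - bin_width**2 / 12.0, (bin_width / 4) ** 2)))
    return mu, sigma


def fit_focal_gaussian(
    x0,
    y0,
    bin_width: float = DEFAULT_FIT_BIN,
    fit_window: float = DEFAULT_FIT_WINDOW,
    n_sigma: float = 3.0,
    baseline: bool = False,
) -> GaussianFocalFit:
    """Least-squares Gaussian fit to the focal-plane X and Y profiles.

    Each axis is histogrammed with ``bin_width`` over ``|t| <= fit_window``
    (the central peak only) and fitted with A*exp(-(t-mu)^2 / 2 sigma^2),
    optionally plus a constant baseline.
    """
    edges = _fit_edges(bin_width, fit_window)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fits = []
    for axis, vals in (("x", np.asarray(x0)), ("y", np.asarray(y0))):
        counts, _ = np.histogram(vals, bins=edges)
        fits.append(_fit_axis_hist(centers, counts.astype(np.float64),
                                   axis, bin_width, baseline))
    (mu_x, sig_x), (mu_y, sig_y) = fits
    return GaussianFocalFit(mu_x, sig_x, mu_y, sig_y, n_sigma=n_sigma)


def fit_focal_gaussian_from_hists(
    counts_x: np.ndarray,
    counts_y: np.ndarray,
    bin_width: float = DEFAULT_FIT_BIN,
    fit_window: float = DEFAULT_FIT_WINDOW,
    n_sigma: float = 3.0,
    baseline: bool = False,
) -> GaussianFocalFit:
    """Fit from pre-accumulated axis histograms (streaming builds)."""
    edges = _fit_edges(bin_width, fit_window)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu_x, sig_x = _fit_axis_hist(centers, np.asarray(counts_x, float), "x",
                                 bin_width, baseline)
    mu_y, sig_y = _fit_axis_hist(centers, np.asarray(counts_y, float), "y",
                                 bin_width, baseline)
    return GaussianFocalFit(mu_x, sig_x, mu_y, sig_y, n_sigma=n_sigma)


def _fit_edges(bin_width: float, fit_window: float) -> np.ndarray:
    n = int(round(2 * fit_window / bin_width))
    return np.linspace(-fit_window, fit_window, n + 1)


def classification_mask(x, y, u, v, fit: GaussianFocalFit,
                        scoring_plane_z: float = 26.7) -> np.ndarray:
    """Boolean mask: True where the photon is primary (inside the window)."""
    x0, y0 = reverse_transport_to_focal(x, y, u, v, scoring_plane_z)
    x0 = np.asarray(x0)
    y0 = np.asarray(y0)
    return (np.abs(x0 - fit.mu_x) <= fit.n_sigma * fit.sigma_x) & (
        np.abs(y0 - fit.mu_y) <= fit.n_sigma * fit.sigma_y
    )


def classify_photon(record: PhaseSpaceRecord, fit: GaussianFocalFit,
                    scoring_plane_z: float = 26.7) -> str:
    """Classify a single photon record as ``"primary"`` or ``"scattered"``."""
    if record.species != Species.PHOTON:
        raise TypeError(
            f"classify_photon expects a photon, got {record.species.name}"
        )
    mask = classification_mask(record.x, record.y, record.u, record.v, fit,
                               scoring_plane_z)
    return "primary" if bool(mask) else "scattered"


def primary_fraction(records, fit: GaussianFocalFit,
                     scoring_plane_z: float = 26.7) -> float:
    """Streaming primary/(primary+scattered) fraction over photon records.

    ``records`` may be a structured array (photons are selected by type code),
    an iterable of structured chunks, or an iterable of PhaseSpaceRecord.
    """
    n_primary = 0
    n_total = 0
    if isinstance(records, np.ndarray):
        records = (records,)
    for item in records:
        if isinstance(item, PhaseSpaceRecord):
            if item.species != Species.PHOTON:
                continue
            n_total += 1
            if classify_photon(item, fit, scoring_plane_z) == "primary":
                n_primary += 1
        else:
            chunk = item
            ph = chunk[chunk["type"] == int(Species.PHOTON)]
            if len(ph) == 0:
                continue
            mask = classification_mask(ph["x"], ph["y"], ph["u"], ph["v"],
                                       fit, scoring_plane_z)
            n_total += len(ph)
            n_primary += int(mask.sum())
    if n_total == 0:
        raise ValueError("no photons in input stream")
    return n_primary / n_total
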