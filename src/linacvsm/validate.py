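"""Statistical comparison of a virtual source model with its phase space.

Two-histogram chi-square tests (for unequal totals), central-range truncation
with the retained probability fraction, an end-to-end model-vs-phase-space
validation report, and a gamma-index dose comparator.

The chi-square statistic for two histograms with counts n1i, n2i and totals
N1, N2 is

    X^2 = sum_i (N2 n1i - N1 n2i)^2 / (N1 N2 (n1i + n2i))

over bins with n1i + n2i > 0, asymptotically chi-square with
(number of non-empty bins - 1) degrees of freedom when both histograms are
drawn from the same distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2 as chi2_dist

from . import phsp_io
from .model import VsmModel
from .sampler import sample_array
from .transport import transport_to_plane

#: default central truncation ranges, overridable per call:
#: positions at the scoring plane keep full support, downstream planes keep
#: +/-18.5 cm; direction cosines keep +/-0.19; energy keeps
#: (0.1, e_max - 0.3) MeV.
DEFAULT_TRUNCATION = {
    "pos_plane": (-5.5, 5.5),
    "pos_downstream": (-18.5, 18.5),
    "dir": (-0.19, 0.19),
    "energy_margin": (0.1, 0.3),
}


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float
    n_bins_used: int
    truncation_range: tuple[float, float] | None = None
    fraction_retained: float | None = None


def chi2_two_histograms(h1, h2, edges1=None, edges2=None) -> ChiSquareResult:
    """Two-histogram chi-square comparison on identical binning."""
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ValueError("histograms must share their binning")
    if edges1 is not None and edges2 is not None and not np.allclose(edges1, edges2):
        raise ValueError("histogram bin edges differ")
    n1, n2 = h1.sum(), h2.sum()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both histograms must have positive totals")
    used = (h1 + h2) > 0
    k = int(used.sum())
    num = (n2 * h1[used] - n1 * h2[used]) ** 2
    den = n1 * n2 * (h1[used] + h2[used])
    statistic = float(np.sum(num / den))
    dof = max(k - 1, 1)
    p = float(chi2_dist.sf(statistic, dof))
    return ChiSquareResult(statistic, dof, p, k)


def fraction_retained(counts, edges, truncation_range) -> float:
    """Probability mass of a histogram inside a range (partial bins linear)."""
    counts = np.asarray(counts, dtype=np.float64)
    edges = np.asarray(edges, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    lo, hi = truncation_range
    left = np.clip(edges[:-1], lo, hi)
    right = np.clip(edges[1:], lo, hi)
    overlap = (right - left) / np.diff(edges)
    return float(np.sum(counts * overlap) / total)


def _truncated_chi2(h1, h2, edges, rng) -> ChiSquareResult:
    lo, hi = rng
    centers = 0.5 * (edges[:-1] + edges[1:])
    sel = (centers > lo) & (centers < hi)
    res = chi2_two_histograms(h1[sel], h2[sel])
    frac = fraction_retained(h1, edges, rng)
    return ChiSquareResult(res.statistic, res.dof, res.p_value, res.n_bins_used,
                           truncation_range=(lo, hi), fraction_retained=frac)


@dataclass
class ValidationReport:
    """Full and truncated chi-square results per particle parameter."""

    full: dict = field(default_factory=dict)
    truncated: dict = field(default_factory=dict)
    n_samples: int = 0
    n_reference: int = 0
    planes: tuple = ()

    def all_truncated_pass(self, alpha: float = 0.05) -> bool:
        return all(r.p_value > alpha for r in self.truncated.values())

    def failures(self, alpha: float = 0.05) -> list[str]:
        return [k for k, r in self.truncated.items() if r.p_value <= alpha]


def _histograms_for(arr, planes, z, e_max, pos_bin_plane=0.1,
                    pos_bin_down=0.5, dir_bin=0.005, e_bin=0.02):
    """Global x/y histograms per transport plane plus u, v, E histograms."""
    x = np.asarray(arr["x"], dtype=np.float64)
    y = np.asarray(arr["y"], dtype=np.float64)
    u = np.asarray(arr["u"], dtype=np.float64)
    v = np.asarray(arr["v"], dtype=np.float64)
    e = np.asarray(arr["energy"], dtype=np.float64)
    out = {}
    for dz in planes:
        if dz == 0:
            xt, yt = x, y
            edges = np.arange(-5.5, 5.5 + pos_bin_plane / 2, pos_bin_plane)
        else:
            xt, yt = transport_to_plane(x, y, u, v, dz)
            edges = np.arange(-50.0, 50.0 + pos_bin_down / 2, pos_bin_down)
        out[f"x@{dz:g}cm"] = (np.histogram(xt, bins=edges)[0], edges)
        out[f"y@{dz:g}cm"] = (np.histogram(yt, bins=edges)[0], edges)
    dir_edges = np.arange(-1.0, 1.0 + dir_bin / 2, dir_bin)
    out["u"] = (np.histogram(u, bins=dir_edges)[0], dir_edges)
    out["v"] = (np.histogram(v, bins=dir_edges)[0], dir_edges)
    e_edges = np.arange(0.0, e_max + e_bin / 2, e_bin)
    out["E"] = (np.histogram(e, bins=e_edges)[0], e_edges)
    return out


def validate_model(
    model: VsmModel,
    phsp,
    n_samples: int = 1_000_000,
    planes=(0, 70),
    seed: int = 0,
    truncation: dict | None = None,
) -> ValidationReport:
    """Compare model-sampled particles with the source phase space.

    Samples ``n_samples`` particles, transports both populations to each
    plane (cm downstream of the scoring plane), and compares global x, y
    histograms per plane plus single global u, v and kinetic-energy
    histograms, with and without central truncation.
    """
    trunc = dict(DEFAULT_TRUNCATION)
    trunc.update(truncation or {})
    if isinstance(phsp, np.ndarray):
        ref = phsp
    else:
        ref = phsp_io.read_phsp_array(phsp)
    samples = sample_array(model, n_samples, seed)
    z = model.scoring_plane_z
    h_ref = _histograms_for(ref, planes, z, model.e_max)
    h_vsm = _histograms_for(samples, planes, z, model.e_max)

    report = ValidationReport(n_samples=len(samples), n_reference=len(ref),
                              planes=tuple(planes))
    e_lo, e_hi_margin = trunc["energy_margin"]
    for key in h_ref:
        c1, edges = h_ref[key]
        c2, _ = h_vsm[key]
        report.full[key] = chi2_two_histograms(c1, c2)
        if key.startswith(("x@", "y@")):
            rng = trunc["pos_plane"] if key.endswith("@0cm") else trunc["pos_downstream"]
        elif key in ("u", "v"):
            rng = trunc["dir"]
        else:
            rng = (e_lo, model.e_max - e_hi_margin)
        report.truncated[key] = _truncated_chi2(c1, c2, edges, rng)
    return report


def shuffled_energy_model(model: VsmModel, shift: int = 1) -> VsmModel:
    """Negative control: cyclically permute the radial energy tables.

    Radial softening makes the per-ring spectra differ, so a model whose
    E|R tables are scrambled produces a visibly wrong energy distribution
    while positions and directions stay intact.
    """
    import copy

    corrupted = copy.copy(model)
    corrupted.tables = dict(model.tables)
    for g in ("primary", "scattered", "charged"):
        key = (g, "er")
        corrupted.tables[key] = np.roll(model.tables[key], shift, axis=0)
    return corrupted


# -- gamma index ------------------------------------------------------------

@dataclass
class GammaResult:
    gamma_map: np.ndarray
    pass_rate: float              # % of evaluated voxels with gamma <= 1
    dose_diff_criterion: float    # %
    dta_criterion: float          # mm
    low_dose_threshold: float     # % of the normalisation dose
    n_evaluated: int = 0


def gamma_index(
    ref_dose: np.ndarray,
    eval_dose: np.ndarray,
    coords: tuple | None = None,
    spacing: tuple | float | None = None,
    dd_percent: float = 3.0,
    dta_mm: float = 3.0,
    threshold_percent: float = 10.0,
    search_factor: float = 3.0,
) -> GammaResult:
    """Global-normalisation gamma comparison of two dose grids (1-3 D).

    For each reference voxel above ``threshold_percent`` of the reference
    maximum, gamma is the minimum over evaluated points within
    ``search_factor * dta_mm`` of sqrt((dD/dd)^2 + (dr/dta)^2), with dD
    normalised to the reference maximum (global criterion).  ``coords`` gives
    per-axis coordinate vectors in mm; alternatively ``spacing`` (mm) builds
    them from voxel indices.  Voxels below threshold carry gamma = NaN.
    """
    ref = np.asarray(ref_dose, dtype=np.float64)
    ev = np.asarray(eval_dose, dtype=np.float64)
    if ref.ndim != ev.ndim:
        raise ValueError("dose grids must share dimensionality")
    if coords is None:
        if spacing is None:
            spacing = 1.0
        if np.isscalar(spacing):
            spacing = (float(spacing),) * ref.ndim
        coords_ref = tuple(np.arange(s) * sp for s, sp in zip(ref.shape, spacing))
        coords_ev = tuple(np.arange(s) * sp for s, sp in zip(ev.shape, spacing))
    else:
        if len(coords) == 2 and isinstance(coords[0], (tuple, list)):
            coords_ref, coords_ev = coords
        else:
            coords_ref = coords_ev = tuple(np.asarray(c, float) for c in coords)
    for axis in range(ref.ndim):
        if (coords_ev[axis][-1] < coords_ref[axis][0]
                or coords_ev[axis][0] > coords_ref[axis][-1]):
            raise ValueError("dose grids do not overlap")

    d_max = ref.max()
    if d_max <= 0:
        raise ValueError("reference dose is non-positive everywhere")
    dd_abs = dd_percent / 100.0 * d_max
    thresh = threshold_percent / 100.0 * d_max

    mesh_ev = np.meshgrid(*coords_ev, indexing="ij")
    pts_ev = np.stack([m.ravel() for m in mesh_ev], axis=-1)
    dose_ev = ev.ravel()
    tree = cKDTree(pts_ev)

    mesh_ref = np.meshgrid(*coords_ref, indexing="ij")
    pts_ref = np.stack([m.ravel() for m in mesh_ref], axis=-1)
    dose_ref = ref.ravel()
    gamma = np.full(dose_ref.shape, np.nan)
    radius = search_factor * dta_mm
    evaluate = dose_ref >= thresh
    for i in np.flatnonzero(evaluate):
        nb = tree.query_ball_point(pts_ref[i], radius)
        if not nb:
            gamma[i] = np.inf
            continue
        nb = np.asarray(nb)
        dr2 = np.sum((pts_ev[nb] - pts_ref[i]) ** 2, axis=-1)
        dd2 = (dose_ev[nb] - dose_ref[i]) ** 2
        gamma[i] = np.sqrt(np.min(dd2 / dd_abs**2 + dr2 / dta_mm**2))
    n_eval = int(evaluate.sum())
    pass_rate = 100.0 * float(np.sum(gamma[evaluate] <= 1.0)) / max(n_eval, 1)
    return GammaResult(gamma.reshape(ref.shape), pass_rate, dd_percent,
                       dta_mm, threshold_percent, n_evaluated=n_eval)
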