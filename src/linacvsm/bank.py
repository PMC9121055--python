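"""Conditional histogram bank scored from classified phase-space records.

Particles at the scoring plane are split into three groups — primary photons,
scattered photons, and charged particles (electrons and positrons pooled as
pure scatter) — and five histogram families are filled per group:

* ``x``: crossplane position;
* ``yx``: inplane position, one histogram per x bin;
* ``er``: kinetic energy, one histogram per 0.5 cm radial ring up to
  R = 5.5 cm plus a single overflow ring (12 rings total);
* ``dux``: direction residual U' - U with U' = X/Z, one histogram per x bin;
* ``dvy``: direction residual V' - V with V' = Y/Z, one histogram per y bin.

Bin widths: photon positions 0.1 cm, charged 0.2 cm; photon energy 0.02 MeV,
charged 0.05 MeV; photon direction residuals 0.0005, charged 0.02.  The
position support is fixed to +/-5.5 cm; out-of-support values land in the
edge bins and are tallied in clipping counters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .classify import GaussianFocalFit, classification_mask
from .phsp_io import Species

GROUPS = ("primary", "scattered", "charged")

POS_SUPPORT = 5.5       # cm
DIR_SUPPORT = 1.25      # dimensionless; covers |U' - U| for any in-support ray
R_RING_WIDTH = 0.5      # cm
N_RINGS = 12            # 11 rings in [0, 5.5) plus one overflow

PHOTON_POS_BIN = 0.1
CHARGED_POS_BIN = 0.2
PHOTON_E_BIN = 0.02
CHARGED_E_BIN = 0.05
PHOTON_DIR_BIN = 0.0005
CHARGED_DIR_BIN = 0.02


@dataclass(frozen=True)
class GroupBinning:
    pos_bin: float
    e_bin: float
    dir_bin: float
    e_max: float
    pos_support: float = POS_SUPPORT
    dir_support: float = DIR_SUPPORT

    @property
    def n_pos(self) -> int:
        return int(round(2 * self.pos_support / self.pos_bin))

    @property
    def n_e(self) -> int:
        return int(round(self.e_max / self.e_bin))

    @property
    def n_dir(self) -> int:
        return int(round(2 * self.dir_support / self.dir_bin))

    @property
    def pos_edges(self) -> np.ndarray:
        return np.linspace(-self.pos_support, self.pos_support, self.n_pos + 1)

    @property
    def e_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.e_max, self.n_e + 1)

    @property
    def dir_edges(self) -> np.ndarray:
        return np.linspace(-self.dir_support, self.dir_support, self.n_dir + 1)


def binning_for(group: str, e_max: float) -> GroupBinning:
    if group in ("primary", "scattered"):
        return GroupBinning(PHOTON_POS_BIN, PHOTON_E_BIN, PHOTON_DIR_BIN, e_max)
    if group == "charged":
        return GroupBinning(CHARGED_POS_BIN, CHARGED_E_BIN, CHARGED_DIR_BIN, e_max)
    raise ValueError(f"unknown group {group!r}")


@dataclass
class GroupHistograms:
    binning: GroupBinning
    x: np.ndarray          # (n_pos,)
    yx: np.ndarray         # (n_pos, n_pos)
    er: np.ndarray         # (N_RINGS, n_e)
    dux: np.ndarray        # (n_pos, n_dir)
    dvy: np.ndarray        # (n_pos, n_dir)
    n_scored: int = 0
    n_pos_clipped: int = 0
    n_dir_clipped: int = 0
    n_e_clipped: int = 0

    @classmethod
    def empty(cls, binning: GroupBinning) -> "GroupHistograms":
        npos, ne, nd = binning.n_pos, binning.n_e, binning.n_dir
        return cls(
            binning,
            x=np.zeros(npos, dtype=np.int64),
            yx=np.zeros((npos, npos), dtype=np.int64),
            er=np.zeros((N_RINGS, ne), dtype=np.int64),
            dux=np.zeros((npos, nd), dtype=np.int64),
            dvy=np.zeros((npos, nd), dtype=np.int64),
        )


@dataclass(frozen=True)
class GroupFractions:
    """Particle-group shares used by the sampler's first two uniforms."""

    photon: float
    electron: float
    positron: float
    primary_given_photon: float

    @property
    def charged(self) -> float:
        return self.electron + self.positron

    @property
    def positron_given_charged(self) -> float:
        tot = self.charged
        return self.positron / tot if tot > 0 else 0.0


@dataclass
class HistogramBank:
    groups: dict
    fractions: GroupFractions
    scoring_plane_z: float
    e_max: float
    n_records: int
    n_skipped: int = 0
    clipping: dict = field(default_factory=dict)

    @property
    def total_scored(self) -> int:
        return sum(g.n_scored for g in self.groups.values())


def _digitize_clip(values: np.ndarray, lo: float, width: float, n: int):
    idx = np.floor((values - lo) / width).astype(np.int64)
    clipped = int(((idx < 0) | (idx >= n)).sum())
    return np.clip(idx, 0, n - 1), clipped


def _fill_group(gh: GroupHistograms, x, y, u, v, energy, z: float) -> None:
    b = gh.binning
    npos, ne, nd = b.n_pos, b.n_e, b.n_dir

    bx, cx = _digitize_clip(x, -b.pos_support, b.pos_bin, npos)
    by, cy = _digitize_clip(y, -b.pos_support, b.pos_bin, npos)
    gh.n_pos_clipped += cx + cy

    gh.x += np.bincount(bx, minlength=npos)
    gh.yx += np.bincount(bx * npos + by, minlength=npos * npos).reshape(npos, npos)

    du = x / z - u
    dv = y / z - v
    bdu, cu = _digitize_clip(du, -b.dir_support, b.dir_bin, nd)
    bdv, cv = _digitize_clip(dv, -b.dir_support, b.dir_bin, nd)
    gh.n_dir_clipped += cu + cv
    gh.dux += np.bincount(bx * nd + bdu, minlength=npos * nd).reshape(npos, nd)
    gh.dvy += np.bincount(by * nd + bdv, minlength=npos * nd).reshape(npos, nd)

    ring = np.minimum((np.hypot(x, y) / R_RING_WIDTH).astype(np.int64), N_RINGS - 1)
    be, ce = _digitize_clip(energy, 0.0, b.e_bin, ne)
    gh.n_e_clipped += ce
    gh.er += np.bincount(ring * ne + be, minlength=N_RINGS * ne).reshape(N_RINGS, ne)

    gh.n_scored += len(x)


def score_bank(
    records,
    fit: GaussianFocalFit,
    e_max: float,
    scoring_plane_z: float = 26.7,
) -> HistogramBank:
    """Fill the conditional histogram bank from classified records.

    ``records`` is a structured array or an iterable of structured chunks.
    Photons are classified primary/scattered with ``fit``; electrons and
    positrons go to the pooled charged group.  Photons whose direction cannot
    be reverse-transported (u^2 + v^2 >= 1) are skipped and counted.
    """
    groups = {g: GroupHistograms.empty(binning_for(g, e_max)) for g in GROUPS}
    counts = {Species.PHOTON: 0, Species.ELECTRON: 0, Species.POSITRON: 0}
    n_primary = 0
    n_records = 0
    n_skipped = 0
    z = scoring_plane_z

    if isinstance(records, np.ndarray):
        records = (records,)
    for chunk in records:
        n_records += len(chunk)
        tc = chunk["type"]
        x = np.asarray(chunk["x"], dtype=np.float64)
        y = np.asarray(chunk["y"], dtype=np.float64)
        u = np.asarray(chunk["u"], dtype=np.float64)
        v = np.asarray(chunk["v"], dtype=np.float64)
        e = np.asarray(chunk["energy"], dtype=np.float64)

        is_photon = tc == int(Species.PHOTON)
        ok = u * u + v * v < 1.0
        n_skipped += int((is_photon & ~ok).sum())
        ph = is_photon & ok
        counts[Species.PHOTON] += int(ph.sum())
        counts[Species.ELECTRON] += int((tc == int(Species.ELECTRON)).sum())
        counts[Species.POSITRON] += int((tc == int(Species.POSITRON)).sum())

        if ph.any():
            prim = classification_mask(x[ph], y[ph], u[ph], v[ph], fit, z)
            n_primary += int(prim.sum())
            idx = np.flatnonzero(ph)
            for gname, sel in (("primary", idx[prim]), ("scattered", idx[~prim])):
                if len(sel):
                    _fill_group(groups[gname], x[sel], y[sel], u[sel], v[sel],
                                e[sel], z)
        ch = ~is_photon
        if ch.any():
            _fill_group(groups["charged"], x[ch], y[ch], u[ch], v[ch], e[ch], z)

    n_ph = counts[Species.PHOTON]
    n_tot = n_ph + counts[Species.ELECTRON] + counts[Species.POSITRON]
    if n_tot == 0:
        raise ValueError("no valid records to score")
    fractions = GroupFractions(
        photon=n_ph / n_tot,
        electron=counts[Species.ELECTRON] / n_tot,
        positron=counts[Species.POSITRON] / n_tot,
        primary_given_photon=(n_primary / n_ph) if n_ph else 0.0,
    )
    clipping = {
        g: {"position": gh.n_pos_clipped, "direction": gh.n_dir_clipped,
            "energy": gh.n_e_clipped}
        for g, gh in groups.items()
    }
    return HistogramBank(groups, fractions, z, e_max, n_records,
                         n_skipped=n_skipped, clipping=clipping)
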