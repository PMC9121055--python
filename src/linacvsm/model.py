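"""Inverse-CDF lookup-table model built from the histogram bank.

Every scored histogram is normalised to a CDF and its generalised inverse is
tabulated on a regular probability grid with step 0.00005 (20,001 points
including both endpoints).  Linear interpolation of the CDF inside occupied
bins yields continuous sampled values (piecewise-uniform density); the
inverse at p = 0 and p = 1 returns the edges of the occupied support.  Empty
conditional histograms (sparse charged bins) fall back to the group's
marginal table so sampling stays total; the fallbacks are counted in the
model provenance.

The serialized model is a single binary file: a magic string, a JSON metadata
block (fit, group fractions, geometry, table index, provenance) and the
packed little-endian float32 tables.  For the paper-specified binning this is
864 tables of 20,001 values, ~66 MiB.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import bank as bank_mod
from . import phsp_io
from .bank import (GROUPS, GroupFractions, HistogramBank, N_RINGS,
                   binning_for, score_bank)
from .classify import GaussianFocalFit, fit_focal_gaussian_from_hists
from .classify import DEFAULT_FIT_BIN, DEFAULT_FIT_WINDOW, _fit_edges

logger = logging.getLogger(__name__)

PROBABILITY_STEP = 5e-5
N_GRID = 20_001  # both endpoints included
MAGIC = b"LINACVSM1\n"
FORMAT_VERSION = 1

FAMILIES = ("x", "yx", "er", "dux", "dvy")


@dataclass(frozen=True)
class InverseCdfTable:
    """Generalised inverse CDF tabulated on the regular probability grid."""

    values: np.ndarray            # float32, (N_GRID,)
    support: tuple[float, float]  # occupied extent of the scored histogram
    probability_step: float = PROBABILITY_STEP
    empty: bool = False

    def sample(self, p) -> np.ndarray:
        """Evaluate the inverse CDF at probabilities ``p`` (interpolated)."""
        if self.empty:
            raise ValueError("cannot sample from an empty table")
        return _lookup(self.values[np.newaxis, :], np.zeros(np.shape(p), int),
                       np.asarray(p, dtype=np.float64), self.probability_step)


def _lookup(tables: np.ndarray, rows, p: np.ndarray, step: float) -> np.ndarray:
    """Interpolated lookup ``tables[rows, p/step]`` for stacked tables."""
    g = p / step
    n = tables.shape[-1]
    i = np.minimum(g.astype(np.int64), n - 2)
    frac = g - i
    v0 = tables[rows, i].astype(np.float64)
    v1 = tables[rows, i + 1].astype(np.float64)
    return v0 + (v1 - v0) * frac


def to_inverse_cdf(
    counts: np.ndarray,
    edges: np.ndarray,
    probability_step: float = PROBABILITY_STEP,
) -> InverseCdfTable:
    """Convert one histogram into an inverse-CDF table.

    The histogram is trimmed to its occupied extent, its CDF is linearly
    interpolated within bins, and the inverse is evaluated on the grid
    {0, step, ..., 1}.  An all-zero histogram returns a table flagged empty.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n_grid = int(round(1.0 / probability_step)) + 1
    p_grid = np.linspace(0.0, 1.0, n_grid)
    nz = np.flatnonzero(counts > 0)
    if len(nz) == 0:
        return InverseCdfTable(np.zeros(n_grid, dtype=np.float32), (0.0, 0.0),
                               probability_step, empty=True)
    i0, i1 = nz[0], nz[-1]
    c = counts[i0:i1 + 1]
    e = np.asarray(edges, dtype=np.float64)[i0:i1 + 2]
    cdf = np.concatenate(([0.0], np.cumsum(c) / c.sum()))
    cdf[-1] = 1.0
    # drop edges where the CDF does not increase (interior empty bins) so the
    # generalised inverse jumps across zero-probability gaps
    keep = np.concatenate(([True], np.diff(cdf) > 0))
    values = np.interp(p_grid, cdf[keep], e[keep]).astype(np.float32)
    return InverseCdfTable(values, (float(e[0]), float(e[-1])), probability_step)


@dataclass
class VsmModel:
    """Dual-source virtual source model: fractions + inverse-CDF table bank.

    ``tables[(group, family)]`` is a stacked float32 array with one row per
    conditioning bin (a single row for the ``x`` marginals).
    """

    fit: GaussianFocalFit
    fractions: GroupFractions
    scoring_plane_z: float
    e_max: float
    probability_step: float
    tables: dict
    empty_rows: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_grid(self) -> int:
        return int(round(1.0 / self.probability_step)) + 1

    @property
    def table_count(self) -> int:
        return sum(arr.shape[0] for arr in self.tables.values())

    @property
    def table_nbytes(self) -> int:
        return sum(arr.nbytes for arr in self.tables.values())

    def binning(self, group: str) -> bank_mod.GroupBinning:
        return binning_for(group, self.e_max)

    def get_table(self, group: str, family: str, index: int = 0) -> InverseCdfTable:
        arr = self.tables[(group, family)]
        row = arr[index]
        empty = index in self.empty_rows.get((group, family), ())
        support = (float(row[0]), float(row[-1]))
        return InverseCdfTable(row, support, self.probability_step, empty=empty)


_FAMILY_SHAPES = {
    "x": lambda b: 1,
    "yx": lambda b: b.n_pos,
    "er": lambda b: N_RINGS,
    "dux": lambda b: b.n_pos,
    "dvy": lambda b: b.n_pos,
}


def bank_to_model(bank: HistogramBank, fit: GaussianFocalFit,
                  probability_step: float = PROBABILITY_STEP,
                  provenance: dict | None = None) -> VsmModel:
    """Convert a scored histogram bank into the inverse-CDF model."""
    n_grid = int(round(1.0 / probability_step)) + 1
    tables: dict = {}
    empty_rows: dict = {}
    fallback_counts: dict = {}
    for gname in GROUPS:
        gh = bank.groups[gname]
        b = gh.binning
        family_data = {
            "x": (gh.x[np.newaxis, :], b.pos_edges),
            "yx": (gh.yx, b.pos_edges),
            "er": (gh.er, b.e_edges),
            "dux": (gh.dux, b.dir_edges),
            "dvy": (gh.dvy, b.dir_edges),
        }
        for fam, (counts2d, edges) in family_data.items():
            marginal = counts2d.sum(axis=0)
            marg_table = to_inverse_cdf(marginal, edges, probability_step)
            out = np.empty((counts2d.shape[0], n_grid), dtype=np.float32)
            empties = []
            n_fallback = 0
            for i in range(counts2d.shape[0]):
                row = counts2d[i]
                if row.sum() == 0:
                    if marg_table.empty:
                        empties.append(i)
                        out[i] = 0.0
                    else:
                        n_fallback += 1
                        out[i] = marg_table.values
                else:
                    out[i] = to_inverse_cdf(row, edges, probability_step).values
            tables[(gname, fam)] = out
            if empties:
                empty_rows[(gname, fam)] = tuple(empties)
            if n_fallback:
                fallback_counts[f"{gname}.{fam}"] = n_fallback
                logger.info("group %s family %s: %d empty conditional bins "
                            "fall back to the marginal", gname, fam, n_fallback)
    prov = dict(provenance or {})
    prov.update(
        n_records=bank.n_records,
        n_skipped=bank.n_skipped,
        clipping=bank.clipping,
        marginal_fallbacks=fallback_counts,
    )
    return VsmModel(
        fit=fit,
        fractions=bank.fractions,
        scoring_plane_z=bank.scoring_plane_z,
        e_max=bank.e_max,
        probability_step=probability_step,
        tables=tables,
        empty_rows=empty_rows,
        provenance=prov,
    )


def build_model(
    phsp,
    n_sigma: float = 3.0,
    e_max: float | None = None,
    probability_step: float = PROBABILITY_STEP,
    max_records: int | None = None,
    fit_baseline: bool = False,
    scoring_plane_z: float | None = None,
) -> VsmModel:
    """Two-pass build: reverse transport + Gaussian fit, then classify + score.

    ``phsp`` is a phase-space path (streamed in chunks) or a structured
    record array.  ``e_max`` defaults to the data maximum rounded up to the
    next MeV (6 or 10 for the clinical beam energies).
    """
    from .classify import reverse_transport_to_focal

    def chunk_iter():
        if isinstance(phsp, np.ndarray):
            yield phsp
        else:
            yield from phsp_io.iter_phsp_chunks(phsp, max_records=max_records)

    if scoring_plane_z is None:
        if isinstance(phsp, np.ndarray):
            scoring_plane_z = phsp_io.DEFAULT_SCORING_PLANE_Z
        else:
            scoring_plane_z = phsp_io.read_header(phsp).scoring_plane_z
    z = scoring_plane_z

    # pass 1: focal-plane histograms of photons + energy support scan
    edges = _fit_edges(DEFAULT_FIT_BIN, DEFAULT_FIT_WINDOW)
    hx = np.zeros(len(edges) - 1, dtype=np.int64)
    hy = np.zeros_like(hx)
    seen_e_max = 0.0
    for chunk in chunk_iter():
        seen_e_max = max(seen_e_max, float(chunk["energy"].max()))
        ph = chunk["type"] == int(phsp_io.Species.PHOTON)
        if not ph.any():
            continue
        u = np.asarray(chunk["u"][ph], dtype=np.float64)
        v = np.asarray(chunk["v"][ph], dtype=np.float64)
        ok = u * u + v * v < 1.0
        x = np.asarray(chunk["x"][ph], dtype=np.float64)[ok]
        y = np.asarray(chunk["y"][ph], dtype=np.float64)[ok]
        x0, y0 = reverse_transport_to_focal(x, y, u[ok], v[ok], z)
        hx += np.histogram(x0, bins=edges)[0]
        hy += np.histogram(y0, bins=edges)[0]
    fit = fit_focal_gaussian_from_hists(hx, hy, n_sigma=n_sigma,
                                        baseline=fit_baseline)
    if e_max is None:
        e_max = float(np.ceil(seen_e_max))

    # pass 2: classify and score
    the_bank = score_bank(chunk_iter(), fit, e_max=e_max, scoring_plane_z=z)
    fit = fit.with_primary_fraction(the_bank.fractions.primary_given_photon)

    provenance = {
        "source": str(phsp) if not isinstance(phsp, np.ndarray) else "<array>",
        "n_sigma": n_sigma,
    }
    model = bank_to_model(the_bank, fit, probability_step, provenance)
    return model


# -- serialization ----------------------------------------------------------

def serialize_model(model: VsmModel, path: str | os.PathLike) -> int:
    """Write the model to one binary file; returns the file size in bytes."""
    path = Path(path)
    index = []
    offset = 0
    keys = sorted(model.tables.keys())
    for key in keys:
        arr = model.tables[key]
        index.append({
            "group": key[0], "family": key[1],
            "shape": list(arr.shape), "offset": offset,
        })
        offset += arr.nbytes
    meta = {
        "format_version": FORMAT_VERSION,
        "probability_step": model.probability_step,
        "scoring_plane_z": model.scoring_plane_z,
        "e_max": model.e_max,
        "fit": asdict(model.fit),
        "fractions": asdict(model.fractions),
        "empty_rows": {f"{g}.{f}": list(rows)
                       for (g, f), rows in model.empty_rows.items()},
        "provenance": model.provenance,
        "tables": index,
    }
    blob = json.dumps(meta, indent=1).encode()
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "wb") as fh:
        fh.write(MAGIC)
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        for key in keys:
            arr = np.ascontiguousarray(model.tables[key], dtype="<f4")
            fh.write(arr.tobytes())
    tmp.replace(path)
    return path.stat().st_size


class ModelFormatError(Exception):
    """The model file is unreadable or incompatible with this version."""


def load_model(path: str | os.PathLike) -> VsmModel:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(len(MAGIC))
        if magic != MAGIC:
            raise ModelFormatError(f"{path}: not a linacvsm model file")
        blob_len = int.from_bytes(fh.read(8), "little")
        meta = json.loads(fh.read(blob_len).decode())
        if meta.get("format_version") != FORMAT_VERSION:
            raise ModelFormatError(
                f"{path}: model format version {meta.get('format_version')} "
                f"is not supported (expected {FORMAT_VERSION})"
            )
        step = float(meta["probability_step"])
        n_grid = int(round(1.0 / step)) + 1
        tables = {}
        for entry in meta["tables"]:
            shape = tuple(entry["shape"])
            if shape[1] != n_grid:
                raise ModelFormatError(
                    f"{path}: table grid {shape[1]} inconsistent with "
                    f"probability step {step}"
                )
            data = fh.read(shape[0] * shape[1] * 4)
            if len(data) != shape[0] * shape[1] * 4:
                raise ModelFormatError(f"{path}: truncated table data")
            tables[(entry["group"], entry["family"])] = np.frombuffer(
                data, dtype="<f4").reshape(shape).copy()
    fit_meta = dict(meta["fit"])
    fit = GaussianFocalFit(**fit_meta)
    fractions = GroupFractions(**meta["fractions"])
    empty_rows = {}
    for key, rows in meta.get("empty_rows", {}).items():
        g, f = key.split(".")
        empty_rows[(g, f)] = tuple(rows)
    return VsmModel(
        fit=fit,
        fractions=fractions,
        scoring_plane_z=float(meta["scoring_plane_z"]),
        e_max=float(meta["e_max"]),
        probability_step=step,
        tables=tables,
        empty_rows=empty_rows,
        provenance=meta.get("provenance", {}),
    )
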