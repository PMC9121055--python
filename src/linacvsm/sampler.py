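"""Inverse-transform particle sampling from a virtual source model.

Each particle consumes seven uniforms U0..U6 in a fixed order:

* U0 selects the species (photon vs. charged by the stored fractions);
* U1 selects primary/scatter for photons, electron/positron for charged;
* U2 samples the crossplane position x from the group's x table;
* U3 samples y from the y|x table of the bin containing x;
* U4 samples the residual du = U' - U (U' = x/Z) from the du|x table,
  giving the direction cosine U = x/Z - du;
* U5 samples dv analogously from the dv|y table, giving V = y/Z - dv;
* U6 samples the kinetic energy from the E|R table of the ring containing
  R = sqrt(x^2 + y^2).

The longitudinal cosine is reconstructed as w = sqrt(1 - u^2 - v^2).  If a
draw lands on u^2 + v^2 >= 1 the direction residuals are redrawn with fresh
uniforms (up to 100 times; counted in the returned statistics).  No
rotational augmentation is applied anywhere — the sampled density keeps the
square footprint of the scoring plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from . import phsp_io
from .model import VsmModel, _lookup
from .phsp_io import Species

GROUP_CODES = {"primary": 0, "scattered": 1, "charged": 2}

#: structured dtype for sampled batches: phase-space fields plus group label
SAMPLE_DTYPE = np.dtype([
    ("type", "i1"), ("energy", "<f4"), ("x", "<f4"), ("y", "<f4"),
    ("u", "<f4"), ("v", "<f4"), ("group", "i1"),
])

_MAX_REDRAWS = 100


class EmptyTableError(RuntimeError):
    """A group with nonzero probability has no scored table to sample from."""


@dataclass(frozen=True)
class SampledParticle:
    species: Species
    group: str
    energy: float
    x: float
    y: float
    u: float
    v: float
    w: float
    weight: float = 1.0


@dataclass
class SampleStats:
    n_sampled: int = 0
    n_residual_redraws: int = 0


def _group_masks(model: VsmModel, u0: np.ndarray, u1: np.ndarray):
    fr = model.fractions
    is_photon = u0 < fr.photon
    primary = is_photon & (u1 < fr.primary_given_photon)
    scattered = is_photon & ~primary
    charged = ~is_photon
    positron = charged & (u1 < fr.positron_given_charged)
    return {"primary": primary, "scattered": scattered, "charged": charged}, positron


def _sample_group(model: VsmModel, gname: str, U: np.ndarray, rng, stats):
    """Sample positions, directions, energy for one group from (m, 7) uniforms."""
    m = len(U)
    b = model.binning(gname)
    z = model.scoring_plane_z
    step = model.probability_step

    def table(fam):
        key = (gname, fam)
        if model.empty_rows.get(key) is not None and \
                len(model.empty_rows[key]) == model.tables[key].shape[0]:
            raise EmptyTableError(f"group {gname!r} family {fam!r} is empty")
        return model.tables[key]

    tx = table("x")
    if (gname, "x") in model.empty_rows:
        raise EmptyTableError(f"group {gname!r} has no position table")
    x = _lookup(tx, np.zeros(m, dtype=np.int64), U[:, 2], step)
    bx = np.clip(((x + b.pos_support) / b.pos_bin).astype(np.int64), 0, b.n_pos - 1)
    y = _lookup(table("yx"), bx, U[:, 3], step)
    by = np.clip(((y + b.pos_support) / b.pos_bin).astype(np.int64), 0, b.n_pos - 1)

    du = _lookup(table("dux"), bx, U[:, 4], step)
    dv = _lookup(table("dvy"), by, U[:, 5], step)
    u = x / z - du
    v = y / z - dv
    bad = u * u + v * v >= 1.0
    tries = 0
    while bad.any():
        tries += 1
        if tries > _MAX_REDRAWS:
            raise RuntimeError("direction residual redraw limit exceeded; "
                               "the model direction tables are unphysical")
        k = int(bad.sum())
        stats.n_residual_redraws += k
        fresh = rng.random((k, 2))
        du_b = _lookup(table("dux"), bx[bad], fresh[:, 0], step)
        dv_b = _lookup(table("dvy"), by[bad], fresh[:, 1], step)
        u[bad] = x[bad] / z - du_b
        v[bad] = y[bad] / z - dv_b
        bad2 = u * u + v * v >= 1.0
        bad = bad & bad2  # only the still-bad subset is redrawn again

    ring = np.minimum((np.hypot(x, y) / 0.5).astype(np.int64),
                      model.tables[(gname, "er")].shape[0] - 1)
    energy = np.maximum(_lookup(table("er"), ring, U[:, 6], step), 1e-6)
    return x, y, u, v, energy


def sample_uniform_block(model: VsmModel, uniforms: np.ndarray,
                         rng=None) -> tuple[np.ndarray, SampleStats]:
    """Sample a batch of particles from an (m, 7) block of uniforms.

    ``rng`` supplies fresh uniforms only for the rare residual redraws; if
    None and a redraw is needed, an error is raised (the seven supplied
    uniforms then do not determine the particle).
    """
    U = np.atleast_2d(np.asarray(uniforms, dtype=np.float64))
    if U.shape[1] != 7:
        raise ValueError("expected 7 uniforms per particle")
    if rng is None:
        class _NoRng:
            def random(self, shape):
                raise RuntimeError("residual redraw required but no rng supplied")
        rng = _NoRng()
    m = len(U)
    stats = SampleStats(n_sampled=m)
    out = np.empty(m, dtype=SAMPLE_DTYPE)
    masks, positron = _group_masks(model, U[:, 0], U[:, 1])
    for gname, mask in masks.items():
        if not mask.any():
            continue
        x, y, u, v, e = _sample_group(model, gname, U[mask], rng, stats)
        out["x"][mask] = x
        out["y"][mask] = y
        out["u"][mask] = u
        out["v"][mask] = v
        out["energy"][mask] = e
        out["group"][mask] = GROUP_CODES[gname]
    out["type"] = np.where(masks["charged"],
                           np.where(positron, int(Species.POSITRON),
                                    int(Species.ELECTRON)),
                           int(Species.PHOTON))
    return out, stats


def sample_particle(model: VsmModel, uniforms, rng=None) -> SampledParticle:
    """Sample one particle from seven uniforms U0..U6."""
    arr, _ = sample_uniform_block(model, np.asarray(uniforms).reshape(1, 7), rng)
    row = arr[0]
    u, v = float(row["u"]), float(row["v"])
    gname = {v_: k for k, v_ in GROUP_CODES.items()}[int(row["group"])]
    return SampledParticle(
        species=Species(int(row["type"])),
        group=gname,
        energy=float(row["energy"]),
        x=float(row["x"]), y=float(row["y"]),
        u=u, v=v, w=float(np.sqrt(1.0 - u * u - v * v)),
    )


def sample_batch(
    model: VsmModel, n: int, seed: int, chunk_size: int = 1_000_000
) -> Iterator[np.ndarray]:
    """Stream ``n`` sampled particles as SAMPLE_DTYPE chunks (memory bounded).

    Reproducible: a given (model, seed) pair yields identical streams.  Each
    particle consumes exactly seven uniforms in the order U0..U6 (plus fresh
    uniforms for logged residual redraws).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    remaining = n
    while remaining > 0:
        m = min(chunk_size, remaining)
        U = rng.random((m, 7))
        chunk, _ = sample_uniform_block(model, U, rng)
        yield chunk
        remaining -= m


def sample_array(model: VsmModel, n: int, seed: int,
                 chunk_size: int = 1_000_000) -> np.ndarray:
    return np.concatenate(list(sample_batch(model, n, seed, chunk_size)))


def samples_to_phsp(samples: np.ndarray) -> np.ndarray:
    """Strip the group label so a batch can be written with write_phsp."""
    out = np.empty(len(samples), dtype=phsp_io.layout_dtype(phsp_io.LAYOUT_BASIC))
    for name in out.dtype.names:
        out[name] = samples[name]
    return out
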