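"""Reader/writer for IAEA-style phase-space file pairs.

A phase space is stored as two files sharing a base name: ``<base>.IAEAheader``
(plain ``key: value`` text) and ``<base>.IAEAphsp`` (packed little-endian
binary records).  One canonical record layout is supported: a 1-byte particle
type code (1=photon, 2=electron, 3=positron) followed by kinetic energy (MeV),
crossplane/inplane positions X, Y (cm) and direction cosines U, V as 4-byte
floats, with an optional trailing 4-byte statistical weight.  All particles
are forward-going; the third direction cosine W is never stored and is
reconstructed downstream as sqrt(1 - u^2 - v^2).

Units are cm and MeV throughout.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

HEADER_SUFFIX = ".IAEAheader"
PHSP_SUFFIX = ".IAEAphsp"

LAYOUT_BASIC = "type:i1,energy:f4,x:f4,y:f4,u:f4,v:f4"
LAYOUT_WEIGHT = LAYOUT_BASIC + ",weight:f4"
_SUPPORTED_LAYOUTS = (LAYOUT_BASIC, LAYOUT_WEIGHT)

#: direction-cosine tolerance for u^2 + v^2 <= 1 after float32 storage
_DIR_TOL = 1e-6

DEFAULT_SCORING_PLANE_Z = 26.7  # cm from the focal spot


class Species(enum.IntEnum):
    """Particle species with its on-disk type code."""

    PHOTON = 1
    ELECTRON = 2
    POSITRON = 3


class PhspFormatError(Exception):
    """Structural problem with a phase-space header/binary pair."""


class PhspRecordError(Exception):
    """A single record violates the format or the physical invariants."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"record {index}: {message}")


@dataclass(frozen=True)
class PhaseSpaceRecord:
    """One particle tallied at the scoring plane.

    energy is kinetic energy in MeV; x, y are crossplane/inplane positions in
    cm; u, v are the crossplane/inplane direction cosines.
    """

    species: Species
    energy: float
    x: float
    y: float
    u: float
    v: float
    weight: float = 1.0


@dataclass
class PhspHeader:
    record_count: int
    layout: str = LAYOUT_BASIC
    scoring_plane_z: float = DEFAULT_SCORING_PLANE_Z
    extra: dict = field(default_factory=dict)

    @property
    def dtype(self) -> np.dtype:
        return layout_dtype(self.layout)

    @property
    def record_size(self) -> int:
        return self.dtype.itemsize

    @property
    def byte_count(self) -> int:
        return self.record_count * self.record_size

    @property
    def has_weight(self) -> bool:
        return "weight" in self.dtype.names


def layout_dtype(layout: str) -> np.dtype:
    if layout not in _SUPPORTED_LAYOUTS:
        raise PhspFormatError(
            f"unsupported record layout {layout!r}; supported: {_SUPPORTED_LAYOUTS}"
        )
    fields = []
    for item in layout.split(","):
        name, code = item.split(":")
        fields.append((name, "<" + code))
    return np.dtype(fields)


def phsp_paths(path: str | os.PathLike) -> tuple[Path, Path]:
    """Resolve a base path or header path to (header, binary) paths."""
    p = Path(path)
    if p.suffix == HEADER_SUFFIX.lstrip("."):  # pragma: no cover - defensive
        base = p.with_suffix("")
    elif str(p).endswith(HEADER_SUFFIX):
        base = Path(str(p)[: -len(HEADER_SUFFIX)])
    elif str(p).endswith(PHSP_SUFFIX):
        base = Path(str(p)[: -len(PHSP_SUFFIX)])
    else:
        base = p
    return Path(str(base) + HEADER_SUFFIX), Path(str(base) + PHSP_SUFFIX)


def read_header(path: str | os.PathLike) -> PhspHeader:
    header_path, binary_path = phsp_paths(path)
    if not header_path.exists():
        raise PhspFormatError(f"missing header file {header_path}")
    values: dict[str, str] = {}
    for line in header_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise PhspFormatError(f"malformed header line {line!r}")
        key, _, val = line.partition(":")
        values[key.strip().upper()] = val.strip()
    try:
        record_count = int(values.pop("RECORD_COUNT"))
        layout = values.pop("RECORD_LAYOUT")
    except KeyError as exc:
        raise PhspFormatError(f"header missing required key {exc}") from exc
    scoring_plane_z = float(values.pop("SCORING_PLANE_Z_CM", DEFAULT_SCORING_PLANE_Z))
    declared_bytes = values.pop("BYTE_COUNT", None)
    header = PhspHeader(record_count, layout, scoring_plane_z, extra=values)
    if declared_bytes is not None and int(declared_bytes) != header.byte_count:
        raise PhspFormatError(
            f"header BYTE_COUNT {declared_bytes} inconsistent with "
            f"record_count x record_size = {header.byte_count}"
        )
    if not binary_path.exists():
        raise PhspFormatError(f"missing binary file {binary_path}")
    actual = binary_path.stat().st_size
    if actual != header.byte_count:
        raise PhspFormatError(
            f"{binary_path}: expected {header.byte_count} bytes "
            f"({header.record_count} records x {header.record_size} B), found {actual}"
        )
    return header


def iter_phsp_chunks(
    path: str | os.PathLike,
    chunk_size: int = 1_000_000,
    max_records: int | None = None,
) -> Iterator[np.ndarray]:
    """Stream the binary file as structured-array chunks (memory bounded)."""
    header = read_header(path)
    _, binary_path = phsp_paths(path)
    dtype = header.dtype
    remaining = header.record_count
    if max_records is not None:
        remaining = min(remaining, max_records)
    offset = 0
    with open(binary_path, "rb") as fh:
        while remaining > 0:
            n = min(chunk_size, remaining)
            chunk = np.fromfile(fh, dtype=dtype, count=n)
            if len(chunk) < n:  # pragma: no cover - guarded by size check
                raise PhspFormatError(
                    f"binary file truncated at record {offset + len(chunk)}"
                )
            bad = (chunk["type"] < 1) | (chunk["type"] > 3)
            if bad.any():
                idx = int(np.argmax(bad))
                raise PhspRecordError(
                    offset + idx, f"unknown particle type code {chunk['type'][idx]}"
                )
            yield chunk
            offset += n
            remaining -= n


def read_phsp(
    path: str | os.PathLike,
    max_records: int | None = None,
    chunk_size: int = 1_000_000,
) -> Iterator[PhaseSpaceRecord]:
    """Yield :class:`PhaseSpaceRecord` objects one at a time (streaming)."""
    header = read_header(path)
    has_weight = header.has_weight
    for chunk in iter_phsp_chunks(path, chunk_size=chunk_size, max_records=max_records):
        for row in chunk:
            yield PhaseSpaceRecord(
                species=Species(int(row["type"])),
                energy=float(row["energy"]),
                x=float(row["x"]),
                y=float(row["y"]),
                u=float(row["u"]),
                v=float(row["v"]),
                weight=float(row["weight"]) if has_weight else 1.0,
            )


def read_phsp_array(
    path: str | os.PathLike, max_records: int | None = None
) -> np.ndarray:
    """Read the whole file (or the first ``max_records``) into one array."""
    chunks = list(iter_phsp_chunks(path, max_records=max_records))
    if not chunks:
        return np.empty(0, dtype=layout_dtype(LAYOUT_BASIC))
    return np.concatenate(chunks)


def _validate_chunk(chunk: np.ndarray, offset: int) -> None:
    e = np.asarray(chunk["energy"], dtype=np.float64)
    x = np.asarray(chunk["x"], dtype=np.float64)
    y = np.asarray(chunk["y"], dtype=np.float64)
    u = np.asarray(chunk["u"], dtype=np.float64)
    v = np.asarray(chunk["v"], dtype=np.float64)
    checks = [
        (~(e > 0), "kinetic energy must be > 0"),
        (~np.isfinite(x) | ~np.isfinite(y), "positions must be finite"),
        (u * u + v * v > 1.0 + _DIR_TOL, "direction cosines violate u^2+v^2 <= 1"),
        ((chunk["type"] < 1) | (chunk["type"] > 3), "unknown particle type code"),
    ]
    if "weight" in chunk.dtype.names:
        w = np.asarray(chunk["weight"], dtype=np.float64)
        checks.append((~(w > 0), "statistical weight must be > 0"))
    for bad, msg in checks:
        if bad.any():
            raise PhspRecordError(offset + int(np.argmax(bad)), msg)


def records_to_array(
    records: Iterable[PhaseSpaceRecord], with_weight: bool = False
) -> np.ndarray:
    layout = LAYOUT_WEIGHT if with_weight else LAYOUT_BASIC
    dtype = layout_dtype(layout)
    rows = list(records)
    out = np.empty(len(rows), dtype=dtype)
    for i, r in enumerate(rows):
        if with_weight:
            out[i] = (int(r.species), r.energy, r.x, r.y, r.u, r.v, r.weight)
        else:
            out[i] = (int(r.species), r.energy, r.x, r.y, r.u, r.v)
    return out


def write_phsp(
    records,
    out_path: str | os.PathLike,
    scoring_plane_z: float = DEFAULT_SCORING_PLANE_Z,
    with_weight: bool = False,
    extra_meta: dict | None = None,
) -> PhspHeader:
    """Write a header/binary pair readable by :func:`read_phsp`.

    ``records`` may be a structured array, an iterable of structured-array
    chunks, or an iterable of :class:`PhaseSpaceRecord`.  Records violating
    the invariants are rejected with their index and no files are left behind.
    """
    header_path, binary_path = phsp_paths(out_path)
    layout = LAYOUT_WEIGHT if with_weight else LAYOUT_BASIC
    dtype = layout_dtype(layout)

    if isinstance(records, np.ndarray):
        chunk_iter: Iterable[np.ndarray] = (records,)
    else:
        records = iter(records)
        first = next(records, None)
        if first is None:
            chunk_iter = ()
        elif isinstance(first, PhaseSpaceRecord):
            def _regroup(first_rec, rest, size=500_000):
                buf = [first_rec]
                for r in rest:
                    buf.append(r)
                    if len(buf) >= size:
                        yield records_to_array(buf, with_weight)
                        buf = []
                if buf:
                    yield records_to_array(buf, with_weight)

            chunk_iter = _regroup(first, records)
        else:
            import itertools

            chunk_iter = itertools.chain((first,), records)

    tmp_binary = Path(str(binary_path) + ".tmp")
    count = 0
    try:
        with open(tmp_binary, "wb") as fh:
            for chunk in chunk_iter:
                if chunk.dtype != dtype:
                    if set(chunk.dtype.names) < set(dtype.names):
                        raise PhspFormatError(
                            f"chunk layout {chunk.dtype} missing fields of {layout}"
                        )
                    conv = np.empty(len(chunk), dtype=dtype)
                    for name in dtype.names:
                        conv[name] = chunk[name]
                    chunk = conv
                _validate_chunk(chunk, count)
                chunk.tofile(fh)
                count += len(chunk)
    except Exception:
        tmp_binary.unlink(missing_ok=True)
        raise
    tmp_binary.replace(binary_path)

    header = PhspHeader(count, layout, scoring_plane_z, extra=dict(extra_meta or {}))
    lines = [
        "# IAEA-style phase space header (linacvsm canonical layout)",
        f"RECORD_COUNT: {count}",
        f"RECORD_LAYOUT: {layout}",
        f"SCORING_PLANE_Z_CM: {scoring_plane_z:g}",
        f"BYTE_COUNT: {header.byte_count}",
    ]
    for key, val in header.extra.items():
        lines.append(f"{key.upper()}: {val}")
    header_path.write_text("\n".join(lines) + "\n")
    return header
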