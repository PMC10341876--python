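"""Flat-text readers and writers for stationary-point databases and XYZ.

The database format follows the established landscape-ecosystem convention:

``min.data``
    one minimum per line: ``energy  log_freq_product  degeneracy  1.0 1.0 1.0``
    (the trailing three columns are moments-of-inertia placeholders, written
    as 1.0 and ignored on read).

``ts.data``
    one transition state per line: ``energy  log_freq_product  degeneracy
    min1  min2  1.0 1.0 1.0`` where ``min1``/``min2`` are **1-based**
    minimum ids on disk (converted to the internal 0-based ids on read).

Values round-trip exactly at 17 significant digits.  All writes are atomic
(temp file + rename), so interrupted runs never leave half-written files.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .database import (
    DatabaseError,
    MinimumRecord,
    StationaryPointDatabase,
    TransitionStateRecord,
)

__all__ = [
    "FormatError",
    "atomic_write_text",
    "write_min_data",
    "read_min_data",
    "write_ts_data",
    "read_ts_data",
    "write_database",
    "read_database",
    "write_xyz",
    "read_xyz",
    "write_json",
]


class FormatError(ValueError):
    """Malformed file content; the message names the offending line."""


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text atomically: temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_min_data(path: str | Path, minima: Iterable[MinimumRecord]) -> None:
    lines = [
        f"{_fmt(m.energy)} {_fmt(m.log_freq_product)} {_fmt(m.degeneracy)} 1.0 1.0 1.0"
        for m in minima
    ]
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_min_data(path: str | Path) -> list[MinimumRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(cols)}"
                )
            try:
                energy, lfp, deg = (float(c) for c in cols[:3])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            records.append(MinimumRecord(len(records), energy, lfp, deg))
    return records


def write_ts_data(path: str | Path, transition_states: Iterable[TransitionStateRecord]) -> None:
    lines = [
        f"{_fmt(t.energy)} {_fmt(t.log_freq_product)} {_fmt(t.degeneracy)} "
        f"{t.min1_id + 1} {t.min2_id + 1} 1.0 1.0 1.0"
        for t in transition_states
    ]
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_ts_data(path: str | Path) -> list[TransitionStateRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 8:
                raise FormatError(
                    f"{path}: line {lineno}: expected 8 columns, got {len(cols)}"
                )
            try:
                energy, lfp, deg = (float(c) for c in cols[:3])
                min1, min2 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if min1 < 1 or min2 < 1:
                raise FormatError(
                    f"{path}: line {lineno}: minimum ids are 1-based on disk"
                )
            records.append(
                TransitionStateRecord(len(records), energy, min1 - 1, min2 - 1, lfp, deg)
            )
    return records


def write_database(directory: str | Path, db: StationaryPointDatabase) -> None:
    """Write min.data, ts.data, metadata.json and (if present) coordinates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_min_data(directory / "min.data", db.minima)
    write_ts_data(directory / "ts.data", db.transition_states)
    meta = dict(db.metadata)
    meta.setdefault("units", "reduced")
    meta["kappa"] = db.kappa
    meta["ndim"] = db.ndim
    write_json(directory / "metadata.json", meta)
    if any(m.coordinates is not None for m in db.minima):
        frames = [
            (m.coordinates.reshape(-1, db.ndim), f"minimum {m.id} energy {_fmt(m.energy)}")
            for m in db.minima
            if m.coordinates is not None
        ]
        write_xyz(directory / "minima.xyz", frames, ndim=db.ndim)


def read_database(directory: str | Path) -> StationaryPointDatabase:
    """Assemble and validate a database from a directory of flat files."""
    directory = Path(directory)
    minima = read_min_data(directory / "min.data")
    ts_path = directory / "ts.data"
    transition_states = read_ts_data(ts_path) if ts_path.exists() else []
    meta_path = directory / "metadata.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    db = StationaryPointDatabase(
        kappa=meta.get("kappa"), ndim=int(meta.get("ndim", 3)), metadata=meta
    )
    db.minima = minima
    db.transition_states = transition_states
    coords_path = directory / "minima.xyz"
    if coords_path.exists():
        frames = read_xyz(coords_path)
        for m, (pos, _) in zip(db.minima, frames):
            m.coordinates = pos[:, : db.ndim].ravel()
    dangling = [
        ts.id
        for ts in db.transition_states
        if not (0 <= ts.min1_id < len(minima) and 0 <= ts.min2_id < len(minima))
    ]
    if dangling:
        raise DatabaseError(
            f"{ts_path}: transition states {dangling} reference unknown minima"
        )
    return db


def write_xyz(
    path: str | Path,
    frames: Sequence[tuple[np.ndarray, str]],
    element: str = "C",
    ndim: int = 3,
) -> None:
    """Standard multi-frame XYZ; 2D configurations are padded with z = 0."""
    chunks = []
    for pos, comment in frames:
        pos = np.asarray(pos, dtype=float).reshape(-1, ndim)
        if ndim == 2:
            pos = np.hstack([pos, np.zeros((pos.shape[0], 1))])
        lines = [str(pos.shape[0]), comment.replace("\n", " ")]
        lines += [
            f"{element} {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}" for p in pos
        ]
        chunks.append("\n".join(lines))
    atomic_write_text(path, "\n".join(chunks) + "\n")


def read_xyz(path: str | Path) -> list[tuple[np.ndarray, str]]:
    """Read a multi-frame XYZ archive; returns (positions (n,3), comment) pairs."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: line {i + 1}: expected an atom count")
        if i + 1 + n >= len(lines) + 1:
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        comment = lines[i + 1]
        pos = np.empty((n, 3))
        for k in range(n):
            cols = lines[i + 2 + k].split()
            if len(cols) < 4:
                raise FormatError(f"{path}: line {i + 3 + k}: expected element + 3 coords")
            pos[k] = [float(c) for c in cols[1:4]]
        frames.append((pos, comment))
        i += 2 + n
    return frames


def write_json(path: str | Path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
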