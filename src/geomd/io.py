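"""Configuration parsing and trajectory serialization.

Interchange format is extended XYZ (human readable, one comment line per
frame carrying the box, time and energies); lossless internal records go
to HDF5 (bit-exact round trip).  Run configurations are YAML mappings.
Friction is specified in ps^-1 and stepsizes in fs at this boundary;
conversion to internal units happens here and nowhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .core import internal_to_fs, fs_to_internal
from .integrators import SCHEME_CODES
from .trajectory import TrajectoryRecord

__all__ = [
    "ConfigError",
    "XYZParseError",
    "RunConfig",
    "parse_config",
    "write_xyz",
    "read_xyz",
    "write_record_hdf5",
    "read_record_hdf5",
    "write_trajectory",
    "read_trajectory",
]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every failure found."""


class XYZParseError(ValueError):
    def __init__(self, message, frame=None):
        super().__init__(message + ("" if frame is None else f" (frame {frame})"))
        self.frame = frame


_DEFAULTS = dict(
    n_inner=1,
    kp=1,
    gamma_ps=1.0,
    temperature=300.0,
    scheme="gBAOAB",
    equilibration_steps=0,
    snapshot_stride=0,
    energy_stride=1,
    seed=0,
)


@dataclass
class RunConfig:
    system: dict
    scheme: str
    dt_fs: float
    n_steps: int
    n_inner: int = 1
    kp: int = 1
    gamma_ps: float = 1.0
    temperature: float = 300.0
    equilibration_steps: int = 0
    snapshot_stride: int = 0
    energy_stride: int = 1
    seed: int = 0
    output: dict = field(default_factory=dict)


def parse_config(source) -> RunConfig:
    """Validate a YAML file path or a mapping into a :class:`RunConfig`.

    Missing optional keys get defaults (n_inner=1, Kp=1, gamma=1 ps^-1,
    T=300 K).  All validation failures are collected and reported in one
    :class:`ConfigError`.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")

    errors = []
    for key in ("system", "dt_fs", "n_steps"):
        if key not in raw:
            errors.append(f"missing required key: {key}")
    merged = {**_DEFAULTS, **raw}
    if merged.get("scheme") not in SCHEME_CODES:
        errors.append(
            f"unknown scheme {merged.get('scheme')!r}; known: {SCHEME_CODES}"
        )
    for key, cond in [
        ("dt_fs", lambda v: v > 0),
        ("n_steps", lambda v: v >= 0),
        ("n_inner", lambda v: v >= 1),
        ("kp", lambda v: v >= 1),
        ("gamma_ps", lambda v: v >= 0),
        ("temperature", lambda v: v > 0),
        ("equilibration_steps", lambda v: v >= 0),
    ]:
        if key in merged and merged[key] is not None:
            try:
                if not cond(float(merged[key])):
                    errors.append(f"invalid value for {key}: {merged[key]}")
            except (TypeError, ValueError):
                errors.append(f"non-numeric value for {key}: {merged[key]!r}")
    system = merged.get("system")
    if system is not None and not isinstance(system, dict):
        errors.append("system must be a mapping with at least a 'name'")
    elif isinstance(system, dict) and "name" not in system:
        errors.append("system mapping needs a 'name'")
    if errors:
        raise ConfigError("; ".join(errors))
    known = set(RunConfig.__dataclass_fields__)
    fields = {k: v for k, v in merged.items() if k in known}
    fields["output"] = merged.get("output") or {}
    return RunConfig(**fields)


# ----------------------------------------------------------------------
# extended XYZ
# ----------------------------------------------------------------------
def _lattice_string(box) -> str:
    b = np.asarray(box, dtype=float)
    return (
        f'Lattice="{b[0]:.10g} 0 0 0 {b[1]:.10g} 0 0 0 {b[2]:.10g}"'
    )


def write_xyz(path, frames, species, box=None, times_fs=None, energies=None):
    """Write frames as extended XYZ.

    ``frames``: iterable of (n_atoms, 3) position arrays (angstrom).
    The per-frame comment line carries Lattice, Properties, time and
    (optionally) the potential energy.
    """
    frames = list(frames)
    with open(path, "w") as fh:
        for k, q in enumerate(frames):
            q = np.asarray(q, dtype=float)
            parts = []
            if box is not None:
                parts.append(_lattice_string(box))
            parts.append("Properties=species:S:1:pos:R:3")
            if times_fs is not None:
                parts.append(f"time_fs={times_fs[k]:.10g}")
            if energies is not None:
                parts.append(f"potential_kcal_mol={energies[k]:.10g}")
            fh.write(f"{q.shape[0]}\n{' '.join(parts)}\n")
            for sp, row in zip(species, q):
                fh.write(f"{sp} {row[0]:.8f} {row[1]:.8f} {row[2]:.8f}\n")


def read_xyz(path):
    """Read an (extended) XYZ file.

    Returns (frames, species, comments): frames is a list of
    (n_atoms, 3) arrays, species the first frame's species column,
    comments the raw per-frame comment lines.  Raises
    :class:`XYZParseError` with the frame index on malformed input.
    """
    frames, comments, species = [], [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame = 0
    while pos < len(lines):
        if lines[pos].strip() == "" and pos == len(lines) - 1:
            break
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise XYZParseError(f"bad atom count line: {lines[pos]!r}", frame) from exc
        if pos + 2 + n > len(lines):
            raise XYZParseError("truncated frame", frame)
        comments.append(lines[pos + 1])
        sp, coords = [], []
        for line in lines[pos + 2 : pos + 2 + n]:
            tokens = line.split()
            if len(tokens) < 4:
                raise XYZParseError(f"bad atom line: {line!r}", frame)
            sp.append(tokens[0])
            try:
                coords.append([float(t) for t in tokens[1:4]])
            except ValueError as exc:
                raise XYZParseError(f"bad coordinates: {line!r}", frame) from exc
        if species is None:
            species = sp
        frames.append(np.array(coords))
        pos += 2 + n
        frame += 1
    return frames, species or [], comments


# ----------------------------------------------------------------------
# HDF5 records
# ----------------------------------------------------------------------
def write_record_hdf5(record: TrajectoryRecord, path):
    with h5py.File(path, "w") as f:
        f.attrs["metadata"] = json.dumps(record.metadata)
        f.attrs["unstable"] = record.unstable
        f.attrs["abort_reason"] = record.abort_reason or ""
        f.attrs["n_steps_completed"] = record.n_steps_completed
        f.create_dataset("times", data=np.asarray(record.times, dtype=float))
        f.create_dataset(
            "potential", data=np.asarray(record.potential_energies, dtype=float)
        )
        f.create_dataset(
            "kinetic", data=np.asarray(record.kinetic_energies, dtype=float)
        )
        f.create_dataset("residual_g", data=np.asarray(record.residual_g, dtype=float))
        f.create_dataset("residual_p", data=np.asarray(record.residual_p, dtype=float))
        f.create_dataset(
            "snapshot_times", data=np.asarray(record.snapshot_times, dtype=float)
        )
        if record.snapshots:
            f.create_dataset("snapshots", data=np.asarray(record.snapshots))
        grp = f.create_group("observables")
        for name, series in record.observables.items():
            grp.create_dataset(name, data=np.asarray(series, dtype=float))


def read_record_hdf5(path) -> TrajectoryRecord:
    with h5py.File(path, "r") as f:
        record = TrajectoryRecord(metadata=json.loads(f.attrs["metadata"]))
        record.unstable = bool(f.attrs["unstable"])
        record.abort_reason = f.attrs["abort_reason"] or None
        record.n_steps_completed = int(f.attrs["n_steps_completed"])
        record.times = list(f["times"][()])
        record.potential_energies = list(f["potential"][()])
        record.kinetic_energies = list(f["kinetic"][()])
        record.residual_g = list(f["residual_g"][()])
        record.residual_p = list(f["residual_p"][()])
        record.snapshot_times = list(f["snapshot_times"][()])
        if "snapshots" in f:
            record.snapshots = [q for q in f["snapshots"][()]]
        for name in f["observables"]:
            record.observables[name] = list(f["observables"][name][()])
    return record


def write_trajectory(record: TrajectoryRecord, path, species=None, box=None):
    """Dispatch on extension: .h5/.hdf5 lossless, .xyz extended XYZ."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        write_record_hdf5(record, path)
    elif path.suffix == ".xyz":
        if species is None:
            species = record.metadata.get("species")
        if species is None:
            raise ValueError("species are required to write XYZ")
        write_xyz(
            path,
            record.snapshots,
            species,
            box=box if box is not None else record.metadata.get("box"),
            times_fs=[internal_to_fs(t) for t in record.snapshot_times],
        )
    else:
        raise ValueError(f"unknown trajectory format: {path.suffix}")


def read_trajectory(path):
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_record_hdf5(path)
    if path.suffix == ".xyz":
        return read_xyz(path)
    raise ValueError(f"unknown trajectory format: {path.suffix}")
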