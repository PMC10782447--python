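"""File formats and run configuration.

Canonical labeled-data/trajectory format is extended XYZ with force columns
(text, self-describing header).  A LAMMPS-dump-style dialect (``id element
x y z [fx fy fz]``) is supported for interoperability, plus a lossy plain
XYZ writer for third-party viewers.  Result tables go through pandas as TSV.

Run configuration is a strict nested YAML document: unknown keys are
rejected, and a fully-resolved copy (all defaults materialized) is persisted
next to every run's outputs so that config + seeds reproduce the run.
"""

from __future__ import annotations

import dataclasses
import shlex
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correction import DescriptorConfig
from .md import MDConfig, Trajectory
from .prior import PriorConfig
from .synthetic import FixtureSpec
from .system import ParticleSystem, SpeciesParams, make_system
from .training import LabeledConfiguration, TrainingOptions


class ParseError(ValueError):
    def __init__(self, path, line, message):
        super().__init__(f"{path}:{line}: {message}")
        self.line = line


class MissingForcesError(ValueError):
    """Labeled access to a file read without force columns."""


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_EXT_COLUMNS = "species:S:1:pos:R:3:forces:R:3:charge:R:1:mass:R:1:mobile:I:1:ml_visible:I:1"


def _frame_header(system: ParticleSystem, time_ps=None, with_forces=True) -> str:
    b = [float(x) for x in system.box]
    lattice = f"{b[0]!r} 0.0 0.0 0.0 {b[1]!r} 0.0 0.0 0.0 {b[2]!r}"
    props = _EXT_COLUMNS if with_forces else _EXT_COLUMNS.replace(":forces:R:3", "")
    head = f'Lattice="{lattice}" Properties={props} units=nm,kJ/mol'
    if time_ps is not None:
        head += f" Time={float(time_ps)!r}"
    return head


def _write_frame(fh, system: ParticleSystem, forces=None, time_ps=None):
    fh.write(f"{len(system)}\n")
    fh.write(_frame_header(system, time_ps, with_forces=forces is not None) + "\n")
    for k in range(len(system)):
        parts = [str(system.species[k])]
        parts += [repr(float(x)) for x in system.positions[k]]
        if forces is not None:
            parts += [repr(float(x)) for x in forces[k]]
        parts += [repr(float(system.charges[k])), repr(float(system.masses[k])),
                  str(int(system.mobile[k])), str(int(system.ml_visible[k]))]
        fh.write(" ".join(parts) + "\n")


def write_configurations(data, path, format: str = "extxyz"):
    """Write labeled configurations or a trajectory.

    ``data`` may be a list of :class:`LabeledConfiguration`, a
    :class:`Trajectory`, or a list of :class:`ParticleSystem` (unlabeled).
    An empty sequence produces a valid empty file.
    """
    path = Path(path)
    if format == "extxyz":
        with open(path, "w") as fh:
            for system, forces, t in _iter_frames(data):
                _write_frame(fh, system, forces, t)
    elif format == "xyz":
        with open(path, "w") as fh:
            for system, _, t in _iter_frames(data):
                fh.write(f"{len(system)}\n")
                fh.write(f"t={t}\n" if t is not None else "frame\n")
                for k in range(len(system)):
                    x, y, z = system.positions[k] * 10.0  # plain XYZ in Angstrom
                    fh.write(f"{system.species[k]} {x:.8f} {y:.8f} {z:.8f}\n")
    elif format == "lammps-dump":
        with open(path, "w") as fh:
            for step, (system, forces, t) in enumerate(_iter_frames(data)):
                fh.write("ITEM: TIMESTEP\n%d\n" % step)
                fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % len(system))
                fh.write("ITEM: BOX BOUNDS pp pp pp\n")
                for e in system.box:
                    fh.write(f"0.0 {float(e)!r}\n")
                cols = "id element x y z" + (" fx fy fz" if forces is not None else "")
                fh.write(f"ITEM: ATOMS {cols}\n")
                for k in range(len(system)):
                    parts = [str(k + 1), str(system.species[k])]
                    parts += [repr(float(v)) for v in system.positions[k]]
                    if forces is not None:
                        parts += [repr(float(v)) for v in forces[k]]
                    fh.write(" ".join(parts) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _iter_frames(data):
    if isinstance(data, Trajectory):
        forces = data.forces
        for k in range(len(data)):
            yield data.frame(k), (forces[k] if forces is not None else None), data.times[k]
    else:
        for item in data:
            if isinstance(item, LabeledConfiguration):
                yield item.system, item.forces, item.metadata.get("time_ps")
            else:
                yield item, None, None


def _parse_ext_header(line: str, path, lineno: int):
    fields = {}
    for token in shlex.split(line):
        if "=" in token:
            key, val = token.split("=", 1)
            fields[key] = val
    if "Lattice" not in fields:
        raise ParseError(path, lineno, "missing Lattice in frame header")
    lat = np.fromstring(fields["Lattice"], sep=" ")
    if lat.size != 9:
        raise ParseError(path, lineno, "Lattice must have 9 entries")
    box = lat.reshape(3, 3).diagonal().copy()
    props = fields.get("Properties", "species:S:1:pos:R:3")
    toks = props.split(":")
    columns = []
    col = 0
    for k in range(0, len(toks), 3):
        name, _, width = toks[k], toks[k + 1], int(toks[k + 2])
        columns.append((name, col, width))
        col += width
    time_ps = float(fields["Time"]) if "Time" in fields else None
    return box, columns, col, time_ps


def read_configurations(path, format: str = "extxyz"):
    """Read an extended-XYZ or LAMMPS-dump file.

    Returns a list of :class:`LabeledConfiguration` when force columns are
    present, else a list of :class:`ParticleSystem`.  Malformed or truncated
    frames raise :class:`ParseError` with the offending line/frame.
    """
    path = Path(path)
    if format == "extxyz":
        return _read_extxyz(path)
    if format == "lammps-dump":
        return _read_lammps_dump(path)
    raise ValueError(f"unknown format {format!r}")


def _read_extxyz(path):
    out = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    frame_index = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise ParseError(path, ln + 1, f"expected atom count, got {lines[ln]!r}")
        if ln + 1 >= len(lines):
            raise ParseError(path, ln + 1, f"truncated frame {frame_index}: missing header")
        box, columns, n_cols, time_ps = _parse_ext_header(lines[ln + 1], path, ln + 2)
        if ln + 2 + n > len(lines):
            raise ParseError(path, len(lines), f"truncated frame {frame_index}: "
                             f"expected {n} atom lines")
        colmap = {name: (start, width) for name, start, width in columns}
        species, pos, forces = [], [], []
        charges, masses, mobile, mlvis = [], [], [], []
        for a in range(n):
            parts = lines[ln + 2 + a].split()
            if len(parts) < n_cols:
                raise ParseError(path, ln + 3 + a,
                                 f"expected {n_cols} columns, got {len(parts)}")
            def col(name, default=None):
                if name not in colmap:
                    return default
                s, w = colmap[name]
                vals = parts[s:s + w]
                return vals[0] if w == 1 else vals
            species.append(col("species"))
            pos.append([float(v) for v in col("pos")])
            if "forces" in colmap:
                forces.append([float(v) for v in col("forces")])
            charges.append(float(col("charge", "nan")))
            masses.append(float(col("mass", "nan")))
            mobile.append(bool(int(col("mobile", "1"))))
            mlvis.append(bool(int(col("ml_visible", "1"))))
        if np.all(np.isnan(charges)):
            system = make_system(pos, species, box, mobile=np.array(mobile),
                                 ml_visible=np.array(mlvis))
        else:
            system = ParticleSystem(positions=np.array(pos),
                                    species=np.array(species, dtype=object),
                                    charges=np.array(charges), masses=np.array(masses),
                                    box=box, mobile=np.array(mobile),
                                    ml_visible=np.array(mlvis))
        if forces:
            out.append(LabeledConfiguration(system=system, forces=np.array(forces),
                                            index=frame_index,
                                            metadata={"time_ps": time_ps}))
        else:
            out.append(system)
        ln += 2 + n
        frame_index += 1
    return out


def _read_lammps_dump(path):
    out = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    ln = 0
    frame_index = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        if not lines[ln].startswith("ITEM: TIMESTEP"):
            raise ParseError(path, ln + 1, "expected ITEM: TIMESTEP")
        try:
            n = int(lines[ln + 3])
            box = np.array([float(lines[ln + 5 + k].split()[1])
                            - float(lines[ln + 5 + k].split()[0]) for k in range(3)])
            header = lines[ln + 8]
        except (IndexError, ValueError):
            raise ParseError(path, ln + 1, f"truncated frame {frame_index}")
        cols = header.replace("ITEM: ATOMS", "").split()
        rows = lines[ln + 9: ln + 9 + n]
        if len(rows) < n:
            raise ParseError(path, len(lines), f"truncated frame {frame_index}")
        species, pos, forces = [], [], []
        has_f = "fx" in cols
        for r, row in enumerate(rows):
            parts = row.split()
            if len(parts) < len(cols):
                raise ParseError(path, ln + 10 + r, "short atom line")
            rec = dict(zip(cols, parts))
            species.append(rec.get("element", rec.get("type", "X")))
            pos.append([float(rec["x"]), float(rec["y"]), float(rec["z"])])
            if has_f:
                forces.append([float(rec["fx"]), float(rec["fy"]), float(rec["fz"])])
        order = np.argsort([int(r.split()[0]) for r in rows])
        species = np.array(species, dtype=object)[order]
        pos = np.array(pos)[order]
        system = make_system(pos, species, box)
        if has_f:
            out.append(LabeledConfiguration(system=system,
                                            forces=np.array(forces)[order],
                                            index=frame_index))
        else:
            out.append(system)
        ln += 9 + n
        frame_index += 1
    return out


def as_labeled(items) -> list:
    """Assert that a read result is labeled; raise a clear error otherwise."""
    bad = [k for k, it in enumerate(items) if not isinstance(it, LabeledConfiguration)]
    if bad:
        raise MissingForcesError(
            f"frame(s) {bad[:3]}... have no force columns: file was read as "
            "unlabeled; re-write with forces to use as training data")
    return list(items)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(path, **columns):
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "prior": PriorConfig,
    "descriptor": DescriptorConfig,
    "training": TrainingOptions,
    "md": MDConfig,
    "fixture": FixtureSpec,
}


class RunConfig:
    """Nested, strictly-validated run configuration with defaults."""

    def __init__(self, sections: dict = None):
        sections = dict(sections or {})
        self.sections = {}
        for name, cls in _SECTION_TYPES.items():
            given = sections.pop(name, {}) or {}
            defaults = {f.name: getattr(cls(), f.name) for f in dataclasses.fields(cls)}
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            defaults.update(given)
            self.sections[name] = defaults
        self.sections["species"] = sections.pop("species", {}) or {}
        self.sections["model"] = {"hidden": 32, "seed": 0,
                                  **(sections.pop("model", {}) or {})}
        if sections:
            raise ValueError(f"unknown config sections: {sorted(sections)}")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def save_resolved(self, path):
        def _clean(v):
            if isinstance(v, tuple):
                return [_clean(x) for x in v]
            if isinstance(v, (list, dict, str, int, float, bool)) or v is None:
                return v
            return str(v)
        data = {k: {kk: _clean(vv) for kk, vv in v.items()} if isinstance(v, dict) else v
                for k, v in self.sections.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def prior_config(self) -> PriorConfig:
        return PriorConfig(**self.sections["prior"])

    def descriptor_config(self) -> DescriptorConfig:
        d = dict(self.sections["descriptor"])
        if isinstance(d.get("angular_zeta"), list):
            d["angular_zeta"] = tuple(tuple(p) for p in d["angular_zeta"])
        return DescriptorConfig(**d)

    def training_options(self) -> TrainingOptions:
        return TrainingOptions(**self.sections["training"])

    def md_config(self) -> MDConfig:
        return MDConfig(**self.sections["md"])

    def fixture_spec(self) -> FixtureSpec:
        d = dict(self.sections["fixture"])
        if isinstance(d.get("box"), list):
            d["box"] = tuple(d["box"])
        return FixtureSpec(**d)

    def species_params(self) -> SpeciesParams:
        sp = SpeciesParams()
        for name, block in self.sections["species"].items():
            if name == "pair_overrides":
                sp.pair_overrides.update(
                    {tuple(sorted(k.split("-"))): tuple(v) for k, v in block.items()})
            else:
                sp.table.setdefault(name, {}).update(block)
        return sp
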