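"""Extended-XYZ snapshots, bond sidecars, and run manifests.

One frame per snapshot: bead count, a comment line carrying the box
(`Lattice=...`, angstrom), column layout (`Properties=...`) and mapped
time, then one line per bead with species, position (angstrom), velocity
(reduced), molecule id, reduced mass and molecule template name.  Bonds go
to a sidecar CSV (`bead_i,bead_j`) since XYZ has no bond record.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .builder import Configuration
from .units import SimulationUnits

__all__ = ["write_snapshot", "read_snapshot", "write_bonds", "read_bonds",
           "RunManifest"]

_PROPERTIES = (
    "species:S:1:pos:R:3:vel:R:3:molecule_id:I:1:mass:R:1:mol_name:S:1"
)


def _frame_text(config: Configuration, time_ps: float) -> str:
    u = config.units
    lat = " ".join(
        f"{x:.6f}" for x in np.diag(config.box * u.r_c).flatten()
    )
    lines = [
        str(config.n_beads),
        f'Lattice="{lat}" Properties={_PROPERTIES} Time={time_ps:.3f} '
        f"r_c={u.r_c} mass_unit={u.mass_unit} "
        f"time_per_step_ps={u.time_per_step_ps}",
    ]
    mol_names = config.molecule_templates
    for k in range(config.n_beads):
        p = config.positions[k] * u.r_c
        v = config.velocities[k]
        m = int(config.molecule_id[k])
        lines.append(
            f"{config.species[k]} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
            f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {m} "
            f"{config.masses[k]:.6f} {mol_names[m]}"
        )
    return "\n".join(lines) + "\n"


def write_snapshot(
    config: Configuration, path: str | Path, time_ps: float = 0.0,
    append: bool = False,
) -> Path:
    """Write one extended-XYZ frame (positions externalized in angstrom)."""
    path = Path(path)
    try:
        with open(path, "a" if append else "w") as fh:
            fh.write(_frame_text(config, time_ps))
    except OSError as exc:
        raise OSError(f"cannot write snapshot to {path}: {exc}") from exc
    return path


def write_trajectory(trajectory, path: str | Path) -> Path:
    path = Path(path)
    units = trajectory.snapshots[0].units
    with open(path, "w") as fh:
        for snap, step in zip(
            trajectory.snapshots, trajectory.scalars["step"], strict=True
        ):
            fh.write(_frame_text(snap, step * units.time_per_step_ps))
    return path


def _parse_comment(line: str) -> dict:
    out: dict[str, str] = {}
    k = 0
    while k < len(line):
        eq = line.find("=", k)
        if eq < 0:
            break
        key = line[k:eq].strip().split()[-1]
        if eq + 1 < len(line) and line[eq + 1] == '"':
            end = line.find('"', eq + 2)
            out[key] = line[eq + 2 : end]
            k = end + 1
        else:
            end = line.find(" ", eq + 1)
            end = len(line) if end < 0 else end
            out[key] = line[eq + 1 : end]
            k = end + 1
    return out


def read_snapshot(path: str | Path, frame: int = -1) -> Configuration:
    """Read one frame (default: last) of an extended-XYZ file."""
    frames = read_frames(path)
    return frames[frame]


def read_frames(path: str | Path) -> list[Configuration]:
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Configuration] = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k])
        except ValueError:
            raise ValueError(f"{path}:{k + 1}: malformed frame header") from None
        if k + 2 + n > len(lines):
            raise ValueError(f"{path}:{k + 1}: truncated frame")
        meta = _parse_comment(lines[k + 1])
        lat = np.array([float(x) for x in meta["Lattice"].split()])
        units = SimulationUnits(
            r_c=float(meta.get("r_c", 6.46)),
            mass_unit=float(meta.get("mass_unit", 54.0)),
            time_per_step_ps=float(meta.get("time_per_step_ps", 3.0)),
        )
        box = np.array([lat[0], lat[4], lat[8]]) / units.r_c
        species, pos, vel, mol, masses = [], [], [], [], []
        mol_name: dict[int, str] = {}
        for row in lines[k + 2 : k + 2 + n]:
            parts = row.split()
            species.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
            vel.append([float(x) for x in parts[4:7]])
            mol.append(int(parts[7]))
            masses.append(float(parts[8]))
            mol_name[int(parts[7])] = parts[9]
        n_mol = (max(mol) + 1) if mol else 0
        templates = np.array(
            [mol_name.get(m, "?") for m in range(n_mol)], dtype="U16"
        )
        frames.append(
            Configuration(
                box=box,
                positions=(np.array(pos).reshape(-1, 3) / units.r_c) % box,
                velocities=np.array(vel).reshape(-1, 3),
                species=np.array(species, dtype="U4"),
                masses=np.array(masses, float),
                molecule_id=np.array(mol, np.int64),
                molecule_templates=templates,
                bonds=np.empty((0, 2), np.int64),
                units=units,
            )
        )
        k += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def write_bonds(config: Configuration, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("bead_i,bead_j\n")
        for i, j in config.bonds:
            fh.write(f"{i},{j}\n")
    return path


def read_bonds(path: str | Path) -> np.ndarray:
    rows = Path(path).read_text().splitlines()[1:]
    if not rows:
        return np.empty((0, 2), np.int64)
    return np.array(
        [[int(x) for x in r.split(",")] for r in rows if r.strip()], np.int64
    )


@dataclass
class RunManifest:
    """Everything needed to regenerate a pipeline output."""

    scenario: str
    seed: int
    builder_params: dict = field(default_factory=dict)
    engine_params: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    matrix_source: str = ""
    outputs: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
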