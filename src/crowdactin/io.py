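"""File formats shared by all analysis stages.

Dialects (all plain text except TIFF):

* **XYZ trajectories** — one block per frame: atom count, then a
  comment line ``frame=<i> t_ns=<time>``, then one line per atom of the
  form ``<group>.<name> x y z`` (e.g. ``F1.CA``), coordinates in Å.
* **Multi-model PDB trajectories** — MODEL/ENDMDL per frame with a
  ``REMARK   6 t_ns=<time>`` line in each model; filament subunit
  groups ``F1``..``F5`` map to chains A–E and the monomer group ``G``
  to chain G; Cα records carry atom name ``CA``.
* **Point-charge systems** — CSV with columns ``x,y,z,q`` or a minimal
  PDB where the charge is stored in the occupancy column.
* **Time series** — CSV with a header row whose column names embed the
  units (``time_s``/``time_ns``, ``intensity_au``, ``length_um``,
  ``msd_A2`` …) and optional ``# key=value`` metadata comment lines.
* **Timelapse stacks** — multi-frame TIFF plus a JSON sidecar with
  ``pixel_size_um``, ``frame_interval_s`` and ``line_row``.

Image convention: row-major, origin top-left, frame index 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .electrostatics import PointChargeSystem
from .synthetic_data import FluorescenceTimeSeries, TimelapseStack
from .trajectory_analysis import Trajectory

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "read_pdb",
    "read_trajectory",
    "write_point_charges_csv",
    "read_point_charges_csv",
    "write_point_charges_pdb",
    "read_point_charges_pdb",
    "write_series",
    "read_series",
    "write_fluorescence_series",
    "read_fluorescence_series",
    "write_stack",
    "read_stack",
    "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, line_no: int, msg: str):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.line_no = line_no


# ---------------------------------------------------------------- trajectories

def write_xyz(traj: Trajectory, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame={f} t_ns={traj.frame_times[f]:.9g}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(
                    f"{traj.group_ids[a]}.{traj.atom_names[a]} "
                    f"{x:.6f} {y:.6f} {z:.6f}\n"
                )


def read_xyz(path) -> Trajectory:
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    times: list[float] = []
    labels0: list[tuple[str, str]] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(path, i + 1, f"expected atom count, got {lines[i]!r}")
        if i + 1 >= len(lines):
            raise ParseError(path, i + 2, "truncated file: missing comment line")
        comment = lines[i + 1]
        t = None
        for tok in comment.split():
            if tok.startswith("t_ns="):
                t = float(tok[5:])
        if t is None:
            raise ParseError(path, i + 2, "comment line lacks t_ns=")
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(path, len(lines) + 1, f"truncated file: frame {len(frames)} "
                             f"has {len(block)} of {n} atom lines")
        coords = np.empty((n, 3))
        labels: list[tuple[str, str]] = []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(path, i + 3 + j, f"malformed atom line {line!r}")
            tag = parts[0]
            group, _, name = tag.partition(".")
            labels.append((group, name or "CA"))
            try:
                coords[j] = [float(p) for p in parts[1:]]
            except ValueError:
                raise ParseError(path, i + 3 + j, f"non-numeric coordinate in {line!r}")
        if labels0 is None:
            labels0 = labels
        elif len(labels) != len(labels0):
            raise ParseError(
                path, i + 1,
                f"frame {len(frames)} has {len(labels)} atoms, frame 0 has {len(labels0)}",
            )
        frames.append(coords)
        times.append(t)
        i += 2 + n
    if not frames:
        raise ParseError(path, 1, "no frames found")
    assert labels0 is not None
    return Trajectory(
        frame_times=np.array(times),
        coords=np.stack(frames),
        group_ids=np.array([g for g, _ in labels0], dtype=object),
        atom_names=np.array([a for _, a in labels0], dtype=object),
    )


_CHAIN_ALPHABET = "ABCDEFHIJKLMNOPQRSTUVWXYZ"  # G reserved for the monomer


def _chain_map(group_names: list[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    it = iter(_CHAIN_ALPHABET)
    for g in group_names:
        mapping[g] = "G" if g == "G" else next(it)
    return mapping


def write_pdb(traj: Trajectory, path) -> None:
    """Multi-model PDB; group→chain mapping F1..Fk → A..E, G → G."""
    path = Path(path)
    chain_of = _chain_map(traj.group_names)
    group_index = {g: i + 1 for i, g in enumerate(traj.group_names)}
    with path.open("w") as fh:
        fh.write("REMARK   6 GROUPS " +
                 " ".join(f"{g}:{c}" for g, c in chain_of.items()) + "\n")
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            fh.write(f"REMARK   6 t_ns={traj.frame_times[f]:.9g}\n")
            for a in range(traj.n_atoms):
                g = str(traj.group_ids[a])
                name = str(traj.atom_names[a])
                x, y, z = traj.coords[f, a]
                fh.write(
                    f"ATOM  {a + 1:5d} {name:^4s} ACT {chain_of[g]}{group_index[g]:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path) -> Trajectory:
    path = Path(path)
    chain_to_group: dict[str, str] = {}
    frames: list[list[list[float]]] = []
    times: list[float] = []
    groups: list[str] = []
    names: list[str] = []
    current: list[list[float]] | None = None
    n0: int | None = None
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if line.startswith("REMARK   6 GROUPS"):
            for pair in line.split()[3:]:
                g, _, c = pair.partition(":")
                chain_to_group[c] = g
        elif rec == "MODEL ":
            current = []
        elif line.startswith("REMARK   6 t_ns="):
            times.append(float(line.split("t_ns=")[1]))
        elif rec == "ATOM  " or rec == "HETATM":
            if current is None:
                current = []
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError:
                raise ParseError(path, ln, "malformed coordinate fields")
            current.append(xyz)
            if not frames:  # labels from first model only
                chain = line[21]
                groups.append(chain_to_group.get(chain, "G" if chain == "G" else f"F{ord(chain) - 64}"))
                names.append(line[12:16].strip())
        elif rec == "ENDMDL":
            if current is None:
                raise ParseError(path, ln, "ENDMDL without MODEL")
            if n0 is None:
                n0 = len(current)
            elif len(current) != n0:
                raise ParseError(
                    path, ln, f"model {len(frames)} has {len(current)} atoms, model 0 has {n0}"
                )
            frames.append(current)
            current = None
    if not frames:
        raise ParseError(path, 1, "no models found")
    if len(times) != len(frames):
        times = list(np.arange(len(frames), dtype=float))
    return Trajectory(
        frame_times=np.array(times),
        coords=np.array(frames),
        group_ids=np.array(groups, dtype=object),
        atom_names=np.array(names, dtype=object),
    )


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Dispatch on format (``xyz`` | ``pdb``), inferred from the suffix."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "pdb":
        return read_pdb(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ------------------------------------------------------------- point charges

def write_point_charges_csv(system: PointChargeSystem, path) -> None:
    df = pd.DataFrame(system.positions, columns=["x", "y", "z"])
    df["q"] = system.charges
    df.to_csv(path, index=False)


def read_point_charges_csv(path, label: str = "") -> PointChargeSystem:
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "z", "q") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return PointChargeSystem(
        positions=df[["x", "y", "z"]].to_numpy(float),
        charges=df["q"].to_numpy(float),
        label=label or Path(path).stem,
    )


def write_point_charges_pdb(system: PointChargeSystem, path) -> None:
    """Minimal PDB dialect: the particle charge sits in the occupancy column."""
    with Path(path).open("w") as fh:
        for i, (pos, q) in enumerate(zip(system.positions, system.charges)):
            fh.write(
                f"ATOM  {i + 1:5d}  Q   CHG X{i + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{q:6.2f}{0.0:6.2f}\n"
            )
        fh.write("END\n")


def read_point_charges_pdb(path, label: str = "") -> PointChargeSystem:
    positions, charges = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            try:
                positions.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
                charges.append(float(line[54:60]))
            except ValueError:
                raise ParseError(path, ln, "malformed ATOM record")
    if not positions:
        raise ParseError(path, 1, "no ATOM records")
    return PointChargeSystem(
        positions=np.array(positions),
        charges=np.array(charges),
        label=label or Path(path).stem,
    )


# ------------------------------------------------------------------- series

def write_series(path, columns: dict[str, np.ndarray],
                 metadata: dict | None = None) -> None:
    """CSV with unit-suffixed column names and ``# key=value`` metadata."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(columns).to_csv(fh, index=False)


def read_series(path, required: tuple[str, ...] = ()) -> tuple[pd.DataFrame, dict]:
    """Read a series CSV; returns (dataframe, metadata dict)."""
    path = Path(path)
    metadata: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                metadata[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df, metadata


def write_fluorescence_series(series: FluorescenceTimeSeries, path) -> None:
    write_series(
        path,
        {"time_s": series.times, "intensity_au": series.intensities},
        metadata={"polymerization_start_s": series.polymerization_start,
                  "label": series.label},
    )


def read_fluorescence_series(path) -> FluorescenceTimeSeries:
    df, meta = read_series(path, required=("time_s", "intensity_au"))
    times = df["time_s"].to_numpy(float)
    dts = np.diff(times)
    if dts.size and (np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6)):
        raise ValueError(f"{path}: pyrene time column must be uniformly spaced")
    return FluorescenceTimeSeries(
        times=times,
        intensities=df["intensity_au"].to_numpy(float),
        polymerization_start=float(meta.get("polymerization_start_s", 0.0)),
        label=meta.get("label", Path(path).stem),
    )


# -------------------------------------------------------------------- stacks

def write_stack(stack: TimelapseStack, path) -> None:
    """Multi-frame TIFF plus a ``.json`` sidecar with the calibration."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "line_row": stack.line_row,
    }, indent=2) + "\n")


def read_stack(path) -> TimelapseStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"calibration sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    return TimelapseStack(
        frames=frames,
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_s"]),
        line_row=int(meta.get("line_row", frames.shape[1] // 2)),
    )


# ------------------------------------------------------------------ manifest

def write_manifest(output_dir, config: dict, seed: int | None = None) -> Path:
    """Record the fully resolved run configuration next to the outputs."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "config": config}
    path = output_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
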