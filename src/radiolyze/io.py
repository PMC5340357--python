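"""Trajectory input/output in a fixed extended-XYZ dialect.

The dialect is deliberately narrow: the comment line of each frame carries an
orthorhombic ``Lattice="ax 0 0 0 by 0 0 0 cz"``, the frame ``Time=<fs>`` and
the ``Projectile=<index>`` (0-based), plus a ``Properties=`` string naming the
per-atom columns in order.  Recognised columns are ``species:S:1``,
``pos:R:3``, ``vel:R:3`` and ``mulliken:R:1``.  Trajectory-level metadata
(initial speed, snapshot id, entry point, seed, slab interval) is written on
the first frame's comment line so a single file round-trips a full
:class:`Trajectory`.

Units are fixed throughout the package: Å, fs, eV, unified atomic mass units.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "EnsembleManifest",
    "TrajectoryParseError",
    "read_trajectory",
    "write_trajectory",
    "load_ensemble",
    "write_manifest",
]

MANIFEST_COLUMNS = ["path", "speed_bohr_per_fs", "snapshot", "entry_y", "entry_z"]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file (bad header, inconsistent frames, ...)."""


@dataclass
class Frame:
    """One time-step snapshot of all atoms.

    Parameters
    ----------
    index : int
        Ordinal of the frame within its trajectory.
    time : float
        Simulation time in fs.
    box : ndarray, shape (3,)
        Orthorhombic edge lengths in Å.
    symbols : ndarray of str, shape (n,)
        Element symbol per atom.
    positions : ndarray, shape (n, 3)
        Cartesian coordinates in Å.
    velocities : ndarray, shape (n, 3), optional
        Å/fs; ``None`` when the file has no velocity columns.
    populations : ndarray, shape (n,), optional
        Electrons assigned per atom (Mulliken-style); non-negative.
    projectile_index : int, optional
        0-based index of the projectile atom, if any.
    """

    index: int
    time: float
    box: np.ndarray
    symbols: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None = None
    populations: np.ndarray | None = None
    projectile_index: int | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.symbols = np.asarray(self.symbols, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=float)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def validate(self) -> None:
        n = self.n_atoms
        if n < 1:
            raise ValueError("frame must contain at least one atom")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.velocities is not None and self.velocities.shape != (n, 3):
            raise ValueError("velocities must have shape (n_atoms, 3)")
        if self.populations is not None:
            if self.populations.shape != (n,):
                raise ValueError("populations must have shape (n_atoms,)")
            if np.any(self.populations < 0):
                raise ValueError("populations must be non-negative")
        if self.projectile_index is not None and not (
            0 <= int(self.projectile_index) < n
        ):
            raise ValueError("projectile_index out of range")


@dataclass
class Trajectory:
    """Time-ordered frames plus run metadata."""

    frames: list[Frame]
    initial_speed: float | None = None  # Bohr/fs
    snapshot_id: int | None = None
    entry_point: tuple[float, float] | None = None  # (y, z) Å
    seed: int | None = None
    slab_interval: tuple[float, float] | None = None  # (x_entry, x_exit) Å

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def projectile_index(self) -> int | None:
        return self.frames[0].projectile_index

    def validate(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        times = np.array([f.time for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        n = self.frames[0].n_atoms
        pidx = self.frames[0].projectile_index
        for f in self.frames:
            if f.n_atoms != n:
                raise TrajectoryParseError(
                    "inconsistent atom counts across frames "
                    f"({f.n_atoms} != {n} at frame {f.index})"
                )
            if f.projectile_index != pidx:
                raise ValueError("projectile_index must be constant across frames")


@dataclass
class EnsembleManifest:
    """Grouping of trajectory files by initial projectile speed."""

    entries: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=MANIFEST_COLUMNS)


# --------------------------------------------------------------------------
# extended-XYZ dialect

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_KV_RE = re.compile(r'(\w+)=("[^"]*"|\S+)')

_FMT = "%.12g"  # >= 9 significant digits, deterministic round-trip


def _parse_comment(line: str, lineno: int) -> dict:
    meta: dict = {}
    m = _LATTICE_RE.search(line)
    if m is None:
        raise TrajectoryParseError(f"line {lineno}: missing Lattice in comment line")
    vals = [float(v) for v in m.group(1).split()]
    if len(vals) != 9:
        raise TrajectoryParseError(f"line {lineno}: Lattice needs 9 numbers")
    lat = np.array(vals).reshape(3, 3)
    off = lat - np.diag(np.diag(lat))
    if np.any(off != 0.0):
        raise TrajectoryParseError(
            f"line {lineno}: non-orthorhombic box is not supported"
        )
    meta["box"] = np.diag(lat).copy()
    for key, raw in _KV_RE.findall(line):
        if key == "Lattice":
            continue
        meta[key] = raw.strip('"')
    if "Properties" not in meta:
        raise TrajectoryParseError(f"line {lineno}: missing Properties in comment line")
    return meta


def _parse_properties(spec: str, lineno: int) -> list[tuple[str, int]]:
    toks = spec.split(":")
    if len(toks) % 3 != 0:
        raise TrajectoryParseError(f"line {lineno}: malformed Properties string")
    cols = []
    for i in range(0, len(toks), 3):
        name, _kind, width = toks[i], toks[i + 1], int(toks[i + 2])
        cols.append((name, width))
    return cols


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory file in the package dialect.

    Missing optional columns (velocities, populations) yield absent fields on
    the returned frames, never zero-filled arrays.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    traj_meta: dict = {}
    i = 0
    findex = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 >= len(lines):
            raise TrajectoryParseError(f"line {i + 2}: truncated frame header")
        meta = _parse_comment(lines[i + 1], i + 2)
        cols = _parse_properties(meta["Properties"], i + 2)
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) < natoms:
            raise TrajectoryParseError(
                f"line {i + 2}: frame declares {natoms} atoms but file ends early"
            )
        symbols = np.empty(natoms, dtype=object)
        pos = np.empty((natoms, 3))
        vel = None
        pop = None
        names = [c[0] for c in cols]
        if "vel" in names:
            vel = np.empty((natoms, 3))
        if "mulliken" in names:
            pop = np.empty(natoms)
        for a, row in enumerate(body):
            toks = row.split()
            if len(toks) != sum(w for _, w in cols):
                raise TrajectoryParseError(
                    f"line {i + 3 + a}: expected {sum(w for _, w in cols)} "
                    f"columns, got {len(toks)}"
                )
            off = 0
            for name, width in cols:
                chunk = toks[off : off + width]
                off += width
                if name == "species":
                    symbols[a] = chunk[0]
                elif name == "pos":
                    pos[a] = [float(v) for v in chunk]
                elif name == "vel":
                    vel[a] = [float(v) for v in chunk]
                elif name == "mulliken":
                    pop[a] = float(chunk[0])
        pidx = int(meta["Projectile"]) if "Projectile" in meta else None
        frames.append(
            Frame(
                index=findex,
                time=float(meta.get("Time", findex)),
                box=meta["box"],
                symbols=symbols,
                positions=pos,
                velocities=vel,
                populations=pop,
                projectile_index=pidx,
            )
        )
        if findex == 0:
            if "Speed" in meta:
                traj_meta["initial_speed"] = float(meta["Speed"])
            if "Snapshot" in meta:
                traj_meta["snapshot_id"] = int(meta["Snapshot"])
            if "Entry" in meta:
                y, z = (float(v) for v in meta["Entry"].split())
                traj_meta["entry_point"] = (y, z)
            if "Seed" in meta:
                traj_meta["seed"] = int(meta["Seed"])
            if "Slab" in meta:
                a, b = (float(v) for v in meta["Slab"].split())
                traj_meta["slab_interval"] = (a, b)
        findex += 1
        i += 2 + natoms
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    return Trajectory(frames=frames, **traj_meta)


def _format_comment(frame: Frame, traj: Trajectory | None) -> str:
    b = frame.box
    lat = f'Lattice="{_FMT % b[0]} 0 0 0 {_FMT % b[1]} 0 0 0 {_FMT % b[2]}"'
    props = ["species:S:1", "pos:R:3"]
    if frame.velocities is not None:
        props.append("vel:R:3")
    if frame.populations is not None:
        props.append("mulliken:R:1")
    parts = [lat, "Properties=" + ":".join(props), f"Time={_FMT % frame.time}"]
    if frame.projectile_index is not None:
        parts.append(f"Projectile={frame.projectile_index}")
    if traj is not None:
        if traj.initial_speed is not None:
            parts.append(f"Speed={_FMT % traj.initial_speed}")
        if traj.snapshot_id is not None:
            parts.append(f"Snapshot={traj.snapshot_id}")
        if traj.entry_point is not None:
            y, z = traj.entry_point
            parts.append(f'Entry="{_FMT % y} {_FMT % z}"')
        if traj.seed is not None:
            parts.append(f"Seed={traj.seed}")
        if traj.slab_interval is not None:
            a, c = traj.slab_interval
            parts.append(f'Slab="{_FMT % a} {_FMT % c}"')
    return " ".join(parts)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write ``traj`` in the package dialect (parseable by read_trajectory)."""
    path = Path(path)
    out: list[str] = []
    for k, frame in enumerate(traj.frames):
        out.append(str(frame.n_atoms))
        out.append(_format_comment(frame, traj if k == 0 else None))
        for a in range(frame.n_atoms):
            toks = [str(frame.symbols[a])]
            toks += [_FMT % v for v in frame.positions[a]]
            if frame.velocities is not None:
                toks += [_FMT % v for v in frame.velocities[a]]
            if frame.populations is not None:
                toks.append(_FMT % frame.populations[a])
            out.append(" ".join(toks))
    path.write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# ensemble manifests


def write_manifest(manifest: EnsembleManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def load_ensemble(
    manifest_path: str | Path,
) -> dict[float, list[Trajectory]]:
    """Load all trajectories referenced by a manifest, grouped by speed.

    Paths in the manifest are resolved relative to the manifest file.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"manifest missing columns: {missing}")
    if df.empty:
        warnings.warn("manifest is empty", stacklevel=2)
        return {}
    paths = df["path"].tolist()
    dupes = {p for p in paths if paths.count(p) > 1}
    if dupes:
        raise TrajectoryParseError(f"duplicate paths in manifest: {sorted(dupes)}")
    groups: dict[float, list[Trajectory]] = {}
    for _, row in df.iterrows():
        p = manifest_path.parent / row["path"]
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file: {p}")
        traj = read_trajectory(p)
        groups.setdefault(float(row["speed_bohr_per_fs"]), []).append(traj)
    return groups
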