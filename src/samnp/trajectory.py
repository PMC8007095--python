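"""Trajectory container and multi-frame readers/writers.

Frames are dense (n_frames, n_atoms, 3) coordinate arrays in Å with one
timestamp (ns) per frame and an optional orthorhombic box.  Multi-frame XYZ
is read and written natively (the comment line carries ``t= <ns>``); DCD and
XTC go through MDAnalysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class TrajectoryFormatError(ValueError):
    """Unsupported or malformed trajectory format."""


@dataclass
class Trajectory:
    coords: np.ndarray              # (F, N, 3) Å
    times: np.ndarray               # (F,) ns
    elements: list[str] | None = None
    box: np.ndarray | None = None   # (3,) orthorhombic box lengths, Å
    topology: object | None = None  # optional samnp.topology.Topology

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.times = np.asarray(self.times, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (F, N, 3), got {self.coords.shape}")
        if len(self.times) != len(self.coords):
            raise ValueError("one timestamp per frame required")
        if self.box is not None:
            self.box = np.asarray(self.box, float).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ns (0 for single-frame trajectories)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    return suffix or "xyz"


def write_trajectory(traj: Trajectory, path: str | Path,
                     fmt: str | None = None) -> None:
    """Write ``traj`` to ``path`` as multi-frame XYZ, DCD or XTC."""
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        _write_xyz(traj, path)
    elif fmt in ("dcd", "xtc"):
        _write_mda(traj, path, fmt)
    else:
        raise TrajectoryFormatError(f"unsupported trajectory format {fmt!r}")


def read_trajectory(path: str | Path, fmt: str | None = None,
                    elements: list[str] | None = None) -> Trajectory:
    """Read a trajectory; DCD/XTC need no element list, XYZ carries its own."""
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt in ("dcd", "xtc"):
        return _read_mda(path, fmt, elements)
    raise TrajectoryFormatError(f"unsupported trajectory format {fmt!r}")


# ----------------------------------------------------------------------
# native multi-frame XYZ
# ----------------------------------------------------------------------

def _write_xyz(traj: Trajectory, path: str | Path) -> None:
    elements = traj.elements or ["X"] * traj.n_atoms
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {traj.times[f]:.6f} ns\n")
            for e, (x, y, z) in zip(elements, traj.coords[f]):
                fh.write(f"{e:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def _read_xyz(path: str | Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames, times = [], []
    elements: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = 0.0
        for tok_i, tok in enumerate(parts := comment.split()):
            if tok == "t=" and tok_i + 1 < len(parts):
                t = float(parts[tok_i + 1])
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise TrajectoryFormatError(
                f"{path}: truncated frame starting at line {i + 1}"
            )
        frame_elements, coords = [], []
        for k, line in enumerate(body):
            toks = line.split()
            if len(toks) < 4:
                raise TrajectoryFormatError(
                    f"{path}: line {i + 3 + k}: malformed atom record {line!r}"
                )
            frame_elements.append(toks[0])
            coords.append([float(toks[1]), float(toks[2]), float(toks[3])])
        if elements is None:
            elements = frame_elements
        frames.append(coords)
        times.append(t)
        i += 2 + n
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return Trajectory(np.array(frames), np.array(times), elements=elements)


# ----------------------------------------------------------------------
# DCD / XTC via MDAnalysis
# ----------------------------------------------------------------------

def _write_mda(traj: Trajectory, path: str | Path, fmt: str) -> None:
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    box = traj.box if traj.box is not None else np.array([500.0, 500.0, 500.0])
    kwargs = {}
    if fmt == "dcd" and traj.n_frames > 1:
        # DCD stores a single frame spacing in its header (ps)
        kwargs["dt"] = traj.dt * 1000.0
    with mda.Writer(str(path), n_atoms=traj.n_atoms, **kwargs) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f].astype(np.float32)
            u.trajectory.ts.dimensions = np.array(
                [box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32
            )
            # MDAnalysis times are ps; ours are ns
            u.trajectory.ts.time = traj.times[f] * 1000.0
            u.trajectory.ts.frame = f
            w.write(u.atoms)


def _read_mda(path: str | Path, fmt: str,
              elements: list[str] | None) -> Trajectory:
    import MDAnalysis as mda

    n_atoms = None
    if elements is not None:
        n_atoms = len(elements)
    else:
        # peek at the file to size an empty Universe
        from MDAnalysis.coordinates.core import get_reader_for

        reader = get_reader_for(str(path))(str(path))
        n_atoms = reader.n_atoms
        reader.close()
    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.load_new(str(path))
    frames, times = [], []
    box = None
    for ts in u.trajectory:
        frames.append(ts.positions.astype(float).copy())
        times.append(ts.time / 1000.0)
        if ts.dimensions is not None:
            box = np.asarray(ts.dimensions[:3], float)
    return Trajectory(
        np.array(frames), np.array(times), elements=elements, box=box
    )
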