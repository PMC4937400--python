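"""Frames, trajectories and the plain-text formats that carry them.

Units are fixed package-wide: coordinates in Å, time in ps.  Boxes are
orthorhombic only; triclinic cells are rejected rather than silently
wrapped, because every downstream operation (minimum image, cell lists,
RDF shells) assumes orthogonal axes.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np


class FormatError(ValueError):
    """Raised on malformed or unsupported structure/trajectory files."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box; edge lengths in Å."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(f"box lengths must be positive, got {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz


@dataclass
class Frame:
    """One configuration: n×3 positions (Å) in a periodic box at a time (ps)."""

    positions: np.ndarray
    box: Box
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


class Trajectory:
    """Ordered frames with a constant atom count and strictly increasing time."""

    def __init__(self, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = frames[0].n_atoms
        for i, f in enumerate(frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, expected {n}"
                )
        times = np.array([f.time for f in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def positions(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinate array."""
        return np.stack([f.positions for f in self.frames])

    def uniform_dt(self, rtol: float = 1e-6) -> float:
        """Frame spacing in ps; raises unless spacing is uniform."""
        t = self.times
        if len(t) < 2:
            raise ValueError("need at least two frames for a time spacing")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=rtol, atol=0):
            raise ValueError("trajectory frame spacing is not uniform")
        return float(dt[0])


@dataclass
class PDBNames:
    """Atom/residue labelling preserved from a PDB parse, in file order."""

    atom_names: list[str]
    residue_names: list[str]
    residue_ids: list[int]


# --------------------------------------------------------------------- PDB

_CRYST1 = re.compile(r"^CRYST1")


def read_pdb(path: str | os.PathLike) -> tuple[PDBNames, Trajectory]:
    """Parse a (possibly multi-MODEL) PDB file.

    CRYST1 is mandatory — the analysis is meaningless without a periodic
    box.  Returns the names needed for topology inference plus one frame
    per MODEL (a single frame when no MODEL records are present).
    Coordinates are taken at the format's fixed 3-decimal precision.
    """
    box: Box | None = None
    frames: list[np.ndarray] = []
    current: list[list[float]] = []
    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    first_model_done = False
    in_model = False
    model_index = 0

    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if _CRYST1.match(line):
                a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                alpha = float(line[33:40]) if line[33:40].strip() else 90.0
                beta = float(line[40:47]) if line[40:47].strip() else 90.0
                gamma = float(line[47:54]) if line[47:54].strip() else 90.0
                if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
                    raise FormatError(
                        "only orthorhombic boxes are supported "
                        f"(CRYST1 angles {alpha}, {beta}, {gamma})"
                    )
                box = Box(a, b, c)
            elif rec == "MODEL ":
                in_model = True
                model_index += 1
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                current.append([x, y, z])
                if not first_model_done:
                    names.append(line[12:16].strip())
                    resnames.append(line[17:21].strip())
                    resids.append(int(line[22:26]))
            elif rec == "ENDMDL":
                if frames and len(current) != len(frames[0]):
                    raise FormatError(
                        f"MODEL {model_index} has {len(current)} atoms, "
                        f"expected {len(frames[0])}"
                    )
                frames.append(np.array(current, dtype=float))
                first_model_done = True
                current = []
                in_model = False

    if box is None:
        raise FormatError(
            "PDB file has no CRYST1 record; a periodic box is required"
        )
    if current:
        # trailing atoms outside MODEL/ENDMDL (or a file with no MODELs)
        if frames and len(current) != len(frames[0]):
            raise FormatError(
                f"MODEL {model_index or 'trailing block'} has {len(current)} "
                f"atoms, expected {len(frames[0])}"
            )
        frames.append(np.array(current, dtype=float))
    if not frames:
        raise FormatError("PDB file contains no coordinates")

    traj = Trajectory([Frame(p, box, time=float(i)) for i, p in enumerate(frames)])
    return PDBNames(names, resnames, resids), traj


def write_pdb(
    path: str | os.PathLike,
    trajectory: Trajectory,
    atom_names: Sequence[str] | None = None,
    residue_names: Sequence[str] | None = None,
    residue_ids: Sequence[int] | None = None,
) -> None:
    """Write a multi-MODEL PDB (coordinates rounded to 3 decimals)."""
    n = trajectory.n_atoms
    atom_names = list(atom_names) if atom_names is not None else ["X"] * n
    residue_names = list(residue_names) if residue_names is not None else ["UNK"] * n
    residue_ids = list(residue_ids) if residue_ids is not None else [1] * n
    box = trajectory[0].box
    cryst = (
        f"CRYST1{box.lx:9.3f}{box.ly:9.3f}{box.lz:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
    )
    with open(path, "w") as fh:
        for m, frame in enumerate(trajectory, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            fh.write(cryst)  # per-MODEL box, the convention MD viewers expect
            for i in range(n):
                x, y, z = frame.positions[i]
                name = atom_names[i][:4]
                fh.write(
                    f"ATOM  {min(i + 1, 99999):5d} {name:<4s} "
                    f"{residue_names[i][:4]:<4s} {residue_ids[i] % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ------------------------------------------------------------ extended XYZ

_LATTICE = re.compile(r'Lattice\s*=\s*"([^"]+)"', re.IGNORECASE)
_TIME = re.compile(r"Time\s*=\s*([0-9eE+.\-]+)", re.IGNORECASE)


def read_xyz(path: str | os.PathLike) -> Trajectory:
    """Read an extended-XYZ trajectory (Lattice="..." in the comment line).

    Only diagonal (orthorhombic) lattices are accepted; off-diagonal terms
    raise an unsupported-geometry error.  Full float precision.
    """
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"expected atom count at line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _LATTICE.search(comment)
        if not m:
            raise FormatError(
                f"frame {frame_no}: comment line lacks a Lattice specification"
            )
        cell = np.array([float(v) for v in m.group(1).split()], dtype=float)
        if cell.size != 9:
            raise FormatError(f"frame {frame_no}: Lattice must have 9 components")
        cell = cell.reshape(3, 3)
        off = cell - np.diag(np.diag(cell))
        if np.any(np.abs(off) > 1e-10):
            raise FormatError(
                f"frame {frame_no}: non-orthorhombic lattice is unsupported"
            )
        box = Box(cell[0, 0], cell[1, 1], cell[2, 2])
        tmatch = _TIME.search(comment)
        time = float(tmatch.group(1)) if tmatch else float(frame_no)
        coords = np.empty((n, 3), dtype=float)
        for k in range(n):
            parts = lines[i + 2 + k].split()
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(coords, box, time=time))
        i += 2 + n
        frame_no += 1
    if not frames:
        raise FormatError("empty XYZ file")
    return Trajectory(frames)


def write_xyz(
    path: str | os.PathLike,
    trajectory: Trajectory,
    symbols: Sequence[str] | None = None,
) -> None:
    n = trajectory.n_atoms
    symbols = list(symbols) if symbols is not None else ["X"] * n
    with open(path, "w") as fh:
        for frame in trajectory:
            b = frame.box
            fh.write(f"{n}\n")
            fh.write(
                f'Lattice="{b.lx:.10g} 0 0 0 {b.ly:.10g} 0 0 0 {b.lz:.10g}" '
                f'Properties=species:S:1:pos:R:3 Time={frame.time:.10g}\n'
            )
            for i in range(n):
                x, y, z = frame.positions[i]
                fh.write(f"{symbols[i]} {x:.12g} {y:.12g} {z:.12g}\n")
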