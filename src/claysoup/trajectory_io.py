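"""Multi-frame trajectory I/O with periodic-cell and timing metadata.

The on-disk format is concatenated XYZ with an extended-XYZ ``Lattice=``
record in every comment line (orthorhombic cells only).  All lengths are in
Å and all times in fs.  Coordinates are written with six decimal places,
which makes ``read_trajectory(write_trajectory(t))`` the identity at that
precision.

Coordinates are *not* wrapped into the cell on read: downstream modules
apply the minimum-image convention to every distance, and unwrapped
coordinates preserve continuity for displacement and RMSD analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SimulationCell",
    "Frame",
    "Trajectory",
    "TrajectoryError",
    "TrajectoryFormatError",
    "TrajectoryStructureError",
    "UnknownElementError",
    "read_trajectory",
    "write_trajectory",
    "ELEMENT_SYMBOLS",
]

# IUPAC element symbols, H..Og — used only to validate input files.
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


class TrajectoryError(Exception):
    """Base class for trajectory I/O problems."""


class TrajectoryFormatError(TrajectoryError):
    """A line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TrajectoryStructureError(TrajectoryError):
    """Frames disagree on atom count or element identity."""


class UnknownElementError(TrajectoryError):
    """An element symbol is not in the periodic table."""


@dataclass(frozen=True)
class SimulationCell:
    """Orthorhombic periodic cell with edge lengths in Å."""

    a: float
    b: float
    c: float
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"cell lengths must be positive, got {(self.a, self.b, self.c)}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @property
    def volume(self) -> float:
        return float(self.a * self.b * self.c)

    def min_edge(self) -> float:
        return float(min(self.a, self.b, self.c))


@dataclass
class Frame:
    """One snapshot: ordinal index, time in fs, N×3 Cartesian Å positions."""

    index: int
    time: float
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be N×3, got shape {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.index < 0:
            raise ValueError("frame index must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class TrajectoryMetadata:
    """Optional provenance of the MD run the trajectory came from."""

    temperature: float | None = None  # K
    timestep_fs: float | None = None  # MD integration step
    save_stride: int | None = None  # MD steps per saved frame


@dataclass
class Trajectory:
    """Element list + ordered frames + cell.

    Frame times must be strictly increasing and uniformly spaced; the
    element list is shared by every frame.
    """

    elements: list[str]
    frames: list[Frame]
    cell: SimulationCell
    metadata: TrajectoryMetadata = field(default_factory=TrajectoryMetadata)

    def __post_init__(self):
        self.elements = list(self.elements)
        for el in self.elements:
            if el not in ELEMENT_SYMBOLS:
                raise UnknownElementError(f"unknown element symbol {el!r}")
        n = len(self.elements)
        for fr in self.frames:
            if fr.n_atoms != n:
                raise TrajectoryStructureError(
                    f"frame {fr.index} has {fr.n_atoms} atoms, expected {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        if len(times) > 2:
            spacings = np.diff(times)
            if not np.allclose(spacings, spacings[0], rtol=1e-6, atol=1e-6):
                raise ValueError("frame times must be uniformly spaced")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)

    @property
    def frame_spacing_fs(self) -> float:
        """Time between consecutive saved frames, fs."""
        if self.n_frames >= 2:
            return float(self.frames[1].time - self.frames[0].time)
        if self.metadata.timestep_fs and self.metadata.save_stride:
            return self.metadata.timestep_fs * self.metadata.save_stride
        return 4.0  # default: 20 ps / 5000 frames

    @property
    def duration_ps(self) -> float:
        """Sampled duration: n_frames × frame spacing, in ps."""
        return self.n_frames * self.frame_spacing_fs / 1000.0

    def positions_array(self) -> np.ndarray:
        """All coordinates as an (n_frames, N, 3) array."""
        return np.stack([fr.positions for fr in self.frames])

    def __len__(self) -> int:
        return self.n_frames


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-+0-9.eE]+)")


def _parse_lattice(comment: str, line_no: int) -> SimulationCell | None:
    m = _LATTICE_RE.search(comment)
    if m is None:
        return None
    try:
        nums = [float(x) for x in m.group(1).split()]
    except ValueError as exc:
        raise TrajectoryFormatError(f"bad Lattice record: {exc}", line_no) from None
    if len(nums) != 9:
        raise TrajectoryFormatError("Lattice record must have 9 numbers", line_no)
    mat = np.array(nums).reshape(3, 3)
    off = mat - np.diag(np.diag(mat))
    if np.any(off != 0.0):
        raise TrajectoryFormatError("only orthorhombic (diagonal) lattices supported", line_no)
    return SimulationCell(mat[0, 0], mat[1, 1], mat[2, 2])


def read_trajectory(
    path: str | Path,
    cell: SimulationCell | None = None,
    frame_spacing: float = 4.0,
    metadata: TrajectoryMetadata | None = None,
) -> Trajectory:
    """Read a concatenated-(extended-)XYZ file.

    Parameters
    ----------
    path:
        File of repeated blocks: count line, comment line, then one
        ``element x y z`` line per atom.
    cell:
        Periodic cell to attach.  An extended-XYZ ``Lattice=`` record in the
        comment line overrides it.
    frame_spacing:
        Time between frames in fs; frame ``i`` gets time ``i × frame_spacing``
        unless the comment line carries a ``Time=`` record.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    elements: list[str] | None = None
    frames: list[Frame] = []
    file_cell = cell
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"expected atom count, got {lines[i]!r}", i + 1
            ) from None
        if n <= 0:
            raise TrajectoryFormatError("atom count must be positive", i + 1)
        if i + 1 >= len(lines):
            raise TrajectoryFormatError("missing comment line", i + 2)
        comment = lines[i + 1]
        lat = _parse_lattice(comment, i + 2)
        if lat is not None:
            file_cell = lat
        tm = _TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else frame_idx * frame_spacing
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise TrajectoryFormatError(
                f"frame {frame_idx + 1} truncated: expected {n} atom lines", len(lines)
            )
        frame_elements: list[str] = []
        coords = np.empty((n, 3), dtype=float)
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"expected 'element x y z', got {line!r}", i + 3 + j
                )
            sym = parts[0]
            if sym not in ELEMENT_SYMBOLS:
                raise UnknownElementError(
                    f"line {i + 3 + j}: unknown element symbol {sym!r}"
                )
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryFormatError(
                    f"unparseable coordinate in {line!r}", i + 3 + j
                ) from None
            frame_elements.append(sym)
        if elements is None:
            elements = frame_elements
        else:
            if len(frame_elements) != len(elements):
                raise TrajectoryStructureError(
                    f"frame {frame_idx + 1} has {len(frame_elements)} atoms, "
                    f"expected {len(elements)} (frame 1)"
                )
            if frame_elements != elements:
                raise TrajectoryStructureError(
                    f"frame {frame_idx + 1} changes element identities"
                )
        frames.append(Frame(index=frame_idx, time=time, positions=coords))
        frame_idx += 1
        i += 2 + n
    if elements is None:
        raise TrajectoryFormatError("file contains no frames", 1)
    if file_cell is None:
        raise ValueError("no cell given and no Lattice record in file")
    return Trajectory(
        elements=elements,
        frames=frames,
        cell=file_cell,
        metadata=metadata or TrajectoryMetadata(),
    )


def write_trajectory(traj: Trajectory, path: str | Path, precision: int = 6) -> None:
    """Write extended-XYZ with a ``Lattice=`` + ``Time=`` record per frame."""
    if traj.n_frames == 0:
        raise ValueError("cannot write a trajectory with zero frames")
    path = Path(path)
    cell = traj.cell
    lattice = (
        f'Lattice="{cell.a:.6f} 0.0 0.0 0.0 {cell.b:.6f} 0.0 0.0 0.0 {cell.c:.6f}"'
    )
    fmt = f"{{sym}} {{x:.{precision}f}} {{y:.{precision}f}} {{z:.{precision}f}}"
    out: list[str] = []
    for fr in traj.frames:
        out.append(str(traj.n_atoms))
        out.append(
            f"{lattice} Properties=species:S:1:pos:R:3 Time={fr.time:.6f}"
        )
        for sym, (x, y, z) in zip(traj.elements, fr.positions):
            out.append(fmt.format(sym=sym, x=x, y=y, z=z))
    path.write_text("\n".join(out) + "\n")
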