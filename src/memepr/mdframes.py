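"""Multi-frame coordinate containers and light trajectory file dialects.

:class:`TrajectoryFrames` stores an ordered set of frames with a constant
atom roster (molecule id, residue name, atom name) and coordinates in Å,
plus an optional orthorhombic box per frame.  Two text dialects:

``pdb_like``
    Standard multi-MODEL PDB, read and written through MDAnalysis.

``gro_like``
    Concatenated fixed-column frames in the GROMACS .gro column layout but
    with coordinates in Å (title line, atom count, atom lines, box line per
    frame); kept deliberately simple so frames survive a round trip at
    format precision (1e-3 Å).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "TrajectoryFrames",
    "TrajectoryError",
    "read_frames",
    "write_frames",
]


class TrajectoryError(ValueError):
    """Invalid trajectory data; carries the frame index when known."""

    def __init__(self, message: str, frame: Optional[int] = None):
        self.frame = frame
        suffix = f" (frame {frame})" if frame is not None else ""
        super().__init__(message + suffix)


@dataclass
class TrajectoryFrames:
    """Constant-roster coordinate frames (Å) with optional orthorhombic box."""

    mol_ids: np.ndarray  # (n_atoms,) int
    resnames: np.ndarray  # (n_atoms,) str
    atom_names: np.ndarray  # (n_atoms,) str
    coords: np.ndarray  # (n_frames, n_atoms, 3) float, Å
    box: Optional[np.ndarray] = None  # (n_frames, 3) float, Å
    normal_axis: int = 2  # bilayer normal (default z)

    def __post_init__(self) -> None:
        self.mol_ids = np.asarray(self.mol_ids)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise TrajectoryError("need at least one frame")
        n_atoms = self.coords.shape[1]
        for name, arr in (
            ("mol_ids", self.mol_ids),
            ("resnames", self.resnames),
            ("atom_names", self.atom_names),
        ):
            if arr.shape != (n_atoms,):
                raise TrajectoryError(
                    f"{name} length {arr.shape} does not match {n_atoms} atoms"
                )
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise TrajectoryError(
                    f"box must have shape (n_frames, 3), got {self.box.shape}"
                )
        if self.normal_axis not in (0, 1, 2):
            raise TrajectoryError("normal_axis must be 0 (x), 1 (y) or 2 (z)")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def atom_index(self) -> dict[tuple[int, str], int]:
        """(mol_id, atom_name) -> roster position; roster must be unambiguous."""
        index: dict[tuple[int, str], int] = {}
        for i, (mol, name) in enumerate(zip(self.mol_ids, self.atom_names)):
            key = (int(mol), str(name))
            if key in index:
                raise TrajectoryError(f"duplicate atom {key} in roster")
            index[key] = i
        return index


def _read_pdb_like(path: Path) -> TrajectoryFrames:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            universe = mda.Universe(str(path))
        except Exception as exc:  # MDAnalysis raises a mix of error types
            raise TrajectoryError(f"cannot parse {path.name}: {exc}") from exc
        coords = []
        boxes = []
        have_box = True
        try:
            for ts in universe.trajectory:
                coords.append(universe.atoms.positions.astype(float).copy())
                if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                    have_box = False
                else:
                    boxes.append(ts.dimensions[:3].astype(float).copy())
        except Exception as exc:
            raise TrajectoryError(
                f"cannot read {path.name}: {exc}", frame=len(coords)
            ) from exc
        atoms = universe.atoms
        return TrajectoryFrames(
            mol_ids=atoms.resids.astype(int),
            resnames=np.array(atoms.resnames, dtype=object),
            atom_names=np.array(atoms.names, dtype=object),
            coords=np.array(coords),
            box=np.array(boxes) if have_box and boxes else None,
        )


def _read_gro_like(path: Path) -> TrajectoryFrames:
    lines = path.read_text(encoding="utf-8").splitlines()
    pos = 0
    frames: list[np.ndarray] = []
    boxes: list[np.ndarray] = []
    roster: Optional[tuple[tuple[int, str, str], ...]] = None
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        if pos + 1 >= len(lines):
            raise TrajectoryError("truncated frame header", frame=frame_no)
        try:
            n_atoms = int(lines[pos + 1].strip())
        except ValueError:
            raise TrajectoryError(
                f"expected atom count, got {lines[pos + 1]!r}", frame=frame_no
            )
        atom_lines = lines[pos + 2 : pos + 2 + n_atoms]
        if len(atom_lines) < n_atoms:
            raise TrajectoryError("truncated frame", frame=frame_no)
        this_roster = []
        xyz = np.empty((n_atoms, 3))
        for k, line in enumerate(atom_lines):
            try:
                resid = int(line[0:5])
                resname = line[5:10].strip()
                name = line[10:15].strip()
                xyz[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except (ValueError, IndexError):
                raise TrajectoryError(
                    f"unparseable atom line {line!r}", frame=frame_no
                )
            this_roster.append((resid, resname, name))
        box_line = lines[pos + 2 + n_atoms].split()
        try:
            box = np.array([float(v) for v in box_line[:3]])
        except (ValueError, IndexError):
            raise TrajectoryError("unparseable box line", frame=frame_no)
        this_roster = tuple(this_roster)
        if roster is None:
            roster = this_roster
        elif this_roster != roster:
            raise TrajectoryError("atom roster changed mid-file", frame=frame_no)
        frames.append(xyz)
        boxes.append(box)
        pos += 3 + n_atoms
        frame_no += 1
    if roster is None:
        raise TrajectoryError("no frames found")
    return TrajectoryFrames(
        mol_ids=np.array([r[0] for r in roster]),
        resnames=np.array([r[1] for r in roster], dtype=object),
        atom_names=np.array([r[2] for r in roster], dtype=object),
        coords=np.array(frames),
        box=np.array(boxes) if np.all(np.array(boxes) > 0) else None,
    )


def read_frames(path, dialect: str = "pdb_like") -> TrajectoryFrames:
    """Read a multi-frame coordinate file.

    Parameters
    ----------
    path : file path
    dialect : {"pdb_like", "gro_like"}
    """
    path = Path(path)
    if dialect == "pdb_like":
        return _read_pdb_like(path)
    if dialect == "gro_like":
        return _read_gro_like(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_pdb_like(frames: TrajectoryFrames, path: Path) -> None:
    import MDAnalysis as mda

    mol_ids = frames.mol_ids.astype(int)
    _, resindex = np.unique(mol_ids, return_inverse=True)
    n_res = int(resindex.max()) + 1
    universe = mda.Universe.empty(
        n_atoms=frames.n_atoms,
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    res_order = np.zeros(n_res, dtype=int)
    res_order[resindex] = mol_ids
    res_names = np.empty(n_res, dtype=object)
    res_names[resindex] = frames.resnames
    universe.add_TopologyAttr("names", [str(n) for n in frames.atom_names])
    universe.add_TopologyAttr("resnames", [str(n) for n in res_names])
    universe.add_TopologyAttr("resids", res_order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), frames.n_atoms, multiframe=True) as writer:
            for i in range(frames.n_frames):
                universe.atoms.positions = frames.coords[i]
                if frames.box is not None:
                    universe.dimensions = [*frames.box[i], 90.0, 90.0, 90.0]
                writer.write(universe.atoms)


def _write_gro_like(frames: TrajectoryFrames, path: Path) -> None:
    out = []
    for i in range(frames.n_frames):
        out.append(f"memepr frame {i}")
        out.append(f"{frames.n_atoms:5d}")
        for k in range(frames.n_atoms):
            x, y, z = frames.coords[i, k]
            out.append(
                f"{int(frames.mol_ids[k]) % 100000:5d}"
                f"{str(frames.resnames[k]):<5s}{str(frames.atom_names[k]):>5s}"
                f"{(k + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        box = frames.box[i] if frames.box is not None else np.zeros(3)
        out.append(f"{box[0]:10.4f}{box[1]:10.4f}{box[2]:10.4f}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def write_frames(frames: TrajectoryFrames, path, dialect: str = "pdb_like") -> None:
    """Write frames re-readable by :func:`read_frames` at format precision."""
    path = Path(path)
    if dialect == "pdb_like":
        _write_pdb_like(frames, path)
    elif dialect == "gro_like":
        _write_gro_like(frames, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
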