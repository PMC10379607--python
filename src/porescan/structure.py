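"""Coordinate containers and structure/trajectory file I/O.

Internally everything is nanometres; PDB files (which are in Ångström) are
converted on read/write. Atoms are matched strictly by position in the file
(index i ↔ index i); no name-based mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import EmptyInputError, FormatError, InvalidArgumentError, ShapeError

A_PER_NM = 10.0


@dataclass
class Structure:
    """A single labelled conformation.

    Parameters
    ----------
    coords : (n_atoms, 3) float array, nm
    atom_ids : optional ordered identifiers; defaults to 0..n_atoms-1
    """

    coords: np.ndarray
    atom_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coords must be (n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise EmptyInputError("structure has zero atoms")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidArgumentError("coordinates must be finite")
        if self.atom_ids is None:
            self.atom_ids = np.arange(self.n_atoms)
        else:
            self.atom_ids = np.asarray(self.atom_ids)
            if len(self.atom_ids) != self.n_atoms:
                raise ShapeError("atom_ids length does not match coords")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Structure":
        return Structure(self.coords.copy(), np.array(self.atom_ids))


@dataclass
class ReplicaTrajectory:
    """Ordered frames of one replica.

    Frames are stored as one ``(n_frames, n_atoms, 3)`` array in nm. Frame
    *i* is at time ``origin_time + i * frame_interval`` (ps). By convention
    the first saved frame is at ``t = frame_interval``, i.e. a trajectory of
    duration T ns sampled every dt ps has exactly ``T*1000/dt`` frames.
    """

    replica_id: str
    coords: np.ndarray
    frame_interval: float  # ps
    origin_time: float | None = None  # ps; defaults to frame_interval

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise EmptyInputError("trajectory has zero frames")
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be positive")
        if self.origin_time is None:
            self.origin_time = self.frame_interval

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps."""
        return self.origin_time + self.frame_interval * np.arange(self.n_frames)

    def frame(self, i: int) -> Structure:
        return Structure(self.coords[i])

    def __iter__(self) -> Iterator[Structure]:
        return (self.frame(i) for i in range(self.n_frames))


def _to_atom_array(coords_nm: np.ndarray) -> struc.AtomArray:
    n = coords_nm.shape[0]
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords_nm, dtype=float) * A_PER_NM
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, "GLY")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, False)
    return arr


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB (coordinates nm → Å)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure.coords))
    pdb.write(str(path))


def write_trajectory(replica: ReplicaTrajectory, path: str | Path) -> None:
    """Write a multi-model PDB, one MODEL per frame."""
    template = _to_atom_array(replica.coords[0])
    stack = struc.AtomArrayStack(replica.n_frames, replica.n_atoms)
    for name in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(name, template.get_annotation(name))
    stack.coord = replica.coords * A_PER_NM
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a single-model structure; coordinates converted Å → nm."""
    if format != "pdb":
        raise InvalidArgumentError(f"unsupported structure format: {format!r}")
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except FileNotFoundError:
        raise
    except Exception as exc:  # biotite raises assorted ValueErrors
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise EmptyInputError(f"no atoms found in {path}")
    return Structure(arr.coord / A_PER_NM)


def read_trajectory(
    reference_path: str | Path,
    traj_path: str | Path,
    format: str = "multi-model-pdb",
    frame_interval: float = 10.0,
    replica_id: str | None = None,
) -> ReplicaTrajectory:
    """Read a trajectory and check it against a reference structure.

    ``multi-model-pdb`` is the native format; ``xtc``/``dcd`` are read
    through mdtraj using the reference PDB as topology. ``frame_interval``
    (ps) overrides any file metadata, which plain PDB lacks anyway.
    """
    reference = read_structure(reference_path)
    traj_path = Path(traj_path)
    if replica_id is None:
        replica_id = traj_path.stem
    if format in ("multi-model-pdb", "pdb"):
        try:
            pdb = PDBFile.read(str(traj_path))
            stack = pdb.get_structure()
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise FormatError(f"could not parse PDB trajectory {traj_path}: {exc}") from exc
        coords = np.atleast_3d(stack.coord)
        if coords.ndim == 2:  # single model read back as AtomArray
            coords = coords[None]
        coords = coords / A_PER_NM
    elif format in ("xtc", "dcd"):
        import mdtraj

        traj = mdtraj.load(str(traj_path), top=str(reference_path))
        coords = np.asarray(traj.xyz, dtype=float)  # mdtraj is already nm
    else:
        raise InvalidArgumentError(f"unsupported trajectory format: {format!r}")
    if coords.shape[1] != reference.n_atoms:
        raise ShapeError(
            f"trajectory has {coords.shape[1]} atoms but reference has {reference.n_atoms}"
        )
    return ReplicaTrajectory(replica_id, coords, frame_interval)
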