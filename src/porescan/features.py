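"""Per-frame observables: superposed RMSD and fraction of native contacts.

The two quantities every downstream stage consumes:

* **RMSD** between two conformations, minimised over rigid motions with the
  Kabsch algorithm (all atoms, strictly index-matched). ``fit=False`` gives
  the raw deviation without superposition.
* **FNC** — the fraction of reference-frame contacts (atom pairs within a
  hard cutoff, 0.8 nm = 8 Å by default) still present in a frame. Hard
  cutoff, no smoothing.

Both are offered in single-pair form and in vectorised per-trajectory form
(batched 3×3 SVDs), which is what makes 200-replica campaigns cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    InvalidArgumentError,
    ShapeError,
    UndefinedFractionError,
)
from .structure import ReplicaTrajectory, Structure

DEFAULT_CONTACT_CUTOFF_NM = 0.8  # the canonical hard 8 Å contact cutoff


# --------------------------------------------------------------------------
# Kabsch superposition
# --------------------------------------------------------------------------

def _kabsch_rmsd_batch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimum RMSD of each frame in ``mobile`` (F, n, 3) onto ``target`` (n, 3).

    Uses the closed form rmsd² = (tr(PᵀP) + tr(QᵀQ) − 2(σ₁+σ₂±σ₃))/n with the
    sign of σ₃ flipped when the optimal orthogonal map would be a reflection.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.ndim == 2:
        mobile = mobile[None]
    p = mobile - mobile.mean(axis=1, keepdims=True)
    q = target - target.mean(axis=0)
    h = np.einsum("fni,nj->fij", p, q)
    s = np.linalg.svd(h, compute_uv=False)
    # det(H) < 0 → proper rotation requires flipping the smallest singular value
    sign = np.sign(np.linalg.det(h))
    sign[sign == 0] = 1.0
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    n = mobile.shape[1]
    sq = (np.einsum("fni,fni->f", p, p) + np.einsum("ni,ni->", q, q) - 2.0 * trace) / n
    return np.sqrt(np.maximum(sq, 0.0))


def superpose(mobile: Structure, target: Structure):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords @ rotation.T + translation`` maps mobile onto target in the
    least-squares sense. The rotation is proper (det = +1).

    Raises
    ------
    DegenerateGeometryError
        if there are fewer than three non-collinear atoms, in which case the
        optimal rotation is not unique (the RMSD value still is; use
        :func:`rmsd` for that).
    """
    if mobile.n_atoms != target.n_atoms:
        raise ShapeError(
            f"atom counts differ: {mobile.n_atoms} vs {target.n_atoms}"
        )
    p = mobile.coords - mobile.coords.mean(axis=0)
    q = target.coords - target.coords.mean(axis=0)
    if mobile.n_atoms < 3 or np.linalg.matrix_rank(p, tol=1e-10) < 2:
        raise DegenerateGeometryError(
            "superposition needs at least 3 non-collinear atoms"
        )
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = target.coords.mean(axis=0) - rot @ mobile.coords.mean(axis=0)
    value = float(_kabsch_rmsd_batch(mobile.coords[None], target.coords)[0])
    return rot, trans, value


def rmsd(x: Structure, y: Structure, fit: bool = True) -> float:
    """All-atom RMSD between two conformations (nm).

    With ``fit=True`` (default) the value is minimised over rigid motions
    (Kabsch); with ``fit=False`` coordinates are compared as-is.
    """
    if x.n_atoms != y.n_atoms:
        raise ShapeError(f"atom counts differ: {x.n_atoms} vs {y.n_atoms}")
    if not fit:
        return float(np.sqrt(np.mean(np.sum((x.coords - y.coords) ** 2, axis=1))))
    if x.n_atoms < 2:
        return 0.0
    return float(_kabsch_rmsd_batch(x.coords[None], y.coords)[0])


def rmsd_series(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch RMSD of every frame in ``coords`` (F, n, 3) vs ``reference`` (n, 3)."""
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.shape[1] != reference.shape[0]:
        raise ShapeError("frame atom count does not match reference")
    return _kabsch_rmsd_batch(coords, reference)


# --------------------------------------------------------------------------
# Native contacts
# --------------------------------------------------------------------------

@dataclass
class ContactSet:
    """Unordered atom-index pairs within ``cutoff`` in a stated reference."""

    pairs: np.ndarray  # (n_pairs, 2) int, i < j
    cutoff: float  # nm
    n_atoms: int
    reference_id: str = "reference"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if self.n_pairs and (
            np.any(self.pairs[:, 0] >= self.pairs[:, 1])
            or np.any(self.pairs >= self.n_atoms)
            or np.any(self.pairs < 0)
        ):
            raise InvalidArgumentError("contact pairs must satisfy 0 <= i < j < n_atoms")

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def native_contacts(
    reference: Structure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    min_sequence_separation: int = 0,
    reference_id: str = "reference",
) -> ContactSet:
    """All pairs (i, j), j − i ≥ max(1, min_sequence_separation), within ``cutoff``.

    ``min_sequence_separation=0`` (the bead-model default) only excludes
    self pairs; use 3 for real chains to drop trivially bonded neighbours.
    """
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be positive")
    sep = max(1, int(min_sequence_separation))
    diff = reference.coords[:, None, :] - reference.coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    i, j = np.triu_indices(reference.n_atoms, k=sep)
    keep = dist[i, j] <= cutoff
    pairs = np.column_stack([i[keep], j[keep]])
    return ContactSet(pairs, cutoff, reference.n_atoms, reference_id)


def fnc(frame: Structure, contacts: ContactSet) -> float:
    """Fraction of native contacts of ``frame`` with respect to ``contacts``."""
    if frame.n_atoms != contacts.n_atoms:
        raise ShapeError("frame atom count does not match contact indexing")
    return float(fnc_series(frame.coords[None], contacts)[0])


def fnc_series(coords: np.ndarray, contacts: ContactSet) -> np.ndarray:
    """FNC of every frame in ``coords`` (F, n, 3)."""
    if contacts.n_pairs == 0:
        raise UndefinedFractionError("fraction undefined for an empty contact set")
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] != contacts.n_atoms:
        raise ShapeError("frame atom count does not match contact indexing")
    d = coords[:, contacts.pairs[:, 0]] - coords[:, contacts.pairs[:, 1]]
    dist = np.sqrt(np.sum(d**2, axis=-1))
    return np.mean(dist <= contacts.cutoff, axis=1)


# --------------------------------------------------------------------------
# Per-replica feature series
# --------------------------------------------------------------------------

@dataclass
class FeatureSeries:
    """Per-frame (time, RMSD, FNC) of one replica against its first frame."""

    replica_id: str
    times: np.ndarray  # ps
    rmsd: np.ndarray  # nm
    fnc: np.ndarray  # fraction

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        self.fnc = np.asarray(self.fnc, dtype=float)
        if not (len(self.times) == len(self.rmsd) == len(self.fnc)):
            raise ShapeError("times, rmsd and fnc must have equal lengths")
        if len(self.times) == 0:
            raise EmptyInputError("empty feature series")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        """Sampling interval in ps (from the time grid; series are uniform)."""
        if self.n_frames < 2:
            return float(self.times[0])
        return float(self.times[1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replica_id": self.replica_id,
                "time_ps": self.times,
                "rmsd_nm": self.rmsd,
                "fnc": self.fnc,
            }
        )


def featurize(
    replica: ReplicaTrajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    min_sequence_separation: int = 0,
) -> FeatureSeries:
    """RMSD and FNC of every frame against the replica's own first frame.

    The first frame is the reference by construction, so ``rmsd[0] == 0``
    and ``fnc[0] == 1`` exactly.
    """
    reference = replica.coords[0]
    contacts = native_contacts(
        Structure(reference), cutoff, min_sequence_separation, replica.replica_id
    )
    r = rmsd_series(replica.coords, reference)
    f = fnc_series(replica.coords, contacts)
    r[0] = 0.0
    f[0] = 1.0
    return FeatureSeries(replica.replica_id, replica.times, r, f)


def write_features_tsv(series_list: list[FeatureSeries], path: str | Path) -> None:
    """Write one long TSV (`replica_id  time_ps  rmsd_nm  fnc`) for many replicas."""
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_features_tsv(path: str | Path) -> list[FeatureSeries]:
    df = pd.read_csv(path, sep="\t", dtype={"replica_id": str})
    out = []
    for rid, grp in df.groupby("replica_id", sort=False):
        out.append(
            FeatureSeries(
                str(rid),
                grp["time_ps"].to_numpy(),
                grp["rmsd_nm"].to_numpy(),
                grp["fnc"].to_numpy(),
            )
        )
    return out
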