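"""The 3-D pairwise tuple space: P(x, y) = (RMSD(x,y), FNC(x,x₀), FNC(y,y₀)).

Frames subsampled from every kept replica are compared pairwise; each
unordered pair {x, y} yields one tuple of the pair RMSD plus each frame's
fraction of native contacts against its *own replica's* first frame.
Tuples that coincide after rounding are merged and carry a multiplicity
weight, and the cloud is standardised (weighted z-score by default) before
clustering.

Frames are ordered canonically (replica id, then frame index) so the
fnc_x / fnc_y assignment is reproducible regardless of input order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateScalingError, EmptyInputError, InvalidArgumentError
from .features import (
    DEFAULT_CONTACT_CUTOFF_NM,
    fnc_series,
    native_contacts,
    rmsd_series,
)
from .structure import ReplicaTrajectory, Structure

PAIRINGS = ("all_cross", "within")


def subsample(replica: ReplicaTrajectory, stride_ns: float = 1.0) -> np.ndarray:
    """Indices of frames at t = stride, 2·stride, … (ns).

    The replica's first frame — the FNC reference — is *not* part of the
    subsample; it is retained separately by :func:`prepare_replica_frames`.
    ``stride_ns`` must be a multiple of the frame interval.
    """
    stride_ps = stride_ns * 1000.0
    ratio = stride_ps / replica.frame_interval
    if stride_ns <= 0 or abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise InvalidArgumentError(
            f"stride {stride_ns} ns is not a positive multiple of the "
            f"{replica.frame_interval} ps frame interval"
        )
    times = replica.times
    rem = np.mod(times, stride_ps)
    on_grid = (np.minimum(rem, stride_ps - rem) < 1e-6) & (times > stride_ps / 2)
    return np.nonzero(on_grid)[0]


@dataclass
class ReplicaFrames:
    """Subsampled frames of one replica plus their FNC values."""

    replica_id: str
    frame_indices: np.ndarray  # indices into the full trajectory
    coords: np.ndarray  # (m, n_atoms, 3)
    fnc: np.ndarray  # (m,) vs this replica's own first frame

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def prepare_replica_frames(
    replica: ReplicaTrajectory,
    stride_ns: float = 1.0,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    min_sequence_separation: int = 0,
) -> ReplicaFrames:
    """Subsample a replica and compute each kept frame's FNC."""
    idx = subsample(replica, stride_ns)
    contacts = native_contacts(
        Structure(replica.coords[0]), cutoff, min_sequence_separation, replica.replica_id
    )
    coords = replica.coords[idx]
    return ReplicaFrames(replica.replica_id, idx, coords, fnc_series(coords, contacts))


@dataclass
class TupleSet:
    """A (possibly merged) weighted set of pair tuples.

    ``values`` holds the raw coordinates (rmsd_xy nm, fnc_x, fnc_y);
    ``pair_provenance`` one row per *original* frame pair
    (replica_index_x, frame_x, replica_index_y, frame_y) with
    ``pair_to_tuple`` mapping each pair row to its (merged) tuple row, so
    tuple weights always equal their provenance multiplicities.
    """

    values: np.ndarray  # (U, 3)
    weights: np.ndarray  # (U,)
    pair_provenance: np.ndarray  # (P, 4) int
    pair_to_tuple: np.ndarray  # (P,) int
    replica_ids: list[str] = field(default_factory=list)

    @property
    def n_tuples(self) -> int:
        return self.values.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def provenance_of(self, u: int) -> np.ndarray:
        """All (rep_ix, frame_x, rep_iy, frame_y) pairs behind tuple ``u``."""
        return self.pair_provenance[self.pair_to_tuple == u]

    def first_pairs(self) -> np.ndarray:
        """The canonical (lowest pair row) provenance pair per tuple, (U, 4)."""
        order = np.argsort(self.pair_to_tuple, kind="stable")
        sorted_p2t = self.pair_to_tuple[order]
        firsts = order[np.searchsorted(sorted_p2t, np.arange(self.n_tuples))]
        return self.pair_provenance[firsts]


def build_tuples(
    replica_frames: list[ReplicaFrames], pairing: str = "all_cross"
) -> TupleSet:
    """Unmerged tuple set over all unordered frame pairs.

    ``all_cross`` pairs frames within and across replicas; ``within``
    restricts to same-replica pairs (which keeps each latent conformation's
    tuples from mixing with cross-state pairs). With x before y in the
    canonical order, fnc_x belongs to x and fnc_y to y.
    """
    if pairing not in PAIRINGS:
        raise InvalidArgumentError(f"pairing must be one of {PAIRINGS}")
    if not replica_frames:
        raise EmptyInputError("no replica frames given")
    ordered = sorted(replica_frames, key=lambda rf: rf.replica_id)
    replica_ids = [rf.replica_id for rf in ordered]
    coords = np.concatenate([rf.coords for rf in ordered], axis=0)
    fnc_all = np.concatenate([rf.fnc for rf in ordered])
    rep_idx = np.concatenate(
        [np.full(rf.n_frames, i, dtype=int) for i, rf in enumerate(ordered)]
    )
    frame_idx = np.concatenate([rf.frame_indices for rf in ordered])
    n = coords.shape[0]
    if n < 2:
        raise EmptyInputError("need at least two frames to build a pair tuple")
    rows_i, rows_j, rmsd_vals = [], [], []
    for i in range(n - 1):
        j = np.arange(i + 1, n)
        if pairing == "within":
            j = j[rep_idx[j] == rep_idx[i]]
            if j.size == 0:
                continue
        rows_i.append(np.full(j.size, i))
        rows_j.append(j)
        rmsd_vals.append(rmsd_series(coords[j], coords[i]))
    if not rows_i:
        raise EmptyInputError("pairing produced no frame pairs")
    ii = np.concatenate(rows_i)
    jj = np.concatenate(rows_j)
    values = np.column_stack([np.concatenate(rmsd_vals), fnc_all[ii], fnc_all[jj]])
    prov = np.column_stack([rep_idx[ii], frame_idx[ii], rep_idx[jj], frame_idx[jj]])
    m = values.shape[0]
    return TupleSet(values, np.ones(m), prov, np.arange(m), replica_ids)


def merge_weights(tuples: TupleSet, decimals: int = 4) -> TupleSet:
    """Merge tuples identical after rounding to ``decimals`` places.

    Merged coordinates are the rounded values; weights are summed (total
    weight conserved) and provenance concatenated via the pair→tuple map.
    """
    if decimals < 0:
        raise InvalidArgumentError("decimals must be >= 0")
    rounded = np.round(tuples.values, decimals)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    weights = np.bincount(inverse, weights=tuples.weights, minlength=uniq.shape[0])
    return TupleSet(
        uniq,
        weights,
        tuples.pair_provenance,
        inverse[tuples.pair_to_tuple],
        tuples.replica_ids,
    )


class TupleStandardScaler(BaseEstimator, TransformerMixin):
    """Weighted per-dimension standardisation of the tuple cloud.

    ``method="standard"`` subtracts the weighted mean and divides by the
    weighted (population) standard deviation; ``method="minmax"`` maps the
    weighted support onto [0, 1]. A zero-variance dimension gets scale 1
    with a warning rather than an error.
    """

    def __init__(self, method: str = "standard"):
        self.method = method

    def fit(self, X, y=None, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InvalidArgumentError("X must be 2-D")
        if self.method not in ("standard", "minmax"):
            raise InvalidArgumentError("method must be 'standard' or 'minmax'")
        if np.unique(X, axis=0).shape[0] < 2:
            raise DegenerateScalingError("scaling needs at least 2 distinct tuples")
        w = np.ones(X.shape[0]) if sample_weight is None else np.asarray(sample_weight, float)
        if self.method == "standard":
            mean = np.average(X, axis=0, weights=w)
            var = np.average((X - mean) ** 2, axis=0, weights=w)
            scale = np.sqrt(var)
        else:
            mean = X.min(axis=0)
            scale = X.max(axis=0) - mean
        zero = scale <= 1e-9 * np.maximum(1.0, np.abs(mean))
        if np.any(zero):
            warnings.warn(
                f"zero-variance dimension(s) {np.nonzero(zero)[0].tolist()}; scale set to 1",
                RuntimeWarning,
                stacklevel=2,
            )
            scale = np.where(zero, 1.0, scale)
        self.center_ = mean
        self.scale_ = scale
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.center_) / self.scale_

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        return X * self.scale_ + self.center_

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TupleStandardScaler":
        obj = cls(method=d["method"])
        obj.center_ = np.asarray(d["center"], dtype=float)
        obj.scale_ = np.asarray(d["scale"], dtype=float)
        obj.n_features_in_ = len(d["center"])
        return obj


@dataclass
class TupleSpace:
    """A merged tuple set together with its fitted scaler."""

    tuples: TupleSet
    scaled: np.ndarray  # (U, 3) standardised coordinates
    scaler: TupleStandardScaler
    subsample_stride: float = 1.0  # ns

    @property
    def weights(self) -> np.ndarray:
        return self.tuples.weights

    @property
    def total_weight(self) -> float:
        return self.tuples.total_weight


def scale(
    tuples: TupleSet, subsample_stride: float = 1.0, method: str = "standard"
) -> TupleSpace:
    """Fit the scaler (under tuple weights) and return the scaled space."""
    scaler = TupleStandardScaler(method=method)
    scaler.fit(tuples.values, sample_weight=tuples.weights)
    return TupleSpace(tuples, scaler.transform(tuples.values), scaler, subsample_stride)


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def write_tuples_tsv(tuples: TupleSet, path: str | Path) -> None:
    """`tuples.tsv`: coordinates, weight and the canonical provenance pair."""
    fp = tuples.first_pairs()
    ids = tuples.replica_ids
    pd.DataFrame(
        {
            "rmsd_nm": tuples.values[:, 0],
            "fnc_x": tuples.values[:, 1],
            "fnc_y": tuples.values[:, 2],
            "weight": tuples.weights,
            "x_replica": [ids[k] for k in fp[:, 0]],
            "x_frame": fp[:, 1],
            "y_replica": [ids[k] for k in fp[:, 2]],
            "y_frame": fp[:, 3],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tuples_tsv(path: str | Path) -> TupleSet:
    """Read `tuples.tsv` back (provenance reduced to the canonical pair)."""
    df = pd.read_csv(path, sep="\t", dtype={"x_replica": str, "y_replica": str})
    ids = sorted(set(df["x_replica"]) | set(df["y_replica"]))
    lookup = {r: k for k, r in enumerate(ids)}
    prov = np.column_stack(
        [
            df["x_replica"].map(lookup).to_numpy(),
            df["x_frame"].to_numpy(),
            df["y_replica"].map(lookup).to_numpy(),
            df["y_frame"].to_numpy(),
        ]
    )
    values = df[["rmsd_nm", "fnc_x", "fnc_y"]].to_numpy()
    return TupleSet(
        values, df["weight"].to_numpy(float), prov, np.arange(len(df)), ids
    )


def write_scaler_json(scaler: TupleStandardScaler, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scaler.to_dict(), indent=2))


def read_scaler_json(path: str | Path) -> TupleStandardScaler:
    return TupleStandardScaler.from_dict(json.loads(Path(path).read_text()))
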