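"""Weighted k-means over tuple space, elbow selection, KDE representatives.

The clustering stage answers three questions about the tuple cloud:

* how many conformational groups are there? — k-means over a k range with
  an automated elbow (knee of the inertia curve);
* how big is each group? — per-cluster population = total tuple weight;
* which single conformation pair best represents each group? — the member
  tuple closest (least squares) to the maximum of the cluster's weighted
  Gaussian kernel density estimate.

k-means and KDE are delegated to scikit-learn (with sample weights); the
estimator classes here add weighted semantics, canonical descending-
population labelling and the representative search.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.neighbors import KernelDensity

from .errors import DegenerateKDEError, InvalidArgumentError
from .structure import Structure, write_structure
from .tuples import TupleSpace

logger = logging.getLogger(__name__)


class WeightedKMeans(BaseEstimator, ClusterMixin):
    """k-means on weighted points with population-ordered labels.

    Thin estimator over :class:`sklearn.cluster.KMeans` (k-means++
    seeding, best of ``n_init`` restarts by inertia, deterministic for a
    fixed ``random_state``). A point of weight w is equivalent to w unit
    replicas of itself. After fitting, clusters are relabelled in
    descending order of population (total member weight), so label 0 is
    always the most populated cluster.

    Attributes (after ``fit``): ``cluster_centers_``, ``labels_``,
    ``inertia_`` (weighted within-cluster sum of squares) and
    ``populations_``.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_init: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None, sample_weight=None):
        X = np.asarray(X, dtype=float)
        w = np.ones(X.shape[0]) if sample_weight is None else np.asarray(sample_weight, float)
        if self.n_clusters > np.unique(X, axis=0).shape[0]:
            raise InvalidArgumentError(
                f"n_clusters={self.n_clusters} exceeds the number of distinct points"
            )
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_init,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(X, sample_weight=w)
        pops = np.bincount(km.labels_, weights=w, minlength=self.n_clusters)
        order = np.argsort(-pops, kind="stable")
        relabel = np.empty(self.n_clusters, dtype=int)
        relabel[order] = np.arange(self.n_clusters)
        self.cluster_centers_ = km.cluster_centers_[order]
        self.labels_ = relabel[km.labels_]
        self.populations_ = pops[order]
        self.inertia_ = float(km.inertia_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.argmin(cdist(X, self.cluster_centers_, "sqeuclidean"), axis=1)

    def fit_predict(self, X, y=None, sample_weight=None):
        return self.fit(X, sample_weight=sample_weight).labels_


@dataclass
class ElbowResult:
    k_opt: int
    k_values: np.ndarray
    inertias: np.ndarray
    curvature: np.ndarray  # second difference of log-inertia, per interior k
    low_confidence: bool


def elbow(
    X,
    sample_weight=None,
    k_range: Sequence[int] = range(1, 9),
    random_state: int | None = None,
    n_init: int = 10,
) -> ElbowResult:
    """Pick the cluster count at the knee of the inertia curve.

    The knee is the k maximising the discrete second difference of
    **log**-inertia, which keys on the relative collapse of inertia at the
    true cluster count and is insensitive to the cluster arrangement
    (near-collinear centroids defeat the plain-inertia second difference).
    The full curve is returned so a human can always override k.

    ``low_confidence`` is set when the inertia at the chosen k is not much
    smaller than at k=1 (ratio > 0.3) — i.e. there is little cluster
    structure to find.
    """
    ks = np.asarray(sorted(k_range), dtype=int)
    if len(ks) < 3:
        raise InvalidArgumentError("k_range must contain at least 3 values")
    X = np.asarray(X, dtype=float)
    inertias = []
    for k in ks:
        km = WeightedKMeans(n_clusters=int(k), n_init=n_init, random_state=random_state)
        km.fit(X, sample_weight=sample_weight)
        inertias.append(km.inertia_)
    inertias = np.asarray(inertias)
    floor = max(inertias[0], 1.0) * 1e-12
    log_i = np.log(np.maximum(inertias, floor))
    curvature = log_i[:-2] - 2.0 * log_i[1:-1] + log_i[2:]
    k_opt = int(ks[1:-1][int(np.argmax(curvature))])
    ratio = inertias[ks == k_opt][0] / inertias[0] if inertias[0] > 0 else 0.0
    return ElbowResult(k_opt, ks, inertias, curvature, bool(ratio > 0.3))


class WeightedKDE:
    """Weighted Gaussian KDE in the scaled tuple space.

    ``bandwidth`` may be a fixed float or ``"scott"``: Scott's rule on the
    weighted effective sample size n_eff = (Σw)²/Σw², with the average
    per-dimension weighted standard deviation as the scale,
    h = σ̄ · n_eff^(−1/(d+4)).
    """

    def __init__(self, bandwidth: float | str = "scott"):
        self.bandwidth = bandwidth

    def fit(self, X, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        w = np.ones(X.shape[0]) if sample_weight is None else np.asarray(sample_weight, float)
        if X.shape[0] < 2:
            raise DegenerateKDEError("KDE needs at least 2 points")
        mean = np.average(X, axis=0, weights=w)
        var = np.average((X - mean) ** 2, axis=0, weights=w)
        if np.all(var <= 0):
            raise DegenerateKDEError("KDE needs non-degenerate spread")
        if self.bandwidth == "scott":
            n_eff = w.sum() ** 2 / np.sum(w**2)
            sigma = float(np.sqrt(np.mean(var)))
            h = sigma * n_eff ** (-1.0 / (X.shape[1] + 4))
        else:
            h = float(self.bandwidth)
        if h <= 0:
            raise DegenerateKDEError(f"non-positive bandwidth {h}")
        self.bandwidth_ = h
        self._kde = KernelDensity(kernel="gaussian", bandwidth=h).fit(X, sample_weight=w)
        self.n_features_in_ = X.shape[1]
        return self

    def log_density(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._kde.score_samples(X)

    def density(self, X) -> np.ndarray:
        return np.exp(self.log_density(X))


def kde_fit(X, sample_weight=None, bandwidth: float | str = "scott") -> WeightedKDE:
    """Fit a weighted Gaussian KDE to one cluster's tuples."""
    return WeightedKDE(bandwidth=bandwidth).fit(X, sample_weight=sample_weight)


@dataclass
class Representative:
    """The member tuple nearest the KDE density maximum of its cluster."""

    cluster_id: int
    member_index: int  # index into the cluster's member arrays
    tuple_index: int  # index into the full tuple set
    point: np.ndarray  # scaled coordinates of the representative tuple
    density_at_tuple: float
    kde_bandwidth: float
    density_max_point: np.ndarray
    provenance: tuple  # ((replica_id, frame), (replica_id, frame))


def find_representative(
    members: np.ndarray,
    kde: WeightedKDE,
    weights: np.ndarray | None = None,
    cluster_id: int = 0,
    tuple_indices: np.ndarray | None = None,
) -> Representative:
    """Locate the KDE maximum and return the member tuple nearest to it.

    The maximum is found by ascent (Nelder–Mead on −log density) started
    from the highest-density member; if the ascent fails the start point
    itself is used (logged). The representative minimises the squared
    Euclidean distance to the maximum; ties break toward higher weight,
    then lower tuple index.
    """
    members = np.asarray(members, dtype=float)
    w = np.ones(members.shape[0]) if weights is None else np.asarray(weights, float)
    dens = kde.log_density(members)
    start = members[int(np.argmax(dens))]
    res = minimize(
        lambda z: -kde.log_density(z[None])[0],
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
    )
    if res.success:
        x_max = res.x
    else:
        logger.warning(
            "KDE ascent did not converge for cluster %d; using densest member", cluster_id
        )
        x_max = start
    d2 = np.sum((members - x_max) ** 2, axis=1)
    # lexicographic tie-break: distance, then -weight, then index
    order = np.lexsort((np.arange(len(d2)), -w, np.round(d2, 12)))
    best = int(order[0])
    tuple_idx = int(tuple_indices[best]) if tuple_indices is not None else best
    return Representative(
        cluster_id=cluster_id,
        member_index=best,
        tuple_index=tuple_idx,
        point=members[best],
        density_at_tuple=float(np.exp(dens[best])),
        kde_bandwidth=kde.bandwidth_,
        density_max_point=np.asarray(x_max),
        provenance=(),
    )


def representatives_for(
    space: TupleSpace,
    model: WeightedKMeans,
    bandwidth: float | str = "scott",
    global_kde: bool = False,
) -> list[Representative]:
    """One representative per cluster, searched among that cluster's members.

    With ``global_kde=True`` the density is estimated once from all tuples
    and each cluster's representative maximises that shared density over
    its own members.
    """
    labels = model.labels_
    reps = []
    shared = (
        kde_fit(space.scaled, space.weights, bandwidth) if global_kde else None
    )
    for c in range(model.n_clusters):
        idx = np.nonzero(labels == c)[0]
        members = space.scaled[idx]
        w = space.weights[idx]
        kde = shared if shared is not None else kde_fit(members, w, bandwidth)
        rep = find_representative(members, kde, w, cluster_id=c, tuple_indices=idx)
        pair = space.tuples.first_pairs()[rep.tuple_index]
        ids = space.tuples.replica_ids
        rep.provenance = (
            (ids[pair[0]], int(pair[1])),
            (ids[pair[2]], int(pair[3])),
        )
        reps.append(rep)
    return reps


def map_to_frames(
    representative: Representative,
    frame_loader: Callable[[str, int], Structure],
    outdir: str | Path | None = None,
) -> tuple[Structure, Structure]:
    """Fetch the frame pair behind a representative tuple.

    ``frame_loader(replica_id, frame_index)`` must return the frame as a
    :class:`Structure`; it raises ``IOError`` naming the file when a
    trajectory is missing. If ``outdir`` is given both structures are
    written there as PDBs.
    """
    (rid_x, fx), (rid_y, fy) = representative.provenance
    x = frame_loader(rid_x, fx)
    y = frame_loader(rid_y, fy)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        c = representative.cluster_id
        write_structure(x, outdir / f"cluster{c + 1}_x_{rid_x}_f{fx}.pdb")
        write_structure(y, outdir / f"cluster{c + 1}_y_{rid_y}_f{fy}.pdb")
    return x, y


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def write_cluster_outputs(
    space: TupleSpace,
    model: WeightedKMeans,
    elbow_result: ElbowResult | None,
    outdir: str | Path,
    seed: int | None = None,
    density_grid: int = 40,
) -> None:
    """`clusters.json`, `assignments.tsv` and `density_profiles.tsv`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    centers_raw = space.scaler.inverse_transform(model.cluster_centers_)
    payload = {
        "k": int(model.n_clusters),
        "seed": seed,
        "inertia": model.inertia_,
        "populations": model.populations_.tolist(),
        "centroids_scaled": model.cluster_centers_.tolist(),
        "centroids_raw": centers_raw.tolist(),
    }
    if elbow_result is not None:
        payload["elbow"] = {
            "k_values": elbow_result.k_values.tolist(),
            "inertias": elbow_result.inertias.tolist(),
            "k_opt": elbow_result.k_opt,
            "low_confidence": elbow_result.low_confidence,
        }
    (outdir / "clusters.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame(
        {
            "tuple_index": np.arange(space.tuples.n_tuples),
            "cluster": model.labels_,
            "weight": space.weights,
        }
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    # 2-D (rmsd, fnc_x) density grid per cluster, for plotting
    rows = []
    for c in range(model.n_clusters):
        idx = np.nonzero(model.labels_ == c)[0]
        if idx.size < 2:
            continue
        pts = space.scaled[idx][:, :2]
        try:
            kde = kde_fit(pts, space.weights[idx])
        except DegenerateKDEError:
            continue
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        gx, gy = [np.linspace(lo[d] - 0.5, hi[d] + 0.5, density_grid) for d in (0, 1)]
        mx, my = np.meshgrid(gx, gy, indexing="ij")
        grid = np.column_stack([mx.ravel(), my.ravel()])
        dens = kde.density(grid)
        raw = space.scaler.inverse_transform(
            np.column_stack([grid, np.zeros(len(grid))])
        )
        rows.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "rmsd_nm": raw[:, 0],
                    "fnc_x": raw[:, 1],
                    "density": dens,
                }
            )
        )
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "density_profiles.tsv", sep="\t", index=False, float_format="%.6g"
        )


def write_representatives_json(reps: list[Representative], path: str | Path) -> None:
    payload = [
        {
            "cluster": r.cluster_id,
            "tuple_index": r.tuple_index,
            "point_scaled": r.point.tolist(),
            "density_at_tuple": r.density_at_tuple,
            "kde_bandwidth": r.kde_bandwidth,
            "density_max_scaled": r.density_max_point.tolist(),
            "x": {"replica_id": r.provenance[0][0], "frame": r.provenance[0][1]},
            "y": {"replica_id": r.provenance[1][0], "frame": r.provenance[1][1]},
        }
        for r in reps
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
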