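"""Synthetic replica campaigns with known latent conformational states.

The generator emulates the study design the analysis stack is built for:
many short replicas of a small helix-bundle bead model, each relaxing from
a shared native conformation toward one of K latent conformational states
(closed / simple pore / complex pore) under thermal noise. Everything the
downstream stages measure — RMSD plateaus, FNC decay, filter pass rates,
cluster populations, ΔG — is controllable ground truth here.

Dynamics are an Ornstein–Uhlenbeck-like mean path: the frame at time t is
``native + (1 − e^{−rt})(template − native)`` plus i.i.d. Gaussian
displacement per coordinate. Replicas flagged *unstable* get an
accelerating (quadratic-in-time) drift over the final analysis window so
the RMSD first derivative keeps changing there; replicas flagged *closed*
are pinned near the native conformation so their final RMSD stays below
the pore threshold. There is no force field, no membrane and no field:
atoms are identical beads and only coordinates matter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidArgumentError
from .structure import ReplicaTrajectory, Structure

# funnel defaults mirror a 200 → 162 → 142 replica selection
DEFAULT_STATE_POPULATIONS = (0.404, 0.392, 0.204)
DEFAULT_FRACTION_UNSTABLE = 0.19
DEFAULT_FRACTION_CLOSED = 20.0 / 162.0


class StateLabel(str, enum.Enum):
    CLOSED = "closed"
    SIMPLE_PORE = "simple_pore"
    COMPLEX_PORE = "complex_pore"


@dataclass
class LatentState:
    """One target conformation a replica can relax toward."""

    state_id: int
    template: Structure
    label: StateLabel
    population: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.population <= 1.0:
            raise InvalidArgumentError("population must be in [0, 1]")


@dataclass
class GeneratorConfig:
    """Campaign-level knobs.

    Units: ``duration`` ns, ``frame_interval`` ps, ``noise_sigma`` and
    ``displacement_per_state`` nm, ``relaxation_rate`` 1/ns.
    """

    n_replicas: int = 200
    duration: float = 10.0
    frame_interval: float = 10.0
    n_atoms: int = 40
    relaxation_rate: float = 4.0
    noise_sigma: float = 0.025
    state_noise_scale: tuple[float, ...] = (1.0, 1.5, 2.0)
    state_populations: tuple[float, ...] = DEFAULT_STATE_POPULATIONS
    seed: int = 0
    fraction_unstable: float = DEFAULT_FRACTION_UNSTABLE
    fraction_closed: float = DEFAULT_FRACTION_CLOSED
    displacement_per_state: float = 0.5
    unstable_ramp_window: float = 10.0  # ns; clipped to duration
    unstable_drift: float = 1.0  # nm of extra RMS displacement at the endpoint

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise InvalidArgumentError("n_replicas must be >= 1")
        if self.n_atoms < 4:
            raise InvalidArgumentError("n_atoms must be >= 4")
        if self.noise_sigma < 0:
            raise InvalidArgumentError("noise_sigma must be >= 0")
        for name in ("fraction_unstable", "fraction_closed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must be in [0, 1]")
        pops = np.asarray(self.state_populations, dtype=float)
        if np.any(pops < 0) or np.any(pops > 1) or abs(pops.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("state_populations must be in [0,1] and sum to 1")
        scales = np.asarray(self.state_noise_scale, dtype=float)
        if len(scales) != len(pops) or np.any(scales <= 0):
            raise InvalidArgumentError(
                "state_noise_scale must be positive and match state_populations"
            )
        n = self.duration * 1000.0 / self.frame_interval
        if self.duration <= 0 or self.frame_interval <= 0 or abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise InvalidArgumentError(
                "duration/frame_interval must be a positive integer frame count"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * 1000.0 / self.frame_interval))


def make_native(n_atoms: int, seed: int) -> Structure:
    """A reproducible four-pseudo-helix bead bundle.

    Beads are laid out as four antiparallel helices on a circle (bundle
    radius 0.5 nm, helix radius 0.25 nm, 0.15 nm rise per bead) with a
    small seeded jitter; the result is rescaled if necessary so at least
    one bead pair sits within the 0.8 nm contact cutoff.
    """
    if n_atoms < 4:
        raise InvalidArgumentError("n_atoms must be >= 4")
    rng = np.random.default_rng(seed)
    bundle_radius, helix_radius, rise, turn = 0.5, 0.25, 0.15, np.deg2rad(100.0)
    per_helix = [n_atoms // 4 + (1 if h < n_atoms % 4 else 0) for h in range(4)]
    coords = np.empty((n_atoms, 3))
    idx = 0
    for h, m in enumerate(per_helix):
        ang = 2.0 * np.pi * h / 4.0
        center = bundle_radius * np.array([np.cos(ang), np.sin(ang), 0.0])
        direction = 1.0 if h % 2 == 0 else -1.0  # antiparallel bundle
        for k in range(m):
            phase = k * turn + ang
            coords[idx] = center + np.array(
                [
                    helix_radius * np.cos(phase),
                    helix_radius * np.sin(phase),
                    direction * (k - (m - 1) / 2.0) * rise,
                ]
            )
            idx += 1
    coords += rng.normal(0.0, 0.01, coords.shape)
    # guarantee at least one native contact even for sparse bead counts
    diff = coords[:, None] - coords[None, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    dmin = dist.min()
    if dmin > 0.8:
        coords *= 0.79 / dmin
    return Structure(coords)


def _rigid_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3n) of infinitesimal rigid motions at ``coords``."""
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    basis = []
    for a in range(3):
        t = np.zeros((n, 3))
        t[:, a] = 1.0
        basis.append(t.ravel())
    for a in range(3):
        omega = np.zeros(3)
        omega[a] = 1.0
        basis.append(np.cross(np.broadcast_to(omega, (n, 3)), centered).ravel())
    q, _ = np.linalg.qr(np.array(basis).T)
    return q.T


def make_state_templates(
    native: Structure,
    displacement_per_state: float = 0.5,
    seed: int = 0,
    n_states: int = 3,
    populations: Sequence[float] = DEFAULT_STATE_POPULATIONS,
    labels: Sequence[StateLabel] = (
        StateLabel.CLOSED,
        StateLabel.SIMPLE_PORE,
        StateLabel.COMPLEX_PORE,
    ),
) -> list[LatentState]:
    """Latent-state templates at increasing distance from the native.

    Template k (1-based) is the native plus a smooth random deformation
    mode of RMS amplitude ``k * displacement_per_state``. Each mode has its
    rigid-motion component projected out, so superposed RMSD(native,
    template_k) stays close to the nominal amplitude and is strictly
    increasing in k.
    """
    if displacement_per_state <= 0:
        raise InvalidArgumentError("displacement_per_state must be > 0")
    if len(populations) != n_states:
        raise InvalidArgumentError("populations length must equal n_states")
    rng = np.random.default_rng(seed)
    rigid = _rigid_basis(native.coords)
    states = []
    for k in range(1, n_states + 1):
        mode = rng.normal(size=native.coords.shape)
        mode = gaussian_filter1d(mode, sigma=3.0, axis=0, mode="wrap")
        flat = mode.ravel()
        flat -= rigid.T @ (rigid @ flat)  # remove net translation/rotation
        mode = flat.reshape(native.coords.shape)
        mode /= np.sqrt(np.mean(np.sum(mode**2, axis=1)))  # unit RMS amplitude
        template = Structure(native.coords + k * displacement_per_state * mode)
        states.append(
            LatentState(
                state_id=k,
                template=template,
                label=StateLabel(labels[k - 1]),
                population=float(populations[k - 1]),
            )
        )
    return states


def simulate_replica(
    native: Structure,
    state: LatentState,
    config: GeneratorConfig,
    seed: int | None = None,
    replica_id: str = "r000",
    is_unstable: bool = False,
    is_closed: bool = False,
    noise_scale: float = 1.0,
) -> ReplicaTrajectory:
    """One replica relaxing from the native toward its state template.

    Frames are at t = Δt, 2Δt, …, duration; the first frame is the native
    plus noise (the relaxation has barely begun at t = Δt), and the late-
    time mean RMSD to the native plateaus at RMSD(native, template).
    ``noise_scale`` multiplies the thermal noise, letting more open latent
    states fluctuate more (their data clouds are visibly more dispersed,
    as in real pore-forming conformations).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_frames, n_atoms = config.n_frames, native.n_atoms
    t_ns = (np.arange(1, n_frames + 1) * config.frame_interval) / 1000.0
    target = native.coords if is_closed else state.template.coords
    alpha = 1.0 - np.exp(-config.relaxation_rate * t_ns)
    coords = native.coords[None] + alpha[:, None, None] * (target - native.coords)[None]
    if is_unstable and config.unstable_drift > 0:
        ramp = min(config.unstable_ramp_window, config.duration)
        t0 = config.duration - ramp
        tau = np.clip((t_ns - t0) / ramp, 0.0, None)
        dirs = rng.normal(size=(n_atoms, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = coords + (config.unstable_drift * tau**2)[:, None, None] * dirs[None]
    sigma = config.noise_sigma * noise_scale
    if sigma > 0:
        coords = coords + rng.normal(0.0, sigma, coords.shape)
    return ReplicaTrajectory(replica_id, coords, config.frame_interval)


def _campaign_seeds(config: GeneratorConfig):
    root = np.random.SeedSequence(config.seed)
    ss_native, ss_templates, ss_assign, ss_reps = root.spawn(4)
    return ss_native, ss_templates, ss_assign, ss_reps.spawn(config.n_replicas)


def campaign_native_and_states(
    config: GeneratorConfig,
) -> tuple[Structure, list[LatentState]]:
    """The shared native structure and state templates a campaign uses."""
    ss_native, ss_templates, _, _ = _campaign_seeds(config)
    native = make_native(config.n_atoms, ss_native.generate_state(1)[0])
    states = make_state_templates(
        native,
        config.displacement_per_state,
        seed=ss_templates.generate_state(1)[0],
        n_states=len(config.state_populations),
        populations=config.state_populations,
        labels=list(StateLabel)[: len(config.state_populations)],
    )
    return native, states


def campaign_labels(config: GeneratorConfig) -> pd.DataFrame:
    """Ground-truth assignment table (replica_id, state_id, flags) of a campaign."""
    _, _, ss_assign, _ = _campaign_seeds(config)
    rng = np.random.default_rng(ss_assign)
    n = config.n_replicas
    state_ids = rng.choice(
        np.arange(1, len(config.state_populations) + 1),
        size=n,
        p=np.asarray(config.state_populations, dtype=float),
    )
    unstable = rng.random(n) < config.fraction_unstable
    closed = rng.random(n) < config.fraction_closed
    labels = [StateLabel(list(StateLabel)[s - 1]).value for s in state_ids]
    return pd.DataFrame(
        {
            "replica_id": [f"r{i:03d}" for i in range(n)],
            "state_id": state_ids,
            "label": labels,
            "is_unstable": unstable,
            "is_closed": closed,
        }
    )


def iter_campaign(
    config: GeneratorConfig,
) -> Iterator[tuple[ReplicaTrajectory, dict]]:
    """Yield (trajectory, ground-truth row) one replica at a time.

    Streaming counterpart of :func:`simulate_campaign`; identical output
    for identical config (every replica has its own derived seed, so any
    single replica can also be regenerated in isolation).
    """
    native, states = campaign_native_and_states(config)
    labels = campaign_labels(config)
    _, _, _, rep_seeds = _campaign_seeds(config)
    for i, row in labels.iterrows():
        traj = simulate_replica(
            native,
            states[int(row.state_id) - 1],
            config,
            seed=rep_seeds[i],
            replica_id=row.replica_id,
            is_unstable=bool(row.is_unstable),
            is_closed=bool(row.is_closed),
            noise_scale=1.0 if row.is_closed else config.state_noise_scale[int(row.state_id) - 1],
        )
        yield traj, row.to_dict()


def simulate_campaign(
    config: GeneratorConfig,
) -> tuple[list[ReplicaTrajectory], pd.DataFrame]:
    """Generate a full campaign: replicas plus the ground-truth label table."""
    trajs = [traj for traj, _ in iter_campaign(config)]
    return trajs, campaign_labels(config)


def regenerate_replica(config: GeneratorConfig, index: int) -> ReplicaTrajectory:
    """Rebuild replica ``index`` of a campaign without generating the rest."""
    if not 0 <= index < config.n_replicas:
        raise InvalidArgumentError(f"replica index {index} out of range")
    native, states = campaign_native_and_states(config)
    row = campaign_labels(config).iloc[index]
    _, _, _, rep_seeds = _campaign_seeds(config)
    return simulate_replica(
        native,
        states[int(row.state_id) - 1],
        config,
        seed=rep_seeds[index],
        replica_id=row.replica_id,
        is_unstable=bool(row.is_unstable),
        is_closed=bool(row.is_closed),
        noise_scale=1.0 if row.is_closed else config.state_noise_scale[int(row.state_id) - 1],
    )


def write_labels_tsv(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index=False)
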