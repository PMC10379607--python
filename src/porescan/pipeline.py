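"""End-to-end orchestration: generate → featurize → filter → tuples → cluster → ΔG.

One YAML config drives a reproducible run. Every stage persists plain-text
intermediates (TSV/JSON) into the output directory, and any stage can be
re-run from its persisted inputs (``from_stage``): synthetic coordinates
are never cached in bulk — they are bit-identically regenerable from the
config seed, which is what makes resuming cheap and auditable.

A single global seed fans out to the stochastic stages through
stage-name-hashed SeedSequences, so re-running one stage in isolation sees
the same stream it saw in the full run.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    ElbowResult,
    WeightedKMeans,
    elbow,
    map_to_frames,
    representatives_for,
    write_cluster_outputs,
    write_representatives_json,
)
from .errors import InvalidArgumentError, StageError
from .features import featurize, read_features_tsv, write_features_tsv
from .filtering import FilterConfig, apply_funnel, write_filter_outputs
from .structure import Structure, read_trajectory, write_structure, write_trajectory
from .synthetic import (
    GeneratorConfig,
    campaign_labels,
    campaign_native_and_states,
    iter_campaign,
    regenerate_replica,
    write_labels_tsv,
)
from .thermo import ThermoConfig, free_energy_table, write_free_energy_tsv
from .tuples import (
    build_tuples,
    merge_weights,
    prepare_replica_frames,
    read_tuples_tsv,
    read_scaler_json,
    scale,
    write_scaler_json,
    write_tuples_tsv,
    TupleSpace,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "filter", "tuples", "cluster", "thermo")

_LENGTH_UNITS = {"nm": 1.0, "a": 0.1, "angstrom": 0.1, "å": 0.1}
_TIME_UNITS_NS = {"ns": 1.0, "ps": 1e-3}
_TIME_UNITS_PS = {"ps": 1.0, "ns": 1e3}


def _parse_quantity(value: Any, kind: str, key: str) -> float:
    """Normalise `8 A` / `0.8 nm` / bare numbers into the field's native unit."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 2:
            try:
                mag = float(parts[0])
            except ValueError as exc:
                raise InvalidArgumentError(f"{key}: cannot parse {value!r}") from exc
            unit = parts[1].lower()
            table = {
                "length_nm": _LENGTH_UNITS,
                "time_ns": _TIME_UNITS_NS,
                "time_ps": _TIME_UNITS_PS,
            }[kind]
            if unit not in table:
                raise InvalidArgumentError(
                    f"{key}: unknown unit {parts[1]!r} (expected one of {sorted(table)})"
                )
            return mag * table[unit]
        try:
            return float(value)
        except ValueError as exc:
            raise InvalidArgumentError(
                f"{key}: ambiguous value {value!r}; give a number or 'number unit'"
            ) from exc
    raise InvalidArgumentError(f"{key}: cannot interpret {value!r}")


# (default, kind) per key; kind None → taken as-is
_SCHEMA: dict[str, dict[str, tuple[Any, str | None]]] = {
    "synthetic": {
        "n_replicas": (200, None),
        "duration": (10.0, "time_ns"),
        "frame_interval": (10.0, "time_ps"),
        "n_atoms": (40, None),
        "relaxation_rate": (4.0, None),
        "noise_sigma": (0.025, "length_nm"),
        "state_noise_scale": ((1.0, 1.5, 2.0), None),
        "state_populations": ((0.404, 0.392, 0.204), None),
        "fraction_unstable": (0.19, None),
        "fraction_closed": (20.0 / 162.0, None),
        "displacement_per_state": (0.5, "length_nm"),
        "unstable_ramp_window": (10.0, "time_ns"),
        "unstable_drift": (1.0, "length_nm"),
        "write_trajectories": (False, None),
    },
    "features": {
        "cutoff": (0.8, "length_nm"),
        "min_sequence_separation": (0, None),
    },
    "filter": {
        "window": (10.0, "time_ns"),
        "max_derivative_change": (0.15, None),
        "min_final_rmsd": (0.35, "length_nm"),
        "slope_floor": (0.005, None),
    },
    "tuples": {
        "stride": (1.0, "time_ns"),
        "pairing": ("all_cross", None),
        "decimals": (4, None),
        "scaling": ("standard", None),
    },
    "cluster": {
        "k": ("auto", None),
        "k_max": (8, None),
        "n_init": (10, None),
        "bandwidth": ("scott", None),
        "global_kde": (False, None),
    },
    "thermo": {
        "temperature": (310.0, None),
        "gas_constant": (8.314, None),
    },
}
_TOP_LEVEL = {"seed": 0, "output_dir": "porescan_run", "log_level": "INFO"}


def validate_config(config: dict | str | Path | None) -> dict:
    """Normalise a config mapping (or YAML path) against the schema.

    Unknown keys are rejected by name; units are normalised (Å→nm, ps↔ns);
    defaults are filled in so the returned dict always echoes the full
    parameter set.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    if not isinstance(config, dict):
        raise InvalidArgumentError("config must be a mapping")
    errors = []
    out: dict[str, Any] = {}
    for key, default in _TOP_LEVEL.items():
        out[key] = config.get(key, default)
    for block, fields in _SCHEMA.items():
        given = config.get(block, {}) or {}
        if not isinstance(given, dict):
            errors.append(f"{block}: must be a mapping")
            given = {}
        for unknown in set(given) - set(fields):
            errors.append(f"unknown key {block}.{unknown}")
        norm = {}
        for name, (default, kind) in fields.items():
            value = given.get(name, default)
            if kind is not None and value is not None:
                try:
                    value = _parse_quantity(value, kind, f"{block}.{name}")
                except InvalidArgumentError as exc:
                    errors.append(str(exc))
                    continue
            norm[name] = value
        out[block] = norm
    for unknown in set(config) - set(_TOP_LEVEL) - set(_SCHEMA):
        errors.append(f"unknown key {unknown}")
    if errors:
        raise InvalidArgumentError("invalid config: " + "; ".join(sorted(errors)))
    return out


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage deterministic seed derived from the run's global seed."""
    return int(
        np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def _generator_config(cfg: dict) -> GeneratorConfig:
    syn = {k: v for k, v in cfg["synthetic"].items() if k != "write_trajectories"}
    if isinstance(syn["state_populations"], list):
        syn["state_populations"] = tuple(syn["state_populations"])
    return GeneratorConfig(seed=stage_seed(cfg["seed"], "synthetic"), **syn)


def _iter_trajectories(cfg: dict, outdir: Path, only_ids: set[str] | None = None):
    """Yield replica trajectories either from persisted files or regenerated."""
    gen = _generator_config(cfg)
    traj_dir = outdir / "trajectories"
    if traj_dir.is_dir() and any(traj_dir.glob("r*.pdb")):
        ref = outdir / "reference.pdb"
        for path in sorted(traj_dir.glob("r*.pdb")):
            if only_ids is not None and path.stem not in only_ids:
                continue
            yield read_trajectory(ref, path, "multi-model-pdb", gen.frame_interval)
    else:
        for traj, _ in iter_campaign(gen):
            if only_ids is not None and traj.replica_id not in only_ids:
                continue
            yield traj


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def _stage_simulate(cfg: dict, outdir: Path, report: dict) -> None:
    gen = _generator_config(cfg)
    native, states = campaign_native_and_states(gen)
    write_structure(native, outdir / "reference.pdb")
    for s in states:
        write_structure(s.template, outdir / f"template_state{s.state_id}.pdb")
    labels = campaign_labels(gen)
    write_labels_tsv(labels, outdir / "labels.tsv")
    if cfg["synthetic"]["write_trajectories"]:
        traj_dir = outdir / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        for traj, _ in iter_campaign(gen):
            write_trajectory(traj, traj_dir / f"{traj.replica_id}.pdb")
    report["simulate"] = {
        "n_replicas": gen.n_replicas,
        "n_frames_per_replica": gen.n_frames,
        "seed": gen.seed,
    }


def _stage_features(cfg: dict, outdir: Path, report: dict) -> None:
    fcfg = cfg["features"]
    series = [
        featurize(traj, fcfg["cutoff"], fcfg["min_sequence_separation"])
        for traj in _iter_trajectories(cfg, outdir)
    ]
    write_features_tsv(series, outdir / "features.tsv")
    report["features"] = {"n_replicas": len(series), "n_frames": sum(s.n_frames for s in series)}


def _stage_filter(cfg: dict, outdir: Path, report: dict) -> None:
    series = read_features_tsv(outdir / "features.tsv")
    fc = FilterConfig(**cfg["filter"])
    kept, table = apply_funnel(series, fc)
    write_filter_outputs(table, outdir)
    report["filter"] = {
        "n_in": len(series),
        "n_stable": int(table["passed_stability"].sum()),
        "n_kept": len(kept),
    }


def _stage_tuples(cfg: dict, outdir: Path, report: dict) -> None:
    kept_path = outdir / "kept.list"
    kept = [l for l in kept_path.read_text().splitlines() if l.strip()]
    if not kept:
        report["tuples"] = {"n_tuples": 0, "total_weight": 0.0, "note": "empty kept set"}
        return
    tcfg, fcfg = cfg["tuples"], cfg["features"]
    frames = [
        prepare_replica_frames(
            traj, tcfg["stride"], fcfg["cutoff"], fcfg["min_sequence_separation"]
        )
        for traj in _iter_trajectories(cfg, outdir, only_ids=set(kept))
    ]
    ts = merge_weights(build_tuples(frames, tcfg["pairing"]), tcfg["decimals"])
    space = scale(ts, tcfg["stride"], tcfg["scaling"])
    write_tuples_tsv(ts, outdir / "tuples.tsv")
    write_scaler_json(space.scaler, outdir / "scaler.json")
    report["tuples"] = {
        "n_frames": int(sum(f.n_frames for f in frames)),
        "n_tuples": ts.n_tuples,
        "total_weight": ts.total_weight,
    }


def _load_space(cfg: dict, outdir: Path) -> TupleSpace:
    ts = read_tuples_tsv(outdir / "tuples.tsv")
    scaler = read_scaler_json(outdir / "scaler.json")
    return TupleSpace(ts, scaler.transform(ts.values), scaler, cfg["tuples"]["stride"])


def _stage_cluster(cfg: dict, outdir: Path, report: dict) -> None:
    ccfg = cfg["cluster"]
    space = _load_space(cfg, outdir)
    seed = stage_seed(cfg["seed"], "cluster")
    elbow_result: ElbowResult | None = None
    if ccfg["k"] == "auto":
        k_hi = min(int(ccfg["k_max"]), space.tuples.n_tuples)
        elbow_result = elbow(
            space.scaled,
            space.weights,
            k_range=range(1, k_hi + 1),
            random_state=seed,
            n_init=int(ccfg["n_init"]),
        )
        k = elbow_result.k_opt
    else:
        k = int(ccfg["k"])
    model = WeightedKMeans(n_clusters=k, n_init=int(ccfg["n_init"]), random_state=seed)
    model.fit(space.scaled, sample_weight=space.weights)
    write_cluster_outputs(space, model, elbow_result, outdir, seed=seed)
    bw = ccfg["bandwidth"]
    reps = representatives_for(
        space, model, bandwidth=bw if bw == "scott" else float(bw),
        global_kde=bool(ccfg["global_kde"]),
    )
    rep_dir = outdir / "representatives"
    rep_dir.mkdir(exist_ok=True)
    write_representatives_json(reps, rep_dir / "representatives.json")
    loader = _make_frame_loader(cfg, outdir)
    for rep in reps:
        map_to_frames(rep, loader, rep_dir)
    report["cluster"] = {
        "k": k,
        "seed": seed,
        "populations": model.populations_.tolist(),
        "inertia": model.inertia_,
        "low_confidence_elbow": elbow_result.low_confidence if elbow_result else None,
        "representatives": [
            {"cluster": r.cluster_id, "x": r.provenance[0], "y": r.provenance[1]}
            for r in reps
        ],
    }


def _make_frame_loader(cfg: dict, outdir: Path):
    gen = _generator_config(cfg)
    traj_dir = outdir / "trajectories"
    labels = campaign_labels(gen)
    index_of = {rid: i for i, rid in enumerate(labels["replica_id"])}
    cache: dict[str, Any] = {}

    def loader(replica_id: str, frame_index: int) -> Structure:
        if replica_id not in cache:
            path = traj_dir / f"{replica_id}.pdb"
            if traj_dir.is_dir() and any(traj_dir.glob("r*.pdb")):
                if not path.is_file():
                    raise IOError(f"trajectory file not found: {path}")
                cache[replica_id] = read_trajectory(
                    outdir / "reference.pdb", path, "multi-model-pdb", gen.frame_interval
                )
            else:
                cache[replica_id] = regenerate_replica(gen, index_of[replica_id])
        return cache[replica_id].frame(frame_index)

    return loader


def _stage_thermo(cfg: dict, outdir: Path, report: dict) -> None:
    clusters = json.loads((outdir / "clusters.json").read_text())
    tc = ThermoConfig(**cfg["thermo"])
    table = free_energy_table(clusters["populations"], tc)
    write_free_energy_tsv(table, outdir / "free_energy.tsv")
    report["thermo"] = {
        "temperature_K": tc.temperature,
        "delta_g_J_per_mol": {
            row["pair"]: row["delta_g_J_per_mol"] for _, row in table.iterrows()
        },
    }


_STAGE_FN = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "filter": _stage_filter,
    "tuples": _stage_tuples,
    "cluster": _stage_cluster,
    "thermo": _stage_thermo,
}


def run(
    config: dict | str | Path | None = None,
    output_dir: str | Path | None = None,
    from_stage: str = "simulate",
) -> dict:
    """Execute the pipeline and return the machine-readable run report.

    ``from_stage`` resumes at a later stage using persisted intermediates
    (and deterministic regeneration of synthetic coordinates). On a stage
    failure a :class:`StageError` names the stage; earlier outputs are
    retained. An empty post-filter set stops the run gracefully after the
    filter stage, with the report saying so.
    """
    cfg = validate_config(config)
    if from_stage not in STAGES:
        raise InvalidArgumentError(f"from_stage must be one of {STAGES}")
    outdir = Path(output_dir) if output_dir is not None else Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    logging.getLogger().addHandler(fh)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "stages": {},
    }
    stages = STAGES[STAGES.index(from_stage):]
    try:
        for name in stages:
            t0 = time.perf_counter()
            logger.info("stage %s ...", name)
            try:
                _STAGE_FN[name](cfg, outdir, report["stages"])
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            report["stages"].setdefault(name, {})["elapsed_s"] = round(
                time.perf_counter() - t0, 3
            )
            if name == "filter" and report["stages"]["filter"]["n_kept"] == 0:
                report["stopped_after"] = "filter"
                report["note"] = "no replicas survived the funnel; nothing to cluster"
                logger.warning(report["note"])
                break
            if name == "tuples" and report["stages"]["tuples"]["n_tuples"] == 0:
                report["stopped_after"] = "tuples"
                report["note"] = "empty tuple set; nothing to cluster"
                break
    finally:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        (outdir / "report.md").write_text(_render_report_md(report))
        logging.getLogger().removeHandler(fh)
        fh.close()
    return report


def _render_report_md(report: dict) -> str:
    lines = [
        "# porescan run report",
        "",
        f"- version: {report['version']}",
        f"- seed: {report['seed']}",
        "",
    ]
    for name, info in report.get("stages", {}).items():
        lines.append(f"## {name}")
        for k, v in info.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    if "note" in report:
        lines.append(f"**{report['note']}**")
        lines.append("")
    return "\n".join(lines)
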