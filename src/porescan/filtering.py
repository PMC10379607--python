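"""Replica-selection funnel: RMSD-derivative stability, then a pore proxy.

Two sequential criteria decide which replicas enter the tuple space:

1. **Stability** — the RMSD first derivative must change by less than a
   fraction (default 15%) over the final analysis window (default 10 ns).
   Operationalised as the relative difference of least-squares slopes of
   the two halves of that window; a small slope floor keeps flat series
   from dividing by ~0 (flat always passes).
2. **Pore proxy** — replicas whose final RMSD is below a threshold
   (default 0.35 nm) never opened a conclusive pore and are excluded. The
   boundary is inclusive-pass: "less than 0.35 nm" is removed, 0.35 keeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError
from .features import FeatureSeries


@dataclass
class FilterConfig:
    window: float = 10.0  # ns
    max_derivative_change: float = 0.15  # fraction
    min_final_rmsd: float = 0.35  # nm
    slope_floor: float = 0.005  # nm/ns

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise InvalidArgumentError("window must be > 0")
        if not 0.0 < self.max_derivative_change < 1.0:
            raise InvalidArgumentError("max_derivative_change must be in (0, 1)")
        if self.min_final_rmsd < 0:
            raise InvalidArgumentError("min_final_rmsd must be >= 0")
        if self.slope_floor <= 0:
            raise InvalidArgumentError("slope_floor must be > 0")


@dataclass
class FilterReport:
    replica_id: str
    slope_early: float  # nm/ns
    slope_late: float  # nm/ns
    relative_change: float
    final_rmsd: float  # nm
    passed_stability: bool
    passed_pore: bool

    @property
    def kept(self) -> bool:
        return self.passed_stability and self.passed_pore


def stability_pass(series: FeatureSeries, cfg: FilterConfig | None = None) -> FilterReport:
    """Evaluate the derivative-stability criterion on one RMSD series.

    The final ``cfg.window`` ns are split into two equal halves; each half
    gets a least-squares linear slope of RMSD vs time, and the replica
    passes iff |slope_late − slope_early| / max(|slope_early|, floor) is
    below ``cfg.max_derivative_change``. The pore flag in the returned
    report is filled in too, so this doubles as the full per-replica
    evaluation.
    """
    cfg = cfg or FilterConfig()
    t_ns = series.times / 1000.0
    dt = series.frame_interval / 1000.0
    span = t_ns[-1] - t_ns[0] + dt  # duration covered, counting the first bin
    if span + 1e-9 < cfg.window:
        raise InsufficientDataError(
            f"series spans {span:g} ns, shorter than the {cfg.window:g} ns window"
        )
    n_window = int(round(cfg.window / dt))
    t = t_ns[-n_window:]
    r = series.rmsd[-n_window:]
    half = n_window // 2
    if half < 2:
        raise InsufficientDataError("fewer than 2 frames per half-window")
    slope_early = float(np.polyfit(t[:half], r[:half], 1)[0])
    slope_late = float(np.polyfit(t[half:], r[half:], 1)[0])
    rel = abs(slope_late - slope_early) / max(abs(slope_early), cfg.slope_floor)
    final = float(series.rmsd[-1])
    return FilterReport(
        replica_id=series.replica_id,
        slope_early=slope_early,
        slope_late=slope_late,
        relative_change=rel,
        final_rmsd=final,
        passed_stability=rel < cfg.max_derivative_change,
        passed_pore=final >= cfg.min_final_rmsd,
    )


def pore_pass(series: FeatureSeries, cfg: FilterConfig | None = None) -> bool:
    """True iff the final-frame RMSD reaches the pore threshold (inclusive)."""
    cfg = cfg or FilterConfig()
    return float(series.rmsd[-1]) >= cfg.min_final_rmsd


def apply_funnel(
    all_series: list[FeatureSeries], cfg: FilterConfig | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Run both criteria on every replica.

    Returns the kept replica ids (stability ∧ pore) and a report table
    with one row per input replica, kept or not.
    """
    cfg = cfg or FilterConfig()
    if not all_series:
        raise InvalidArgumentError("apply_funnel needs at least one series")
    reports = [stability_pass(s, cfg) for s in all_series]
    table = pd.DataFrame(
        {
            "replica_id": [r.replica_id for r in reports],
            "slope_early_nm_per_ns": [r.slope_early for r in reports],
            "slope_late_nm_per_ns": [r.slope_late for r in reports],
            "relative_change": [r.relative_change for r in reports],
            "final_rmsd_nm": [r.final_rmsd for r in reports],
            "passed_stability": [r.passed_stability for r in reports],
            "passed_pore": [r.passed_pore for r in reports],
            "kept": [r.kept for r in reports],
        }
    )
    kept = [r.replica_id for r in reports if r.kept]
    return kept, table


def write_filter_outputs(table: pd.DataFrame, outdir: str | Path) -> None:
    outdir = Path(outdir)
    table.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    kept = table.loc[table["kept"], "replica_id"]
    (outdir / "kept.list").write_text("\n".join(kept) + ("\n" if len(kept) else ""))
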