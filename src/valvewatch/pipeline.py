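"""Configuration-driven orchestration over constructs and replicates.

Runs any subset of analyses for every construct, keeps per-replicate
artifacts (CSV/JSON/DX), averages at the summary layer only, and emits a
structured report with provenance.  A failure in one construct is
recorded and does not abort the others.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .core import load_structure, load_trajectory, trim_equilibration
from .density import average_grids, density_grid, displacement_grid, write_dx
from .flexibility import average_rmsf_profiles, rmsf_profile, sasa_series
from .flux import count_crossings, flux_summary
from .geometry import boxplot_stats, distance_series

logger = logging.getLogger("valvewatch")

__all__ = ["Report", "run"]


@dataclass
class Report:
    summaries: dict = field(default_factory=dict)   # construct -> analysis -> values
    artifacts: list[str] = field(default_factory=list)
    errors: dict = field(default_factory=dict)      # construct -> message
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(
            {
                "summaries": self.summaries,
                "artifacts": self.artifacts,
                "errors": self.errors,
                "provenance": self.provenance,
            },
            indent=1,
            default=float,
        )


def _sem(values: np.ndarray) -> float | None:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def _summary_entry(values) -> dict:
    arr = np.asarray(values, dtype=float)
    entry = {"mean": float(arr.mean()), "per_replicate": [float(v) for v in arr]}
    sem = _sem(arr)
    if sem is not None:
        entry["sem"] = sem
    return entry


def run(config: RunConfig) -> Report:
    """Execute the configured analyses and write the report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = Report(
        provenance={
            "package_version": __version__,
            "config_hash": config.config_hash,
            "seed": config.seed,
            "equilibration_ns": config.equilibration_ns,
        }
    )
    eq_ps = config.equilibration_ns * 1000.0
    for construct in config.constructs:
        label = construct.label
        safe = label.replace(" ", "_").replace("/", "-")
        try:
            topology, _ = load_structure(construct.topology)
            replicates = []
            for tp in construct.trajectories:
                traj = load_trajectory(topology, tp)
                if eq_ps > 0:
                    if eq_ps > traj.times[-1]:
                        raise ValueError(
                            f"equilibration {config.equilibration_ns} ns exceeds "
                            f"trajectory span ({traj.times[-1] / 1000.0:.3f} ns)"
                        )
                    traj = trim_equilibration(traj, eq_ps)
                replicates.append(traj)
            report.summaries[label] = {}
            for name, params in config.analyses.items():
                report.summaries[label][name] = _run_analysis(
                    name, params, replicates, out, safe, report
                )
                logger.info("construct %s: %s done", label, name)
        except Exception as exc:  # noqa: BLE001 - per-construct isolation
            logger.error("construct %s failed: %s", label, exc)
            report.errors[label] = str(exc)
    (out / "report.json").write_text(report.to_json())
    report.artifacts.append(str(out / "report.json"))
    return report


def _run_analysis(name, params, replicates, out, safe, report) -> dict:
    if name == "flux":
        records = [
            count_crossings(
                t,
                valve_selection=params["valve_selection"],
                stride_ps=params["stride_ps"],
            )
            for t in replicates
        ]
        for i, rec in enumerate(records):
            path = out / f"{safe}_flux_rep{i + 1}.csv"
            pd.DataFrame(
                {
                    "time_ps": rec.times,
                    "events": rec.counts_per_interval,
                    "cumulative": rec.cumulative,
                }
            ).to_csv(path, index=False)
            report.artifacts.append(str(path))
        entry = _summary_entry([r.total_events for r in records])
        if len(records) >= 2:
            s = flux_summary(records)
            entry["mean"], entry["sem"] = s.mean, s.sem
        return entry

    if name in ("density", "displacement"):
        make = density_grid if name == "density" else displacement_grid
        kwargs = {"voxel_edge": params["voxel_edge"]}
        if name == "displacement":
            kwargs["dt_ps"] = params["dt_ps"]
        grids = [make(t, **kwargs) for t in replicates]
        avg = average_grids(grids)
        path = out / f"{safe}_{name}.dx"
        write_dx(avg, path)
        report.artifacts.append(str(path))
        return _summary_entry([float(g.values.mean()) for g in grids])

    if name == "geometry":
        results = {}
        for pair in params["pairs"]:
            rows = []
            for i, t in enumerate(replicates):
                for s in distance_series(t, pair, stride_ps=params["stride_ps"]):
                    rows.append((i, s))
            path = out / f"{safe}_geometry_{pair.replace('/', '').replace(':', '')}.csv"
            pd.DataFrame(
                [
                    {
                        "replicate": i + 1,
                        "chain": s.chain,
                        "time_ps": t_,
                        "distance_nm": d,
                    }
                    for i, s in rows
                    for t_, d in zip(s.times, s.distances)
                ]
            ).to_csv(path, index=False)
            report.artifacts.append(str(path))
            pooled = np.concatenate([s.distances for _, s in rows])
            bs = boxplot_stats(pooled)
            results[pair] = {
                "mean": bs.mean,
                "q1": bs.q1,
                "q3": bs.q3,
                "min": bs.minimum,
                "max": bs.maximum,
                "n": bs.n,
            }
            sem = _sem(
                np.array(
                    [float(np.mean(s.distances)) for _, s in rows], dtype=float
                )
            )
            if sem is not None:
                results[pair]["sem"] = sem
        return results

    if name == "rmsf":
        profiles = [
            rmsf_profile(t, params["fit_selection"], params["target_selection"])
            for t in replicates
        ]
        avg = average_rmsf_profiles(profiles)
        path = out / f"{safe}_rmsf.csv"
        pd.DataFrame(
            {"chain": avg.chains, "resid": avg.resids, "rmsf_nm": avg.rmsf}
        ).to_csv(path, index=False)
        report.artifacts.append(str(path))
        return _summary_entry([float(p.rmsf.mean()) for p in profiles])

    if name == "sasa":
        cavity = [
            tuple(r) if isinstance(r, (list, tuple)) else r
            for r in params["cavity_residues"]
        ]
        series = [
            sasa_series(
                t,
                cavity,
                stride_ps=params["stride_ps"],
                window_ps=params["window_ps"],
            )
            for t in replicates
        ]
        for i, s in enumerate(series):
            path = out / f"{safe}_sasa_rep{i + 1}.csv"
            pd.DataFrame(
                {"time_ps": s.times, "sasa_nm2": s.raw, "smoothed_nm2": s.smoothed}
            ).to_csv(path, index=False)
            report.artifacts.append(str(path))
        return _summary_entry([float(s.raw.mean()) for s in series])

    raise ValueError(f"unknown analysis {name!r}")
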