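"""Tidy-format readers/writers for trajectories, diagrams and populations.

Trajectories are written as tidy CSV (``time, series, value`` — species and
derived observables alike) plus a JSON sidecar with protocol and solver
metadata.  Bifurcation diagrams become a per-point CSV (parameter, species
value, stability, envelope bounds) plus a JSON summary of Hopf/fold points
and bistable intervals.  ABC-SMC populations are one row per particle with
generation, weight, frequency and the parameter columns.  Run
configurations use a small declarative YAML schema covering model variant
flags, parameter overrides, the stress protocol and analysis settings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bifurcation import BifurcationDiagram
from .dynamics import StressProtocol, Trajectory
from .oscillation_scan import ParticlePopulation

__all__ = [
    "trajectory_to_csv",
    "trajectory_from_csv",
    "trajectory_meta_json",
    "diagram_to_csv",
    "diagram_summary_json",
    "populations_to_csv",
    "populations_from_csv",
    "load_config",
    "protocol_from_config",
]


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> pd.DataFrame:
    """Write a trajectory as tidy CSV (time, series, value); returns the frame."""
    frames = []
    for i, sid in enumerate(traj.species_ids):
        frames.append(pd.DataFrame(
            {"time": traj.times, "series": sid, "value": traj.states[:, i]}))
    for name, series in traj.observables.items():
        frames.append(pd.DataFrame({"time": traj.times, "series": name, "value": series}))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False)
    return df


def trajectory_from_csv(path: str | Path,
                        species_ids: Sequence[str] | None = None) -> Trajectory:
    """Rebuild a trajectory from a tidy CSV written by :func:`trajectory_to_csv`.

    ``species_ids`` selects which series are state columns; all remaining
    series are attached as observables.
    """
    df = pd.read_csv(path)
    wide = df.pivot(index="time", columns="series", values="value").sort_index()
    all_series = list(wide.columns)
    if species_ids is None:
        species_ids = all_series
    missing = set(species_ids) - set(all_series)
    if missing:
        raise ValueError(f"CSV lacks series {sorted(missing)}")
    obs = {s: wide[s].to_numpy() for s in all_series if s not in set(species_ids)}
    return Trajectory(
        times=wide.index.to_numpy(float),
        states=wide[list(species_ids)].to_numpy(float),
        species_ids=list(species_ids),
        observables=obs,
        check_negative=False,
    )


def trajectory_meta_json(traj: Trajectory, path: str | Path) -> None:
    meta = dict(traj.meta)
    if traj.protocol is not None:
        meta["protocol_segments"] = [list(seg) for seg in traj.protocol.segments]
    Path(path).write_text(json.dumps(meta, indent=2, default=str))


def diagram_to_csv(diagram: BifurcationDiagram, species_ids: Sequence[str],
                   path: str | Path) -> pd.DataFrame:
    """Branch points as CSV: one row per (branch point, species)."""
    rows = []
    for bp in diagram.branch:
        for i, sid in enumerate(species_ids):
            rows.append({
                "parameter": bp.parameter, "species": sid,
                "steady_value": bp.state[i], "stable": bp.stable,
            })
    df = pd.DataFrame(rows)
    env_rows = []
    for sid, (grid, mins, maxs) in diagram.envelopes.items():
        for g, lo, hi in zip(grid, mins, maxs):
            env_rows.append({"parameter": g, "species": sid,
                             "envelope_min": lo, "envelope_max": hi})
    if env_rows:
        df = pd.concat([df, pd.DataFrame(env_rows)], ignore_index=True)
    df.to_csv(path, index=False)
    return df


def diagram_summary_json(diagram: BifurcationDiagram, path: str | Path) -> dict:
    summary = {
        "parameter": diagram.parameter_name,
        "hopf_points": [
            {"parameter": h.parameter, "omega": h.omega} for h in diagram.hopf_points
        ],
        "fold_points": [{"parameter": f.parameter} for f in diagram.fold_points],
        "bistable_intervals": [list(iv) for iv in diagram.bistable_intervals],
        "n_branch_points": len(diagram.branch),
    }
    Path(path).write_text(json.dumps(summary, indent=2))
    return summary


def populations_to_csv(generations: Sequence[ParticlePopulation], path: str | Path,
                       meta: Mapping | None = None) -> pd.DataFrame:
    """All generations of an ABC-SMC run, one row per particle.

    If ``meta`` is given (seed, priors, schedule) it is written alongside
    as ``<path>.meta.json``.
    """
    rows = []
    for g, pop in enumerate(generations):
        P = pop.parameters
        for i in range(pop.n):
            row = {"generation": g, "weight": pop.weights[i],
                   "frequency": pop.frequencies[i], "epsilon": pop.epsilon}
            row.update({name: P[i, j] for j, name in enumerate(pop.names)})
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    if meta is not None:
        Path(str(path) + ".meta.json").write_text(
            json.dumps(dict(meta), indent=2, default=str))
    return df


def populations_from_csv(path: str | Path) -> list[ParticlePopulation]:
    df = pd.read_csv(path)
    fixed = {"generation", "weight", "frequency", "epsilon"}
    names = [c for c in df.columns if c not in fixed]
    out = []
    for g, sub in df.groupby("generation"):
        out.append(ParticlePopulation(
            names=names,
            log_parameters=np.log(sub[names].to_numpy(float)),
            weights=sub["weight"].to_numpy(float),
            frequencies=sub["frequency"].to_numpy(float),
            epsilon=float(sub["epsilon"].iloc[0]),
            n_proposals=len(sub),
        ))
    return out


# ---------------------------------------------------------------------------
# declarative run configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a run configuration (YAML) and apply schema defaults.

    Schema::

        model:
          overrides: {parameter: value, ...}
          knockouts: [transfer|cleavage|wfs1, ...]
          include_apoptosis: true
        protocol:
          preset: mild | moderate | severe        # or explicit segments:
          segments: [[value, duration], ...]
          duration: 1000.0
        analysis:
          seed: 0
          rtol: 1.0e-8
          atol: 1.0e-10
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = {
        "model": {"overrides": {}, "knockouts": [], "include_apoptosis": True},
        "protocol": {"preset": None, "segments": None, "duration": 1000.0},
        "analysis": {"seed": 0, "rtol": 1e-8, "atol": 1e-10},
    }
    for section, defaults in cfg.items():
        user = raw.get(section, {}) or {}
        unknown = set(user) - set(defaults)
        if unknown:
            raise ValueError(f"unknown {section} config keys {sorted(unknown)}")
        defaults.update(user)
    return cfg


def protocol_from_config(cfg: Mapping) -> StressProtocol:
    proto = cfg["protocol"]
    if proto.get("segments"):
        return StressProtocol(tuple((float(v), float(d)) for v, d in proto["segments"]))
    if proto.get("preset"):
        return StressProtocol.preset(proto["preset"], float(proto["duration"]))
    raise ValueError("config protocol needs either 'preset' or 'segments'")
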