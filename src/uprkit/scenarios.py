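"""End-to-end stress scenarios and module response curves.

A scenario starts from the pre-equilibrated unstressed steady state of the
full model, applies a stress protocol (one of the mild/moderate/severe
presets, the stepwise preconditioning schedule, or any explicit
piecewise-constant protocol), and returns the trajectory together with the
derived verdicts: the activity-state label, the BAX switch status, and the
activation ordering of the translation-attenuation cascade.  Verdicts are
pure functions of the stored trajectory, so they can be recomputed from a
serialised run.

The BAX verdict follows the bistable structure of the apoptosis switch:
BAX counts as active when it lies above the midpoint between the two
stable branches of the switch evaluated at the prevailing CHOP level (the
mid-separatrix surrogate); where only one branch exists the midpoint
degenerates to that branch and a 50%-of-total fallback threshold applies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import __version__ as _pkg_version
from . import dynamics
from .bifurcation import ActivityState
from .dynamics import PRESETS, StressProtocol, Trajectory, integrate, oscillation_metrics
from .model_assembly import (
    ApoptosisConfig,
    Atf6Config,
    Ire1Config,
    ReceptorModuleConfig,
    assemble_full_model,
    build_apoptosis_module,
    build_atf6_branch,
    build_ire1_branch,
    build_receptor_module,
)
from .network import CompiledModel, ModelSpec

__all__ = [
    "ScenarioResult",
    "run_stress_scenario",
    "run_preconditioning",
    "run_response_curve",
    "bax_threshold",
    "classify_trajectory",
]

#: fraction of total eIF2α below which translation counts as suspended
ATTENUATION_FRACTION = 0.1


@dataclass
class ScenarioResult:
    """One scenario run: trajectory, verdicts and provenance."""

    scenario_id: str
    trajectory: Trajectory
    verdicts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ScenarioResult {self.scenario_id!r}: {self.verdicts}>"


def _config_hash(payload: Mapping) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def bax_threshold(
    chop_level: float,
    overrides: Mapping[str, float] | None = None,
) -> float:
    """Activation threshold for the BAX verdict at a given CHOP level.

    Midpoint between the off- and on-branch steady states of the
    stand-alone apoptosis switch at that CHOP value, found by relaxing the
    module from an all-inactive and an all-active start.  In monostable
    regions both relaxations coincide and the midpoint falls back to 50%
    of the BAX total.
    """
    module = build_apoptosis_module(ApoptosisConfig(chop=chop_level,
                                                    overrides=dict(overrides or {})))
    cm = module.compile()
    i_bax = module.index["BAXa"]
    baxt = module.parameters["BAXT"]

    branches = []
    for bax0 in (0.0, 0.95 * baxt):
        y0 = module.initial_state.copy()
        y0[i_bax] = bax0
        traj = integrate(cm, y0, t_end=3000.0, n_points=60)
        branches.append(traj.final_state[i_bax])
    off, on = min(branches), max(branches)
    if on - off < 0.05 * baxt:  # monostable at this CHOP level
        return 0.5 * baxt
    return 0.5 * (off + on)


def classify_trajectory(
    traj: Trajectory,
    eif2a_total: float,
    chop_bounds: tuple[float, float],
    transient_fraction: float = 0.5,
) -> ActivityState:
    """Activity-state verdict from a finished scenario trajectory.

    intermediate = sustained CHOP oscillation over the post-transient
    window; otherwise low/high by the late CHOP level against the midpoint
    of ``chop_bounds`` and the late translation level against the
    recovery/attenuation thresholds.
    """
    try:
        freq, amp, sustained = oscillation_metrics(traj, "CHOP", transient_fraction)
    except ValueError:
        freq, amp, sustained = 0.0, 0.0, False
    n_tail = max(len(traj.times) // 10, 1)
    chop_late = float(np.mean(traj.series("CHOP")[-n_tail:]))
    eif_late = float(np.mean(traj.series("eIF2a")[-n_tail:]))
    chop_mid = 0.5 * (chop_bounds[0] + chop_bounds[1])
    window = (float(traj.times[0]), float(traj.times[-1]))
    diag = {"frequency": freq, "relative_amplitude": amp, "sustained": sustained,
            "chop_late": chop_late, "eif2a_late": eif_late, "chop_midpoint": chop_mid}
    if sustained:
        return ActivityState("intermediate", window, diag)
    if chop_late < chop_mid and eif_late > 0.5 * eif2a_total:
        return ActivityState("low", window, diag)
    if chop_late >= chop_mid and eif_late < ATTENUATION_FRACTION * eif2a_total:
        return ActivityState("high", window, diag)
    return ActivityState("ambiguous", window, diag)


def _chop_bounds(model: ModelSpec, cm: CompiledModel,
                 overrides: Mapping[str, float] | None) -> tuple[float, float]:
    """Low/high CHOP asymptotes: basal steady CHOP and the high-state CHOP
    under strongly saturating stress."""
    lo_state, _ = dynamics.steady_state(cm, overrides={**dict(overrides or {}), "mUFPT": 0.0})
    hi_traj = integrate(cm, lo_state, t_end=600.0,
                        overrides={**dict(overrides or {}), "mUFPT": 40.0}, n_points=300)
    i = model.index["CHOP"]
    return float(lo_state[i]), float(np.max(hi_traj.series("CHOP")))


def run_stress_scenario(
    preset: str | StressProtocol,
    model: ModelSpec | None = None,
    duration: float = 1000.0,
    overrides: Mapping[str, float] | None = None,
    seed: int | None = None,
    n_points: int = 2000,
) -> ScenarioResult:
    """Simulate one stress scenario of the full UPR model.

    ``preset`` is ``mild``/``moderate``/``severe`` (mUFPT 12/15/18 for
    ``duration`` atu; the default window is long enough for the
    post-transient behaviour that defines each state to establish itself)
    or an explicit :class:`StressProtocol`.  The run starts from the
    computed unstressed steady state.  Verdicts: activity
    label, BAX status at the end of the run, and the activation ordering
    of phospho-eIF2α, ATF4, CHOP and GADD34.
    """
    protocol = (StressProtocol.preset(preset, duration)
                if isinstance(preset, str) else preset)
    m = model if model is not None else assemble_full_model()
    cm = m.compile()
    y0 = dynamics.equilibrate(cm, 0.0, overrides=overrides)
    traj = integrate(cm, y0, protocol, n_points=n_points, overrides=overrides)

    bounds = _chop_bounds(m, cm, overrides)
    state = classify_trajectory(traj, m.parameters["eIF2aT"], bounds)
    chop_late = state.diagnostics["chop_late"]
    thr = bax_threshold(chop_late, overrides)
    bax_end = float(traj.series("BAXa")[-1])
    timing = dynamics.activation_timing(traj, ["eIF2aP", "ATF4", "CHOP", "GADD34"])

    scenario_id = preset if isinstance(preset, str) else "protocol"
    payload = {"protocol": protocol.segments, "overrides": dict(overrides or {}),
               "n_points": n_points}
    return ScenarioResult(
        scenario_id=scenario_id,
        trajectory=traj,
        verdicts={
            "activity_state": state.label,
            "activity_diagnostics": state.diagnostics,
            "bax_active": bax_end > thr,
            "bax_end": bax_end,
            "bax_threshold": thr,
            "activation_timing": timing,
        },
        provenance={"config_hash": _config_hash(payload), "seed": seed,
                    "package_version": _pkg_version},
    )


def run_preconditioning(
    steps: Sequence[str | float] = ("mild", "moderate", "severe"),
    step_duration: float = 500.0,
    model: ModelSpec | None = None,
    overrides: Mapping[str, float] | None = None,
    seed: int | None = None,
    n_points: int = 3000,
) -> ScenarioResult:
    """Stepwise stress escalation (the preconditioning protocol).

    ``steps`` are preset names or explicit mUFPT values applied
    sequentially for ``step_duration`` atu each, starting from the
    unstressed steady state.  The verdicts report the BAX status at the
    end of every step, which is where the protective effect of
    preconditioning shows: the moderate step stays on the inactive branch.
    """
    values = [PRESETS[s] if isinstance(s, str) else float(s) for s in steps]
    protocol = StressProtocol.stepwise(values, step_duration)
    m = model if model is not None else assemble_full_model()
    cm = m.compile()
    y0 = dynamics.equilibrate(cm, 0.0, overrides=overrides)
    traj = integrate(cm, y0, protocol, n_points=n_points, overrides=overrides)

    bax = traj.series("BAXa")
    chop = traj.series("CHOP")
    per_step = []
    for k in range(len(values)):
        t_edge = step_duration * (k + 1)
        i = min(np.searchsorted(traj.times, t_edge), len(traj.times) - 1)
        thr = bax_threshold(float(chop[i]), overrides)
        per_step.append({
            "step": k, "mufpt": values[k], "t": float(traj.times[i]),
            "bax": float(bax[i]), "bax_threshold": thr,
            "bax_active": bool(bax[i] > thr),
        })
    payload = {"steps": values, "step_duration": step_duration,
               "overrides": dict(overrides or {})}
    return ScenarioResult(
        scenario_id="preconditioning",
        trajectory=traj,
        verdicts={"steps": per_step,
                  "bax_active_final": per_step[-1]["bax_active"]},
        provenance={"config_hash": _config_hash(payload), "seed": seed,
                    "package_version": _pkg_version},
    )


def run_response_curve(
    module: str,
    sweep: Sequence[float] | None = None,
    variant: str = "standard",
    knockouts: Sequence[str] = (),
    ext_xbp: float = 0.0,
    ext_bip: float = 0.0,
    receptor_n: int = 4,
    receptor_kf: float | None = None,
    overrides: Mapping[str, float] | None = None,
    t_relax: float = 6000.0,
) -> dict[str, np.ndarray]:
    """Steady response of an isolated module against unfolded-protein load.

    ``module`` is ``receptor``, ``ire1`` or ``atf6``.  For the receptor
    module the sweep variable is the conserved total unfolded protein
    (UFPT) directly; for the branch modules it is the accumulation rate
    mUFPT, and the attained steady UFPT is reported alongside, so response
    curves are plotted against total unfolded protein in either case.
    Returns a dict of aligned arrays (``sweep``, ``UFPT``, ``IRE1A``,
    and ``BiPT`` where the module expresses BiP).
    """
    ov = dict(overrides or {})
    if module == "receptor":
        cfg = ReceptorModuleConfig(variant=variant, n=receptor_n,
                                   kf=receptor_kf, overrides=ov)
        m = build_receptor_module(cfg)
        cm = m.compile()
        sweep = np.asarray(sweep if sweep is not None else np.linspace(0, 60, 25), float)
        i_ufp = m.index["UFP"]
        out = {"sweep": sweep, "UFPT": sweep,
               "IRE1A": np.empty(len(sweep))}
        y = m.initial_state
        for k, total in enumerate(sweep):
            y0 = y.copy()
            # re-seed the conserved UFP pool; bound pool restarts empty
            y0[i_ufp] = total
            y0[m.index["bUFP"]] = 0.0
            traj = integrate(cm, y0, t_end=t_relax, n_points=60)
            y = traj.final_state
            out["IRE1A"][k] = traj.observables["IRE1A"][-1]
        return out

    if module == "ire1":
        cfg = Ire1Config(ext_xbp=ext_xbp, ext_bip=ext_bip, overrides=ov)
        m = build_ire1_branch(cfg)
    elif module == "atf6":
        flags = {f"knockout_{k}": True for k in knockouts}
        m = build_atf6_branch(Atf6Config(**flags, overrides=ov))
    else:
        raise ValueError(f"unknown module {module!r}")
    cm = m.compile()
    sweep = np.asarray(sweep if sweep is not None else np.linspace(0, 24, 13), float)
    out = {"sweep": sweep, "UFPT": np.empty(len(sweep)),
           "BiPT": np.empty(len(sweep)), "IRE1A": np.empty(len(sweep))}
    y = m.initial_state
    for k, mu in enumerate(sweep):
        traj = integrate(cm, y, t_end=t_relax, overrides={**ov, "mUFPT": mu},
                         n_points=60)
        y = traj.final_state
        for name in ("UFPT", "BiPT", "IRE1A"):
            out[name][k] = traj.observables[name][-1]
    return out
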