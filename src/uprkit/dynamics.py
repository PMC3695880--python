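"""Time integration, steady states and trajectory-level analysis.

Stress enters the model as a piecewise-constant schedule of the
unfolded-protein accumulation rate ``mUFPT`` (:class:`StressProtocol`);
integration restarts at every segment boundary, so discontinuous input
changes are handled exactly.  The integrator is stiff-capable (LSODA with
the model's exact symbolic Jacobian) with tight default tolerances
(rtol 1e-8, atol 1e-10) and dense output on a uniform grid.

The module also provides the two-variable ATF4/GADD34 delay model used to
probe the origin of the translation-attenuation oscillations
(:class:`ReducedDelayModel`, integrated by the method of steps), and the
trajectory metrics used throughout the analysis: oscillation detection,
0–100% renormalisation and activation-order timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root
from scipy.signal import find_peaks

from .network import CompiledModel, ModelSpec
from .rate_laws import tqssa_rate, EnzymeRateParams

__all__ = [
    "StressProtocol",
    "Trajectory",
    "IntegrationError",
    "rhs",
    "integrate",
    "equilibrate",
    "steady_state",
    "ReducedDelayModel",
    "integrate_dde",
    "oscillation_metrics",
    "renormalize_trajectory",
    "activation_timing",
]

#: default integrator tolerances (relative, absolute)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: named stress presets: constant unfolded-protein accumulation rates
PRESETS = {"mild": 12.0, "moderate": 15.0, "severe": 18.0}


class IntegrationError(RuntimeError):
    """Integration failure; carries the last time reached in ``last_time``."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class StressProtocol:
    """Piecewise-constant schedule of the stress input mUFPT.

    ``segments`` is an ordered list of ``(mUFPT value, duration)`` pairs in
    acu/atu and atu.  Presets ``mild``/``moderate``/``severe`` are constant
    rates 12, 15 and 18.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for value, duration in self.segments:
            if duration <= 0:
                raise ValueError("segment durations must be positive")
            if value < 0:
                raise ValueError("mUFPT values must be non-negative")

    @classmethod
    def constant(cls, value: float, duration: float = np.inf) -> "StressProtocol":
        return cls(((float(value), float(duration)),))

    @classmethod
    def preset(cls, name: str, duration: float = 500.0) -> "StressProtocol":
        return cls.constant(PRESETS[name], duration)

    @classmethod
    def stepwise(cls, values: Sequence[float], step_duration: float = 500.0) -> "StressProtocol":
        """Sequential constant steps, e.g. the 12 -> 15 -> 18 preconditioning run."""
        return cls(tuple((float(v), float(step_duration)) for v in values))

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    def value_at(self, t: float) -> float:
        """mUFPT at time ``t`` (the last segment extends to infinity)."""
        acc = 0.0
        for value, duration in self.segments:
            acc += duration
            if t < acc:
                return value
        return self.segments[-1][0]

    def boundaries(self, t_end: float) -> list[tuple[float, float, float]]:
        """(start, stop, value) triples clipped to ``[0, t_end]``."""
        out, acc = [], 0.0
        for value, duration in self.segments:
            start, stop = acc, min(acc + duration, t_end)
            if stop > start:
                out.append((start, stop, value))
            acc += duration
            if acc >= t_end:
                return out
        if acc < t_end:  # extend final value
            out.append((acc, t_end, self.segments[-1][0]))
        return out


@dataclass
class Trajectory:
    """A simulated time course: state matrix plus derived observables.

    ``states`` has shape (time, species); ``observables`` maps names to
    series on the same grid.  ``protocol`` and ``meta`` record provenance
    (solver, tolerances, parameter overrides).
    """

    times: np.ndarray
    states: np.ndarray
    species_ids: list[str]
    observables: dict[str, np.ndarray] = field(default_factory=dict)
    protocol: StressProtocol | None = None
    meta: dict = field(default_factory=dict)
    #: concentration trajectories must stay non-negative; generic (signed)
    #: state trajectories such as test DDE solutions set this to False
    check_negative: bool = True

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (len(self.times), len(self.species_ids)):
            raise ValueError("state matrix shape does not match times/species")
        if self.check_negative and self.states.min() < -1e-9:
            raise ValueError(
                f"negative concentration beyond tolerance: {self.states.min():.3g}"
            )

    def series(self, name: str) -> np.ndarray:
        """A species or observable series by name."""
        if name in self.observables:
            return self.observables[name]
        try:
            return self.states[:, self.species_ids.index(name)]
        except ValueError:
            raise KeyError(f"unknown series {name!r}") from None

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def _compiled(model: ModelSpec | CompiledModel) -> CompiledModel:
    return model if isinstance(model, CompiledModel) else model.compile()


def rhs(
    model: ModelSpec | CompiledModel,
    state: np.ndarray,
    t: float = 0.0,
    protocol: StressProtocol | None = None,
    overrides: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Time derivatives of all species at ``state`` under the protocol.

    Evaluates every reaction rate law plus the protocol's current mUFPT
    input; raises a diagnostic error naming the offending reaction if any
    rate is non-finite.
    """
    cm = _compiled(model)
    ov = dict(overrides or {})
    if protocol is not None:
        ov["mUFPT"] = protocol.value_at(t)
    p = cm.model.parameter_vector(ov)
    return cm.rhs(np.asarray(state, dtype=float), p)


def integrate(
    model: ModelSpec | CompiledModel,
    initial_state: np.ndarray | None = None,
    protocol: StressProtocol | None = None,
    t_end: float | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_points: int = 2000,
    overrides: Mapping[str, float] | None = None,
    method: str = "LSODA",
    nonnegative: bool = True,
) -> Trajectory:
    """Integrate the model under a stress protocol on a dense uniform grid.

    Each protocol segment is integrated separately (event-free piecewise
    integration); the state is continuous across boundaries while the
    mUFPT input jumps.  Small negative excursions within solver tolerance
    are clamped to zero in the returned trajectory; ``nonnegative=False``
    (for generic signed systems such as bifurcation test models) skips the
    concentration checks entirely.
    """
    cm = _compiled(model)
    m = cm.model
    y0 = m.initial_state if initial_state is None else np.asarray(initial_state, float)
    if t_end is None:
        if protocol is None or not np.isfinite(protocol.total_duration):
            raise ValueError("t_end is required for unbounded protocols")
        t_end = protocol.total_duration
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    grid = np.linspace(0.0, t_end, n_points)
    states = np.empty((n_points, m.n_species))
    has_mufpt = "mUFPT" in m.parameters
    segs = (
        protocol.boundaries(t_end)
        if (protocol is not None and has_mufpt)
        else [(0.0, t_end, None)]
    )

    y = y0.copy()
    for start, stop, value in segs:
        ov = dict(overrides or {})
        if value is not None:
            ov["mUFPT"] = value
        p = m.parameter_vector(ov)
        mask = (grid >= start) & (grid <= stop) if stop == t_end else (grid >= start) & (grid < stop)
        t_eval = grid[mask]
        # segment endpoints are always solved so the state chains correctly
        sol = solve_ivp(
            lambda t, yy: cm.rhs(yy, p),
            (start, stop),
            y,
            method=method,
            jac=lambda t, yy: cm.jac(yy, p),
            rtol=rtol,
            atol=atol,
            t_eval=np.unique(np.concatenate([t_eval, [stop]])),
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed in segment [{start:g}, {stop:g}]: {sol.message}",
                last_time=float(sol.t[-1]) if len(sol.t) else start,
            )
        cols = {t: i for i, t in enumerate(sol.t)}
        for tg in t_eval:
            states[np.searchsorted(grid, tg)] = sol.y[:, cols[tg]]
        y = sol.y[:, -1]

    if nonnegative:
        if states.min() < -1e-9:
            raise IntegrationError(
                f"negative concentrations beyond tolerance: min={states.min():.3g}"
            )
        states = np.clip(states, 0.0, None)

    p_last = m.parameter_vector(
        {**(overrides or {}), **({"mUFPT": segs[-1][2]} if segs[-1][2] is not None else {})}
    )
    obs = cm.observable_series(states, p_last)
    return Trajectory(
        times=grid,
        states=states,
        species_ids=m.species_ids,
        observables=obs,
        protocol=protocol,
        meta={"rtol": rtol, "atol": atol, "method": method,
              "overrides": dict(overrides or {})},
        check_negative=nonnegative,
    )


def equilibrate(
    model: ModelSpec | CompiledModel,
    mufpt: float = 0.0,
    overrides: Mapping[str, float] | None = None,
    t_relax: float = 20000.0,
) -> np.ndarray:
    """Pre-equilibrated steady state at a constant stress level.

    Long relaxation followed by Newton polishing; scenario runs start from
    the mUFPT=0 state returned by this function (computed, not hard-coded).
    """
    ov = dict(overrides or {})
    if "mUFPT" in _compiled(model).model.parameters:
        ov["mUFPT"] = mufpt
    state, _ = steady_state(model, overrides=ov, t_relax=t_relax)
    return state


def steady_state(
    model: ModelSpec | CompiledModel,
    guess: np.ndarray | None = None,
    overrides: Mapping[str, float] | None = None,
    tol: float = 1e-10,
    t_relax: float = 20000.0,
) -> tuple[np.ndarray, bool]:
    """Solve for a steady state and report its linear stability.

    Newton (scipy ``root`` with the analytic Jacobian) from ``guess``;
    if root-finding stalls or lands on a negative state, falls back to
    long-time integration and retries.  Returns ``(state, stable)`` where
    ``stable`` means all Jacobian eigenvalues have negative real part
    (tolerance 1e-8).
    """
    cm = _compiled(model)
    m = cm.model
    p = m.parameter_vector(overrides)
    y0 = m.initial_state if guess is None else np.asarray(guess, dtype=float)

    # conserved totals make the steady-state Jacobian singular, letting a
    # plain Newton drift along the invariant direction to spurious roots;
    # pin them to the guess's totals by augmenting the residual
    C = cm.conservation_matrix
    c0 = C @ np.clip(y0, 0, None) if len(C) else None

    def _G(yy):
        F = cm.rhs(yy, p)
        return F + C.T @ (C @ yy - c0) if len(C) else F

    def _J(yy):
        J = cm.jac(yy, p)
        return J + C.T @ C if len(C) else J

    def polish(y):
        # solver status alone is unreliable; judge convergence by residual
        sol = root(_G, y, jac=_J, method="hybr", tol=tol * 1e-2)
        return sol.x

    def converged(y):
        if not np.all(np.isfinite(y)) or y.min() < -1e-9:
            return False
        if np.linalg.norm(cm.rhs(y, p)) >= tol:
            return False
        return not len(C) or np.linalg.norm(C @ y - c0) < 1e-6 * max(np.linalg.norm(c0), 1.0)

    y = polish(y0)
    if not converged(y):
        sol = solve_ivp(lambda t, yy: cm.rhs(yy, p), (0.0, t_relax), np.clip(y0, 0, None),
                        method="LSODA", jac=lambda t, yy: cm.jac(yy, p),
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise IntegrationError("relaxation fallback failed: " + sol.message)
        y = polish(sol.y[:, -1])
        if not converged(y):
            raise IntegrationError(
                f"no steady state found (residual {np.linalg.norm(cm.rhs(y, p)):.2e})"
            )
    y = np.where(np.abs(y) < 1e-14, 0.0, y)
    eig = np.linalg.eigvals(cm.jac(y, p))
    stable = bool(np.all(eig.real < 1e-8))
    return y, stable


# ---------------------------------------------------------------------------
# reduced ATF4/GADD34 delay model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReducedDelayModel:
    """Two-variable ATF4/GADD34 skeleton of the PERK branch with delay.

    The eIF2α phosphorylation cycle is treated as instantaneous (its
    protein-level kinetics are much faster than the genetic steps): active
    eIF2α is the quasi-steady balance point of the saturated kinase
    (activity ``perka``) and phosphatase (``crep + gadd34``) pair.  ATF4 is
    translated through the repressing Hill response of active eIF2α, and
    GADD34 production responds to ATF4 delayed by ``tau`` — the condensed
    transcription/translation lag of the ATF4 → CHOP → GADD34 cascade.

    ``d ATF4/dt  = sA * H_rep(E_qss(GADD34)) − dA * ATF4``
    ``d GADD34/dt = sG * ATF4(t−τ)/(KG + ATF4(t−τ)) − dG * GADD34``

    This is a deliberate reconstruction at the topology level: it keeps the
    delayed negative feedback and the ultrasensitive switch, and drops
    everything else.
    """

    perka: float
    tau: float = 0.0
    eif2a_total: float = 100.0
    kphos: float = 2.0
    kdephos: float = 2.0
    km: float = 1.0
    crep: float = 2.0
    k_atf4: float = 10.0
    nh: float = 4.0
    sA: float = 2.0
    dA: float = 0.3
    sG: float = 0.6
    KG: float = 2.0
    dG: float = 0.15

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("delay tau must be non-negative")

    def eif2a_qss(self, gadd34: float) -> float:
        """Quasi-steady active eIF2α given the current phosphatase level."""
        phos = EnzymeRateParams(self.kphos, self.km)
        deph = EnzymeRateParams(self.kdephos, self.km)
        ph_tot = self.crep + max(gadd34, 0.0)

        def net(e):
            # d(active eIF2a)/dt at active level e: dephosphorylation feeds
            # the active pool, phosphorylation drains it
            return (tqssa_rate(deph, self.eif2a_total - e, ph_tot)
                    - tqssa_rate(phos, e, self.perka))

        lo, hi = 0.0, self.eif2a_total
        if net(lo) <= 0:
            return 0.0
        if net(hi) >= 0:
            return self.eif2a_total
        return brentq(net, lo, hi, xtol=1e-10)

    def derivatives(self, y: np.ndarray, y_lag: np.ndarray) -> np.ndarray:
        atf4, gadd34 = y
        atf4_lag = y_lag[0]
        e = self.eif2a_qss(gadd34)
        h = self.k_atf4**self.nh / (self.k_atf4**self.nh + e**self.nh)
        datf4 = self.sA * h - self.dA * atf4
        dgadd = self.sG * max(atf4_lag, 0.0) / (self.KG + max(atf4_lag, 0.0)) - self.dG * gadd34
        return np.array([datf4, dgadd])


def integrate_dde(
    f: Callable[[float, np.ndarray, np.ndarray], np.ndarray] | ReducedDelayModel,
    history: np.ndarray | Callable[[float], np.ndarray],
    tau: float | None = None,
    t_end: float = 1000.0,
    n_points: int = 2000,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Delay-differential integration by the method of steps.

    ``f(t, y, y_lag)`` is the right-hand side (for a :class:`ReducedDelayModel`
    pass the model itself); ``history`` is the constant state, or a callable,
    on ``[-tau, 0]``.  For ``tau = 0`` the same solver path runs with
    ``y_lag = y``, so the ODE limit is reproduced exactly.  Within each step
    of length ``tau``, the lagged state is read from the previous step's
    dense (cubic) interpolant.
    """
    if isinstance(f, ReducedDelayModel):
        model = f
        tau = model.tau if tau is None else tau
        fun = lambda t, y, ylag: model.derivatives(y, ylag)
        names = ["ATF4", "GADD34"]
    else:
        fun = f
        names = None
        if tau is None:
            raise ValueError("tau is required for a bare right-hand side")
    if tau < 0:
        raise ValueError("delay tau must be non-negative")

    hist = history if callable(history) else (lambda t, h=np.asarray(history, float): h)
    y0 = np.atleast_1d(np.asarray(hist(0.0), dtype=float))
    n = len(y0)
    names = names or [f"x{i}" for i in range(n)]

    grid = np.linspace(0.0, t_end, n_points)
    if tau == 0.0:
        sol = solve_ivp(lambda t, y: fun(t, y, y), (0.0, t_end), y0, method="LSODA",
                        rtol=rtol, atol=atol, t_eval=grid)
        if not sol.success:
            raise IntegrationError("DDE (tau=0) integration failed: " + sol.message)
        return Trajectory(grid, sol.y.T, names,
                          meta={"tau": 0.0, "rtol": rtol, "atol": atol},
                          check_negative=False)

    # method of steps: dense interpolants of completed steps serve as history
    interpolants: list = []
    starts: list[float] = []

    def lagged(t: float) -> np.ndarray:
        tl = t - tau
        if tl <= 0:
            return np.atleast_1d(np.asarray(hist(tl), dtype=float))
        k = np.searchsorted(starts, tl, side="right") - 1
        return interpolants[k](tl)

    states = np.empty((n_points, n))
    states[0] = y0
    y = y0
    t0 = 0.0
    while t0 < t_end - 1e-12:
        t1 = min(t0 + tau, t_end)
        sol = solve_ivp(lambda t, yy: fun(t, yy, lagged(t)), (t0, t1), y,
                        method="LSODA", rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise IntegrationError(f"DDE integration failed at t={sol.t[-1]:.3g}",
                                   last_time=float(sol.t[-1]))
        starts.append(t0)
        interpolants.append(sol.sol)
        mask = (grid > t0) & (grid <= t1)
        if mask.any():
            states[mask] = sol.sol(grid[mask]).T
        y = sol.y[:, -1]
        t0 = t1
    return Trajectory(grid, states, names,
                      meta={"tau": tau, "rtol": rtol, "atol": atol},
                      check_negative=False)


# ---------------------------------------------------------------------------
# trajectory metrics
# ---------------------------------------------------------------------------


def oscillation_metrics(
    traj: Trajectory,
    species: str,
    transient_fraction: float = 0.5,
    amplitude_threshold: float = 0.01,
    decay_ratio: float = 0.95,
    min_peaks: int = 5,
) -> tuple[float, float, bool]:
    """(frequency, relative amplitude, sustained flag) of one series.

    The first ``transient_fraction`` of the window is discarded.  Frequency
    is ``(number of maxima − 1) / (time between first and last maximum)``.
    ``sustained`` requires the relative peak-to-trough amplitude to exceed
    ``amplitude_threshold`` of the series mean *and* the last/first peak
    height ratio to exceed ``decay_ratio`` (a decaying transient fails).
    Constant or converging series return ``(0, 0, False)``.
    """
    x = traj.series(species)
    t = traj.times
    i0 = int(len(t) * transient_fraction)
    x, t = x[i0:], t[i0:]
    if len(x) < 8:
        raise ValueError("window too short after transient discard; increase t_end")

    mean = float(np.mean(np.abs(x)))
    span = float(x.max() - x.min())
    rel_amp = span / mean if mean > 0 else 0.0
    if mean == 0 or rel_amp < amplitude_threshold:
        return 0.0, rel_amp, False

    prom = 0.05 * span
    peaks, props = find_peaks(x, prominence=prom)
    if len(peaks) < 2:
        return 0.0, rel_amp, False
    freq = (len(peaks) - 1) / (t[peaks[-1]] - t[peaks[0]])
    # non-decaying check on peak heights above the window floor
    first_amp = x[peaks[0]] - x.min()
    last_amp = x[peaks[-1]] - x.min()
    sustained = bool(last_amp >= decay_ratio * first_amp and rel_amp > amplitude_threshold)
    if sustained and len(peaks) < min_peaks:
        raise ValueError(
            f"only {len(peaks)} oscillation peaks in the analysis window; "
            "increase t_end for a reliable frequency estimate"
        )
    return float(freq), float(rel_amp), sustained


def renormalize_trajectory(
    traj: Trajectory, species: Sequence[str]
) -> dict[str, np.ndarray]:
    """Rescale each selected series to 0–100% of its own range.

    The minimum maps to 0 and the maximum to 100 over the trajectory
    window; a constant series maps to 0 everywhere (declared convention).
    """
    if not species:
        raise ValueError("empty species selection")
    out: dict[str, np.ndarray] = {}
    for name in species:
        x = traj.series(name)
        span = x.max() - x.min()
        out[name] = np.zeros_like(x) if span == 0 else 100.0 * (x - x.min()) / span
    return out


def activation_timing(
    traj: Trajectory, species: Sequence[str], threshold_percent: float = 50.0
) -> dict[str, float | None]:
    """First time each renormalised series crosses ``threshold_percent``.

    Series that never cross are reported as ``None`` (absent), not as an
    error.  The dict preserves the requested order; compare values to
    establish the activation sequence.
    """
    norm = renormalize_trajectory(traj, species)
    out: dict[str, float | None] = {}
    for name in species:
        above = norm[name] >= threshold_percent
        idx = np.argmax(above)
        out[name] = float(traj.times[idx]) if above.any() else None
    return out
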