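"""Steady-state continuation, stability, Hopf/fold detection and the
three-activity-state classification.

The continuation is natural-parameter stepping with a secant predictor and
Newton corrector, switching to pseudo-arclength steps whenever the branch
approaches a fold, so S-shaped branches are traversed rather than
truncated.  Eigenvalues of the exact symbolic Jacobian are attached to
every accepted point; Hopf points are located by bisection on the real
part of the leading complex pair, folds by the turning of the parameter
along the arclength.

Limit-cycle envelopes are measured by long simulation inside the
oscillatory window (limit-cycle continuation/collocation is out of scope);
bistability is detected by the classical quasi-static two-sweep protocol
and cross-checked against folds where a branch is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import dynamics
from .dynamics import IntegrationError, StressProtocol, integrate, oscillation_metrics, steady_state
from .network import CompiledModel, ModelSpec

__all__ = [
    "BranchPoint",
    "HopfPoint",
    "FoldPoint",
    "BifurcationDiagram",
    "ActivityState",
    "continue_branch",
    "detect_hopf",
    "detect_folds",
    "limit_cycle_envelope",
    "detect_bistability",
    "classify_activity_state",
]

#: |Re| below which an eigenvalue pair counts as on the imaginary axis
HOPF_TOL = 1e-8
STABILITY_TOL = 1e-8


@dataclass
class BranchPoint:
    """One steady state on a continuation branch."""

    parameter: float
    state: np.ndarray
    eigenvalues: np.ndarray
    residual: float

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < STABILITY_TOL))

    @property
    def leading_real(self) -> float:
        return float(self.eigenvalues.real.max())

    @property
    def leading_complex_real(self) -> float:
        """Largest real part among genuinely complex eigenvalue pairs."""
        mask = np.abs(self.eigenvalues.imag) > 1e-9
        return float(self.eigenvalues.real[mask].max()) if mask.any() else -np.inf


@dataclass
class HopfPoint:
    """Parameter value where a complex pair crosses the imaginary axis."""

    parameter: float
    state: np.ndarray
    omega: float  # |Im| of the crossing pair: angular frequency at onset

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("Hopf point requires a non-zero imaginary pair")


@dataclass
class FoldPoint:
    parameter: float
    state: np.ndarray


@dataclass
class BifurcationDiagram:
    """Continuation branch plus detected features and cycle envelopes."""

    parameter_name: str
    branch: list[BranchPoint]
    hopf_points: list[HopfPoint] = field(default_factory=list)
    fold_points: list[FoldPoint] = field(default_factory=list)
    envelopes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    bistable_intervals: list[tuple[float, float]] = field(default_factory=list)

    def stability_profile(self) -> list[tuple[float, bool]]:
        return [(bp.parameter, bp.stable) for bp in self.branch]


@dataclass(frozen=True)
class ActivityState:
    """Classification of the UPR response at one stress/input level.

    ``label`` is one of low / intermediate / high; ``window`` is the
    parameter interval the label was established on (degenerate for a
    point query); diagnostics carry the measured CHOP, translation and
    oscillation numbers behind the verdict.
    """

    label: str
    window: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)


def _compiled(model):
    return model if isinstance(model, CompiledModel) else model.compile()


def _solve_point(cm, pname, pval, guess, overrides, tol=1e-10):
    ov = dict(overrides or {})
    ov[pname] = pval
    y, _ = steady_state(cm, guess=guess, overrides=ov, tol=tol)
    p = cm.model.parameter_vector(ov)
    eig = np.linalg.eigvals(cm.jac(y, p))
    res = float(np.linalg.norm(cm.rhs(y, p)))
    return BranchPoint(float(pval), y, eig, res)


def _branch_point(cm, pname, pval, y, overrides) -> BranchPoint:
    ov = dict(overrides or {})
    ov[pname] = float(pval)
    p = cm.model.parameter_vector(ov)
    eig = np.linalg.eigvals(cm.jac(y, p))
    return BranchPoint(float(pval), y, eig, float(np.linalg.norm(cm.rhs(y, p))))


def _conservation_rows(cm) -> np.ndarray:
    """Orthonormal basis of conserved linear combinations (left null space
    of the stoichiometric matrix).  Conservation makes the steady-state
    Jacobian structurally singular; continuation pins the conserved totals
    by augmenting the residual with ``C^T (C y − c0)``, which has the same
    zero set restricted to the invariant manifold but full rank."""
    from scipy.linalg import null_space
    C = null_space(cm.model.stoichiometry.T, rcond=1e-10).T
    return C


def _newton_arclength(cm, pname, overrides, y0, l0, ty, tl, ds, tol,
                      C=None, c0=None, max_iter=25):
    """One pseudo-arclength corrector step.

    Solves F(y, λ) = 0 together with the arclength constraint
    ``(y−y0)·ty + (λ−l0)·tl − ds = 0`` by a bordered Newton iteration;
    the Jacobian column ∂F/∂λ is taken by central finite difference.
    ``C``/``c0`` pin conserved totals (see :func:`_conservation_rows`).
    Returns (y, λ) or None on failure.
    """
    n = len(y0)
    y = y0 + ty * ds
    lam = l0 + tl * ds
    scale = max(np.linalg.norm(y0), 1.0)
    for _ in range(max_iter):
        ov = dict(overrides or {})
        ov[pname] = lam
        p = cm.model.parameter_vector(ov)
        try:
            F = cm.rhs(y, p)
        except FloatingPointError:
            return None
        if C is not None and len(C):
            F = F + C.T @ (C @ y - c0)
        g = float((y - y0) @ ty + (lam - l0) * tl - ds)
        if np.linalg.norm(F) < tol * scale and abs(g) < 1e-12 * max(abs(ds), 1.0):
            return y, lam
        J = cm.jac(y, p)
        if C is not None and len(C):
            J = J + C.T @ C
        dl = 1e-7 * max(abs(lam), 1.0)
        ovp, ovm = dict(ov), dict(ov)
        ovp[pname] = lam + dl
        ovm[pname] = lam - dl
        Fl = (cm.rhs(y, cm.model.parameter_vector(ovp))
              - cm.rhs(y, cm.model.parameter_vector(ovm))) / (2 * dl)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = J
        A[:n, n] = Fl
        A[n, :n] = ty
        A[n, n] = tl
        rhs_vec = -np.concatenate([F, [g]])
        try:
            step = np.linalg.solve(A, rhs_vec)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        y = y + step[:n]
        lam = lam + step[n]
    return None


def continue_branch(
    model: ModelSpec | CompiledModel,
    parameter: str,
    p_range: tuple[float, float],
    n_steps: int = 100,
    start_state: np.ndarray | None = None,
    overrides: Mapping[str, float] | None = None,
    tol: float = 1e-10,
    max_points: int | None = None,
) -> list[BranchPoint]:
    """Continue a steady-state branch over ``parameter`` across ``p_range``.

    The first point is found by relaxation plus Newton polishing; from
    there the branch is followed by pseudo-arclength continuation (secant
    tangent predictor, bordered Newton corrector), so folds are traversed
    — the parameter simply reverses along the arclength — rather than
    truncated.  The arclength step adapts: it halves on corrector failure
    and recovers on success, with the parameter-direction component capped
    near the nominal step ``(hi−lo)/n_steps``.  The sweep stops once the
    parameter reaches the far end of the range (in either branch
    direction), leaves the range on the near side after a fold, or the
    point budget is exhausted; if the corrector fails at the minimal step
    the partial branch is returned with a warning.
    """
    cm = _compiled(model)
    p_lo, p_hi = map(float, p_range)
    direction = 1.0 if p_hi >= p_lo else -1.0
    h = abs(p_hi - p_lo) / n_steps
    max_points = max_points or 8 * n_steps
    span = abs(p_hi - p_lo)

    first = _solve_point(cm, parameter, p_lo, start_state, overrides, tol)
    branch = [first]

    # second point by a small natural step to establish the secant tangent
    second = _solve_point(cm, parameter, p_lo + direction * h, first.state, overrides, tol)
    branch.append(second)

    C = _conservation_rows(cm)
    c0 = C @ first.state if len(C) else None

    # state scaling keeps the arclength metric balanced between state and
    # parameter directions
    w = 1.0 / max(np.linalg.norm(second.state), 1.0)
    ds = h
    while len(branch) < max_points:
        a, b = branch[-2], branch[-1]
        dy = (b.state - a.state) * w
        dl = b.parameter - a.parameter
        norm = np.hypot(np.linalg.norm(dy), dl)
        if norm == 0:
            break
        ty, tl = dy / norm, dl / norm
        sol = _newton_arclength(cm, parameter, overrides, b.state, b.parameter,
                                ty * w, tl, ds, tol, C=C, c0=c0)
        if sol is None:
            if ds > h / 256:
                ds *= 0.5
                continue
            warnings.warn(
                f"continuation lost the branch at {parameter}={b.parameter:.6g}; "
                "returning partial branch",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        y, lam = sol
        branch.append(_branch_point(cm, parameter, lam, y, overrides))
        if ds < h:
            ds = min(2 * ds, h)
        # reached the far end of the sweep (on any branch segment)
        if (lam - p_hi) * direction >= 0:
            break
        # folded back out of the range on the starting side
        if (lam - p_lo) * direction < -0.02 * span:
            break
    return branch


def detect_hopf(
    branch: Sequence[BranchPoint],
    model: ModelSpec | CompiledModel | None = None,
    parameter: str | None = None,
    overrides: Mapping[str, float] | None = None,
    refine_tol: float = HOPF_TOL,
) -> list[HopfPoint]:
    """Hopf points along a branch: sign changes of the leading complex pair.

    Between adjacent branch points whose maximal complex-pair real part
    changes sign, the crossing is refined by bisection (re-solving the
    steady state at each midpoint) until ``|Re| < refine_tol``.  Passing
    the model enables refinement; without it the midpoint of the bracketing
    interval is returned.  An empty result is a valid outcome.
    """
    out: list[HopfPoint] = []
    cm = _compiled(model) if model is not None else None

    def pair_real(bp: BranchPoint) -> float:
        return bp.leading_complex_real

    def omega_of(bp: BranchPoint) -> float:
        mask = np.abs(bp.eigenvalues.imag) > 1e-9
        if not mask.any():
            return 0.0
        lead = bp.eigenvalues[mask]
        return float(abs(lead[np.argmax(lead.real)].imag))

    for a, b in zip(branch[:-1], branch[1:]):
        ra, rb = pair_real(a), pair_real(b)
        if not (np.isfinite(ra) and np.isfinite(rb)) or ra * rb >= 0:
            continue
        lo, hi = a, b
        if cm is not None and parameter is not None:
            for _ in range(200):
                if abs(pair_real(lo)) < refine_tol or abs(hi.parameter - lo.parameter) < 1e-13:
                    break
                mid = _solve_point(
                    cm, parameter, 0.5 * (lo.parameter + hi.parameter),
                    0.5 * (lo.state + hi.state), overrides,
                )
                if pair_real(lo) * pair_real(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            crossing = lo if abs(pair_real(lo)) <= abs(pair_real(hi)) else hi
        else:
            crossing = a if abs(ra) <= abs(rb) else b
        out.append(HopfPoint(crossing.parameter, crossing.state, omega_of(crossing)))
    return out


def detect_folds(branch: Sequence[BranchPoint]) -> list[FoldPoint]:
    """Fold (turning) points: local extrema of the parameter along the branch."""
    out = []
    for i in range(1, len(branch) - 1):
        dp1 = branch[i].parameter - branch[i - 1].parameter
        dp2 = branch[i + 1].parameter - branch[i].parameter
        if dp1 * dp2 < 0:
            out.append(FoldPoint(branch[i].parameter, branch[i].state))
    return out


def limit_cycle_envelope(
    model: ModelSpec | CompiledModel,
    parameter: str,
    grid: Sequence[float],
    species: Sequence[str],
    start_state: np.ndarray | None = None,
    overrides: Mapping[str, float] | None = None,
    t_end: float = 2000.0,
    transient_fraction: float = 0.5,
    nonnegative: bool = True,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-species (grid, min, max) limit-cycle envelopes by simulation.

    At each grid value the model is integrated for ``t_end`` atu from the
    previous grid point's final state (quasi-static sweep); the envelope is
    the post-transient min/max.  Grid points where no sustained oscillation
    is detected are flagged with NaN envelopes.
    """
    cm = _compiled(model)
    y = start_state if start_state is not None else cm.model.initial_state
    grid = np.asarray(list(grid), dtype=float)
    mins = {s: np.full(len(grid), np.nan) for s in species}
    maxs = {s: np.full(len(grid), np.nan) for s in species}
    for i, pv in enumerate(grid):
        ov = dict(overrides or {})
        ov[parameter] = pv
        traj = integrate(cm, y, t_end=t_end, overrides=ov, n_points=2000,
                         nonnegative=nonnegative)
        y = traj.final_state
        i0 = int(len(traj.times) * transient_fraction)
        for s in species:
            try:
                _, _, sustained = oscillation_metrics(traj, s, transient_fraction)
            except ValueError:
                sustained = False
            if sustained:
                x = traj.series(s)[i0:]
                mins[s][i], maxs[s][i] = x.min(), x.max()
    return {s: (grid, mins[s], maxs[s]) for s in species}


def detect_bistability(
    model: ModelSpec | CompiledModel,
    parameter: str,
    p_range: tuple[float, float],
    observable: str,
    n_steps: int = 100,
    dwell: float = 500.0,
    overrides: Mapping[str, float] | None = None,
    separation: float | None = None,
    nonnegative: bool = True,
) -> list[tuple[float, float]]:
    """Bistable interval(s) by the quasi-static two-sweep protocol.

    The parameter is stepped up and then back down in ``n_steps``
    increments (1% of range by default) with ``dwell`` atu of
    re-equilibration per step; an interval is bistable where the up- and
    down-sweep states of ``observable`` differ by more than ``separation``
    (default: 10% of the overall observable range).  An empty list is a
    valid outcome (monostable system).
    """
    cm = _compiled(model)
    m = cm.model
    grid = np.linspace(p_range[0], p_range[1], n_steps + 1)

    def sweep(values):
        y = m.initial_state
        out = np.empty(len(values))
        for i, pv in enumerate(values):
            ov = dict(overrides or {})
            ov[parameter] = pv
            traj = integrate(cm, y, t_end=dwell, overrides=ov, n_points=50,
                             nonnegative=nonnegative)
            y = traj.final_state
            out[i] = traj.series(observable)[-1] if observable in (
                m.species_ids + list(traj.observables)
            ) else np.nan
        return out

    up = sweep(grid)
    down = sweep(grid[::-1])[::-1]
    span = max(np.nanmax(np.concatenate([up, down])) - np.nanmin(np.concatenate([up, down])), 1e-12)
    sep = separation if separation is not None else 0.1 * span
    mask = np.abs(up - down) > sep
    intervals: list[tuple[float, float]] = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            intervals.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    return intervals


def classify_activity_state(
    model: ModelSpec | CompiledModel,
    value: float,
    parameter: str = "mUFPT",
    chop_bounds: tuple[float, float] | None = None,
    attenuation_fraction: float = 0.1,
    t_end: float = 2000.0,
    start_state: np.ndarray | None = None,
    overrides: Mapping[str, float] | None = None,
) -> ActivityState:
    """Classify the response at one stress level as low/intermediate/high.

    intermediate: sustained CHOP oscillations (via oscillation metrics on a
    long run).  Otherwise the verdict rests on the late steady levels:
    low = CHOP below the midpoint of its low/high asymptotes and
    translation above its midpoint; high = CHOP above midpoint and active
    eIF2α below ``attenuation_fraction`` of total (translation virtually
    suspended).  The CHOP asymptotes default to the model's own extremes
    (steady CHOP at zero drive and at saturating drive) and are
    configurable through ``chop_bounds``.  A pattern matching neither
    combination is labelled ``ambiguous`` with full diagnostics rather
    than silently coerced.
    """
    cm = _compiled(model)
    m = cm.model
    ov = dict(overrides or {})
    if start_state is None:
        start_state = dynamics.equilibrate(cm, 0.0, overrides=ov) if parameter == "mUFPT" \
            else m.initial_state
    ov[parameter] = value
    traj = integrate(cm, start_state, t_end=t_end, overrides=ov, n_points=2000)

    try:
        freq, amp, sustained = oscillation_metrics(traj, "CHOP", 0.5)
    except ValueError:
        freq, amp, sustained = 0.0, 0.0, False

    eif_total = m.parameters.get("eIF2aT", np.nan)
    chop_late = float(np.mean(traj.series("CHOP")[-200:]))
    eif_late = float(np.mean(traj.series("eIF2a")[-200:]))

    if chop_bounds is None:
        lo_ref = _saturating_chop(cm, parameter, 0.0, ov)
        hi_ref = _saturating_chop(cm, parameter, None, ov)
        chop_bounds = (lo_ref, hi_ref)
    chop_mid = 0.5 * (chop_bounds[0] + chop_bounds[1])
    atten = attenuation_fraction * eif_total

    diag = {
        "frequency": freq, "relative_amplitude": amp, "sustained": sustained,
        "chop_late": chop_late, "eif2a_late": eif_late,
        "chop_midpoint": chop_mid, "attenuation_level": atten,
    }
    if sustained:
        return ActivityState("intermediate", (value, value), diag)
    if chop_late < chop_mid and eif_late > 0.5 * eif_total:
        return ActivityState("low", (value, value), diag)
    if chop_late >= chop_mid and eif_late < atten:
        return ActivityState("high", (value, value), diag)
    return ActivityState("ambiguous", (value, value), diag)


def _saturating_chop(cm, parameter, value, overrides) -> float:
    """Steady CHOP at zero drive (value=0) or at a saturating drive (None)."""
    ov = dict(overrides)
    if value is None:
        base = cm.model.parameters[parameter]
        ov[parameter] = max(4.0 * base, 40.0)
    else:
        ov[parameter] = value
    try:
        y, _ = steady_state(cm, overrides=ov)
        return float(y[cm.model.index["CHOP"]])
    except IntegrationError:
        # oscillatory at the probe value: use the mean of a long run
        traj = integrate(cm, cm.model.initial_state, t_end=2000.0, overrides=ov, n_points=500)
        return float(np.mean(traj.series("CHOP")[-250:]))
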