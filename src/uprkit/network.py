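"""Declarative reaction-network container and its compiled numeric form.

A :class:`ModelSpec` is a list of species, a list of reactions whose rate
laws are :mod:`sympy` expressions over species and parameter symbols, a
parameter table and a table of derived observables (totals such as BiPT or
UFPT).  Networks are assembled with :class:`NetworkBuilder`, which also
collects per-gene promoter contributions so that modules can each add
transcription-factor terms to a shared gene; at :meth:`NetworkBuilder.build`
time every promoter becomes a single transcription reaction carrying the
competitive regulation law.

Compilation (:meth:`ModelSpec.compile`) produces vectorised numpy callables
for the right-hand side and the exact symbolic Jacobian, both taking the
full parameter vector as an argument so that parameter sweeps do not pay
recompilation costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

from .rate_laws import regulation_expr

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "ModelSpec",
    "NetworkBuilder",
    "CompiledModel",
    "AssemblyError",
]

COMPARTMENTS = ("ER", "nucleus", "Golgi", "cytoplasm")


class AssemblyError(ValueError):
    """Raised on inconsistent network composition (id collisions etc.)."""


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species with its compartment and initial amount (acu)."""

    id: str
    compartment: str
    initial: float = 0.0
    role: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise AssemblyError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.initial < 0:
            raise AssemblyError(f"species {self.id!r}: negative initial amount")

    @property
    def symbol(self) -> sp.Symbol:
        return sp.Symbol(self.id)


@dataclass(frozen=True)
class ReactionDef:
    """A reaction channel: stoichiometry plus a symbolic rate law (acu/atu).

    ``reactants``/``products`` map species ids to positive integer
    stoichiometries; the rate expression may reference any species or
    parameter symbol of the enclosing model.
    """

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: sp.Expr
    note: str = ""

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for spid, nu in side.items():
                if int(nu) != nu or nu <= 0:
                    raise AssemblyError(
                        f"reaction {self.id!r}: stoichiometry of {spid} must be "
                        "a positive integer"
                    )

    @property
    def free_symbols(self) -> set[sp.Symbol]:
        return self.rate.free_symbols


class ModelSpec:
    """An assembled reaction network.

    Parameters
    ----------
    species, reactions :
        Ordered definitions; ids must be unique.
    parameters :
        Mapping of parameter name to value.  Every non-species symbol used
        by a rate law or observable must appear here.
    observables :
        Named derived quantities (sympy expressions over species and
        parameters), e.g. totals like ``BiPT``.
    """

    def __init__(
        self,
        species: Sequence[SpeciesDef],
        reactions: Sequence[ReactionDef],
        parameters: Mapping[str, float],
        observables: Mapping[str, sp.Expr] | None = None,
        name: str = "model",
    ) -> None:
        self.name = name
        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = dict(parameters)
        self.observables = dict(observables or {})
        self._validate()

    # -- introspection -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(species, reactions, parameters) of the assembled network."""
        return (self.n_species, self.n_reactions, self.n_parameters)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @cached_property
    def index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def _validate(self) -> None:
        ids = self.species_ids
        if len(set(ids)) != len(ids):
            raise AssemblyError("duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise AssemblyError("duplicate reaction ids")
        known = set(ids) | set(self.parameters)
        for r in self.reactions:
            for spid in list(r.reactants) + list(r.products):
                if spid not in self.index:
                    raise AssemblyError(
                        f"reaction {r.id!r} references unknown species {spid!r}"
                    )
            missing = {str(s) for s in r.free_symbols} - known
            if missing:
                raise AssemblyError(
                    f"reaction {r.id!r} references unknown symbols {sorted(missing)}"
                )

    # -- numeric views -------------------------------------------------
    @cached_property
    def stoichiometry(self) -> np.ndarray:
        """Species x reactions stoichiometric matrix."""
        N = np.zeros((self.n_species, self.n_reactions))
        for j, r in enumerate(self.reactions):
            for spid, nu in r.reactants.items():
                N[self.index[spid], j] -= nu
            for spid, nu in r.products.items():
                N[self.index[spid], j] += nu
        return N

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([s.initial for s in self.species], dtype=float)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.parameters)

    def parameter_vector(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        p = dict(self.parameters)
        if overrides:
            unknown = set(overrides) - set(p)
            if unknown:
                raise KeyError(f"unknown parameters {sorted(unknown)}")
            p.update(overrides)
        return np.array([p[k] for k in self.parameters], dtype=float)

    def with_parameters(self, **overrides: float) -> "ModelSpec":
        """A copy of the model with some parameter values replaced."""
        p = dict(self.parameters)
        unknown = set(overrides) - set(p)
        if unknown:
            raise KeyError(f"unknown parameters {sorted(unknown)}")
        p.update(overrides)
        return ModelSpec(self.species, self.reactions, p, self.observables, self.name)

    def compile(self) -> "CompiledModel":
        return CompiledModel(self)

    # -- conservation --------------------------------------------------
    def conserved_totals(self) -> dict[str, sp.Expr]:
        """Left null-space combinations of the stoichiometric matrix.

        Returns integer-combination expressions of species amounts that are
        invariant under every reaction channel (binding/conversion moieties
        such as total eIF2alpha).
        """
        N = sp.Matrix(self.stoichiometry.astype(int))
        null = N.T.nullspace()
        out: dict[str, sp.Expr] = {}
        syms = [s.symbol for s in self.species]
        for k, vec in enumerate(null):
            v = vec.T
            denlcm = sp.lcm([sp.nsimplify(x).q for x in v if x != 0] or [1])
            v = v * denlcm
            expr = sum(c * s for c, s in zip(v, syms))
            out[f"conserved_{k}"] = sp.expand(expr)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        s, r, p = self.counts
        return f"<ModelSpec {self.name!r}: {s} species, {r} reactions, {p} parameters>"


class NetworkBuilder:
    """Incremental network assembly with shared-promoter bookkeeping.

    Modules register species, parameters and reactions; transcription
    regulation is registered per gene as (regulator concentration, kc, Km)
    symbol triples via :meth:`add_promoter_term` and turned into one
    competitive-regulation reaction per gene when :meth:`build` is called.
    Re-registration of an identical species/parameter is idempotent (shared
    species such as BiP merge by id); conflicting definitions raise
    :class:`AssemblyError`.
    """

    def __init__(self, name: str = "model") -> None:
        self.name = name
        self._species: dict[str, SpeciesDef] = {}
        self._parameters: dict[str, float] = {}
        self._reactions: dict[str, ReactionDef] = {}
        self._promoters: dict[str, dict] = {}
        self._observables: dict[str, sp.Expr] = {}

    # -- registration --------------------------------------------------
    def add_species(
        self, id: str, compartment: str, initial: float = 0.0, role: str = ""
    ) -> sp.Symbol:
        new = SpeciesDef(id, compartment, initial, role)
        old = self._species.get(id)
        if old is not None and old != new:
            raise AssemblyError(f"conflicting definitions for species {id!r}")
        self._species[id] = new
        return new.symbol

    def add_parameter(self, name: str, value: float) -> sp.Symbol:
        old = self._parameters.get(name)
        if old is not None and old != value:
            raise AssemblyError(f"conflicting values for parameter {name!r}")
        self._parameters[name] = float(value)
        return sp.Symbol(name)

    def add_reaction(
        self,
        id: str,
        reactants: Mapping[str, int],
        products: Mapping[str, int],
        rate: sp.Expr,
        note: str = "",
    ) -> None:
        new = ReactionDef(id, dict(reactants), dict(products), sp.sympify(rate), note)
        old = self._reactions.get(id)
        if old is not None:
            same = (
                old.reactants == new.reactants
                and old.products == new.products
                and sp.simplify(old.rate - new.rate) == 0
            )
            if not same:
                raise AssemblyError(f"conflicting definitions for reaction {id!r}")
            return
        self._reactions[id] = new

    def declare_promoter(self, gene: str, product: str, reaction_id: str | None = None) -> None:
        """Register a regulated gene whose transcription produces ``product``."""
        entry = {"product": product, "rid": reaction_id or f"tx_{gene}", "terms": []}
        old = self._promoters.get(gene)
        if old is not None:
            if old["product"] != product or old["rid"] != entry["rid"]:
                raise AssemblyError(f"conflicting promoter declarations for {gene!r}")
            return
        self._promoters[gene] = entry

    def add_promoter_term(self, gene: str, conc: sp.Expr, kc: sp.Expr, Km: sp.Expr) -> None:
        if gene not in self._promoters:
            raise AssemblyError(f"promoter {gene!r} has not been declared")
        self._promoters[gene]["terms"].append((sp.sympify(conc), sp.sympify(kc), sp.sympify(Km)))

    def add_observable(self, name: str, expr: sp.Expr) -> None:
        old = self._observables.get(name)
        if old is not None and sp.simplify(old - expr) != 0:
            raise AssemblyError(f"conflicting definitions for observable {name!r}")
        self._observables[name] = sp.sympify(expr)

    # -- finalisation --------------------------------------------------
    def build(self) -> ModelSpec:
        reactions = list(self._reactions.values())
        for gene in sorted(self._promoters):
            entry = self._promoters[gene]
            terms = sorted(entry["terms"], key=lambda t: sp.srepr(t))
            rate = regulation_expr(terms)
            reactions.append(
                ReactionDef(
                    entry["rid"],
                    {},
                    {entry["product"]: 1},
                    rate,
                    note=f"regulated transcription of {gene}",
                )
            )
        # canonical order: species and reactions sorted by id so that module
        # composition is order-independent
        species = sorted(self._species.values(), key=lambda s: s.id)
        reactions = sorted(reactions, key=lambda r: r.id)
        return ModelSpec(species, reactions, dict(self._parameters), self._observables, self.name)


class CompiledModel:
    """Numeric right-hand side, Jacobian and observables of a model.

    The compiled callables take ``(y, p)`` with ``y`` the species state and
    ``p`` the full parameter vector (order of
    :attr:`ModelSpec.parameter_names`), so parameter changes are free.
    """

    def __init__(self, model: ModelSpec) -> None:
        self.model = model
        ysyms = [s.symbol for s in model.species]
        psyms = [sp.Symbol(k) for k in model.parameters]
        N = sp.Matrix(model.stoichiometry.astype(int))
        rates = sp.Matrix([r.rate for r in model.reactions])
        rhs = N * rates
        jac = rhs.jacobian(ysyms)
        self._rates = sp.lambdify((ysyms, psyms), rates, "numpy", cse=True)
        self._rhs = sp.lambdify((ysyms, psyms), rhs, "numpy", cse=True)
        # recombine x**h/x terms that sympy's quotient rule leaves behind:
        # as written they are 0/0 at zero concentrations although the
        # derivative itself is finite (Hill exponents are >= 1)
        jac = jac.applyfunc(lambda e: sp.powsimp(e, force=True))
        self._jac = sp.lambdify((ysyms, psyms), jac, "numpy")
        obs_names = list(model.observables)
        obs_exprs = sp.Matrix([model.observables[k] for k in obs_names]) if obs_names else None
        self.observable_names = obs_names
        self._obs = (
            sp.lambdify((ysyms, psyms), obs_exprs, "numpy", cse=True)
            if obs_exprs is not None
            else None
        )

    def rates(self, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.asarray(self._rates(y, p), dtype=float).ravel()

    def rhs(self, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        out = np.asarray(self._rhs(y, p), dtype=float).ravel()
        if not np.all(np.isfinite(out)):
            bad = [
                self.model.reactions[j].id
                for j, v in enumerate(self.rates_safe(y, p))
                if not np.isfinite(v)
            ]
            raise FloatingPointError(
                f"non-finite rate in reactions {bad or '<derivative>'} at state {y!r}"
            )
        return out

    def rates_safe(self, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            return np.asarray(self._rates(y, p), dtype=float).ravel()

    def jac(self, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.asarray(self._jac(y, p), dtype=float)

    @cached_property
    def conservation_matrix(self) -> np.ndarray:
        """Orthonormal rows spanning the conserved linear combinations
        (left null space of the stoichiometric matrix)."""
        from scipy.linalg import null_space
        return null_space(self.model.stoichiometry.T, rcond=1e-10).T

    def jac_fd(self, y: np.ndarray, p: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
        """Central finite-difference Jacobian (cross-check for the symbolic one)."""
        n = len(y)
        J = np.zeros((n, n))
        for i in range(n):
            h = rel_step * max(abs(y[i]), 1.0)
            yp, ym = y.copy(), y.copy()
            yp[i] += h
            ym[i] -= h
            J[:, i] = (self.rhs(yp, p) - self.rhs(ym, p)) / (2 * h)
        return J

    def observables(self, y: np.ndarray, p: np.ndarray) -> dict[str, float]:
        if self._obs is None:
            return {}
        vals = np.asarray(self._obs(y, p), dtype=float).ravel()
        return dict(zip(self.observable_names, vals))

    def observable_series(self, Y: np.ndarray, p: np.ndarray) -> dict[str, np.ndarray]:
        """Observables evaluated along a trajectory (state matrix time x species)."""
        if self._obs is None:
            return {}
        out = {k: np.empty(Y.shape[0]) for k in self.observable_names}
        for i, y in enumerate(Y):
            vals = np.asarray(self._obs(y, p), dtype=float).ravel()
            for k, v in zip(self.observable_names, vals):
                out[k][i] = v
        return out
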