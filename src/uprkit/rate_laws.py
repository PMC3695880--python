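"""Kinetic rate laws of the unfolded-protein-response (UPR) model.

Four bespoke laws drive the network:

* :func:`tqssa_rate` — an extended (total quasi-steady-state) Michaelis–Menten
  product-formation rate valid when enzyme and substrate totals are of
  comparable magnitude, as they are for IRE1α complexes acting on XBP1 mRNA.
* :func:`regulation_rate` — a competitive multi-regulator transcription law
  for a single (or low-copy) gene shared by several transcription factors.
* :func:`hill_response` — normalised Hill activation/repression, used for the
  translation-attenuation readout of active eIF2α and for CHOP's repression
  of Bcl-2.
* :func:`receptor_fluxes` — the three receptor activation/deactivation flux
  variants (standard mass-action oligomerisation, direct unfolded-protein
  assistance, and unfolded-protein stabilisation of the active complex).

All quantities use arbitrary concentration/time units (acu, atu).  Each law
has a numeric form (floats in, floats out) and a symbolic form (``*_expr``)
returning a :mod:`sympy` expression, so that assembled models can be
compiled and differentiated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import math

import sympy as sp

__all__ = [
    "EnzymeRateParams",
    "RegulatorTerm",
    "ReceptorKineticParams",
    "HillParams",
    "tqssa_rate",
    "tqssa_expr",
    "regulation_rate",
    "regulation_expr",
    "hill_response",
    "hill_expr",
    "receptor_fluxes",
]

#: tolerance below which a (floating-point) negative discriminant is clamped
_DISC_CLAMP = -1e-12


@dataclass(frozen=True)
class EnzymeRateParams:
    """Parameters of the extended Michaelis–Menten law.

    kc : maximal catalytic rate per unit of saturated enzyme (acu/atu).
    Km : substrate amount giving half-maximal catalysis (acu).
    """

    kc: float
    Km: float

    def __post_init__(self) -> None:
        if self.kc < 0 or self.Km < 0:
            raise ValueError("kc and Km must be non-negative")


@dataclass(frozen=True)
class RegulatorTerm:
    """One transcription regulator in the competitive promoter-occupancy law.

    concentration : regulator level [TF] (acu).
    kc : maximal transcription rate contributed when this regulator occupies
        the promoter (acu/atu); 0 for a pure repressor.
    Km : relative affinity of the regulator for the gene (acu); must be > 0.
    """

    concentration: float
    kc: float
    Km: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("regulator concentration must be non-negative")
        if self.kc < 0:
            raise ValueError("kc must be non-negative (0 for a repressor)")
        if self.Km <= 0:
            raise ValueError("Km must be strictly positive")

    @property
    def is_repressor(self) -> bool:
        return self.kc == 0


ReceptorVariant = Literal["standard", "direct_ufp", "ufp_stabilised"]

_VARIANTS = ("standard", "direct_ufp", "ufp_stabilised")


@dataclass(frozen=True)
class ReceptorKineticParams:
    """Activation kinetics of an ER-stress receptor (IRE1α, PERK or ATF6).

    kf, kr : association (activation) and dissociation (deactivation) rate
        constants.  Active complexes revert without an external phosphatase.
    n : stoichiometry of the activated complex (monomers per complex).
    ext_stab : stabilisation strength of unfolded protein on the active
        complex (per acu); only used by the ``ufp_stabilised`` variant.
    variant : which activation hypothesis the fluxes follow.
    """

    kf: float
    kr: float
    n: int = 1
    ext_stab: float = 0.0
    variant: ReceptorVariant = "standard"

    def __post_init__(self) -> None:
        if self.kf < 0 or self.kr < 0 or self.ext_stab < 0:
            raise ValueError("rate constants must be non-negative")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("stoichiometry n must be a positive integer")
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown receptor variant {self.variant!r}")


@dataclass(frozen=True)
class HillParams:
    """Normalised Hill response with midpoint ``K`` and coefficient ``h``."""

    K: float
    h: float
    direction: Literal["activating", "repressing"] = "activating"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("Hill midpoint K must be strictly positive")
        if self.h <= 0:
            raise ValueError("Hill coefficient h must be strictly positive")
        if self.direction not in ("activating", "repressing"):
            raise ValueError(f"unknown direction {self.direction!r}")


def tqssa_rate(params: EnzymeRateParams, St: float, Et: float) -> float:
    """Extended Michaelis–Menten (total-QSSA) product-formation rate.

    ``rate = kc/2 * (St + Et + Km - sqrt((St + Et + Km)**2 - 4*St*Et))``

    Valid for arbitrary total substrate ``St`` and total enzyme ``Et``
    (acu); unlike the classical law it does not require an excess of
    substrate over enzyme.  The rate is symmetric in ``St`` and ``Et`` and
    bounded by ``kc * min(St, Et)``.
    """
    if St < 0 or Et < 0:
        raise ValueError("substrate and enzyme totals must be non-negative")
    s = St + Et + params.Km
    disc = s * s - 4.0 * St * Et
    if disc < 0.0:
        if disc < _DISC_CLAMP * max(1.0, s * s):
            raise ValueError("negative discriminant for valid inputs")
        disc = 0.0
    return 0.5 * params.kc * (s - math.sqrt(disc))


def tqssa_expr(kc, Km, St, Et) -> sp.Expr:
    """Symbolic form of :func:`tqssa_rate` (discriminant clamped at 0)."""
    s = St + Et + Km
    disc = s**2 - 4 * St * Et
    return sp.Rational(1, 2) * kc * (s - sp.sqrt(sp.Max(disc, 0)))


def regulation_rate(regulators: Sequence[RegulatorTerm]) -> float:
    """Competitive transcription rate of a single gene under many regulators.

    ``rate = sum_i kc_i*[TF]_i/Km_i / (1 + sum_j [TF]_j/Km_j)`` where the
    numerator runs over activators (``kc_i > 0``) and the denominator over
    every regulator.  An empty regulator set transcribes at rate 0; genes
    with constitutive expression carry an explicit fixed-concentration
    activator term rather than a hidden basal rate.
    """
    num = 0.0
    den = 1.0
    for term in regulators:
        x = term.concentration / term.Km
        num += term.kc * x
        den += x
    return num / den


def regulation_expr(terms: Iterable[tuple]) -> sp.Expr:
    """Symbolic competitive regulation law.

    ``terms`` is an iterable of ``(concentration, kc, Km)`` sympy
    expressions/symbols; repressors enter with ``kc = 0``.
    """
    num = sp.Integer(0)
    den = sp.Integer(1)
    for conc, kc, Km in terms:
        num += kc * conc / Km
        den += conc / Km
    return num / den


def hill_response(x: float, params: HillParams) -> float:
    """Normalised Hill response in [0, 1]; activating rises, repressing falls."""
    if x < 0:
        raise ValueError("Hill input must be non-negative")
    try:
        xh = (x / params.K) ** params.h
    except OverflowError:
        xh = math.inf
    if params.direction == "activating":
        return 1.0 if math.isinf(xh) else xh / (1.0 + xh)
    return 0.0 if math.isinf(xh) else 1.0 / (1.0 + xh)


def hill_expr(x, K, h, direction: str = "activating") -> sp.Expr:
    """Symbolic normalised Hill response."""
    if direction == "activating":
        return x**h / (K**h + x**h)
    if direction == "repressing":
        return K**h / (K**h + x**h)
    raise ValueError(f"unknown direction {direction!r}")


def receptor_fluxes(
    params: ReceptorKineticParams, R: float, Ract: float, UFP: float = 0.0
) -> tuple[float, float]:
    """Activation/deactivation fluxes (vact, vdeact) of a stress receptor.

    standard       : vact = kf*R**n,        vdeact = kr*Ract
    direct_ufp     : vact = kf*UFP*R**n,    vdeact = kr*Ract
    ufp_stabilised : vact = kf*R**n,        vdeact = kr*Ract/(1 + ext_stab*UFP)
    """
    if R < 0 or Ract < 0 or UFP < 0:
        raise ValueError("concentrations must be non-negative")
    vact = params.kf * R**params.n
    vdeact = params.kr * Ract
    if params.variant == "direct_ufp":
        vact *= UFP
    elif params.variant == "ufp_stabilised":
        vdeact /= 1.0 + params.ext_stab * UFP
    return vact, vdeact
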