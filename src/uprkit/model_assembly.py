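"""Assembly of the UPR reaction network and its functional modules.

The unfolded protein response is modelled as four interconnected modules in
four compartments (ER, Golgi, nucleus, cytoplasm):

* a generic *receptor activation* module — BiP partitions competitively
  between the stress receptors and unfolded protein (UFP); unbound receptor
  monomers oligomerise into active complexes and revert spontaneously;
* the *IRE1α branch* — active IRE1α quadromers (4 monomers, 2 catalytic
  domains each) splice XBP1 mRNA; spliced XBP1 protein activates BiP
  expression, closing the adaptive negative feedback on receptor activation;
* the *ATF6 branch* — BiP-free ATF6 monomers translocate to the Golgi and
  are cleaved to the transcription factor ATF6p50, which feeds the XBP1, BiP
  and CHOP promoters and induces its own negative regulator WFS1;
* the *PERK branch / translation attenuation* — an ultrasensitive
  phosphorylation cycle of eIF2α (PERK kinase versus CReP/GADD34
  phosphatases) gates ATF4 translation through a Hill response centred at a
  90% drop of active eIF2α; the genetic cascade ATF4 → CHOP → GADD34 closes
  a delayed negative feedback that can oscillate;
* a condensed *BAX/BAK/BH3* apoptosis switch driven by CHOP, which represses
  Bcl-2 (Hill) and induces Bim/BH3, with BAX auto-activation providing
  bistability and hysteresis.

Stress enters as a constant accumulation rate of unfolded protein
(parameter ``mUFPT``, acu/atu); the unmitigated-stress assumption means no
UPR-dependent UFP clearance.  Module-level builds omit receptor turnover
and UFP influx/decay so that receptor and UFP totals are conserved and
response curves can be swept over total UFP directly.

The bundled reference parameterisation
(``data/reference_parameters_synthetic.yaml``) is a synthetic
reconstruction: it was calibrated against the qualitative design targets
the model is defined by (3–4x BiP induction, a Hopf pair over PERKA,
a bistable apoptotic switch aligned with the intermediate CHOP range, and
the low/intermediate/high states at mUFPT = 12/15/18) rather than
transcribed from a published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import sympy as sp
import yaml

from .network import AssemblyError, ModelSpec, NetworkBuilder
from .rate_laws import ReceptorKineticParams, hill_expr, tqssa_expr

__all__ = [
    "Ire1Config",
    "Atf6Config",
    "PerkConfig",
    "ApoptosisConfig",
    "ReceptorModuleConfig",
    "load_reference_parameters",
    "build_receptor_module",
    "build_ire1_branch",
    "build_atf6_branch",
    "build_perk_branch",
    "build_apoptosis_module",
    "assemble_full_model",
]

_REF_FILE = "reference_parameters_synthetic.yaml"


def load_reference_parameters() -> dict[str, float]:
    """Load the bundled (synthetic) reference parameter set as a flat dict."""
    text = resources.files("uprkit.data").joinpath(_REF_FILE).read_text()
    raw = yaml.safe_load(text)
    flat: dict[str, float] = {}
    for group in raw["parameters"].values():
        for k, v in group.items():
            if k in flat:
                raise AssemblyError(f"duplicate parameter {k!r} in reference file")
            flat[k] = float(v)
    return flat


def _params(overrides: Mapping[str, float] | None) -> dict[str, float]:
    p = load_reference_parameters()
    if overrides:
        unknown = set(overrides) - set(p)
        if unknown:
            raise KeyError(f"unknown reference parameters {sorted(unknown)}")
        p.update(overrides)
    return p


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReceptorModuleConfig:
    """Stand-alone receptor activation module (defaults mirror IRE1α).

    ``variant`` selects the activation hypothesis; ``ext_stab`` is only used
    by ``ufp_stabilised``.  ``bip_total``/``ufp_total`` set the conserved
    chaperone and unfolded-protein pools of the isolated module.
    """

    variant: str = "standard"
    n: int = 4
    kf: float | None = None
    kr: float | None = None
    ext_stab: float = 0.0
    bip_total: float = 30.0
    ufp_total: float = 0.0
    overrides: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Ire1Config:
    """IRE1α branch: receptor core plus XBP1 splicing and BiP induction.

    ``oligomer_size`` monomers form one active complex carrying
    ``catalytic_domains`` XBP1-splicing sites.  ``ext_xbp``/``ext_bip`` are
    fixed external activator concentrations standing in for the ATF6 input
    on the XBP1 and BiP promoters in the isolated branch.
    """

    oligomer_size: int = 4
    catalytic_domains: int = 2
    ext_xbp: float = 0.0
    ext_bip: float = 0.0
    overrides: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Atf6Config:
    """ATF6 branch (composed with the IRE1α branch as its reference target).

    Knockout flags force the corresponding reaction rate to zero without
    changing the network's species/reaction counts.
    """

    knockout_transfer: bool = False
    knockout_cleavage: bool = False
    knockout_wfs1: bool = False
    overrides: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PerkConfig:
    """PERK branch / translation attenuation module.

    In the stand-alone module the activated-PERK level enters as the
    parameter ``PERKA`` (the bifurcation/scan variable); ``ext_chop`` is a
    fixed external activator concentration standing in for the ATF6/XBP1
    drive on the CHOP promoter.
    """

    perka: float = 0.0
    ext_chop: float = 0.0
    overrides: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ApoptosisConfig:
    """Condensed BAX/BAK/BH3 switch with CHOP as its input.

    The stand-alone module exposes CHOP as the parameter ``CHOP`` (the
    original switch's "Stress" input replaced by CHOP concentration).
    """

    chop: float = 0.0
    overrides: Mapping[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# module contributions
# ---------------------------------------------------------------------------


def _S(name: str) -> sp.Symbol:
    return sp.Symbol(name)


def _contribute_chaperone(nb: NetworkBuilder, p: Mapping[str, float], ufp_initial: float,
                          bip_initial: float, ufp_turnover: bool) -> None:
    """BiP/UFP pool: competitive client binding, BiP turnover, optional influx."""
    BiP = nb.add_species("BiP", "ER", bip_initial, role="chaperone")
    UFP = nb.add_species("UFP", "ER", ufp_initial, role="client")
    bUFP = nb.add_species("bUFP", "ER", 0.0, role="complex")
    kon = nb.add_parameter("konBiP", p["konBiP"])
    koff = nb.add_parameter("koffBiPUFP", p["koffBiPUFP"])
    kdBiP = nb.add_parameter("kdBiP", p["kdBiP"])
    nb.add_reaction("bind_BiP_UFP", {"BiP": 1, "UFP": 1}, {"bUFP": 1}, kon * BiP * UFP)
    nb.add_reaction("unbind_BiP_UFP", {"bUFP": 1}, {"BiP": 1, "UFP": 1}, koff * bUFP)
    nb.add_reaction("deg_BiP", {"BiP": 1}, {}, kdBiP * BiP)
    if ufp_turnover:
        mUFPT = nb.add_parameter("mUFPT", p["mUFPT"])
        kdUFP = nb.add_parameter("kdUFP", p["kdUFP"])
        kdb = nb.add_parameter("kdbUFP", p["kdbUFP"])
        nb.add_reaction("influx_UFP", {}, {"UFP": 1}, mUFPT,
                        note="constant unfolded-protein accumulation (stress input)")
        nb.add_reaction("deg_UFP", {"UFP": 1}, {}, kdUFP * UFP)
        # clearance of chaperone-held client consumes the chaperone with it,
        # so sustained stress drains folding capacity at ~mUFPT acu/atu
        nb.add_reaction("deg_bUFP", {"bUFP": 1}, {}, kdb * bUFP)


def _contribute_receptor(
    nb: NetworkBuilder,
    p: Mapping[str, float],
    name: str,
    n: int,
    variant: str = "standard",
    ext_stab: float = 0.0,
    turnover: bool = False,
    kf: float | None = None,
    kr: float | None = None,
    initial: float = 1.0,
) -> None:
    """Generic stress receptor: BiP sequestration plus cooperative activation."""
    R = nb.add_species(name, "ER", initial, role="receptor")
    Ra = nb.add_species(f"{name}a", "ER", 0.0, role="active complex")
    bR = nb.add_species(f"b{name}", "ER", 0.0, role="complex")
    UFP = _S("UFP")
    kon = nb.add_parameter("konBiP", p["konBiP"])
    koff = nb.add_parameter(f"koffBiP{name}", p[f"koffBiP{name}"])
    kf_s = nb.add_parameter(f"kf{name}", p[f"kf{name}"] if kf is None else kf)
    kr_s = nb.add_parameter(f"kr{name}", p[f"kr{name}"] if kr is None else kr)
    nb.add_parameter(f"n{name}", n)
    nb.add_reaction(f"bind_BiP_{name}", {"BiP": 1, name: 1}, {f"b{name}": 1},
                    kon * _S("BiP") * R)
    nb.add_reaction(f"unbind_BiP_{name}", {f"b{name}": 1}, {"BiP": 1, name: 1},
                    koff * bR)
    vact = kf_s * R**n
    vdeact = kr_s * Ra
    if variant == "direct_ufp":
        vact = vact * UFP
    elif variant == "ufp_stabilised":
        ext = nb.add_parameter(f"ext{name}", ext_stab)
        vdeact = vdeact / (1 + ext * UFP)
    elif variant != "standard":
        raise AssemblyError(f"unknown receptor variant {variant!r}")
    nb.add_reaction(f"act_{name}", {name: n}, {f"{name}a": 1}, vact,
                    note=f"oligomerisation into the active {n}-mer")
    nb.add_reaction(f"deact_{name}", {f"{name}a": 1}, {name: n}, vdeact)
    if turnover:
        ks = nb.add_parameter(f"ks{name}", p[f"ks{name}"])
        kd = nb.add_parameter(f"kd{name}", p[f"kd{name}"])
        nb.add_reaction(f"syn_{name}", {}, {name: 1}, ks)
        nb.add_reaction(f"deg_{name}", {name: 1}, {}, kd * R)
        nb.add_reaction(f"deg_b{name}", {f"b{name}": 1}, {"BiP": 1}, kd * bR,
                        note="receptor turnover within the BiP complex")
        kda = nb.add_parameter("kdRact", p["kdRact"])
        nb.add_reaction(f"deg_{name}a", {f"{name}a": 1}, {}, kda * Ra,
                        note="turnover of the active receptor complex")


def _contribute_ire1_genetics(
    nb: NetworkBuilder, p: Mapping[str, float], catalytic_domains: int,
    ext_xbp: float = 0.0, ext_bip: float = 0.0, standalone: bool = False
) -> None:
    """XBP1 splicing by active IRE1α and the XBP1s → BiP adaptive arm."""
    mX = nb.add_species("mXBP1", "cytoplasm", 0.0, role="mRNA")
    mXs = nb.add_species("mXBP1s", "cytoplasm", 0.0, role="mRNA")
    Xs = nb.add_species("XBP1s", "nucleus", 0.0, role="TF")

    nb.declare_promoter("XBP1", "mXBP1")
    kcXbas = nb.add_parameter("kcXbas", p["kcXbas"])
    KmXbas = nb.add_parameter("KmXbas", p["KmXbas"])
    nb.add_promoter_term("XBP1", sp.Integer(1), kcXbas, KmXbas)

    nb.declare_promoter("BiP", "BiP")
    kcBx = nb.add_parameter("kcBxbp", p["kcBxbp"])
    KmBx = nb.add_parameter("KmBxbp", p["KmBxbp"])
    nb.add_promoter_term("BiP", Xs, kcBx, KmBx)
    ksBiP = nb.add_parameter("ksBiP", p["ksBiP"])
    nb.add_reaction("syn_BiP_basal", {}, {"BiP": 1}, ksBiP,
                    note="constitutive chaperone expression")

    if standalone and ext_xbp:
        # external drive through the (otherwise absent) ATF6 input port
        e = nb.add_parameter("extXBP", ext_xbp)
        nb.add_promoter_term("XBP1", e, nb.add_parameter("kcXatf6", p["kcXatf6"]),
                             nb.add_parameter("KmXatf6", p["KmXatf6"]))
    if standalone and ext_bip:
        e = nb.add_parameter("extBiP", ext_bip)
        nb.add_promoter_term("BiP", e, nb.add_parameter("kcBatf6", p["kcBatf6"]),
                             nb.add_parameter("KmBatf6", p["KmBatf6"]))

    kcS = nb.add_parameter("kcSplice", p["kcSplice"])
    KmS = nb.add_parameter("KmSplice", p["KmSplice"])
    nCat = int(catalytic_domains)
    nb.add_parameter("nCatalytic", nCat)
    nb.add_reaction(
        "splice_XBP1", {"mXBP1": 1}, {"mXBP1s": 1},
        tqssa_expr(kcS, KmS, mX, nCat * _S("IRE1a")),
        note="unconventional splicing by the catalytic domains of active IRE1α",
    )
    for sid, kname in (("mXBP1", "kdmXBP1"), ("mXBP1s", "kdmXBP1s"), ("XBP1s", "kdXBP1s")):
        k = nb.add_parameter(kname, p[kname])
        nb.add_reaction(f"deg_{sid}", {sid: 1}, {}, k * _S(sid))
    ktl = nb.add_parameter("ktlXBP1", p["ktlXBP1"])
    nb.add_reaction("tl_XBP1s", {}, {"XBP1s": 1}, ktl * mXs)


def _contribute_atf6(
    nb: NetworkBuilder, p: Mapping[str, float],
    knockout_transfer: bool = False, knockout_cleavage: bool = False,
    knockout_wfs1: bool = False,
) -> None:
    """ATF6 core: Golgi transfer, cleavage to ATF6p50, WFS1 negative feedback."""
    A = nb.add_species("ATF6", "ER", 0.0, role="receptor")
    bA = nb.add_species("bATF6", "ER", 0.0, role="complex")
    Ag = nb.add_species("ATF6g", "Golgi", 0.0, role="receptor")
    p50 = nb.add_species("ATF6p50", "nucleus", 0.0, role="TF")
    W = nb.add_species("WFS1", "ER", 0.0, role="regulator")

    kon = nb.add_parameter("konBiP", p["konBiP"])
    koff = nb.add_parameter("koffBiPATF6", p["koffBiPATF6"])
    nb.add_reaction("bind_BiP_ATF6", {"BiP": 1, "ATF6": 1}, {"bATF6": 1},
                    kon * _S("BiP") * A)
    nb.add_reaction("unbind_BiP_ATF6", {"bATF6": 1}, {"BiP": 1, "ATF6": 1}, koff * bA)

    ks = nb.add_parameter("ksATF6", p["ksATF6"])
    kd = nb.add_parameter("kdATF6", p["kdATF6"])
    nb.add_reaction("syn_ATF6", {}, {"ATF6": 1}, ks)
    nb.add_reaction("deg_ATF6", {"ATF6": 1}, {}, kd * A)
    nb.add_reaction("deg_bATF6", {"bATF6": 1}, {"BiP": 1}, kd * bA)

    kw = nb.add_parameter("kwfs1", p["kwfs1"])
    wfs_gate = sp.Integer(0) if knockout_wfs1 else sp.Integer(1)
    nb.add_reaction("deg_ATF6_wfs1", {"ATF6": 1}, {}, wfs_gate * kw * W * A,
                    note="WFS1-enhanced degradation of membrane ATF6")

    ktr = nb.add_parameter("ktransfer", p["ktransfer"])
    tr_gate = sp.Integer(0) if knockout_transfer else sp.Integer(1)
    nb.add_reaction("transfer_ATF6", {"ATF6": 1}, {"ATF6g": 1}, tr_gate * ktr * A,
                    note="translocation of BiP-free ATF6 to the Golgi")
    kcl = nb.add_parameter("kcleave", p["kcleave"])
    cl_gate = sp.Integer(0) if knockout_cleavage else sp.Integer(1)
    nb.add_reaction("cleave_ATF6", {"ATF6g": 1}, {"ATF6p50": 1}, cl_gate * kcl * Ag,
                    note="serine-protease cleavage releasing the ATF6p50 TF")
    nb.add_reaction("deg_ATF6p50", {"ATF6p50": 1}, {},
                    nb.add_parameter("kdATF6p50", p["kdATF6p50"]) * p50)

    nb.declare_promoter("WFS1", "WFS1")
    nb.add_promoter_term("WFS1", p50, nb.add_parameter("kcWFS1", p["kcWFS1"]),
                         nb.add_parameter("KmWFS1", p["KmWFS1"]))
    nb.add_reaction("deg_WFS1", {"WFS1": 1}, {},
                    nb.add_parameter("kdWFS1", p["kdWFS1"]) * W)


def _wire_atf6_outputs(nb: NetworkBuilder, p: Mapping[str, float],
                       include_chop: bool) -> None:
    """ATF6p50 activator terms on the XBP1, BiP and (optionally) CHOP promoters."""
    p50 = _S("ATF6p50")
    nb.add_promoter_term("XBP1", p50, nb.add_parameter("kcXatf6", p["kcXatf6"]),
                         nb.add_parameter("KmXatf6", p["KmXatf6"]))
    nb.add_promoter_term("BiP", p50, nb.add_parameter("kcBatf6", p["kcBatf6"]),
                         nb.add_parameter("KmBatf6", p["KmBatf6"]))
    if include_chop:
        nb.add_promoter_term("CHOP", p50, nb.add_parameter("kcCatf6", p["kcCatf6"]),
                             nb.add_parameter("KmCatf6", p["KmCatf6"]))
        nb.add_promoter_term("CHOP", _S("XBP1s"), nb.add_parameter("kcCxbp", p["kcCxbp"]),
                             nb.add_parameter("KmCxbp", p["KmCxbp"]))


def _contribute_perk_genetics(
    nb: NetworkBuilder, p: Mapping[str, float], perka: sp.Expr,
    ext_chop: float | None = None,
) -> None:
    """eIF2α phosphorylation cycle and the ATF4 → CHOP → GADD34 cascade.

    ``perka`` is the kinase amount seen by eIF2α: the ``PERKA`` input
    parameter in the stand-alone module, or the phosphorylated-monomer total
    of the assembled model.
    """
    eIF2aT = p["eIF2aT"]
    E = nb.add_species("eIF2a", "cytoplasm", eIF2aT, role="initiation factor")
    EP = nb.add_species("eIF2aP", "cytoplasm", 0.0, role="initiation factor")
    A4 = nb.add_species("ATF4", "nucleus", 0.0, role="TF")
    mC = nb.add_species("mCHOP", "cytoplasm", 0.0, role="mRNA")
    C = nb.add_species("CHOP", "nucleus", 0.0, role="TF")
    mG = nb.add_species("mGADD34", "cytoplasm", 0.0, role="mRNA")
    G = nb.add_species("GADD34", "cytoplasm", 0.0, role="phosphatase")

    nb.add_parameter("eIF2aT", eIF2aT)
    kphos = nb.add_parameter("kphos", p["kphos"])
    kmChop = nb.add_parameter("kmChop", p["kmChop"])
    KmE = nb.add_parameter("KmEif2a", p["KmEif2a"])
    kdeph = nb.add_parameter("kdephos", p["kdephos"])
    CReP = nb.add_parameter("CReP", p["CReP"])

    # zero-order (saturated) kinase/phosphatase pair => ultrasensitive switch;
    # CHOP weakens the effective phosphorylation capacity
    nb.add_reaction("phos_eIF2a", {"eIF2a": 1}, {"eIF2aP": 1},
                    tqssa_expr(kphos / (1 + C / kmChop), KmE, E, perka))
    nb.add_reaction("dephos_eIF2a_CReP", {"eIF2aP": 1}, {"eIF2a": 1},
                    tqssa_expr(kdeph, KmE, EP, CReP))
    nb.add_reaction("dephos_eIF2a_GADD34", {"eIF2aP": 1}, {"eIF2a": 1},
                    tqssa_expr(kdeph, KmE, EP, G))

    ktlA4 = nb.add_parameter("ktlATF4", p["ktlATF4"])
    kA4 = nb.add_parameter("kATF4", p["kATF4"])
    nh = nb.add_parameter("nh", p["nh"])
    nb.add_reaction("tl_ATF4", {}, {"ATF4": 1},
                    ktlA4 * hill_expr(E, kA4, nh, "repressing"),
                    note="ribosomal-shift translation of ATF4 when active eIF2α is scarce")
    nb.add_reaction("deg_ATF4", {"ATF4": 1}, {},
                    nb.add_parameter("kdATF4", p["kdATF4"]) * A4)

    nb.declare_promoter("CHOP", "mCHOP")
    nb.add_promoter_term("CHOP", A4, nb.add_parameter("kcCatf4", p["kcCatf4"]),
                         nb.add_parameter("kmAtff", p["kmAtff"]))
    if ext_chop is not None:
        e = nb.add_parameter("extCHOP", ext_chop)
        nb.add_promoter_term("CHOP", e, nb.add_parameter("kcCatf6", p["kcCatf6"]),
                             nb.add_parameter("KmCatf6", p["KmCatf6"]))
    nb.add_reaction("deg_mCHOP", {"mCHOP": 1}, {},
                    nb.add_parameter("kdmCHOP", p["kdmCHOP"]) * mC)
    nb.add_reaction("tl_CHOP", {}, {"CHOP": 1},
                    nb.add_parameter("ktlCHOP", p["ktlCHOP"]) * mC)
    nb.add_reaction("deg_CHOP", {"CHOP": 1}, {},
                    nb.add_parameter("kdCHOP", p["kdCHOP"]) * C)

    nb.declare_promoter("GADD34", "mGADD34")
    nb.add_promoter_term("GADD34", C, nb.add_parameter("kcGchop", p["kcGchop"]),
                         nb.add_parameter("KmGchop", p["KmGchop"]))
    nb.add_reaction("deg_mGADD34", {"mGADD34": 1}, {},
                    nb.add_parameter("kdmGADD34", p["kdmGADD34"]) * mG)
    nb.add_reaction("tl_GADD34", {}, {"GADD34": 1},
                    nb.add_parameter("ktlGADD34", p["ktlGADD34"]) * mG)
    nb.add_reaction("deg_GADD34", {"GADD34": 1}, {},
                    nb.add_parameter("kdGADD34", p["kdGADD34"]) * G)

    nb.add_observable("translation", E / nb.add_parameter("eIF2aT", eIF2aT))


def _contribute_apoptosis(nb: NetworkBuilder, p: Mapping[str, float],
                          chop: sp.Expr) -> None:
    """Condensed BAX/BAK/BH3 switch: CHOP represses Bcl-2 and induces BH3."""
    B3 = nb.add_species("BH3", "cytoplasm", 0.0, role="apoptotic")
    B2 = nb.add_species("Bcl2", "cytoplasm", 0.0, role="apoptotic")
    BX = nb.add_species("BAXa", "cytoplasm", 0.0, role="apoptotic")

    nb.add_reaction("syn_BH3", {}, {"BH3": 1},
                    nb.add_parameter("ksBH3", p["ksBH3"])
                    + nb.add_parameter("kaBH3", p["kaBH3"]) * chop,
                    note="basal plus CHOP-induced Bim/BH3 expression")
    nb.add_reaction("deg_BH3", {"BH3": 1}, {},
                    nb.add_parameter("kdBH3", p["kdBH3"]) * B3)
    ksB2 = nb.add_parameter("ksBcl2", p["ksBcl2"])
    KrC = nb.add_parameter("KrCHOP", p["KrCHOP"])
    hrC = nb.add_parameter("hrCHOP", p["hrCHOP"])
    nb.add_reaction("syn_Bcl2", {}, {"Bcl2": 1},
                    ksB2 * hill_expr(chop, KrC, hrC, "repressing"),
                    note="Bcl-2 expression blocked by CHOP (Hill repression)")
    nb.add_reaction("deg_Bcl2", {"Bcl2": 1}, {},
                    nb.add_parameter("kdBcl2", p["kdBcl2"]) * B2)

    BAXT = nb.add_parameter("BAXT", p["BAXT"])
    kaB = nb.add_parameter("kaBAX", p["kaBAX"])
    kfb = nb.add_parameter("kfbBAX", p["kfbBAX"])
    Kfb = nb.add_parameter("KfbBAX", p["KfbBAX"])
    nb.add_reaction("act_BAX_BH3", {}, {"BAXa": 1}, kaB * B3 * (BAXT - BX),
                    note="BH3-catalysed BAX activation from the inactive pool")
    nb.add_reaction("act_BAX_auto", {}, {"BAXa": 1},
                    kfb * BX**2 / (Kfb**2 + BX**2) * (BAXT - BX),
                    note="cooperative auto-activation (source of bistability)")
    nb.add_reaction("inact_BAX_Bcl2", {"BAXa": 1}, {},
                    nb.add_parameter("kiBAX", p["kiBAX"]) * B2 * BX)
    nb.add_reaction("inact_BAX", {"BAXa": 1}, {},
                    nb.add_parameter("kdBAXa", p["kdBAXa"]) * BX)


def _common_observables(nb: NetworkBuilder, have: set[str]) -> None:
    if {"UFP", "bUFP"} <= have:
        nb.add_observable("UFPT", _S("UFP") + _S("bUFP"))
    bip_forms = [s for s in ("BiP", "bIRE1", "bPERK", "bATF6", "bUFP") if s in have]
    if "BiP" in have:
        nb.add_observable("BiPT", sum(_S(s) for s in bip_forms))
    if "IRE1a" in have:
        nb.add_observable("IRE1A", _S("nIRE1") * _S("IRE1a"))
    if "PERKa" in have:
        nb.add_observable("PERKA", _S("nPERK") * _S("PERKa"))
    if "ATF6p50" in have:
        total = _S("ATF6") + _S("bATF6") + _S("ATF6g") + _S("ATF6p50")
        # tiny floor keeps the ratio defined before any receptor is made
        nb.add_observable("ATF6cleaved_pct", 100 * _S("ATF6p50") / (total + 1e-30))


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------


def build_receptor_module(config: ReceptorModuleConfig | None = None) -> ModelSpec:
    """Isolated receptor activation module (receptor + BiP + UFP pools).

    Receptor, BiP and UFP totals are conserved; the response curve of the
    module is swept by setting the initial UFP pool.
    """
    cfg = config or ReceptorModuleConfig()
    p = _params(cfg.overrides)
    nb = NetworkBuilder("receptor_module")
    nb.add_species("BiP", "ER", cfg.bip_total, role="chaperone")
    nb.add_species("UFP", "ER", cfg.ufp_total, role="client")
    nb.add_species("bUFP", "ER", 0.0, role="complex")
    kon = nb.add_parameter("konBiP", p["konBiP"])
    koff = nb.add_parameter("koffBiPUFP", p["koffBiPUFP"])
    nb.add_reaction("bind_BiP_UFP", {"BiP": 1, "UFP": 1}, {"bUFP": 1},
                    kon * _S("BiP") * _S("UFP"))
    nb.add_reaction("unbind_BiP_UFP", {"bUFP": 1}, {"BiP": 1, "UFP": 1},
                    koff * _S("bUFP"))
    _contribute_receptor(nb, p, "IRE1", cfg.n, cfg.variant, cfg.ext_stab,
                         turnover=False, kf=cfg.kf, kr=cfg.kr)
    _common_observables(nb, {"BiP", "UFP", "bUFP", "IRE1a"})
    return nb.build()


def build_ire1_branch(config: Ire1Config | None = None) -> ModelSpec:
    """IRE1α branch: receptor module plus XBP1 splicing and BiP induction."""
    cfg = config or Ire1Config()
    p = _params(cfg.overrides)
    nb = NetworkBuilder("ire1_branch")
    _contribute_chaperone(nb, p, 0.0, bip_initial=p["ksBiP"] / p["kdBiP"],
                          ufp_turnover=True)
    _contribute_receptor(nb, p, "IRE1", cfg.oligomer_size, turnover=False)
    _contribute_ire1_genetics(nb, p, cfg.catalytic_domains,
                              cfg.ext_xbp, cfg.ext_bip, standalone=True)
    _common_observables(nb, {"BiP", "UFP", "bUFP", "bIRE1", "IRE1a"})
    return nb.build()


def build_atf6_branch(config: Atf6Config | None = None) -> ModelSpec:
    """ATF6 branch composed with the IRE1α/XBP1 branch it regulates."""
    cfg = config or Atf6Config()
    p = _params(cfg.overrides)
    nb = NetworkBuilder("atf6_branch")
    _contribute_chaperone(nb, p, 0.0, bip_initial=p["ksBiP"] / p["kdBiP"],
                          ufp_turnover=True)
    _contribute_receptor(nb, p, "IRE1", 4, turnover=False)
    _contribute_ire1_genetics(nb, p, 2, standalone=False)
    _contribute_atf6(nb, p, cfg.knockout_transfer, cfg.knockout_cleavage,
                     cfg.knockout_wfs1)
    _wire_atf6_outputs(nb, p, include_chop=False)
    _common_observables(nb, {"BiP", "UFP", "bUFP", "bIRE1", "bATF6", "IRE1a", "ATF6p50"})
    return nb.build()


def build_perk_branch(config: PerkConfig | None = None) -> ModelSpec:
    """Stand-alone translation attenuation module driven by the PERKA parameter."""
    cfg = config or PerkConfig()
    p = _params(cfg.overrides)
    nb = NetworkBuilder("perk_branch")
    perka = nb.add_parameter("PERKA", cfg.perka)
    _contribute_perk_genetics(nb, p, perka, ext_chop=cfg.ext_chop)
    nb.add_observable("PERKA", perka)
    return nb.build()


def build_apoptosis_module(config: ApoptosisConfig | None = None) -> ModelSpec:
    """Stand-alone BAX/BAK/BH3 switch driven by the CHOP parameter."""
    cfg = config or ApoptosisConfig()
    p = _params(cfg.overrides)
    nb = NetworkBuilder("apoptosis_module")
    chop = nb.add_parameter("CHOP", cfg.chop)
    _contribute_apoptosis(nb, p, chop)
    return nb.build()


def assemble_full_model(
    ire1: Ire1Config | None = None,
    atf6: Atf6Config | None = None,
    perk: PerkConfig | None = None,
    apoptosis: ApoptosisConfig | None = None,
    include_apoptosis: bool = True,
    overrides: Mapping[str, float] | None = None,
) -> ModelSpec:
    """The complete UPR model (27 species, 62 reactions, 82 parameters).

    Shared species (BiP, UFP, CHOP, ATF6p50, XBP1s) merge by id; the
    external-drive stand-ins of the isolated modules (extXBP, extBiP,
    extCHOP, PERKA) are replaced by the actual cross-module couplings.
    Knockout flags of ``atf6`` carry over with unchanged network counts.
    """
    ire1 = ire1 or Ire1Config()
    atf6 = atf6 or Atf6Config()
    merged: dict[str, float] = {}
    for cfg in (ire1, atf6, perk, apoptosis):
        if cfg is not None and cfg.overrides:
            for k, v in cfg.overrides.items():
                if k in merged and merged[k] != v:
                    raise AssemblyError(f"conflicting override for parameter {k!r}")
                merged[k] = v
    if overrides:
        merged.update(overrides)
    p = _params(merged)

    nb = NetworkBuilder("upr_full")
    _contribute_chaperone(nb, p, ufp_initial=0.0,
                          bip_initial=p["ksBiP"] / p["kdBiP"], ufp_turnover=True)
    _contribute_receptor(nb, p, "IRE1", ire1.oligomer_size, turnover=True)
    _contribute_receptor(nb, p, "PERK", int(p["nPERK"]), turnover=True)
    _contribute_ire1_genetics(nb, p, ire1.catalytic_domains, standalone=False)
    _contribute_atf6(nb, p, atf6.knockout_transfer, atf6.knockout_cleavage,
                     atf6.knockout_wfs1)
    # kinase capacity of PERK = phosphorylated monomers in active complexes
    perka_expr = sp.Symbol("nPERK") * _S("PERKa")
    _contribute_perk_genetics(nb, p, perka_expr, ext_chop=None)
    _wire_atf6_outputs(nb, p, include_chop=True)
    if include_apoptosis:
        _contribute_apoptosis(nb, p, _S("CHOP"))
    _common_observables(nb, {"BiP", "UFP", "bUFP", "bIRE1", "bPERK", "bATF6",
                             "IRE1a", "PERKa", "ATF6p50"})
    return nb.build()
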