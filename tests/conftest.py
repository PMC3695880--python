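"""Shared fixtures: compiled models and pre-run scenarios.

Model compilation and scenario integration are the expensive steps, so
they are session-scoped; tests treat the returned objects as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import uprkit as uk
from uprkit import dynamics as dyn
from uprkit import scenarios as sc
from uprkit.network import NetworkBuilder


@pytest.fixture(scope="session")
def full_model():
    return uk.assemble_full_model()


@pytest.fixture(scope="session")
def full_compiled(full_model):
    return full_model.compile()


@pytest.fixture(scope="session")
def basal_state(full_compiled):
    """Pre-equilibrated unstressed steady state of the full model."""
    return dyn.equilibrate(full_compiled, 0.0)


@pytest.fixture(scope="session")
def perk_model():
    return uk.build_perk_branch()


@pytest.fixture(scope="session")
def perk_compiled(perk_model):
    return perk_model.compile()


@pytest.fixture(scope="session")
def apoptosis_model():
    return uk.build_apoptosis_module()


@pytest.fixture(scope="session")
def preset_scenarios():
    """The three direct stress scenarios, run once for the whole session."""
    return {name: sc.run_stress_scenario(name) for name in ("mild", "moderate", "severe")}


@pytest.fixture(scope="session")
def preconditioning_run():
    return sc.run_preconditioning()


@pytest.fixture(scope="session")
def perk_branch_diagram(perk_compiled):
    """PERK-branch continuation over PERKA with refined Hopf points."""
    from uprkit import bifurcation as bif

    branch = bif.continue_branch(perk_compiled, "PERKA", (0.0, 10.0), n_steps=100)
    hopfs = bif.detect_hopf(branch, perk_compiled, "PERKA")
    return branch, hopfs


def linear_decay_model(k: float = 3.0, x0: float = 2.0):
    """dX/dt = -k X, closed form X(t) = x0 exp(-k t)."""
    nb = NetworkBuilder("decay")
    X = nb.add_species("X", "cytoplasm", x0)
    ks = nb.add_parameter("k", k)
    nb.add_reaction("dec", {"X": 1}, {}, ks * X)
    return nb.build()


def production_decay_model(k: float = 4.0, d: float = 0.5):
    """dX/dt = k - d X with steady state k/d."""
    nb = NetworkBuilder("proddec")
    X = nb.add_species("X", "cytoplasm", 0.0)
    nb.add_reaction("syn", {}, {"X": 1}, nb.add_parameter("k", k))
    nb.add_reaction("deg", {"X": 1}, {}, nb.add_parameter("d", d) * X)
    return nb.build()


def cubic_model():
    """dx/dt = p + x - x**3: S-shaped branch with folds at +/- 2/(3 sqrt 3)."""
    nb = NetworkBuilder("cubic")
    x = nb.add_species("X", "cytoplasm", 2.0)
    p = nb.add_parameter("p", 2.0)
    nb.add_reaction("prod", {}, {"X": 1}, p + x)
    nb.add_reaction("rem", {"X": 1}, {}, x**3)
    return nb.build()


def hopf_normal_form():
    """Supercritical Hopf normal form in Cartesian coordinates.

    x' = mu x - y - x (x^2 + y^2);  y' = x + mu y - y (x^2 + y^2):
    Hopf at mu = 0 with onset frequency 1, cycle radius sqrt(mu).
    """
    nb = NetworkBuilder("hopf_nf")
    x = nb.add_species("X", "cytoplasm", 0.3)
    y = nb.add_species("Y", "cytoplasm", 0.0)
    mu = nb.add_parameter("mu", -0.5)
    nb.add_reaction("fx", {}, {"X": 1}, mu * x - y - x * (x**2 + y**2))
    nb.add_reaction("fy", {}, {"Y": 1}, x + mu * y - y * (x**2 + y**2))
    return nb.build()
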