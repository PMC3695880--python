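"""Scenario verdicts, module response-curve orderings, serialisation, SBML, CLI."""

from __future__ import annotations

import json

import numpy as np
import pytest

import uprkit as uk
from uprkit import dynamics as dyn
from uprkit import io as uio
from uprkit import sbml as usbml
from uprkit import scenarios as sc


@pytest.fixture(scope="module")
def ufpt_grid():
    return np.linspace(0.0, 16.0, 9)


@pytest.fixture(scope="module")
def ire1_reference_curve(ufpt_grid):
    return sc.run_response_curve("ire1", ufpt_grid)


@pytest.fixture(scope="module")
def atf6_reference_curve(ufpt_grid):
    return sc.run_response_curve("atf6", ufpt_grid)


class TestResponseCurves:
    def test_receptor_activation_is_sigmoidal_with_lag(self):
        sweep = np.linspace(0.0, 60.0, 13)
        out = sc.run_response_curve("receptor", sweep)
        act = out["IRE1A"]
        assert np.all(np.diff(act) >= -1e-9)  # monotone in total UFP
        # lag phase: negligible activation over the first third of the sweep
        assert act[2] < 0.05 * act[-1]
        assert act[-1] > 0.1

    def test_higher_cooperativity_delays_and_steepens_the_threshold(self):
        sweep = np.linspace(0.0, 60.0, 121)
        ref = sc.run_response_curve("receptor", sweep)
        coop = sc.run_response_curve("receptor", sweep,
                                     receptor_n=6, receptor_kf=40.0)

        def rise(curve):
            a = curve["IRE1A"] / max(curve["IRE1A"].max(), 1e-12)
            t10 = sweep[np.argmax(a >= 0.1)]
            t90 = sweep[np.argmax(a >= 0.9)]
            return t10, t90 - t10  # onset position, 10-90% rise width

        onset_ref, width_ref = rise(ref)
        onset_coop, width_coop = rise(coop)
        assert onset_coop >= onset_ref          # delayed response
        assert width_coop <= width_ref + 1e-9   # steeper threshold

    def test_direct_ufp_variant_has_lower_basal_activity(self):
        sweep = np.array([0.0, 4.0, 8.0])
        stab = sc.run_response_curve("receptor", sweep, variant="ufp_stabilised")
        direct = sc.run_response_curve("receptor", sweep, variant="direct_ufp")
        assert direct["IRE1A"][0] <= stab["IRE1A"][0]

    def test_ire1_branch_bip_saturates_at_a_plateau(self, ufpt_grid,
                                                    ire1_reference_curve):
        bip = ire1_reference_curve["BiPT"]
        # past the onset (the first point reflects pre-induction capacity
        # consumption) the response rises monotonically ...
        assert np.all(np.diff(bip[1:]) > -1e-6)
        # ... and the marginal gain collapses at high load: a plateau
        assert (bip[-1] - bip[-2]) < 0.2 * np.max(np.diff(bip))

    def test_external_xbp1_drive_raises_the_plateau(self, ufpt_grid,
                                                    ire1_reference_curve):
        boosted = sc.run_response_curve("ire1", ufpt_grid, ext_xbp=2.0)
        assert boosted["BiPT"][-1] > 1.1 * ire1_reference_curve["BiPT"][-1]

    def test_external_bip_drive_raises_basal_and_delays_activation(
            self, ufpt_grid, ire1_reference_curve):
        boosted = sc.run_response_curve("ire1", ufpt_grid, ext_bip=2.0)
        assert boosted["BiPT"][0] > 1.2 * ire1_reference_curve["BiPT"][0]
        # elongated initial lag: receptor activation needs more load
        assert boosted["IRE1A"][2] < ire1_reference_curve["IRE1A"][2] + 1e-9

    def test_atf6_amplifies_basal_and_maximal_capacity(
            self, ire1_reference_curve, atf6_reference_curve):
        assert atf6_reference_curve["BiPT"][0] > ire1_reference_curve["BiPT"][0]
        assert atf6_reference_curve["BiPT"][-1] > ire1_reference_curve["BiPT"][-1]

    def test_wfs1_knockout_raises_bip_at_every_load(self, ufpt_grid,
                                                    atf6_reference_curve):
        ko = sc.run_response_curve("atf6", ufpt_grid, knockouts=("wfs1",))
        assert np.all(ko["BiPT"] > atf6_reference_curve["BiPT"] - 1e-9)
        assert ko["BiPT"][0] > atf6_reference_curve["BiPT"][0]

    def test_transfer_knockout_accumulates_membrane_atf6(self):
        """Blocking Golgi transfer leaves ATF6 stranded on the ER membrane
        and abolishes the cleaved transcription factor."""
        grid = np.array([0.0, 8.0])
        m_ref = uk.build_atf6_branch()
        m_ko = uk.build_atf6_branch(uk.Atf6Config(knockout_transfer=True))

        def late(model, mu):
            cm = model.compile()
            traj = dyn.integrate(cm, model.initial_state, t_end=4000.0,
                                 overrides={"mUFPT": mu}, n_points=50)
            i = model.index
            return traj.final_state[i["ATF6"]], traj.final_state[i["ATF6p50"]]

        mem_ref, p50_ref = late(m_ref, 8.0)
        mem_ko, p50_ko = late(m_ko, 8.0)
        assert mem_ko > 10 * mem_ref      # unbound receptor stranded on the ER
        assert p50_ko < 1e-6 and p50_ref > 0.05

    def test_unknown_module_rejected(self):
        with pytest.raises(ValueError):
            sc.run_response_curve("mystery")


class TestScenarios:
    def test_mild_scenario_signature(self, preset_scenarios):
        v = preset_scenarios["mild"].verdicts
        traj = preset_scenarios["mild"].trajectory
        assert v["activity_state"] == "low"
        assert not v["bax_active"]
        chop = traj.series("CHOP")
        assert chop.max() > 3 * v["activity_diagnostics"]["chop_late"]  # transient
        assert v["activity_diagnostics"]["eif2a_late"] > 50.0  # translation back

    def test_moderate_scenario_signature(self, preset_scenarios):
        v = preset_scenarios["moderate"].verdicts
        assert v["activity_state"] == "intermediate"
        assert v["activity_diagnostics"]["sustained"]
        assert v["bax_active"]

    def test_severe_scenario_signature(self, preset_scenarios):
        v = preset_scenarios["severe"].verdicts
        assert v["activity_state"] == "high"
        assert v["bax_active"]
        assert v["activity_diagnostics"]["eif2a_late"] < 10.0

    def test_activation_order_of_the_cascade(self, preset_scenarios):
        t = preset_scenarios["moderate"].verdicts["activation_timing"]
        assert t["eIF2aP"] < t["ATF4"] < t["CHOP"] < t["GADD34"]

    def test_translation_responds_before_folding_capacity(self, preset_scenarios):
        traj = preset_scenarios["moderate"].trajectory
        order = dyn.activation_timing(traj, ["eIF2aP", "BiPT"])
        assert order["eIF2aP"] < order["BiPT"]

    def test_scenarios_are_deterministic(self):
        a = sc.run_stress_scenario("mild", duration=120.0, n_points=200)
        b = sc.run_stress_scenario("mild", duration=120.0, n_points=200)
        assert np.array_equal(a.trajectory.states, b.trajectory.states)
        assert a.verdicts["activity_diagnostics"] == b.verdicts["activity_diagnostics"]
        assert a.provenance["config_hash"] == b.provenance["config_hash"]

    def test_all_zero_protocol_stays_basal(self, full_compiled, basal_state):
        res = sc.run_stress_scenario(dyn.StressProtocol.stepwise([0.0, 0.0], 100.0))
        drift = np.abs(res.trajectory.final_state - basal_state)
        assert np.max(drift / np.maximum(basal_state, 1.0)) < 1e-5

    def test_preconditioning_protects_through_the_moderate_step(
            self, preconditioning_run, preset_scenarios):
        steps = preconditioning_run.verdicts["steps"]
        assert [s["mufpt"] for s in steps] == [12.0, 15.0, 18.0]
        assert not steps[0]["bax_active"]
        assert not steps[1]["bax_active"]  # the protected moderate step
        assert steps[2]["bax_active"]      # commitment once BiP is exhausted
        # contrast: the direct moderate scenario does activate BAX
        assert preset_scenarios["moderate"].verdicts["bax_active"]


class TestSerialisation:
    def test_trajectory_csv_roundtrip(self, tmp_path, preset_scenarios):
        traj = preset_scenarios["mild"].trajectory
        path = tmp_path / "run.csv"
        uio.trajectory_to_csv(traj, path)
        back = uio.trajectory_from_csv(path, species_ids=traj.species_ids)
        assert np.allclose(back.states, traj.states)
        assert np.allclose(back.series("BiPT"), traj.series("BiPT"))

    def test_verdicts_recomputable_from_written_csv(self, tmp_path, preset_scenarios):
        res = preset_scenarios["severe"]
        path = tmp_path / "severe.csv"
        uio.trajectory_to_csv(res.trajectory, path)
        back = uio.trajectory_from_csv(path, species_ids=res.trajectory.species_ids)
        diag = res.verdicts["activity_diagnostics"]
        state = sc.classify_trajectory(back, eif2a_total=100.0,
                                       chop_bounds=(0.0, 2 * diag["chop_midpoint"]))
        assert state.label == res.verdicts["activity_state"]
        assert state.diagnostics["chop_late"] == pytest.approx(diag["chop_late"])

    def test_population_csv_roundtrip(self, tmp_path):
        from test_oscillation_scan import toy_oscillator_frequency
        from uprkit import oscillation_scan as osc
        gens = osc.abc_smc(toy_oscillator_frequency,
                           osc.PriorSpec({"theta": (0.1, 10.0)}),
                           n_particles=60, n_generations=2, seed=1)
        path = tmp_path / "pop.csv"
        uio.populations_to_csv(gens, path, meta={"seed": 1})
        back = uio.populations_from_csv(path)
        assert len(back) == 2
        assert np.allclose(back[-1].parameters, gens[-1].parameters)
        assert (path.parent / (path.name + ".meta.json")).exists()

    def test_config_schema(self, tmp_path):
        cfg_file = tmp_path / "run.yaml"
        cfg_file.write_text(
            "model:\n  overrides: {mUFPT: 9.0}\nprotocol:\n  preset: mild\n")
        cfg = uio.load_config(cfg_file)
        assert cfg["model"]["overrides"] == {"mUFPT": 9.0}
        proto = uio.protocol_from_config(cfg)
        assert proto.segments == ((12.0, 1000.0),)
        cfg_file.write_text("protocol:\n  cadence: fast\n")
        with pytest.raises(ValueError):
            uio.load_config(cfg_file)


class TestSbml:
    def test_roundtrip_preserves_counts_and_identity(self, full_model):
        doc = usbml.export_sbml(full_model)
        back = usbml.import_sbml(doc)
        assert back.counts == (27, 62, 82)
        assert back.species_ids == full_model.species_ids
        assert back.parameters == pytest.approx(full_model.parameters)

    def test_roundtrip_preserves_simulated_trajectories(self, full_model,
                                                        basal_state):
        back = usbml.import_sbml(usbml.export_sbml(full_model))
        kw = dict(t_end=100.0, overrides={"mUFPT": 15.0}, n_points=150,
                  rtol=1e-10, atol=1e-12)
        t1 = dyn.integrate(full_model.compile(), basal_state, **kw)
        t2 = dyn.integrate(back.compile(), basal_state, **kw)
        dev = np.max(np.abs(t1.states - t2.states)
                     / np.maximum(np.abs(t1.states), 1e-6))
        assert dev < 1e-6

    def test_unsupported_construct_is_named_in_the_error(self, full_model):
        from lxml import etree
        doc = etree.fromstring(usbml.export_sbml(full_model))
        mdl = doc.find(f"{{{usbml.SBML_NS}}}model")
        etree.SubElement(mdl, f"{{{usbml.SBML_NS}}}listOfRules")
        with pytest.raises(usbml.SbmlError, match="listOfRules"):
            usbml.import_sbml(etree.tostring(doc))


class TestCli:
    def test_export_import_cycle(self, tmp_path):
        from click.testing import CliRunner
        from uprkit.cli import main
        runner = CliRunner()
        path = str(tmp_path / "model.xml")
        res = runner.invoke(main, ["export-sbml", path])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["import-sbml", path])
        assert res.exit_code == 0
        assert json.loads(res.output) == {"species": 27, "reactions": 62,
                                          "parameters": 82}

    def test_simulate_writes_tidy_csv(self, tmp_path):
        from click.testing import CliRunner
        from uprkit.cli import main
        runner = CliRunner()
        out = str(tmp_path / "run")
        res = runner.invoke(main, ["simulate", "-o", out, "--preset", "mild",
                                   "--t-end", "50"])
        assert res.exit_code == 0, res.output
        df = uio.trajectory_from_csv(out + ".csv", species_ids=["CHOP"])
        assert len(df.times) > 100
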