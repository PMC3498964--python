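"""Trial execution, effect arithmetic and the fitting harness."""

import numpy as np
import pytest

from npsim.dynamics import ConfigurationError
from npsim.engine import Simulator
from npsim.executive import TheoryWeights, build_paradigm, theory_preset
from npsim.experiment import (FitSpec, compute_effects, fit_parameters,
                              run_trial, simulate_word_picture_quantities)
from npsim.params import word_picture_profile


class TestComputeEffects:
    def test_printed_empirical_table_exactly(self):
        """Effect = control mean minus condition mean, to the printed cent."""
        means = {"CO": 660.22, "DT": 681.57, "DTTD": 685.92,
                 "TT": 625.02, "DDTT": 600.69}
        eff = compute_effects(means)
        assert eff["DT"] == pytest.approx(-21.35, abs=0.005)
        assert eff["DTTD"] == pytest.approx(-25.70, abs=0.005)
        assert eff["TT"] == pytest.approx(35.20, abs=0.005)
        assert eff["DDTT"] == pytest.approx(59.53, abs=0.005)

    def test_zero_difference(self):
        assert compute_effects({"CO": 600.0, "DT": 600.0})["DT"] == 0.0

    def test_suffixed_conditions_use_matching_control(self):
        eff = compute_effects({"COs": 800.0, "COr": 820.0,
                               "DTs": 810.0, "DTr": 805.0})
        assert eff["DTs"] == pytest.approx(-10.0)
        assert eff["DTr"] == pytest.approx(15.0)

    def test_missing_control_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_effects({"DT": 600.0})


class TestRunTrial:
    def test_single_target_display_names_target(self, voicekey, vk_params,
                                                er_weights):
        sim = Simulator(voicekey, er_weights, vk_params)
        res = run_trial(sim, voicekey.make_display("tree", "bus"))
        assert not res.omission
        assert res.response == "name:tree"
        assert res.correct

    def test_rt_exceeds_recognition_plus_motor_time(self, voicekey, vk_params,
                                                    er_weights):
        sim = Simulator(voicekey, er_weights, vk_params)
        res = run_trial(sim, voicekey.make_display("ball", "book"))
        assert res.rt >= vk_params.t_recognition + vk_params.t_motor

    def test_deterministic(self, voicekey, vk_params, er_weights):
        rts = []
        for _ in range(2):
            sim = Simulator(voicekey, er_weights, vk_params)
            run_trial(sim, voicekey.make_display("tree", "bus"))
            res = run_trial(sim, voicekey.make_display("bus", "ball"))
            rts.append(res.rt)
        assert rts[0] == rts[1]

    def test_timeout_yields_omission_not_exception(self, voicekey, er_weights,
                                                   vk_params):
        # a drive too weak to ever cross the action threshold
        params = vk_params.replace(sigma_s_a=0.001, timeout=400, rsi=50)
        sim = Simulator(voicekey, er_weights, params)
        res = run_trial(sim, voicekey.make_display("tree", "bus"))
        assert res.omission and res.rt is None

    def test_episode_stored_at_response(self, voicekey, vk_params, er_weights):
        sim = Simulator(voicekey, er_weights, vk_params)
        assert len(sim.store.traces) == 0
        run_trial(sim, voicekey.make_display("tree", "bus"))
        assert len(sim.store.traces) == 1

    def test_no_memory_written_when_semaphore_off(self, voicekey, vk_params):
        weights = TheoryWeights(xi_er=0, xi_rr=0, xi_ib=1)
        sim = Simulator(voicekey, weights, vk_params)
        run_trial(sim, voicekey.make_display("tree", "bus"))
        assert sim.store.traces == []

    def test_binding_slots_never_exceed_capacity(self, voicekey, vk_params,
                                                 er_weights):
        from npsim.executive import generate_sequence
        sim = Simulator(voicekey, er_weights, vk_params.replace(rsi=200))
        seq = generate_sequence(voicekey, ["CO", "DT"], 3, seed=9)
        for disp in seq:
            sim.set_display(disp)
            onset = sim.t
            while not sim.responded and sim.t - onset < vk_params.timeout:
                sim.step()
                assert sim.bindings.n_active <= vk_params.n_binding_slots
            sim.mark_offset()
            while sim.t < sim.offset + vk_params.t_afterimage + 1:
                sim.step()
            sim.clear_display()
            for _ in range(200):
                sim.step()


class TestWordPicture:
    def test_comparison_task_answers_correctly(self, word_picture, wp_params):
        th = theory_preset("distractor_inhibition")
        sim = Simulator(word_picture, th, wp_params)
        res = run_trial(sim, word_picture.make_display("tree", "bus", word="tree"))
        assert res.response == "yes"
        sim2 = Simulator(word_picture, th, wp_params)
        res2 = run_trial(sim2, word_picture.make_display("tree", "bus", word="ball"))
        assert res2.response == "no"

    def test_quantities_have_expected_keys(self, wp_params):
        th = theory_preset("distractor_inhibition")
        q = simulate_word_picture_quantities(th, wp_params)
        assert set(q) == {"COs", "COr", "DTs", "DTr", "TTs", "TTr"}
        assert q["COs"] > 0 and q["COr"] > 0


class TestFitting:
    def test_rmse_hand_example(self):
        from npsim.experiment import _rmse
        sim_q = {"a": 825.5, "b": -4.2}
        targets = {"a": 821.2, "b": -20.8}
        assert _rmse(sim_q, targets) == pytest.approx(
            np.sqrt((4.3 ** 2 + 16.6 ** 2) / 2), abs=1e-9)
        assert _rmse(sim_q, targets) == pytest.approx(12.13, abs=0.005)

    def test_self_consistent_targets_converge_immediately(self):
        th = theory_preset("distractor_inhibition")
        base = word_picture_profile()
        targets = simulate_word_picture_quantities(th, base)
        spec = FitSpec(
            theory=th,
            free={"rho_a": (base.rho_a, 0.0015, 0.01)},
            targets=targets, base_params=base, max_iter=2, tol=0.5)
        result = fit_parameters(spec)
        assert result.rmse <= 0.5
        assert result.converged

    def test_bad_bounds_rejected(self):
        th = theory_preset("distractor_inhibition")
        with pytest.raises(ConfigurationError):
            FitSpec(theory=th, free={"rho_a": (0.5, 0.6, 0.4)}, targets={"COs": 800})

    def test_unknown_free_parameter_rejected(self):
        th = theory_preset("distractor_inhibition")
        with pytest.raises(ConfigurationError):
            FitSpec(theory=th, free={"warp_speed": (0.1, 0.0, 1.0)},
                    targets={"COs": 800})
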