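"""Feature layer, selection signals and the binding pool."""

import numpy as np
import pytest

from npsim.dynamics import ConfigurationError
from npsim.features import BindingLayer, FeatureLayer, SelectionSignals
from npsim.params import ModelParams


@pytest.fixture
def layer(voicekey, vk_params):
    return FeatureLayer(voicekey, vk_params)


class TestSelectionSignals:
    def test_amplification_ramps_linearly(self):
        sig = SelectionSignals(alpha=0.0005, k=0.0)
        for _ in range(100):
            sig.step(input_active=True, response_given=False)
        assert sig.A == pytest.approx(0.05)

    def test_amplification_resets_at_response(self):
        sig = SelectionSignals(alpha=0.0005, k=0.0)
        for _ in range(50):
            sig.step(True, False)
        sig.step(True, True)
        assert sig.A == 0.0

    def test_inhibition_ramps_down_to_floor(self):
        sig = SelectionSignals(alpha=0.0, k=0.0005)
        sig.I = 0.02
        for n in range(60):
            sig.step(False, False)
            if n == 39:
                assert sig.I == pytest.approx(0.0)
        assert sig.I == 0.0

    def test_negative_slope_rejected(self):
        with pytest.raises(ConfigurationError):
            SelectionSignals(alpha=-0.1, k=0.0)


class TestFeatureInput:
    def test_onset_overshoot_adds_residual(self, layer):
        i = layer.idx(("shape", "ball"))
        layer.f[i] = 0.3
        layer.perception_onset(np.array([i]))
        assert layer.F[i] == pytest.approx(layer.p.F_hat + 0.3)

    def test_absent_instance_sits_at_baseline(self, layer):
        layer.perception_onset(np.array([layer.idx(("shape", "ball"))]))
        layer.step_input()
        j = layer.idx(("shape", "tree"))
        assert layer.F[j] == layer.p.F_check

    def test_overshoot_relaxes_toward_unit_input(self, layer):
        i = layer.idx(("shape", "ball"))
        layer.f[i] = 1.5
        layer.perception_onset(np.array([i]))
        start = layer.F[i]
        for _ in range(400):
            layer.step_input()
        assert layer.p.F_hat < layer.F[i] < start

    def test_target_boost_and_distractor_inhibition(self, layer):
        gi = layer.idx(("color", "green"))
        ri = layer.idx(("color", "red"))
        layer.perception_onset(np.array([gi, ri]))
        sig = SelectionSignals(alpha=0.0005, k=0.0005)
        sig.A, sig.I = 0.2, 0.1
        F = layer.effective_input(sig, gi, ri)
        base = layer.F
        assert F[gi] == pytest.approx(base[gi] + 0.2)
        assert F[ri] == pytest.approx(base[ri] - 0.1)

    def test_unknown_instance_rejected(self, layer):
        with pytest.raises(ConfigurationError):
            layer.idx(("shape", "zeppelin"))


class TestFeatureDynamics:
    def test_at_input_fixed_point_nothing_moves(self, layer):
        F = layer.f.copy()
        layer.step(F, np.zeros_like(F), [], beta_eff=0.0,
                   forced_decay=False, phi_eff=0.0)
        assert np.allclose(layer.f, F)

    def test_broadening_conserves_dimension_sum_and_contracts(self, voicekey):
        p = ModelParams()
        layer = FeatureLayer(voicekey, p)
        hi = layer.idx(("shape", "tree"))
        lo = layer.idx(("shape", "bus"))
        layer.f[:] = 0.0
        layer.f[hi], layer.f[lo] = 0.8, 0.4
        # remaining four shapes at 0 participate in the dimension mean
        before = layer.f[layer.dim_slices["shape"]].sum()
        layer.step(layer.f.copy(), np.zeros_like(layer.f), [],
                   beta_eff=0.1, forced_decay=False, phi_eff=0.0)
        after = layer.f[layer.dim_slices["shape"]].sum()
        assert after == pytest.approx(before, abs=1e-10)
        mean = before / 6
        assert abs(layer.f[hi] - mean) < abs(0.8 - mean)
        assert abs(layer.f[lo] - mean) < abs(0.4 - mean)

    def test_two_instance_broadening_hand_example(self, voicekey):
        """Two instances at 0.8/0.4 with rate 0.1 drift to 0.78/0.42."""
        p = ModelParams()
        layer = FeatureLayer(voicekey, p)
        # isolate the color dimension (exactly two instances)
        gi, ri = layer.idx(("color", "green")), layer.idx(("color", "red"))
        layer.f[:] = 1.0
        layer.f[gi], layer.f[ri] = 0.8, 0.4
        drift_free = layer.f.copy()
        layer.step(drift_free, np.zeros_like(layer.f), [],
                   beta_eff=0.1, forced_decay=False, phi_eff=0.0)
        assert layer.f[gi] == pytest.approx(0.78)
        assert layer.f[ri] == pytest.approx(0.42)

    def test_binding_exchange_moves_pair_toward_mean(self, voicekey, vk_params):
        layer = FeatureLayer(voicekey, vk_params)
        bindings = BindingLayer(vk_params)
        a = layer.idx(("color", "green"))
        b = layer.idx(("shape", "tree"))
        bindings.bind_display([(a, b)])
        bindings.strength[0] = 0.04
        layer.f[a], layer.f[b] = 0.9, 0.5
        drift = bindings.exchange_drift(layer.f)
        # each member moves by b * (other - self)
        assert drift[a] == pytest.approx(0.04 * (0.5 - 0.9))
        assert drift[b] == pytest.approx(0.04 * (0.9 - 0.5))

    def test_memory_feedback_drifts_toward_stored(self, layer):
        stored = layer.f + 1.0
        before = layer.f.copy()
        layer.step(before.copy(), np.zeros_like(before), [(0.01, stored)],
                   beta_eff=0.0, forced_decay=False, phi_eff=0.0)
        assert np.allclose(layer.f, before + 0.01)


class TestBindings:
    def test_perceived_slot_grows_toward_maximum(self, vk_params):
        b = BindingLayer(vk_params)
        b.bind_display([(0, 2)])
        b.step()
        assert b.strength[0] == pytest.approx(
            vk_params.rho_b * vk_params.b_hat)  # 0.008 * 0.05 = 0.0004

    def test_saturated_slot_stays_at_maximum(self, vk_params):
        b = BindingLayer(vk_params)
        b.bind_display([(0, 2)])
        b.strength[0] = vk_params.b_hat
        b.step()
        assert b.strength[0] == pytest.approx(vk_params.b_hat)

    def test_unperceived_slot_decays(self, vk_params):
        b = BindingLayer(vk_params)
        b.bind_display([(0, 2)])
        b.strength[0] = 0.05
        b.release_all()
        b.step()
        assert b.strength[0] == pytest.approx(0.05 * (1 - vk_params.delta_b))

    def test_recognition_preserves_strength(self, vk_params):
        b = BindingLayer(vk_params)
        b.bind_display([(0, 2)])
        b.strength[0] = 0.03
        b.release_all()
        b.bind_display([(0, 2)])
        assert b.n_active == 1
        assert b.strength[0] == pytest.approx(0.03)
        assert b.perceived[0]

    def test_overwrite_picks_weakest_unperceived(self, vk_params):
        b = BindingLayer(vk_params)
        tuples = [(i, 10 + i) for i in range(7)]
        b.bind_display(tuples)
        b.release_all()
        strengths = [0.04, 0.01, 0.02, 0.03, 0.05, 0.045, 0.035]
        b.strength[:] = strengths
        b.bind_display([tuples[1]])  # re-perceive the weakest slot
        b.bind_display([(8, 21)])    # must overwrite the weakest unperceived
        new_slot = b.tuples.index((8, 21))
        assert strengths[new_slot] == min(
            s for i, s in enumerate(strengths) if i != 1)
        assert b.strength[new_slot] == 0.0

    def test_capacity_error_when_all_perceived(self):
        p = ModelParams(n_binding_slots=2)
        b = BindingLayer(p)
        b.bind_display([(0, 2), (1, 3)])
        with pytest.raises(ConfigurationError):
            b.bind_display([(4, 5)])

    def test_overwrite_matches_brute_force_min_oracle(self, vk_params):
        rng = np.random.default_rng(42)
        for _ in range(50):
            b = BindingLayer(vk_params)
            tuples = [(i, 10 + i) for i in range(7)]
            b.bind_display(tuples)
            b.release_all()
            b.strength[:] = rng.uniform(0, 0.05, 7)
            perceived = rng.choice(7, size=3, replace=False)
            for i in perceived:
                b.bind_display([tuples[i]])
            expected = min(
                (i for i in range(7) if i not in perceived),
                key=lambda i: b.strength[i])
            b.bind_display([(99, 100)])
            assert b.tuples[expected] == (99, 100)
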