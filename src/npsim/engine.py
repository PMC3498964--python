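"""The step-by-step simulation engine.

One :class:`Simulator` instance owns the full model state — feature
activations, bindings, selection signals, semantic and action layers with
their thresholds, gates, episodic memory and the discrimination variables —
and advances it one millisecond per :meth:`Simulator.step`.  The update
order per step follows the feed-forward information flow: perceptual input
and selection signals first, then features and bindings, then the memory
signals and gates, then the semantic and action layers, and finally the
decision test.

The engine is deliberately noise-free: identical state, display and
parameters yield bit-identical trajectories.
"""

from __future__ import annotations

import numpy as np

from .dynamics import ConfigurationError
from .executive import Display, Paradigm, TheoryWeights
from .features import BindingLayer, FeatureLayer, SelectionSignals
from .memory import (DiscriminationState, MemoryStore, old_new_signal,
                     retrieval_strengths)
from .params import ModelParams
from .semantics import ActionLayer, GateState, SemanticLayer

__all__ = ["Simulator"]

# a feature channel counts as driving a concept when it exceeds the
# baseline by this much (comparison-task yes/no mapping)
CHANNEL_MARGIN = 0.05


class Simulator:
    def __init__(self, paradigm: Paradigm, theory: TheoryWeights,
                 params: ModelParams) -> None:
        self.paradigm = paradigm
        self.theory = theory
        self.p = params

        # the inhibition-vs-boost semaphore enforces a pure mechanism:
        # boost mode zeroes the inhibition slope, inhibition mode the boost slope
        alpha_eff = params.alpha if theory.xi_ib else 0.0
        k_eff = params.k_inhibition if not theory.xi_ib else 0.0
        self.signals = SelectionSignals(alpha_eff, k_eff)

        self.features = FeatureLayer(paradigm, params)
        self.bindings = BindingLayer(params)
        self.semantic = SemanticLayer(len(paradigm.concepts), params)
        self.actions = ActionLayer(len(paradigm.actions), params)
        self.gates = GateState(params, theory)
        self.store = MemoryStore(params)
        self.disc = DiscriminationState(params)

        # static index arrays
        self.shape_idx = np.array(
            [self.features.idx(("shape", c)) for c in paradigm.concepts], dtype=int)
        if "word" in paradigm.dimensions:
            self.word_idx = np.array(
                [self.features.idx(("word", c)) for c in paradigm.concepts], dtype=int)
        else:
            self.word_idx = None
        self.target_def_idx = self.features.idx(paradigm.target_defining)
        self.distractor_def_idx = self.features.idx(paradigm.distractor_defining)
        if paradigm.kind == "naming":
            self.concept_action = np.array(
                [paradigm.actions.index(f"name:{c}") for c in paradigm.concepts], dtype=int)
        else:
            self.yes_idx = paradigm.actions.index("yes")
            self.no_idx = paradigm.actions.index("no")

        # clock / display state
        self.t = 0
        self.display: Display | None = None
        self.onset: int | None = None
        self.offset: int | None = None
        self._responded = False
        self._decision_step: int | None = None
        self._response_idx: int | None = None
        self._input_was_active = False
        self._display_mask = np.zeros(self.features.n, dtype=bool)
        self._display_tuples: list = []

        # per-step memory signals (weights lag one step behind by design)
        self._mem_weights: list = []
        self.last_r: list = []      # r_k per trace, most recent first
        self.last_o: float = 1.0    # old/new signal of the most recent trace

    # ------------------------------------------------------------------
    # display control
    # ------------------------------------------------------------------
    def set_display(self, display: Display) -> None:
        if self.display is not None:
            raise ConfigurationError("previous display not cleared")
        if len(display.objects) != self.paradigm.n_objects:
            raise ConfigurationError(
                f"display has {len(display.objects)} objects, paradigm expects "
                f"{self.paradigm.n_objects}")
        self.display = display
        self.onset = self.t
        self.offset = None
        self._responded = False
        self._decision_step = None
        self._response_idx = None
        self._display_tuples = [
            tuple(sorted(self.features.idx(inst) for inst in obj.features))
            for obj in display.objects
        ]
        self._display_mask[:] = False
        for tup in self._display_tuples:
            self._display_mask[list(tup)] = True

    def mark_offset(self) -> None:
        """Stimulus removed from the screen (response given or timeout)."""
        if self.offset is None:
            self.offset = self.t

    def clear_display(self) -> None:
        self.display = None
        self.onset = None
        self.offset = None

    def input_active(self) -> bool:
        """Is perceptual input currently arriving at the feature layers?"""
        if self.display is None or self.onset is None:
            return False
        if self.t < self.onset + self.p.t_recognition:
            return False
        if self.offset is not None and self.t >= self.offset + self.p.t_afterimage:
            return False
        return True

    # ------------------------------------------------------------------
    # the step
    # ------------------------------------------------------------------
    def step(self) -> None:
        p, th = self.p, self.theory
        active = self.input_active()

        # perception edges
        if active and not self._input_was_active:
            present_idx = np.flatnonzero(self._display_mask)
            self.features.perception_onset(present_idx)
            self.bindings.bind_display(self._display_tuples)
            self.disc.onset()
        elif self._input_was_active and not active:
            self.features.perception_offset()
            self.bindings.release_all()
            self.disc.offset()
        self._input_was_active = active

        # selection signals, then feature input
        self.signals.step(active, self._responded)
        self.features.step_input()
        F_eff = self.features.effective_input(
            self.signals, self.target_def_idx, self.distractor_def_idx)

        # feature dynamics
        binding_drift = self.bindings.exchange_drift(self.features.f)
        xi_full = th.xi_er * th.xi_rr
        mem_f = [(w * xi_full, tr.f) for w, tr in self._mem_weights] if xi_full else []
        forced = bool(
            th.xi_gt and self.display is not None
            and self.t - self.onset < p.t_recognition
        )
        self.features.step(
            F_eff, binding_drift, mem_f,
            beta_eff=p.beta * th.xi_gt,
            forced_decay=forced, phi_eff=p.phi,
        )
        self.bindings.step()

        # memory signals and gates
        self.store.decay()
        self.disc.step()
        percept_slots = self.bindings.strongest(self.paradigm.n_objects)
        percept_tuples = [self.bindings.tuples[i] for i in percept_slots]
        percept_strengths = [self.bindings.strength[i] for i in percept_slots]
        f = self.features.f
        weights = []
        self.last_r = retrieval_strengths(
            f, percept_tuples, percept_strengths, self.store.traces,
            self.paradigm.n_features_relevant, p)
        for r_k, tr in zip(self.last_r, self.store.traces):
            # retrieval is triggered by the similarity of the current
            # percept; without perceptual input there is nothing to match
            w = r_k * tr.strength if active else 0.0
            if th.xi_td and old_new_signal(r_k, self.disc) == 0.5:
                w = 0.0  # retrieval waits for the old/new classification
            weights.append((w, tr))
        self._mem_weights = weights
        self.last_o = (old_new_signal(self.last_r[0], self.disc)
                       if self.last_r else 1.0)
        self.gates.step_block(self.last_o)

        # semantic layer
        drive = self._semantic_drive(f)
        mem_s = [(w * xi_full, tr.s) for w, tr in weights] if xi_full else []
        self.semantic.step(drive, self.gates.gain_fs, mem_s)

        # action layer; the formal no-action is bookkeeping, not a motor
        # representation, so retrieval reinstates only the real responses
        a_drive = self._action_drive(f, active)
        mem_a = []
        for w, tr in weights:
            if w > 0.0:
                stored_a = tr.a.copy()
                stored_a[0] = self.actions.a[0]
                mem_a.append((w, stored_a))
        self.actions.step(a_drive, self.gates.retrieval_gain, mem_a)

        # periodic sanity guard (cheap; blowups grow over many steps)
        if (self.t & 0xFF) == 0:
            total = float(self.features.f.sum()) + float(self.semantic.s.sum()) \
                + float(self.actions.a.sum())
            if not np.isfinite(total):
                from .dynamics import InvalidStateError
                raise InvalidStateError("activations left the finite domain")

        # decision test
        if self.display is not None and not self._responded:
            sel = self.actions.select()
            if sel is not None and sel != 0:
                self._responded = True
                self._decision_step = self.t
                self._response_idx = sel
                self.store.store(
                    self.features.f, self.semantic.s, self.actions.a,
                    self.bindings.snapshot(), th.xi_er)
                self.mark_offset()

        self.t += 1

    # ------------------------------------------------------------------
    # task mappings
    # ------------------------------------------------------------------
    def _semantic_drive(self, f: np.ndarray) -> np.ndarray:
        """Gating function S(f): only feature activations above the
        perceptual floor pass to the semantic layer, so sub-threshold
        residuals of earlier trials do not re-enter the race."""
        p = self.p
        base = p.F_check
        drive = base + p.sigma_shape_s * np.maximum(0.0, f[self.shape_idx] - p.f_gate)
        if self.word_idx is not None and p.sigma_word_s > 0.0:
            drive = drive + p.sigma_word_s * np.maximum(0.0, f[self.word_idx] - p.f_gate)
        return drive

    def _action_drive(self, f: np.ndarray, active: bool) -> np.ndarray:
        p = self.p
        drive = np.zeros(len(self.actions.a))
        drive[0] = 0.0 if active else 1.0
        if not active:
            return drive
        s = self.semantic.s
        order = np.argsort(s)
        winner = int(order[-1])
        runner_up = float(s[order[-2]])
        gain = p.sigma_s_a * self.gates.gain_fsa
        if self.paradigm.kind == "naming":
            # competitive readout: only the winning concept is passed on,
            # with a drive that grows with its lead over the stronger of
            # the runner-up and the semantic threshold, saturating at 1
            lead = s[winner] - max(runner_up, self.semantic.threshold.value)
            if lead <= 0.0:
                return drive
            drive[self.concept_action[winner]] = min(1.0, gain * lead / p.s_margin)
        else:
            # comparison readout: the winner's margin above the adaptive
            # threshold expresses the evidence; the word/picture channel
            # agreement decides which response it supports
            margin = s[winner] - self.semantic.threshold.value
            if margin <= 0.0:
                return drive
            shape_on = f[self.shape_idx[winner]] - p.F_check > CHANNEL_MARGIN
            word_on = f[self.word_idx[winner]] - p.F_check > CHANNEL_MARGIN
            idx = self.yes_idx if (shape_on and word_on) else self.no_idx
            drive[idx] = min(1.0, gain * margin / p.s_margin)
        return drive

    # ------------------------------------------------------------------
    @property
    def responded(self) -> bool:
        return self._responded

    @property
    def decision_step(self) -> int | None:
        return self._decision_step

    @property
    def response_label(self) -> str | None:
        if self._response_idx is None:
            return None
        return self.paradigm.actions[self._response_idx]
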