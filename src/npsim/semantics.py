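"""Semantic and action layers with adaptive thresholds and synaptic gating.

The semantic layer receives a task-defined drive from the feature layers
through a gated channel and singles out a winner with an adaptive threshold
whose fixed point lies between the two highest activations.  The action
layer races response alternatives (including the formal no-action ``a0``)
against its own adaptive threshold; a unique suprathreshold action is the
decision.  An old/new blocking variable modulates the channel gains and,
inversely, the retrieval gain of the action layer.
"""

from __future__ import annotations

import numpy as np

from .dynamics import ConfigurationError, ThresholdVar
from .executive import TheoryWeights
from .params import ModelParams

__all__ = [
    "gate_strength",
    "GateState",
    "SemanticLayer",
    "ActionLayer",
]


def gate_strength(floor: float, sigma_block: float) -> float:
    """Synaptic gain ``(1 - floor) + floor * sigma_block``.

    ``floor`` is the modulation depth: 0 disables modulation (gain 1),
    1 lets the blocking variable close the channel entirely.
    """
    if not (0.0 <= floor <= 1.0) or not (0.0 <= sigma_block <= 1.0):
        raise ConfigurationError(
            f"gate inputs must lie in [0, 1]; got floor={floor}, sigma_block={sigma_block}"
        )
    return (1.0 - floor) + floor * sigma_block


class GateState:
    """Blocking variable and the channel gains / retrieval gain derived from it."""

    def __init__(self, params: ModelParams, theory: TheoryWeights) -> None:
        self.p = params
        self.theory = theory
        # modulation depths are only engaged by their semaphores
        self.floor_fs = params.sigma_check_fs * theory.xi_fsb
        self.floor_fsa = params.sigma_check_fsa * theory.xi_sab
        self.sigma_block = 1.0

    def step_block(self, o_k: float) -> None:
        """Drive the blocking variable toward the old/new signal (if gating is on)."""
        if self.theory.xi_td:
            self.sigma_block += self.p.tau_block * (o_k - self.sigma_block)
        else:
            self.sigma_block = 1.0

    @property
    def gain_fs(self) -> float:
        return gate_strength(self.floor_fs, self.sigma_block)

    @property
    def gain_fsa(self) -> float:
        return gate_strength(self.floor_fsa, self.sigma_block)

    @property
    def retrieval_gain(self) -> float:
        """Action-layer retrieval gain, anti-symmetric to the channel gain:
        an *old* display (sigma_block -> 0) closes the direct channel and
        boosts retrieval; a *new* one does the opposite."""
        m = max(self.floor_fsa, self.floor_fs)
        return 1.0 + m - 2.0 * m * self.sigma_block


class SemanticLayer:
    def __init__(self, n_concepts: int, params: ModelParams) -> None:
        self.p = params
        self.s = np.full(n_concepts, params.F_check, dtype=float)
        self.threshold = ThresholdVar(
            value=params.F_check,
            time_scale=params.tau_s_theta,
            scale=params.nu_s_theta,
            baseline=params.F_check,
        )

    def step(self, drive: np.ndarray, gain_fs: float, memory_terms: list) -> None:
        s = self.s
        tau = np.where(drive > s, self.p.rho_s, self.p.delta_s)
        ds = gain_fs * tau * (drive - s)
        for w, stored in memory_terms:
            ds += w * (stored - s)
        s += ds
        th = self.threshold
        drive_sum = th.scale * (s.sum() - s.size * th.baseline)
        th.value += th.time_scale * (drive_sum - (th.value - th.baseline))

    def suprathreshold(self) -> np.ndarray:
        return np.flatnonzero(self.s > self.threshold.value)


class ActionLayer:
    """Response activations including the formal no-action at index 0."""

    def __init__(self, n_actions: int, params: ModelParams) -> None:
        if n_actions < 2:
            raise ConfigurationError("need a0 plus at least one real action")
        self.p = params
        self.a = np.zeros(n_actions, dtype=float)
        self.a[0] = 1.0  # resting state: only the no-action is active
        self.threshold = ThresholdVar(
            value=params.nu_a_theta,  # fixed point of the resting state
            time_scale=params.tau_a_theta,
            scale=params.nu_a_theta,
            baseline=0.0,
        )

    def step(self, drive: np.ndarray, retrieval_gain: float, memory_terms: list) -> None:
        a = self.a
        tau = np.where(drive > a, self.p.rho_a, self.p.delta_a)
        da = tau * (drive - a)
        for w, stored in memory_terms:
            da += retrieval_gain * w * (stored - a)
        a += da
        th = self.threshold
        drive_sum = th.scale * (a.sum() - a.size * th.baseline)
        th.value += th.time_scale * (drive_sum - (th.value - th.baseline))

    def select(self) -> int | None:
        """Index of the unique suprathreshold action, or None.

        With zero or two-plus suprathreshold actions no decision is taken
        (the threshold keeps adapting).  Index 0 (a0) means "do nothing".
        """
        supra = np.flatnonzero(self.a > self.threshold.value)
        if supra.size == 1:
            return int(supra[0])
        return None
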