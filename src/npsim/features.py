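"""Feature layers, attentional selection signals and the binding layer.

Feature-instance activations are driven by perceptual input with a residual
overshoot at onset, shaped by target amplification / distractor inhibition,
within-dimension broadening, binding-mediated exchange between the features
of one object, and feedback from retrieved episodes.  Bindings live in a
small pool of slots; when the pool is full the weakest binding that is not
currently perceived is overwritten.
"""

from __future__ import annotations

import numpy as np

from .dynamics import ConfigurationError
from .executive import Paradigm
from .params import ModelParams

__all__ = ["SelectionSignals", "FeatureLayer", "BindingLayer"]


class SelectionSignals:
    """Target amplification A and distractor inhibition I.

    A ramps linearly (slope ``alpha``) while perceptual input is active and
    resets to zero at the response or when no stimulus is present.
    I ramps linearly (slope ``k``) during input and ramps back down after
    input offset, floored at zero, so inhibition persists briefly after the
    display is gone (inhibitory rebound).
    """

    def __init__(self, alpha: float, k: float) -> None:
        if alpha < 0 or k < 0:
            raise ConfigurationError("selection slopes must be nonnegative")
        self.alpha = alpha
        self.k = k
        self.A = 0.0
        self.I = 0.0

    def step(self, input_active: bool, response_given: bool) -> None:
        if response_given or not input_active:
            self.A = 0.0
        else:
            self.A += self.alpha
        if input_active:
            self.I += self.k
        else:
            self.I = max(0.0, self.I - self.k)


class FeatureLayer:
    """All feature-instance activations of a paradigm, flattened to one array."""

    def __init__(self, paradigm: Paradigm, params: ModelParams) -> None:
        self.paradigm = paradigm
        self.p = params
        self.instances = paradigm.instance_list()
        self.index = {inst: i for i, inst in enumerate(self.instances)}
        n = len(self.instances)
        self.n = n
        self.f = np.full(n, params.F_check, dtype=float)
        self.F = np.full(n, params.F_check, dtype=float)  # raw input before selection
        self.present = np.zeros(n, dtype=bool)
        # index arrays per dimension for the broadening term
        self.dim_slices = {}
        for d in paradigm.dimensions:
            self.dim_slices[d] = np.array(
                [i for i, (dd, _) in enumerate(self.instances) if dd == d], dtype=int
            )

    def idx(self, instance: tuple) -> int:
        try:
            return self.index[instance]
        except KeyError:
            raise ConfigurationError(f"feature instance {instance!r} not registered") from None

    # ------------------------------------------------------------------
    # perceptual input
    # ------------------------------------------------------------------
    def perception_onset(self, present_idx: np.ndarray) -> None:
        """Perceptual input reaches the layer: residual overshoot F = F_hat + f."""
        self.present[:] = False
        self.present[present_idx] = True
        self.F[present_idx] = self.p.F_hat + self.f[present_idx]

    def perception_offset(self) -> None:
        self.present[:] = False

    def step_input(self) -> None:
        """Relax present inputs from the overshoot toward the unit input; absent -> baseline."""
        pres = self.present
        over = pres & (self.F > self.p.F_hat)
        self.F[over] += self.p.delta_f * (self.p.F_hat - self.F[over])
        self.F[~pres] = self.p.F_check

    def effective_input(self, signals: SelectionSignals,
                        target_idx: int | None, distractor_idx: int | None) -> np.ndarray:
        """Add target amplification / subtract distractor inhibition."""
        F = self.F.copy()
        if target_idx is not None and self.present[target_idx]:
            F[target_idx] += signals.A
        if distractor_idx is not None:
            # inhibition persists after offset, so it applies regardless of presence
            F[distractor_idx] -= signals.I
        return F

    # ------------------------------------------------------------------
    # dynamics
    # ------------------------------------------------------------------
    def step(self, F_eff: np.ndarray, binding_drift: np.ndarray,
             memory_terms: list, beta_eff: float,
             forced_decay: bool, phi_eff: float) -> None:
        """One update of all feature activations (simultaneous, from start-of-step values)."""
        f = self.f
        tau = np.where(F_eff > f, self.p.rho_f, self.p.delta_f)
        df = tau * (F_eff - f)
        if beta_eff > 0.0:
            for sl in self.dim_slices.values():
                df[sl] += beta_eff * (f[sl].mean() - f[sl])
        df += binding_drift
        for w, stored in memory_terms:
            df += w * (stored - f)
        f += df
        if forced_decay and phi_eff > 0.0:
            residual = (~self.present) & (f > self.p.F_check)
            f[residual] = self.p.F_check + (f[residual] - self.p.F_check) * (1.0 - phi_eff)


class BindingLayer:
    """Capacity-limited pool of feature bindings.

    Each slot holds one object's feature tuple (as instance indices), a
    strength in [0, b_hat] and a perceived flag.  A perceived object's slot
    is driven toward the maximum strength; unperceived slots passively
    decay.  Recognition: an object whose tuple already occupies a slot
    re-claims it with its strength preserved.
    """

    def __init__(self, params: ModelParams) -> None:
        self.p = params
        self.capacity = params.n_binding_slots
        self.tuples: list = [None] * self.capacity   # tuple of instance indices or None
        self.strength = np.zeros(self.capacity, dtype=float)
        self.perceived = np.zeros(self.capacity, dtype=bool)

    @property
    def n_active(self) -> int:
        return sum(t is not None for t in self.tuples)

    def bind_display(self, object_tuples: list) -> None:
        """Claim slots for the displayed objects (recognition / overwrite-weakest)."""
        for tup in object_tuples:
            tup = tuple(sorted(tup))
            slot = next((i for i, t in enumerate(self.tuples) if t == tup), None)
            if slot is not None:
                self.perceived[slot] = True  # recognition, strength preserved
                continue
            free = next((i for i, t in enumerate(self.tuples) if t is None), None)
            if free is None:
                candidates = [i for i in range(self.capacity) if not self.perceived[i]]
                if not candidates:
                    raise ConfigurationError(
                        "binding capacity exhausted: all slots subject to current input"
                    )
                free = min(candidates, key=lambda i: self.strength[i])
            self.tuples[free] = tup
            self.strength[free] = 0.0
            self.perceived[free] = True

    def release_all(self) -> None:
        self.perceived[:] = False

    def step(self) -> None:
        for i, t in enumerate(self.tuples):
            if t is None:
                continue
            if self.perceived[i]:
                self.strength[i] += self.p.rho_b * (self.p.b_hat - self.strength[i])
            else:
                self.strength[i] -= self.p.delta_b * self.strength[i]

    def exchange_drift(self, f: np.ndarray) -> np.ndarray:
        """Binding-mediated drift of each member feature toward the mean of
        the *other* features of its object, at a rate given by the binding
        strength."""
        drift = np.zeros_like(f)
        for i, tup in enumerate(self.tuples):
            if tup is None or len(tup) < 2:
                continue
            b = self.strength[i]
            if b <= 1e-12:
                continue
            k1 = len(tup) - 1
            total = 0.0
            for idx in tup:
                total += f[idx]
            # mean over the other members: (total - f_j) / (k - 1)
            for idx in tup:
                fj = f[idx]
                drift[idx] += b * ((total - fj) / k1 - fj)
        return drift

    def strongest(self, n: int) -> list:
        """Indices of the n strongest active slots (the subjective percept)."""
        order = sorted(
            (i for i, t in enumerate(self.tuples) if t is not None),
            key=lambda i: -self.strength[i],
        )
        return order[:n]

    def snapshot(self) -> dict:
        return {t: float(self.strength[i]) for i, t in enumerate(self.tuples) if t is not None}
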