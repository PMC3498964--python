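"""Episodic memory: decaying full-state traces, similarity-based retrieval
strength, and the temporal-discrimination old/new classifier.

A trace is a snapshot of every model variable taken at the moment a
response is made; its strength starts at ``e_hat`` and decays freely.
Retrieval strength compares the current *subjective percept* — the objects
held by the strongest bindings — against the stored values: the more
similar the display, the stronger the trace drives the present dynamics.
The old/new classifier locates the retrieval signal relative to a
prototype similarity time course with a shrinking uncertainty band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "EpisodeTrace",
    "MemoryStore",
    "DiscriminationState",
    "retrieval_strength",
    "old_new_signal",
]


@dataclass
class EpisodeTrace:
    """Snapshot of the model state at response time with a decaying strength."""

    f: np.ndarray
    s: np.ndarray
    a: np.ndarray
    bindings: dict        # feature tuple (sorted instance indices) -> strength
    strength: float
    age: int = 0


class MemoryStore:
    """Ordered trace list, most recent first (k = 1)."""

    def __init__(self, params: ModelParams) -> None:
        self.p = params
        self.traces: list = []

    def store(self, f: np.ndarray, s: np.ndarray, a: np.ndarray,
              bindings: dict, xi_er: int) -> None:
        """Write a new episode; every existing trace shifts one recency rank.

        The initial strength is scaled by the retrieval semaphore: with
        ``xi_er = 0`` nothing is stored at all.
        """
        e0 = self.p.e_hat * xi_er
        if e0 <= 0.0:
            return
        self.traces.insert(0, EpisodeTrace(
            f=f.copy(), s=s.copy(), a=a.copy(), bindings=dict(bindings), strength=e0,
        ))
        del self.traces[self.p.memory_capacity:]

    def decay(self) -> None:
        for tr in self.traces:
            tr.strength -= self.p.delta_e * tr.strength
            tr.age += 1


def retrieval_strengths(f: np.ndarray, percept_tuples: list,
                        percept_bindings: list, traces: list,
                        n_features_relevant: int,
                        params: ModelParams) -> list:
    """Similarity of the current percept to each stored episode.

    ``percept_tuples`` are the feature tuples of the objects held by the n
    strongest bindings and ``percept_bindings`` their current strengths.
    The significance of the percept (supra-baseline activation per relevant
    feature dimension; the baseline is the model's virtual zero, so a
    percept at rest carries no significance) multiplies the mean inverse
    per-object mismatch between current and stored feature/binding values.
    The per-object form lets one closely matching object trigger retrieval
    even next to an entirely new one; ``epsilon_r`` regularises the
    reciprocal so an exact repeat yields a large but finite strength.
    """
    if not percept_tuples or not traces:
        return [0.0] * len(traces)
    base = params.F_check
    perceived = {i for tup in percept_tuples for i in tup}
    significance = 0.0
    for i in perceived:
        significance += f[i] - base
    significance /= n_features_relevant
    if significance <= 0.0:
        return [0.0] * len(traces)
    inv_b_hat = 1.0 / params.b_hat
    eps = params.epsilon_r
    n_obj = len(percept_tuples)
    out = []
    for tr in traces:
        tf = tr.f
        inv_mismatch = 0.0
        for tup, b in zip(percept_tuples, percept_bindings):
            mismatch = abs(b - tr.bindings.get(tup, 0.0)) * inv_b_hat
            for i in tup:
                mismatch += abs(f[i] - tf[i])
            inv_mismatch += 1.0 / (mismatch + eps)
        out.append(significance * inv_mismatch / n_obj)
    return out


def retrieval_strength(f: np.ndarray, percept_tuples: list, percept_bindings: list,
                       trace: EpisodeTrace, n_features_relevant: int,
                       params: ModelParams) -> float:
    """Similarity of the current percept to one stored episode."""
    return retrieval_strengths(f, percept_tuples, percept_bindings, [trace],
                               n_features_relevant, params)[0]


@dataclass
class DiscriminationState:
    """Prototype similarity level d and shrinking uncertainty half-width u."""

    p: ModelParams
    d: float = 0.0
    u: float = 0.0
    active: bool = field(default=False)

    def onset(self) -> None:
        self.d = self.p.d_check
        self.u = self.p.u_check
        self.active = True

    def step(self) -> None:
        if self.active:
            self.d += self.p.tau_d * (self.p.d_hat - self.d)
            self.u -= self.p.tau_u * self.u

    def offset(self) -> None:
        self.d = 0.0
        self.u = 0.0
        self.active = False


def old_new_signal(r_k: float, disc: DiscriminationState) -> float:
    """Three-valued classification of one trace against the prototype band.

    Returns 0 (*old*: similarity above the band — the blocking variable is
    driven toward 0, closing the direct channels and boosting retrieval),
    1 (*new*: below the band) or 1/2 (not yet classified).
    """
    if r_k > disc.d + disc.u:
        return 0.0
    if r_k < disc.d - disc.u:
        return 1.0
    return 0.5
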