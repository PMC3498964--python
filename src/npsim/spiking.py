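"""Recurrent integrate-and-fire network justifying the exponential abstraction.

A cluster of all-to-all coupled integrate-and-fire neurons receives noisy
external input during a stimulus window.  Averaged over many trials, the
population firing rate rises toward its maximum and decays back with
approximately exponential time courses; the per-step relative change of the
trial-averaged rate (toward the current fixed point) estimates the
effective time constants that motivate the one-variable exponential
dynamics used everywhere else in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import ConfigurationError

__all__ = [
    "IFNetworkConfig",
    "RateTrace",
    "simulate_if_network",
    "estimate_time_constants",
    "membrane_histogram",
]


@dataclass(frozen=True)
class IFNetworkConfig:
    n_neurons: int = 1000
    theta: float = 1.0            # firing threshold
    h0: float = 0.0               # resting potential
    total_out: float = 0.87       # column sum of the synaptic weight matrix
    steps_per_second: int = 50
    stimulus_steps: int = 50      # 1 s of stimulation
    gap_steps: int = 50           # 1 s inter-stimulus interval
    input_sd_fraction: float = 0.5  # input SD as a fraction of the mean
    trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ConfigurationError("need at least two neurons")
        if self.total_out >= 1.0:
            warnings.warn(
                f"total synaptic output {self.total_out} >= 1: runaway regime",
                RuntimeWarning, stacklevel=2)

    @property
    def input_mean(self) -> float:
        """Mean external input per step: over the stimulus window a neuron
        receives on average exactly threshold minus resting potential, so
        without coupling it fires once per stimulus."""
        if self.stimulus_steps == 0:
            return 0.0
        return (self.theta - self.h0) / self.stimulus_steps


@dataclass
class RateTrace:
    """Trial-averaged per-step spike counts, normalised at stimulus offset."""

    rate: np.ndarray              # normalised rate per step
    raw_rate: np.ndarray          # mean spikes per neuron per step
    rise_tau: float               # mean relative change toward 1 during input
    decay_tau: float              # mean relative change toward 0 after input
    rise_changes: np.ndarray = field(repr=False, default=None)
    decay_changes: np.ndarray = field(repr=False, default=None)


def _make_weights(rng: np.random.Generator, n: int, total_out: float) -> np.ndarray:
    """Nonnegative weights with every column summing to ``total_out``."""
    w = rng.uniform(0.0, 1.0, size=(n, n))
    np.fill_diagonal(w, 0.0)
    return w * (total_out / w.sum(axis=0, keepdims=True))


def simulate_if_network(config: IFNetworkConfig,
                        record_potentials: int = 0) -> dict:
    """Simulate the network; returns per-step spike counts per trial.

    Returns a dict with ``spikes`` (trials x steps array of population
    spike counts) and, if ``record_potentials`` > 0, ``potentials``
    (that many trials x steps x neurons of membrane potentials).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    steps = config.stimulus_steps + config.gap_steps
    w = _make_weights(rng, n, config.total_out)
    spikes = np.zeros((config.trials, steps), dtype=np.int64)
    potentials = (np.zeros((record_potentials, steps, n), dtype=np.float32)
                  if record_potentials else None)
    mean, sd = config.input_mean, config.input_mean * config.input_sd_fraction
    for trial in range(config.trials):
        # desynchronised start: potentials uniform between rest and threshold,
        # so the accumulated input of one stimulus window yields on average
        # exactly one threshold crossing per neuron without coupling
        if config.stimulus_steps > 0:
            h = rng.uniform(config.h0, config.theta, size=n)
        else:
            h = np.full(n, config.h0, dtype=float)
        for t in range(steps):
            if t < config.stimulus_steps:
                h += rng.normal(mean, sd, size=n)
            fired = h >= config.theta
            # spikes propagate through the recurrent weights; the spiking
            # neurons are reset by the threshold value
            if fired.any():
                h += w @ fired.astype(float)
                h[fired] -= config.theta
            spikes[trial, t] = int(fired.sum())
            if potentials is not None and trial < record_potentials:
                potentials[trial, t] = h
    out = {"spikes": spikes}
    if potentials is not None:
        out["potentials"] = potentials
    return out


def estimate_time_constants(spikes: np.ndarray, config: IFNetworkConfig) -> RateTrace:
    """Average the raster over trials and extract effective time constants.

    The rate is normalised by its value at the last stimulated step; the
    relative change toward the fixed point (1 during input, 0 after) is
    averaged over the rise window (after onset transients) and the decay
    window.
    """
    raw = spikes.mean(axis=0) / config.n_neurons
    offset_idx = config.stimulus_steps - 1
    norm = raw[offset_idx]
    if norm <= 0.0:
        raise ConfigurationError("no spikes at stimulus offset: cannot normalise")
    rate = raw / norm

    # relative change toward the current fixed point:
    # rise: (f_{n+1} - f_n) / (1 - f_n); decay: (f_{n+1} - f_n) / (0 - f_n)
    # the relative change is ill-conditioned where the distance to the
    # fixed point is small, so both windows keep a 5% floor
    rise, decay = [], []
    for t in range(1, config.stimulus_steps - 1):
        gap = 1.0 - rate[t]
        if gap > 0.05:
            rise.append((rate[t + 1] - rate[t]) / gap)
    for t in range(config.stimulus_steps, len(rate) - 1):
        if rate[t] > 0.05:
            decay.append((rate[t] - rate[t + 1]) / rate[t])
    if not decay:
        raise ConfigurationError("rate trace too sparse to estimate time constants")
    rise = np.asarray(rise) if rise else np.array([])
    decay = np.asarray(decay)
    return RateTrace(
        rate=rate, raw_rate=raw,
        rise_tau=float(rise.mean()) if rise.size else float("nan"),
        decay_tau=float(decay.mean()),
        rise_changes=rise, decay_changes=decay,
    )


def exponential_fit_r2(rate: np.ndarray, config: IFNetworkConfig) -> tuple:
    """R-squared of single-exponential fits to the rise and decay windows.

    Both fits are log-linear on the distance to the fixed point and, like
    the time-constant estimator, keep a 5% floor on that distance: the log
    of a vanishing gap amplifies trial-count noise without bound.
    """
    t_on = np.arange(1, config.stimulus_steps)
    gap_on = 1.0 - rate[1:config.stimulus_steps]
    mask_on = gap_on > 0.05
    r2_rise = _loglinear_r2(t_on[mask_on], gap_on[mask_on])
    t_off = np.arange(config.stimulus_steps, len(rate))
    y_off = rate[config.stimulus_steps:]
    mask_off = y_off > 0.05
    r2_decay = _loglinear_r2(t_off[mask_off], y_off[mask_off])
    return r2_rise, r2_decay


def _loglinear_r2(t: np.ndarray, y: np.ndarray) -> float:
    mask = y > 1e-8
    t, ly = t[mask], np.log(y[mask])
    if t.size < 3:
        raise ConfigurationError("too few points for an exponential fit")
    coef = np.polyfit(t, ly, 1)
    pred = np.polyval(coef, t)
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def membrane_histogram(potentials: np.ndarray, bins: int = 50,
                       v_range: tuple = (-0.5, 1.5)) -> dict:
    """Per-step occupancy histogram of membrane potentials.

    Returns ``hist`` (steps x bins, rows normalised to 1) and ``edges``.
    During input, few neurons sit just above the post-spike reset level —
    the depletion band visible in the full network simulation.
    """
    if potentials.ndim != 3:
        raise ConfigurationError("expected trials x steps x neurons potentials")
    steps = potentials.shape[1]
    hist = np.zeros((steps, bins))
    edges = np.linspace(v_range[0], v_range[1], bins + 1)
    for t in range(steps):
        h, _ = np.histogram(potentials[:, t, :].ravel(), bins=edges)
        total = h.sum()
        hist[t] = h / total if total else 0.0
    return {"hist": hist, "edges": edges}
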