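"""Trial execution, reaction-time statistics, priming effects and fitting.

A trial presents a display, steps the engine until a unique non-``a0``
action becomes suprathreshold (or a timeout), records RT = decision latency
plus the motor constant, stores the episode, and lets the state evolve
through the afterimage and the response–stimulus interval.  Experiments
aggregate per-condition means and report effects as control minus
condition (positive = faster than control).  The fitting harness wraps a
projected finite-difference gradient descent around the word-picture
comparison task.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import ConfigurationError
from .engine import Simulator
from .executive import Display, Paradigm, TheoryWeights, build_paradigm
from .params import ModelParams

__all__ = [
    "TrialResult",
    "ExperimentResult",
    "run_trial",
    "run_experiment",
    "compute_effects",
    "FitSpec",
    "FitResult",
    "fit_parameters",
    "simulate_word_picture_quantities",
    "default_fit_spec",
]


@dataclass
class TrialResult:
    rt: Optional[float]          # ms; None on omission
    response: Optional[str]
    condition: Optional[str]
    correct: bool
    omission: bool
    mean_retrieval: Optional[float] = None       # mean r_1 during the display
    classification_latency: Optional[int] = None  # steps to first old/new verdict


@dataclass
class ExperimentResult:
    trials: list
    summary: pd.DataFrame        # per-condition mean, sd, n
    effects: dict                # condition -> CO mean - condition mean (ms)

    def mean_rt(self, condition: str) -> float:
        return float(self.summary.loc[condition, "mean_rt"])


def run_trial(sim: Simulator, display: Display,
              truncate: bool = False) -> TrialResult:
    """Run one trial to its response (or timeout) and through the RSI.

    With ``truncate`` the trial stops right after the decision (the
    simulator state is then not valid for further trials) — used when only
    the RT of a final probe is needed.
    """
    p = sim.p
    sim.set_display(display)
    onset = sim.t
    deadline = onset + p.timeout
    r_sum, r_n = 0.0, 0
    latency: Optional[int] = None
    while not sim.responded and sim.t < deadline:
        sim.step()
        if sim.last_r and sim.disc.active:
            r_sum += sim.last_r[0]
            r_n += 1
            if latency is None and sim.last_o != 0.5:
                latency = sim.t - onset
    omission = not sim.responded
    rt = None
    response = None
    if omission:
        sim.mark_offset()
    else:
        rt = float(sim.decision_step - onset + p.t_motor)
        response = sim.response_label
    if not truncate:
        offset = sim.offset
        while sim.t < offset + p.t_afterimage + 1:
            sim.step()
        sim.clear_display()
        for _ in range(p.rsi):
            sim.step()

    if sim.paradigm.kind == "comparison":
        expected = display.correct_response
    else:
        expected = f"name:{display.target.label('shape')}"
    return TrialResult(
        rt=rt,
        response=response,
        condition=display.condition,
        correct=(response == expected),
        omission=omission,
        mean_retrieval=(r_sum / r_n) if r_n else None,
        classification_latency=latency,
    )


def run_experiment(sequence: Sequence[Display], paradigm: Paradigm,
                   theory: TheoryWeights, params: ModelParams) -> ExperimentResult:
    """Run a continuous display sequence and aggregate per-condition RTs."""
    sim = Simulator(paradigm, theory, params)
    trials = [run_trial(sim, disp) for disp in sequence]
    rows = [
        {"condition": tr.condition, "rt": tr.rt}
        for tr in trials
        if tr.condition is not None and not tr.omission
    ]
    if not rows:
        raise ConfigurationError("no classified, responded trials to aggregate")
    df = pd.DataFrame(rows)
    summary = df.groupby("condition")["rt"].agg(
        mean_rt="mean", sd_rt="std", n="count")
    if summary.shape[0] < 2:
        raise ConfigurationError("need at least two conditions for priming statistics")
    means = summary["mean_rt"].to_dict()
    effects = compute_effects(means)
    return ExperimentResult(trials=trials, summary=summary, effects=effects)


def compute_effects(means: dict) -> dict:
    """Priming effects: control mean RT minus condition mean RT (ms).

    For response-relation-suffixed labels (comparison task) each condition
    is referenced to the control cell of the same relation (COs / COr).
    """
    effects = {}
    for cond, m in means.items():
        if cond in ("CO", "COs", "COr"):
            continue
        base = "CO" + cond[-1] if cond[-1] in ("s", "r") and cond[:-1] != "CO" else "CO"
        if base not in means:
            raise ConfigurationError(f"control condition {base!r} missing for {cond!r}")
        effects[cond] = means[base] - m
    return effects


# ----------------------------------------------------------------------
# word-picture fitting harness
# ----------------------------------------------------------------------

# Fixed object assignment for the deterministic prime/probe probes.  The
# prime display is always (tree | bus); probes realise each priming
# condition; "no" words are drawn from objects absent in both displays.
_PRIME = ("tree", "bus")
_PROBES = {"CO": ("ball", "book"), "DT": ("bus", "ball"), "TT": ("tree", "ball")}
_NO_WORD_PRIME = "bed"
_NO_WORD_PROBE = "bench"


def simulate_word_picture_quantities(theory: TheoryWeights, params: ModelParams,
                                     paradigm: Optional[Paradigm] = None) -> dict:
    """Simulated control RTs and priming effects of the comparison task.

    Returns {"COs", "COr": RT in ms; "DTs", "DTr", "TTs", "TTr": effects}.
    Each cell averages the two response polarities (yes/no) so that the
    response-relation factor is not confounded with a yes-bias.  An
    omission enters as the timeout latency (upper bound on the RT).
    """
    paradigm = paradigm or build_paradigm("word_picture")

    def prime_state(resp: str) -> Simulator:
        sim = Simulator(paradigm, theory, params)
        word = _PRIME[0] if resp == "yes" else _NO_WORD_PRIME
        run_trial(sim, paradigm.make_display(*_PRIME, word=word))
        return sim

    primed = {resp: prime_state(resp) for resp in ("yes", "no")}

    def probe_rt(prime_resp: str, cond: str, probe_resp: str) -> float:
        sim = copy.deepcopy(primed[prime_resp])
        t, d = _PROBES[cond]
        word = t if probe_resp == "yes" else _NO_WORD_PROBE
        res = run_trial(sim, paradigm.make_display(t, d, word=word), truncate=True)
        return res.rt if res.rt is not None else float(params.timeout + params.t_motor)

    cell = {}
    for cond in _PROBES:
        cell[cond + "s"] = 0.5 * (probe_rt("yes", cond, "no") + probe_rt("no", cond, "yes"))
        cell[cond + "r"] = 0.5 * (probe_rt("yes", cond, "yes") + probe_rt("no", cond, "no"))
    return {
        "COs": cell["COs"],
        "COr": cell["COr"],
        "DTs": cell["COs"] - cell["DTs"],
        "DTr": cell["COr"] - cell["DTr"],
        "TTs": cell["COs"] - cell["TTs"],
        "TTr": cell["COr"] - cell["TTr"],
    }


@dataclass
class FitSpec:
    """A fitting problem: free parameters, fixed theory weights, targets."""

    theory: TheoryWeights
    free: dict                    # name -> (init, lo, hi)
    targets: dict                 # quantity name -> empirical value
    base_params: ModelParams = field(default_factory=ModelParams)
    max_iter: int = 12
    fd_eps: float = 0.05          # finite-difference step in normalised coords
    init_step: float = 0.25       # initial descent step in normalised coords
    min_step: float = 1e-3
    seed: int = 0
    retries: int = 2
    tol: float = 1e-3             # stop when the RMSE improvement falls below

    def __post_init__(self) -> None:
        for name, (init, lo, hi) in self.free.items():
            if not (lo < hi) or not (lo <= init <= hi):
                raise ConfigurationError(f"bad bounds for {name}: {(init, lo, hi)}")
            if name not in ModelParams.field_names():
                raise ConfigurationError(f"unknown free parameter {name!r}")
        if any(not math.isfinite(v) for v in self.targets.values()):
            raise ConfigurationError("targets must be finite")


@dataclass
class FitResult:
    params: ModelParams
    rmse: float
    trace: list                   # (iteration, rmse) pairs
    n_evaluations: int
    converged: bool


def default_fit_spec(theory: TheoryWeights, targets: dict,
                     base_params: Optional[ModelParams] = None, **kw) -> FitSpec:
    """Free-parameter set for the comparison-task fit.

    Frees the selection slopes and the response-layer dynamics — the
    quantities that shape absolute RT level and the interaction of priming
    condition with response relation — around the fitted starting profile.
    """
    from .params import word_picture_profile
    base = base_params or word_picture_profile()
    free = {
        "alpha": (base.alpha, 0.0, 0.002),
        "k_inhibition": (base.k_inhibition, 0.0, 0.002),
        "rho_a": (base.rho_a, 0.0015, 0.01),
        "delta_a": (base.delta_a, 0.0005, 0.008),
        "nu_a_theta": (base.nu_a_theta, 0.35, 0.85),
        "nu_s_theta": (base.nu_s_theta, 0.25, 0.65),
    }
    return FitSpec(theory=theory, free=free, targets=targets, base_params=base, **kw)


def _rmse(sim_q: dict, targets: dict) -> float:
    errs = [sim_q[k] - v for k, v in targets.items()]
    return float(np.sqrt(np.mean(np.square(errs))))


def fit_parameters(fit: FitSpec, paradigm: Optional[Paradigm] = None) -> FitResult:
    """Projected finite-difference gradient descent with backtracking.

    Deterministic given the spec (seed only perturbs restart jitter).
    Divergent evaluations (non-finite loss) trigger a jittered restart up
    to the retry budget.
    """
    paradigm = paradigm or build_paradigm("word_picture")
    names = list(fit.free)
    lo = np.array([fit.free[n][1] for n in names])
    hi = np.array([fit.free[n][2] for n in names])
    x_init = (np.array([fit.free[n][0] for n in names]) - lo) / (hi - lo)
    rng = np.random.default_rng(fit.seed)
    n_eval = 0

    def loss(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        values = lo + np.clip(x, 0.0, 1.0) * (hi - lo)
        try:
            params = fit.base_params.replace(**dict(zip(names, values)))
            q = simulate_word_picture_quantities(fit.theory, params, paradigm)
            return _rmse(q, fit.targets)
        except (ConfigurationError, FloatingPointError, OverflowError):
            return float("nan")

    best_x, best_loss, best_trace = None, float("inf"), []
    for attempt in range(fit.retries + 1):
        # first attempt descends from the configured starting profile;
        # later attempts restart from seeded points across the bounds, as
        # the RT surface has several basins separated by decision-channel
        # switches
        if attempt == 0:
            x = x_init.copy()
        else:
            x = rng.uniform(0.0, 1.0, len(names))
        cur = loss(x)
        if not math.isfinite(cur):
            continue
        trace = [(0, cur)]
        step = fit.init_step
        converged = False
        for it in range(1, fit.max_iter + 1):
            if cur <= fit.tol:
                converged = True
                break
            grad = np.zeros(len(names))
            probes = []
            for i in range(len(names)):
                xe = x.copy()
                eps = fit.fd_eps if x[i] + fit.fd_eps <= 1.0 else -fit.fd_eps
                xe[i] += eps
                le = loss(xe)
                grad[i] = (le - cur) / eps if math.isfinite(le) else 0.0
                probes.append((le, xe))
            gnorm = float(np.linalg.norm(grad))
            if gnorm == 0.0:
                converged = True
                break
            direction = -grad / gnorm
            # backtracking line search, restarted from a healthy step each
            # iteration so one bad direction does not end the descent
            improved = False
            step = max(step, fit.init_step / 4)
            while step >= fit.min_step:
                cand = np.clip(x + step * direction, 0.0, 1.0)
                lc = loss(cand)
                if math.isfinite(lc) and lc < cur - fit.tol:
                    x, cur = cand, lc
                    improved = True
                    step *= 1.3
                    break
                step *= 0.5
            if not improved:
                # coordinate fallback: the finite-difference probes (and
                # their mirrors) may still contain a descent move even when
                # the combined gradient direction does not
                for i in range(len(names)):
                    xe = x.copy()
                    eps = fit.fd_eps if x[i] - fit.fd_eps >= 0.0 else -fit.fd_eps
                    xe[i] -= eps
                    probes.append((loss(xe), xe))
                best_probe = min(probes, key=lambda p: p[0] if math.isfinite(p[0]) else float("inf"))
                if math.isfinite(best_probe[0]) and best_probe[0] < cur - fit.tol:
                    cur, x = best_probe[0], best_probe[1]
                    improved = True
                    step = fit.init_step / 2
            trace.append((it, cur))
            if not improved:
                converged = True
                break
        if cur < best_loss:
            best_x, best_loss, best_trace = x, cur, trace
            best_converged = converged
    if best_x is None:
        raise ConfigurationError("fit diverged on every restart attempt")
    values = lo + best_x * (hi - lo)
    return FitResult(
        params=fit.base_params.replace(**dict(zip(names, values))),
        rmse=best_loss,
        trace=best_trace,
        n_evaluations=n_eval,
        converged=best_converged,
    )
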