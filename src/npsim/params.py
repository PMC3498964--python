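"""The full model parameter set.

All layer time constants, selection slopes, gating depths, memory constants
and trial timing live in one flat dataclass so that configuration files,
fitting and provenance echoes all speak the same vocabulary.  Defaults are
the published voicekey naming-task profile; :func:`word_picture_profile`
returns the fitted comparison-task variant.

Units: rates are per step (1 step = 1 ms), times are steps, activations are
dimensionless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .dynamics import ConfigurationError

__all__ = ["ModelParams", "voicekey_profile", "word_picture_profile"]

# Parameters whose values are (0,1) per-step gains.
_RATE_FIELDS = (
    "rho_f", "delta_f", "rho_b", "delta_b", "rho_s", "delta_s",
    "rho_a", "delta_a", "tau_s_theta", "tau_a_theta", "delta_e",
    "tau_block", "tau_d", "tau_u",
)


@dataclass
class ModelParams:
    # -- selection signals -------------------------------------------------
    alpha: float = 0.0005          # target amplification slope (per step)
    k_inhibition: float = 0.0005   # distractor inhibition slope; defaults to alpha

    # -- feature layers ----------------------------------------------------
    F_hat: float = 2.0             # input while a feature is shown: one unit above baseline
    F_check: float = 1.0           # baseline input / virtual zero
    rho_f: float = 0.01
    delta_f: float = 0.003
    beta: float = 0.00155          # within-dimension broadening rate (active iff xi_gt)
    phi: float = 0.00011           # forced-decay rate after display change (active iff xi_gt)
    iota: float = 0.000001         # reserved constant from the fitted profile; inert

    # -- feature bindings --------------------------------------------------
    b_hat: float = 0.05            # maximum binding strength
    n_binding_slots: int = 7       # binding capacity (#b)
    rho_b: float = 0.008
    delta_b: float = 0.005

    # -- semantic layer ----------------------------------------------------
    rho_s: float = 0.01            # defaults mirror the feature rates
    delta_s: float = 0.003
    tau_s_theta: float = 0.002
    nu_s_theta: float = 0.51

    # -- channel gains (semantic drive / action drive) ---------------------
    sigma_shape_s: float = 0.1     # shape -> semantic channel gain
    sigma_word_s: float = 0.0      # word -> semantic channel gain (comparison task only)
    sigma_s_a: float = 1.2         # semantic -> action drive gain
    s_margin: float = 0.026        # semantic lead at which action drive saturates
    f_gate: float = 1.5            # perceptual floor of the semantic gating function S(f)

    # -- action layer ------------------------------------------------------
    rho_a: float = 0.004
    delta_a: float = 0.002
    tau_a_theta: float = 0.002
    nu_a_theta: float = 0.5

    # -- episodic memory ---------------------------------------------------
    e_hat: float = 0.002           # initial trace strength
    delta_e: float = 0.003         # trace decay rate
    memory_capacity: int = 3
    epsilon_r: float = 0.2         # regulariser of the similarity reciprocal

    # -- connectivity gating (temporal-discrimination machinery) -----------
    sigma_check_fs: float = 0.2    # modulation depth features -> semantic
    sigma_check_fsa: float = 0.2   # modulation depth features/semantic -> action
    tau_block: float = 0.01

    # -- old/new discrimination prototype ----------------------------------
    d_check: float = 0.05          # prototype similarity at display onset
    d_hat: float = 1.2             # prototype asymptote
    tau_d: float = 0.01
    u_check: float = 1.0           # uncertainty half-width at onset
    tau_u: float = 0.012

    # -- trial timing ------------------------------------------------------
    t_recognition: int = 50
    t_afterimage: int = 30
    t_motor: int = 80
    rsi: int = 1400                # response-stimulus interval (blank, steps)
    timeout: int = 3000            # maximal display duration before an omission

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1); got {v}")
        if self.alpha < 0 or self.k_inhibition < 0:
            raise ConfigurationError("selection slopes must be nonnegative")
        if self.F_check > self.F_hat:
            raise ConfigurationError("baseline F_check must not exceed unit input F_hat")
        if self.n_binding_slots < 1 or self.memory_capacity < 1:
            raise ConfigurationError("capacities must be >= 1")
        if not (0.0 <= self.sigma_check_fs <= 1.0 and 0.0 <= self.sigma_check_fsa <= 1.0):
            raise ConfigurationError("gate modulation depths must lie in [0, 1]")
        if self.b_hat <= 0 or self.e_hat < 0 or self.epsilon_r <= 0:
            raise ConfigurationError("b_hat, epsilon_r must be positive, e_hat nonnegative")
        for name in ("t_recognition", "t_afterimage", "t_motor", "rsi", "timeout"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in dataclasses.fields(cls))


def voicekey_profile() -> ModelParams:
    """Published parameter list of the voicekey naming-task run."""
    return ModelParams()


def word_picture_profile() -> ModelParams:
    """Fitted parameter list of the word-picture comparison run."""
    return ModelParams(
        rho_f=0.009,
        rho_b=0.0096,
        nu_s_theta=0.4131,
        sigma_shape_s=0.1,
        sigma_word_s=0.12,
        sigma_s_a=1.0,
        rho_a=0.0036,
        nu_a_theta=0.6,
        beta=0.00155,
        phi=0.00011,
        s_margin=0.05,
        rsi=1200,
    )
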