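"""Configuration loading, validation, provenance echo and result writing.

A run configuration is a flat JSON object: a paradigm name, either a
theory preset name or an explicit semaphore vector, any subset of model
parameters (defaults come from the shipped paradigm profile), a sequence
specification and an output directory.  Unknown keys are rejected by name;
every echoed configuration can be re-loaded to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

from .dynamics import ConfigurationError
from .executive import CONDITIONS, TheoryWeights, theory_preset
from .params import ModelParams, voicekey_profile, word_picture_profile

__all__ = ["RunConfig", "load_config", "write_results", "default_profile"]

_XI_KEYS = ("xi_er", "xi_rr", "xi_ib", "xi_gt", "xi_fsb", "xi_sab", "xi_td")
_SEQ_KEYS = ("conditions", "n_per_condition", "seed")
_TOP_KEYS = {"paradigm", "theory", "sequence", "out_dir"} | set(_XI_KEYS)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_RUNTIME_ERROR = 3


def default_profile(paradigm: str) -> ModelParams:
    if paradigm == "voicekey":
        return voicekey_profile()
    if paradigm == "word_picture":
        return word_picture_profile()
    raise ConfigurationError(f"unknown paradigm {paradigm!r}")


@dataclass
class RunConfig:
    paradigm: str = "voicekey"
    theory: str | None = "episodic_retrieval"
    weights: TheoryWeights = field(default_factory=lambda: theory_preset("episodic_retrieval"))
    params: ModelParams = field(default_factory=voicekey_profile)
    conditions: tuple = ("CO", "DT", "TT", "TD", "DD")
    n_per_condition: int = 20
    seed: int = 1
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = {
            "paradigm": self.paradigm,
            "theory": self.theory,
            "sequence": {
                "conditions": list(self.conditions),
                "n_per_condition": self.n_per_condition,
                "seed": self.seed,
            },
            "out_dir": self.out_dir,
        }
        d.update(self.weights.as_dict())
        d.update(self.params.to_dict())
        return d


def _from_mapping(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigurationError("configuration must be a JSON object")
    param_names = set(ModelParams.field_names())
    unknown = set(data) - _TOP_KEYS - param_names
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}")

    paradigm = data.get("paradigm", "voicekey")
    base = default_profile(paradigm)

    overrides = {}
    for name in param_names & set(data):
        value = data[name]
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigurationError(f"parameter {name!r} must be a number")
        overrides[name] = type(getattr(base, name))(value)
    params = base.replace(**overrides)  # re-validates ranges

    theory_name = data.get("theory")
    if theory_name is not None:
        weights = theory_preset(theory_name)
        explicit = {k: data[k] for k in _XI_KEYS if k in data}
        if explicit:
            weights = TheoryWeights(**{**weights.as_dict(), **explicit})
    else:
        weights = TheoryWeights(**{k: data.get(k, 0) for k in _XI_KEYS})

    seq = data.get("sequence", {})
    if not isinstance(seq, dict) or set(seq) - set(_SEQ_KEYS):
        raise ConfigurationError(
            f"sequence must be an object with keys among {_SEQ_KEYS}")
    conditions = tuple(seq.get("conditions", ("CO", "DT", "TT", "TD", "DD")))
    for c in conditions:
        stem = c[:-1] if c[-1:] in ("s", "r") and c[:-1] in CONDITIONS else c
        if stem not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {c!r}")
    return RunConfig(
        paradigm=paradigm,
        theory=theory_name,
        weights=weights,
        params=params,
        conditions=conditions,
        n_per_condition=int(seq.get("n_per_condition", 20)),
        seed=int(seq.get("seed", 1)),
        out_dir=str(data.get("out_dir", "results")),
    )


def load_config(path: str | None = None, data: Optional[dict] = None) -> RunConfig:
    """Load and validate a run configuration from a JSON file (or mapping)."""
    if data is None:
        if path is None:
            raise ConfigurationError("either a path or a mapping is required")
        try:
            with open(path) as fh:
                data = json.load(fh)
        except FileNotFoundError:
            raise ConfigurationError(f"configuration file not found: {path}") from None
        except json.JSONDecodeError as err:
            raise ConfigurationError(f"invalid JSON in {path}: {err}") from None
    return _from_mapping(data)


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.12g}"
    return str(x)


def write_results(result, config: RunConfig, outdir: str,
                  force: bool = False) -> list:
    """Write trial/summary/effects TSVs plus the resolved config echo.

    Returns the manifest of written paths.  Refuses to overwrite an
    existing results directory unless ``force`` is set.
    """
    import pandas as pd

    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise ConfigurationError(
            f"output directory {outdir!r} is not empty (use force to overwrite)")
    os.makedirs(outdir, exist_ok=True)
    manifest = []

    def path(name):
        p = os.path.join(outdir, name)
        manifest.append(p)
        return p

    rows = []
    for i, tr in enumerate(result.trials):
        rows.append({
            "trial": i,
            "condition": tr.condition or "lead-in",
            "rt_ms": _fmt(tr.rt) if tr.rt is not None else "NA",
            "response": tr.response or "NA",
            "correct": int(tr.correct),
            "omission": int(tr.omission),
            "mean_retrieval": _fmt(tr.mean_retrieval) if tr.mean_retrieval is not None else "NA",
        })
    pd.DataFrame(rows).to_csv(path("trials.tsv"), sep="\t", index=False)

    summary = result.summary.reset_index()
    summary.to_csv(path("summary.tsv"), sep="\t", index=False,
                   float_format="%.12g")
    eff = pd.DataFrame(
        [{"condition": c, "effect_ms": v} for c, v in sorted(result.effects.items())])
    eff.to_csv(path("effects.tsv"), sep="\t", index=False, float_format="%.12g")

    with open(path("config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
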