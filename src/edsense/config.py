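"""Key-value configuration files for the engine.

A config file is a flat JSON object; unknown keys are rejected so typos
fail loudly.  Example::

    {
      "p_retain": 0.9, "p_acquire": 0.1,
      "slip": 0.1, "guess": 0.2, "hint_discount": 1.0,
      "memory": 5, "damping": 0.5,
      "adapt_amount": 0.1, "semantics": "mastery_advance",
      "mastery_stop": 0.95, "consecutive_stop": 2, "step_cap": 500,
      "init_PLT": 0.0, "init_PUT": 1.0
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .controller import ControllerConfig
from .student_model import DEFAULT_MEMORY, EmissionParams, TransitionParams

_TRANSITION_KEYS = {"p_retain", "p_acquire"}
_EMISSION_KEYS = {"slip", "guess", "hint_discount"}
_CONTROLLER_KEYS = {"adapt_amount", "semantics", "mastery_stop",
                    "consecutive_stop", "step_cap", "init_PLT", "init_PUT"}
_ENGINE_KEYS = {"memory", "damping"}


@dataclass(frozen=True)
class EngineConfig:
    """Everything tunable in one place: student-model parameters,
    belief-window length, propagation damping, controller policy."""

    controller: ControllerConfig = ControllerConfig()
    memory: int = DEFAULT_MEMORY
    damping: float = 0.5


def load_engine_config(text: str) -> EngineConfig:
    doc = json.loads(text)
    if not isinstance(doc, dict):
        raise ValueError("config must be a JSON object")
    unknown = set(doc) - _TRANSITION_KEYS - _EMISSION_KEYS \
        - _CONTROLLER_KEYS - _ENGINE_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    tparams = TransitionParams(**{k: doc[k] for k in _TRANSITION_KEYS if k in doc})
    eparams = EmissionParams(**{k: doc[k] for k in _EMISSION_KEYS if k in doc})
    controller = ControllerConfig(
        transition=tparams, emission=eparams,
        **{k: doc[k] for k in _CONTROLLER_KEYS if k in doc})
    return EngineConfig(controller=controller,
                        memory=int(doc.get("memory", DEFAULT_MEMORY)),
                        damping=float(doc.get("damping", 0.5)))
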