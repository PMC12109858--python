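"""Knowledge tracing with a windowed dynamic-Bayesian-network forward pass.

Each skill carries a latent binary mastery state K_t (learned /
unlearned).  Between practice steps the state evolves with retention
probability ``p_retain`` (P(K_t=1 | K_{t-1}=1), default 0.9) and
acquisition probability ``p_acquire`` (P(K_t=1 | K_{t-1}=0), default
0.1).  Observed evidence at each step — hint count H, attempts A,
correct answers C, wrong answers W, and specific (diagnostically
recognizable) wrong answers SW — enters through a slip/guess emission
model: a mastered learner answers correctly with probability 1−slip, an
unmastered one with probability guess.

Posteriors start at the maximum-entropy prior 0.5 and are recomputed by
a sum-product forward recursion over a bounded window of the most
recent observations (a "memory of five" by default): when an
observation falls out of the window, the recursion is re-anchored at
the 0.5 prior over the retained window only.  On a chain this forward
filtering is exact, i.e. identical to marginalizing over every latent
mastery path through the window.
"""

from __future__ import annotations

import json

from collections import deque
from dataclasses import dataclass, field

from .skill_graph import SkillGraph, precursors, successors

DEFAULT_MEMORY = 5
MAX_ENTROPY_PRIOR = 0.5


@dataclass(frozen=True)
class Observation:
    """Evidence from one practice step on one skill.

    ``SW`` counts wrong answers that match a recognizable dyscalculia
    error pattern; it is a subset of ``W`` (SW <= W), and C + W cannot
    exceed the number of attempts A.
    """

    skill_id: str
    H: int = 0
    A: int = 1
    C: int = 0
    W: int = 0
    SW: int = 0
    response_time: float = 0.0

    def __post_init__(self) -> None:
        if min(self.H, self.C, self.W, self.SW) < 0 or self.A < 1:
            raise ValueError("counts must be non-negative and A >= 1")
        if self.SW > self.W:
            raise ValueError("SW must not exceed W")
        if self.C + self.W > self.A:
            raise ValueError("C + W must not exceed A")
        if self.response_time < 0:
            raise ValueError("response_time must be >= 0")

    def to_dict(self) -> dict:
        return {"skill_id": self.skill_id, "H": self.H, "A": self.A,
                "C": self.C, "W": self.W, "SW": self.SW,
                "response_time": self.response_time}

    @classmethod
    def from_dict(cls, d: dict) -> "Observation":
        return cls(**d)


@dataclass(frozen=True)
class TransitionParams:
    """Per-step mastery dynamics: P(K_t=1|K_{t-1}=1) and P(K_t=1|K_{t-1}=0)."""

    p_retain: float = 0.9
    p_acquire: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.p_retain, self.p_acquire):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class EmissionParams:
    """Slip/guess response model.

    ``hint_discount`` < 1 shrinks the evidential weight of each correct
    answer by that factor per hint received (hinted successes say less
    about mastery); 1.0 disables the discount.
    """

    slip: float = 0.10
    guess: float = 0.20
    hint_discount: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.slip, self.guess):
            if not 0.0 < p < 1.0:
                raise ValueError("slip and guess must lie in (0, 1)")
        if not 0.0 <= self.hint_discount <= 1.0:
            raise ValueError("hint_discount must lie in [0, 1]")


@dataclass
class KnowledgeState:
    """Belief state of the tracer: per-skill posteriors plus the
    bounded observation windows they were computed from."""

    posteriors: dict[str, float] = field(default_factory=dict)
    windows: dict[str, deque] = field(default_factory=dict)
    last_message: dict[str, float] = field(default_factory=dict)
    memory: int = DEFAULT_MEMORY

    def copy(self) -> "KnowledgeState":
        return KnowledgeState(dict(self.posteriors),
                              {k: deque(v, maxlen=self.memory)
                               for k, v in self.windows.items()},
                              dict(self.last_message), self.memory)

    def to_json(self) -> str:
        return json.dumps({
            "memory": self.memory,
            "posteriors": self.posteriors,
            "last_message": self.last_message,
            "windows": {k: [o.to_dict() for o in v]
                        for k, v in self.windows.items()},
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KnowledgeState":
        doc = json.loads(text)
        memory = doc["memory"]
        return cls(posteriors=doc["posteriors"],
                   windows={k: deque((Observation.from_dict(d) for d in v),
                                     maxlen=memory)
                            for k, v in doc["windows"].items()},
                   last_message=doc["last_message"],
                   memory=memory)


def init_state(graph: SkillGraph, memory: int = DEFAULT_MEMORY) -> KnowledgeState:
    """Maximum-entropy initialization: every skill starts at P(K=1)=0.5."""
    return KnowledgeState(
        posteriors={sid: MAX_ENTROPY_PRIOR for sid in graph.ids()},
        windows={sid: deque(maxlen=memory) for sid in graph.ids()},
        last_message={},
        memory=memory)


def transition_message(prior: float, params: TransitionParams = TransitionParams()) -> float:
    """One time-slice of mastery dynamics:
    M = p_retain * prior + p_acquire * (1 - prior)."""
    if not 0.0 <= prior <= 1.0:
        raise ValueError(f"prior {prior} outside [0, 1]")
    return params.p_retain * prior + params.p_acquire * (1.0 - prior)


def emission_likelihood(obs: Observation, k: int,
                        params: EmissionParams = EmissionParams()) -> float:
    """P(observed C corrects and W wrongs | K=k) under slip/guess.

    Specific wrongs are counted inside W.  With ``hint_discount`` d < 1
    the effective correct count is C * d**H, pulling hinted successes
    toward uninformativeness.
    """
    if k not in (0, 1):
        raise ValueError("k must be 0 or 1")
    c_eff = obs.C * params.hint_discount ** obs.H
    if k == 1:
        return (1.0 - params.slip) ** c_eff * params.slip ** obs.W
    return params.guess ** c_eff * (1.0 - params.guess) ** obs.W


def forward_posterior(window, tparams: TransitionParams,
                      eparams: EmissionParams,
                      prior: float = MAX_ENTROPY_PRIOR) -> tuple[float, float]:
    """Sum-product forward recursion over an observation window.

    Returns (posterior, last transition message).  Each step computes
    the transition message M from the running posterior, multiplies the
    two mastery hypotheses by their emission likelihoods, and
    normalizes:  p' = e1*M / (e1*M + e0*(1-M)).
    """
    p = prior
    msg = transition_message(p, tparams)
    for obs in window:
        msg = transition_message(p, tparams)
        e1 = emission_likelihood(obs, 1, eparams)
        e0 = emission_likelihood(obs, 0, eparams)
        num = e1 * msg
        den = num + e0 * (1.0 - msg)
        p = num / den if den > 0 else msg
    return p, msg


def update_posterior(state: KnowledgeState, obs: Observation,
                     tparams: TransitionParams = TransitionParams(),
                     eparams: EmissionParams = EmissionParams()) -> KnowledgeState:
    """Absorb one observation and return the updated belief state.

    The observation joins the skill's bounded window; the posterior is
    the forward recursion re-run from the 0.5 prior over the retained
    window (equivalent to the incremental Bayes update until the window
    first overflows).
    """
    if obs.skill_id not in state.posteriors:
        raise KeyError(f"unknown skill {obs.skill_id!r}")
    new = state.copy()
    new.windows[obs.skill_id].append(obs)
    p, msg = forward_posterior(new.windows[obs.skill_id], tparams, eparams)
    new.posteriors[obs.skill_id] = p
    new.last_message[obs.skill_id] = msg
    return new


def propagate(graph: SkillGraph, state: KnowledgeState, skill_id: str,
              damping: float = 0.5) -> KnowledgeState:
    """Damped one-hop spread of evidence to graph neighbours.

    A strong posterior on a skill lifts its direct precursors (a learner
    who can add two-digit numbers can very likely add one-digit ones)
    and a weak posterior caps its direct successors.  This is a
    heuristic, not full belief propagation: each precursor moves to
    max(own, damping*p) and each successor to min(own, 1 - damping*(1-p)).
    """
    if not 0.0 <= damping <= 1.0:
        raise ValueError("damping must lie in [0, 1]")
    p = state.posteriors.get(skill_id)
    if p is None:
        raise KeyError(f"unknown skill {skill_id!r}")
    new = state.copy()
    for pre in precursors(graph, skill_id):
        new.posteriors[pre] = min(1.0, max(new.posteriors[pre], damping * p))
    for suc in successors(graph, skill_id):
        new.posteriors[suc] = max(0.0, min(new.posteriors[suc],
                                           1.0 - damping * (1.0 - p)))
    return new


def predict_correct(state: KnowledgeState, skill_id: str,
                    eparams: EmissionParams = EmissionParams()) -> float:
    """Predicted probability of a correct answer: p(1-slip) + (1-p)guess."""
    p = state.posteriors.get(skill_id)
    if p is None:
        raise KeyError(f"unknown skill {skill_id!r}")
    return p * (1.0 - eparams.slip) + (1.0 - p) * eparams.guess


# -- observation stream I/O -------------------------------------------------

def write_observations(stream) -> str:
    """Serialize observations to JSONL, one per line."""
    return "\n".join(json.dumps(o.to_dict()) for o in stream) + "\n"


def read_observations(text: str) -> list[Observation]:
    return [Observation.from_dict(json.loads(line))
            for line in text.splitlines() if line.strip()]
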