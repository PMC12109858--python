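"""Pedagogical control: choose the next task from mastery posteriors.

The controller walks the skill DAG starting at the easiest skill.  At
each step it compares the current skill's posterior with an adaptive
band [PLT, PUT] (posterior lower / upper threshold, initialized to
[0, 1]): a posterior above the band advances to a successor skill, one
below the band remediates to the precursor with the lowest mastery,
and an in-band posterior keeps practising the current skill.  Each
out-of-band event tightens the corresponding threshold by
``adapt_amount / n_samples``, so the band adapts quickly early in a
session and stabilizes as evidence accumulates.  A skill is retired
once its posterior stays at or above ``mastery_stop`` for
``consecutive_stop`` consecutive tasks; the session ends when the
final skill in topological order is retired (or a step cap is hit, in
which case the log is marked truncated).

Two branch semantics are available: ``mastery_advance`` (default;
high posterior advances, low posterior remediates) and ``as_printed``
(the transposed variant with the two branches swapped).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from . import arithmetic_domain as arith
from .skill_graph import SkillGraph, precursors, successors, topological_order
from .student_model import (EmissionParams, KnowledgeState, Observation,
                            TransitionParams, update_posterior)


class Action(enum.Enum):
    ADVANCE = "advance"
    STAY = "stay"
    REMEDIATE = "remediate"


@dataclass
class ControllerState:
    current_skill: str
    PLT: float = 0.0
    PUT: float = 1.0
    n_samples: int = 0
    training_level: str = "current"   # precursor | current | successor
    terminal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.PLT <= self.PUT <= 1.0:
            raise ValueError("thresholds must satisfy 0 <= PLT <= PUT <= 1")


@dataclass(frozen=True)
class ControllerConfig:
    adapt_amount: float = 0.1
    semantics: str = "mastery_advance"      # or "as_printed"
    mastery_stop: float = 0.95
    consecutive_stop: int = 2
    step_cap: int = 500
    init_PLT: float = 0.0
    init_PUT: float = 1.0
    transition: TransitionParams = TransitionParams()
    emission: EmissionParams = EmissionParams()

    def __post_init__(self) -> None:
        if self.adapt_amount <= 0:
            raise ValueError("adapt_amount must be > 0")
        if self.semantics not in ("mastery_advance", "as_printed"):
            raise ValueError(f"unknown semantics {self.semantics!r}")


class Decision(NamedTuple):
    action: Action
    target: str
    terminal: bool = False


def _best_successor(graph: SkillGraph, skill_id: str) -> str | None:
    succ = successors(graph, skill_id)
    if not succ:
        return None
    return min(succ, key=lambda s: (graph.skill(s).difficulty_rank, s))


def _weakest_precursor(graph: SkillGraph, skill_id: str,
                       posteriors: dict[str, float]) -> str | None:
    pre = precursors(graph, skill_id)
    if not pre:
        return None
    return min(pre, key=lambda s: (posteriors.get(s, 0.5), s))


def next_action(graph: SkillGraph, cstate: ControllerState,
                posteriors: dict[str, float],
                config: ControllerConfig = ControllerConfig()) -> Decision:
    """Pick the next move from the current skill's posterior.

    High posterior -> ADVANCE to the easiest direct successor; low ->
    REMEDIATE to the precursor with the lowest mastery posterior;
    in-band -> STAY.  At a leaf (no successor) or root (no precursor)
    the move degrades to STAY, with ``terminal`` flagged at a leaf.
    """
    skill = cstate.current_skill
    if skill not in posteriors:
        raise KeyError(f"no posterior for skill {skill!r}")
    p = posteriors[skill]
    if config.semantics == "mastery_advance":
        high, low = Action.ADVANCE, Action.REMEDIATE
    else:                              # literal pseudocode: branches swapped
        high, low = Action.REMEDIATE, Action.ADVANCE
    if p > cstate.PUT:
        chosen = high
    elif p < cstate.PLT:
        chosen = low
    else:
        return Decision(Action.STAY, skill)
    if chosen is Action.ADVANCE:
        target = _best_successor(graph, skill)
        if target is None:
            return Decision(Action.STAY, skill, terminal=True)
        return Decision(Action.ADVANCE, target)
    target = _weakest_precursor(graph, skill, posteriors)
    if target is None:
        return Decision(Action.STAY, skill)
    return Decision(Action.REMEDIATE, target)


def update_thresholds(cstate: ControllerState, event: str | None,
                      config: ControllerConfig = ControllerConfig()) -> ControllerState:
    """Adapt the band after an out-of-band event.

    ``event`` is "high" (posterior exceeded PUT), "low" (below PLT), or
    None (in-band; no change).  Steps shrink as adapt_amount/n_samples;
    n_samples is taken as at least 1 so the first adaptation is well
    defined.  The result is clamped to 0 <= PLT <= PUT <= 1.
    """
    if event is None:
        return cstate
    n = max(cstate.n_samples, 1)
    step = config.adapt_amount / n
    plt, put = cstate.PLT, cstate.PUT
    if event == "high":
        put = put - step
    elif event == "low":
        plt = plt + step
    else:
        raise ValueError(f"unknown event {event!r}")
    plt = min(max(plt, 0.0), 1.0)
    put = min(max(put, 0.0), 1.0)
    if plt > put:
        plt = put = (plt + put) / 2.0
    return replace(cstate, PLT=plt, PUT=put)


@dataclass
class SessionLog:
    """Time-ordered record of one tutoring session."""

    records: list[dict] = field(default_factory=list)
    truncated: bool = False
    seed: int | None = None
    learner_id: str | None = None
    # end-of-session snapshots, used by cohort analytics
    final_posteriors: dict[str, float] = field(default_factory=dict)
    final_mastery: dict[str, bool] = field(default_factory=dict)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r, sort_keys=True) for r in self.records) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "SessionLog":
        return cls(records=[json.loads(line) for line in text.splitlines()
                            if line.strip()])

    def observed_skills(self) -> set[str]:
        return {r["skill_id"] for r in self.records}


def run_session(graph: SkillGraph, model_state: KnowledgeState, learner,
                config: ControllerConfig = ControllerConfig(),
                seed: int = 0) -> SessionLog:
    """Run one adaptive tutoring session against a (simulated) learner.

    ``learner`` must provide ``respond(task, difficulty_rank, rng)``
    returning an object with answer/rt_seconds/hints/attempts, and
    ``practice(skill_id, rng)`` applying one practice opportunity.
    The session starts at the first skill in topological order and ends
    when the last skill in that order is retired by the mastery-stop
    rule, or at the step cap (log marked truncated).
    """
    order = topological_order(graph)
    log = SessionLog(seed=seed,
                     learner_id=getattr(learner, "learner_id", None))
    if not order:
        return log
    rng = np.random.default_rng(seed)
    state = model_state
    cstate = ControllerState(current_skill=order[0], PLT=config.init_PLT,
                             PUT=config.init_PUT)
    last_skill = order[-1]
    retired: set[str] = set()
    consec: dict[str, int] = {}

    for step in range(config.step_cap):
        sid = cstate.current_skill
        skill = graph.skill(sid)
        task = arith.generate_task(skill, rng)
        truth_mastery = getattr(learner, "true_mastery", {}).get(sid)
        resp = learner.respond(task, skill.difficulty_rank, rng)
        truth = arith.correct_answer(task)
        correct = resp.answer == truth
        cls = arith.classify_error(task, resp.answer)
        specific = cls.primary in arith.BUGGY_CASES
        obs = Observation(skill_id=sid, H=resp.hints, A=resp.attempts,
                          C=int(correct), W=int(not correct),
                          SW=int(specific), response_time=resp.rt_seconds)
        p_before = state.posteriors[sid]
        state = update_posterior(state, obs, config.transition, config.emission)
        p_after = state.posteriors[sid]
        cstate.n_samples += 1

        # mastery-stop bookkeeping
        if p_after >= config.mastery_stop:
            consec[sid] = consec.get(sid, 0) + 1
        else:
            consec[sid] = 0

        if consec.get(sid, 0) >= config.consecutive_stop:
            # retire the skill and resume at the easiest unfinished one
            retired.add(sid)
            action, event = Action.ADVANCE, None
            target = next((s for s in order if s not in retired), None)
        else:
            decision = next_action(graph, cstate, state.posteriors, config)
            action, target = decision.action, decision.target
            if decision.terminal:
                cstate.terminal = True
            event = ("high" if p_after > cstate.PUT
                     else "low" if p_after < cstate.PLT else None)
            cstate = replace(update_thresholds(cstate, event, config),
                             n_samples=cstate.n_samples,
                             terminal=cstate.terminal)
            if action in (Action.STAY, Action.REMEDIATE):
                learner.practice(sid, rng)
        cstate.training_level = {Action.ADVANCE: "successor",
                                 Action.STAY: "current",
                                 Action.REMEDIATE: "precursor"}[action]
        log.records.append({
            "step": step, "skill_id": sid, "task": str(task),
            "answer": int(resp.answer), "correct": bool(correct),
            "error_case": cls.primary.value,
            "posterior_before": p_before, "posterior_after": p_after,
            "action": action.value, "PLT": cstate.PLT, "PUT": cstate.PUT,
            "rt_seconds": float(resp.rt_seconds),
            # latent state that generated this response (simulated
            # learners only; None for real/interactive ones)
            "mastered": truth_mastery,
        })
        if (sid == last_skill and sid in retired) or target is None:
            break
        cstate.current_skill = target
    else:
        log.truncated = True

    log.final_posteriors = dict(state.posteriors)
    mastery = getattr(learner, "true_mastery", None)
    if mastery is not None:
        log.final_mastery = dict(mastery)
    return log
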