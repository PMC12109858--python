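"""Simulated learners: synthetic dyscalculic and typical cohorts.

Each learner carries a latent per-skill mastery map, slip/guess response
probabilities, a practice-driven learning rate, an error profile over
the five buggy-rule cases, and a lognormal response-time model whose
location grows with skill difficulty.  Error profiles follow the memory
subtypes associated with the five cases: "semantic" learners weight
operation misattribution and zero absorption (Cases 1/5),
"visuospatial" learners the no-carry concatenation (Case 2), and
"procedural" learners digit collapse and carry omission (Cases 3/4);
typical learners make mostly unstructured mistakes.

None of this is fitted to real children: the generator exists so the
tracer, controller and analytics can be exercised end-to-end on data
with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import arithmetic_domain as arith
from .arithmetic_domain import BUGGY_CASES, ErrorCase, Task
from .controller import ControllerConfig, SessionLog, run_session
from .skill_graph import SkillGraph
from .student_model import init_state

GENERIC = "generic"

# error-profile presets keyed by memory subtype
ERROR_PRESETS: dict[str, dict] = {
    "semantic": {ErrorCase.CASE1_OPERATION_MISATTRIBUTION: 0.35,
                 ErrorCase.CASE5_ZERO_ABSORPTION: 0.35,
                 ErrorCase.CASE2_NO_CARRY_CONCATENATION: 0.05,
                 ErrorCase.CASE3_DIGIT_COLLAPSE: 0.05,
                 ErrorCase.CASE4_CARRY_OMISSION: 0.05,
                 GENERIC: 0.15},
    "visuospatial": {ErrorCase.CASE2_NO_CARRY_CONCATENATION: 0.60,
                     ErrorCase.CASE4_CARRY_OMISSION: 0.15,
                     ErrorCase.CASE1_OPERATION_MISATTRIBUTION: 0.05,
                     ErrorCase.CASE3_DIGIT_COLLAPSE: 0.05,
                     ErrorCase.CASE5_ZERO_ABSORPTION: 0.00,
                     GENERIC: 0.15},
    "procedural": {ErrorCase.CASE3_DIGIT_COLLAPSE: 0.35,
                   ErrorCase.CASE4_CARRY_OMISSION: 0.35,
                   ErrorCase.CASE1_OPERATION_MISATTRIBUTION: 0.05,
                   ErrorCase.CASE2_NO_CARRY_CONCATENATION: 0.05,
                   ErrorCase.CASE5_ZERO_ABSORPTION: 0.05,
                   GENERIC: 0.15},
    "typical": {ErrorCase.CASE1_OPERATION_MISATTRIBUTION: 0.04,
                ErrorCase.CASE2_NO_CARRY_CONCATENATION: 0.04,
                ErrorCase.CASE3_DIGIT_COLLAPSE: 0.04,
                ErrorCase.CASE4_CARRY_OMISSION: 0.04,
                ErrorCase.CASE5_ZERO_ABSORPTION: 0.04,
                GENERIC: 0.80},
}


class Response(NamedTuple):
    answer: int
    rt_seconds: float
    hints: int = 0
    attempts: int = 1


@dataclass
class LearnerProfile:
    """Ground-truth generative model for one synthetic learner."""

    true_mastery: dict[str, bool]
    learn_rate: float = 0.3
    slip: float = 0.10
    guess: float = 0.20
    error_profile: dict = field(
        default_factory=lambda: dict(ERROR_PRESETS["typical"]))
    rt_mu0: float = 2.5        # log-seconds at difficulty rank 0 (~12 s)
    rt_dmu: float = 0.08       # log-seconds added per difficulty rank
    rt_sigma: float = 0.5
    learner_id: str = "learner"

    def __post_init__(self) -> None:
        for p in (self.learn_rate, self.slip, self.guess):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.error_profile.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"error_profile sums to {total}, expected 1")


def _wrong_fallback(truth: int, rng: np.random.Generator) -> int:
    """Unstructured wrong answer: a small nonzero offset from the truth."""
    off = int(rng.integers(1, 10)) * int(rng.choice([-1, 1]))
    cand = truth + off
    return cand if cand >= 0 else truth + abs(off)


def simulate_response(profile: LearnerProfile, task: Task,
                      rng: np.random.Generator,
                      difficulty_rank: int = 0) -> Response:
    """One response: correct w.p. 1-slip if the skill is learned, w.p.
    guess otherwise; wrong answers are drawn from the learner's error
    profile and realized through the matching buggy rule."""
    learned = profile.true_mastery.get(task.skill_id, False)
    p_correct = 1.0 - profile.slip if learned else profile.guess
    truth = arith.correct_answer(task)
    rt = float(rng.lognormal(profile.rt_mu0 + profile.rt_dmu * difficulty_rank,
                             profile.rt_sigma))
    if rng.random() < p_correct:
        return Response(truth, rt)
    cases = list(profile.error_profile)
    weights = np.array([profile.error_profile[c] for c in cases])
    case = cases[int(rng.choice(len(cases), p=weights / weights.sum()))]
    answer = None
    if case in BUGGY_CASES:
        try:
            answer = arith.buggy_answer(task, case)
        except ValueError:
            answer = None
    if answer is None or answer == truth:
        answer = _wrong_fallback(truth, rng)
    return Response(int(answer), rt)


def practice_update(profile: LearnerProfile, skill_id: str,
                    rng: np.random.Generator) -> LearnerProfile:
    """One practice opportunity: an unlearned skill flips to learned
    with probability ``learn_rate`` (in place; profile returned)."""
    if not profile.true_mastery.get(skill_id, False):
        if rng.random() < profile.learn_rate:
            profile.true_mastery[skill_id] = True
    return profile


class SimulatedLearner:
    """Adapter giving a :class:`LearnerProfile` the learner contract
    expected by :func:`edsense.controller.run_session`."""

    def __init__(self, profile: LearnerProfile, graph: SkillGraph):
        self.profile = profile
        self._ranks = {s.id: s.difficulty_rank for s in graph.skills}

    @property
    def learner_id(self) -> str:
        return self.profile.learner_id

    @property
    def true_mastery(self) -> dict[str, bool]:
        return self.profile.true_mastery

    def respond(self, task: Task, difficulty_rank: int,
                rng: np.random.Generator) -> Response:
        return simulate_response(self.profile, task, rng, difficulty_rank)

    def practice(self, skill_id: str, rng: np.random.Generator) -> None:
        practice_update(self.profile, skill_id, rng)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_learners: int = 50
    fraction_dyscalculic: float = 0.5
    seed: int = 0
    learn_rate_typical: tuple[float, float] = (0.4, 0.7)
    learn_rate_dyscalculic: tuple[float, float] = (0.1, 0.3)
    slip_range: tuple[float, float] = (0.05, 0.15)
    guess_range: tuple[float, float] = (0.15, 0.25)
    rt_dmu_range: tuple[float, float] = (0.05, 0.12)

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")


def make_profile(graph: SkillGraph, dyscalculic: bool,
                 rng: np.random.Generator, learner_id: str = "learner",
                 learn_rate: float | None = None,
                 config: CohortConfig = CohortConfig()) -> LearnerProfile:
    """Draw one learner.  Everyone starts with all skills unlearned
    (the intervention begins at the floor of the topology); dyscalculic
    learners get a lower learning rate and a structured error profile
    drawn from the memory-subtype presets."""
    lo, hi = (config.learn_rate_dyscalculic if dyscalculic
              else config.learn_rate_typical)
    if learn_rate is None:
        learn_rate = float(rng.uniform(lo, hi))
    subtype = (str(rng.choice(["semantic", "visuospatial", "procedural"]))
               if dyscalculic else "typical")
    return LearnerProfile(
        true_mastery={sid: False for sid in graph.ids()},
        learn_rate=learn_rate,
        slip=float(rng.uniform(*config.slip_range)),
        guess=float(rng.uniform(*config.guess_range)),
        error_profile=dict(ERROR_PRESETS[subtype]),
        rt_dmu=float(rng.uniform(*config.rt_dmu_range)),
        learner_id=learner_id)


def simulate_cohort(graph: SkillGraph, config: CohortConfig = CohortConfig(),
                    controller_config: ControllerConfig = ControllerConfig(),
                    ) -> list[SessionLog]:
    """Run a full tutoring session per learner; reproducible under seed."""
    rng = np.random.default_rng(config.seed)
    n_dys = round(config.n_learners * config.fraction_dyscalculic)
    logs: list[SessionLog] = []
    for i in range(config.n_learners):
        dys = i < n_dys
        profile = make_profile(graph, dys, rng,
                               learner_id=f"{'dys' if dys else 'typ'}-{i:03d}",
                               config=config)
        session_seed = int(rng.integers(0, 2**31 - 1))
        learner = SimulatedLearner(profile, graph)
        logs.append(run_session(graph, init_state(graph), learner,
                                controller_config, seed=session_seed))
    return logs
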