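"""Arithmetic tasks and buggy-rule diagnosis of dyscalculia error patterns.

Wrong answers are matched against five executable "buggy rules", each
an error pattern tied to a memory subtype observed in dyscalculic
learners:

* Case 1 (semantic) — operation misattribution: the learner multiplies
  instead of adding/subtracting (3 + 5 = 15).
* Case 2 (visuospatial) — no-carry concatenation: every column is
  summed independently and all column-sum digits are written out
  without carrying (28 + 14 = 312).
* Case 3 (procedural) — digit collapse: every digit of both operands
  is summed into a single number (92 + 43 = 18).
* Case 4 (procedural) — carry omission / vanishing digits: per-column
  sums keep only the units digit, carries are discarded (39 + 25 = 54).
* Case 5 (semantic) — zero absorption: any column containing a zero
  produces zero, other columns are computed normally (26 + 20 = 40).

For subtraction, Cases 2-4 use the borrow-omission mirrors of the
carry rules (column-wise |a - b|, digit-difference collapse, borrow
discarded).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

import numpy as np

from .skill_graph import Skill


class ErrorCase(enum.Enum):
    CASE1_OPERATION_MISATTRIBUTION = "case1_operation_misattribution"
    CASE2_NO_CARRY_CONCATENATION = "case2_no_carry_concatenation"
    CASE3_DIGIT_COLLAPSE = "case3_digit_collapse"
    CASE4_CARRY_OMISSION = "case4_carry_omission"
    CASE5_ZERO_ABSORPTION = "case5_zero_absorption"
    GENERIC_WRONG = "generic_wrong"
    CORRECT = "correct"


BUGGY_CASES = (ErrorCase.CASE1_OPERATION_MISATTRIBUTION,
               ErrorCase.CASE2_NO_CARRY_CONCATENATION,
               ErrorCase.CASE3_DIGIT_COLLAPSE,
               ErrorCase.CASE4_CARRY_OMISSION,
               ErrorCase.CASE5_ZERO_ABSORPTION)


@dataclass(frozen=True)
class Task:
    """One arithmetic item bound to a skill."""

    operand_a: int
    operand_b: int
    operation: str
    skill_id: str = ""

    def __post_init__(self) -> None:
        if self.operand_a < 0 or self.operand_b < 0:
            raise ValueError("operands must be non-negative")
        if self.operation == "subtraction" and self.operand_a < self.operand_b:
            raise ValueError("subtraction tasks must have operand_a >= operand_b")

    def __str__(self) -> str:
        sym = {"addition": "+", "subtraction": "-", "multiplication": "*"}[self.operation]
        return f"{self.operand_a}{sym}{self.operand_b}"

    @classmethod
    def parse(cls, text: str, skill_id: str = "") -> "Task":
        m = re.fullmatch(r"\s*(\d+)\s*([-+*x])\s*(\d+)\s*", text)
        if not m:
            raise ValueError(f"cannot parse task {text!r}")
        op = {"+": "addition", "-": "subtraction",
              "*": "multiplication", "x": "multiplication"}[m.group(2)]
        return cls(int(m.group(1)), int(m.group(3)), op, skill_id)


@dataclass(frozen=True)
class ClassificationResult:
    primary: ErrorCase
    matches: tuple[ErrorCase, ...] = ()


def correct_answer(task: Task) -> int:
    if task.operation == "addition":
        return task.operand_a + task.operand_b
    if task.operation == "subtraction":
        return task.operand_a - task.operand_b
    if task.operation == "multiplication":
        return task.operand_a * task.operand_b
    raise ValueError(f"unknown operation {task.operation!r}")


# ---------------------------------------------------------------------------
# buggy rules
# ---------------------------------------------------------------------------

def _columns(a: int, b: int) -> list[tuple[int, int]]:
    """Digit columns, most significant first, zero-padded to equal width."""
    width = max(len(str(a)), len(str(b)))
    da, db = str(a).zfill(width), str(b).zfill(width)
    return [(int(x), int(y)) for x, y in zip(da, db)]


def _column_op(task: Task) -> list[int]:
    """Per-column raw result (sum, or absolute difference for subtraction)."""
    cols = _columns(task.operand_a, task.operand_b)
    if task.operation == "addition":
        return [x + y for x, y in cols]
    return [abs(x - y) for x, y in cols]


def buggy_answer(task: Task, case: ErrorCase,
                 zero_absorbs_all: bool = False) -> int:
    """Answer a learner following the given buggy rule would produce.

    ``zero_absorbs_all`` switches Case 5 from column-level absorption
    (the default, matching observed responses such as 26 + 20 = 40) to
    the literal misconception that the whole result is zero whenever a
    zero appears anywhere.
    """
    if case not in BUGGY_CASES:
        raise ValueError(f"{case} is not a buggy rule")
    if task.operation == "multiplication" and case is not ErrorCase.CASE1_OPERATION_MISATTRIBUTION:
        raise ValueError(f"{case.name} is defined for addition/subtraction only")
    a, b = task.operand_a, task.operand_b

    if case is ErrorCase.CASE1_OPERATION_MISATTRIBUTION:
        if task.operation == "multiplication":
            # misattributed the other way: multiplies become additions
            return a + b
        return a * b

    if case is ErrorCase.CASE2_NO_CARRY_CONCATENATION:
        # each column computed independently; all digits of every column
        # result concatenated, no carrying
        return int("".join(str(c) for c in _column_op(task)))

    if case is ErrorCase.CASE3_DIGIT_COLLAPSE:
        digits_a = [int(d) for d in str(a)]
        digits_b = [int(d) for d in str(b)]
        if task.operation == "addition":
            return sum(digits_a) + sum(digits_b)
        return abs(sum(digits_a) - sum(digits_b))

    if case is ErrorCase.CASE4_CARRY_OMISSION:
        # keep only each column's units digit; carries/borrows vanish
        return int("".join(str(c % 10) for c in _column_op(task)))

    # CASE5_ZERO_ABSORPTION
    if zero_absorbs_all:
        has_zero = "0" in str(a) + str(b)
        return 0 if has_zero else correct_answer(task)
    cols = _columns(a, b)
    out = []
    for (x, y), col in zip(cols, _column_op(task)):
        out.append(0 if 0 in (x, y) else col)
    # columns without zeros are computed normally, including carries
    # between them; a zero column forces 0 and blocks any incoming carry
    total, carry = [], 0
    for (x, y), v in zip(reversed(cols), reversed(out)):
        if 0 in (x, y):
            total.append(0)
            carry = 0
        else:
            raw = v + carry
            total.append(raw % 10)
            carry = raw // 10
    digits = list(reversed(total))
    if carry:
        digits.insert(0, carry)
    return int("".join(map(str, digits)))


def classify_error(task: Task, answer: int) -> ClassificationResult:
    """Diagnose a response: CORRECT, one of the five buggy cases
    (fixed precedence Case 1 -> Case 5), or GENERIC_WRONG."""
    if answer == correct_answer(task):
        return ClassificationResult(ErrorCase.CORRECT)
    matches = []
    for case in BUGGY_CASES:
        try:
            if buggy_answer(task, case) == answer:
                matches.append(case)
        except ValueError:
            continue
    if not matches:
        return ClassificationResult(ErrorCase.GENERIC_WRONG)
    return ClassificationResult(matches[0], tuple(matches))


# ---------------------------------------------------------------------------
# task generation
# ---------------------------------------------------------------------------

_RANGE_BOUND = {"0-10": 10, "0-100": 100, "0-1000": 1000}


def _digit_span(d: int) -> tuple[int, int]:
    return (0, 9) if d == 1 else (10 ** (d - 1), 10 ** d - 1)


def _operand_spans(skill: Skill) -> tuple[tuple[int, int], tuple[int, int]]:
    da, db = skill.digits
    span_a, span_b = _digit_span(da), _digit_span(db)
    if (skill.operation == "subtraction" and da == 1
            and "bridging_to_10" in skill.variant_tags):
        # borrowing from single-digit numbers needs a teen minuend
        # (12 - 5 bridges down through 10)
        span_a = (11, 18)
    return span_a, span_b


def _satisfies(skill: Skill, a: int, b: int) -> bool:
    """Constraint predicate for a candidate operand pair."""
    (lo_a, hi_a), (lo_b, hi_b) = _operand_spans(skill)
    if not (lo_a <= a <= hi_a and lo_b <= b <= hi_b):
        return False
    bound = _RANGE_BOUND[skill.number_range]
    bridging = "bridging_to_10" in skill.variant_tags
    if skill.operation == "addition":
        if a + b > bound and not (bridging and skill.number_range == "0-10"):
            return False
        if bridging:
            return a % 10 + b % 10 >= 10
        # without bridging every column must be carry-free
        return all(x + y <= 9 for x, y in _columns(a, b))
    if skill.operation == "subtraction":
        if a < b:
            return False
        if bridging:
            return a % 10 < b % 10
        # without bridging no borrow in any column
        return all(x >= y for x, y in _columns(a, b))
    # multiplication: keep factors >= 2 so tasks are non-degenerate
    return a >= 2 and b >= 2


def generate_task(skill: Skill, rng: np.random.Generator) -> Task:
    """Draw operands uniformly from the skill's constraint set
    (rejection sampling; deterministic under a seeded generator)."""
    (lo_a, hi_a), (lo_b, hi_b) = _operand_spans(skill)
    for _ in range(10_000):
        a = int(rng.integers(lo_a, hi_a + 1))
        b = int(rng.integers(lo_b, hi_b + 1))
        if (skill.operation == "subtraction" and a < b
                and (lo_a, hi_a) == (lo_b, hi_b)):
            a, b = b, a
        if _satisfies(skill, a, b):
            return Task(a, b, skill.operation, skill.id)
    raise RuntimeError(f"could not generate a task for skill {skill.id!r}")
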