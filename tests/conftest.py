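import hypothesis
import numpy as np
import pytest

from edsense.skill_graph import Skill, SkillGraph, build_default_topology

hypothesis.settings.register_profile(
    "det", derandomize=True, max_examples=40, deadline=None)
hypothesis.settings.load_profile("det")


@pytest.fixture(scope="session")
def default_graph() -> SkillGraph:
    return build_default_topology()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dag(rng: np.random.Generator, n: int = 10,
               edge_prob: float = 0.3) -> SkillGraph:
    """Random valid DAG: nodes indexed 0..n-1 with rank = index, edges
    only from lower to higher index (acyclic and difficulty-monotone
    by construction)."""
    ops = ["addition", "subtraction", "multiplication"]
    ranges = ["0-10", "0-100", "0-1000"]
    tags = [frozenset(), frozenset({"support"}), frozenset({"mental"}),
            frozenset({"bridging_to_10"})]
    op = ops[int(rng.integers(len(ops)))]
    skills = [Skill(f"s{i:02d}", f"Skill {i}", op,
                    ranges[int(rng.integers(len(ranges)))], i,
                    tags[int(rng.integers(len(tags)))])
              for i in range(n)]
    edges = {(f"s{i:02d}", f"s{j:02d}")
             for i in range(n) for j in range(i + 1, n)
             if rng.random() < edge_prob}
    return SkillGraph(skills, edges)
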