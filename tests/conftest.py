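import numpy as np
import pytest

from autoshape.learning import LearningParams, MBModel
from autoshape.mdp import build_default_mdp


@pytest.fixture(scope="session")
def mdp():
    return build_default_mdp(1.0)


def true_model(mdp, gamma: float) -> MBModel:
    """MBModel loaded with the exact transition and reward tables."""
    m = MBModel(mdp, LearningParams(alpha=1.0, gamma=gamma))
    for (s, a), s2 in mdp.next_of.items():
        m.T[(s, a)] = {s2: 1.0}
        m.R[(s, a)] = mdp.reward_of[(s, a)]
    return m.plan()


def backward_induction(mdp, gamma: float) -> dict:
    """Independent finite-horizon oracle: recursive expectimax on the DAG."""
    cache: dict = {}

    def value(s) -> float:
        acts = mdp.actions_of.get(s)
        if not acts:
            return 0.0
        return max(q(s, a) for a in acts)

    def q(s, a) -> float:
        if (s, a) not in cache:
            s2 = mdp.next_of[(s, a)]
            cache[(s, a)] = mdp.reward_of[(s, a)] + gamma * value(s2)
        return cache[(s, a)]

    for s in mdp.actions_of:
        for a in mdp.actions_of[s]:
            q(s, a)
    return cache


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
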