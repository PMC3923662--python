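"""Learning rules: planner, feature-value TD, Q-learning, integration, softmax."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autoshape.learning import (
    FMFValues,
    LearningParams,
    MBModel,
    QLearner,
    RPEvent,
    integrate,
    softmax_policy,
)
from autoshape.mdp import Action, EventTag, Feature, State, build_default_mdp
from conftest import backward_induction, true_model


@pytest.mark.parametrize("alpha, n", [(0.1, 1), (0.1, 5), (0.3, 7), (1.0, 1)])
def test_transition_and_reward_learning_closed_form(mdp, alpha, n):
    """Repeated observation of one deterministic transition follows 1-(1-a)^n."""
    m = MBModel(mdp, LearningParams(alpha, 0.9))
    for _ in range(n):
        m.update(State.S_US_CM, Action.eat, State.S_END, 1.0)
    expected = 1 - (1 - alpha) ** n
    assert m.T[(State.S_US_CM, Action.eat)][State.S_END] == pytest.approx(expected)
    assert m.R[(State.S_US_CM, Action.eat)] == pytest.approx(expected)


def test_transition_mass_stays_a_subdistribution(mdp):
    m = MBModel(mdp, LearningParams(0.2, 0.9))
    pairs = [(State.S_CS, Action.goL, State.S_CS_L), (State.S_CS, Action.goL, State.S_CS_M)]
    for s, a, s2 in pairs * 10:
        m.update(s, a, s2, 0.0)
        total = sum(m.T[(s, a)].values())
        assert 0.0 <= total <= 1.0 + 1e-12


def test_planner_matches_backward_induction_oracle(mdp):
    """Value iteration on the true model equals the independent DAG oracle."""
    for gamma in (0.5, 0.9, 0.98):
        m = true_model(mdp, gamma)
        oracle = backward_induction(mdp, gamma)
        for key, q in oracle.items():
            assert m.Q[key] == pytest.approx(q, abs=1e-9)


def test_planner_hand_values_gamma_09(mdp):
    m = true_model(mdp, 0.9)
    assert m.Q[(State.S_US_CM, Action.eat)] == pytest.approx(1.0)
    assert m.Q[(State.S_CS, Action.goM)] == pytest.approx(0.81)
    assert m.Q[(State.S_CS, Action.goL)] == pytest.approx(0.729)
    assert m.advantage(State.S_CS, Action.goM) == pytest.approx(0.0)
    assert m.advantage(State.S_CS, Action.goL) == pytest.approx(-0.081)
    # advantages are never positive
    for s in mdp.actions_of:
        for a in mdp.actions_of[s]:
            assert m.advantage(s, a) <= 1e-12


class TestFeatureModelFree:
    def make(self, gamma=0.9, alpha=0.1, u=0.0, v0=None):
        return FMFValues(LearningParams(alpha, gamma), u=u, v0=v0 or {})

    def test_rpe_at_unexpected_reward(self, mdp):
        v = self.make()
        e = v.rpe(mdp, State.S_US_CM, Action.eat, 1.0, State.S_END)
        assert e.delta == pytest.approx(1.0)
        assert e.feature is Feature.FOOD

    def test_rpe_bootstraps_best_successor_feature(self, mdp):
        v = self.make(v0={Feature.FOOD: 0.9, Feature.MAGAZINE: 0.5})
        e = v.rpe(mdp, State.S_CS_M, Action.eng, 0.0, State.S_US_CM)
        assert e.delta == pytest.approx(0.0 + 0.9 * 0.9 - 0.5)

    def test_cs_onset_rpe_uses_best_available_stimulus(self, mdp):
        v = self.make(v0={Feature.LEVER: 0.8, Feature.MAGAZINE: 0.4})
        e = v.rpe(mdp, State.S_PRE, Action.exp, 0.0, State.S_CS)
        assert e.delta == pytest.approx(0.9 * 0.8)  # V(None) pinned at 0

    def test_update_moves_only_the_focused_feature(self, mdp):
        v = self.make(alpha=0.1)
        v.update(RPEvent(1.0, Feature.FOOD, EventTag.OTHER))
        assert v.V[Feature.FOOD] == pytest.approx(0.1)
        assert all(v.V[f] == 0 for f in (Feature.LEVER, Feature.MAGAZINE, Feature.NONE))

    def test_none_feature_never_learns(self, mdp):
        v = self.make()
        v.update(RPEvent(5.0, Feature.NONE, EventTag.OTHER))
        assert v.V[Feature.NONE] == 0.0

    def test_repeated_consumption_drives_food_value_to_reward(self, mdp):
        v = self.make(alpha=0.2)
        for _ in range(200):
            v.update(v.rpe(mdp, State.S_US_CM, Action.eat, 1.0, State.S_END))
        assert v.V[Feature.FOOD] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("u, start, expected", [
        (0.2, 0.5, 0.4), (0.0, 0.5, 0.5), (1.0, 0.5, 0.0),
    ])
    def test_iti_decay(self, u, start, expected):
        v = self.make(u=u, v0={Feature.MAGAZINE: start})
        v.iti_decay()
        assert v.V[Feature.MAGAZINE] == pytest.approx(expected)
        assert v.V[Feature.FOOD] == 0.0  # untouched

    def test_feature_generalization_across_states(self, mdp):
        """A magazine value revised at one point in the trial is the same
        value consulted at a different state sharing the feature."""
        v = self.make(v0={Feature.MAGAZINE: 0.5})
        before = v.rpe(mdp, State.S_CS, Action.goM, 0.0, State.S_CS_M).delta
        v.update(RPEvent(-1.0, Feature.MAGAZINE, EventTag.OTHER))
        after = v.rpe(mdp, State.S_CS, Action.goM, 0.0, State.S_CS_M).delta
        assert after != before  # CS-period estimate changed by an ITI-style revision

    @given(deltas=st.lists(st.floats(-1, 1), max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_values_bounded_with_bounded_rewards(self, deltas):
        """With rewards in [0, 1] and inits in [0, 1], TD keeps V in [0, 1]."""
        mdp = build_default_mdp(1.0)
        v = FMFValues(LearningParams(0.5, 0.9), u=0.3,
                      v0={Feature.MAGAZINE: 0.25, Feature.FOOD: 0.5})
        pairs = [(s, a) for s in mdp.actions_of for a in mdp.actions_of[s]]
        for i, _ in enumerate(deltas):
            s, a = pairs[i % len(pairs)]
            e = v.rpe(mdp, s, a, mdp.reward_of[(s, a)], mdp.next_of[(s, a)])
            v.update(e)
            v.iti_decay()
            assert all(-1e-9 <= val <= 1.0 + 1e-9 for val in v.V.values())


class TestQLearner:
    def test_single_step_toward_unexpected_reward(self, mdp):
        q = QLearner(mdp, LearningParams(0.1, 0.9))
        delta = q.update(State.S_US_CM, Action.eat, 1.0, State.S_END)
        assert delta == pytest.approx(1.0)
        assert q.Q[(State.S_US_CM, Action.eat)] == pytest.approx(0.1)

    def test_fixed_point_has_zero_rpe(self, mdp):
        q = QLearner(mdp, LearningParams(0.5, 0.9))
        q.Q[(State.S_US_CM, Action.eat)] = 1.0
        assert q.rpe(State.S_US_CM, Action.eat, 1.0, State.S_END) == pytest.approx(0.0)

    def test_converges_to_planner_values_under_exploration(self, mdp):
        """Q-learning on the deterministic task converges to the planning
        oracle everywhere reachable (the variant-equivalence property)."""
        gamma = 0.9
        q = QLearner(mdp, LearningParams(0.2, gamma))
        rng = np.random.default_rng(0)
        for _ in range(2000):
            s = State.S_PRE
            while s != mdp.terminal:
                a = mdp.actions_of[s][rng.integers(len(mdp.actions_of[s]))]
                q.update(s, a, mdp.reward_of[(s, a)], mdp.next_of[(s, a)])
                s = mdp.next_of[(s, a)]
        oracle = backward_induction(mdp, gamma)
        for key, val in oracle.items():
            assert q.Q[key] == pytest.approx(val, abs=1e-6)


class TestIntegration:
    def test_omega_zero_returns_pure_advantage(self, mdp):
        m = true_model(mdp, 0.9)
        v = FMFValues(LearningParams(0.1, 0.9), v0={Feature.LEVER: 0.7})
        p = integrate("model", 0.0, mdp, State.S_CS, fmf=v, mb=m)
        assert p.P[Action.goL] == pytest.approx(m.advantage(State.S_CS, Action.goL))

    def test_omega_one_returns_pure_feature_values(self, mdp):
        m = true_model(mdp, 0.9)
        v = FMFValues(LearningParams(0.1, 0.9), v0={Feature.LEVER: 0.7})
        p = integrate("model", 1.0, mdp, State.S_CS, fmf=v, mb=m)
        assert p.P[Action.goL] == pytest.approx(0.7)
        assert p.P[Action.exp] == pytest.approx(0.0)

    def test_weighted_sum_example(self, mdp):
        m = true_model(mdp, 0.9)
        m.Q[(State.S_CS, Action.goL)] = m.Q[(State.S_CS, Action.goM)] - 0.2 / 0.9
        v = FMFValues(LearningParams(0.1, 0.9), v0={Feature.LEVER: 0.6})
        p = integrate("model", 0.5, mdp, State.S_CS, fmf=v, mb=m)
        # 0.5*0.6 + 0.5*A with A = -0.2/0.9*0.9
        assert p.P[Action.goL] == pytest.approx(0.5 * 0.6 + 0.5 * -(0.2 / 0.9))

    def test_v2_bonus_only_on_lever_actions(self, mdp):
        q = QLearner(mdp, LearningParams(0.1, 0.9))
        q.Q[(State.S_CS, Action.goM)] = 0.8
        p2 = integrate("v2", 0.5, mdp, State.S_CS, mf=q)
        p3 = integrate("v3", 0.5, mdp, State.S_CS, mf=q)
        bonus = 0.5 * 0.8
        assert p2.P[Action.goL] - p2.P[Action.exp] == pytest.approx(bonus)
        assert p2.P[Action.goM] - p2.P[Action.exp] == pytest.approx(bonus)  # advantage only
        # v3 extends the bonus to the magazine-directed action
        assert p3.P[Action.goM] - p2.P[Action.goM] == pytest.approx(bonus)
        assert p3.P[Action.goM] == pytest.approx(p3.P[Action.goL] + bonus)

    def test_unknown_variant_rejected(self, mdp):
        with pytest.raises(ValueError, match="variant"):
            integrate("v9", 0.5, mdp, State.S_CS)

    def test_omega_bounds_enforced(self, mdp):
        with pytest.raises(ValueError, match="omega"):
            integrate("model", 1.5, mdp, State.S_CS)


class TestSoftmax:
    def make_values(self, vals, mdp):
        from autoshape.learning import IntegratedValues
        acts = mdp.actions_of[State.S_CS]
        return IntegratedValues(State.S_CS, dict(zip(acts, vals)), 0.5)

    def test_equal_values_uniform(self, mdp, rng):
        p = self.make_values([0.3, 0.3, 0.3], mdp)
        _, probs = softmax_policy(p, 1.0, rng)
        assert all(np.isclose(x, 1 / 3) for x in probs.values())

    def test_two_action_logistic_by_hand(self, mdp, rng):
        from autoshape.learning import IntegratedValues
        p = IntegratedValues(State.S_CS, {Action.goL: 1.0, Action.goM: 0.0}, 0.5)
        _, probs = softmax_policy(p, 1.0, rng)
        assert probs[Action.goL] == pytest.approx(0.731, abs=5e-4)
        assert probs[Action.goM] == pytest.approx(0.269, abs=5e-4)

    def test_high_temperature_flattens(self, mdp, rng):
        p = self.make_values([1.0, 0.0, -1.0], mdp)
        _, probs = softmax_policy(p, 1e6, rng)
        assert all(abs(x - 1 / 3) < 1e-5 for x in probs.values())

    @given(vals=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
           beta=st.floats(0.01, 10))
    @settings(deadline=None, max_examples=100)
    def test_normalization_and_monotonicity(self, vals, beta):
        mdp = build_default_mdp(1.0)
        rng = np.random.default_rng(1)
        p = self.make_values(vals, mdp)
        _, probs = softmax_policy(p, beta, rng)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        ordered = sorted(probs, key=lambda a: p.P[a])
        assert probs[ordered[0]] <= probs[ordered[-1]] + 1e-12

    def test_beta_must_be_positive(self, mdp, rng):
        with pytest.raises(ValueError):
            softmax_policy(self.make_values([0, 0, 0], mdp), 0.0, rng)


def test_learning_params_bounds():
    with pytest.raises(ValueError):
        LearningParams(0.0, 0.9)
    with pytest.raises(ValueError):
        LearningParams(0.1, 1.0)
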