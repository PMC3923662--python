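"""Learning systems: model-based planner, feature-value TD learner, Q-learner.

Three learners share the task interface of :mod:`autoshape.mdp`:

``MBModel``
    A model-based (MB) system.  It estimates the transition and reward
    functions by exponential averaging and plans state--action values by
    value iteration; its output is the advantage A(s, a) = Q(s, a) - max Q,
    which is 0 for the best known action and negative otherwise.  Because it
    learns a *model* rather than values-from-errors, its learning is
    unaffected by manipulations of the reward-prediction error.

``FMFValues``
    The feature-model-free (FMF) system.  A temporal-difference learner whose
    value table is indexed by *features* (lever, magazine, food) instead of
    states, so a value revised at one moment of the trial is the same value
    consulted at any other moment involving that stimulus.  Its
    reward-prediction errors (RPEs) are the model's analogue of phasic
    dopamine.  The inter-trial interval enters only through
    :func:`fmf_iti_decay`, a per-episode depression of the magazine value
    standing in for unrewarded magazine checks between trials.

``QLearner``
    A classical state--action model-free learner (Q-learning / advantage
    learning), used by the model variants.

Values from two systems are combined by :func:`integrate` (a convex
combination weighted by ``omega``) and turned into choice by
:func:`softmax_policy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

from .mdp import Action, AutoshapingMDP, EventTag, Feature, State

if TYPE_CHECKING:  # pragma: no cover
    from .pharmacology import DrugCondition

__all__ = [
    "LearningParams",
    "MBModel",
    "FMFValues",
    "QLearner",
    "RPEvent",
    "IntegratedValues",
    "integrate",
    "softmax_policy",
    "VARIANTS",
]

VARIANTS = ("model", "v1", "v2", "v3", "v4")


@dataclass(frozen=True)
class LearningParams:
    """Learning rate ``alpha`` in (0, 1] and discount ``gamma`` in [0, 1)."""

    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")


@dataclass(frozen=True)
class RPEvent:
    """One reward-prediction error, tagged with its generating context."""

    delta: float
    feature: Feature
    event: EventTag
    trial_index: int = 0
    session_index: int = 0


class MBModel:
    """Model-based learner: learned T and R, planned Q and advantages."""

    def __init__(self, mdp: AutoshapingMDP, params: LearningParams,
                 r0: float = 0.0, q0: float = 0.0) -> None:
        self.mdp = mdp
        self.params = params
        self.T: dict[tuple[State, Action], dict[State, float]] = {}
        self.R: dict[tuple[State, Action], float] = {}
        self.Q: dict[tuple[State, Action], float] = {}
        self._r0 = r0
        for s in mdp.actions_of:
            for a in mdp.actions_of[s]:
                self.R[(s, a)] = r0
                self.Q[(s, a)] = q0
        # successors-first sweep order; exact single-sweep planning on a DAG
        self._order = [s for s in mdp.topological_order() if mdp.actions_of.get(s)]

    def update(self, s: State, a: Action, s_next: State, r: float) -> "MBModel":
        """Exponential-average update of T(s, a, .) and R(s, a)."""
        alpha = self.params.alpha
        row = self.T.setdefault((s, a), {})
        for x in row:
            row[x] += alpha * ((x == s_next) - row[x])
        if s_next not in row:
            row[s_next] = alpha
        self.R[(s, a)] += alpha * (r - self.R[(s, a)])
        return self

    def plan(self, max_iter: int = 1000, tol: float = 1e-12) -> "MBModel":
        """Value iteration to the fixed point of the learned model.

        On the (acyclic) default task a single successors-first sweep is
        exact; on cyclic task graphs iteration continues to ``tol`` and a
        failure to converge within ``max_iter`` sweeps raises.
        """
        gamma = self.params.gamma
        Q, T, R, mdp = self.Q, self.T, self.R, self.mdp
        for it in range(max_iter):
            biggest = 0.0
            for s in self._order:
                acts = mdp.actions_of[s]
                for a in acts:
                    q = R[(s, a)]
                    for s2, p in T.get((s, a), {}).items():
                        succ = mdp.actions_of.get(s2)
                        if succ:
                            q += gamma * p * max(Q[(s2, a2)] for a2 in succ)
                    diff = q - Q[(s, a)]
                    if diff > biggest or -diff > biggest:
                        biggest = abs(diff)
                    Q[(s, a)] = q
            if biggest <= tol:
                return self
            if it == 0 and self._is_dag:
                return self  # one sweep is exact on a DAG
        raise RuntimeError("value iteration did not converge")

    @property
    def _is_dag(self) -> bool:
        return True  # topological_order() already raised if cyclic

    def advantage(self, s: State, a: Action) -> float:
        best = max(self.Q[(s, b)] for b in self.mdp.actions_of[s])
        return self.Q[(s, a)] - best

    def advantages(self, s: State) -> dict[Action, float]:
        acts = self.mdp.actions_of[s]
        best = max(self.Q[(s, a)] for a in acts)
        return {a: self.Q[(s, a)] - best for a in acts}

    def snapshot(self) -> dict:
        """Plain-document view of the learner state (for logs and tests)."""
        return {
            "Q": {f"{s.value}/{a.value}": q for (s, a), q in self.Q.items()},
            "R": {f"{s.value}/{a.value}": r for (s, a), r in self.R.items()},
            "T": {
                f"{s.value}/{a.value}": {s2.value: p for s2, p in row.items()}
                for (s, a), row in self.T.items()
            },
        }


class FMFValues:
    """Feature-value table of the feature-model-free system.

    ``V[Feature.NONE]`` is pinned at zero and never learned: actions directed
    at no stimulus carry no motivational value, and the pin is what keeps the
    CS-onset prediction error from being absorbed over training.
    """

    def __init__(self, params: LearningParams, u: float = 0.0,
                 v0: Mapping[Feature, float] | None = None) -> None:
        if not 0.0 <= u <= 1.0:
            raise ValueError("u must be in [0, 1]")
        self.params = params
        self.u = u
        self.V: dict[Feature, float] = {f: 0.0 for f in Feature}
        for f, v in (v0 or {}).items():
            if f is not Feature.NONE:
                self.V[f] = float(v)

    def rpe(self, mdp: AutoshapingMDP, s: State, a: Action, r: float,
            s_next: State, event: EventTag = EventTag.OTHER,
            trial_index: int = 0, session_index: int = 0) -> RPEvent:
        """delta = r + gamma * max_{a'} V(f(s', a')) - V(f(s, a)).

        The successor value is the best feature value reachable by any legal
        next action; terminal successors contribute nothing.
        """
        succ = mdp.actions_of.get(s_next)
        future = 0.0
        if succ:
            future = max(self.V[mdp.feature_of[(s_next, a2)]] for a2 in succ)
        feature = mdp.feature_of[(s, a)]
        delta = r + self.params.gamma * future - self.V[feature]
        return RPEvent(delta, feature, event, trial_index, session_index)

    def update(self, e: RPEvent) -> "FMFValues":
        if e.feature is not Feature.NONE:
            self.V[e.feature] += self.params.alpha * e.delta
        return self

    def iti_decay(self, drug: "DrugCondition | None" = None) -> "FMFValues":
        """Per-episode depression of the magazine value: V(M) <- (1 - u) V(M).

        The decay summarises unrewarded, dopamine-dependent TD revisions of
        the magazine value during the inter-trial interval, so a dopamine
        antagonist attenuates it exactly as it attenuates any other RPE.
        """
        decrement = -self.u * self.V[Feature.MAGAZINE]
        if drug is not None:
            from .pharmacology import attenuate_rpe

            decrement = attenuate_rpe(decrement, drug)
        self.V[Feature.MAGAZINE] += decrement
        return self

    def snapshot(self) -> dict:
        return {f.value: v for f, v in self.V.items()}


class QLearner:
    """Classical state-action Q-learning with the same advantage read-out."""

    def __init__(self, mdp: AutoshapingMDP, params: LearningParams, q0: float = 0.0) -> None:
        self.mdp = mdp
        self.params = params
        self.Q: dict[tuple[State, Action], float] = {
            (s, a): q0 for s in mdp.actions_of for a in mdp.actions_of[s]
        }

    def rpe(self, s: State, a: Action, r: float, s_next: State) -> float:
        succ = self.mdp.actions_of.get(s_next)
        future = max(self.Q[(s_next, a2)] for a2 in succ) if succ else 0.0
        return r + self.params.gamma * future - self.Q[(s, a)]

    def update(self, s: State, a: Action, r: float, s_next: State,
               delta: float | None = None) -> float:
        """One TD(0) step; returns the (possibly pre-attenuated) delta used."""
        if delta is None:
            delta = self.rpe(s, a, r, s_next)
        self.Q[(s, a)] += self.params.alpha * delta
        return delta

    def advantages(self, s: State) -> dict[Action, float]:
        acts = self.mdp.actions_of[s]
        best = max(self.Q[(s, a)] for a in acts)
        return {a: self.Q[(s, a)] - best for a in acts}

    def max_q(self, s: State) -> float:
        return max(self.Q[(s, a)] for a in self.mdp.actions_of[s])

    def snapshot(self) -> dict:
        return {f"{s.value}/{a.value}": q for (s, a), q in self.Q.items()}


@dataclass(frozen=True)
class IntegratedValues:
    """Decision values P(s, a) for one state, with the weight that built them."""

    state: State
    P: dict[Action, float]
    omega: float


def integrate(
    variant: str,
    omega: float,
    mdp: AutoshapingMDP,
    s: State,
    fmf: FMFValues | None = None,
    mb: MBModel | None = None,
    mf: QLearner | None = None,
) -> IntegratedValues:
    """Combine the two systems' outputs into decision values for state ``s``.

    ``model``  P = omega * V(f(s, a)) + (1 - omega) * A_MB(s, a)
    ``v1``     as ``model`` with the model-free advantage A_MF in place of A_MB
    ``v2``     P = (1 - omega) * A_MF + omega * [f(s, a) = Lever] * max_a' Q_MF(s, a')
    ``v3``     as ``v2`` with the bonus on both lever- and magazine-directed actions
    ``v4``     P = omega * A_MF + (1 - omega) * A_MB  (no feature values at all)

    ``omega`` always weighs the system that can favour sign-tracking, so a
    high ``omega`` pushes toward the lever wherever that is possible at all.
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    acts = mdp.actions_of[s]
    if variant == "model":
        adv = mb.advantages(s)
        P = {a: omega * fmf.V[mdp.feature_of[(s, a)]] + (1 - omega) * adv[a] for a in acts}
    elif variant == "v1":
        adv = mf.advantages(s)
        P = {a: omega * fmf.V[mdp.feature_of[(s, a)]] + (1 - omega) * adv[a] for a in acts}
    elif variant in ("v2", "v3"):
        adv = mf.advantages(s)
        bonus_features = (
            (Feature.LEVER,) if variant == "v2" else (Feature.LEVER, Feature.MAGAZINE)
        )
        vmax = mf.max_q(s)
        P = {
            a: (1 - omega) * adv[a]
            + (omega * vmax if mdp.feature_of[(s, a)] in bonus_features else 0.0)
            for a in acts
        }
    elif variant == "v4":
        adv_mf = mf.advantages(s)
        adv_mb = mb.advantages(s)
        P = {a: omega * adv_mf[a] + (1 - omega) * adv_mb[a] for a in acts}
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return IntegratedValues(s, P, omega)


def softmax_policy(
    p: IntegratedValues,
    beta: float,
    rng: np.random.Generator,
) -> tuple[Action, dict[Action, float]]:
    """Sample an action with prob(a) proportional to exp(P(s, a) / beta).

    A high temperature ``beta`` flattens the distribution toward uniform; a
    low one makes the best-valued action almost exclusive.  Probabilities are
    returned alongside the sample for logging and value-based probes.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    acts = list(p.P)
    vals = np.array([p.P[a] for a in acts], dtype=float) / beta
    vals -= vals.max()
    w = np.exp(vals)
    w /= w.sum()
    idx = rng.choice(len(acts), p=w)
    return acts[idx], dict(zip(acts, w))
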