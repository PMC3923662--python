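"""Episodic MDP of the autoshaping task.

The task is an eight-state, deterministic, finite-horizon decision process.
Each episode is one conditioning trial: the agent waits in an empty pre-CS
state, the lever appears (CS onset), the agent commits to approaching the
lever, approaching the food magazine, or exploring, the lever retracts and
food is delivered (US), and the trial ends once the food is consumed.

States are annotated with stimulus-availability flags, and every legal
(state, action) pair carries a *feature*: the stimulus the action is directed
at (lever, magazine, food, or nothing).  Feature-based learners attach value
to these features rather than to states, which is what lets value generalise
across different moments of the trial.

The inter-trial interval is deliberately not represented as states; its only
effect is a per-episode depression of the magazine's feature value, applied
by the learning layer (see :mod:`autoshape.learning`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "State",
    "Action",
    "Feature",
    "EventTag",
    "TransitionOutcome",
    "AutoshapingMDP",
    "build_default_mdp",
    "step",
    "event_tag",
]


class State(str, Enum):
    """Task states. ``S_PRE`` is initial, ``S_END`` terminal."""

    S_PRE = "S_PRE"        # empty box, pre-CS
    S_CS = "S_CS"          # lever has appeared (CS onset)
    S_CS_L = "S_CS_L"      # close to the lever, CS period
    S_CS_M = "S_CS_M"      # close to the magazine, CS period
    S_CS_E = "S_CS_E"      # exploring, CS period
    S_US_FAR = "S_US_FAR"  # food delivered, agent far from magazine
    S_US_CM = "S_US_CM"    # food delivered, agent at the magazine
    S_END = "S_END"        # trial over (start of ITI)


class Action(str, Enum):
    goL = "goL"  # approach the lever
    goM = "goM"  # approach the magazine
    eng = "eng"  # engage the proximal stimulus
    exp = "exp"  # explore
    eat = "eat"  # consume the food


class Feature(str, Enum):
    """Stimulus an action is directed at; ``NONE`` carries no learnable value."""

    LEVER = "Lever"
    MAGAZINE = "Magazine"
    FOOD = "Food"
    NONE = "None"


class EventTag(str, Enum):
    CS_ONSET = "CS_onset"
    US_DELIVERY = "US_delivery"
    OTHER = "other"


@dataclass(frozen=True)
class StateFlags:
    lever_available: bool = False
    food_available: bool = False
    close_to: str = "none"  # "lever" | "magazine" | "none"
    terminal: bool = False


#: Stimulus-availability annotation of each default state.
DEFAULT_FLAGS: Mapping[State, StateFlags] = {
    State.S_PRE: StateFlags(),
    State.S_CS: StateFlags(lever_available=True),
    State.S_CS_L: StateFlags(lever_available=True, close_to="lever"),
    State.S_CS_M: StateFlags(lever_available=True, close_to="magazine"),
    State.S_CS_E: StateFlags(lever_available=True),
    State.S_US_FAR: StateFlags(food_available=True),
    State.S_US_CM: StateFlags(food_available=True, close_to="magazine"),
    State.S_END: StateFlags(terminal=True),
}


@dataclass(frozen=True)
class TransitionOutcome:
    next_state: State
    reward: float
    feature: Feature


@dataclass
class AutoshapingMDP:
    """Data-driven episodic task graph.

    All behaviour is carried by explicit tables so alternative topologies can
    be loaded from configuration; nothing about the default task is hard-coded
    in the operations below.
    """

    initial: State
    terminal: State
    actions_of: dict[State, tuple[Action, ...]]
    next_of: dict[tuple[State, Action], State]
    reward_of: dict[tuple[State, Action], float]
    feature_of: dict[tuple[State, Action], Feature]
    flags: dict[State, StateFlags] = field(default_factory=lambda: dict(DEFAULT_FLAGS))

    @property
    def states(self) -> tuple[State, ...]:
        return tuple(self.actions_of)

    def legal(self, s: State) -> tuple[Action, ...]:
        return self.actions_of[s]

    def validate(self) -> None:
        """Check structural invariants: totality, acyclicity, reachability."""
        for (s, a), _ in self.next_of.items():
            if a not in self.actions_of[s]:
                raise ValueError(f"transition for illegal pair ({s}, {a})")
        for s, acts in self.actions_of.items():
            if s == self.terminal:
                continue
            if not acts:
                raise ValueError(f"non-terminal state {s} has no actions")
            for a in acts:
                for table, name in (
                    (self.next_of, "next_of"),
                    (self.reward_of, "reward_of"),
                    (self.feature_of, "feature_of"),
                ):
                    if (s, a) not in table:
                        raise ValueError(f"{name} not total: missing ({s}, {a})")
        # acyclic + every path reaches terminal: DFS from the initial state
        order = self.topological_order()  # successors first
        reachable = {self.initial}
        for s in reversed(order):
            if s in reachable:
                for a in self.actions_of.get(s, ()):
                    reachable.add(self.next_of[(s, a)])
        if self.terminal not in reachable:
            raise ValueError("terminal state unreachable from the initial state")

    def topological_order(self) -> list[State]:
        """States in dependency order (successors first); raises on cycles."""
        colour: dict[State, int] = {}
        out: list[State] = []

        def visit(s: State) -> None:
            if colour.get(s) == 2:
                return
            if colour.get(s) == 1:
                raise ValueError("task graph contains a cycle")
            colour[s] = 1
            for a in self.actions_of.get(s, ()):
                visit(self.next_of[(s, a)])
            colour[s] = 2
            out.append(s)

        for s in self.actions_of:
            visit(s)
        return out

    # -- plain-document serialization ------------------------------------
    def to_dict(self) -> dict:
        return {
            "initial": self.initial.value,
            "terminal": self.terminal.value,
            "actions": {s.value: [a.value for a in acts] for s, acts in self.actions_of.items()},
            "transitions": [
                {
                    "state": s.value,
                    "action": a.value,
                    "next": self.next_of[(s, a)].value,
                    "reward": self.reward_of[(s, a)],
                    "feature": self.feature_of[(s, a)].value,
                }
                for (s, a) in self.next_of
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "AutoshapingMDP":
        actions_of = {
            State(s): tuple(Action(a) for a in acts) for s, acts in doc["actions"].items()
        }
        next_of, reward_of, feature_of = {}, {}, {}
        for t in doc["transitions"]:
            key = (State(t["state"]), Action(t["action"]))
            next_of[key] = State(t["next"])
            reward_of[key] = float(t["reward"])
            feature_of[key] = Feature(t["feature"])
        mdp = cls(
            initial=State(doc["initial"]),
            terminal=State(doc["terminal"]),
            actions_of=actions_of,
            next_of=next_of,
            reward_of=reward_of,
            feature_of=feature_of,
        )
        mdp.validate()
        return mdp


def build_default_mdp(r_food: float = 1.0) -> AutoshapingMDP:
    """Build the eight-state autoshaping task.

    Parameters
    ----------
    r_food
        Magnitude of the single food reward, delivered on consumption
        (``(S_US_CM, eat)``).  Dimensionless; must be positive.

    Notes
    -----
    The goal-tracking path (``S_CS -> goM``) reaches reward in four actions,
    one fewer than the sign-tracking and exploration paths, so a planner with
    any discounting strictly prefers it.  Post-delivery approach to the
    magazine (``S_US_FAR, goM``) is directed at the delivered food, so its
    feature is ``Food``: this is what lets the lever, one step upstream,
    anchor close to the full discounted food value while the magazine's own
    value is repeatedly depressed by inter-trial revisions.
    """
    if r_food <= 0:
        raise ValueError("r_food must be positive")
    S, A, F = State, Action, Feature
    edges = [
        # (state, action, next_state, reward, feature)
        (S.S_PRE, A.exp, S.S_CS, 0.0, F.NONE),
        (S.S_CS, A.goL, S.S_CS_L, 0.0, F.LEVER),
        (S.S_CS, A.goM, S.S_CS_M, 0.0, F.MAGAZINE),
        (S.S_CS, A.exp, S.S_CS_E, 0.0, F.NONE),
        (S.S_CS_L, A.eng, S.S_US_FAR, 0.0, F.LEVER),
        (S.S_CS_M, A.eng, S.S_US_CM, 0.0, F.MAGAZINE),
        (S.S_CS_E, A.exp, S.S_US_FAR, 0.0, F.NONE),
        (S.S_US_FAR, A.goM, S.S_US_CM, 0.0, F.FOOD),
        (S.S_US_CM, A.eat, S.S_END, r_food, F.FOOD),
    ]
    actions_of: dict[State, tuple[Action, ...]] = {s: () for s in State}
    next_of, reward_of, feature_of = {}, {}, {}
    for s, a, s2, r, f in edges:
        actions_of[s] = actions_of[s] + (a,)
        next_of[(s, a)] = s2
        reward_of[(s, a)] = r
        feature_of[(s, a)] = f
    mdp = AutoshapingMDP(
        initial=S.S_PRE,
        terminal=S.S_END,
        actions_of=actions_of,
        next_of=next_of,
        reward_of=reward_of,
        feature_of=feature_of,
    )
    mdp.validate()
    return mdp


def step(mdp: AutoshapingMDP, s: State, a: Action) -> TransitionOutcome:
    """Execute one deterministic transition.

    Raises
    ------
    ValueError
        If ``s`` is terminal or ``a`` is not legal in ``s`` — either one
        indicates a protocol bug, not an agent mistake.
    """
    if mdp.flags.get(s, StateFlags()).terminal or s == mdp.terminal:
        raise ValueError(f"cannot act in terminal state {s}")
    if a not in mdp.actions_of[s]:
        raise ValueError(f"action {a} is not legal in state {s}")
    key = (s, a)
    return TransitionOutcome(mdp.next_of[key], mdp.reward_of[key], mdp.feature_of[key])


def event_tag(s: State, a: Action) -> EventTag:
    """Classify a transition as CS onset, US delivery, or neither.

    CS onset is the transition into lever appearance; US delivery is any
    transition out of a CS-period state into a food-delivered state (the
    moment of lever retraction + food drop).  Post-delivery locomotion and
    consumption are ``other``.
    """
    if (s, a) == (State.S_PRE, Action.exp):
        return EventTag.CS_ONSET
    if (s, a) in (
        (State.S_CS_L, Action.eng),
        (State.S_CS_M, Action.eng),
        (State.S_CS_E, Action.exp),
    ):
        return EventTag.US_DELIVERY
    return EventTag.OTHER
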