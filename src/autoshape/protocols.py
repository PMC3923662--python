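"""Experiment protocols and figure-level metrics.

This module turns the learners of :mod:`autoshape.learning` into simulated
rats and runs the study's five experiments:

* plain autoshaping acquisition (group engagement curves and per-session
  CS / US reward-prediction-error traces),
* the conditioned-reinforcement probe and the feature-value ("incentive
  salience") contribution to engagement,
* systemic flupentixol during acquisition with a drug-free test session,
* local (intra-accumbens) flupentixol dose--response on expression,
* the inter-trial-interval (ITI) manipulation predictions.

Groups differ only in their parameter vector; the canonical phenotypes vary
just the integration weight ``omega`` (sign-trackers high, goal-trackers
low, intermediates near the phenotype boundary).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .learning import (
    FMFValues,
    IntegratedValues,
    LearningParams,
    MBModel,
    QLearner,
    RPEvent,
    integrate,
    softmax_policy,
)
from .mdp import Action, AutoshapingMDP, EventTag, Feature, State, build_default_mdp, event_tag, step
from .pharmacology import NO_DRUG, DrugCondition, Site, attenuate_rpe, elevate_temperature

__all__ = [
    "AgentConfig",
    "GroupSpec",
    "Schedule",
    "Agent",
    "TrialRecord",
    "GroupResult",
    "default_groups",
    "run_trial",
    "run_autoshaping",
    "run_systemic_flu",
    "run_local_flu_dose_response",
    "probe_conditioned_reinforcement",
    "fmf_contribution",
    "run_iti_manipulation",
    "BLOCK_TRIALS",
]

#: Engagement curves are reported in 50-trial (two-session) blocks.
BLOCK_TRIALS = 50


@dataclass(frozen=True)
class AgentConfig:
    """Parameter vector of one simulated rat.

    The defaults are the package's shared calibration: every phenotype uses
    them and only ``omega`` differs between groups (see the methods note for
    the regime analysis that fixed them).
    """

    omega: float = 0.35
    alpha: float = 0.1
    gamma: float = 0.98
    beta: float = 0.1
    u: float = 0.3
    v0_magazine: float = 0.1
    v0_food: float = 0.5
    r0: float = 0.0
    q0: float = 0.0
    r_food: float = 1.0
    variant: str = "model"

    def params(self) -> LearningParams:
        return LearningParams(self.alpha, self.gamma)


#: Canonical phenotype weights: only omega varies across groups.
OMEGA_ST, OMEGA_IG, OMEGA_GT = 0.8, 0.35, 0.05


def default_groups(n_agents: int = 14, variant: str = "model", **overrides) -> list["GroupSpec"]:
    """The three canonical groups (ST / IG / GT) sharing all non-omega parameters."""
    return [
        GroupSpec("ST", n_agents, AgentConfig(omega=OMEGA_ST, variant=variant, **overrides)),
        GroupSpec("IG", n_agents, AgentConfig(omega=OMEGA_IG, variant=variant, **overrides)),
        GroupSpec("GT", n_agents, AgentConfig(omega=OMEGA_GT, variant=variant, **overrides)),
    ]


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_agents: int = 14
    config: AgentConfig = field(default_factory=AgentConfig)

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")


@dataclass(frozen=True)
class Schedule:
    """Session structure; ``drug_by_session[i]`` applies to session ``i``."""

    n_sessions: int = 8
    trials_per_session: int = 25
    drug_by_session: tuple[DrugCondition, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("session and trial counts must be >= 1")
        if self.drug_by_session is not None and len(self.drug_by_session) != self.n_sessions:
            raise ValueError("drug_by_session must have one entry per session")

    def drug(self, session: int) -> DrugCondition:
        if self.drug_by_session is None:
            return NO_DRUG
        return self.drug_by_session[session]

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session


@dataclass
class TrialRecord:
    actions: list[tuple[State, Action]]
    rpes: list[RPEvent]
    lever_engaged: bool
    magazine_engaged: bool


class Agent:
    """One simulated rat: learners plus a private seeded random stream."""

    def __init__(self, config: AgentConfig, seed_key: Sequence[int],
                 mdp: AutoshapingMDP | None = None) -> None:
        self.config = config
        self.mdp = mdp if mdp is not None else build_default_mdp(config.r_food)
        self.rng = np.random.default_rng(list(seed_key))
        params = config.params()
        v0 = {Feature.MAGAZINE: config.v0_magazine, Feature.FOOD: config.v0_food}
        self.fmf = FMFValues(params, u=config.u, v0=v0) if config.variant in ("model", "v1") else None
        self.mb = MBModel(self.mdp, params, r0=config.r0, q0=config.q0) if config.variant in ("model", "v4") else None
        self.mf = QLearner(self.mdp, params, q0=config.q0) if config.variant != "model" else None
        # the ITI decay needs a magazine value even in feature-free variants
        self.trial_count = 0

    # ------------------------------------------------------------------
    def decision_values(self, s: State) -> IntegratedValues:
        return integrate(self.config.variant, self.config.omega, self.mdp, s,
                         fmf=self.fmf, mb=self.mb, mf=self.mf)

    def policy(self, s: State, drug: DrugCondition = NO_DRUG) -> dict[Action, float]:
        beta = elevate_temperature(self.config.beta, drug)
        p = self.decision_values(s)
        vals = np.array([p.P[a] for a in p.P]) / beta
        vals -= vals.max()
        w = np.exp(vals)
        w /= w.sum()
        return dict(zip(p.P, w))

    def snapshot(self) -> dict:
        out: dict = {"config": self.config.__dict__ | {}, "trials": self.trial_count}
        if self.fmf is not None:
            out["fmf"] = self.fmf.snapshot()
        if self.mb is not None:
            out["mb"] = self.mb.snapshot()
        if self.mf is not None:
            out["mf"] = self.mf.snapshot()
        return out


def run_trial(agent: Agent, drug: DrugCondition = NO_DRUG,
              session_index: int = 0, collect_rpes: bool = True) -> TrialRecord:
    """Run one episode: ITI decay, then act/learn until the terminal state.

    Within each transition the order is: softmax choice on integrated values
    (temperature possibly drug-elevated), environment step, feature-level RPE
    (drug-attenuated before it reaches any model-free learner), value
    updates, model-based update + replanning.  A trial counts as
    lever-engaged if the agent approached and then engaged the lever during
    the CS period, magazine-engaged likewise for the magazine; the task
    allows at most one engagement per trial, so the two flags are exclusive.
    """
    cfg = agent.config
    mdp = agent.mdp
    beta = elevate_temperature(cfg.beta, drug)
    systemic = drug.site is Site.SYSTEMIC
    local_or_sys = drug.site is not Site.NONE

    if agent.fmf is not None:
        agent.fmf.iti_decay(drug if local_or_sys else None)

    s = mdp.initial
    path: list[tuple[State, Action]] = []
    rpes: list[RPEvent] = []
    while s != mdp.terminal:
        p = agent.decision_values(s)
        a, _ = softmax_policy(p, beta, agent.rng)
        out = step(mdp, s, a)
        tag = event_tag(s, a)

        if agent.fmf is not None:
            e = agent.fmf.rpe(mdp, s, a, out.reward, out.next_state, tag,
                              agent.trial_count, session_index)
            if local_or_sys:
                e = replace(e, delta=attenuate_rpe(e.delta, drug))
            agent.fmf.update(e)
            if collect_rpes:
                rpes.append(e)
        if agent.mf is not None:
            delta = agent.mf.rpe(s, a, out.reward, out.next_state)
            if systemic:
                delta = attenuate_rpe(delta, drug)
            agent.mf.update(s, a, out.reward, out.next_state, delta=delta)
            if agent.fmf is None and collect_rpes:
                rpes.append(RPEvent(delta, out.feature, tag, agent.trial_count, session_index))
        if agent.mb is not None:
            agent.mb.update(s, a, out.next_state, out.reward)
            agent.mb.plan()

        path.append((s, a))
        s = out.next_state

    agent.trial_count += 1
    pairs = set(zip([sa[0] for sa in path], [sa[1] for sa in path]))
    lever = (State.S_CS, Action.goL) in pairs and (State.S_CS_L, Action.eng) in pairs
    magazine = (State.S_CS, Action.goM) in pairs and (State.S_CS_M, Action.eng) in pairs
    return TrialRecord(path, rpes, lever, magazine)


@dataclass
class GroupResult:
    """Aggregated engagement and RPE traces for one group of agents."""

    label: str
    lever: np.ndarray      # (n_agents, n_trials) engagement flags
    magazine: np.ndarray   # (n_agents, n_trials)
    cs_delta: np.ndarray   # (n_agents, n_sessions) per-session mean CS RPE
    us_delta: np.ndarray   # (n_agents, n_sessions)
    us_delta_gt: np.ndarray  # mean US RPE on magazine-CR trials (NaN if none)
    agents: list[Agent]

    @property
    def n_blocks(self) -> int:
        return self.lever.shape[1] // BLOCK_TRIALS

    def _blocked(self, flags: np.ndarray) -> np.ndarray:
        n = self.n_blocks
        return flags[:, : n * BLOCK_TRIALS].reshape(flags.shape[0], n, BLOCK_TRIALS).mean(axis=2)

    def engagement_curve(self, stimulus: str) -> tuple[np.ndarray, np.ndarray]:
        """Mean and s.e.m. (across agents) engagement probability per block."""
        flags = self.lever if stimulus == "lever" else self.magazine
        per_agent = self._blocked(flags)
        return per_agent.mean(axis=0), per_agent.std(axis=0, ddof=1) / np.sqrt(per_agent.shape[0])

    def rpe_curve(self, event: str) -> tuple[np.ndarray, np.ndarray]:
        per_agent = self.cs_delta if event == "CS" else self.us_delta
        return (np.nanmean(per_agent, axis=0),
                np.nanstd(per_agent, axis=0, ddof=1) / np.sqrt(per_agent.shape[0]))


def _run_group(spec: GroupSpec, schedule: Schedule, seed_key: Sequence[int],
               collect_rpes: bool = True,
               agents: list[Agent] | None = None) -> GroupResult:
    n_tr = schedule.n_trials
    lever = np.zeros((spec.n_agents, n_tr), dtype=bool)
    magazine = np.zeros((spec.n_agents, n_tr), dtype=bool)
    cs = np.zeros((spec.n_agents, schedule.n_sessions))
    us = np.zeros((spec.n_agents, schedule.n_sessions))
    us_gt = np.full((spec.n_agents, schedule.n_sessions), np.nan)
    continuing = agents
    agents = []
    for ai in range(spec.n_agents):
        agent = continuing[ai] if continuing is not None else Agent(spec.config, seed_key=[*seed_key, ai])
        t = 0
        for sess in range(schedule.n_sessions):
            drug = schedule.drug(sess)
            cs_v: list[float] = []
            us_v: list[float] = []
            us_gt_v: list[float] = []
            for _ in range(schedule.trials_per_session):
                rec = run_trial(agent, drug, session_index=sess, collect_rpes=collect_rpes)
                lever[ai, t] = rec.lever_engaged
                magazine[ai, t] = rec.magazine_engaged
                for e in rec.rpes:
                    if e.event is EventTag.CS_ONSET:
                        cs_v.append(e.delta)
                    elif e.event is EventTag.US_DELIVERY:
                        us_v.append(e.delta)
                        if rec.magazine_engaged:
                            us_gt_v.append(e.delta)
                t += 1
            cs[ai, sess] = np.mean(cs_v) if cs_v else np.nan
            us[ai, sess] = np.mean(us_v) if us_v else np.nan
            if us_gt_v:
                us_gt[ai, sess] = np.mean(us_gt_v)
        agents.append(agent)
    return GroupResult(spec.label, lever, magazine, cs, us, us_gt, agents)


def run_autoshaping(groups: Sequence[GroupSpec], schedule: Schedule | None = None,
                    seed: int = 0, collect_rpes: bool = True) -> dict[str, GroupResult]:
    """Simulate every group independently and aggregate figure-level curves.

    Each agent draws from its own random stream derived from
    ``(seed, group index, agent index)``, so results are reproducible and
    independent of execution order.
    """
    schedule = schedule or Schedule()
    return {
        spec.label: _run_group(spec, schedule, [seed, gi], collect_rpes)
        for gi, spec in enumerate(groups)
    }


# ----------------------------------------------------------------------
# pharmacological protocols
# ----------------------------------------------------------------------

@dataclass
class SystemicFluResult:
    """Per-arm results plus learner snapshots taken before the drug-free test."""

    arms: dict[str, GroupResult]
    snapshots_after_drug: dict[str, list[dict]]


def _concat_results(a: GroupResult, b: GroupResult) -> GroupResult:
    return GroupResult(
        a.label,
        np.hstack([a.lever, b.lever]),
        np.hstack([a.magazine, b.magazine]),
        np.hstack([a.cs_delta, b.cs_delta]),
        np.hstack([a.us_delta, b.us_delta]),
        np.hstack([a.us_delta_gt, b.us_delta_gt]),
        b.agents,
    )


def run_systemic_flu(
    groups: Sequence[GroupSpec] | None = None,
    dose: float = 2.0,
    k_rpe: float = 1.0,
    k_temp: float = 10.0,
    n_sessions: int = 8,
    trials_per_session: int = 25,
    seed: int = 0,
) -> SystemicFluResult:
    """Systemic drug before sessions 1..7, drug-free test on the last session.

    Arms are keyed ``"<label>-flu"`` and ``"<label>-sal"``; the two arms of a
    group share agent seed keys.  The default dose fully blocks feature-level
    learning (eta_rpe exceeds the largest attainable RPE) and flattens choice
    toward uniform.  Learner snapshots are captured at the end of the drugged
    phase (end of session 7), before any drug-free relearning.
    """
    groups = groups if groups is not None else default_groups()
    drug = DrugCondition(dose=dose, site=Site.SYSTEMIC, k_rpe=k_rpe, k_temp=k_temp)
    arms: dict[str, GroupResult] = {}
    snaps: dict[str, list[dict]] = {}
    for gi, spec in enumerate(groups):
        for arm, sess_drug in (("flu", drug), ("sal", NO_DRUG)):
            phase1 = Schedule(n_sessions - 1, trials_per_session,
                              tuple([sess_drug] * (n_sessions - 1)))
            r1 = _run_group(spec, phase1, [seed, gi])
            snaps[f"{spec.label}-{arm}"] = [agent.snapshot() for agent in r1.agents]
            r2 = _run_group(spec, Schedule(1, trials_per_session), [seed, gi],
                            agents=r1.agents)
            arms[f"{spec.label}-{arm}"] = _concat_results(r1, r2)
    return SystemicFluResult(arms, snaps)


def run_local_flu_dose_response(
    groups: Sequence[GroupSpec] | None = None,
    doses: Sequence[float] = (0.0, 1.0, 2.0, 4.0),
    k_rpe: float = 0.05,
    pretrain: Schedule | None = None,
    test_sessions: int = 8,
    trials_per_session: int = 25,
    seed: int = 0,
) -> dict[float, dict[str, float]]:
    """Dose--response of intra-accumbens drug on the *expression* of tracking.

    The whole (mixed) population is first trained drug-free, then, from
    identical post-training snapshots, re-run for ``test_sessions`` under
    each dose with only the RPE effect active.  Expression effects emerge
    through relearning: attenuated RPEs block the inter-trial depression of
    the magazine value faster than they block its reloading, so the magazine
    value climbs dose-dependently and competes with the lever.  The default
    ``k_rpe`` keeps the top dose on the monotone branch of that equilibrium
    (eta below u times the equilibrium magazine value).

    All doses share one test random stream per agent (common random
    numbers), so dose differences reflect the drug, not sampling noise.
    Returns per-dose population probabilities of sign- and goal-tracking
    during the test sessions.
    """
    if sorted(doses) != list(doses) or doses[0] != 0:
        raise ValueError("doses must be sorted ascending and include 0")
    groups = groups if groups is not None else default_groups()
    pretrain = pretrain or Schedule()
    trained = run_autoshaping(groups, pretrain, seed=seed, collect_rpes=False)
    out: dict[float, dict[str, float]] = {}
    for dose in doses:
        drug = DrugCondition(dose=dose, site=Site.LOCAL_NACC, k_rpe=k_rpe)
        p_lever, p_mag = [], []
        for gi, res in enumerate(trained.values()):
            for ai, agent in enumerate(res.agents):
                test_agent = copy.deepcopy(agent)
                test_agent.rng = np.random.default_rng([seed, 77, gi, ai])
                for _ in range(test_sessions * trials_per_session):
                    run_trial(test_agent, drug, collect_rpes=False)
                # value-based probe: softmax probabilities at lever appearance,
                # free of trial-sampling noise
                pol = test_agent.policy(State.S_CS, drug)
                p_lever.append(pol[Action.goL])
                p_mag.append(pol[Action.goM])
        out[dose] = {
            "sign_tracking": float(np.mean(p_lever)),
            "goal_tracking": float(np.mean(p_mag)),
        }
    return out


# ----------------------------------------------------------------------
# value-based probes on trained agents
# ----------------------------------------------------------------------

def probe_conditioned_reinforcement(results: dict[str, GroupResult]) -> dict[str, float]:
    """P(engage lever) with the magazine removed: softmax over {goL, exp} only.

    Emulates the conditioned-reinforcement test, where the lever is presented
    in a context with no food magazine; the probability is computed from the
    trained integrated values, restricted to the lever-approach and explore
    actions at lever appearance.  A random-policy comparator ("UN") is 0.5.
    """
    out = {"UN": 0.5}
    for label, res in results.items():
        probs = []
        for agent in res.agents:
            p = agent.decision_values(State.S_CS)
            restricted = {a: p.P[a] for a in (Action.goL, Action.exp)}
            beta = agent.config.beta
            vals = np.array(list(restricted.values())) / beta
            vals -= vals.max()
            w = np.exp(vals)
            probs.append(float(w[0] / w.sum()))
        out[label] = float(np.mean(probs))
    return out


def _cs_choice_prob(agent: Agent, action: Action, ablate_fmf: bool) -> float:
    p = agent.decision_values(State.S_CS)
    values = dict(p.P)
    if ablate_fmf and agent.fmf is not None:
        omega = agent.config.omega
        values[action] -= omega * agent.fmf.V[agent.mdp.feature_of[(State.S_CS, action)]]
    vals = np.array(list(values.values())) / agent.config.beta
    vals -= vals.max()
    w = np.exp(vals)
    w /= w.sum()
    return float(w[list(values).index(action)])


def fmf_contribution(results: dict[str, GroupResult]) -> dict[str, float]:
    """Percentage of the favoured-stimulus engagement probability owed to
    the feature value of that stimulus: 100 * (P_full - P_ablated) / P_full,
    where the ablation zeroes the omega-weighted feature-value bonus of the
    favoured action (the motivational bonus attached to the stimulus being
    engaged; feature values are non-negative, so the contribution is too).

    The favoured CS-period action is the one the group engaged more over the
    final block (lever approach for sign-trackers, magazine approach for
    goal-trackers).
    """
    out: dict[str, float] = {}
    for label, res in results.items():
        lev, _ = res.engagement_curve("lever")
        mag, _ = res.engagement_curve("magazine")
        favoured = Action.goL if lev[-1] >= mag[-1] else Action.goM
        contribs = []
        for agent in res.agents:
            p_full = _cs_choice_prob(agent, favoured, ablate_fmf=False)
            if p_full == 0.0:
                continue
            p_abl = _cs_choice_prob(agent, favoured, ablate_fmf=True)
            contribs.append(100.0 * (p_full - p_abl) / p_full)
        out[label] = float(np.mean(contribs)) if contribs else float("nan")
    return out


# ----------------------------------------------------------------------
# ITI-manipulation predictions
# ----------------------------------------------------------------------

def run_iti_manipulation(
    u_values: Sequence[float] = (0.0, 0.1, 0.3, 0.5),
    base_config: AgentConfig | None = None,
    n_agents: int = 14,
    n_sessions: int = 12,
    trials_per_session: int = 25,
    seed: int = 0,
) -> dict[float, dict[str, float]]:
    """Sweep the ITI-interaction parameter ``u`` in a goal-tracking group.

    For each ``u`` the group is trained to convergence and two quantities are
    reported: the mean food-delivery RPE on magazine-CR trials over the final
    two sessions (the model's US dopamine burst in goal-trackers — computed
    on the trials expressing the goal-tracking CR, which is what the burst
    prediction is about), and the population goal-tracking probability over
    the final block.
    """
    if 0.0 not in u_values:
        raise ValueError("u_values must include 0")
    base = base_config or AgentConfig(omega=OMEGA_GT)
    schedule = Schedule(n_sessions, trials_per_session)
    out: dict[float, dict[str, float]] = {}
    for ui, u in enumerate(u_values):
        spec = GroupSpec("GT", n_agents, replace(base, u=u))
        res = _run_group(spec, schedule, [seed, ui])
        tail = res.us_delta_gt[:, -2:]
        mag, _ = res.engagement_curve("magazine")
        out[u] = {
            "us_delta": float(np.nanmean(tail)),
            "goal_tracking": float(mag[-1]),
        }
    return out
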